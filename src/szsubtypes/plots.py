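"""Basic figure exports: PCA scatter of samples and per-dataset PPV bars."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

_GROUP_COLORS = {"Cluster I": "#c0392b", "Cluster II": "#2980b9", "control": "#7f8c8d"}


def pca_scatter(coords: pd.DataFrame, samples: pd.DataFrame, path: str | Path) -> None:
    """PC1/PC2 scatter colored by Cluster I / Cluster II / control."""
    group = pd.Series("control", index=coords.index)
    cl = samples.reindex(coords.index)["cluster"]
    group[cl == 0] = "Cluster I"
    group[cl == 1] = "Cluster II"
    fig, ax = plt.subplots(figsize=(5, 4))
    for name, color in _GROUP_COLORS.items():
        sub = coords[group == name]
        ax.scatter(sub["PC1"], sub["PC2"], s=12, label=name, color=color, alpha=0.8)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def ppv_bars(report: dict, path: str | Path) -> None:
    """Bar chart of per-dataset PPV with the pooled prevalence as a baseline."""
    entries = [e for e in report["per_dataset"] if e["ppv_defined"]]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    names = [e["dataset_id"] for e in entries]
    ppvs = [e["PPV"] for e in entries]
    ax.bar(names, ppvs, color="#2980b9")
    ax.axhline(report["pooled_prevalence"], ls="--", color="#7f8c8d", label="pooled prevalence")
    for i, v in enumerate(ppvs):
        ax.text(i, v + 0.01, f"{100 * v:.0f}%", ha="center", fontsize=8)
    ax.set_ylabel("PPV")
    ax.set_ylim(0, 1.05)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
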