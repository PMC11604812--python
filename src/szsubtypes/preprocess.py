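"""Probe-to-gene collapsing and low-variance gene filtering.

Input matrices are assumed already normalized upstream (background
correction, variance-stabilizing transform, between-array normalization);
this module only unites duplicate probes for the same gene and removes
genes with low across-sample variability, which are expected to be
expressed similarly in all samples and are uninformative for subtyping.
"""

from __future__ import annotations

import math
from typing import Literal

import numpy as np
import pandas as pd

CollapseMethod = Literal["mean", "median", "max_variance"]


def collapse_probes(
    m: pd.DataFrame, probe_map: pd.Series, method: CollapseMethod = "mean"
) -> pd.DataFrame:
    """Collapse probe rows to one row per gene symbol.

    ``method`` is the per-gene summary across its probes: ``mean`` (default),
    ``median``, or ``max_variance`` (keep the probe with the highest
    across-sample variance). Sample order is preserved; output rows are
    sorted by gene symbol. Every probe of ``m`` must appear in ``probe_map``.
    """
    missing = m.index.difference(probe_map.index)
    if len(missing):
        raise KeyError(
            f"{len(missing)} probes missing from probe map: {sorted(missing)[:10]}"
        )
    genes = probe_map.reindex(m.index)
    if method in ("mean", "median"):
        out = m.groupby(genes, sort=True).agg(method)
    elif method == "max_variance":
        var = m.var(axis=1, ddof=1)
        # highest-variance probe per gene; probe-id tie-break for determinism
        order = pd.DataFrame({"gene": genes, "var": var}).sort_values(
            ["gene", "var"], ascending=[True, False], kind="mergesort"
        )
        best = order.groupby("gene", sort=True).head(1).index
        out = m.loc[best].copy()
        out.index = genes.loc[best]
        out = out.sort_index()
    else:
        raise ValueError(f"unknown collapse method: {method!r}")
    out.index.name = "gene_symbol"
    return out


def filter_low_variance(
    m: pd.DataFrame, keep_fraction: float = 0.5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep the ``ceil(keep_fraction * n_genes)`` highest-variance genes.

    Returns ``(filtered_matrix, report)`` where the report lists every input
    gene with its variance and kept flag. Variance ties are broken by gene id
    (lexicographic), making the result invariant to input row order.
    """
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError("keep_fraction must lie in (0, 1]")
    if m.shape[1] < 2:
        raise ValueError("variance undefined: matrix has fewer than 2 samples")
    var = m.var(axis=1, ddof=1)
    n_keep = math.ceil(keep_fraction * len(m))
    # two-key sort: variance descending, gene id ascending (deterministic ties)
    order = (
        var.rename("variance")
        .rename_axis("gene")
        .reset_index()
        .sort_values(["variance", "gene"], ascending=[False, True], kind="mergesort")
    )
    kept = set(order["gene"].head(n_keep))
    report = order.assign(kept=order["gene"].isin(kept)).reset_index(drop=True)
    filtered = m.loc[[g for g in m.index if g in kept]].sort_index()
    filtered.index.name = m.index.name
    return filtered, report


def preprocess(
    m: pd.DataFrame,
    probe_map: pd.Series,
    method: CollapseMethod = "mean",
    keep_fraction: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse probes then filter low-variance genes; returns (matrix, report)."""
    collapsed = collapse_probes(m, probe_map, method=method)
    if not np.isfinite(collapsed.to_numpy()).all():
        raise ValueError("expression matrix contains non-finite values")
    return filter_low_variance(collapsed, keep_fraction=keep_fraction)
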