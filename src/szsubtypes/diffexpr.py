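"""Per-gene two-group differential expression and DE-gene selection.

The test statistic is the Welch (unequal-variance) two-sample t-test; logFC
is the difference of group means on the log scale (data arrive
log-transformed, so a mean difference is a log fold change); multiple
testing is adjusted by Benjamini-Hochberg. Genes enter the subtype
clustering when |logFC| > 0.1 and q < 0.05 (strict inequalities).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class ContrastSpec:
    """Two disjoint sample groups and a label, e.g. "SZ vs control"."""

    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.group_a) < 2 or len(self.group_b) < 2:
            raise ValueError(f"contrast {self.label!r}: each group needs >= 2 samples")
        if set(self.group_a) & set(self.group_b):
            raise ValueError(f"contrast {self.label!r}: groups overlap")


def differential_expression(m: pd.DataFrame, contrast: ContrastSpec) -> pd.DataFrame:
    """Welch t-test per gene for group A vs group B.

    Returns a DETable: one row per gene with columns ``logFC`` (mean A -
    mean B), ``p`` (Welch two-sided), ``q`` (Benjamini-Hochberg over all
    genes of ``m``) and ``direction`` (up iff logFC > 0). A gene identical
    in both groups (zero variance, zero difference) gets p = 1 by the t = 0
    convention; zero variance with differing means gets p = 0.
    """
    missing = (set(contrast.group_a) | set(contrast.group_b)) - set(m.columns)
    if missing:
        raise KeyError(f"contrast samples absent from matrix: {sorted(missing)[:10]}")
    a = m.loc[:, list(contrast.group_a)].to_numpy(float)
    b = m.loc[:, list(contrast.group_b)].to_numpy(float)
    logfc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    # degenerate genes: both groups constant -> scipy yields nan
    degenerate = ~np.isfinite(p)
    p[degenerate & (logfc == 0.0)] = 1.0
    p[degenerate & (logfc != 0.0)] = 0.0
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "logFC": logfc,
            "p": p,
            "q": q,
            "direction": np.where(logfc > 0, "up", "down"),
        },
        index=m.index.rename("gene"),
    )


def select_de_genes(
    de: pd.DataFrame, min_abs_logfc: float = 0.1, max_q: float = 0.05
) -> pd.DataFrame:
    """Genes with |logFC| strictly above ``min_abs_logfc`` and q strictly below ``max_q``.

    Returns the selected DETable rows (with direction); an empty selection
    is valid. A gene at |logFC| == min_abs_logfc exactly is excluded.
    """
    mask = (de["logFC"].abs() > min_abs_logfc) & (de["q"] < max_q)
    return de.loc[mask]


def geneset_direction_summary(
    de: pd.DataFrame, sets: dict[str, dict], max_q: float = 0.05,
    min_abs_logfc: float = 0.0,
) -> pd.DataFrame:
    """Per-set counts of significant DE genes split by direction.

    For each gene set, counts members present in ``de`` (``n_genes``), those
    significant at ``q < max_q`` (and ``|logFC| > min_abs_logfc`` if given),
    and the up/down split; ``n_up + n_down == n_significant``. A set with no
    members present yields zero counts and ``warning=True``.
    """
    if len(de) == 0:
        raise ValueError("empty DE table")
    if not sets:
        raise ValueError("empty gene-set collection")
    rows = []
    for name, body in sets.items():
        genes = body["genes"] if isinstance(body, dict) else list(body)
        present = de.index.intersection(genes)
        sub = de.loc[present]
        sig = sub[(sub["q"] < max_q) & (sub["logFC"].abs() > min_abs_logfc)]
        rows.append(
            {
                "set_name": name,
                "n_genes": len(present),
                "n_significant": len(sig),
                "n_up": int((sig["direction"] == "up").sum()),
                "n_down": int((sig["direction"] == "down").sum()),
                "warning": len(present) == 0,
            }
        )
    return pd.DataFrame(rows).set_index("set_name")


def relative_expression(m: pd.DataFrame, control_ids: Sequence[str]) -> pd.DataFrame:
    """Expression of each cell divided by the gene's mean over controls.

    C[gene, sample] = expression[gene, sample] / mean(expression[gene, controls]);
    by construction the row-mean of C over controls is 1 for every gene.
    """
    control_ids = list(control_ids)
    if not control_ids:
        raise ValueError("control_ids is empty")
    missing = set(control_ids) - set(m.columns)
    if missing:
        raise KeyError(f"control samples absent from matrix: {sorted(missing)[:10]}")
    ref = m.loc[:, control_ids].mean(axis=1)
    zero = ref.index[ref == 0.0]
    if len(zero):
        raise ZeroDivisionError(
            f"control mean is 0 for genes {list(zero[:10])}; relative expression undefined"
        )
    return m.div(ref, axis=0)
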