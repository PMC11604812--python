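"""Confounder checks for the discovered subtypes: age, sex, and regression.

Cluster differences in age are tested with the Welch (unequal-variance)
t-test from per-cluster summary statistics; sex with the two-sided Fisher
exact test; and the contribution of age versus cluster membership to
panel-gene expression with per-gene ordinary least squares of expression
on (age, cluster indicator). If the subtype signal is real rather than an
age artifact, the age coefficients sit near zero while the cluster
coefficients carry the shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class GroupSummary:
    """Per-cluster demographic summary: size, age mean/SD (years), male count."""

    n: int
    age_mean: float
    age_sd: float
    n_male: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_male <= self.n:
            raise ValueError("n_male must lie in [0, n]")
        if self.age_sd < 0:
            raise ValueError("age_sd must be >= 0")


def summarize_group(samples: pd.DataFrame, ids: list[str]) -> GroupSummary:
    """GroupSummary from a sample table subset (columns age, sex)."""
    sub = samples.loc[ids]
    return GroupSummary(
        n=len(sub),
        age_mean=float(sub["age"].mean()),
        age_sd=float(sub["age"].std(ddof=1)),
        n_male=int((sub["sex"] == "M").sum()),
    )


def welch_t_from_summary(a: GroupSummary, b: GroupSummary) -> tuple[float, float, float]:
    """Welch t statistic, Satterthwaite df, and two-sided p from summaries."""
    if a.n < 2 or b.n < 2:
        raise ValueError("each group needs n >= 2")
    if a.age_sd == 0 and b.age_sd == 0:
        if a.age_mean == b.age_mean:
            return 0.0, float(a.n + b.n - 2), 1.0
        return float(np.inf), float(a.n + b.n - 2), 0.0
    res = stats.ttest_ind_from_stats(
        a.age_mean, a.age_sd, a.n, b.age_mean, b.age_sd, b.n, equal_var=False
    )
    va, vb = a.age_sd**2 / a.n, b.age_sd**2 / b.n
    df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def fisher_exact_sex(a: GroupSummary, b: GroupSummary) -> tuple[float, float]:
    """Sample odds ratio and two-sided Fisher exact p for the male/female 2x2.

    Two-sided by the probability-mass rule: the p-value sums the
    probabilities of all tables (at fixed margins) no more probable than the
    observed one. An empty margin yields p = 1 by convention.
    """
    table = np.array([[a.n_male, a.n - a.n_male], [b.n_male, b.n - b.n_male]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return float("nan"), 1.0
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def age_cluster_regression(
    m: pd.DataFrame,
    samples: pd.DataFrame,
    panel: list[str],
    cluster_col: str = "cluster",
) -> pd.DataFrame:
    """Per-gene OLS of expression on (age, cluster indicator) over patients.

    The cluster indicator is 1 for Cluster I (cluster index 0) and 0 for
    Cluster II, so ``cluster_coef`` is the Cluster-I expression shift at
    fixed age (expression units), and ``age_coef`` is in expression units
    per year. All coefficients for all panel genes are solved in one
    least-squares call; statsmodels reproduces them gene-by-gene (tested).
    """
    missing = set(panel) - set(m.index)
    if missing:
        raise KeyError(f"panel genes absent from matrix: {sorted(missing)[:10]}")
    patients = samples.index[samples[cluster_col].notna()]
    patients = [s for s in patients if s in set(m.columns)]
    if len(patients) < 3:
        raise ValueError("need at least 3 clustered patients")
    age = samples.loc[patients, "age"].to_numpy(float)
    cluster = (samples.loc[patients, cluster_col].to_numpy(float) == 0).astype(float)
    if np.ptp(age) == 0:
        raise ValueError("age is constant; regression degenerate")
    if cluster.min() == cluster.max():
        raise ValueError("single cluster present; regression degenerate")
    design = np.column_stack([np.ones(len(patients)), age, cluster])
    y = m.loc[panel, patients].to_numpy(float).T  # samples x genes
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return pd.DataFrame(
        {"intercept": coef[0], "age_coef": coef[1], "cluster_coef": coef[2]},
        index=pd.Index(panel, name="gene"),
    )


def cluster_characteristics(
    samples: pd.DataFrame, cluster_col: str = "cluster"
) -> pd.DataFrame:
    """Per-cluster demographic table with the age and sex comparison p-values.

    Mirrors the usual per-cluster characteristics table: N, age mean +- SD,
    male count/fraction per cluster, Welch-t p for age and Fisher p for sex
    (two clusters required for the p-values).
    """
    clustered = samples[samples[cluster_col].notna()]
    groups = {}
    for c, sub in clustered.groupby(cluster_col):
        groups[int(c)] = summarize_group(samples, list(sub.index))
    rows = [
        {
            "cluster": "I" if c == 0 else "II" if c == 1 else str(c + 1),
            "n": g.n,
            "age_mean": g.age_mean,
            "age_sd": g.age_sd,
            "n_male": g.n_male,
            "male_fraction": g.n_male / g.n,
        }
        for c, g in sorted(groups.items())
    ]
    out = pd.DataFrame(rows).set_index("cluster")
    if len(groups) == 2:
        a, b = (groups[c] for c in sorted(groups))
        out["age_p"] = welch_t_from_summary(a, b)[2]
        out["sex_p"] = fisher_exact_sex(a, b)[1]
    return out
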