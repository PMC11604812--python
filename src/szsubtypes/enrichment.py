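"""Hypergeometric gene-set overrepresentation with Bonferroni adjustment.

A local stand-in for web-based annotation tools: for a query gene list
(here, the top-third most clustering-important genes) and a collection of
gene sets, the upper-tail hypergeometric probability of the observed
overlap is computed against a stated gene universe (by default, all genes
surviving preprocessing), and adjusted by Bonferroni over the number of
sets tested. Equivalent to a one-sided Fisher exact test on the 2x2
overlap table.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd
from scipy import stats


def hypergeometric_enrichment(
    gene_list: Sequence[str],
    sets: dict[str, dict],
    universe: Sequence[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Overrepresentation of each set in ``gene_list`` against ``universe``.

    ``p = P[X >= n_overlap]`` for X ~ Hypergeometric(N=n_universe,
    K=n_set_in_universe, n=n_list); sets are intersected with the universe
    before testing; ``p_bonferroni = min(1, p * n_sets_tested)``;
    ``significant`` flags ``p_bonferroni < alpha``. The query list must be a
    subset of the universe.
    """
    universe_set = set(universe)
    genes = set(gene_list)
    foreign = genes - universe_set
    if foreign:
        raise ValueError(
            f"{len(foreign)} query genes not in universe: {sorted(foreign)[:10]}"
        )
    if not sets:
        raise ValueError("empty gene-set collection")
    n_universe, n_list = len(universe_set), len(genes)
    rows = []
    for name, body in sets.items():
        members = body["genes"] if isinstance(body, dict) else list(body)
        in_universe = set(members) & universe_set
        k_set = len(in_universe)
        overlap = len(in_universe & genes)
        if k_set == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(overlap - 1, n_universe, k_set, n_list))
        rows.append(
            {
                "set_name": name,
                "n_universe": n_universe,
                "n_set_in_universe": k_set,
                "n_list": n_list,
                "n_overlap": overlap,
                "p": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows).set_index("set_name")
    out["p_bonferroni"] = (out["p"] * len(sets)).clip(upper=1.0)
    out["significant"] = out["p_bonferroni"] < alpha
    return out.sort_values(["p", "set_name"], kind="mergesort")


def significant_sets(result: pd.DataFrame) -> list[str]:
    """Names of Bonferroni-significant sets, most significant first."""
    return list(result.index[result["significant"]])
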