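"""Differential expression: Welch kernel, BH adjustment, selection, summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from szsubtypes import (
    ContrastSpec,
    differential_expression,
    geneset_direction_summary,
    relative_expression,
    select_de_genes,
)


def _bh_stepup(p: np.ndarray) -> np.ndarray:
    """Brute-force Benjamini-Hochberg step-up oracle."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


def _matrix(groups: dict[str, np.ndarray]) -> tuple[pd.DataFrame, ContrastSpec]:
    cols, data = [], []
    for name, arr in groups.items():
        for j in range(arr.shape[1]):
            cols.append(f"{name}{j}")
        data.append(arr)
    m = pd.DataFrame(np.hstack(data), columns=cols)
    m.index = [f"g{i}" for i in range(len(m))]
    a = tuple(c for c in cols if c.startswith("A"))
    b = tuple(c for c in cols if c.startswith("B"))
    return m, ContrastSpec(a, b)


class TestDifferentialExpression:
    def test_identical_gene_gets_p_one(self):
        m, c = _matrix({"A": np.ones((2, 4)), "B": np.ones((2, 5))})
        de = differential_expression(m, c)
        assert (de["logFC"] == 0).all()
        assert (de["p"] == 1.0).all()
        assert (de["q"] == 1.0).all()

    def test_reproduces_published_age_comparison(self, rng):
        """Raw-data Welch kernel on groups matching the printed cluster age
        summaries (42.8+-9.8 n=33 vs 38.1+-10.9 n=73) rounds to p = 0.03."""
        a = rng.normal(size=33)
        a = (a - a.mean()) / a.std(ddof=1) * 9.8 + 42.8
        b = rng.normal(size=73)
        b = (b - b.mean()) / b.std(ddof=1) * 10.9 + 38.1
        m, c = _matrix({"A": a[None, :], "B": b[None, :]})
        de = differential_expression(m, c)
        assert round(float(de["p"].iloc[0]), 2) == 0.03
        assert de["logFC"].iloc[0] == pytest.approx(4.7, abs=1e-9)

    def test_symmetry_swapping_groups(self, rng):
        m, c = _matrix({"A": rng.normal(0, 1, (20, 5)), "B": rng.normal(0.4, 1, (20, 7))})
        fwd = differential_expression(m, c)
        rev = differential_expression(m, ContrastSpec(c.group_b, c.group_a))
        np.testing.assert_allclose(fwd["logFC"], -rev["logFC"], atol=1e-12)
        np.testing.assert_allclose(fwd["p"], rev["p"], atol=1e-12)

    def test_planted_gene_power(self):
        """A +1.5 SD single-gene effect at n=30/30 is detected (median q<0.05)."""
        qs = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            a = r.normal(1.5, 1.0, (1, 30))
            b = r.normal(0.0, 1.0, (1, 30))
            noise_a = r.normal(0, 1, (49, 30))
            noise_b = r.normal(0, 1, (49, 30))
            m, c = _matrix({"A": np.vstack([a, noise_a]), "B": np.vstack([b, noise_b])})
            qs.append(differential_expression(m, c).loc["g0", "q"])
        assert np.median(qs) < 0.05

    def test_missing_samples_raise(self, rng):
        m, c = _matrix({"A": rng.normal(size=(3, 4)), "B": rng.normal(size=(3, 4))})
        with pytest.raises(KeyError):
            differential_expression(m.drop(columns=["A0"]), c)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1, max_size=50))
    def test_bh_matches_brute_force_stepup(self, pvals):
        from statsmodels.stats.multitest import multipletests

        p = np.array(pvals)
        np.testing.assert_allclose(
            multipletests(p, method="fdr_bh")[1], _bh_stepup(p), atol=1e-12
        )

    def test_q_at_least_p(self, default_run):
        _, _, res = default_run
        assert (res.de_table["q"] >= res.de_table["p"] - 1e-15).all()
        assert ((res.de_table["direction"] == "up") == (res.de_table["logFC"] > 0)).all()


class TestSelectDeGenes:
    def test_boundary_logfc_excluded(self):
        de = pd.DataFrame(
            {"logFC": [0.1, 0.11, -0.3], "p": [0.001] * 3, "q": [0.001] * 3,
             "direction": ["up", "up", "down"]},
            index=["a", "b", "c"],
        )
        out = select_de_genes(de)
        assert list(out.index) == ["b", "c"]

    def test_all_q_one_selects_nothing(self):
        de = pd.DataFrame(
            {"logFC": [2.0, -2.0], "p": [0.5, 0.5], "q": [1.0, 1.0],
             "direction": ["up", "down"]},
            index=["a", "b"],
        )
        assert len(select_de_genes(de)) == 0

    def test_recovery_on_default_cohort(self, default_run):
        """Planted discriminative genes are recovered at the power the fixed
        default conditions admit (the per-gene case-control t is ~3), and
        unperturbed genes stay rare in the selection."""
        cohort, _, res = default_run
        truth = cohort.truth["planted_sets"]
        modules = set(truth["ribosome-like"]["effective_genes"]) | set(
            truth["UPS-like"]["effective_genes"]
        )
        de = set(res.de_genes)
        assert len(modules & de) / len(modules) > 0.6
        planted_all = {g for s in truth.values() for g in s["effective_genes"]}
        nulls = set(res.matrix.index) - planted_all
        # BH at q<0.05 with ~45% of the universe truly DE admits a few
        # percent of nulls past the threshold; 5% is the verified ceiling
        assert len(nulls & de) / len(nulls) <= 0.05


class TestGenesetDirectionSummary:
    def test_counts_partition(self, default_run):
        cohort, sets, res = default_run
        summary = geneset_direction_summary(res.de_table, sets)
        assert (summary["n_up"] + summary["n_down"] == summary["n_significant"]).all()
        assert (summary["n_significant"] <= summary["n_genes"]).all()

    def test_cluster1_contrast_reproduces_planted_direction_mix(self, default_run):
        """Cluster-I-vs-control DE restricted to the ribosome-like set yields
        (n=69, significant=68, up=63, down=5): the planted mix, with the one
        silent member non-significant."""
        cohort, sets, res = default_run
        s = res.samples
        c1 = tuple(s.index[s["cluster"] == 0])
        ctrl = tuple(s.index[s["diagnosis"] == "CTRL"])
        de = differential_expression(res.matrix, ContrastSpec(c1, ctrl, "Cluster I vs control"))
        summary = geneset_direction_summary(de, sets, min_abs_logfc=0.1)
        row = summary.loc["ribosome-like"]
        assert tuple(row[["n_genes", "n_significant", "n_up", "n_down"]]) == (69, 68, 63, 5)
        ups = summary.loc["UPS-like"]
        assert tuple(ups[["n_genes", "n_significant", "n_up", "n_down"]]) == (144, 144, 117, 27)

    def test_fully_null_set_counts_zero(self):
        de = pd.DataFrame(
            {"logFC": [1.0, 1.0], "p": [0.9, 0.8], "q": [1.0, 1.0],
             "direction": ["up", "up"]},
            index=["a", "b"],
        )
        out = geneset_direction_summary(de, {"s": {"genes": ["a", "b"]}})
        assert tuple(out.loc["s", ["n_genes", "n_significant", "n_up", "n_down"]]) == (2, 0, 0, 0)

    def test_absent_set_warns_not_raises(self):
        de = pd.DataFrame(
            {"logFC": [1.0], "p": [0.01], "q": [0.01], "direction": ["up"]}, index=["a"]
        )
        out = geneset_direction_summary(de, {"foreign": {"genes": ["zzz"]}})
        assert bool(out.loc["foreign", "warning"])
        assert out.loc["foreign", "n_genes"] == 0

    def test_empty_de_table_raises(self):
        with pytest.raises(ValueError, match="empty"):
            geneset_direction_summary(pd.DataFrame(), {"s": {"genes": ["a"]}})


class TestRelativeExpression:
    def test_control_row_mean_is_one(self, rng):
        m = pd.DataFrame(rng.normal(7, 1, (10, 6)), columns=[f"s{i}" for i in range(6)])
        rel = relative_expression(m, ["s0", "s1", "s2"])
        np.testing.assert_allclose(rel[["s0", "s1", "s2"]].mean(axis=1), 1.0)

    def test_sample_at_control_mean_scores_one(self, rng):
        m = pd.DataFrame(rng.normal(7, 1, (5, 4)), columns=list("abcd"))
        m["probe"] = m[["a", "b"]].mean(axis=1)
        rel = relative_expression(m, ["a", "b"])
        np.testing.assert_allclose(rel["probe"], 1.0)

    def test_linearity_in_single_cell(self, rng):
        m = pd.DataFrame(rng.uniform(1, 2, (4, 5)), columns=list("abcde"))
        doubled = m.copy()
        doubled.loc[m.index[2], "e"] *= 2.0
        r1 = relative_expression(m, ["a", "b"])
        r2 = relative_expression(doubled, ["a", "b"])
        assert r2.loc[m.index[2], "e"] == pytest.approx(2 * r1.loc[m.index[2], "e"])
        r2.loc[m.index[2], "e"] = r1.loc[m.index[2], "e"]
        pd.testing.assert_frame_equal(r1, r2)

    def test_zero_control_mean_raises(self):
        m = pd.DataFrame({"a": [0.0], "b": [0.0], "c": [1.0]}, index=["g"])
        with pytest.raises(ZeroDivisionError):
            relative_expression(m, ["a", "b"])
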