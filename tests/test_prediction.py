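"""Panel construction, LASSO fitting, harmonization, and PPV scoring."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from szsubtypes import (
    build_panel,
    fit_lasso_logistic,
    harmonize,
    pool_reports,
    pooled_ppv_significance,
    predict_and_score,
)
from szsubtypes.prediction import PanelModel


def _train_frame(rng, n=60, n_genes=8, signal_gene=0, effect=3.0):
    """Genes-by-samples frame where gene 0 separates cases from controls."""
    y = pd.Series([1] * (n // 2) + [0] * (n - n // 2),
                  index=[f"s{i}" for i in range(n)])
    x = rng.normal(size=(n_genes, n))
    x[signal_gene, : n // 2] += effect
    m = pd.DataFrame(x, index=[f"g{i}" for i in range(n_genes)], columns=y.index)
    return m, y


class TestBuildPanel:
    def _enrichment(self, sig):
        return pd.DataFrame(
            {"significant": [name in sig for name in ["A", "B", "C"]]},
            index=pd.Index(["A", "B", "C"], name="set_name"),
        )

    def test_union_of_significant_sets_intersected(self):
        sets = {"A": {"genes": ["g1", "g2"]}, "B": {"genes": ["g3"]}, "C": {"genes": ["g9"]}}
        panels = build_panel(
            self._enrichment({"A", "B"}),
            sets,
            train_genes=["g1", "g2", "g3", "g4"],
            test_genes_per_dataset={"d1": ["g1", "g2", "g3"], "d2": ["g2", "g5"]},
        )
        assert panels == {"d1": ["g1", "g2", "g3"], "d2": ["g2"]}

    def test_disjoint_sets_full_coverage_size(self):
        sets = {
            "A": {"genes": [f"a{i}" for i in range(69)]},
            "B": {"genes": [f"b{i}" for i in range(144)]},
            "C": {"genes": ["zzz"]},
        }
        genes = sets["A"]["genes"] + sets["B"]["genes"]
        panels = build_panel(
            self._enrichment({"A", "B"}), sets, genes, {"d": genes}
        )
        assert len(panels["d"]) == 213

    def test_no_significant_set_raises(self):
        with pytest.raises(ValueError, match="significant"):
            build_panel(self._enrichment(set()), {"A": {"genes": ["g"]}}, ["g"], {"d": ["g"]})

    def test_empty_intersection_names_dataset(self):
        sets = {"A": {"genes": ["g1"]}, "B": {"genes": []}, "C": {"genes": []}}
        sets["B"]["genes"] = ["g2"]
        sets["C"]["genes"] = ["g3"]
        with pytest.raises(ValueError, match="d2"):
            build_panel(
                self._enrichment({"A"}), sets, ["g1"], {"d1": ["g1"], "d2": ["g9"]}
            )


class TestHarmonize:
    def test_zscore_idempotent(self, rng):
        m = pd.DataFrame(rng.normal(5, 2, (6, 20)))
        once = harmonize(m)
        twice = harmonize(once)
        pd.testing.assert_frame_equal(once, twice, atol=1e-9, check_exact=False)

    def test_none_is_identity(self, rng):
        m = pd.DataFrame(rng.normal(size=(3, 5)))
        assert harmonize(m, "none") is m

    def test_zero_variance_gene_zeroed_with_warning(self):
        m = pd.DataFrame({"s1": [1.0, 2.0], "s2": [1.0, 3.0]}, index=["flat", "g"])
        with pytest.warns(UserWarning, match="zero-spread"):
            out = harmonize(m)
        assert (out.loc["flat"] == 0).all()

    def test_dataset_shift_invariance_of_predictions(self, rng):
        m, y = _train_frame(rng)
        model = fit_lasso_logistic(harmonize(m), y, list(m.index),
                                   lambda_grid=(1.0,), seed=0)
        test = pd.DataFrame(
            rng.normal(size=(8, 30)), index=m.index, columns=[f"t{i}" for i in range(30)]
        )
        p1 = model.predict_proba(harmonize(test))
        p2 = model.predict_proba(harmonize(test + 10.0))
        pd.testing.assert_series_equal(p1, p2, atol=1e-9, check_exact=False)


class TestFitLassoLogistic:
    def test_infinite_penalty_gives_prevalence_intercept(self, rng):
        m, y = _train_frame(rng, n=50)
        model = fit_lasso_logistic(m, y, list(m.index), lambda_grid=(1e6,), seed=0)
        assert np.all(model.coefficients == 0.0)
        prevalence = y.mean()
        assert model.intercept == pytest.approx(
            np.log(prevalence / (1 - prevalence)), abs=0.01
        )

    def test_separating_gene_gets_positive_sign(self, rng):
        m, y = _train_frame(rng, effect=5.0)
        model = fit_lasso_logistic(m, y, list(m.index), lambda_grid=(0.5,), seed=0)
        assert model.coefficients[model.panel.index("g0")] > 0

    def test_sparsity_monotone_in_lambda(self, rng):
        m, y = _train_frame(rng, n=80, n_genes=20, effect=2.0)
        nnz = []
        for lam in (0.1, 1.0, 10.0, 100.0):
            model = fit_lasso_logistic(m, y, list(m.index), lambda_grid=(lam,), seed=0)
            nnz.append(len(model.nonzero_genes))
        assert all(a >= b for a, b in zip(nnz, nnz[1:]))

    def test_single_class_raises(self, rng):
        m, y = _train_frame(rng)
        with pytest.raises(ValueError, match="single class"):
            fit_lasso_logistic(m, y * 0, list(m.index), lambda_grid=(1.0,))

    def test_deterministic_given_seed(self, rng):
        m, y = _train_frame(rng, n=40)
        a = fit_lasso_logistic(m, y, list(m.index), seed=5)
        b = fit_lasso_logistic(m, y, list(m.index), seed=5)
        assert a.lambda_ == b.lambda_
        np.testing.assert_array_equal(a.coefficients, b.coefficients)

    def test_support_recovery_on_module_panel(self, default_cohort):
        """On the pipeline's own panel (the planted module sets), the genes
        the LASSO keeps are overwhelmingly the truly perturbed ones."""
        from szsubtypes.preprocess import preprocess as pp

        cohort = default_cohort
        matrix, _ = pp(cohort.expression, cohort.probe_map, keep_fraction=0.5)
        truth = cohort.truth["planted_sets"]
        panel = sorted(
            (set(truth["ribosome-like"]["genes"]) | set(truth["UPS-like"]["genes"]))
            & set(matrix.index)
        )
        y = (cohort.samples["diagnosis"] == "SZ").astype(int)
        model = fit_lasso_logistic(harmonize(matrix), y, panel, seed=11)
        nz = set(model.nonzero_genes)
        effective = set(truth["ribosome-like"]["effective_genes"]) | set(
            truth["UPS-like"]["effective_genes"]
        )
        assert len(nz) >= 5
        assert len(nz & effective) / len(nz) >= 0.7


class TestScoring:
    def _model(self):
        return PanelModel(
            panel=["g0"], intercept=-10.0, coefficients=np.array([10.0]), lambda_=1.0
        )

    def test_ppv_arithmetic(self):
        m = pd.DataFrame([[2.0, 2.0, 2.0, 2.0, -2.0]], index=["g0"],
                         columns=list("abcde"))
        y = pd.Series([1, 1, 1, 0, 1], index=list("abcde"))
        entry = predict_and_score(self._model(), m, y, "d")
        assert (entry["TP"], entry["FP"]) == (3, 1)
        assert entry["PPV"] == pytest.approx(0.75)

    def test_all_negative_flags_undefined(self):
        m = pd.DataFrame([[-1.0, -1.0]], index=["g0"], columns=["a", "b"])
        y = pd.Series([1, 0], index=["a", "b"])
        entry = predict_and_score(self._model(), m, y, "d")
        assert not entry["ppv_defined"]
        assert np.isnan(entry["PPV"])

    def test_pooled_excludes_undefined_with_warning(self):
        good = {"dataset_id": "a", "n_samples": 10, "n_cases": 5,
                "n_predicted_positive": 4, "TP": 3, "FP": 1, "PPV": 0.75,
                "ppv_defined": True}
        bad = {"dataset_id": "b", "n_samples": 8, "n_cases": 4,
               "n_predicted_positive": 0, "TP": 0, "FP": 0, "PPV": float("nan"),
               "ppv_defined": False}
        with pytest.warns(UserWarning, match="excluded"):
            report = pool_reports([good, bad])
        assert report["pooled_TP"] == 3 and report["pooled_FP"] == 1
        assert report["pooled_prevalence"] == 0.5

    def test_pooled_ppv_between_min_and_max(self):
        entries = [
            {"dataset_id": d, "n_samples": 20, "n_cases": 10,
             "n_predicted_positive": tp + fp, "TP": tp, "FP": fp,
             "PPV": tp / (tp + fp), "ppv_defined": True}
            for d, tp, fp in [("a", 8, 2), ("b", 3, 3), ("c", 5, 1)]
        ]
        report = pool_reports(entries)
        ppvs = [e["PPV"] for e in entries]
        assert min(ppvs) <= report["pooled_PPV"] <= max(ppvs)

    def test_binomial_closed_form(self):
        """TP=10, FP=0 against prevalence 0.5 -> p = 0.5^10."""
        assert pooled_ppv_significance(10, 0, 0.5) == pytest.approx(0.5**10, rel=1e-12)

    def test_ppv_at_prevalence_not_significant(self):
        assert pooled_ppv_significance(50, 50, 0.5) >= 0.5

    def test_degenerate_prevalence_raises(self):
        with pytest.raises(ValueError, match="prevalence"):
            pooled_ppv_significance(5, 5, 1.0)
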