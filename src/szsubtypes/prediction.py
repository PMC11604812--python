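"""Cross-cohort case/control prediction from an enriched gene panel.

An L1-penalized (LASSO) logistic regression is trained on one dataset using
the genes of the enrichment-significant sets that are shared with the test
dataset, and evaluated on independent datasets by positive predictive value
PPV = TP / (TP + FP). PPV is the natural score here because only the
molecularly distinct patient subtype is expected to be recognizable: the
model cannot recall every case, but the cases it does call should be real.
Pooled PPV across test datasets is compared with the pooled case prevalence
by an exact one-sided binomial test.

Expression scales differ across platforms, so matrices are harmonized by
per-gene location/scale standardization within each dataset (robust
median/MAD scaling by default) before training or prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold

DEFAULT_LAMBDA_GRID: tuple[float, ...] = tuple(
    round(float(x), 5) for x in np.logspace(-2, 2, 12)
)


@dataclass
class PanelModel:
    """A fitted sparse logistic model over an ordered gene panel."""

    panel: list[str]
    intercept: float
    coefficients: np.ndarray  # aligned with panel; many exactly zero
    lambda_: float
    train_dataset_id: str = "train"
    harmonization: str = "robust_zscore"
    cv_log_loss: dict[float, float] = field(default_factory=dict)

    @property
    def nonzero_genes(self) -> list[str]:
        return [g for g, c in zip(self.panel, self.coefficients) if c != 0.0]

    def predict_proba(self, m: pd.DataFrame) -> pd.Series:
        """Case probability per sample of a harmonized genes-by-samples matrix."""
        missing = set(self.panel) - set(m.index)
        if missing:
            raise KeyError(f"panel genes absent from matrix: {sorted(missing)[:10]}")
        x = m.loc[self.panel].to_numpy(float).T
        z = self.intercept + x @ self.coefficients
        return pd.Series(1.0 / (1.0 + np.exp(-z)), index=m.columns, name="p_case")


def harmonize(m: pd.DataFrame, method: str = "robust_zscore") -> pd.DataFrame:
    """Per-gene location/scale standardization within a dataset.

    Methods: ``robust_zscore`` (default) centers each gene at its median and
    scales by 1.4826x the median absolute deviation; ``zscore_per_gene``
    uses mean/SD; ``none`` is the identity. The robust variant is preferred
    for cross-cohort transfer: when a shifted minority subgroup (the
    molecular subtype) makes up a different fraction of each cohort, means
    and SDs move with that fraction while medians and MADs do not, so the
    robust scaling keeps the majority of samples on a common scale across
    datasets. A zero-spread gene cannot be scaled and is set to 0 with a
    warning.
    """
    if method == "none":
        return m
    if method == "zscore_per_gene":
        mu = m.mean(axis=1)
        sd = m.std(axis=1, ddof=0)
    elif method == "robust_zscore":
        mu = m.median(axis=1)
        sd = m.sub(mu, axis=0).abs().median(axis=1) * 1.4826
    else:
        raise ValueError(f"unknown harmonization method: {method!r}")
    flat = sd.index[sd == 0.0]
    if len(flat):
        warnings.warn(f"{len(flat)} zero-spread genes set to 0 during harmonization",
                      stacklevel=2)
    sd = sd.mask(sd == 0.0, 1.0)
    return m.sub(mu, axis=0).div(sd, axis=0)


def build_panel(
    enrichment_result: pd.DataFrame,
    sets: dict[str, dict],
    train_genes: list[str],
    test_genes_per_dataset: dict[str, list[str]],
) -> dict[str, list[str]]:
    """Per-test-dataset panels: union of significant sets ∩ train ∩ test genes.

    The intersection is computed per train-test pair (the model is refit per
    pair), mirroring panels restricted to genes measured on both platforms.
    Raises if no set is significant or if a pair's intersection is empty.
    """
    sig = list(enrichment_result.index[enrichment_result["significant"]])
    if not sig:
        raise ValueError("no enrichment-significant gene set; panel undefined")
    union: set[str] = set()
    for name in sig:
        body = sets[name]
        union |= set(body["genes"] if isinstance(body, dict) else body)
    train_panel = union & set(train_genes)
    panels: dict[str, list[str]] = {}
    for ds, genes in test_genes_per_dataset.items():
        panel = sorted(train_panel & set(genes))
        if not panel:
            raise ValueError(f"empty panel for test dataset {ds!r}")
        panels[ds] = panel
    return panels


def fit_lasso_logistic(
    m_train: pd.DataFrame,
    labels: pd.Series,
    panel: list[str],
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID,
    cv_folds: int = 5,
    seed: int = 0,
    train_dataset_id: str = "train",
    harmonization: str = "robust_zscore",
    cv_rule: str = "1se",
) -> PanelModel:
    """L1-penalized logistic fit with lambda chosen by stratified CV log-loss.

    ``labels`` maps sample id to 1 (case) / 0 (control); both classes must
    be present. C = 1/lambda is passed to the saga solver (the intercept is
    not penalized, so lambda -> inf drives every gene coefficient to zero
    while the intercept tends to the training log-odds).

    ``cv_rule`` picks the penalty from the CV curve: ``"min"`` takes the
    loss-minimizing lambda (sparsest on exact ties); ``"1se"`` (default, the
    usual parsimony rule) takes the largest lambda whose mean CV loss is
    within one standard error of the minimum — with far more panel genes
    than informative samples the loss-minimizing fit memorizes noise in the
    non-subtype samples, and the sparser fit transfers better across
    cohorts. Deterministic given ``seed``.
    """
    y = labels.loc[list(m_train.columns)].to_numpy(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    missing = set(panel) - set(m_train.index)
    if missing:
        raise KeyError(f"panel genes absent from training matrix: {sorted(missing)[:10]}")
    x = m_train.loc[panel].to_numpy(float).T

    def _fit(xa: np.ndarray, ya: np.ndarray, lam: float) -> LogisticRegression:
        clf = LogisticRegression(
            penalty="l1", C=1.0 / lam, solver="saga", max_iter=3000, tol=1e-4,
            random_state=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(xa, ya)
        return clf

    if cv_rule not in ("min", "1se"):
        raise ValueError("cv_rule must be 'min' or '1se'")
    grid = sorted(set(float(l) for l in lambda_grid))
    cv_loss: dict[float, float] = {}
    if len(grid) > 1:
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        folds = list(skf.split(x, y))
        fold_losses: dict[float, list[float]] = {}
        for lam in grid:
            losses = []
            for tr, te in folds:
                clf = _fit(x[tr], y[tr], lam)
                p = clf.predict_proba(x[te])[:, 1]
                losses.append(log_loss(y[te], p, labels=[0, 1]))
            fold_losses[lam] = losses
            cv_loss[lam] = float(np.mean(losses))
        best_loss = min(cv_loss.values())
        lam_min = max(l for l in grid if cv_loss[l] <= best_loss + 1e-10)
        if cv_rule == "1se":
            se = float(np.std(fold_losses[lam_min], ddof=1) / np.sqrt(cv_folds))
            # largest lambda within one SE whose full-data fit is non-null:
            # an intercept-only model predicts the prevalence for everyone
            # and is never preferred over an in-band model with signal
            candidates = sorted(
                (l for l in grid if cv_loss[l] <= best_loss + se), reverse=True
            )
            lam_best = lam_min
            for lam in candidates:
                if lam <= lam_min:
                    break
                if np.any(_fit(x, y, lam).coef_ != 0.0):
                    lam_best = lam
                    break
        else:
            lam_best = lam_min
    else:
        lam_best = grid[0]
    clf = _fit(x, y, lam_best)
    coef = clf.coef_.ravel().copy()
    coef[np.abs(coef) < 1e-10] = 0.0
    return PanelModel(
        panel=list(panel),
        intercept=float(clf.intercept_[0]),
        coefficients=coef,
        lambda_=lam_best,
        train_dataset_id=train_dataset_id,
        harmonization=harmonization,
        cv_log_loss=cv_loss,
    )


def predict_and_score(
    model: PanelModel,
    m_test: pd.DataFrame,
    labels_test: pd.Series,
    dataset_id: str = "test",
    threshold: float = 0.5,
) -> dict:
    """Per-dataset prediction report entry.

    A sample is predicted positive iff its fitted case probability exceeds
    ``threshold``; TP/FP are tallied against ``labels_test`` (1 = case).
    With zero predicted positives PPV is undefined and the entry is flagged
    for exclusion from pooling.
    """
    proba = model.predict_proba(m_test)
    y = labels_test.loc[proba.index].to_numpy(int)
    pos = proba.to_numpy() > threshold
    tp = int((pos & (y == 1)).sum())
    fp = int((pos & (y == 0)).sum())
    return {
        "dataset_id": dataset_id,
        "n_samples": len(y),
        "n_cases": int(y.sum()),
        "n_predicted_positive": int(pos.sum()),
        "TP": tp,
        "FP": fp,
        "PPV": tp / (tp + fp) if tp + fp > 0 else float("nan"),
        "ppv_defined": tp + fp > 0,
    }


def pooled_ppv_significance(tp: int, fp: int, prevalence: float) -> float:
    """One-sided exact binomial p for pooled TP of (TP+FP) against prevalence."""
    if tp + fp <= 0:
        raise ValueError("no predicted positives; pooled PPV undefined")
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie strictly between 0 and 1")
    return float(stats.binomtest(tp, tp + fp, prevalence, alternative="greater").pvalue)


def pool_reports(entries: list[dict]) -> dict:
    """PredictionReport: per-dataset entries plus pooled PPV and significance.

    Pooled TP/FP are summed over datasets with defined PPV; the null
    prevalence is the pooled case fraction of those datasets. Undefined
    entries are excluded with a warning.
    """
    defined = [e for e in entries if e["ppv_defined"]]
    skipped = [e["dataset_id"] for e in entries if not e["ppv_defined"]]
    if skipped:
        warnings.warn(f"datasets with no predicted positives excluded: {skipped}",
                      stacklevel=2)
    if not defined:
        raise ValueError("no dataset produced predicted positives")
    tp = sum(e["TP"] for e in defined)
    fp = sum(e["FP"] for e in defined)
    n = sum(e["n_samples"] for e in defined)
    cases = sum(e["n_cases"] for e in defined)
    prevalence = cases / n
    return {
        "per_dataset": entries,
        "pooled_TP": tp,
        "pooled_FP": fp,
        "pooled_PPV": tp / (tp + fp),
        "pooled_prevalence": prevalence,
        "p_vs_prevalence": pooled_ppv_significance(tp, fp, prevalence),
    }
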