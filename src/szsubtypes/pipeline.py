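"""End-to-end orchestration of the subtype-discovery and validation analyses.

Stages mirror the published workflow: probe collapsing and variance
filtering; case-control differential expression; DE-gene-restricted k-means
subtyping of patients with elbow k-selection; leave-one-gene-out silhouette
importance; hypergeometric enrichment of the top-third important genes;
demographic confounder checks; and LASSO panel prediction on independent
datasets scored by PPV. Every stage is callable in memory; the ``run_*``
wrappers add file I/O and a reproducibility manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .clustering import ClusterResult, _patient_matrix, elbow_select_k, kmeans_cluster, pca_project
from .config import PipelineConfig
from .confounders import age_cluster_regression, cluster_characteristics
from .diffexpr import ContrastSpec, differential_expression, select_de_genes
from .enrichment import hypergeometric_enrichment, significant_sets
from .importance import loo_silhouette_importance, recluster_loo_silhouette_importance
from .prediction import (
    build_panel,
    fit_lasso_logistic,
    harmonize,
    pool_reports,
    predict_and_score,
)
from .preprocess import preprocess
from .synthetic import (
    FIVE_PLATFORM_SIZES,
    SyntheticCohort,
    default_cohort_spec,
    generate_cohort,
    split_platforms,
    validation_cohort_spec,
)

log = logging.getLogger("szsubtypes")


def _timed(stage: str):
    class _T:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", stage)
            return self

        def __exit__(self, *exc):
            log.info("stage %s: %.2fs", stage, time.perf_counter() - self.t0)

    return _T()


@dataclass
class SubtypeResult:
    """Everything the discovery pipeline produces on one dataset."""

    matrix: pd.DataFrame  # preprocessed genes x samples
    filter_report: pd.DataFrame
    de_table: pd.DataFrame
    de_genes: list[str]
    samples: pd.DataFrame  # with cluster column when clustering ran
    cluster: ClusterResult | None = None
    importance: pd.DataFrame | None = None
    top_genes: list[str] = field(default_factory=list)
    enrichment: pd.DataFrame | None = None
    characteristics: pd.DataFrame | None = None
    coefficient_pairs: pd.DataFrame | None = None
    pca_coords: pd.DataFrame | None = None

    @property
    def clustered(self) -> bool:
        return self.cluster is not None


def make_gene_sets(
    cohort: SyntheticCohort, n_decoys: int = 3, decoy_size: int = 50, seed: int = 0
) -> dict[str, dict]:
    """Gene-set collection from a synthetic cohort's truth: the planted
    subtype-discriminative modules plus random decoy sets of unperturbed
    genes. The anonymous disease-wide background set is deliberately not a
    curated set (it models DE genes that belong to no pathway of interest).
    """
    sets: dict[str, dict] = {}
    planted: set[str] = set()
    for name, body in cohort.truth["planted_sets"].items():
        planted |= set(body["genes"])
        if not body["shared"]:
            sets[name] = {"description": "planted discriminative module", "genes": body["genes"]}
    rng = np.random.default_rng(seed)
    null_pool = sorted(
        set(cohort.gene_ids) - planted - set(cohort.truth["low_variance_genes"])
    )
    if len(null_pool) < decoy_size:  # tiny universes: allow low-variance decoys
        null_pool = sorted(set(cohort.gene_ids) - planted)
    for i in range(n_decoys):
        if not null_pool:
            break
        genes = sorted(rng.choice(null_pool, size=min(decoy_size, len(null_pool)), replace=False))
        sets[f"decoy-{i + 1}"] = {"description": "random unperturbed genes", "genes": genes}
    return sets


def subtype_pipeline(
    expression: pd.DataFrame,
    probe_map: pd.Series,
    samples: pd.DataFrame,
    gene_sets: dict[str, dict] | None,
    cfg: PipelineConfig,
) -> SubtypeResult:
    """Discovery analysis: preprocess, DE, cluster, importance, enrichment,
    confounders. Returns early (no clustering) when no gene passes DE
    selection."""
    cfg.validate()
    with _timed("preprocess"):
        matrix, report = preprocess(
            expression, probe_map, method=cfg.collapse_method, keep_fraction=cfg.keep_fraction
        )
    cases = list(samples.index[samples["diagnosis"] == "SZ"])
    controls = list(samples.index[samples["diagnosis"] == "CTRL"])
    with _timed("differential_expression"):
        de = differential_expression(
            matrix, ContrastSpec(tuple(cases), tuple(controls), "SZ vs control")
        )
        selected = select_de_genes(de, cfg.min_abs_logfc, cfg.max_q)
    de_genes = sorted(selected.index)
    out_samples = samples.copy()
    out_samples["cluster"] = np.nan
    if len(de_genes) < 3:
        log.warning("only %d DE genes selected; no clustering performed", len(de_genes))
        return SubtypeResult(matrix, report, de, de_genes, out_samples)

    with _timed("clustering"):
        if cfg.k is None:
            chosen_k, curve = elbow_select_k(
                matrix, cases, de_genes, k_max=cfg.k_max, seed=cfg.seed,
                n_init=cfg.n_init, standardize=cfg.standardize,
            )
        else:
            chosen_k, curve = cfg.k, {}
        cluster = kmeans_cluster(
            matrix, cases, controls, de_genes, k=chosen_k, seed=cfg.seed,
            n_init=cfg.n_init, standardize=cfg.standardize,
        )
        cluster.inertia_curve = curve
        cluster.chosen_k = chosen_k
    out_samples.loc[cluster.labels.index, "cluster"] = cluster.labels.astype(float)

    with _timed("importance"):
        x, _, _, order = _patient_matrix(matrix, cases, de_genes, cfg.standardize)
        labels = cluster.labels.loc[order].to_numpy()
        if cfg.recluster_loo:
            importance = recluster_loo_silhouette_importance(
                x, de_genes, k=chosen_k, seed=cfg.seed, top_fraction=cfg.top_fraction
            )
        else:
            importance = loo_silhouette_importance(
                x, labels, de_genes, s_full=cluster.mean_silhouette,
                top_fraction=cfg.top_fraction,
            )
    top_genes = sorted(importance.index[importance["top_third"]])

    enrich = None
    panel: list[str] = []
    if gene_sets:
        with _timed("enrichment"):
            enrich = hypergeometric_enrichment(
                top_genes, gene_sets, universe=list(matrix.index), alpha=cfg.bonferroni_alpha
            )
        for name in significant_sets(enrich):
            body = gene_sets[name]
            panel += [g for g in (body["genes"] if isinstance(body, dict) else body)]
        panel = sorted(set(panel) & set(matrix.index))

    characteristics = None
    coef_pairs = None
    pca_coords = None
    if chosen_k == 2:
        characteristics = cluster_characteristics(out_samples)
        if panel:
            coef_pairs = age_cluster_regression(matrix, out_samples, panel)
    if panel:
        pca_coords, _, _ = pca_project(matrix, panel, n_components=2)

    return SubtypeResult(
        matrix, report, de, de_genes, out_samples, cluster, importance,
        top_genes, enrich, characteristics, coef_pairs, pca_coords,
    )


def validation_pipeline(
    datasets: list[SyntheticCohort],
    cfg: PipelineConfig,
    gene_sets: dict[str, dict] | None = None,
    train_result: SubtypeResult | None = None,
) -> tuple[dict, SubtypeResult]:
    """Train on the first dataset, score PPV on the rest, pool.

    Runs the discovery pipeline on the training dataset (unless supplied),
    builds per-pair panels from the enrichment-significant sets, refits the
    LASSO per train-test pair on harmonized matrices, and pools per-dataset
    TP/FP into a combined PPV with its exact binomial significance against
    the pooled prevalence.
    """
    if len(datasets) < 2:
        raise ValueError("validation needs a training dataset and >= 1 test dataset")
    train, tests = datasets[0], datasets[1:]
    if gene_sets is None:
        gene_sets = make_gene_sets(train, seed=cfg.seed)
    if train_result is None:
        train_result = subtype_pipeline(
            train.expression, train.probe_map, train.samples, gene_sets, cfg
        )
    if train_result.enrichment is None:
        raise ValueError("training dataset produced no enrichment result")

    test_matrices: dict[str, pd.DataFrame] = {}
    test_labels: dict[str, pd.Series] = {}
    for t in tests:
        ds = str(t.samples["dataset_id"].iloc[0])
        m, _ = preprocess(
            t.expression, t.probe_map, method=cfg.collapse_method, keep_fraction=1.0
        )
        test_matrices[ds] = m
        test_labels[ds] = (t.samples["diagnosis"] == "SZ").astype(int)

    panels = build_panel(
        train_result.enrichment,
        gene_sets,
        train_genes=list(train_result.matrix.index),
        test_genes_per_dataset={ds: list(m.index) for ds, m in test_matrices.items()},
    )
    train_h = harmonize(train_result.matrix, cfg.harmonization)
    y_train = (train.samples["diagnosis"] == "SZ").astype(int)
    # the penalty is a property of the training problem: cross-validate it
    # once on the train-side panel, then refit per train-test pair at that
    # strength on the pair's shared genes
    train_panel = sorted(set().union(*panels.values()))
    with _timed("lambda_cv"):
        ref_model = fit_lasso_logistic(
            train_h, y_train, train_panel,
            lambda_grid=tuple(cfg.lambda_grid), cv_folds=cfg.cv_folds,
            seed=cfg.seed, harmonization=cfg.harmonization, cv_rule=cfg.cv_rule,
        )
    entries = []
    models = {}
    for ds in sorted(test_matrices):
        with _timed(f"predict[{ds}]"):
            model = fit_lasso_logistic(
                train_h, y_train, panels[ds],
                lambda_grid=(ref_model.lambda_,), cv_folds=cfg.cv_folds,
                seed=cfg.seed, harmonization=cfg.harmonization, cv_rule=cfg.cv_rule,
            )
            model.cv_log_loss = ref_model.cv_log_loss
            models[ds] = model
            entry = predict_and_score(
                model, harmonize(test_matrices[ds], cfg.harmonization),
                test_labels[ds], dataset_id=ds, threshold=cfg.threshold,
            )
            entries.append(entry)
    report = pool_reports(entries)
    report["models"] = {
        ds: {
            "panel_size": len(m.panel),
            "n_nonzero": len(m.nonzero_genes),
            "lambda": m.lambda_,
            "intercept": m.intercept,
        }
        for ds, m in models.items()
    }
    return report, train_result


# ---------------------------------------------------------------------------
# file-based runners


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(outdir: Path, cfg: PipelineConfig, outputs: list[Path]) -> Path:
    import sklearn

    manifest = {
        "config": cfg.to_dict(),
        "versions": {
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return path


def run_simulate(cfg: PipelineConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate the default synthetic cohort and write all its files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(default_cohort_spec(seed=cfg.seed, n_genes=cfg.n_genes))
    paths = cohort.write(outdir)
    sets = make_gene_sets(cohort, seed=cfg.seed)
    gmt = outdir / "gene_sets.gmt"
    sio.write_gmt(sets, gmt)
    paths["gmt"] = gmt
    _write_manifest(outdir, cfg, list(paths.values()))
    return paths


def run_subtype(cfg: PipelineConfig, outdir: str | Path) -> SubtypeResult:
    """Load inputs from the config paths, run discovery, write all outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expression = sio.read_expression_tsv(cfg.expression)
    samples = sio.read_sample_tsv(cfg.metadata)
    probe_map = sio.read_probe_map_tsv(cfg.probe_map)
    gene_sets = sio.read_gmt(cfg.gmt) if cfg.gmt else None
    res = subtype_pipeline(expression, probe_map, samples, gene_sets, cfg)

    written: list[Path] = []

    def w(df: pd.DataFrame, name: str, **kw) -> None:
        p = outdir / name
        df.to_csv(p, sep="\t", **kw)
        written.append(p)

    w(res.de_table, "de_table.tsv")
    w(res.filter_report, "filter_report.tsv", index=False)
    w(res.samples, "samples_clustered.tsv", index_label="sample_id")
    if res.clustered:
        cluster_json = outdir / "cluster_result.json"
        cluster_json.write_text(
            json.dumps(
                {
                    "labels": res.cluster.labels.astype(int).to_dict(),
                    "k": res.cluster.k,
                    "chosen_k": res.cluster.chosen_k,
                    "inertia": res.cluster.inertia,
                    "inertia_curve": {str(k): v for k, v in res.cluster.inertia_curve.items()},
                    "mean_silhouette": res.cluster.mean_silhouette,
                    "seed": res.cluster.seed,
                },
                indent=1,
                sort_keys=True,
            )
            + "\n"
        )
        written.append(cluster_json)
        w(res.importance, "importance_table.tsv")
        top = outdir / "top_third_genes.txt"
        top.write_text("\n".join(res.top_genes) + "\n")
        written.append(top)
        if res.enrichment is not None:
            w(res.enrichment, "enrichment.tsv")
        if res.characteristics is not None:
            w(res.characteristics, "cluster_characteristics.tsv")
        if res.coefficient_pairs is not None:
            w(res.coefficient_pairs, "age_cluster_coefficients.tsv")
        if res.pca_coords is not None:
            w(res.pca_coords, "pca_coordinates.tsv")
    _write_manifest(outdir, cfg, written)
    return res


def run_validate(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Five-platform synthetic validation run: train, predict, pool, write."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = validation_cohort_spec(seed=cfg.seed, n_genes=cfg.n_genes)
    mega = generate_cohort(spec)
    coverages = [1.0] + [cfg.coverage] * (cfg.n_datasets - 1)
    sizes = FIVE_PLATFORM_SIZES if cfg.n_datasets == 5 else None
    datasets = split_platforms(
        mega, cfg.n_datasets, coverages, seed=cfg.seed, sizes=sizes
    )
    report, _ = validation_pipeline(datasets, cfg)
    per_ds = pd.DataFrame(report["per_dataset"]).set_index("dataset_id")
    per_ds.to_csv(outdir / "prediction_report.tsv", sep="\t")
    payload = {k: v for k, v in report.items() if k != "per_dataset"}
    (outdir / "prediction_report.json").write_text(
        json.dumps(payload, indent=1, sort_keys=True, default=float) + "\n"
    )
    _write_manifest(
        outdir, cfg, [outdir / "prediction_report.tsv", outdir / "prediction_report.json"]
    )
    return report
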