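"""Synthetic multi-dataset case-control expression cohorts with a planted two-subtype structure.

The generator emulates the structure of blood microarray case-control studies
of schizophrenia: a control population; a majority patient subgroup whose
expression is near that of controls on the subtype-discriminative gene
modules; a minority patient subgroup with strong shifts concentrated in
planted modules (a ribosome-like and a UPS-like set); a broad disease-wide
expression shift affecting all patients (the background of case-control DE
genes that carries no subtype information); duplicate probes per gene;
low-variance genes; and multiple "platform" datasets with partially
overlapping gene coverage and disjoint samples.

Every downstream stage of the pipeline has a ground-truth acceptance surface
against the planted structure returned in :class:`SyntheticCohort`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


class CohortSpecError(ValueError):
    """A CohortSpec field violates an invariant; the message names the field."""


@dataclass(frozen=True)
class PlantedGeneSet:
    """A named set of gene indices carrying a planted expression effect.

    Parameters
    ----------
    name:
        Set label, e.g. ``"ribosome-like"``.
    genes:
        Gene indices (into the cohort's gene list) belonging to the set.
    effect_size:
        Shift applied to subtype-I patients, in units of the gene's control SD.
    directions:
        Per-gene direction: +1 (up in patients), -1 (down), or 0 (member of
        the set but carrying no effect). Length must equal ``len(genes)``.
    shared:
        If True the full effect is applied to *both* patient subtypes, so the
        set is differentially expressed case-vs-control but carries no
        subtype-discriminative signal (disease-wide background genes).
    subtype2_effect:
        Shift applied to subtype-II patients (same per-gene directions), in
        control-SD units. None falls back to the cohort-wide
        ``background_effect`` (ignored for shared sets, which always apply
        the full effect to both subtypes).
    """

    name: str
    genes: tuple[int, ...]
    effect_size: float
    directions: tuple[int, ...]
    shared: bool = False
    subtype2_effect: float | None = None

    def __post_init__(self) -> None:
        if len(self.directions) != len(self.genes):
            raise CohortSpecError(
                f"planted_sets[{self.name}]: directions length {len(self.directions)} "
                f"!= genes length {len(self.genes)}"
            )
        if any(d not in (-1, 0, 1) for d in self.directions):
            raise CohortSpecError(f"planted_sets[{self.name}]: directions must be -1, 0 or +1")
        if self.effect_size < 0:
            raise CohortSpecError(f"planted_sets[{self.name}]: effect_size must be >= 0")

    @property
    def effective_genes(self) -> tuple[int, ...]:
        """Genes of the set whose direction is nonzero (truly perturbed)."""
        return tuple(g for g, d in zip(self.genes, self.directions) if d != 0)


@dataclass(frozen=True)
class AgeParams:
    mean: float
    sd: float


@dataclass(frozen=True)
class CohortSpec:
    """Full parameterization of a synthetic case-control cohort.

    Defaults mirror the scale of the training study: 96 controls and 106
    patients of whom round(33/106 * 106) = 33 form the distinct subtype I;
    a 69-gene ribosome-like module (63 up, 5 down, 1 silent) and a 144-gene
    UPS-like module (117 up, 27 down) shifted 1.5 control-SD in subtype I
    only; and a 1000-gene disease-wide background shifted 0.6 SD in all
    patients. Ages and male fractions follow the published per-cluster
    demographics (42.8±9.8 vs 38.1±10.9 years; 79% vs 68% male).
    """

    n_controls: int = 96
    n_patients: int = 106
    subtype1_fraction: float = 33.0 / 106.0
    n_genes: int = 5000
    planted_sets: tuple[PlantedGeneSet, ...] = ()
    background_effect: float = 0.0
    noise_sd: float = 0.5
    duplicate_probe_rate: float = 0.3
    low_variance_fraction: float = 0.5
    low_variance_scale: float = 0.3
    age_params: dict = field(
        default_factory=lambda: {
            "control": AgeParams(39.5, 12.5),
            "subtype1": AgeParams(42.8, 9.8),
            "subtype2": AgeParams(38.1, 10.9),
        }
    )
    male_fraction: dict = field(
        default_factory=lambda: {
            "control": 0.60,
            "subtype1": 26.0 / 33.0,
            "subtype2": 50.0 / 73.0,
        }
    )
    allow_overlap: bool = False
    seed: int = 0

    # -- derived counts -------------------------------------------------
    @property
    def n_subtype1(self) -> int:
        return int(round(self.subtype1_fraction * self.n_patients))

    @property
    def n_subtype2(self) -> int:
        return self.n_patients - self.n_subtype1

    def validate(self) -> None:
        if self.n_controls < 2:
            raise CohortSpecError("n_controls: must be >= 2")
        if self.n_patients < 4:
            raise CohortSpecError("n_patients: must be >= 4")
        if not 0.0 < self.subtype1_fraction < 1.0:
            raise CohortSpecError("subtype1_fraction: must lie in (0, 1)")
        if self.n_subtype1 < 2 or self.n_subtype2 < 2:
            raise CohortSpecError(
                "subtype1_fraction: each patient subtype must contain >= 2 samples "
                f"(got {self.n_subtype1} and {self.n_subtype2})"
            )
        if self.n_genes < 1:
            raise CohortSpecError("n_genes: must be >= 1")
        if not 0.0 <= self.duplicate_probe_rate <= 1.0:
            raise CohortSpecError("duplicate_probe_rate: must lie in [0, 1]")
        if not 0.0 <= self.low_variance_fraction <= 1.0:
            raise CohortSpecError("low_variance_fraction: must lie in [0, 1]")
        if self.noise_sd < 0:
            raise CohortSpecError("noise_sd: must be >= 0")
        seen: set[int] = set()
        for ps in self.planted_sets:
            idx = set(ps.genes)
            if not idx <= set(range(self.n_genes)):
                raise CohortSpecError(f"planted_sets[{ps.name}]: gene indices out of range")
            if not self.allow_overlap and idx & seen:
                raise CohortSpecError(
                    f"planted_sets[{ps.name}]: overlaps another set and allow_overlap is False"
                )
            seen |= idx


@dataclass
class SyntheticCohort:
    """A generated cohort: probe-level expression, sample metadata, and truth.

    ``expression`` has one row per probe and one column per sample (log-scale
    intensities); ``probe_map`` maps every probe to its gene symbol;
    ``samples`` is indexed by sample id with columns diagnosis / age / sex /
    dataset_id / true_subtype; ``truth`` records the planted sets and the
    per-gene true effect (signed, in control-SD units, for subtype I).
    """

    expression: pd.DataFrame
    probe_map: pd.Series
    samples: pd.DataFrame
    truth: dict
    spec: CohortSpec | None = None

    @property
    def gene_ids(self) -> list[str]:
        return sorted(set(self.probe_map))

    def write(self, outdir: str | Path, prefix: str = "cohort") -> dict[str, Path]:
        """Write expression / metadata / probe-map TSVs and truth JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "expression": outdir / f"{prefix}_expression.tsv",
            "samples": outdir / f"{prefix}_samples.tsv",
            "probe_map": outdir / f"{prefix}_probe_map.tsv",
            "truth": outdir / f"{prefix}_truth.json",
        }
        from . import io as _io

        _io.write_expression_tsv(self.expression, paths["expression"])
        _io.write_sample_tsv(self.samples, paths["samples"])
        _io.write_probe_map_tsv(self.probe_map, paths["probe_map"])
        paths["truth"].write_text(json.dumps(self.truth, indent=1, sort_keys=True) + "\n")
        return paths


# ---------------------------------------------------------------------------
# default study design


def default_planted_sets(
    n_genes: int = 5000,
    module_effect: float = 1.5,
    disease_wide_effect: float = 0.6,
    n_disease_wide: int = 1000,
) -> tuple[PlantedGeneSet, ...]:
    """The default planted design.

    Ribosome-like: 69 genes, 63 up / 5 down / 1 silent; UPS-like: 144 genes,
    117 up / 27 down — both shifted ``module_effect`` control-SD in subtype I
    only. Disease-wide: ``n_disease_wide`` genes, half up / half down,
    shifted ``disease_wide_effect`` SD in *all* patients (case-control DE
    background with no subtype signal). For small universes (n_genes below
    the canonical design's footprint) every set is scaled down
    proportionally, keeping the up/down mix. Gene indices are assigned from
    the front of the gene list; the generator scatters roles over symbols so
    the layout is irrelevant downstream.
    """
    need = 69 + 144 + n_disease_wide
    if n_genes >= 2 * (need + 2):
        n_ribo, n_ups, n_dw = 69, 144, n_disease_wide
        ribo_dirs = [1] * 63 + [-1] * 5 + [0]
        ups_dirs = [1] * 117 + [-1] * 27
    else:
        # scaled-down design for small universes (planted <= half the genes)
        f = n_genes / (2.0 * (need + 2))
        n_ribo = max(6, round(69 * f))
        n_ups = max(9, round(144 * f))
        n_dw = max(20, round(n_disease_wide * f))
        if n_ribo + n_ups + n_dw > n_genes // 2:
            raise CohortSpecError(
                f"n_genes: {n_genes} too small for the planted design"
            )
        ribo_down = max(1, round(5 / 69 * n_ribo))
        ups_down = max(1, round(27 / 144 * n_ups))
        ribo_dirs = [1] * (n_ribo - ribo_down) + [-1] * ribo_down
        ups_dirs = [1] * (n_ups - ups_down) + [-1] * ups_down
    # subtype II carries a small ribosomal shift (about a sixth of the
    # subtype-I effect): the majority subtype is near controls but not
    # identical to them on the ribosomal module, while the UPS module stays
    # at control level
    ribo = PlantedGeneSet(
        "ribosome-like", tuple(range(n_ribo)), module_effect, tuple(ribo_dirs),
        subtype2_effect=module_effect / 6.0,
    )
    ups = PlantedGeneSet(
        "UPS-like", tuple(range(n_ribo, n_ribo + n_ups)), module_effect, tuple(ups_dirs)
    )
    half = n_dw // 2
    dw = PlantedGeneSet(
        "disease-wide",
        tuple(range(n_ribo + n_ups, n_ribo + n_ups + n_dw)),
        disease_wide_effect,
        tuple([1] * half + [-1] * (n_dw - half)),
        shared=True,
    )
    return (ribo, ups, dw)


def default_cohort_spec(seed: int = 0, **overrides) -> CohortSpec:
    """The default 202-sample training-scale cohort (96 controls, 106 patients)."""
    n_genes = int(overrides.pop("n_genes", 5000))
    planted = overrides.pop("planted_sets", default_planted_sets(n_genes))
    return CohortSpec(n_genes=n_genes, planted_sets=planted, seed=seed, **overrides)


def null_cohort_spec(seed: int = 0, **overrides) -> CohortSpec:
    """Same design with every planted effect set to zero (null calibration)."""
    spec = default_cohort_spec(seed=seed, **overrides)
    nulled = tuple(
        dataclasses.replace(ps, effect_size=0.0, subtype2_effect=None)
        for ps in spec.planted_sets
    )
    return dataclasses.replace(spec, planted_sets=nulled)


def validation_cohort_spec(seed: int = 0, **overrides) -> CohortSpec:
    """398-sample design (186 controls, 212 patients) for the five-platform split."""
    return default_cohort_spec(seed=seed, n_controls=186, n_patients=212, **overrides)


#: (n_controls, n_patients) of the five platforms in the published design:
#: the training beadchip cohort plus four independent test cohorts.
FIVE_PLATFORM_SIZES: tuple[tuple[int, int], ...] = (
    (96, 106),
    (29, 43),
    (22, 15),
    (8, 13),
    (31, 35),
)


# ---------------------------------------------------------------------------
# generation


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, size: int,
                      lower: float = 18.0) -> np.ndarray:
    a = (lower - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a cohort from ``spec``; bit-reproducible given ``spec.seed``.

    Controls are drawn gene-wise from N(mu_g, sd_g) with mu_g ~ N(7, 1) and
    sd_g ~ |N(0.5, 0.1)| (low-variance genes scaled down), mimicking
    log-scale microarray intensities. Subtype-I patients add the full planted
    effect (direction * effect_size * sd_g); subtype-II patients add the
    background_effect on non-shared planted genes and the full effect on
    shared sets. Duplicate probes are independent noisy replicates
    (gene value + N(0, noise_sd/2)).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_genes, n_ctrl, n_pat = spec.n_genes, spec.n_controls, spec.n_patients
    n_s1, n_s2 = spec.n_subtype1, spec.n_subtype2
    n_samples = n_ctrl + n_pat

    width = max(5, len(str(n_genes)))
    gene_ids = np.array([f"G{i:0{width}d}" for i in range(n_genes)])

    mu = rng.normal(7.0, 1.0, n_genes)
    sd = np.abs(rng.normal(0.5, 0.1, n_genes))
    sd = np.maximum(sd, 1e-3)
    n_lv = int(round(spec.low_variance_fraction * n_genes))
    planted_idx = sorted({g for ps in spec.planted_sets for g in ps.genes})
    # low-variance role assigned to non-planted genes only
    candidates = np.setdiff1d(np.arange(n_genes), np.array(planted_idx, dtype=int))
    if n_lv > len(candidates):
        raise CohortSpecError(
            "low_variance_fraction: not enough non-planted genes to mark low-variance"
        )
    lv_idx = rng.choice(candidates, size=n_lv, replace=False)
    sd[lv_idx] *= spec.low_variance_scale

    # per-gene signed true effect for subtype I (SD units) and the shared flag
    effect_s1 = np.zeros(n_genes)
    effect_s2 = np.zeros(n_genes)
    for ps in spec.planted_sets:
        g = np.array(ps.genes, dtype=int)
        d = np.array(ps.directions, dtype=float)
        effect_s1[g] += d * ps.effect_size
        if ps.shared:
            e2 = ps.effect_size
        elif ps.subtype2_effect is not None:
            e2 = ps.subtype2_effect
        else:
            e2 = spec.background_effect
        effect_s2[g] += d * e2

    # sample layout: controls first, then subtype-I, then subtype-II patients
    values = rng.normal(0.0, 1.0, (n_genes, n_samples)) * sd[:, None] + mu[:, None]
    s1_cols = slice(n_ctrl, n_ctrl + n_s1)
    s2_cols = slice(n_ctrl + n_s1, n_samples)
    values[:, s1_cols] += (effect_s1 * sd)[:, None]
    values[:, s2_cols] += (effect_s2 * sd)[:, None]

    sample_ids = [f"CTRL_{i + 1:03d}" for i in range(n_ctrl)] + [
        f"SZ_{i + 1:03d}" for i in range(n_pat)
    ]
    diagnosis = ["CTRL"] * n_ctrl + ["SZ"] * n_pat
    subtype = ["none"] * n_ctrl + ["I"] * n_s1 + ["II"] * n_s2

    ages = np.concatenate(
        [
            _truncated_normal(rng, spec.age_params["control"].mean, spec.age_params["control"].sd, n_ctrl),
            _truncated_normal(rng, spec.age_params["subtype1"].mean, spec.age_params["subtype1"].sd, n_s1),
            _truncated_normal(rng, spec.age_params["subtype2"].mean, spec.age_params["subtype2"].sd, n_s2),
        ]
    )
    male = np.concatenate(
        [
            rng.random(n_ctrl) < spec.male_fraction["control"],
            rng.random(n_s1) < spec.male_fraction["subtype1"],
            rng.random(n_s2) < spec.male_fraction["subtype2"],
        ]
    )
    samples = pd.DataFrame(
        {
            "diagnosis": diagnosis,
            "age": np.round(ages, 1),
            "sex": np.where(male, "M", "F"),
            "dataset_id": "synthetic",
            "true_subtype": subtype,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    # probe expansion: every gene gets probe _p1 = exact value; a random
    # duplicate_probe_rate fraction gets a second noisy replicate probe.
    n_dup = int(round(spec.duplicate_probe_rate * n_genes))
    dup_idx = np.sort(rng.choice(n_genes, size=n_dup, replace=False))
    probe_rows = [values]
    probe_ids = [f"{g}_p1" for g in gene_ids]
    probe_genes = list(gene_ids)
    if n_dup:
        noise_scale = spec.noise_sd / 2.0
        dup_vals = values[dup_idx] + rng.normal(0.0, noise_scale, (n_dup, n_samples))
        probe_rows.append(dup_vals)
        probe_ids += [f"{gene_ids[i]}_p2" for i in dup_idx]
        probe_genes += [gene_ids[i] for i in dup_idx]
    expr = pd.DataFrame(
        np.vstack(probe_rows), index=pd.Index(probe_ids, name="probe_id"), columns=sample_ids
    )
    probe_map = pd.Series(probe_genes, index=expr.index, name="gene_symbol")

    truth = {
        "planted_sets": {
            ps.name: {
                "genes": [gene_ids[g] for g in ps.genes],
                "effect_size": ps.effect_size,
                "directions": list(ps.directions),
                "shared": ps.shared,
                "effective_genes": [gene_ids[g] for g in ps.effective_genes],
            }
            for ps in spec.planted_sets
        },
        "true_effect_subtype1": {
            gene_ids[i]: float(effect_s1[i]) for i in np.flatnonzero(effect_s1)
        },
        "true_effect_subtype2": {
            gene_ids[i]: float(effect_s2[i]) for i in np.flatnonzero(effect_s2)
        },
        "low_variance_genes": [gene_ids[i] for i in np.sort(lv_idx)],
        "subtype1_samples": sample_ids[n_ctrl : n_ctrl + n_s1],
        "seed": spec.seed,
    }
    return SyntheticCohort(expr, probe_map, samples, truth, spec=spec)


# ---------------------------------------------------------------------------
# platform splitting


def split_platforms(
    cohort: SyntheticCohort,
    n_datasets: int,
    coverage: float | Sequence[float],
    seed: int,
    sizes: Sequence[tuple[int, int]] | None = None,
) -> list[SyntheticCohort]:
    """Split a cohort into ``n_datasets`` disjoint-sample "platform" datasets.

    Each derived dataset retains a random ``coverage`` fraction of genes
    (scalar, or one fraction per dataset) and a disjoint subset of samples,
    stratified by diagnosis and — when a true subtype label is present — by
    subtype, so every derived cohort reflects the source population's case
    composition (as independently recruited cohorts would) rather than
    inheriting partition noise. ``sizes`` optionally fixes per-dataset
    (n_controls, n_patients); by default samples are partitioned
    near-equally. With ``coverage=1.0, n_datasets=1`` the input cohort is
    returned intact.
    """
    cov = [float(coverage)] * n_datasets if np.isscalar(coverage) else list(coverage)
    if len(cov) != n_datasets:
        raise ValueError(f"coverage: expected 1 or {n_datasets} values, got {len(cov)}")
    if any(not 0.0 < c <= 1.0 for c in cov):
        raise ValueError("coverage: fractions must lie in (0, 1]")
    samples = cohort.samples
    ctrl_ids = list(samples.index[samples["diagnosis"] == "CTRL"])
    pat_ids = list(samples.index[samples["diagnosis"] == "SZ"])
    if n_datasets > min(len(ctrl_ids), len(pat_ids)):
        raise ValueError(
            f"n_datasets={n_datasets} exceeds available samples per class "
            f"({len(ctrl_ids)} controls, {len(pat_ids)} patients)"
        )
    if sizes is not None:
        if len(sizes) != n_datasets:
            raise ValueError("sizes: one (n_controls, n_patients) pair per dataset required")
        if sum(s[0] for s in sizes) != len(ctrl_ids) or sum(s[1] for s in sizes) != len(pat_ids):
            raise ValueError(
                "sizes: per-dataset counts must sum to the cohort totals "
                f"({len(ctrl_ids)} controls, {len(pat_ids)} patients)"
            )
    else:
        base_c, rem_c = divmod(len(ctrl_ids), n_datasets)
        base_p, rem_p = divmod(len(pat_ids), n_datasets)
        sizes = [
            (base_c + (1 if i < rem_c else 0), base_p + (1 if i < rem_p else 0))
            for i in range(n_datasets)
        ]

    rng = np.random.default_rng(seed)
    ctrl_perm = list(rng.permutation(ctrl_ids))
    if "true_subtype" in samples.columns:
        # interleave shuffled subtype strata so every sample-count prefix
        # carries the population's subtype mix
        strata = [
            list(rng.permutation(list(samples.index[samples["true_subtype"] == sub])))
            for sub in ("I", "II")
        ]
        strata = [s for s in strata if s]
        if strata:
            weights = np.array([len(s) for s in strata], dtype=float)
            pat_perm = []
            taken = [0] * len(strata)
            for _ in range(len(pat_ids)):
                deficit = [
                    (taken[i] + 1) / weights[i] if taken[i] < len(strata[i]) else np.inf
                    for i in range(len(strata))
                ]
                i = int(np.argmin(deficit))
                pat_perm.append(strata[i][taken[i]])
                taken[i] += 1
        else:
            pat_perm = list(rng.permutation(pat_ids))
    else:
        pat_perm = list(rng.permutation(pat_ids))
    genes = np.array(cohort.gene_ids)

    out: list[SyntheticCohort] = []
    c_ofs = p_ofs = 0
    for i, (nc, npat) in enumerate(sizes):
        sub_samples = ctrl_perm[c_ofs : c_ofs + nc] + pat_perm[p_ofs : p_ofs + npat]
        c_ofs += nc
        p_ofs += npat
        if cov[i] >= 1.0:
            keep_genes = set(genes)
        else:
            n_keep = int(round(cov[i] * len(genes)))
            keep_genes = set(rng.choice(genes, size=n_keep, replace=False))
        keep_probes = cohort.probe_map.index[cohort.probe_map.isin(keep_genes)]
        # preserve original sample order within the subset
        sub_samples = [s for s in cohort.samples.index if s in set(sub_samples)]
        ds_id = f"dataset_{i + 1}"
        meta = cohort.samples.loc[sub_samples].copy()
        meta["dataset_id"] = ds_id
        sub_truth = dict(cohort.truth)
        sub_truth["dataset_id"] = ds_id
        out.append(
            SyntheticCohort(
                expression=cohort.expression.loc[keep_probes, sub_samples].copy(),
                probe_map=cohort.probe_map.loc[keep_probes].copy(),
                samples=meta,
                truth=sub_truth,
                spec=cohort.spec,
            )
        )
    return out


def gene_intersection(cohorts: Sequence[SyntheticCohort]) -> list[str]:
    """Genes covered by every dataset of a platform split."""
    common: set[str] | None = None
    for c in cohorts:
        g = set(c.probe_map)
        common = g if common is None else common & g
    return sorted(common or set())
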