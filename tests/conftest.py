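"""Shared fixtures: small fast cohorts and one default-scale pipeline run."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from szsubtypes import (
    CohortSpec,
    PipelineConfig,
    PlantedGeneSet,
    default_cohort_spec,
    generate_cohort,
)
from szsubtypes.pipeline import make_gene_sets, subtype_pipeline


def small_planted_sets(n_genes: int = 400) -> tuple[PlantedGeneSet, ...]:
    """Scaled-down planted design: 20 + 30 module genes, 80 disease-wide."""
    ribo = PlantedGeneSet("ribosome-like", tuple(range(20)), 1.5,
                          tuple([1] * 17 + [-1] * 2 + [0]))
    ups = PlantedGeneSet("UPS-like", tuple(range(20, 50)), 1.5,
                         tuple([1] * 24 + [-1] * 6))
    dw = PlantedGeneSet("disease-wide", tuple(range(50, 130)), 0.6,
                        tuple([1] * 40 + [-1] * 40), shared=True)
    return (ribo, ups, dw)


def small_spec(seed: int = 0, **overrides) -> CohortSpec:
    kwargs = dict(
        n_controls=40,
        n_patients=45,
        subtype1_fraction=1.0 / 3.0,
        n_genes=400,
        planted_sets=small_planted_sets(),
        duplicate_probe_rate=0.3,
    )
    kwargs.update(overrides)
    return CohortSpec(seed=seed, **kwargs)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_spec(seed=7))


@pytest.fixture(scope="session")
def default_cohort():
    """One full-scale (202-sample, 5000-gene) cohort shared across tests."""
    return generate_cohort(default_cohort_spec(seed=11))


@pytest.fixture(scope="session")
def default_run(default_cohort):
    """Discovery pipeline executed once on the full-scale cohort."""
    sets = make_gene_sets(default_cohort, seed=11)
    cfg = PipelineConfig(seed=11)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = subtype_pipeline(
            default_cohort.expression,
            default_cohort.probe_map,
            default_cohort.samples,
            sets,
            cfg,
        )
    return default_cohort, sets, res


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
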