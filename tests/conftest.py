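"""Shared fixtures: gating config and small synthetic cohorts.

All fixtures are generated programmatically; cohort sizes are kept small so
the whole suite runs in minutes on one CPU.
"""

import logging

import pytest

from spatialtme.gating import assign_barcodes, assign_states, load_gating_config
from spatialtme.synth import GeneratorConfig, generate_cohort

logging.getLogger("spatialtme").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def gating():
    return load_gating_config()


@pytest.fixture(scope="session")
def small_cohort(gating):
    """Tiny two-site cohort with the default planted effects."""
    config = GeneratorConfig(
        seed=11,
        n_patients_per_cohort={"naive": 5, "aCD40": 6},
        regions_per_patient={"T": 1, "IA": 2},
        cells_per_region=120,
    )
    cells, regions, patients, truth = generate_cohort(config, gating)
    return config, cells, regions, patients, truth


@pytest.fixture(scope="session")
def phenotyped_cohort(small_cohort, gating):
    config, cells, regions, patients, truth = small_cohort
    cells = assign_barcodes(assign_states(cells, gating), gating)
    return config, cells, regions, patients, truth


@pytest.fixture(scope="session")
def feature_matrix(phenotyped_cohort, gating):
    from spatialtme.features import compute_features

    _, cells, regions, *_ = phenotyped_cohort
    return compute_features(cells, regions, gating.leaves)


@pytest.fixture(scope="session")
def pipeline_bundle(small_cohort, gating):
    """One full pipeline run on the small cohort (shared across tests)."""
    from spatialtme.pipeline import AnalysisConfig, run_full

    _, cells, regions, patients, _ = small_cohort
    return run_full(cells, regions, patients, AnalysisConfig(seed=2), gating)
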