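"""Shared fixtures: one default synthetic bundle + pipeline run per session."""

import warnings

import pytest

from cypminer.pipeline import run_on_bundle, run_synthetic
from cypminer.synthetic_data import SimulationConfig, generate_bundle

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def bundle_and_result(default_config):
    """Default noise-free bundle and its full pipeline run (shared)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_synthetic(default_config)


@pytest.fixture(scope="session")
def bundle(bundle_and_result):
    return bundle_and_result[0]


@pytest.fixture(scope="session")
def pipeline_result(bundle_and_result):
    return bundle_and_result[1]


@pytest.fixture(scope="session")
def panel(bundle):
    return bundle.panel


@pytest.fixture(scope="session")
def tiny_bundle():
    """Small single-family bundle for expression/qPCR-level tests."""
    config = SimulationConfig(
        seed=11, n_families=1, n_subfamilies_per_family=1,
        n_members_per_subfamily=1, n_full=6, n_partial=0, n_antisense=2,
        n_decoys=2, identity_targets=(0.98,), n_coexpressed=3,
        n_anticorrelated=1, n_antisense_positive=1, n_antisense_negative=1,
        n_pathway_coexpressed=2, n_pathway_other=1, n_qpcr_genes=4)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_bundle(config)
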