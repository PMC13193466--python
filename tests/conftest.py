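"""Shared fixtures: one small synthetic cohort generated per session."""

import pytest

import mirtraject as mt


@pytest.fixture(scope="session")
def small_cohort():
    """~100-pair cohort with default signal panel (seed 11)."""
    cfg = mt.GeneratorConfig.from_dict({"scale": 0.08}, seed=11)
    manifest, matrix, truth = mt.generate_cohort(cfg)
    return manifest, matrix, truth


@pytest.fixture(scope="session")
def small_normed(small_cohort):
    manifest, matrix, truth = small_cohort
    normed, factors = mt.normalize_pipeline(matrix)
    return manifest, normed, factors


@pytest.fixture(scope="session")
def signal_panel():
    return {p.probe_id: p for p in mt.default_trajectory_panel()}
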