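"""Shared fixtures: one default synthetic study, calibrated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from phosdyn import (
    SimConfig,
    calibration_pipeline,
    differential_sites,
    simulate_phosphoproteome,
)


@pytest.fixture(scope="session")
def default_study():
    """Default-condition study: 3 stages x 5 replicates, 75% regulated, sigma 0.15."""
    return simulate_phosphoproteome(SimConfig(seed=1))


@pytest.fixture(scope="session")
def calibrated(default_study):
    return calibration_pipeline(
        default_study.site_intensity,
        default_study.protein_intensity,
        default_study.site_to_protein,
    )


@pytest.fixture(scope="session")
def calls(default_study, calibrated):
    return differential_sites(calibrated, default_study.design)


@pytest.fixture(scope="session")
def noise_free_study():
    """Zero-noise limit with full protein coverage (every site calibratable)."""
    return simulate_phosphoproteome(
        SimConfig(seed=2, sigma=0.0, protein_detected_fraction=1.0)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
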