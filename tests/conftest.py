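"""Shared fixtures: small synthetic cohorts and reusable building blocks."""

from __future__ import annotations

import numpy as np
import pytest

import eegmicrostates as em


@pytest.fixture(scope="session")
def templates64() -> em.MicrostateMaps:
    """Ground-truth 64-channel template maps (canonical orientations)."""
    return em.make_templates(64, 4)


@pytest.fixture(scope="session")
def small_cfg() -> em.GeneratorConfig:
    """A scaled-down generator configuration for fast unit tests."""
    return em.GeneratorConfig(
        group_sizes={"seizure": 2, "seizure_free": 2, "control": 2},
        epochs_per_subject=6,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg) -> em.Cohort:
    """One small generated cohort reused by read-only tests."""
    return em.make_cohort(small_cfg, seed=2024)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
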