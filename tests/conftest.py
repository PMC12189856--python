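"""Shared fixtures: small synthetic cohorts reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from ctesm import CohortSpec, generate_cohort, window
from ctesm.features import FeatureConfig, extract_cohort_features


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def tiny_cohort():
    """3 subjects/class, 8 channels, 6 s — fast enough for unit tests."""
    spec = CohortSpec(
        n_subjects_per_class=3,
        n_channels=8,
        duration_s=6.0,
        class_effect={"PD": {"beta": 3.0}, "HC": {}},
        seed=11,
    )
    return spec, generate_cohort(spec)


@pytest.fixture(scope="session")
def tiny_features(tiny_cohort):
    """Feature instances extracted from the tiny cohort (2 s / 1 s frames)."""
    _, recordings = tiny_cohort
    framesets = [window(rec) for rec in recordings]
    return extract_cohort_features(framesets, FeatureConfig())


@pytest.fixture(scope="session")
def separable_cohort():
    """A cohort with a strong beta-band class effect used by the classifier
    tests: 10 subjects/class, 16 channels, 8 s recordings."""
    spec = CohortSpec(
        n_subjects_per_class=10,
        n_channels=16,
        duration_s=8.0,
        class_effect={"PD": {"beta": 2.0}, "HC": {}},
        seed=7,
    )
    return spec, generate_cohort(spec)


@pytest.fixture(scope="session")
def separable_features(separable_cohort):
    _, recordings = separable_cohort
    framesets = [window(rec) for rec in recordings]
    return extract_cohort_features(framesets, FeatureConfig())
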