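"""Shared fixtures: small simulated cohorts and random segments."""

from __future__ import annotations

import numpy as np
import pytest

from emgmh.cohort import CohortSpec, simulate_cohort
from emgmh.pipeline import matrices_by_motion, segment_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def tiny_cohort():
    """2 patients x 2 motions x 1 rep: the smallest structurally valid cohort."""
    spec = CohortSpec(n_patients=2, n_repetitions=1, motions=("EF", "WF"), seed=11)
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def small_segments():
    """Segments of a 3-patient, 2-motion cohort (shared across feature tests)."""
    spec = CohortSpec(n_patients=3, n_repetitions=2, motions=("EF", "EE"), seed=5)
    cohort = simulate_cohort(spec)
    return segment_cohort(cohort).segments


@pytest.fixture(scope="session")
def fs1_matrices(small_segments):
    return matrices_by_motion(small_segments, "FS1")

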