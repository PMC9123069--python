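from __future__ import annotations

import pytest

from wardalarm import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def quiet_spec() -> CohortSpec:
    """Small cohort with no degradation: pure signal structure."""
    return CohortSpec(
        n_patients=6,
        duration_median_h=48.0,
        duration_sigma=0.0,
        duration_min_h=48.0,
        duration_max_h=48.0,
        missing_fraction=0.0,
        artifact_rate_per_day=0.0,
        ae_incidence=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully featured cohort (events, noise, gaps, artifacts)."""
    spec = CohortSpec(
        n_patients=12,
        duration_median_h=60.0,
        duration_min_h=30.0,
        duration_max_h=120.0,
        ae_incidence=0.6,
        seed=11,
    )
    return generate_cohort(spec)
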