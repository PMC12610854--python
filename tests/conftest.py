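import numpy as np
import pytest

from fatiguekin import (
    CohortConfig,
    ExtractionConfig,
    MotionParams,
    NoiseParams,
    extract_cohort,
    simulate_cohort,
    simulate_subject,
)


@pytest.fixture(scope="session")
def stationary_subject():
    """Zero-drift, zero-noise recording: T0 = 2 s, arm amplitude 1 rad,
    30 fps, 120 s. The closed-form motion makes every extracted quantity
    analytically checkable."""
    params = MotionParams(
        base_period=2.0,
        arm_amplitude=1.0,
        leg_amplitude=0.5,
        period_growth=0.0,
        amplitude_decay=0.0,
        fatigue_rate=1.0,
    )
    seq, log = simulate_subject(
        params, NoiseParams.noiseless(), duration=120.0, fps=30.0, seed=0
    )
    return params, seq, log


@pytest.fixture(scope="session")
def drifting_subject():
    """Default drift, zero noise: cycles slow and shrink as F(t) rises."""
    params = MotionParams()
    seq, log = simulate_subject(
        params, NoiseParams.noiseless(), duration=180.0, fps=30.0, seed=0
    )
    return params, seq, log


@pytest.fixture(scope="session")
def small_cohort_table():
    """Feature table of a 4-subject, 120-s cohort (fast evaluation tests)."""
    cohort = simulate_cohort(CohortConfig(n_subjects=4, duration=120.0,
                                          seed=7))
    return extract_cohort(cohort, ExtractionConfig())


@pytest.fixture(scope="session")
def default_cohort_table():
    """Feature table of the full default cohort (n=10, 180 s, seed 42)."""
    return extract_cohort(simulate_cohort(CohortConfig(seed=42)))
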