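import numpy as np
import pytest
from hypothesis import settings

from psadyn import DailyTransition, PSASeries

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def identity_d() -> DailyTransition:
    """Identity dynamics: every compartment unchanged day to day."""
    return DailyTransition.from_vector([1, 0, 1, 0, 0, 1, 1, 0, 1, 1])


@pytest.fixture
def feasible_d() -> DailyTransition:
    """A parameter set strictly inside the penalty box (d1_33 in [1, 1.2])."""
    return DailyTransition(
        d1_11=0.9, d1_21=0.05, d1_22=0.95, d1_31=0.01, d1_32=0.02, d1_33=1.01,
        d0_11=1.05, d0_12=0.05, d0_22=0.95, d0_33=0.9,
    )


def diagonal_d(on_diag, off_diag) -> DailyTransition:
    a, b, c = on_diag
    p, q, r = off_diag
    return DailyTransition.from_vector([a, 0, b, 0, 0, c, p, 0, q, r])


def make_series(times, psa, intervals, patient_id="T") -> PSASeries:
    return PSASeries(
        patient_id=patient_id,
        times=np.asarray(times, dtype=int),
        psa=np.asarray(psa, dtype=float),
        intervals=tuple(intervals),
    )


@pytest.fixture
def two_cycle_series() -> PSASeries:
    """A small alternating on/off history with observations in every interval."""
    intervals = [(0, 100, True), (100, 200, False), (200, 300, True),
                 (300, 400, False), (400, 500, True), (500, 600, False),
                 (600, 700, True)]
    times = [0, 50, 120, 210, 320, 450, 520, 650]
    psa = [10.0, 5.0, 2.0, 4.0, 1.5, 1.0, 2.5, 0.8]
    return make_series(times, psa, intervals)
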