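import numpy as np
import pytest

from pippk import (
    InfusionEvent,
    InfusionSchedule,
    PKParameters,
)


@pytest.fixture
def single_infusion():
    """4 g over 4 h starting at t=0, 48 h horizon."""
    return InfusionSchedule((InfusionEvent(0.0, 4.0, 4000.0),), horizon=48.0)


@pytest.fixture
def q8h_extended():
    """4 g / 4 h q8h for 48 h."""
    events = tuple(InfusionEvent(t, 4.0, 4000.0) for t in (0, 8, 16, 24, 32, 40))
    return InfusionSchedule(events, horizon=48.0)


@pytest.fixture
def mid_params():
    """CL = 10 L/h at CrCl 10 L/h, Vc = 20 L."""
    return PKParameters(intercept=0.0, slope=1.0, vc=20.0)


def random_schedule(rng: np.random.Generator) -> InfusionSchedule:
    """A small random multi-event schedule (overlaps allowed)."""
    n = rng.integers(1, 5)
    events = []
    for _ in range(n):
        start = rng.uniform(0.0, 30.0)
        dur = rng.uniform(0.25, 6.0)
        dose = rng.uniform(500.0, 6000.0)
        events.append(InfusionEvent(start, dur, dose))
    return InfusionSchedule(tuple(events), horizon=48.0)


def random_params(rng: np.random.Generator) -> PKParameters:
    return PKParameters(
        intercept=rng.uniform(0.5, 10.0),
        slope=rng.uniform(0.1, 3.0),
        vc=rng.uniform(5.0, 80.0),
    )
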