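import numpy as np
import pytest

from sleepspace import (
    Oscillation,
    SyntheticSpec,
    generate_hypnogram,
    generate_recording,
)


@pytest.fixture(scope="session")
def night():
    """One 90-minute synthetic subject with a 48-s C3/C4 oscillation."""
    spec = SyntheticSpec(
        duration=5400.0,
        seed=1,
        oscillation=Oscillation(pair=("C3", "C4"), period_s=48.0, depth=0.5),
    )
    hyp = generate_hypnogram(spec)
    rec = generate_recording(spec, hyp)
    return rec, hyp


@pytest.fixture(scope="session")
def cohort6():
    """Six independent 90-minute subjects from the default generative model."""
    from sleepspace import make_cohort

    return make_cohort(6, duration=5400.0, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)
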