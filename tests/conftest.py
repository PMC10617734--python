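import numpy as np
import pytest

from tidecycle.types import ActivityRecord


def make_record(
    counts,
    animal_id: str = "a1",
    start_ct: float = 96.0,
    bin_width_h: float = 0.5,
    **kw,
) -> ActivityRecord:
    return ActivityRecord(animal_id=animal_id, counts=np.asarray(counts),
                          start_ct=start_ct, bin_width_h=bin_width_h, **kw)


def cosine_record(
    period_h: float = 12.4,
    days: float = 8.0,
    amplitude: float = 50.0,
    baseline: float = 50.0,
    bin_width_h: float = 0.5,
    start_ct: float = 96.0,
    phase: float = 0.0,
    noise_rng=None,
) -> ActivityRecord:
    """Noiseless (or Poisson-noisy) discretised cosine activity record."""
    n = int(round(days * 24 / bin_width_h))
    t = np.arange(n) * bin_width_h
    lam = baseline + amplitude * np.cos(2 * np.pi * t / period_h + phase)
    lam = np.maximum(lam, 0)
    if noise_rng is None:
        counts = np.round(lam).astype(int)
    else:
        counts = noise_rng.poisson(lam)
    return make_record(counts, start_ct=start_ct, bin_width_h=bin_width_h)


@pytest.fixture
def rng():
    return np.random.default_rng(20160914)
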