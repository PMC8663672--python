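import numpy as np
import pytest

from biocue.hrstream import HeartRateSample
from biocue.baseline import BaselineModel


def make_stream(bpms, t0=0.0, cadence=20.0, reliable=None):
    """Samples at a fixed cadence from a bpm sequence."""
    if reliable is None:
        reliable = [True] * len(bpms)
    return [
        HeartRateSample(t=t0 + i * cadence, bpm=float(b), reliable=bool(r))
        for i, (b, r) in enumerate(zip(bpms, reliable))
    ]


@pytest.fixture
def constant_stream():
    """250 reliable samples at 70 bpm, exact 20-s cadence."""
    return make_stream([70.0] * 250)


@pytest.fixture
def baseline70():
    """Calibrated constant baseline: mean 70 bpm, SD floored to 1.0."""
    return BaselineModel(
        mean_bpm=70.0, sd_bpm=1.0, raw_sd_bpm=0.0, n_samples=200,
        interval_s=20.0, started_at=0.0, completed_at=199 * 20.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
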