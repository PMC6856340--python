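import numpy as np
import pytest

from swaymetrics.signal import SSD_OFF, CopTrial, DirectionalSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_trial(ap, ml, fs=100.0, subject="S01", condition=SSD_OFF, index=1,
               preprocessed=False):
    ap = np.asarray(ap, dtype=float)
    t = np.arange(len(ap)) / fs
    return CopTrial(
        subject_id=subject, condition=condition, trial_index=index,
        fs=fs, t=t, ap=ap, ml=np.asarray(ml, dtype=float),
        preprocessed=preprocessed,
    )


@pytest.fixture
def random_trial(rng):
    """A 30 s bounded random sway trial at 100 Hz (AR(1) channels)."""
    n = 3000
    ap = np.empty(n)
    ml = np.empty(n)
    ap[0] = ml[0] = 0.0
    wa = rng.normal(0, 0.5, n)
    wm = rng.normal(0, 0.5, n)
    for i in range(1, n):
        ap[i] = 0.99 * ap[i - 1] + wa[i]
        ml[i] = 0.99 * ml[i - 1] + wm[i]
    return make_trial(ap, ml)


def make_series(x, direction="AP", fs=100.0):
    return DirectionalSeries(direction=direction, fs=fs, x=np.asarray(x, float))
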