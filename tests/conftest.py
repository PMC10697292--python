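import numpy as np
import pytest

from copreact.epochs import OnsetEvent, PerturbationEpoch, subtract_baseline
from copreact.synthetic import response_curve

FS = 100.0


def sample_grid(t_pre=-0.4, t_post=2.0, fs=FS):
    """Epoch time grid hitting 0 exactly at the onset sample."""
    return np.round(np.arange(round(t_pre * fs), round(t_post * fs) + 1)) / fs


def make_epoch(ml, ap=None, fs=FS, t_pre=-0.4, t_post=2.0, corrected=False):
    t = sample_grid(t_pre, t_post, fs)
    ml = np.broadcast_to(np.asarray(ml, float), t.shape).copy()
    ap = ml.copy() if ap is None else np.broadcast_to(np.asarray(ap, float), t.shape).copy()
    ep = PerturbationEpoch(
        rel_time=t,
        cop_ml=ml,
        cop_ap=ap,
        fs=fs,
        onset=OnsetEvent(sample_index=int(round(-t_pre * fs)), time_s=-t_pre),
    )
    return subtract_baseline(ep) if corrected else ep


@pytest.fixture
def closed_form_epoch():
    """Noiseless analytic response epoch: A = 12 mm, tau = 0.15 s, AP = ML / 2."""
    t = sample_grid()
    x = response_curve(t, 12.0, 0.15)
    return make_epoch(x, 0.5 * x, corrected=True)


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)
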