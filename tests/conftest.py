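"""Shared fixtures: small simulated sessions reused across test modules."""

import numpy as np
import pytest
from scipy import signal as sps

from lfpdecode import SimConfig, simulate_session


@pytest.fixture(scope="session")
def strong_session():
    """A session with pronounced beta ERD / gamma ERS, modest trial counts."""
    cfg = SimConfig(
        n_left=25, n_right=25, n_rest=25, seed=11,
        band_modulation={"low_beta": 0.4, "high_beta": 0.4,
                         "low_gamma": 1.3, "high_gamma": 1.2},
    )
    return cfg, simulate_session(cfg)


@pytest.fixture(scope="session")
def null_session():
    """A session with all modulation switched off (noise + carriers only)."""
    cfg = SimConfig(n_left=25, n_right=25, n_rest=1, seed=5).null()
    return cfg, simulate_session(cfg)


def envelope_ratio_oracle(session, f_lo, f_hi, *, side="contra", per_trial=False):
    """Independent ERD/ERS estimate: Butterworth band-pass + Hilbert envelope.

    Mean envelope 0..350 ms post-response divided by the 1-2 s pre-response
    baseline, averaged over movement trials.  'side' picks the channel
    relative to the cued hand.
    """
    fs = session.fs
    sos = sps.butter(4, [f_lo / (fs / 2), f_hi / (fs / 2)], btype="band", output="sos")
    env = {
        "left": np.abs(sps.hilbert(sps.sosfiltfilt(sos, session.left))),
        "right": np.abs(sps.hilbert(sps.sosfiltfilt(sos, session.right))),
    }
    ratios = []
    for ev in session.events:
        if ev.label == "rest":
            continue
        contra_chan = "right" if ev.label == "left" else "left"
        chan = contra_chan if side == "contra" else ("left" if contra_chan == "right" else "right")
        e = env[chan]
        tr = ev.response_time_s
        i0, i1 = int(tr * fs), int((tr + 0.35) * fs)
        b0, b1 = int((tr - 2.0) * fs), int((tr - 1.0) * fs)
        ratios.append(e[i0:i1].mean() / e[b0:b1].mean())
    return np.asarray(ratios) if per_trial else float(np.mean(ratios))
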