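"""Simulate a bilateral deep-brain LFP session and verify its ground truth.

Generates a cued finger-movement protocol with beta-band desynchronization
(gain 0.5 on the contralateral channel) and re-measures that modulation from
the raw signal with an independent band-pass + Hilbert estimate.
"""

import numpy as np
from scipy import signal as sps

from lfpdecode import SimConfig, session_trial_summary, simulate_session

cfg = SimConfig(
    n_left=30, n_right=30, n_rest=30, seed=7,
    band_modulation={"low_beta": 0.5, "high_beta": 0.5},
)
session = simulate_session(cfg)

print("session:", f"{session.duration_s:.0f} s at {session.fs:g} Hz,",
      len(session.events), "events")
print("trial summary:", session_trial_summary(session))

# re-measure the configured beta ERD: mean 13-32 Hz envelope 0-350 ms after
# the motor response, relative to the 1-2 s pre-response baseline, on the
# channel contralateral to the cued hand
sos = sps.butter(4, [13 / 1000, 32 / 1000], btype="band", output="sos")
env = {c: np.abs(sps.hilbert(sps.sosfiltfilt(sos, getattr(session, c))))
       for c in ("left", "right")}
ratios = []
for ev in session.events:
    if ev.label == "rest":
        continue
    e = env["right" if ev.label == "left" else "left"]
    tr, fs = ev.response_time_s, session.fs
    post = e[int(tr * fs): int((tr + 0.35) * fs)].mean()
    base = e[int((tr - 2) * fs): int((tr - 1) * fs)].mean()
    ratios.append(post / base)

print(f"measured contralateral beta envelope ratio: {np.mean(ratios):.3f} "
      f"(configured gain 0.5)")
print("a ratio below 1 is event-related desynchronization; the small excess "
      "over 0.5 is the expected bias from unmodulated background noise "
      "inside the beta band.")
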