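"""Raw LFP conditioning: zero-phase low-pass, 50 Hz notch, resample to 256 Hz.

All filters are applied forward-backward (``sosfiltfilt``/``filtfilt``) so the
net phase shift is zero and event times keep their meaning: an event at
``t`` seconds indexes sample ``round(t * 256)`` after the full pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .errors import SamplingRateError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessParams:
    """Filter and resampling settings.

    The Chebyshev order/ripple are chosen so the forward-backward response
    keeps the passband flat to better than 1% while attenuating 120 Hz by
    more than 40 dB: order 7 (odd, so DC gain is exactly 1) with 0.05 dB
    passband ripple.
    """

    lowpass_cutoff_hz: float = 90.0
    lowpass_family: str = "cheby1"
    chebyshev_ripple_db: float = 0.05
    filter_order: int = 7
    notch_hz: float = 50.0
    notch_q: float = 30.0
    target_fs_hz: float = 256.0


def lowpass_zero_phase(signal: np.ndarray, fs: float,
                       params: PreprocessParams = PreprocessParams()) -> np.ndarray:
    """Type-I Chebyshev low-pass at 90 Hz, applied forward-backward."""
    if fs <= 2 * params.lowpass_cutoff_hz:
        raise SamplingRateError(
            f"fs={fs} Hz too low for a {params.lowpass_cutoff_hz} Hz low-pass"
        )
    sos = sps.cheby1(params.filter_order, params.chebyshev_ripple_db,
                     params.lowpass_cutoff_hz, btype="low", fs=fs, output="sos")
    log.info("lowpass: cheby1 order=%d ripple=%gdB cutoff=%gHz (zero-phase)",
             params.filter_order, params.chebyshev_ripple_db, params.lowpass_cutoff_hz)
    return sps.sosfiltfilt(sos, np.asarray(signal, dtype=float))


def notch_50(signal: np.ndarray, fs: float,
             params: PreprocessParams = PreprocessParams()) -> np.ndarray:
    """Second-order IIR notch at 50 Hz (Q=30), applied forward-backward."""
    if fs <= 100.0:
        raise SamplingRateError(f"fs={fs} Hz too low for a {params.notch_hz} Hz notch")
    b, a = sps.iirnotch(params.notch_hz, params.notch_q, fs=fs)
    log.info("notch: %gHz Q=%g (zero-phase)", params.notch_hz, params.notch_q)
    return sps.filtfilt(b, a, np.asarray(signal, dtype=float))


def resample_to_256(signal: np.ndarray, fs_in: float,
                    params: PreprocessParams = PreprocessParams()) -> np.ndarray:
    """Polyphase rational resampling down to 256 Hz (anti-aliased).

    Output length is round(len * 256 / fs_in); upsampling is not supported.
    """
    target = params.target_fs_hz
    if fs_in < target:
        raise SamplingRateError(
            f"fs_in={fs_in} Hz is below the target {target} Hz; upsampling unsupported"
        )
    x = np.asarray(signal, dtype=float)
    if fs_in == target:
        return x.copy()
    frac = Fraction(target / fs_in).limit_denominator(10000)
    up, down = frac.numerator, frac.denominator
    log.info("resample: %gHz -> %gHz (polyphase %d/%d)", fs_in, target, up, down)
    y = sps.resample_poly(x, up, down)
    m = int(round(len(x) * target / fs_in))
    return y[:m] if len(y) >= m else np.pad(y, (0, m - len(y)))


def preprocess_channel(signal: np.ndarray, fs: float,
                       params: PreprocessParams = PreprocessParams()) -> np.ndarray:
    """Low-pass → notch → resample, the full conditioning chain."""
    x = lowpass_zero_phase(signal, fs, params)
    x = notch_50(x, fs, params)
    return resample_to_256(x, fs, params)
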