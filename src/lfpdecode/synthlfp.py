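"""Synthetic bilateral LFP sessions with controlled band-specific ERD/ERS.

The generator emulates a cued finger-pressing protocol recorded from two
bipolar deep-brain channels (left and right STN/GPI): a visual cue appears,
the subject presses a left or right key ~half a second later, and the
band-limited oscillatory amplitude around the motor response is modulated —
beta-band desynchronization (ERD), gamma-band synchronization (ERS), and a
transient delta surge at movement onset — more strongly on the channel
contralateral to the moving hand.  Rest trials carry a cue but no response
and no modulation.

Each band oscillation is amplitude-modulated narrowband Gaussian noise
(band-pass-filtered white noise), not a sinusoid, so envelope statistics are
nondegenerate; on top sit a 1/f background and 50 Hz line interference.
All randomness flows from one integer seed: identical config + seed gives a
bit-identical session.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .bandfeat import BAND_NAMES, NOMINAL_EDGES
from .errors import ConfigurationError, SignalLengthError

#: default per-band carrier RMS amplitudes (arbitrary voltage-like units);
#: amplitude falls with frequency as in real LFP spectra
DEFAULT_BAND_AMP: dict[str, float] = {
    "delta": 1.0,
    "theta": 0.8,
    "alpha": 0.7,
    "low_beta": 0.6,
    "high_beta": 0.5,
    "low_gamma": 0.3,
    "high_gamma": 0.2,
}

#: default movement-locked contralateral envelope gains: beta ERD, gamma ERS
DEFAULT_BAND_MODULATION: dict[str, float] = {
    "delta": 1.0,
    "theta": 1.0,
    "alpha": 1.0,
    "low_beta": 0.6,
    "high_beta": 0.7,
    "low_gamma": 1.3,
    "high_gamma": 1.2,
}


@dataclass(frozen=True)
class SimConfig:
    """Everything that defines one simulated recording session."""

    fs_raw: float = 2000.0
    n_left: int = 58
    n_right: int = 58
    n_rest: int = 58
    #: per-band multiplicative envelope gain on the *contralateral* channel
    #: during movement (<1 = ERD, >1 = ERS); ipsilateral modulation depth is
    #: divided by ``laterality_contrast``
    band_modulation: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_MODULATION)
    )
    laterality_contrast: float = 2.0
    #: relative delta-envelope surge at the motor response (0 disables)
    delta_burst_amp: float = 1.5
    noise_exponent: float = -1.0  # power-spectral slope of the background
    noise_amp: float = 0.5  # background RMS
    line_amp: float = 0.2  # 50 Hz interference amplitude
    inter_event_gap_s: tuple[float, float] = (1.0, 5.0)
    reaction_time_s: tuple[float, float] = (0.5, 0.08)  # mean, sd (clipped 0.25..0.8)
    band_base_amp: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BAND_AMP))
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_left", "n_right", "n_rest"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.fs_raw <= 180.0:
            raise ConfigurationError(f"fs_raw must exceed 2 x 90 Hz, got {self.fs_raw}")
        for band, g in self.band_modulation.items():
            if band not in BAND_NAMES:
                raise ConfigurationError(f"band_modulation: unknown band {band!r}")
            if g <= 0:
                raise ConfigurationError(f"band_modulation[{band!r}] must be > 0, got {g}")
        if self.laterality_contrast <= 0:
            raise ConfigurationError(
                f"laterality_contrast must be > 0, got {self.laterality_contrast}"
            )
        if self.delta_burst_amp < 0:
            raise ConfigurationError(f"delta_burst_amp must be >= 0, got {self.delta_burst_amp}")
        if self.noise_amp < 0:
            raise ConfigurationError(f"noise_amp must be >= 0, got {self.noise_amp}")
        if self.line_amp < 0:
            raise ConfigurationError(f"line_amp must be >= 0, got {self.line_amp}")
        lo, hi = self.inter_event_gap_s
        if not (1.0 <= lo <= hi <= 5.0):
            raise ConfigurationError(
                f"inter_event_gap_s must lie within [1, 5] s with lo <= hi, got {self.inter_event_gap_s}"
            )
        for band, a in self.band_base_amp.items():
            if band not in BAND_NAMES:
                raise ConfigurationError(f"band_base_amp: unknown band {band!r}")
            if a < 0:
                raise ConfigurationError(f"band_base_amp[{band!r}] must be >= 0, got {a}")

    def null(self) -> "SimConfig":
        """A copy with all movement-locked modulation switched off."""
        return replace(
            self,
            band_modulation={b: 1.0 for b in BAND_NAMES},
            delta_burst_amp=0.0,
        )


@dataclass(frozen=True)
class EventRecord:
    """One trial: cue onset, motor response (movement trials only), label."""

    stimulus_time_s: float
    response_time_s: float | None
    label: str  # 'rest' | 'left' | 'right'

    def __post_init__(self):
        if self.label not in ("rest", "left", "right"):
            raise ConfigurationError(f"label must be rest/left/right, got {self.label!r}")
        if self.label == "rest":
            if self.response_time_s is not None:
                raise ConfigurationError("rest events carry stimulus_time_s only")
        else:
            if self.response_time_s is None or self.response_time_s <= self.stimulus_time_s:
                raise ConfigurationError(
                    "movement events need response_time_s > stimulus_time_s"
                )


@dataclass
class LfpSession:
    """Two bipolar channels plus the event table for one recording."""

    left: np.ndarray
    right: np.ndarray
    fs: float
    events: list[EventRecord]

    def __post_init__(self):
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        if self.left.shape != self.right.shape or self.left.ndim != 1:
            raise SignalLengthError("channels must be 1-D and of equal length")
        if self.fs <= 0:
            raise ConfigurationError(f"fs must be > 0, got {self.fs}")
        times = [e.stimulus_time_s for e in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ConfigurationError("event times must be strictly increasing")
        dur = len(self.left) / self.fs
        if times and (times[0] < 0 or times[-1] > dur):
            raise ConfigurationError("event times must lie inside the recording")

    @property
    def duration_s(self) -> float:
        return len(self.left) / self.fs


# ---------------------------------------------------------------------------
# signal building blocks
# ---------------------------------------------------------------------------


def _powerlaw_noise(n: int, fs: float, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with power spectrum S(f) ~ f**exponent, unit variance."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    f[0] = f[1] if n > 1 else 1.0  # avoid the DC singularity
    spec *= f ** (exponent / 2.0)
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _band_carrier(n: int, fs: float, f_lo: float, f_hi: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS narrowband Gaussian noise in [f_lo, f_hi] Hz."""
    white = rng.standard_normal(n)
    nyq = fs / 2
    hi = min(f_hi, 0.99 * nyq)
    if f_lo <= 0:
        sos = sps.butter(4, hi / nyq, btype="low", output="sos")
    else:
        sos = sps.butter(4, [f_lo / nyq, hi / nyq], btype="band", output="sos")
    x = sps.sosfiltfilt(sos, white)
    sd = x.std()
    return x / sd if sd > 0 else x


def _modulation_profile(t: np.ndarray, response_t: float) -> np.ndarray:
    """Raised-cosine ERD/ERS time course in [0, 1].

    Rises over 200 ms starting 150 ms before the response, holds at 1 for
    500 ms, and falls back over 200 ms — so the -150..+350 ms feature
    windows sit on the modulated segment.
    """
    rise, hold = 0.2, 0.5
    u = t - (response_t - 0.15)
    w = np.zeros_like(t)
    m = (u >= 0) & (u < rise)
    w[m] = 0.5 * (1 - np.cos(np.pi * u[m] / rise))
    m = (u >= rise) & (u < rise + hold)
    w[m] = 1.0
    m = (u >= rise + hold) & (u < 2 * rise + hold)
    w[m] = 0.5 * (1 + np.cos(np.pi * (u[m] - rise - hold) / rise))
    return w


def _gaussian_bump(t: np.ndarray, center: float, sigma: float = 0.15) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / sigma) ** 2)


# ---------------------------------------------------------------------------
# session generation
# ---------------------------------------------------------------------------

_PAD_S = 4.0  # recording padding before the first and after the last event


def simulate_session(config: SimConfig) -> LfpSession:
    """Generate one bilateral session per the configured protocol.

    Movement trials multiply each band's carrier envelope by the configured
    gain on the contralateral channel (ipsilateral modulation depth reduced
    by ``laterality_contrast``); rest trials leave all carriers untouched.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.fs_raw

    labels = ["left"] * config.n_left + ["right"] * config.n_right + ["rest"] * config.n_rest
    labels = [labels[i] for i in rng.permutation(len(labels))]

    gaps = rng.uniform(*config.inter_event_gap_s, size=len(labels))
    stim_times = _PAD_S + np.concatenate(([0.0], np.cumsum(gaps[:-1])))
    rt_mean, rt_sd = config.reaction_time_s
    rts = np.clip(rng.normal(rt_mean, rt_sd, size=len(labels)), 0.25, 0.8)

    events: list[EventRecord] = []
    for lab, st, rt in zip(labels, stim_times, rts):
        resp = None if lab == "rest" else float(st + rt)
        events.append(EventRecord(float(st), resp, lab))

    duration = stim_times[-1] + _PAD_S
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    channels = {}
    for side in ("left", "right"):  # anatomical hemisphere of the electrode
        x = config.noise_amp * _powerlaw_noise(n, fs, config.noise_exponent, rng)
        x += config.line_amp * np.sin(2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi))
        for band in BAND_NAMES:
            carrier = _band_carrier(n, fs, *NOMINAL_EDGES[band], rng)
            gain = np.ones(n)
            g_contra = config.band_modulation.get(band, 1.0)
            for ev in events:
                if ev.label == "rest":
                    continue
                contra = (ev.label == "left") == (side == "right")
                depth = (g_contra - 1.0) if contra else (g_contra - 1.0) / config.laterality_contrast
                if depth != 0.0:
                    gain *= 1.0 + depth * _modulation_profile(t, ev.response_time_s)
                if band == "delta" and config.delta_burst_amp > 0:
                    gain *= 1.0 + config.delta_burst_amp * _gaussian_bump(t, ev.response_time_s)
            x = x + config.band_base_amp.get(band, 0.0) * gain * carrier
        channels[side] = x

    return LfpSession(left=channels["left"], right=channels["right"], fs=fs, events=events)


def session_trial_summary(session: LfpSession) -> dict:
    """Per-class trial counts and the left/right imbalance fraction."""
    if not session.events:
        raise SignalLengthError("session has no events")
    counts = {"left": 0, "right": 0, "rest": 0}
    for ev in session.events:
        counts[ev.label] += 1
    n_l, n_r = counts["left"], counts["right"]
    imbalance = abs(n_l - n_r) / (n_l + n_r) if (n_l + n_r) else float("nan")
    return {
        "n_left": n_l,
        "n_right": n_r,
        "n_rest": counts["rest"],
        "total": len(session.events),
        "imbalance": imbalance,
    }
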