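"""Band-limited feature extraction from preprocessed (256 Hz) LFP.

Each channel is decomposed with a level-5 wavelet packet transform (WPT,
discrete Meyer wavelet) into 32 terminal nodes of 4 Hz each; frequency-ordered
nodes are grouped into the seven canonical LFP bands, the instantaneous
amplitude of each band is taken as the magnitude of the analytic signal
(Hilbert envelope), and per-trial features are the mean envelope in five
consecutive 100 ms windows around the behavioural anchor.  Two channels x
7 bands x 5 windows = 70 features per trial.

Band edges snap to the 4 Hz dyadic grid: the 12-13 Hz sliver is indivisible
at this resolution and is assigned to low beta (keeping the analysis-critical
beta range intact), and high gamma runs to 92 Hz (the node containing 90 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy.signal import hilbert

from .errors import BoundaryError, EpochExcludedError, SignalLengthError

FEATURE_FS = 256.0
WPT_LEVEL = 5
#: width in Hz of one terminal WPT node at 256 Hz, level 5
NODE_WIDTH_HZ = FEATURE_FS / 2 / 2**WPT_LEVEL  # = 4 Hz

SIDES = ("left_channel", "right_channel")


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band and the terminal WPT nodes that realize it.

    ``wpt_nodes`` are indices into the *frequency-ordered* list of level-5
    terminal nodes (node k covers [4k, 4k+4) Hz at 256 Hz).
    """

    name: str
    f_lo: float
    f_hi: float
    wpt_nodes: tuple[int, ...]


#: The seven analysis bands.  Nominal edges follow the standard LFP
#: nomenclature (delta 0-4, theta 4-8, alpha 8-12, low beta 13-20,
#: high beta 20-32, low gamma 32-60, high gamma 60-90); realized edges
#: snap to the 4 Hz node grid as documented in the module docstring.
BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.0, 4.0, (0,)),
    BandDefinition("theta", 4.0, 8.0, (1,)),
    BandDefinition("alpha", 8.0, 12.0, (2,)),
    BandDefinition("low_beta", 13.0, 20.0, (3, 4)),
    BandDefinition("high_beta", 20.0, 32.0, (5, 6, 7)),
    BandDefinition("low_gamma", 32.0, 60.0, (8, 9, 10, 11, 12, 13, 14)),
    BandDefinition("high_gamma", 60.0, 90.0, tuple(range(15, 23))),
)

BAND_NAMES: tuple[str, ...] = tuple(b.name for b in BANDS)

#: nominal band edges, used e.g. by the simulator to synthesize carriers
NOMINAL_EDGES: dict[str, tuple[float, float]] = {b.name: (b.f_lo, b.f_hi) for b in BANDS}

#: frequency-ordered node edges actually realized by each band
def realized_edges(band: BandDefinition) -> tuple[float, float]:
    lo = min(band.wpt_nodes) * NODE_WIDTH_HZ
    hi = (max(band.wpt_nodes) + 1) * NODE_WIDTH_HZ
    return lo, hi


@dataclass(frozen=True)
class EpochSpec:
    """Epoch geometry: anchor event field, half-width, and feature windows.

    ``feature_windows`` are five contiguous half-open 100 ms intervals
    (seconds relative to the anchor).
    """

    anchor: str  # 'response' or 'stimulus'
    half_width_s: float
    feature_windows: tuple[tuple[float, float], ...]

    def __post_init__(self):
        if len(self.feature_windows) != 5:
            raise ValueError("feature_windows: exactly 5 windows required")
        for (lo, hi) in self.feature_windows:
            if abs((hi - lo) - 0.1) > 1e-9:
                raise ValueError("feature_windows: each window must be 100 ms")


def _contiguous(edges: tuple[float, ...]) -> tuple[tuple[float, float], ...]:
    return tuple((edges[i], edges[i + 1]) for i in range(len(edges) - 1))


#: movement trials: 4 s epoch around the motor response, features from
#: five 100 ms windows spanning -150 .. +350 ms
MOVEMENT_SPEC = EpochSpec(
    anchor="response",
    half_width_s=2.0,
    feature_windows=_contiguous((-0.15, -0.05, 0.05, 0.15, 0.25, 0.35)),
)

#: rest trials: 2 s epoch around the stimulus, features from the
#: pre-stimulus baseline -750 .. -250 ms
REST_SPEC = EpochSpec(
    anchor="stimulus",
    half_width_s=1.0,
    feature_windows=_contiguous((-0.75, -0.65, -0.55, -0.45, -0.35, -0.25)),
)


N_FEATURES = len(SIDES) * len(BANDS) * 5


def feature_names() -> list[str]:
    """Ordered names of the 70 features: side x band x window."""
    names = []
    for side in SIDES:
        for band in BAND_NAMES:
            for w in range(1, 6):
                names.append(f"{side}_{band}_w{w}")
    return names


@dataclass
class FeatureVector:
    """70 ordered mean-envelope features for one trial."""

    values: np.ndarray
    label: str
    trial_id: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_FEATURES,):
            raise ValueError(f"FeatureVector needs {N_FEATURES} values, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("FeatureVector values must be finite")
        if np.any(self.values < 0):
            raise ValueError("FeatureVector values are envelope means and must be >= 0")


# ---------------------------------------------------------------------------
# wavelet packet decomposition
# ---------------------------------------------------------------------------


def _meyer_nu(x: np.ndarray) -> np.ndarray:
    """The C^3 Meyer auxiliary polynomial on [0, 1]."""
    x = np.clip(x, 0.0, 1.0)
    return x**4 * (35 - 84 * x + 70 * x**2 - 20 * x**3)


def _meyer_fir(n_taps: int = 160, grid: int = 2**16) -> np.ndarray:
    """FIR truncation of the ideal discrete Meyer conjugate mirror filter.

    The Meyer scaling symbol H(w) = sqrt(2) * phi_hat(2w) is sampled on a
    dense frequency grid, inverted by FFT and truncated to ``n_taps``
    centered coefficients.  160 taps keep the filter-bank reconstruction
    error of a level-5 packet tree near 1e-7 (shorter truncations of the
    Meyer filter reconstruct only to ~1e-5..1e-2).
    """
    w = np.fft.fftfreq(grid) * 2 * np.pi
    two = np.abs(2 * w)
    phihat = np.where(
        two <= 2 * np.pi / 3,
        1.0,
        np.where(two <= 4 * np.pi / 3,
                 np.cos(np.pi / 2 * _meyer_nu(3 * two / (2 * np.pi) - 1)), 0.0),
    )
    h = np.real(np.fft.ifft(np.sqrt(2) * phihat))
    return np.concatenate([h[-(n_taps // 2):], h[: n_taps - n_taps // 2]])


def _meyer_wavelet() -> pywt.Wavelet:
    h = _meyer_fir()
    g = np.array([(-1) ** k for k in range(len(h))]) * h[::-1]
    fb = [list(h[::-1]), list(g[::-1]), list(h), list(g)]
    return pywt.Wavelet("meyer_fir", filter_bank=fb)


_WAVELET = _meyer_wavelet()


def _decompose_tree(x: np.ndarray) -> tuple[pywt.WaveletPacket, list]:
    wp = pywt.WaveletPacket(data=x, wavelet=_WAVELET, mode="symmetric", maxlevel=WPT_LEVEL)
    nodes = wp.get_level(WPT_LEVEL, order="freq")  # frequency (sequency) ordered
    return wp, nodes


def _reconstruct_nodes(wp, nodes, keep: set[int], n: int) -> np.ndarray:
    """Inverse transform with all terminal nodes outside ``keep`` zeroed."""
    saved = [nd.data for nd in nodes]
    try:
        for k, nd in enumerate(nodes):
            if k not in keep:
                nd.data = np.zeros_like(saved[k])
        return np.asarray(wp.reconstruct(update=False))[:n]
    finally:
        for nd, data in zip(nodes, saved):
            nd.data = data


def wpt_band_decompose(
    signal: np.ndarray, *, return_residual: bool = False
) -> dict[str, np.ndarray]:
    """Split a 256 Hz signal into the 7 band-limited time series.

    Each band is the joint reconstruction of its frequency-ordered terminal
    WPT nodes (all other nodes zeroed).  With ``return_residual`` the
    reconstruction of the unassigned 92-128 Hz nodes is returned under key
    ``"_residual"``; band signals plus residual sum back to the input to
    numerical precision.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise SignalLengthError("wpt_band_decompose expects a 1-D signal")
    if len(x) < 2**WPT_LEVEL:
        raise SignalLengthError(
            f"signal too short for level-{WPT_LEVEL} WPT: {len(x)} < {2 ** WPT_LEVEL} samples"
        )
    wp, nodes = _decompose_tree(x)
    out: dict[str, np.ndarray] = {}
    for band in BANDS:
        out[band.name] = _reconstruct_nodes(wp, nodes, set(band.wpt_nodes), len(x))
    if return_residual:
        assigned = {k for b in BANDS for k in b.wpt_nodes}
        rest = set(range(2**WPT_LEVEL)) - assigned
        out["_residual"] = _reconstruct_nodes(wp, nodes, rest, len(x))
    return out


def hilbert_envelope(band_signal: np.ndarray) -> np.ndarray:
    """Instantaneous amplitude: magnitude of the analytic signal."""
    x = np.asarray(band_signal, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("hilbert_envelope: signal must be finite")
    return np.abs(hilbert(x))


def band_envelopes(left: np.ndarray, right: np.ndarray) -> np.ndarray:
    """Envelope block for a whole session: shape (2 sides, 7 bands, n).

    Envelopes are computed over the full recording (not per epoch) so that
    Hilbert edge artifacts stay at the recording boundaries.
    """
    if len(left) != len(right):
        raise SignalLengthError("band_envelopes: channels must have equal length")
    out = np.empty((2, len(BANDS), len(left)))
    for s, chan in enumerate((left, right)):
        bands = wpt_band_decompose(chan)
        for b, name in enumerate(BAND_NAMES):
            out[s, b] = hilbert_envelope(bands[name])
    return out


# ---------------------------------------------------------------------------
# epoching and feature extraction
# ---------------------------------------------------------------------------

#: valid closed range of consecutive inter-event onset gaps, seconds
INTER_EVENT_VALID_S = (1.0, 5.0)


@dataclass
class Epoch:
    """An envelope block cut around one event."""

    block: np.ndarray  # (2, 7, n_epoch)
    anchor_sample: int  # index of the anchor within the full envelope series
    start_sample: int  # index of block[..., 0] within the full series
    event: "object"
    excluded: bool = False
    exclusion_reason: str = ""


def _anchor_time(event, spec: EpochSpec) -> float:
    if spec.anchor == "response":
        t = getattr(event, "response_time_s", None)
        if t is None:
            raise BoundaryError(f"event at {event.stimulus_time_s:.3f}s has no response time")
        return t
    return event.stimulus_time_s


def segment_epoch(
    session_envelopes: np.ndarray,
    event,
    spec: EpochSpec,
    *,
    fs: float = FEATURE_FS,
    neighbor_onsets: tuple[float | None, float | None] = (None, None),
) -> Epoch:
    """Cut the epoch window around an event out of the session envelopes.

    ``neighbor_onsets`` are the stimulus-onset times of the previous and next
    events (None at the session edges); an epoch whose onset gap to either
    neighbor falls outside the 1-5 s validity range is flagged excluded
    rather than dropped, so callers can report exclusions.
    """
    env = np.asarray(session_envelopes)
    if env.ndim != 3 or env.shape[0] != 2 or env.shape[1] != len(BANDS):
        raise SignalLengthError("session_envelopes must have shape (2, 7, n)")
    n = env.shape[2]
    t0 = _anchor_time(event, spec)
    anchor = int(round(t0 * fs))
    half = int(round(spec.half_width_s * fs))
    start, stop = anchor - half, anchor + half
    if start < 0 or stop > n:
        raise BoundaryError(
            f"epoch for event at {t0:.3f}s (label={event.label}) spans samples "
            f"[{start}, {stop}) outside the recording of {n} samples"
        )
    excluded, reason = False, ""
    lo, hi = INTER_EVENT_VALID_S
    onset = event.stimulus_time_s
    for nb in neighbor_onsets:
        if nb is None:
            continue
        gap = abs(onset - nb)
        if not (lo <= gap <= hi):
            excluded = True
            reason = f"inter-event gap {gap:.3f}s outside [{lo}, {hi}]s"
            break
    return Epoch(
        block=env[:, :, start:stop],
        anchor_sample=anchor,
        start_sample=start,
        event=event,
        excluded=excluded,
        exclusion_reason=reason,
    )


def window_slices(spec: EpochSpec, *, fs: float = FEATURE_FS) -> list[tuple[int, int]]:
    """Half-open sample ranges of the five feature windows, relative to the anchor.

    A 100 ms window holds 25.6 samples at 256 Hz; the half-open rounding
    [round(t_lo*fs), round(t_hi*fs)) yields 25 or 26 samples per window.
    """
    return [(int(round(lo * fs)), int(round(hi * fs))) for lo, hi in spec.feature_windows]


def extract_features(epoch: Epoch, spec: EpochSpec, *, trial_id: int = -1) -> FeatureVector:
    """Mean envelope per side x band x window → 70-dim feature vector."""
    if epoch.excluded:
        raise EpochExcludedError(
            f"epoch for event at {epoch.event.stimulus_time_s:.3f}s excluded: "
            f"{epoch.exclusion_reason}"
        )
    rel_anchor = epoch.anchor_sample - epoch.start_sample
    vals = np.empty(N_FEATURES)
    i = 0
    for s in range(2):
        for b in range(len(BANDS)):
            for (a, z) in window_slices(spec):
                seg = epoch.block[s, b, rel_anchor + a : rel_anchor + z]
                if seg.size == 0:
                    raise BoundaryError("feature window outside epoch block")
                vals[i] = float(np.mean(seg))
                i += 1
    return FeatureVector(values=vals, label=epoch.event.label, trial_id=trial_id)


def sweep_window_centers(
    session_envelopes: np.ndarray,
    events: list,
    centers_s: list[float],
    *,
    width_s: float = 0.1,
    fs: float = FEATURE_FS,
) -> dict[float, np.ndarray]:
    """Exploratory sweep: mean movement-band envelope at varying window centers.

    For each candidate center (seconds relative to the motor response) the
    five contiguous windows of ``width_s`` are re-centred there and the mean
    feature matrix over the supplied movement events is returned.  The
    shipped default windows (-150..+350 ms) correspond to ``center=0.1``.
    """
    out = {}
    for c in centers_s:
        edges = tuple(c - 2.5 * width_s + k * width_s for k in range(6))
        spec = EpochSpec(anchor="response", half_width_s=2.0,
                         feature_windows=_contiguous(edges))
        rows = []
        for i, ev in enumerate(events):
            if ev.label not in ("left", "right"):
                continue
            ep = segment_epoch(session_envelopes, ev, spec, fs=fs)
            rows.append(extract_features(ep, spec, trial_id=i).values)
        out[c] = np.asarray(rows)
    return out
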