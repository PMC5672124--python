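"""Wavelet-packet band decomposition, envelopes, epoching and features."""

import numpy as np
import pytest

from lfpdecode.bandfeat import (BANDS, MOVEMENT_SPEC, N_FEATURES, REST_SPEC,
                                EpochSpec, FeatureVector, band_envelopes,
                                extract_features, feature_names, hilbert_envelope,
                                segment_epoch, sweep_window_centers,
                                window_slices, wpt_band_decompose)
from lfpdecode.errors import (BoundaryError, EpochExcludedError, SignalLengthError)
from lfpdecode.experiment import session_features
from lfpdecode.synthlfp import EventRecord

FS = 256.0


class TestBandPartition:
    def test_nodes_disjoint_and_cover_0_to_92(self):
        all_nodes = [k for b in BANDS for k in b.wpt_nodes]
        assert len(all_nodes) == len(set(all_nodes))
        assert sorted(all_nodes) == list(range(23))  # 23 nodes x 4 Hz = 0-92 Hz

    def test_band_names_order_and_feature_count(self):
        assert [b.name for b in BANDS] == [
            "delta", "theta", "alpha", "low_beta", "high_beta", "low_gamma", "high_gamma"
        ]
        assert N_FEATURES == 70
        assert len(feature_names()) == 70


class TestWptDecompose:
    def test_perfect_reconstruction(self):
        x = np.random.default_rng(0).standard_normal(2048)
        bands = wpt_band_decompose(x, return_residual=True)
        recon = sum(bands.values())
        assert np.linalg.norm(recon - x) / np.linalg.norm(x) <= 1e-6

    @pytest.mark.parametrize(
        "freq, band",
        [(10.0, "alpha"), (25.0, "high_beta"), (2.0, "delta"), (6.0, "theta"),
         (16.0, "low_beta"), (45.0, "low_gamma"), (78.0, "high_gamma")],
    )
    def test_pure_tone_energy_lands_in_band(self, freq, band):
        t = np.arange(4096) / FS
        x = np.sin(2 * np.pi * freq * t)
        out = wpt_band_decompose(x, return_residual=True)
        energies = {k: float(np.sum(v**2)) for k, v in out.items()}
        total = sum(energies.values())
        assert energies[band] / total >= 0.90
        # FFT oracle: the band signal's spectral mass sits at the tone
        spec = np.abs(np.fft.rfft(out[band])) ** 2
        f = np.fft.rfftfreq(len(x), 1 / FS)
        centroid = float(np.sum(f * spec) / np.sum(spec))
        assert abs(centroid - freq) < 4.0  # within one node width

    def test_zero_signal_zero_bands(self):
        out = wpt_band_decompose(np.zeros(256))
        for v in out.values():
            np.testing.assert_allclose(v, 0.0)

    def test_band_signals_keep_input_length(self):
        x = np.random.default_rng(1).standard_normal(1000)
        out = wpt_band_decompose(x)
        assert all(len(v) == 1000 for v in out.values())

    def test_too_short_signal(self):
        with pytest.raises(SignalLengthError):
            wpt_band_decompose(np.zeros(16))


class TestHilbertEnvelope:
    def test_sinusoid_amplitude(self):
        t = np.arange(2048) / FS
        env = hilbert_envelope(3.0 * np.sin(2 * np.pi * 20 * t))
        interior = env[102:-102]  # 5% taper excluded
        np.testing.assert_allclose(interior, 3.0, rtol=0.02)

    def test_zero_signal(self):
        np.testing.assert_allclose(hilbert_envelope(np.zeros(512)), 0.0)

    def test_envelope_dominates_signal(self):
        x = np.random.default_rng(2).standard_normal(1024)
        env = hilbert_envelope(x)
        assert np.all(env >= np.abs(x) - 1e-9)

    def test_tracks_slow_modulator(self):
        t = np.arange(4096) / FS
        A = 1.0 + 0.5 * np.sin(2 * np.pi * 0.5 * t)
        env = hilbert_envelope(A * np.sin(2 * np.pi * 20 * t))
        interior = slice(205, -205)
        np.testing.assert_allclose(env[interior], A[interior], rtol=0.05)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            hilbert_envelope(np.array([1.0, np.nan]))


def _env_block(n, value=1.0):
    return np.full((2, 7, n), value)


def _movement_event(t, label="left"):
    return EventRecord(t - 0.5, t, label)


class TestSegmentEpoch:
    def test_window_arithmetic(self):
        env = _env_block(int(20 * FS))
        ep = segment_epoch(env, _movement_event(10.0), MOVEMENT_SPEC)
        assert ep.block.shape == (2, 7, 1024)  # 4 s at 256 Hz
        assert not ep.excluded

    def test_rest_epoch_is_2s(self):
        env = _env_block(int(20 * FS))
        ev = EventRecord(10.0, None, "rest")
        ep = segment_epoch(env, ev, REST_SPEC)
        assert ep.block.shape == (2, 7, 512)

    def test_close_neighbor_flags_exclusion(self):
        env = _env_block(int(20 * FS))
        ep = segment_epoch(env, _movement_event(10.0), MOVEMENT_SPEC,
                           neighbor_onsets=(9.0, None))
        assert ep.excluded  # 0.5 s onset gap: 9.5 - 9.0
        ok = segment_epoch(env, _movement_event(10.0), MOVEMENT_SPEC,
                           neighbor_onsets=(7.5, 11.5))
        assert not ok.excluded

    def test_far_neighbor_flags_exclusion(self):
        env = _env_block(int(40 * FS))
        ep = segment_epoch(env, _movement_event(20.0), MOVEMENT_SPEC,
                           neighbor_onsets=(10.0, None))
        assert ep.excluded  # 9.5 s gap exceeds the 5 s validity bound

    def test_out_of_range_event_raises(self):
        env = _env_block(int(20 * FS))
        with pytest.raises(BoundaryError):
            segment_epoch(env, _movement_event(1.0), MOVEMENT_SPEC)


class TestExtractFeatures:
    def test_constant_envelope_gives_constant_features(self):
        env = _env_block(int(20 * FS), value=2.5)
        ep = segment_epoch(env, _movement_event(10.0), MOVEMENT_SPEC)
        fv = extract_features(ep, MOVEMENT_SPEC, trial_id=0)
        assert fv.values.shape == (70,)
        np.testing.assert_allclose(fv.values, 2.5)

    def test_excluded_epoch_raises(self):
        env = _env_block(int(20 * FS))
        ep = segment_epoch(env, _movement_event(10.0), MOVEMENT_SPEC,
                           neighbor_onsets=(9.2, None))
        with pytest.raises(EpochExcludedError):
            extract_features(ep, MOVEMENT_SPEC)

    def test_window_sample_counts(self):
        for a, z in window_slices(MOVEMENT_SPEC):
            assert z - a in (25, 26)  # 100 ms at 256 Hz

    def test_translation_consistency(self):
        rng = np.random.default_rng(3)
        env = rng.uniform(0.5, 1.5, size=(2, 7, int(30 * FS)))
        k = 37
        shifted = np.roll(env, k, axis=2)
        ev = _movement_event(10.0)
        ev_shift = _movement_event(10.0 + k / FS)
        f0 = extract_features(segment_epoch(env, ev, MOVEMENT_SPEC), MOVEMENT_SPEC)
        f1 = extract_features(segment_epoch(shifted, ev_shift, MOVEMENT_SPEC), MOVEMENT_SPEC)
        np.testing.assert_allclose(f0.values, f1.values, rtol=1e-12)

    def test_feature_vector_validation(self):
        with pytest.raises(ValueError):
            FeatureVector(values=np.zeros(69), label="rest", trial_id=0)
        with pytest.raises(ValueError):
            FeatureVector(values=np.full(70, -1.0), label="rest", trial_id=0)


class TestEpochSpecs:
    def test_movement_windows_span_minus150_to_350ms(self):
        edges = [w for win in MOVEMENT_SPEC.feature_windows for w in win]
        assert min(edges) == pytest.approx(-0.15)
        assert max(edges) == pytest.approx(0.35)

    def test_rest_windows_span_minus750_to_minus250ms(self):
        edges = [w for win in REST_SPEC.feature_windows for w in win]
        assert min(edges) == pytest.approx(-0.75)
        assert max(edges) == pytest.approx(-0.25)

    def test_five_contiguous_100ms_windows_enforced(self):
        with pytest.raises(ValueError):
            EpochSpec(anchor="response", half_width_s=2.0,
                      feature_windows=((0.0, 0.1), (0.1, 0.2)))


class TestOnSimulatedData:
    def test_beta_erd_visible_in_features(self, strong_session):
        _, session = strong_session
        feats, _ = session_features(session)
        names = feature_names()
        beta_cols = [i for i, n in enumerate(names)
                     if ("low_beta" in n or "high_beta" in n)]
        mov = np.array([f.values for f in feats if f.label != "rest"])
        rest = np.array([f.values for f in feats if f.label == "rest"])
        # movement windows sit on the ERD; rest windows on baseline
        assert mov[:, beta_cols].mean() < rest[:, beta_cols].mean()

    def test_window_sweep_shapes(self, strong_session):
        _, session = strong_session
        from lfpdecode.preprocess import preprocess_channel
        left = preprocess_channel(session.left, session.fs)
        right = preprocess_channel(session.right, session.fs)
        env = band_envelopes(left, right)
        out = sweep_window_centers(env, session.events[:8], [-0.1, 0.1, 0.3])
        assert set(out) == {-0.1, 0.1, 0.3}
        for mat in out.values():
            assert mat.shape[1] == 70
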