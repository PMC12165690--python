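import numpy as np
import pytest
from scipy import signal as spsignal

from crpnet import fc
from crpnet.signals import BandSpec, RegionSignalSet

from conftest import make_frames


def tone(freq, fs=250.0, dur=10.0, amp=1.0, phase=0.0):
    t = np.arange(int(dur * fs)) / fs
    return amp * np.cos(2 * np.pi * freq * t + phase), t


class TestBandpass:
    def test_passband_center_preserved(self):
        for name, lo, hi in [("alpha", 8, 13), ("gamma", 31, 60)]:
            x, _ = tone(np.sqrt(lo * hi))
            s = RegionSignalSet(x[None, :], fs=250.0)
            y = fc.bandpass(s, name).values[0]
            mid = slice(500, -500)
            assert np.abs(y[mid]).max() == pytest.approx(1.0, rel=0.10)

    def test_stopband_attenuation_one_octave(self):
        # sinusoid at twice the high edge: >= 40 dB down (amplitude <= 1e-2)
        x, _ = tone(26.0)  # 2 x alpha high edge
        s = RegionSignalSet(x[None, :], fs=250.0)
        y = fc.bandpass(s, "alpha").values[0]
        assert np.abs(y[500:-500]).max() < 1e-2

    def test_gamma_valid_at_250hz(self, fast_signals):
        out = fc.bandpass(fast_signals, "gamma")
        assert out.band.name == "gamma"

    def test_band_above_nyquist_rejected(self, fast_signals):
        with pytest.raises(ValueError, match="Nyquist"):
            fc.bandpass(fast_signals, BandSpec("high", 100.0, 130.0))

    def test_zero_phase(self):
        # forward-backward filtering must not delay the carrier
        x, t = tone(10.0)
        s = RegionSignalSet(x[None, :], fs=250.0)
        y = fc.bandpass(s, "alpha").values[0]
        mid = slice(1000, -1000)
        lag = np.argmax(np.correlate(y[mid], x[mid], "full")) - (x[mid].size - 1)
        assert lag == 0


class TestHilbert:
    def test_envelope_of_tone(self):
        x, _ = tone(10.0, amp=2.0)
        env, _ = fc.hilbert_env_phase(RegionSignalSet(x[None, :], fs=250.0))
        assert np.allclose(env.values[0][200:-200], 2.0, rtol=0.02)

    def test_phase_slope_matches_frequency(self):
        x, t = tone(10.0)
        _, phase = fc.hilbert_env_phase(RegionSignalSet(x[None, :], fs=250.0))
        slope = np.polyfit(t[200:-200], phase.values[0][200:-200], 1)[0]
        assert slope == pytest.approx(2 * np.pi * 10.0, rel=0.01)

    def test_unwrapped_no_jumps(self):
        x, _ = tone(10.0)
        _, phase = fc.hilbert_env_phase(RegionSignalSet(x[None, :], fs=250.0))
        assert np.all(np.abs(np.diff(phase.values[0])) < np.pi)

    def test_am_tone_recovers_modulator(self):
        t = np.arange(5000) / 250.0
        mod = 1.0 + 0.5 * np.sin(2 * np.pi * 0.5 * t)
        x = mod * np.cos(2 * np.pi * 20.0 * t)
        env, _ = fc.hilbert_env_phase(RegionSignalSet(x[None, :], fs=250.0))
        r = np.corrcoef(env.values[0][200:-200], mod[200:-200])[0, 1]
        assert r > 0.99

    def test_zero_channel_flagged(self):
        vals = np.vstack([np.zeros(1000), np.sin(np.arange(1000) / 10)])
        with pytest.warns(UserWarning, match="undefined"):
            env, phase = fc.hilbert_env_phase(RegionSignalSet(vals, fs=100.0))
        assert np.all(env.values[0] == 0)
        assert np.all(np.isnan(phase.values[0]))


class TestAmplitudeCoupling:
    def test_self_product_identity(self, rng):
        # two identical channels: time-average of the edge equals mean(z^2) = 1
        base = np.abs(spsignal.sosfiltfilt(
            spsignal.butter(2, 0.1, output="sos"), rng.standard_normal(6000)))
        env = RegionSignalSet(np.vstack([base, base, rng.random(6000) + 1.0]),
                              fs=100.0)
        frames = fc.eeg_fc_amp(env, tr=3.0)  # 300 samples/window, 20 frames
        assert frames.n_frames == 20
        assert frames.frames[:, 0].mean() == pytest.approx(1.0, abs=1e-12)

    def test_independent_envelopes_fluctuate_around_zero(self, rng):
        env = RegionSignalSet(rng.random((4, 30000)) + 0.5, fs=100.0)
        frames = fc.eeg_fc_amp(env, tr=2.0)
        assert abs(frames.frames.mean()) < 0.02

    def test_window_count_tr3_fs250(self, rng):
        env = RegionSignalSet(rng.random((3, 7500)) + 0.5, fs=250.0)
        frames = fc.eeg_fc_amp(env, tr=3.0)
        assert frames.n_frames == 10  # 30 s / 3 s, N = 750 per window

    def test_zero_variance_channel_rejected(self, rng):
        env = RegionSignalSet(
            np.vstack([np.ones(1000), rng.random(1000) + 0.5]), fs=100.0)
        with pytest.raises(ValueError, match="zero-variance"):
            fc.eeg_fc_amp(env, tr=2.0)


class TestPhaseCoupling:
    def test_identical_phases_give_unity(self):
        t = np.arange(3000) / 100.0
        ph = np.vstack([2 * np.pi * 5 * t, 2 * np.pi * 5 * t])
        frames = fc.eeg_fc_phase(RegionSignalSet(ph, fs=100.0), tr=3.0)
        assert np.allclose(frames.frames, 1.0, atol=1e-12)

    def test_constant_offset_gives_unity(self):
        t = np.arange(3000) / 100.0
        ph = np.vstack([2 * np.pi * 5 * t, 2 * np.pi * 5 * t + np.pi / 3])
        frames = fc.eeg_fc_phase(RegionSignalSet(ph, fs=100.0), tr=3.0)
        assert np.allclose(frames.frames, 1.0, atol=1e-12)

    def test_uniform_phase_difference_gives_zero(self):
        # second channel advances exactly one extra cycle per window
        t = np.arange(3000) / 100.0
        ph = np.vstack([2 * np.pi * 5 * t, 2 * np.pi * (5 + 1 / 3.0) * t])
        frames = fc.eeg_fc_phase(RegionSignalSet(ph, fs=100.0), tr=3.0)
        assert np.all(frames.frames < 1e-10)

    def test_values_bounded(self, rng):
        ph = np.cumsum(rng.random((4, 2000)), axis=1)
        frames = fc.eeg_fc_phase(RegionSignalSet(ph, fs=100.0), tr=2.0)
        assert frames.frames.min() >= 0.0 and frames.frames.max() <= 1.0


class TestBoldEdgeSeries:
    def test_time_mean_equals_pearson(self, rng):
        bold = RegionSignalSet(rng.standard_normal((6, 60)), fs=1 / 3.0,
                               modality="slow")
        frames = fc.fmri_edge_series(bold)
        means = fc.static_fc(frames)
        expected = np.corrcoef(bold.values)[np.triu_indices(6, 1)]
        np.testing.assert_allclose(means, expected, atol=1e-12)

    def test_identical_regions_mean_one(self, rng):
        x = rng.standard_normal(30)
        bold = RegionSignalSet(np.vstack([x, x, rng.standard_normal(30)]),
                               fs=0.5, modality="slow")
        frames = fc.fmri_edge_series(bold)
        assert frames.frames[:, 0].mean() == pytest.approx(1.0, abs=1e-12)

    def test_matches_hand_computation(self):
        # brute-force oracle: explicit z-scores and per-frame products
        vals = np.array([[1.0, 2.0, 4.0, 3.0, 0.0, 1.0, 2.0, 5.0],
                         [2.0, 1.0, 3.0, 5.0, 1.0, 0.0, 2.0, 4.0]])
        bold = RegionSignalSet(vals, fs=0.5, modality="slow")
        frames = fc.fmri_edge_series(bold)
        z = (vals - vals.mean(1, keepdims=True)) / vals.std(1, keepdims=True)
        for t in range(8):
            assert frames.frames[t, 0] == pytest.approx(z[0, t] * z[1, t], abs=1e-14)

    def test_zero_variance_rejected(self):
        bold = RegionSignalSet(np.vstack([np.ones(20), np.arange(20.0)]),
                               fs=0.5, modality="slow")
        with pytest.raises(ValueError, match="zero-variance"):
            fc.fmri_edge_series(bold)


class TestHemodynamicShift:
    @pytest.mark.parametrize("lag,tr,k", [(6.0, 3.0, 2), (6.0, 2.0, 3), (0.0, 3.0, 0)])
    def test_shift_frame_counts(self, toy_frames, lag, tr, k):
        import dataclasses
        frames = dataclasses.replace(toy_frames, tr=tr,
                                     frame_times=(np.arange(40) + 0.5) * tr)
        out = fc.apply_hemodynamic_shift(frames, lag, tr)
        assert out.n_frames == 40 - k
        assert out.shifted
        np.testing.assert_array_equal(out.frames, frames.frames[k:])

    def test_non_multiple_lag_rejected(self, toy_frames):
        with pytest.raises(ValueError, match="multiple of TR"):
            fc.apply_hemodynamic_shift(toy_frames, 5.0, 3.0)

    def test_shift_composition_restores_overlap(self, toy_frames):
        fwd = fc.apply_hemodynamic_shift(toy_frames, 6.0, 3.0)
        back = fc.apply_hemodynamic_shift(fwd, -6.0, 3.0)
        np.testing.assert_array_equal(back.frames, toy_frames.frames[2:-2])


class TestHrf:
    def test_impulse_response_peaks_near_six_seconds(self):
        imp = np.zeros((1, 64))
        imp[0, 0] = 1.0
        out = fc.hrf_convolve(RegionSignalSet(imp, fs=1.0))
        assert np.argmax(out.values[0]) == 6
        assert out.values[0].max() == pytest.approx(1.0)

    def test_constant_input_steady_state(self):
        const = np.full((1, 200), 2.0)
        out = fc.hrf_convolve(RegionSignalSet(const, fs=1.0))
        ksum = fc.canonical_hrf(1.0).sum()
        assert out.values[0, -1] == pytest.approx(2.0 * ksum, rel=1e-9)

    def test_white_noise_lowpass_shaped(self, rng):
        x = rng.standard_normal((1, 4096))
        out = fc.hrf_convolve(RegionSignalSet(x, fs=1.0))
        f = np.fft.rfftfreq(4096, 1.0)
        pin = np.abs(np.fft.rfft(x[0])) ** 2
        pout = np.abs(np.fft.rfft(out.values[0])) ** 2
        gain_low = pout[(f > 0) & (f < 0.03)].mean() / pin[(f > 0) & (f < 0.03)].mean()
        gain_high = pout[f > 0.3].mean() / pin[f > 0.3].mean()
        assert gain_high < gain_low / 100


def test_static_fc(toy_frames, rng):
    single = make_frames(toy_frames.frames[:1], 10)
    np.testing.assert_array_equal(fc.static_fc(single), toy_frames.frames[0])
    loop = np.array([toy_frames.frames[:, e].mean() for e in range(45)])
    np.testing.assert_allclose(fc.static_fc(toy_frames), loop, atol=1e-14)
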