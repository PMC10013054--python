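import numpy as np
import pytest

from musicbrain.eeg import (
    BAND_EDGES_HZ,
    CHANNELS_32,
    EEGRecording,
    band_correlation_profile,
    band_decompose,
    block_average,
    correlation_dynamics,
    cwt_band,
    default_alpha,
    generate_synthetic_eeg,
    grand_average,
    mexican_hat,
    octave_scales,
    select_top_k,
    stimulus_blocks,
    windowed_correlation,
)


def make_recording(rng, duration=10.0, fs=500.0):
    n = int(duration * fs)
    return EEGRecording(rng.standard_normal((n, 32)), fs)


class TestGrandAverage:
    def test_copies_average_to_themselves(self, rng):
        rec = make_recording(rng, 2.0)
        avg = grand_average([rec] * 10)
        np.testing.assert_allclose(avg.data, rec.data)

    def test_antiphase_pair_cancels(self, rng):
        rec = make_recording(rng, 2.0)
        neg = EEGRecording(-rec.data, rec.sample_rate)
        avg = grand_average([rec, neg])
        assert np.abs(avg.data).max() < 1e-14

    def test_noise_reduction_scales_with_sqrt_n(self, rng):
        n_trials = 75
        recs = [make_recording(rng, 2.0) for _ in range(n_trials)]
        avg = grand_average(recs)
        ratio = avg.data.std() / recs[0].data.std()
        assert ratio == pytest.approx(1 / np.sqrt(n_trials), rel=0.15)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            grand_average([make_recording(rng, 1.0), make_recording(rng, 2.0)])


class TestMexicanHat:
    def test_central_peak_value(self):
        for width in (0.5, 1.0, 2.0):
            expected = 2 / (np.pi**0.25 * np.sqrt(3 * width))
            assert mexican_hat(0.0, width) == pytest.approx(expected)

    def test_zero_crossings_at_width(self):
        for width in (0.5, 1.0, 3.0):
            assert mexican_hat(width, width) == pytest.approx(0.0, abs=1e-15)
            assert mexican_hat(-width, width) == pytest.approx(0.0, abs=1e-15)

    def test_zero_mean(self):
        x = np.linspace(-30, 30, 600_001)
        integral = np.trapezoid(mexican_hat(x, 1.0), x)
        assert abs(integral) < 1e-8

    def test_positive_width_required(self):
        with pytest.raises(ValueError):
            mexican_hat(0.0, -1.0)


class TestOctaveScales:
    def test_nine_scales_doubling(self):
        scales = octave_scales()
        assert scales.size == 9
        np.testing.assert_allclose(scales[1:] / scales[:-1], 2.0)

    def test_calibration_places_bands_at_their_edges(self):
        # a tone at each band's geometric-mean frequency must elicit maximal
        # wavelet energy in that band
        fs = 500.0
        t = np.arange(int(8 * fs)) / fs
        scales = octave_scales()
        for b in (0, 2, 4):
            lo, hi = BAND_EDGES_HZ[b]
            f_c = np.sqrt(lo * hi)
            x = np.sin(2 * np.pi * f_c * t)
            energies = []
            for s in scales:
                w, valid = cwt_band(x, s, 1 / fs)
                energies.append(np.sum(w[valid] ** 2))
            assert int(np.argmax(energies)) == b

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            octave_scales(alpha=-1.0)


class TestCWT:
    def test_zero_input_zero_output(self):
        w, _ = cwt_band(np.zeros(1000), 0.01, 0.002)
        assert np.all(w == 0)

    def test_linearity(self, rng):
        x = rng.standard_normal(2000)
        y = rng.standard_normal(2000)
        s, dt = 0.02, 0.002
        wx, _ = cwt_band(x, s, dt)
        wy, _ = cwt_band(y, s, dt)
        wxy, _ = cwt_band(3.0 * x - 0.5 * y, s, dt)
        np.testing.assert_allclose(wxy, 3.0 * wx - 0.5 * wy, atol=1e-10)

    def test_constant_input_gives_near_zero(self):
        w, valid = cwt_band(np.full(3000, 5.0), 0.05, 0.002)
        assert np.abs(w[valid]).max() < 1e-8

    def test_oversized_scale_rejected(self):
        with pytest.raises(ValueError, match="too large"):
            cwt_band(np.zeros(100), 10.0, 0.002)


class TestWindowedCorrelation:
    def test_identical_series_give_ones(self, rng):
        x = rng.standard_normal(2500)
        r = windowed_correlation(x, x, 500)
        np.testing.assert_allclose(r, 1.0)

    def test_one_value_per_second(self, rng):
        x = rng.standard_normal(270 * 500)
        r = windowed_correlation(x, rng.standard_normal(x.size), 500)
        assert r.size == 270

    def test_white_noise_null_level(self, rng):
        x = rng.standard_normal(100 * 500)
        y = rng.standard_normal(x.size)
        r = windowed_correlation(x, y, 500)
        assert abs(r.mean()) < 3 * 2 / np.sqrt(500)

    def test_zero_variance_window_flagged_as_zero(self, rng):
        x = np.concatenate([np.zeros(500), rng.standard_normal(500)])
        y = rng.standard_normal(1000)
        with pytest.warns(UserWarning, match="zero-variance"):
            r = windowed_correlation(x, y, 500)
        assert r[0] == 0.0 and abs(r[1]) <= 1.0


class TestBlockAverage:
    def test_simple_block(self):
        np.testing.assert_allclose(block_average(np.array([1.0, 2, 3, 4])), [2.5])

    def test_constant_series_unchanged(self):
        out = block_average(np.full(12, 7.0))
        np.testing.assert_allclose(out, 7.0)

    def test_trailing_partial_block_dropped(self):
        out = block_average(np.arange(270.0))
        assert out.size == 67

    def test_stimulus_blocks_rectifies_and_averages(self):
        fs = 100.0
        x = -np.ones(int(8 * fs))  # constant negative amplitude
        blocks = stimulus_blocks(x, fs)
        np.testing.assert_allclose(blocks, 1.0)


class TestSelectTopK:
    def _dynamics(self, rng, n_win=40, n_pairs=30, n_bands=3):
        from musicbrain.eeg import CorrelationDynamics

        r = rng.uniform(-1, 1, (n_bands, n_win, n_pairs))
        pairs = [(i, j) for i in range(9) for j in range(i + 1, 9)][:n_pairs]
        return CorrelationDynamics(r, pairs, [f"ch{i}" for i in range(9)])

    def test_k_equal_to_pairs_is_plain_mean(self, rng):
        corr = self._dynamics(rng)
        stim = rng.uniform(0, 1, 10)
        selected, means, _ = select_top_k(corr, stim, k=corr.r.shape[2])
        blocked = block_average(np.moveaxis(corr.r, 1, 0))
        np.testing.assert_allclose(means[0], blocked[:10, 0, :].mean(axis=1))

    def test_planted_series_recovered_first(self, rng):
        corr = self._dynamics(rng)
        stim = rng.uniform(0, 1, 10)
        # plant: pair 17's blocked series in band 1 equals the stimulus
        planted = np.repeat(stim, 4)
        corr.r[1, :, 17] = planted
        selected, _, r_all = select_top_k(corr, stim, k=1)
        assert selected[1] == [17]
        assert r_all[1, 17] == pytest.approx(1.0)

    def test_matches_brute_force_ranking(self, rng):
        corr = self._dynamics(rng)
        stim = rng.uniform(0, 1, 10)
        k = 7
        selected, _, r_all = select_top_k(corr, stim, k=k)
        blocked = block_average(np.moveaxis(corr.r, 1, 0))[:10]
        for b in range(corr.r.shape[0]):
            scored = []
            for p in range(corr.r.shape[2]):
                series = blocked[:, b, p]
                num = ((series - series.mean()) * (stim - stim.mean())).sum()
                den = np.sqrt(
                    ((series - series.mean()) ** 2).sum()
                    * ((stim - stim.mean()) ** 2).sum()
                )
                scored.append((-num / den if den else 0.0, p))
            expected = sorted(p for _, p in sorted(scored)[:k])
            assert selected[b] == expected

    def test_k_too_large_rejected(self, rng):
        corr = self._dynamics(rng)
        with pytest.raises(ValueError):
            select_top_k(corr, np.ones(10), k=1000)


class TestPipeline:
    def test_cardinality_and_window_count(self, rng):
        duration = 20.0
        rec = make_recording(rng, duration)
        decomp = band_decompose(rec)
        corr = correlation_dynamics(decomp)
        assert corr.r.shape[0] == 9
        assert corr.r.shape[2] == 32 * 31 // 2
        assert corr.n_series == 4464
        assert corr.r.shape[1] == int(duration)

    def test_profile_values_bounded(self, rng):
        rec = make_recording(rng, 24.0)
        stim = np.abs(rng.standard_normal(int(24 * 100)))
        prof = band_correlation_profile(rec, stim, 100.0)
        assert np.all(prof.per_band >= -1) and np.all(prof.per_band <= 1)
        assert -1 <= prof.overall <= 1

    def test_constant_stimulus_rejected(self, rng):
        rec = make_recording(rng, 16.0)
        with pytest.raises(ValueError, match="constant"):
            band_correlation_profile(rec, np.ones(1600), 100.0)


class TestSyntheticEEG:
    def test_deterministic_under_seed(self):
        env = np.ones(100)
        gain = np.zeros(9)
        gain[1] = 1.0
        a = generate_synthetic_eeg(env, 10.0, gain, seed=3, duration=4.0)
        b = generate_synthetic_eeg(env, 10.0, gain, seed=3, duration=4.0)
        assert np.array_equal(a[0].data, b[0].data)

    def test_recording_format(self):
        env = np.ones(100)
        recs = generate_synthetic_eeg(
            env, 10.0, np.zeros(9), n_subjects=2, n_trials=3, seed=0, duration=4.0
        )
        assert len(recs) == 6
        assert recs[0].n_channels == 32
        assert recs[0].channels == CHANNELS_32
        assert recs[0].sample_rate == 500.0

    def test_injected_band_recovered(self):
        # stimulus-locked coupling in FB2 only: the band profile peaks there
        fs_env = 10.0
        t = np.arange(int(120 * fs_env)) / fs_env
        env = 0.5 + 0.5 * np.sign(np.sin(2 * np.pi * t / 16))
        gain = np.zeros(9)
        gain[1] = 1.0
        recs = generate_synthetic_eeg(env, fs_env, gain, seed=2, duration=120.0)
        prof = band_correlation_profile(grand_average(recs), env, fs_env)
        assert int(prof.per_band.argmax()) + 1 in (1, 2, 3)
        assert prof.per_band[1] > np.median(prof.per_band[4:])

    def test_band_gain_length_checked(self):
        with pytest.raises(ValueError):
            generate_synthetic_eeg(np.ones(10), 10.0, np.zeros(5))
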