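import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from emgsynergy import (CoherenceConfig, GlobalCoherence, global_coherence,
                        monte_carlo_threshold, morlet_cwt, significant_bands,
                        wavelet_coherence)
from emgsynergy.coherence import FrequencyBand

FS = 1000.0


def _tone(f, dur=10.0, fs=FS):
    t = np.arange(int(dur * fs)) / fs
    return np.sin(2 * np.pi * f * t)


class TestMorletCWT:
    def test_pure_tone_peaks_at_nearest_grid_frequency(self):
        cfg = CoherenceConfig()
        W = morlet_cwt(_tone(10.0), FS, cfg)
        mid = np.abs(W[:, W.shape[1] // 2])
        nearest = np.argmin(np.abs(cfg.frequencies - 10.0))
        assert np.argmax(mid) == nearest

    def test_linearity(self, rng):
        cfg = CoherenceConfig()
        x, y = rng.standard_normal(3000), rng.standard_normal(3000)
        Wx, Wy = morlet_cwt(x, FS, cfg), morlet_cwt(y, FS, cfg)
        np.testing.assert_allclose(morlet_cwt(2.5 * x, FS, cfg), 2.5 * Wx, rtol=1e-9)
        np.testing.assert_allclose(morlet_cwt(x + y, FS, cfg), Wx + Wy,
                                   rtol=1e-9, atol=1e-9 * np.abs(Wx).max())

    def test_signal_shorter_than_wavelet_support_rejected(self):
        with pytest.raises(ValueError, match="short"):
            morlet_cwt(np.zeros(100), FS, CoherenceConfig())


class TestWaveletCoherence:
    def test_self_coherence_is_one_inside_cone(self, rng):
        x = rng.standard_normal(8000)
        m = wavelet_coherence(x, x, FS)
        assert m.values[m.in_coi].min() >= 0.99

    def test_symmetric_in_arguments(self, rng):
        x, y = rng.standard_normal(4000), rng.standard_normal(4000)
        a = wavelet_coherence(x, y, FS)
        b = wavelet_coherence(y, x, FS)
        np.testing.assert_allclose(a.values, b.values, atol=1e-6)

    def test_independent_noise_mean_below_half(self):
        means = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            m = wavelet_coherence(r.standard_normal(10000), r.standard_normal(10000), FS)
            means.append(m.values[m.in_coi].mean())
        assert np.mean(means) < 0.5

    def test_shared_tone_dominates_its_band(self, rng):
        tone = _tone(10.0)
        x = tone + rng.standard_normal(tone.size) * tone.std()
        y = tone + rng.standard_normal(tone.size) * tone.std()
        m = wavelet_coherence(x, y, FS)
        band = (m.freqs >= 9) & (m.freqs <= 11)
        vals = m.values[band][m.in_coi[band]]
        assert np.median(vals) > 0.7

    def test_unequal_lengths_and_zero_channel_rejected(self, rng):
        x = rng.standard_normal(4000)
        with pytest.raises(ValueError, match="equal-length"):
            wavelet_coherence(x, x[:-1], FS)
        with pytest.raises(ValueError, match="zero"):
            wavelet_coherence(x, np.zeros_like(x), FS)

    @given(seed=st.integers(0, 10_000), scale=st.floats(1e-3, 1e3))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_values_always_within_unit_interval(self, seed, scale):
        r = np.random.default_rng(seed)
        cfg = CoherenceConfig(max_analysis_fs=200.0)
        x = scale * r.standard_normal(700)
        y = scale * np.cumsum(r.standard_normal(700))  # red-ish partner
        m = wavelet_coherence(x, y, 200.0, cfg)
        assert m.values.min() >= 0.0
        assert m.values.max() <= 1.0 + 1e-9


class TestMonteCarloThreshold:
    def test_thresholds_strictly_inside_unit_interval(self, rng):
        cfg = CoherenceConfig(n_surrogates=100, surrogate_duration_s=5.0)
        thr = monte_carlo_threshold(rng.standard_normal(5000),
                                    rng.standard_normal(5000), FS, cfg, seed=1)
        assert np.all(thr > 0) and np.all(thr < 1)
        assert thr.shape == (cfg.n_freqs,)

    def test_too_few_surrogates_rejected(self):
        with pytest.raises(ValueError, match="n_surrogates"):
            CoherenceConfig(n_surrogates=50)

    def test_wider_time_smoothing_does_not_raise_thresholds(self, rng):
        base = dict(n_surrogates=100, surrogate_duration_s=5.0)
        for seed in range(3):
            r = np.random.default_rng(100 + seed)
            x, y = r.standard_normal(5000), r.standard_normal(5000)
            t1 = monte_carlo_threshold(x, y, FS, CoherenceConfig(**base), seed=seed)
            t2 = monte_carlo_threshold(x, y, FS,
                                       CoherenceConfig(time_smoothing=2.0, **base), seed=seed)
            assert np.all(t2 <= t1 + 0.005)

    def test_deterministic_given_seed(self, rng):
        cfg = CoherenceConfig(n_surrogates=100, surrogate_duration_s=5.0)
        x, y = rng.standard_normal(4000), rng.standard_normal(4000)
        np.testing.assert_array_equal(monte_carlo_threshold(x, y, FS, cfg, seed=9),
                                      monte_carlo_threshold(x, y, FS, cfg, seed=9))


class TestGlobalCoherence:
    def test_all_ones_map_gives_unit_power(self, rng):
        m = wavelet_coherence(rng.standard_normal(4000), rng.standard_normal(4000), FS)
        m.values = np.ones_like(m.values)
        m.threshold = np.full(m.freqs.size, 0.5)
        gc = global_coherence(m)
        np.testing.assert_allclose(gc.power, 1.0)
        assert gc.significance.all()

    def test_threshold_required(self, rng):
        m = wavelet_coherence(rng.standard_normal(4000), rng.standard_normal(4000), FS)
        with pytest.raises(ValueError, match="threshold"):
            global_coherence(m)

    def test_shared_narrowband_drive_flagged_significant_at_ten_hz(self, rng):
        from scipy import signal as sg

        cfg = CoherenceConfig(n_surrogates=100)
        n = int(20 * FS)
        sos = sg.butter(4, [9.0, 11.0], btype="bandpass", fs=FS, output="sos")
        drive = sg.sosfiltfilt(sos, rng.standard_normal(n))
        drive /= drive.std()
        x = rng.standard_normal(n) + drive
        y = rng.standard_normal(n) + drive
        m = wavelet_coherence(x, y, FS, cfg)
        m.threshold = monte_carlo_threshold(x, y, FS, cfg, seed=2)
        gc = global_coherence(m, cfg)
        nearest = np.argmin(np.abs(gc.freqs - 10.0))
        assert gc.significance[nearest]

    def test_independent_pair_rarely_significant(self):
        cfg = CoherenceConfig(n_surrogates=100)
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            x, y = r.standard_normal(10000), r.standard_normal(10000)
            m = wavelet_coherence(x, y, FS, cfg)
            m.threshold = monte_carlo_threshold(x, y, FS, cfg, seed=seed)
            gc = global_coherence(m, cfg)
            if gc.significance.mean() <= 0.10:
                hits += 1
        assert hits >= 9


class TestSignificantBands:
    def _gc(self, freqs, sig):
        return GlobalCoherence(freqs=np.asarray(freqs, float),
                               power=np.ones(len(freqs)),
                               significance=np.asarray(sig, bool))

    def test_single_run_becomes_one_band(self):
        bands = significant_bands(self._gc([8, 9, 10, 11, 12], [0, 1, 1, 1, 0]))
        assert bands == [FrequencyBand(9.0, 11.0)]

    def test_no_significance_gives_empty_list(self):
        assert significant_bands(self._gc([8, 9, 10], [0, 0, 0])) == []

    def test_isolated_point_is_peak_only(self):
        bands = significant_bands(self._gc([8, 9, 10], [0, 1, 0]))
        assert len(bands) == 1 and bands[0].is_peak_only

    def test_disjoint_runs_stay_separate(self):
        bands = significant_bands(self._gc([5, 6, 7, 8, 9, 10], [1, 1, 0, 0, 1, 1]))
        assert bands == [FrequencyBand(5.0, 6.0), FrequencyBand(9.0, 10.0)]
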