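"""Spectral power, coherence, robust decay fits, shuffle statistics and
entrainment measures."""

import numpy as np
import pytest
from scipy import signal as sps

from swostim import analysis
from swostim.analysis import (
    band_power_series,
    coherence_time,
    decay_rate,
    dominant_frequency,
    fdr_bh,
    paired_shuffle_test,
    phase_locking,
    rayleigh_p,
    spatial_coherence_series,
)

FS = 20.0


class TestBandPower:
    def test_sinusoid_parseval(self):
        # pure 0.75 Hz sinusoid of amplitude A -> SWO band power A^2/2
        t = np.arange(0, 400, 1 / FS)
        a = 1.7
        x = a * np.sin(2 * np.pi * 0.75 * t)
        s = band_power_series(x, FS, (0.5, 1.0), 40.0)
        assert np.allclose(s.values, a**2 / 2, rtol=1e-6)

    def test_white_noise_band_fraction(self, rng):
        # flat spectrum: band power ~ variance * band fraction of Nyquist
        x = rng.standard_normal(int(4000 * FS))
        s = band_power_series(x, FS, (0.5, 4.0), 40.0)
        frac = (4.0 - 0.5) / (FS / 2)
        assert s.values.mean() == pytest.approx(frac * 1.0, rel=0.05)

    def test_zero_signal_masked_db(self):
        s = band_power_series(np.zeros(int(80 * FS)), FS)
        assert (s.values == 0).all()
        assert np.isnan(s.db).all()

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            band_power_series(np.zeros(1000), 2.0, (0.5, 1.5))


class TestSpatialCoherence:
    def test_identical_channels_unity(self, rng):
        x = rng.standard_normal(int(80 * FS))
        out = spatial_coherence_series(np.vstack([x, x]), FS)
        for s in out:
            assert np.allclose(s.values, 1.0, atol=1e-9)

    def test_independent_noise_small_and_shrinking(self, rng):
        a = rng.standard_normal(int(400 * FS))
        b = rng.standard_normal(int(400 * FS))
        short = spatial_coherence_series(np.vstack([a, b]), FS, seg_len=4.0)[0]
        long_ = spatial_coherence_series(np.vstack([a, b]), FS, seg_len=4.0,
                                         window_len=80.0)[0]
        assert short.values.mean() < 0.25
        assert long_.values.mean() < short.values.mean() + 0.05

    def test_shared_source_closed_form(self, rng):
        # x = sqrt(rho) s + sqrt(1-rho) n_k  ->  squared coherence rho^2
        n = int(2000 * FS)
        sos = sps.butter(4, (0.5, 1.0), btype="bandpass", fs=FS, output="sos")
        mk = lambda: sps.sosfiltfilt(sos, rng.standard_normal(n))
        s = mk()
        rho = 0.6
        x = np.sqrt(rho) * s + np.sqrt(1 - rho) * mk()
        y = np.sqrt(rho) * s + np.sqrt(1 - rho) * mk()
        out = spatial_coherence_series(np.vstack([x, y]), FS)[0]
        assert out.values.mean() == pytest.approx(rho**2, abs=0.05)

    def test_amplitude_invariance(self, rng):
        x = rng.standard_normal(int(160 * FS))
        y = x + 0.5 * rng.standard_normal(x.size)
        a = spatial_coherence_series(np.vstack([x, y]), FS)[0].values
        b = spatial_coherence_series(np.vstack([3.7 * x, 0.2 * y]), FS)[0].values
        assert np.allclose(a, b, atol=1e-9)

    def test_single_channel_rejected(self, rng):
        with pytest.raises(ValueError):
            spatial_coherence_series(rng.standard_normal((1, 1000)), FS)


class TestDecayRate:
    def test_exact_line_recovered(self):
        # constructed series at the sham-night slope
        t = np.linspace(0, 4.5, 60)
        y = -1.22 * t + 3.0
        fit = decay_rate(y, t)
        assert fit.slope == pytest.approx(-1.22, abs=1e-9)
        assert fit.method == "ols-exact"

    def test_robust_to_gross_outliers(self, rng):
        t = np.linspace(0, 4.5, 100)
        y = -1.22 * t + 0.1 * rng.standard_normal(t.size)
        idx = rng.choice(t.size, 10, replace=False)
        y[idx] += 15.0  # 10% gross outliers
        fit = decay_rate(y, t)
        assert fit.slope == pytest.approx(-1.22, abs=0.05)

    def test_constant_series_zero_slope(self):
        t = np.linspace(0, 2, 20)
        assert decay_rate(np.full(20, 5.0), t).slope == pytest.approx(0.0, abs=1e-9)

    def test_fit_window_and_min_windows(self):
        t = np.linspace(0, 10, 50)
        with pytest.raises(ValueError):
            decay_rate(-t, t, fit_window=(0.0, 0.5))

    def test_nan_masking(self):
        t = np.linspace(0, 4, 40)
        y = -2.0 * t
        y[::7] = np.nan
        assert decay_rate(y, t).slope == pytest.approx(-2.0, abs=1e-9)


class TestPairedShuffle:
    def test_identical_vectors_p_one(self):
        x = np.arange(8.0)
        assert paired_shuffle_test(x, x) == 1.0

    def test_uniform_shift_exact_enumeration(self):
        # n=10 equal same-sign differences: two-sided p = 2/2^10
        sham = np.zeros(10)
        stim = np.full(10, 0.5)
        assert paired_shuffle_test(sham, stim) == pytest.approx(2 / 1024)

    def test_matches_brute_force_on_random_instance(self, rng):
        sham = rng.standard_normal(7)
        stim = sham + 0.4 + 0.3 * rng.standard_normal(7)
        d = stim - sham
        obs = abs(d.mean())
        count = 0
        for m in range(2**7):
            signs = [1 if (m >> i) & 1 else -1 for i in range(7)]
            if abs(np.dot(signs, d) / 7) >= obs - 1e-12 * (1 + obs):
                count += 1
        assert paired_shuffle_test(sham, stim) == pytest.approx(count / 2**7)

    def test_sampled_path_add_one(self, rng):
        sham = rng.standard_normal(20)
        stim = sham + 1.0
        p = paired_shuffle_test(sham, stim, n_perm=999, seed=5)
        assert p == pytest.approx(1 / 1000)

    def test_null_calibration(self, rng):
        # no true effect: rejection rate at alpha=0.05 is ~5%
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            sham = rng.standard_normal(10)
            stim = rng.standard_normal(10)
            rejections += paired_shuffle_test(sham, stim) < 0.05
        rate = rejections / n_rep
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_rep)


class TestFdrBH:
    def test_single_p_unchanged(self):
        reject, p_adj = fdr_bh([0.04])
        assert p_adj[0] == pytest.approx(0.04)
        assert reject[0]

    def test_step_up_hand_case(self):
        # p=(0.01,0.02,0.03,0.04), m=4: adjusted = min over j>=i of m p_j / j
        reject, p_adj = fdr_bh([0.01, 0.02, 0.03, 0.04], q=0.05)
        assert reject.all()
        assert np.allclose(p_adj, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_none_rejected(self):
        reject, p_adj = fdr_bh([1.0, 1.0, 1.0])
        assert not reject.any()
        assert np.allclose(p_adj, 1.0)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.2])


class TestPhaseLocking:
    def test_perfect_locking(self):
        fs, f = 100.0, 0.75
        t = np.arange(0, 120, 1 / fs)
        lfp = np.sin(2 * np.pi * f * t)
        onsets = np.arange(5, 110, 1 / f)
        plv, _, p = phase_locking(lfp, fs, onsets)
        assert plv > 0.99
        assert p < 1e-6

    def test_null_plv_scale(self, rng):
        # uniform random phases: PLV ~ 1/sqrt(n)
        fs = 100.0
        lfp = sps.sosfiltfilt(
            sps.butter(3, (0.5, 1.0), "bandpass", fs=fs, output="sos"),
            rng.standard_normal(int(600 * fs)),
        )
        onsets = np.sort(rng.uniform(10, 590, 100))
        plv, _, p = phase_locking(lfp, fs, onsets)
        assert plv < 3.0 / np.sqrt(100)
        assert p > 1e-3

    def test_too_few_cycles(self):
        with pytest.raises(ValueError):
            phase_locking(np.zeros(1000), 100.0, np.arange(5))

    def test_rayleigh_extremes(self, rng):
        locked = np.full(50, 1.3)
        assert rayleigh_p(locked) < 1e-10
        assert rayleigh_p(rng.uniform(0, 2 * np.pi, 2000)) > 0.01


class TestSpectralSummaries:
    def test_dominant_frequency(self):
        fs = 50.0
        t = np.arange(0, 300, 1 / fs)
        x = np.sin(2 * np.pi * 0.75 * t) + 0.1 * np.sin(2 * np.pi * 3.0 * t)
        assert dominant_frequency(x, fs) == pytest.approx(0.75, abs=0.05)

    @pytest.mark.parametrize("target", [2.0, 6.0])
    def test_coherence_time_tracks_phase_diffusion(self, target):
        # oracle: cosine with phase random walk; ensemble autocorrelation
        # envelope decays with tau = target/f0
        fs, f0 = 100.0, 0.8
        n = int(300 * fs)
        ests = []
        for seed in range(6):
            rng = np.random.default_rng(seed)
            D = 2.0 * f0 / target
            dphi = rng.normal(0, np.sqrt(D / fs), n).cumsum()
            x = np.cos(2 * np.pi * f0 * np.arange(n) / fs + dphi)
            ests.append(coherence_time(x, fs))
        est = np.median(ests)
        assert 0.5 * target < est < 2.0 * target

    def test_coherence_time_monotone_in_diffusion(self):
        fs, f0 = 100.0, 0.8
        n = int(300 * fs)
        meds = []
        for target in (1.5, 4.0, 10.0):
            ests = []
            for seed in range(5):
                rng = np.random.default_rng(seed)
                D = 2.0 * f0 / target
                dphi = rng.normal(0, np.sqrt(D / fs), n).cumsum()
                x = np.cos(2 * np.pi * f0 * np.arange(n) / fs + dphi)
                ests.append(coherence_time(x, fs))
            meds.append(np.median(ests))
        assert meds[0] < meds[1] < meds[2]
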