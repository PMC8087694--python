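"""Rhythmometry: z-scoring, binning, cosinor, circular stats, correlograms,
dependency curves, smoothing, detrending and RR heatmaps."""

import numpy as np
import pytest

import chronoecg as ce
from chronoecg.rhythms import (Cosinor, bin_series, circular_mean_h,
                               cohort_phase_delay, crosscorr,
                               delta_dependency, detrend_moving_average,
                               fit_correlogram_peak, rr_heatmap,
                               smooth_profile, watson_williams,
                               zscore_session)


class TestZscore:
    def test_sample_sd_convention(self):
        z = zscore_session(np.array([1.0, 2.0, 3.0]))
        assert np.allclose(z, [-1.0, 0.0, 1.0])  # sample (n-1) SD

    def test_shift_invariance(self):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        assert np.allclose(zscore_session(x), zscore_session(x + 42.0))

    def test_nan_entries_do_not_shift_mean(self):
        x = np.array([1.0, 2.0, 3.0, np.nan])
        z = zscore_session(x)
        assert np.allclose(z[:3], [-1.0, 0.0, 1.0])
        assert np.isnan(z[3])

    def test_constant_series_raises(self):
        with pytest.raises(ValueError):
            zscore_session(np.ones(10))

    def test_idempotence(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        z = zscore_session(x)
        assert np.allclose(zscore_session(z), z, atol=1e-12)


class TestBinning:
    def test_full_coverage(self):
        t = np.arange(288) * 300.0  # one sweep per 5-min bin
        b = bin_series(t, np.sin(t))
        assert not b.excluded
        assert b.nonempty_fraction == 1.0
        assert len(b.values) == 288

    def test_dropping_35_percent_of_bins_flags_subject(self):
        rng = np.random.default_rng(1)
        t = np.arange(288) * 300.0
        v = np.sin(t / 1000)
        drop = rng.choice(288, size=101, replace=False)  # 35%
        v[drop] = np.nan
        b = bin_series(t, v)
        assert b.excluded

    def test_width_must_divide_day(self):
        with pytest.raises(ValueError):
            bin_series(np.arange(10.0), np.arange(10.0), width_min=7.0)


class TestCosinor:
    def test_noiseless_recovery_exact(self):
        t = np.arange(0, 24, 24 / 288)
        y = 0.5 + 1.0 * np.cos(2 * np.pi * (t - 6.0) / 24.0)
        res = Cosinor(y, t).fit()
        assert res.mesor == pytest.approx(0.5, abs=1e-8)
        assert res.amplitude == pytest.approx(1.0, abs=1e-8)
        assert res.acrophase_h == pytest.approx(6.0, abs=1e-8)
        assert res.p_rhythm < 1e-12

    def test_type_one_error_near_nominal(self):
        """Zero-amplitude F-test calibration on white noise (reduced MC
        here; the full 1000-run calibration lives in the acceptance suite).
        """
        rng = np.random.default_rng(2)
        t = np.arange(0, 24, 24 / 96)
        rej = sum(Cosinor(rng.normal(size=96), t).fit().p_rhythm < 0.05
                  for _ in range(300))
        assert 0.02 <= rej / 300 <= 0.09

    def test_acrophase_recovery_at_unit_snr(self):
        rng = np.random.default_rng(3)
        t = np.arange(0, 24, 24 / 288)
        errs = []
        n_sim = 100
        for _ in range(n_sim):
            y = np.cos(2 * np.pi * (t - 10.0) / 24.0) + rng.normal(size=288)
            phi = Cosinor(y, t).fit().acrophase_h
            errs.append(min(abs(phi - 10.0), 24 - abs(phi - 10.0)))
        errs = np.asarray(errs)
        # theory: SE(acrophase) = (sigma/A) sqrt(2/n) / omega ~ 0.32 h at
        # unit SNR, so ~88% of fits land within 0.5 h
        assert np.median(errs) <= 0.5
        assert np.mean(errs <= 0.5) >= 0.8

    def test_requires_phase_span(self):
        t = np.linspace(0, 10, 50)  # < half a period
        with pytest.raises(ValueError, match="span"):
            Cosinor(np.sin(t), t)

    def test_summary_and_se(self):
        t = np.arange(0, 48, 0.5)
        rng = np.random.default_rng(4)
        y = 1 + 0.5 * np.cos(2 * np.pi * (t - 3) / 24) + rng.normal(0, .1, len(t))
        res = Cosinor(y, t).fit()
        s = res.summary()
        assert "acrophase" in s and "mesor" in s
        assert 0 < res.bse["amplitude"] < 0.1


class TestWatsonWilliams:
    def test_identical_groups_high_p(self):
        g = [2.0, 3.0, 2.5, 3.5]
        res = watson_williams([g, list(g)])
        assert res.p_value > 0.9

    def test_separated_groups_agree_with_permutation_oracle(self):
        rng = np.random.default_rng(5)
        g1 = (2.0 + rng.normal(0, 0.5, 8)) % 24
        g2 = (14.0 + rng.normal(0, 0.5, 8)) % 24
        res = watson_williams([list(g1), list(g2)])
        assert res.p_value < 0.001
        # permutation oracle on the same angles and statistic
        pooled = np.concatenate([g1, g2])
        n1 = len(g1)
        count = 0
        n_perm = 500
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            f = watson_williams([list(perm[:n1]), list(perm[n1:])]).f_stat
            if f >= res.f_stat:
                count += 1
        assert (count + 1) / (n_perm + 1) < 0.01

    def test_wraparound_circular_mean(self):
        m = circular_mean_h(np.array([23.5, 0.5]))
        assert min(m, 24 - m) == pytest.approx(0.0, abs=1e-9)  # not 12 h

    def test_low_concentration_flagged(self):
        rng = np.random.default_rng(6)
        g1 = rng.uniform(0, 24, 10)
        g2 = rng.uniform(0, 24, 10)
        res = watson_williams([list(g1), list(g2)])
        assert not res.reliable


class TestCrosscorr:
    def _series(self, delay_h=0.0, noise=0.0, seed=0, days=3):
        rng = np.random.default_rng(seed)
        t = np.arange(0, days * 24, 5 / 60)
        a = np.cos(2 * np.pi * (t - 6) / 24) + rng.normal(0, noise, len(t))
        b = (np.cos(2 * np.pi * (t - 6 - delay_h) / 24)
             + rng.normal(0, noise, len(t)))
        return a, b

    def test_autocorrelation_peaks_at_zero(self):
        a, _ = self._series()
        lags, corr = crosscorr(a, a, 5 / 60)
        fit = fit_correlogram_peak(lags, corr)
        assert abs(fit.mean_h) <= 5 / 60
        assert corr[len(lags) // 2] == pytest.approx(1.0)

    @pytest.mark.parametrize("delay", [0.0, 0.5, 1.0, 1.5, 3.0])
    def test_recovers_injected_delay_within_one_bin(self, delay):
        a, b = self._series(delay_h=delay)
        lags, corr = crosscorr(a, b, 5 / 60)
        fit = fit_correlogram_peak(lags, corr)
        assert abs(fit.mean_h - delay) <= 5 / 60

    def test_cohort_delay_detected(self):
        pairs = [self._series(delay_h=1.0, noise=0.6, seed=s)
                 for s in range(12)]
        res = cohort_phase_delay(pairs, 5 / 60)
        assert res.p_value < 0.05
        assert np.mean(res.subject_lags_h) == pytest.approx(1.0, abs=0.4)

    def test_no_positive_peak_raises(self):
        with pytest.raises(ValueError, match="peak"):
            fit_correlogram_peak(np.array([-1.0, 0.0, 1.0]),
                                 np.array([-0.5, -0.8, -0.3]))


class TestDependency:
    def test_identity_curve(self):
        rng = np.random.default_rng(7)
        rr = rng.normal(size=500)
        c = delta_dependency(rr, rr, 0.5)
        slope, _ = c.slope()
        assert slope == pytest.approx(1.0, abs=1e-12)

    def test_regression_oracle_slope(self):
        rng = np.random.default_rng(8)
        rr = rng.normal(size=2000)
        other = 0.8 * rr + rng.normal(0, 0.3, 2000)
        curve = delta_dependency(rr, other, 0.25)
        slope, se = curve.slope()
        # oracle: ordinary regression of the raw difference pairs
        drr = np.diff(rr)
        dot = np.diff(other)
        beta = np.polyfit(drr, dot, 1)[0]
        assert slope == pytest.approx(beta, abs=1e-9)
        assert slope == pytest.approx(0.8, abs=3 * se)

    def test_independent_series_flat(self):
        rng = np.random.default_rng(9)
        rr = rng.normal(size=3000)
        other = rng.normal(size=3000)
        curve = delta_dependency(rr, other, 0.5)
        big = curve.n_per_bin >= 30
        assert np.nanmax(np.abs(curve.mean_delta[big])) < 0.3

    def test_gap_skips_pair(self):
        rr = np.array([0.0, 1.0, np.nan, 2.0, 2.5])
        other = rr.copy()
        curve = delta_dependency(rr, other, 0.5)
        assert len(curve.pairs) == 2  # (0,1) and (3,4) only


class TestSmoothingDetrending:
    def test_constant_profile_unchanged(self):
        t = np.arange(0, 24, 0.5)
        prof = np.full((3, len(t)), 2.0)
        out = smooth_profile(prof, t)
        assert np.allclose(out.smoothed, 2.0)

    def test_cosine_argmax_near_acrophase(self):
        t = np.arange(0, 24, 5 / 60)
        prof = np.cos(2 * np.pi * (t - 8.0) / 24)[None, :].repeat(2, axis=0)
        out = smooth_profile(prof, t)
        tmax = t[np.nanargmax(out.smoothed.to_numpy())]
        assert abs(tmax - 8.0) <= 0.5

    def test_single_subject_sem_absent(self):
        t = np.arange(0, 24, 1.0)
        out = smooth_profile(np.sin(t)[None, :], t)
        assert out["sem"].isna().all()

    def test_detrend_preserves_24h_cosine(self):
        t = np.arange(0, 96, 0.5)  # 4 whole periods
        y = np.cos(2 * np.pi * t / 24)
        d = detrend_moving_average(y, t)
        ok = np.isfinite(d)
        assert np.allclose(d[ok], y[ok], atol=0.02)

    def test_detrend_removes_linear_trend(self):
        t = np.arange(0, 96, 0.5)
        y = 0.3 * t + 2.0 * np.cos(2 * np.pi * t / 24)
        d = detrend_moving_average(y, t)
        ok = np.isfinite(d)
        amp = Cosinor(d[ok], t[ok]).fit().amplitude
        assert amp == pytest.approx(2.0, rel=0.02)

    def test_detrend_constant_is_zero(self):
        t = np.arange(0, 72, 1.0)
        d = detrend_moving_average(np.full(len(t), 5.0), t)
        ok = np.isfinite(d)
        assert np.allclose(d[ok], 0.0, atol=1e-12)


class TestHeatmap:
    def test_point_mass_before_smoothing(self):
        t = np.arange(0, 5 * 86400, 300.0)
        rr = np.full(len(t), 100.0)
        hm = rr_heatmap(rr, t, smooth=False, rr_range=(90, 110))
        cols = hm.prob.sum(axis=0)
        assert np.allclose(cols, 1.0)
        assert (hm.prob > 0).sum(axis=0).max() == 1  # one bin per column

    def test_columns_renormalised_after_smoothing(self):
        rng = np.random.default_rng(10)
        t = np.arange(0, 5 * 86400, 300.0)
        rr = rng.normal(100, 5, len(t))
        hm = rr_heatmap(rr, t)
        assert np.allclose(hm.prob.sum(axis=0), 1.0, atol=1e-9)

    def test_circular_padding_rotation_invariance(self):
        """Rotating the input by whole time bins rotates the smoothed map."""
        rng = np.random.default_rng(11)
        t = np.arange(0, 2 * 86400, 300.0)
        rr = 100 + 5 * np.cos(2 * np.pi * t / 86400) + rng.normal(0, 1, len(t))
        hm1 = rr_heatmap(rr, t, rr_range=(80, 120))
        shift_cols = 8  # 2 h in 15-min columns
        hm2 = rr_heatmap(rr, (t + shift_cols * 900.0) % 86400,
                         rr_range=(80, 120))
        assert np.allclose(np.roll(hm1.prob, shift_cols, axis=1), hm2.prob,
                           atol=1e-12)

    def test_bimodal_day_night_modes_differ(self, mouse_cohort_sweeps):
        sp = mouse_cohort_sweeps.sweep_params
        hm = rr_heatmap(sp.rr_ms.to_numpy(), sp.t0_s.to_numpy())
        centers = (hm.rr_edges_ms[:-1] + hm.rr_edges_ms[1:]) / 2
        modes = centers[np.argmax(hm.prob, axis=0)]
        light = modes[:48].mean()   # ZT0-12 columns
        dark = modes[48:].mean()
        assert light > dark  # rest-phase RR longer than active-phase RR
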