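import dataclasses

import numpy as np
import pandas as pd
import pytest

from chronolfp import (
    day_matrix, detrend_daily, diurnal_profile, fit_time_of_day,
    generate_diurnal_series, periodogram, temporal_shuffle_test,
    variance_explained, windowed_variance_explained,
    TimeOfDayModel,
)
from chronolfp.diurnal import TimeOfDayFit
from chronolfp.exceptions import AnalysisError, ValidationError
from chronolfp.simulate import noise_cv_for_fraction, sleep_indicator

from conftest import make_series


def clock_series(fn, n_days=3, interval_min=10):
    """Series whose value is a pure function of clock minutes."""
    n = n_days * (1440 // interval_min)
    s = make_series(np.zeros(n), interval_min=interval_min)
    return s.with_values(fn(s.clock_minutes))


class TestTimeOfDayFit:
    def test_bin_center_anchors_bin_mean(self):
        rng = np.random.default_rng(0)
        s = make_series(rng.lognormal(0, 0.4, 4 * 144))
        fit = fit_time_of_day(s)
        # machine-precision agreement at every bin centre
        assert np.allclose(fit.predict(fit.bin_centers), fit.bin_means,
                           rtol=0, atol=1e-12)

    def test_midpoint_interpolation(self):
        fit = TimeOfDayFit(30.0, np.arange(48, dtype=float), np.ones(48))
        fit.bin_means[0], fit.bin_means[1] = 2.0, 4.0
        # clock 30 min is midway between centres 15 and 45
        assert fit.predict([30.0])[0] == pytest.approx(3.0)

    def test_wraparound_interpolation(self):
        means = np.zeros(48)
        means[-1], means[0] = 10.0, 20.0  # centres 23:45 and 00:15
        fit = TimeOfDayFit(30.0, means, np.ones(48))
        # 23:52 = 1432 min sits 7/30 of the way from 23:45 towards 00:15
        expected = 10.0 + (20.0 - 10.0) * (1432 - 1425) / 30.0
        assert fit.predict([1432.0])[0] == pytest.approx(expected)
        # non-wrapping mode clamps instead
        flat = TimeOfDayFit(30.0, means, np.ones(48), wrap=False)
        assert flat.predict([1432.0])[0] == pytest.approx(10.0)

    def test_empty_bins_interpolated_across(self):
        s = clock_series(lambda m: 1.0 + m / 1440.0)
        # drop all afternoon samples
        keep = s.clock_minutes < 720
        sub = make_series(s.values[keep])
        sub = sub.with_values(s.values[keep])
        fit = fit_time_of_day(make_series_subset(s, keep))
        assert np.all(np.isfinite(fit.bin_means))

    def test_single_bin_rejected(self):
        s = make_series([1.0, 2.0])  # both samples in bin 0
        with pytest.raises(AnalysisError):
            fit_time_of_day(s)

    def test_bad_bin_width_rejected(self):
        s = make_series(np.ones(144))
        with pytest.raises(ValidationError):
            fit_time_of_day(s, bin_minutes=37.0)


def make_series_subset(series, mask):
    from chronolfp import BandPowerSeries
    return BandPowerSeries(series.timestamps[mask], series.values[mask],
                           sample_interval=series.sample_interval)


class TestVarianceExplained:
    def test_exact_clock_function_gives_unit_ve(self):
        # a pure clock function sampled at the bin centres: every sample's
        # fit value is its own bin mean, so the fit removes everything
        n = 3 * 48
        s = make_series(np.zeros(n), start="2021-06-01 00:15", interval_min=30)
        s = s.with_values(1.0 + np.sin(2 * np.pi * s.clock_minutes / 1440.0))
        ve = variance_explained(s)
        assert ve.ve == pytest.approx(1.0, abs=1e-12)
        assert ve.var_residual == pytest.approx(0.0, abs=1e-12)

    def test_unrelated_fit_on_noise_is_near_zero(self):
        ves = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            noise_a = make_series(rng.lognormal(0, 0.3, 30 * 144))
            noise_b = make_series(rng.lognormal(0, 0.3, 30 * 144))
            fit = fit_time_of_day(noise_a)
            ves.append(variance_explained(noise_b, fit).ve)
        assert abs(np.mean(ves)) < 0.05

    def test_recovers_generator_fraction(self, noisy_config):
        cv = noise_cv_for_fraction(noisy_config, 0.4)
        ves = []
        for seed in range(20):
            cfg = dataclasses.replace(noisy_config, noise_cv=cv, seed=seed)
            ves.append(variance_explained(generate_diurnal_series(cfg)).ve)
        assert np.mean(ves) == pytest.approx(0.40, abs=0.05)

    def test_monotone_in_true_fraction(self, noisy_config):
        means = []
        for frac in (0.1, 0.25, 0.5):
            cv = noise_cv_for_fraction(noisy_config, frac)
            ves = [variance_explained(generate_diurnal_series(
                       dataclasses.replace(noisy_config, noise_cv=cv, seed=s))).ve
                   for s in range(20)]
            means.append(np.mean(ves))
        assert means[0] < means[1] < means[2]

    def test_observed_ve_never_exceeds_one(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            s = make_series(rng.lognormal(0, 0.5, 5 * 144))
            assert variance_explained(s).ve <= 1.0

    def test_zero_variance_rejected(self):
        with pytest.raises(AnalysisError):
            variance_explained(make_series(np.full(288, 2.0)))


class TestShuffleTest:
    def test_strong_diurnal_attains_floor(self, noisy_config):
        cv = noise_cv_for_fraction(noisy_config, 0.4)
        s = generate_diurnal_series(
            dataclasses.replace(noisy_config, noise_cv=cv, seed=42))
        res = temporal_shuffle_test(s, n_shuffles=1000, seed=7)
        assert res.p_value == pytest.approx(1 / 1001)
        assert res.p_value < 0.001

    def test_null_distribution_size(self, noisy_config):
        s = generate_diurnal_series(noisy_config)
        res = temporal_shuffle_test(s, n_shuffles=200, seed=1)
        assert res.null_ve.shape == (200,)
        assert res.n_shuffles == 200

    def test_deterministic_given_seed(self, noisy_config):
        s = generate_diurnal_series(noisy_config)
        a = temporal_shuffle_test(s, 100, seed=5)
        b = temporal_shuffle_test(s, 100, seed=5)
        assert np.array_equal(a.null_ve, b.null_ve)
        assert a.p_value == b.p_value

    def test_fewer_than_two_days_rejected(self):
        s = make_series(np.random.default_rng(0).lognormal(0, 0.3, 100))
        with pytest.raises(AnalysisError):
            temporal_shuffle_test(s, 10, seed=0)

    def test_null_p_values_roughly_uniform(self, flat_config):
        # on pre-shuffled (structure-free) data p should be uniform on its
        # achievable grid; check via a KS statistic over 60 runs
        ps = []
        for seed in range(60):
            s = generate_diurnal_series(
                dataclasses.replace(flat_config, seed=100 + seed))
            ps.append(temporal_shuffle_test(s, 99, seed=seed).p_value)
        from scipy.stats import kstest
        assert kstest(ps, "uniform").pvalue > 0.01


class TestPeriodogram:
    def test_noiseless_12h_sinusoid(self):
        s = clock_series(lambda m: 3.0 + np.sin(2 * np.pi * m / 720.0),
                         n_days=12)
        res = periodogram(s)
        assert res.dominant_period_h == pytest.approx(12.0, rel=0.02)

    def test_synthetic_diurnal_dominant_24h(self, noisy_config):
        s = detrend_daily(generate_diurnal_series(noisy_config))
        res = periodogram(s)
        assert res.dominant_period_h == pytest.approx(24.0, rel=0.01)

    def test_white_noise_has_no_dominant_peak(self, flat_config):
        ratios = []
        for seed in range(20):
            s = generate_diurnal_series(
                dataclasses.replace(flat_config, seed=seed))
            res = periodogram(detrend_daily(s))
            search = (res.periods_h >= 2) & (res.periods_h <= 15 * 24)
            ratios.append(res.power[search].max()
                          / np.median(res.power[search]))
        assert np.mean(ratios) < 5.0

    def test_short_record_rejected(self):
        s = make_series(np.random.default_rng(0).lognormal(0, 0.3, 144))
        with pytest.raises(AnalysisError):
            periodogram(s)

    def test_long_gap_split_still_finds_24h(self, noisy_config):
        s = generate_diurnal_series(noisy_config)
        keep = np.ones(len(s), dtype=bool)
        keep[10 * 144:12 * 144] = False  # two-day hole
        sub = make_series_subset(s, keep)
        sub.sample_interval = s.sample_interval
        res = periodogram(detrend_daily(sub))
        assert res.dominant_period_h == pytest.approx(24.0, rel=0.01)


class TestWindowedVE:
    def test_flat_levels_have_no_within_window_structure(self, noisy_config):
        day_ves, night_ves, full_ves = [], [], []
        for seed in range(20):
            s = generate_diurnal_series(
                dataclasses.replace(noisy_config, seed=seed))
            day_ves.append(windowed_variance_explained(s, ("08:00", "20:00")).ve)
            night_ves.append(windowed_variance_explained(s, ("00:30", "05:30")).ve)
            full_ves.append(variance_explained(s).ve)
        assert abs(np.mean(day_ves)) < 0.05
        assert abs(np.mean(night_ves)) < 0.05
        assert np.mean(full_ves) > 0.3

    def test_daytime_ramp_yields_positive_day_ve(self, noisy_config):
        ves = []
        for seed in range(10):
            s = generate_diurnal_series(
                dataclasses.replace(noisy_config, seed=seed))
            ramp = 1.0 + 0.5 * np.clip((s.clock_minutes - 480) / 720, 0, 1)
            s = s.with_values(s.values * ramp)
            ves.append(windowed_variance_explained(s, ("08:00", "20:00")).ve)
        assert np.mean(ves) > 0.1

    def test_full_day_window_equals_plain_ve(self, noisy_config):
        s = generate_diurnal_series(noisy_config)
        full = windowed_variance_explained(s, ("00:00", "00:00"))
        assert full.ve == variance_explained(s).ve

    def test_empty_window_rejected(self, noisy_config):
        s = generate_diurnal_series(noisy_config)
        sub = make_series_subset(s, s.clock_minutes < 600)
        with pytest.raises(AnalysisError):
            windowed_variance_explained(sub, ("12:00", "14:00"))


class TestProfilesAndMatrix:
    def test_two_level_profile_ordering(self, step_config):
        s = detrend_daily(generate_diurnal_series(step_config))
        prof = diurnal_profile(s)
        night_bins = (prof.bin_centers_min > 30) & (prof.bin_centers_min < 330)
        day_bins = (prof.bin_centers_min > 420) & (prof.bin_centers_min < 1410)
        assert (prof.stat_per_bin[night_bins] < 1).all()
        assert (prof.stat_per_bin[day_bins] >= 1).all()

    def test_constant_series_profile_is_unity(self):
        s = detrend_daily(make_series(np.full(2 * 144, 7.0)))
        prof = diurnal_profile(s)
        assert np.allclose(prof.stat_per_bin, 1.0)
        assert prof.count_per_bin.sum() == len(s)

    def test_sinusoid_profile_matches_closed_form_bin_average(self):
        # closed form (Lagrange/Dirichlet identity) for the average of
        # sin(w(a+j)), j = 0..N-1:  sin(wa + w(N-1)/2) * sin(Nw/2)/(N sin(w/2))
        s = clock_series(lambda m: 5.0 + np.sin(2 * np.pi * m / 1440.0),
                         n_days=2, interval_min=1)
        prof = diurnal_profile(s, statistic="mean")
        w = 2 * np.pi / 1440.0
        a = np.arange(48) * 30.0
        N = 30
        exact = 5.0 + (np.sin(w * a + w * (N - 1) / 2)
                       * np.sin(N * w / 2) / (N * np.sin(w / 2)))
        assert np.allclose(prof.stat_per_bin, exact, atol=1e-10)

    def test_per_day_first_variant(self, noisy_config):
        s = detrend_daily(generate_diurnal_series(noisy_config))
        prof = diurnal_profile(s, per_day_first=True)
        assert np.isfinite(prof.stat_per_bin).all()

    def test_day_matrix_constant_series(self):
        s = detrend_daily(make_series(np.full(2 * 144, 3.0)))
        dm = day_matrix(s)
        assert dm.matrix.shape == (2, 48)
        assert np.allclose(dm.matrix, 1.0)

    def test_day_matrix_missing_cells_flagged(self, step_config):
        s = generate_diurnal_series(step_config)
        keep = ~((s.clock_minutes >= 720) & (s.clock_minutes < 1080)
                 & (s.local_dates == s.local_dates[0]))
        dm = day_matrix(make_series_subset(s, keep))
        afternoon = (dm.bin_centers_min >= 720) & (dm.bin_centers_min < 1080)
        assert np.isnan(dm.matrix[0, afternoon]).all()
        assert np.isfinite(dm.matrix[1:]).all()

    def test_day_matrix_row_medians_one_after_detrend(self, flat_config):
        # detrending pins each day's sample median at 1; for structure-free
        # noise the per-day median of bin medians concentrates there too
        s = detrend_daily(generate_diurnal_series(flat_config))
        dm = day_matrix(s)
        row_meds = np.nanmedian(dm.matrix, axis=1)
        assert np.allclose(row_meds, 1.0, atol=0.1)
        codes, _ = s.day_codes()
        for day in np.unique(codes):
            assert np.median(s.values[codes == day]) == pytest.approx(1.0)


class TestModelObjects:
    def test_fit_and_summary(self, noisy_config):
        s = detrend_daily(generate_diurnal_series(noisy_config))
        res = TimeOfDayModel(s).fit()
        res.shuffle_test(100, seed=3)
        text = res.summary()
        assert "Variance explained" in text and "Shuffle p-value" in text
        assert res.ve.ve > 0.2

    def test_from_dataframe(self, noisy_config):
        s = generate_diurnal_series(noisy_config)
        df = pd.DataFrame({"timestamp": s.timestamps, "value": s.values})
        res = TimeOfDayModel.from_dataframe(df).fit()
        assert res.ve.ve == pytest.approx(variance_explained(s).ve)

    def test_predict_at_clock_times(self, noisy_config):
        s = generate_diurnal_series(noisy_config)
        res = TimeOfDayModel(s).fit()
        lo = res.predict("03:00")[0]
        hi = res.predict("12:00")[0]
        assert lo < hi
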