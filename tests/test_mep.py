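import numpy as np
import pandas as pd
import pytest
from scipy import stats

from satrace import (SimConfig, bca_interval, buildup_slope,
                     cluster_amplitude_test, difference_records,
                     kernel_smooth, permutation_slope_test,
                     predict_mep_signal, zscore_amplitudes)
from satrace.mep import FWHM_TO_SD
from satrace.params import make_parameters


def _mep_frame(rows):
    return pd.DataFrame(rows, columns=["trial_id", "participant_id",
                                       "session", "muscle_role",
                                       "tms_latency", "amplitude"])


class TestZScore:
    def test_three_point_group_closed_form(self):
        df = _mep_frame([(i, 1, 1, "responding", 0.1 * i, float(a))
                         for i, a in enumerate((1, 2, 3))])
        z = zscore_amplitudes(df)["amplitude_z"].to_numpy()
        assert np.allclose(z, [-1.0, 0.0, 1.0])

    def test_idempotent_on_standardized_input(self, rng):
        amp = rng.normal(size=200)
        amp = (amp - amp.mean()) / amp.std(ddof=1)
        df = _mep_frame([(i, 1, 1, "responding", 0.0, a)
                         for i, a in enumerate(amp)])
        z = zscore_amplitudes(df)["amplitude_z"].to_numpy()
        assert np.allclose(z, amp, atol=1e-12)

    def test_groupwise_means_vanish(self, rng):
        rows = []
        for pid in (1, 2):
            for i in range(20):
                rows.append((i, pid, 1, "responding", 0.0,
                             rng.normal(loc=pid * 3)))
        out = zscore_amplitudes(_mep_frame(rows))
        for _, sub in out.groupby("participant_id"):
            assert sub["amplitude_z"].mean() == pytest.approx(0.0, abs=1e-12)
            assert sub["amplitude_z"].std(ddof=1) == pytest.approx(1.0)

    def test_zero_variance_group_dropped_with_warning(self):
        rows = [(i, 1, 1, "responding", 0.0, 5.0) for i in range(5)]
        rows += [(i, 2, 1, "responding", 0.0, float(i)) for i in range(5)]
        with pytest.warns(UserWarning):
            out = zscore_amplitudes(_mep_frame(rows))
        assert set(out["participant_id"]) == {2}


class TestDifferenceRecords:
    def _paired(self, resp, nonr):
        rows = []
        for i, (r, n) in enumerate(zip(resp, nonr)):
            rows.append((i, 1, 1, "responding", 0.1 * i, r))
            rows.append((i, 1, 1, "nonresponding", 0.1 * i, n))
        return _mep_frame(rows)

    def test_subtraction(self):
        t, d = difference_records(self._paired([1.2], [0.4]))
        assert d[0] == pytest.approx(0.8)

    def test_identical_amplitudes_give_zero(self):
        _, d = difference_records(self._paired([0.7, 0.7], [0.7, 0.7]))
        assert np.allclose(d, 0.0)

    def test_role_swap_negates_differences(self):
        df = self._paired([1.0, 2.0], [0.5, -0.5])
        _, d1 = difference_records(df)
        swapped = df.copy()
        swapped["muscle_role"] = swapped["muscle_role"].map(
            {"responding": "nonresponding", "nonresponding": "responding"})
        _, d2 = difference_records(swapped)
        assert np.allclose(d1, -d2)

    def test_unpaired_trial_reported_by_id(self):
        df = self._paired([1.0], [0.5])
        df = pd.concat([df, _mep_frame([(99, 1, 1, "responding", 0.3, 1.0)])])
        with pytest.raises(ValueError, match="99"):
            difference_records(df)


class TestKernelSmooth:
    GRID = np.linspace(0.0, 1.0, 101)

    def test_single_point_gives_constant_signal(self):
        sig = kernel_smooth([0.5], [2.0], self.GRID, fwhm=0.05,
                            min_effective=0.0)
        assert np.allclose(sig.values, 2.0)

    def test_symmetric_points_average_at_midpoint(self):
        for fwhm in (0.02, 0.1, 0.5):
            sig = kernel_smooth([0.4, 0.6], [0.0, 1.0], np.array([0.5]),
                                fwhm, min_effective=0.0)
            assert sig.values[0] == pytest.approx(0.5)

    def test_matches_direct_weight_formula(self):
        t = np.array([0.4, 0.6])
        y = np.array([0.0, 1.0])
        fwhm = 0.05
        sd = fwhm / (2 * np.sqrt(2 * np.log(2)))
        w = np.exp(-((0.45 - t) ** 2) / (2 * sd ** 2))
        expected = (w @ y) / w.sum()
        sig = kernel_smooth(t, y, np.array([0.45]), fwhm, min_effective=0.0)
        assert sig.values[0] == pytest.approx(expected, rel=1e-12)

    def test_output_bounded_by_input_range(self, rng):
        t = rng.random(100)
        y = rng.normal(size=100)
        sig = kernel_smooth(t, y, self.GRID, 0.05)
        ok = sig.mask
        assert np.nanmax(sig.values[ok]) <= y.max() + 1e-12
        assert np.nanmin(sig.values[ok]) >= y.min() - 1e-12

    def test_shift_equivariance(self, rng):
        t = rng.random(50)
        y = rng.normal(size=50)
        a = kernel_smooth(t, y, self.GRID, 0.05)
        b = kernel_smooth(t + 3.7, y, self.GRID + 3.7, 0.05)
        assert np.allclose(a.values, b.values, equal_nan=True)

    def test_sparse_edges_masked(self):
        sig = kernel_smooth([0.5], [1.0], np.array([0.5, 5.0]), fwhm=0.05)
        assert np.isfinite(sig.values[0])
        assert np.isnan(sig.values[1])


class TestBCa:
    def test_degenerate_data_gives_point_interval(self):
        sig = bca_interval(np.linspace(0, 1, 20), np.full(20, 3.0),
                           np.array([0.5]), 0.2, n_boot=199, seed=1)
        assert sig.ci_low[0] == sig.ci_high[0] == pytest.approx(3.0)

    def test_symmetric_distribution_bc_close_to_percentile(self, rng):
        t = rng.random(150)
        y = rng.normal(size=150)
        grid = np.array([0.5])
        sig = bca_interval(t, y, grid, 0.3, n_boot=1999, accelerated=False,
                           seed=3)
        # percentile interval from an independent plain bootstrap
        vals = []
        rng2 = np.random.default_rng(99)
        sd = 0.3 * FWHM_TO_SD
        for _ in range(1999):
            idx = rng2.integers(0, 150, 150)
            w = np.exp(-0.5 * ((0.5 - t[idx]) / sd) ** 2)
            vals.append((w @ y[idx]) / w.sum())
        lo, hi = np.quantile(vals, [0.025, 0.975])
        width = hi - lo
        assert sig.ci_low[0] == pytest.approx(lo, abs=0.15 * width)
        assert sig.ci_high[0] == pytest.approx(hi, abs=0.15 * width)

    def test_matches_reference_bca_implementation(self, rng):
        """Cross-check against scipy's BCa bootstrap of the same weighted-
        mean statistic on a small instance (different resampling stream, so
        agreement is up to bootstrap error)."""
        t = rng.random(40)
        y = t * 2.0 + rng.normal(size=40) * 0.5
        g = 0.5
        fwhm = 0.4
        sd = fwhm * FWHM_TO_SD

        def stat(t_s, y_s):
            w = np.exp(-0.5 * ((g - t_s) / sd) ** 2)
            return (w @ y_s) / w.sum()

        ref = stats.bootstrap(
            (t, y), stat, paired=True, vectorized=False, method="BCa",
            n_resamples=4999, confidence_level=0.95,
            rng=np.random.default_rng(5))
        sig = bca_interval(t, y, np.array([g]), fwhm, n_boot=4999, seed=11)
        width = ref.confidence_interval.high - ref.confidence_interval.low
        assert sig.ci_low[0] == pytest.approx(
            ref.confidence_interval.low, abs=0.1 * width)
        assert sig.ci_high[0] == pytest.approx(
            ref.confidence_interval.high, abs=0.1 * width)

    def test_band_brackets_point_estimate(self, rng):
        t = rng.random(200)
        y = np.sin(2 * np.pi * t) + rng.normal(size=200) * 0.3
        grid = np.linspace(0.1, 0.9, 30)
        sig = bca_interval(t, y, grid, 0.1, n_boot=499, seed=2)
        ok = sig.mask
        assert np.all(sig.ci_low[ok] <= sig.values[ok] + 1e-9)
        assert np.all(sig.ci_high[ok] >= sig.values[ok] - 1e-9)


class TestSlope:
    def test_exact_line_recovered(self):
        grid = np.linspace(0, 1, 101)
        from satrace.signal import Signal
        sig = Signal("stimulus", grid, 2.0 * grid)
        assert buildup_slope(sig, (0.2, 0.8)) == pytest.approx(2.0)

    def test_constant_signal_has_zero_slope(self):
        grid = np.linspace(0, 1, 101)
        from satrace.signal import Signal
        sig = Signal("stimulus", grid, np.full(101, 0.7))
        assert buildup_slope(sig, (0.0, 1.0)) == pytest.approx(0.0)

    def test_matches_polyfit_on_noisy_line(self, rng):
        grid = np.linspace(0, 1, 101)
        vals = 1.3 * grid + rng.normal(size=101) * 0.1
        from satrace.signal import Signal
        sig = Signal("stimulus", grid, vals)
        sel = (grid >= 0.25) & (grid <= 0.75)
        expected = np.polyfit(grid[sel], vals[sel], 1)[0]
        assert buildup_slope(sig, (0.25, 0.75)) == pytest.approx(expected)

    def test_window_outside_grid_rejected(self):
        from satrace.signal import Signal
        sig = Signal("stimulus", np.linspace(0, 1, 11), np.zeros(11))
        with pytest.raises(ValueError):
            buildup_slope(sig, (0.5, 1.5))


class TestPermutationSlopeTest:
    GRID = np.linspace(0.0, 1.0, 51)

    def test_identical_groups_give_zero_and_null_p(self, rng):
        """Duplicating one group gives a zero observed difference; the
        two-sided permutation p sits at the top of its range (the null is
        symmetric around the observed value)."""
        t = rng.random(80)
        y = rng.normal(size=80)
        obs, p = permutation_slope_test((t, y), (t.copy(), y.copy()),
                                        (0.2, 0.8), self.GRID, 0.1,
                                        n_perm=199, seed=0)
        assert obs == pytest.approx(0.0, abs=1e-12)
        assert p >= 0.9

    def test_large_injected_slope_detected(self, rng):
        t_a = rng.random(150)
        t_b = rng.random(150)
        y_a = rng.normal(size=150) * 0.2
        y_b = 5.0 * t_b + rng.normal(size=150) * 0.2
        _, p = permutation_slope_test((t_a, y_a), (t_b, y_b), (0.1, 0.9),
                                      self.GRID, 0.1, n_perm=399, seed=1)
        assert p < 0.01

    def test_too_few_permutations_rejected(self, rng):
        t = rng.random(10)
        with pytest.raises(ValueError):
            permutation_slope_test((t, t), (t, t), (0.2, 0.8), self.GRID,
                                   0.1, n_perm=10)


class TestClusterTest:
    GRID = np.linspace(0.0, 1.0, 41)

    def test_identical_groups_have_no_clusters(self, rng):
        t = rng.random(120)
        y = rng.normal(size=120)
        out = cluster_amplitude_test((t, y), (t.copy(), y.copy()), self.GRID,
                                     0.12, n_boot=199, n_perm=49, seed=0)
        assert out == []

    def test_huge_offset_yields_significant_full_span_cluster(self, rng):
        t_a = rng.random(150)
        t_b = rng.random(150)
        y_a = rng.normal(size=150) * 0.1
        y_b = rng.normal(size=150) * 0.1 + 3.0
        out = cluster_amplitude_test((t_a, y_a), (t_b, y_b), self.GRID,
                                     0.12, n_boot=199, n_perm=99, seed=1)
        assert len(out) == 1
        cl = out[0]
        assert cl["p"] == pytest.approx(1.0 / 100.0)
        span = cl["end"] - cl["start"]
        assert span > 0.9 * (self.GRID[-1] - self.GRID[0])
        assert cl["sum"] < 0  # group A sits 3 units below group B


class TestPredictMepSignal:
    def test_zero_noise_pulse_reads_closed_form_difference(self):
        params = make_parameters(
            a_speed=1.0, sz_accuracy=0.0, sz_speed=0.0,
            v_correct_easy=2.0, v_correct_hard=1.0,
            v_incorrect_easy=0.5, v_incorrect_hard=0.25,
            noise_sd=0.0, t_er=0.3, s_ter=0.0)
        dt = 0.01
        pulse = 0.3 + 10 * dt  # ten steps after accumulation onset
        sched = {("accuracy", "easy"): np.array([pulse])}
        grid = np.array([pulse])
        preds = predict_mep_signal(params, sched,
                                   SimConfig(dt, 5.0, 50, 3), scale=2.0,
                                   grid_stim=grid, grid_resp=np.array([-0.1]),
                                   fwhm=0.05)
        sig_s, _ = preds[("accuracy", "easy")]
        expected = (2.0 - 0.5) * 10 * dt * 2.0
        assert sig_s.values[0] == pytest.approx(expected, rel=1e-9)

    def test_pulse_before_accumulation_onset_reads_zero(self):
        params = make_parameters(
            a_speed=1.0, sz_accuracy=0.4, sz_speed=0.4,
            v_correct_easy=2.0, v_correct_hard=1.0,
            v_incorrect_easy=0.0, v_incorrect_hard=0.0,
            noise_sd=0.0, t_er=0.3, s_ter=0.0)
        sched = {("accuracy", "easy"): np.array([0.1])}
        preds = predict_mep_signal(params, sched,
                                   SimConfig(0.01, 5.0, 50, 3), scale=1.0,
                                   grid_stim=np.array([0.1]),
                                   grid_resp=np.array([-0.1]), fwhm=0.05)
        sig_s, _ = preds[("accuracy", "easy")]
        assert sig_s.values[0] == pytest.approx(0.0, abs=1e-12)

    def test_pulses_after_response_are_censored(self):
        # deterministic RT = 0.3 + 0.5; every pulse arrives later -> no
        # surviving samples and the smoother has nothing to average
        params = make_parameters(
            a_speed=1.0, sz_accuracy=0.0, sz_speed=0.0,
            v_correct_easy=2.0, v_correct_hard=2.0,
            v_incorrect_easy=0.0, v_incorrect_hard=0.0,
            noise_sd=0.0, t_er=0.3, s_ter=0.0)
        sched = {("accuracy", "easy"): np.array([2.0])}
        with pytest.raises(ValueError):
            predict_mep_signal(params, sched, SimConfig(0.01, 5.0, 20, 3),
                               1.0, np.array([2.0]), np.array([-0.1]), 0.05)
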