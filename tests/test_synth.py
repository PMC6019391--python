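import numpy as np
import pandas as pd
import pytest
from scipy import stats

from satrace import (NondecisionSplit, ReadoutModel, SimConfig, StudyDesign,
                     censored_average, generate_behavior, generate_cpp_epochs,
                     generate_mep_records, generate_tms_schedule,
                     predict_cpp_traces)


def small_design(**kw):
    base = dict(n_participants=2, trials_per_cell=100, dropout=0.0,
                t_er_jitter=0.0)
    base.update(kw)
    return StudyDesign(**base)


class TestBehavior:
    def test_fixed_seed_reproduces_csv_bytes(self, small_params, tmp_path):
        d = small_design()
        t1, _ = generate_behavior(small_params, d, seed=5)
        t2, _ = generate_behavior(small_params, d, seed=5)
        assert t1.to_csv(index=False) == t2.to_csv(index=False)

    def test_zero_participants_gives_empty_table(self, small_params):
        t, truth = generate_behavior(small_params,
                                     small_design(n_participants=0), seed=1)
        assert len(t) == 0
        assert truth["participants"] == []

    def test_easy_more_accurate_than_hard(self, tms_params):
        d = small_design(n_participants=1, trials_per_cell=5000)
        t, _ = generate_behavior(tms_params, d, seed=3)
        acc = t[t["choice"] != "none"].groupby(
            ["instruction", "difficulty"], observed=True)["choice"].apply(
            lambda c: (c == "correct").mean())
        for ins in ("accuracy", "speed"):
            assert acc[(ins, "easy")] > acc[(ins, "hard")]

    def test_manifest_records_participant_seeds(self, small_params):
        t, truth = generate_behavior(small_params, small_design(), seed=9)
        assert len(truth["participants"]) == 2
        for part in truth["participants"]:
            sub = t[t["participant_id"] == part["participant_id"]]
            assert sub["trial_seed"].iloc[0] == part["seed"]


class TestSchedule:
    def test_zero_fraction_gives_empty_schedule(self, small_params):
        t, _ = generate_behavior(small_params, small_design(), seed=2)
        sched = generate_tms_schedule(t, small_design(tms_fraction=0.0), 3)
        assert len(sched) == 0

    def test_bins_equiprobable_chi_square(self, small_params):
        d = small_design(n_participants=1, trials_per_cell=2500,
                         tms_fraction=1.0)
        t, _ = generate_behavior(small_params, d, seed=4)
        sched = generate_tms_schedule(t, d, 5)
        counts = sched["bin"].value_counts().reindex([1, 2, 3, 4]).to_numpy()
        assert stats.chisquare(counts).pvalue > 0.001

    def test_pulse_cancelled_when_response_first(self, small_params):
        d = small_design(tms_fraction=1.0)
        t, _ = generate_behavior(small_params, d, seed=6)
        sched = generate_tms_schedule(t, d, 7)
        merged = sched.merge(t[["trial_id", "rt"]], on="trial_id")
        cancelled = ~merged["delivered"]
        assert (merged.loc[cancelled, "rt"] <=
                merged.loc[cancelled, "pulse_time"]).all()

    def test_all_delivered_when_rts_exceed_window(self, small_params):
        d = small_design(tms_fraction=1.0)
        t, _ = generate_behavior(small_params, d, seed=6)
        t = t.copy()
        t["rt"] = 99.0
        sched = generate_tms_schedule(t, d, 7)
        assert sched["delivered"].all()

    def test_pulse_times_within_instruction_window(self, small_params):
        d = small_design(tms_fraction=1.0)
        t, _ = generate_behavior(small_params, d, seed=8)
        sched = generate_tms_schedule(t, d, 9)
        for ins, (lo, hi) in d.tms_windows.items():
            sub = sched[sched["instruction"] == ins]
            assert sub["pulse_time"].between(lo, hi).all()


class TestMepRecords:
    def test_noiseless_readout_equals_accumulator_state(self, small_params):
        d = small_design(tms_fraction=1.0)
        t, truth = generate_behavior(small_params, d, seed=11)
        sched = generate_tms_schedule(t, d, 12)
        readout = ReadoutModel(mep_gain=1.0, mep_baseline=0.0,
                               mep_noise_sd=0.0)
        recs = generate_mep_records(t, sched, small_params, readout, 13,
                                    design=d)
        assert len(recs) > 0
        assert np.allclose(recs["amplitude"], recs["x_true"])
        # paired structure: one responding + one nonresponding per trial
        roles = recs.groupby("trial_id")["muscle_role"].apply(
            lambda r: sorted(r))
        assert all(r == ["nonresponding", "responding"] for r in roles)

    def test_gain_and_baseline_applied(self, small_params):
        d = small_design(tms_fraction=1.0)
        t, _ = generate_behavior(small_params, d, seed=11)
        sched = generate_tms_schedule(t, d, 12)
        readout = ReadoutModel(mep_gain=2.0, mep_baseline=0.5,
                               mep_noise_sd=0.0)
        recs = generate_mep_records(t, sched, small_params, readout, 13,
                                    design=d)
        assert np.allclose(recs["amplitude"],
                           0.5 + 2.0 * recs["x_true"])

    def test_zero_gain_difference_has_zero_mean(self, small_params):
        d = small_design(n_participants=1, trials_per_cell=2000,
                         tms_fraction=1.0)
        t, _ = generate_behavior(small_params, d, seed=14)
        sched = generate_tms_schedule(t, d, 15)
        readout = ReadoutModel(mep_gain=0.0, mep_noise_sd=1.0)
        recs = generate_mep_records(t, sched, small_params, readout, 16,
                                    design=d)
        resp = recs[recs["muscle_role"] == "responding"].set_index("trial_id")
        nonr = recs[recs["muscle_role"] == "nonresponding"].set_index(
            "trial_id")
        diff = (resp["amplitude"] - nonr.loc[resp.index, "amplitude"])
        t_stat = diff.mean() / (diff.std(ddof=1) / np.sqrt(len(diff)))
        assert abs(t_stat) < 4.0

    def test_dropout_removes_trials(self, small_params):
        d_full = small_design(n_participants=1, trials_per_cell=1000,
                              tms_fraction=1.0)
        t, _ = generate_behavior(small_params, d_full, seed=17)
        sched = generate_tms_schedule(t, d_full, 18)
        readout = ReadoutModel(mep_noise_sd=0.0)
        full = generate_mep_records(t, sched, small_params, readout, 19,
                                    design=d_full)
        d_drop = small_design(n_participants=1, trials_per_cell=1000,
                              tms_fraction=1.0, dropout=0.5)
        dropped = generate_mep_records(t, sched, small_params, readout, 19,
                                       design=d_drop)
        frac = len(dropped) / len(full)
        assert 0.4 < frac < 0.6


class TestCppEpochs:
    GRID = np.arange(-0.2, 3.0, 0.01)

    def _early_window(self, eps, n_col=60):
        """Samples every trial is guaranteed to cover (before the earliest
        response censors anything)."""
        alive = eps.rt > self.GRID[n_col] + 0.05
        x = eps.data[alive][:, :n_col]
        return x[np.isfinite(x).all(axis=1)]

    def test_noiseless_epochs_match_prediction_exactly(self, small_params):
        """With no observation noise, unit gain and no participant jitter,
        censored averages of generated epochs equal the model's own
        censored-average prediction (same seeds end to end)."""
        d = small_design(n_participants=1, trials_per_cell=300)
        t, _ = generate_behavior(small_params, d, seed=21)
        t_er = small_params.t_er_for("accuracy")
        split = NondecisionSplit.from_t_er(t_er, t_er - 0.1)
        readout = ReadoutModel(epoch_gain=1.0, epoch_noise_sd=0.0)
        eps = generate_cpp_epochs(t, small_params, split, readout, 22,
                                  grid=self.GRID,
                                  sim=SimConfig(0.01, 5.0, 1, 21))
        corr = eps.labels["choice"] == "correct"
        from satrace.cpp import EpochSet
        obs = censored_average(
            EpochSet(self.GRID, eps.data[corr.to_numpy()],
                     eps.rt[corr.to_numpy()]), "stimulus")
        cells = sorted(small_params.cells)
        pred = predict_cpp_traces(small_params, split,
                                  SimConfig(0.01, 5.0, 300, 21),
                                  self.GRID, cells=cells)
        pooled_data = np.vstack([pred[c].data for c in cells])
        pooled_rt = np.concatenate([pred[c].rt for c in cells])
        exp = censored_average(EpochSet(self.GRID, pooled_data, pooled_rt),
                               "stimulus")
        assert np.allclose(obs.values, exp.values, equal_nan=True)

    def test_white_noise_has_no_lag_one_autocorrelation(self, small_params):
        d = small_design(n_participants=1, trials_per_cell=30)
        t, _ = generate_behavior(small_params, d, seed=23)
        readout = ReadoutModel(epoch_gain=0.0, epoch_noise_sd=1.0,
                               epoch_ar1=0.0)
        eps = generate_cpp_epochs(t, small_params, NondecisionSplit(0.1, 0.2),
                                  readout, 24, grid=self.GRID,
                                  sim=SimConfig(0.01, 5.0, 1, 23))
        x = self._early_window(eps)
        r1 = np.mean([np.corrcoef(row[:-1], row[1:])[0, 1] for row in x])
        assert abs(r1) < 0.05

    def test_ar1_noise_is_autocorrelated(self, small_params):
        d = small_design(n_participants=1, trials_per_cell=30)
        t, _ = generate_behavior(small_params, d, seed=23)
        readout = ReadoutModel(epoch_gain=0.0, epoch_noise_sd=1.0,
                               epoch_ar1=0.8)
        eps = generate_cpp_epochs(t, small_params, NondecisionSplit(0.1, 0.2),
                                  readout, 24, grid=self.GRID,
                                  sim=SimConfig(0.01, 5.0, 1, 23))
        x = self._early_window(eps)
        r1 = np.mean([np.corrcoef(row[:-1], row[1:])[0, 1] for row in x])
        assert r1 > 0.6

    def test_zero_gain_average_flat_within_noise(self, small_params):
        d = small_design(n_participants=1, trials_per_cell=200)
        t, _ = generate_behavior(small_params, d, seed=25)
        readout = ReadoutModel(epoch_gain=0.0, epoch_noise_sd=0.5,
                               epoch_ar1=0.0)
        eps = generate_cpp_epochs(t, small_params, NondecisionSplit(0.1, 0.2),
                                  readout, 26, grid=self.GRID,
                                  sim=SimConfig(0.01, 5.0, 1, 25))
        sig = censored_average(eps, "stimulus")
        ok = (sig.n_effective > 100)
        assert np.nanmax(np.abs(sig.values[ok])) < 5 * 0.5 / np.sqrt(100)
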