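"""Synthetic study generation with known ground truth.

Emulates the structure of a speed/accuracy random-dot study well enough to
exercise every pipeline stage without any empirical data: behavioral trial
tables generated by the race model under the 2x2 instruction x difficulty
design, a four-bin TMS stimulation schedule planned on a fraction of trials
with pulse cancellation when the response precedes the pulse, MEP amplitudes
as noisy linear readouts of the accumulator states at the pulse time, and
CPP-like epochs as noisy summed-accumulator traces censored at the response.

Because each simulated trial carries its own seed, the generators can
re-derive the exact accumulator state of any trial at any time — the
ground-truth manifest is the (parameters, design, seeds) triple.

The observation models are deliberately simple stand-ins for physiology:
MEP noise is Gaussian on the z-scale, epoch noise is stationary AR(1), and
attrition (artifact rejection, amplifier saturation, pre-pulse muscle
activity) is a single random dropout rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .cpp import EpochSet, NondecisionSplit
from .params import ModelParameters
from .simulate import (SimConfig, _race_probe_kernel, _race_trace_kernel,
                       cell_seed, simulate_dataset)

CELL_ORDER = (("accuracy", "easy"), ("accuracy", "hard"),
              ("speed", "easy"), ("speed", "hard"))


@dataclass(frozen=True)
class StudyDesign:
    """Structural constants of a synthetic study.

    ``tms_windows`` give the planned-pulse window per instruction in the
    declared time unit (5-500 ms after motion onset under speed and 5-600 ms
    under accuracy instructions, here expressed in the declared unit);
    pulses are planned on ``tms_fraction`` of trials in four equal-width,
    equiprobable bins.  ``dropout`` is the fraction of MEP records lost to
    (emulated) artifact attrition.
    """

    n_participants: int = 18
    trials_per_cell: int = 324  # per participant, pooled over sessions
    tms_fraction: float = 0.66
    tms_windows: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"speed": (0.0125, 1.25),
                                 "accuracy": (0.0125, 1.5)})
    n_bins: int = 4
    dropout: float = 0.3565
    t_er_jitter: float = 0.05  # relative participant jitter on T_er
    unit: str = "fraction"  # of median RT; or 'ms' / 's'
    epoch_grid: np.ndarray | None = None

    def validate(self) -> None:
        if not 0 <= self.tms_fraction <= 1:
            raise ValueError("tms_fraction must lie in [0, 1]")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        for ins, (lo, hi) in self.tms_windows.items():
            if not (0 <= lo < hi):
                raise ValueError(f"invalid TMS window for {ins}")


@dataclass(frozen=True)
class ReadoutModel:
    """Linear observation model mapping accumulator state to signals."""

    mep_gain: float = 1.0
    mep_baseline: float = 0.0
    mep_noise_sd: float = 1.0
    epoch_gain: float = 25.0
    epoch_noise_sd: float = 10.0
    epoch_ar1: float = 0.9

    def validate(self) -> None:
        if self.mep_noise_sd < 0 or self.epoch_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if not abs(self.epoch_ar1) < 1:
            raise ValueError("|AR(1) coefficient| must be < 1")


def generate_behavior(
    params: ModelParameters,
    design: StudyDesign,
    seed: int,
    sim: SimConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate the behavioral trial table of a whole synthetic study.

    Each participant gets a mild uniform jitter on T_er (the study pooled
    trials, so heterogeneity is minimal by default).  Returns the table plus
    a ground-truth manifest sufficient to regenerate every derived quantity.
    """
    design.validate()
    if sim is None:
        sim = SimConfig(dt=0.01, max_time=5.0, n_trials=design.trials_per_cell,
                        seed=seed)
    rng = np.random.default_rng(seed)
    frames = []
    truth_parts = []
    for p in range(design.n_participants):
        jit = 1.0 + design.t_er_jitter * (2 * rng.random() - 1)
        t_er = {ins: te * jit for ins, te in params.t_er.items()}
        p_params = ModelParameters.from_cells(params.cells, t_er,
                                              params.s_ter,
                                              params.scaling_reference)
        p_seed = cell_seed(seed, 101 * p)
        tab = simulate_dataset(
            p_params,
            [(ins, diff, design.trials_per_cell) for ins, diff in CELL_ORDER],
            SimConfig(sim.dt, sim.max_time, design.trials_per_cell, p_seed),
        )
        tab.insert(0, "session", 1)
        tab.insert(0, "participant_id", p + 1)
        frames.append(tab)
        truth_parts.append({"participant_id": p + 1, "t_er": t_er,
                            "seed": p_seed})
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["participant_id", "session", "instruction", "difficulty",
                 "choice", "decision_time", "rt", "start_correct",
                 "start_incorrect", "trial_seed"])
    table.insert(0, "trial_id", np.arange(len(table)))
    truth = {
        "parameters": params.to_dict(),
        "design": {k: v for k, v in asdict(design).items()
                   if k != "epoch_grid"},
        "sim": {"dt": sim.dt, "max_time": sim.max_time},
        "seed": seed,
        "participants": truth_parts,
    }
    return table, truth


def generate_tms_schedule(
    trials: pd.DataFrame,
    design: StudyDesign,
    seed: int,
) -> pd.DataFrame:
    """Plan TMS pulses for a trial table.

    A pulse is planned on ``tms_fraction`` of trials; its bin is uniform over
    the four equal-width bins of the instruction's window and the exact time
    uniform within the bin.  ``delivered`` is False when the trial's response
    preceded the planned pulse (the pulse is cancelled).
    """
    design.validate()
    rng = np.random.default_rng(seed)
    n = len(trials)
    planned = rng.random(n) < design.tms_fraction
    bins = rng.integers(0, design.n_bins, size=n)
    u = rng.random(n)
    rows = []
    for i, (idx, tr) in enumerate(trials.iterrows()):
        if not planned[i]:
            continue
        lo, hi = design.tms_windows[tr["instruction"]]
        width = (hi - lo) / design.n_bins
        pulse = lo + (bins[i] + u[i]) * width
        rt = tr["rt"]
        delivered = bool(np.isnan(rt) or rt > pulse)
        rows.append({
            "trial_id": tr["trial_id"],
            "instruction": tr["instruction"],
            "difficulty": tr["difficulty"],
            "bin": int(bins[i]) + 1,
            "pulse_time": pulse,
            "delivered": delivered,
        })
    return pd.DataFrame(
        rows, columns=["trial_id", "instruction", "difficulty", "bin",
                       "pulse_time", "delivered"])


def generate_mep_records(
    trials: pd.DataFrame,
    schedule: pd.DataFrame,
    params: ModelParameters,
    readout: ReadoutModel,
    seed: int,
    sim: SimConfig | None = None,
    design: StudyDesign | None = None,
    participant_t_er: Mapping[int, Mapping[str, float]] | None = None,
) -> pd.DataFrame:
    """Paired responding/nonresponding MEP amplitudes for delivered pulses.

    Re-simulates each trial from its stored seed to read both accumulators at
    the pulse time, then applies the linear readout with Gaussian noise:
    responding amplitude tracks the chosen response's accumulator,
    nonresponding the other.  Random dropout emulates artifact attrition.
    """
    readout.validate()
    if sim is None:
        sim = SimConfig(dt=0.01, max_time=5.0, n_trials=1, seed=seed)
    sched = schedule[schedule["delivered"]]
    merged = sched.merge(trials, on=["trial_id", "instruction", "difficulty"],
                         how="left")
    rng = np.random.default_rng(cell_seed(seed, 17))
    rows = []
    group_cols = ["participant_id", "instruction", "difficulty"]
    for (pid, ins, diff), sub in merged.groupby(group_cols, observed=True):
        cp = params.cell(ins, diff)
        # use the participant's jittered T_er when the manifest provides it,
        # so re-simulated trajectories match the behavioral table exactly
        if participant_t_er is not None and pid in participant_t_er:
            t_er = participant_t_er[pid][ins]
        else:
            t_er = params.t_er_for(ins)
        seeds = sub["trial_seed"].to_numpy(np.int64)
        pulses = sub["pulse_time"].to_numpy(float)
        choice, rts, pc, pi = _race_probe_kernel(
            len(sub), cp.boundary, cp.start_range, cp.drift_correct,
            cp.drift_incorrect, cp.noise_sd, t_er, params.s_ter,
            sim.dt, sim.max_steps, seeds, pulses,
        )
        for k in range(len(sub)):
            ch = choice[k]
            if ch == 0:
                continue
            x_resp, x_nonr = (pc[k], pi[k]) if ch == 1 else (pi[k], pc[k])
            noise_r, noise_n = rng.normal(size=2) * readout.mep_noise_sd
            base = {
                "trial_id": sub["trial_id"].iloc[k],
                "participant_id": pid,
                "session": sub["session"].iloc[k] if "session" in sub else 1,
                "instruction": ins,
                "difficulty": diff,
                "choice": "correct" if ch == 1 else "incorrect",
                "tms_latency": pulses[k],
                "rt": rts[k],
            }
            rows.append({**base, "muscle_role": "responding",
                         "amplitude": readout.mep_baseline
                         + readout.mep_gain * x_resp + noise_r,
                         "x_true": x_resp})
            rows.append({**base, "muscle_role": "nonresponding",
                         "amplitude": readout.mep_baseline
                         + readout.mep_gain * x_nonr + noise_n,
                         "x_true": x_nonr})
    records = pd.DataFrame(rows)
    if design is not None and design.dropout > 0 and len(records):
        kept_trials = records["trial_id"].unique()
        keep = rng.random(kept_trials.size) >= design.dropout
        records = records[records["trial_id"].isin(kept_trials[keep])]
        records = records.reset_index(drop=True)
    return records


def generate_cpp_epochs(
    trials: pd.DataFrame,
    params: ModelParameters,
    split: NondecisionSplit,
    readout: ReadoutModel,
    seed: int,
    grid: np.ndarray,
    sim: SimConfig | None = None,
) -> EpochSet:
    """ERP-like epochs: gain x summed-accumulator trace + AR(1) noise.

    Traces are re-derived from each trial's stored seed with the sensory/
    motor split applied (onset after T_e with the S_Ter jitter, accumulation
    continuing for T_r after the boundary); epochs are censored at the
    response, and the pre-stimulus baseline region is pure noise.
    """
    readout.validate()
    grid = np.asarray(grid, float)
    if sim is None:
        sim = SimConfig(dt=float(grid[1] - grid[0]), max_time=float(grid[-1]),
                        n_trials=1, seed=seed)
    rng = np.random.default_rng(cell_seed(seed, 23))
    all_traces, all_rts, labels = [], [], []
    group_cols = ["participant_id", "instruction", "difficulty"]
    for (pid, ins, diff), sub in trials.groupby(group_cols, observed=True):
        cp = params.cell(ins, diff)
        seeds = sub["trial_seed"].to_numpy(np.int64)
        traces, rts, choice = _race_trace_kernel(
            len(sub), cp.boundary, cp.start_range, cp.drift_correct,
            cp.drift_incorrect, cp.noise_sd, split.t_e, split.t_r,
            params.s_ter, sim.dt, sim.max_steps, seeds, grid,
        )
        all_traces.append(traces)
        all_rts.append(rts)
        labels.append(pd.DataFrame({
            "trial_id": sub["trial_id"].to_numpy(),
            "participant_id": pid, "instruction": ins, "difficulty": diff,
            "choice": np.where(choice == 1, "correct",
                               np.where(choice == -1, "incorrect", "none")),
        }))
    data = np.vstack(all_traces) * readout.epoch_gain
    if readout.epoch_noise_sd > 0:
        n_tr, n_g = data.shape
        eps = rng.normal(size=(n_tr, n_g)) * readout.epoch_noise_sd
        if readout.epoch_ar1 != 0:
            phi = readout.epoch_ar1
            ar = np.empty_like(eps)
            ar[:, 0] = eps[:, 0]
            innov_sd = np.sqrt(1 - phi ** 2)
            for g in range(1, n_g):
                ar[:, g] = phi * ar[:, g - 1] + innov_sd * eps[:, g]
            eps = ar
        data = data + eps  # NaN (censored) samples stay NaN
    return EpochSet(
        grid=grid, data=data, rt=np.concatenate(all_rts),
        labels=pd.concat(labels, ignore_index=True),
    )


def tms_design(**overrides) -> StudyDesign:
    """TMS-style preset: time normalized to median RT (median ~ 1)."""
    return StudyDesign(**overrides)


def eeg_design(**overrides) -> StudyDesign:
    """EEG-style preset: milliseconds... of a ~ 1 s decision epoch.

    Epoch grid -200..2000 ms at 10-ms steps stimulus-locked; TMS fields are
    unused for EEG-style studies.
    """
    defaults = dict(
        n_participants=23, trials_per_cell=200, tms_fraction=0.0,
        dropout=0.0, unit="ms",
        tms_windows={"speed": (5.0, 500.0), "accuracy": (5.0, 600.0)},
        epoch_grid=np.arange(-200.0, 2000.0 + 5.0, 10.0),
    )
    defaults.update(overrides)
    return StudyDesign(**defaults)
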