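"""Centroparietal-positivity (CPP) style predictions from the race model.

The CPP is a parietal ERP whose build-up tracks decision evidence regardless
of the response effector, so it is modelled as the *sum* of the two
accumulators.  Sensory and motor parts of non-decision time matter here: the
summed trace stays flat for an encoding delay ``T_e``, accumulates until the
boundary is reached, then keeps accumulating for a motor duration ``T_r``
(the stimulus is still on until the overt response), with
``T_e + T_r = T_er``.  Each trial's trace is baseline-corrected by its first
sample, and condition averages censor every trial from the moment it has
responded — the same censored averaging applied to empirical epochs.

The split of ``T_er`` into ``T_e``/``T_r`` and a single amplitude scale are
free when matching predictions to an observed signal, shared across all
conditions and both time alignments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .params import ModelParameters
from .signal import Signal
from .simulate import SimConfig, _race_trace_kernel, cell_seed, trial_seeds


@dataclass(frozen=True)
class NondecisionSplit:
    """Division of non-decision time into sensory (T_e) and motor (T_r)."""

    t_e: float
    t_r: float

    def __post_init__(self):
        if self.t_e < 0 or self.t_r < 0:
            raise ValueError("T_e and T_r must be >= 0")

    @property
    def t_er(self) -> float:
        return self.t_e + self.t_r

    @staticmethod
    def from_t_er(t_er: float, t_e: float) -> "NondecisionSplit":
        if not 0 <= t_e <= t_er:
            raise ValueError("T_e must lie in [0, T_er]")
        return NondecisionSplit(t_e, t_er - t_e)


@dataclass
class EpochSet:
    """Per-trial time series on a shared grid, with per-trial RTs.

    ``data`` is (n_trials, n_grid); NaN marks undefined samples (a trial is
    undefined after its response).  ``rt`` is np.inf for non-responses.
    """

    grid: np.ndarray
    data: np.ndarray
    rt: np.ndarray
    labels: pd.DataFrame | None = None
    alignment: str = "stimulus"

    def __post_init__(self):
        self.grid = np.asarray(self.grid, float)
        self.data = np.asarray(self.data, float)
        self.rt = np.asarray(self.rt, float)
        if self.data.ndim != 2 or self.data.shape[1] != self.grid.size:
            raise ValueError("data must be (n_trials, n_grid)")
        if self.rt.shape != (self.data.shape[0],):
            raise ValueError("rt must have one entry per trial")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


def predict_cpp_traces(
    params: ModelParameters,
    split: NondecisionSplit,
    sim: SimConfig,
    grid: np.ndarray,
    cells: Sequence[tuple[str, str]] | None = None,
    correct_only: bool = True,
) -> dict[tuple[str, str], EpochSet]:
    """Simulate summed-accumulator epochs per condition cell on ``grid``.

    The uniform non-decision spread S_Ter jitters the sensory onset T_e
    (mirroring the MEP-side convention); simulated RT = boundary crossing +
    T_r, so the RT distribution matches the behavioral simulation with
    T_er = T_e + T_r.  With ``correct_only`` (default) error and non-response
    trials are dropped, matching the empirical conditioning on correct
    responses.
    """
    params.validate()
    sim.validate()
    grid = np.asarray(grid, float)
    out = {}
    cell_list = cells if cells is not None else sorted(params.cells)
    for j, cell in enumerate(cell_list):
        ins, diff = cell
        cp = params.cell(ins, diff)
        traces, rts, choice = _race_trace_kernel(
            sim.n_trials, cp.boundary, cp.start_range, cp.drift_correct,
            cp.drift_incorrect, cp.noise_sd, split.t_e, split.t_r,
            params.s_ter, sim.dt, sim.max_steps,
            trial_seeds(cell_seed(sim.seed, j), sim.n_trials), grid,
        )
        if correct_only:
            keep = choice == 1
            traces, rts = traces[keep], rts[keep]
        labels = pd.DataFrame({
            "instruction": ins, "difficulty": diff,
        }, index=range(traces.shape[0]))
        out[cell] = EpochSet(grid=grid, data=traces, rt=rts, labels=labels)
    return out


def baseline_correct(epochs: EpochSet) -> EpochSet:
    """Shift every trial so its first sample is zero."""
    if epochs.n_trials == 0:
        raise ValueError("empty epoch set")
    base = epochs.data[:, [0]]
    return EpochSet(grid=epochs.grid, data=epochs.data - base,
                    rt=epochs.rt, labels=epochs.labels,
                    alignment=epochs.alignment)


def censored_average(
    epochs: EpochSet,
    alignment: str = "stimulus",
    grid_resp: np.ndarray | None = None,
) -> Signal:
    """Average epochs with response censoring.

    Stimulus-locked: at each grid time ``t`` only trials with ``rt > t``
    (and a defined sample) contribute.  Response-locked: traces are aligned
    at each trial's response and averaged over the trials covering each
    pre-response time; times after the response are masked.
    """
    if alignment == "stimulus":
        alive = epochs.rt[:, None] > epochs.grid[None, :]
        vals = np.where(alive, epochs.data, np.nan)
        fin = np.isfinite(vals)
        n_eff = fin.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(n_eff > 0,
                            np.where(fin, vals, 0.0).sum(axis=0)
                            / np.maximum(n_eff, 1.0), np.nan)
        return Signal("stimulus", epochs.grid, mean, n_effective=n_eff)
    if alignment != "response":
        raise ValueError("alignment must be 'stimulus' or 'response'")
    if grid_resp is None:
        span = epochs.grid[-1] - epochs.grid[0]
        h = epochs.grid[1] - epochs.grid[0]
        grid_resp = -np.arange(0, span + h / 2, h)[::-1]
    h = epochs.grid[1] - epochs.grid[0]
    g0 = epochs.grid[0]
    n_grid = epochs.grid.size
    sums = np.zeros(grid_resp.size)
    cnts = np.zeros(grid_resp.size)
    for i in range(epochs.n_trials):
        rt = epochs.rt[i]
        if not np.isfinite(rt):
            continue
        t_abs = rt + grid_resp
        idx = np.round((t_abs - g0) / h).astype(int)
        ok = (grid_resp <= 1e-12) & (idx >= 0) & (idx < n_grid)
        vi = np.full(grid_resp.size, np.nan)
        vi[ok] = epochs.data[i, idx[ok]]
        fin = np.isfinite(vi)
        sums[fin] += vi[fin]
        cnts[fin] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(cnts > 0, sums / cnts, np.nan)
    return Signal("response", np.asarray(grid_resp, float), mean,
                  n_effective=cnts)


def _stack_overlap(pred: Signal, obs: Signal) -> tuple[np.ndarray, np.ndarray]:
    if pred.grid.shape != obs.grid.shape or not np.allclose(pred.grid, obs.grid):
        raise ValueError("prediction and observation must share the grid")
    ok = pred.mask & obs.mask
    return pred.values[ok], obs.values[ok]


def fit_scale_and_split(
    prediction_generator: Callable[[NondecisionSplit], Mapping],
    observed: Mapping,
    t_er: float,
    n_grid_te: int = 21,
    refine: bool = True,
) -> tuple[float, NondecisionSplit, float]:
    """Find the amplitude scale and T_e/T_r split best matching ``observed``.

    ``prediction_generator(split)`` must return the same mapping structure
    as ``observed``: cell -> (stimulus Signal, response Signal).  For each
    candidate T_e on a grid over [0, T_er] the optimal scale has the closed
    form ``sum(p*o)/sum(p*p)`` over all unmasked overlapping points; the best
    grid point is then refined by bounded scalar minimization.  A single
    scale and split are shared across conditions and alignments.
    """

    def mse_for(t_e: float) -> tuple[float, float]:
        split = NondecisionSplit.from_t_er(t_er, float(t_e))
        preds = prediction_generator(split)
        p_all, o_all = [], []
        for cell, obs_pair in observed.items():
            pred_pair = preds[cell]
            for pred, obs in zip(pred_pair, obs_pair):
                pv, ov = _stack_overlap(pred, obs)
                p_all.append(pv)
                o_all.append(ov)
        p = np.concatenate(p_all)
        o = np.concatenate(o_all)
        denom = float(p @ p)
        scale = float(p @ o) / denom if denom > 0 else 0.0
        scale = max(scale, 0.0)
        return float(np.mean((scale * p - o) ** 2)), scale

    te_grid = np.linspace(0.0, t_er, n_grid_te)
    results = [mse_for(te) for te in te_grid]
    best = int(np.argmin([r[0] for r in results]))
    best_te = te_grid[best]
    best_mse, best_scale = results[best]
    if refine and t_er > 0:
        lo = te_grid[max(best - 1, 0)]
        hi = te_grid[min(best + 1, te_grid.size - 1)]
        res = optimize.minimize_scalar(
            lambda te: mse_for(te)[0], bounds=(lo, hi), method="bounded",
            options={"xatol": t_er * 1e-3},
        )
        m, s = mse_for(res.x)
        if m < best_mse:
            best_te, best_mse, best_scale = float(res.x), m, s
    return best_scale, NondecisionSplit.from_t_er(t_er, best_te), best_mse
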