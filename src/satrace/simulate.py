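"""Trial-level simulation of the rectified two-accumulator race model.

Evidence for the correct and the incorrect response accumulates independently
in discrete time.  Per step of length ``dt`` each accumulator gains
``v * dt + sigma * sqrt(dt) * N(0, 1)`` (Euler–Maruyama discretization of a
drift–diffusion increment) and is rectified at zero, so accumulated evidence
can never be negative.  The first accumulator to reach the boundary ``A``
determines the choice; decision time is the first-crossing step index times
``dt``; observed reaction time adds a uniform non-decision time of mean
``T_er`` and width ``S_Ter``.

Random-number discipline: every trial owns a private seed derived from the
dataset seed, and consumes draws in a fixed order (start point correct, start
point incorrect, non-decision time, then two normals per step).  Two parameter
sets that differ only by a common positive scaling of the evidence-unit
parameters therefore reproduce each other's choices and reaction times
*exactly*, trial for trial — the scaling property the forced-excursion
re-expression relies on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

from .params import ConditionParams, ModelParameters

_SEED_MOD = 2**31 - 1
_CELL_STRIDE = 10_000_019  # prime stride separating per-cell seed blocks

CHOICE_LABELS = {1: "correct", -1: "incorrect", 0: "none"}


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings: step size, censoring horizon, trial count, seed.

    ``dt`` and ``max_time`` are in the same (declared) unit as reaction
    times; trials that have not crossed by ``max_time`` are labelled
    ``choice='none'``.
    """

    dt: float
    max_time: float
    n_trials: int
    seed: int = 0
    record_traces: bool = False

    def validate(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.max_time <= 0:
            raise ValueError("max_time must be > 0")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")

    @property
    def max_steps(self) -> int:
        return int(math.ceil(self.max_time / self.dt))


def step_accumulators(
    state: tuple[float, float],
    cond: ConditionParams,
    dt: float,
    noise_pair: tuple[float, float],
) -> tuple[float, float]:
    """Advance both accumulators by one time step and rectify at zero.

    ``noise_pair`` are two standard-normal draws (one per accumulator); the
    update is ``max(x + v*dt + sigma*sqrt(dt)*n, 0)``.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    xc, xi = state
    if xc < 0 or xi < 0:
        raise ValueError("accumulator state must be >= 0")
    sq = math.sqrt(dt)
    nc, ni = noise_pair
    xc = max(xc + cond.drift_correct * dt + cond.noise_sd * sq * nc, 0.0)
    xi = max(xi + cond.drift_incorrect * dt + cond.noise_sd * sq * ni, 0.0)
    return xc, xi


# ---------------------------------------------------------------------------
# numba kernels.  All kernels consume per-trial draws in the identical order.
# ---------------------------------------------------------------------------


@njit(cache=True)
def _race_kernel(n_trials, A, Sz, vc, vi, sigma, ter, ster, dt, max_steps,
                 seeds):
    choice = np.zeros(n_trials, np.int8)
    steps = np.zeros(n_trials, np.int64)
    tnd = np.empty(n_trials, np.float64)
    start_c = np.empty(n_trials, np.float64)
    start_i = np.empty(n_trials, np.float64)
    sq = math.sqrt(dt)
    Athr = A - 1e-9 * A  # tolerant boundary: absorbs float summation error
    for i in range(n_trials):
        np.random.seed(seeds[i])
        xc = Sz * np.random.random()
        xi = Sz * np.random.random()
        t_nd = ter + ster * (np.random.random() - 0.5)
        start_c[i] = xc
        start_i[i] = xi
        tnd[i] = t_nd
        ch = 0
        k_cross = 0
        for k in range(1, max_steps + 1):
            xc = xc + vc * dt + sigma * sq * np.random.normal()
            if xc < 0.0:
                xc = 0.0
            xi = xi + vi * dt + sigma * sq * np.random.normal()
            if xi < 0.0:
                xi = 0.0
            hit_c = xc >= Athr
            hit_i = xi >= Athr
            if hit_c or hit_i:
                if hit_c and hit_i:
                    if xc > xi:
                        ch = 1
                    elif xi > xc:
                        ch = -1
                    else:
                        ch = 1 if np.random.random() < 0.5 else -1
                elif hit_c:
                    ch = 1
                else:
                    ch = -1
                k_cross = k
                break
        choice[i] = ch
        steps[i] = k_cross
    return choice, steps, tnd, start_c, start_i


@njit(cache=True)
def _race_kernel_fast(n_trials, A, Sz, vc, vi, sigma, ter, ster, dt,
                      max_steps, seed):
    """Fitting-objective race kernel: per-trial seed streams with
    block-generated noise.

    Per-trial streams make the seeded objective a smooth function of the
    parameters under common random numbers (a trial's draws never depend on
    how long other trials ran), which differential evolution and simplex
    refinement need; block generation of the normals keeps it fast.
    """
    choice = np.zeros(n_trials, np.int8)
    rts = np.full(n_trials, np.inf)
    sq = sigma * math.sqrt(dt)
    Athr = A - 1e-9 * A
    nbuf = 256
    for i in range(n_trials):
        np.random.seed((seed + i) % 2147483647)
        xc = Sz * np.random.random()
        xi = Sz * np.random.random()
        tnd = ter + ster * (np.random.random() - 0.5)
        buf = np.random.standard_normal(nbuf)
        bi = 0
        ch = 0
        k_cross = 0
        for k in range(1, max_steps + 1):
            if bi + 2 > nbuf:
                buf = np.random.standard_normal(nbuf)
                bi = 0
            xc = xc + vc * dt + sq * buf[bi]
            bi += 1
            if xc < 0.0:
                xc = 0.0
            xi = xi + vi * dt + sq * buf[bi]
            bi += 1
            if xi < 0.0:
                xi = 0.0
            hit_c = xc >= Athr
            hit_i = xi >= Athr
            if hit_c or hit_i:
                if hit_c and hit_i:
                    if xc > xi:
                        ch = 1
                    elif xi > xc:
                        ch = -1
                    else:
                        ch = 1 if np.random.random() < 0.5 else -1
                elif hit_c:
                    ch = 1
                else:
                    ch = -1
                k_cross = k
                break
        choice[i] = ch
        if ch != 0:
            rts[i] = k_cross * dt + tnd
    return choice, rts


@njit(cache=True)
def _race_probe_kernel(n_trials, A, Sz, vc, vi, sigma, ter, ster, dt,
                       max_steps, seeds, probe_times):
    """Race kernel that additionally reads out both accumulators at one
    per-trial probe time (absolute, stimulus-locked).

    Accumulation starts at onset = non-decision draw (the whole of T_er is
    treated as pre-accumulation delay); the probed value is 0 before onset.
    """
    choice = np.zeros(n_trials, np.int8)
    rts = np.empty(n_trials, np.float64)
    probe_c = np.zeros(n_trials, np.float64)
    probe_i = np.zeros(n_trials, np.float64)
    sq = math.sqrt(dt)
    Athr = A - 1e-9 * A  # tolerant boundary: absorbs float summation error
    for i in range(n_trials):
        np.random.seed(seeds[i])
        xc = Sz * np.random.random()
        xi = Sz * np.random.random()
        onset = ter + ster * (np.random.random() - 0.5)
        p = probe_times[i]
        if p >= onset:
            k_probe = int(math.floor((p - onset) / dt + 1e-9))
        else:
            k_probe = -1  # pulse precedes accumulation onset -> reads 0
        if k_probe == 0:
            probe_c[i] = xc
            probe_i[i] = xi
        ch = 0
        k_cross = 0
        for k in range(1, max_steps + 1):
            xc = xc + vc * dt + sigma * sq * np.random.normal()
            if xc < 0.0:
                xc = 0.0
            xi = xi + vi * dt + sigma * sq * np.random.normal()
            if xi < 0.0:
                xi = 0.0
            if k == k_probe:
                probe_c[i] = xc
                probe_i[i] = xi
            hit_c = xc >= Athr
            hit_i = xi >= Athr
            if hit_c or hit_i:
                if hit_c and hit_i:
                    if xc > xi:
                        ch = 1
                    elif xi > xc:
                        ch = -1
                    else:
                        ch = 1 if np.random.random() < 0.5 else -1
                elif hit_c:
                    ch = 1
                else:
                    ch = -1
                k_cross = k
                break
        choice[i] = ch
        rts[i] = onset + k_cross * dt if ch != 0 else np.inf
    return choice, rts, probe_c, probe_i


@njit(cache=True)
def _race_trace_kernel(n_trials, A, Sz, vc, vi, sigma, t_e, t_r, ster, dt,
                       max_steps, seeds, grid):
    """Summed-accumulator traces on ``grid`` (stimulus-locked times).

    Accumulation starts at onset = T_e plus uniform jitter of width S_Ter;
    after the boundary crossing it continues for T_r (motor execution, during
    which the stimulus is still integrated); reaction time = crossing time +
    T_r.  Grid samples strictly after the reaction time are NaN (the trial
    has responded and its trace is undefined); samples before onset are zero.
    """
    n_grid = grid.shape[0]
    traces = np.full((n_trials, n_grid), np.nan)
    rts = np.empty(n_trials, np.float64)
    choice = np.zeros(n_trials, np.int8)
    k_post = int(round(t_r / dt))
    sq = math.sqrt(dt)
    Athr = A - 1e-9 * A  # tolerant boundary: absorbs float summation error
    buf = np.empty(max_steps + k_post + 2, np.float64)
    for i in range(n_trials):
        np.random.seed(seeds[i])
        xc = Sz * np.random.random()
        xi = Sz * np.random.random()
        onset = t_e + ster * (np.random.random() - 0.5)
        buf[0] = xc + xi
        ch = 0
        k_cross = 0
        n_steps = 0
        for k in range(1, max_steps + 1):
            xc = xc + vc * dt + sigma * sq * np.random.normal()
            if xc < 0.0:
                xc = 0.0
            xi = xi + vi * dt + sigma * sq * np.random.normal()
            if xi < 0.0:
                xi = 0.0
            buf[k] = xc + xi
            n_steps = k
            hit_c = xc >= Athr
            hit_i = xi >= Athr
            if hit_c or hit_i:
                if hit_c and hit_i:
                    if xc > xi:
                        ch = 1
                    elif xi > xc:
                        ch = -1
                    else:
                        ch = 1 if np.random.random() < 0.5 else -1
                elif hit_c:
                    ch = 1
                else:
                    ch = -1
                k_cross = k
                break
        if ch != 0:
            for k in range(k_cross + 1, k_cross + k_post + 1):
                xc = xc + vc * dt + sigma * sq * np.random.normal()
                if xc < 0.0:
                    xc = 0.0
                xi = xi + vi * dt + sigma * sq * np.random.normal()
                if xi < 0.0:
                    xi = 0.0
                buf[k] = xc + xi
                n_steps = k
            rt = onset + (k_cross + k_post) * dt
        else:
            rt = np.inf
        choice[i] = ch
        rts[i] = rt
        for g in range(n_grid):
            t = grid[g]
            if t > rt + 1e-9:
                continue  # post-response: undefined
            if t < 0.0:
                traces[i, g] = 0.0
            elif t < onset:
                traces[i, g] = 0.0
            else:
                ks = int(math.floor((t - onset) / dt + 1e-9))
                if ks > n_steps:
                    ks = n_steps
                traces[i, g] = buf[ks]
    return traces, rts, choice


@njit(cache=True)
def _race_fulltrace_kernel(n_trials, A, Sz, vc, vi, sigma, ter, ster, dt,
                           max_steps, seeds):
    """Both accumulators' step-by-step paths up to (and including) the
    crossing step; NaN afterwards.  Used for small-n trace inspection."""
    tr_c = np.full((n_trials, max_steps + 1), np.nan)
    tr_i = np.full((n_trials, max_steps + 1), np.nan)
    choice = np.zeros(n_trials, np.int8)
    steps = np.zeros(n_trials, np.int64)
    tnd = np.empty(n_trials, np.float64)
    sq = math.sqrt(dt)
    Athr = A - 1e-9 * A  # tolerant boundary: absorbs float summation error
    for i in range(n_trials):
        np.random.seed(seeds[i])
        xc = Sz * np.random.random()
        xi = Sz * np.random.random()
        tnd[i] = ter + ster * (np.random.random() - 0.5)
        tr_c[i, 0] = xc
        tr_i[i, 0] = xi
        ch = 0
        k_cross = 0
        for k in range(1, max_steps + 1):
            xc = xc + vc * dt + sigma * sq * np.random.normal()
            if xc < 0.0:
                xc = 0.0
            xi = xi + vi * dt + sigma * sq * np.random.normal()
            if xi < 0.0:
                xi = 0.0
            tr_c[i, k] = xc
            tr_i[i, k] = xi
            hit_c = xc >= Athr
            hit_i = xi >= Athr
            if hit_c or hit_i:
                if hit_c and hit_i:
                    if xc > xi:
                        ch = 1
                    elif xi > xc:
                        ch = -1
                    else:
                        ch = 1 if np.random.random() < 0.5 else -1
                elif hit_c:
                    ch = 1
                else:
                    ch = -1
                k_cross = k
                break
        choice[i] = ch
        steps[i] = k_cross
    return tr_c, tr_i, choice, steps, tnd


# ---------------------------------------------------------------------------
# public wrappers
# ---------------------------------------------------------------------------


def cell_seed(master_seed: int, cell_index: int) -> int:
    """Deterministic per-cell seed block, spaced so per-trial seeds of
    different cells do not collide for any realistic trial count."""
    return (int(master_seed) + cell_index * _CELL_STRIDE) % _SEED_MOD


def trial_seeds(seed_base: int, n_trials: int) -> np.ndarray:
    """Consecutive per-trial seeds starting at ``seed_base``."""
    return (int(seed_base) + np.arange(n_trials, dtype=np.int64)) % _SEED_MOD


def simulate_cell(
    cond: ConditionParams,
    t_er: float,
    s_ter: float,
    sim: SimConfig,
    seed_base: int | None = None,
) -> pd.DataFrame:
    """Simulate ``sim.n_trials`` trials of one condition cell.

    Returns a DataFrame with columns choice, decision_time, rt, start_correct,
    start_incorrect, trial_seed.  Non-crossing trials have choice 'none' and
    NaN times.
    """
    cond.validate()
    sim.validate()
    if seed_base is None:
        seed_base = cell_seed(sim.seed, 0)
    seeds = trial_seeds(seed_base, sim.n_trials)
    choice, steps, tnd, sc, si = _race_kernel(
        sim.n_trials, cond.boundary, cond.start_range, cond.drift_correct,
        cond.drift_incorrect, cond.noise_sd, t_er, s_ter, sim.dt,
        sim.max_steps, seeds,
    )
    dec = steps * sim.dt
    rt = dec + tnd
    none = choice == 0
    dec = dec.astype(float)
    dec[none] = np.nan
    rt[none] = np.nan
    return pd.DataFrame(
        {
            "choice": pd.Categorical.from_codes(
                (choice + 1).astype(np.int8),
                categories=["incorrect", "none", "correct"],
            ).astype(str),
            "decision_time": dec,
            "rt": rt,
            "start_correct": sc,
            "start_incorrect": si,
            "trial_seed": seeds,
        }
    )


def simulate_trial(
    cond: ConditionParams,
    t_er: float,
    s_ter: float,
    sim: SimConfig,
    seed: int | None = None,
):
    """Simulate a single trial; returns a dict-like row, with traces when
    ``sim.record_traces`` is set."""
    cond.validate()
    sim.validate()
    seed_base = sim.seed if seed is None else seed
    if sim.record_traces:
        tr_c, tr_i, choice, steps, tnd = _race_fulltrace_kernel(
            1, cond.boundary, cond.start_range, cond.drift_correct,
            cond.drift_incorrect, cond.noise_sd, t_er, s_ter, sim.dt,
            sim.max_steps, trial_seeds(seed_base, 1),
        )
        ch = int(choice[0])
        k = int(steps[0])
        out = {
            "choice": CHOICE_LABELS[ch],
            "decision_time": k * sim.dt if ch != 0 else np.nan,
            "rt": k * sim.dt + tnd[0] if ch != 0 else np.nan,
            "start_correct": tr_c[0, 0],
            "start_incorrect": tr_i[0, 0],
            "trace_correct": tr_c[0, : (k if ch else sim.max_steps) + 1],
            "trace_incorrect": tr_i[0, : (k if ch else sim.max_steps) + 1],
        }
        return out
    row = simulate_cell(cond, t_er, s_ter,
                        SimConfig(sim.dt, sim.max_time, 1, seed_base),
                        seed_base=seed_base).iloc[0]
    return row.to_dict()


def simulate_dataset(
    params: ModelParameters,
    design: Sequence[tuple[str, str, int]],
    sim: SimConfig,
) -> pd.DataFrame:
    """Simulate a labelled trial table over the given design cells.

    ``design`` is a sequence of (instruction, difficulty, n_trials); each cell
    draws from its own deterministic seed block so the table is reproducible
    and per-cell comparable under common random numbers.
    """
    params.validate()
    sim.validate()
    frames = []
    for j, (ins, diff, n) in enumerate(design):
        if (ins, diff) not in params.cells:
            raise KeyError(f"condition cell {(ins, diff)!r} not in parameters")
        if n == 0:
            continue
        cond = params.cell(ins, diff)
        cfg = SimConfig(sim.dt, sim.max_time, n, sim.seed)
        tab = simulate_cell(cond, params.t_er_for(ins), params.s_ter, cfg,
                            seed_base=cell_seed(sim.seed, j))
        tab.insert(0, "difficulty", diff)
        tab.insert(0, "instruction", ins)
        frames.append(tab)
    if not frames:
        return pd.DataFrame(
            columns=["instruction", "difficulty", "choice", "decision_time",
                     "rt", "start_correct", "start_incorrect", "trial_seed"]
        )
    return pd.concat(frames, ignore_index=True)
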