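"""Continuous MEP-average signals and their statistics.

Motor-evoked potentials (MEPs) elicited at random latencies during the
reaction-time period give a sparse, irregular sample of corticospinal
excitability.  After z-scoring amplitudes within muscle x participant x
session, the samples are turned into a continuous excitability signal by
Gaussian-kernel weighted averaging on a fixed time grid (default 1% of
median RT steps; kernel FWHM 5% of median RT):

    M(t) = sum_i w_i Y_i / sum_i w_i,   w_i = exp(-(t - t_i)^2 / (2 s^2)),

with ``s = FWHM / (2 sqrt(2 ln 2))``.  Confidence bands use the
bias-corrected-and-accelerated (BCa) bootstrap over trials; hypothesis tests
are label permutations: a build-up-slope test on the stimulus-locked signal
and a cluster-amplitude test whose cluster-forming rule is non-overlap of
the two groups' 90% BCa bands, with family-wise control via the permutation
distribution of the largest cluster sum.

Model-predicted MEP signals are built the same way from simulated trials:
each simulated TMS pulse reads out both accumulators at the pulse time
(accumulation begins only after the non-decision delay, so earlier pulses
read zero), pulses landing after the simulated response are discarded, and
the responding-minus-nonresponding difference is smoothed on the data grids.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .params import ModelParameters
from .signal import Signal
from .simulate import SimConfig, _race_probe_kernel, cell_seed, trial_seeds

FWHM_TO_SD = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
MIN_EFFECTIVE_WEIGHT = 1.0  # grid points with less total weight are masked


# ---------------------------------------------------------------------------
# record preparation
# ---------------------------------------------------------------------------

def zscore_amplitudes(
    records: pd.DataFrame,
    group_cols: Sequence[str] = ("muscle_role", "participant_id", "session"),
) -> pd.DataFrame:
    """Z-transform MEP amplitudes within each grouping cell.

    Adds an ``amplitude_z`` column (sample SD, ddof=1).  Groups with fewer
    than two records or zero variance are dropped with a warning.
    """
    records = records.copy()
    keep = []
    zs = pd.Series(np.nan, index=records.index, dtype=float)
    for key, sub in records.groupby(list(group_cols), observed=True):
        amp = sub["amplitude"].to_numpy(float)
        sd = amp.std(ddof=1) if amp.size > 1 else 0.0
        if amp.size < 2 or sd == 0.0:
            warnings.warn(
                f"dropping group {key}: fewer than 2 records or zero variance"
            )
            continue
        zs.loc[sub.index] = (amp - amp.mean()) / sd
        keep.append(sub.index)
    if not keep:
        raise ValueError("no group had enough records to z-score")
    idx = keep[0].append(keep[1:]) if len(keep) > 1 else keep[0]
    out = records.loc[records.index.isin(idx)].copy()
    out["amplitude_z"] = zs.loc[out.index]
    return out


def difference_records(paired: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Responding-minus-nonresponding amplitude difference per trial.

    Expects one 'responding' and one 'nonresponding' record per trial_id at
    the same latency; returns (latencies, differences).
    """
    col = "amplitude_z" if "amplitude_z" in paired.columns else "amplitude"
    resp = paired[paired["muscle_role"] == "responding"]
    nonr = paired[paired["muscle_role"] == "nonresponding"]
    merged = resp.merge(
        nonr, on="trial_id", suffixes=("_r", "_n"), how="outer",
        indicator=True,
    )
    bad = merged[merged["_merge"] != "both"]
    if len(bad):
        raise ValueError(
            f"unpaired MEP records for trial_id(s) "
            f"{sorted(bad['trial_id'].tolist())[:5]}"
        )
    lat = merged["tms_latency_r"].to_numpy(float)
    if not np.allclose(lat, merged["tms_latency_n"].to_numpy(float)):
        raise ValueError("paired records disagree on tms_latency")
    diff = merged[f"{col}_r"].to_numpy(float) - merged[f"{col}_n"].to_numpy(float)
    return lat, diff


# ---------------------------------------------------------------------------
# kernel smoothing
# ---------------------------------------------------------------------------

def _weights(grid: np.ndarray, t: np.ndarray, fwhm: float) -> np.ndarray:
    """Gaussian weight matrix W[g, i] = exp(-(grid_g - t_i)^2 / (2 s^2))."""
    s = fwhm * FWHM_TO_SD
    d = grid[:, None] - t[None, :]
    return np.exp(-0.5 * (d / s) ** 2)


def kernel_smooth(
    t: np.ndarray,
    y: np.ndarray,
    grid: np.ndarray,
    fwhm: float,
    alignment: str = "stimulus",
    min_effective: float = MIN_EFFECTIVE_WEIGHT,
) -> Signal:
    """Gaussian-kernel weighted average of points (t_i, Y_i) on ``grid``.

    Grid points whose total kernel weight falls below ``min_effective`` are
    masked (NaN): with almost no nearby samples the weighted mean is
    dominated by one far-away point and is not interpretable.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    if t.size == 0:
        raise ValueError("kernel_smooth needs at least one point")
    if fwhm <= 0:
        raise ValueError("fwhm must be > 0")
    W = _weights(np.asarray(grid, float), t, fwhm)
    den = W.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = (W @ y) / den
    vals[den < min_effective] = np.nan
    return Signal(alignment=alignment, grid=np.asarray(grid, float),
                  values=vals, n_effective=den)


# ---------------------------------------------------------------------------
# BCa bootstrap band for the smoothed signal
# ---------------------------------------------------------------------------

def _boot_matrix(W, y, n_boot, rng):
    """Bootstrap smoothed signals: resample points with replacement.

    Returns array (n_grid, n_boot).  Uses multinomial resample counts so the
    whole bootstrap is two matrix products.
    """
    n = y.size
    counts = rng.multinomial(n, np.full(n, 1.0 / n), size=n_boot).T  # n x B
    num = W @ (counts * y[:, None])
    den = W @ counts
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def bca_interval(
    t: np.ndarray,
    y: np.ndarray,
    grid: np.ndarray,
    fwhm: float,
    n_boot: int = 1999,
    level: float = 0.95,
    accelerated: bool = True,
    seed: int = 0,
    alignment: str = "stimulus",
) -> Signal:
    """Smoothed signal with a per-grid-point BCa (or, with
    ``accelerated=False``, bias-corrected-only) bootstrap band.

    The bias correction z0 comes from the proportion of bootstrap signals
    below the observed signal; the acceleration constant from the jackknife
    skewness of the leave-one-out signals.
    """
    if n_boot < 199:
        raise ValueError("n_boot must be >= 199")
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    base = kernel_smooth(t, y, grid, fwhm, alignment=alignment)
    obs = base.values
    if np.ptp(y) == 0.0:
        # degenerate data: every resample gives the same signal
        warnings.warn("degenerate bootstrap distribution; point interval")
        return Signal(alignment, base.grid, obs, obs.copy(), obs.copy(),
                      base.n_effective)
    W = _weights(base.grid, t, fwhm)
    rng = np.random.default_rng(seed)
    boot = _boot_matrix(W, y, n_boot, rng)  # (G, B)
    G = obs.size

    frac_below = np.nanmean(boot < obs[:, None], axis=1)
    frac_below = np.clip(frac_below, 1.0 / (n_boot + 1),
                         n_boot / (n_boot + 1.0))
    z0 = norm.ppf(frac_below)

    if accelerated:
        num_tot = W @ y
        den_tot = W.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            jack = (num_tot[:, None] - W * y[None, :]) / \
                   (den_tot[:, None] - W)  # (G, n) leave-one-out signals
        jmean = np.nanmean(jack, axis=1, keepdims=True)
        d = jmean - jack
        s2 = np.nansum(d ** 2, axis=1)
        s3 = np.nansum(d ** 3, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            a = s3 / (6.0 * s2 ** 1.5)
        a = np.where(np.isfinite(a), a, 0.0)
    else:
        a = np.zeros(G)

    alpha = (1.0 - level) / 2.0
    z_lo, z_hi = norm.ppf(alpha), norm.ppf(1.0 - alpha)
    with np.errstate(invalid="ignore", divide="ignore"):
        a_lo = norm.cdf(z0 + (z0 + z_lo) / (1.0 - a * (z0 + z_lo)))
        a_hi = norm.cdf(z0 + (z0 + z_hi) / (1.0 - a * (z0 + z_hi)))
    a_lo = np.clip(a_lo, 0.0, 1.0)
    a_hi = np.clip(a_hi, 0.0, 1.0)

    boot_sorted = np.sort(boot, axis=1)
    lo_idx = np.clip((a_lo * (n_boot - 1)).round().astype(int), 0, n_boot - 1)
    hi_idx = np.clip((a_hi * (n_boot - 1)).round().astype(int), 0, n_boot - 1)
    rows = np.arange(G)
    ci_low = boot_sorted[rows, lo_idx]
    ci_high = boot_sorted[rows, hi_idx]
    bad = ~np.isfinite(obs)
    ci_low[bad] = np.nan
    ci_high[bad] = np.nan
    return Signal(alignment, base.grid, obs, ci_low, ci_high,
                  base.n_effective)


# ---------------------------------------------------------------------------
# slope and cluster statistics
# ---------------------------------------------------------------------------

def buildup_slope(signal: Signal, window: tuple[float, float]) -> float:
    """OLS slope of the signal over grid points in ``[t_start, t_end]``."""
    lo, hi = window
    if lo < signal.grid[0] - 1e-12 or hi > signal.grid[-1] + 1e-12:
        raise ValueError("slope window lies outside the signal grid")
    sel = (signal.grid >= lo) & (signal.grid <= hi) & signal.mask
    if sel.sum() < 3:
        raise ValueError("need at least 3 unmasked grid points in the window")
    x = signal.grid[sel]
    v = signal.values[sel]
    xm = x - x.mean()
    return float((xm @ (v - v.mean())) / (xm @ xm))


def _group_signals(W, y, mask):
    """Smoothed signals of a group (mask) and its complement from a shared
    weight matrix."""
    m = mask.astype(float)
    num_a = W @ (m * y)
    den_a = W @ m
    num_b = W @ ((1.0 - m) * y)
    den_b = W @ (1.0 - m)
    with np.errstate(invalid="ignore", divide="ignore"):
        sa = np.where(den_a >= MIN_EFFECTIVE_WEIGHT, num_a / den_a, np.nan)
        sb = np.where(den_b >= MIN_EFFECTIVE_WEIGHT, num_b / den_b, np.nan)
    return sa, sb


def _slope(grid, vals):
    ok = np.isfinite(vals)
    if ok.sum() < 3:
        return np.nan
    x = grid[ok]
    v = vals[ok]
    xm = x - x.mean()
    return (xm @ (v - v.mean())) / (xm @ xm)


def permutation_slope_test(
    a: tuple[np.ndarray, np.ndarray],
    b: tuple[np.ndarray, np.ndarray],
    window: tuple[float, float],
    grid: np.ndarray,
    fwhm: float,
    n_perm: int = 1999,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation test on the difference of build-up slopes.

    ``a`` and ``b`` are (latencies, amplitudes) of the two trial groups.
    Group labels are permuted; per permutation both smoothed signals and
    their slopes over ``window`` are recomputed.  Returns (observed slope
    difference, two-sided permutation p with the +1 exact-test correction).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    ta, ya = map(np.asarray, a)
    tb, yb = map(np.asarray, b)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    grid = np.asarray(grid, float)
    lo, hi = window
    gsel = (grid >= lo) & (grid <= hi)
    gwin = grid[gsel]
    t_all = np.concatenate([ta, tb])
    y_all = np.concatenate([ya, yb])
    W = _weights(gwin, t_all, fwhm)
    n_a = ta.size
    mask = np.zeros(t_all.size, bool)
    mask[:n_a] = True
    sa, sb = _group_signals(W, y_all, mask)
    observed = _slope(gwin, sa) - _slope(gwin, sb)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for p in range(n_perm):
        perm = rng.permutation(t_all.size)
        m = np.zeros(t_all.size, bool)
        m[perm[:n_a]] = True
        pa, pb = _group_signals(W, y_all, m)
        null[p] = _slope(gwin, pa) - _slope(gwin, pb)
    null = null[np.isfinite(null)]
    n_eff = null.size
    ge = int(np.sum(null >= observed))
    le = int(np.sum(null <= observed))
    p_two = 2.0 * min((1 + ge) / (1 + n_eff), (1 + le) / (1 + n_eff))
    return observed, min(p_two, 1.0)


def _clusters_from_bands(sig_a: Signal, sig_b: Signal):
    """Maximal runs of grid points where the two 90% bands do not overlap."""
    ok = sig_a.mask & sig_b.mask & np.isfinite(sig_a.ci_low) \
        & np.isfinite(sig_b.ci_low)
    apart = ok & ((sig_a.ci_low > sig_b.ci_high)
                  | (sig_b.ci_low > sig_a.ci_high))
    clusters = []
    i = 0
    n = apart.size
    diff = sig_a.values - sig_b.values
    while i < n:
        if apart[i]:
            j = i
            while j + 1 < n and apart[j + 1]:
                j += 1
            clusters.append({
                "start": float(sig_a.grid[i]),
                "end": float(sig_a.grid[j]),
                "indices": (i, j),
                "sum": float(np.nansum(diff[i:j + 1])),
            })
            i = j + 1
        else:
            i += 1
    return clusters


def cluster_amplitude_test(
    a: tuple[np.ndarray, np.ndarray],
    b: tuple[np.ndarray, np.ndarray],
    grid: np.ndarray,
    fwhm: float,
    n_boot: int = 1999,
    cluster_level: float = 0.90,
    n_perm: int = 1999,
    seed: int = 0,
) -> list[dict]:
    """Cluster-based amplitude comparison of two MEP signals.

    Candidate clusters are contiguous grid runs where the groups' BCa bands
    (at ``cluster_level``) do not overlap; each cluster's statistic is the
    sum of point-wise signal differences; family-wise significance compares
    each cluster sum against the permutation distribution of the largest
    absolute cluster sum.  Returns clusters sorted by onset (possibly empty).
    """
    ta, ya = map(np.asarray, a)
    tb, yb = map(np.asarray, b)
    grid = np.asarray(grid, float)
    rng = np.random.default_rng(seed)

    def bands(t1, y1, t2, y2, s1, s2):
        sig1 = bca_interval(t1, y1, grid, fwhm, n_boot=n_boot,
                            level=cluster_level, seed=s1)
        sig2 = bca_interval(t2, y2, grid, fwhm, n_boot=n_boot,
                            level=cluster_level, seed=s2)
        return sig1, sig2

    sig_a, sig_b = bands(ta, ya, tb, yb, seed + 1, seed + 2)
    clusters = _clusters_from_bands(sig_a, sig_b)

    t_all = np.concatenate([ta, tb])
    y_all = np.concatenate([ya, yb])
    n_a = ta.size
    null_max = np.zeros(n_perm)
    for p in range(n_perm):
        perm = rng.permutation(t_all.size)
        ia, ib = perm[:n_a], perm[n_a:]
        s1, s2 = bands(t_all[ia], y_all[ia], t_all[ib], y_all[ib],
                       seed + 1000 + 2 * p, seed + 1001 + 2 * p)
        cl = _clusters_from_bands(s1, s2)
        if cl:
            null_max[p] = max(abs(c["sum"]) for c in cl)
    for c in clusters:
        c["p"] = float((1 + np.sum(null_max >= abs(c["sum"])))
                       / (1 + n_perm))
    return sorted(clusters, key=lambda c: c["start"])


# ---------------------------------------------------------------------------
# model-predicted MEP signals
# ---------------------------------------------------------------------------

def predict_mep_signal(
    params: ModelParameters,
    schedule: Mapping[tuple[str, str], np.ndarray] | pd.DataFrame,
    sim: SimConfig,
    scale: float,
    grid_stim: np.ndarray,
    grid_resp: np.ndarray,
    fwhm: float,
) -> dict[tuple[str, str], tuple[Signal, Signal]]:
    """Simulate MEP-difference signals predicted by the race model.

    For each condition cell, ``sim.n_trials`` accumulation paths are probed
    at TMS latencies drawn from the cell's ``schedule`` entries (an array of
    pulse times, or a DataFrame with instruction/difficulty/pulse_time
    columns).  The whole non-decision time precedes accumulation, so pulses
    earlier than the per-trial onset read zero from both accumulators.  Only
    correct trials whose simulated response follows the pulse contribute; the
    correct-minus-incorrect readout, times ``scale``, is smoothed on the
    stimulus- and response-locked grids.
    """
    if isinstance(schedule, pd.DataFrame):
        sched = {
            cell: sub["pulse_time"].to_numpy(float)
            for cell, sub in schedule.groupby(
                ["instruction", "difficulty"], observed=True)
        }
    else:
        sched = {k: np.asarray(v, float) for k, v in schedule.items()}
    out = {}
    for j, (cell, pulses) in enumerate(sorted(sched.items())):
        ins, diff = cell
        cp = params.cell(ins, diff)
        seed_base = cell_seed(sim.seed, j)
        rng = np.random.default_rng(seed_base)
        probe_t = rng.choice(pulses, size=sim.n_trials, replace=True)
        choice, rts, pc, pi = _race_probe_kernel(
            sim.n_trials, cp.boundary, cp.start_range, cp.drift_correct,
            cp.drift_incorrect, cp.noise_sd, params.t_er_for(ins),
            params.s_ter, sim.dt, sim.max_steps,
            trial_seeds(seed_base, sim.n_trials), probe_t,
        )
        keep = (choice == 1) & (rts > probe_t)
        t_stim = probe_t[keep]
        amp = (pc[keep] - pi[keep]) * scale
        t_resp = t_stim - rts[keep]
        sig_s = kernel_smooth(t_stim, amp, grid_stim, fwhm,
                              alignment="stimulus")
        sig_r = kernel_smooth(t_resp, amp, grid_resp, fwhm,
                              alignment="response")
        out[cell] = (sig_s, sig_r)
    return out
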