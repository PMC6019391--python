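"""Quantifying model–signal correspondence and free vs forced comparison.

Predicted signals are matched to observed signals by a single multiplicative
amplitude scale per model (shared across conditions and alignments), then
compared by mean squared error (MSE).  For MEP-style signals an AIC is formed
directly from the MSE, ``AIC = n ln(MSE) + 2K`` with ``K = 1`` (only the
amplitude was free), and converted to Akaike weights.  The free- vs
forced-excursion contrast is additionally assessed by a trial-level bootstrap
of the MSE difference with a bias-corrected (BC) confidence interval.

Sign convention: ``delta_mse = MSE(free) - MSE(forced)``, so positive values
favor the forced-excursion variant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .fitting import akaike_weights


def _flatten_pairs(predicted, observed) -> tuple[np.ndarray, np.ndarray]:
    """Stack unmasked overlapping grid points of matching signal sets.

    Both arguments are mappings cell -> (Signal, ...) with identical layout,
    or bare sequences of Signals.
    """
    def pairs():
        if isinstance(predicted, Mapping):
            for cell in predicted:
                for p, o in zip(predicted[cell], observed[cell]):
                    yield p, o
        else:
            for p, o in zip(predicted, observed):
                yield p, o

    ps, os_ = [], []
    for p, o in pairs():
        if p.grid.shape != o.grid.shape or not np.allclose(p.grid, o.grid):
            raise ValueError("signals must share their grids")
        ok = p.mask & o.mask
        ps.append(p.values[ok])
        os_.append(o.values[ok])
    pv = np.concatenate(ps) if ps else np.array([])
    ov = np.concatenate(os_) if os_ else np.array([])
    if pv.size == 0:
        raise ValueError("no overlapping unmasked grid points to compare")
    return pv, ov


def signal_mse(predicted, observed) -> float:
    """Mean squared point-wise difference over all conditions/alignments,
    excluding masked points pairwise."""
    pv, ov = _flatten_pairs(predicted, observed)
    return float(np.mean((pv - ov) ** 2))


def fit_amplitude_scale(predicted, observed) -> float:
    """Least-squares amplitude factor applied to all of a model's predicted
    signals: ``scale = sum(p*o) / sum(p*p)``."""
    pv, ov = _flatten_pairs(predicted, observed)
    denom = float(pv @ pv)
    if denom == 0.0:
        raise ValueError("all-zero prediction cannot be scaled")
    return float(pv @ ov) / denom


def scaled_mse(predicted, observed) -> tuple[float, float]:
    """Fit the amplitude scale, then return (MSE at that scale, scale)."""
    pv, ov = _flatten_pairs(predicted, observed)
    denom = float(pv @ pv)
    if denom == 0.0:
        raise ValueError("all-zero prediction cannot be scaled")
    scale = float(pv @ ov) / denom
    return float(np.mean((scale * pv - ov) ** 2)), scale


def aic_from_mse(mse: float, n: int, k: int = 1) -> float:
    """AIC of a least-squares signal match: ``n ln(MSE) + 2K``."""
    if mse <= 0:
        raise ValueError("mse must be > 0")
    return n * math.log(mse) + 2 * k


@dataclass
class ComparisonResult:
    """MSEs, AICs and Akaike weights of competing model variants."""

    mse: dict
    scale: dict
    n_points: int
    aic: dict | None = None
    weights: dict | None = None


def compare_models(
    predictions: Mapping[str, Mapping],
    observed: Mapping,
    k: int = 1,
    with_aic: bool = True,
) -> ComparisonResult:
    """Scale and score several models' predicted signal sets against the same
    observed signals; AIC/weights are skipped for ``with_aic=False`` (the
    EEG-style case, where temporal autocorrelation invalidates the
    independence assumption behind the AIC)."""
    mses, scales = {}, {}
    n_points = None
    for name, pred in predictions.items():
        pv, ov = _flatten_pairs(pred, observed)
        if n_points is None:
            n_points = pv.size
        elif pv.size != n_points:
            raise ValueError("models must be compared on equal point counts")
        m, s = scaled_mse(pred, observed)
        mses[name], scales[name] = m, s
    res = ComparisonResult(mse=mses, scale=scales, n_points=int(n_points))
    if with_aic:
        names = list(mses)
        aics = {nm: aic_from_mse(mses[nm], n_points, k) for nm in names}
        w = akaike_weights([aics[nm] for nm in names])
        res.aic = aics
        res.weights = dict(zip(names, (float(x) for x in w)))
    return res


# ---------------------------------------------------------------------------
# bootstrap of the MSE difference
# ---------------------------------------------------------------------------

def bc_interval_from_boot(
    boot: np.ndarray, observed: float, level: float = 0.95
) -> tuple[float, float]:
    """Bias-corrected percentile interval from a bootstrap sample."""
    boot = np.asarray(boot, float)
    n = boot.size
    if np.all(boot == boot[0]):
        return float(boot[0]), float(boot[0])
    frac = np.clip(np.mean(boot < observed), 1.0 / (n + 1), n / (n + 1.0))
    z0 = norm.ppf(frac)
    alpha = (1.0 - level) / 2.0
    a_lo = norm.cdf(2 * z0 + norm.ppf(alpha))
    a_hi = norm.cdf(2 * z0 + norm.ppf(1 - alpha))
    return (float(np.quantile(boot, a_lo)), float(np.quantile(boot, a_hi)))


def bc_pvalue_from_boot(boot: np.ndarray, observed: float) -> float:
    """Smallest alpha at which the (1-alpha) BC interval excludes zero."""
    boot = np.asarray(boot, float)
    if np.all(boot == boot[0]):
        return 0.0 if boot[0] != 0 else 1.0
    for alpha in np.linspace(1e-4, 0.9999, 2000):
        lo, hi = bc_interval_from_boot(boot, observed, level=1 - alpha)
        if lo > 0 or hi < 0:
            return float(alpha)
    return 1.0


@dataclass
class BootstrapComparison:
    observed_delta: float
    ci_low: float
    ci_high: float
    p: float
    n_boot: int
    n_failed: int
    deltas: np.ndarray = field(repr=False, default=None)


def bootstrap_mse_difference(
    pipeline: Callable[[int], float],
    observed_delta: float,
    n_boot: int = 1999,
    seed: int = 0,
    level: float = 0.95,
    max_failure_rate: float = 0.05,
) -> BootstrapComparison:
    """Bootstrap distribution of the free-minus-forced MSE difference.

    ``pipeline(replicate_seed)`` must perform one full replicate — resample
    the RT data within condition, refit locally from the original parameters,
    derive the forced-excursion twin, regenerate both predictions, resample
    the neural data equivalently, re-fit amplitude scales — and return
    ``MSE(free) - MSE(forced)``.  Failed replicates (exceptions) are dropped
    and counted; more than ``max_failure_rate`` aborts.
    """
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=n_boot)
    deltas = []
    failed = 0
    for s in rep_seeds:
        try:
            deltas.append(float(pipeline(int(s))))
        except Exception:
            failed += 1
            if failed > max_failure_rate * n_boot:
                raise RuntimeError(
                    f"{failed} bootstrap replicates failed "
                    f"(> {max_failure_rate:.0%} of {n_boot})"
                )
    deltas = np.asarray(deltas)
    lo, hi = bc_interval_from_boot(deltas, observed_delta, level)
    p = bc_pvalue_from_boot(deltas, observed_delta)
    return BootstrapComparison(observed_delta, lo, hi, p, n_boot, failed,
                               deltas)


def resample_within_condition(
    data, rng, cond_cols: Sequence[str] = ("instruction", "difficulty")
):
    """Resample a trial table with replacement within each condition cell."""
    parts = []
    for _, sub in data.groupby(list(cond_cols), observed=True):
        idx = rng.integers(0, len(sub), size=len(sub))
        parts.append(sub.iloc[idx])
    import pandas as pd
    return pd.concat(parts, ignore_index=True)
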