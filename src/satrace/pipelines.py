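"""End-to-end comparison of free- vs forced-excursion neural predictions.

Glue that the bootstrap comparison resamples: fit (or refit) the behavioral
model, derive its forced-excursion twin, predict the MEP-difference signal
for both under the observed TMS latencies, fit each model's single amplitude
scale, and score both against the observed smoothed signals by MSE.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .compare import aic_from_mse, scaled_mse
from .fitting import ModelSpec, OptimizerConfig, akaike_weights, refit_simplex
from .mep import kernel_smooth, predict_mep_signal
from .params import ModelParameters, to_forced_excursion
from .signal import default_grid
from .simulate import SimConfig


@dataclass
class MepComparisonConfig:
    """Grids, smoothing and simulation sizes for the MEP comparison."""

    fwhm: float = 0.05
    grid_stim: np.ndarray = field(default_factory=lambda: default_grid("stimulus"))
    grid_resp: np.ndarray = field(default_factory=lambda: default_grid("response"))
    n_sim_predict: int = 20_000
    dt_predict: float = 0.005
    max_time: float = 5.0
    refit_maxfev: int = 100  # per bootstrap replicate


def observed_mep_signals(mep_cells: Mapping, cfg: MepComparisonConfig):
    """Smooth observed MEP-difference points per condition cell.

    ``mep_cells`` maps (instruction, difficulty) -> dict with arrays
    ``t_stim`` (stimulus-locked latencies), ``t_resp`` (response-locked
    latencies) and ``y`` (difference amplitudes).
    """
    out = {}
    for cell, d in mep_cells.items():
        out[cell] = (
            kernel_smooth(d["t_stim"], d["y"], cfg.grid_stim, cfg.fwhm,
                          alignment="stimulus"),
            kernel_smooth(d["t_resp"], d["y"], cfg.grid_resp, cfg.fwhm,
                          alignment="response"),
        )
    return out


def predicted_mep_signals(params: ModelParameters, mep_cells: Mapping,
                          cfg: MepComparisonConfig, seed: int):
    schedule = {cell: np.asarray(d["t_stim"], float)
                for cell, d in mep_cells.items()}
    sim = SimConfig(cfg.dt_predict, cfg.max_time, cfg.n_sim_predict, seed)
    return predict_mep_signal(params, schedule, sim, 1.0, cfg.grid_stim,
                              cfg.grid_resp, cfg.fwhm)


def compare_free_forced_mep(
    params: ModelParameters,
    mep_cells: Mapping,
    cfg: MepComparisonConfig,
    seed: int = 0,
) -> dict:
    """Score free- and forced-excursion predictions against observed MEP
    signals: per-model amplitude scale, MSE, MSE-based AIC (K=1) and Akaike
    weights, plus the free-minus-forced MSE difference."""
    observed = observed_mep_signals(mep_cells, cfg)
    forced = to_forced_excursion(params, "speed")
    out = {"models": {}}
    n_pts = None
    for name, p in (("free", params), ("forced", forced)):
        preds = predicted_mep_signals(p, mep_cells, cfg, seed)
        mse, scale = scaled_mse(preds, observed)
        if n_pts is None:
            from .compare import _flatten_pairs
            n_pts = _flatten_pairs(preds, observed)[0].size
        out["models"][name] = {"mse": mse, "scale": scale}
    aics = {m: aic_from_mse(out["models"][m]["mse"], n_pts, 1)
            for m in out["models"]}
    w = akaike_weights([aics["free"], aics["forced"]])
    out["models"]["free"]["aic"] = aics["free"]
    out["models"]["forced"]["aic"] = aics["forced"]
    out["weights"] = {"free": float(w[0]), "forced": float(w[1])}
    out["delta_mse"] = out["models"]["free"]["mse"] \
        - out["models"]["forced"]["mse"]
    out["n_points"] = int(n_pts)
    return out


def make_mep_delta_pipeline(
    trials: pd.DataFrame,
    mep_cells: Mapping,
    start_params: ModelParameters,
    spec: ModelSpec | str,
    opt_cfg: OptimizerConfig,
    cmp_cfg: MepComparisonConfig,
):
    """Build the bootstrap replicate function for the free-vs-forced MSE
    difference.

    Each replicate resamples RT trials within condition, locally refits from
    the original parameters, rebuilds the forced twin, resamples the MEP
    points within cell, and returns MSE(free) - MSE(forced); positive values
    favor the forced-excursion variant.
    """
    from .compare import resample_within_condition

    def pipeline(rep_seed: int) -> float:
        rng = np.random.default_rng(rep_seed)
        boot_trials = resample_within_condition(trials, rng)
        fit = refit_simplex(boot_trials, start_params, spec, opt_cfg,
                            maxfev=cmp_cfg.refit_maxfev)
        boot_cells = {}
        for cell, d in mep_cells.items():
            n = len(d["y"])
            idx = rng.integers(0, n, n)
            boot_cells[cell] = {k: np.asarray(d[k])[idx]
                                for k in ("t_stim", "t_resp", "y")}
        res = compare_free_forced_mep(fit.parameters, boot_cells, cmp_cfg,
                                      seed=int(rep_seed % 2**31))
        return res["delta_mse"]

    return pipeline


def mep_cells_from_records(records: pd.DataFrame) -> dict:
    """Convert paired MEP records (with rt column) into the per-cell point
    sets the comparison consumes; restricted to correct trials."""
    from .mep import difference_records

    cells = {}
    sub = records[records.get("choice", "correct") == "correct"]
    for cell, grp in sub.groupby(["instruction", "difficulty"],
                                 observed=True):
        t, y = difference_records(grp)
        rt = grp.drop_duplicates("trial_id").set_index("trial_id")["rt"]
        order = grp.drop_duplicates("trial_id")["trial_id"]
        cells[cell] = {"t_stim": t, "y": y,
                       "t_resp": t - rt.loc[order].to_numpy(float)}
    return cells
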