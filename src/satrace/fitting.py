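"""Quantile maximum probability estimation (QMPE) of the race model.

The RT distributions of correct and erroneous responses in each condition are
summarized by their 0.1/0.3/0.5/0.7/0.9 quantiles; the quantile edges define
six bins per response type whose observed counts follow a multinomial
distribution with bin probabilities predicted by model simulation.  Fitting
maximizes ``sum_i N_i * ln p_i`` over parameters, with the simulation seed
held fixed (and one seed stream per simulated trial) so the objective is a
deterministic, smooth-under-common-random-numbers surface; the global search
is differential evolution followed by a bounded Powell refinement, and a
Nelder–Mead simplex refits locally inside bootstrap loops.

Three model variants differ in which parameters may vary between speed and
accuracy instructions, with the accuracy boundary always pinned at 1:

========  ==========================================  ==============
variant   free across instructions                    free parameters
========  ==========================================  ==============
model1    boundary A                                  9
model2    boundary A and start-point range S_z        10
model3    boundary A and non-decision mean T_er       10
========  ==========================================  ==============

Drift rates always vary with difficulty (shared across instructions) and
noise SD is common to all cells.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .params import (DIFFICULTIES, INSTRUCTIONS, Cell, ConditionParams,
                     ModelParameters)
from .simulate import SimConfig, _race_kernel_fast, cell_seed

EPS_PROP = 1e-10
DEFAULT_PROBS = (0.1, 0.3, 0.5, 0.7, 0.9)

CELLS: tuple[Cell, ...] = tuple(
    (ins, diff) for ins in INSTRUCTIONS for diff in DIFFICULTIES
)


@dataclass(frozen=True)
class ModelSpec:
    """Which parameters are free across speed/accuracy instructions."""

    name: str
    free_across_instructions: frozenset[str]
    n_free_parameters: int

    @staticmethod
    def by_name(name: str) -> "ModelSpec":
        try:
            return MODEL_SPECS[name]
        except KeyError:
            raise ValueError(
                f"unknown model {name!r}; expected one of {sorted(MODEL_SPECS)}"
            ) from None


MODEL_SPECS = {
    "model1": ModelSpec("model1", frozenset({"A"}), 9),
    "model2": ModelSpec("model2", frozenset({"A", "S_z"}), 10),
    "model3": ModelSpec("model3", frozenset({"A", "T_er"}), 10),
}


def empirical_quantiles(rts: Sequence[float], probs: Sequence[float]) -> np.ndarray:
    """Linear-interpolation (type-7) quantiles of an RT sample."""
    rts = np.asarray(rts, float)
    if rts.size == 0:
        raise ValueError("cannot compute quantiles of an empty sample")
    if rts.size < 2:
        raise ValueError("need at least 2 observations for quantile bins")
    probs = np.asarray(probs, float)
    if not (np.all(np.diff(probs) > 0) and probs[0] > 0 and probs[-1] < 1):
        raise ValueError("probs must be strictly increasing within (0, 1)")
    return np.quantile(rts, probs)


@dataclass
class CellBins:
    """Quantile-bin summary of one condition cell's data."""

    correct_edges: np.ndarray
    correct_counts: np.ndarray
    error_edges: np.ndarray  # may be empty (no-error collapse)
    error_counts: np.ndarray
    n_trials: int  # responded trials in this cell


@dataclass
class QuantileScheme:
    """Per-cell quantile bin edges and observed counts for QMPE."""

    probs: tuple[float, ...]
    cells: Mapping[Cell, CellBins]

    @property
    def n_observations(self) -> int:
        return int(sum(c.n_trials for c in self.cells.values()))

    def flatten_counts(self) -> np.ndarray:
        out = []
        for cell in CELLS:
            if cell not in self.cells:
                continue
            cb = self.cells[cell]
            out.append(cb.correct_counts)
            out.append(cb.error_counts)
        return np.concatenate(out)


def _bin_counts(rts: np.ndarray, edges: np.ndarray) -> np.ndarray:
    return np.bincount(np.searchsorted(edges, rts, side="right"),
                       minlength=len(edges) + 1).astype(float)


def build_scheme(
    data: pd.DataFrame,
    probs: Sequence[float] = DEFAULT_PROBS,
    min_errors_full: int = 10,
) -> QuantileScheme:
    """Build quantile bins from a trial table.

    Error distributions with fewer than ``min_errors_full`` trials collapse to
    a median-split (2 bins); cells with no errors keep a single error-mass
    bin so the error rate still constrains the fit.
    """
    cells: dict[Cell, CellBins] = {}
    for cell, sub in data.groupby(["instruction", "difficulty"], observed=True):
        sub = sub[sub["choice"] != "none"]
        corr = sub.loc[sub["choice"] == "correct", "rt"].to_numpy(float)
        err = sub.loc[sub["choice"] == "incorrect", "rt"].to_numpy(float)
        if corr.size < 2:
            raise ValueError(f"cell {cell} has fewer than 2 correct trials")
        c_edges = empirical_quantiles(corr, probs)
        if err.size >= min_errors_full:
            e_edges = empirical_quantiles(err, probs)
        elif err.size >= 2:
            e_edges = np.array([np.median(err)])
        else:
            e_edges = np.array([])
        cells[cell] = CellBins(
            correct_edges=c_edges,
            correct_counts=_bin_counts(corr, c_edges),
            error_edges=e_edges,
            error_counts=_bin_counts(err, e_edges) if e_edges.size
            else np.array([float(err.size)]),
            n_trials=int(corr.size + err.size),
        )
    return QuantileScheme(tuple(probs), cells)


def qmpe_loglik(observed_counts: np.ndarray, predicted_props: np.ndarray) -> float:
    """Multinomial log-probability kernel ``sum N_i ln max(p_i, eps)``.

    Bins with zero count contribute exactly zero regardless of their
    predicted proportion.
    """
    counts = np.asarray(observed_counts, float)
    props = np.asarray(predicted_props, float)
    if counts.shape != props.shape:
        raise ValueError("counts and proportions must have matching shapes")
    logp = np.log(np.maximum(props, EPS_PROP))
    return float(np.sum(np.where(counts > 0, counts * logp, 0.0)))


def predicted_proportions(
    params: ModelParameters,
    scheme: QuantileScheme,
    sim: SimConfig,
) -> np.ndarray:
    """Simulate each condition cell and bin simulated RTs by the scheme's
    edges; proportions are over responded simulated trials."""
    out = []
    for j, cell in enumerate(CELLS):
        if cell not in scheme.cells:
            continue
        ins, diff = cell
        cp = params.cell(ins, diff)
        choice, rt = _race_kernel_fast(
            sim.n_trials, cp.boundary, cp.start_range, cp.drift_correct,
            cp.drift_incorrect, cp.noise_sd, params.t_er_for(ins),
            params.s_ter, sim.dt, sim.max_steps, cell_seed(sim.seed, j),
        )
        resp = choice != 0
        n_resp = max(int(resp.sum()), 1)
        cb = scheme.cells[cell]
        c_rt = rt[choice == 1]
        e_rt = rt[choice == -1]
        out.append(_bin_counts(c_rt, cb.correct_edges) / n_resp)
        if cb.error_edges.size:
            out.append(_bin_counts(e_rt, cb.error_edges) / n_resp)
        else:
            out.append(np.array([e_rt.size / n_resp]))
    return np.concatenate(out)


def evaluate_model(
    params: ModelParameters,
    scheme: QuantileScheme,
    sim: SimConfig,
) -> float:
    """QMPE objective (nats; larger is better) of ``params`` against the
    scheme, by seeded simulation."""
    props = predicted_proportions(params, scheme, sim)
    return qmpe_loglik(scheme.flatten_counts(), props)


def information_criteria(loglik: float, k: int, n: int) -> tuple[float, float]:
    """AIC and BIC from a log-likelihood (nats)."""
    if n < 1 or k < 1:
        raise ValueError("n and K must be >= 1")
    aic = -2.0 * loglik + 2.0 * k
    bic = -2.0 * loglik + k * math.log(n)
    return aic, bic


def akaike_weights(aics: Sequence[float]) -> np.ndarray:
    """Akaike model weights ``exp(-delta/2)`` normalized to sum to one."""
    aics = np.asarray(aics, float)
    if aics.size < 2:
        raise ValueError("need at least two models to compare")
    delta = aics - aics.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


# ---------------------------------------------------------------------------
# parameter-vector encoding per model variant
# ---------------------------------------------------------------------------

# theta layout (common prefix):
#   0 A_speed, 1..4 v_c_easy, v_c_hard, v_i_easy, v_i_hard, 5 sigma
# then per variant:
#   model1: 6 sz_frac,             7 t_er,                8 s_ter_ratio
#   model2: 6 sz_frac_acc, 7 sz_frac_speed, 8 t_er,       9 s_ter_ratio
#   model3: 6 sz_frac,     7 t_er_acc, 8 t_er_speed,      9 s_ter_ratio


def _decode(theta: np.ndarray, spec: ModelSpec) -> ModelParameters:
    a_speed = theta[0]
    vce, vch, vie, vih = theta[1:5]
    sigma = theta[5]
    boundaries = {"accuracy": 1.0, "speed": a_speed}
    if spec.name == "model2":
        sz = {"accuracy": theta[6] * 1.0, "speed": theta[7] * a_speed}
        t_er = {ins: theta[8] for ins in INSTRUCTIONS}
        s_ter = theta[9] * theta[8]
    elif spec.name == "model3":
        cap = min(1.0, a_speed)
        sz = {ins: theta[6] * cap for ins in INSTRUCTIONS}
        t_er = {"accuracy": theta[7], "speed": theta[8]}
        s_ter = theta[9] * min(theta[7], theta[8])
    else:
        cap = min(1.0, a_speed)
        sz = {ins: theta[6] * cap for ins in INSTRUCTIONS}
        t_er = {ins: theta[7] for ins in INSTRUCTIONS}
        s_ter = theta[8] * theta[7]
    cells = {}
    for ins in INSTRUCTIONS:
        for diff, vc, vi in (("easy", vce, vie), ("hard", vch, vih)):
            cells[(ins, diff)] = ConditionParams(
                boundary=boundaries[ins], start_range=sz[ins],
                drift_correct=vc, drift_incorrect=vi, noise_sd=sigma,
            )
    return ModelParameters.from_cells(cells, t_er, s_ter)


def _encode(params: ModelParameters, spec: ModelSpec) -> np.ndarray:
    acc_e = params.cell("accuracy", "easy")
    acc_h = params.cell("accuracy", "hard")
    spd_e = params.cell("speed", "easy")
    a_speed = spd_e.boundary
    head = [a_speed, acc_e.drift_correct, acc_h.drift_correct,
            acc_e.drift_incorrect, acc_h.drift_incorrect, acc_e.noise_sd]
    ter_acc = params.t_er_for("accuracy")
    ter_spd = params.t_er_for("speed")
    if spec.name == "model2":
        tail = [acc_e.start_range / 1.0, spd_e.start_range / a_speed,
                ter_acc, params.s_ter / max(ter_acc, 1e-12)]
    elif spec.name == "model3":
        cap = min(1.0, a_speed)
        tail = [acc_e.start_range / cap, ter_acc, ter_spd,
                params.s_ter / max(min(ter_acc, ter_spd), 1e-12)]
    else:
        cap = min(1.0, a_speed)
        tail = [acc_e.start_range / cap, ter_acc,
                params.s_ter / max(ter_acc, 1e-12)]
    return np.array(head + tail, float)


def _search_box(spec: ModelSpec, median_rt: float) -> list[tuple[float, float]]:
    """Scale-aware ranges for the global-search phase.

    Drifts scale like 1/median RT and noise like 1/sqrt(median RT), so one
    box serves median-normalized and seconds-based data.  The local polish
    runs on the full bounds, so estimates may leave this box.
    """
    m = median_rt
    box = [(0.3, 1.8)]  # A_speed
    box += [(0.1 / m, 4.0 / m)] * 2  # correct drifts
    box += [(0.0, 1.5 / m)] * 2  # incorrect drifts
    box += [(0.1 / math.sqrt(m), 1.6 / math.sqrt(m))]  # sigma
    if spec.name == "model2":
        box += [(0.0, 0.95), (0.0, 0.95), (0.05 * m, 0.8 * m), (0.0, 2.0)]
    elif spec.name == "model3":
        box += [(0.0, 0.95), (0.05 * m, 0.8 * m), (0.05 * m, 0.8 * m),
                (0.0, 2.0)]
    else:
        box += [(0.0, 0.95), (0.05 * m, 0.8 * m), (0.0, 2.0)]
    return box


def _bounds(spec: ModelSpec, median_rt: float) -> list[tuple[float, float]]:
    b = [(0.2, 2.0)]  # A_speed
    b += [(0.0, 10.0)] * 4  # drifts
    b += [(0.01, 5.0)]  # sigma
    # T_er can exceed the fastest RT (start points may begin near the
    # boundary), so the cap is tied to the typical RT, not the minimum
    ter_hi = 0.8 * median_rt
    if spec.name == "model2":
        b += [(0.0, 0.95), (0.0, 0.95), (0.0, ter_hi), (0.0, 2.0)]
    elif spec.name == "model3":
        b += [(0.0, 0.95), (0.0, ter_hi), (0.0, ter_hi), (0.0, 2.0)]
    else:
        b += [(0.0, 0.95), (0.0, ter_hi), (0.0, 2.0)]
    return b


@dataclass
class OptimizerConfig:
    """Settings for the QMPE objective and its optimizers.

    ``n_sim`` simulated trials per condition evaluate the objective (with a
    seed fixed per fit so the surface is deterministic); ``dt`` and
    ``max_time`` are in the data's declared time unit.
    """

    dt: float
    max_time: float
    n_sim: int = 10_000
    n_sim_search: int = 1_200
    n_sim_polish: int = 5_000
    seed: int = 0
    de_popsize: int = 6
    de_maxiter: int = 42
    de_tol: float = 0.0  # run the full iteration budget
    polish_maxfev: int = 400


@dataclass
class FitResult:
    """A fitted model: parameters plus fit statistics and provenance."""

    parameters: ModelParameters
    log_likelihood: float
    aic: float
    bic: float
    n_observations: int
    k: int
    model: str
    seed: int
    n_evaluations: int = 0
    converged: bool = True
    data_hash: str = ""

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "parameters": self.parameters.to_dict(),
            "log_likelihood": self.log_likelihood,
            "aic": self.aic,
            "bic": self.bic,
            "n_observations": self.n_observations,
            "k": self.k,
            "seed": self.seed,
            "n_evaluations": self.n_evaluations,
            "converged": self.converged,
            "data_hash": self.data_hash,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @staticmethod
    def from_dict(d: dict) -> "FitResult":
        return FitResult(
            parameters=ModelParameters.from_dict(d["parameters"]),
            log_likelihood=d["log_likelihood"], aic=d["aic"], bic=d["bic"],
            n_observations=d["n_observations"], k=d["k"], model=d["model"],
            seed=d["seed"], n_evaluations=d.get("n_evaluations", 0),
            converged=d.get("converged", True),
            data_hash=d.get("data_hash", ""),
        )

    @staticmethod
    def from_json(path) -> "FitResult":
        with open(path) as fh:
            return FitResult.from_dict(json.load(fh))


def _table_hash(data: pd.DataFrame) -> str:
    h = hashlib.sha256()
    h.update(pd.util.hash_pandas_object(
        data[["instruction", "difficulty", "choice", "rt"]], index=False
    ).to_numpy().tobytes())
    return h.hexdigest()[:16]


def _check_data(data: pd.DataFrame) -> None:
    for cell in CELLS:
        sub = data[(data["instruction"] == cell[0])
                   & (data["difficulty"] == cell[1])]
        n_corr = int((sub["choice"] == "correct").sum())
        if n_corr < 20:
            raise ValueError(
                f"cell {cell} has only {n_corr} correct trials (need >= 20)"
            )


def _result_from_theta(theta, spec, scheme, sim, cfg, n_evals, converged,
                       data_hash) -> FitResult:
    params = _decode(np.asarray(theta, float), spec)
    ll = evaluate_model(params, scheme, sim)
    n = scheme.n_observations
    aic, bic = information_criteria(ll, spec.n_free_parameters, n)
    return FitResult(
        parameters=params, log_likelihood=ll, aic=aic, bic=bic,
        n_observations=n, k=spec.n_free_parameters, model=spec.name,
        seed=cfg.seed, n_evaluations=n_evals, converged=converged,
        data_hash=data_hash,
    )


def fit_model(
    data: pd.DataFrame,
    spec: ModelSpec | str,
    cfg: OptimizerConfig,
    scheme: QuantileScheme | None = None,
) -> FitResult:
    """Fit one model variant to a trial table by differential evolution on
    the QMPE objective, followed by a Nelder–Mead polish."""
    if isinstance(spec, str):
        spec = ModelSpec.by_name(spec)
    _check_data(data)
    if scheme is None:
        scheme = build_scheme(data)
    sim = SimConfig(cfg.dt, cfg.max_time, cfg.n_sim, cfg.seed)
    # the search phase censors earlier: implausible candidates (low drift,
    # high boundary) would otherwise burn the full horizon on every trial
    sim_search = SimConfig(cfg.dt, 0.6 * cfg.max_time, cfg.n_sim_search,
                           cfg.seed)
    counts = scheme.flatten_counts()

    n_evals = 0

    def make_obj(s):
        def neg_obj(theta):
            nonlocal n_evals
            n_evals += 1
            props = predicted_proportions(_decode(theta, spec), scheme, s)
            return -qmpe_loglik(counts, props)
        return neg_obj

    med_rt = float(data.loc[data["choice"] != "none", "rt"].median())
    bounds = _bounds(spec, med_rt)
    # global search on a cheaper simulation over the plausible sub-box,
    # then refinement on a larger simulation over the full bounds
    box = [(max(b[0], g[0]), min(b[1], g[1]))
           for b, g in zip(_search_box(spec, med_rt), bounds)]
    de = optimize.differential_evolution(
        make_obj(sim_search), box, seed=cfg.seed, maxiter=cfg.de_maxiter,
        popsize=cfg.de_popsize, tol=cfg.de_tol, polish=False,
        init="sobol", updating="immediate",
    )
    theta = de.x
    if cfg.polish_maxfev > 0:
        neg_full = make_obj(sim)
        f0 = neg_full(theta)
        nm = optimize.minimize(
            neg_full, theta, method="Nelder-Mead",
            bounds=bounds,
            options={"maxfev": cfg.polish_maxfev, "xatol": 1e-4,
                     "fatol": 1e-3},
        )
        if nm.fun <= f0:
            theta = nm.x
    return _result_from_theta(theta, spec, scheme, sim, cfg, n_evals, True,
                              _table_hash(data))


def refit_simplex(
    data: pd.DataFrame,
    start: ModelParameters,
    spec: ModelSpec | str,
    cfg: OptimizerConfig,
    scheme: QuantileScheme | None = None,
    maxfev: int | None = None,
) -> FitResult:
    """Local Nelder–Mead refinement from a previous fit's parameters.

    Used inside bootstrap loops where a full global search per replicate is
    not affordable.  Never returns a worse objective than the start point;
    non-convergence is flagged, not raised.
    """
    if isinstance(spec, str):
        spec = ModelSpec.by_name(spec)
    if scheme is None:
        scheme = build_scheme(data)
    sim = SimConfig(cfg.dt, cfg.max_time, cfg.n_sim, cfg.seed)
    counts = scheme.flatten_counts()
    n_evals = 0

    def neg_obj(theta):
        nonlocal n_evals
        n_evals += 1
        props = predicted_proportions(_decode(theta, spec), scheme, sim)
        return -qmpe_loglik(counts, props)

    theta0 = _encode(start, spec)
    med_rt = float(data.loc[data["choice"] != "none", "rt"].median())
    bounds = _bounds(spec, med_rt)
    theta0 = np.clip(theta0, [b[0] for b in bounds], [b[1] for b in bounds])
    f0 = neg_obj(theta0)
    res = optimize.minimize(
        neg_obj, theta0, method="Nelder-Mead", bounds=bounds,
        options={"maxfev": maxfev or cfg.polish_maxfev,
                 "xatol": 1e-4, "fatol": 1e-3},
    )
    theta, converged = (res.x, bool(res.success)) if res.fun <= f0 \
        else (theta0, False)
    return _result_from_theta(theta, spec, scheme, sim, cfg, n_evals,
                              converged, _table_hash(data))
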