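"""Decision-parameter containers for the rectified two-accumulator race model.

A perceptual decision between two responses is modelled as a race between a
"correct" and an "incorrect" evidence accumulator.  Each condition cell
(instruction x difficulty) owns a boundary ``A``, a start-point range ``S_z``
(starting points are uniform on ``[0, S_z]``), two drift rates and a diffusion
noise standard deviation.  Non-decision time is uniform with mean ``T_er`` and
width ``S_Ter`` and is shared across cells (optionally per-instruction).

Because race models are identified only up to a common scaling of the
evidence-unit parameters, one boundary is pinned to 1 (the accuracy boundary
by convention).  :func:`to_forced_excursion` re-expresses a fitted parameter
set so that *every* instruction shares the same boundary, transferring the
speed/accuracy effect onto drifts, start-point range and noise — a
mathematically equivalent model in which the tradeoff is carried by a global
gain change rather than a shorter excursion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping

INSTRUCTIONS = ("accuracy", "speed")
DIFFICULTIES = ("easy", "hard")

Cell = tuple[str, str]  # (instruction, difficulty)


@dataclass(frozen=True)
class ConditionParams:
    """Decision parameters of one instruction x difficulty cell.

    All quantities are in evidence units; drifts are evidence per unit time
    and ``noise_sd`` is evidence per square-root unit time.
    """

    boundary: float
    start_range: float
    drift_correct: float
    drift_incorrect: float
    noise_sd: float

    def validate(self) -> None:
        if not self.boundary > 0:
            raise ValueError(f"boundary must be > 0, got {self.boundary}")
        if not 0 <= self.start_range < self.boundary:
            raise ValueError(
                f"start_range must satisfy 0 <= S_z < A, got "
                f"S_z={self.start_range}, A={self.boundary}"
            )
        if self.drift_correct < 0 or self.drift_incorrect < 0:
            raise ValueError("drift rates must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def scaled(self, factor: float) -> "ConditionParams":
        """Multiply every evidence-unit parameter by ``factor``."""
        if factor <= 0:
            raise ValueError("scale factor must be > 0")
        return ConditionParams(
            boundary=self.boundary * factor,
            start_range=self.start_range * factor,
            drift_correct=self.drift_correct * factor,
            drift_incorrect=self.drift_incorrect * factor,
            noise_sd=self.noise_sd * factor,
        )


@dataclass(frozen=True)
class ModelParameters:
    """Full parameter set: one :class:`ConditionParams` per condition cell plus
    non-decision time.

    ``t_er`` maps instruction -> mean non-decision time; in most model variants
    the two instructions share a single value.  ``scaling_reference`` names the
    instruction whose boundary is pinned to 1 for identifiability.
    """

    cells: Mapping[Cell, ConditionParams]
    t_er: Mapping[str, float] = field(default_factory=dict)
    s_ter: float = 0.0
    scaling_reference: str = "accuracy"

    @staticmethod
    def from_cells(
        cells: Mapping[Cell, ConditionParams],
        t_er: float | Mapping[str, float],
        s_ter: float = 0.0,
        scaling_reference: str = "accuracy",
    ) -> "ModelParameters":
        if isinstance(t_er, (int, float)):
            t_er = {ins: float(t_er) for ins in INSTRUCTIONS}
        p = ModelParameters(
            cells=dict(cells), t_er=dict(t_er), s_ter=float(s_ter),
            scaling_reference=scaling_reference,
        )
        p.validate()
        return p

    def validate(self) -> None:
        for cell, cp in self.cells.items():
            ins, diff = cell
            if ins not in INSTRUCTIONS or diff not in DIFFICULTIES:
                raise ValueError(f"unknown condition cell {cell!r}")
            cp.validate()
        for ins, te in self.t_er.items():
            if te < 0:
                raise ValueError("T_er must be >= 0")
            if te - self.s_ter / 2 < 0:
                raise ValueError("T_er - S_Ter/2 must be >= 0")
        if self.s_ter < 0:
            raise ValueError("S_Ter must be >= 0")

    def t_er_for(self, instruction: str) -> float:
        return self.t_er[instruction]

    def cell(self, instruction: str, difficulty: str) -> ConditionParams:
        return self.cells[(instruction, difficulty)]

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "cells": {
                f"{ins}/{diff}": {
                    "boundary": cp.boundary,
                    "start_range": cp.start_range,
                    "drift_correct": cp.drift_correct,
                    "drift_incorrect": cp.drift_incorrect,
                    "noise_sd": cp.noise_sd,
                }
                for (ins, diff), cp in self.cells.items()
            },
            "t_er": dict(self.t_er),
            "s_ter": self.s_ter,
            "scaling_reference": self.scaling_reference,
        }

    @staticmethod
    def from_dict(d: dict) -> "ModelParameters":
        cells = {}
        for key, cp in d["cells"].items():
            ins, diff = key.split("/")
            cells[(ins, diff)] = ConditionParams(**cp)
        return ModelParameters.from_cells(
            cells, d["t_er"], d.get("s_ter", 0.0),
            d.get("scaling_reference", "accuracy"),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @staticmethod
    def from_json(path) -> "ModelParameters":
        with open(path) as fh:
            return ModelParameters.from_dict(json.load(fh))


def make_parameters(
    *,
    a_accuracy: float = 1.0,
    a_speed: float,
    sz_accuracy: float,
    sz_speed: float,
    v_correct_easy: float,
    v_correct_hard: float,
    v_incorrect_easy: float,
    v_incorrect_hard: float,
    noise_sd: float,
    t_er: float | Mapping[str, float],
    s_ter: float,
) -> ModelParameters:
    """Build a standard 2x2 parameter set in which drifts and noise are shared
    across instructions (the free-excursion layout)."""
    cells = {}
    for ins, a, sz in (("accuracy", a_accuracy, sz_accuracy),
                       ("speed", a_speed, sz_speed)):
        for diff, vc, vi in (("easy", v_correct_easy, v_incorrect_easy),
                             ("hard", v_correct_hard, v_incorrect_hard)):
            cells[(ins, diff)] = ConditionParams(
                boundary=a, start_range=sz, drift_correct=vc,
                drift_incorrect=vi, noise_sd=noise_sd,
            )
    return ModelParameters.from_cells(cells, t_er, s_ter)


def to_forced_excursion(
    params: ModelParameters, reference_cell: str = "speed"
) -> ModelParameters:
    """Re-express ``params`` so the ``reference_cell`` instruction's boundary
    equals the pinned boundary.

    Every evidence-unit parameter (A, S_z, both drifts, noise SD) of each cell
    belonging to ``reference_cell`` is divided by that cell's original
    boundary; non-decision time is untouched; the other instruction's cells
    are returned unchanged.  The race model's scaling property makes the
    result behaviourally identical, trial-for-trial under common random
    numbers.
    """
    if reference_cell not in INSTRUCTIONS:
        raise ValueError(f"unknown instruction {reference_cell!r}")
    new_cells = {}
    for cell, cp in params.cells.items():
        ins, _ = cell
        if ins == reference_cell:
            if cp.boundary <= 0:
                raise ValueError("cannot rescale a cell with boundary <= 0")
            new_cells[cell] = cp.scaled(1.0 / cp.boundary)
        else:
            new_cells[cell] = cp
    return replace(params, cells=new_cells)


# ---------------------------------------------------------------------------
# Reference group-level estimates for the random-dot motion speed/accuracy
# study the package is built around (best-supported variant: boundary and
# start-point range free across instructions, drifts free across difficulty).
# The TMS-session estimates are on time normalized to each session's median
# EMG reaction time; the EEG-session estimates are on seconds.
# ---------------------------------------------------------------------------

TMS_STUDY_PARAMS = make_parameters(
    a_speed=0.893,
    sz_accuracy=0.447,
    sz_speed=0.523,
    v_correct_easy=1.280,
    v_correct_hard=0.634,
    v_incorrect_easy=0.098,
    v_incorrect_hard=0.004,
    noise_sd=0.499,
    t_er=0.382,
    s_ter=0.374,
)

EEG_STUDY_PARAMS = make_parameters(
    a_speed=0.815,
    sz_accuracy=0.319,
    sz_speed=0.541,
    v_correct_easy=2.475,
    v_correct_hard=1.350,
    v_incorrect_easy=0.253,
    v_incorrect_hard=0.054,
    noise_sd=0.785,
    t_er=0.257,
    s_ter=0.229,
)
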