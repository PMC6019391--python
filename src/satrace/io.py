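"""CSV/JSON readers and writers with schema validation.

All files are plain text.  Times are floating point in the unit declared by
the run configuration; no hidden unit conversions happen on read or write.
Schema violations are reported with the offending row number.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .cpp import EpochSet
from .signal import Signal

TRIAL_COLUMNS = ["participant_id", "session", "instruction", "difficulty",
                 "choice", "rt"]
MEP_COLUMNS = ["trial_id", "participant_id", "session", "instruction",
               "difficulty", "muscle_role", "tms_latency", "amplitude"]
VALID_INSTRUCTIONS = {"speed", "accuracy"}
VALID_DIFFICULTIES = {"easy", "hard"}
VALID_CHOICES = {"correct", "incorrect", "none"}
VALID_ROLES = {"responding", "nonresponding"}


@dataclass
class RunConfig:
    """Run-wide settings: time unit, step sizes, grids, simulation and
    resampling counts, seeds."""

    unit: str = "fraction"
    dt: float = 0.01
    max_time: float = 5.0
    n_sim_fit: int = 10_000
    n_sim_predict: int = 20_000
    n_boot: int = 1999
    n_perm: int = 1999
    fwhm: float = 0.05
    seed: int = 0
    extras: dict = field(default_factory=dict)

    def validate(self) -> None:
        for name in ("n_sim_fit", "n_sim_predict", "n_boot", "n_perm"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.dt <= 0 or self.max_time <= 0 or self.fwhm <= 0:
            raise ValueError("dt, max_time and fwhm must be > 0")

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: raw.pop(k) for k in list(raw)
                 if k in RunConfig.__dataclass_fields__ and k != "extras"}
        cfg = RunConfig(**known, extras=raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__
             if k != "extras"}
        d.update(self.extras)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def _check_values(df, col, valid, path):
    bad = ~df[col].isin(valid)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"{path}: row {row + 2}: invalid {col} value "
            f"{df[col].iloc[row]!r} (expected one of {sorted(valid)})"
        )


def _check_numeric(df, col, path, allow_nan=True):
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() & df[col].notna() if allow_nan else vals.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"{path}: row {row + 2}: non-numeric {col} value "
            f"{df[col].iloc[row]!r}"
        )
    return vals


def read_trial_table(path) -> pd.DataFrame:
    """Read and validate a behavioral trial table CSV."""
    df = pd.read_csv(path)
    _require_columns(df, TRIAL_COLUMNS, path)
    _check_values(df, "instruction", VALID_INSTRUCTIONS, path)
    _check_values(df, "difficulty", VALID_DIFFICULTIES, path)
    _check_values(df, "choice", VALID_CHOICES, path)
    df["rt"] = _check_numeric(df, "rt", path)
    return df


def write_trial_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_mep_table(path) -> pd.DataFrame:
    """Read and validate a trial-level MEP record CSV."""
    df = pd.read_csv(path)
    _require_columns(df, MEP_COLUMNS, path)
    _check_values(df, "instruction", VALID_INSTRUCTIONS, path)
    _check_values(df, "difficulty", VALID_DIFFICULTIES, path)
    _check_values(df, "muscle_role", VALID_ROLES, path)
    df["tms_latency"] = _check_numeric(df, "tms_latency", path,
                                       allow_nan=False)
    df["amplitude"] = _check_numeric(df, "amplitude", path, allow_nan=False)
    return df


def read_epochs(path, trials_path=None) -> EpochSet:
    """Read ERP-like epochs from a long-format CSV.

    Expected columns: trial_id, time, amplitude, rt, plus condition labels
    (instruction, difficulty).  Rows of one trial share rt and labels.
    """
    df = pd.read_csv(path)
    _require_columns(df, ["trial_id", "time", "amplitude", "rt"], path)
    df["time"] = _check_numeric(df, "time", path, allow_nan=False)
    df["amplitude"] = _check_numeric(df, "amplitude", path)
    wide = df.pivot_table(index="trial_id", columns="time",
                          values="amplitude", dropna=False)
    grid = wide.columns.to_numpy(float)
    meta = df.drop_duplicates("trial_id").set_index("trial_id")
    meta = meta.loc[wide.index]
    label_cols = [c for c in ("participant_id", "instruction", "difficulty",
                              "choice") if c in meta.columns]
    return EpochSet(
        grid=grid,
        data=wide.to_numpy(float),
        rt=meta["rt"].to_numpy(float),
        labels=meta[label_cols].reset_index(),
    )


def write_epochs(path, epochs: EpochSet) -> None:
    """Write epochs in the long format read_epochs expects."""
    n, g = epochs.data.shape
    labels = epochs.labels if epochs.labels is not None else pd.DataFrame(
        {"trial_id": np.arange(n)})
    rows = pd.DataFrame({
        "trial_id": np.repeat(labels["trial_id"].to_numpy()
                              if "trial_id" in labels else np.arange(n), g),
        "time": np.tile(epochs.grid, n),
        "amplitude": epochs.data.ravel(),
        "rt": np.repeat(epochs.rt, g),
    })
    for c in ("participant_id", "instruction", "difficulty", "choice"):
        if labels is not None and c in labels:
            rows[c] = np.repeat(labels[c].to_numpy(), g)
    rows.to_csv(path, index=False)


def write_signal(path, signal: Signal) -> None:
    df = pd.DataFrame({"time": signal.grid, "value": signal.values})
    if signal.ci_low is not None:
        df["ci_low"] = signal.ci_low
        df["ci_high"] = signal.ci_high
    if signal.n_effective is not None:
        df["n_effective"] = signal.n_effective
    df.insert(0, "alignment", signal.alignment)
    df.to_csv(path, index=False)


def read_signal(path) -> Signal:
    df = pd.read_csv(path)
    return Signal(
        alignment=df["alignment"].iloc[0],
        grid=df["time"].to_numpy(float),
        values=df["value"].to_numpy(float),
        ci_low=df["ci_low"].to_numpy(float) if "ci_low" in df else None,
        ci_high=df["ci_high"].to_numpy(float) if "ci_high" in df else None,
        n_effective=df["n_effective"].to_numpy(float)
        if "n_effective" in df else None,
    )


def write_report(path, result) -> None:
    """Serialize a comparison result (or any plain mapping) as JSON."""
    if hasattr(result, "__dataclass_fields__"):
        from dataclasses import asdict
        result = asdict(result)

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(f"cannot serialize {type(o)}")

    with open(path, "w") as fh:
        json.dump(result, fh, indent=2, default=default)
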