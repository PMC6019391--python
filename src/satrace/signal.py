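"""Time-grid signal container shared by the MEP and CPP analyses."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Signal:
    """A signal on an evenly spaced time grid, stimulus- or response-locked.

    ``values`` may contain NaN where the estimate is masked (insufficient
    contributing data); optional ``ci_low``/``ci_high`` bracket the values;
    ``n_effective`` records the summed kernel weight (or trial count) behind
    each grid point.
    """

    alignment: str
    grid: np.ndarray
    values: np.ndarray
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    n_effective: np.ndarray | None = None

    def __post_init__(self):
        self.grid = np.asarray(self.grid, float)
        self.values = np.asarray(self.values, float)
        if self.alignment not in ("stimulus", "response"):
            raise ValueError("alignment must be 'stimulus' or 'response'")
        if self.grid.ndim != 1 or self.grid.shape != self.values.shape:
            raise ValueError("grid and values must be matching 1-d arrays")
        d = np.diff(self.grid)
        if self.grid.size > 1 and not np.all(d > 0):
            raise ValueError("grid must be strictly increasing")

    @property
    def mask(self) -> np.ndarray:
        """True where the value is defined."""
        return np.isfinite(self.values)


def default_grid(alignment: str, unit: str = "fraction") -> np.ndarray:
    """Analysis grids: 1%-of-median-RT steps on normalized time.

    Stimulus-locked 0..150% of median RT; response-locked -100%..0%.
    With ``unit='ms'`` the same spans are interpreted in milliseconds times
    ten (suitable for ~400-ms median RTs); explicit grids are preferred for
    millisecond data.
    """
    if alignment == "stimulus":
        lo, hi = 0.0, 1.5
    elif alignment == "response":
        lo, hi = -1.0, 0.0
    else:
        raise ValueError("alignment must be 'stimulus' or 'response'")
    step = 0.01
    if unit == "ms":
        lo, hi, step = lo * 400, hi * 400, 4.0
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(n + 1)
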