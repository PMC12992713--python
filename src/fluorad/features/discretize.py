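"""ROI gray-level discretization for the texture matrices."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DiscretizationSpec", "discretize"]


@dataclass(frozen=True)
class DiscretizationSpec:
    """Either a fixed number of equal-width bins over [min, max] of the ROI,
    or fixed-width bins anchored at the ROI minimum."""

    mode: str = "fixed-bin-count"
    value: float = 32

    def __post_init__(self):
        if self.mode not in ("fixed-bin-count", "fixed-bin-width"):
            raise ValueError(f"unknown discretization mode {self.mode!r}")
        if self.mode == "fixed-bin-count" and (self.value < 2 or self.value != int(self.value)):
            raise ValueError("bin count must be an integer >= 2")
        if self.mode == "fixed-bin-width" and self.value <= 0:
            raise ValueError("bin width must be > 0")


def discretize(values: np.ndarray, d: DiscretizationSpec) -> tuple[np.ndarray, int]:
    """Map ROI intensities to integer gray levels 1..Ng.

    A constant ROI collapses to a single level (Ng = 1); callers treat that
    as degenerate.  With fixed-bin-width, level = floor((x − min)/w) + 1.
    With fixed-bin-count, Nb equal-width bins span [min, max] and the
    maximum maps into the top bin.
    """
    values = np.asarray(values, float).ravel()
    if values.size == 0:
        raise ValueError("cannot discretize an empty ROI")
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        return np.ones(values.shape, dtype=int), 1
    if d.mode == "fixed-bin-width":
        levels = np.floor((values - lo) / d.value).astype(int) + 1
        return levels, int(levels.max())
    nb = int(d.value)
    width = (hi - lo) / nb
    levels = np.minimum(np.floor((values - lo) / width).astype(int), nb - 1) + 1
    return levels, nb
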