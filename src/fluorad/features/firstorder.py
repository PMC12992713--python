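"""First-order (intensity-distribution) features, 18 values.

Definitions follow the standard radiomics reference set: energy is the sum
of squared intensities, total energy scales it by the physical voxel
volume, entropy/uniformity are computed on the discretized gray-level
histogram (log base 2), skewness and kurtosis use population moments
(kurtosis is not excess-corrected: a Gaussian scores 3).
"""

from __future__ import annotations

import numpy as np

from .discretize import DiscretizationSpec, discretize

__all__ = ["FIRSTORDER_NAMES", "firstorder_features"]

FIRSTORDER_NAMES = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "10Percentile",
    "90Percentile",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
)


def firstorder_features(
    values: np.ndarray,
    voxel_volume: float,
    disc: DiscretizationSpec | None = None,
) -> dict[str, float]:
    x = np.asarray(values, float).ravel()
    if x.size == 0:
        raise ValueError("first-order features need a nonempty ROI")
    n = x.size
    mean = x.mean()
    var = x.var()  # population
    sd = np.sqrt(var)

    levels, _ = discretize(x, disc or DiscretizationSpec())
    p = np.bincount(levels)[1:] / n
    p = p[p > 0]

    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    if sd > 0:
        skew = np.mean((x - mean) ** 3) / sd**3
        kurt = np.mean((x - mean) ** 4) / var**2
    else:
        skew, kurt = 0.0, 0.0

    energy = float(np.sum(x**2))
    return {
        "Energy": energy,
        "TotalEnergy": energy * voxel_volume,
        "Entropy": float(-np.sum(p * np.log2(p))),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(x - mean))),
        "RobustMeanAbsoluteDeviation": float(
            np.mean(np.abs(robust - robust.mean())) if robust.size else 0.0
        ),
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Skewness": float(skew),
        "Kurtosis": float(kurt),
        "Variance": float(var),
        "Uniformity": float(np.sum(p**2)),
    }
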