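"""Whole-image filters applied before feature extraction.

Intensity maps (square, square-root, logarithm, exponential) use the
range-normalizing closed forms of the reference radiomics implementation so
that filtered intensities stay on a scale comparable to the input:

* square:      f(x) = (c·x)²  with  c = 1/√(max|x|)
* squareroot:  f(x) = √(c·x) for x ≥ 0, −√(−c·x) otherwise, c = max|x|
* logarithm:   f(x) = c·log(x + 1) for x ≥ 0, −c·log(−x + 1) otherwise,
               c = max|x| / log(max|x| + 1)
* exponential: f(x) = exp(c·x)  with  c = log(max|x|)/max|x|

Gradient is the magnitude of central differences over physical spacing;
log-sigma is the scale-normalized (σ²-weighted) Laplacian-of-Gaussian at σ
given in mm; wavelet is a one-level undecimated separable Haar transform
producing the 8 L/H subband combinations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import ndimage

from ..volume import ScanVolume

__all__ = ["FilterSpec", "apply_filter"]

WAVELET_SUBBANDS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")

_NAMES = {
    "original",
    "square",
    "squareroot",
    "logarithm",
    "exponential",
    "gradient",
    "log-sigma",
    "wavelet",
}


@dataclass(frozen=True)
class FilterSpec:
    """One filter in a feature-extraction configuration.

    ``sigma_mm`` applies to log-sigma; ``subband`` to wavelet.
    """

    name: str
    sigma_mm: float | None = None
    subband: str | None = None

    def __post_init__(self):
        if self.name not in _NAMES:
            raise ValueError(f"unknown filter {self.name!r}")
        if self.name == "log-sigma":
            if self.sigma_mm is None or self.sigma_mm <= 0:
                raise ValueError("log-sigma requires sigma_mm > 0")
        if self.name == "wavelet":
            if self.subband not in WAVELET_SUBBANDS:
                raise ValueError(f"wavelet subband must be one of {WAVELET_SUBBANDS}")

    @property
    def label(self) -> str:
        """Column-name prefix, e.g. ``log-sigma-2mm`` or ``wavelet-HLL``."""
        if self.name == "log-sigma":
            s = f"{self.sigma_mm:g}"
            return f"log-sigma-{s}mm"
        if self.name == "wavelet":
            return f"wavelet-{self.subband}"
        return self.name


def _intensity_map(data: np.ndarray, name: str) -> np.ndarray:
    m = float(np.max(np.abs(data)))
    if m == 0:
        return np.zeros_like(data) if name != "exponential" else np.ones_like(data)
    if name == "square":
        c = 1.0 / np.sqrt(m)
        return (c * data) ** 2
    if name == "squareroot":
        return np.where(data >= 0, np.sqrt(m * np.abs(data)), -np.sqrt(m * np.abs(data)))
    if name == "logarithm":
        c = m / np.log(m + 1.0)
        return np.sign(data) * c * np.log(np.abs(data) + 1.0)
    if name == "exponential":
        c = np.log(m) / m
        return np.exp(c * data)
    raise AssertionError(name)


def _gradient_magnitude(data: np.ndarray, spacing) -> np.ndarray:
    gx, gy, gz = np.gradient(data, *spacing)
    return np.sqrt(gx**2 + gy**2 + gz**2)


def _log_filter(data: np.ndarray, spacing, sigma_mm: float) -> np.ndarray:
    sigma_vox = [sigma_mm / s for s in spacing]
    return sigma_mm**2 * ndimage.gaussian_laplace(data, sigma=sigma_vox)


def _wavelet(data: np.ndarray, subband: str) -> np.ndarray:
    # undecimated transform needs even extents: symmetric-pad, then crop
    pads = [(0, n % 2) for n in data.shape]
    padded = np.pad(data, pads, mode="symmetric")
    coeffs = pywt.swtn(padded, wavelet="haar", level=1)[0]
    key = subband.replace("L", "a").replace("H", "d")
    out = coeffs[key]
    return out[tuple(slice(0, n) for n in data.shape)]


def apply_filter(vol: ScanVolume, f: FilterSpec) -> ScanVolume:
    """Return the filtered image as a derived volume (same grid/spacing)."""
    if f.name == "original":
        out = vol.data.copy()
    elif f.name in ("square", "squareroot", "logarithm", "exponential"):
        out = _intensity_map(vol.data, f.name)
    elif f.name == "gradient":
        out = _gradient_magnitude(vol.data, vol.spacing)
    elif f.name == "log-sigma":
        out = _log_filter(vol.data, vol.spacing, f.sigma_mm)
    elif f.name == "wavelet":
        out = _wavelet(vol.data, f.subband)
    else:  # pragma: no cover - guarded by FilterSpec
        raise ValueError(f"unknown filter {f.name!r}")
    return vol.copy(data=out, filter=f.label)
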