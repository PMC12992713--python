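"""Seeded synthetic ¹⁹F MR acquisitions.

The study's scans are not public, so this module generates phantom,
in-vivo-like, and pure-noise acquisitions with the statistical structure the
downstream analysis assumes:

* ¹⁹F is background-free and spin-density weighted, so the noiseless signal
  is **exactly proportional** to the local ¹⁹F nuclei concentration (mM).
* Magnitude reconstruction turns complex Gaussian receiver noise into
  **Rician** noise; background-only voxels follow a Rayleigh law.
* An intrasession retest differs from its test only through the noise
  realization; an intersession retest additionally undergoes rigid
  repositioning, a smooth multiplicative bias-field change (B1/coil profile),
  a global gain drift, and a noise-level drift.

Every generator output is a pure function of its specs and seeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .volume import DEFAULT_SPACING, ScanVolume, Spacing

__all__ = [
    "Tube",
    "PhantomSpec",
    "AcquisitionSpec",
    "SessionPerturbation",
    "render_phantom",
    "add_rician_noise",
    "acquire_noise_scan",
    "apply_session_perturbation",
    "sample_perturbation",
    "simulate_test_retest",
    "render_invivo_scene",
    "detection_series",
    "default_phantom",
    "default_acquisition",
    "spawn_seeds",
]

#: ¹⁹F nuclei content (mM) of the high- and low-loaded phantom tubes;
#: 5.8 mM PFPE ≡ 244 mM ¹⁹F, 2.8 mM PFPE ≡ 118 mM ¹⁹F, matched in the
#: PFCE phantom.
HIGH_F19_MM = 244.0
LOW_F19_MM = 118.0

#: ¹⁹F nuclei content of the 5 mM PFPE in-vivo reference tube, same
#: nuclei-per-molecule ratio as the loaded tubes (244/5.8 per mM agent).
REFERENCE_TUBE_F19_MM = 5.0 * HIGH_F19_MM / 5.8


@dataclass(frozen=True)
class Tube:
    """A cylindrical agarose tube within the phantom.

    ``center`` is in physical mm, ``axis`` is the cylinder axis direction
    (normalized on construction), ``f19_mm`` the ¹⁹F nuclei concentration.
    """

    center: tuple[float, float, float]
    radius: float
    length: float
    f19_mm: float
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("tube radius must be > 0")
        if self.length <= 0:
            raise ValueError("tube length must be > 0")
        if self.f19_mm < 0:
            raise ValueError("concentration must be >= 0")
        a = np.asarray(self.axis, float)
        n = np.linalg.norm(a)
        if n == 0:
            raise ValueError("tube axis must be a nonzero vector")
        object.__setattr__(self, "axis", tuple(a / n))


@dataclass
class PhantomSpec:
    """Tube layout of one agarose phantom plus its contrast-agent label."""

    tubes: list[Tube]
    agent: str = "PFPE"

    def scaled(self, factor: float) -> "PhantomSpec":
        """Same geometry with every concentration multiplied by ``factor``."""
        return PhantomSpec(
            [replace(t, f19_mm=t.f19_mm * factor) for t in self.tubes], self.agent
        )


@dataclass
class AcquisitionSpec:
    """Sampling grid, signal scaling, and noise level of one acquisition.

    ``gain`` is intensity units per mM ¹⁹F; ``sigma`` is the per-channel
    Gaussian noise SD in intensity units.  ``bias_amplitude`` is the maximum
    fractional deviation of the multiplicative bias field (0 = flat).
    """

    shape: tuple[int, int, int] = (64, 64, 12)
    spacing: Spacing = DEFAULT_SPACING
    gain: float = 0.15
    sigma: float = 1.0
    bias_amplitude: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if any(n < 1 for n in self.shape):
            raise ValueError("grid shape must be >= 1 per axis")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.bias_amplitude < 0:
            raise ValueError("bias amplitude must be >= 0")

    @property
    def extent(self) -> np.ndarray:
        """Physical size of the field of view per axis, mm."""
        return np.array(self.shape) * np.array(self.spacing)


@dataclass
class SessionPerturbation:
    """Between-session acquisition change: repositioning plus drifts.

    All-zero/identity values denote intrasession conditions (no change).
    """

    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    bias_amplitude: float = 0.0
    gain_factor: float = 1.0
    noise_drift: float = 1.0

    def __post_init__(self):
        if self.gain_factor <= 0:
            raise ValueError("gain factor must be > 0")
        if self.bias_amplitude < 0:
            raise ValueError("bias amplitude must be >= 0")
        if self.noise_drift <= 0:
            raise ValueError("noise drift factor must be > 0")

    @property
    def is_identity(self) -> bool:
        return (
            all(t == 0 for t in self.translation)
            and all(r == 0 for r in self.rotation_deg)
            and self.bias_amplitude == 0
            and self.gain_factor == 1.0
            and self.noise_drift == 1.0
        )


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministically expand one master seed into ``n`` per-scan seeds."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def default_phantom(agent: str = "PFPE") -> PhantomSpec:
    """The five-tube study phantom: 2 high, 2 low, 1 unloaded control.

    All five tubes are the same tube type (identical radius), seated in a
    quincunx around the FOV center; only fill height and seating depth vary
    slightly, as hand-filled tubes do.  Segments therefore share geometry
    up to partial-volume digitization — the condition under which the study
    evaluates shape-feature repeatability.
    """
    cx, cy, cz = 17.6, 17.6, 9.0  # center of the default 35.2×35.2×18 mm FOV
    r = 8.0
    return PhantomSpec(
        tubes=[
            Tube((cx - r, cy, cz - 0.2), 3.0, 12.0, HIGH_F19_MM),
            Tube((cx + r, cy, cz + 0.2), 3.0, 12.8, HIGH_F19_MM),
            Tube((cx, cy - r, cz), 3.0, 12.4, LOW_F19_MM),
            Tube((cx, cy + r, cz - 0.4), 3.0, 13.0, LOW_F19_MM),
            Tube((cx, cy, cz), 3.0, 12.5, 0.0),  # agarose-only control
        ],
        agent=agent,
    )


def default_acquisition(**overrides) -> AcquisitionSpec:
    """64×64 in-plane matrix at 0.55 × 0.55 × 1.5 mm³ voxels.

    Default gain/sigma put the low-concentration tubes at SNR ≈ 18 and the
    high tubes at SNR ≈ 37, comfortably above the SNR > 5 the protocol
    requires for robust boundary delineation.
    """
    return AcquisitionSpec(**overrides)


# ---------------------------------------------------------------------------
# rendering


def _grid_coords(acq: AcquisitionSpec) -> list[np.ndarray]:
    return [
        (np.arange(n) + 0.5) * d for n, d in zip(acq.shape, acq.spacing)
    ]


def _tube_fraction(tube: Tube, acq: AcquisitionSpec, supersample: int = 3) -> np.ndarray:
    """Partial-volume occupancy of ``tube`` per voxel via subvoxel supersampling."""
    xs, ys, zs = _grid_coords(acq)
    # subvoxel offsets: supersample^3 points per voxel, cell-centered
    offs = (np.arange(supersample) + 0.5) / supersample - 0.5
    frac = np.zeros(acq.shape, dtype=float)
    axis = np.asarray(tube.axis)
    center = np.asarray(tube.center)
    for ox in offs * acq.spacing[0]:
        for oy in offs * acq.spacing[1]:
            for oz in offs * acq.spacing[2]:
                px = xs + ox
                py = ys + oy
                pz = zs + oz
                dx = px[:, None, None] - center[0]
                dy = py[None, :, None] - center[1]
                dz = pz[None, None, :] - center[2]
                t = dx * axis[0] + dy * axis[1] + dz * axis[2]
                r2 = (dx - t * axis[0]) ** 2 + (dy - t * axis[1]) ** 2 + (
                    dz - t * axis[2]
                ) ** 2
                inside = (np.abs(t) <= tube.length / 2) & (r2 <= tube.radius**2)
                frac += inside
    return frac / supersample**3


def bias_field(acq: AcquisitionSpec) -> np.ndarray:
    """Smooth multiplicative B1-like field: product of per-axis quadratics.

    Normalized to mean 1 with max fractional deviation equal to
    ``acq.bias_amplitude`` exactly; deterministic (no free parameters).
    """
    if acq.bias_amplitude == 0:
        return np.ones(acq.shape)
    parts = []
    for n in acq.shape:
        u = np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(1)
        parts.append(1.0 + 0.5 * (u**2 - np.mean(u**2)))
    b = parts[0][:, None, None] * parts[1][None, :, None] * parts[2][None, None, :]
    b = b / b.mean()
    dev = b - 1.0
    peak = np.max(np.abs(dev))
    if peak == 0:
        return np.ones(acq.shape)
    return 1.0 + acq.bias_amplitude * dev / peak


def render_phantom(
    spec: PhantomSpec, acq: AcquisitionSpec, supersample: int = 3, **meta
) -> ScanVolume:
    """Noiseless render: voxel value = gain × local ¹⁹F concentration.

    Boundary voxels get the partial-volume fraction of their subvoxel
    samples inside the tube; background is exactly 0 (¹⁹F has no tissue
    background).  A non-flat bias field on ``acq`` multiplies the render.
    """
    if acq.gain <= 0:
        raise ValueError("signal gain must be > 0")
    data = np.zeros(acq.shape, dtype=float)
    extent = acq.extent
    for i, tube in enumerate(spec.tubes):
        frac = _tube_fraction(tube, acq, supersample)
        if frac.max() == 0 and tube.f19_mm > 0:
            c = np.asarray(tube.center)
            if np.any(c < -tube.radius) or np.any(c > extent + tube.radius):
                warnings.warn(
                    f"tube {i} lies entirely outside the grid; contributes nothing",
                    stacklevel=2,
                )
        data += acq.gain * tube.f19_mm * frac
    data *= bias_field(acq)
    md = {"agent": spec.agent, "kind": "phantom", **meta}
    return ScanVolume(data, acq.spacing, md)


# ---------------------------------------------------------------------------
# noise


def add_rician_noise(vol: ScanVolume, sigma: float, seed: int) -> ScanVolume:
    """Magnitude-reconstruction noise: |S + g1 + i·g2| per voxel.

    ``g1, g2`` are independent zero-mean Gaussians of SD ``sigma``; the
    output is non-negative everywhere and bit-deterministic given ``seed``.
    Background (S = 0) voxels follow a Rayleigh law with mean σ√(π/2).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return vol.copy(seed=seed, sigma=0.0)
    rng = np.random.default_rng(seed)
    g1 = rng.normal(0.0, sigma, vol.shape)
    g2 = rng.normal(0.0, sigma, vol.shape)
    noisy = np.sqrt((vol.data + g1) ** 2 + g2**2)
    return vol.copy(data=noisy, seed=seed, sigma=sigma)


def acquire_noise_scan(acq: AcquisitionSpec, seed: int, **meta) -> ScanVolume:
    """A pure-noise calibration acquisition (empty magnet bore)."""
    empty = render_phantom(PhantomSpec(tubes=[], agent="none"), acq)
    out = add_rician_noise(empty, acq.sigma, seed)
    out.meta.update({"kind": "noise", **meta})
    return out


# ---------------------------------------------------------------------------
# session perturbation


def apply_session_perturbation(
    spec: PhantomSpec, acq: AcquisitionSpec, pert: SessionPerturbation
) -> tuple[PhantomSpec, AcquisitionSpec]:
    """Carry a phantom/acquisition pair into a new session.

    Tube centers and axes are rigidly transformed about the FOV center
    (rotation in degrees per axis, then translation in mm); the gain is
    multiplied by the drift factor, the noise sigma by the noise drift, and
    the bias-field amplitude replaced.  The noiseless image of the new
    session is re-rendered analytically from the transformed geometry.
    """
    rot = Rotation.from_euler("xyz", pert.rotation_deg, degrees=True)
    center = acq.extent / 2.0
    shift = np.asarray(pert.translation)
    new_tubes = []
    for t in spec.tubes:
        c = rot.apply(np.asarray(t.center) - center) + center + shift
        a = rot.apply(np.asarray(t.axis))
        new_tubes.append(replace(t, center=tuple(c), axis=tuple(a)))
    new_spec = PhantomSpec(new_tubes, spec.agent)
    new_acq = replace(
        acq,
        gain=acq.gain * pert.gain_factor,
        sigma=acq.sigma * pert.noise_drift,
        bias_amplitude=pert.bias_amplitude,
    )
    if new_tubes:
        ext = new_acq.extent
        all_out = all(
            np.any(np.asarray(t.center) < -t.radius - t.length / 2)
            or np.any(np.asarray(t.center) > ext + t.radius + t.length / 2)
            for t in new_tubes
        )
        if all_out:
            raise ValueError("perturbation moved every tube outside the grid")
    return new_spec, new_acq


def sample_perturbation(
    rng: np.random.Generator,
    translation_mm: float = 1.0,
    rotation_deg: float = 3.0,
    bias_amplitude: float = 0.1,
    gain_drift: float = 0.05,
    noise_drift: float = 0.1,
) -> SessionPerturbation:
    """Draw one repositioning realization with the given magnitudes.

    Translation/rotation components are uniform in ±magnitude; gain and
    noise factors are uniform in [1-drift, 1+drift]; the bias amplitude is
    uniform in [0, bias_amplitude].
    """
    return SessionPerturbation(
        translation=tuple(rng.uniform(-translation_mm, translation_mm, 3)),
        rotation_deg=tuple(rng.uniform(-rotation_deg, rotation_deg, 3)),
        bias_amplitude=float(rng.uniform(0, bias_amplitude)),
        gain_factor=float(rng.uniform(1 - gain_drift, 1 + gain_drift)),
        noise_drift=float(rng.uniform(1 - noise_drift, 1 + noise_drift)),
    )


def simulate_test_retest(
    spec: PhantomSpec,
    acq: AcquisitionSpec,
    mode: str,
    seeds: tuple[int, int],
    pert: SessionPerturbation | None = None,
    **meta,
) -> tuple[ScanVolume, ScanVolume]:
    """One test/retest pair.

    ``intrasession``: identical geometry, two independent noise seeds.
    ``intersession``: the retest is re-acquired after a session perturbation
    (repositioning + drifts) with its own noise seed.
    """
    if mode not in ("intrasession", "intersession"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "intrasession":
        if pert is not None and not pert.is_identity:
            raise ValueError("intrasession pairs must not carry a perturbation")
        clean = render_phantom(spec, acq)
        test = add_rician_noise(clean, acq.sigma, seeds[0])
        retest = add_rician_noise(clean, acq.sigma, seeds[1])
    else:
        if pert is None:
            raise ValueError("intersession mode requires a SessionPerturbation")
        test = add_rician_noise(render_phantom(spec, acq), acq.sigma, seeds[0])
        spec2, acq2 = apply_session_perturbation(spec, acq, pert)
        retest = add_rician_noise(render_phantom(spec2, acq2), acq2.sigma, seeds[1])
    test.meta.update({"arm": "test", "trial": mode, **meta})
    retest.meta.update({"arm": "retest", "trial": mode, **meta})
    return test, retest


# ---------------------------------------------------------------------------
# in-vivo-like scene


def _ellipsoid_profile(
    coords: list[np.ndarray],
    center: tuple[float, float, float],
    semiaxes: tuple[float, float, float],
    edge: float = 0.25,
) -> np.ndarray:
    """Soft ellipsoid: 1 in the core, tapering to 0 over an ``edge`` margin.

    Organ uptake has no hard wall; the taper puts boundary voxels near the
    segmentation threshold, which is what makes in-vivo delineation (and
    hence shape features) noise-sensitive.
    """
    xs, ys, zs = coords
    q = (
        ((xs[:, None, None] - center[0]) / semiaxes[0]) ** 2
        + ((ys[None, :, None] - center[1]) / semiaxes[1]) ** 2
        + ((zs[None, None, :] - center[2]) / semiaxes[2]) ** 2
    )
    r = np.sqrt(q)
    return np.clip((1.0 + edge - r) / edge, 0.0, 1.0) ** 1.5


def render_invivo_scene(
    acq: AcquisitionSpec,
    seeds: tuple[int, int],
    texture_seed: int = 0,
    liver_f19_mm: float = 150.0,
    tumor_f19_mm: float = 100.0,
    **meta,
) -> tuple[tuple[ScanVolume, ScanVolume], np.ndarray]:
    """Mouse-abdomen-like scene: liver, tumor, and a 5 mM PFPE reference tube.

    The liver is a lobed ellipsoid (three overlapping sub-lobes with
    different uptake), the tumor a smaller ellipsoid, the reference tube a
    hard-walled cylinder at the fixed reference concentration.  Each organ
    carries internal texture from a smoothed multiplicative log-normal
    field.  Returns an intrasession test/retest pair plus the ground-truth
    label mask (1 = liver, 2 = tumor, 3 = reference tube).
    """
    coords = _grid_coords(acq)
    ex, ey, ez = acq.extent
    rng = np.random.default_rng(texture_seed)

    lobes = (
        ((0.30 * ex, 0.42 * ey, 0.50 * ez), (7.5, 5.5, 5.5), 1.00),
        ((0.36 * ex, 0.55 * ey, 0.45 * ez), (5.0, 4.5, 5.0), 0.80),
        ((0.25 * ex, 0.55 * ey, 0.58 * ez), (4.0, 4.0, 4.5), 1.15),
    )
    liver = np.zeros(acq.shape)
    for center, axes, rel in lobes:
        liver = np.maximum(liver, rel * _ellipsoid_profile(coords, center, axes))
    tumor = _ellipsoid_profile(
        coords, (0.72 * ex, 0.68 * ey, 0.5 * ez), (4.5, 3.8, 4.0)
    )
    ref = Tube(
        (0.75 * ex, 0.25 * ey, 0.5 * ez), 2.0, 0.8 * ez, REFERENCE_TUBE_F19_MM
    )
    ref_frac = _tube_fraction(ref, acq)

    def textured(base: np.ndarray, strength: float) -> np.ndarray:
        f = ndimage.gaussian_filter(rng.standard_normal(acq.shape), sigma=1.5)
        f /= max(f.std(), 1e-12)
        return base * np.exp(strength * f)

    conc = (
        textured(liver_f19_mm * liver, 0.25)
        + textured(tumor_f19_mm * tumor, 0.30)
        + ref.f19_mm * ref_frac
    )
    clean = ScanVolume(
        acq.gain * conc * bias_field(acq),
        acq.spacing,
        {"kind": "invivo", "agent": "PFPE", **meta},
    )
    test = add_rician_noise(clean, acq.sigma, seeds[0])
    retest = add_rician_noise(clean, acq.sigma, seeds[1])
    test.meta.update({"arm": "test", "trial": "intrasession"})
    retest.meta.update({"arm": "retest", "trial": "intrasession"})

    labels = np.zeros(acq.shape, dtype=int)
    labels[liver > 0.5] = 1
    labels[tumor > 0.5] = 2
    labels[ref_frac > 0.5] = 3
    return (test, retest), labels


# ---------------------------------------------------------------------------
# detection-limit calibration


def detection_series(
    concentrations: list[float],
    acq: AcquisitionSpec,
    replicates: int,
    master_seed: int,
) -> dict:
    """Calibration of mean ROI intensity vs ¹⁹F concentration.

    A single center tube is rendered per concentration, ``replicates``
    noisy acquisitions are measured (mean intensity over the true tube
    voxels), and the detection floor is the smallest concentration whose
    mean ROI intensity exceeds five times the SD of the background noise
    magnitude (measured on a pure-noise scan).
    """
    if not concentrations:
        raise ValueError("concentration list must not be empty")
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    seeds = spawn_seeds(master_seed, len(concentrations) * replicates + 1)
    noise_scan = acquire_noise_scan(acq, seeds[-1])
    noise_sd = float(noise_scan.data.std())
    threshold = 5.0 * noise_sd

    center = tuple(acq.extent / 2.0)
    rows = []
    k = 0
    for conc in sorted(concentrations):
        tube = Tube(center, 3.0, 12.0, conc)
        clean = render_phantom(PhantomSpec([tube]), acq)
        roi = _tube_fraction(tube, acq) >= 0.999  # interior voxels only
        means = []
        for _ in range(replicates):
            noisy = add_rician_noise(clean, acq.sigma, seeds[k])
            k += 1
            means.append(float(noisy.data[roi].mean()))
        rows.append(
            {
                "f19_mm": conc,
                "mean_intensity": float(np.mean(means)),
                "sd_intensity": float(np.std(means, ddof=1)),
                "above_floor": bool(np.mean(means) > threshold),
            }
        )
    floor = next((r["f19_mm"] for r in rows if r["above_floor"]), None)
    return {
        "table": rows,
        "noise_sd": noise_sd,
        "threshold": threshold,
        "detection_floor_mm": floor,
    }
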