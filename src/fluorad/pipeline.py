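"""End-to-end simulated repeatability studies.

``run_study`` replays the study design on synthetic acquisitions: simulate
test/retest scans for each experiment arm (PFPE-like phantom, PFCE-like
phantom, in-vivo-like scene), segment them against a matched pure-noise
scan, extract the full radiomic feature table, score per-feature CCC/NDR
agreement, and assemble class/filter summaries, stable-set intersections,
and a threshold-sensitivity grid.  Everything is a pure function of the
study config and its master seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from . import agreement, segmentation, synthdata
from .features import FeatureConfig, default_config, extract_all, feature_class, feature_filter
from .segmentation import RegionPrior
from .volume import ScanVolume

__all__ = [
    "PhantomBlock",
    "StudyConfig",
    "StudyResult",
    "run_study",
    "intersect_stable_sets",
    "sensitivity_grid",
    "report",
]

CLASSES = ("shape", "intensity", "texture")


@dataclass
class PhantomBlock:
    """One phantom experiment: agent label plus trial counts and the
    repositioning magnitudes applied between sessions."""

    name: str
    agent: str
    intra_pairs: int = 8
    inter_pairs: int = 8
    translation_mm: float = 1.0
    rotation_deg: float = 3.0
    bias_amplitude: float = 0.1
    gain_drift: float = 0.05
    noise_drift: float = 0.1

    def __post_init__(self):
        if self.intra_pairs < 1 or self.inter_pairs < 0:
            raise ValueError("trial counts must be >= 1 intra, >= 0 inter")


@dataclass
class StudyConfig:
    """Full study replica: two phantoms plus an intrasession in-vivo arm."""

    phantoms: list[PhantomBlock] = field(
        default_factory=lambda: [PhantomBlock("pfpe", "PFPE"), PhantomBlock("pfce", "PFCE")]
    )
    invivo_pairs: int = 2
    features: FeatureConfig = field(default_factory=default_config)
    ccc_min: float = agreement.CCC_DEFAULT
    ndr_min: float = agreement.NDR_DEFAULT
    threshold_k: float = 3.0
    sigma: float = 1.0
    master_seed: int = 0


@dataclass
class StudyResult:
    manifest: pd.DataFrame
    agreement: dict[str, pd.DataFrame]  # arm -> per-feature table
    class_summary: pd.DataFrame
    stable_counts: pd.DataFrame
    stable_sets: dict[str, set]
    intersections: dict
    normalization: dict
    config: StudyConfig

    @property
    def arms(self) -> list[str]:
        return list(self.agreement)


# ---------------------------------------------------------------------------
# study execution


def _segment_scan(
    scan: ScanVolume,
    priors: list[RegionPrior],
    k: float,
    noise_seed: int,
    sigma: float,
) -> segmentation.SegmentMask:
    acq = synthdata.AcquisitionSpec(
        shape=scan.shape, spacing=scan.spacing, sigma=sigma
    )
    noise = synthdata.acquire_noise_scan(acq, noise_seed)
    profile = segmentation.estimate_noise(noise)
    # exact-zero voxels are never ¹⁹F signal (background-free modality);
    # excluding them keeps the noiseless (sigma = 0) limit well posed
    mask = segmentation.threshold_mask(scan, profile, k) & (scan.data > 0)
    return segmentation.delineate_rois(mask, priors, scan.spacing)


def _phantom_priors(spec: synthdata.PhantomSpec) -> list[RegionPrior]:
    return [
        RegionPrior(t.center, f"tube{i + 1}")
        for i, t in enumerate(spec.tubes)
        if t.f19_mm > 0
    ]


def _collect_histogram_pairs(
    test: ScanVolume,
    retest: ScanVolume,
    mask_t: segmentation.SegmentMask,
    mask_r: segmentation.SegmentMask,
) -> list[dict]:
    pairs = []
    roles = set(mask_t.roles.values()) & set(mask_r.roles.values())
    inv_t = {v: k for k, v in mask_t.roles.items()}
    inv_r = {v: k for k, v in mask_r.roles.items()}
    fg_t = test.data[mask_t.labels > 0]
    fg_r = retest.data[mask_r.labels > 0]
    if fg_t.size == 0 or fg_r.size == 0:
        return pairs
    for role in sorted(roles):
        pairs.append(
            {
                "test": test.data[mask_t.labels == inv_t[role]],
                "retest": retest.data[mask_r.labels == inv_r[role]],
                "test_mean": float(fg_t.mean()),
                "test_sd": float(fg_t.std()) or 1.0,
                "retest_mean": float(fg_r.mean()),
                "retest_sd": float(fg_r.std()) or 1.0,
            }
        )
    return pairs


def _run_phantom_arm(
    block: PhantomBlock,
    mode: str,
    n_pairs: int,
    cfg: StudyConfig,
    ss: np.random.SeedSequence,
) -> tuple[pd.DataFrame, pd.DataFrame, list[dict]]:
    """Feature tables (test, retest) for one phantom arm, rows = pair:role."""
    spec = synthdata.default_phantom(block.agent)
    acq = synthdata.default_acquisition(sigma=cfg.sigma)
    test_rows, retest_rows = [], []
    hist_pairs: list[dict] = []
    children = ss.spawn(n_pairs)
    for p in range(n_pairs):
        child = children[p]
        s1, s2, sn1, sn2 = [int(s.generate_state(1)[0] % 2**31) for s in child.spawn(4)]
        pert = None
        if mode == "intersession":
            rng = np.random.default_rng(child.spawn(1)[0])
            pert = synthdata.sample_perturbation(
                rng,
                translation_mm=block.translation_mm,
                rotation_deg=block.rotation_deg,
                bias_amplitude=block.bias_amplitude,
                gain_drift=block.gain_drift,
                noise_drift=block.noise_drift,
            )
        test, retest = synthdata.simulate_test_retest(
            spec, acq, mode, seeds=(s1, s2), pert=pert, experiment=block.name, pair=p
        )
        mask_t = _segment_scan(test, _phantom_priors(spec), cfg.threshold_k, sn1, acq.sigma)
        if mode == "intersession":
            spec_r, acq_r = synthdata.apply_session_perturbation(spec, acq, pert)
            mask_r = _segment_scan(
                retest, _phantom_priors(spec_r), cfg.threshold_k, sn2, acq_r.sigma
            )
        else:
            mask_r = _segment_scan(retest, _phantom_priors(spec), cfg.threshold_k, sn2, acq.sigma)
        ft = extract_all(test, mask_t, cfg.features)
        fr = extract_all(retest, mask_r, cfg.features)
        ft.index = [f"p{p}:{r}" for r in ft.index]
        fr.index = [f"p{p}:{r}" for r in fr.index]
        test_rows.append(ft)
        retest_rows.append(fr)
        if p == 0:
            hist_pairs = _collect_histogram_pairs(test, retest, mask_t, mask_r)
    cols = cfg.features.column_names()
    t = pd.concat(test_rows).reindex(columns=cols)
    r = pd.concat(retest_rows).reindex(columns=cols)
    return t, r, hist_pairs


def _run_invivo_arm(
    cfg: StudyConfig, ss: np.random.SeedSequence
) -> tuple[pd.DataFrame, pd.DataFrame]:
    test_rows, retest_rows = [], []
    children = ss.spawn(cfg.invivo_pairs)
    roles = {1: "liver", 2: "tumor", 3: "reference"}
    for subj in range(cfg.invivo_pairs):
        child = children[subj]
        s1, s2, sn1, sn2, st = [int(s.generate_state(1)[0] % 2**31) for s in child.spawn(5)]
        acq = synthdata.default_acquisition(sigma=cfg.sigma)
        (test, retest), truth = synthdata.render_invivo_scene(
            acq, seeds=(s1, s2), texture_seed=st, subject=subj
        )
        sp = np.asarray(acq.spacing)
        priors = []
        for lab, role in roles.items():
            if (truth == lab).any():
                c = (np.asarray(ndi.center_of_mass(truth == lab)) + 0.5) * sp
                priors.append(RegionPrior(tuple(c), role))
        mask_t = _segment_scan(test, priors, cfg.threshold_k, sn1, acq.sigma)
        mask_r = _segment_scan(retest, priors, cfg.threshold_k, sn2, acq.sigma)
        ft = extract_all(test, mask_t, cfg.features)
        fr = extract_all(retest, mask_r, cfg.features)
        ft.index = [f"m{subj}:{r}" for r in ft.index]
        fr.index = [f"m{subj}:{r}" for r in fr.index]
        test_rows.append(ft)
        retest_rows.append(fr)
    cols = cfg.features.column_names()
    return (
        pd.concat(test_rows).reindex(columns=cols),
        pd.concat(retest_rows).reindex(columns=cols),
    )


def _annotate(agree: pd.DataFrame) -> pd.DataFrame:
    agree = agree.copy()
    agree["class"] = [feature_class(f) for f in agree.index]
    agree["filter"] = [feature_filter(f) for f in agree.index]
    return agree


def run_study(cfg: StudyConfig | None = None) -> StudyResult:
    """Simulate, segment, extract, and score one full study replica."""
    cfg = cfg or StudyConfig()
    root = np.random.SeedSequence(cfg.master_seed)
    arm_tables: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = {}
    normalization: dict[str, dict] = {}

    seeds = root.spawn(2 * len(cfg.phantoms) + 1)
    si = 0
    for block in cfg.phantoms:
        for mode, n_pairs in (
            ("intrasession", block.intra_pairs),
            ("intersession", block.inter_pairs),
        ):
            if n_pairs == 0:
                si += 1
                continue
            arm = f"{block.name}_{'intra' if mode == 'intrasession' else 'inter'}"
            t, r, hist = _run_phantom_arm(block, mode, n_pairs, cfg, seeds[si])
            si += 1
            arm_tables[arm] = (t, r)
            if hist:
                normalization[arm] = agreement.normalization_check(hist)
    if cfg.invivo_pairs > 0:
        arm_tables["invivo_intra"] = _run_invivo_arm(cfg, seeds[si])

    agree = {
        arm: _annotate(
            agreement.evaluate_features(t, r, cfg.ccc_min, cfg.ndr_min)
        )
        for arm, (t, r) in arm_tables.items()
    }

    class_summary = _class_summary(agree)
    stable_counts = _stable_counts(agree)
    stable_sets = {arm: set(df.index[df["stable"]]) for arm, df in agree.items()}
    # per-phantom "both sessions" sets, then the cross-phantom core
    named: dict[str, set] = {}
    for block in cfg.phantoms:
        intra = stable_sets.get(f"{block.name}_intra", set())
        inter = stable_sets.get(f"{block.name}_inter", set())
        named[block.name] = intra & inter if f"{block.name}_inter" in stable_sets else intra
    universe = set(cfg.features.column_names())
    intersections = intersect_stable_sets(named, universe)
    if "invivo_intra" in stable_sets:
        core = intersections["core"]
        overlap = core & stable_sets["invivo_intra"]
        intersections["core_invivo"] = {
            "count": len(overlap),
            "fraction_of_core": len(overlap) / len(core) if core else float("nan"),
        }

    manifest = segmentation.build_manifest(
        [
            {
                "name": b.name,
                "intra_scans": 2 * b.intra_pairs,
                "inter_scans": 2 * b.inter_pairs,
                "segments_per_scan": 4,
            }
            for b in cfg.phantoms
        ]
        + (
            [
                {
                    "name": "invivo",
                    "intra_scans": 2 * cfg.invivo_pairs,
                    "inter_scans": 0,
                    "segments_per_scan": 3,
                }
            ]
            if cfg.invivo_pairs
            else []
        )
    )
    return StudyResult(
        manifest=manifest,
        agreement=agree,
        class_summary=class_summary,
        stable_counts=stable_counts,
        stable_sets=stable_sets,
        intersections=intersections,
        normalization=normalization,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# summaries


def _class_summary(agree: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Median (IQR) CCC per arm and feature class; degenerate features are
    excluded from the quantiles, never imputed."""
    rows = []
    for arm, df in agree.items():
        ok = df[~df["degenerate"] & np.isfinite(df["ccc"])]
        for cls in ("overall",) + CLASSES:
            sub = ok if cls == "overall" else ok[ok["class"] == cls]
            if len(sub) == 0:
                rows.append({"arm": arm, "class": cls, "n": 0})
                continue
            q1, med, q3 = np.percentile(sub["ccc"], [25, 50, 75])
            rows.append(
                {
                    "arm": arm,
                    "class": cls,
                    "n": len(sub),
                    "median_ccc": med,
                    "iqr_low": q1,
                    "iqr_high": q3,
                }
            )
    return pd.DataFrame(rows)


def _stable_counts(agree: dict[str, pd.DataFrame]) -> pd.DataFrame:
    rows = []
    for arm, df in agree.items():
        for cls in ("overall",) + CLASSES:
            sub = df if cls == "overall" else df[df["class"] == cls]
            total = len(sub)
            stable = int(sub["stable"].sum())
            rows.append(
                {
                    "arm": arm,
                    "class": cls,
                    "stable": stable,
                    "total": total,
                    "fraction": stable / total if total else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def intersect_stable_sets(named: dict[str, set], universe: set) -> dict:
    """Venn-style bookkeeping over a common feature universe."""
    for name, s in named.items():
        if not s <= universe:
            raise ValueError(f"set {name!r} contains features outside the universe")
    names = list(named)
    pairwise = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            pairwise[f"{a}&{b}"] = named[a] & named[b]
    core = set(universe)
    for s in named.values():
        core &= s
    return {
        "sizes": {n: len(s) for n, s in named.items()},
        "pairwise_counts": {k: len(v) for k, v in pairwise.items()},
        "core": core,
        "core_count": len(core),
        "core_fraction": len(core) / len(universe) if universe else float("nan"),
        "universe_count": len(universe),
    }


def sensitivity_grid(
    agree: pd.DataFrame, ccc_grid, ndr_grid
) -> pd.DataFrame:
    """Stable-feature count per (CCC, NDR) threshold pair; monotone
    nonincreasing along both axes by construction of the conjunctive call."""
    ccc_grid = list(ccc_grid)
    ndr_grid = list(ndr_grid)
    if not all(0 < c <= 1 for c in ccc_grid + ndr_grid):
        raise ValueError("thresholds must lie in (0, 1]")
    cc = agree["ccc"].to_numpy()
    nn = agree["ndr"].to_numpy()
    out = np.zeros((len(ccc_grid), len(ndr_grid)), dtype=int)
    for i, cmin in enumerate(ccc_grid):
        for j, nmin in enumerate(ndr_grid):
            out[i, j] = int(
                np.sum((cc >= cmin) & (nn >= nmin) & np.isfinite(cc) & np.isfinite(nn))
            )
    return pd.DataFrame(out, index=ccc_grid, columns=ndr_grid)


# ---------------------------------------------------------------------------
# reporting


def report(result: StudyResult, outdir: str | Path) -> dict[str, Path]:
    """Write the study's tables as CSV/JSON artifacts; idempotent."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["manifest"] = outdir / "manifest.csv"
    result.manifest.to_csv(paths["manifest"], index=False)

    paths["class_summary"] = outdir / "class_summary.csv"
    result.class_summary.to_csv(paths["class_summary"], index=False)

    paths["stable_counts"] = outdir / "stable_counts.csv"
    result.stable_counts.to_csv(paths["stable_counts"], index=False)

    for arm, df in result.agreement.items():
        p = outdir / f"agreement_{arm}.csv"
        df.to_csv(p)
        paths[f"agreement_{arm}"] = p

    filt = (
        pd.concat(
            [
                df.assign(arm=arm)
                .groupby("filter")["ccc"]
                .median()
                .rename(arm)
                for arm, df in result.agreement.items()
            ],
            axis=1,
        )
    )
    paths["filter_median_ccc"] = outdir / "filter_median_ccc.csv"
    filt.to_csv(paths["filter_median_ccc"])

    summary = {
        "stable_set_sizes": {a: len(s) for a, s in result.stable_sets.items()},
        "intersections": {
            k: (sorted(v) if isinstance(v, set) else v)
            for k, v in result.intersections.items()
        },
        "normalization": result.normalization,
    }
    paths["summary"] = outdir / "summary.json"
    paths["summary"].write_text(json.dumps(summary, indent=2, default=str))
    return paths
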