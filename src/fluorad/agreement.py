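"""Test-retest agreement statistics.

The repeatability of a radiomic feature is scored by the concordance
correlation coefficient

    CCC = 2·σ₁₂ / (σ₁² + σ₂² + (μ₁ − μ₂)²)

with population (1/n) moments of the test and retest vectors, and its
informativeness by the normalized dynamic range

    NDR = 1 − (1/n) Σᵢ |Testᵢ − Retestᵢ| / (Max − Min)

with Max/Min pooled over test ∪ retest.  A feature is called *stable* when
CCC ≥ 0.85 and NDR ≥ 0.90 (both thresholds inclusive and configurable).

The module also provides Bland–Altman limits of agreement with an
expected-CCC reference band, a two-way random-effects absolute-agreement
ICC for reader studies, the Jensen–Shannon intensity-histogram check, and
rank-based stratified distribution comparisons with Benjamini–Hochberg
correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import jensenshannon
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AgreementResult",
    "ccc",
    "ndr",
    "stability_call",
    "evaluate_paired",
    "evaluate_features",
    "bland_altman",
    "icc",
    "js_divergence",
    "normalization_check",
    "compare_distributions",
    "CCC_DEFAULT",
    "NDR_DEFAULT",
]

CCC_DEFAULT = 0.85
NDR_DEFAULT = 0.90


@dataclass
class AgreementResult:
    """Per-feature agreement summary."""

    ccc: float
    ndr: float
    stable: bool
    n: int
    degenerate: bool = False


def ccc(x, y) -> float:
    """Lin's concordance correlation coefficient with 1/n moments.

    Symmetric in its arguments.  When the denominator vanishes: identical
    constant vectors agree perfectly (1.0); otherwise the value is reported
    as 0 and the caller should treat the pair as degenerate.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("need two equal-length 1D vectors")
    if x.size < 2:
        raise ValueError("CCC needs at least 2 observations")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    cov = np.mean((x - mx) * (y - my))
    denom = vx + vy + (mx - my) ** 2
    if denom == 0:
        return 1.0 if np.array_equal(x, y) else 0.0
    return float(2.0 * cov / denom)


def ndr(x, y) -> float:
    """Normalized dynamic range; NaN when the pooled range is zero."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise ValueError("need two equal-length nonempty 1D vectors")
    pooled = np.concatenate([x, y])
    rng = pooled.max() - pooled.min()
    if rng == 0:
        return float("nan")
    return float(1.0 - np.mean(np.abs(x - y)) / rng)


def stability_call(
    ccc_value: float, ndr_value: float, ccc_min: float = CCC_DEFAULT, ndr_min: float = NDR_DEFAULT
) -> bool:
    """Both criteria must hold; boundary values pass; NaN fails."""
    if not (0 < ccc_min <= 1 and 0 < ndr_min <= 1):
        raise ValueError("thresholds must lie in (0, 1]")
    if np.isnan(ccc_value) or np.isnan(ndr_value):
        return False
    return bool(ccc_value >= ccc_min and ndr_value >= ndr_min)


def evaluate_paired(
    x, y, ccc_min: float = CCC_DEFAULT, ndr_min: float = NDR_DEFAULT
) -> AgreementResult:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 2:
        return AgreementResult(float("nan"), float("nan"), False, int(x.size), True)
    c = ccc(x, y)
    d = ndr(x, y)
    pooled_range = np.ptp(np.concatenate([x, y]))
    degenerate = pooled_range == 0 or (x.var() + y.var() + (x.mean() - y.mean()) ** 2) == 0
    if degenerate and np.array_equal(x, y):
        # constant feature reproduced exactly: perfect agreement, no range
        return AgreementResult(1.0, float("nan"), False, int(x.size), True)
    return AgreementResult(c, d, stability_call(c, d, ccc_min, ndr_min), int(x.size), bool(degenerate))


def evaluate_features(
    test: pd.DataFrame,
    retest: pd.DataFrame,
    ccc_min: float = CCC_DEFAULT,
    ndr_min: float = NDR_DEFAULT,
) -> pd.DataFrame:
    """Per-feature CCC/NDR over aligned test/retest tables.

    Rows of the two tables are paired by index (observation id); rows
    missing on either side are excluded pairwise per feature.
    """
    if list(test.columns) != list(retest.columns):
        raise ValueError("test and retest tables must share one column set")
    common = test.index.intersection(retest.index)
    t = test.loc[common]
    r = retest.loc[common]
    records = []
    for col in test.columns:
        res = evaluate_paired(t[col].to_numpy(), r[col].to_numpy(), ccc_min, ndr_min)
        records.append(
            {
                "feature": col,
                "ccc": res.ccc,
                "ndr": res.ndr,
                "stable": res.stable,
                "n": res.n,
                "degenerate": res.degenerate,
            }
        )
    return pd.DataFrame.from_records(records).set_index("feature")


def bland_altman(x, y, expected_ccc: float = CCC_DEFAULT) -> dict:
    """Bland–Altman bias and 95% limits of agreement plus a reference band.

    The band is the ±1.96·√(2·s̄²·(1 − CCC₀)) envelope expected for
    differences of an equal-variance, zero-bias pair whose concordance is
    exactly ``expected_ccc`` (s̄² is the pooled population variance): under
    those assumptions Var(x−y) = 2σ²(1−ρ) and CCC reduces to ρ.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3 or x.shape != y.shape:
        raise ValueError("Bland–Altman needs at least 3 paired observations")
    diff = x - y
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    pooled_var = 0.5 * (x.var() + y.var())
    band = float(1.96 * np.sqrt(2.0 * pooled_var * (1.0 - expected_ccc)))
    return {
        "bias": bias,
        "loa_low": bias - 1.96 * sd,
        "loa_high": bias + 1.96 * sd,
        "reference_band": band,
        "mean": (x + y) / 2.0,
        "diff": diff,
    }


def icc(reads: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``reads`` is (n_readers, n_items); complete cases only.  Degenerate
    between-item variance yields NaN.
    """
    m = np.asarray(reads, float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need >= 2 readers and >= 2 items")
    k, n = m.shape
    grand = m.mean()
    item_means = m.mean(axis=0)
    reader_means = m.mean(axis=1)
    ss_item = k * np.sum((item_means - grand) ** 2)
    ss_reader = n * np.sum((reader_means - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_item - ss_reader
    msr = ss_item / (n - 1)
    msc = ss_reader / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        if np.allclose(m, m[0]):
            return 1.0
        return float("nan")
    return float((msr - mse) / denom)


def js_divergence(a, b, bins: int = 64) -> float:
    """Jensen–Shannon divergence (base 2, so in [0, 1]) between the intensity
    histograms of two samples over a common binning of the pooled range."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("empty input sample")
    pooled = np.concatenate([a, b])
    lo, hi = pooled.min(), pooled.max()
    if hi == lo:
        return 0.0
    edges = np.linspace(lo, hi, bins + 1)
    pa, _ = np.histogram(a, bins=edges)
    pb, _ = np.histogram(b, bins=edges)
    return float(jensenshannon(pa, pb, base=2) ** 2)


def normalization_check(pairs: list[dict], bins: int = 64) -> dict:
    """Δ% of mean per-segment JSD after per-scan standardization.

    Each element of ``pairs`` carries raw test/retest voxel samples for one
    segment plus the foreground mean/SD of the parent scans; standardization
    maps v → (v − mean)/SD per scan.  Returns the mean JSD of raw and
    standardized intensities and the relative change in percent.
    """
    raw, norm = [], []
    for p in pairs:
        t, r = np.asarray(p["test"], float), np.asarray(p["retest"], float)
        raw.append(js_divergence(t, r, bins))
        tz = (t - p["test_mean"]) / p["test_sd"]
        rz = (r - p["retest_mean"]) / p["retest_sd"]
        norm.append(js_divergence(tz, rz, bins))
    mean_raw = float(np.mean(raw))
    mean_norm = float(np.mean(norm))
    delta = (mean_norm - mean_raw) / mean_raw * 100.0 if mean_raw > 0 else 0.0
    return {"jsd_raw": mean_raw, "jsd_normalized": mean_norm, "delta_percent": float(delta)}


def compare_distributions(groups: dict[str, np.ndarray], pool: np.ndarray | None = None) -> dict:
    """Stratified comparison of CCC distributions.

    Shapiro–Wilk gates each group for normality (motivating the rank-based
    tests), Kruskal–Wallis compares all groups jointly, and each group is
    compared against the pooled reference (defaults to the concatenation of
    all groups) with a two-sided Mann–Whitney test; the family of per-group
    p-values is Benjamini–Hochberg adjusted.  Groups smaller than 3 are
    excluded with a warning entry.
    """
    clean = {}
    excluded = []
    for name, vals in groups.items():
        v = np.asarray(vals, float)
        v = v[np.isfinite(v)]
        if v.size < 3:
            excluded.append(name)
        else:
            clean[name] = v
    if len(clean) < 2:
        raise ValueError("need at least 2 usable groups")
    if pool is None:
        pool = np.concatenate(list(clean.values()))
    shapiro = {
        name: stats.shapiro(v if v.size <= 5000 else v[:5000]).pvalue
        for name, v in clean.items()
    }
    kw_stat, kw_p = stats.kruskal(*clean.values())
    names = list(clean)
    raw_p = [
        stats.mannwhitneyu(clean[name], pool, alternative="two-sided").pvalue
        for name in names
    ]
    adj = multipletests(raw_p, method="fdr_bh")[1]
    return {
        "shapiro_p": shapiro,
        "kruskal_stat": float(kw_stat),
        "kruskal_p": float(kw_p),
        "group_vs_pool_p": dict(zip(names, map(float, raw_p))),
        "group_vs_pool_p_adjusted": dict(zip(names, map(float, adj))),
        "excluded": excluded,
    }
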