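"""Nonparametric two-group comparison of per-block feature distributions.

Mann-Whitney U tests the null of equal distributions; because it is a test of
equal medians only under restrictive conditions, the medians themselves are
additionally compared via bootstrap resampling of the difference of medians
(percentile confidence interval). Notched-box statistics use notches of
median +/- 2 standard errors of the median, with SE(median) estimated by
bootstrap.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .config import StatsConfig


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U for sample x, p-value).

    U = #{x_i > y_j} + 0.5 * #{x_i = y_j}. The p-value is exact (full
    enumeration of the rank distribution) when there are no ties and
    n*m <= 400, otherwise a normal approximation with tie-corrected variance
    and continuity correction.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = x.size, y.size
    combined = np.concatenate([x, y])
    if np.unique(combined).size == 1:
        return n * m / 2.0, 1.0  # all values identical: zero-variance null
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (not has_ties and n * m <= 400) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def _boot_medians(values: np.ndarray, n_boot: int, rng: np.random.Generator) -> np.ndarray:
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    return np.median(values[idx], axis=1)


def bootstrap_median_diff(x, y, n_boot: int = 10_000, seed: int = 0,
                          ci_level: float = 0.95) -> tuple[float, float, float]:
    """Observed median(x) - median(y) with a percentile bootstrap CI.

    x and y are resampled independently with replacement ``n_boot`` times;
    the CI is the (alpha/2, 1 - alpha/2) percentile interval of the bootstrap
    difference distribution. Deterministic given the seed.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    diffs = _boot_medians(x, n_boot, rng) - _boot_medians(y, n_boot, rng)
    observed = float(np.median(x) - np.median(y))
    alpha = 1.0 - ci_level
    lo, hi = np.percentile(diffs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return observed, float(lo), float(hi)


def median_se(x, n_boot: int = 10_000, seed: int = 0) -> float:
    """Standard error of the median: SD of bootstrap medians."""
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise ValueError("sample must be non-empty")
    rng = np.random.default_rng(seed)
    med = _boot_medians(x, n_boot, rng)
    return float(np.std(med, ddof=1))


@dataclass(frozen=True)
class NotchedBoxStats:
    median: float
    q1: float
    q3: float
    notch_low: float
    notch_high: float


def notched_box_stats(x, n_boot: int = 10_000, seed: int = 0) -> NotchedBoxStats:
    """Box-plot statistics with notches at median +/- 2 * SE(median).

    Quartiles use the linear-interpolation convention of ``numpy.percentile``.
    """
    x = np.asarray(x, dtype=np.float64)
    med = float(np.median(x))
    q1, q3 = np.percentile(x, [25, 75])
    se = median_se(x, n_boot=n_boot, seed=seed)
    return NotchedBoxStats(med, float(q1), float(q3), med - 2 * se, med + 2 * se)


@dataclass(frozen=True)
class GroupComparisonResult:
    feature_name: str
    u_statistic: float
    p_value: float
    median_a: float
    median_b: float
    median_diff: float
    ci_low: float
    ci_high: float
    se_median_a: float
    se_median_b: float
    notch_a: tuple[float, float]
    notch_b: tuple[float, float]
    n_a: int
    n_b: int

    def to_dict(self) -> dict:
        d = asdict(self)
        d["notch_a"] = list(self.notch_a)
        d["notch_b"] = list(self.notch_b)
        return d


def _pool(table: pd.DataFrame, group: str, feature: str, pooling: str) -> np.ndarray:
    sub = table[table["group"] == group]
    if pooling == "image":
        vals = sub.groupby("image_id")[feature].mean().to_numpy(dtype=np.float64)
    else:
        vals = sub[feature].to_numpy(dtype=np.float64)
    return vals[np.isfinite(vals)]


def compare_groups(table: pd.DataFrame, group_a: str, group_b: str,
                   config: StatsConfig | None = None) -> list[GroupComparisonResult]:
    """Compare every configured feature between two groups of blocks.

    Blocks from all images of a group are pooled into one sample per feature
    (or averaged per image with ``pooling='image'``); undefined entries (NaN,
    e.g. patch means of zero-patch blocks) are dropped per feature, with the
    per-feature n reported. Per-feature bootstrap seeds derive from the
    master seed, so results are reproducible and independent of feature order
    subsetting.
    """
    config = config or StatsConfig()
    for g in (group_a, group_b):
        if g not in set(table["group"]):
            raise ValueError(f"group {g!r} not present in the feature table")
    results = []
    master = np.random.SeedSequence(config.seed)
    seeds = master.spawn(len(config.features))
    for feature, fseed in zip(config.features, seeds):
        if feature not in table.columns:
            raise ValueError(f"feature column {feature!r} missing from the table")
        a = _pool(table, group_a, feature, config.pooling)
        b = _pool(table, group_b, feature, config.pooling)
        if a.size < 2 or b.size < 2:
            raise ValueError(
                f"feature {feature!r}: need >= 2 defined values per group "
                f"(got {a.size} in {group_a!r}, {b.size} in {group_b!r})"
            )
        s_diff, s_a, s_b = (int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in fseed.spawn(3))
        u, p = mann_whitney_u(a, b)
        diff, lo, hi = bootstrap_median_diff(a, b, config.n_boot, s_diff, config.ci_level)
        se_a = median_se(a, config.n_boot, s_a)
        se_b = median_se(b, config.n_boot, s_b)
        med_a, med_b = float(np.median(a)), float(np.median(b))
        results.append(GroupComparisonResult(
            feature_name=feature, u_statistic=u, p_value=p,
            median_a=med_a, median_b=med_b, median_diff=diff,
            ci_low=lo, ci_high=hi, se_median_a=se_a, se_median_b=se_b,
            notch_a=(med_a - 2 * se_a, med_a + 2 * se_a),
            notch_b=(med_b - 2 * se_b, med_b + 2 * se_b),
            n_a=int(a.size), n_b=int(b.size),
        ))
    if config.correction != "none":
        adjusted = multipletests([r.p_value for r in results],
                                 method=config.correction)[1]
        results = [
            GroupComparisonResult(**{**asdict(r), "p_value": float(p),
                                     "notch_a": r.notch_a, "notch_b": r.notch_b})
            for r, p in zip(results, adjusted)
        ]
    return results
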