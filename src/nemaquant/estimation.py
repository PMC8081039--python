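"""Estimation statistics: bootstrap effect sizes and hatch-rate summaries.

Instead of reporting only p-values, group comparisons are summarized the
estimation-graphics way: the mean difference (or percent of control) with
a bootstrap confidence interval, by default bias-corrected-and-accelerated
(BCa), resampling both groups independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "EffectSize",
    "HatchSummary",
    "mean_difference",
    "percent_of_control",
    "hatch_summary",
]

MIN_B = 1000


@dataclass(frozen=True)
class EffectSize:
    """A bootstrap effect-size estimate with its confidence interval."""

    estimate: float
    ci_low: float
    ci_high: float
    n_control: int
    n_test: int
    B: int
    alpha: float
    method: str
    degenerate: bool = False
    bootstrap_distribution: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("CI must bracket the estimate")


@dataclass(frozen=True)
class HatchSummary:
    """Per-replicate percent of viable eggs, with mean and SD across replicates."""

    percent_viable: np.ndarray
    mean_percent: float
    sd_percent: float


def _jackknife_values(control: np.ndarray, test: np.ndarray, statistic) -> np.ndarray:
    """Leave-one-out statistic values across both groups."""
    n_c, n_t = len(control), len(test)
    drop = lambda x, i: np.delete(x, i)
    vals = [statistic(drop(test, i), control, axis=-1) for i in range(n_t)]
    vals += [statistic(test, drop(control, i), axis=-1) for i in range(n_c)]
    return np.asarray(vals, dtype=float)


def _bootstrap_two_sample(
    control: np.ndarray,
    test: np.ndarray,
    statistic,
    B: int,
    alpha: float,
    method: str,
    seed,
) -> tuple[float, float, float, str, bool, np.ndarray]:
    """Shared two-sample bootstrap machinery with BCa -> percentile fallback.

    Both groups are resampled independently with replacement.
    ``statistic`` must be vectorized over an ``axis`` keyword.  The BCa
    interval uses expanded percentile levels (the nominal normal quantile
    is replaced by sqrt(n/(n-1)) times the t quantile with
    min(n_c, n_t) - 1 degrees of freedom), the standard small-sample
    correction for the narrowness bias of resampling intervals.
    """
    estimate = float(statistic(test, control, axis=-1))
    if np.ptp(control) == 0 and np.ptp(test) == 0:
        # Zero variance in both groups: the bootstrap distribution is a
        # point mass; the CI collapses to the estimate and is flagged.
        dist = np.full(B, estimate)
        return estimate, estimate, estimate, "degenerate", True, dist

    rng = np.random.default_rng(seed)
    n_c, n_t = len(control), len(test)
    idx_t = rng.integers(0, n_t, size=(B, n_t))
    idx_c = rng.integers(0, n_c, size=(B, n_c))
    dist = np.asarray(statistic(test[idx_t], control[idx_c], axis=-1), dtype=float)

    if method == "percentile":
        lo = float(np.percentile(dist, 100 * alpha / 2))
        hi = float(np.percentile(dist, 100 * (1 - alpha / 2)))
        used = "percentile"
    else:
        jack = _jackknife_values(control, test, statistic)
        diffs = jack.mean() - jack
        denom = 6.0 * (diffs**2).sum() ** 1.5
        if denom == 0:
            # Acceleration undefined (all jackknife values equal): fall
            # back to the percentile interval.
            lo = float(np.percentile(dist, 100 * alpha / 2))
            hi = float(np.percentile(dist, 100 * (1 - alpha / 2)))
            used = "percentile_fallback"
        else:
            accel = (diffs**3).sum() / denom
            prop = (np.sum(dist < estimate) + 0.5 * np.sum(dist == estimate)) / B
            prop = np.clip(prop, 1.0 / (2 * B), 1.0 - 1.0 / (2 * B))
            z0 = stats.norm.ppf(prop)
            # Expanded nominal levels (small-sample width correction).
            n_min = min(n_c, n_t)
            z_lo = np.sqrt(n_min / (n_min - 1)) * stats.t.ppf(alpha / 2, n_min - 1)
            z_hi = -z_lo
            a1 = stats.norm.cdf(z0 + (z0 + z_lo) / (1 - accel * (z0 + z_lo)))
            a2 = stats.norm.cdf(z0 + (z0 + z_hi) / (1 - accel * (z0 + z_hi)))
            lo = float(np.quantile(dist, np.clip(a1, 0.0, 1.0)))
            hi = float(np.quantile(dist, np.clip(a2, 0.0, 1.0)))
            used = "bca"
    # Guard against the estimate falling just outside a resampled interval.
    lo, hi = min(lo, estimate), max(hi, estimate)
    return estimate, lo, hi, used, False, dist


def mean_difference(
    control: np.ndarray,
    test: np.ndarray,
    B: int = 5000,
    alpha: float = 0.05,
    method: str = "bca",
    seed: int | None = None,
) -> EffectSize:
    """Bootstrap mean difference mean(test) - mean(control) with CI.

    Both groups are resampled independently with replacement; the default
    interval is BCa with a percentile fallback when the acceleration is
    undefined.  ``B`` below 1000 is rejected (CI stability).
    """
    control = np.asarray(control, dtype=float)
    test = np.asarray(test, dtype=float)
    if len(control) < 3 or len(test) < 3:
        raise ValueError("both groups need >= 3 values")
    if B < MIN_B:
        raise ValueError(f"B must be >= {MIN_B}")
    if method not in ("bca", "percentile"):
        raise ValueError(f"unknown method: {method}")

    est, lo, hi, used, degen, dist = _bootstrap_two_sample(
        control, test,
        lambda t, c, axis=-1: np.mean(t, axis=axis) - np.mean(c, axis=axis),
        B, alpha, method, seed,
    )
    return EffectSize(est, lo, hi, len(control), len(test), B, alpha, used, degen, dist)


def percent_of_control(
    control: np.ndarray,
    test: np.ndarray,
    B: int = 5000,
    alpha: float = 0.05,
    method: str = "bca",
    seed: int | None = None,
) -> EffectSize:
    """Bootstrap estimate of 100 * mean(test) / mean(control), in percent.

    The "x% +/- y%" reporting form corresponds to the estimate and the
    half-width of the CI.
    """
    control = np.asarray(control, dtype=float)
    test = np.asarray(test, dtype=float)
    if len(control) < 3 or len(test) < 3:
        raise ValueError("both groups need >= 3 values")
    if np.mean(control) <= 0:
        raise ValueError("control mean must be positive")
    if B < MIN_B:
        raise ValueError(f"B must be >= {MIN_B}")

    est, lo, hi, used, degen, dist = _bootstrap_two_sample(
        control, test,
        lambda t, c, axis=-1: 100.0 * np.mean(t, axis=axis) / np.mean(c, axis=axis),
        B, alpha, method, seed,
    )
    return EffectSize(est, lo, hi, len(control), len(test), B, alpha, used, degen, dist)


def hatch_summary(viable_counts, total_counts) -> HatchSummary:
    """Percent of viable eggs per replicate, with mean and SD across replicates."""
    viable = np.asarray(viable_counts, dtype=float)
    total = np.asarray(total_counts, dtype=float)
    if viable.shape != total.shape:
        raise ValueError("viable and total must align")
    if (total <= 0).any():
        raise ValueError("replicate with total = 0 rejected")
    if (viable < 0).any() or (viable > total).any():
        raise ValueError("need 0 <= viable <= total per replicate")
    pct = 100.0 * viable / total
    sd = float(np.std(pct, ddof=1)) if len(pct) > 1 else 0.0
    return HatchSummary(percent_viable=pct, mean_percent=float(np.mean(pct)), sd_percent=sd)
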