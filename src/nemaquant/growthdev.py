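"""Growth-trajectory summaries and developmental timing analysis.

A single animal's development is recorded as a length-vs-time series from
egg to egg-laying adult.  This module fits the 3-parameter logistic growth
model, computes median growth curves with bootstrap confidence bands,
derives developmental timings (ex-utero, larval, generation time) from
event tables, and implements the windowed bootstrap length-ratio
comparison between two cohorts: development is split into 15 windows of
4 h 16 min tiling [0, 64 h], and within each window ratios of randomly
paired mutant/wild-type measurements (paired only if taken within 1.5 h of
each other) are bootstrapped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "GrowthTrajectory",
    "LogisticFit",
    "DevEvents",
    "Timings",
    "WindowRatioResult",
    "DegenerateTrajectoryError",
    "logistic",
    "fit_logistic",
    "median_curve",
    "extract_timings",
    "windowed_ratio_bootstrap",
    "WINDOW_LEN_H",
]

#: Default window length: 4 h 16 min.  Fifteen such windows tile [0, 64 h].
WINDOW_LEN_H = 4.0 + 16.0 / 60.0


class DegenerateTrajectoryError(ValueError):
    """Raised when a trajectory carries no usable growth signal."""


@dataclass
class GrowthTrajectory:
    """Per-animal body length time series (times in h, lengths in um).

    Missing lengths are encoded as NaN.  Times must be strictly increasing
    and lie in [0, 100] h.
    """

    animal_id: str
    times_h: np.ndarray
    lengths_um: np.ndarray

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.lengths_um = np.asarray(self.lengths_um, dtype=float)
        if self.times_h.shape != self.lengths_um.shape:
            raise ValueError("times and lengths must have equal length")
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("times_h must be strictly increasing")
        if self.times_h.size and (self.times_h[0] < 0 or self.times_h[-1] > 100):
            raise ValueError("times_h must lie within [0, 100] h")
        finite = np.isfinite(self.lengths_um)
        if np.any(self.lengths_um[finite] <= 0):
            raise ValueError("lengths_um must be positive where present")

    def dropna(self) -> tuple[np.ndarray, np.ndarray]:
        ok = np.isfinite(self.lengths_um)
        return self.times_h[ok], self.lengths_um[ok]


@dataclass(frozen=True)
class LogisticFit:
    """Least-squares logistic growth summary: L(t) = l_max / (1 + e^{-rate (t-shift)})."""

    l_max_um: float
    rate_per_h: float
    shift_h: float
    rss: float
    converged: bool

    def predict(self, t: np.ndarray) -> np.ndarray:
        return logistic(np.asarray(t, dtype=float), self.l_max_um, self.rate_per_h, self.shift_h)


@dataclass(frozen=True)
class DevEvents:
    """Developmental event times in hours; any may be missing (None)."""

    t_laid_h: float | None = None
    t_hatch_h: float | None = None
    t_first_egg_h: float | None = None


@dataclass(frozen=True)
class Timings:
    """Developmental intervals: generation = ex_utero + larval when complete."""

    ex_utero_h: float | None
    larval_h: float | None
    generation_h: float | None


@dataclass(frozen=True)
class WindowRatioResult:
    """Bootstrap summary of the length ratio (group_b / group_a) in one window."""

    window_index: int
    t_start_h: float
    t_end_h: float
    mean_ratio: float
    ci_low: float
    ci_high: float
    n_accepted: int
    n_rejected: int


def logistic(t: np.ndarray, l_max: float, rate: float, shift: float) -> np.ndarray:
    return l_max / (1.0 + np.exp(-rate * (t - shift)))


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    # l_max: slightly above the observed max; shift: time of steepest
    # (smoothed) increase; rate: 4 * max slope / l_max (slope of a logistic
    # at its midpoint is rate * l_max / 4).
    l_max0 = 1.05 * float(np.max(y))
    k = max(len(y) // 20, 1)
    kernel = np.ones(2 * k + 1) / (2 * k + 1)
    y_s = np.convolve(y, kernel, mode="same")
    slopes = np.gradient(y_s, t)
    i = int(np.argmax(slopes))
    shift0 = float(t[i])
    rate0 = max(4.0 * float(slopes[i]) / l_max0, 1e-3)
    return l_max0, rate0, shift0


def fit_logistic(
    trajectory: GrowthTrajectory,
    init: tuple[float, float, float] | None = None,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
) -> LogisticFit:
    """Fit the 3-parameter logistic growth model by least squares.

    Requires at least 8 non-missing points spanning at least 10 h.  A
    constant trajectory is degenerate (the rate is unidentifiable) and
    raises :class:`DegenerateTrajectoryError`.  Non-convergence is reported
    honestly via ``converged=False``; the best parameters found are still
    returned.
    """
    t, y = trajectory.dropna()
    if len(t) < 8:
        raise ValueError("need >= 8 non-missing points to fit")
    if t[-1] - t[0] < 10.0:
        raise ValueError("trajectory must span >= 10 h")
    if np.ptp(y) < 1e-12 * max(np.max(np.abs(y)), 1.0):
        raise DegenerateTrajectoryError("constant trajectory: logistic rate unidentifiable")

    p0 = np.asarray(init if init is not None else _initial_guess(t, y), dtype=float)
    if bounds is None:
        lo = np.array([1e-9, 1e-9, -np.inf])
        hi = np.array([np.inf, np.inf, np.inf])
    else:
        lo, hi = np.asarray(bounds[0], float), np.asarray(bounds[1], float)
    p0 = np.clip(p0, lo, hi)

    res = optimize.least_squares(
        lambda p: logistic(t, *p) - y, p0, bounds=(lo, hi), method="trf",
        xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=5000,
    )
    l_max, rate, shift = res.x
    return LogisticFit(
        l_max_um=float(l_max),
        rate_per_h=float(rate),
        shift_h=float(shift),
        rss=float(2.0 * res.cost),
        converged=bool(res.success),
    )


def median_curve(
    trajectories: list[GrowthTrajectory],
    time_grid: np.ndarray,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    min_animals: int = 3,
) -> pd.DataFrame:
    """Median growth curve with a bootstrap CI of the median.

    Each animal's series is linearly interpolated onto ``time_grid``
    (missing outside its observed range); at each grid point with at least
    ``min_animals`` contributing animals, the across-animal median and a
    percentile bootstrap interval of the median (resampling animals with
    replacement, ``B`` resamples) are reported.  Grid points with fewer
    contributors are returned as NaN.
    """
    time_grid = np.asarray(time_grid, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(trajectories)
    if n == 0:
        raise ValueError("need at least one trajectory")

    interp = np.full((n, len(time_grid)), np.nan)
    for i, tr in enumerate(trajectories):
        t, y = tr.dropna()
        if len(t) < 2:
            continue
        inside = (time_grid >= t[0]) & (time_grid <= t[-1])
        interp[i, inside] = np.interp(time_grid[inside], t, y)

    n_contrib = np.sum(np.isfinite(interp), axis=0)
    valid = n_contrib >= min_animals

    med = np.full(len(time_grid), np.nan)
    lo = np.full(len(time_grid), np.nan)
    hi = np.full(len(time_grid), np.nan)
    med[valid] = np.nanmedian(interp[:, valid], axis=0)

    idx = rng.integers(0, n, size=(B, n))
    boot = np.full((B, int(valid.sum())), np.nan)
    cols = np.nonzero(valid)[0]
    sub = interp[:, cols]
    for b in range(B):
        boot[b] = np.nanmedian(sub[idx[b]], axis=0)
    lo[cols] = np.nanpercentile(boot, 100 * alpha / 2, axis=0)
    hi[cols] = np.nanpercentile(boot, 100 * (1 - alpha / 2), axis=0)

    return pd.DataFrame(
        {
            "time_h": time_grid,
            "median_um": med,
            "ci_low_um": lo,
            "ci_high_um": hi,
            "n_animals": n_contrib,
        }
    )


def extract_timings(events: DevEvents) -> Timings:
    """Interval arithmetic on developmental events.

    ex_utero = hatch - laid; larval = first egg - hatch; generation =
    first egg - laid.  A missing input propagates to the intervals that
    need it; out-of-order events reject the record.
    """
    laid, hatch, egg = events.t_laid_h, events.t_hatch_h, events.t_first_egg_h
    present = [v for v in (laid, hatch, egg) if v is not None]
    ordered = [v for v in (laid, hatch, egg) if v is not None]
    if ordered != sorted(ordered) or len(set(present)) != len(present):
        raise ValueError(
            f"events out of order: laid={laid}, hatch={hatch}, first_egg={egg}"
        )
    ex_utero = hatch - laid if (laid is not None and hatch is not None) else None
    larval = egg - hatch if (hatch is not None and egg is not None) else None
    generation = egg - laid if (laid is not None and egg is not None) else None
    return Timings(ex_utero_h=ex_utero, larval_h=larval, generation_h=generation)


def _flatten(group: list[GrowthTrajectory]) -> tuple[np.ndarray, np.ndarray]:
    ts, ys = [], []
    for tr in group:
        t, y = tr.dropna()
        ts.append(t)
        ys.append(y)
    if not ts:
        return np.empty(0), np.empty(0)
    return np.concatenate(ts), np.concatenate(ys)


def windowed_ratio_bootstrap(
    group_a: list[GrowthTrajectory],
    group_b: list[GrowthTrajectory],
    window_len_h: float = WINDOW_LEN_H,
    n_windows: int = 15,
    start_h: float = 0.0,
    max_dt_h: float = 1.5,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    attempt_cap_factor: int = 100,
) -> list[WindowRatioResult]:
    """Windowed bootstrap of the length ratio group_b / group_a.

    Development time is tiled into ``n_windows`` half-open windows
    ``[start + k*w, start + (k+1)*w)``.  Within each window, ``B`` ratios
    are collected: draw one measurement uniformly with replacement from
    each group (restricted to the window); if the two measurements are more
    than ``max_dt_h`` apart in real time the pair is rejected and redrawn.
    The mean ratio and the percentile (alpha/2, 1-alpha/2) interval of the
    accepted draws are reported per window, along with acceptance counts.

    A window in which either group has no measurement, or in which no pair
    can satisfy the time constraint within ``attempt_cap_factor * B``
    draws, is reported empty (``n_accepted=0``, NaN summaries).
    """
    rng = np.random.default_rng(seed)
    ta, ya = _flatten(group_a)
    tb, yb = _flatten(group_b)

    results: list[WindowRatioResult] = []
    for k in range(n_windows):
        t0 = start_h + k * window_len_h
        t1 = t0 + window_len_h
        in_a = (ta >= t0) & (ta < t1)
        in_b = (tb >= t0) & (tb < t1)
        wa_t, wa_y = ta[in_a], ya[in_a]
        wb_t, wb_y = tb[in_b], yb[in_b]

        if len(wa_t) == 0 or len(wb_t) == 0:
            results.append(
                WindowRatioResult(k, t0, t1, np.nan, np.nan, np.nan, 0, 0)
            )
            continue

        cap = attempt_cap_factor * B
        ratios = np.empty(B)
        filled = 0
        attempts = 0
        rejected = 0
        while filled < B and attempts < cap:
            m = min(B - filled, cap - attempts)
            ia = rng.integers(0, len(wa_t), size=m)
            ib = rng.integers(0, len(wb_t), size=m)
            attempts += m
            ok = np.abs(wa_t[ia] - wb_t[ib]) <= max_dt_h
            rejected += int(m - ok.sum())
            n_ok = int(ok.sum())
            ratios[filled : filled + n_ok] = wb_y[ib[ok]] / wa_y[ia[ok]]
            filled += n_ok

        if filled < B:
            results.append(
                WindowRatioResult(k, t0, t1, np.nan, np.nan, np.nan, 0, rejected)
            )
            continue

        results.append(
            WindowRatioResult(
                window_index=k,
                t_start_h=t0,
                t_end_h=t1,
                mean_ratio=float(np.mean(ratios)),
                ci_low=float(np.percentile(ratios, 100 * alpha / 2)),
                ci_high=float(np.percentile(ratios, 100 * (1 - alpha / 2))),
                n_accepted=B,
                n_rejected=rejected,
            )
        )
    return results
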