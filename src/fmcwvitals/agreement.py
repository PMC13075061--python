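"""Method comparison between radar-derived and reference breathing rates.

Mirrors the standard evaluation of a candidate monitor against an
established one: resample both rate series to a common grid, find the lag
maximizing Pearson correlation, then summarize agreement by the squared
correlation, Bland-Altman bias and 95% limits of agreement
(bias +/- 1.96 SD of the paired differences), and per-pair relative
differences as a function of the pair-mean rate.
"""

from __future__ import annotations

import logging

import numpy as np

from .core import AgreementReport, RateSeries

__all__ = [
    "synchronize",
    "r_squared",
    "bland_altman",
    "relative_differences",
    "evaluate_agreement",
]

logger = logging.getLogger(__name__)


def _to_grid(series: RateSeries, grid: np.ndarray) -> np.ndarray:
    """Linear interpolation of a rate series onto *grid*, sentinel-aware.

    Grid points bridging a gap in the valid samples wider than twice the
    series' median sampling interval become the sentinel rather than being
    interpolated across.
    """
    t, r = series.timestamps, series.rate
    valid = np.isfinite(r)
    if valid.sum() < 2:
        return np.full(grid.size, np.nan)
    tv, rv = t[valid], r[valid]
    out = np.interp(grid, tv, rv, left=np.nan, right=np.nan)
    # invalidate grid points whose bracketing valid samples are too far apart
    dt = np.median(np.diff(t)) if t.size > 1 else np.inf
    hi = np.searchsorted(tv, grid, side="left")
    inside = (hi > 0) & (hi < tv.size)
    gap = np.full(grid.size, np.inf)
    gap[inside] = tv[hi[inside]] - tv[hi[inside] - 1]
    exact = np.isin(grid, tv)
    out[~exact & (gap > 2.0 * dt)] = np.nan
    return out


def synchronize(
    radar: RateSeries,
    reference: RateSeries,
    max_lag: float = 30.0,
    grid_rate: float = 1.0,
) -> tuple[float, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Align the radar series to the reference by correlation-maximizing lag.

    Both series are linearly interpolated onto a common ``grid_rate`` grid
    over their overlap.  Integer-step lags within ``+/- max_lag`` are
    scanned; the lag maximizing the Pearson correlation of the valid pairs
    wins, ties breaking toward smaller ``|lag|``.  Returns
    ``(lag_seconds, (grid_times, radar_aligned, reference_aligned))`` where
    ``radar_aligned[i]`` is the radar rate at ``grid_times[i] - lag``.
    """
    t0 = max(radar.timestamps[0], reference.timestamps[0])
    t1 = min(radar.timestamps[-1], reference.timestamps[-1])
    step = 1.0 / grid_rate
    grid = np.arange(np.ceil(t0 / step) * step, t1 + 1e-9, step)
    if grid.size < 30:
        raise ValueError(
            f"insufficient overlap: {grid.size} common grid samples, need >= 30"
        )
    a = _to_grid(radar, grid)
    b = _to_grid(reference, grid)

    max_shift = int(round(max_lag * grid_rate))
    best_lag, best_corr = 0, -np.inf
    for shift in sorted(range(-max_shift, max_shift + 1), key=abs):
        if shift >= 0:
            x, y = a[: a.size - shift or None], b[shift:]
        else:
            x, y = a[-shift:], b[: b.size + shift]
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3:
            continue
        xs, ys = x[ok], y[ok]
        if xs.std() == 0 or ys.std() == 0:
            continue
        c = float(np.corrcoef(xs, ys)[0, 1])
        if c > best_corr + 1e-12:
            best_corr, best_lag = c, shift
    if not np.isfinite(best_corr):
        raise ValueError("synchronization failed: no lag yields enough valid pairs")

    lag = best_lag * step
    if best_lag >= 0:
        times = grid[best_lag:]
        aligned_a = a[: a.size - best_lag or None]
        aligned_b = b[best_lag:]
    else:
        times = grid[: grid.size + best_lag]
        aligned_a = a[-best_lag:]
        aligned_b = b[: b.size + best_lag]
    logger.info("synchronized with lag %.1f s (corr %.4f)", lag, best_corr)
    return lag, (times, aligned_a, aligned_b)


def _valid_pairs(radar: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    radar = np.asarray(radar, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if radar.shape != reference.shape:
        raise ValueError("paired series must have equal length")
    ok = np.isfinite(radar) & np.isfinite(reference)
    return radar[ok], reference[ok]


def r_squared(radar: np.ndarray, reference: np.ndarray) -> float:
    """Squared Pearson correlation of the paired rates."""
    x, y = _valid_pairs(radar, reference)
    if x.size < 3:
        raise ValueError(f"need >= 3 valid pairs for r_squared, got {x.size}")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("undefined correlation: zero variance in a series")
    r = float(np.corrcoef(x, y)[0, 1])
    return r * r


def bland_altman(radar: np.ndarray, reference: np.ndarray) -> tuple[float, float, float]:
    """Bland-Altman bias and 95% limits of agreement, radar minus reference.

    Returns ``(mean_difference, loa_lower, loa_upper)`` with limits at
    ``mean +/- 1.96`` sample standard deviations (n-1 denominator).
    """
    x, y = _valid_pairs(radar, reference)
    if x.size < 2:
        raise ValueError(f"need >= 2 valid pairs for bland_altman, got {x.size}")
    d = x - y
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return mean, mean - 1.96 * sd, mean + 1.96 * sd


def relative_differences(
    radar: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair mean rate and relative difference in percent.

    ``mean = (radar + reference) / 2``; ``rel = 100 (radar - reference) / mean``.
    Pairs with zero mean are skipped with a warning.
    """
    x, y = _valid_pairs(radar, reference)
    mean = (x + y) / 2.0
    nonzero = mean != 0
    if not nonzero.all():
        logger.warning("skipping %d pair(s) with zero mean rate", int((~nonzero).sum()))
    x, y, mean = x[nonzero], y[nonzero], mean[nonzero]
    rel = 100.0 * (x - y) / mean
    return mean, rel


def evaluate_agreement(
    radar: RateSeries,
    reference: RateSeries,
    max_lag: float = 30.0,
    grid_rate: float = 1.0,
) -> AgreementReport:
    """Full comparison: synchronize, then R², Bland-Altman and relative diffs."""
    lag, (times, a, b) = synchronize(radar, reference, max_lag=max_lag, grid_rate=grid_rate)
    r2 = r_squared(a, b)
    mean_diff, loa_lo, loa_hi = bland_altman(a, b)
    means, rels = relative_differences(a, b)
    ok = np.isfinite(a) & np.isfinite(b)
    return AgreementReport(
        lag=lag,
        r_squared=r2,
        mean_difference=mean_diff,
        loa_lower=loa_lo,
        loa_upper=loa_hi,
        relative_differences=rels,
        mean_rates=means,
        n_pairs=int(ok.sum()),
    )
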