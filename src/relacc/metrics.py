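"""Absolute cut-point-free metrics: AvAcc, intensity gradient, MX profiles.

All metrics are computed per midnight-to-midnight day on the epoch grid and
then arithmetically averaged across a participant's valid days (optionally
restricted to weekdays or weekend days for sensitivity analyses).

* AvAcc (average acceleration, mg): arithmetic mean of epoch ENMO over the
  full 24-h day; a proxy for total activity volume.
* IG (intensity gradient): time accumulated in incremental 25-mg intensity
  bins is regressed, log-log, on the bin mid-points; the slope is the IG.
  Natural logarithms are used (the slope is base-invariant); zero-time bins
  are excluded (log 0 undefined); bins extend to the maximum observed epoch
  value with no fixed cap.
* MX (mg): the acceleration above which the most active X minutes of the day
  are accumulated -- the (X * 60 / epoch_seconds)-th largest epoch value,
  rank-based and non-contiguous by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import datetime as dt

import numpy as np

from .epochs import EpochSeries

#: MX profile grid in minutes, spanning the most active minute to 12 h.
MX_GRID = (1, 2, 5, 10, 15, 30, 60, 120, 240, 360, 480, 600, 720)
DEFAULT_BIN_WIDTH_MG = 25.0


class UndefinedIGError(ValueError):
    """Fewer than two nonzero intensity bins: the log-log slope is undefined."""


class MissingDataError(ValueError):
    """Metric requested on a day with missing epochs (run validity first)."""


@dataclass
class IGResult:
    slope: float
    intercept: float
    r_squared: float
    n_bins_used: int


def _complete_values(series: EpochSeries, what: str) -> np.ndarray:
    vals = series.enmo
    if not np.isfinite(vals).all():
        n_missing = int((~np.isfinite(vals)).sum())
        raise MissingDataError(
            f"{what} requires a full imputed day; {n_missing} epoch(s) missing "
            f"for {series.participant_id} {series.date}"
        )
    return vals


def avacc_abs(series: EpochSeries) -> float:
    """Average acceleration: mean ENMO (mg) over the full 24-h day."""
    return float(_complete_values(series, "avacc_abs").mean())


def ig_from_bin_minutes(minutes: np.ndarray, midpoints: np.ndarray) -> IGResult:
    """Least-squares fit of ln(minutes) on ln(mid-intensity) over nonzero bins."""
    minutes = np.asarray(minutes, dtype=float)
    midpoints = np.asarray(midpoints, dtype=float)
    keep = minutes > 0
    n_bins = int(keep.sum())
    if n_bins < 2:
        raise UndefinedIGError(
            f"intensity gradient undefined: only {n_bins} nonzero bin(s)"
        )
    x = np.log(midpoints[keep])
    y = np.log(minutes[keep])
    xm, ym = x.mean(), y.mean()
    sxx = ((x - xm) ** 2).sum()
    sxy = ((x - xm) * (y - ym)).sum()
    slope = sxy / sxx
    intercept = ym - slope * xm
    syy = ((y - ym) ** 2).sum()
    r2 = 1.0 if syy == 0 else (sxy * sxy) / (sxx * syy)
    return IGResult(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(r2),
        n_bins_used=n_bins,
    )


def bin_minutes_abs(
    series: EpochSeries, bin_width_mg: float = DEFAULT_BIN_WIDTH_MG
) -> tuple[np.ndarray, np.ndarray]:
    """Minutes accumulated per incremental intensity bin and bin mid-points."""
    vals = _complete_values(series, "ig_abs")
    idx = np.floor_divide(vals, bin_width_mg).astype(np.int64)
    counts = np.bincount(idx)
    minutes = counts * (series.epoch_seconds / 60.0)
    mids = (np.arange(len(counts)) + 0.5) * bin_width_mg
    return minutes, mids


def ig_abs(
    series: EpochSeries, bin_width_mg: float = DEFAULT_BIN_WIDTH_MG
) -> IGResult:
    """Absolute intensity gradient of one day (25-mg bins by default)."""
    if bin_width_mg <= 0:
        raise ValueError("bin_width_mg must be positive")
    minutes, mids = bin_minutes_abs(series, bin_width_mg)
    return ig_from_bin_minutes(minutes, mids)


def mx(series: EpochSeries, minutes: int) -> float:
    """MX: ENMO above which the most active ``minutes`` are accumulated."""
    vals = _complete_values(series, "mx")
    k = minutes * 60 / series.epoch_seconds
    if k != int(k):
        raise ValueError(
            f"X = {minutes} min is not a whole number of {series.epoch_seconds}-s epochs"
        )
    k = int(k)
    if not 1 <= k <= len(vals):
        raise ValueError(f"X = {minutes} min outside the {len(vals)}-epoch day")
    # value of the k-th largest epoch
    return float(np.partition(vals, len(vals) - k)[len(vals) - k])


def mx_profile(
    series: EpochSeries, grid: tuple[int, ...] = MX_GRID
) -> dict[int, float]:
    """MX at every grid duration via a single descending sort."""
    vals = np.sort(_complete_values(series, "mx"))[::-1]
    out: dict[int, float] = {}
    for x in grid:
        k = x * 60 / series.epoch_seconds
        if k != int(k) or not 1 <= k <= len(vals):
            raise ValueError(f"X = {x} min invalid for this epoch grid")
        out[x] = float(vals[int(k) - 1])
    return out


@dataclass
class DailyMetrics:
    """Per-day metric bundle (relative entries filled by metrics_relative)."""

    date: dt.date
    day_type: str
    avacc_abs: float
    ig_abs: IGResult | None = None
    mx: dict[int, float] = field(default_factory=dict)
    ig_rel: IGResult | None = None


@dataclass
class PersonMetrics:
    """Across-day arithmetic means of daily metrics for one participant."""

    avacc_abs: float
    ig_abs: IGResult | None
    mx: dict[int, float]
    ig_rel: IGResult | None
    n_days: int
    day_filter: str


def _mean_ig(results: list[IGResult]) -> IGResult:
    return IGResult(
        slope=float(np.mean([r.slope for r in results])),
        intercept=float(np.mean([r.intercept for r in results])),
        r_squared=float(np.mean([r.r_squared for r in results])),
        n_bins_used=int(round(np.mean([r.n_bins_used for r in results]))),
    )


def average_over_days(
    daily: list[DailyMetrics], day_filter: str = "all"
) -> PersonMetrics:
    """Element-wise arithmetic mean over days after the requested filter.

    IG is averaged on the slope scale; MX per grid duration.  Filters:
    ``all``, ``weekdays`` (Monday-Friday), ``weekend`` (Saturday + Sunday).
    """
    if day_filter == "all":
        kept = list(daily)
    elif day_filter == "weekdays":
        kept = [d for d in daily if d.day_type == "weekday"]
    elif day_filter == "weekend":
        kept = [d for d in daily if d.day_type in ("saturday", "sunday")]
    else:
        raise ValueError(f"unknown day filter {day_filter!r}")
    if not kept:
        raise ValueError(f"no days remain after filter {day_filter!r}")
    igs = [d.ig_abs for d in kept if d.ig_abs is not None]
    igs_rel = [d.ig_rel for d in kept if d.ig_rel is not None]
    mx_keys = kept[0].mx.keys()
    return PersonMetrics(
        avacc_abs=float(np.mean([d.avacc_abs for d in kept])),
        ig_abs=_mean_ig(igs) if len(igs) == len(kept) and igs else None,
        mx={x: float(np.mean([d.mx[x] for d in kept])) for x in mx_keys},
        ig_rel=_mean_ig(igs_rel) if len(igs_rel) == len(kept) and igs_rel else None,
        n_days=len(kept),
        day_filter=day_filter,
    )
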