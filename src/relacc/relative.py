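"""Fitness-relative metrics: predicted maximum ENMO and _REL re-expression.

The individual's maximum (aerobic) acceleration is predicted by extrapolating
a linear VO2-ENMO calibration to the measured VO2peak:

    max_enmo (mg) = (vo2peak - intercept) / slope

Average acceleration and MX values are then expressed as a percentage of this
maximum; the relative intensity gradient re-bins each day's epochs on the
percent-of-maximum scale (5 %-wide bins with one open-ended bin above 300 %)
before the same log-log regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .epochs import EpochSeries
from .metrics import IGResult, _complete_values, ig_from_bin_minutes

DEFAULT_BIN_WIDTH_PCT = 5.0
DEFAULT_TOP_OPEN_AT_PCT = 300.0


class NonPositiveCapacityError(ValueError):
    """VO2peak at or below the model intercept: no positive predicted maximum."""


@dataclass
class Vo2EnmoModel:
    """Linear VO2 (mL.kg-1.min-1) ~ ENMO (mg) calibration used for extrapolation."""

    slope: float
    intercept: float
    source_label: str = ""

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("Vo2EnmoModel slope must be positive")


def predict_max_enmo(vo2peak: float, model: Vo2EnmoModel) -> float:
    """Maximum aerobic acceleration (mg) by inverting the linear calibration."""
    if vo2peak <= model.intercept:
        raise NonPositiveCapacityError(
            f"vo2peak {vo2peak:g} <= model intercept {model.intercept:g}: "
            "predicted maximum ENMO would be non-positive; participant must be "
            "excluded from relative metrics"
        )
    return (vo2peak - model.intercept) / model.slope


def avacc_rel(avacc_abs: float, max_enmo: float) -> float:
    """AvAcc as a percentage of the predicted maximum acceleration."""
    if max_enmo <= 0:
        raise ValueError("max_enmo must be positive")
    return 100.0 * avacc_abs / max_enmo


def relative_mx(mx_value: float, max_enmo: float) -> float:
    """MX as a percentage of the predicted maximum acceleration."""
    if max_enmo <= 0:
        raise ValueError("max_enmo must be positive")
    return 100.0 * mx_value / max_enmo


def bin_minutes_rel(
    series: EpochSeries,
    max_enmo: float,
    bin_width_pct: float = DEFAULT_BIN_WIDTH_PCT,
    top_open_at_pct: float = DEFAULT_TOP_OPEN_AT_PCT,
) -> tuple[np.ndarray, np.ndarray]:
    """Minutes per relative-intensity bin and bin mid-percentages.

    Bins are [0, 5), [5, 10), ... up to ``top_open_at_pct``, then a single
    open-ended bin; its mid-point continues the grid (302.5 % by default).
    The first bin starts at 0 % so that epochs below 5 % of maximum still
    contribute (mid 2.5 %).
    """
    if max_enmo <= 0:
        raise ValueError("max_enmo must be positive")
    vals = _complete_values(series, "ig_rel")
    rel = vals * (100.0 / max_enmo)
    n_closed = int(top_open_at_pct / bin_width_pct)
    idx = np.minimum(
        np.floor_divide(rel, bin_width_pct).astype(np.int64), n_closed
    )
    counts = np.bincount(idx, minlength=n_closed + 1)
    minutes = counts * (series.epoch_seconds / 60.0)
    mids = (np.arange(n_closed + 1) + 0.5) * bin_width_pct
    return minutes, mids


def ig_rel(
    series: EpochSeries,
    max_enmo: float,
    bin_width_pct: float = DEFAULT_BIN_WIDTH_PCT,
    top_open_at_pct: float = DEFAULT_TOP_OPEN_AT_PCT,
) -> IGResult:
    """Relative intensity gradient of one day on the percent-of-maximum scale."""
    minutes, mids = bin_minutes_rel(series, max_enmo, bin_width_pct, top_open_at_pct)
    return ig_from_bin_minutes(minutes, mids)


@dataclass
class RelativeMetrics:
    """Person-level relative metric bundle."""

    max_enmo: float
    avacc_rel: float
    ig_rel: IGResult | None
    rel_mx: dict[int, float] = field(default_factory=dict)


def relative_from_person(
    avacc_abs_value: float,
    mx_values: dict[int, float],
    ig_rel_mean: IGResult | None,
    vo2peak: float,
    model: Vo2EnmoModel,
) -> RelativeMetrics:
    """Assemble person-level relative metrics from absolute ones and VO2peak."""
    max_enmo = predict_max_enmo(vo2peak, model)
    return RelativeMetrics(
        max_enmo=max_enmo,
        avacc_rel=avacc_rel(avacc_abs_value, max_enmo),
        ig_rel=ig_rel_mean,
        rel_mx={x: relative_mx(v, max_enmo) for x, v in mx_values.items()},
    )
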