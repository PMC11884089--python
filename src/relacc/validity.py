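"""Wear-time, valid-day, participant-inclusion rules and non-wear imputation.

A valid day has >= 14 h of wear.  A participant is included when they have at
least four valid weekdays plus one valid Saturday and one valid Sunday, and
wear data cover every 15-min slot of the 24-h cycle pooled across their valid
days.  Metrics are computed on imputed, full 24-h days: non-wear epochs are
replaced by the mean of the same clock-time epoch over the participant's
other valid days (where worn).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import datetime as dt

import numpy as np

from .epochs import EpochSeries

WEAR_HOURS_REQUIRED = 14.0
COVERAGE_SLOT_SECONDS = 900  # 15-min slots of the 24-h cycle
MIN_VALID_WEEKDAYS = 4
MIN_VALID_SATURDAYS = 1
MIN_VALID_SUNDAYS = 1


@dataclass
class DayValidity:
    date: dt.date
    day_type: str
    wear_hours: float
    valid: bool


@dataclass
class InclusionDecision:
    participant_id: str
    n_valid_weekdays: int
    n_valid_saturdays: int
    n_valid_sundays: int
    coverage_ok: bool
    included: bool
    reasons: list[str] = field(default_factory=list)


def assess_day(series: EpochSeries) -> DayValidity:
    """Wear hours and the >= 14 h validity rule (boundary inclusive)."""
    wear_hours = series.wear.sum() * series.epoch_seconds / 3600.0
    return DayValidity(
        date=series.date,
        day_type=series.day_type,
        wear_hours=float(wear_hours),
        valid=wear_hours >= WEAR_HOURS_REQUIRED,
    )


def _coverage_slots(days: list[EpochSeries]) -> np.ndarray:
    """Boolean per 15-min slot: any wear epoch in any of the given days."""
    n_slots = 86400 // COVERAGE_SLOT_SECONDS
    covered = np.zeros(n_slots, dtype=bool)
    for s in days:
        per_slot = 900 // s.epoch_seconds
        covered |= s.wear.reshape(n_slots, per_slot).any(axis=1)
    return covered


def decide_inclusion(days: list[EpochSeries]) -> InclusionDecision:
    """Apply the participant-inclusion rule; reasons list every failure.

    The 15-min coverage rule is pooled across valid days: a slot counts as
    covered when any valid day has wear there.  The decision is invariant to
    the order of ``days``.
    """
    if not days:
        raise ValueError("decide_inclusion requires at least one day")
    pid = days[0].participant_id
    validities = [assess_day(s) for s in days]
    valid_days = [s for s, v in zip(days, validities) if v.valid]
    n_wd = sum(1 for v in validities if v.valid and v.day_type == "weekday")
    n_sat = sum(1 for v in validities if v.valid and v.day_type == "saturday")
    n_sun = sum(1 for v in validities if v.valid and v.day_type == "sunday")
    reasons: list[str] = []
    if n_wd < MIN_VALID_WEEKDAYS:
        reasons.append(
            f"fewer than {MIN_VALID_WEEKDAYS} valid weekdays (got {n_wd})"
        )
    if n_sat < MIN_VALID_SATURDAYS:
        reasons.append("missing valid Saturday")
    if n_sun < MIN_VALID_SUNDAYS:
        reasons.append("missing valid Sunday")
    covered = _coverage_slots(valid_days) if valid_days else np.zeros(96, dtype=bool)
    coverage_ok = bool(covered.all())
    if not coverage_ok:
        gaps = np.flatnonzero(~covered)
        reasons.append(
            f"coverage: {len(gaps)} uncovered 15-min slot(s) of the 24-h "
            f"cycle (first at slot {gaps[0]})"
        )
    included = not reasons
    return InclusionDecision(
        participant_id=pid,
        n_valid_weekdays=n_wd,
        n_valid_saturdays=n_sat,
        n_valid_sundays=n_sun,
        coverage_ok=coverage_ok,
        included=included,
        reasons=reasons,
    )


def impute_nonwear(
    series: EpochSeries, sibling_days: list[EpochSeries]
) -> EpochSeries:
    """Fill non-wear epochs from the same clock-time epoch of sibling days.

    Donors are the sibling days that are themselves valid; the imputed value
    is the mean over donors that were worn at that epoch.  Worn epochs are
    never modified.  Slots with no donor anywhere are left missing (NaN) and
    not flagged imputed; such a participant later fails the coverage rule.
    """
    out = series.copy()
    target = ~series.wear
    if not target.any():
        return out
    donors = [
        s
        for s in sibling_days
        if s is not series
        and s.epoch_seconds == series.epoch_seconds
        and assess_day(s).valid
    ]
    if donors:
        vals = np.stack([d.enmo for d in donors])
        worn = np.stack([d.wear for d in donors]) & np.isfinite(vals)
        vals = np.where(worn, vals, 0.0)
        counts = worn.sum(axis=0)
        sums = vals.sum(axis=0)
        have_donor = counts > 0
        means = np.divide(sums, counts, out=np.zeros_like(sums), where=have_donor)
    else:
        have_donor = np.zeros(series.n_epochs, dtype=bool)
        means = np.zeros(series.n_epochs)
    fill = target & have_donor
    out.enmo[fill] = means[fill]
    out.imputed[fill] = True
    out.enmo[target & ~have_donor] = np.nan
    return out


def impute_participant(days: list[EpochSeries]) -> list[EpochSeries]:
    """Impute every day of one participant against their other valid days."""
    return [impute_nonwear(s, [d for d in days if d is not s]) for s in days]
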