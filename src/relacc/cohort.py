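"""Synthetic activity-cohort generator with known planted effects.

Generates a full synthetic study -- covariates, VO2peak, and multi-day
epoch-level ENMO traces -- so that every downstream stage (validity rules,
metrics, adjusted regressions) can be tested against ground truth.

Model sketch
------------
* Covariates: age uniform over the study range; sex by a fixed proportion;
  occupation type sampled with an age ramp so the "no work-related PA"
  category is dominated by older, retired participants, and a sex tilt so
  women are over-represented in at-least-moderate-PA occupations; employment
  level conditional on occupation; body fat normal by sex; season uniform.
* VO2peak: log-linear in age, sex and body fat plus a log-normal residual.
  Part of the sex gap is mediated by body fat, so the sex contrast
  conditional on body fat (what an adjusted regression recovers) is smaller
  than the marginal one.
* Activity traces: a sleep window of near-zero acceleration, a low-intensity
  waking baseline, and Poisson activity bouts whose intensities follow a
  Pareto (power-law) distribution with durations shrinking as intensity
  grows -- the heavy tail is what gives the intensity gradient its
  characteristic log-log decay.  Two per-person knobs steer the trace: a
  whole-day multiplier (volume) and a volume-compensated intensity-span
  shift (distribution shape).
* Planted effects are specified as targets on (log average acceleration,
  IG slope) and mapped to the two knobs through the measured response
  matrix: sex and occupation contrasts, a smooth age trajectory peaking
  near age 42, person-level heterogeneity, and a coupling to the VO2peak
  residual so fitter people move more.  Occupation effects load mostly on
  weekdays.

All defaults are frozen outputs of the calibration routine in
:mod:`relacc.calibration` against the target summary statistics recorded in
``defaults.yaml``.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .epochs import SECONDS_PER_DAY, EpochSeries, day_type_of

OCCUPATIONS = ("at-least-moderate-PA", "no-work-PA", "sitting/standing")
EMPLOYMENT_LEVELS = ("not working", "10-50%", "60-90%", "100%")
SEASONS = ("spring", "summer", "autumn", "winter")
SEXES = ("female", "male")

#: First monitored day (a Monday); a 7-day protocol spans Monday..Sunday.
START_DATE = dt.date(2024, 3, 4)


class ConfigurationError(ValueError):
    """Invalid cohort/activity specification."""


def _check_probs(name: str, probs, n: int) -> tuple[float, ...]:
    probs = tuple(float(p) for p in probs)
    if len(probs) != n:
        raise ConfigurationError(f"{name} must have {n} entries")
    if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
        raise ConfigurationError(f"{name} must be non-negative and sum to 1")
    return probs


@dataclass
class ActivitySpec:
    """Parameters of the within-day activity trace model (see module docs)."""

    baseline_mg: float = 28.0           # mean of the waking-baseline gamma (mg)
    baseline_shape: float = 2.0         # gamma shape of the waking baseline
    sleep_mg: float = 3.81              # mean ENMO during the sleep window (mg)
    bout_rate: float = 6.81             # expected activity bouts per waking hour
    bout_duration_median_min: float = 4.0
    bout_duration_sigma: float = 0.75   # log-scale SD of bout duration
    bout_duration_intensity_exp: float = 0.5  # duration ~ intensity^(-exp)
    bout_alpha: float = 1.8             # Pareto tail exponent of bout intensity
    bout_mean_mg: float = 102.0         # mean bout intensity (mg); fixes the scale
    bout_jitter_sigma: float = 0.25     # within-bout log-normal epoch jitter
    span_volume_comp: float = 0.89      # bout-rate counter-scaling per log span
    # measured response matrix of the two trace knobs (log multiplier, log
    # span) on (log average acceleration, IG slope); used to convert planted
    # effect targets into knob settings and re-measured by the calibration
    # routine whenever the trace model changes.
    ig_volume_gain: float = 0.31        # d(IG slope) / d(log volume)
    ig_span_gain: float = 0.315         # d(IG slope) / d(log span)
    span_volume_leak: float = 0.24      # d(log volume) / d(log span)
    sleep_start_hour: float = 23.0
    sleep_end_hour: float = 7.0
    nonwear_prob_per_day: float = 0.15
    nonwear_duration_median_min: float = 45.0
    nonwear_duration_sigma: float = 0.5

    def __post_init__(self) -> None:
        for name in ("baseline_mg", "sleep_mg", "bout_mean_mg", "bout_rate",
                     "nonwear_prob_per_day"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.bout_alpha <= 1.0:
            raise ConfigurationError("bout_alpha must exceed 1 (finite mean)")
        if not 0 <= self.nonwear_prob_per_day <= 1:
            raise ConfigurationError("nonwear_prob_per_day must be in [0, 1]")

    def effect_knobs(self, d_log_avacc, d_ig_slope):
        """Solve (volume knob, span knob) for a planted (volume, IG) target.

        Inverts the measured 2x2 response matrix; accepts scalars or arrays.
        """
        det = self.ig_span_gain - self.ig_volume_gain * self.span_volume_leak
        span = (d_ig_slope - self.ig_volume_gain * d_log_avacc) / det
        vol = d_log_avacc - self.span_volume_leak * span
        return vol, span


@dataclass
class Vo2PeakModel:
    """Log-linear VO2peak model: age, sex (direct), body fat, residual."""

    vo2_ref: float = 37.9           # mL.kg-1.min-1 at the reference point
    age_ref: float = 55.0
    age_log_slope: float = -0.0104  # per year of age, on log VO2peak
    sex_log_offset: float = -0.081  # female vs male at equal age and body fat
    bodyfat_log_slope: float = -0.0193  # per body-fat percentage point
    bodyfat_ref: float = 20.5
    resid_log_sd: float = 0.15
    floor: float = 8.0              # mL.kg-1.min-1; draws below are floored

    def __post_init__(self) -> None:
        if self.age_log_slope > 0:
            raise ConfigurationError("vo2peak must decline monotonically with age")
        if self.vo2_ref <= 0 or self.floor <= 0:
            raise ConfigurationError("vo2_ref and floor must be positive")


@dataclass
class BodyfatModel:
    female_mean: float = 27.0
    female_sd: float = 7.0
    male_mean: float = 20.5
    male_sd: float = 6.5
    lower: float = 6.0
    upper: float = 55.0


@dataclass
class PlantedEffects:
    """Ground-truth effect *targets* injected into the generator.

    Volume targets are on the log scale of a person's average acceleration;
    intensity-distribution targets are on the intensity-gradient slope scale.
    The generator converts each (volume, gradient) target pair into its two
    trace knobs -- a whole-trace multiplier and a volume-compensated
    intensity-span shift -- through the measured response matrix on the
    :class:`ActivitySpec` (see ``effect_knobs``), so both the average
    acceleration and the intensity gradient land on their targets
    simultaneously.

    Defaults are the frozen calibration recorded in ``defaults.yaml``:
    women +5 % average acceleration with a slightly steeper intensity
    gradient (more of the volume from lower intensities); sitting/standing
    occupations -10.9 % average acceleration (recovering an adjusted -9.8 %
    contrast after the weekday/weekend split and non-wear imputation) with
    no gradient difference; a smooth age trajectory peaking near age 42.
    """

    sex_avacc_log: float = math.log(1.05)
    sex_ig_slope: float = -0.020        # women - men, IG slope units
    occ_sitstand_avacc_log: float = math.log(1 - 0.109)
    occ_nowork_avacc_log: float = math.log(0.95)
    occ_ig_slope: float = 0.0           # occupation effect on the IG slope
    occ_weekend_share: float = 0.25     # weekend log effect as share of weekday
    age_coefs: tuple[float, float, float] = (-0.25, -0.35, 0.0)
    ig_age_coefs: tuple[float, float] = (-0.05, -0.08)
    saturday_log: float = math.log(0.97)
    sunday_log: float = math.log(0.92)

    @classmethod
    def null(cls) -> "PlantedEffects":
        """All planted contrasts zero (for null-calibration studies)."""
        return cls(
            sex_avacc_log=0.0,
            sex_ig_slope=0.0,
            occ_sitstand_avacc_log=0.0,
            occ_nowork_avacc_log=0.0,
            occ_ig_slope=0.0,
            age_coefs=(0.0, 0.0, 0.0),
            ig_age_coefs=(0.0, 0.0),
            saturday_log=0.0,
            sunday_log=0.0,
        )


@dataclass
class PopulationVariation:
    """Person-level heterogeneity beyond the planted effects."""

    activity_log_sd: float = 0.157      # residual SD of the person volume knob
    ig_span_sd: float = 0.25            # person SD of the log intensity span
    fitness_coupling: float = 0.711     # log-activity per unit VO2peak residual


@dataclass
class CohortSpec:
    """Everything needed to generate one synthetic study (fully seeded)."""

    n_participants: int = 460
    seed: int = 0
    age_range: tuple[float, float] = (20.0, 89.0)
    prop_female: float = 0.48
    occupation_probs: tuple[float, float, float] = (0.29, 0.18, 0.53)
    occupation_sex_ratio: float = 1.64  # female/male odds of a moderate-PA job
    employment_probs: tuple[float, float, float, float] = (0.06, 0.16, 0.26, 0.52)
    nowork_not_working_prob: float = 0.975
    season_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    bodyfat_model: BodyfatModel = field(default_factory=BodyfatModel)
    vo2peak_model: Vo2PeakModel = field(default_factory=Vo2PeakModel)
    activity_model: ActivitySpec = field(default_factory=ActivitySpec)
    effects: PlantedEffects = field(default_factory=PlantedEffects)
    variation: PopulationVariation = field(default_factory=PopulationVariation)
    n_days: int = 7
    epoch_seconds: int = 5

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        lo, hi = self.age_range
        if not (20.0 <= lo < hi <= 89.0):
            raise ConfigurationError("age_range must lie within [20, 89]")
        if not 0 <= self.prop_female <= 1:
            raise ConfigurationError("prop_female must be in [0, 1]")
        self.occupation_probs = _check_probs(
            "occupation_probs", self.occupation_probs, 3)
        self.employment_probs = _check_probs(
            "employment_probs", self.employment_probs, 4)
        self.season_probs = _check_probs("season_probs", self.season_probs, 4)
        if SECONDS_PER_DAY % self.epoch_seconds != 0:
            raise ConfigurationError("epoch_seconds must divide 86400")
        if self.n_days < 1:
            raise ConfigurationError("n_days must be >= 1")

    @property
    def age_mid(self) -> float:
        return 0.5 * (self.age_range[0] + self.age_range[1])

    @property
    def age_half(self) -> float:
        return 0.5 * (self.age_range[1] - self.age_range[0])


@dataclass
class ParticipantRecord:
    id: str
    age: float
    sex: str
    occupation: str
    employment: str
    bodyfat_pct: float
    season: str
    vo2peak: float

    def __post_init__(self) -> None:
        if self.vo2peak <= 0:
            raise ValueError("vo2peak must be positive")
        if not 0 < self.bodyfat_pct < 60:
            raise ValueError("bodyfat_pct must be in (0, 60)")

    @property
    def retired(self) -> bool:
        return self.occupation == "no-work-PA" and self.employment == "not working"


@dataclass
class SimulatedCohort:
    """Participant table, epoch traces, and the ground-truth sidecar."""

    participants: pd.DataFrame
    series: dict[str, list[EpochSeries]]
    truth: pd.DataFrame
    spec: CohortSpec


# --------------------------------------------------------------------------
# VO2peak


def generate_vo2peak(
    age: float,
    sex: str,
    model: Vo2PeakModel,
    rng: np.random.Generator,
    bodyfat: float | None = None,
) -> float:
    """One VO2peak draw (mL.kg-1.min-1); strictly positive, floored if needed.

    When ``bodyfat`` is omitted the model reference value is used, so the
    body-fat-mediated part of the sex gap is absent and a zero
    ``sex_log_offset`` yields equal expectations for both sexes.
    """
    bf = model.bodyfat_ref if bodyfat is None else bodyfat
    mu = (
        math.log(model.vo2_ref)
        + model.age_log_slope * (age - model.age_ref)
        + (model.sex_log_offset if sex == "female" else 0.0)
        + model.bodyfat_log_slope * (bf - model.bodyfat_ref)
    )
    eps = rng.normal(0.0, model.resid_log_sd) if model.resid_log_sd > 0 else 0.0
    return max(model.floor, math.exp(mu + eps))


# --------------------------------------------------------------------------
# Epoch traces

_MASK_CACHE: dict[tuple, np.ndarray] = {}


def _sleep_mask(epoch_seconds: int, start_hour: float, end_hour: float) -> np.ndarray:
    key = (epoch_seconds, start_hour, end_hour)
    if key not in _MASK_CACHE:
        n = SECONDS_PER_DAY // epoch_seconds
        hours = np.arange(n) * (epoch_seconds / 3600.0)
        _MASK_CACHE[key] = (hours >= start_hour) | (hours < end_hour)
    return _MASK_CACHE[key]


_CANONICAL_DATES = {
    "weekday": dt.date(2024, 3, 4),
    "saturday": dt.date(2024, 3, 9),
    "sunday": dt.date(2024, 3, 10),
}


def generate_epoch_trace(
    spec: ActivitySpec,
    rng: np.random.Generator,
    *,
    participant_id: str = "sim",
    date: dt.date | None = None,
    day_type: str = "weekday",
    log_multiplier: float = 0.0,
    log_span: float = 0.0,
    alpha: float | None = None,
    epoch_seconds: int = 5,
) -> EpochSeries:
    """One synthetic midnight-to-midnight day of epoch ENMO values.

    ``log_multiplier`` scales the whole trace (volume effects).
    ``log_span`` shifts the person's intensity span: bout intensities are
    scaled by ``exp(log_span)`` while the bout rate is counter-scaled so the
    expected activity volume stays fixed -- a volume-neutral knob for the
    intensity gradient.  ``alpha`` overrides the Pareto tail exponent of
    bout intensities (the mean bout intensity is kept fixed).  Injected
    non-wear zeroes the trace and clears the wear flag.
    """
    if date is None:
        date = _CANONICAL_DATES[day_type]
    n = SECONDS_PER_DAY // epoch_seconds
    sleep = _sleep_mask(epoch_seconds, spec.sleep_start_hour, spec.sleep_end_hour)
    waking_idx = np.flatnonzero(~sleep)
    n_wake = len(waking_idx)

    values = np.empty(n)
    values[sleep] = rng.exponential(spec.sleep_mg, int(sleep.sum()))
    shape = spec.baseline_shape
    if shape == int(shape) and 1 <= shape <= 4:
        # integer-shape gamma as a sum of exponentials (much faster draw)
        base = rng.standard_exponential((int(shape), n_wake)).sum(axis=0)
    else:
        base = rng.standard_gamma(shape, n_wake)
    values[waking_idx] = base * (spec.baseline_mg / shape)

    a = spec.bout_alpha if alpha is None else float(alpha)
    if a <= 1.0:
        raise ConfigurationError("bout intensity exponent must exceed 1")
    waking_hours = n_wake * epoch_seconds / 3600.0
    g = spec.bout_duration_intensity_exp
    # volume-neutral span shift: intensity up, bout rate down.  The
    # compensation exponent is calibrated empirically (duration rounding and
    # baseline masking make the analytic exponent 1-g insufficient).
    rate = spec.bout_rate * math.exp(-log_span * spec.span_volume_comp)
    bout_mean = spec.bout_mean_mg * math.exp(log_span)
    k = int(rng.poisson(rate * waking_hours)) if rate > 0 else 0
    if k > 0 and n_wake > 0:
        starts = rng.integers(0, n_wake, k)
        dur_min = rng.lognormal(
            math.log(spec.bout_duration_median_min), spec.bout_duration_sigma, k
        )
        xm = bout_mean * (a - 1.0) / a
        intensities = xm * (1.0 + rng.pareto(a, k))
        if g:
            # vigorous bouts are shorter: duration scales with intensity^-g
            dur_min = dur_min * (intensities / xm) ** (-g)
        durs = np.maximum(1, np.rint(dur_min * 60.0 / epoch_seconds)).astype(np.int64)
        total = int(durs.sum())
        rep_start = np.repeat(starts, durs)
        offsets = np.arange(total) - np.repeat(np.cumsum(durs) - durs, durs)
        pos = rep_start + offsets
        keep = pos < n_wake
        pos = pos[keep]
        j = spec.bout_jitter_sigma
        jitter = np.exp(rng.normal(-0.5 * j * j, j, total))[keep]
        bout_vals = np.repeat(intensities, durs)[keep] * jitter
        np.maximum.at(values, waking_idx[pos], bout_vals)

    if log_multiplier != 0.0:
        values *= math.exp(log_multiplier)

    wear = np.ones(n, dtype=bool)
    if spec.nonwear_prob_per_day > 0 and rng.random() < spec.nonwear_prob_per_day:
        nw_min = rng.lognormal(
            math.log(spec.nonwear_duration_median_min), spec.nonwear_duration_sigma
        )
        nw_ep = int(min(n, max(1, round(nw_min * 60.0 / epoch_seconds))))
        start = int(rng.integers(0, n - nw_ep + 1))
        wear[start : start + nw_ep] = False
        values[start : start + nw_ep] = 0.0

    return EpochSeries(
        participant_id=participant_id,
        date=date,
        epoch_seconds=epoch_seconds,
        enmo=values,
        wear=wear,
    )


# --------------------------------------------------------------------------
# Cohort assembly


def _nowork_prob(ages: np.ndarray, spec: CohortSpec) -> np.ndarray:
    """Age-ramped probability of the no-work-PA category, matching the marginal."""
    def ramp(a):
        return 1.0 / (1.0 + np.exp(-(a - 67.0) / 3.0))

    lo, hi = spec.age_range
    grid = np.linspace(lo, hi, 2001)
    mean_ramp = float(np.trapezoid(ramp(grid), grid) / (hi - lo))
    p = spec.occupation_probs[1] * ramp(ages) / mean_ramp
    return np.clip(p, 0.0, 0.95)


def _sample_participants(
    spec: CohortSpec, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    n = spec.n_participants
    ages = rng.uniform(spec.age_range[0], spec.age_range[1], n)
    female = rng.random(n) < spec.prop_female
    sex = np.where(female, "female", "male")

    # occupation: age ramp for no-work-PA, sex tilt for moderate vs sit/stand
    p_nw = _nowork_prob(ages, spec)
    p0, _, p2 = spec.occupation_probs
    base_mod = p0 / (p0 + p2)
    r = spec.occupation_sex_ratio
    pf = spec.prop_female
    mm = base_mod / (pf * r + (1.0 - pf))
    p_mod_given_work = np.where(female, r * mm, mm)
    u = rng.random(n)
    occupation = np.where(
        u < p_nw,
        "no-work-PA",
        np.where(
            rng.random(n) < p_mod_given_work, "at-least-moderate-PA", "sitting/standing"
        ),
    )

    employment = np.empty(n, dtype=object)
    emp_probs = np.asarray(spec.employment_probs)
    working_probs = emp_probs[1:] / emp_probs[1:].sum()
    for i in range(n):
        if occupation[i] == "no-work-PA":
            if rng.random() < spec.nowork_not_working_prob:
                employment[i] = "not working"
            else:
                employment[i] = EMPLOYMENT_LEVELS[1:][rng.choice(3, p=working_probs)]
        else:
            employment[i] = EMPLOYMENT_LEVELS[rng.choice(4, p=emp_probs)]

    season = np.asarray(SEASONS, dtype=object)[
        rng.choice(4, size=n, p=spec.season_probs)
    ]

    bf = spec.bodyfat_model
    bodyfat = np.where(
        female,
        rng.normal(bf.female_mean, bf.female_sd, n),
        rng.normal(bf.male_mean, bf.male_sd, n),
    )
    bodyfat = np.clip(bodyfat, bf.lower, bf.upper)

    vm = spec.vo2peak_model
    eps_v = (
        rng.normal(0.0, vm.resid_log_sd, n) if vm.resid_log_sd > 0 else np.zeros(n)
    )
    mu = (
        math.log(vm.vo2_ref)
        + vm.age_log_slope * (ages - vm.age_ref)
        + np.where(female, vm.sex_log_offset, 0.0)
        + vm.bodyfat_log_slope * (bodyfat - vm.bodyfat_ref)
    )
    vo2 = np.maximum(vm.floor, np.exp(mu + eps_v))

    eff, var = spec.effects, spec.variation
    uage = (ages - spec.age_mid) / spec.age_half
    c1, c2, c3 = eff.age_coefs
    f_age = c1 * uage + c2 * uage**2 + c3 * uage**3
    a1, a2 = eff.ig_age_coefs
    g_age = a1 * uage + a2 * uage**2
    # planted targets on (log average acceleration, IG slope) ...
    target_vol = f_age + np.where(female, eff.sex_avacc_log, 0.0)
    target_ig = g_age + np.where(female, eff.sex_ig_slope, 0.0)
    # ... converted to trace knobs, plus person-level noise on the knobs
    # (raw-knob noise makes volume and gradient naturally correlated)
    vol_eff, span_eff = spec.activity_model.effect_knobs(target_vol, target_ig)
    log_mult = (
        vol_eff
        + var.fitness_coupling * eps_v
        + rng.normal(0.0, var.activity_log_sd, n)
    )
    log_span = span_eff + rng.normal(0.0, var.ig_span_sd, n)

    ids = [f"P{i + 1:04d}" for i in range(n)]
    retired = (occupation == "no-work-PA") & (employment == "not working")
    participants = pd.DataFrame(
        {
            "id": ids,
            "age": ages,
            "sex": sex,
            "occupation": occupation,
            "employment": employment,
            "bodyfat_pct": bodyfat,
            "season": season,
            "vo2peak": vo2,
            "retired": retired,
        }
    )
    truth = pd.DataFrame(
        {
            "id": ids,
            "log_activity_multiplier": log_mult,
            "log_intensity_span": log_span,
            "vo2_residual_log": eps_v,
            "age_log_effect": f_age,
        }
    )
    return participants, truth


def _occupation_day_knobs(
    occupation: str, spec: CohortSpec, n_weekday: int, n_weekend: int
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Per-day-type (volume knob, span knob) for the occupation effect.

    The person-level occupation target (on log average acceleration and IG
    slope) loads mostly on weekdays: the weekend carries ``occ_weekend_share``
    of the weekday log effect, scaled so the across-day mean equals the
    target.  Returns ``((vol_weekday, span_weekday), (vol_weekend,
    span_weekend))``.
    """
    eff = spec.effects
    total_vol = {
        "at-least-moderate-PA": 0.0,
        "no-work-PA": eff.occ_nowork_avacc_log,
        "sitting/standing": eff.occ_sitstand_avacc_log,
    }[occupation]
    total_ig = 0.0 if occupation == "at-least-moderate-PA" else eff.occ_ig_slope
    if total_vol == 0.0 and total_ig == 0.0:
        return (0.0, 0.0), (0.0, 0.0)
    n_days = n_weekday + n_weekend
    s = eff.occ_weekend_share
    if n_weekend == 0 or n_weekday == 0:
        scale_w = scale_e = 1.0
    else:
        scale_w = n_days / (n_weekday + s * n_weekend)
        scale_e = s * scale_w
    am = spec.activity_model
    return (
        am.effect_knobs(total_vol * scale_w, total_ig * scale_w),
        am.effect_knobs(total_vol * scale_e, total_ig * scale_e),
    )


def sample_cohort_frame(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Covariates and ground-truth sidecar only (no traces)."""
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.n_participants + 1)
    master = np.random.Generator(np.random.PCG64(children[0]))
    return _sample_participants(spec, master)


def iter_participant_weeks(spec: CohortSpec):
    """Yield ``(participant_row, [EpochSeries, ...])`` one participant at a
    time so a whole cohort never has to be held in memory.

    The stream is bit-identical to :func:`generate_cohort` for the same spec.
    """
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.n_participants + 1)
    master = np.random.Generator(np.random.PCG64(children[0]))
    participants, truth = _sample_participants(spec, master)

    dates = [START_DATE + dt.timedelta(days=j) for j in range(spec.n_days)]
    day_types = [day_type_of(d) for d in dates]
    n_wd = sum(t == "weekday" for t in day_types)
    n_we = spec.n_days - n_wd
    eff = spec.effects
    dt_logs = {"weekday": 0.0, "saturday": eff.saturday_log, "sunday": eff.sunday_log}

    for i, row in enumerate(participants.itertuples(index=False)):
        rng = np.random.Generator(np.random.PCG64(children[i + 1]))
        (vw, sw), (ve, se) = _occupation_day_knobs(row.occupation, spec, n_wd, n_we)
        base = truth["log_activity_multiplier"].iat[i]
        span = truth["log_intensity_span"].iat[i]
        days = []
        for date, dtype in zip(dates, day_types):
            occ_vol, occ_span = (vw, sw) if dtype == "weekday" else (ve, se)
            days.append(
                generate_epoch_trace(
                    spec.activity_model,
                    rng,
                    participant_id=row.id,
                    date=date,
                    log_multiplier=base + occ_vol + dt_logs[dtype],
                    log_span=span + occ_span,
                    epoch_seconds=spec.epoch_seconds,
                )
            )
        yield row, days


def generate_cohort(spec: CohortSpec) -> SimulatedCohort:
    """Generate covariates, VO2peak, and per-day epoch traces for one study.

    Identical spec (including seed) yields bit-identical output.  For large
    cohorts where the traces are immediately reduced to metrics, prefer the
    streaming :func:`iter_participant_weeks`.
    """
    participants, truth = sample_cohort_frame(spec)
    series = {row.id: days for row, days in iter_participant_weeks(spec)}
    dates = [START_DATE + dt.timedelta(days=j) for j in range(spec.n_days)]
    day_types = [day_type_of(d) for d in dates]
    n_wd = sum(t == "weekday" for t in day_types)
    n_we = spec.n_days - n_wd
    knobs = [
        _occupation_day_knobs(occ, spec, n_wd, n_we)
        for occ in participants["occupation"]
    ]
    truth = truth.assign(
        occ_weekday_vol_knob=[k[0][0] for k in knobs],
        occ_weekend_vol_knob=[k[1][0] for k in knobs],
    )
    return SimulatedCohort(
        participants=participants, series=series, truth=truth, spec=spec
    )


def spec_to_dict(spec: CohortSpec) -> dict:
    """Plain-dict view of a spec (for manifests and ground-truth sidecars)."""
    return asdict(spec)
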