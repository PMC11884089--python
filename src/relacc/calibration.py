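"""Calibration of the synthetic generator against its target statistics.

The generator's emergent quantities (cohort medians of average acceleration,
intensity gradient and predicted maximum ENMO; adjusted-model coefficients
for the planted sex and occupation effects) cannot be written down in closed
form, so the mapping from targets to generator parameters is found once by
the routines here -- iterative proportional/secant updates over replicate
simulations -- and frozen into the package defaults.  The routines stay in
the package so the calibration is reproducible and re-runnable after any
change to the trace model.

Calibrated quantities:

* global intensity scale (baseline, sleep and mean bout intensity together)
  and a global intensity-span shift, alternated until the cohort medians of
  average acceleration and intensity gradient hit their targets;
* the 2x2 response matrix of (log average acceleration, IG slope) to the
  two per-person trace knobs (log multiplier, log span), measured by paired
  day simulations and inverted by ``ActivitySpec.effect_knobs`` to convert
  planted effect targets into knob settings;
* the planted sex/occupation targets themselves, centred by
  common-random-number paired replicate runs so the *recovered* adjusted
  coefficients match the target coefficient table.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .cohort import CohortSpec
from .config import vo2_enmo_model
from .pipeline import simulate_tables
from .stats import AnalysisConfig, fit_adjusted_model, person_table


def cohort_person_table(
    spec: CohortSpec,
    metrics: tuple = ("avacc_abs", "ig_abs", "ig_rel"),
    day_filter: str = "all",
) -> pd.DataFrame:
    """Simulate one cohort (streaming) and reduce it to the person-level
    analysis table."""
    daily, parts, _ = simulate_tables(spec, vo2_enmo_model(), metrics)
    return person_table(daily, parts, day_filter)


def cohort_medians(spec: CohortSpec, metrics=("avacc_abs", "ig_abs")) -> dict:
    table = cohort_person_table(spec, metrics)
    out = {
        "avacc_abs": float(table["avacc_abs"].median()),
        "avacc_rel": float(table["avacc_rel"].median()),
        "pred_max_enmo": float(table["max_enmo"].median()),
        "vo2peak": float(table["vo2peak"].median()),
        "sd_log_avacc_abs": float(np.log(table["avacc_abs"]).std(ddof=1)),
        "n": int(len(table)),
    }
    for col in ("ig_abs", "ig_rel"):
        if col in table:
            out[col] = float(table[col].median())
            out[f"sd_{col}"] = float(table[col].std(ddof=1))
    return out


def recover_coefficients(
    spec: CohortSpec,
    dependents: tuple = ("avacc_abs", "avacc_rel", "ig_abs"),
    metrics: tuple = ("avacc_abs", "ig_abs"),
) -> dict:
    """Fit the adjusted models on one simulated cohort; pull out the planted
    contrasts (sex coefficient on the Z scale, sitting/standing percent
    difference, and the CI of the sex coefficient)."""
    table = cohort_person_table(spec, metrics)
    out: dict = {}
    for dep in dependents:
        res = fit_adjusted_model(table, AnalysisConfig(dependent=dep))
        sex = res.coefficients.query("term == 'sex[female]'").iloc[0]
        out[f"sex_{dep}_z"] = float(sex["estimate"])
        out[f"sex_{dep}_ci_low"] = float(sex["ci_low"])
        out[f"sex_{dep}_ci_high"] = float(sex["ci_high"])
        pct = res.percent_diffs.query(
            "contrast == 'occupation[sitting/standing vs at-least-moderate-PA]'"
        )
        if len(pct):
            out[f"occ_sitstand_{dep}_pct"] = float(pct["percent"].iloc[0])
    return out


def replicate_recovery(
    spec: CohortSpec,
    seeds: range,
    dependents: tuple = ("avacc_abs", "avacc_rel", "ig_abs"),
    metrics: tuple = ("avacc_abs", "ig_abs"),
) -> pd.DataFrame:
    """Planted-effect recovery over replicate cohorts (one row per seed)."""
    rows = []
    for s in seeds:
        row = recover_coefficients(
            replace(spec, seed=int(s)), dependents, metrics
        )
        row["seed"] = int(s)
        rows.append(row)
    return pd.DataFrame(rows)


def calibrate_trace_model(
    spec: CohortSpec,
    avacc_target: float,
    ig_target: float,
    n_iter: int = 4,
    verbose: bool = False,
) -> CohortSpec:
    """Alternate scale/shape updates until the cohort medians hit the targets.

    Each iteration (a) rescales all intensity parameters by the ratio of
    target to realized median average acceleration and (b) applies a
    volume-neutral intensity-span shift (bout intensity up, bout rate down)
    sized by the intensity-gradient error; the fitted log-log slope responds
    to the log span with a gain of roughly 0.6-0.7.
    """
    current = spec
    for it in range(n_iter):
        med = cohort_medians(current)
        am = current.activity_model
        dv = (ig_target - med["ig_abs"]) / am.ig_span_gain
        scale = avacc_target / med["avacc_abs"] * np.exp(-am.span_volume_leak * dv)
        am = replace(
            am,
            baseline_mg=am.baseline_mg * scale,
            sleep_mg=am.sleep_mg * scale,
            bout_mean_mg=am.bout_mean_mg * scale * np.exp(dv),
            bout_rate=am.bout_rate * np.exp(-dv * am.span_volume_comp),
        )
        current = replace(current, activity_model=am)
        if verbose:
            print(
                f"iter {it}: avacc {med['avacc_abs']:.2f} ig {med['ig_abs']:.3f}"
                f" -> scale {scale:.3f}, span shift {dv:+.3f}"
            )
    return current


def measure_knob_response(
    activity, n_days: int = 200, probe: float = 0.25, seed: int = 97
) -> dict:
    """Measure the trace-knob response matrix by paired day simulations.

    Returns the gains that :meth:`ActivitySpec.effect_knobs` inverts:
    ``ig_volume_gain`` (IG slope per log whole-trace multiplier),
    ``ig_span_gain`` (IG slope per log span) and ``span_volume_leak``
    (log average acceleration per log span).  These are frozen into the
    activity-model defaults and must be re-measured after any change to the
    trace model.
    """
    from .cohort import generate_epoch_trace
    from .metrics import bin_minutes_abs, ig_from_bin_minutes

    def stats(log_mult: float, log_span: float) -> tuple[float, float]:
        rng = np.random.default_rng(seed)
        avs, igs = [], []
        probe_spec = replace(activity, nonwear_prob_per_day=0.0)
        for _ in range(n_days):
            s = generate_epoch_trace(
                probe_spec, rng, log_multiplier=log_mult, log_span=log_span
            )
            avs.append(s.enmo.mean())
            m, mids = bin_minutes_abs(s)
            igs.append(ig_from_bin_minutes(m, mids).slope)
        return float(np.log(np.mean(avs))), float(np.mean(igs))

    la0, ig0 = stats(-probe, 0.0)
    la1, ig1 = stats(probe, 0.0)
    lb0, igb0 = stats(0.0, -probe)
    lb1, igb1 = stats(0.0, probe)
    return {
        "ig_volume_gain": (ig1 - ig0) / (la1 - la0),
        "ig_span_gain": (igb1 - igb0) / (2 * probe),
        "span_volume_leak": (lb1 - lb0) / (2 * probe),
    }
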