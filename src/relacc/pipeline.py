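"""Config-driven orchestration: generate/ingest -> validity -> metrics -> stats.

``run_pipeline`` executes the full chain in memory and writes delimited-text
outputs plus a JSON manifest (files, counts, checksums, seed).  The staged CLI
verbs (see :mod:`relacc.cli`) use the same building blocks against an output
directory as a working store.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    ActivitySpec,
    BodyfatModel,
    CohortSpec,
    PlantedEffects,
    PopulationVariation,
    SimulatedCohort,
    Vo2PeakModel,
    generate_cohort,
    spec_to_dict,
)
from .config import vo2_enmo_model
from .epochs import EpochSeries, read_epoch_file, write_epoch_file
from .metrics import (
    MX_GRID,
    MissingDataError,
    avacc_abs,
    ig_abs,
    mx_profile,
)
from .relative import NonPositiveCapacityError, Vo2EnmoModel, ig_rel, predict_max_enmo
from .stats import AnalysisConfig, ModelResult, fit_adjusted_model, person_table
from .validity import decide_inclusion, impute_participant

log = logging.getLogger("relacc")

DEFAULT_METRICS = ("avacc_abs", "ig_abs", "ig_rel")

#: in-memory name -> written (units-suffixed) column name for person tables
EXTERNAL_COLUMNS = {
    "avacc_abs": "avacc_abs_mg",
    "max_enmo": "max_enmo_mg",
    "avacc_rel": "avacc_rel_pct",
    "day_filter": "filter",
}


def to_external(person: pd.DataFrame) -> pd.DataFrame:
    return person.rename(columns=EXTERNAL_COLUMNS)


def from_external(person: pd.DataFrame) -> pd.DataFrame:
    return person.rename(columns={v: k for k, v in EXTERNAL_COLUMNS.items()})


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and participant."""


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    mode: str = "simulate"  # simulate | ingest
    output_dir: str = "relacc_out"
    seed: int = 0
    cohort: dict = field(default_factory=dict)  # CohortSpec overrides
    input_dir: str | None = None  # ingest: epoch files + participants.csv
    vo2_enmo_model: str | None = None
    metrics: tuple = DEFAULT_METRICS
    mx_grid: tuple | None = None
    analyses: list = field(default_factory=lambda: [{"dependent": "avacc_abs"}])
    write_epoch_files: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text("utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def build_cohort_spec(self) -> CohortSpec:
        over = dict(self.cohort)
        nested = {
            "activity_model": ActivitySpec,
            "vo2peak_model": Vo2PeakModel,
            "bodyfat_model": BodyfatModel,
            "effects": PlantedEffects,
            "variation": PopulationVariation,
        }
        kwargs = {}
        for key, val in over.items():
            if key in nested and isinstance(val, dict):
                kwargs[key] = nested[key](**val)
            else:
                kwargs[key] = tuple(val) if isinstance(val, list) else val
        kwargs.setdefault("seed", self.seed)
        return CohortSpec(**kwargs)


# --------------------------------------------------------------------------
# metric computation over a cohort


def participant_daily_metrics(
    days: list[EpochSeries],
    metrics: tuple = DEFAULT_METRICS,
    mx_grid: tuple = MX_GRID,
    max_enmo: float | None = None,
) -> list[dict]:
    """Per-day metric rows for one included participant (imputed days)."""
    rows = []
    for day in days:
        row: dict = {
            "id": day.participant_id,
            "date": day.date.isoformat(),
            "day_type": day.day_type,
        }
        row["avacc_abs"] = avacc_abs(day)
        if "ig_abs" in metrics:
            ig = ig_abs(day)
            row["ig_abs"] = ig.slope
            row["ig_abs_intercept"] = ig.intercept
            row["ig_abs_r2"] = ig.r_squared
            row["ig_abs_nbins"] = ig.n_bins_used
        if "ig_rel" in metrics and max_enmo is not None and np.isfinite(max_enmo):
            igr = ig_rel(day, max_enmo)
            row["ig_rel"] = igr.slope
            row["ig_rel_r2"] = igr.r_squared
        if "mx" in metrics:
            for x, v in mx_profile(day, mx_grid).items():
                row[f"m{x}"] = v
        rows.append(row)
    return rows


def add_max_enmo(
    participants: pd.DataFrame, model: Vo2EnmoModel
) -> pd.DataFrame:
    """Append the predicted maximum ENMO column (NaN when non-positive)."""
    out = participants.copy()
    max_vals = []
    for v in out["vo2peak"]:
        try:
            max_vals.append(predict_max_enmo(float(v), model))
        except NonPositiveCapacityError:
            max_vals.append(np.nan)
    out["max_enmo"] = max_vals
    return out


def cohort_tables(
    series_by_id: dict[str, list[EpochSeries]],
    participants: pd.DataFrame,
    vo2_model: Vo2EnmoModel | None = None,
    metrics: tuple = DEFAULT_METRICS,
    mx_grid: tuple = MX_GRID,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Validity -> imputation -> daily metrics for a whole cohort.

    Returns ``(daily, participants_with_max_enmo, inclusion_report)``; the
    daily table contains only included participants.
    """
    if vo2_model is None:
        vo2_model = vo2_enmo_model()
    parts = add_max_enmo(participants, vo2_model)
    max_by_id = dict(zip(parts["id"], parts["max_enmo"]))
    incl_rows = []
    daily_rows: list[dict] = []
    for pid, days in series_by_id.items():
        incl, rows = _process_participant(
            pid, days, metrics, mx_grid, max_by_id.get(pid)
        )
        incl_rows.append(incl)
        daily_rows.extend(rows)
    inclusion = pd.DataFrame(incl_rows)
    daily = pd.DataFrame(daily_rows)
    return daily, parts, inclusion


def _process_participant(pid, days, metrics, mx_grid, max_enmo):
    decision = decide_inclusion(days)
    reasons = list(decision.reasons)
    rows: list[dict] = []
    if decision.included:
        imputed = impute_participant(days)
        valid = [d for d, v in zip(imputed, days) if _is_valid(v)]
        try:
            rows = participant_daily_metrics(valid, metrics, mx_grid, max_enmo)
        except MissingDataError as exc:
            reasons.append(f"unimputable epochs: {exc}")
            decision.included = False
            rows = []
    incl = {
        "participant_id": pid,
        "n_valid_weekdays": decision.n_valid_weekdays,
        "n_valid_saturdays": decision.n_valid_saturdays,
        "n_valid_sundays": decision.n_valid_sundays,
        "coverage_ok": decision.coverage_ok,
        "included": decision.included,
        "reasons": "; ".join(reasons),
    }
    return incl, rows


def simulate_tables(
    spec,
    vo2_model: Vo2EnmoModel | None = None,
    metrics: tuple = DEFAULT_METRICS,
    mx_grid: tuple = MX_GRID,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Streaming equivalent of ``generate_cohort`` + :func:`cohort_tables`.

    Generates one participant-week at a time and reduces it to metrics
    immediately, so cohort-scale runs never hold all traces in memory.
    Output is identical to the non-streaming path for the same spec.
    """
    from .cohort import iter_participant_weeks, sample_cohort_frame

    if vo2_model is None:
        vo2_model = vo2_enmo_model()
    participants, _ = sample_cohort_frame(spec)
    parts = add_max_enmo(participants, vo2_model)
    max_by_id = dict(zip(parts["id"], parts["max_enmo"]))
    incl_rows = []
    daily_rows: list[dict] = []
    for row, days in iter_participant_weeks(spec):
        incl, rows = _process_participant(
            row.id, days, metrics, mx_grid, max_by_id.get(row.id)
        )
        incl_rows.append(incl)
        daily_rows.extend(rows)
    return pd.DataFrame(daily_rows), parts, pd.DataFrame(incl_rows)


def _is_valid(day: EpochSeries) -> bool:
    from .validity import assess_day

    return assess_day(day).valid


# --------------------------------------------------------------------------
# staged I/O helpers


def write_cohort(cohort: SimulatedCohort, outdir: Path, epoch_files: bool) -> list[Path]:
    written = []
    outdir.mkdir(parents=True, exist_ok=True)
    p = outdir / "participants.csv"
    cohort.participants.to_csv(p, index=False)
    written.append(p)
    t = outdir / "ground_truth.csv"
    cohort.truth.to_csv(t, index=False)
    written.append(t)
    s = outdir / "cohort_spec.json"
    s.write_text(json.dumps(spec_to_dict(cohort.spec), indent=2, default=str))
    written.append(s)
    if epoch_files:
        edir = outdir / "epochs"
        edir.mkdir(exist_ok=True)
        for pid, days in cohort.series.items():
            for day in days:
                f = edir / f"{pid}_{day.date.isoformat()}.csv"
                write_epoch_file(day, f)
                written.append(f)
    return written


def read_epoch_dir(path: Path) -> dict[str, list[EpochSeries]]:
    series: dict[str, list[EpochSeries]] = {}
    for f in sorted(path.glob("*.csv")):
        s = read_epoch_file(f)
        series.setdefault(s.participant_id, []).append(s)
    if not series:
        raise PipelineError(f"no epoch files found under {path}")
    return series


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# --------------------------------------------------------------------------
# full run


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order; returns (and writes) the run manifest.

    Re-running the same config and seed in simulate mode is bit-identical.
    Any stage error aborts with the stage name (and participant where known).
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    stage = "generate" if config.mode == "simulate" else "ingest"
    try:
        if config.mode == "simulate":
            spec = config.build_cohort_spec()
            cohort = generate_cohort(spec)
            series, participants = cohort.series, cohort.participants
            written += write_cohort(cohort, outdir, config.write_epoch_files)
        elif config.mode == "ingest":
            if not config.input_dir:
                raise PipelineError("ingest mode requires input_dir")
            indir = Path(config.input_dir)
            participants = pd.read_csv(indir / "participants.csv")
            if "retired" not in participants.columns:
                participants["retired"] = (
                    participants["occupation"].eq("no-work-PA")
                    & participants["employment"].eq("not working")
                )
            series = read_epoch_dir(indir / "epochs")
        else:
            raise PipelineError(f"unknown mode {config.mode!r}")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    stage = "metrics"
    vo2m = vo2_enmo_model(config.vo2_enmo_model)
    mx_grid = tuple(config.mx_grid) if config.mx_grid else MX_GRID
    try:
        daily, parts, inclusion = cohort_tables(
            series, participants, vo2m, tuple(config.metrics), mx_grid
        )
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    f = outdir / "inclusion_report.csv"
    inclusion.to_csv(f, index=False)
    written.append(f)
    f = outdir / "daily_metrics.csv"
    daily.to_csv(f, index=False)
    written.append(f)
    person = person_table(daily, parts, "all")
    f = outdir / "person_metrics.csv"
    to_external(person).to_csv(f, index=False)
    written.append(f)

    stage = "stats"
    model_summaries = {}
    for analysis in config.analyses:
        cfg = AnalysisConfig(**analysis)
        try:
            if cfg.day_filter == "all":
                result = fit_adjusted_model(person, cfg)
            else:
                result = fit_adjusted_model(
                    person_table(daily, parts, cfg.day_filter), cfg
                )
        except Exception as exc:
            raise PipelineError(
                f"stage 'stats' ({cfg.dependent}) failed: {exc}"
            ) from exc
        written += write_model_result(result, outdir)
        sexrow = result.coefficients.query("term == 'sex[female]'")
        model_summaries[cfg.dependent] = {
            "n": result.diagnostics["n"],
            "sex_female_estimate": (
                float(sexrow["estimate"].iloc[0]) if len(sexrow) else None
            ),
        }

    import statsmodels

    manifest = {
        "relacc_version": __version__,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
        },
        "mode": config.mode,
        "seed": config.seed,
        "n_participants": int(len(participants)),
        "n_included": int(inclusion["included"].sum()),
        "models": model_summaries,
        "files": {
            str(p.relative_to(outdir)): {
                "sha256": _sha256(p),
                "bytes": p.stat().st_size,
            }
            for p in written
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def write_model_result(result: ModelResult, outdir: Path) -> list[Path]:
    written = []
    base = f"model_{result.dependent}"
    filt = result.provenance["config"].get("day_filter", "all")
    if filt != "all":
        base += f"_{filt}"
    if result.provenance["config"].get("exclude_retired"):
        base += "_noretired"
    for name, frame in (
        ("coefficients", result.coefficients),
        ("percent_diffs", result.percent_diffs),
        ("marginal_means", result.marginal_means),
        ("age_curve", result.age_curve),
    ):
        f = outdir / f"{base}_{name}.csv"
        frame.to_csv(f, index=False)
        written.append(f)
    f = outdir / f"{base}_diagnostics.json"
    f.write_text(json.dumps(result.diagnostics, indent=2))
    written.append(f)
    return written
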