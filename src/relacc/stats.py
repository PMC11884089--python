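"""Cohort-level inference on the four cut-point-free metrics.

Implements the study's inferential layer: Z-transformation of dependent
metrics, Spearman/PCA overlap analysis, adjusted OLS models with third-degree
orthogonal polynomials for continuous covariates, effect-size categories on
the Z scale, marginal means and percent differences, adjusted MX group
profiles, and the sensitivity variants (weekday-only, weekend-only, retired
excluded).

The adjustment set is fixed to the study's six variables: age, sex,
occupation type, body fat percentage, season, and level of employment; no
multiple-testing correction is applied (plain 95% CIs are reported).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

EFFECT_BOUNDS = ((0.1, "small"), (0.3, "medium"), (0.5, "large"))

OCCUPATION_REF = "at-least-moderate-PA"
SEASON_REF = "spring"
EMPLOYMENT_REF = "100%"

DEFAULT_METRICS = ("avacc_rel", "avacc_abs", "ig_rel", "ig_abs")

AGE_BANDS = ((20, 40), (41, 60), (61, 90))


def z_transform(values) -> np.ndarray:
    """Center to mean 0 and scale to sample SD 1 (ddof=1)."""
    x = np.asarray(values, dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("z_transform requires at least two distinct values")
    return (x - x.mean()) / x.std(ddof=1)


def categorize_effect(estimate: float) -> str:
    """Z-scale effect-size category: negligible / small / medium / large.

    Thresholds are left-closed at |estimate| = 0.1, 0.3 and 0.5.
    """
    if not np.isfinite(estimate):
        raise ValueError("estimate must be finite")
    mag = abs(estimate)
    category = "negligible"
    for bound, name in EFFECT_BOUNDS:
        if mag >= bound:
            category = name
    return category


class OrthoPoly:
    """Orthonormal polynomial basis via the three-term recurrence.

    Equivalent to R's ``poly()``: fitted on the observed values, evaluable at
    new points, numerically stable at degree 3 and beyond.  The constant term
    is dropped from the returned design columns.
    """

    def __init__(self, x, degree: int):
        x = np.asarray(x, dtype=float)
        if degree < 1:
            raise ValueError("degree must be >= 1")
        if len(np.unique(x)) <= degree:
            raise ValueError("need more distinct x values than the degree")
        self.degree = degree
        P = np.empty((len(x), degree + 1))
        P[:, 0] = 1.0
        alpha = np.empty(degree)
        norm2 = np.empty(degree + 1)
        norm2[0] = float(len(x))
        for j in range(degree):
            pj = P[:, j]
            alpha[j] = (x * pj * pj).sum() / norm2[j]
            pnew = (x - alpha[j]) * pj
            if j > 0:
                pnew = pnew - (norm2[j] / norm2[j - 1]) * P[:, j - 1]
            P[:, j + 1] = pnew
            norm2[j + 1] = (pnew * pnew).sum()
        self.alpha = alpha
        self.norm2 = norm2

    def transform(self, xnew) -> np.ndarray:
        xnew = np.atleast_1d(np.asarray(xnew, dtype=float))
        P = np.empty((len(xnew), self.degree + 1))
        P[:, 0] = 1.0
        for j in range(self.degree):
            pnew = (xnew - self.alpha[j]) * P[:, j]
            if j > 0:
                pnew = pnew - (self.norm2[j] / self.norm2[j - 1]) * P[:, j - 1]
            P[:, j + 1] = pnew
        return P[:, 1:] / np.sqrt(self.norm2[1:])


@dataclass
class AnalysisConfig:
    dependent: str = "avacc_abs"
    z_transform: bool = True
    log_before_z: str = "auto"  # auto | always | never
    polynomial_degree: int = 3
    day_filter: str = "all"     # all | weekdays | weekend
    exclude_retired: bool = False
    skew_threshold: float = 1.0
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.log_before_z not in ("auto", "always", "never"):
            raise ValueError("log_before_z must be auto, always or never")
        if self.day_filter not in ("all", "weekdays", "weekend"):
            raise ValueError("day_filter must be all, weekdays or weekend")


@dataclass
class ModelResult:
    """Adjusted-model output: coefficient table and derived summaries.

    ``coefficients`` is on the model (Z) scale; ``percent_diffs`` expresses
    the sex and occupation contrasts on the metric's natural scale;
    ``marginal_means`` are occupation means on a balanced categorical grid
    with continuous covariates at their observed means; ``age_curve`` is the
    model-implied age trajectory on the Z scale.
    """

    dependent: str
    coefficients: pd.DataFrame
    percent_diffs: pd.DataFrame
    marginal_means: pd.DataFrame
    age_curve: pd.DataFrame
    diagnostics: dict
    provenance: dict


@dataclass
class OverlapResult:
    spearman: pd.DataFrame
    variance_fractions: np.ndarray
    loadings: pd.DataFrame


def _dummies(df: pd.DataFrame, col: str, ref: str) -> tuple[np.ndarray, list[str]]:
    levels = sorted(df[col].unique())
    if len(levels) < 2:
        raise ValueError(
            f"column {col!r} has a single level ({levels[0]!r}); "
            "cannot adjust for it"
        )
    others = [lv for lv in levels if lv != ref]
    if len(others) == len(levels):
        # reference absent; fall back to first level as reference
        ref = levels[0]
        others = levels[1:]
    cols = np.column_stack([(df[col] == lv).astype(float) for lv in others])
    names = [f"{col}[{lv}]" for lv in others]
    return cols, names


@dataclass
class _Design:
    X: np.ndarray
    names: list[str]
    age_poly: OrthoPoly
    bf_poly: OrthoPoly
    cat_levels: dict[str, list[str]]
    refs: dict[str, str]
    means: dict[str, float]


def _build_design(df: pd.DataFrame, degree: int) -> _Design:
    n = len(df)
    cols = [np.ones((n, 1))]
    names = ["const"]
    sx, sn = _dummies(df, "sex", "male")
    cols.append(sx)
    names.extend(sn)
    ox, on = _dummies(df, "occupation", OCCUPATION_REF)
    cols.append(ox)
    names.extend(on)
    age_poly = OrthoPoly(df["age"].to_numpy(), degree)
    cols.append(age_poly.transform(df["age"].to_numpy()))
    names.extend([f"age^{k}" for k in range(1, degree + 1)])
    bf_poly = OrthoPoly(df["bodyfat_pct"].to_numpy(), degree)
    cols.append(bf_poly.transform(df["bodyfat_pct"].to_numpy()))
    names.extend([f"bodyfat^{k}" for k in range(1, degree + 1)])
    ssx, ssn = _dummies(df, "season", SEASON_REF)
    cols.append(ssx)
    names.extend(ssn)
    ex, en = _dummies(df, "employment", EMPLOYMENT_REF)
    cols.append(ex)
    names.extend(en)
    X = np.hstack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        culprits = [
            names[j]
            for j in range(1, X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == np.linalg.matrix_rank(X)
        ]
        raise ValueError(
            "design matrix is rank deficient; collinear term(s): "
            + (", ".join(culprits) or "unidentified")
        )
    cat_levels = {
        c: sorted(df[c].unique()) for c in ("sex", "occupation", "season", "employment")
    }
    refs = {
        "sex": "male",
        "occupation": OCCUPATION_REF,
        "season": SEASON_REF,
        "employment": EMPLOYMENT_REF,
    }
    means = {"age": float(df["age"].mean()), "bodyfat_pct": float(df["bodyfat_pct"].mean())}
    return _Design(X, names, age_poly, bf_poly, cat_levels, refs, means)


def _grid_row(
    design: _Design,
    *,
    occupation: str | dict | None = None,
    sex: str | dict | None = None,
    age: float | None = None,
) -> np.ndarray:
    """One prediction row: balanced categorical weights, means for continuous."""

    def weights(col: str, setting) -> dict[str, float]:
        levels = design.cat_levels[col]
        if setting is None:
            return {lv: 1.0 / len(levels) for lv in levels}
        if isinstance(setting, str):
            return {setting: 1.0}
        return setting

    row: dict[str, float] = {"const": 1.0}
    for col, setting in (
        ("sex", sex),
        ("occupation", occupation),
        ("season", None),
        ("employment", None),
    ):
        w = weights(col, setting)
        for lv, p in w.items():
            name = f"{col}[{lv}]"
            if lv != design.refs[col] and p:
                row[name] = p
    age_val = design.means["age"] if age is None else age
    for k, v in enumerate(design.age_poly.transform(age_val)[0], start=1):
        row[f"age^{k}"] = v
    for k, v in enumerate(design.bf_poly.transform(design.means["bodyfat_pct"])[0], start=1):
        row[f"bodyfat^{k}"] = v
    return np.array([row.get(name, 0.0) for name in design.names])


def _near_zero_flag(lo: float, hi: float) -> bool:
    """Flag when a CI limit lies within +-5% of the interval width of zero."""
    width = hi - lo
    tol = 0.05 * width
    return abs(lo) <= tol or abs(hi) <= tol


def _prepare_dependent(
    df: pd.DataFrame, config: AnalysisConfig, design: _Design
) -> tuple[np.ndarray, dict]:
    raw = df[config.dependent].to_numpy(dtype=float)
    if not np.isfinite(raw).all():
        raise ValueError(f"dependent {config.dependent!r} contains missing values")
    positive = bool((raw > 0).all())
    log_applied = False
    if config.log_before_z == "always":
        if not positive:
            raise ValueError("log transform requested on non-positive values")
        log_applied = True
    elif config.log_before_z == "auto" and positive:
        # deterministic stand-in for visual residual diagnostics
        probe = sm.OLS(z_transform(raw) if config.z_transform else raw, design.X).fit()
        log_applied = bool(
            abs(scipy.stats.skew(probe.resid)) > config.skew_threshold
        )
    y_nat = np.log(raw) if log_applied else raw
    scale = {
        "log_applied": log_applied,
        "nat_mean": float(y_nat.mean()),
        "nat_sd": float(y_nat.std(ddof=1)),
        "raw_mean": float(raw.mean()),
    }
    y = z_transform(y_nat) if config.z_transform else y_nat
    return y, scale


def fit_adjusted_model(table: pd.DataFrame, config: AnalysisConfig) -> ModelResult:
    """Adjusted OLS of one (Z-transformed) metric on the six study covariates.

    The dependent may be log-transformed before Z-transformation (``always``)
    or when the residual skewness of the untransformed fit exceeds the
    configured threshold (``auto``).  Percent differences are computed on the
    natural scale: back-transformed when the log was applied, otherwise
    relative to the magnitude of the reference-group model-implied mean.
    """
    df = table
    if config.exclude_retired:
        df = df.loc[~df["retired"].astype(bool)]
    df = df.reset_index(drop=True)
    design = _build_design(df, config.polynomial_degree)
    y, scale = _prepare_dependent(df, config, design)
    fit = sm.OLS(y, design.X).fit()
    ci = fit.conf_int(alpha=1 - config.ci_level)

    # original-scale companion values: undo the Z scaling (these stay on the
    # log scale when the log was applied; the percent table is the
    # back-transformed view)
    nat = scale["nat_sd"] if config.z_transform else 1.0
    rows = []
    for i, name in enumerate(design.names):
        lo, hi = float(ci[i, 0]), float(ci[i, 1])
        est = float(fit.params[i])
        is_contrast = "[" in name
        rows.append(
            {
                "term": name,
                "estimate": est,
                "ci_low": lo,
                "ci_high": hi,
                "estimate_original": est * nat,
                "ci_low_original": lo * nat,
                "ci_high_original": hi * nat,
                "near_zero_flag": _near_zero_flag(lo, hi),
                "effect_size": categorize_effect(est)
                if (is_contrast and config.z_transform)
                else "",
            }
        )
    coef = pd.DataFrame(rows)

    cov = np.asarray(fit.cov_params())
    zcrit = scipy.stats.norm.ppf(0.5 + config.ci_level / 2)

    def marginal(row_vec: np.ndarray) -> tuple[float, float]:
        est = float(row_vec @ fit.params)
        se = float(np.sqrt(row_vec @ cov @ row_vec))
        return est, se

    # occupation marginal means
    mm_rows = []
    occ_rows = {}
    for lv in design.cat_levels["occupation"]:
        rv = _grid_row(design, occupation=lv)
        occ_rows[lv] = rv
        est, se = marginal(rv)
        mm_rows.append({"occupation": lv, "mean": est, "se": se})
    marginal_means = pd.DataFrame(mm_rows)

    # percent differences on the natural scale
    def pct_contrast(label: str, rv_g: np.ndarray, rv_ref: np.ndarray) -> dict:
        c = rv_g - rv_ref
        diff = float(c @ fit.params)
        se = float(np.sqrt(c @ cov @ c))
        lo, hi = diff - zcrit * se, diff + zcrit * se
        sd = scale["nat_sd"] if config.z_transform else 1.0
        if scale["log_applied"]:
            conv = lambda d: 100.0 * (np.exp(d * sd) - 1.0)
        else:
            m_ref = float(rv_ref @ fit.params) * sd + (
                scale["nat_mean"] if config.z_transform else 0.0
            )
            if m_ref == 0:
                raise ZeroDivisionError("reference marginal mean is zero")
            conv = lambda d: 100.0 * d * sd / abs(m_ref)
        return {
            "contrast": label,
            "percent": conv(diff),
            "ci_low": conv(lo),
            "ci_high": conv(hi),
        }

    pct_rows = []
    ref_occ = design.refs["occupation"]
    if ref_occ in occ_rows:
        for lv in design.cat_levels["occupation"]:
            if lv != ref_occ:
                pct_rows.append(
                    pct_contrast(f"occupation[{lv} vs {ref_occ}]", occ_rows[lv], occ_rows[ref_occ])
                )
    if "female" in design.cat_levels["sex"] and "male" in design.cat_levels["sex"]:
        pct_rows.append(
            pct_contrast(
                "sex[female vs male]",
                _grid_row(design, sex="female"),
                _grid_row(design, sex="male"),
            )
        )
    percent_diffs = pd.DataFrame(pct_rows)

    ages = np.arange(
        np.floor(df["age"].min()), np.ceil(df["age"].max()) + 1.0
    )
    curve_rows = []
    for a in ages:
        est, se = marginal(_grid_row(design, age=float(a)))
        curve_rows.append({"age": float(a), "mean": est, "se": se})
    age_curve = pd.DataFrame(curve_rows)

    diagnostics = {
        "n": int(len(df)),
        "r_squared": float(fit.rsquared),
        "residual_skewness": float(scipy.stats.skew(fit.resid)),
        **scale,
    }
    return ModelResult(
        dependent=config.dependent,
        coefficients=coef,
        percent_diffs=percent_diffs,
        marginal_means=marginal_means,
        age_curve=age_curve,
        diagnostics=diagnostics,
        provenance={"config": asdict(config)},
    )


def metric_overlap(
    table: pd.DataFrame, columns: tuple[str, ...] = DEFAULT_METRICS
) -> OverlapResult:
    """Spearman correlations and PCA of the four cut-point-free metrics.

    PCA is the eigendecomposition of the Pearson correlation matrix of the
    standardized metrics; variance fractions sum to one by construction.
    """
    sub = table.loc[:, list(columns)].astype(float)
    if sub.isna().any().any():
        raise ValueError("metric columns contain missing values")
    rho, _ = scipy.stats.spearmanr(sub.to_numpy())
    rho = np.atleast_2d(rho)
    spearman = pd.DataFrame(rho, index=columns, columns=columns)
    corr = np.corrcoef(sub.to_numpy(), rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    # orient each component so its largest-magnitude loading is positive
    for j in range(eigvec.shape[1]):
        if eigvec[np.argmax(np.abs(eigvec[:, j])), j] < 0:
            eigvec[:, j] *= -1
    fractions = eigval / eigval.sum()
    loadings = pd.DataFrame(
        eigvec, index=columns, columns=[f"PC{j + 1}" for j in range(len(columns))]
    )
    return OverlapResult(spearman=spearman, variance_fractions=fractions, loadings=loadings)


def assign_age_band(age) -> str:
    """Band a continuous age into 20-40 / 41-60 / 61-90 (cut at 40 and 60)."""
    if age < AGE_BANDS[0][0] or age > AGE_BANDS[-1][1]:
        raise ValueError(f"age {age} outside the {AGE_BANDS} bands")
    if age <= 40:
        return "20-40"
    if age <= 60:
        return "41-60"
    return "61-90"


def mx_group_profiles(
    table: pd.DataFrame,
    grouping: str,
    scale: str = "z",
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Adjusted MX curves per group with uncertainty bands.

    ``grouping`` is one of ``age_band``, ``sex``, ``occupation``.  For every
    MX column (``m<X>`` or ``rel_m<X>``) the grouping variable is the
    exposure in a model adjusted for body fat, season and employment
    (plus the grouping variable itself); group means are marginal means on a
    balanced categorical grid.  With ``scale='z'`` each MX column is
    Z-transformed across the cohort first.
    """
    if grouping not in ("age_band", "sex", "occupation"):
        raise ValueError("grouping must be age_band, sex or occupation")
    df = table.copy().reset_index(drop=True)
    if grouping == "age_band":
        df["age_band"] = [assign_age_band(a) for a in df["age"]]
    levels = sorted(df[grouping].unique())
    if len(levels) < 2:
        raise ValueError(f"grouping {grouping!r} has a single level")
    mx_cols = [c for c in df.columns if _is_mx_column(c)]
    if not mx_cols:
        raise ValueError("no MX columns (m<X> / rel_m<X>) in the table")

    n = len(df)
    cols = [np.ones((n, 1))]
    names = ["const"]
    gx, gn = _dummies(df, grouping, levels[0])
    cols.append(gx)
    names.extend(gn)
    bf_poly = OrthoPoly(df["bodyfat_pct"].to_numpy(), 3)
    cols.append(bf_poly.transform(df["bodyfat_pct"].to_numpy()))
    names.extend([f"bodyfat^{k}" for k in (1, 2, 3)])
    for cat, ref in (("season", SEASON_REF), ("employment", EMPLOYMENT_REF)):
        cx, cn = _dummies(df, cat, ref)
        cols.append(cx)
        names.extend(cn)
    X = np.hstack(cols)
    zcrit = scipy.stats.norm.ppf(0.5 + ci_level / 2)

    cat_levels = {c: sorted(df[c].unique()) for c in ("season", "employment")}

    def grid_row(level: str) -> np.ndarray:
        row = {"const": 1.0, f"{grouping}[{level}]": 1.0}
        for k, v in enumerate(bf_poly.transform(df["bodyfat_pct"].mean())[0], start=1):
            row[f"bodyfat^{k}"] = v
        for cat in ("season", "employment"):
            for lv in cat_levels[cat]:
                row.setdefault(f"{cat}[{lv}]", 1.0 / len(cat_levels[cat]))
        return np.array([row.get(nm, 0.0) for nm in names])

    out = []
    for col in mx_cols:
        y = df[col].to_numpy(dtype=float)
        if scale == "z":
            y = z_transform(y)
        fit = sm.OLS(y, X).fit()
        cov = np.asarray(fit.cov_params())
        for lv in levels:
            rv = grid_row(lv)
            est = float(rv @ fit.params)
            se = float(np.sqrt(rv @ cov @ rv))
            out.append(
                {
                    "metric": col,
                    "minutes": int(col.split("m")[-1]),
                    "group": lv,
                    "mean": est,
                    "se": se,
                    "ci_low": est - zcrit * se,
                    "ci_high": est + zcrit * se,
                }
            )
    return pd.DataFrame(out)


def _is_mx_column(name: str) -> bool:
    for prefix in ("rel_m", "m"):
        if name.startswith(prefix) and name[len(prefix):].isdigit():
            return True
    return False


# --------------------------------------------------------------------------
# person-level aggregation and sensitivity variants


def person_table(
    daily: pd.DataFrame, participants: pd.DataFrame, day_filter: str = "all"
) -> pd.DataFrame:
    """Aggregate a tidy per-day metric table to the person level and join
    covariates.

    ``daily`` has one row per included participant-day with metric columns
    (``avacc_abs``, ``ig_abs``, optionally ``ig_rel`` and MX columns);
    ``participants`` carries covariates plus ``max_enmo`` when relative
    metrics are wanted.  Relative volume metrics are derived after averaging
    (``avacc_rel = 100 * avacc_abs / max_enmo``, likewise per MX duration).
    """
    if day_filter == "all":
        kept = daily
    elif day_filter == "weekdays":
        kept = daily.loc[daily["day_type"] == "weekday"]
    elif day_filter == "weekend":
        kept = daily.loc[daily["day_type"].isin(["saturday", "sunday"])]
    else:
        raise ValueError(f"unknown day filter {day_filter!r}")
    if kept.empty:
        raise ValueError(f"no days remain after filter {day_filter!r}")
    metric_cols = [
        c for c in kept.columns if c not in ("id", "date", "day_type")
    ]
    agg = kept.groupby("id", sort=True)[metric_cols].mean()
    agg["n_valid_days"] = kept.groupby("id").size()
    out = participants.merge(agg, left_on="id", right_index=True, how="inner")
    if "max_enmo" in out.columns:
        out["avacc_rel"] = 100.0 * out["avacc_abs"] / out["max_enmo"]
        for col in [c for c in metric_cols if _is_mx_column(c) and not c.startswith("rel_")]:
            out[f"rel_{col}"] = 100.0 * out[col] / out["max_enmo"]
    out["day_filter"] = day_filter
    return out.reset_index(drop=True)


def run_sensitivity(
    daily: pd.DataFrame,
    participants: pd.DataFrame,
    variant: str,
    config: AnalysisConfig,
) -> ModelResult:
    """Re-run the adjusted model under one sensitivity variant.

    ``weekdays_only`` / ``weekend_only`` restrict the days averaged into the
    person-level metrics; ``exclude_retired`` drops retired participants.
    The dependent is re-standardised within each run.
    """
    if variant == "weekdays_only":
        cfg = AnalysisConfig(**{**asdict(config), "day_filter": "weekdays"})
    elif variant == "weekend_only":
        cfg = AnalysisConfig(**{**asdict(config), "day_filter": "weekend"})
    elif variant == "exclude_retired":
        cfg = AnalysisConfig(**{**asdict(config), "exclude_retired": True})
    else:
        raise ValueError(f"unknown sensitivity variant {variant!r}")
    table = person_table(daily, participants, cfg.day_filter)
    return fit_adjusted_model(table, cfg)
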