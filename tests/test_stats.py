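import numpy as np
import pandas as pd
import pytest

from relacc import (
    AnalysisConfig,
    categorize_effect,
    fit_adjusted_model,
    metric_overlap,
    mx_group_profiles,
    person_table,
    run_sensitivity,
    z_transform,
)
from relacc.stats import OrthoPoly, _near_zero_flag


def synthetic_table(n=400, seed=0, sex_shift=0.0, occ_shift=0.0):
    """Person-level analysis table with a known additive structure (no trace
    generation; used to exercise the model layer in isolation)."""
    rng = np.random.default_rng(seed)
    age = rng.uniform(20, 89, n)
    sex = np.where(rng.random(n) < 0.5, "female", "male")
    occupation = rng.choice(
        ["at-least-moderate-PA", "no-work-PA", "sitting/standing"],
        size=n,
        p=[0.3, 0.2, 0.5],
    )
    season = rng.choice(["spring", "summer", "autumn", "winter"], size=n)
    employment = rng.choice(
        ["not working", "10-50%", "60-90%", "100%"], size=n, p=[0.2, 0.2, 0.2, 0.4]
    )
    bodyfat = rng.normal(23, 6, n)
    y = (
        30.0
        + 0.05 * (age - 55)
        + sex_shift * (sex == "female")
        + occ_shift * (occupation == "sitting/standing")
        + rng.normal(0, 3, n)
    )
    return pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "occupation": occupation,
            "season": season,
            "employment": employment,
            "bodyfat_pct": bodyfat,
            "retired": (occupation == "no-work-PA") & (employment == "not working"),
            "avacc_abs": y,
            "m30": y * 3 + rng.normal(0, 1, n),
            "m720": y + rng.normal(0, 1, n),
        }
    )


class TestZTransform:
    def test_three_point_example(self):
        assert np.allclose(z_transform([1, 2, 3]), [-1, 0, 1])

    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(1)
        z = z_transform(rng.gamma(2, 10, 500))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(5, 2, 100)
        assert np.allclose(z_transform(x), z_transform(3.5 * x - 11.0))

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            z_transform([4.0, 4.0, 4.0])


class TestEffectCategories:
    @pytest.mark.parametrize(
        "estimate,category",
        [
            (0.05, "negligible"),
            (0.1, "small"),       # left-closed boundary
            (0.18, "small"),
            (0.3, "medium"),
            (0.45, "medium"),
            (0.5, "large"),
            (-0.45, "medium"),    # magnitude-based
        ],
    )
    def test_thresholds(self, estimate, category):
        assert categorize_effect(estimate) == category


class TestNearZeroFlag:
    def test_limit_within_five_percent_of_width(self):
        assert _near_zero_flag(-0.01, 0.99)       # lower limit near zero
        assert _near_zero_flag(-0.99, 0.02)       # upper limit near zero
        assert not _near_zero_flag(0.2, 0.8)      # CI away from zero
        assert not _near_zero_flag(-0.5, 0.5)     # zero well inside


class TestOrthoPoly:
    def test_columns_orthonormal(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 10, 200)
        P = OrthoPoly(x, 3).transform(x)
        gram = P.T @ P
        assert np.allclose(gram, np.eye(3), atol=1e-10)
        assert np.allclose(P.sum(axis=0), 0.0, atol=1e-9)

    def test_prediction_matches_fit_points(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 10, 50)
        poly = OrthoPoly(x, 3)
        assert np.allclose(poly.transform(x[:5]), poly.transform(x)[:5])


class TestAdjustedModel:
    def test_recovers_planted_additive_sex_effect(self):
        df = synthetic_table(n=2000, seed=5, sex_shift=2.0)
        res = fit_adjusted_model(df, AnalysisConfig(dependent="avacc_abs",
                                                    z_transform=False))
        coef = res.coefficients.set_index("term")
        est = coef.loc["sex[female]", "estimate"]
        assert est == pytest.approx(2.0, abs=0.4)

    def test_percent_diff_sign_matches_coefficient(self):
        df = synthetic_table(n=1500, seed=6, occ_shift=-3.0)
        res = fit_adjusted_model(df, AnalysisConfig(dependent="avacc_abs"))
        coef = res.coefficients.set_index("term")
        pct = res.percent_diffs.set_index("contrast")
        contrast = "occupation[sitting/standing vs at-least-moderate-PA]"
        assert (
            np.sign(pct.loc[contrast, "percent"])
            == np.sign(coef.loc["occupation[sitting/standing]", "estimate"])
        )
        assert pct.loc[contrast, "percent"] == pytest.approx(-10.0, abs=3.0)

    def test_single_level_season_rejected(self):
        df = synthetic_table(n=200, seed=7)
        df["season"] = "summer"
        with pytest.raises(ValueError, match="season"):
            fit_adjusted_model(df, AnalysisConfig(dependent="avacc_abs"))

    def test_log_never_on_negative_metric(self):
        df = synthetic_table(n=300, seed=8)
        df["ig_abs"] = -2.5 + 0.1 * np.random.default_rng(0).normal(size=300)
        res = fit_adjusted_model(df, AnalysisConfig(dependent="ig_abs"))
        assert res.diagnostics["log_applied"] is False

    def test_log_always_back_transforms_percent(self):
        df = synthetic_table(n=1500, seed=9, occ_shift=0.0)
        df["avacc_abs"] = np.exp(
            3.4
            - 0.10 * (df["occupation"] == "sitting/standing")
            + np.random.default_rng(1).normal(0, 0.15, len(df))
        )
        res = fit_adjusted_model(
            df, AnalysisConfig(dependent="avacc_abs", log_before_z="always")
        )
        pct = res.percent_diffs.set_index("contrast")
        got = pct.loc["occupation[sitting/standing vs at-least-moderate-PA]", "percent"]
        assert got == pytest.approx(100 * (np.exp(-0.10) - 1), abs=2.5)

    def test_ci_contains_estimate_and_marginal_means_exist(self):
        df = synthetic_table(n=400, seed=10)
        res = fit_adjusted_model(df, AnalysisConfig(dependent="avacc_abs"))
        c = res.coefficients
        assert ((c["ci_low"] <= c["estimate"]) & (c["estimate"] <= c["ci_high"])).all()
        assert set(res.marginal_means["occupation"]) == {
            "at-least-moderate-PA",
            "no-work-PA",
            "sitting/standing",
        }
        assert len(res.age_curve) >= 60


class TestOverlap:
    def test_duplicated_column_perfectly_correlated(self):
        df = synthetic_table(n=300, seed=11)
        df["avacc_rel"] = df["avacc_abs"]
        df["ig_abs"] = df["m30"]
        df["ig_rel"] = df["m720"]
        res = metric_overlap(df)
        assert res.spearman.loc["avacc_abs", "avacc_rel"] == pytest.approx(1.0)
        assert np.allclose(res.spearman, res.spearman.T)
        assert np.allclose(np.diag(res.spearman), 1.0)
        assert res.variance_fractions.sum() == pytest.approx(1.0)

    def test_independent_noise_splits_variance_evenly(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame(rng.normal(size=(20000, 4)),
                          columns=["avacc_rel", "avacc_abs", "ig_rel", "ig_abs"])
        res = metric_overlap(df)
        assert np.allclose(res.variance_fractions, 0.25, atol=0.02)

    def test_missing_values_rejected(self):
        df = synthetic_table(n=50, seed=13)
        df["avacc_rel"] = df["avacc_abs"]
        df["ig_abs"] = df["m30"]
        df["ig_rel"] = df["m720"]
        df.loc[3, "ig_rel"] = np.nan
        with pytest.raises(ValueError):
            metric_overlap(df)


class TestMxProfiles:
    def test_identical_groups_have_identical_curves(self):
        df = synthetic_table(n=400, seed=14)
        half = len(df) // 2
        df["sex"] = ["female"] * half + ["male"] * half
        # make the metric independent of sex by mirroring rows
        mirrored = df.copy()
        mirrored["sex"] = np.where(df["sex"] == "female", "male", "female")
        big = pd.concat([df, mirrored], ignore_index=True)
        prof = mx_group_profiles(big, "sex")
        wide = prof.pivot_table(index="minutes", columns="group", values="mean")
        assert np.allclose(wide["female"], wide["male"], atol=1e-10)

    def test_planted_group_separation_detected(self):
        df = synthetic_table(n=600, seed=15, sex_shift=4.0)
        prof = mx_group_profiles(df, "sex")
        wide = prof.pivot_table(index="minutes", columns="group", values="mean")
        assert (wide["female"] > wide["male"]).all()

    def test_age_band_grouping(self):
        df = synthetic_table(n=500, seed=16)
        prof = mx_group_profiles(df, "age_band")
        assert set(prof["group"]) == {"20-40", "41-60", "61-90"}


class TestSensitivity:
    def make_daily(self, n=60, seed=17, weekday_only_effect=-0.3):
        rng = np.random.default_rng(seed)
        rows = []
        participants = synthetic_table(n=n, seed=seed).drop(
            columns=["avacc_abs", "m30", "m720"]
        )
        participants["id"] = [f"P{i:03d}" for i in range(n)]
        participants["max_enmo"] = 1000.0
        for i, row in participants.iterrows():
            sit = row["occupation"] == "sitting/standing"
            for day_type, nd in (("weekday", 5), ("saturday", 1), ("sunday", 1)):
                for d in range(nd):
                    eff = weekday_only_effect if (sit and day_type == "weekday") else 0.0
                    rows.append(
                        {
                            "id": row["id"],
                            "date": f"2024-03-{4 + d:02d}",
                            "day_type": day_type,
                            "avacc_abs": 30 + 10 * eff + rng.normal(0, 1),
                        }
                    )
        return pd.DataFrame(rows), participants

    def test_weekday_filter_bookkeeping(self):
        daily, parts = self.make_daily()
        t_all = person_table(daily, parts, "all")
        t_wd = person_table(daily, parts, "weekdays")
        t_we = person_table(daily, parts, "weekend")
        assert (t_all["n_valid_days"] == 7).all()
        assert (t_wd["n_valid_days"] == 5).all()
        assert (t_we["n_valid_days"] == 2).all()
        assert "avacc_rel" in t_all.columns

    def test_weekday_loaded_effect_attenuates_on_weekends(self):
        daily, parts = self.make_daily()
        cfg = AnalysisConfig(dependent="avacc_abs", z_transform=False)
        wd = run_sensitivity(daily, parts, "weekdays_only", cfg)
        we = run_sensitivity(daily, parts, "weekend_only", cfg)
        term = "occupation[sitting/standing]"
        est_wd = wd.coefficients.set_index("term").loc[term, "estimate"]
        est_we = we.coefficients.set_index("term").loc[term, "estimate"]
        assert est_wd < -1.5
        assert abs(est_we) < abs(est_wd) / 2

    def test_exclude_retired_identity_when_none_retired(self):
        daily, parts = self.make_daily()
        parts = parts.copy()
        parts["retired"] = False
        cfg = AnalysisConfig(dependent="avacc_abs")
        main = fit_adjusted_model(person_table(daily, parts, "all"), cfg)
        sens = run_sensitivity(daily, parts, "exclude_retired", cfg)
        assert np.allclose(
            main.coefficients["estimate"], sens.coefficients["estimate"]
        )
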