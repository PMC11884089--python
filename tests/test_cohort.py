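import dataclasses
import math

import numpy as np
import pytest

from relacc import (
    ActivitySpec,
    CohortSpec,
    ConfigurationError,
    Vo2PeakModel,
    default_cohort_spec,
    generate_cohort,
    generate_epoch_trace,
    generate_vo2peak,
)


def small_spec(n=12, seed=5, **kw):
    return CohortSpec(n_participants=n, seed=seed, **kw)


class TestSeedDeterminism:
    def test_identical_seed_bit_identical(self):
        a = generate_cohort(small_spec())
        b = generate_cohort(small_spec())
        assert a.participants.equals(b.participants)
        assert a.truth.equals(b.truth)
        for pid in a.series:
            for da, db in zip(a.series[pid], b.series[pid]):
                assert np.array_equal(da.enmo, db.enmo)
                assert np.array_equal(da.wear, db.wear)

    def test_different_seed_differs(self):
        a = generate_cohort(small_spec(seed=5))
        b = generate_cohort(small_spec(seed=6))
        assert not a.participants["age"].equals(b.participants["age"])


class TestCohortStructure:
    def test_single_participant(self):
        c = generate_cohort(small_spec(n=1))
        assert len(c.participants) == 1
        (days,) = c.series.values()
        assert len(days) == 7
        types = [d.day_type for d in days]
        assert types.count("weekday") == 5
        assert types.count("saturday") == 1 and types.count("sunday") == 1

    def test_female_fraction_within_binomial_bounds(self):
        # n=460, p=0.48: 99% binomial bounds are +-2.576*sqrt(p(1-p)/n)
        spec = CohortSpec(n_participants=460, seed=17)
        c = generate_cohort(
            dataclasses.replace(spec, n_days=1)  # covariates only need 1 day
        )
        frac = (c.participants["sex"] == "female").mean()
        half_width = 2.576 * math.sqrt(0.48 * 0.52 / 460)
        assert abs(frac - 0.48) < half_width

    def test_retired_only_in_nowork_stratum(self):
        c = generate_cohort(small_spec(n=200, n_days=1))
        df = c.participants
        retired = df[df["retired"]]
        assert (retired["occupation"] == "no-work-PA").all()
        assert (retired["employment"] == "not working").all()

    def test_invalid_probability_vector_rejected(self):
        with pytest.raises(ConfigurationError):
            CohortSpec(occupation_probs=(0.5, 0.5, 0.5))

    def test_bodyfat_and_vo2_in_valid_ranges(self):
        c = generate_cohort(small_spec(n=100, n_days=1))
        assert ((c.participants["bodyfat_pct"] > 0)
                & (c.participants["bodyfat_pct"] < 60)).all()
        assert (c.participants["vo2peak"] > 0).all()


class TestVo2Peak:
    def test_zero_residual_is_deterministic(self):
        model = Vo2PeakModel(resid_log_sd=0.0)
        rng = np.random.default_rng(0)
        v1 = generate_vo2peak(50.0, "male", model, rng)
        v2 = generate_vo2peak(50.0, "male", model, np.random.default_rng(99))
        assert v1 == v2

    def test_zero_sex_gap_gives_equal_expectations(self):
        model = Vo2PeakModel(sex_log_offset=0.0, resid_log_sd=0.0)
        rng = np.random.default_rng(0)
        m = generate_vo2peak(40.0, "male", model, rng, bodyfat=22.0)
        f = generate_vo2peak(40.0, "female", model, rng, bodyfat=22.0)
        assert m == pytest.approx(f)

    def test_monotone_decline_with_age(self):
        model = Vo2PeakModel(resid_log_sd=0.0)
        rng = np.random.default_rng(0)
        vals = [generate_vo2peak(a, "male", model, rng) for a in range(20, 90, 5)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_men_exceed_women_at_fixed_age(self):
        model = Vo2PeakModel(resid_log_sd=0.0)
        rng = np.random.default_rng(0)
        assert generate_vo2peak(50.0, "male", model, rng) > generate_vo2peak(
            50.0, "female", model, rng
        )

    def test_floor_applied(self):
        model = Vo2PeakModel(resid_log_sd=0.0, floor=25.0)
        rng = np.random.default_rng(0)
        assert generate_vo2peak(89.0, "female", model, rng, bodyfat=50.0) == 25.0


class TestEpochTrace:
    def test_all_zero_when_silent(self):
        spec = ActivitySpec(
            baseline_mg=0.0, sleep_mg=0.0, bout_rate=0.0, nonwear_prob_per_day=0.0
        )
        s = generate_epoch_trace(spec, np.random.default_rng(1))
        assert np.all(s.enmo == 0.0)

    def test_trace_shape_and_nonnegativity(self):
        s = generate_epoch_trace(ActivitySpec(), np.random.default_rng(2))
        assert s.n_epochs == 17280
        assert (s.enmo >= 0).all()

    def test_forced_nonwear_duration_boundary(self):
        # certain non-wear of exactly 10 h leaves 14.0 h of wear
        spec = ActivitySpec(
            nonwear_prob_per_day=1.0,
            nonwear_duration_median_min=600.0,
            nonwear_duration_sigma=0.0,
        )
        s = generate_epoch_trace(spec, np.random.default_rng(3))
        assert s.wear.sum() * 5 / 3600 == pytest.approx(14.0)
        assert np.all(s.enmo[~s.wear] == 0.0)

    def test_sleep_window_quieter_than_waking(self):
        s = generate_epoch_trace(
            ActivitySpec(nonwear_prob_per_day=0.0), np.random.default_rng(4)
        )
        hours = np.arange(17280) * 5 / 3600
        sleep = (hours >= 23) | (hours < 7)
        assert s.enmo[sleep].mean() < 0.25 * s.enmo[~sleep].mean()

    def test_volume_multiplier_scales_avacc(self):
        spec = ActivitySpec(nonwear_prob_per_day=0.0)
        a = generate_epoch_trace(spec, np.random.default_rng(5)).enmo.mean()
        b = generate_epoch_trace(
            spec, np.random.default_rng(5), log_multiplier=math.log(2)
        ).enmo.mean()
        assert b == pytest.approx(2 * a)


class TestDefaultsFile:
    def test_yaml_defaults_match_dataclass_defaults(self):
        a, b = default_cohort_spec(), CohortSpec()

        def walk(x, y, path=""):
            if dataclasses.is_dataclass(x):
                for f in dataclasses.fields(x):
                    walk(getattr(x, f.name), getattr(y, f.name), path + "." + f.name)
            elif isinstance(x, tuple):
                for i, (xi, yi) in enumerate(zip(x, y)):
                    walk(xi, yi, f"{path}[{i}]")
            elif isinstance(x, float):
                assert x == pytest.approx(y, rel=1e-8), path
            else:
                assert x == y, path

        walk(a, b)


class TestEmergentRelativeConsistency:
    def test_wider_vo2_sex_gap_raises_relative_not_absolute_contrast(self):
        """Increasing the planted VO2peak sex gap must raise the sex
        coefficient on relative volume while leaving the absolute one
        unchanged in expectation."""
        from relacc.calibration import replicate_recovery

        base = CohortSpec(n_participants=300)
        wide = dataclasses.replace(
            base,
            vo2peak_model=dataclasses.replace(
                base.vo2peak_model, sex_log_offset=-0.20
            ),
        )
        seeds = range(1, 6)
        a = replicate_recovery(base, seeds, dependents=("avacc_abs", "avacc_rel"),
                               metrics=("avacc_abs",))
        b = replicate_recovery(wide, seeds, dependents=("avacc_abs", "avacc_rel"),
                               metrics=("avacc_abs",))
        assert b["sex_avacc_rel_z"].mean() > a["sex_avacc_rel_z"].mean() + 0.1
        diff_abs = b["sex_avacc_abs_z"].mean() - a["sex_avacc_abs_z"].mean()
        assert abs(diff_abs) < 0.05  # common random numbers: tight bound


class TestWeekdayLoadedOccupationEffect:
    def test_occupation_contrast_attenuates_on_weekend_days(self):
        """The planted occupation effect loads on weekdays, so the adjusted
        contrast estimated from weekend days alone must be much smaller."""
        from relacc import simulate_tables, person_table, fit_adjusted_model
        from relacc.stats import AnalysisConfig

        contrast = "occupation[sitting/standing vs at-least-moderate-PA]"
        wd, we = [], []
        for seed in (2, 3, 4):
            daily, parts, _ = simulate_tables(
                CohortSpec(n_participants=300, seed=seed),
                metrics=("avacc_abs",),
            )
            for filt, acc in (("weekdays", wd), ("weekend", we)):
                res = fit_adjusted_model(
                    person_table(daily, parts, filt),
                    AnalysisConfig(dependent="avacc_abs"),
                )
                acc.append(
                    res.percent_diffs.set_index("contrast").loc[contrast, "percent"]
                )
        assert np.mean(wd) < -8.0
        assert abs(np.mean(we)) < 0.5 * abs(np.mean(wd))
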