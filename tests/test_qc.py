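"""Quality-control cascade: boundary conventions, stages, idempotence, scoring."""

import numpy as np
import pandas as pd
import pytest

from resiphen import QCConfig, run_qc, score_against_ledger
from resiphen.qc import (
    age_window_and_eligibility,
    apply_gross_limits,
    feed_behaviour_limits,
    gap_filter,
    min_record_filter,
    pen_rmse_screen,
    rolling_median_filter,
)

from conftest import linear_records


def _one_animal(ages, weights):
    df = linear_records(n_animals=1, ages=np.asarray(ages))
    df["weight_kg"] = np.asarray(weights, dtype=float)
    return df


class TestGrossLimits:
    @pytest.mark.parametrize(
        "weight,age,kept",
        [
            (9.9, 100, False),   # below the 10 kg floor
            (10.0, 100, True),   # boundary: "below" is strict
            (160.5, 159, False), # above 160 kg before 160 d
            (160.5, 161, True),  # same weight past 160 d is plausible
        ],
    )
    def test_boundaries(self, weight, age, kept):
        df = _one_animal([age], [weight])
        out = apply_gross_limits(df, QCConfig())
        assert out["weight_kg"].notna().iloc[0] == kept


class TestMinRecords:
    @pytest.mark.parametrize("n,kept", [(19, False), (20, True)])
    def test_boundary(self, n, kept):
        df = linear_records(n_animals=1, ages=np.arange(95, 95 + n))
        out = min_record_filter(df, QCConfig())
        assert (len(out) > 0) == kept

    def test_constructed_cohort(self):
        # animals 1-9 get 60 records, animal 10 only 15: exactly it is removed
        parts = [linear_records(n_animals=9)]
        short = linear_records(n_animals=1, ages=np.arange(95, 110))
        short["animal_id"] = 10
        df = pd.concat(parts + [short], ignore_index=True)
        out = min_record_filter(df, QCConfig())
        assert set(out["animal_id"]) == set(range(1, 10))


class TestPenScreen:
    def test_clean_pens_not_flagged(self):
        df = pd.concat(
            [linear_records(n_animals=5, pen=p).assign(
                animal_id=lambda d, p=p: d["animal_id"] + 10 * p)
             for p in range(6)],
            ignore_index=True,
        )
        out, table, flagged = pen_rmse_screen(df, QCConfig())
        assert flagged == []
        pd.testing.assert_frame_equal(out, df)

    def test_adaptation_pen_has_max_rmse_and_is_flagged(self):
        rng = np.random.default_rng(0)
        parts = []
        for p in range(8):
            d = linear_records(n_animals=5, noise=0.5, seed=p, pen=p)
            d["animal_id"] = d["animal_id"] + 10 * p
            parts.append(d)
        df = pd.concat(parts, ignore_index=True)
        # inflate the first 3 days of every animal in pen 7 (entry adaptation)
        bad = (df["pen"] == 7) & (df["age_d"] <= 97)
        df.loc[bad, "weight_kg"] *= 1.9
        out, table, flagged = pen_rmse_screen(df, QCConfig())
        assert table.set_index("pen")["rmse"].idxmax() == 7
        assert flagged == [7]
        # the inflated records were set missing, animals retained
        assert out.loc[bad, "weight_kg"].isna().all()
        assert out["animal_id"].nunique() == df["animal_id"].nunique()

    def test_short_spike_sets_missing_but_keeps_animal(self):
        parts = []
        for p in range(8):
            d = linear_records(n_animals=5, noise=0.5, seed=p, pen=p)
            d["animal_id"] = d["animal_id"] + 10 * p
            parts.append(d)
        df = pd.concat(parts, ignore_index=True)
        spike = (df["animal_id"] == 71) & df["age_d"].between(120, 124)
        df.loc[spike, "weight_kg"] += 30.0
        out, table, flagged = pen_rmse_screen(df, QCConfig())
        assert 7 in flagged
        assert out.loc[spike, "weight_kg"].isna().all()
        assert 71 in set(out["animal_id"])

    def test_long_error_removes_animal(self):
        parts = []
        for p in range(8):
            d = linear_records(n_animals=5, noise=0.5, seed=p, pen=p)
            d["animal_id"] = d["animal_id"] + 10 * p
            parts.append(d)
        df = pd.concat(parts, ignore_index=True)
        long_err = (df["animal_id"] == 71) & df["age_d"].between(110, 140)
        df.loc[long_err, "weight_kg"] += 40.0
        out, table, flagged = pen_rmse_screen(df, QCConfig())
        assert 71 not in set(out["animal_id"])


class TestRollingMedian:
    def test_constant_series_with_spike(self):
        w = np.full(20, 50.0)
        w[10] = 55.0
        df = _one_animal(np.arange(95, 115), w)
        out = rolling_median_filter(df, QCConfig(quadratic_pass=False))
        assert out["weight_kg"].isna().sum() == 1
        assert np.isnan(out.loc[out["age_d"] == 105, "weight_kg"]).all()

    def test_linear_growth_untouched(self):
        df = linear_records(n_animals=3, slope=1.0)
        out = rolling_median_filter(df, QCConfig(quadratic_pass=False))
        assert out["weight_kg"].notna().all()

    def test_deviation_of_exactly_3kg_retained(self):
        w = np.full(20, 50.0)
        w[10] = 53.0  # deviates exactly 3 kg: "more than 3 kg" is strict
        df = _one_animal(np.arange(95, 115), w)
        out = rolling_median_filter(df, QCConfig(quadratic_pass=False))
        assert out["weight_kg"].notna().all()

    def test_quadratic_pass_catches_first_record_error(self):
        df = linear_records(n_animals=1)
        df.loc[df["age_d"] == 95, "weight_kg"] += 20.0
        out_med = rolling_median_filter(df, QCConfig(quadratic_pass=False))
        out_full = rolling_median_filter(df, QCConfig(quadratic_pass=True))
        # the median window at the first record is one-sided -> passes;
        # the quadratic residual pass catches it
        assert out_med["weight_kg"].notna().all()
        assert out_full.loc[out_full["age_d"] == 95, "weight_kg"].isna().all()


class TestGapFilter:
    @pytest.mark.parametrize("gap,kept", [(10, True), (11, False)])
    def test_boundary(self, gap, kept):
        ages = np.concatenate([np.arange(95, 121), np.arange(120 + gap, 156)])
        df = linear_records(n_animals=1, ages=ages)
        out = gap_filter(df, QCConfig())
        assert (len(out) > 0) == kept

    def test_missing_block_removes_animal_with_reason(self):
        ages = np.concatenate([np.arange(95, 120), np.arange(134, 156)])  # 14-d hole
        df = linear_records(n_animals=1, ages=ages)
        ledger = []
        out = gap_filter(df, QCConfig(), ledger)
        assert out.empty
        assert all(e["reason"] == "gap" for e in ledger)


class TestFeedLimits:
    def test_boundary_and_extreme(self):
        rng = np.random.default_rng(0)
        df = linear_records(n_animals=10)
        df["fi_g_per_d"] = rng.normal(2300, 100, len(df))
        mu, sd = df["fi_g_per_d"].mean(), df["fi_g_per_d"].std(ddof=1)
        df.loc[df.index[0], "fi_g_per_d"] = mu + 10 * sd  # far out
        out = feed_behaviour_limits(df, QCConfig())
        assert np.isnan(out["fi_g_per_d"].iloc[0])
        # a value exactly at mean + 4 SD is retained (strictly "exceeding")
        df2 = df.copy()
        mu2, sd2 = df2["fi_g_per_d"].mean(), df2["fi_g_per_d"].std(ddof=1)
        df2.loc[df2.index[1], "fi_g_per_d"] = mu2 + 4 * sd2
        thr_before = df2["fi_g_per_d"].mean() + 4 * df2["fi_g_per_d"].std(ddof=1)
        out2 = feed_behaviour_limits(df2, QCConfig())
        if df2["fi_g_per_d"].iloc[1] <= thr_before:
            assert not np.isnan(out2["fi_g_per_d"].iloc[1])

    def test_gaussian_tail_fraction(self):
        rng = np.random.default_rng(1)
        df = linear_records(n_animals=1, ages=np.arange(0, 100_000))
        df["fi_g_per_d"] = rng.normal(0, 1, len(df))
        out = feed_behaviour_limits(df, QCConfig())
        frac = out["fi_g_per_d"].isna().mean()
        # one-sided 4-SD normal tail ~ 3.2e-5
        assert frac < 3e-4


class TestEligibility:
    def test_late_starter_removed(self):
        df = linear_records(n_animals=1, ages=np.arange(111, 156))
        out = age_window_and_eligibility(df, QCConfig())
        assert out.empty

    def test_early_finisher_removed(self):
        df = linear_records(n_animals=1, ages=np.arange(95, 120))  # max age 119
        out = age_window_and_eligibility(df, QCConfig())
        assert out.empty

    def test_missing_fraction_rule(self):
        # 60 possible days, 19 missing weights -> 31.7% > 30% -> removed
        df = linear_records(n_animals=1, ages=np.arange(95, 155))
        df.loc[df.index[:19], "weight_kg"] = np.nan
        out = age_window_and_eligibility(df, QCConfig())
        assert out.empty
        df2 = linear_records(n_animals=1, ages=np.arange(95, 155))
        df2.loc[df2.index[:17], "weight_kg"] = np.nan  # 28.3% -> kept
        out2 = age_window_and_eligibility(df2, QCConfig())
        assert not out2.empty

    def test_records_outside_window_dropped(self):
        df = linear_records(n_animals=1, ages=np.arange(90, 160))
        out = age_window_and_eligibility(df, QCConfig())
        assert out["age_d"].between(95, 155).all()


class TestRunQC:
    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            run_qc(pd.DataFrame(columns=["animal_id", "age_d", "weight_kg"]))

    def test_counts_monotone_and_ledger_consistent(self, small_sim):
        cleaned, report = run_qc(small_sim.records)
        counts = report.summary()["n_weight_records"].to_numpy()
        assert (np.diff(counts) <= 0).all()
        animals = report.summary()["n_animals"].to_numpy()
        assert (np.diff(animals) <= 0).all()

    def test_values_never_altered_only_removed(self, small_sim):
        cleaned, _ = run_qc(small_sim.records)
        merged = cleaned.merge(
            small_sim.records, on=["animal_id", "age_d"], suffixes=("", "_raw")
        )
        for col in ("weight_kg", "fi_g_per_d", "dur_s_per_d", "nvisits_per_d"):
            kept = merged[col].notna()
            np.testing.assert_allclose(
                merged.loc[kept, col], merged.loc[kept, f"{col}_raw"]
            )

    def test_idempotent(self, small_sim):
        once, _ = run_qc(small_sim.records)
        twice, _ = run_qc(once)
        pd.testing.assert_frame_equal(
            once.reset_index(drop=True), twice.reset_index(drop=True)
        )

    def test_artifact_free_survival(self, clean_sim):
        cleaned, _ = run_qc(clean_sim.records)
        frac = cleaned["weight_kg"].notna().sum() / clean_sim.records["weight_kg"].notna().sum()
        assert frac >= 0.99

    def test_sensitivity_specificity_on_ledger(self, small_sim):
        cleaned, _ = run_qc(small_sim.records)
        score = score_against_ledger(small_sim.records, cleaned, small_sim.artifact_ledger)
        assert score["sensitivity"] >= 0.95
        assert score["clean_removed_frac"] <= 0.01
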