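"""Per-meal errors, summaries, rank test, outlier rule, stratification."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from carbplate.errors import SchemaError
from carbplate.scene_synth import StudyTableParams, make_study_table
from carbplate.study_stats import (
    SuccessCounts,
    compute_errors,
    exclude_outlier_participants,
    mann_whitney_u,
    size_stratified_summary,
    success_rate,
    summarize,
)


def _toy_table(true, self_g, system_g=None, sizes=None, participants=None):
    n = len(true)
    return pd.DataFrame({
        "meal_id": range(n),
        "participant_id": participants if participants is not None else [0] * n,
        "size": sizes if sizes is not None else ["medium"] * n,
        "true_g": true,
        "self_g": self_g,
        "system_g": system_g if system_g is not None else true,
    })


class TestComputeErrors:
    def test_basic_arithmetic(self):
        t = _toy_table([50.0], [60.0])
        e = compute_errors(t, "self")
        assert e["signed_g"].iloc[0] == 10.0
        assert e["abs_g"].iloc[0] == 10.0
        assert e["pct"].iloc[0] == pytest.approx(20.0)

    def test_perfect_estimates_have_zero_error(self):
        t = _toy_table([40.0, 55.0, 70.0], [40.0, 55.0, 70.0])
        e = compute_errors(t, "self")
        assert (e["abs_g"] == 0).all()

    def test_five_row_hand_computation(self):
        true = [50.0, 80.0, 25.0, 100.0, 60.0]
        est = [45.0, 95.0, 25.0, 80.0, 72.0]
        e = compute_errors(_toy_table(true, est), "self")
        assert e["signed_g"].tolist() == [-5.0, 15.0, 0.0, -20.0, 12.0]
        assert e["abs_g"].tolist() == [5.0, 15.0, 0.0, 20.0, 12.0]
        assert e["pct"].tolist() == pytest.approx([10.0, 18.75, 0.0, 20.0, 20.0])

    def test_zero_truth_rejected(self):
        with pytest.raises(SchemaError):
            compute_errors(_toy_table([0.0], [10.0]), "self")


class TestSummarize:
    def test_band_and_balance_fractions(self):
        # 92 of 114 within +/-20 g; 69 under, 45 over (no exact hits)
        rng = np.random.default_rng(0)
        signed = np.concatenate([
            -rng.uniform(1, 19.9, 60), rng.uniform(1, 19.9, 32),   # within band
            -rng.uniform(21, 60, 9), rng.uniform(21, 60, 13),      # outside band
        ])
        assert len(signed) == 114 and np.sum(signed < 0) == 69
        t = _toy_table([100.0] * 114, 100.0 + signed)
        s = summarize(compute_errors(t, "self"))
        assert s.pct_within_band == 80.7
        assert round(100 * s.frac_under, 1) == 60.5
        assert s.frac_under + s.frac_over == pytest.approx(1.0)

    def test_all_zero_errors(self):
        t = _toy_table([50.0] * 4, [50.0] * 4)
        s = summarize(compute_errors(t, "self"))
        assert s.mae_g == 0.0
        assert s.frac_within_band == 1.0
        assert s.frac_under == s.frac_over == 0.0

    def test_band_is_strict_inequality(self):
        t = _toy_table([100.0, 100.0], [120.0, 119.99])
        s = summarize(compute_errors(t, "self"))
        assert s.frac_within_band == 0.5

    def test_row_order_invariance(self):
        rng = np.random.default_rng(1)
        true = rng.uniform(30, 120, 40)
        est = true + rng.normal(0, 25, 40)
        t = _toy_table(true, np.maximum(est, 0))
        s1 = summarize(compute_errors(t, "self"))
        s2 = summarize(compute_errors(t.sample(frac=1.0, random_state=5), "self"))
        assert s1 == s2


class TestSuccessRate:
    @pytest.mark.parametrize("num,den,expected", [
        (86, 114, 75.4),
        (291, 342, 85.1),
        (92, 114, 80.7),
        (69, 114, 60.5),
        (0, 10, 0.0),
    ])
    def test_printed_percentages(self, num, den, expected):
        assert success_rate(SuccessCounts(num, den)) == expected

    def test_invalid_counts_rejected(self):
        with pytest.raises(SchemaError):
            SuccessCounts(5, 0)
        with pytest.raises(SchemaError):
            SuccessCounts(11, 10)


class TestMannWhitney:
    def test_fully_separated_groups(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_groups_u_is_half_product(self):
        u, _ = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert u == 3 * 3 / 2

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_exact_p_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            na, nb = rng.integers(2, 7, 2)
            a = rng.normal(size=na)
            b = rng.normal(size=nb)
            u_obs, p = mann_whitney_u(a, b)
            # independent oracle: recompute U for every labeling directly
            combined = np.concatenate([a, b])
            n = na + nb
            us = []
            for pos in combinations(range(n), int(na)):
                av = combined[list(pos)]
                bv = np.delete(combined, list(pos))
                us.append(np.sum(av[:, None] > bv[None, :])
                          + 0.5 * np.sum(av[:, None] == bv[None, :]))
            us = np.asarray(us, dtype=float)
            total = comb(n, int(na))
            p_ref = min(1.0, 2 * min(np.mean(us <= u_obs), np.mean(us >= u_obs)))
            assert abs(p - p_ref) < 1e-12
            assert len(us) == total

    def test_matches_scipy_exact_small_samples(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            a = rng.normal(size=int(rng.integers(2, 7)))
            b = rng.normal(size=int(rng.integers(2, 7)))
            u, p = mann_whitney_u(a, b)
            ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.integers(0, 50), min_size=8, max_size=40),
           st.lists(st.integers(0, 50), min_size=8, max_size=40))
    def test_large_sample_p_matches_scipy_asymptotic(self, a, b):
        u, p = mann_whitney_u(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, abs=1e-9)


class TestOutlierExclusion:
    def test_injected_extreme_overestimator_removed(self):
        t = make_study_table(StudyTableParams(
            n_meals=114, self_error_sd_g=25.0, outlier_fraction=0.0, seed=2))
        bad = t["participant_id"] == 7
        t.loc[bad, "self_g"] += 150.0
        out, removed = exclude_outlier_participants(t)
        assert removed == [7]
        assert len(out) == 114 - 6

    def test_no_outliers_leaves_table_unchanged(self):
        t = make_study_table(StudyTableParams(
            n_meals=114, self_error_sd_g=25.0, outlier_fraction=0.0, seed=3))
        out, removed = exclude_outlier_participants(t)
        assert removed == []
        assert out.equals(t)

    def test_nineteen_participants_six_meals_leaves_108_rows(self):
        t = make_study_table(StudyTableParams(
            n_meals=114, self_error_sd_g=20.0, outlier_fraction=0.0,
            meals_per_participant=6, seed=4))
        t.loc[t["participant_id"] == 0, "self_g"] += 160.0
        out, removed = exclude_outlier_participants(t)
        assert len(removed) == 1
        assert len(out) == 108


class TestSizeStratified:
    def test_matches_hand_computation(self):
        t = _toy_table(
            true=[50.0, 50.0, 80.0, 80.0, 120.0, 120.0],
            self_g=[55.0, 45.0, 90.0, 60.0, 150.0, 120.0],
            sizes=["small", "small", "medium", "medium", "large", "large"])
        out = size_stratified_summary(t, "self")
        assert out["small"].mae_g == pytest.approx(5.0)
        assert out["medium"].mae_g == pytest.approx(15.0)
        assert out["large"].mae_g == pytest.approx(15.0)

    def test_single_stratum_is_fine(self):
        t = _toy_table([50.0, 60.0], [55.0, 50.0], sizes=["large", "large"])
        out = size_stratified_summary(t, "self")
        assert set(out) == {"large"}

    def test_unknown_size_rejected(self):
        t = _toy_table([50.0], [55.0], sizes=["jumbo"])
        with pytest.raises(SchemaError):
            size_stratified_summary(t, "self")

    def test_strata_aggregate_to_pooled_mae(self):
        t = make_study_table(StudyTableParams(n_meals=60, seed=5))
        strata = size_stratified_summary(t, "self")
        pooled = summarize(compute_errors(t, "self"))
        weighted = sum(s.mae_g * s.n for s in strata.values()) / sum(
            s.n for s in strata.values())
        assert weighted == pytest.approx(pooled.mae_g, abs=1e-9)
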