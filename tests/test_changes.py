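import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from deltanet.changes import (
    SeasonalModel,
    apply_seasonal_adjustment,
    default_seasonal_config,
    fit_seasonal_model,
    flag_out_of_range,
    out_of_range_change_table,
    paired_t_test,
    wilcoxon_signed_rank,
)
from deltanet.io import default_range_rules
from conftest import make_pairs


def enumerate_signed_rank_p(diffs):
    """Exhaustive two-sided signed-rank p over all 2^n sign patterns."""
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    total = ranks.sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=len(d))
    ]
    ws = np.asarray(ws)
    lower = np.mean(ws <= w_obs)
    upper = np.mean(ws >= w_obs)
    return min(1.0, 2 * min(lower, upper))


PARTICIPANTS = pd.DataFrame(
    {
        "participant_id": ["m1", "f1", "u1"],
        "sex": ["male", "female", None],
        "age": [40, 40, 40],
    }
)


class TestOutOfRangeFlags:
    def test_vitamin_d_below_threshold_flagged(self):
        pairs = make_pairs(
            participant_id=["m1"], biomarker=["VITD"],
            baseline_value=[23.7], followup_value=[32.4],
        )
        flagged = flag_out_of_range(pairs, default_range_rules(), PARTICIPANTS)
        assert bool(flagged.loc[0, "out_of_range"])

    def test_boundary_value_is_in_range(self):
        pairs = make_pairs(
            participant_id=["m1"], biomarker=["LDL"],
            baseline_value=[130.0], followup_value=[120.0],
        )
        flagged = flag_out_of_range(pairs, default_range_rules(), PARTICIPANTS)
        assert not bool(flagged.loc[0, "out_of_range"])

    def test_sex_specific_threshold_splits_alt_at_35(self):
        pairs = make_pairs(
            participant_id=["m1", "f1"], biomarker=["ALT", "ALT"],
            baseline_value=[35.0, 35.0], followup_value=[30.0, 30.0],
        )
        flagged = flag_out_of_range(pairs, default_range_rules(), PARTICIPANTS)
        assert not bool(flagged.loc[0, "out_of_range"])  # male threshold 46
        assert bool(flagged.loc[1, "out_of_range"])      # female threshold 29

    def test_unknown_sex_excluded_from_sex_specific_rule_only(self):
        pairs = make_pairs(
            participant_id=["u1", "u1"], biomarker=["ALT", "LDL"],
            baseline_value=[50.0, 150.0], followup_value=[30.0, 120.0],
        )
        flagged = flag_out_of_range(pairs, default_range_rules(), PARTICIPANTS)
        assert pd.isna(flagged.loc[0, "out_of_range"])
        assert "unknown sex" in flagged.loc[0, "excluded_reason"]
        assert bool(flagged.loc[1, "out_of_range"])

    def test_invariant_to_row_order(self):
        pairs = make_pairs(
            participant_id=["m1", "f1", "m1"], biomarker=["LDL", "ALT", "VITD"],
            baseline_value=[150.0, 40.0, 20.0], followup_value=[120.0, 30.0, 35.0],
        )
        a = flag_out_of_range(pairs, default_range_rules(), PARTICIPANTS)
        b = flag_out_of_range(
            pairs.iloc[[2, 0, 1]].reset_index(drop=True), default_range_rules(), PARTICIPANTS
        )
        merged = a.merge(b, on=["participant_id", "biomarker"], suffixes=("_a", "_b"))
        assert (merged["out_of_range_a"] == merged["out_of_range_b"]).all()


class TestSeasonalModel:
    def test_exact_two_group_offset(self):
        dates = pd.to_datetime(["2016-01-15"] * 12 + ["2016-07-15"] * 12)
        values = pd.Series([30.0] * 12 + [33.5] * 12)
        model = fit_seasonal_model(values, dates, "VITD")
        assert model.offset_estimate == pytest.approx(3.5)

    def test_one_season_data_refused(self):
        dates = pd.to_datetime(["2016-01-15"] * 30)
        with pytest.raises(ValueError, match="per season"):
            fit_seasonal_model(pd.Series(np.arange(30.0)), dates, "VITD")

    def test_planted_offset_recovered_from_noisy_data(self):
        # per-replicate SE is ~0.38 (sd 8, n=2000, summer fraction 0.33),
        # so check the mean estimate over 10 replicates
        rng = np.random.default_rng(4)
        n = 2000
        estimates = []
        for _ in range(10):
            summer = rng.random(n) < 0.33
            dates = pd.Series(pd.to_datetime(np.where(summer, "2016-07-15", "2016-02-15")))
            values = pd.Series(rng.normal(33, 8, n) + 2.5 * summer)
            estimates.append(fit_seasonal_model(values, dates, "VITD").offset_estimate)
        assert np.mean(estimates) == pytest.approx(2.5, abs=0.3)

    def test_adjustment_touches_only_summer_values_of_its_biomarker(self):
        pairs = make_pairs(
            participant_id=["a", "b", "c"], biomarker=["VITD", "VITD", "LDL"],
            baseline_value=[28.0, 28.0, 120.0], followup_value=[32.4, 32.4, 110.0],
            baseline_date=["2016-02-01", "2016-07-01", "2016-07-01"],
            followup_date=["2016-08-01", "2016-12-01", "2016-12-01"],
        )
        model = SeasonalModel("VITD", offset_estimate=2.5)
        adjusted = apply_seasonal_adjustment(pairs, model)
        assert adjusted.loc[0, "followup_value"] == pytest.approx(29.9)  # summer followup
        assert adjusted.loc[0, "baseline_value"] == 28.0                 # winter baseline
        assert adjusted.loc[1, "baseline_value"] == pytest.approx(25.5)  # summer baseline
        assert adjusted.loc[2, "followup_value"] == 110.0                # other biomarker

    def test_both_endpoints_in_summer_leave_delta_unchanged(self):
        pairs = make_pairs(
            biomarker=["VITD"], baseline_value=[28.0], followup_value=[35.0],
            baseline_date=["2016-06-15"], followup_date=["2016-09-15"],
        )
        adjusted = apply_seasonal_adjustment(pairs, SeasonalModel("VITD", 2.5))
        assert adjusted.loc[0, "delta"] == pytest.approx(pairs.loc[0, "delta"])

    def test_default_config_designates_vitamin_d(self):
        config = default_seasonal_config()
        assert config["VITD"]["offset"] == 2.5
        assert config["VITD"]["summer_months"] == frozenset({6, 7, 8, 9})


class TestWilcoxonSignedRank:
    def test_uniform_shift_n10_has_minimal_two_sided_p(self):
        base = np.arange(10.0)
        p, n = wilcoxon_signed_rank(base, base + 3.0)
        assert n == 10
        assert p == pytest.approx(2 / 1024)

    def test_no_change_returns_one_flagged(self):
        base = np.ones(8)
        assert wilcoxon_signed_rank(base, base) == (1.0, 0)

    def test_hand_example_n6_matches_enumeration(self):
        diffs = np.array([1.0, 2, 3, 4, 5, -6])
        p, _ = wilcoxon_signed_rank(np.zeros(6), diffs)
        assert p == pytest.approx(enumerate_signed_rank_p(diffs))

    @pytest.mark.parametrize("seed", range(12))
    def test_exact_branch_matches_enumeration_with_ties_and_zeros(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 13))
        diffs = rng.integers(-5, 6, size=n).astype(float)
        if not (diffs != 0).any():
            diffs[0] = 1.0
        p, _ = wilcoxon_signed_rank(np.zeros(n), diffs)
        assert p == pytest.approx(enumerate_signed_rank_p(diffs), abs=1e-12)

    def test_large_sample_uses_continuity_corrected_normal(self):
        rng = np.random.default_rng(8)
        base = rng.normal(size=80)
        foll = base + rng.normal(0.1, 1, size=80)
        p, n = wilcoxon_signed_rank(base, foll)
        expected = stats.wilcoxon(
            foll - base, zero_method="wilcox", correction=True, method="approx"
        ).pvalue
        assert n == 80 and p == pytest.approx(expected)


class TestPairedT:
    def test_hand_computed_differences(self):
        diffs = np.array([1.0, -1, 2, -2, 3])
        mean_change, p = paired_t_test(np.zeros(5), diffs)
        se = diffs.std(ddof=1) / math.sqrt(5)
        t = diffs.mean() / se
        expected_p = 2 * stats.t.sf(abs(t), df=4)
        assert mean_change == pytest.approx(0.6)
        assert p == pytest.approx(expected_p)

    def test_zero_variance_is_degenerate(self):
        with pytest.raises(ValueError, match="variance"):
            paired_t_test(np.array([1.0, 2.0]), np.array([2.0, 3.0]))

    def test_planted_mean_shift_recovered(self):
        rng = np.random.default_rng(15)
        before = rng.normal(25, 4, 400)
        after = before + rng.normal(-0.25, 1.0, 400)
        mean_change, _ = paired_t_test(before, after)
        assert mean_change == pytest.approx(-0.25, abs=0.15)


class TestChangeTable:
    def _cohort(self, n=300, improve=-20.0, seed=0):
        """Participants out of range high for LDL, with a planted improvement."""
        rng = np.random.default_rng(seed)
        base = rng.uniform(140, 200, n)
        foll = base + rng.normal(improve, 15, n)
        pairs = make_pairs(
            participant_id=[f"p{i}" for i in range(n)],
            biomarker=["LDL"] * n, baseline_value=base, followup_value=foll,
        )
        participants = pd.DataFrame(
            {"participant_id": [f"p{i}" for i in range(n)], "sex": ["male"] * n,
             "age": [40] * n}
        )
        return pairs, participants

    def test_group_below_minimum_omitted_and_logged(self):
        pairs, participants = self._cohort(n=19)
        table, log = out_of_range_change_table(pairs, default_range_rules(), participants)
        assert table.empty
        assert any("LDL" in line and "19" in line for line in log)

    def test_planted_improvement_detected(self):
        pairs, participants = self._cohort(n=300, improve=-20.0)
        table, _ = out_of_range_change_table(pairs, default_range_rules(), participants)
        row = table.set_index("biomarker").loc["LDL"]
        assert row["p_value"] < 0.001
        assert row["improvement_direction"] == "decrease"
        # median moves toward the threshold
        assert row["followup_median"] < row["baseline_median"]

    def test_null_biomarker_p_values_are_uniform(self):
        pvals = []
        for seed in range(60):
            pairs, participants = self._cohort(n=60, improve=0.0, seed=seed)
            table, _ = out_of_range_change_table(pairs, default_range_rules(), participants)
            pvals.append(float(table["p_value"].iloc[0]))
        assert stats.kstest(pvals, "uniform").pvalue > 0.05

    def test_sex_stratified_rows_for_testosterone(self):
        n = 60
        rng = np.random.default_rng(1)
        base = rng.uniform(150, 240, n)
        pairs = make_pairs(
            participant_id=[f"p{i}" for i in range(n)],
            biomarker=["TESTO"] * n, baseline_value=base,
            followup_value=base + rng.normal(40, 30, n),
        )
        participants = pd.DataFrame(
            {"participant_id": [f"p{i}" for i in range(n)],
             "sex": ["male"] * 40 + ["female"] * 20, "age": [40] * n}
        )
        table, log = out_of_range_change_table(
            pairs, default_range_rules(), participants, min_group=20
        )
        assert table["stratum"].tolist() == ["male"]  # female threshold 0: none flagged
        assert any("TESTO [female]" in line for line in log)
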