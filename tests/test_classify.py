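"""Rank-sum machinery, per-eddy outcomes, proportions and group comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eddyforage import (classify_samples, compare_characteristics, rank_sum_test,
                        summarize_proportions)
from eddyforage.classify import classify_eddy, stratified_rank_sum
from eddyforage.collocation import SampledEddy
from eddyforage.synthetic import lognormal_factors


class TestRankSum:
    def test_exact_enumeration_example(self):
        # C(4,2)=6 assignments; one-sided tail {1,2} has mass 1/6 -> p = 1/3
        p, stat = rank_sum_test([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3)
        assert stat < 0

    def test_identical_multisets_give_p_one(self):
        p, stat = rank_sum_test([1, 2, 3], [3, 2, 1])
        assert p == 1.0

    def test_constant_samples_give_p_one(self):
        assert rank_sum_test([5.0, 5.0], [5.0, 5.0]) == (1.0, 0.0)

    def test_complete_separation_large_n(self):
        x = np.arange(100, 120)
        y = np.arange(0, 20)
        p, stat = rank_sum_test(x, y)
        assert p < 0.001
        assert stat > 0

    def test_statistic_sign_follows_direction(self):
        p_up, s_up = rank_sum_test([10, 11, 12], [1, 2, 3])
        p_dn, s_dn = rank_sum_test([1, 2, 3], [10, 11, 12])
        assert s_up > 0 > s_dn
        assert p_up == pytest.approx(p_dn)

    def test_exact_matches_permutation_oracle_with_ties(self, rng):
        for _ in range(60):
            n, m = rng.integers(2, 8, size=2)
            x = rng.integers(0, 5, n).astype(float)
            y = rng.integers(0, 5, m).astype(float)
            if np.all(np.concatenate([x, y]) == x[0]):
                continue
            p_mine, _ = rank_sum_test(x, y)
            oracle = stats.mannwhitneyu(x, y, alternative="two-sided",
                                        method=stats.PermutationMethod(n_resamples=10**6))
            assert p_mine == pytest.approx(float(oracle.pvalue), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestStratified:
    def test_single_stratum_falls_back_to_exact(self):
        p1, _ = stratified_rank_sum({"day": np.array([1.0, 2.0])},
                                    {"day": np.array([3.0, 4.0])})
        p2, _ = rank_sum_test([1, 2], [3, 4])
        assert p1 == p2

    def test_opposite_period_shifts_cancel(self, rng):
        # inside higher by day, lower by night with equal magnitude:
        # the combined statistic is near zero
        day_in = rng.normal(1.0, 0.1, 20)
        day_out = rng.normal(0.0, 0.1, 20)
        night_in = rng.normal(0.0, 0.1, 20)
        night_out = rng.normal(1.0, 0.1, 20)
        p, stat = stratified_rank_sum({"day": day_in, "night": night_in},
                                      {"day": day_out, "night": night_out})
        assert abs(stat) < 1e-9
        assert p > 0.9

    def test_consistent_shift_detected(self, rng):
        inside = {"day": 10 + rng.normal(0, 1, 15), "night": 30 + rng.normal(0, 1, 15)}
        outside = {"day": rng.normal(0, 1, 15), "night": 20 + rng.normal(0, 1, 15)}
        p, stat = stratified_rank_sum(inside, outside)
        assert p < 1e-4 and stat > 0


class TestClassifySamples:
    def test_noiseless_increase(self):
        inside = {"day": np.full(30, 130.0)}
        outside = {"day": np.full(30, 100.0)}
        outcome, p, stat = classify_samples(inside, outside)
        assert outcome == "increase" and p < 0.05

    def test_noiseless_decrease_symmetric(self):
        inside = {"day": np.full(30, 70.0)}
        outside = {"day": np.full(30, 100.0)}
        assert classify_samples(inside, outside)[0] == "decrease"

    def test_type_one_error_near_nominal(self, rng):
        # 400 null eddies at alpha=0.05: non-null rate inside the 95%
        # binomial band around 5%
        hits = 0
        for _ in range(400):
            inside = {"day": lognormal_factors(rng, 0.3, 15),
                      "night": lognormal_factors(rng, 0.3, 15)}
            outside = {"day": lognormal_factors(rng, 0.3, 15),
                       "night": lognormal_factors(rng, 0.3, 15)}
            if classify_samples(inside, outside)[0] != "null":
                hits += 1
        assert 0.026 <= hits / 400 <= 0.078

    def test_direction_never_inverted_under_positive_effect(self, rng):
        for _ in range(200):
            inside = {"day": 1.3 * lognormal_factors(rng, 0.5, 30)}
            outside = {"day": lognormal_factors(rng, 0.5, 30)}
            assert classify_samples(inside, outside)[0] != "decrease"

    def test_alpha_extremes(self):
        inside = {"day": np.array([1.0, 3.0, 2.0])}
        outside = {"day": np.array([2.5, 1.5, 2.0])}
        assert classify_samples(inside, outside, alpha=0.0)[0] == "null"


class TestClassifyEddy:
    def _sampled(self, factor):
        from eddyforage import NASC_COLUMNS
        def table(vals):
            df = pd.DataFrame({"profile_id": range(len(vals)), "period": "day",
                               "sst_c": 18.0, "chl": 0.2})
            for c in NASC_COLUMNS:
                df[c] = np.asarray(vals, dtype=float)
            return df
        rng = np.random.default_rng(0)
        return SampledEddy(eddy_id=1, polarity="AE",
                           inside=table(factor * lognormal_factors(rng, 0.2, 30) * 100),
                           control=table(lognormal_factors(rng, 0.2, 30) * 100),
                           zones_sampled=("core", "intern"))

    def test_effect_eddy_classified_increase(self):
        res = classify_eddy(self._sampled(1.5), "nasc_epipelagic")
        assert res.outcome == "increase"
        assert res.n_inside == res.n_outside == 30

    def test_constant_surface_variable_is_null(self):
        res = classify_eddy(self._sampled(1.5), "sst")
        assert res.outcome == "null" and res.p_value == 1.0

    def test_unknown_variable_rejected(self):
        with pytest.raises(ValueError, match="unknown variable"):
            classify_eddy(self._sampled(1.0), "nasc_bathypelagic")


class TestSummaries:
    def test_proportions_10_20_70(self):
        df = pd.DataFrame({
            "eddy_id": range(10), "polarity": "AE", "variable": "nasc_epipelagic",
            "outcome": ["increase"] + ["decrease"] * 2 + ["null"] * 7,
        })
        out = summarize_proportions(df)
        row = out.iloc[0]
        assert (row["pct_increase"], row["pct_decrease"], row["pct_null"]) == (10.0, 20.0, 70.0)
        assert row["pct_increase"] + row["pct_decrease"] + row["pct_null"] == 100.0

    def test_all_null(self):
        df = pd.DataFrame({"eddy_id": range(4), "polarity": "CE",
                           "variable": "sst", "outcome": "null"})
        row = summarize_proportions(df).iloc[0]
        assert row["pct_null"] == 100.0 and row["pct_increase"] == 0.0

    def test_pooled_counts_equal_sum_of_polarity_cells(self):
        df = pd.DataFrame({
            "eddy_id": range(12),
            "polarity": ["AE"] * 7 + ["CE"] * 5,
            "variable": "nasc_epipelagic",
            "outcome": ["increase"] * 3 + ["null"] * 9,
        })
        per_cell = summarize_proportions(df)
        pooled = summarize_proportions(df.assign(polarity="ALL"))
        assert per_cell["n_eddies"].sum() == pooled["n_eddies"].iloc[0] == 12

    def test_mean_anomaly_per_outcome_class(self):
        df = pd.DataFrame({"eddy_id": [0, 1, 2], "polarity": "AE",
                           "variable": "nasc_epipelagic",
                           "outcome": ["increase", "increase", "null"]})
        anoms = pd.DataFrame({"eddy_id": [0, 1, 2], "variable": "nasc_epipelagic",
                              "anomaly": [0.5, 0.3, -0.01]})
        row = summarize_proportions(df, anoms).iloc[0]
        assert row["mean_anomaly_increase"] == pytest.approx(0.4)
        assert row["abs_mean_anomaly_increase"] == pytest.approx(0.4)


class TestCompareCharacteristics:
    def _results(self, n_inc=10, n_null=40):
        return pd.DataFrame({"eddy_id": range(n_inc + n_null),
                             "outcome": ["increase"] * n_inc + ["null"] * n_null})

    def test_constructed_separation_detected(self, rng):
        res = self._results()
        chars = pd.DataFrame({
            "eddy_id": range(50),
            # increasing eddies drawn 2 sd above the null population
            "amplitude_m": np.concatenate([rng.normal(0.3, 0.05, 10),
                                           rng.normal(0.2, 0.05, 40)]),
            "trapping": rng.normal(2.0, 0.5, 50),
        })
        out = compare_characteristics(res, chars)
        amp = out[(out["characteristic"] == "amplitude_m")
                  & (out["comparison"] == "increase_vs_null")].iloc[0]
        trap = out[(out["characteristic"] == "trapping")
                   & (out["comparison"] == "increase_vs_null")].iloc[0]
        assert amp["significant"]
        assert not trap["significant"]
        assert amp["effect_median"] > amp["null_median"]

    def test_identical_characteristic_not_significant(self):
        res = self._results(5, 5)
        chars = pd.DataFrame({"eddy_id": range(10), "age_days": 30.0})
        out = compare_characteristics(res, chars)
        assert (out["p_value"].dropna() >= 0.05).all()

    def test_singleton_group_still_defined(self):
        res = self._results(1, 20)
        chars = pd.DataFrame({"eddy_id": range(21),
                              "amplitude_m": np.linspace(0.0, 1.0, 21)})
        out = compare_characteristics(res, chars)
        row = out[out["comparison"] == "increase_vs_null"].iloc[0]
        assert np.isfinite(row["p_value"])

    def test_empty_group_skipped_with_notice(self):
        res = pd.DataFrame({"eddy_id": range(5), "outcome": "null"})
        chars = pd.DataFrame({"eddy_id": range(5), "amplitude_m": 0.1})
        out = compare_characteristics(res, chars)
        assert out["p_value"].isna().all()
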