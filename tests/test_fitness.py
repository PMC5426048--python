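"""Growth-rate inference: normalization, filtering, robust fits, hit calls."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poolfit import (
    FitnessSpec,
    SimConfig,
    call_hits,
    call_survivors,
    collapse_technical,
    combine_barcodes,
    count_identified,
    filter_low,
    fit_growth_rates,
    fit_slope,
    hybrid_specific_set,
    normalize,
    simulate_counts,
    standardize,
)
from poolfit.fitness import huber_slopes

from conftest import toy_counts


def ols_slope(x, y):
    """Closed-form least-squares slope, the independent oracle."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc = x - x.mean()
    return float(xc @ (y - y.mean()) / (xc @ xc))


class TestNormalize:
    def test_two_strain_example(self):
        counts = toy_counts([
            {"strain_id": "a", "count": 10},
            {"strain_id": "b", "count": 90},
        ])
        tpm = normalize(counts)["tpm"].tolist()
        assert tpm == [1e5, 9e5]

    def test_three_strain_example(self):
        counts = toy_counts([
            {"strain_id": "a", "count": 1},
            {"strain_id": "b", "count": 1},
            {"strain_id": "c", "count": 2},
        ])
        assert normalize(counts)["tpm"].tolist() == [250000.0, 250000.0, 500000.0]

    def test_tpm_sums_to_one_million_per_sample(self, small_experiment):
        _, counts = small_experiment
        tpm = normalize(counts)
        sums = tpm.groupby(["bio_rep", "tech_rep", "timepoint_index", "barcode_position"])["tpm"].sum()
        assert np.allclose(sums, 1e6)

    def test_zero_total_sample_raises_naming_sample(self):
        counts = toy_counts([
            {"strain_id": "a", "count": 0},
            {"strain_id": "b", "count": 0},
        ])
        with pytest.raises(ValueError, match="zero total"):
            normalize(counts)

    def test_positions_normalized_separately(self):
        counts = toy_counts([
            {"strain_id": "a", "count": 10, "barcode_position": "B1"},
            {"strain_id": "a", "count": 40, "barcode_position": "B2"},
        ])
        assert normalize(counts)["tpm"].tolist() == [1e6, 1e6]


class TestCollapseTechnical:
    def test_log_scale_average(self):
        # TPM pseudocounted to 4 and 16 -> (log2 4 + log2 16)/2 = 3
        counts = toy_counts([
            {"strain_id": "a", "count": 3, "tech_rep": 1},
            {"strain_id": "b", "count": 997, "tech_rep": 1},
            {"strain_id": "a", "count": 15, "tech_rep": 2},
            {"strain_id": "b", "count": 985, "tech_rep": 2},
        ])
        counts["count"] *= 1  # totals 1000 -> tpm = 1000 * count
        # rescale so strain a has TPM 3 and 15: totals must be 1e6
        counts.loc[counts["strain_id"] == "b", "count"] = [10**6 - 3, 10**6 - 15]
        ab = collapse_technical(normalize(counts))
        a_val = ab.loc[ab["strain_id"] == "a", "a"].item()
        assert a_val == pytest.approx(3.0, abs=1e-12)

    def test_single_replicate_is_identity(self):
        counts = toy_counts([
            {"strain_id": "a", "count": 3},
            {"strain_id": "b", "count": 10**6 - 3},
        ])
        ab = collapse_technical(normalize(counts))
        assert ab.loc[ab["strain_id"] == "a", "a"].item() == pytest.approx(2.0)

    def test_absent_strain_contributes_log2_one(self):
        # strain present in one tech rep only: missing rep counts as TPM 0
        counts = toy_counts([
            {"strain_id": "a", "count": 15, "tech_rep": 1},
            {"strain_id": "b", "count": 10**6 - 15, "tech_rep": 1},
            {"strain_id": "b", "count": 10**6, "tech_rep": 2},
        ])
        ab = collapse_technical(normalize(counts))
        a_val = ab.loc[ab["strain_id"] == "a", "a"].item()
        assert a_val == pytest.approx((math.log2(16) + 0.0) / 2)


class TestFilterLow:
    def test_strictly_more_than_threshold(self):
        counts = toy_counts([
            {"strain_id": "pass", "count": 31},
            {"strain_id": "edge", "count": 30},
            {"strain_id": "gone", "count": 0},
        ])
        kept = set(filter_low(counts)["strain_id"])
        assert kept == {"pass"}

    def test_technical_replicates_summed(self):
        counts = toy_counts([
            {"strain_id": "a", "count": 16, "tech_rep": 1},
            {"strain_id": "a", "count": 16, "tech_rep": 2},
        ])
        assert set(filter_low(counts)["strain_id"]) == {"a"}

    def test_only_first_timepoint_counts(self):
        counts = toy_counts([
            {"strain_id": "a", "count": 5, "timepoint_index": 0, "generations": 0.0},
            {"strain_id": "a", "count": 500, "timepoint_index": 1, "generations": 3.0},
        ])
        assert filter_low(counts).empty

    def test_positions_filtered_independently(self):
        rows = []
        for t, g in enumerate((0.0, 3.0, 6.0)):
            rows += [
                {"strain_id": "a", "barcode_position": "B1", "count": 100, "timepoint_index": t, "generations": g},
                {"strain_id": "a", "barcode_position": "B2", "count": 5, "timepoint_index": t, "generations": g},
                {"strain_id": "b", "barcode_position": "B1", "count": 900, "timepoint_index": t, "generations": g},
                {"strain_id": "b", "barcode_position": "B2", "count": 995, "timepoint_index": t, "generations": g},
            ]
        counts = toy_counts(rows)
        passing = filter_low(counts)
        a_pos = set(passing.loc[passing["strain_id"] == "a", "barcode_position"])
        assert a_pos == {"B1"}
        growth = fit_growth_rates(counts)
        row = growth[growth["strain_id"] == "a"].iloc[0]
        assert not np.isnan(row["slope_B1"])
        assert np.isnan(row["slope_B2"])
        assert row["slope"] == row["slope_B1"]  # B1-only slope reported


class TestFitSlope:
    def test_noiseless_line_recovered_exactly(self):
        g = np.array([0, 3, 6, 9, 12], float)
        a = 10 - 0.5 * g
        assert fit_slope(g, a) == pytest.approx(-0.5, abs=1e-12)

    def test_two_points_give_exact_difference_quotient(self):
        assert fit_slope([0, 4], [1.0, 3.0]) == pytest.approx(0.5)

    def test_fewer_than_two_points_undefined(self):
        assert math.isnan(fit_slope([0.0], [1.0]))
        assert math.isnan(fit_slope([0.0, float("nan")], [1.0, 2.0]))

    def test_huber_equals_ols_on_clean_data_within_1e6(self):
        rng = np.random.default_rng(0)
        g = np.arange(0, 30, 3.0)
        for _ in range(20):
            a = 5 - 0.2 * g  # noiseless: any M-estimator equals OLS
            assert abs(fit_slope(g, a) - ols_slope(g, a)) < 1e-6

    def test_huber_downweights_gross_outlier(self):
        g = np.arange(0, 27, 3.0)  # 9 points
        a = 8 - 0.5 * g
        a[-1] += 5.0  # gross outlier at a high-leverage point
        hub = fit_slope(g, a)
        ols = ols_slope(g, a)
        assert abs(hub - (-0.5)) < abs(ols - (-0.5))
        assert abs(hub - (-0.5)) < 0.02

    def test_batched_fit_matches_single_series(self):
        rng = np.random.default_rng(5)
        g = np.array([0, 3, 6, 10, 13, 16, 20], float)
        Y = 3 + rng.normal(0, 0.3, (12, g.size)) - 0.1 * g
        batched = huber_slopes(g, Y)
        singles = np.array([fit_slope(g, y) for y in Y])
        assert np.allclose(batched, singles, atol=1e-10)

    def test_agrees_with_statsmodels_rlm_under_contamination(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        g = np.arange(0, 30, 3.0)
        slopes_mine, slopes_sm = [], []
        for _ in range(25):
            a = 6 - 0.3 * g + rng.normal(0, 0.1, g.size)
            a[rng.integers(g.size)] += rng.choice([-4, 4])
            slopes_mine.append(fit_slope(g, a))
            X = sm.add_constant(g)
            fit = sm.RLM(a, X, M=sm.robust.norms.HuberT(t=1.345)).fit()
            slopes_sm.append(fit.params[1])
        assert np.allclose(slopes_mine, slopes_sm, atol=5e-3)


class TestCombineAndStandardize:
    def test_mean_of_two_defined(self):
        assert combine_barcodes(-0.4, -0.6) == pytest.approx(-0.5)

    def test_single_defined_passes_through(self):
        assert combine_barcodes(-0.4, float("nan")) == pytest.approx(-0.4)

    def test_both_undefined_is_missing(self):
        assert math.isnan(combine_barcodes(float("nan"), float("nan")))

    def test_three_value_example_sample_sd(self):
        z = standardize(pd.Series([1.0, 2.0, 3.0]))
        assert np.allclose(z, [-1, 0, 1])  # sample sd (n-1) of (1,2,3) is 1

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        st.lists(st.floats(-10, 10, allow_nan=False), min_size=3, max_size=50).filter(
            lambda v: max(v) - min(v) > 1e-6
        )
    )
    def test_output_has_mean_zero_sd_one(self, values):
        z = standardize(pd.Series(values, dtype=float))
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.std(ddof=1) == pytest.approx(1.0, rel=1e-9)

    def test_missing_values_stay_missing(self):
        z = standardize(pd.Series([1.0, np.nan, 3.0, 5.0]))
        assert math.isnan(z.iloc[1]) and not z.drop(index=1).isna().any()

    def test_degenerate_stratum_raises(self):
        with pytest.raises(ValueError):
            standardize(pd.Series([2.0, 2.0, 2.0]))
        with pytest.raises(ValueError):
            standardize(pd.Series([2.0, np.nan]))


def growth_row(strain, rep, z):
    return {
        "strain_id": strain, "pool": "hybrid", "condition": "YPD", "bio_rep": rep,
        "slope_B1": 0.0, "slope_B2": 0.0, "slope": 0.0, "n_points": 5, "z": z,
    }


class TestCallHits:
    @pytest.mark.parametrize(
        "za,zb,expected",
        [(-2.0, -1.6, True), (-2.0, -1.0, False), (-1.5, -1.5, False), (-1.51, -1.51, True)],
    )
    def test_threshold_is_strict_and_requires_both_reps(self, za, zb, expected):
        growth = pd.DataFrame([growth_row("s", "A", za), growth_row("s", "B", zb)])
        hit = call_hits(growth)
        assert bool(hit["is_hit"].item()) is expected

    def test_missing_replicate_is_unevaluable_not_hit(self):
        growth = pd.DataFrame([growth_row("s", "A", -3.0), growth_row("s", "B", np.nan)])
        hit = call_hits(growth)
        assert not hit["is_hit"].item()
        assert not hit["evaluable"].item()


def abundance_rows(strain, rep, tpms, pool="cerevisiae", condition="EtOH8"):
    return [
        {
            "strain_id": strain, "pool": pool, "background": pool, "condition": condition,
            "bio_rep": rep, "barcode_position": pos, "timepoint_index": t,
            "generations": 3.0 * t, "a": math.log2(tpm + 1),
        }
        for t, tpm in enumerate(tpms)
        for pos in ("B1", "B2")
    ]


class TestCallSurvivors:
    def test_abundant_in_all_four_cells_is_survivor(self):
        ab = pd.DataFrame(abundance_rows("s", "A", [9, 9, 9]) + abundance_rows("s", "B", [0, 9, 9]))
        surv = call_survivors(ab, "cerevisiae", "EtOH8")
        assert surv["is_survivor"].item()

    def test_threshold_is_strict(self):
        # TPM 3 -> log2(4) = 2 exactly: not above the cut
        ab = pd.DataFrame(abundance_rows("s", "A", [9, 9, 3]) + abundance_rows("s", "B", [9, 9, 9]))
        assert not call_survivors(ab, "cerevisiae", "EtOH8")["is_survivor"].item()

    def test_absent_strain_is_not_survivor(self):
        ab = pd.DataFrame(abundance_rows("s", "A", [0, 0, 0]) + abundance_rows("s", "B", [0, 0, 0]))
        assert not call_survivors(ab, "cerevisiae", "EtOH8")["is_survivor"].item()

    def test_must_hold_in_every_replicate(self):
        ab = pd.DataFrame(abundance_rows("s", "A", [9, 9, 9]) + abundance_rows("s", "B", [9, 9, 1]))
        assert not call_survivors(ab, "cerevisiae", "EtOH8")["is_survivor"].item()


class TestHybridSpecificSet:
    def hits_table(self, rows):
        return pd.DataFrame(
            [{"strain_id": s, "pool": p, "condition": c, "is_hit": h, "evaluable": True} for s, p, c, h in rows]
        )

    def test_hybrid_only_hit_included(self):
        hits = self.hits_table([("s", "hybrid", "YPD", True), ("s", "cerevisiae", "YPD", False)])
        assert hybrid_specific_set(hits) == {"s"}

    def test_hit_in_both_backgrounds_excluded(self):
        hits = self.hits_table([("s", "hybrid", "YPD", True), ("s", "cerevisiae", "YPD", True)])
        assert hybrid_specific_set(hits) == set()

    def test_cross_condition_cerevisiae_hit_excluded_under_no_condition_rule(self):
        hits = self.hits_table([("s", "hybrid", "YPD", True), ("s", "cerevisiae", "EtOH", True)])
        assert hybrid_specific_set(hits, mode="no_condition") == set()
        assert hybrid_specific_set(hits, mode="per_condition") == {"s"}


class TestCountIdentified:
    def test_single_passing_strain(self):
        counts = toy_counts([
            {"strain_id": "a", "count": 31},
            {"strain_id": "b", "count": 12},
            {"strain_id": "c", "count": 0},
        ])
        per_pool, per_tp = count_identified(counts)
        assert per_pool["hybrid"] == 1
        assert per_tp["n_identified"].tolist() == [1]

    def test_all_zero_counts(self):
        counts = toy_counts([{"strain_id": "a", "count": 0}, {"strain_id": "b", "count": 1}])
        per_pool, _ = count_identified(counts)
        assert per_pool.get("hybrid", 0) == 0

    def test_additive_over_disjoint_strain_sets(self):
        c1 = toy_counts([{"strain_id": "a", "count": 40}])
        c2 = toy_counts([{"strain_id": "b", "count": 50}])
        both = pd.concat([c1, c2], ignore_index=True)
        assert count_identified(both)[0]["hybrid"] == count_identified(c1)[0]["hybrid"] + count_identified(c2)[0]["hybrid"]


class TestReplicateStructure:
    def test_within_condition_replicates_correlate_more_than_across_conditions(self):
        # condition-specific fitness effects: replicates of the same condition
        # must agree better than different conditions do
        base = dict(n_strains=400, depth=200_000, schedule=(0, 5, 10, 15, 20), n_tech_reps=1)
        cfg1 = SimConfig(**base, seed=41, condition="YPD", fitness_spec=FitnessSpec(0.15, 0.7, 0.9))
        cfg2 = SimConfig(**base, seed=42, condition="EtOH", fitness_spec=FitnessSpec(0.15, 0.7, 0.9))
        frames = []
        for cfg in (cfg1, cfg2):
            _, counts = simulate_counts(cfg)
            frames.append(fit_growth_rates(counts))
        growth = pd.concat(frames, ignore_index=True)
        wide = growth.pivot_table(index="strain_id", columns=["condition", "bio_rep"], values="slope")
        within = wide[("YPD", "A")].corr(wide[("YPD", "B")])
        across = wide[("YPD", "A")].corr(wide[("EtOH", "A")])
        assert within > 0.8
        assert within > across + 0.3
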