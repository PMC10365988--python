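"""Two-stage Monte Carlo: determinism, common random numbers, skew diagnostics."""

import itertools

import numpy as np
import pandas as pd
import pytest

import dietfootprint as dfp
from dietfootprint.cohort import item_column
from dietfootprint.lca import LCADatabase
from dietfootprint.linkage import FFQItem, LinkTable
from dietfootprint.montecarlo import (MCConfig, group_iteration_values, intake_matrix,
                                      iterationwise_ratios, median_of_sum_oracle, skew_gap,
                                      stage1_draws, stage2_footprints, summarize_group)
from conftest import cohort_frame, make_cohort_row


def single_indicator_db(categories: dict[str, list[float]]) -> LCADatabase:
    """Categories whose records put their value in the CO2 (other-stage) slot."""
    rows = []
    for cat, values in categories.items():
        for i, v in enumerate(values):
            rows.append(dict(category=cat, enteric_co2e=0.0, fertilizer_co2e=0.0, other_co2e=v,
                             land_m2=v, water_m3=0.0, eutrophication_gpo4e=0.0, biodiversity=0.0,
                             organic=False, source_id=f"{cat}-{i}"))
    return LCADatabase(pd.DataFrame(rows))


def direct_links(categories, meat=None) -> LinkTable:
    return LinkTable([FFQItem(c, category=c, is_meat=(c == meat)) for c in categories])


class TestStage1:
    def test_determinism(self, default_db, default_links):
        cfg = MCConfig(n_iterations=50, seed=9)
        a = stage1_draws(default_db, default_links, cfg)
        b = stage1_draws(default_db, default_links, cfg)
        assert np.array_equal(a.values, b.values)
        c = stage1_draws(default_db, default_links, MCConfig(n_iterations=50, seed=10))
        assert not np.array_equal(a.values, c.values)

    def test_point_mass_database_gives_identical_iterations(self, point_mass_db, default_links):
        draws = stage1_draws(point_mass_db, default_links, MCConfig(n_iterations=20, seed=1))
        assert np.allclose(draws.values, draws.values[0])

    def test_single_iteration_shape(self, default_db, default_links):
        draws = stage1_draws(default_db, default_links, MCConfig(n_iterations=1, seed=1))
        assert draws.values.shape == (1, len(default_links.items), 7)

    def test_item_order_independence(self):
        db = single_indicator_db({"a": [1, 2, 3], "b": [4, 5, 6]})
        cfg = MCConfig(n_iterations=100, seed=3)
        fwd = stage1_draws(db, direct_links(["a", "b"]), cfg)
        rev = stage1_draws(db, direct_links(["b", "a"]), cfg)
        assert np.array_equal(fwd.values[:, 0], rev.values[:, 1])  # item "a"
        assert np.array_equal(fwd.values[:, 1], rev.values[:, 0])  # item "b"

    def test_marginal_mode_breaks_joint_coherence(self):
        rows = {"x": [1.0, 10.0]}
        db = single_indicator_db(rows)
        cfg_r = MCConfig(n_iterations=400, seed=5, draw_mode="record")
        cfg_m = MCConfig(n_iterations=400, seed=5, draw_mode="marginal")
        links = direct_links(["x"])
        rec = stage1_draws(db, links, cfg_r).values[:, 0]
        assert np.allclose(rec[:, 0], rec[:, 3])  # co2 slot always matches land slot
        mar = stage1_draws(db, links, cfg_m).values[:, 0]
        assert not np.allclose(mar[:, 0], mar[:, 3])


class TestStage2:
    def test_zero_intakes_zero_footprint(self, point_mass_db, default_links):
        row = make_cohort_row(item_ids=default_links.item_ids)  # all intakes 0
        cfg = MCConfig(n_iterations=5, seed=1, energy_standardize=False)
        draws = stage1_draws(point_mass_db, default_links, cfg)
        totals = stage2_footprints(cohort_frame([row]), draws, cfg)
        assert np.all(totals == 0.0)

    def test_linearity_under_common_draws(self, default_db, default_links):
        rng = np.random.default_rng(0)
        base = {i: float(rng.uniform(10, 200)) for i in default_links.item_ids}
        rows = [make_cohort_row("a", intakes=base, item_ids=default_links.item_ids),
                make_cohort_row("b", intakes={k: 2 * v for k, v in base.items()},
                                item_ids=default_links.item_ids)]
        cfg = MCConfig(n_iterations=40, seed=2, energy_standardize=False)
        draws = stage1_draws(default_db, default_links, cfg)
        totals = stage2_footprints(cohort_frame(rows), draws, cfg)
        assert np.array_equal(totals[1], 2.0 * totals[0])

    def test_point_mass_single_item_value(self):
        db = single_indicator_db({"c": [10.0]})  # 10 kg CO2 / kg -> 0.01 / g
        links = direct_links(["c"])
        cfg = MCConfig(n_iterations=7, seed=1, energy_standardize=False)
        draws = stage1_draws(db, links, cfg)
        totals = stage2_footprints(
            cohort_frame([make_cohort_row(intakes={"c": 100.0}, item_ids=["c"])]), draws, cfg)
        assert np.allclose(totals[0, :, 0], 1.0)  # 100 g x 0.01 kg/g

    def test_misaligned_items_raise(self, default_db, default_links):
        cfg = MCConfig(n_iterations=2, seed=1)
        draws = stage1_draws(default_db, default_links, cfg)
        with pytest.raises(dfp.AlignmentError):
            stage2_footprints(cohort_frame([make_cohort_row(item_ids=["meat"])]), draws, cfg)


class TestSummaries:
    def test_percentile_sanity_and_zero_width_at_point_mass(self, point_mass_db, default_links,
                                                            small_cohort):
        mc = dfp.FootprintMonteCarlo(database=point_mass_db, links=default_links,
                                     n_iterations=30, seed=4).fit(small_cohort)
        t = mc.group_summary_.table
        assert (t["lower"] <= t["median"] + 1e-12).all()
        assert (t["median"] <= t["upper"] + 1e-12).all()
        assert np.allclose(t["upper"] - t["lower"], 0.0, atol=1e-12)

    def test_interval_width_shrinks_with_sigma(self, default_links, small_cohort):
        widths = []
        for s in (1.0, 0.25):
            db = dfp.gen_lca_database(dfp.default_lca_spec(sigma_scale=s), seed=11)
            mc = dfp.FootprintMonteCarlo(database=db, links=default_links,
                                         n_iterations=150, seed=4).fit(small_cohort)
            t = mc.group_summary_.table
            widths.append(float((t["upper"] - t["lower"]).sum()))
        assert widths[1] < widths[0]

    def test_standardization_removes_age_mix_confounding(self):
        # two groups identical within stratum but with opposite age mixes
        db = single_indicator_db({"c": [1.0, 3.0, 9.0]})
        links = direct_links(["c"])
        rows = []
        intake_by_stratum = {25: 50.0, 65: 150.0}
        mix = {"ga": [25] * 8 + [65] * 2, "gb": [25] * 2 + [65] * 8}
        for g, ages in mix.items():
            for i, age in enumerate(ages):
                rows.append(make_cohort_row(f"{g}{i}", age=age,
                                            intakes={"c": intake_by_stratum[age]}, item_ids=["c"]))
        df = cohort_frame(rows)
        groups = pd.Series(["ga"] * 10 + ["gb"] * 10)
        cfg = MCConfig(n_iterations=50, seed=8, energy_standardize=False)
        draws = stage1_draws(db, links, cfg)
        totals = stage2_footprints(df, draws, cfg)
        weights = dfp.stratum_weights(df)
        from dietfootprint.cohort import strata
        summary = summarize_group(totals, groups, weights, cfg, strata(df))
        a = summary.table.loc[("ga", "co2_kg"), "median"]
        b = summary.table.loc[("gb", "co2_kg"), "median"]
        assert a == pytest.approx(b)  # identical standardized summaries

    def test_empty_stratum_renormalized_with_warning(self, caplog):
        db = single_indicator_db({"c": [2.0]})
        links = direct_links(["c"])
        rows = [make_cohort_row("a", age=25, intakes={"c": 100.0}, item_ids=["c"]),
                make_cohort_row("b", age=65, intakes={"c": 100.0}, item_ids=["c"]),
                make_cohort_row("d", age=25, intakes={"c": 100.0}, item_ids=["c"])]
        df = cohort_frame(rows)
        groups = pd.Series(["ga", "ga", "gb"])  # gb missing from the 60|F stratum
        cfg = MCConfig(n_iterations=3, seed=8, energy_standardize=False)
        draws = stage1_draws(db, links, cfg)
        totals = stage2_footprints(df, draws, cfg)
        from dietfootprint.cohort import strata
        with caplog.at_level("WARNING"):
            summary = summarize_group(totals, groups, dfp.stratum_weights(df), cfg, strata(df))
        assert "renormalized" in caplog.text
        assert summary.table.loc[("gb", "co2_kg"), "median"] == pytest.approx(0.2)


class TestRatios:
    def test_reference_ratio_is_identically_one(self, default_db, default_links, small_cohort):
        mc = dfp.FootprintMonteCarlo(database=default_db, links=default_links,
                                     n_iterations=60, seed=2).fit(small_cohort)
        ref = mc.ratio_summary_.table.loc["high_meat"]
        assert np.allclose(ref[["median", "lower", "upper"]], 1.0)

    def test_common_draw_cancellation_for_scaled_diets(self, default_db, default_links):
        # group "b" eats exactly 2x group "a": iteration-wise ratio is exactly 2,
        # with zero interval width despite food-level uncertainty
        rng = np.random.default_rng(1)
        items = default_links.item_ids
        rows = []
        labels = []
        for p in range(12):
            base = {i: float(rng.uniform(5, 300)) for i in items}
            rows.append(make_cohort_row(f"a{p}", intakes=base, item_ids=items))
            labels.append("a")
            rows.append(make_cohort_row(f"b{p}", intakes={k: 2 * v for k, v in base.items()},
                                        item_ids=items))
            labels.append("b")
        df = cohort_frame(rows)
        cfg = MCConfig(n_iterations=200, seed=3, energy_standardize=False, reference_group="a")
        draws = stage1_draws(default_db, default_links, cfg)
        totals = stage2_footprints(df, draws, cfg)
        from dietfootprint.cohort import strata
        summary = summarize_group(totals, pd.Series(labels), dfp.stratum_weights(df), cfg, strata(df))
        ratios = iterationwise_ratios(summary, cfg)
        b = ratios.table.loc["b"]
        assert np.allclose(b["median"], 2.0, rtol=0, atol=1e-12)
        assert np.allclose(b["upper"] - b["lower"], 0.0, atol=1e-12)

    def test_ratio_interval_narrower_than_naive_percentile_division(self, default_db,
                                                                    default_links, small_cohort):
        # shared draws correlate groups across iterations, so iteration-wise
        # ratio intervals beat dividing independently-formed percentiles
        mc = dfp.FootprintMonteCarlo(database=default_db, links=default_links,
                                     n_iterations=400, seed=6).fit(small_cohort)
        g = mc.group_summary_.table
        r = mc.ratio_summary_.table
        for group in ("vegan", "vegetarian", "low_meat"):
            for ind in ("co2_kg", "land_m2"):
                ref = g.loc[("high_meat", ind)]
                naive_lo = g.loc[(group, ind), "lower"] / ref["upper"]
                naive_hi = g.loc[(group, ind), "upper"] / ref["lower"]
                width = r.loc[(group, ind), "upper"] - r.loc[(group, ind), "lower"]
                assert width < (naive_hi - naive_lo)

    def test_missing_reference_raises(self, default_db, default_links, small_cohort):
        mc = dfp.FootprintMonteCarlo(database=default_db, links=default_links, n_iterations=5,
                                     seed=1, reference_group="nope")
        with pytest.raises(dfp.DataError):
            mc.fit(small_cohort)


class TestDiceOracle:
    @pytest.mark.parametrize("faces,n,expected", [
        ([2, 4, 8, 16, 32, 64], 2, 35.0),   # doubling dice: heavily right-skewed
        ([2, 4, 8, 16, 32, 64], 1, 12.0),
        ([1, 2, 3, 4, 5, 6], 2, 7.0),       # standard dice: no skew, median doubles
        ([1, 2, 3, 4, 5, 6], 1, 3.5),
    ])
    def test_worked_examples(self, faces, n, expected):
        assert median_of_sum_oracle(faces, n) == expected

    @pytest.mark.parametrize("faces,n", [
        ([2, 4, 8, 16, 32, 64], 2), ([1, 2, 3], 3), ([1, 5, 9, 13], 2), ([2, 3], 4),
    ])
    def test_agrees_with_independent_brute_force(self, faces, n):
        # independent enumeration: repeated outer sums + numpy median
        sums = np.array([0.0])
        for _ in range(n):
            sums = np.add.outer(sums, np.asarray(faces, float)).ravel()
        assert median_of_sum_oracle(faces, n) == pytest.approx(np.median(sums))

    def test_input_validation(self):
        with pytest.raises(dfp.DataError):
            median_of_sum_oracle([], 2)
        with pytest.raises(dfp.DataError):
            median_of_sum_oracle([1, 2], 7)


class TestSkewGap:
    def test_point_mass_gap_is_zero(self, point_mass_db, default_links):
        cfg = MCConfig(n_iterations=50, seed=2, energy_standardize=False)
        diet = {i: 100.0 for i in default_links.item_ids}
        gap = skew_gap(point_mass_db, default_links, diet, cfg)
        assert np.allclose(gap.values, 0.0, atol=1e-9)

    def test_doubling_dice_database(self):
        # two items, each a doubling die (1000 g at X kg/kg = X per die):
        # median of MC sums ~35 versus sum of medians 24 -> gap ~11
        faces = [2.0, 4.0, 8.0, 16.0, 32.0, 64.0]
        db = single_indicator_db({"d1": faces, "d2": faces})
        links = direct_links(["d1", "d2"])
        cfg = MCConfig(n_iterations=20_000, seed=10, energy_standardize=False)
        gap = skew_gap(db, links, {"d1": 1000.0, "d2": 1000.0}, cfg)
        assert gap["co2_kg"] == pytest.approx(11.0, abs=1.5)  # sampling granularity of the sum

    def test_lognormal_database_positive_gap(self):
        spec = dfp.LCAGeneratorSpec({
            f"c{k}": dfp.CategoryLaw(co2e_median=1.0, land_m2=1.0, water_m3=1.0,
                                     eutrophication_gpo4e=1.0, biodiversity=1.0,
                                     sigma=1.0, n_records=40, stage_split=(0.3, 0.3, 0.4))
            for k in range(50)})
        db = dfp.gen_lca_database(spec, seed=33)
        links = direct_links([f"c{k}" for k in range(50)])
        cfg = MCConfig(n_iterations=10_000, seed=7, energy_standardize=False)
        gap = skew_gap(db, links, {f"c{k}": 100.0 for k in range(50)}, cfg)
        assert (gap.values > 0).all()


class TestEstimatorSurface:
    def test_sklearn_params_round_trip(self, default_db, default_links):
        mc = dfp.FootprintMonteCarlo(database=default_db, links=default_links, n_iterations=3)
        params = mc.get_params(deep=False)
        assert params["n_iterations"] == 3
        mc.set_params(n_iterations=5, seed=42)
        assert mc.n_iterations == 5 and mc.seed == 42

    def test_fit_deterministic(self, default_db, default_links, small_cohort):
        a = dfp.FootprintMonteCarlo(database=default_db, links=default_links,
                                    n_iterations=40, seed=5).fit(small_cohort)
        b = dfp.FootprintMonteCarlo(database=default_db, links=default_links,
                                    n_iterations=40, seed=5).fit(small_cohort)
        pd.testing.assert_frame_equal(a.group_summary_.table, b.group_summary_.table)
        pd.testing.assert_frame_equal(a.ratio_summary_.table, b.ratio_summary_.table)

    def test_group_statistic_median_path(self, default_db, default_links, small_cohort):
        mc = dfp.FootprintMonteCarlo(database=default_db, links=default_links, n_iterations=20,
                                     seed=5, group_statistic="median").fit(small_cohort)
        t = mc.group_summary_.table
        assert (t["lower"] <= t["median"] + 1e-12).all()

    def test_energy_standardization_commutes_with_footprint(self, point_mass_db, default_links):
        # footprint of standardized diet = (2000/energy) x footprint of raw diet
        items = default_links.item_ids
        row = make_cohort_row(energy=1000.0, intakes={i: 50.0 for i in items}, item_ids=items)
        df = cohort_frame([row])
        cfg_raw = MCConfig(n_iterations=4, seed=1, energy_standardize=False)
        cfg_std = MCConfig(n_iterations=4, seed=1, energy_standardize=True)
        draws = stage1_draws(point_mass_db, default_links, cfg_raw)
        raw = stage2_footprints(df, draws, cfg_raw)
        std = stage2_footprints(df, draws, cfg_std)
        assert np.allclose(std, 2.0 * raw)

    def test_invalid_config_rejected(self):
        with pytest.raises(dfp.ConfigurationError):
            MCConfig(n_iterations=0)
        with pytest.raises(dfp.ConfigurationError):
            MCConfig(percentiles=(97.5, 2.5))
        with pytest.raises(dfp.ConfigurationError):
            MCConfig(draw_mode="bogus")
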