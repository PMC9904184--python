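"""Unit tests for the mobile-bag design and disappearance statistics."""

import numpy as np
import pytest

from fermkin import (
    BagRecord,
    DesignPlan,
    assign_interval,
    common_slope_fit,
    disappearance_table,
    enumerate_bags,
    fsa,
    nutrient_disappearance,
    pool_residues,
    recovery_rate,
    transit_time,
    washing_loss,
)
from fermkin.errors import (
    DesignError,
    DomainError,
    MissingNutrientError,
    NoDataError,
    SingularDesignError,
)


def _bag(hour, grass="PR", harvest="early", pore=15, feed_in=0.5, residue=0.3,
         site="caecum", comp=None):
    return BagRecord(
        bag_id=f"b{hour}-{np.random.default_rng(0).integers(1e6)}",
        grass=grass, harvest=harvest, pore_size=pore, feed_in=feed_in,
        recovery_site=site, recovery_hour=hour, residue_mass=residue,
        residue_composition=comp,
    )


class TestDesign:
    def test_default_plan_yields_352_bags(self):
        records = enumerate_bags(DesignPlan(), seed=0)
        assert len(records) == 352
        assert sum(r.recovery_site == "wash_control" for r in records) == 32

    def test_total_is_product_of_factors(self):
        # 2 grasses x 2 harvests x 2 pores x (40 + 4)
        assert DesignPlan().total_bags == 2 * 2 * 2 * (40 + 4)

    def test_single_cell_plan(self):
        plan = DesignPlan(
            grasses=("PR",), harvests=("early",), pore_sizes=(15,),
            intubated_reps=40, wash_reps=0, horses=0, periods=0,
        )
        assert len(enumerate_bags(plan, seed=0)) == 40

    def test_latin_square_balance(self):
        records = enumerate_bags(DesignPlan(), seed=3)
        intubated = [r for r in records if r.recovery_site != "wash_control"]
        # 20 bags per horse per period
        from collections import Counter

        cells = Counter((r.horse, r.period) for r in intubated)
        assert set(cells.values()) == {20}
        # each horse sees each feed exactly once across periods
        feeds_per_horse = Counter((r.horse, r.grass, r.harvest) for r in intubated)
        assert set(feeds_per_horse.values()) == {20}

    def test_mismatched_square_raises(self):
        plan = DesignPlan(grasses=("PR",), horses=4, periods=4)
        with pytest.raises(DesignError):
            enumerate_bags(plan, seed=0)


class TestFsa:
    def test_reference_loading(self):
        value = fsa(0.5, 24.0)
        assert value == pytest.approx(20.83, abs=0.01)
        assert round(value) == 21

    def test_proportionality(self):
        assert fsa(0.24, 24.0) == pytest.approx(10.0)
        assert fsa(0.5, 12.0) == pytest.approx(2 * fsa(0.5, 24.0))

    def test_zero_area_raises(self):
        with pytest.raises(DomainError):
            fsa(0.5, 0.0)


class TestTransitTime:
    def test_single_check(self):
        assert transit_time([_bag(5), _bag(5)]) == pytest.approx(4.5)

    def test_weighted_mean_by_hand(self):
        bags = [_bag(2), _bag(2), _bag(4), _bag(4)]
        assert transit_time(bags) == pytest.approx(2.5)

    def test_convex_combination_bound(self):
        bags = [_bag(h) for h in (1, 3, 7, 10, 10)]
        value = transit_time(bags)
        assert 0.5 <= value <= 9.5

    def test_duplication_invariance(self):
        bags = [_bag(2), _bag(5), _bag(9)]
        assert transit_time(bags * 3) == pytest.approx(transit_time(bags))

    def test_empty_raises(self):
        with pytest.raises(NoDataError):
            transit_time([_bag(3, site="feces")])


class TestRecoveryRate:
    def test_extremes(self):
        lost = [_bag(None, site="lost") for _ in range(5)]
        assert recovery_rate(lost).caecal == 0.0
        found = [_bag(h) for h in (1, 2, 3)]
        assert recovery_rate(found) == (100.0, 100.0)

    def test_reference_scale(self):
        bags = [_bag(3) for _ in range(250)]
        bags += [_bag(None, site="feces") for _ in range(60)]
        bags += [_bag(None, site="lost") for _ in range(10)]
        rates = recovery_rate(bags)
        assert rates.caecal == pytest.approx(78.1, abs=0.05)
        assert rates.total == pytest.approx(96.9, abs=0.05)
        assert rates.caecal <= rates.total <= 100.0

    def test_wash_controls_excluded(self):
        bags = [_bag(3), _bag(None, site="wash_control")]
        assert recovery_rate(bags).caecal == 100.0

    def test_no_intubated_raises(self):
        with pytest.raises(DomainError):
            recovery_rate([_bag(None, site="wash_control")])


class TestAssignInterval:
    @pytest.mark.parametrize(
        "hour, label",
        [(1, "1-3"), (3, "1-3"), (4, "4-6"), (6, "4-6"), (7, "7-10"), (10, "7-10")],
    )
    def test_boundaries(self, hour, label):
        assert assign_interval(hour) == label

    @pytest.mark.parametrize("hour", [0, 11, 12])
    def test_out_of_range(self, hour):
        with pytest.raises(DomainError):
            assign_interval(hour)


class TestNutrientDisappearance:
    FEED = {"WSC": 200.0, "CP": 150.0}

    def test_extremes(self):
        assert nutrient_disappearance(0.5, self.FEED, 0.0, {"WSC": 0.0}, "WSC") == 100.0
        assert nutrient_disappearance(0.5, self.FEED, 0.5, self.FEED, "WSC") == 0.0

    def test_wsc_scale(self):
        # 0.5 g feed at 200 g/kg WSC, 0.25 g residue at 8 g/kg
        d = nutrient_disappearance(0.5, self.FEED, 0.25, {"WSC": 8.0}, "WSC")
        assert d == pytest.approx(98.0, abs=0.01)

    def test_scale_invariance(self):
        d1 = nutrient_disappearance(0.5, self.FEED, 0.3, {"WSC": 50.0}, "WSC")
        d2 = nutrient_disappearance(1.5, self.FEED, 0.9, {"WSC": 50.0}, "WSC")
        assert d1 == pytest.approx(d2, rel=1e-12)

    def test_missing_nutrient(self):
        with pytest.raises(MissingNutrientError):
            nutrient_disappearance(0.5, self.FEED, 0.25, {"WSC": 8.0}, "fructan")

    def test_dm_uses_masses_only(self):
        assert nutrient_disappearance(0.5, {}, 0.25, {}, "DM") == pytest.approx(50.0)


class TestWashingLoss:
    FEED = {("PR", "early"): {"WSC": 200.0, "fructan": 100.0}}

    def test_residue_equal_to_feed_is_zero_loss(self):
        bag = _bag(None, site="wash_control", residue=0.5,
                   comp={"WSC": 200.0, "fructan": 100.0})
        out = washing_loss([bag], self.FEED, nutrients=("WSC", "fructan"))
        assert np.allclose(out["loss_pct"], 0.0)

    def test_fully_soluble_nutrient_is_total_loss(self):
        bag = _bag(None, site="wash_control", residue=0.3,
                   comp={"WSC": 0.0, "fructan": 50.0})
        out = washing_loss([bag], self.FEED, nutrients=("WSC",))
        assert out["loss_pct"].iloc[0] == pytest.approx(100.0)

    def test_generated_fructan_loss_recovers_target(self):
        # generator round-trip: wash controls built from a 70% soluble fraction
        from fermkin import BagScenario, simulate_bag_study

        records, truth = simulate_bag_study(BagScenario(seed=5))
        wash = [r for r in records if r.recovery_site == "wash_control"]
        out = washing_loss(wash, BagScenario().feed_comps, nutrients=("fructan",))
        assert np.allclose(out["loss_pct"], 70.0, atol=0.5)


class TestPooling:
    @staticmethod
    def _study():
        from fermkin import BagScenario, simulate_bag_study

        records, _ = simulate_bag_study(BagScenario(seed=13))
        return records

    def test_default_study_yields_24_pools(self):
        pools = [p for p in pool_residues(self._study()) if not p.empty]
        assert len(pools) == 24  # 2 x 2 x 2 x 3

    def test_pooled_mass_is_sum_of_members(self):
        records = self._study()
        pools = pool_residues(records)
        for pool in pools:
            members = [
                r for r in records
                if r.recovery_site == "caecum"
                and (r.grass, r.harvest, r.pore_size) == (pool.grass, pool.harvest, pool.pore_size)
                and assign_interval(r.recovery_hour) == pool.interval
            ]
            assert pool.pooled_mass == pytest.approx(sum(r.residue_mass for r in members))
            assert pool.n_bags == len(members)

    def test_single_bag_pool_equals_that_bag(self):
        bag = _bag(2, residue=0.31, comp={"WSC": 10.0})
        pool = [p for p in pool_residues([bag]) if not p.empty][0]
        assert pool.pooled_mass == pytest.approx(0.31)
        assert pool.composition == pytest.approx({"WSC": 10.0})
        assert pool.interval == "1-3"

    def test_pooled_disappearance_equals_mass_weighted_mean(self):
        # oracle: for equal feed composition, pooled disappearance equals the
        # feed-amount-weighted mean of per-bag disappearances
        feed = {("PR", "early"): {"WSC": 200.0}}
        bags = [
            _bag(2, feed_in=0.5, residue=0.30, comp={"WSC": 12.0}),
            _bag(3, feed_in=0.4, residue=0.20, comp={"WSC": 30.0}),
        ]
        per_bag = [
            nutrient_disappearance(b.feed_in, feed[("PR", "early")], b.residue_mass,
                                   b.residue_composition, "WSC")
            for b in bags
        ]
        weights = [b.feed_in * 200.0 for b in bags]
        expected = np.average(per_bag, weights=weights)
        pools = [p for p in pool_residues(bags) if not p.empty]
        table = disappearance_table(pools, feed, nutrients=("WSC",))
        assert table["disappearance_pct"].iloc[0] == pytest.approx(expected, rel=1e-12)


class TestCommonSlopeFit:
    INTERCEPTS = {
        ("PR", "early"): 38.01,
        ("PR", "late"): 32.51,
        ("CF", "early"): 35.29,
        ("CF", "late"): 21.37,
    }

    def _noiseless_points(self):
        times = np.arange(0.5, 10.0, 1.0)
        return [
            (group, t, intercept + 0.608 * t)
            for group, intercept in self.INTERCEPTS.items()
            for t in times
        ]

    def test_exact_recovery_of_reference_equations(self):
        fit = common_slope_fit(self._noiseless_points())
        assert fit.slope == pytest.approx(0.608, abs=1e-10)
        for group, intercept in self.INTERCEPTS.items():
            assert fit.intercepts[group] == pytest.approx(intercept, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_flat_identical_groups(self):
        pts = [(("PR", "early"), t, 50.0) for t in (1.0, 2.0, 3.0)]
        pts += [(("CF", "late"), t, 50.0) for t in (1.0, 2.0, 3.0)]
        fit = common_slope_fit(pts)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.intercepts[("PR", "early")] == pytest.approx(fit.intercepts[("CF", "late")])

    def test_affine_equivariance(self):
        pts = self._noiseless_points()
        fit = common_slope_fit(pts)
        shifted = common_slope_fit([(g, t, d + 7.5) for g, t, d in pts])
        assert shifted.slope == pytest.approx(fit.slope, abs=1e-10)
        for group in fit.intercepts:
            assert shifted.intercepts[group] == pytest.approx(
                fit.intercepts[group] + 7.5, abs=1e-9
            )

    def test_singular_design_raises(self):
        pts = [(("PR", "early"), 2.0, 40.0), (("CF", "late"), 2.0, 30.0)]
        with pytest.raises(SingularDesignError):
            common_slope_fit(pts)

    def test_monte_carlo_slope_recovery(self):
        # heteroscedastic noise sd 2, 40 points/group, 200 seeds:
        # the Monte-Carlo mean slope stays within +/-0.1 of truth
        rng = np.random.default_rng(42)
        groups = list(self.INTERCEPTS)
        slopes = []
        for _ in range(200):
            pts = []
            for group in groups:
                t = rng.uniform(0.5, 9.5, 40)
                scale = 2.0 * (0.5 + rng.random(40))  # heteroscedastic
                d = self.INTERCEPTS[group] + 0.608 * t + rng.normal(0, scale)
                pts += list(zip([group] * 40, t, d))
            slopes.append(common_slope_fit(pts).slope)
        assert abs(np.mean(slopes) - 0.608) < 0.1
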