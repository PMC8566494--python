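"""Cost-model tests: the printed cost curves at hand-evaluated points, the
modality costs on constructed layouts, and the objective combination."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epilayout import (
    Electrode,
    Layout,
    LowerBounds,
    Weights,
    baseline_area,
    build_baseline_layout,
    eda_cost,
    eda_gland_count,
    ecg_cost,
    emg_muscle_cost,
    emg_total,
    global_objective,
    lower_bound_penalty,
    nu,
    omega,
)
from epilayout.costs import (
    EDA_ELECTRODE_RADIUS,
    EMG_ELECTRODE_RADIUS,
    area_cost,
    combine_objective,
    layout_hull_area,
    measurement_roster,
)
from epilayout.errors import ConfigError, DomainError, RoleError


def emg_el(center, muscle="PL", member="A"):
    return Electrode(tuple(center), EMG_ELECTRODE_RADIUS, "emg",
                     member=member, muscle=muscle)


def eda_el(center, member="A"):
    return Electrode(tuple(center), EDA_ELECTRODE_RADIUS, "eda", member=member)


def ecg_el(center, member="A"):
    return Electrode(tuple(center), EMG_ELECTRODE_RADIUS, "ecg", member=member)


class TestOrientationCost:
    @pytest.mark.parametrize("theta, expected", [
        (0.0, 0.0),
        (10.0, 0.0057 * 10 + 0.000181 * 100),
        (30.0, 0.3339),
        (45.0, 0.0057 * 45 + 0.000181 * 2025),
        (60.0, 0.0057 * 60 + 0.000181 * 3600),
        (60.0001, 1.0),
        (75.0, 1.0),
        (90.0, 1.0),
    ])
    def test_printed_polynomial(self, theta, expected):
        assert omega(theta) == pytest.approx(expected, abs=1e-12)

    def test_nondecreasing_up_to_sixty(self):
        thetas = np.linspace(0, 60, 601)
        vals = [omega(t) for t in thetas]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("bad", [-1.0, 90.5, 180.0])
    def test_domain_error(self, bad):
        with pytest.raises(DomainError):
            omega(bad)


class TestDistanceCost:
    @pytest.mark.parametrize("d, expected", [
        (3.0, 1.0),                       # below the modelled range
        (5.0, 1.0),
        (10.0, 0.4965),
        (15.0, 1.0125 - 0.0586 * 15 + 0.0007 * 225),
        (20.0, 1.0125 - 0.0586 * 20 + 0.0007 * 400),
        (25.0, 0.0),                      # max(0, -0.015): continuous break
        (40.0, 0.0),
        (60.0, 0.0),
        (60.0001, 1.0),
        (70.0, 1.0),
    ])
    def test_printed_piecewise(self, d, expected):
        assert nu(d) == pytest.approx(expected, abs=1e-12)

    def test_continuity_at_25(self):
        assert abs(nu(25.0 - 1e-9) - nu(25.0 + 1e-9)) < 1e-6

    def test_nonincreasing_on_taper(self):
        ds = np.linspace(5.001, 25, 400)
        vals = [nu(d) for d in ds]
        assert all(b <= a + 1e-12 for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("bad", [0.0, -3.0])
    def test_domain_error(self, bad):
        with pytest.raises(DomainError):
            nu(bad)


class TestEmgMuscleCost:
    def test_aligned_pair_on_line_scores_zero(self, model):
        mg = model.muscles["PL"]
        (x1, y1), _ = mg.segment
        pair = (emg_el((x1, y1 + 1.0)), emg_el((x1, y1 + 31.0), member="B"))
        assert emg_muscle_cost(pair, mg) == pytest.approx(0.0, abs=1e-9)

    def test_offset_beyond_one_cm_scores_one(self, model):
        mg = model.muscles["PL"]
        (x1, y1), _ = mg.segment
        pair = (emg_el((x1 + 15.0, y1)), emg_el((x1, y1 + 30.0), member="B"))
        assert emg_muscle_cost(pair, mg) == 1.0

    def test_disk_overlapping_iz_scores_one(self, model):
        mg = model.muscles["PL"]
        iz_center = np.mean(mg.iz[0], axis=0)
        near = (iz_center[0], iz_center[1] - 6.0)  # disk reaches the zone
        pair = (emg_el(near), emg_el((near[0], near[1] + 30.0), member="B"))
        assert emg_muscle_cost(pair, mg) == 1.0

    def test_combined_angle_and_distance_score(self, model):
        # theta = 30 deg at d = 10 mm: 0.5*0.3339 + 0.5*0.4965
        mg = model.muscles["PL"]
        a, b = np.asarray(mg.segment[0]), np.asarray(mg.segment[1])
        direction = (b - a) / np.linalg.norm(b - a)
        rot = np.array([
            [math.cos(math.radians(30)), -math.sin(math.radians(30))],
            [math.sin(math.radians(30)), math.cos(math.radians(30))]])
        start = a - direction * 5.0  # near the distal keypoint, clear of the IZ
        e2 = start + (rot @ direction) * 10.0
        pair = (emg_el(tuple(start)), emg_el(tuple(e2), member="B"))
        assert emg_muscle_cost(pair, mg) == pytest.approx(0.4152, abs=1e-4)

    def test_symmetric_in_pair_order(self, model, rng):
        mg = model.muscles["FCU"]
        for _ in range(50):
            c1 = rng.uniform([-30, 50], [30, 150])
            c2 = rng.uniform([-30, 50], [30, 150])
            if np.allclose(c1, c2):
                continue
            p1 = (emg_el(tuple(c1), "FCU"), emg_el(tuple(c2), "FCU", "B"))
            p2 = (emg_el(tuple(c2), "FCU"), emg_el(tuple(c1), "FCU", "B"))
            assert emg_muscle_cost(p1, mg) == pytest.approx(emg_muscle_cost(p2, mg))

    def test_wrong_role_rejected(self, model):
        pair = (eda_el((0, 80)), eda_el((0, 110), "B"))
        with pytest.raises(RoleError):
            emg_muscle_cost(pair, model.muscles["PL"])


class TestEmgTotal:
    def test_mean_over_selected_muscles(self, model):
        # PL pair perfect (cost 0), FCU pair 15 mm off its line (cost 1)
        pl = model.muscles["PL"].segment
        electrodes = (
            emg_el((pl[0][0], pl[0][1] + 1), "PL", "A"),
            emg_el((pl[0][0], pl[0][1] + 31), "PL", "B"),
            emg_el((30.0, 200.0), "FCU", "A"),
            emg_el((30.0, 230.0), "FCU", "B"),
        )
        total, per = emg_total(Layout(electrodes), model, ("PL", "FCU"))
        assert per["PL"] == pytest.approx(0.0, abs=1e-9)
        assert per["FCU"] == 1.0
        assert total == pytest.approx(0.5, abs=1e-9)

    def test_muscle_order_irrelevant(self, model):
        base = build_baseline_layout(model, ("FCR", "BR", "PL"), ("emg",))
        t1, _ = emg_total(base, model, ("FCR", "BR", "PL"))
        t2, _ = emg_total(base, model, ("PL", "FCR", "BR"))
        assert t1 == t2

    def test_no_muscles_is_config_error(self, model):
        with pytest.raises(ConfigError):
            emg_total(Layout(()), model, ())


class TestEdaModel:
    def test_max_gland_count_on_forearm(self):
        # recommended 6 cm spacing, r = 0.5 cm, 108 glands/cm^2
        assert eda_gland_count(60.0, 5.0, 1.08) == pytest.approx(732.82, abs=0.01)

    def test_coincident_electrodes_cover_disk_only(self):
        assert eda_gland_count(0.0, 5.0, 1.08) == pytest.approx(
            math.pi * 25 * 1.08)

    def test_hand_evaluated_mid_distance(self):
        assert eda_gland_count(30.0, 5.0, 1.08) == pytest.approx(408.82, abs=0.01)

    def test_domain_error(self):
        with pytest.raises(DomainError):
            eda_gland_count(-1.0, 5.0, 1.08)

    def test_cost_zero_at_recommended_distance(self):
        pair = (eda_el((0, 0)), eda_el((0, 60), "B"))
        assert eda_cost(pair, 1.08) == pytest.approx(0.0, abs=1e-12)

    def test_cost_one_when_too_few_glands(self):
        # at 3 mm spacing barely 117 glands are covered
        pair = (eda_el((0, 0)), eda_el((0, 3), "B"))
        assert eda_cost(pair, 1.08) == 1.0

    def test_cost_one_beyond_recommended_distance(self):
        pair = (eda_el((0, 0)), eda_el((0, 61), "B"))
        assert eda_cost(pair, 1.08) == 1.0

    def test_hand_evaluated_cost_at_30mm(self):
        pair = (eda_el((0, 0)), eda_el((0, 30), "B"))
        assert eda_cost(pair, 1.08) == pytest.approx(1 - 408.82 / 732.82, abs=1e-4)

    def test_strictly_decreasing_in_distance(self):
        ds = np.linspace(6.0, 60.0, 100)
        costs = [eda_cost((eda_el((0, 0)), eda_el((0, d), "B")), 1.08)
                 for d in ds]
        assert all(b < a for a, b in zip(costs, costs[1:]))


class TestEcgModel:
    def test_best_pair_scores_zero(self, model):
        k1, k2 = model.ecg_pairs["upper"].points
        assert ecg_cost((ecg_el(k1), ecg_el(k2, "B")), model) == pytest.approx(0.0)

    def test_wrist_pair_scores_three_quarters(self, model):
        k1, k2 = model.ecg_pairs["wrist"].points
        assert ecg_cost((ecg_el(k1), ecg_el(k2, "B")), model) == pytest.approx(0.75)

    def test_swapped_assignment_handled(self, model):
        k1, k2 = model.ecg_pairs["upper"].points
        assert ecg_cost((ecg_el(k2), ecg_el(k1, "B")), model) == pytest.approx(0.0)

    def test_far_from_all_candidates_scores_one(self, model):
        # mid-forearm ulnar edge, > 50 mm from every candidate keypoint
        pair = (ecg_el((-30.0, 155.0)), ecg_el((-30.0, 170.0), "B"))
        assert ecg_cost(pair, model) == 1.0


class TestAreaCost:
    def test_baseline_self_ratio_is_one(self, model, uni_muscles):
        base = build_baseline_layout(model, uni_muscles, ("emg",))
        ref = baseline_area(model, uni_muscles, ("emg",))
        ratio, hull = area_cost(base, ref)
        assert ratio == pytest.approx(1.0)
        assert hull == pytest.approx(ref)

    def test_ratio_scales_with_hull(self, model, uni_muscles):
        base = build_baseline_layout(model, uni_muscles, ("emg",))
        ref = baseline_area(model, uni_muscles, ("emg",))
        ratio, hull = area_cost(base, 2.0 * ref)
        assert ratio == pytest.approx(0.5)

    def test_disk_hull_matches_shapely_buffer_union(self, rng):
        shapely = pytest.importorskip("shapely")
        from shapely.geometry import Point
        from shapely.ops import unary_union

        for _ in range(5):
            centers = rng.uniform(0, 80, size=(5, 2))
            electrodes = tuple(
                emg_el(tuple(c), "PL", "AB"[i % 2]) for i, c in enumerate(centers))
            expected = unary_union([
                Point(*c).buffer(EMG_ELECTRODE_RADIUS, quad_segs=256)
                for c in centers]).convex_hull.area
            assert layout_hull_area(Layout(electrodes)) == pytest.approx(
                expected, rel=1e-4)

    def test_collinear_strip_has_capsule_footprint(self):
        electrodes = tuple(emg_el((0.0, 15.0 * i), "PL") for i in range(4))
        r = EMG_ELECTRODE_RADIUS
        expected = math.pi * r * r + 2 * r * 45.0
        assert layout_hull_area(Layout(electrodes)) == pytest.approx(expected)

    def test_two_electrode_layout_has_capsule_footprint(self):
        pair = Layout((eda_el((0, 0)), eda_el((0, 60), "B")))
        expected = math.pi * 25 + 10 * 60
        assert layout_hull_area(pair) == pytest.approx(expected)


class TestLowerBoundPenalty:
    def test_zero_when_within_bound(self):
        assert lower_bound_penalty(0.2, 0.3, 1.0) == 0.0
        assert lower_bound_penalty(0.3, 0.3, 5.0) == 0.0

    def test_zero_softness_disables(self):
        assert lower_bound_penalty(0.9, 0.1, 0.0) == 0.0

    def test_hand_evaluated_violation(self):
        assert lower_bound_penalty(0.4, 0.3, 1.0) == pytest.approx(
            math.exp(0.1) - 1.0, abs=1e-12)


class TestCombineObjective:
    def test_single_modality_reduces_to_its_cost(self):
        obj, pen, quality = combine_objective(
            {"emg": 0.3}, 0.0, Weights(emg=1.0), "weights")
        assert obj == pytest.approx(0.3)
        assert quality == pytest.approx(0.7)
        assert pen == {}

    def test_weighted_sum_by_hand(self):
        w = Weights(emg=0.5, eda=0.3, ecg=0.2, area=0.0)
        obj, _, _ = combine_objective(
            {"emg": 0.2, "eda": 0.5, "ecg": 1.0}, 0.0, w, "weights")
        assert obj == pytest.approx(0.45)

    def test_bound_scheme_reduces_to_area_when_bounds_met(self):
        w = Weights(area=1.0)
        bounds = LowerBounds(emg=0.5, eda=0.5, ecg=0.5, softness=2.0)
        obj, pen, _ = combine_objective(
            {"emg": 0.1, "eda": 0.2, "ecg": 0.3}, 0.7, w, "bounds", bounds)
        assert obj == pytest.approx(0.7)
        assert all(v == 0.0 for v in pen.values())

    def test_hybrid_adds_penalties(self):
        w = Weights(emg=1.0, area=0.0)
        bounds = LowerBounds(emg=0.2, softness=1.0)
        obj, pen, _ = combine_objective({"emg": 0.5}, 0.0, w, "hybrid", bounds)
        assert obj == pytest.approx(0.5 + math.exp(0.3) - 1.0)

    def test_unnormalized_weights_rejected(self):
        with pytest.raises(ConfigError):
            combine_objective({"emg": 0.5, "eda": 0.5}, 0.0,
                              Weights(emg=0.5, eda=0.2), "weights")

    def test_objective_linear_in_each_cost(self, rng):
        w = Weights(emg=0.5, eda=0.3, ecg=0.2, area=0.1)
        c0 = {"emg": 0.2, "eda": 0.4, "ecg": 0.6}
        base, _, _ = combine_objective(c0, 0.5, w, "weights")
        for key, wk in (("emg", 0.5), ("eda", 0.3), ("ecg", 0.2)):
            bumped = dict(c0)
            bumped[key] = c0[key] + 0.1
            obj, _, _ = combine_objective(bumped, 0.5, w, "weights")
            assert obj - base == pytest.approx(wk * 0.1)


class TestGlobalObjective:
    def test_multimodal_baseline_has_quality_one(self, model):
        muscles = ("FCR", "BR", "PL", "PQ", "FCU")
        mods = ("emg", "eda", "ecg")
        layout = build_baseline_layout(model, muscles, mods)
        ref = baseline_area(model, muscles, mods)
        w = Weights(emg=1 / 3, eda=1 / 3, ecg=1 / 3, area=0.0)
        cost = global_objective(layout, model, w, baseline_area=ref)
        assert cost.quality == pytest.approx(1.0, abs=1e-6)
        assert cost.aggregate == pytest.approx(0.0, abs=1e-6)
        assert cost.area_ratio == pytest.approx(1.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_modality_costs_always_in_unit_interval(self, model, seed):
        g = np.random.default_rng(seed)
        muscles = ("FCR", "PL")
        roster = measurement_roster(muscles, ("emg", "eda", "ecg"))
        placed = tuple(
            e.moved_to((g.uniform(-40, 40), g.uniform(0, 250))) for e in roster)
        w = Weights(emg=0.4, eda=0.3, ecg=0.3, area=0.0)
        cost = global_objective(Layout(placed), model, w, baseline_area=1000.0)
        for val in (cost.emg, cost.eda, cost.ecg):
            assert 0.0 <= val <= 1.0
        for val in cost.muscle_costs.values():
            assert 0.0 <= val <= 1.0
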