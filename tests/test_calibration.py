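import numpy as np
import pandas as pd
import pytest

from seqsafe.calibration import (
    ConstraintSpec,
    MisclassificationTable,
    SimulationConfig,
    build_scenarios,
    calibrate_final_thresholds,
    default_accrual,
    default_threshold_grid,
    max_class_b,
    misclassification_rates,
    rates_from_probabilities,
    scale_prevalence,
    select_rule,
    simulate_trials,
)
from seqsafe.decision import ArmPrior, PriorPair, build_prior_grid
from seqsafe.mixtures import BetaMixture, point_mass_mixture
from seqsafe.schedules import schedule_table

from conftest import CONTROL_RATES, EVENTS

FLAT = PriorPair(ArmPrior(1, 1), ArmPrior(1, 1), label=1)


def _wide_margin():
    # nearly all mass above 0.5
    return BetaMixture(shapes=((60.0, 20.0),), weights=(1.0,))


class TestBuildScenarios:
    def test_table_rows(self):
        scen = {s.scenario_id: s for s in build_scenarios(CONTROL_RATES, EVENTS)}
        assert scen["A"].theta1 == pytest.approx(CONTROL_RATES)
        assert scen["B"].theta1 == pytest.approx((0.26, 0.10, 0.04, 0.03))
        assert scen["C"].theta1 == pytest.approx((0.58, 0.23, 0.09, 0.06))
        assert scen["D"].theta1 == pytest.approx((0.78, 0.30, 0.12, 0.08))
        assert scen["E"].theta1 == pytest.approx((1.00, 0.45, 0.18, 0.12))

    def test_cap_at_one(self):
        assert scale_prevalence(0.39, "E") == 1.0

    def test_truth_label_defaults(self):
        scen = {s.scenario_id: s for s in build_scenarios(CONTROL_RATES, EVENTS)}
        assert scen["B"].truth_labels == ("Acceptable",) * 4
        assert scen["C"].truth_labels == (
            "Unacceptable", "Unacceptable", "Acceptable", "Acceptable")
        assert scen["D"].truth_labels == ("Unacceptable",) * 4

    def test_defaults_require_four_events(self):
        with pytest.raises(ValueError, match="4-event"):
            build_scenarios((0.1, 0.2))

    def test_custom_truth_labels(self):
        scen = build_scenarios((0.1, 0.2), ("x", "y"), first_unacceptable=("E", "C"))
        by_id = {s.scenario_id: s for s in scen}
        assert by_id["D"].truth_labels == ("Acceptable", "Unacceptable")


class TestMaxClassB:
    @pytest.mark.parametrize("w,expected", [(100, 0.10), (88, 0.16), (70, 0.25),
                                            (60, 0.30), (0, 0.60)])
    def test_formula(self, w, expected):
        assert max_class_b(w) == pytest.approx(expected)

    def test_bounds(self):
        with pytest.raises(ValueError):
            max_class_b(101)

    def test_constraint_spec_from_weights(self):
        spec = ConstraintSpec.from_weights(dict(zip(EVENTS, (100, 88, 70, 60))))
        assert spec.max_class_a == 0.10
        assert spec.max_class_b_per_event["nec"] == pytest.approx(0.25)


class TestMisclassificationRates:
    def test_perfect_classifier(self):
        t = misclassification_rates(["Acc", "U"], ["Acc", "U"])
        assert (t.rate_a, t.rate_b) == (0.0, 0.0)

    def test_count_arithmetic(self):
        conclusions = ["U"] + ["Acc"] * 9
        t = misclassification_rates(conclusions, ["Acc"] * 10)
        assert t.rate_a == pytest.approx(0.1)
        assert t.rate_b is None  # no truly-unacceptable trials

    def test_enumerated_table(self):
        t = misclassification_rates(["U", "Acc", "Acc", "U"], ["Acc", "Acc", "U", "U"])
        assert (t.A, t.B, t.C, t.D) == (1, 1, 1, 1)
        assert t.rate_a == t.rate_b == 0.5

    def test_counts_sum_to_total(self):
        rng = np.random.default_rng(0)
        conc = rng.random(50) < 0.3
        truth = rng.random(50) < 0.5
        t = misclassification_rates(conc, truth)
        assert t.n_trials == 50

    def test_misaligned_inputs(self):
        with pytest.raises(ValueError):
            misclassification_rates(["U"], ["U", "Acc"])

    def test_rate_identity_from_raw_records(self):
        rng = np.random.default_rng(5)
        conc = rng.random(200) < 0.4
        truth = rng.random(200) < 0.5
        t = misclassification_rates(conc, truth)
        A = int(np.sum(conc & ~truth))
        B = int(np.sum(~conc & truth))
        assert t.rate_a == A / (A + int(np.sum(~conc & ~truth)))
        assert t.rate_b == B / (B + int(np.sum(conc & truth)))


class TestSimulationConfig:
    def test_default_accrual(self):
        cfg = SimulationConfig(n_per_arm=162, L=11, n_trials=10)
        assert cfg.accrual[-1] == 162
        assert len(cfg.accrual) == 11
        assert all(b > a for a, b in zip(cfg.accrual, cfg.accrual[1:]))

    def test_explicit_accrual_validated(self):
        with pytest.raises(ValueError, match="increasing"):
            SimulationConfig(n_per_arm=30, L=3, accrual=(10, 10, 30))
        with pytest.raises(ValueError, match="n_per_arm"):
            SimulationConfig(n_per_arm=30, L=3, accrual=(5, 10, 20))

    def test_default_accrual_helper(self):
        assert default_accrual(162, 11)[:3] == (15, 30, 45)


class TestSimulateTrials:
    CFG = SimulationConfig(n_per_arm=60, L=4, n_trials=60, seed=11, mc_samples=2000)

    def test_wide_margin_rarely_concludes_unacceptable(self):
        scen = build_scenarios(CONTROL_RATES, EVENTS)[0]  # theta1 == theta0
        sched = schedule_table([(e, 0.7) for e in EVENTS], L=4)
        res = simulate_trials(scen, self.CFG, FLAT, _wide_margin(), sched)
        assert res.conclusions.mean() < 0.01

    def test_extreme_effect_always_flagged(self):
        scen = build_scenarios(CONTROL_RATES, EVENTS)[4]  # death prevalence 1.0
        sched = schedule_table([(e, 0.7) for e in EVENTS], L=4)
        margin = point_mass_mixture(0.1)
        res = simulate_trials(scen, self.CFG, FLAT, margin, sched)
        death = list(scen.event_ids).index("death")
        assert res.conclusions[:, death].mean() > 0.95

    def test_same_seed_identical_conclusions(self):
        scen = build_scenarios(CONTROL_RATES, EVENTS)[2]
        sched = schedule_table([(e, 0.8) for e in EVENTS], L=4)
        margin = point_mass_mixture(0.05)
        r1 = simulate_trials(scen, self.CFG, FLAT, margin, sched)
        r2 = simulate_trials(scen, self.CFG, FLAT, margin, sched)
        np.testing.assert_array_equal(r1.conclusions, r2.conclusions)
        np.testing.assert_array_equal(r1.probabilities, r2.probabilities)

    def test_conclusion_iff_any_flag(self):
        scen = build_scenarios(CONTROL_RATES, EVENTS)[3]
        sched = schedule_table([(e, 0.8) for e in EVENTS], L=4)
        res = simulate_trials(scen, self.CFG, FLAT, point_mass_mixture(0.05), sched)
        np.testing.assert_array_equal(res.conclusions, res.flags.any(axis=1))
        flagged = res.first_flagged > 0
        np.testing.assert_array_equal(res.conclusions, flagged)


class TestCalibrateFinalThresholds:
    def test_fixture_rates_match_hand_enumeration(self):
        rng = np.random.default_rng(8)
        probs = rng.random(100)
        truth = rng.random(100) < 0.5
        frame = rates_from_probabilities(probs, truth, [0.8])
        row = frame.iloc[0]
        concluded = probs >= 0.8
        A = int(np.sum(concluded & ~truth))
        C = int(np.sum(~concluded & ~truth))
        B = int(np.sum(~concluded & truth))
        D = int(np.sum(concluded & truth))
        assert (row.A, row.B, row.C, row.D) == (A, B, C, D)
        assert row.rate_a == pytest.approx(A / (A + C))
        assert row.rate_b == pytest.approx(B / (B + D))

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(9)
        probs = rng.random(300)
        truth = rng.random(300) < 0.4
        frame = rates_from_probabilities(probs, truth, default_threshold_grid())
        assert np.all(np.diff(frame.rate_a.to_numpy()) <= 1e-12)
        assert np.all(np.diff(frame.rate_b.to_numpy()) >= -1e-12)

    def test_extreme_threshold_rarely_concludes(self):
        rng = np.random.default_rng(10)
        probs = rng.random(500) * 0.95
        truth = rng.random(500) < 0.5
        frame = rates_from_probabilities(probs, truth, [0.99])
        assert frame.iloc[0].rate_a < 0.05

    def test_grid_must_be_inside_interval(self):
        scen = build_scenarios(CONTROL_RATES, EVENTS)
        cfg = SimulationConfig(n_per_arm=20, L=2, n_trials=5, mc_samples=1000)
        with pytest.raises(ValueError, match="inside"):
            calibrate_final_thresholds(scen, cfg, [FLAT], point_mass_mixture(0.1),
                                       threshold_grid=[0.5])

    def test_end_to_end_small_run(self, narrow_margin):
        scen = build_scenarios(CONTROL_RATES, EVENTS)
        cfg = SimulationConfig(n_per_arm=40, L=2, n_trials=40, seed=2, mc_samples=1000)
        grids = {e: build_prior_grid(r, 0.02)[:2]
                 for e, r in zip(EVENTS, CONTROL_RATES)}
        frame = calibrate_final_thresholds(scen, cfg, grids, narrow_margin,
                                           threshold_grid=[0.6, 0.8])
        assert set(frame.prior_label) == {1, 2}
        assert len(frame) == 2 * 4 * 2
        # monotonicity holds within every (prior, event) block
        for _key, g in frame.groupby(["prior_label", "event_id"]):
            g = g.sort_values("tau_final")
            assert np.all(np.diff(g.rate_a.to_numpy()) <= 1e-12)


class TestSelectRule:
    @staticmethod
    def _calib(rows):
        return pd.DataFrame(rows, columns=["prior_label", "event_id", "tau_final",
                                           "rate_a", "rate_b"])

    def test_vacuous_constraints_pick_deterministically(self):
        calib = self._calib([
            (1, "x", 0.6, 0.2, 0.3), (1, "x", 0.7, 0.1, 0.4),
            (2, "x", 0.6, 0.3, 0.2), (2, "x", 0.7, 0.2, 0.3),
        ])
        spec = ConstraintSpec(max_class_a=1.0, max_class_b_per_event={"x": 1.0})
        sel = select_rule(calib, spec)
        assert sel.admissible
        assert sel.prior_label == 2  # lowest summed rate_b at its chosen tau
        assert sel.tau_final == {"x": 0.6}

    def test_infeasible_constraints_report_nearest_miss(self):
        calib = self._calib([(1, "x", 0.6, 0.2, 0.3), (2, "x", 0.6, 0.1, 0.2)])
        spec = ConstraintSpec(max_class_a=0.0, max_class_b_per_event={"x": 0.0})
        sel = select_rule(calib, spec)
        assert not sel.admissible
        assert sel.nearest_miss["prior_label"] == 2

    def test_only_admissible_prior_selected(self):
        calib = self._calib([
            (1, "x", 0.6, 0.05, 0.1), (1, "y", 0.6, 0.08, 0.1),
            (2, "x", 0.6, 0.05, 0.1), (2, "y", 0.6, 0.30, 0.1),
        ])
        spec = ConstraintSpec(max_class_a=0.10,
                              max_class_b_per_event={"x": 0.5, "y": 0.5})
        sel = select_rule(calib, spec)
        assert sel.prior_label == 1

    def test_family_selection(self):
        calib = self._calib([(1, "x", 0.6, 0.05, 0.1)])
        spec = ConstraintSpec(max_class_a=0.10, max_class_b_per_event={"x": 0.5})
        fam = pd.DataFrame([
            {"family": "uniform", "event_id": "x", "rate_a": 0.2, "rate_b": 0.1},
            {"family": "exponential", "event_id": "x", "rate_a": 0.05, "rate_b": 0.1},
        ])
        sel = select_rule(calib, spec, family_results=fam)
        assert sel.family == "exponential"

    def test_missing_ceiling_errors(self):
        calib = self._calib([(1, "x", 0.6, 0.05, 0.1)])
        with pytest.raises(ValueError, match="ceiling"):
            select_rule(calib, ConstraintSpec(max_class_a=0.1))


def test_misclassification_table_rates_undefined_flagged():
    t = MisclassificationTable(A=0, B=0, C=0, D=5)
    assert t.rate_a is None
    assert t.rate_b == 0.0
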