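import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seqsafe.elicitation import (
    ExpertAnswer,
    FitConfig,
    FitDiagnostics,
    WEIGHT_GRID,
    compute_differences,
    fit_hybrid,
    fit_manual_two_component,
    fit_mixture_em,
    median_weight,
    select_margin_fit,
)
from seqsafe.mixtures import BetaMixture, fit_beta_ml


def _answers(rates, event="ivh"):
    return [
        ExpertAnswer(expert_id=f"e{i}", event_id=event, acceptable_rate=r, severity_weight=50)
        for i, r in enumerate(rates)
    ]


class TestComputeDifferences:
    def test_direct_subtraction(self):
        d = compute_differences(_answers([0.20]), control_rate=0.15)
        assert d.differences == pytest.approx((0.05,))

    def test_zero_difference_clamped(self):
        d = compute_differences(_answers([0.15]), control_rate=0.15, eps=1e-3)
        assert d.differences == (1e-3,)

    def test_vectorized_subtraction_preserves_order(self):
        d = compute_differences(_answers([0.18, 0.25, 0.16]), control_rate=0.15)
        assert d.differences == pytest.approx((0.03, 0.10, 0.01))
        assert d.n_experts == 3

    def test_empty_answers_error(self):
        with pytest.raises(ValueError, match="no elicitation data"):
            compute_differences([], control_rate=0.15)

    def test_invalid_rate_rejected_at_construction(self):
        with pytest.raises(ValueError):
            ExpertAnswer("e", "ivh", acceptable_rate=1.2, severity_weight=50)

    def test_mixed_events_rejected(self):
        answers = _answers([0.2]) + _answers([0.3], event="nec")
        with pytest.raises(ValueError, match="multiple events"):
            compute_differences(answers, control_rate=0.15)

    @settings(max_examples=100, deadline=None)
    @given(
        h=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20),
        f=st.floats(0.01, 0.99),
    )
    def test_clamping_never_leaves_open_interval(self, h, f):
        d = compute_differences(_answers(h), control_rate=f, eps=1e-3)
        assert all(0.0 < v < 1.0 for v in d.differences)


class TestMedianWeight:
    def test_worked_configuration_values(self):
        # per-event medians of constant panels reproduce the printed weights
        for w in (100, 88, 70, 60):
            panel = [ExpertAnswer("e", "x", 0.2, w)] * 5
            assert median_weight(panel) == w

    def test_singleton(self):
        assert median_weight([70]) == 70

    def test_even_count(self):
        assert median_weight([60, 80]) == 70


class TestFitMixtureEM:
    def test_single_component_reduces_to_beta_ml(self, rng):
        x = rng.beta(3, 20, size=300)
        mixture, diag = fit_mixture_em(x, max_components=1)
        a, b = fit_beta_ml(x)
        assert mixture.n_components == 1
        assert mixture.shapes[0][0] == pytest.approx(a, rel=1e-6)
        assert mixture.shapes[0][1] == pytest.approx(b, rel=1e-6)
        assert diag.method_id == "em_mixture"
        assert diag.chosen_cut is None and diag.chosen_weight is None

    def test_two_component_recovery(self, two_component_mixture, fast_fit_config):
        x = two_component_mixture.sample(2000, seed=42)
        mixture, _diag = fit_mixture_em(x, 3, fast_fit_config)
        assert mixture.n_components == 2
        order = np.argsort(mixture.component_means)
        weights = np.array(mixture.weights)[order]
        means = np.array(mixture.component_means)[order]
        assert weights == pytest.approx([0.6, 0.4], abs=0.05)
        assert means == pytest.approx([2 / 42, 10 / 40], abs=0.02)

    def test_loglik_trace_monotone(self, two_component_mixture, fast_fit_config):
        x = two_component_mixture.sample(500, seed=1)
        _m, diag = fit_mixture_em(x, 2, fast_fit_config)
        trace = np.asarray(diag.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-10 * np.maximum(1.0, np.abs(trace[:-1])))

    def test_density_normalised(self, two_component_mixture, fast_fit_config):
        from scipy import integrate

        x = two_component_mixture.sample(800, seed=9)
        m, _ = fit_mixture_em(x, 2, fast_fit_config)
        val, _err = integrate.quad(m.pdf, 0, 1, limit=200)
        assert val == pytest.approx(1.0, abs=1e-6)


class TestManualTwoComponent:
    def test_weight_grid_has_21_values(self):
        assert len(WEIGHT_GRID) == 21
        assert WEIGHT_GRID[0] == 0.0 and WEIGHT_GRID[-1] == 1.0
        assert np.allclose(np.diff(WEIGHT_GRID), 0.05)

    def test_separated_clusters_recovered(self, fast_fit_config, rng):
        low = np.clip(rng.normal(0.01, 0.003, 500), 1e-4, None)
        high = rng.normal(0.2, 0.02, 500)
        x = np.concatenate([low, high])
        mixture, diag = fit_manual_two_component(x, fast_fit_config)
        xs = np.sort(x)
        # the chosen cut lands at the cluster boundary, up to the spacing of
        # the capped candidate grid (1000/40 = 25 order statistics)
        assert xs[diag.chosen_cut - 1] < 0.1
        assert abs(diag.chosen_cut - 500) <= 25
        assert diag.chosen_weight == pytest.approx(0.5, abs=0.1)
        assert sorted(mixture.component_means) == pytest.approx([0.01, 0.2], abs=0.02)

    def test_boundary_weight_reduces_to_single_side(self, rng):
        # unimodal data: the grid endpoint w in {0, 1} should yield 1 component
        x = rng.beta(5, 45, size=80)
        mixture, diag = fit_manual_two_component(x, FitConfig(max_cut_candidates=20))
        if diag.chosen_weight in (0.0, 1.0):
            assert mixture.n_components == 1

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            fit_manual_two_component([0.1, 0.2, 0.3])

    def test_diagnostics_carry_cut_and_weight(self, fast_fit_config, rng):
        x = rng.beta(2, 30, size=40)
        _m, diag = fit_manual_two_component(x, fast_fit_config)
        assert diag.method_id == "manual_two_component"
        assert diag.chosen_cut is not None and diag.chosen_weight is not None


class TestHybrid:
    def test_weight_arithmetic(self):
        # (0.5, 0.5) EM weights with w1 = 0.6 -> (0.6, 0.2, 0.2)
        w1 = 0.6
        v = (0.5, 0.5)
        final = (w1, (1 - w1) * v[0], (1 - w1) * v[1])
        assert final == pytest.approx((0.6, 0.2, 0.2))
        m = BetaMixture(shapes=((1, 9), (5, 20), (8, 20)), weights=final)
        assert sum(m.weights) == pytest.approx(1.0, abs=1e-9)

    def test_weights_sum_to_one(self, fast_fit_config, rng):
        x = np.concatenate(
            [rng.beta(1, 99, 300), rng.beta(16, 184, 300), rng.beta(20, 80, 300)]
        )
        mixture, diag = fit_hybrid(x, fast_fit_config)
        assert sum(mixture.weights) == pytest.approx(1.0, abs=1e-9)
        assert diag.method_id == "hybrid"

    def test_trimodal_recovery(self, fast_fit_config, rng):
        x = np.concatenate(
            [rng.beta(2, 198, 400), rng.beta(16, 184, 300), rng.beta(40, 160, 300)]
        )
        mixture, _diag = fit_hybrid(x, fast_fit_config)
        if mixture.n_components == 3:
            means = np.sort(mixture.component_means)
            assert means == pytest.approx([0.01, 0.08, 0.2], abs=0.03)

    def test_fallback_warns(self):
        # only three distinct values: every right side is too small for a
        # 2-component EM, so the manual result is returned with a warning
        x = [0.01, 0.02, 0.03, 0.01, 0.02, 0.03, 0.01, 0.02]
        with pytest.warns(UserWarning):
            mixture, diag = fit_hybrid(x, FitConfig(max_cut_candidates=5))
        assert diag.method_id == "hybrid"
        assert mixture.n_components <= 2

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="at least 6"):
            fit_hybrid([0.1, 0.2, 0.3, 0.4, 0.5])


class TestSelectMarginFit:
    def test_unimodal_sample_prefers_single_em_component(self, fast_fit_config, rng):
        x = rng.beta(3, 60, size=400)
        mixture, diag = select_margin_fit(x, fast_fit_config)
        assert diag.method_id == "em_mixture"
        assert mixture.n_components == 1

    def test_diagnostics_list_all_competitors(self, fast_fit_config, rng):
        x = rng.beta(3, 60, size=100)
        _m, diag = select_margin_fit(x, fast_fit_config)
        assert set(diag.competing) == {"em_mixture", "manual_two_component", "hybrid"}

    def test_tie_break_prefers_fewer_components(self):
        # tie-break contract is exercised directly on the diagnostics ordering
        d1 = FitDiagnostics("em_mixture", -1.0, {"bic": 5.0}, n_components=1)
        d2 = FitDiagnostics(
            "manual_two_component", -1.0, {"bic": 5.0}, chosen_cut=2, chosen_weight=0.5,
            n_components=2,
        )
        candidates = {"em_mixture": (None, d1), "manual_two_component": (None, d2)}
        winner = min(
            candidates,
            key=lambda k: (candidates[k][1].criterion_values["bic"],
                           candidates[k][1].n_components),
        )
        assert winner == "em_mixture"


class TestRecoveryProperty:
    def test_select_recovers_two_component_mixtures(self, two_component_mixture):
        # separated means (gap ~0.2): component count and weights recovered
        # in >= 90% of seeded replicates
        cfg = FitConfig(n_restarts=2, max_cut_candidates=30)
        hits = 0
        n_rep = 20
        for seed in range(n_rep):
            x = two_component_mixture.sample(2000, seed=seed)
            mixture, _ = select_margin_fit(x, cfg)
            if mixture.n_components != 2:
                continue
            w = np.sort(mixture.weights)
            if np.allclose(w, [0.4, 0.6], atol=0.05):
                hits += 1
        assert hits >= 0.9 * n_rep


def test_diagnostics_invariants():
    with pytest.raises(ValueError, match="non-empty"):
        FitDiagnostics("em_mixture", 0.0, {})
    with pytest.raises(ValueError, match="cut"):
        FitDiagnostics("em_mixture", 0.0, {"bic": 1.0}, chosen_cut=3, chosen_weight=0.5)
    with pytest.raises(ValueError, match="require"):
        FitDiagnostics("hybrid", 0.0, {"bic": 1.0})
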