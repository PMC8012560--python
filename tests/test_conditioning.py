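"""Conditioning hybrid models on RP-factor values."""

import numpy as np
import pandas as pd
import pytest

import netresil as nr
from netresil.conditioning import ConditionedMeans


def toy_model(coef_sf=-0.5, coef_ss=0.0, intercept=1.0, n_sympt=1):
    """Small hybrid model: n symptoms, one factor f on a 0-5 scale."""
    k = n_sympt + 1
    coef = np.zeros((k, k))
    coef[:n_sympt, -1] = coef_sf
    if n_sympt == 2:
        coef[0, 1] = coef[1, 0] = coef_ss
    f_base = 2.0
    intercepts = np.full(k, 0.0)
    base_s = np.linalg.solve(
        np.eye(n_sympt) - coef[:n_sympt, :n_sympt],
        np.full(n_sympt, intercept) + coef[:n_sympt, -1] * f_base,
    )
    intercepts[:n_sympt] = intercept
    return nr.HybridNodewiseModel(
        symptom_labels=tuple(f"s{i}" for i in range(n_sympt)),
        factor_labels=("f",),
        intercepts=intercepts,
        coef=coef,
        scale_min=np.array([-100.0] * n_sympt + [0.0]),
        scale_max=np.array([100.0] * n_sympt + [5.0]),
        baseline_means=np.concatenate([base_s, [f_base]]),
        factor_roles={"f": "protective"},
    )


class TestConditionMeans:
    def test_zero_coupling_leaves_baseline(self):
        model = toy_model(coef_sf=0.0)
        cm = nr.condition_means(model, nr.ConditioningScenario({"f": 5.0}))
        assert cm.means["s0"] == pytest.approx(model.baseline_means[0], abs=1e-10)

    def test_single_symptom_linear_response(self):
        """coef -0.5 on f: raising f by 1 lowers the symptom mean by 0.5."""
        model = toy_model(coef_sf=-0.5)
        base = nr.condition_means(model, nr.ConditioningScenario({}))
        up = nr.condition_means(model, nr.ConditioningScenario({"f": 3.0}))
        assert up.means["s0"] - base.means["s0"] == pytest.approx(-0.5, abs=1e-8)

    def test_coupled_pair_matches_linear_solve(self):
        """Fixed point equals the closed-form 2x2 linear-system solution."""
        model = toy_model(coef_sf=-0.4, coef_ss=0.3, n_sympt=2)
        f_val = 4.0
        cm = nr.condition_means(model, nr.ConditioningScenario({"f": f_val}))
        A = model.coef[:2, :2]
        b = model.intercepts[:2] + model.coef[:2, 2] * f_val
        expected = np.linalg.solve(np.eye(2) - A, b)
        assert np.allclose(cm.means.to_numpy(), expected, atol=1e-8)

    def test_one_step_mode_ignores_indirect_effects(self):
        model = toy_model(coef_sf=-0.4, coef_ss=0.3, n_sympt=2)
        one = nr.condition_means(model, nr.ConditioningScenario({"f": 4.0}), one_step=True)
        fixed = nr.condition_means(model, nr.ConditioningScenario({"f": 4.0}))
        assert one.n_iter == 1
        assert not np.allclose(one.means, fixed.means)

    def test_nonconvergence_reports_nodes(self):
        model = toy_model(coef_sf=-0.4, coef_ss=1.5, n_sympt=2)  # explosive coupling
        with pytest.raises(RuntimeError, match="converge"):
            nr.condition_means(model, nr.ConditioningScenario({"f": 5.0}))

    def test_scenario_validation(self):
        model = toy_model()
        with pytest.raises(ValueError, match="not an RP factor"):
            nr.condition_means(model, nr.ConditioningScenario({"s0": 1.0}))
        with pytest.raises(ValueError, match="outside scale"):
            nr.condition_means(model, nr.ConditioningScenario({"f": 9.0}))

    def test_clipping_is_logged(self):
        # symptom scale bound above its conditioned value forces a clip
        model = nr.HybridNodewiseModel(
            symptom_labels=("s0",), factor_labels=("f",),
            intercepts=np.array([1.0, 0.0]),
            coef=np.array([[0.0, -0.5], [0.0, 0.0]]),
            scale_min=np.array([0.5, 0.0]), scale_max=np.array([1.5, 5.0]),
            baseline_means=np.array([1.0, 0.0]),
        )
        cm = nr.condition_means(model, nr.ConditioningScenario({"f": 5.0}))
        assert cm.clip_count == 1 and cm.means["s0"] == 0.5  # 1 - 2.5 clipped up


class TestEsa:
    def test_scale_bound_27_items(self):
        """27 items on a 0-4 scale cap ESA at 108."""
        assert nr.conditioned_esa([4.0] * 27) == pytest.approx(108.0)
        assert nr.conditioned_esa(np.zeros(27)) == 0.0

    def test_esa_accepts_conditioned_means(self):
        model = toy_model()
        cm = nr.condition_means(model, nr.ConditioningScenario({}))
        assert nr.conditioned_esa(cm) == pytest.approx(float(cm.means.sum()))

    def test_empty_scenario_delta_zero(self):
        model = toy_model(coef_sf=-0.5, coef_ss=0.3, n_sympt=2)
        assert nr.esa_delta(model, nr.ConditioningScenario({})) == pytest.approx(0.0)

    def test_linearity_closed_form(self):
        """No symptom-symptom coupling: delta = sum coef x displacement."""
        model = toy_model(coef_sf=-0.4, coef_ss=0.0, n_sympt=2)
        displacement = 5.0 - model.baseline_means[2]
        delta = nr.esa_delta(model, nr.ConditioningScenario({"f": 5.0}))
        assert delta == pytest.approx(2 * (-0.4) * displacement, abs=1e-10)

    def test_unreachable_symptom_unchanged(self):
        """A factor with no direct or indirect path cannot move a symptom."""
        import networkx as nx

        _, model = nr.generate_hybrid_dataset(
            nr.HybridGeneratorSpec(
                n_symptoms=8, n_persons=10, seed=3,
                factors=(nr.FactorSpec("f", "risk"),),
                ss_density=0.15, sf_density=0.25,
            )
        )
        G = nx.Graph()
        labels = model.labels
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if model.coef[i, j] != 0.0 or model.coef[j, i] != 0.0:
                    G.add_edge(a, b)
        G.add_nodes_from(labels)
        reachable = nx.node_connected_component(G, "f") if "f" in G else {"f"}
        base = nr.condition_means(model, nr.ConditioningScenario({}))
        cond = nr.condition_means(model, nr.ConditioningScenario({"f": 1.0}))
        for s in model.symptom_labels:
            if s not in reachable:
                assert cond.means[s] == pytest.approx(base.means[s], abs=1e-10)


class TestPresenceScenarios:
    def test_presence_is_scale_max_absence_zero(self):
        model = toy_model()
        sc = nr.presence_scenario(model, present=["f"])
        assert sc.fixed == {"f": 5.0}
        sc = nr.presence_scenario(model, absent=["f"])
        assert sc.fixed == {"f": 0.0}

    def test_planted_signs_drive_delta_signs(self):
        spec = nr.HybridGeneratorSpec(
            n_symptoms=10, n_persons=50, seed=0,
            factors=(nr.FactorSpec("risk1", "risk"),
                     nr.FactorSpec("prot1", "protective", kind="ordinal", levels=5)),
        )
        _, model = nr.generate_hybrid_dataset(spec)
        protective = nr.presence_scenario(model, present=["prot1"], absent=["risk1"])
        risky = nr.presence_scenario(model, present=["risk1"], absent=["prot1"])
        assert nr.esa_delta(model, protective) < 0 < nr.esa_delta(model, risky)


class TestNodewiseFit:
    def test_ols_baseline_is_fixed_point(self):
        """OLS regressions pass through the data means, so the fitted
        model's conditioned baseline equals the empirical symptom means."""
        data, model = nr.generate_hybrid_dataset(
            nr.HybridGeneratorSpec(n_symptoms=6, n_persons=3000, seed=7,
                                   factors=(nr.FactorSpec("f", "risk"),))
        )
        fit = nr.fit_nodewise_linear(data, model.symptom_labels, model.factor_labels,
                                     factor_roles=model.factor_roles)
        base = nr.condition_means(fit, nr.ConditioningScenario({}))
        emp = data[list(model.symptom_labels)].mean()
        assert np.allclose(base.means, emp, atol=1e-6)

    def test_fitted_model_recovers_delta_signs(self):
        data, model = nr.generate_hybrid_dataset(
            nr.HybridGeneratorSpec(
                n_symptoms=10, n_persons=4000, seed=21,
                factors=(nr.FactorSpec("r", "risk"),
                         nr.FactorSpec("p", "protective", kind="ordinal", levels=5)),
            )
        )
        fit = nr.fit_nodewise_linear(data, model.symptom_labels, model.factor_labels,
                                     factor_roles=model.factor_roles)
        assert nr.esa_delta(fit, nr.presence_scenario(fit, present=["p"], absent=["r"])) < 0
        assert nr.esa_delta(fit, nr.presence_scenario(fit, present=["r"], absent=["p"])) > 0


class TestModelValidation:
    def test_self_coefficients_rejected(self):
        with pytest.raises(ValueError, match="self-coefficients"):
            nr.HybridNodewiseModel(
                symptom_labels=("s",), factor_labels=("f",),
                intercepts=np.zeros(2), coef=np.eye(2),
                scale_min=np.zeros(2), scale_max=np.ones(2),
                baseline_means=np.full(2, 0.5),
            )

    def test_baseline_outside_scale_rejected(self):
        with pytest.raises(ValueError, match="outside its scale"):
            nr.HybridNodewiseModel(
                symptom_labels=("s",), factor_labels=("f",),
                intercepts=np.zeros(2), coef=np.zeros((2, 2)),
                scale_min=np.zeros(2), scale_max=np.ones(2),
                baseline_means=np.array([2.0, 0.5]),
            )
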