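"""Pathway model structure, kinetics, simulation and steady-state initialization."""

import numpy as np
import pytest

from circuitbo import (
    ConfigurationError,
    DomainError,
    ToxicityParams,
    build_model,
    enzyme_expression_rates,
    miox_rate,
    simulate,
    steady_state_init,
    toxicity_factor,
)
from circuitbo.models import MODEL_IDS


EXPECTED_DIMS = {
    # model_id: (n_continuous, n_architectures, n_metabolites, n_proteins, n_odes)
    "toy": (4, 4, 2, 2, 4),
    "glucaric_acid": (4, 4, 3, 2, 5),
    "fatty_acid": (2, 4, 1, 2, 3),
    "p_aminostyrene": (16, 27, 7, 6, 23),
}


class TestStructure:
    @pytest.mark.parametrize("model_id", MODEL_IDS)
    def test_dimensions(self, model_id):
        m = build_model(model_id)
        pc, arch, met, enz, odes = EXPECTED_DIMS[model_id]
        assert m.n_continuous == pc
        assert len(m.architectures()) == arch
        assert len(m.metabolites) == met
        assert len(m.proteins) == enz
        assert m.n_states == odes

    def test_unknown_model_rejected(self):
        with pytest.raises(ConfigurationError):
            build_model("citric_acid")

    def test_unknown_override_rejected(self):
        with pytest.raises(ConfigurationError):
            build_model("toy", overrides={"kcat_99": 1.0})

    def test_override_applies(self):
        m = build_model("glucaric_acid", overrides={"Vm_MIOX": 0.07})
        assert m.kinetics["Vm_MIOX"] == 0.07

    def test_toy_named_architectures(self, toy_model):
        names = {a.name for a in toy_model.architectures()}
        assert names == {
            "open_loop", "upstream_repression", "downstream_activation", "dual_control",
        }

    def test_model_card_is_serializable(self, glucaric_model):
        import yaml

        card = glucaric_model.model_card()
        assert yaml.safe_load(yaml.safe_dump(card)) == card


class TestMioxRate:
    def test_zero_substrate_zero_flux(self, glucaric_model):
        assert miox_rate(0.0, 5.0, glucaric_model.kinetics) == 0.0

    def test_no_allostery_reduces_to_michaelis_menten(self):
        params = {"Vm_MIOX": 2.0, "km_MIOX": 1.0, "ka_MIOX": 1.0, "a_MIOX": 1e-12}
        v = miox_rate(3.0, 2.0, params)
        assert v == pytest.approx(2.0 * 2.0 * 3.0 / 4.0, rel=1e-6)

    def test_saturating_bound(self, glucaric_model):
        k = glucaric_model.kinetics
        bound = k["Vm_MIOX"] * 2.0 * (1 + k["a_MIOX"])
        v_inf = miox_rate(1e9, 2.0, k)
        assert v_inf < bound
        assert v_inf == pytest.approx(bound, rel=1e-6)

    def test_monotone_in_substrate_and_linear_in_enzyme(self, glucaric_model):
        k = glucaric_model.kinetics
        s = np.linspace(0, 10, 50)
        v = [miox_rate(x, 1.0, k) for x in s]
        assert np.all(np.diff(v) > 0)
        assert miox_rate(1.0, 3.0, k) == pytest.approx(3 * miox_rate(1.0, 1.0, k))

    def test_negative_inputs_rejected(self, glucaric_model):
        with pytest.raises(DomainError):
            miox_rate(-1.0, 1.0, glucaric_model.kinetics)


class TestToxicityFactor:
    def test_no_toxicity_gives_unity(self):
        tau = toxicity_factor({"pACA": 5.0, "Pump": 2.0, "v_LAAO": 1.0},
                              ToxicityParams(0, 0, 0))
        assert tau == 1.0

    def test_strictly_decreasing_in_paca(self):
        tox = ToxicityParams(t_l=0.0, t_a=0.1, t_p=0.0)
        taus = [toxicity_factor({"pACA": c}, tox) for c in (0.0, 1.0, 5.0, 50.0)]
        assert taus[0] == 1.0
        assert np.all(np.diff(taus) < 0)
        assert all(0 < t <= 1 for t in taus)

    def test_scales_pas_expression_rates(self):
        # doubling metabolite toxicity slows p-AS protein accumulation
        mild = build_model("p_aminostyrene", overrides={"t_a": 1e-4})
        harsh = build_model("p_aminostyrene", overrides={"t_a": 5e-1})
        arch = mild.architectures()[0]
        pc = mild.pc_defaults
        y_mild = simulate(mild, arch, pc).y[-1]
        y_harsh = simulate(harsh, arch, pc).y[-1]
        # total folded protein is lower under stronger toxicity
        assert y_harsh[17:].sum() < y_mild[17:].sum()


class TestSimulate:
    def test_no_influx_keeps_metabolites_at_zero(self, toy_model):
        m = build_model("toy", overrides={"V_in": 0.0})
        arch = m.architecture_by_name("open_loop")
        res = simulate(m, arch, m.pc_defaults)
        assert res.success
        assert np.abs(res.y[:, :2]).max() < 1e-7

    def test_constitutive_enzyme_reaches_u_over_lambda(self, toy_model):
        # linear ODE e' = u0 - lam*e from zero: e(t) = u0/lam * (1 - exp(-lam t))
        u0, lam = 2.0, toy_model.dilution
        arch = toy_model.architecture_by_name("open_loop")
        res = simulate(toy_model, arch, [u0, 1.0, u0, 1.0], rtol=1e-10, atol=1e-12)
        expected = u0 / lam * (1 - np.exp(-lam * res.t))
        for enz in ("E1", "E2"):
            assert np.allclose(res.state(enz), expected, rtol=1e-6, atol=1e-9)

    def test_enzyme_decay_closed_form(self):
        # zero expression: e(t) = e0 * exp(-lam t) to 1e-6 relative
        m = build_model("toy")
        arch = m.architecture_by_name("open_loop")
        x0 = np.array([1.0, 0.5, 3.0, 1.5])
        res = simulate(m, arch, [0.0, 1.0, 0.0, 1.0], init=x0, rtol=1e-10, atol=1e-12)
        for idx, e0 in ((2, 3.0), (3, 1.5)):
            expected = e0 * np.exp(-m.dilution * res.t)
            assert np.allclose(res.y[:, idx], expected, rtol=1e-6)

    @pytest.mark.parametrize("model_id", MODEL_IDS)
    def test_states_remain_nonnegative(self, model_id):
        m = build_model(model_id)
        arch = m.architectures()[-1]
        res = simulate(m, arch, m.pc_defaults)
        assert res.success
        assert res.y.min() > -1e-6

    def test_rhs_matches_public_expression_rates(self, glucaric_model):
        # the inline control terms in the RHS must agree with the public API
        m = glucaric_model
        arch = m.architecture_by_name("dual_control")
        pc = np.array([3.0, 0.2, 2.0, 0.1])
        x = np.array([0.8, 0.35, 0.1, 4.0, 2.0])
        dx = m.rhs(0.0, x, arch, pc)
        rates = enzyme_expression_rates(
            {"MI": x[1]}, m.promoter_params(pc, arch), arch, m.regulatory_spec
        )
        lam = m.dilution
        assert dx[3] == pytest.approx(rates["Ino1"] - lam * x[3])
        assert dx[4] == pytest.approx(rates["MIOX"] - lam * x[4])

    def test_toy_mass_balance(self, toy_model):
        # flux out of X0 equals native drain + flux into X1 chain
        m = toy_model
        arch = m.architecture_by_name("open_loop")
        pc = np.array([1.0, 1.0, 1.0, 1.0])
        x = np.array([0.7, 0.4, 2.0, 1.0])
        dx = m.rhs(0.0, x, arch, pc)
        k = m.kinetics
        v1 = k["kcat1"] * x[2] * x[0] / (k["Km1"] + x[0])
        v2 = k["kcat2"] * x[3] * x[1] / (k["Km2"] + x[1])
        assert dx[0] == pytest.approx(m.v_in - k["k_nat"] * x[0] - v1)
        assert dx[1] == pytest.approx(v1 - v2)
        assert m.product_flux(x[None, :])[0] == pytest.approx(v2)

    def test_bad_init_shape_rejected(self, toy_model):
        arch = toy_model.architectures()[0]
        with pytest.raises(ConfigurationError):
            simulate(toy_model, arch, toy_model.pc_defaults, init=np.zeros(3))

    def test_solver_tolerance_robustness(self, toy_model):
        from circuitbo import ObjectiveSpec, cost_benefit_loss

        arch = toy_model.architecture_by_name("dual_control")
        spec = ObjectiveSpec(alpha1=1.0, alpha2=toy_model.default_cost_weights[1])
        losses = []
        for rtol, atol in ((1e-6, 1e-9), (5e-7, 5e-10)):
            res = simulate(toy_model, arch, toy_model.pc_defaults, rtol=rtol, atol=atol)
            losses.append(cost_benefit_loss(res, toy_model, spec))
        assert abs(losses[1] - losses[0]) / losses[0] < 1e-3

    def test_bdf_agrees_with_lsoda(self, glucaric_model):
        arch = glucaric_model.architecture_by_name("dual_control")
        pc = glucaric_model.pc_defaults
        a = simulate(glucaric_model, arch, pc, method="lsoda")
        b = simulate(glucaric_model, arch, pc, method="bdf")
        assert a.success and b.success
        assert np.allclose(a.y[-1], b.y[-1], rtol=1e-3, atol=1e-6)


class TestSteadyStateInit:
    @pytest.mark.parametrize("model_id", MODEL_IDS)
    def test_residual_below_tolerance(self, model_id):
        m = build_model(model_id)
        s = steady_state_init(m)
        x = np.zeros(m.n_states)
        x[: len(m.metabolites)] = s
        resid = np.abs(m.rhs(0.0, x, m.architectures()[0],
                             np.asarray(m.pc_defaults))[: len(m.metabolites)])
        scale = max(np.abs(s).max(), 1.0)
        assert resid.max() / scale < 1e-8

    def test_zero_influx_gives_zero_state(self):
        m = build_model("toy", overrides={"V_in": 0.0})
        assert np.abs(steady_state_init(m)).max() < 1e-10

    def test_idempotence_flat_trajectories(self, toy_model):
        # simulating from the steady state with zero heterologous enzymes and
        # zero expression stays flat
        s = steady_state_init(toy_model)
        x0 = np.concatenate([s, [0.0, 0.0]])
        arch = toy_model.architecture_by_name("open_loop")
        res = simulate(toy_model, arch, [0.0, 1.0, 0.0, 1.0], init=x0)
        assert np.allclose(res.y, res.y[0], rtol=1e-6, atol=1e-8)
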