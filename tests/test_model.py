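"""Linear ODE model: effective regulation, steady states, dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gtrn_refactor._errors import NumericalError, StabilityWarning, ValidationError
from gtrn_refactor.model import (
    Environment,
    effective_regulation,
    expression_profile,
    response_time,
    simulate_dynamics,
    steady_state,
)
from gtrn_refactor.synth import SynthesisSpec, generate_environments, generate_gtrn

from conftest import make_gtrn


class TestEffectiveRegulation:
    def test_primary_only_is_identity(self, single_gene_gtrn):
        reg = effective_regulation(single_gene_gtrn, "op1")
        assert (reg.alpha, reg.beta, reg.gamma) == (2.0, {}, {})

    def test_tandem_terms_add_elementwise(self):
        g = make_gtrn(
            genes={"gA": 1.0},
            operons={"op1": {"genes": ["gA"], "primary_promoter": "P",
                             "tandem_promoters": ["T"]}},
            promoters={"P": (1.0, {"tfA": 0.5}, {}),
                       "T": (0.2, {"tfB": -0.3}, {}),
                       },
        )
        # regulator ids need not resolve to genes until matrix assembly
        reg = effective_regulation(g, "op1")
        assert reg.alpha == pytest.approx(1.2)
        assert reg.beta == {"tfA": 0.5, "tfB": -0.3}

    def test_removing_tandem_restores_primary_terms(self):
        g = make_gtrn(
            genes={"gA": 1.0},
            operons={"op1": {"genes": ["gA"], "primary_promoter": "P",
                             "tandem_promoters": ["T"]}},
            promoters={"P": (1.0, {"tfA": 0.5}, {}),
                       "T": (0.2, {"tfB": -0.3}, {})},
        )
        g.operons["op1"].tandem_promoters.clear()
        reg = effective_regulation(g, "op1")
        assert (reg.alpha, reg.beta) == (1.0, {"tfA": 0.5})

    def test_order_independent_in_tandem_list(self):
        proms = {"P": (1.0, {"a": 0.1}, {"O2": 0.2}),
                 "T1": (0.5, {"b": -0.2}, {}),
                 "T2": (0.25, {"a": 0.3}, {"glc": -0.1})}
        regs = []
        for order in (["T1", "T2"], ["T2", "T1"]):
            g = make_gtrn(
                genes={"gA": 1.0},
                operons={"op1": {"genes": ["gA"], "primary_promoter": "P",
                                 "tandem_promoters": order}},
                promoters=proms,
            )
            regs.append(effective_regulation(g, "op1"))
        assert regs[0].alpha == regs[1].alpha
        assert regs[0].beta == pytest.approx(regs[1].beta)
        assert regs[0].gamma == pytest.approx(regs[1].gamma)

    def test_unknown_promoter_names_operon(self, single_gene_gtrn):
        single_gene_gtrn.operons["op1"].tandem_promoters.append("ghost")
        with pytest.raises(ValidationError, match="op1.*ghost"):
            effective_regulation(single_gene_gtrn, "op1")


class TestSteadyState:
    def test_isolated_gene_alpha_over_delta(self, single_gene_gtrn,
                                            env_neutral):
        y = steady_state(single_gene_gtrn, env_neutral)
        assert y["gA"] == pytest.approx(2.0, abs=1e-12)

    def test_environmental_input_closed_form(self):
        # y = (alpha + gamma*dv)/delta = (1 + 0.2*5)/1 = 2
        g = make_gtrn(
            genes={"gA": 1.0},
            operons={"op1": (["gA"], "P1")},
            promoters={"P1": (1.0, {}, {"O2": 0.2})},
        )
        env = Environment(id="e", v={"O2": 15.0}, v_opt={"O2": 10.0})
        assert steady_state(g, env)["gA"] == pytest.approx(2.0, abs=1e-12)

    def test_two_gene_cascade_forward_substitution(self, cascade_gtrn,
                                                   env_neutral):
        y = steady_state(cascade_gtrn, env_neutral)
        assert y["gA"] == pytest.approx(1.0, abs=1e-12)
        assert y["gB"] == pytest.approx(1.0, abs=1e-12)

    def test_unregulated_genome_is_alpha_over_delta_exactly(self):
        rng = np.random.default_rng(5)
        alphas = rng.uniform(0.5, 5.0, 8)
        deltas = rng.uniform(0.1, 2.0, 8)
        g = make_gtrn(
            genes={f"g{i}": float(deltas[i]) for i in range(8)},
            operons={f"op{i}": ([f"g{i}"], f"P{i}") for i in range(8)},
            promoters={f"P{i}": (float(alphas[i]), {}, {}) for i in range(8)},
        )
        env = Environment(id="any", v={"O2": 3.0}, v_opt={"O2": 1.0})
        y = steady_state(g, env)
        for i in range(8):
            assert y[f"g{i}"] == pytest.approx(alphas[i] / deltas[i],
                                               rel=1e-12)

    def test_negative_solution_clipped_and_reported(self):
        g = make_gtrn(
            genes={"gA": 1.0},
            operons={"op1": (["gA"], "P1")},
            promoters={"P1": (1.0, {}, {"O2": -1.0})},
        )
        env = Environment(id="e", v={"O2": 6.0}, v_opt={"O2": 1.0})
        y, info = steady_state(g, env, return_diagnostics=True)
        assert y["gA"] == 0.0
        assert info.raw["gA"] == pytest.approx(-4.0)
        assert info.clipped_genes == ("gA",)

    def test_singular_system_raises_naming_genes(self, env_neutral):
        # self-activation exactly canceling degradation: (delta - beta) = 0
        g = make_gtrn(
            genes={"gA": 1.0},
            operons={"op1": (["gA"], "P1")},
            promoters={"P1": (1.0, {"gA": 1.0}, {})},
        )
        with pytest.raises(NumericalError, match="gA"):
            steady_state(g, env_neutral)

    def test_unknown_environment_factor_with_gamma_raises(self):
        g = make_gtrn(
            genes={"gA": 1.0},
            operons={"op1": (["gA"], "P1")},
            promoters={"P1": (1.0, {}, {"N2": 0.5})},
        )
        env = Environment(id="e", v={"O2": 1.0}, v_opt={"O2": 1.0})
        with pytest.raises(ValidationError, match="N2"):
            steady_state(g, env)

    def test_linearity_of_environmental_response(self):
        """The steady-state response to dv is affine in dv."""
        g = generate_gtrn(SynthesisSpec(n_genes=15, redundancy=1, seed=9))
        v_opt = {"O2": 75.0, "glc": 20.0}

        def env(dv_o2, dv_glc, tag):
            return Environment(
                id=tag,
                v={"O2": 75.0 + dv_o2, "glc": 20.0 + dv_glc},
                v_opt=dict(v_opt),
            )

        def raw(environment):
            _, info = steady_state(g, environment, return_diagnostics=True)
            return info.raw.to_numpy()

        y0 = raw(env(0, 0, "base"))
        d1 = raw(env(30.0, 0.0, "a")) - y0
        d2 = raw(env(0.0, -10.0, "b")) - y0
        d12 = raw(env(30.0, -10.0, "ab")) - y0
        np.testing.assert_allclose(d12, d1 + d2, atol=1e-9)


class TestDynamics:
    def test_fixed_point_stays_constant(self, cascade_gtrn, env_neutral):
        y_ss = steady_state(cascade_gtrn, env_neutral)
        traj = simulate_dynamics(cascade_gtrn, env_neutral, y_ss.to_numpy(),
                                 [0.0, 1.0, 5.0])
        np.testing.assert_allclose(traj.to_numpy(),
                                   np.tile(y_ss.to_numpy(), (3, 1)),
                                   atol=1e-7)

    def test_scalar_relaxation_closed_form(self, single_gene_gtrn,
                                           env_neutral):
        # alpha=2, delta=1, y0=0: y(t) = 2(1 - e^-t)
        t = np.linspace(0.0, 3.0, 7)
        traj = simulate_dynamics(single_gene_gtrn, env_neutral, [0.0], t)
        np.testing.assert_allclose(traj["gA"].to_numpy(),
                                   2.0 * (1 - np.exp(-t)), atol=1e-7)

    def test_independent_genes_separate(self, env_neutral):
        g = make_gtrn(
            genes={"gA": 1.0, "gB": 2.0},
            operons={"opA": (["gA"], "PA"), "opB": (["gB"], "PB")},
            promoters={"PA": (1.0, {}, {}), "PB": (3.0, {}, {})},
        )
        t = np.linspace(0.0, 2.0, 5)
        traj = simulate_dynamics(g, env_neutral, [0.0, 0.0], t)
        np.testing.assert_allclose(traj["gA"], 1.0 * (1 - np.exp(-t)),
                                   atol=1e-7)
        np.testing.assert_allclose(traj["gB"], 1.5 * (1 - np.exp(-2 * t)),
                                   atol=1e-7)

    def test_converges_to_steady_state(self, env_neutral):
        g = generate_gtrn(SynthesisSpec(n_genes=12, redundancy=1, seed=2))
        envs = generate_environments("oxygen", 1, seed=3)
        _, info = steady_state(g, envs[1], return_diagnostics=True)
        t_end = 1e3 / min(gene.delta for gene in g.genes.values())
        traj = simulate_dynamics(g, envs[1],
                                 np.zeros(len(g.genes)), [0.0, t_end])
        np.testing.assert_allclose(traj.iloc[-1].to_numpy(),
                                   info.raw.to_numpy(), rtol=1e-6, atol=1e-9)

    def test_unstable_system_warns(self, env_neutral):
        g = make_gtrn(
            genes={"gA": 1.0},
            operons={"op1": (["gA"], "P1")},
            promoters={"P1": (1.0, {"gA": 2.0}, {})},
        )
        with pytest.warns(StabilityWarning):
            simulate_dynamics(g, env_neutral, [0.0], [0.0, 0.1])

    def test_bad_time_grid_rejected(self, single_gene_gtrn, env_neutral):
        with pytest.raises(ValidationError):
            simulate_dynamics(single_gene_gtrn, env_neutral, [0.0], [1.0, 2.0])


class TestResponseTime:
    def _gtrn(self, delta):
        return make_gtrn(
            genes={"gA": delta},
            operons={"op1": (["gA"], "P1")},
            promoters={"P1": (1.0, {}, {"O2": 1.0})},
        )

    def test_no_perturbation_is_zero(self, env_neutral):
        g = self._gtrn(1.0)
        assert response_time(g, env_neutral, env_neutral) == 0.0

    def test_exponential_relaxation_closed_form(self):
        # single gene delta=1: t* = ln(1/eps)
        g = self._gtrn(1.0)
        a = Environment(id="a", v={"O2": 75.0}, v_opt={"O2": 75.0})
        b = Environment(id="b", v={"O2": 80.0}, v_opt={"O2": 75.0})
        t = response_time(g, a, b, epsilon=0.05)
        assert t == pytest.approx(np.log(1 / 0.05), rel=1e-3)

    def test_rate_scaling_with_delta(self):
        a = Environment(id="a", v={"O2": 75.0}, v_opt={"O2": 75.0})
        b = Environment(id="b", v={"O2": 80.0}, v_opt={"O2": 75.0})
        t1 = response_time(self._gtrn(1.0), a, b, epsilon=0.05)
        t2 = response_time(self._gtrn(2.0), a, b, epsilon=0.05)
        assert t2 == pytest.approx(t1 / 2, rel=1e-3)

    def test_epsilon_domain_checked(self, env_neutral):
        with pytest.raises(ValidationError):
            response_time(self._gtrn(1.0), env_neutral, env_neutral,
                          epsilon=1.5)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_profile_matches_per_environment_solves(seed):
    """expression_profile equals column-by-column steady_state."""
    g = generate_gtrn(SynthesisSpec(n_genes=8, redundancy=2, seed=seed))
    envs = generate_environments("multi", 2, seed=seed)
    prof = expression_profile(g, envs)
    for env in envs:
        np.testing.assert_allclose(prof[env.id].to_numpy(),
                                   steady_state(g, env).to_numpy(),
                                   rtol=1e-12, atol=1e-12)
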