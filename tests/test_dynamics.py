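import numpy as np
import pytest
from scipy import stats

from pollinet import (
    BipartiteNetwork,
    CommunityState,
    ForcingSpec,
    IntegrationError,
    ModelParams,
    effective_pair_strength,
    growth_and_selection,
    pair_interaction_expectation,
    quasi_equilibrium_traits,
    simulate,
)
from tests.conftest import FAST_NODES


def two_species_params(gamma0, sigma=1e-4, **kw):
    kw.setdefault("alpha", np.eye(2))
    kw.setdefault("quadrature_nodes", FAST_NODES)
    return ModelParams(gamma0=gamma0, sigma=sigma, **kw)


class TestParams:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(H=-0.1),
            dict(omega=0.0),
            dict(h2=1.5),
            dict(sigma=0.0),
            dict(kernel="triangular"),
            dict(alpha=np.array([[2.0, 0.0], [0.0, 1.0]])),
            dict(alpha=np.array([[1.0, 1.5], [0.0, 1.0]])),
        ],
    )
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            ModelParams(gamma0=1.0, **kw)

    def test_yaml_roundtrip(self, tmp_path):
        p = ModelParams(gamma0=1.3, sigma=0.02, alpha=np.eye(3))
        path = tmp_path / "params.yaml"
        p.to_yaml(path)
        q = ModelParams.from_yaml(path)
        assert q.gamma0 == p.gamma0 and q.sigma == p.sigma
        assert np.array_equal(q.alpha, p.alpha)


class TestPairStrength:
    def test_matched_traits_vanishing_variance_gives_gamma0(self):
        v = effective_pair_strength(0.3, 0.3, 1e-9, 1e-9, 2.5, 0.35, 1)
        assert v == pytest.approx(2.5)

    def test_degree_trade_off_divides(self):
        v1 = effective_pair_strength(0.0, 0.0, 0.01, 0.01, 1.0, 0.35, 1)
        v5 = effective_pair_strength(0.0, 0.0, 0.01, 0.01, 1.0, 0.35, 5)
        assert v5 == pytest.approx(v1 / 5)

    def test_distant_traits_give_vanishing_strength(self):
        v = effective_pair_strength(-2.0, 2.0, 0.02, 0.02, 1.0, 0.35, 1)
        assert v < 1e-12

    def test_zero_degree_rejected(self):
        with pytest.raises(ValueError):
            effective_pair_strength(0, 0, 0.01, 0.01, 1.0, 0.35, 0)

    def test_quadrature_matches_closed_form_at_zero_handling(self):
        p = ModelParams(gamma0=1.0, H=0.0, omega=0.35)
        q = pair_interaction_expectation(0.1, -0.1, 0.02, 0.03, p, d_i=2)
        c = effective_pair_strength(0.1, -0.1, 0.02, 0.03, 1.0, 0.35, 2)
        assert q == pytest.approx(c, rel=1e-10)

    def test_type2_expectation_matches_grid_quadrature(self):
        # independent oracle: dense trapezoid grid over both trait densities
        u_i, u_k, s_i, s_k, g0, om, H, N_k = 0.1, -0.05, 0.03, 0.02, 2.0, 0.35, 0.25, 1.7
        z = np.linspace(-0.3, 0.5, 2001)
        zp = np.linspace(-0.45, 0.35, 2001)
        pi = stats.norm.pdf(z, u_i, s_i)
        pk = stats.norm.pdf(zp, u_k, s_k)
        g = g0 * np.exp(-((z[:, None] - zp[None, :]) ** 2) / om**2)
        f = g / (1 + H * g * N_k)
        oracle = np.trapezoid(np.trapezoid(f * pk[None, :], zp, axis=1) * pi, z)
        p = ModelParams(gamma0=g0, H=H, omega=om)
        val = pair_interaction_expectation(u_i, u_k, s_i, s_k, p, d_i=1, N_k=N_k)
        assert val == pytest.approx(oracle, rel=1e-7)

    def test_asymmetric_kernel_peak_value(self):
        # at zero trait distance the gamma kernel evaluates at the shifted
        # argument 10, scaled by a factor 10
        p = ModelParams(gamma0=1.0, kernel="asymmetric_gamma", H=0.0,
                        quadrature_nodes=31)
        val = pair_interaction_expectation(0.0, 0.0, 1e-6, 1e-6, p, d_i=1)
        expected = 10 * stats.gamma.pdf(10.0, a=4.5, scale=1 / 0.5)
        assert val == pytest.approx(expected, rel=1e-6)


class TestGrowthAndSelection:
    def test_pure_decay_without_mutualism(self, net30):
        from pollinet import sample_params

        p = sample_params(net30, seed=1, gamma0=0.0, quadrature_nodes=FAST_NODES)
        state = CommunityState(np.ones(30), np.linspace(-0.5, 0.5, 30))
        dN, du = growth_and_selection(state, net30, p)
        assert np.all(dN < 0)
        assert np.allclose(dN, -state.N * (p.alpha @ state.N))

    def test_equal_traits_have_no_selection_gradient(self, net30):
        from pollinet import sample_params

        p = sample_params(net30, seed=1, gamma0=2.0, quadrature_nodes=FAST_NODES)
        state = CommunityState(np.ones(30), np.full(30, 0.2))
        _, du = growth_and_selection(state, net30, p)
        assert np.allclose(du, 0.0, atol=1e-12)

    @pytest.mark.parametrize("gbar", [1.2, 1.5, 2.0])
    def test_rhs_vanishes_at_analytic_fixed_point(self, two_species_net, gbar):
        p = two_species_params(gbar)
        n_star = 4 * (gbar - 1) / gbar
        state = CommunityState(np.full(2, n_star), np.zeros(2))
        dN, du = growth_and_selection(state, two_species_net, p)
        assert np.allclose(dN, 0.0, atol=1e-6)
        assert np.allclose(du, 0.0, atol=1e-10)

    def test_invalid_density_raises_with_species_index(self, two_species_net):
        p = two_species_params(1.5)
        state = CommunityState(np.array([1.0, np.nan]), np.zeros(2))
        with pytest.raises(IntegrationError, match="1"):
            growth_and_selection(state, two_species_net, p)

    def test_degree_scaling_leaves_percapita_gain_invariant(self):
        # with the gamma0/d_i normalization and no handling-time
        # saturation, a plant with d identical partners at equal density
        # and trait receives the same total mutualistic input for any d
        rates = []
        for d in (2, 4):
            net = BipartiteNetwork(["p"], [f"a{i}" for i in range(d)],
                                   np.ones((1, d)))
            p = ModelParams(gamma0=1.5, sigma=0.01, H=0.0,
                            alpha=np.eye(d + 1), quadrature_nodes=FAST_NODES)
            state = CommunityState(np.full(d + 1, 0.7), np.zeros(d + 1))
            dN, _ = growth_and_selection(state, net, p)
            rates.append(dN[0])
        assert rates[0] == pytest.approx(rates[1], rel=1e-10)

    def test_mean_field_denominator_close_to_quadrature(self, net17):
        from pollinet import sample_params

        state = CommunityState(
            np.full(17, 1.2), np.linspace(-0.2, 0.2, 17)
        )
        p = sample_params(net17, seed=2, gamma0=2.0, sigma="high",
                          quadrature_nodes=FAST_NODES)
        dN_full, _ = growth_and_selection(state, net17, p)
        p_mf = p.replace(mean_field_denominator=True)
        dN_mf, _ = growth_and_selection(state, net17, p_mf)
        # the mean-field denominator is an approximation; at these trait
        # variances it should track the full quadrature to a few percent
        # (absolute floor because dN components are differences of larger
        # gain/loss terms)
        assert dN_mf == pytest.approx(dN_full, rel=5e-2, abs=2e-3)


class TestSimulate:
    def test_two_species_converges_to_fixed_point(self, two_species_net):
        p = two_species_params(1.5)
        traj = simulate(CommunityState(np.ones(2), np.zeros(2)),
                        two_species_net, p, t_end=1000)
        assert traj.N[-1] == pytest.approx(4 * 0.5 / 1.5, rel=0.01)

    def test_zero_strength_forcing_matches_unforced(self, net17):
        from pollinet import sample_params

        p = sample_params(net17, seed=2, gamma0=1.5, quadrature_nodes=FAST_NODES)
        state = CommunityState(np.full(17, 0.5), np.linspace(-0.3, 0.3, 17))
        base = simulate(state, net17, p, t_end=50)
        forced = simulate(state, net17, p, t_end=50,
                          forcing=ForcingSpec([0], 0.0, 30.0))
        assert np.allclose(base.N, forced.N)

    def test_traits_frozen_without_heritability(self, net17):
        from pollinet import sample_params

        p = sample_params(net17, seed=2, gamma0=2.0, h2=0.0,
                          quadrature_nodes=FAST_NODES)
        state = CommunityState(np.ones(17), np.linspace(-0.4, 0.4, 17))
        traj = simulate(state, net17, p, t_end=100)
        assert np.allclose(traj.u, traj.u[0], atol=1e-9)

    def test_densities_never_negative(self, net17):
        from pollinet import sample_params

        p = sample_params(net17, seed=2, gamma0=0.3, quadrature_nodes=FAST_NODES)
        rng = np.random.default_rng(0)
        state = CommunityState(rng.uniform(0, 1, 17), rng.uniform(-0.5, 0.5, 17))
        traj = simulate(state, net17, p, t_end=200)
        assert np.all(traj.N >= 0)

    def test_unit_sampling_grid(self, two_species_net):
        p = two_species_params(1.5)
        traj = simulate(CommunityState(np.ones(2), np.zeros(2)),
                        two_species_net, p, t_end=25)
        assert np.allclose(traj.times, np.arange(26))

    def test_forcing_switches_off_at_duration(self, two_species_net):
        # force one species at gamma0 too low to sustain it: density rises
        # while forced, then decays
        p = two_species_params(0.5)
        forcing = ForcingSpec([0], 0.6, 40.0)
        traj = simulate(CommunityState(np.full(2, 0.01), np.zeros(2)),
                        two_species_net, p, t_end=120, forcing=forcing)
        i_T = np.searchsorted(traj.times, 40.0)
        assert traj.N[i_T, 0] > traj.N[0, 0]
        assert traj.N[-1, 0] < traj.N[i_T, 0]

    def test_unknown_forced_species_rejected(self, two_species_net):
        p = two_species_params(1.5)
        with pytest.raises(ValueError, match="not in network"):
            simulate(CommunityState(np.ones(2), np.zeros(2)), two_species_net,
                     p, t_end=10, forcing=ForcingSpec([5], 0.5, 5.0))

    def test_trajectory_frame_is_tidy(self, two_species_net):
        p = two_species_params(1.5)
        traj = simulate(CommunityState(np.ones(2), np.zeros(2)),
                        two_species_net, p, t_end=5)
        df = traj.to_frame(two_species_net)
        assert set(df.columns) == {"time", "species_id", "guild", "N", "u"}
        assert len(df) == 6 * 2


class TestQuasiEquilibriumTraits:
    def test_identical_initial_traits_are_preserved(self, net17):
        from pollinet import sample_params

        p = sample_params(net17, seed=2, quadrature_nodes=FAST_NODES)
        u = quasi_equilibrium_traits(net17, p, seed=0, trait_range=0.0)
        assert np.allclose(u, 0.0, atol=1e-9)

    def test_high_gamma0_run_reaches_positive_biomass(self, net17):
        from pollinet import ModelParams, sample_params

        for seed in (1, 2):
            p = sample_params(net17, seed=2, sigma="high",
                              quadrature_nodes=FAST_NODES)
            rng = np.random.default_rng(seed)
            u0 = rng.uniform(-0.5, 0.5, 17)
            traj = simulate(CommunityState(np.ones(17), u0), net17,
                            p.replace(gamma0=4.0), t_end=1000)
            assert traj.N[-1].mean() > 1.0

    def test_two_species_traits_converge_toward_each_other(self, two_species_net):
        p = ModelParams(gamma0=2.0, sigma=0.05, h2=0.4, alpha=np.eye(2),
                        quadrature_nodes=FAST_NODES)
        traj = simulate(CommunityState(np.ones(2), np.array([-0.2, 0.2])),
                        two_species_net, p, t_end=300)
        gaps = np.abs(traj.u[:, 0] - traj.u[:, 1])
        assert gaps[-1] < gaps[0]
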