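"""Leroux CAR sampler: conditionals, update kernels, chain bookkeeping."""

import math

import numpy as np
import pytest

import carmap.synthetic as syn
from carmap import (AdjacencyGraph, LerouxCAR, McmcConfig, PriorSpec,
                    phi_prior_conditional)
from carmap.model import ChainState


class TestPhiPriorConditional:
    def test_rho_zero_independence(self, path3):
        phi = np.array([5.0, -2.0, 1.0])
        mean, var = phi_prior_conditional(1, phi, rho=0.0, tau2=3.0, graph=path3)
        assert mean == 0.0 and var == 3.0

    def test_intrinsic_limit(self, path3):
        # rho -> 1: mean -> neighbor average, variance -> tau2/d
        phi = np.array([1.0, 0.0, 3.0])
        mean, var = phi_prior_conditional(1, phi, rho=1 - 1e-12, tau2=1.0, graph=path3)
        assert mean == pytest.approx(2.0, rel=1e-9)
        assert var == pytest.approx(0.5, rel=1e-9)

    def test_half_rho_formula(self, path3):
        phi = np.array([1.0, 0.0, 3.0])
        mean, var = phi_prior_conditional(1, phi, rho=0.5, tau2=1.0, graph=path3)
        assert mean == pytest.approx(4 / 3)
        assert var == pytest.approx(2 / 3)

    def test_invalid_domain(self, path3):
        with pytest.raises(ValueError):
            phi_prior_conditional(0, np.zeros(3), rho=1.0, tau2=1.0, graph=path3)
        with pytest.raises(ValueError):
            phi_prior_conditional(0, np.zeros(3), rho=0.5, tau2=0.0, graph=path3)


class _DegenerateRng:
    """Always proposes a zero step and never rejects (u -> small)."""

    def __init__(self, n):
        self.n = n

    def standard_normal(self, size=None):
        return np.zeros(size) if size is not None else 0.0

    def random(self, size=None):
        return np.full(size, 1e-300) if size is not None else 1e-300


class TestUpdates:
    def test_zero_step_proposal_always_accepted(self, path3):
        m = LerouxCAR(np.array([1.0, 2.0, 0.0]), np.ones(3), graph=path3)
        st = ChainState(beta=0.1, phi=np.array([0.2, -0.1, 0.0]), tau2=0.5, rho=0.3)
        rate = m.update_phi_sweep(st, _DegenerateRng(3))
        assert rate == 1.0
        assert m.update_beta(st, _DegenerateRng(3))

    def test_tau2_gibbs_shape_and_scale(self, cycle4):
        # posterior shape a + n/2; with phi = 0 the scale is exactly b
        m = LerouxCAR(np.ones(4), np.ones(4), graph=cycle4,
                      priors=PriorSpec(tau2_shape=1.0, tau2_scale=0.25))
        st = ChainState(beta=0.0, phi=np.zeros(4), tau2=1.0, rho=0.5)
        rng = np.random.default_rng(0)
        draws = []
        for _ in range(20000):
            m.update_tau2(st, rng)
            draws.append(st.tau2)
        draws = np.array(draws)
        a_post, b_post = 1.0 + 2.0, 0.25  # IG(3, 0.25): mean b/(a-1) = 0.125
        assert abs(draws.mean() - b_post / (a_post - 1)) < 0.005
        target_var = b_post ** 2 / ((a_post - 1) ** 2 * (a_post - 2))
        assert abs(draws.var() - target_var) < 0.005

    def test_tau2_quadratic_form_matches_dense(self, lattice33):
        rng = np.random.default_rng(3)
        phi = rng.standard_normal(9)
        m = LerouxCAR(np.ones(9), np.ones(9), graph=lattice33)
        for rho in (0.0, 0.3, 0.9):
            R = rho * lattice33.laplacian() + (1 - rho) * np.eye(9)
            assert m._quad_form(phi, rho) == pytest.approx(phi @ R @ phi, rel=1e-10)

    def test_rho_logdet_identity(self, path3):
        # n=2 path analog: K2 Laplacian eigenvalues {0, 2}
        g = AdjacencyGraph.from_edge_list(["a", "b"], [("a", "b")])
        lam = g.structure_eigenvalues()
        rho = 0.5
        logdet = np.log(rho * lam + 1 - rho).sum()
        R = rho * g.laplacian() + (1 - rho) * np.eye(2)
        assert logdet == pytest.approx(np.log(np.linalg.det(R)))
        assert logdet == pytest.approx(math.log(0.5) + math.log(1.5))

    def test_beta_posterior_mode_near_zero_for_flat_data(self, lattice33):
        # O = E, phi = 0, vague prior: quadrature oracle for the 1-D target
        O = np.full(9, 10.0)
        m = LerouxCAR(O, O.copy(), graph=lattice33, priors=PriorSpec(beta_var=1e5))
        grid = np.linspace(-1, 1, 4001)
        logp = grid * O.sum() - O.sum() * np.exp(grid) - grid ** 2 / (2 * 1e5)
        w = np.exp(logp - logp.max())
        oracle_mean = (w * grid).sum() / w.sum()
        st = ChainState(beta=0.0, phi=np.zeros(9), tau2=0.05, rho=0.0,
                        step_beta=0.2)
        rng = np.random.default_rng(5)
        draws = []
        for _ in range(20000):
            m.update_beta(st, rng)
            draws.append(st.beta)
        assert abs(np.mean(draws[2000:]) - oracle_mean) < 0.01

    def test_small_beta_var_forces_beta_to_zero(self, lattice33):
        O = np.full(9, 4.0)
        m = LerouxCAR(O, np.ones(9), graph=lattice33,
                      priors=PriorSpec(beta_var=1e-6))
        st = ChainState(beta=0.0, phi=np.zeros(9), tau2=0.05, rho=0.0,
                        step_beta=0.01)
        rng = np.random.default_rng(6)
        for _ in range(5000):
            m.update_beta(st, rng)
        assert abs(st.beta) < 0.01


class TestChainBookkeeping:
    def test_retained_draw_count(self, path3):
        m = LerouxCAR(np.array([1.0, 2.0, 0.0]), np.ones(3), graph=path3)
        res = m.fit(McmcConfig(n_burnin=100, n_sample=1000, thin=10, seed=0))
        assert res.draws.n_draws == 100

    def test_same_seed_bit_identical(self, path3):
        m = LerouxCAR(np.array([1.0, 2.0, 0.0]), np.ones(3), graph=path3)
        cfg = McmcConfig(n_burnin=200, n_sample=400, thin=2, seed=33)
        a, b = m.fit(cfg), m.fit(cfg)
        assert (a.draws.phi == b.draws.phi).all()
        assert (a.draws.beta == b.draws.beta).all()
        assert (a.draws.tau2 == b.draws.tau2).all()
        assert (a.draws.rho == b.draws.rho).all()

    def test_prior_only_rho_uniform(self, lattice33):
        # likelihood off: the chain targets the joint prior, so retained rho
        # draws are marginally U(0,1): mean 1/2, variance 1/12
        m = LerouxCAR(graph=lattice33, likelihood=False)
        res = m.fit(McmcConfig(n_burnin=2000, n_sample=30000, thin=3, seed=1))
        assert abs(res.draws.rho.mean() - 0.5) < 0.03
        assert abs(res.draws.rho.var() - 1 / 12) < 0.015

    def test_propriety_of_all_draws(self, lattice33):
        m = LerouxCAR(np.ones(9), np.ones(9), graph=lattice33)
        res = m.fit(McmcConfig(n_burnin=300, n_sample=600, thin=3, seed=2))
        lam = lattice33.structure_eigenvalues()
        assert (res.draws.tau2 > 0).all()
        assert ((res.draws.rho >= 0) & (res.draws.rho < 1)).all()
        vals = res.draws.rho[:, None] * lam[None, :] + 1 - res.draws.rho[:, None]
        assert (vals > 0).all()

    def test_acceptance_near_target_after_adaptation(self):
        g = AdjacencyGraph.lattice(5, 5)
        rng = np.random.default_rng(8)
        E = np.full(25, 5.0)
        O = rng.poisson(E).astype(float)
        m = LerouxCAR(O, E, graph=g)
        res = m.fit(McmcConfig(n_burnin=2000, n_sample=3000, thin=3, seed=4))
        for block in ("phi", "beta", "rho"):
            assert abs(res.draws.acceptance[block] - 0.4) < 0.15

    def test_recentring_leaves_fitted_risk_invariant(self, path3):
        phi = np.array([0.4, -0.2, 0.1])
        beta = 0.3
        E = np.array([1.0, 2.0, 3.0])
        before = E * np.exp(beta + phi)
        m = float(phi.mean())
        after = E * np.exp((beta + m) + (phi - m))
        assert np.allclose(before, after)

    def test_zero_expected_rejected(self, path3):
        with pytest.raises(ValueError, match="positive expected"):
            LerouxCAR(np.ones(3), np.array([1.0, 0.0, 1.0]), graph=path3)

    def test_single_area_runs(self):
        g = AdjacencyGraph(["only"], [])
        m = LerouxCAR(np.array([2.0]), np.array([1.0]), graph=g)
        res = m.fit(McmcConfig(n_burnin=200, n_sample=400, thin=2, seed=0))
        assert res.draws.n_draws == 200

    def test_shrinkage_limit_small_tau2(self, lattice33):
        # tau2 -> 0 with rho = 0: all smoothed IRRs collapse to a common value
        rng = np.random.default_rng(9)
        O = rng.poisson(5.0, 9).astype(float)
        E = np.full(9, 5.0)
        m = LerouxCAR(O, E, graph=lattice33, fixed={"tau2": 1e-8, "rho": 0.0})
        res = m.fit(McmcConfig(n_burnin=500, n_sample=1000, thin=2, seed=3))
        theta = res.smoothed_irr.to_numpy()
        assert theta.max() - theta.min() < 0.01


class TestFromTable:
    def test_standardizes_and_fits(self):
        ds = syn.simulate_dataset(nx=4, ny=4, seed=21)
        m = LerouxCAR.from_table(ds["table"], ds["graph"])
        assert m.graph.n == 16
        assert m.expected.sum() == pytest.approx(m.observed.sum(), rel=1e-10)
        res = m.fit(McmcConfig(n_burnin=200, n_sample=400, thin=4, seed=0))
        assert res.draws.n_draws == 100
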