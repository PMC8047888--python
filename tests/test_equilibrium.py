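import numpy as np
import pytest

import removalopt as ro
from conftest import make_posterior


def _draw(network, **kw):
    base = dict(alpha=1.0, lam=0.0, beta=np.zeros(5), beta6=-0.26, gamma=0.5,
                sigma_rho=0.5, sigma_omega=0.2, sigma_e=0.3, sigma_1=1.0,
                rho=np.zeros(network.n_units),
                omega=np.zeros(8), mu=np.zeros((network.n_units, 9)))
    base.update(kw)
    return ro.ParameterDraw(**base)


class TestEquilibriumLogDensity:
    def test_fixed_point_equals_intercept(self, path3):
        alloc = ro.Allocation.from_effort(np.zeros(3))
        mu_star = ro.equilibrium_log_density(_draw(path3), path3, alloc)
        assert np.allclose(mu_star, 1.0)

    def test_one_over_one_minus_lambda_scaling(self, path3):
        # linear predictor 1, lambda = 0.5 -> mu* = 2
        alloc = ro.Allocation.from_effort(np.zeros(3))
        mu_star = ro.equilibrium_log_density(_draw(path3, lam=0.5), path3, alloc)
        assert np.allclose(mu_star, 2.0)

    def test_matches_50_step_iteration(self, path3):
        """mu* equals the noise-free recursion iterated from 0 on random draws."""
        rng = np.random.default_rng(8)
        for _ in range(10):
            draw = _draw(
                path3, alpha=rng.normal(1, 0.5), lam=rng.uniform(-0.8, 0.8),
                beta=rng.normal(0, 0.2, 5), beta6=rng.normal(-0.3, 0.1),
                rho=rng.normal(0, 0.5, 3),
            )
            effort = rng.uniform(0, 500, 3)
            alloc = ro.Allocation.from_effort(effort)
            h = path3.covariates @ draw.beta
            mu = np.zeros(3)
            for _ in range(50):
                mu = (draw.alpha + draw.lam * mu + h
                      + draw.beta6 * effort / 100.0 + draw.rho)
            assert np.allclose(
                ro.equilibrium_log_density(draw, path3, alloc), mu, atol=1e-6)

    def test_explosive_lambda_rejected(self, path3):
        alloc = ro.Allocation.from_effort(np.zeros(3))
        with pytest.raises(ValueError, match="lambda"):
            ro.equilibrium_log_density(_draw(path3, lam=1.0), path3, alloc)


class TestObjectiveU:
    def test_printed_scale_single_unit_draw(self, path3):
        # mu* = 0 in every unit -> K = 100 per unit on the per-100-trap-day
        # reporting scale, and mean relative density U/(100 I) = exp(0) = 1
        s = make_posterior(path3, n_draws=1, alpha=0.0, lam=0.0)
        res = ro.objective_U(s, path3, ro.Allocation.from_effort(np.zeros(3)))
        assert res.U == pytest.approx(300.0)
        assert res.mean_relative_density == pytest.approx(1.0)

    def test_monotone_decreasing_in_effort(self, path3):
        s = make_posterior(path3, n_draws=20, jitter=0.05, seed=1)
        e = np.array([100.0, 200.0, 300.0])
        U0 = ro.objective_U(s, path3, ro.Allocation.from_effort(e)).U
        e2 = e + np.array([50.0, 0.0, 0.0])
        U1 = ro.objective_U(s, path3, ro.Allocation.from_effort(e2)).U
        assert U1 < U0

    def test_invalid_lambda_draws_counted(self, path3):
        s = make_posterior(path3, n_draws=5)
        s.lam[2] = 1.3
        res = ro.objective_U(s, path3, ro.Allocation.from_effort(np.zeros(3)))
        assert res.invalid_draw_count == 1

    def test_all_draws_invalid_errors(self, path3):
        s = make_posterior(path3, n_draws=2)
        s.lam[:] = 1.5
        with pytest.raises(ValueError):
            ro.objective_U(s, path3, ro.Allocation.from_effort(np.zeros(3)))

    def test_zero_effort_gives_carrying_capacity(self, path3):
        s = make_posterior(path3, n_draws=10, jitter=0.1, seed=3)
        res = ro.objective_U(s, path3, ro.Allocation.from_effort(np.zeros(3)),
                             keep_per_draw=True)
        valid = np.abs(s.lam) < 1
        K = [
            100.0 * np.exp(ro.equilibrium_log_density(
                s.draw(n), path3, ro.Allocation.from_effort(np.zeros(3)))).sum()
            for n in np.where(valid)[0]
        ]
        assert res.U == pytest.approx(np.mean(K))

    def test_midpoint_convexity(self, path3):
        s = make_posterior(path3, n_draws=15, jitter=0.1, seed=7)
        rng = np.random.default_rng(11)
        for _ in range(20):
            a = rng.uniform(0, 400, 3)
            b = rng.uniform(0, 400, 3)
            Ua = ro.objective_U(s, path3, ro.Allocation.from_effort(a)).U
            Ub = ro.objective_U(s, path3, ro.Allocation.from_effort(b)).U
            Um = ro.objective_U(s, path3, ro.Allocation.from_effort((a + b) / 2)).U
            assert Um <= (Ua + Ub) / 2 + 1e-9

    def test_permutation_invariance(self):
        net = ro.generate_river_network(8, 0.2, seed=2)
        s = make_posterior(net, n_draws=12, jitter=0.1, seed=5,
                           rho=np.linspace(-0.4, 0.4, 8))
        e = np.linspace(0, 700, 8)
        U = ro.objective_U(s, net, ro.Allocation.from_effort(e)).U
        perm = np.random.default_rng(0).permutation(8)
        net_p = ro.RiverNetwork(
            unit_ids=tuple(net.unit_ids[i] for i in perm),
            covariates=net.covariates[perm],
            edges=tuple((int(np.where(perm == a)[0][0]), int(np.where(perm == b)[0][0]))
                        for a, b in net.edges),
        )
        s_p = make_posterior(net_p, n_draws=12, jitter=0.0)
        for name in ("alpha", "lam", "beta6", "sigma_omega", "sigma_e"):
            setattr(s_p, name, getattr(s, name).copy())
        s_p.beta = s.beta.copy()
        s_p.rho = s.rho[:, perm].copy()
        U_p = ro.objective_U(s_p, net_p, ro.Allocation.from_effort(e[perm])).U
        assert U_p == pytest.approx(U, rel=1e-12)


class TestAllocation:
    def test_sum_constraint_enforced(self):
        with pytest.raises(ValueError, match="sums to"):
            ro.Allocation(effort=np.array([1.0, 2.0]), total=4.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ro.Allocation(effort=np.array([-1.0, 5.0]), total=4.0)

    def test_uniform_and_scaled(self):
        a = ro.Allocation.uniform(4, 100.0)
        assert np.allclose(a.effort, 25.0)
        b = a.scaled(3.0)
        assert b.total == 300.0 and np.allclose(b.effort, 75.0)


class TestTargetComparison:
    @pytest.mark.parametrize("density,target,expect", [
        (0.027, 0.03, True),    # below target
        (0.03, 0.03, False),    # boundary: strict inequality
        (0.044, 0.03, False),   # above target
    ])
    def test_strict_threshold(self, density, target, expect):
        res = ro.ObjectiveResult(U=density * 100, mean_relative_density=density,
                                 invalid_draw_count=0)
        ok, margin = ro.mean_cpue_vs_target(res, target)
        assert ok is expect
        assert margin == pytest.approx(target - density)

    def test_invalid_target(self):
        res = ro.ObjectiveResult(U=1.0, mean_relative_density=0.01,
                                 invalid_draw_count=0)
        with pytest.raises(ValueError):
            ro.mean_cpue_vs_target(res, 0.0)
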