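"""SMC-ABC machinery: ESS identities, tolerance adaptation, resampling,
the r-hit kernel's exactness and full-run behaviour on tractable targets."""

import numpy as np
import pytest
from scipy import stats

from morphabc.smc import (
    DegeneratePopulationError,
    Prior,
    SMCConfig,
    adapt_epsilon,
    ess,
    resample_systematic,
    rhit_move,
    run_smcabc,
)


class TestESS:
    def test_uniform_weights(self):
        assert ess(np.full(64, 1 / 64)) == pytest.approx(64.0)

    def test_one_hot(self):
        w = np.zeros(10)
        w[3] = 1.0
        assert ess(w) == pytest.approx(1.0)

    def test_half_half(self):
        assert ess([0.5, 0.5, 0.0, 0.0]) == pytest.approx(2.0)

    def test_scale_invariance(self):
        w = np.array([0.1, 0.4, 0.5])
        assert ess(w) == pytest.approx(ess(10 * w))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            ess(np.zeros(5))


def _ess_at(d, w, eps):
    wi = w * (d < eps)
    s = wi.sum()
    return 0.0 if s <= 0 else s * s / np.sum(wi * wi)


class TestAdaptEpsilon:
    def test_two_particle_example(self):
        # distances (1,3), uniform weights: the only ESS jump below 2 is at
        # the distance value 1, so the bisection converges there
        eps = adapt_epsilon([1.0, 3.0], [0.5, 0.5], alpha=0.4, eps_prev=np.inf)
        assert eps == pytest.approx(1.0, abs=1e-6)
        assert _ess_at(np.array([1.0, 3.0]), np.array([0.5, 0.5]), eps + 1e-9) == 1.0

    def test_matches_grid_search_oracle(self, rng):
        for _ in range(25):
            n = rng.integers(5, 60)
            d = rng.exponential(1.0, n)
            w = rng.random(n)
            w /= w.sum()
            alpha = rng.uniform(0.2, 0.9)
            target = alpha * ess(w)
            eps = adapt_epsilon(d, w, alpha, np.inf)
            # oracle: the smallest distance value at which the step-function
            # ESS curve reaches the target level
            cands = np.sort(d)
            d_star = next(
                c for c in cands if _ess_at(d, w, c * (1 + 1e-12)) >= target
            )
            assert eps == pytest.approx(d_star, rel=1e-5, abs=1e-8)

    def test_monotone_contract(self, rng):
        d = rng.exponential(1.0, 40)
        w = np.full(40, 1 / 40)
        eps1 = adapt_epsilon(d, w, 0.6, np.inf)
        w2 = w * (d < eps1)
        w2 /= w2.sum()
        eps2 = adapt_epsilon(d, w2, 0.6, eps1)
        assert eps2 <= eps1

    def test_degenerate_population(self):
        # the only finite-distance particle has zero weight
        with pytest.raises(DegeneratePopulationError):
            adapt_epsilon([1.0, 2.0], [0.0, 0.0], 0.5, np.inf)


class TestResampling:
    def test_uniform_weights_keep_everyone(self, rng):
        idx = resample_systematic(np.full(32, 1 / 32), rng)
        assert sorted(idx) == list(range(32))

    def test_one_hot_duplicates_winner(self, rng):
        w = np.zeros(16)
        w[5] = 1.0
        idx = resample_systematic(w, rng)
        assert np.all(idx == 5)

    def test_mean_preserved_in_expectation(self, rng):
        theta = rng.standard_normal(50)
        w = rng.random(50)
        w /= w.sum()
        means = [
            theta[resample_systematic(w, rng)].mean() for _ in range(1000)
        ]
        target = float(theta @ w)
        se = np.std(means) / np.sqrt(len(means))
        assert abs(np.mean(means) - target) < 3 * se + 1e-12


def _gaussian_toy(obs_mean, m=20):
    def simulate(theta, m_prime, seed):
        r = np.random.default_rng(seed)
        return r.normal(theta[0], 1.0, m_prime)[:, None]

    def distance(q):
        return abs(np.asarray(q)[:, 0].mean() - obs_mean)

    return simulate, distance


class TestRhitMove:
    def test_out_of_support_rejected_without_simulating(self, rng):
        prior = Prior.from_bounds({"x": (0.0, 1.0)})
        calls = []

        def simulate(theta, m, seed):
            calls.append(theta)
            return np.zeros((m, 1))

        theta, q, d, n_sims, acc = rhit_move(
            np.array([0.999]),
            np.zeros((5, 1)),
            0.1,
            eps=0.5,
            prior=prior,
            chol=np.array([[50.0]]),
            simulate=simulate,
            distance_fn=lambda q: 0.0,
            rng=np.random.default_rng(0),
            m_prime=5,
        )
        assert not acc and n_sims == 0 and not calls
        assert theta[0] == pytest.approx(0.999)

    def test_prior_is_stationary_at_infinite_tolerance(self):
        # 2000 chains started from the prior, 5 moves each: if the prior is
        # invariant the pooled end states are still uniform
        prior = Prior.from_bounds({"x": (0.0, 1.0)})
        simulate, distance = _gaussian_toy(0.0, m=3)
        rng = np.random.default_rng(42)
        chol = np.array([[0.3]])
        out = []
        for _ in range(2000):
            th = prior.sample(rng, 1)[0]
            q = simulate(th, 3, int(rng.integers(2**32)))
            d = distance(q)
            for _ in range(5):
                th, q, d, _, _ = rhit_move(
                    th, q, d, np.inf, prior, chol, simulate, distance, rng, 3
                )
            out.append(th[0])
        p = stats.kstest(out, "uniform").pvalue
        assert p > 0.01

    def test_kernel_leaves_abc_target_invariant(self):
        """Apply the kernel repeatedly to exact ABC-posterior samples; the
        distribution must not drift (two-sample KS)."""
        obs_mean = 1.0
        m, eps = 20, 0.35
        prior = Prior.from_bounds({"mu": (-2.0, 4.0)})
        simulate, distance = _gaussian_toy(obs_mean, m)

        def rejection(n, seed):
            r = np.random.default_rng(seed)
            keep = []
            while len(keep) < n:
                th = prior.sample(r, 1)[0]
                q = simulate(th, m, int(r.integers(2**32)))
                d = distance(q)
                if d < eps:
                    keep.append((th, q, d))
            return keep

        state = rejection(1500, seed=1)
        ref = np.array([t[0][0] for t in rejection(1500, seed=2)])
        rng = np.random.default_rng(3)
        chol = np.array([[0.5]])
        for _ in range(30):
            state = [
                rhit_move(th, q, d, eps, prior, chol, simulate, distance, rng, m)[:3]
                for th, q, d in state
            ]
        moved = np.array([s[0][0] for s in state])
        res = stats.ks_2samp(moved, ref)
        assert res.pvalue > 0.01
        # hit datasets stay below the tolerance
        assert max(s[2] for s in state) < eps

    def test_accepted_datasets_are_hits(self):
        prior = Prior.from_bounds({"mu": (-2.0, 4.0)})
        simulate, distance = _gaussian_toy(1.0, 20)
        rng = np.random.default_rng(9)
        th = np.array([1.0])
        q = simulate(th, 20, 1)
        d = distance(q)
        for _ in range(200):
            th, q, d, _, acc = rhit_move(
                th, q, d, 0.4, prior, np.array([[0.3]]), simulate, distance, rng, 20
            )
            assert d < 0.4


class TestRunSMCABC:
    def test_budget_equal_init_returns_prior_sample(self):
        prior = Prior.from_bounds({"x": (2.0, 5.0)})
        simulate, distance = _gaussian_toy(3.0, 10)
        cfg = SMCConfig(n_particles=512, m_prime=10, sim_budget=512 * 10, seed=4)
        ens, trace = run_smcabc(None, simulate, prior, cfg, distance_fn=distance)
        assert len(trace.records) == 1
        u = (ens.thetas[:, 0] - 2.0) / 3.0
        assert stats.kstest(u, "uniform").pvalue > 0.01
        assert np.allclose(ens.weights, 1 / 512)

    def test_gaussian_toy_matches_conjugate_posterior(self):
        """Stopping at the distance's replicate noise floor, the ABC
        posterior mean matches the analytic N(xbar, sigma^2/n) mean and the
        sd is close up to the tolerance-induced smearing."""
        rng = np.random.default_rng(5)
        y = rng.normal(1.0, 1.0, 100)[:, None]
        simulate, _ = _gaussian_toy(0.0, 100)
        from morphabc.distances import wasserstein_distance

        distance = lambda q: wasserstein_distance(y, q)  # noqa: E731
        xbar = float(y.mean())
        fr = np.random.default_rng(99)
        floor = float(
            np.median(
                [
                    wasserstein_distance(
                        simulate([xbar], 100, int(fr.integers(2**32))),
                        simulate([xbar], 100, int(fr.integers(2**32))),
                    )
                    for _ in range(60)
                ]
            )
        )
        prior = Prior.from_bounds({"mu": (-2.0, 4.0)})
        cfg = SMCConfig(
            n_particles=128,
            alpha=0.6,
            m_prime=100,
            sim_budget=3_000_000,
            epsilon_target=floor,
            seed=1,
        )
        ens, trace = run_smcabc(y, simulate, prior, cfg, distance_fn=distance)
        w = ens.weights / ens.weights.sum()
        mean = float(ens.thetas[:, 0] @ w)
        sd = float(np.sqrt((ens.thetas[:, 0] ** 2) @ w - mean**2))
        n_ess = ess(w)
        assert abs(mean - xbar) < 3 * sd / np.sqrt(n_ess)
        assert abs(sd - 0.1) < 0.35 * 0.1

    def test_epsilon_monotone_weights_normalised_deterministic(self):
        prior = Prior.from_bounds({"mu": (-2.0, 4.0)})
        simulate, distance = _gaussian_toy(1.0, 20)
        cfg = SMCConfig(n_particles=64, m_prime=20, sim_budget=60_000, seed=7)
        ens1, tr1 = run_smcabc(None, simulate, prior, cfg, distance_fn=distance)
        ens2, tr2 = run_smcabc(None, simulate, prior, cfg, distance_fn=distance)
        eps = tr1.epsilons[1:]
        assert np.all(np.diff(eps) <= 1e-12)
        assert ens1.weights.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_array_equal(ens1.thetas, ens2.thetas)
        np.testing.assert_array_equal(ens1.weights, ens2.weights)
        assert [r["epsilon"] for r in tr1.records] == [
            r["epsilon"] for r in tr2.records
        ]

    def test_budget_overshoot_bounded_by_one_iteration(self):
        prior = Prior.from_bounds({"mu": (-2.0, 4.0)})
        simulate, distance = _gaussian_toy(1.0, 20)
        cfg = SMCConfig(n_particles=64, m_prime=20, sim_budget=50_000, seed=8)
        _, tr = run_smcabc(None, simulate, prior, cfg, distance_fn=distance)
        used = tr.records[-1]["neurons_used"]
        prev = tr.records[-2]["neurons_used"] if len(tr.records) > 1 else 0
        assert prev < cfg.sim_budget  # last iteration started within budget

    def test_epsilon_target_stops_early(self):
        prior = Prior.from_bounds({"mu": (-2.0, 4.0)})
        simulate, distance = _gaussian_toy(1.0, 20)
        cfg = SMCConfig(
            n_particles=64,
            m_prime=20,
            sim_budget=10**9,
            epsilon_target=0.3,
            max_iterations=60,
            seed=9,
        )
        _, tr = run_smcabc(None, simulate, prior, cfg, distance_fn=distance)
        assert tr.epsilons[-1] <= 0.3 or len(tr.records) - 1 == 60


class TestPriorAndConfig:
    def test_prior_bounds_validation(self):
        with pytest.raises(ValueError):
            Prior.from_bounds({"a": (1.0, 1.0)})

    def test_prior_support(self):
        p = Prior.from_bounds({"a": (0, 1), "b": (-1, 1)})
        assert p.in_support([0.5, 0.0])
        assert not p.in_support([1.5, 0.0])

    @pytest.mark.parametrize(
        "kwargs", [{"n_particles": 1}, {"alpha": 1.0}, {"m_prime": 0}]
    )
    def test_config_validation(self, kwargs):
        with pytest.raises(ValueError):
            SMCConfig(**kwargs)
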