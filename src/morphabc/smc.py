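"""Adaptive SMC-ABC with an ESS-controlled tolerance schedule.

Del Moral-style sequential Monte Carlo over a sequence of ABC targets
``pi_eps(theta) \\propto prior(theta) P(d(y_obs, y_sim) < eps | theta)``
with ``eps_0 = inf > eps_1 > ... `` chosen adaptively so that each
iteration retains a fraction ``alpha`` of the previous effective sample
size.  Particles are rejuvenated with a 2-hit MCMC race kernel: a Gaussian
proposal competes against the current parameter by simulating datasets in
alternating rounds until one side accumulates two sub-threshold datasets.

The simulator contract is ``simulate(theta, m, seed) -> (m, d_qoi) array``;
the distance contract is ``distance_fn(qois) -> float`` against a fixed
observed dataset (see :func:`morphabc.distances.make_distance`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "Prior",
    "SMCConfig",
    "ParticleEnsemble",
    "SMCTrace",
    "DegeneratePopulationError",
    "ess",
    "adapt_epsilon",
    "resample_systematic",
    "rhit_move",
    "run_smcabc",
]


#: multiplier on the weighted empirical covariance used for the
#: Gaussian move proposal (standard adaptive choice)
PROPOSAL_COV_SCALE = 2.0


class DegeneratePopulationError(RuntimeError):
    """No positive tolerance keeps any particle weight alive."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class Prior:
    """Uniform box prior over the parameter domain Omega."""

    names: tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray

    @classmethod
    def from_bounds(cls, bounds: dict[str, tuple[float, float]]) -> "Prior":
        names = tuple(bounds)
        lo = np.array([bounds[k][0] for k in names], float)
        hi = np.array([bounds[k][1] for k in names], float)
        if np.any(lo >= hi):
            raise ValueError("each lower bound must be below its upper bound")
        return cls(names=names, lower=lo, upper=hi)

    @property
    def dim(self) -> int:
        return self.lower.size

    def sample(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        return rng.uniform(self.lower, self.upper, size=(n, self.dim))

    def in_support(self, theta) -> bool:
        theta = np.asarray(theta, float)
        return bool(np.all(theta >= self.lower) and np.all(theta <= self.upper))


@dataclass
class SMCConfig:
    n_particles: int = 256
    alpha: float = 0.6
    m_prime: int = 25
    sim_budget: int = 500_000  # total neuron simulations
    r_hits: int = 2
    epsilon_target: float | None = None
    resample_threshold: float = 0.5
    move_sim_cap: int = 10_000  # datasets per move; stuck-particle guard
    max_iterations: int = 1_000
    seed: int = 0

    def __post_init__(self):
        if self.n_particles < 2:
            raise ValueError("need at least 2 particles")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.m_prime < 1:
            raise ValueError("m_prime must be >= 1")


@dataclass
class ParticleEnsemble:
    """Weighted particles approximating the ABC posterior."""

    thetas: np.ndarray  # (N, dim)
    weights: np.ndarray  # (N,), sums to 1
    distances: np.ndarray  # (N,)
    qois: list  # per-particle latest simulated dataset (m_prime rows)
    names: tuple[str, ...] = ()

    def to_frame(self):
        import pandas as pd

        names = self.names or tuple(f"theta_{i}" for i in range(self.thetas.shape[1]))
        df = pd.DataFrame(self.thetas, columns=list(names))
        df["weight"] = self.weights
        df["distance"] = self.distances
        return df


@dataclass
class SMCTrace:
    records: list[dict] = field(default_factory=list)

    def append(self, **kwargs) -> None:
        self.records.append(kwargs)

    @property
    def epsilons(self) -> np.ndarray:
        return np.array([r["epsilon"] for r in self.records])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.records)


def ess(weights) -> float:
    """Effective sample size ``(sum w)^2 / sum w^2``."""
    w = np.asarray(weights, float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    s = w.sum()
    if s <= 0:
        raise ValueError("weights must not be all zero")
    return float(s * s / np.sum(w * w))


def adapt_epsilon(distances, weights, alpha: float, eps_prev: float) -> float:
    """Largest ``eps <= eps_prev`` with ``ESS(w * 1[d < eps]) = alpha*ESS(w)``.

    Solved by bisection to a relative tolerance of 1e-8; the ESS curve is a
    non-decreasing step function of eps, so the bisection brackets the jump
    where the target level is crossed.
    """
    d = np.asarray(distances, float)
    w = np.asarray(weights, float)
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")

    def ess_at(eps):
        wi = w * (d < eps)
        s = wi.sum()
        return 0.0 if s <= 0 else float(s * s / np.sum(wi * wi))

    hi = float(min(eps_prev, d.max() * (1.0 + 1e-12) + 1e-300))
    if ess_at(hi) <= 0.0:
        raise DegeneratePopulationError("no positive tolerance retains any weight")
    target = alpha * ess(w)
    if ess_at(hi) <= target:
        return hi
    lo = 0.0
    tol = 1e-8 * (hi if not math.isfinite(eps_prev) else eps_prev)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if ess_at(mid) > target:
            hi = mid
        else:
            lo = mid
    return hi


def resample_systematic(weights, rng: np.random.Generator) -> np.ndarray:
    """Systematic resampling; returns the selected ancestor indices."""
    w = np.asarray(weights, float)
    w = w / w.sum()
    n = w.size
    positions = (rng.random() + np.arange(n)) / n
    return np.searchsorted(np.cumsum(w), positions).clip(0, n - 1)


def _cutoff_evaluator(distance_fn: Callable) -> Callable:
    """Use the distance's tolerance-cutoff shortcut when it offers one."""
    import inspect

    try:
        params = inspect.signature(distance_fn).parameters
        has_cutoff = "cutoff" in params
    except (TypeError, ValueError):
        has_cutoff = False
    if has_cutoff:
        return lambda q, eps: float(distance_fn(q, cutoff=eps))
    return lambda q, eps: float(distance_fn(q))


def rhit_move(
    theta,
    qois,
    distance,
    eps: float,
    prior: Prior,
    chol: np.ndarray,
    simulate: Callable,
    distance_fn: Callable,
    rng: np.random.Generator,
    m_prime: int,
    r_hits: int = 2,
    sim_cap: int = 10_000,
    credit_current: bool = True,
):
    """One r-hit move; returns (theta', qois', d', n_datasets, accepted).

    Exact r-hit Metropolis kernel based on inverse-binomial trial counts:
    datasets are simulated for the current parameter until ``r_hits - 1``
    of them fall below the tolerance (N trials) and for the proposal until
    ``r_hits`` do (N' trials); the proposal is accepted with probability
    ``min(1, N / (N' - 1))``.  For a uniform prior and symmetric proposal
    this satisfies detailed balance with respect to the ABC posterior
    ``pi_eps(theta) \\propto prior(theta) P(d < eps | theta)`` — the
    expected acceptance ratio equals the hit-probability ratio exactly.
    With ``r_hits = 1`` it reduces to the classic one-dataset indicator
    kernel.  At ``eps = inf`` every draw hits and every in-support proposal
    is accepted, so the chain random-walks over the prior.

    The race is terminated early as soon as the accept/reject decision is
    determined (``u * (N' - 1) > N`` cannot revert), and a total of
    ``sim_cap`` simulated datasets aborts the move as a rejection
    (stuck-particle guard).  Proposals outside the prior support are
    rejected without simulating.
    """
    theta = np.asarray(theta, float)
    prop = theta + chol @ rng.standard_normal(theta.size)
    if not prior.in_support(prop):
        return theta, qois, distance, 0, False
    eval_dist = _cutoff_evaluator(distance_fn)
    n_sims = 0
    # current parameter simulates until r-1 hits; with ``credit_current``
    # its stored dataset (a hit at the current tolerance by construction)
    # counts as the first, i.e. N = 1 and no stage-1 simulation is needed
    # for r = 2.  Both choices are exactly balanced; the credit variant
    # trades acceptance rate for a much lower simulation cost per move.
    hits_c = 1 if (credit_current and distance < eps) else 0
    best_c = None
    n_c = hits_c
    while hits_c < r_hits - 1:
        if n_sims >= sim_cap:
            return theta, qois, distance, n_sims, False
        qc = simulate(theta, m_prime, int(rng.integers(2**32)))
        n_c += 1
        n_sims += 1
        dc = eval_dist(qc, eps)
        if dc < eps:
            hits_c += 1
            best_c = (qc, dc)
    # proposal simulates until r hits; accept iff u <= N / (N' - 1)
    u = rng.random()
    hits_p = 0
    best_p = None
    n_p = 0
    while n_sims < sim_cap:
        # once u*(N'-1) surely exceeds N the move is a rejection
        if u * n_p > n_c:
            break
        qp = simulate(prop, m_prime, int(rng.integers(2**32)))
        n_p += 1
        n_sims += 1
        dp = eval_dist(qp, eps)
        if dp < eps:
            hits_p += 1
            best_p = (qp, dp)
            if hits_p >= r_hits:
                if u * (n_p - 1) <= n_c:
                    return prop, best_p[0], best_p[1], n_sims, True
                break
    if best_c is not None:
        return theta, best_c[0], best_c[1], n_sims, False
    return theta, qois, distance, n_sims, False


def run_smcabc(
    y_obs_qois,
    simulator: Callable,
    prior: Prior,
    config: SMCConfig,
    distance_fn: Callable | None = None,
    callback: Callable | None = None,
) -> tuple[ParticleEnsemble, SMCTrace]:
    """Approximate the posterior p(theta | y_obs) with adaptive SMC-ABC.

    Starts from an iid prior sample (eps_0 = inf) and iterates
    {adapt eps; reweight; resample if ESS < threshold*N; 2-hit move every
    particle} until the simulation budget is exhausted (the running
    iteration is finished) or ``epsilon_target`` is reached.
    """
    if distance_fn is None:
        from .distances import make_distance

        distance_fn = make_distance("wasserstein", y_obs_qois)
    n = config.n_particles
    root = np.random.SeedSequence(config.seed)
    init_ss, *_ = root.spawn(1)
    rng = np.random.default_rng(init_ss)

    thetas = prior.sample(rng, n)
    qois = []
    dists = np.empty(n)
    for i in range(n):
        q = simulator(thetas[i], config.m_prime, int(rng.integers(2**32)))
        qois.append(q)
        dists[i] = float(distance_fn(q))
    weights = np.full(n, 1.0 / n)
    neurons_used = n * config.m_prime
    eps = math.inf
    trace = SMCTrace()
    trace.append(
        iteration=0,
        epsilon=math.inf,
        ess=float(n),
        acceptance_rate=float("nan"),
        neurons_used=neurons_used,
        resampled=False,
    )

    iteration = 0
    while (
        neurons_used < config.sim_budget
        and iteration < config.max_iterations
        and (config.epsilon_target is None or eps > config.epsilon_target)
    ):
        iteration += 1
        try:
            eps = adapt_epsilon(dists, weights, config.alpha, eps)
        except DegeneratePopulationError as exc:
            exc.trace = trace
            raise
        weights = weights * (dists < eps)
        total = weights.sum()
        if total <= 0:
            raise DegeneratePopulationError(
                "all particle weights vanished after reweighting", trace
            )
        weights = weights / total
        current_ess = ess(weights)
        resampled = current_ess < config.resample_threshold * n
        if resampled:
            it_ss = root.spawn(1)[0]
            idx = resample_systematic(weights, np.random.default_rng(it_ss))
            thetas = thetas[idx]
            dists = dists[idx]
            qois = [qois[i] for i in idx]
            weights = np.full(n, 1.0 / n)

        cov = PROPOSAL_COV_SCALE * np.cov(thetas.T, aweights=np.maximum(weights, 1e-300), ddof=0)
        cov = np.atleast_2d(cov) + 1e-12 * np.eye(prior.dim)
        chol = np.linalg.cholesky(cov)

        accepted = 0
        move_sims = 0
        particle_seeds = root.spawn(n)
        for i in range(n):
            if weights[i] <= 0:
                continue
            prng = np.random.default_rng(particle_seeds[i])
            theta_i, q_i, d_i, n_sims, acc = rhit_move(
                thetas[i],
                qois[i],
                dists[i],
                eps,
                prior,
                chol,
                simulator,
                distance_fn,
                prng,
                config.m_prime,
                r_hits=config.r_hits,
                sim_cap=config.move_sim_cap,
            )
            thetas[i] = theta_i
            qois[i] = q_i
            dists[i] = d_i
            accepted += int(acc)
            move_sims += n_sims
        neurons_used += move_sims * config.m_prime
        trace.append(
            iteration=iteration,
            epsilon=float(eps),
            ess=float(current_ess),
            acceptance_rate=accepted / n,
            neurons_used=neurons_used,
            resampled=bool(resampled),
        )
        if callback is not None:
            callback(trace.records[-1])

    ensemble = ParticleEnsemble(
        thetas=thetas,
        weights=weights,
        distances=dists,
        qois=qois,
        names=prior.names,
    )
    return ensemble, trace
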