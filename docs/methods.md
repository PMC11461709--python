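# Methods

This note documents the models, estimators and numerical choices behind
`morphabc`, and what the shipped tests do and do not demonstrate.

## Resource-driven growth models

A neuron is a rooted tree of cylindrical agents attached to a stationary
spherical soma (radius 7.5 length units).  Time advances in discrete steps
(`dt = 1`); every rate parameter is expressed per step.  Only tip agents
act, and only while their scalar resource `r` exceeds the threshold
`r_min`; once `r ≤ r_min` a tip is idle forever (resources never
increase).

Per step, an active tip:

1. **Elongates** along `d = w_rand·u + w_old·o + w_grad·ĝ` (normalised),
   where `u` is a uniformly random unit vector, `o` the tip's current
   orientation and `ĝ` the normalised gradient of the guidance cue — a
   persistent, biased random walk.  The tip cylinder's endpoint moves by
   `v·d` and the resource drops by `R`.  A cylinder whose chord exceeds
   `l_max` is split into two collinear halves; the distal half is the new
   tip and carries the resource.  Splitting never changes section lengths,
   so the morphometrics are invariant to `l_max`.
2. **Branches** with probability `p_bra`.
   *Model 1 (bifurcation, basal dendrites):* two daughter tips deflected
   by ±`theta_bifurcate` (default 30°) within a random plane through the
   mother's orientation; both inherit the mother's resource.
   *Model 2 (side-branching, apical dendrites):* a continuation daughter
   keeps orientation and resource; a side daughter is deflected by
   `theta_side` (default 60°) at a random azimuth and starts from the
   fixed budget `r_0`.
3. **Model 2 only:** after all tips acted, every agent whose resource
   still exceeds `r_min` decays by `R` (so its floor is `r_min − R`).
   An active Model-2 tip therefore loses `2R` per step (elongation plus
   decay).  Whether the global decay uses the same constant as elongation
   consumption is an assumption; we use the same `R`.

Default parameters are the synthetic-study operating point of Model 2:
`p_bra = 0.38e-1` per step, `R = 0.71e-3` resource units per event,
`v = 1e2` length units per step, `r_min = 0`, `r_init = 1`, `n_steps =
500`.  Direction weights default to `w_rand = 0.4, w_old = 0.5, w_grad =
0.1` with a time-invariant linear guidance field `phi(x) = z`.

**Choice of `r_0` (side-branch budget).**  A side branch born with budget
`r_0` stays active for `(r_0 − r_min)/(2R)` steps, during which it may
itself branch; its expected number of offspring is `rho = p_bra (r_0 −
r_min)/(2R)`.  For the morphology the side-branching model is meant to
produce — one extended main branch with shorter outgrowths — the
side-branch population must be subcritical (`rho < 1`).  We fix
`r_0 = 0.01`, giving `rho ≈ 0.27` at the default operating point
(side-branch lifetime ≈ 7 steps).  Larger budgets (e.g. `r_0 = 0.05`,
`rho ≈ 1.3`) turn the model into an explosively bushy tree with
heavy-tailed segment counts, qualitatively unlike the intended regime.

**Initial configuration.**  Soma at the origin; Model 2 starts from one
apical stub (+z, length 10, anchored at the soma centre following the SWC
convention that the first neurite point's parent is the soma record);
Model 1 from two basal stubs tilted 45° below the xy-plane.  `r_init = 1`
per stub.

**Guards.**  Supercritical corners of parameter space (low `R`, high
`p_bra`) grow exponentially; simulations are truncated at 512 concurrent
tips / 4096 sections (lean kernel) or 200 000 agents (tree simulator).
The caps never bind within many standard deviations of the default
operating point — they only affect parameter corners whose morphologies
are orders of magnitude away from any calibration data and are rejected
by the distance anyway.

**Two implementations, one model.**  `morphabc.growth` is the reference
object-level simulator (full agent tree, SWC export).  `morphabc._fast`
is a numba-compiled kernel that tracks only per-tip state and per-section
lengths — sufficient because internal agents never influence the dynamics
and the four QoIs are functions of section lengths alone.  The two paths
consume different random streams, so they agree in distribution, not
per-seed; `tests/test_simulator_consistency.py` checks the agreement of
all four QoI means at z < 4 on thousands of neurons.  Likelihood-free
calibration uses the lean kernel (~50 µs per neuron at the default
operating point vs ~13 ms for the tree).

## Morphometrics

A *segment* is a maximal unbranched section between topological nodes
(soma attachment, branch point, tip); its length is the sum of its
cylinder lengths.  The QoI vector is (segment count, mean segment length,
standard deviation of segment lengths, total dendritic length); the
standard deviation uses the population convention (`ddof = 0`, switchable).
The soma is excluded; apical (SWC type 4) and basal (type 3) subtrees can
be analysed separately.  Defining segments at section level (rather than
per discretisation cylinder) makes the QoIs invariant to `l_max`
splitting — data and simulation must use the same convention, and do.

## Statistical distances

QoI matrices are compared as point clouds in R^4 after per-column
standardisation with the *observed* data's mean and standard deviation
(switchable; balances counts against lengths).

* **Wasserstein (default):** exact order-2 distance between uniform
  empirical measures.  Equal cardinalities: Hungarian assignment on
  squared Euclidean costs.  Commensurable cardinalities (the calibration
  case, 500 vs 25): the smaller cloud's columns are replicated to a square
  problem — by Birkhoff's theorem an optimal transport plan exists at an
  assignment, so this is exact.  General cardinalities: transportation LP
  (HiGHS).  Inside the ABC accept/reject loop a lower bound
  (`‖Δmean‖ ≤ W2`) short-circuits the assignment solve when a dataset
  already misses the tolerance; the decision is unchanged and accepted
  distances are always exact.
* **Sliced Wasserstein:** root-mean of squared 1-D distances over 50
  seeded random directions; 1-D distances by quantile-function
  integration (exact for unequal sizes).
* **KL divergence:** 1-nearest-neighbour estimator
  `(d/n) Σ log(s_i/r_i) + log(m/(n−1))`; ties guarded by a 1e-12 radius
  floor; negative small-sample estimates pass through unchanged.
* **γ-divergence:** γ-cross-entropy terms with 1-NN density plug-ins;
  analytically reduces to the KL estimator as γ → 0 and down-weights
  low-density outliers for larger γ (default γ = 0.5).

## SMC-ABC

Del Moral-style adaptive SMC over ABC targets
`pi_eps(θ) ∝ prior(θ)·P(d(y_obs, y_sim) < eps | θ)` with a uniform box
prior.  Each iteration: choose the next tolerance by bisection so the
reweighted ESS equals `alpha = 0.6` of the current ESS; reweight by the
indicator; systematically resample when ESS < 0.5 N; move every particle
with an MCMC kernel whose proposal covariance is twice the weighted
empirical covariance.  The run stops when the simulation budget is
exhausted (the running iteration finishes) or an optional tolerance
target is reached.

**The 2-hit move kernel.**  We use an inverse-binomial r-hit kernel:
datasets are simulated for the proposal until `r = 2` of them fall below
the tolerance (`N'` trials) and the current parameter's stored dataset —
a hit at the current tolerance by construction — counts as its
`(r−1)`-th hit (`N = 1`), giving acceptance `min(1, N/(N'−1))`.  The
expected acceptance probability equals the proposal's hit probability
exactly (`E[min(1, 1/(N'−1))] = p` for `N' ~ 2 + NegBin(2, p)`), so the
kernel satisfies detailed balance for the ABC posterior; the race is
aborted as soon as `u·(N'−1) > N` makes rejection certain.  Simpler
symmetric "first to two hits" races are *not* invariant — their
acceptance odds scale like the squared hit-probability ratio, which
visibly over-concentrates the posterior — and are not used.  Invariance
is verified two ways in the tests: at `eps = ∞` the sampler reproduces
the prior, and on a tractable Gaussian toy 50 kernel sweeps leave an
exact rejection-ABC sample distributionally unchanged (two-sample KS).
A per-move cap (default 10⁴ datasets) guards against stuck particles;
a capped move counts as a rejection and the cap is recorded in the run
configuration.

**What a finite tolerance means.**  The ABC posterior at tolerance `eps`
is a smeared version of the Bayes posterior.  On the Gaussian location
toy (n = 100 observations, M' = 100 simulated points, exact Wasserstein),
a brute-force rejection-ABC oracle shows the posterior sd exceeds
`σ/√n` by 10–26 % at every tolerance down to the distance's sampling
noise floor, and *under*-shoots it when the tolerance is pushed toward
the attainable minimum (the Wasserstein-ABC tendency to concentrate on
the minimum-distance estimator).  The sampler is therefore validated
exactly against same-tolerance rejection ABC; against the conjugate
closed form the mean matches to Monte-Carlo error and the sd to the
tolerance-induced smearing.  For this reason the toy runs stop at a
pre-registered tolerance: the median Wasserstein distance between
replicate datasets simulated at the fitted mean (the resolution limit of
the distance at the given M').

## Scaled-down calibration study

The shipped desk profile calibrates Model 2's `(p_bra, R, v)` from 500
synthetic neurons generated at the default operating point, with N = 256
particles, M' = 25 simulations per proposal, `alpha = 0.6` and a budget
of 5·10⁵ neuron simulations, at a reduced horizon of `n_steps = 200`
(the package's desk-scale choice; the full profile in the CLI uses
N = 1024, M' = 50, budget 5·10⁷).  The prior box is `p_bra ∈ [0.01,
0.10]`, `R ∈ [2·10⁻⁴, 1.4·10⁻³]`, `v ∈ [50, 150]`.  Under these
conditions the Wasserstein calibration concentrates the posterior modes
near the data-generating values (a typical run: ≈ 2 % error on `p_bra`,
≈ 1 % on `v`, ≈ 14 % on `R`) in about 4–5 minutes on one core.  The `R`
marginal is the widest (± ≈ 20 % at this budget): at a 5·10⁵-simulation
budget the tolerance only reaches ≈ 0.8–1.0 (standardised units, against
a replicate noise floor near 0.75), and independent replicates can still
miss `R` by more than 15 %.  Sharper `R` recovery requires a larger
budget, consistent with the full-scale profile.

## Sobol sensitivity analysis

Saltelli cross-sampling (`K = n_base·(2d+2)` rows; base matrices from a
scrambled Sobol' sequence), Saltelli-2010 estimator for first-order
indices and Jansen's estimator for total effects, 95 % CIs by
bootstrapping the base-sample index.  The outer bootstrap deliberately
ignores the inner Monte-Carlo error of the expected-QoI estimate
(`m_replicates` stochastic simulations per parameter point).  Zero
output variance yields zero indices with an explicit flag.  Estimator
correctness is checked against additive functions and the Ishigami
function's analytic variance decomposition.

## Posterior summaries and checks

Marginals are weighted Gaussian KDEs with Silverman bandwidth computed on
the effective sample size; a degenerate (single-point) sample falls back
to a scale-aware bandwidth.  The MAP is per-coordinate (the mode of each
marginal KDE on a 512-point grid, ties broken toward the smaller value) —
a joint mode is not attempted; run outputs record this convention.
Predictive checks draw parameters from the weighted ensemble, simulate
M' neurons each and compare QoI marginals (mean, sd, quantiles, pooled
cloud).  Neuron pairing normalises QoIs by the data marginals' standard
deviation and assigns each data neuron its Euclidean-nearest simulated
neuron (with replacement).  The Anderson–Darling normality check uses the
estimated-parameter null with interpolated p-values (clipped by the
tables to [0.01, 0.15]); decisions default to the 1 % level.

## What the synthetic data do and do not show

All tests run on data generated by the package's own simulators; they
demonstrate internal consistency (the inverse machinery recovers the
parameters of the forward model that generated the data) and estimator
correctness against analytic oracles.  They do not show that Models 1/2
describe real dendritic morphologies: real reconstructions carry features
these rules do not produce (straight apical trunks that split, tortuosity
structure, diameter taper), and calibration to real SWC data (supported
via `GrowthCalibration.from_swc_dir`) measures only the four QoIs used
here.

## Reproducibility

Every stochastic component takes an integer seed; child seeds derive from
`numpy.random.SeedSequence`.  A calibration run is bit-reproducible for a
fixed seed in single-process execution (particle moves use per-particle
spawned seeds, so results do not depend on move order).  The numba kernel
uses its own seeded generator, so tree- and fast-path outputs match in
distribution, not per seed.
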