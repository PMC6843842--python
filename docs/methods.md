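# Methods

## Model

Individuals j = 1..n_i nested in areas i = 1..N; binary outcome
y_ij ~ Bernoulli(p_ij) with logit(p_ij) = λ_ij. The four nested variants of
λ_ij (M1–M4, see README) add, in order: dummy-coded individual covariates
Xβ, area-level covariates Wγ (constant within area), and the spatially
structured effect u. Every variant keeps the exchangeable area effect
v_i ~ N(0, σ_v²); u follows the intrinsic CAR prior whose full conditional
for u_i is Normal(neighbour mean, σ_u²/w_i+). Jointly this is the improper
Gaussian kernel exp(−u'Qu/(2σ_u²)) with Q = diag(w_i+) − A (A the 0/1
adjacency); Q is singular with one null (constant) vector per connected
component, so the generalized density uses rank(Q) = N − (#components) in
its normalizer — this rank matters for the σ_u² update and is easy to get
wrong.

Priors: α, β, γ ~ N(0, 10000) (variance scale); the log-precisions of both
variance components have logGamma(shape=1, rate=0.0005) priors,
equivalently Gamma(1, 0.0005) on the precisions in the rate convention.
`ModelSpec(prior_logprec_rate=1.0)` switches to the logGamma(1, 1)
sensitivity prior; a `gamma_scale` flag flips to shape/scale if ever
needed, but rate is the default convention here.

### Identifiability

The intrinsic CAR is flat along each component's constant vector. Two
separate conventions are used:

* the generative sampler (`sample_car`) draws with covariance σ_u²·Q⁺ —
  sum-to-zero within each component by construction;
* the MCMC keeps u unconstrained and, once per sweep, transfers the global
  mean of u to the intercept (u ← u − m, α ← α + m). This moves the state
  along the posterior's only flat direction, so it leaves the posterior
  invariant, and it leaves λ and u'Qu unchanged exactly. Per-component
  means are *not* re-centred: with more than one component they are
  identified by the likelihood (they act as component-level intercepts),
  and folding several of them into a single scalar α would change the
  model. On connected graphs — every default here — the two readings
  coincide.

Islands (areas with no neighbours) have an undefined CAR conditional;
`car_conditional` raises, and `sample_car` sets island effects to 0 (the
usual convention; a `component` policy flag keeps the choice explicit).

## MCMC sampler

Metropolis-within-Gibbs, in one sweep:

1. **Fixed-effect block** (α, β, γ jointly): adaptive random-walk
   Metropolis with a Haario-type empirical-covariance proposal; the global
   step size targets ≈0.23 acceptance by Robbins–Monro during burn-in and
   is frozen afterwards.
2. **CAR field u**: the graph is greedily coloured; each colour class is an
   independent set, so all its areas can be proposed and accepted/rejected
   simultaneously with exact conditional prior terms (neighbours never move
   together). Per-area scales adapt to ≈0.44 acceptance. Per-area
   likelihood changes are aggregated with `bincount` over the row→area
   index.
3. **Unstructured effects v**: same blocked Metropolis, all areas at once
   (their prior is iid).
4. **Exact reallocation of u vs v**: the likelihood only sees
   t_i = u_i + v_i, so conditionally on t, u is Gaussian with precision
   Q/σ_u² + I/σ_v² (proper — the iid term fills the null space) and mean
   solve(·, t/σ_v²). Sampling this full conditional directly (dense
   Cholesky, N ≤ a few hundred) mixes the structured/unstructured split
   orders of magnitude better than the random-walk moves alone; without
   it, σ_v² can stick near zero for thousands of iterations (the familiar
   convolution-model "variance trap").
5. **Variance components**: conjugate Gibbs. τ_v ~ Gamma(shape + N/2,
   rate + Σv²/2); τ_u ~ Gamma(shape + rank(Q)/2, rate + u'Qu/2).
6. **Non-centred scale moves**: a random walk on t = log σ rescales the
   whole effect vector with its standardized form held fixed (interweaving
   step); in (w, t) coordinates the prior reduces to −2·shape·t −
   rate·e^(−2t), plus, for u on multi-component graphs, a Jacobian term
   (#components − 1)·t for the prior-flat relative component means.
7. **Involutive mode swap**: the u-vs-v allocation posterior can be
   genuinely bimodal under these vague precision priors (an
   "all-structured" and an "all-unstructured" explanation of the same
   field). The move proposes u′ = v − mean(v), v′ = u + mean(v) with the
   two variances exchanged: λ is untouched, the map is an involution with
   unit Jacobian, and acceptance is the prior ratio. This lets chains
   traverse both modes.

Defaults: 4 chains × 10,000 iterations, 5,000 burn-in, thin 5 — all
overridable; a seed is mandatory, and chains draw from
`SeedSequence(seed).spawn(...)` streams, so runs are bit-reproducible.
Diagnostics: split-chain Gelman–Rubin R̂ for the intercept, every fixed
effect and the (log) variance components, with a warning above 1.05;
acceptance-rate warnings outside [0.1, 0.6].

The sampler was cross-checked during development against an independent
MCMC implementation of the same posterior on small simulated datasets
(all four parameter types' marginals agreeing within Monte-Carlo error);
the shipped suite enforces correctness through the CAR linear-algebra
oracles, exact-conditional tests, maximum-likelihood concordance of M2
with near-flat priors, and simulate-and-refit coverage.

## Model comparison

DIC = D̄ + p_D with deviance D(θ) = −2·log-likelihood and p_D = D̄ − D(θ̂),
where θ̂ is the componentwise posterior mean of *all* parameters, random
effects included — i.e. conditional DIC, which is what the plug-in formula
implies when the deviance conditions on u and v. Slightly negative p_D
(a known DIC pathology) warns rather than fails. SF is computed from the
raw variance parameters exactly as σ_u²/(σ_u²+σ_v²) — not from the
empirical marginal variance of the CAR field, which differs because σ_u²
is a conditional variance; the per-draw ratio is averaged over the
posterior. SF is reported only for variants containing u.

## Walkability metrics

Areas are sets of 100 m × 100 m urbanized grid cells in a planar metre
coordinate frame (no geodesy — inputs are assumed projected).
`mean_grid_distance` averages, over cell centres, the Euclidean distance
to the nearest destination of a class anywhere in the landscape (a KD-tree
query); restricting search to the home area is deliberately not the
default, since the nearest facility may be across a boundary. Densities
are counts per km² of urbanized land. Land-use mix is the three-category
entropy index −Σ p_k ln p_k / ln 3 over domestic/commercial/business
floor-area shares — 0 for single-use, 1 for a perfectly even mix; the
bounded entropy form is used rather than any raw floor-area ratio, since
only the entropy reading is dimensionless and lies in [0, 1].
Tertiles cut at the 33.3rd/66.7th linear-interpolation percentiles over
areas (one observation per area; population-weighted cuts available);
values tied exactly with a cut fall to the lower tertile. These
conventions are fixed and documented because label assignments at ties
are otherwise ambiguous.

## Screening stage

Descriptive tables give counts and column percents by outcome group.
Univariate logistic screening fits outcome ~ one categorical covariate by
Newton-type maximum likelihood (via statsmodels) separately within the six
gender × age strata; a covariate is selected when the joint Wald test over
its non-reference levels has p below the threshold. The threshold defaults
to 0.05 as an explicit, configurable analysis assumption. Levels with
complete separation are excluded from the Wald test and flagged rather
than crashing the fit.

## Synthetic data generator

`simulate_cohort` runs the model forward: rook-lattice adjacency nearest
to square (realistic neighbour counts ≈ 4, always connected; arbitrary
edge lists accepted), per-area sizes negative-binomial around the mean
(district populations vary widely; dispersion 5 by default), u from the
constrained CAR, v iid normal, categorical covariates from declared level
probabilities, and Bernoulli outcomes. Defaults emulate the targeted study
setting: 546 areas, ~143 individuals per area, baseline log-odds −1.1
(≈25% prevalence). All stages draw from split substreams of one master
seed. `simulate_landscape` produces square per-area cell blocks, Poisson
destination/intersection point processes and Dirichlet floor-area
mixtures; default intensities are set so distances span hundreds of metres
to kilometres and LUM spans (0, 1), the ranges seen in district-level
walkability tables.

What the generator does **not** emulate: survey weights and multistage
sampling, real administrative geographies (adjacency is a lattice unless
an edge list is supplied), item nonresponse, covariate correlation
structure, or measurement error in self-reported height/weight. Passing
recovery tests therefore demonstrates correctness of the estimation
machinery under the model's own assumptions, not robustness to those
real-data features.

## Validation study sizes and numerical choices

The simulate-and-refit study uses 20 replicates of 100 areas × ~80
individuals with truth α = −1.1, β = (+0.4, −0.4), γ = 0.3, σ_u² = 0.5,
σ_v² = 0.1, fit with a single chain of 10,000 iterations (4,000 burn-in,
thin 6) — sizes chosen so the full study runs in minutes on one CPU while
keeping Monte-Carlo error well below the effects being recovered. Fixed
effects are recovered with near-nominal credible-interval coverage. The
variance components are a different matter: the likelihood identifies only
u_i + v_i, so the σ_u²/σ_v² split is weakly identified and its posterior
is prior-sensitive and often bimodal; under the vague Gamma(1, 0.0005)
precision priors the posterior tends to attribute most of the total
area-level variance to whichever component dominates, and interval
coverage for the individual variance parameters falls below nominal even
with a converged sampler. This is a documented property of convolution
models with vague variance priors, not a sampler defect (the posterior was
matched against an independent implementation); the spatial *fraction*
remains directionally informative, which is what the SF recovery check
asserts.

Other numerical choices: logit-scale clipping at ±35 only when converting
to probabilities (the likelihood itself uses `logaddexp` and is stable to
|λ| ≈ 700); CAR draws via per-component eigendecomposition with
eigenvalues below 1e-10 of the largest treated as null; equal-tailed
percentile credible intervals; effects flagged "significant" when the 95%
CrI excludes an odds ratio of 1 (an explicit convention — the criterion is
stated, not inherited).

## Known limitations

* Conditional (not marginalized) DIC; WAIC/LOO are out of scope.
* Proper CAR (with an autocorrelation parameter) and distance-weighted
  adjacency are not implemented.
* The dense Cholesky in the reallocation step is O(N³) per sweep; fine to
  a few hundred areas, would want a sparse factorization beyond that.
* No survey weighting; continuous-BMI outcomes are out of scope.
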