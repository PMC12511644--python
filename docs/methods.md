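# Methods

## Model

Choices follow random utility maximization: `U_nti = V_nti + ε_nti` with
iid type-I extreme-value errors, giving MNL task probabilities
`P_nti = exp(V_nti)/Σ_j exp(V_ntj)` over the *available* alternatives (the
availability mask lets designs omit unrealistic attribute combinations).
Panels multiply task probabilities within person. Random tastes vary across
persons only (no inter-/intra-respondent split); the mixing integral is
simulated with R draws per person and the panel product is averaged over
draws — `P_n = (1/R) Σ_r Π_t P_ntj*(β_r)` — not the product of per-task
averages, because tastes are fixed within a person's panel.

### Mixing families

| tag | natural parameters | draw transform | support |
|---|---|---|---|
| fixed | value | value | point |
| normal | μ, σ | μ + σ·d_N | ℝ |
| uniform | a, b | a + b·d_U | [a, a+b] |
| triangular | a, b | a + b(d_U1 + d_U2) | [a, a+2b] |
| lognormal | μ, σ | s·exp(μ + σ·d_N) | sign(s)·(0,∞) |
| loguniform | a, b | s·exp(a + b·d_U) | sign(s)·[e^a, e^(a+b)] |
| asym. triangular | a, b, c | two-piece inverse CDF | [a, b], mode (a+b)/2 + c |
| fm2 / fm3 | μ, σ_1..σ_P | μ + Σ_p σ_p·u^p | data-dependent |

Notes on deliberate choices:

* **Triangular** is implemented literally as `a + b(d_U1 + d_U2)`; the sum of
  two uniforms makes a symmetric triangle on `[a, a+2b]` with mode `a+b`.
  Users who think of `b` as a half-range should pass half the desired range.
* **Asymmetric triangular** draws one of the two linear pieces with
  probability proportional to its triangle area — `(m−a)/(b−a)` for the
  piece below the mode `m` — and inverts the piece CDF:
  `β_lower = a + (m−a)·√d_U1`, `β_upper = b − (b−m)·√d_U2`. The square root
  is required for the result to be a proper triangular density; a linear
  map would produce a mixture of two uniforms. At `c = 0` this collapses
  exactly to the symmetric triangular on the same support (a property the
  test suite checks by Kolmogorov–Smirnov distance). When differentiating,
  the piece indicator is held fixed, a subgradient that is exact wherever
  no draw sits on the piece boundary.
* **Polynomial expansions (FM)** use powers of a *single* uniform per
  person-draw on top of the mean: `β = μ + Σ_{p=1..P} σ_p u^p`, with the
  σ_p unconstrained in sign. The family is identified only up to the
  reflection `u → 1−u`, which maps `(μ, σ1, σ2) → (μ+σ1+σ2, −σ1−2σ2, σ2)`
  for P = 2 without changing the distribution; recovery checks accept
  either labeling. Non-monotone polynomials fold, producing density spikes
  at the fold points — this is what lets FM3 approximate bimodal tastes.
* **Sign convention**: the log families take a fixed sign `s ∈ {+1, −1}`
  (default −1, the usual choice for price, risk or harm attributes). The
  sign is configuration, not an estimated parameter, avoiding label
  switching.

### Draws

Modified Latin hypercube sampling: per (person, dimension), an equidistant
grid `(i + shift)/R` with one U(0,1) shift, randomly permuted, so the R
values stratify (0,1) exactly. Normal primitives are inverse-CDF transforms
of the uniform primitives. Substreams are keyed by (master seed, person
index, dimension index), so a person's draws are invariant to the sample
size — estimates are reproducible under subsetting. Default R = 500; the
revealed-preference model defaults are fit with R = 100 in the examples
(the two-equation likelihood is flatter, and fewer draws stabilized
estimation in practice).

## Estimation

Maximum simulated likelihood with analytic scores. Scale parameters (σ, the
range b, the asymmetric triangular's span) are optimized as logs with a
floor of 1e-8 representing an exact-zero boundary; the asymmetric
triangular's mode is a logistic fraction of its support when the offset c
is estimated (fixed to zero by default, which drops one parameter per
coefficient). Log-family exponents are capped at ±100 so a wandering line
search cannot overflow. Optimization is L-BFGS-B warm-started at
plain-logit (all-fixed) estimates, means seeded from the logit coefficients
and scales at modest positive values; a stalled line search triggers one
automatic restart from the incumbent. Fits are deterministic given (spec,
data, R, seed, start).

Standard errors come from the central finite-difference Hessian of the
analytic score, inverted on the sub-space of parameters away from their
bounds, and mapped to the natural scale by the delta method (block-diagonal
Jacobian). Scale parameters that collapse below 0.01 leave flat likelihood
directions; they are flagged as boundary solutions and their standard
errors reported as unavailable rather than spuriously large. Confidence
intervals are normal-theory 95% throughout.

In **WTP space**, `V = β_price·(price + Σ_k w_k x_k + ASCs)`. The gradient
treats the product structure exactly (`∂V/∂w_k = β_price·x_k`,
`∂V/∂β_price = bracket`). Note the sign convention this parameterization
implies: `w_k = β_k/β_price`, so with a negative price coefficient a
*valued* attribute has a *negative* money-metric coefficient; negate for
the conventional `−β_k/β_price` reading.

The **revealed-preference model** is two binary logits sharing
`ρ_n ~ N(0, σ_ρ²)` (+ρ in both equations, or −ρ in the second to test
negative association). The person likelihood is the draw-average of
`P_cig^c (1−P_cig)^(1−c) P_ecig^e (1−P_ecig)^(1−e)` — each Bernoulli factor
paired with its complement, as a probability requires. σ_ρ ≥ 0 by the log
parameterization; with the positive-association device, data whose sample
odds ratio is below 1 drive σ_ρ to its zero boundary and the model reduces
to two independent logits, whose score equations force enumerated use
shares to equal observed shares exactly.

## Model averaging

Sequential latent-class averaging: constituents enter through their frozen
person-level likelihood columns P_nk only. Weights use the logistic form
with θ_1 ≡ 0 for identification (the form is otherwise over-parameterized)
and |θ| capped at 30, so degenerate single-model averages are representable
without overflow and reported as boundary solutions. The mixture
log-likelihood is concave in π, so any interior stationary point found
through the softmax is the global optimum; optimization starts at equal
weights and additionally from the best constituent's vertex, and never
reports an average below its best constituent. The conservative information
criterion counts every constituent parameter plus the K−1 weights — an
upper bound on model complexity, chosen deliberately over counting only the
weights. Preset groups: base (S,U,T), extended (+LN,LU), all (+AT,FM2,FM3).
No automatic group selection is attempted; corrected two-stage standard
errors for the weights are out of scope.

## Post-estimation

* **Sample enumeration** averages predicted probabilities over persons,
  tasks and draws (re-generating the estimation draws from the stored seed),
  aggregated by user-supplied alternative groups; an average's enumeration
  is the π-weighted mix of constituent enumerations.
* **Unconditionals** are fresh pseudo-random draws from the fitted mixing
  distributions (population level, not conditioned on individual choices);
  mixture sampling for averages.
* **Densities** use a Gaussian KDE with Silverman bandwidth on a grid padded
  5% beyond the sample range (or a user grid); degenerate samples are
  reported as point masses. Mode detection takes local maxima above 5% of
  the peak.
* **WTP means** are the analytic means of the fitted mixing distributions
  with delta-method intervals; simulation-based intervals can be formed by
  sampling unconditionals instead.

## Synthetic data

The generators produce data with exactly the statistical structure the
estimators assume — their purpose is validation, not realism.

* **Drug-choice DCE**: 1,000 persons × 10 tasks by default, four
  alternatives (two branded, two unbranded) described by country of
  production, drug characteristic (standard / fast acting / double
  strength, dummy-coded), side-effect risk and price. Attribute levels are
  drawn independently and uniformly from fixed grids (risk
  {0.1, 0.2, 0.5, 1.0} in 10-point units, price {2,…,6}); choices compare
  one U(0,1) draw per task against cumulative MNL probabilities, so
  generated frequencies converge to the analytic mixed-logit shares. The
  frozen default tastes deliberately mix families: bimodal branded taste
  (½N(−2,0.5²) + ½N(+2,0.5²)), normal country taste, uniform and triangular
  characteristic tastes, strictly negative lognormal risk taste, fixed
  price taste −0.8. These values are documented choices recorded in the
  truth file, picked once to give realistic mid-range choice shares and
  clearly non-normal heterogeneity.
* **Generic DCE**: arbitrary alternatives, level grids and taste config
  (any mixing family or a finite normal mixture), optional all-zero opt-out.
* **Correlated binaries**: per person ρ ~ N(0, σ_ρ²) and Bernoulli outcomes
  at logistic(V ± ρ); a helper inverts the marginal shares for intercepts,
  and `rp_composition_dataset` reproduces an exact 2×2 use composition
  (defaults: 1,038 / 148 / 619 / 226).

What the generators do *not* emulate: optimized (D-efficient) experimental
designs, attention/data-quality artifacts, deterministic (covariate-linked)
heterogeneity, correlated tastes across attributes, and scale
heterogeneity. Passing recovery tests therefore show the estimators are
correct and well-calibrated under their own assumptions — not that those
assumptions hold in any particular field dataset.

## Validation studies and problem sizes

The test suite runs fixed-seed replicate studies sized for a single CPU:
per-family parameter recovery at 300 persons × 10 tasks × R = 100 with 10
replicates per family (normal, uniform, lognormal, loguniform, FM2),
requiring each generating parameter inside ±3 reported standard errors in
at least 9/10 replicates; weight recovery for averaging at 1,000 persons
(skewed lognormal truth vs. an all-normal rival); and multimodal-density
recovery at 300 persons, where the average over {S, FM2, FM3} must beat the
all-normal model's L1 distance to the bimodal truth in ≥8/10 replicates.
`scripts/acceptance.py` re-runs the same studies from a user seed. The
one-coefficient quadrature cross-check compares the simulated probability
at R = 100,000 MLHS draws to 201-node Gauss–Hermite quadrature (observed
agreement ~1e-5, tolerance 1e-3).

## Numerical details and edge cases

Person likelihoods are floored at 1e-300 before logging; softmax and
Bernoulli logs use max-subtraction / softplus forms; padded (absent) tasks
contribute exactly zero. Draw-average weights for the score are computed in
a numerically stable way from shifted exponentials. The degenerate-mixing
check (all-normal fit to homogeneous data) can legitimately exceed the
plain-logit log-likelihood by an O(1) amount — the boundary likelihood-ratio
statistic — so small positive gaps there are expected noise, not error.

## Known limitations

* AT estimation uses a subgradient in the mode parameter; on some data the
  model collapses to the symmetric triangular (flagged as a boundary
  solution), and hard datasets may fail to converge — failures are recorded
  per-model in the CLI rather than aborting a run.
* FM parameters are reported in one of two observationally equivalent
  labelings (see the reflection above).
* Simulated-likelihood bias at small R affects all families equally here;
  no analytic or bias-corrected alternative is provided.
* Model averaging inherits the space spanned by its constituents and its
  weight uncertainty is not propagated into post-estimation intervals.
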