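# Methods

## Model and priors

Each model is indexed by γ ∈ {0,1}^p. The linear predictor is
η = Zα + X_γ β_γ, with Z the n×q block of always-included covariates
(default: an intercept). Families:

* **logistic** — y_i ~ Bernoulli(logit⁻¹(η_i));
* **cox_pl** — Cox proportional hazards through the partial likelihood
  Π_i [e^{η_i} / Σ_{s∈R(t_i)} e^{η_s}]^{d_i}, R(t) = {s : t_s ≥ t}. Tied
  event times use the Breslow convention (tied events share a risk set);
  the input may contain ties even though the partial likelihood is usually
  written for distinct times;
* **weibull** — hazard λ_i k (λ_i t)^{k-1} with λ_i = exp(η_i); the shape k
  is carried on the log scale, has prior log k ~ N(0, σ_k²), and is
  *conditioned on* by every coefficient integral — it gets its own MCMC
  move. k = 1 recovers the exponential model exactly.

Coefficient prior: α ~ N(0, σ_α² I), β_γ|γ ~ N(0, g I). Model prior:
independent Bernoulli(h) inclusion, or the Beta-binomial integral
p(γ) = B(a+p_γ, b+p−p_γ)/B(a,b). Defaults used in the examples echo a
genetic-mapping configuration: g = 1, σ_α² = 1, Beta(1, (p−5)/5) (prior
mean of about five included covariates).

All engines work family-agnostically through the score ỹ = ∂ℓ/∂η and the
negated curvature W = −∂²ℓ/∂η² in η-space. W is a length-n vector for
logistic/Weibull and a dense n×n matrix for the partial likelihood (cost
O(n²) per evaluation; this is the known bottleneck of the Cox family).

## Marginal-likelihood engines

Let J_γ = [Z X_γ], V_γ = blockdiag(σ_α² I_q, g I_{p_γ}), d = q + p_γ.

* **Laplace (LA).** Newton iteration with step-halving (gradient max-norm
  tolerance 1e-8, at most 100 iterations) gives the mode θ̂ and
  H = JᵀWJ + V⁻¹; log p_LA = log p(y,θ̂|γ) − ½log|H| + (d/2)log 2π.
  Deterministic, so values and modes are memoised per model.
* **ALA.** The same expression expanded at an arbitrary θ⁰ picks up the
  correction +½ g⁰ᵀ(H⁰)⁻¹g⁰ from the non-zero gradient. At θ⁰ = θ̂ it
  coincides with LA to machine precision (this is asserted in the tests).
* **Adaptive ALA.** θ⁰ is the least-squares projection (normal equations,
  ridge 1e-8 on rank deficiency) of a running linear-predictor guess η̂
  onto the columns of J_γ, refined by exactly one Newton step. η̂ is the
  running mean of the MAP linear predictors J_γ θ̂_γ of the models the
  chain visits, so the guess improves as the chain settles; the MAP modes
  are already available from the acceptance-side engine's cache, so the
  update is free.
* **CPM.** p̂ = (1/N) Σ_i p(y|θ⁽ⁱ⁾)p(θ⁽ⁱ⁾|γ)/π_LA(θ⁽ⁱ⁾) with
  θ⁽ⁱ⁾ = θ̂ + L⁻ᵀu_i, computed by log-sum-exp. One shared standard-normal
  block u (N×dim_max) serves every model scored within an MH step — the
  two evidence estimates of a ratio are positively correlated, which
  stabilises the acceptance probability. Between steps the block follows
  the autoregression u′ = ρu + √(1−ρ²)ε. Defaults N = 32, ρ = 0.99 (ρ = 0
  recovers the independent pseudo-marginal sampler). Unbiasedness makes
  the chain target the exact posterior.
* **DA** (logistic). Pólya-gamma augmentation: conditional on
  ω_i ~ PG(1, η_i) the evidence is the exact Gaussian integral
  log p(y|γ,ω) = −n log 2 − ½log|V| − ½log|Λ| + ½ξᵀΛ⁻¹ξ, Λ = JᵀWJ + V⁻¹,
  ξ = Jᵀ(y−½), W = diag(ω). The additive constant is kept exact so the
  same function serves MH ratios and diagnostics. Each iteration performs
  the Gibbs sweep θ|γ,ω then ω|θ; the marginal chain on γ targets the
  exact posterior. PG(1, z) variates come from an exact Devroye-type
  alternating-series sampler (truncation point 0.64, inverse-Gaussian head
  and exponential tail proposals), numba-compiled; there is no truncation
  error. PG(b, 0) for integer b is a sum of b draws.

Indefinite Hessians are jittered once by 1e-8·trace/d on the diagonal; a
still-failing factorisation is surfaced rather than masked.

## Warm-start PIPs

At an anchor model γ⁽⁰⁾ (default: empty), the Rao-Blackwellised PIP of
every covariate needs the Bayes factor p(y|γ_j↑)/p(y|γ_j↓). Under ALA at
the origin both evidences are Gaussian integrals against
Λ = J₀ᵀWJ₀ + V⁻¹ extended or reduced by one row/column, so each factor
follows from the Schur complement:

* adding j:  BF = d↑^{-1/2} g^{-1/2} exp{ s_j²/(2 d↑) } with
  d↑ = X_jᵀWX_j + 1/g − b_jᵀΛ⁻¹b_j, b_j = J₀ᵀWX_j,
  s_j = X_jᵀỹ − b_jᵀΛ⁻¹J₀ᵀỹ;
* removing j: BF = d↓^{-1/2} g^{-1/2} exp{ d↓ m_j²/2 } with
  d↓ = 1/(Λ⁻¹)_{jj}, m_j = (Λ⁻¹J₀ᵀỹ)_j.

One d₀-dimensional factorisation plus O(p) rank-one work gives all p
Bayes factors; the PIPs are BF·r/(1+BF·r) with r the model-prior inclusion
odds, clipped to [ε, 1−ε]. The fixed covariates Z are included in the
anchor design throughout. A numerically non-positive Schur complement
clamps the PIP to the clipping band. These formulas are verified against
direct pairs of ALA evaluations to 1e-8 relative error in the tests.

## The PARNI proposal

Per iteration, with tuning A_j, D_j ∈ [ε, 1−ε]:

1. k_j ~ Bern(A_j) where γ_j = 0 and Bern(D_j) where γ_j = 1; the active
   positions get a fresh uniformly random order.
2. For r = 1..p_k the two-model neighbourhood {current, flip of j_r} is
   scored by the proposal-side engine; the flip weight is
   g_H(exp(Δscore + Δlog p(k|·)))·(ζ/(1−ζ)), the stay weight 1, and the
   pair is normalised exactly. This costs exactly 2 p_k proposal-side
   evaluations (the instrumentation asserts the count).
3. The reverse-path probability re-walks the identical pairs in reverse
   order — the pair at position j_r is the same two models in both
   directions — so no additional engine calls are needed.
4. MH correction with the acceptance-side engine (Hastings ratio including
   the p(k|γ) and path-probability terms). With CPM the same auxiliary
   block scores both models; with DA both conditionals share the current ω.

Adaptation (all diminishing):

* π̂_j = φ_L π̃_j⁽⁰⁾ + (1−φ_L) π̃_j⁽ᴸ⁾ blends the warm start with the
  ergodic inclusion average over *all* iterations; the weight
  φ_l = 1 − ½(N_b−l+1)^{-1/2} before the burn-in boundary and
  ½(l−N_b)^{-1/2} after it, so the warm start dominates early and the
  ergodic average takes over at rate l^{-1/2}.
* A_j = min(1, π̂_j/(1−π̂_j)), D_j = min(1, (1−π̂_j)/π̂_j), clipped to
  [ε, 1−ε] with ε = 0.001.
* ζ follows a Robbins–Monro recursion on the logit scale toward a 0.234
  acceptance target with step l^{-0.7} (a fixed-ζ mode is available).
* η̂ is the running mean of MAP linear predictors (skipped under DA,
  which has no mode; adaptive ALA then effectively starts at the origin).

Reported PIPs use post-burn-in samples only; the adaptation's ergodic
average deliberately uses the whole history.

The baseline ADS sampler picks uniformly among the feasible move types
(add, delete, swap), then uniformly within the type, and corrects the MH
ratio for the differing neighbourhood counts on the two sides.

## Hyper-parameter moves

* **Slab scale.** A half-Cauchy C+(0,1) prior is placed on the slab scale
  √g via the exact inverse-gamma mixture a ~ IG(1/2,1), g|a ~ IG(1/2,1/a);
  the Gibbs sweep is g|a,β ~ IG((p_γ+1)/2, βᵀβ/2 + 1/a), a|g ~ IG(1,1+1/g).
  The coefficient draw β comes from the Pólya-gamma conditional under DA
  and from the LA normal approximation otherwise. Engine caches are
  flushed when g moves.
* **Weibull shape.** Symmetric random walk on log k, acceptance from the
  engine's evidence ratio (the log k prior is already inside the evidence
  value, so nothing is double-counted), step size adapted toward 0.44
  acceptance with step l^{-0.7}.

## Synthetic data

The generator emulates sparse high-dimensional regression studies:
correlated Gaussian covariates (independent, AR(1) with corr(X_j, X_{j+h})
= ρ^h, or block-exchangeable), standardised columns, a sparse support with
alternating-sign effects, and responses from the model itself. Survival
times come from S(t) = exp(−(tλ)^k); censoring is exponential with the
rate calibrated by bisection to a target censored fraction. Defaults:
n = 500, p = 500, 10 effects of magnitude 2 spread evenly, AR(1) ρ = 0.6,
30% censoring, k = 1.5. The examples and the acceptance script use a
reduced n = 300, p = 300 version so a full chain runs in well under a
minute on one CPU.

What the generator does *not* emulate: discrete genotype coding, linkage
blocks with realistic decay, case-control ascertainment, heavy-tailed
measurement noise, or covariate missingness. Passing tests therefore show
algorithmic correctness (the chain targets the right distribution and the
estimators agree with their oracles), not robustness to real-data
pathologies.

## Numerical choices and limitations

* Logistic likelihoods use softplus/log1p forms; Cox risk-set sums use
  max-shifted exponentials; Weibull exponents are clipped at ±700 before
  exponentiation.
* Newton: tolerance 1e-8 (max-norm), 100 iterations, step-halving (40
  halvings max). Degenerate d = 0 models short-circuit to the bare
  log-likelihood.
* Enumeration is the oracle up to p = 15 (2^p engine calls); larger
  problems use a longer reference run as the gold standard.
* Single chain per run; replicates via seeds. All randomness flows through
  one numpy Generator per run, so a fixed seed reproduces the chain
  bit-for-bit.
* The LA/ALA chains target their approximate posteriors, not the exact
  one; only DA and CPM acceptance target p(γ|y) exactly. The proposal-side
  engine affects mixing only.
* Cox curvature is dense (O(n²) memory and time); for n beyond a few
  thousand the Weibull family is the practical choice, matching the known
  scaling limitation of partial-likelihood curvature.
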