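# parnibvs

Bayesian variable selection for **logistic regression**, **Cox proportional
hazards** (partial likelihood) and **Weibull survival** models, driven by an
adaptive, locally informed model-space MCMC sampler.

## The problem

Given n observations of a response (a binary outcome, or a right-censored
survival time) and p candidate covariates — with p possibly in the hundreds
or thousands, as in genetic-mapping studies — we want the posterior
distribution over the 2^p models indexed by the inclusion vector
γ ∈ {0,1}^p under a spike-and-slab prior

    α ~ N(0, σ_α² I_q),   β_γ | γ ~ N(0, g I_{p_γ}),
    p(γ) = h^{p_γ} (1-h)^{p-p_γ}   or its Beta-binomial integral,

and in particular the posterior inclusion probabilities (PIPs)
π_j = P(γ_j = 1 | y). The obstacle is the marginal likelihood
p(y|γ) = ∫ p(y|θ_γ, γ) p(θ_γ|γ) dθ_γ, which has no closed form for any of
these families.

## What the package provides

**Five marginal-likelihood engines** behind one interface:

| engine | idea | targets exact posterior? |
|---|---|---|
| `da`  | Pólya-gamma data augmentation (logistic only): conditional on latent ω, the evidence is a closed-form Gaussian integral | yes |
| `la`  | Laplace approximation at the posterior mode | no (LA posterior) |
| `cpm` | correlated pseudo-marginal: unbiased importance sampling under the LA proposal, auxiliaries shared across the models of an MH ratio | yes |
| `ala` | approximate Laplace approximation: one Taylor expansion at the origin, no optimisation | no (ALA posterior) |
| `adaptive_ala` | ALA initialised from a running average of MAP linear predictors plus one Newton step | proposal-side only |

**The PARNI sampler** (point-wise adaptive random-neighbourhood informed
proposal): each iteration draws a random flip-set k (k_j ~ Bern(A_j) off the
model, Bern(D_j) on it), then walks the flipped positions in random order,
flipping each with a locally informed probability built from the balancing
function g_H(x) = min(1, x) applied to posterior-score ratios, and corrects
with an exact Metropolis–Hastings step. The tuning vectors A, D are adapted
from a blend of a *warm-start* Rao-Blackwellised PIP estimate (computed for
all p covariates from one Schur-complement factorisation under ALA at the
origin) and the running ergodic PIP average. A plain add–delete–swap (ADS)
sampler is included as the baseline, together with hyper-parameter moves
(half-Cauchy slab scale via an inverse-gamma-mixture Gibbs step; adaptive
random walk on the Weibull shape).

## Worked example

```python
import numpy as np
from parnibvs import PriorSpec, run_parni, enumerate_posterior
from parnibvs.synthetic import SimConfig, simulate

data, truth = simulate(SimConfig(n=300, p=300, family="logistic", seed=11))
prior = PriorSpec(g=1.0, h=None, beta_binom=(1.0, (300 - 5) / 5))
out = run_parni(data, prior, n_iter=4000, burnin=1000,
                proposal_engine="adaptive_ala", acceptance_engine="cpm", seed=1)
sup = truth["support"]
print("acceptance rate:", round(out.acceptance_rate, 3))
print("true-covariate PIPs:", np.round(out.pip_estimate[sup], 3))
print("median null PIP:", round(float(np.median(
    np.delete(out.pip_estimate, sup))), 4))
```

prints

```
acceptance rate: 0.386
true-covariate PIPs: [1.    1.    1.    0.999 1.    1.    1.    1.    1.    1.   ]
median null PIP: 0.0068
```

All ten planted effects get PIP ≈ 1 while the 290 noise covariates stay
near zero — the sampler finds the true model in a 2^300 model space in a
few thousand iterations.

The same machinery is exposed on the command line:

```bash
parni simulate --family logistic --n 300 --p 300 --out sim
parni run --data sim.csv --family logistic --z-cols z0 \
      --proposal-engine adaptive_ala --acceptance-engine cpm \
      --iters 4000 --burnin 1000 --seed 1 --out results/
```

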