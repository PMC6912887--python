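# procjs

Bayesian estimation of **process correlations** between adult and juvenile
annual survival from capture–mark–recapture (CMR) data, with a focus on how
the choice of prior for the covariance matrix of random year effects drives
the answer.

## The problem

Demographic rates vary from year to year, and the correlation between those
fluctuations — e.g. between adult and juvenile survival of a goose colony —
speaks directly to life-history trade-offs, demographic buffering, and the
likely effect of management actions. Hierarchical capture–recapture models
estimate this *process* correlation by giving the logit-scale annual survival
probabilities a shared multivariate normal distribution:

    (logit φ_ad,t , logit φ_juv,t) ~ N(μ, Σ),   t = 1, …, T−1
    Σ = [[σ²_ad, σ_ad σ_juv ρ], [σ_ad σ_juv ρ, σ²_juv]]

embedded in an age-structured Cormack–Jolly–Seber (CJS) model: individuals
released as juveniles survive their first interval at the juvenile rate and as
adults thereafter, and live individuals are detected with probability p at
each sampling occasion. The latent alive/dead states are marginalized through
the m-array multinomial likelihood, so fitting cost is independent of the
number of marked individuals.

The covariance matrix needs a prior, and the conventional conjugate choice —
`Σ⁻¹ ~ Wishart(K+1, I)` — is far from innocent: it implies scaled
inverse-chi-square variance marginals that exclude small variances, and a
strong prior dependence between σ and |ρ|. Because temporal variances of
survival on the logit scale are typically small (σ² ≈ 0.1), this prior
attenuates the posterior of ρ toward zero and destroys credible-interval
coverage. The alternative implemented here is the *separated* strategy:
independent hyperpriors directly on the components, `σ_k ~ Uniform(0, 5)` and
`ρ ~ Uniform(−1, 1)`, from which Σ is assembled.

`procjs` provides:

* both covariance priors behind one model class, plus diagnostics that
  quantify each prior's implied marginals on σ, σ² and ρ;
* a seeded CMR simulator with correlated adult/juvenile year effects;
* age-structured m-array reduction and the marginalized CJS likelihood
  (numba-jitted, with a scipy-based reference path tested against it);
* adaptive MCMC (blocked sampler with interweaved non-centered updates;
  plain adaptive-Metropolis and Metropolis-within-Gibbs kinds as
  cross-checks) with rank-normalized split-R̂ and ESS diagnostics;
* a factorial simulation-study harness that scores bias and 95% CRI coverage
  of ρ across study lengths, release numbers and priors;
* a detection variant for real colony data in which second-year and adult
  detection probabilities vary by year (`logit p_k,t = β₀ + ε_k,t`).

## Worked example

```python
from procjs import (SimulationConfig, simulate_dataset, build_marrays,
                    AgeStructuredCJS, PriorSpec, SeparatedPriorConfig)

cfg = SimulationConfig(T=30, releases_per_occasion=1000, rho=0.6, seed=5)
histories, truth = simulate_dataset(cfg)          # 30,000 individuals
model = AgeStructuredCJS(build_marrays(histories),
                         PriorSpec(SeparatedPriorConfig()))
res = model.fit()                                 # 2 chains x 25,000 iters
print(res.summary().loc[["mu_ad", "mu_juv", "sigma2_ad", "sigma2_juv", "rho", "p"]].round(3))
```

prints (machine-generated output):

```
             mean     sd   q2.5    q50  q97.5   rhat       ess
mu_ad       1.020  0.065  0.891  1.020  1.147  1.000  3111.917
mu_juv     -0.984  0.068 -1.120 -0.985 -0.844  1.002  3175.210
sigma2_ad   0.124  0.040  0.067  0.117  0.222  1.000  2489.180
sigma2_juv  0.132  0.043  0.068  0.125  0.235  1.000  2817.409
rho         0.572  0.146  0.248  0.588  0.806  1.000  2491.953
p           0.498  0.003  0.492  0.498  0.504  1.000  3196.682
```

The posterior recovers the generating values (μ_ad = 1, μ_juv = −1,
σ² = 0.1, ρ = 0.6, p = 0.5); `res.rho_cri` gives the central 95% credible
interval for the process correlation. Swapping
`WishartPriorConfig()` for the separated config refits the same data under
the conjugate inverse Wishart prior — on short or sparse datasets its
posterior mean of ρ is visibly pulled toward zero.

The simulation study behind the package's headline numbers runs through
`run_cell` / `run_study`:

```python
from procjs import run_cell, abs_error_table, coverage_table
rows = run_cell(T=10, releases=100, prior="iw", V=100, seed=1)
```

Every function is also reachable from the command line:

```bash
procjs simulate --T 10 --releases 100 --rho random --seed 1 --out-prefix sim
procjs fit --marray-prefix sim_marray --prior separated --seed 1 --out-prefix fit
procjs prior-draws --parameterization iw --n 100000 --seed 1 --out iw.csv
procjs study --grid small --prior both --reps 100 --seed 1 --out-dir study/
```

Each run writes a JSON manifest recording seeds, config hashes and outputs.

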