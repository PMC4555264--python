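# mehgtk — population toxicokinetics of methylmercury

`mehgtk` estimates the **biological half-life of methylmercury in blood**
from paired measurements of blood methylmercury concentration and daily
dietary methylmercury intake, using a hierarchical Bayesian
one-compartment model. It is aimed at exposure scientists and risk
assessors who need population half-life (and hence elimination-constant)
estimates to convert biomarker levels into intake guidelines (RfD, PTWI),
and at statisticians who want a fully tested, reproducible reference
implementation of the model.

## The model

At steady state, intake and first-order elimination balance, so for
subject *i* with intake *d<sub>i</sub>* (µg/kg bw/day), weight
*w<sub>i</sub>* (kg) and half-life *t<sub>1/2,i</sub>* (days):

```
f(d_i) = d_i · t_{1/2,i} · Abs · frac_b · w_i / (ln2 · V_b)
log y_i = log f(d_i) + ε_i,   ε_i ~ N(0, σ²)
```

where *y<sub>i</sub>* is the blood concentration (µg/L), `Abs` the
gastrointestinal absorption fraction, `frac_b` the fraction of the body
burden in blood and `V_b` the blood volume (L). Individual half-lives are
drawn from a truncated-normal population distribution,

```
t_{1/2,i} ~ TN(µ, τ², 0, ∞)
```

with informative priors keeping the nuisance kinetics in their biological
range: `µ ~ TN(72, 10.8², 0, ∞)`, `τ ~ Unif(10, 40)`,
`Abs ~ Unif(0.9, 1)`, `frac_b ~ Unif(0, 0.1)`, `V_b ~ Unif(2.99, 4.34)`,
`σ ~ Unif(0, 100)`. Posterior inference uses a from-scratch
Metropolis-within-Gibbs sampler with vectorized subject updates; see
`docs/methods.md` for the update scheme, adaptation rules and numerical
choices.

The package also ships a dietary-exposure module (food diary × food
concentration table, with half-LOD substitution for non-detects), a
synthetic-cohort generator with known ground truth, convergence
diagnostics (autocorrelation, ESS, split R-hat) and a CLI.

## Worked example

```python
from dataclasses import replace
from mehgtk import (GeneratorConfig, MCMCConfig, generate_cohort,
                    run_mcmc, summarize, elimination_constant)

cohort, truths = generate_cohort(GeneratorConfig(seed=1))   # n=304 adults
fit = run_mcmc(cohort, MCMCConfig(seed=1))                  # 4 x 30,000 iters
print(summarize(fit).round(3))
print("k =", round(float(elimination_constant(summarize(fit).loc['mu', 'Mean'])), 4), "per day")
```

prints (about 10 s on one core):

```
             Mean     SD    2.5%     50%   97.5%
parameter
mu         79.162  8.469  63.446  78.881  96.045
tau        21.127  7.607  10.475  19.906  37.495
Abs         0.953  0.029   0.903   0.954   0.998
V_b         3.489  0.350   3.008   3.430   4.232
frac_b      0.087  0.009   0.066   0.089   0.099
sigma       1.478  0.069   1.344   1.477   1.618
k = 0.0088 per day
```

The cohort was generated with a true population mean half-life of
80.2 days: the posterior mean of `µ` (79.2 d, 95% CrI 63–96 d) recovers
it, `τ`'s credible interval still spans nearly its whole Unif(10, 40)
prior (single-recall intake data barely separate between-person
half-life variation from measurement noise), and `σ ≈ 1.5` tracks the
generating log-scale residual SD of 1.388. The implied elimination
constant is ln2/µ ≈ 0.009 per day.

The same pipeline runs from the shell:

```bash
mehgtk simulate --out run/ --seed 1
mehgtk fit run/cohort.csv --out run/fit --seed 1 --stratify-sex
```

which writes chain files, a posterior-summary table (one block per
stratum), trace/autocorrelation/density plots and a run manifest.

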