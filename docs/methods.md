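# Methods

## Model

The package treats the body as a single well-mixed compartment at steady
state: the daily absorbed dose `d · Abs · w` (µg/day) equals the daily
first-order elimination `k · B` of the body burden `B`, with
`k = ln2 / t_half`. Writing the blood concentration as the blood-borne
fraction of the burden divided by the blood volume,
`y = frac_b · B / V_b`, gives the steady-state relation

    y = d · t_half · Abs · frac_b · w / (ln2 · V_b).

The denominator is the **natural** logarithm of 2 — `log2` notation in
the toxicokinetic literature is sometimes ambiguous, but the first-order
elimination constant is `ln2 / t_half`, and this package commits to that
reading throughout (a 50-day half-life then corresponds to
k = 0.0139 ≈ 0.014 per day).

Measurement error is multiplicative and lognormal: the observed log
blood concentration is the log steady-state prediction plus
`N(0, σ²)` noise. `σ` is therefore the SD of a natural-log residual and
is dimensionless; it absorbs assay error, day-to-day intake variation
(a 24-h recall is a noisy proxy for habitual intake) and model error.
Values near 1.4 — the regime the default generator emulates — mean a
four-fold multiplicative scatter, i.e. single recalls are only weakly
correlated with blood levels.

Individual half-lives follow `TN(µ, τ², 0, ∞)`. Only the half-life is
individual-level; `Abs`, `frac_b`, `V_b` and `σ` are shared across the
cohort (one posterior row each), which is the identifiable choice given
one observation per subject.

### Priors

| parameter | prior | units | rationale |
|---|---|---|---|
| µ | TN(72, 10.8², 0, ∞) | days | literature-range centre for the population mean half-life |
| τ | Unif(10, 40) | days | plausible between-person SD |
| Abs | Unif(0.9, 1) | — | near-complete GI absorption of methylmercury |
| frac_b | Unif(0, 0.1) | — | small fraction of burden in blood |
| V_b | Unif(2.99, 4.34) | L | adult blood-volume range |
| σ | Unif(0, 100) | log-µg/L | non-informative |

All truncated-normal densities carry their normalizing constants
(`Φ(µ/τ)` terms). These depend on µ and τ, so the µ update cannot be
treated as exactly conjugate (below).

## Sampler

Metropolis-within-Gibbs, fixed update order per iteration:

1. **t_half (vector).** Gaussian random walk on the half-lives
   themselves, proposed and accepted element-wise in one vectorized
   operation; proposals ≤ 0 are rejected. The TN normalizer is constant
   in t and cancels.
2. **µ.** Independence proposal from the truncated-normal that would be
   the full conditional if the `Φ(µ/τ)⁻ⁿ` normalizing terms were absent
   (precision `1/10.8² + n/τ²`), followed by a Metropolis correction
   for exactly those terms. At the posteriors the package targets
   (µ/τ ≈ 3) the correction is mild and acceptance is ~90%.
3. **τ.** Scalar random walk on (10, 40), with the `Φ(µ/τ)⁻ⁿ` terms in
   the ratio.
4. **Abs, frac_b, V_b.** Scalar random walks inside their prior boxes.
   They enter the likelihood only through
   `C = log(Abs · frac_b / (ln2 · V_b))`, so the acceptance ratio is
   computed O(1) from the cached residual sums `Σr` and `Σr²`.
5. **σ.** Random walk on log σ with the Jacobian correction for the
   uniform-on-σ prior; also O(1) via `Σr²`.
6. **Group ("interweaving") moves.** In the centered parameterization
   above, µ and τ move only as the latent half-life vector slowly
   drifts, which leaves τ with an effective sample size of ~80 out of
   16,000 retained draws. Two joint moves walk the directions the
   single-site blocks cannot: a translation `(µ, t) → (µ+e, t+e)` and a
   scaling `(τ, t−µ) → (cτ, c(t−µ))` with `c = exp(e)` and the
   corresponding Jacobian factor `c` in the acceptance ratio
   (Liu–Sabatti-style scale-group move). The φ((t−µ)/τ) prior terms
   cancel along these directions, so both moves cost one O(n) residual
   update. They raise τ's ESS above 1,000 and bring split R-hat under
   1.01 at the default schedule. Their correctness was verified against
   dense-grid quadrature oracles of the marginal posteriors at several
   conditioning levels (agreement within Monte-Carlo error).

Proposal scales adapt every 50 iterations during burn-in toward a
20–45% acceptance band (multiplicative update
`s ← s · exp(0.8(rate − 0.3))`) and are frozen at the end of burn-in, so
the retained draws come from a fixed, detailed-balance-preserving
kernel. If any active block accepts nothing during the whole burn-in the
run aborts with its acceptance-rate report rather than returning frozen
chains.

Chain *c* initializes the scalars at independent prior draws from its
own RNG stream (streams are spawned from the single user seed via
`numpy` SeedSequence, so identical seed + config + input reproduce the
ChainSet bit for bit) and the half-lives at the closed-form inversion of
the steady-state relation, clipped to (1, 1000) days.

**Schedule.** The default is 4 chains × 30,000 iterations with 10,000
burn-in and thinning 5 (16,000 retained draws, ~8 s for n=304 on one
core). The model's posterior is largely prior-anchored and the chains
mix with lag ≈ 8–10, so this schedule puts Monte-Carlo error well below
the posterior SDs; heavier schedules remain expressible through
`MCMCConfig` when sharper quantile estimates are wanted.

**Zero-intake subjects** make `log f(d)` undefined and are excluded
before fitting (logged count); `floor_zero_intake` instead floors intake
at half the smallest positive value for sensitivity analyses.

**Truncated-normal sampling** uses inverse-CDF transforms while the
truncation interval overlaps the central ±5 SD region and switches to a
translated-exponential rejection sampler (Robert 1995) for intervals
entirely in a tail, avoiding CDF underflow; tests cross-check both
regimes against `scipy.stats.truncnorm`.

## Dietary exposure

Intake = Σ items (grams/day × µg/g) / body weight, averaged with equal
weight over the distinct 24-h recall days present (equal weighting is
the natural reading of a repeated-recall design; the alternative —
weighting days by item count — has no design justification). Non-detect
items take LOD/2, with the 6 µg/kg assay LOD fixed and converted to
0.003 µg/g internally. Items missing from the concentration table
contribute zero and are logged: only the assayed high-mercury panel is
inside the exposure model.

## Synthetic cohorts

The generator emulates the study conditions the model was built for:
n = 304 adults (167 male / 137 female), weight ~ N(66, 12²) kg truncated
at 30 kg, intake ~ LogNormal(median 0.031 µg/kg bw/day, log-SD 0.9) —
the log-SD is chosen so the lognormal's mean (≈0.05) and SD (≈0.06)
match the reported skewed intake marginals — and then applies the
generative model exactly: `t_half,i ~ TN(80.2, 25², 0, ∞)`, kinetics
(0.955, 0.089, 3.423), lognormal noise with σ = 1.388. Ground truth is
the reported posterior mean vector, so parameter recovery is the
acceptance surface. Per-stratum presets (`stratum_defaults`) carry the
male/female covariates and posterior means (male: n=167, µ=81.6,
weight 72±11; female: n=137, µ=78.9, weight 60±10, intake median 0.033).

What the generator does **not** emulate: the original four-strata
mercury-percentile sampling design, age–intake correlation, and the raw
blood-concentration marginal — with σ = 1.388 the generated
concentrations are intentionally more dispersed than a real cohort's
marginal SD because the generator reproduces the fitted *model*, not the
raw table; median-based checks are therefore the meaningful ones.
Passing tests consequently demonstrate self-consistency of model and
sampler under the stated noise structure, not that the one-compartment
model is adequate for any particular real population. Blood-LOD
left-censoring is off by default (the 0.5 µg/L LOD is far below
generated values) and available as a flag for robustness checks.

`generate_food_records` inverts the exposure computation: it splits each
subject's assigned intake unevenly across two recall days and up to
three items and back-computes grams from effective concentrations, so
`exposure.daily_intake` reproduces the assigned intake to floating
precision and the whole pipeline can be exercised end to end.

## Diagnostics

Autocorrelation is the FFT-based empirical ACF (`statsmodels`); ESS uses
the initial-positive-sequence truncation of the autocorrelation sum,
capped at the chain length; R-hat is the plain split-chain
potential-scale-reduction factor (rank-normalized variants are a
non-goal). Summaries pool post-burn-in thinned draws across chains and
use linear-interpolation ("type 7") empirical quantiles, which makes
summary files bit-reproducible. Chain files store the six scalar
parameters in long format; the per-subject half-life draws stay in
memory (they are ~100× larger and rarely needed downstream — the
ChainSet API exposes them).

Plots (trace, per-parameter autocorrelation, posterior density) are
best-effort: the tested contract is only that they render without error
on valid ChainSets. Half-life axes are labelled in days everywhere.

## Validation choices

- **Oracle equivalence:** a single-subject model with all scalars fixed
  is integrated by dense trapezoid quadrature and must agree with the
  sampler within 1%.
- **Prior dominance:** a zero-subject run must reproduce every prior's
  mean and tail quantiles within Monte-Carlo error (the sampler is
  deliberately run through the same code path, not a shortcut).
- **Noise-free identity:** a σ=0 cohort is fitted with σ fixed at 0.01
  and the kinetics at truth, since a literal σ=0 likelihood is
  degenerate; at that noise level prior shrinkage biases individual
  half-lives by ≪1%, inside the 1% recovery tolerance.
- **Calibration (SBC-lite):** 20 replicate cohorts with µ drawn from its
  hyperprior, run at n=80 with a shortened schedule; the 95% CrI for µ
  must cover truth in ≥85% of replicates. Coverage of a correctly
  specified model does not depend on n or schedule length given mixing,
  which the R-hat checks guard.
- Recovery checks on the default cohort use five replicate seeds with
  the reduced schedule; the between-seed spread of posterior means is
  small relative to the ±2-posterior-SD acceptance bands.

## Known limitations

- Single compartment, steady state, time-invariant intake; no hair
  compartment or hair-to-blood ratio.
- No covariate-dependent half-life (age/sex/body-mass regression on
  t_half); sex effects are handled only by fully independent stratified
  fits.
- τ is only weakly identified at the default noise level: its 95%
  credible interval spans nearly the whole Unif(10, 40) prior. It is
  not, however, completely prior-dominated — on cohorts generated
  exactly from the model at the documented defaults (true τ = 25) the
  pooled posterior mean of τ settles near 21.5–22, a mild downward pull
  that emerges as σ, µ and the kinetic nuisances are marginalized and
  that quadrature oracles confirm is genuine posterior behavior. Fits
  that report τ should quote the full interval, not the mean.
- With one observation per subject, `σ` and `τ` separate only through
  the nonlinearity of the log transform and the priors; fits at other
  noise regimes should re-examine that trade-off.
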