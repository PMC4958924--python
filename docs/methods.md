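# Methods

`weedbayes` implements a hierarchical Bayesian analysis of how herbicide
application rate, filtered through latent farmer- and field-level
"effectiveness", shapes weed species richness and abundance in winter
wheat, together with the linear-mixed-model screening stage that
precedes it. Because no field survey ships with the package, a
synthetic-survey generator with known ground truth stands in for the
data; every empirical statement below is computed by the test suite or
by `scripts/acceptance.py`.

## The model

A field surveyed with no herbicide carries species richness
`R ~ Poisson(mu)`. A total active-ingredient application rate `D`
(kg/ha over the season) reduces the mean through a nonlinear dose
response,

    lambda = mu / (1 + a * eta * D) ** b,

where `a > 0` is a scale factor, `b > 0` a shape (concavity) factor,
and `eta` in [0, 1] is a latent *effectiveness*: `eta = 1` means the
treatment acts at full expected strength, `eta = 0` that it has no
effect. The effective dose `eta * D` sits inside the parenthesis, so
`lambda = mu` exactly when `D = 0` and `lambda -> 0` as `D` grows.
Effectiveness enters at one of three levels, giving the richness family

* `rich_base` — no effectiveness (`eta = 1`),
* `rich_farm` — one `eta_F` per farm, shared by its five fields,
* `rich_field` — `eta_Ff = eta_F * eta_f`, a farm component times a
  field-within-farm component.

The abundance family applies the same reduction to each species'
untreated intensity `mu_s` (plants/m²). Quadrat surveys record only
presence/absence, so the data model is binomial: with quadrat area `w`
(4 m²) and `n` quadrats per field (10), the presence count for species
`s` in a field is `Binomial(n, 1 - exp(-lambda_s * w))` under complete
spatial randomness. `ab_base`, `ab_farm`, `ab_field` share `(a, b)`
across species; `ab_spec` gives each sufficiently common species its own
`(a_s, b_s, eta_Ffs)` (species seen in at least 5 fields by default;
rarer species keep the shared field-level structure, since a
per-species effectiveness for a species observed once is pure prior).

Derived quantities: the probability that at least one individual of a
species persists in a reference area `W` (default 4000 m²) after
treatment is `1 - exp(-W * lambda_s)`; a configuration switch exposes
the complementary zero-count probability `exp(-W * lambda_s)` instead.
The descriptive intensity estimate from a presence count `k` of `n`
quadrats is the ML inversion `-log(1 - k/n) / w`, continuity-corrected
to `-log(1/(2n)) / w` with a saturation flag at `k = n`, where the MLE
diverges.

## Priors and sampling

Priors are `Normal(0, 10)` on `log mu`, `log a`, `log b` (the second
argument read as a standard deviation; a precision-convention switch is
provided) and `Uniform(0, 1)` on every effectiveness. Sampling is
adaptive Metropolis-within-Gibbs on unconstrained scales (log / logit
with exact Jacobians), 3 chains of 20,000 iterations with the first
10,000 discarded at full scale; proposal scales adapt to a 0.44
acceptance target during burn-in and freeze afterwards. Parameters
whose components touch disjoint slices of the data (per farm, field,
species, or field-by-species cell) are proposed and accepted
componentwise in one vectorised pass.

Two structural facts shape the sampler beyond the plain sweep:

* `a` and `eta` enter the likelihood only through their product, so the
  posterior carries a long ridge. Symmetric translation moves trade
  `log a` (and `log b`, which couples the same way in the
  near-exponential regime `a*eta*D << 1`) against all farm logits, and
  an adaptive-covariance joint update moves `(log mu, log a, log b)`
  along their mutual ridges. Effectiveness is therefore identified in
  relative/rank terms only — the tests treat it that way.
* The weak priors admit a remote posterior basin (enormous `mu`
  compensated by an enormous reduction). Chains initialise at
  data-scale moment estimates of the untreated means (mean observed
  richness; presence-implied per-species intensity), with dose-response
  and effectiveness parameters at 1 and 0.5 jittered, which anchors all
  chains in the dominant basin.

Convergence is monitored with the Gelman–Rubin statistic per parameter.
Model selection uses DIC = mean posterior deviance + p_D with
p_D = mean deviance minus the deviance at the posterior mean on the
sampling scale. On weakly identified or misspecified fits that plug-in
point can fall off the curved `(a, b)` ridge and drive p_D strongly
negative — an impossible effective-parameter count; `compute_dic` then
substitutes the coordinatewise posterior median, which in our checks
restores p_D to the expected parameter count. Within a family the
lowest-DIC member wins; a top-two gap under 2 raises an
"indistinguishable" flag and exact ties resolve to fewer parameters.

## Descriptive stage

Per-field responses (yield in q/ha, richness, weed frequency = count of
species-by-quadrat presences) are regressed pairwise on per-field
predictors (total dose or TFI, richness, weed frequency) in a Gaussian
linear mixed model with a random intercept for farm, and for field
nested in farm when fields carry replicate rows; with one row per field
the field intercept is confounded with the residual and the fit reduces
to the farm structure, recording the reduction in its tag. The REML fit
is direct (marginal covariance `V = sigma_u^2 ZZ' + sigma_e^2 I`); the
slope test is type III F with Satterthwaite denominator df computed as
in lmerTest (delta-method variance of the slope variance against the
inverse observed REML information) and agrees with lmerTest to at least
five significant digits on shared data. Covariate screening (the
nitrogen rule) retains a covariate only when it lowers the ML-based AIC
by at least 2. TFI is the sum over a field's applications of applied
over recommended dose.

## Synthetic surveys

The generator realises the design the analysis assumes: 30 farms x 5
fields x 10 quadrats of 4 m², a pool of 108 species with i.i.d.
log-normal intensities (sigma = 1.5, heavy right tail: few abundant,
many rare species) whose location is calibrated by Gauss–Hermite
quadrature so an untreated field holds 9.46 expected species; doses
uniform on [0, 4] kg/ha; effectiveness drawn from configurable Beta
laws (degenerate values allowed) at the chosen level; quadrat presences
independent Bernoulli draws of the closed-form presence probability.
Yields are `Normal(75, 10)` q/ha truncated at 0 plus configurable dose
and weed-frequency coefficients — zero by default, so the generator
embodies the null yield-herbicide-weed regime by construction; three
farms lack yields, mirroring the emulated survey. Application records
(1–3 products per treated field from a synthetic catalogue) carry the
recommended doses TFI needs. A companion generator draws per-field
richness directly from the Poisson richness model, the regime in which
richness-model parameters are exactly recoverable. Ground truth is kept
separate from the fit-facing tables.

What the generator does *not* emulate: within-field spatial
autocorrelation, species interactions, multi-year seed-bank dynamics,
or real species identities. Passing tests therefore demonstrate
internal consistency of model, sampler and pipeline under the model's
own assumptions, not robustness to their violation in real surveys.

## Validation experiments and problem sizes

Run by `tests/test_acceptance.py` and `scripts/acceptance.py`; sizes
chosen to finish on a single CPU while keeping each check informative.

* Closed-form core: 10⁴ random parameter draws against independent
  scalar evaluations (agreement to 1e-12) plus monotonicity ladders.
* Likelihood oracles: brute-force Poisson/binomial pmf summation on a
  2-farm x 2-field x 3-species survey, 100 random parameter sets,
  tolerance 1e-10.
* Prior recovery: empty survey, 3 chains thinned to ~10⁴ near-independent
  draws, Kolmogorov–Smirnov against Normal(0, 10) at alpha = 0.01.
* Simulation-based calibration (scaled): 100 replicates, 50 fields,
  truth from sd-0.5 priors, 3 x 2,000 iterations; 95% interval coverage
  for `mu` expected in [88, 100]%.
* Effectiveness recovery: full 30 x 5 geometry under `rich_field` with
  dispersed Beta(1.2, 1.2) effectiveness and strong doses U(2, 4),
  documented seed 42, chains at twice the full-scale protocol length
  (3 x 40,000; without low-dose fields the mu ridge mixes slowly);
  Spearman(true, posterior mean) of `eta_Ff` at least 0.6 with every
  R-hat at or below 1.1.
* DIC selection: 10 replicates per regime at 3 x 4,000 iterations;
  widely dispersed Beta(0.5, 0.5) effectiveness should elect
  `rich_field` in at least 8, constant effectiveness should elect
  `rich_base` (or flag indistinguishable) in at least 7.
* Rare-species pattern: `ab_spec` fit on 10 farms x 3 fields x 25
  species with a shared true dose response; the dose at which survival
  in `W` first drops below one half, from the fitted shared response
  and per-species untreated intensities, must be non-decreasing in
  abundance — rare species are eliminated first.
* Null reproduction: 100 replicates with zero effectiveness and zero
  yield coefficients; the four pairwise mixed-model slopes reject at
  alpha = 0.05 at an empirical rate inside [1, 11]%, and the
  effectiveness–yield rank correlation's bootstrap interval covers 0.

## Numerical choices and limitations

Presence probabilities use `expm1`; binomial log-terms use
`log(1 - exp(-x))` with exact `-x` for the complement, and zero-count
cells bypass the `0 * log(0)` indeterminate form. Saturated presence
counts are continuity-corrected as above. The `(a, b, eta)` posterior
is heavy-tailed along its ridges under the stated priors: natural-scale
posterior means of `a` and `b` can be dominated by tail draws and
should not be interpreted individually; effectiveness ranks,
treated-intensity predictions and DIC comparisons are the stable
outputs. DIC itself retains its known fragility for weakly identified
hierarchies; the median-plug-in guard removes the impossible negative
p_D cases but does not make DIC a calibrated significance test — hence
selection is validated as a frequency property over replicates.
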