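# Methods

`befstab` implements the statistical chain used to ask how nitrogen addition
and CO₂ enrichment reshape biodiversity–functioning and
biodiversity–stability relationships in a long-running split-plot grassland
experiment: cover-based gap-filling of species biomass, the additive
partition of the net biodiversity effect, the multiplicative partition of
temporal stability, split-plot mixed models with type-III tests, and
multi-group piecewise structural equation models. Because the real
experiment's tables are external, the package ships a synthetic generator
that reproduces the *statistical structure* those methods assume, with known
ground truth, so every stage is testable end to end.

## The quantities

**Additive partition.** For a mixture planted with N species, with Yᵢ the
across-years mean biomass of species *i* in the mixture and Mᵢ its
across-years mean monoculture biomass,

    ΔRYᵢ = Yᵢ/Mᵢ − 1/N
    ΔY   = Σᵢ ΔRYᵢ·Mᵢ = CE + SE
    CE   = k · mean(ΔRY) · mean(M)
    SE   = k · cov_pop(ΔRY, M)

The expected relative yield is 1/planted-N (even seeding). Monoculture
plot-years below 2.5 g m⁻² are dropped before averaging Mᵢ, since relative
yields diverge as the denominator approaches zero; a species whose reference
vanishes entirely is left out of the sums. The multiplier k is the number of
species actually retained — equal to planted N whenever nothing is dropped —
because the partition identity ΔY = CE + SE is exact only for that count,
and the identity is the partition's defining property (asserted to 1e-9 on
every call). The covariance is the population (1/k) form for the same
reason. Monoculture references are stratified by CO₂ × N cell by default
(monoculture performance is treatment-dependent and the design crosses
treatments); `pool_treatments=True` collapses the stratification as a
sensitivity variant.

**Stability partition.** Per plot over T years, with σ denoting temporal
SDs,

    S_com = Y_T/σ_T,   S_sp = Y_T/Σᵢσᵢ,   φ = Σᵢσᵢ/σ_T,   S_com = S_sp·φ

φ ≥ 1 by the triangle inequality (1 = perfect synchrony). SDs are sample
SDs (n−1) by default; the identity is denominator-invariant but reported
magnitudes are not, so `ddof` is exposed. Planted species missing in a year
contribute zero biomass that year — absence is part of variability. A plot
whose community total is constant (σ_T below ~1e-12 of the mean, which
machine arithmetic cannot distinguish from zero) is flagged non-finite and
excluded from downstream models with a logged count.

**Gap-filling.** Unsorted plot-years (community total weighed, species not
sorted) are filled in four steps: per-species through-origin regression of
plot-mean biomass on plot-mean cover over sorted years (slope = Σxy/Σx²);
prediction from the unsorted year's cover; renormalisation to proportions;
multiplication by the observed total. Mass is conserved exactly and the
result is invariant to rescaling all slopes. The through-origin goodness of
fit is the uncentred R² (1 − Σ(y−ŷ)²/Σy²), which can be negative. A species
with no cover model anywhere falls back to allocation by raw cover share
(flagged) rather than dropping the plot-year. Predictability is assessed by
replaying the procedure on sorted plot-years and correlating weighted
predictions with measurements per species; note that renormalisation couples
species within a plot-year, so noise in one species' cover leaks mildly into
its plot-mates' predictability. Sensitivity toggles: `off` (drop unsorted
plot-years) and `noisy` (mean-one lognormal perturbation of predictions
before renormalising, which preserves mass).

**Mixed models.** All inference uses Gaussian linear mixed models fitted by
direct maximum likelihood on the marginal covariance
σ²(D(δ) + Σ γ²_g Z_g Z_g′): random intercepts for ring (whole-plot CO₂) or
richness-within-ring (link models), and optionally an exponential variance
function D = diag(exp(2δvᵢ)) of a covariate v (defaulting to OLS fitted
values), the nlme `varExp` analogue. σ² and the fixed effects are profiled,
leaving one to three variance parameters for a Nelder–Mead search
(|θ| capped at 6 on the log scale; beyond that the covariance is numerically
singular). Categorical treatments are sum-to-zero coded and each term is
tested jointly by a type-III Wald χ² on the ML coefficient covariance — the
statistic the standard `Anova`-style procedure computes; a likelihood-ratio
mode (refit without the term's columns) is available since the two agree to
first order near the null but diverge for large effects. Wald χ² from ML
fits is asymptotic: with few plots and many cells it runs mildly
anticonservative, and with strong variance heterogeneity across richness
levels the homoscedastic version is badly *conservative* (see calibration
below). The suite fits six treatment models (log productivity, log
community stability, CE, SE, log asynchrony, log species stability against
log richness × CO₂ × N) and four link models (log asynchrony / log species
stability against CE or SE × CO₂ × N). CE and SE take both signs and are
never log-transformed.

**Piecewise SEM.** The a-priori DAG has log richness driving the four
mechanisms (CE, SE, asynchrony, species stability), CE/SE driving
productivity and tested as drivers of the stability mechanisms, and the two
stability mechanisms driving community stability; CE~~SE and
asynchrony~~species-stability carry correlated errors. Model fit is judged
by the union-of-parents d-separation basis set — one claim per non-adjacent
pair, conditioned on the union of the pair's parents, correlated-error
pairs exempt; every emitted claim is verified against a brute-force
d-separation oracle in the tests. Claims are tested by regressing the
topologically later variable on the earlier plus the conditioning set;
Fisher's C = −2Σln Pᵢ is χ²(2k) under the model, and AIC = C + 2K with K
the parameter count across component models. Because log community
stability is *identically* log asynchrony + log species stability, its
component model is deterministic; conditional-independence claims about a
response that is an exact function of its parents are vacuously true and
are assigned P = 1 (contributing 0 to C and 2 to df), and no
group-difference test is attempted on its paths. In the multi-group
analysis each path's path-by-group interaction is tested (type-III Wald,
α = 0.05 by default); significant paths are freed with per-group
coefficients, others keep a pooled coefficient, and C is assembled on the
group-aware component models. Standardised coefficients are b·sd(x)/sd(y)
on the transformed scale. Non-significant paths (P ≥ 0.1) are *reported* as
pruning candidates, never auto-removed — simplification is a user decision
with a visible trail.

## The generator

The generator owns the study conditions: 6 rings (3 elevated CO₂),
per-CO₂×N replicate allocation {1: 32, 4: 15, 9: 15, 16: 12} (totalling
296 plots — the experiment's plot count; the true per-richness allocation
is not public, so this default is a synthetic reconstruction), 24 annual
censuses from 1998, 16 species in four functional groups with monoculture
means μᵢ geometrically spread over 40–320 g m⁻², and 24 + 12 plots flagged
for precipitation/warming exclusion. Monoculture compositions cycle
through a per-cell shuffle of the pool so every species has reference
plots; mixtures are sampled without replacement. Expected mixture biomass
is μᵢ(1/N + ΔRYᵢ) with ΔRYᵢ = δ_CE(N)/N + δ_SE(μᵢ−μ̄)/μ̄, so δ_CE and δ_SE
independently set the expected CE and SE; by default δ_CE grows as
0.25·ln N (the overyielding-richness coupling the analysis is designed to
detect) and δ_SE = −0.02. Inter-annual variation is a loading λ = 0.4 on a
mix of one shared annual shock and independent species shocks with weight
ρ_sync = 0.5; observation noise is mean-one lognormal with σ = 0.15. Cover
is biomass divided by a species slope (default μᵢ/50, i.e. ~50% cover for
an average monoculture) with its own 10% lognormal noise, clipped to
[0, 100] — the clip emulates cover saturation and is the one place exact
proportionality breaks. A fraction 0.12 of mixture plot-years is emitted
unsorted, which yields ~11% of records imputed in the default run. Every
plot has its own RNG stream keyed by (seed, plot id), so plot subsets
regenerate identically; one shared stream drives the annual environment.

What the generator does *not* emulate: population dynamics and species
interactions (no Lotka–Volterra coupling, no succession or year trends),
the real experiment's block layout of unsorted years (here they are random
mixture plot-years rather than whole richness-level blocks), cover
estimation error structure beyond lognormal noise, and species-specific
treatment responses finer than functional-group multipliers. Passing tests
therefore demonstrate that the estimators recover known structure of this
statistical form — not that the field data satisfy these assumptions.

## Calibration studies and their problem sizes

`befstab.calibration` quantifies operating characteristics on seeded
replicates; sizes were chosen to resolve the rates of interest in minutes
on one core:

* **Richness–CE recovery power** — 100 replicates of a 112-plot, 8-year
  design with the default overyield coupling; the richness term on CE is
  significant and positive in effectively all replicates.
* **Type-I error** — 400 replicates of a 288-plot null. The naive null
  (realistic unequal μᵢ) violates homoscedasticity so strongly — monoculture
  log-biomass variance is dominated by which species was planted, falling
  ~100-fold from richness 1 to 16 — that the homoscedastic Wald test
  rejects essentially never. The calibration null therefore uses equal
  species means and independent shocks, making Var(log mean biomass) ∝ 1/N
  exactly, and fits with the exponential variance structure in log richness
  (the situation that structure exists for). The measured rate is at the
  nominal 5%. The lesson carries to real data: with responses whose
  variance moves with richness, engage `variance="exp"`.
* **Asynchrony response** — mean mixture φ falls monotonically in the
  shared-shock weight and equals 1 exactly at full synchrony without noise.
* **Multi-group decisions** — 100 replicates of a two-group single-path
  model: identical slopes stay constrained in ≥ 94% (nominal 95% at
  α = 0.05); opposite slopes with small noise are freed in 100%.
* **d-separation calibration** — 200 replicates of a chain fitted as
  generated: the global P rejects at ~6%, within the binomial band of the
  nominal 5%.

## Numerical choices and edge cases

Tolerances: partition identity 1e-9 absolute (g m⁻² scale), stability
identity 1e-12 relative, imputation mass balance 1e-9 relative. Degenerate
inputs: all-zero cover with positive biomass is a hard error (no slope
exists); zero predicted mass against a positive total marks the plot-year
unresolvable and drops it with a count; fewer than two species with
monoculture references leaves a plot's partition undefined (flagged, not
fabricated). Aliased fixed-effect columns raise with the offending column
names. The stability floor for whole-dataset runs is 3 years; the core
function accepts 2 (the algebraic minimum for a sample SD), which the
worked examples use.

## Known limitations

ML (not REML) everywhere, so variance components are biased low in small
samples; Wald tests carry no small-sample denominator-df correction. The
varExp covariate defaults to OLS fitted values computed once, not iterated
with the fit. The exponential variance function is the only
heteroscedasticity model (no per-stratum variances). The multi-group SEM
decides each path's group dependence marginally, not jointly, and the
reconstruction of the a-priori DAG is a package default, not an external
ground truth — with a different DAG the basis set, df, and C change.
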