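# Methods

## The behavioural model

`mifmodel` implements a computational model of effort-based motivated
performance in a monetary incentive force (MIF) task. A participant
squeezes a hand grip to a threshold of 50% of their maximal voluntary
contraction (MVC) to win a trial-specific reward x ∈ {0.2, 0.5, 1} CHF.
The task comprises 80 trials in 2 blocks × 2 sessions × 20 trials
(15 action + 5 rest per session, one rest after every 3 action trials,
each incentive appearing 5 times per session in pseudorandom order);
a rest break separates the blocks.

Three functions map a five-parameter description of a subject to trial
success probabilities:

- utility            u(x) = x^α − τ
- effort cost        τ = b + 2(1 − E)
- performance        P(success) = 1 / (1 + e^{−uβ})

α > 0 is the utility curvature (α < 1: concave valuation of money),
b the effort-cost baseline (utility units; lower b, better initial
performance), β ≥ 0 the sigmoid steepness / inverse temperature
(higher β, less random performance). E is the session energy fraction
on a discrete four-session schedule (1, ε_spr, ε_end, ε_spr·ε_end):
sprint stamina ε_spr ∈ (0, 1] is the energy retained across adjacent
sessions within a block, endurance stamina ε_end ∈ (0, 1] the energy
retained across the between-block break. A reduced single-stamina
variant constrains ε_end = ε_spr², giving energies (1, ε_spr, ε_spr²,
ε_spr³). Composing the three functions over the 3 incentives × 4
sessions grid yields the predicted performance matrix; its 12 cells are
the performance measures (PMs). Success rates are proportions in
[0, 1] internally; percentages appear only in presentation.

Incentives enter the utility in CHF unrescaled: the constant 2 in the
effort cost fixes the scale, and any rescaling of money is absorbed by
α and b. β = 0 is admitted (a degenerate flat performer, P = 0.5
everywhere) to keep the search space closed; α = 0 is excluded. The
sigmoid is evaluated with `scipy.special.expit`, which saturates
exactly to 0/1 for |uβ| ≳ 40 instead of overflowing.

## Fitting

Per subject, fit quality is the weighted sum of squared PM residuals

    χ² = Σ_i (PM_i^obs − PM_i^mod)² / σ_i²,   i = 1..12,

with σ_i² the cross-subject sample variance of PM_i in the cohort,
floored at 10⁻⁴ to guard degenerate cohorts. The fit is evaluated
against the χ² distribution with df = 12 − (free parameters): 7 for the
full model, 8 for the reduced and fixed-parameter variants.

Estimation is a seeded stochastic search:

1. **Broad phase** (default 150 000 draws): independent samples from
   per-parameter distributions — α ~ log-uniform(0.05, 4),
   β ~ log-uniform(0.1, 100), b ~ uniform(−3, 3), ε_spr, ε_end ~
   uniform(0.01, 0.999). Draws come from one row-major uniform block,
   so enlarging the budget extends the candidate stream rather than
   reshuffling it (the best χ² is monotone in the broad budget under a
   fixed seed).
2. **Refinement phase** (default 50 000 draws in 10 batches): Gaussian
   perturbations of parents sampled from an elite set, with the
   proposal covariance taken from the elite's full empirical covariance
   in the sampling-transform space (log scale for α, β). The elite pool
   shrinks geometrically across batches. The full covariance matters:
   the χ² surface has strongly correlated, curved ridges (α–β–b
   trade-offs), on which per-dimension scaling stalls around χ² ≈ 10⁻².
3. **Polish**: a deterministic Nelder–Mead finish from three diverse
   elite starts (greedy farthest-point selection among the top 200),
   run in transform space with out-of-range excursions clipped and
   penalised. On noise-free data this reaches χ² ≈ 10⁻⁹; the surface is
   multimodal at large β, which is why several polish starts are kept.

The best parameter set, its χ², df and upper-tail fit probability are
returned together with the top-4000 archive sorted by χ² (ties broken
by draw order under the seed). Everything is bit-reproducible given
the seed; per-subject seeds are spawned from the cohort-level seed.

Search stability is quantified as the per-parameter Spearman
correlation, across subjects, between two independent-seed cohort fits;
on the default synthetic cohort with noise-free PMs all five parameters
correlate ≥ 0.97 between runs at the default budget. A within-subject
archive-agreement diagnostic is exposed separately.

## Model comparison

The reduced model and two fixed-parameter variants (ε_spr or ε_end
pinned to the cohort mean of the full-model estimates; all remaining
parameters refitted jointly) are estimated with the identical
procedure. Models are compared by mean per-subject χ², the upper-tail
probability of that mean at df = 8, and a paired two-sided t test on
per-subject χ² differences (two-sided is the conservative default; no
information criteria are computed). With matched seeds and the default
budget the full model's per-subject χ² never exceeds a variant's by
more than the 10⁻³ search tolerance.

## Parameter recovery

The recovery experiment draws generating parameter sets from the same
sampling distributions used by the search, computes each subject's PMs,
re-estimates all parameters exactly as for observed data (cohort
variances included), and reports per-parameter Spearman correlations
between generating and recovered values. PMs are model-exact by
default (`noise_free`); `bernoulli` mode instead realises an 80-trial
task run (5 trials per cell), whose binomial noise visibly degrades
recovery and serves as a realism control.

A structural caveat: parameter sets in which every one of the 12 cells
is saturated (all P ≈ 0 or 1; large β combined with extreme b) are
observationally equivalent over whole regions of the stamina
parameters — distinct (ε_spr, ε_end) values reproduce the PMs to
≤ 10⁻⁷. Under the default wide sampling ranges roughly 1–6 of 27 draws
per seed fall in this regime, which caps the stamina recovery
correlations near 0.8 while α, β and b recover at ρ ≈ 0.96–0.99. The
result object flags subjects with generating β > 50 so reports can
separate the identifiable regime; restricting β below ~30 restores
tight fits (χ² < 0.01 for ≥ 95% of subjects at default budget). This is
a property of the experiment design, not of the estimator.

## Synthetic cohort generator

The generator emulates a two-group study design: 27 subjects (15
isolation, 12 competition), a metabolite panel, an effort-perception
score, latent model parameters and simulated trial data. Defaults:

- **Metabolites** (arbitrary concentration units; absolute scales are
  invented fixture values — only ratios drive couplings): Glu 9 ± 1,
  Gln 3 ± 0.5, GABA 1.5 ± 0.4, with a shared latent factor (loading
  0.8) inducing the Glu–Gln correlation. Couplings act on the Gln/Glu
  ratio standardised by its delta-method design mean (1/3) and SD
  (0.0427).
- **Parameters**: α log-normal (median 0.25); β normal per group
  (16.1 ± 13.9 isolation, 7.5 ± 8.0 competition, clamped to the search
  range); b = 0.356 + comp·(−1.17 + 0.9·z) + N(0, 0.5), so competition
  lowers b by ~1.17 on average with the effect concentrated in
  low-ratio subjects (the group × ratio interaction); staminas and
  effort perception are generated on the logit scale —
  ε_end: logit 3.5 (iso) / 2.7 (comp) + 1.0·z + N(0, 1);
  ε_spr: logit 3.0 / 0.6 + 0.5·z + N(0, 1.2);
  effort perception: logit 0 − 0.8·z + N(0, 0.8).
  Group centres are anchored on the two-group parameter summaries the
  model is meant to reproduce qualitatively; coupling magnitudes are
  set to make the ratio→stamina association detectable at n = 27 (the
  published evidence constrains significance patterns, not
  coefficients).
- The logistic link keeps staminas and the perception score in (0, 1)
  without clamping and makes the design rank correlation analytic: for
  a coupling k against noise σ, Spearman ρ = (6/π)·asin(r/2) with
  r = k/√(k²+σ²) (monotone transforms preserve ranks). α and β are
  clamped to the search ranges after effect addition; clamps are
  logged at debug level.

Trial data are simulated as independent Bernoulli draws from the
model's cell probabilities. Everything derives from one master seed via
spawned child seeds and regenerates bit-identically.

What the generator does **not** emulate: spectroscopic uncertainty
(CRLB), voxel composition, force dynamics within a trial, opponent
behaviour, personality covariates, or any trial-level effect of the
competition context (context enters only through parameter shifts).
Passing tests therefore show that the pipeline detects the designed
effect structure at realistic n — not that real data carry it.

## Cohort statistics

Mirrors the cohort-level battery such designs call for: a metabolite × outcome correlation screen
(Pearson, or Spearman when either variable fails normality);
normality-gated two-group contrasts (pooled-variance Student t, or
Mann–Whitney U reporting the rank sum); multiple regression of each
parameter on the Gln/Glu ratio and group coded −1/+1, rank-transforming
non-normal outcomes (rank regression); a two-way interaction ANOVA on
the 2×2 group × (below/above-mean ratio) design with Type-II sums of
squares (the design is unbalanced) and follow-up t tests within ratio
strata; and a PCA dimensionality check of the 12 PMs via
eigendecomposition of their column-centred covariance matrix
(correlation-matrix mode by flag; PMs share the proportion scale, so
covariance is the default). Normality uses the Kolmogorov–Smirnov test
in its Lilliefors form (estimated mean/SD) at α = 0.05 — a plain KS
against a fully specified normal is not meaningful for raw parameters.
No multiple-testing correction is applied by default;
Benjamini–Hochberg is available for the screen.

## Pipeline, problem sizes, determinism

`run_pipeline` executes simulate-cohort → fit → compare → recover →
analyze, writing tidy CSVs whose first line records the configuration
hash and master seed; identical configuration and seed reproduce every
CSV byte-for-byte. Stage seeds are spawned deterministically from the
master seed. Missing upstream artifacts raise an explicit dependency
error.

Default problem sizes match the emulated design: 27 subjects, 80 trials,
200 000-candidate searches, 4000-set archives; the recovery experiment
uses n = 27 with noise-free PMs (the generating distribution and PM
mode are always reported alongside results, since recovery numbers are
meaningless without them). The test suite exercises reduced budgets
(10³–2·10⁴ candidates, 6–20 subjects) where only convergence to a loose
tolerance or a directional property is at stake, and full defaults
where a published quantity is re-derived.

## Known limitations

- Stamina parameters are unidentifiable for fully saturated
  performance profiles (see recovery caveat); fits for such subjects
  are flagged, not excluded.
- The χ² objective treats the 12 PMs as independent; their sampling
  correlation (shared trials within a session) is ignored, as in the
  df = 12 − k accounting it supports.
- The generator's effect sizes are design choices that reproduce
  significance patterns at n = 27; coefficients have no empirical
  anchor.
- Rank regression p-values rely on OLS normal theory applied to ranks,
  adequate at the n used here but approximate.
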