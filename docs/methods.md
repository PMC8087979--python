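# Methods

## The model

Feed efficiency (FE) — body-weight gain per gram of food consumed — is not
directly observable at a single time point, because it changes as an animal
approaches its mature weight.  `fedyn` models a cohort of mice on a
high-fat high-cholesterol diet with two coupled states per animal,
cumulative food consumption `F` and body weight `W`:

    dF/dt = FI
    dW/dt = FE_max * (1 - W/W_max) * FI

`FI` is the animal's intake rate (g/day), `FE_max` the conversion fraction
at negligible body weight, `W_max` the asymptotic weight.  Instantaneous
feed efficiency is the factor in front of `FI`:

    FE(t) = FE_max * (1 - W(t)/W_max)

With constant intake the weight equation has the closed form
`W(t) = W_max - (W_max - W0) exp(-FE_max FI t / W_max)`, which is the
default evaluation path everywhere; a stiff-capable numerical solver
(LSODA, rtol 1e-10, atol 1e-12) exists as a cross-check and as the hook
for future time-varying intake.  The tight tolerances are deliberate: the
analytic oracle makes sub-1e-6-gram agreement cheap to verify, and the
looser conventional settings (rtol 1e-8) measurably miss that bar on
large-`W_max` systems.  Internal units are grams and days; the diet energy
density (5.21 kcal/g) is applied only when formatting intake as kcal/day.

Time zero is the first day of the diet; the day-0 weight is the initial
value (not a fitted latent) and cumulative food starts at 0.

## Hierarchical inference

Each mouse has its own intake `fi_i ~ Normal(fi_mean, fi_sd)`; `FE_max` and
`W_max` are population-level.  Observations enter as independent normal
errors around the model trajectories — weight around `W(t)`, cumulative
food around `fi_i * t` — with scales `sigma_w`, `sigma_f` estimated jointly.
Priors: `fi_mean ~ Normal(2.5, 0.1)` g/day (from an independent study of
the same strain and diet), `W_max ~ Exponential(0.02 /g)` (mean 50 g),
`FE_max ~ Beta(2, 8)`, and half-normal priors on all scales (0.5 g/day for
`fi_sd`, 5 g for the observation scales).

Sampling uses the affine-invariant ensemble sampler (emcee) with
differential-evolution moves, on an unconstrained scale (log for positive
parameters, logit for `FE_max`) with the appropriate Jacobians.  Each
requested chain is an independent ensemble seeded separately; walkers start
from cheap data-driven estimates (least-squares intake slopes, a coarse
grid for `FE_max`/`W_max`) with jitter.  The first half of each chain is
warmup.  Convergence is a hard gate, not a warning: split R-hat <= 1.01
(ensembles as chains, step-major order) and effective sample size >= 100
(walkers as chains), both via arviz, else the fit raises.  Divergent
transitions are a Hamiltonian-sampler concept and have no analogue here;
the acceptance fraction is monitored instead.  Fixed-parameter sub-models
(used for the conjugate closed-form check) are expressed through the
`fixed=` argument; fixing `fi_sd = 0` ties every intake to `fi_mean`.

A correctness anchor worth stating: with food-only data and all other
parameters fixed, the `fi_mean` posterior is conjugate
(normal-normal) and the sampler reproduces the closed-form mean and
standard deviation within Monte-Carlo error.

## Uncertainty propagation

FE at an animal's sacrifice day is recomputed once per retained posterior
draw using that draw's `(fi_i, FE_max, W_max)` jointly — never from
independently resampled marginals, which would break the strong parameter
correlations along the `FE_max`/`W_max` ridge.  The resulting mice x draws
matrix is the uncertain covariate for every downstream stage.  Group
summaries report the credible interval of the *group-average* FE (per-draw
means over mice), so they reflect posterior uncertainty rather than
between-mouse spread.

## Gene association with stability counting

Counts (genes x samples) are filtered to genes observed in ~93% of samples
(the 40-of-43 convention), then each FE draw column yields one analysis:
a negative-binomial GLM per gene with log link, offsets
`log(library size * TMM factor)`, covariates = intercept + FE (percentage
points) + batch factors; a likelihood-ratio chi-square(1) test of the FE
coefficient against the reduced model (batch retained); BH step-up FDR
within the draw.  Counting draws with FDR < 0.05 and declaring association
at >= 95% of draws gives the stability rule.  `logFC` is log2 change per
FE-percentage-point; percent change is `100*(2^logFC - 1)`.

Implementation choices that matter:

* **Batched IRLS.**  The fitter solves all genes simultaneously against the
  shared design (einsum-built normal equations, step-halving on likelihood
  decreases).  This is what makes 250-1000 draws x thousands of genes
  tractable; statsmodels' GLM serves as an independent oracle in the test
  suite (agreement to 1e-8 on the Poisson path).
* **TMM normalization, on by default.**  Raw column-sum offsets are
  composition-biased: strongly FE-linked, highly expressed genes drag the
  library size itself into correlation with FE, and null genes then reject
  at far above nominal rates (we measured 37-86% at p<0.05 in planted
  simulations, restored to ~5% by TMM or by the generative true offsets).
  `normalization="none"` remains available.
* **Dispersion.**  Per-gene Cox-Reid adjusted profile likelihood on a
  log-spaced grid, shrunk toward the all-gene average by adding
  `prior_df = 10` residual degrees of freedom of shared information
  (weighted-likelihood empirical Bayes), with quadratic interpolation
  around the grid argmax.  In stability runs the dispersions are estimated
  once from the mean-FE design and reused across draws
  (`dispersion_mode="per-draw"` re-estimates): dispersion is a gene
  property and is essentially unaffected by jitter in one covariate column.
* **Non-convergence.**  Genes whose full or reduced fit fails to converge
  carry NaN p-values for that draw and are excluded from that draw's BH
  denominator; iterations with >10% such genes are flagged in the result.

Gene-set over-representation uses the hypergeometric upper tail on the
draw's DE list split by fold-change sign (up/down tested separately,
mirroring direction-specific pathway reporting), universe = post-filter
genes, BH across sets within draw and direction, and the same stability
counting.  Phenotype association uses Spearman correlation per draw
(average ranks; t-approximation with n-2 df, exact enumeration available
for n <= 8) with p < 0.05 counting; the summary reports both mean and
median rho since either convention is defensible.

## The synthetic-data generator

The generator emulates the study the pipeline assumes: four
feeding-duration cohorts (20/19/20/46 mice, sacrificed at days
30/60/90/180, weekly measurements), of which 9/10/8/16 animals carry
RNA-seq; true `fi_mean = 2.5` g/day, `FE_max = 0.233`, `W_max = 55.6` g,
baseline weight `Normal(30, 2)` g.  Counts are negative binomial with
`log mu = b0 + ln2 * b1 * (FEpct - mean) + batch + log libsize`: 2000
genes, 5% planted with `|b1| ~ Uniform(0.5, 2)` log2 per FE-percentage-
point, dispersions `LogNormal(ln 0.15, 0.5)`, two 2-level batch factors
(isolation day, reagent lot), lognormal library sizes.  One gene set is
enriched for planted genes (80% of members); the rest are uniform draws.
A single seed fixes every stream.

Between-mouse heterogeneity and observation noise (`fi_sd = 0.5` g/day,
`sigma_w = 4` g, `sigma_f = 5` g) were chosen to reproduce the posterior
interval widths a cohort of this size and design actually yields — a
population FI interval of about ±0.1 g/day implies a between-mouse intake
spread near 0.5 g/day at N=105, and `sigma_w ~ 4` g yields `FE_max` and
`W_max` intervals of roughly ±1.7 percentage points and ±1 g.  The weight
scale should be read as a *residual* scale (real growth curves deviate
from the saturating form by a few grams, and that misfit is what widens
real posteriors), not as balance error.  What the generator does **not**
emulate: within-mouse autocorrelated deviations from the growth curve,
mouse-level variation in `FE_max`/`W_max`, count outliers, or any
realistic gene-gene correlation structure — so passing tests demonstrate
the pipeline's internal consistency, not robustness to those features of
real data.

## Numerical and design notes

* Quantiles are linear-interpolation (numpy default) everywhere.
* `fe_max` draws are validated into (0,1) and all scale draws positive; a
  violated invariant raises rather than warns.
* Posterior rows for FE propagation are subsampled without replacement
  when enough are available; with replacement (with a warning) otherwise.
* Predictive bands include observation noise (they are meant to cover
  measurements, not latent curves) except at day 0, which is a known
  initial value; coverage accounting requires exact day matches and counts
  boundary points as inside.
* The end-to-end closure analysis pools all RNA-seq samples, because the
  generator plants a single global FE-expression slope; per-group analysis
  (the design used on real cohorts, where age confounds between-group FE)
  is exercised separately in the test suite.

## Known limitations

* With weekly data truncated at day 90 and the default (paper-anchored)
  noise level, `FE_max` and `W_max` are only weakly identified: the
  posterior concentrates along their ridge and marginal intervals acquire
  a volume effect, so fixed-truth interval coverage falls below nominal.
  Parameter-recovery checks therefore run at daily cadence and low noise,
  where the data dominate; this is a property of the model's geometry, not
  of the sampler (intervals are unchanged under 4x longer chains).
* Stability counting does not repair the arithmetic of the step-up FDR:
  with R discoveries per draw at FDR 0.05, about 0.05*R chance
  associations are expected, and because they are properties of the fixed
  count matrix they persist across FE draws when the posterior is tight.
  In high-power settings (many strong planted genes) the stable false
  declarations therefore scale with the number of discoveries; the rule is
  most protective exactly where the original design operates — few
  discoveries and appreciable FE uncertainty.
* The LRT chi-square reference is asymptotic; at n = 8-10 samples per
  group it is mildly anticonservative even when everything else is exact.
* The exact-permutation Spearman option enumerates n! orderings and is
  limited to n <= 8.
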