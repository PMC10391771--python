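# Methods

This note documents the models, conventions and design choices behind
`resiphen`, in the order the pipeline runs them.

## Synthetic data: what is emulated and what is not

The generator emulates a finishing-pig test barn with automated feeding
stations: ~15 pigs per pen, pens nested in contemporary groups
(farm × compartment × entry batch), one summary record per animal-day between
95 and 155 days of age carrying weight (kg), feed intake (g/d), feeder-visit
duration (s/d) and visit count.

**Growth.** Each animal grows along a Gompertz curve
`W(t) = A·exp(−B·exp(−k·t))` with population means A = 220 kg, B = 6.0,
k = 0.0135 /d and SDs 25 / 0.8 / 0.002, correlated across parameters
(corr(A,B) = −0.4, corr(A,k) = −0.7, corr(B,k) = 0.8, the sign pattern seen in
fitted finisher curves). These means were chosen so the *mean trajectory*
runs 46.5 → ~109 kg over the 60-day window (ADG ≈ 1.04 kg/d), the level
reported for this kind of population; published *parameter* means from
individually fitted curves are larger because strongly correlated parameter
estimates do not average to the mean curve. Parameters carry additive genetic
and environmental parts matching configurable heritabilities (default
0.07–0.10); breeding values descend the pedigree by mendelian sampling
(midparent + N(0, ½Σ)), ignoring inbreeding depression and dominance — all
fitted models are additive, so the generator is too. Contemporary group, sex
and farm act as small multipliers on the whole curve.

**Dispersion genetics.** The daily weight-measurement noise of animal *i* is
N(0, exp(mu_v + v_i)) with `v` purely additive (variance `sigma2_av`,
default 0.05) — an exponential (multiplicative) model for residual variance,
chosen so that the GCV of ln-variance traits equals the additive SD on the
log scale. The default `mu_v = −1.4` puts the noise SD at ≈ 0.5 kg, the
accuracy class of AFS weighing platforms. This is deliberately *not* the mean
of published lnvar values (~0.85): real Gompertz residuals also contain
autocorrelated biological deviations, and an iid noise floor much above
0.5 kg would make the 3-kg rolling-median rule discard several percent of
clean records, which real QC does not. Consequently simulated lnvar levels
sit below published ones while their genetic architecture is controlled
exactly; passing tests demonstrate recovery of a known architecture, not the
field level of the trait.

**Perturbations.** Disturbance events arrive as a Poisson process (default
0.6 events per animal per window), last 5 days and cut feed intake by a
Beta-distributed fraction (mean 0.5). Lost intake converts to lost gain at
2.24 g feed per g gain, producing a persistent weight deficit — intake reacts
first (short-term response), weight second (moderate-term response). Visit
duration and count dip proportionally. With these defaults roughly 5 % of
animal-days are off-feed, matching the design quantile of the QR traits. The
real perturbation process behind barn data is unknown; this event model is
one plausible choice and results conditional on it should be read as such.

**Artifacts.** Four technical error modes are injected with a ledger of every
corrupted cell: single-day scale spikes (±5–25 kg), pen-clustered adaptation
errors in an animal's first recorded days (a penmate on the platform inflates
the reading up to ~2×, decaying over 2–3 days — short, because the station
learning curve proper has faded by day 95, which is why the window starts
there), missing days, and gross errors (<10 kg or >160 kg). The ledger makes
QC sensitivity/specificity exactly scorable.

## Quality control

Stages run in a fixed order (gross limits → minimum 20 weight records →
pen-level RMSE screen → rolling median → gap filter → pen re-screen →
feed/behaviour limits → age window and eligibility); each stage only sets
cells to missing or drops rows, and every removal is ledgered with a reason
code. Boundary conventions are literal: "below 10 kg", "more than 3 kg",
"exceeding mean + 4 SD" and "larger than ten days" are all strict
inequalities, and the 160-kg cap applies strictly before 160 d of age.

Numerical choices that were genuinely open:

- **Rolling median** is age-based (window |Δage| ≤ 5 d), needs ≥3
  observations *and* at least one on each side; one-sided edge windows are
  biased by the growth trend itself (≈ ADG × 2.6 d) and would flag ~1 % of
  clean first/last records, so edge records pass the median unfiltered —
  the edge semantics of R's rolling-median functions.
- **Quadratic second pass** (per-animal 2nd-order polynomial, same 3-kg
  rule, with one trim-and-refit round so outliers cannot drag the reference
  curve) is **on by default**: it is the only stage that can catch errors in
  the very first record, where the median has no left-hand window. The
  combined median + polynomial filter follows how such filters are used in
  practice on AFS data.
- The median/quadratic stage is **iterated to a fixed point** (2–3 rounds):
  removing a cell shifts neighbouring windows, and a single pass would not be
  idempotent. `run_qc` applied to its own output returns it unchanged.
- **Pen screen**: pens are flagged when the RMSE of a pooled weight-on-age
  regression exceeds Q3 + 1.5·IQR across pens (the threshold is configurable;
  visual inspection is not automatable). Inside a flagged pen each animal is
  compared against a Theil–Sen line so the error episode cannot drag the
  reference; flagged runs shorter than 20 d are set missing, a ≥20-d run (or
  ≥20 flagged days in total, the majority-contamination escape hatch) removes
  the animal. Between-animal weight spread within pens (SD ~8–12 kg) limits
  the power of pen-level RMSE flagging; the quadratic pass carries most of
  the sensitivity in practice.
- **Eligibility** uses each animal's own recorded span as the denominator for
  the 30 %-missing rule, and at least 20 distinct recorded days.
- SDs are sample SDs (n−1) throughout; feed/behaviour thresholds are one-pass
  population statistics on the current dataset.

On default simulations the cascade removes ≥95 % of ledgered corrupted weight
cells at ≤1 % collateral loss of clean cells, and passes ≥99 % of records of
an artifact-free simulation.

## Traits

Gompertz curves are fitted per animal by Levenberg–Marquardt with analytic
Jacobian (ftol = xtol = 1e−12, ≤600 function evaluations); manual anchor
weights (birth, 14 d, start/end of test) enter the fit when available but
residual-based traits use only in-window daily records, so animals with and
without anchors stay comparable. Non-convergence (or a fit leaving the
positive-parameter region) marks curve-based traits missing rather than
raising. Conventions:

- `lnvar` uses the sample variance (n−1); `lnMSE` uses RSS/n (the ML residual
  variance), making the two directly comparable; both shift by `+2·ln s`
  when residuals scale by `s`.
- Skewness is the population-moment g1 (no small-sample correction).
- Lag-1 autocorrelation is the divisor-n, mean-centred estimator with pairs
  formed only across age gaps ≤ `max_gap` (default 1 d); analyses of evenly
  thinned data pass `max_gap = keep_every` so consecutive retained records
  still pair. Gap-breaking avoids the bias of pairing across holes left by QC.
- Standardization uses post-QC population statistics; a day of age with fewer
  than two weighed animals is excluded from every animal's z-series.
- Off-feed days count strictly-below crossings of the τ = 0.05 linear
  quantile-regression line fitted by iteratively reweighted least squares on
  all pooled animal-days; the flagged fraction converges to τ as the pool
  grows (calibration is tested at n = 50,000).
- FCR is AFI/ADG in g feed per g gain, the direction consistent with
  published population means; ADG uses the first and last in-window weights.
- The final 4-SD cross-animal outlier filter is a single pass per trait.
- Feed intake is in g/d throughout, so lnMSE_FI is offset by 2·ln(1000) from
  a kg/d convention; all genetic parameters are invariant to that choice.

## Genetic models

`build_A` implements the tabular method; `build_A_inverse` Henderson's rules
with mendelian-sampling variances adjusted for parental inbreeding (taken
from the tabular diagonal). `build_G` is VanRaden method 1 with observed or
supplied allele frequencies and monomorphic markers dropped. `build_H_inverse`
rescales G so its mean diagonal and off-diagonal match A22, blends
0.95·G + 0.05·A22 for invertibility, and adds the `G*⁻¹ − A22⁻¹` correction
to the sparse A-inverse; a Monte-Carlo gene-dropping estimator of A serves as
an independent oracle in the tests, as do dense-matrix assemblies of H and a
grid search of the restricted likelihood.

REML maximises the restricted likelihood on the mixed-model equations
(fixed effects: sex, farm, centred covariates such as maximum age; random:
additive with K⁻¹, contemporary group as iid; contemporary groups smaller
than 10 merge into a remainder level). Each iteration computes the exact EM
update (restricted likelihood provably non-decreasing) and attempts an
average-information Newton step with step-halving, accepted only when it
stays in the parameter space and does not lower the likelihood; variances at
the zero boundary whose gradient points outward are pinned at a floor of
1e−10 × phenotypic variance and excluded from the active update (otherwise
EM lifts them indefinitely and convergence stalls). Convergence is a relative
parameter change < 1e−8, capped at 500 iterations. Standard errors come from
the inverse AI matrix; h² and r_g SEs by the delta method. Bivariate models
estimate full 2×2 additive and contemporary-group covariances with the
residual covariance fixed at zero — the residual structure these animal
models assume; where both traits share records this understates
residual dependence and is a documented limitation. The GCV for
ln-scale traits is √σ²_a (the exact lognormal alternative
√(exp(σ²_a)−1) is nearly identical for σ²_a ≤ 0.1 and is not used).

## Cross-validation

Variance components are estimated once on the full data and held fixed across
folds, and phenotypes are adjusted once (`y* = y − Xb̂ − Wĉ`) from the same
fit — re-estimating components per training fold would multiply cost ~50×
and changes none of the comparisons the statistic is meant to make. Within-family masking splits each sire's
offspring over 5 folds round-robin after shuffling (so sires with fewer than
5 offspring still have every animal masked exactly once per replicate);
across-family masking partitions sires; temporal masking splits on a birth-date
cutoff (single fit, no SD). Accuracy divides predictive ability by √h² of the
same relationship matrix used for prediction.

## Recording-design robustness

Thinning keeps every k-th record by index within the age-sorted series
(offset 0 preserves the first record and hence ADG's left endpoint); period
splits are half-open on the left ([95,115), [115,135), [135,155]) so boundary
ages belong to the later window. Eligibility within a 20-day window is scaled
to ≥7 recorded days, keeping the 20-of-60 philosophy proportionate.
Agreement is summarised by the Pearson correlation on animals with both trait
versions and, when a relationship matrix is supplied, a bivariate REML
genetic correlation treating the two versions as separate traits.

## Problem sizes used in validation

Recovery experiments use 2,000 phenotyped pigs (40 sires × 400 dams, 5 per
litter) with 61 daily records each: 10 replicates for univariate h² recovery
of ADG and lnvar_weight (tolerance ±0.05 on the replicate mean), 4 replicates
for bivariate r_g recovery (true 0.5, tolerance ±0.1 on the mean; the
Monte-Carlo SE of the mean is ≈0.045). The gene-dropping oracle uses 10⁶
replicates on a 12-animal pedigree; QC scoring uses 300 pigs at default
artifact rates; quantile-regression calibration uses 51,000 pooled
animal-days; robustness orderings use 600 pigs with perturbations active and
`sigma2_av = 0.2` (the same heritable-dispersion condition as the recovery
experiments). The full test battery runs in roughly ten minutes on one CPU.

## Known limitations

- The perturbation and artifact processes are stylised; real AFS data will
  contain error modes (drifting scales, identity swaps) not modelled here.
- Residual autocorrelation within animals is not simulated (only event-driven
  deviations), so lag-1 levels are lower than in barn data.
- The REML engine uses dense mixed-model equations: comfortable to ~5,000
  equations per trait, not intended for national-evaluation scale.
- Bivariate residual covariance is structurally zero (see above).
- Single-generation default pedigrees make across-family pedigree BLUP weakly
  informative unless founders are phenotyped; simulations meant to compare
  masking schemes should phenotype founders or deepen the pedigree.
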