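# Methods

This note documents the models, defaults and numerical choices behind each
module, what the synthetic generator does and does not emulate, and the design
decisions taken where the analysis style left the choice open.

## Synthetic study generator (`phenometab.simulate`)

The generator reproduces the statistical structure of a twelve-genotype
controlled-environment drought experiment.

**Metabolome.** Log-normal peak intensities with additive effects on the log₂
scale:

```
log2 x = b_f + g_{f,geno} + d_{f,t}·[drought] + eps,   eps ~ N(0, sd_f)
```

* `b_f ~ N(10, 1.5)` — feature baselines (intensities around 10³).
* `g_{f,geno} ~ N(0, genotype_sd)` with `genotype_sd = 0.2`.
* `d_{f,t}` — treatment shifts carried by `n_drought_responsive = 40` of the
  200 features. Default effects ramp over the sampling days
  (0.25/0.5/1.0/0.75 of a per-feature size drawn uniformly from 1.2-2.2 log₂
  units), peaking at 22 days after onset of drought (DAD) and partially
  persisting into recovery (28 DAD).
* Noise heterogeneity: 30% of the plain features are intrinsically noisy
  (`sd_f` uniform in 1.3-2.2 log₂ units) — emulating low-abundance GC-MS
  peaks — so that the 25%-highest-RSD filter has a realistic tail to remove
  and does not preferentially delete the designed signal. The designed
  responsive/causal features use `noise_sd = 0.3`.
* Replication follows the study design: 5 control replicates per genotype at
  every timepoint; 5/6/7/5 drought replicates at 7/13/22/28 DAD.
* Blanks: six per timepoint at gamma-distributed background (`blank_mean = 50`);
  5% of the plain quiet features are "contaminated" (blank level near leaf
  level) to exercise the 2-fold blank filter.
* Missingness is MCAR at 5% on leaf samples. GC-MS missingness is in truth
  abundance-dependent; MCAR is the default because the downstream presence
  filter and 1/5-minimum imputation are exercised identically either way,
  and the type-I calibration stays interpretable.

**Latent tolerance.** Each genotype carries a standardized latent tolerance
score τ. The three causal-marker features load on τ
(`causal_loading = 0.9` log₂ units per τ unit, plus an independent genotype
residual of 0.45), and drought performance of the post-harvest traits also
tracks τ. This shared latent axis is what makes metabolite-based tolerance
prediction *recoverable by design*: the coupled trait (grain weight) is a
linear combination of the causal markers' genotype-mean log intensities plus
noise, so the leave-3-genotypes-out PLSR screen has a well-defined target.

**Growth curves.** Per-plant three-parameter logistic biomass
(`k = 0.25/day`, inflection day 18), with multiplicative noise partitioned as
genotype (15%) ≫ plant (6%) ≫ daily measurement (`meas_noise_sd = 3%`).
Height is a square-root transform of the same curve. Under drought, daily
growth increments after `onset_day = 9` are multiplied by a suppression
factor approaching `drought_growth_factor = 0.27` with a one-day exponential
ramp (stomatal closure is fast but not instantaneous; the ramp also keeps the
curve kink-free, which matters for the QC band). Two calibrations were fixed
at design time, before any recovery tests were written against them:

* the suppression factor is chosen so genotype-average biomass loss at the
  end of the drought phase (day 23) is ≈ 62%, the magnitude characteristic of
  severe early-season drought in this design;
* the noise partition is chosen so the per-day treatment ANOVA first becomes
  significant at `onset_day + 1`. Because plant-level intercepts dominate the
  daily noise, the per-day tests are strongly correlated across days and the
  pre-onset false-positive probability stays near a single test's α rather
  than accumulating over days.

**Outlier injection.** `inject_outliers` shifts a random 0-10% of points by
±`magnitude` × local noise sd. When the caller passes the generator's own
relative noise (`rel_noise_sd`), spikes have exactly the nominal size
(ground truth for recovery tests); otherwise the sd is estimated per series
with a trend-robust second-difference estimator (on the log scale for
strictly positive series, since growth-trait noise is multiplicative).
Estimated scales carry ~20-30% sampling error on 22-point series, which is
why the ground-truth path exists.

**What passing tests do not show.** The generator has no retention-index
drift, no abundance-dependent missingness by default, no imaging artefacts,
no heat co-stress, and genotype effects are exchangeable rather than
pedigree-structured. Recovery results demonstrate that the pipeline detects
the designed signal class under the stated noise model — not that it would
behave identically on any real instrument's output.

## HTP time-series QC (`phenometab.qc`)

Per plant × trait series (days ≤ `last_qc_day = 22`; rewatering-phase jumps
are genuine signal and never touched):

1. Strictly positive series are transformed to logs (variance-stabilizing for
   multiplicative noise); residuals are then taken on the relative scale
   `y/ŷ − 1`, which treats up- and down-spikes symmetrically.
2. The fitted value at each day is a leave-one-out local quadratic with
   tricube weights over the `nn_span = 0.5` nearest neighbours. A linear
   local fit was tried first and rejected: on sigmoidal growth curves its
   curvature lack-of-fit both misses genuine spikes and flags clean
   inflection points. The local fit is robustified with an L1 (least absolute
   deviations) IRLS stage plus a 4×MAD trim, so a second outlier inside the
   neighbourhood cannot drag the prediction (the masking failure mode).
3. The noise scale is pooled across all plants of the same trait — imaging
   noise is instrument-driven and shared — using the trimmed RMS (lowest 75%
   of |residuals|, normal-consistency constant 0.3679) of residuals
   standardized by each point's prediction-variance factor. Pooling hundreds
   of points makes the scale nearly exact, which is what pushes 10-sd spike
   recall above 99% at the conventional `conf_int_size = 5` band.
4. Points beyond `conf_int_size` × scale are removed worst-first with
   refitting until the band is clean; `rounds = 2` full passes are run and
   flags are cumulative. Noise-free series (zero scale) fall back to peeling
   the single largest deviation per pass.

The subsequent filters follow the conventional rules exactly: per
genotype × trait × day × treatment cell, values beyond `sd_k = 2` sample
standard deviations (n−1) of the cell mean are excluded (cells under 3 values
skipped); plant × trait series with > 20% of days flagged are dropped
entirely; post-harvest traits get the same SD rule per genotype × treatment.
Note an arithmetic consequence of the 2-SD rule: in a cell of five, a single
outlier can never exceed two SDs (max standardized deviation (n−1)/√n ≈ 1.79),
so the rule only bites in better-replicated cells.

The 2-SD step uses fresh statistics, independent of the local-fit flags.
The per-day onset test is run on data cleaned of local-fit flags only:
trimming 2-SD tails inside the very groups being compared would bias the
ANOVA null.

## Phenotype statistics (`phenometab.phenostats`)

* Variance components by equating two-way ANOVA mean squares to their
  expectations (`MS_err = σ²E`, `MS_GxE = σ²E + r·σ²gxe`,
  `MS_G = σ²E + r·σ²gxe + r·e·σ²g`), with the harmonic-mean cell size for
  near-balanced data and truncation of negatives at zero. Method of moments
  is closed-form and directly testable; REML would differ only for strongly
  unbalanced data.
* `H²` evaluates the variance-ratio formula exactly; it is scale-invariant.
* Loss of trait uses the ×100 percent scale.
* Two-way fixed-effects ANOVA with interaction uses Type II sums of squares
  (statsmodels), appropriate for mildly unbalanced replication.
* Tukey compact letter display: all-pairs studentized-range tests
  (Tukey-Kramer SE for unequal n) followed by insert-and-absorb letter
  assignment; groups share a letter iff not significantly different. Default
  α = 0.01.
* The PSII plasticity ratio is the quantum yield under high light divided by
  the yield under low light.

## Metabolite preprocessing (`phenometab.preprocess`)

Steps run independently per sampling timepoint (the per-timepoint design has
different plants at each timepoint, and retained-feature counts are reported
per timepoint). Conventions, in pipeline order:

* Raw normalization divides each sample by fresh weight × internal-standard
  response × a batch factor (batch mean of sample medians over the grand
  mean) — a simple multiplicative detector correction.
* Blank filter: keep iff mean leaf intensity > 2 × mean blank intensity
  (strict; features absent from blanks always kept).
* "Quantified" means non-missing and non-zero. Presence filter keeps features
  observed in ≥ 80% of samples (a feature at exactly 80% is kept).
* Imputation: missing → 1/5 × feature minimum over the timepoint slice.
* RSD filter: `floor(0.25·n)` highest sd/mean features removed, computed on
  post-imputation, pre-normalization intensities, globally per timepoint;
  ties break by feature ID; zero-mean features count as infinite RSD.
* Median normalization (per sample), log₁₀, Pareto scaling
  (`(x − mean)/√sd`, sample sd). Constant features are left centred and
  flagged. The chain from median normalization onward is invariant to
  per-sample dilution.
* Row normalization (per-feature z-score) is provided for display and for
  the t-test input convention; being affine per feature it does not change
  t statistics.

Every removal is recorded in a `PreprocessReport` whose counts must telescope
(`n_in − n_removed = n_out` at each step); the report validates itself.

## Differential accumulation (`phenometab.dam`)

Equal-variance two-sample t-tests per feature; BH-FDR across the features of
one timepoint/contrast (the FDR family). Fold changes divide drought by
control means on normalized pre-log intensities. Volcano gating: up iff
FDR < α and log₂FC > cut; down mirrored. Zero-pooled-variance features get
p = 1 and a flag.

A note on calibration: with all genotypes present in both arms, genotype
effects cancel in the group-mean difference but still inflate the pooled
variance, so the unpaired t-test is *conservative* under the blocked design
(measured raw α ≈ 0.023 at nominal 0.05 with the default genotype spread).
This mirrors the analysis convention being reproduced. Type-I calibration is
therefore verified under the exchangeable null (`genotype_sd = 0`), where the
measured raw α matches nominal within binomial error.

Per-genotype selection combines t-test FDR < 0.05 with OPLS-DA VIP > 1 on the
same contrast; the tolerant-vs-non-tolerant consensus reports features with a
consistent sign in ≥ k of the four pairwise comparisons (sign-conflicting
features are dropped).

## Chemometrics (`phenometab.multivariate`)

PCA by SVD on the centred (already Pareto-scaled) matrix, with a
deterministic sign convention (largest-magnitude loading element positive).
OPLS-DA codes the classes {−1, +1}, centres both blocks, removes `n_ortho`
orthogonal-signal-correction components, then fits one predictive PLS
component on the deflated matrix; with `n_ortho = 0` it coincides with
one-component NIPALS PLS-DA. Predictive and orthogonal scores are orthogonal
by construction (checked to 1e−8). VIP is computed over the single predictive
component, `VIP_j = √p·|w_j|` with ‖w‖ = 1, so mean(VIP²) = 1 exactly. The
default of one predictive + one orthogonal component is the common two-class
OPLS-DA convention. The matrix is consumed as given (already Pareto-scaled
upstream); no internal re-autoscaling.

## Biomarker screen (`phenometab.biomarker`)

The unit of analysis is the genotype (n = 12): loss-of-trait exists only per
genotype, and genotype means are what the printed effect sizes of this
analysis style are consistent with. The four datasets pair metabolite
genotype means under control (CC, LC) or drought (DD, LD) with phenotype
means under the matching condition (CC, DD) or the per-genotype loss (LC,
LD).

The screen reports Spearman ρ (t-approximation p; at n = 12 its tail at
p < 0.001 is accurate to within the quoted binomial tolerance, checked by
simulation), BH-FDR within the dataset, and R² as the squared Pearson
correlation (equivalently the single-regressor OLS R²; it is *not* ρ²).

PLSR ranking: genotypes are split by a seeded shuffle into four disjoint
test folds of three; per fold a NIPALS PLS regression (centred, no
autoscaling; scikit-learn) is fitted on the nine training genotypes with the
component count (≤ 5) minimizing inner 4-fold cross-validated RMSEP; features
are ranked by |regression coefficient| (sign-blind magnitude is the only
reading that yields a predictor ranking), and the final ordering is the
ascending rank product over the four folds. Held-out predictions are emitted
for reporting predictive ability. The "fourfold cross-validation" is thus
implemented both as the outer 12/3 split and the inner component-selection
CV, both parameterized.

## Tolerance ranking (`phenometab.ranking`)

Per-trait ranks (1 = best, average ranks on ties) are multiplied into a rank
product; the total rank orders products ascending, ties sharing the average
rank. The product rule is deliberately not a mean: one excellent trait rank
pulls the product down multiplicatively, which separates genotype pairs that
mean-rank aggregation would invert (the regression tests pin this down on the
published 12 × 5 rank table).

## Enrichment (`phenometab.enrichment`)

A transparent hypergeometric over-representation analysis over a user-supplied
feature → pathway table with an explicit background universe, BH-FDR across
pathways. This is a deliberate substitute for KEGG network-diffusion
enrichment tools: no external database, an exact null, no topology. It does
not attempt to reproduce diffusion-based pathway figures.

## Problem sizes and seeds

Simulation-based checks use: 100 seeds for the null-DAM calibration, 200 for
the ANOVA-null uniformity, 50 for the PLSR top-5 recovery, 5 for the spiked
DAM recovery and 3 full studies for QC spike recovery (~600 spikes) — sizes
at which the binomial error of each estimated rate is several times smaller
than its distance from the pass bound. All randomness flows through explicit
integer seeds; the acceptance script derives per-task seed streams from its
single `--seed`.

## Known limitations

* The htp-QC band assumes either homoscedastic additive noise (raw scale) or
  multiplicative noise (log scale); count-like traits with neither structure
  would need a variance function.
* Method-of-moments variance components can be noticeably biased for strongly
  unbalanced designs.
* The Spearman p-value is a t-approximation; below n ≈ 9 an exact permutation
  null would be preferable.
* OPLS-DA is two-class only; multi-class contrasts must be decomposed into
  pairwise runs.
* The enrichment module's ORA ignores pathway topology by design.
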