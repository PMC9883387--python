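# Methods

This note documents the models, statistical procedures and numerical choices
behind `fermentomics`, and what the synthetic-data tests do and do not
establish about real fermentation data.

## Experimental design the package assumes

A batch fecal fermentation screened over four arms — a test hydrolysate
(HBPA), the raw substrate (HB), a positive prebiotic control (FOS) and a
blank control (BC) — sampled at a post-adaptation baseline (0 h) and at 6,
18 and 24 h, in two independent biological runs. Community profiles
(relative abundances, %), a five-target qPCR panel (Log₁₀ cells/mL) in
triplicate technical measurements (sextuplicate values per cell), and an
SPME GC-MS VOC table (mg/kg) in duplicate technical measurements. Arm and
time-point labels are configurable; the defaults encode this design.

## qPCR Prebiotic Index

`qpi` evaluates the linear form

    qPI = B/E − En/E + L/E − C/E

on the **Log₁₀ quantities** (B = Bifidobacteriaceae, En = Enterobacteriaceae,
L = Lactobacillales, C = Clostridium cluster I, E = total Eubacteria). The
ratios are deliberately taken on the log scale, as the index is defined, not
on linear cell counts. Values below a detection floor (default Log₁₀ = 2, a
typical qPCR limit of quantification) are substituted by the floor; a row
whose Eubacteria value is at or below the floor has an undefined index (NaN
with a warning). No normalization beyond the division by Eubacteria is
applied. `qpi_timecourse` summarizes replicate values per (treatment, time)
cell and compares cells by one-way ANOVA plus Tukey HSD letters; cells with
fewer than two replicates are excluded with a warning.

Properties guaranteed and tested: linearity in each ratio (beneficial groups
never decrease the index, detrimental groups never increase it), invariance
under a common scaling of all five log quantities, and the closed-form cases
(all-equal → 0; 0.9 − 0.6 + 0.8 − 0.7 = 0.4).

## Baseline-referenced Log₂ fold changes

The baseline reference is the pooled mean of **all** baseline samples across
arms (the fermentations start from one inoculum); the endpoint value per arm
is the pooled mean of its biological replicates. The shift is

    Log₂(F/C) = log₂( max(endpoint, f) / max(baseline, f) ),  f = 0.001 %

where `f` is the OTU detection cutoff; flooring keeps fold changes finite and
reflects that shifts below the detection limit are not quantifiable. The
accompanying p-value is a one-way ANOVA across the groups {baseline, arms} on
raw per-sample abundances, with Tukey HSD letters over the same groups (the
baseline column carries a letter too). Antisymmetry
(`fc(a,b) = −fc(b,a)`) holds whenever both values sit above the floor.

## Diversity

Alpha metrics are computed from their closed forms: observed richness;
bias-corrected Chao1 `S_obs + F₁(F₁−1)/(2(F₂+1))`; Shannon entropy with
natural log by default and an exposed `log_base`; Simpson as `1 − Σ pᵢ²`
(probability two reads differ), with the raw dominance `Σ pᵢ²` also
available; Good's coverage `1 − F₁/N` and its complement `F₁/N` (the
singleton fraction, sometimes called a rarity index — both readings are
exposed because the term is not standard). Count-based metrics refuse
non-integer input.

Bray–Curtis uses the standard quantitative form; unweighted UniFrac is the
unique-branch fraction over the union community on a rooted, fully
branch-lengthed tree (computed through scikit-bio, and checked in the test
suite against an exhaustive branch-enumeration oracle on random trees).
PCoA is classical scaling of the double-centered squared-distance matrix;
axes with negative eigenvalues are reported in the result but never returned
as coordinates, and requesting more axes than positive eigenvalues warns and
truncates.

## Statistical engine

* Normality (Shapiro–Wilk on pooled within-group residuals) and
  homoscedasticity (Levene) are computed and *reported*; they never switch
  the downstream method silently.
* One-way ANOVA is the standard between/within decomposition; a fully
  degenerate input (zero variance everywhere, equal means) yields NaN rather
  than an exception so bulk screens can proceed.
* Tukey HSD pairwise p-values come from the studentized-range distribution;
  the compact-letter display uses the insert-and-absorb construction, with
  letters ordered by descending group mean. The letters are a valid cover:
  two groups share a letter exactly when their pairwise p ≥ α.
* The two-factor attribution fits, per variable, a main-effects two-way
  ANOVA on the categorical predictors substrate ("matrix effect") and time
  ("time effect"). The reported contribution is the partial eta-squared
  × 100; this is an *interpretation* — the multivariate analysis it stands
  in for reports percentages without defining them, and partial eta-squared
  is the conventional effect-size reading. A variable significant for a
  factor at p < 0.01 is labeled a descriptor of that factor's highest-mean
  level (lexicographic tie-break, flagged). Sums of squares below 1e-12 of
  the total are scrubbed to zero so exactly-balanced fixtures do not leak
  float dust into contributions.
* Spearman's rho is the Pearson correlation of average ranks. For n ≤ 9 with
  no ties the two-sided p is exact, from a cached enumeration of the n! rank
  permutations; otherwise the t approximation is used. Constant vectors give
  NaN with a flag.
* No multiple-testing correction is applied by default (raw p-values are
  thresholded at 0.05/0.01, as is conventional for these screens);
  Benjamini–Hochberg is available behind `correct="fdr_bh"`.

## Volatilome chain

Order is enforced by a provenance tag on the table
(`raw → centered/supernormalized → shifts/PCA`):

1. **Censoring**: values < LOD (0.01 mg/kg) are stored at the LOD and
   flagged; values in [LOD, LOQ = 0.03 mg/kg) are flagged semi-quantitative.
   Censored values enter normalization at the floor — no imputation.
2. **Significance screen**: per-compound one-way ANOVA across the
   (treatment, time) cases at α = 0.05; constant compounds are dropped with
   a reason; retention counts are logged.
3. **Mean centering** per compound across the whole dataset (not within
   arm — whole-dataset centering keeps cross-arm comparisons meaningful).
4. **Super-normalization**: the table is split by chemical class
   (organic acids, detrimental aromatics, aldehydes, ketones, alcohols,
   others) and each class is independently re-centered, so low-volatility
   classes are not swamped; unit-variance scaling is an explicit option, off
   by default since only mean centering is part of the named procedure.
5. **Baseline shifts**: per compound, value − baseline mean, with Tukey
   letters across treatments within each time point.
6. **PCA** (SVD on the centered matrix) per class, plus descriptor
   attribution via the two-factor engine.

A helper converts analyte/internal-standard peak-area ratios to mg/kg by
single-point calibration at the spiked standard concentration (default
4 mg/L), assuming unit matrix density.

## Interomics

Taxon and VOC tables are matched on (treatment, time, biological replicate),
averaging VOC technical replicates first; by default only the test-substrate
(HBPA) arm is correlated, with a switch to all arms. Both datasets are
mean-centered first — pure bookkeeping for a rank statistic, kept for
consistency with the normalization convention. All pairs are correlated and
clustered; significance (p < 0.05) is carried as a mask, not a filter.
Row/column clustering uses complete linkage on `1 − Pearson` between
correlation profiles; constant profiles are quarantined with a warning. The
unsupervised cluster count is chosen at the largest *smoothed relative* jump
between successive merge heights (`(hᵢ₊₁+δ)/(hᵢ+δ)`, δ = 5 % of the maximum
height): a plain largest-gap rule always selects the coarsest split, whereas
the relative rule recovers, e.g., two major blocks plus a small third one.
`k_hint` overrides the heuristic.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
its biology:

* **Community.** Each taxon's expected abundance follows
  `baseline · 2^(effect · t/24)` — a log-linear interpolation from baseline
  to the 24 h fold-change target. Endpoint shifts are the only constrained
  quantities; the intermediate-time path is a modeling choice. Replicate
  noise is unit-mean log-normal (CV-parameterized, default 20 %), applied
  before renormalization so abundances stay positive and compositional.
  Dedicated *remainder* taxa (one per major phylum) absorb the compositional
  budget so rows sum to exactly 100 %; at zero noise the configured effects
  are therefore recovered *exactly* by the fold-change analysis (up to the
  detection floor for taxa that drop below it). The default baseline profile
  ships the study's published species panel (≈41 % of the community) with
  remainder bins sized so the baseline Firmicutes/Bacteroidetes ratio is
  1.66. Count tables are multinomial draws at a stated sequencing depth
  (default 50 000 reads) — deterministic rounding when noise is off.
* **qPCR panel.** Per-arm, per-target Log₁₀ shifts at each time point plus
  Gaussian replicate noise (default SD 0.1 Log₁₀), with subgroups capped at
  their row's Eubacteria value. The default scenario reproduces the
  qualitative ordering reported for this assay: the positive control peaks
  at 18 h, the hydrolysate catches up by 24 h, and the blank control falls
  to the dataset minimum at the endpoint. The exact shift values are a
  modeling choice — no replicate-level data are published.
* **VOCs.** Saturating first-order curves `baseline + A(1 − e^(−kt))` per
  (arm, compound), negative `A` for decay (clipped at zero), times unit-mean
  log-normal noise (default 20 % CV), then LOD censoring. Amplitudes are
  sized so *production* — the shift from baseline averaged over the sampled
  post-baseline time points, which is how the cross-arm fold statements are
  framed — matches the reported fold relations (e.g. the positive control
  produces 2.25×/3.37×/4.87× more acetic/propanoic/butanoic acid than the
  hydrolysate, which in turn produces 1.27×/2.08× more pentanoic/hexanoic
  acid); organic-acid baselines use the published absolute quantifications.

All randomness flows from a single seed through named substreams, so a
config reproduces its datasets byte-for-byte.

**What passing tests show — and don't.** Parameter-recovery and calibration
tests demonstrate that the estimators are unbiased (to ±0.1 Log₂ over 100
seeds at 20 % CV), that the screens hold their nominal error rates, and that
the pipeline's plumbing is correct. They do not validate the generator's
kinetic forms against real chromatography or sequencing error, compositional
artifacts of real 16S profiling (primer bias, copy-number variation), or
inter-donor variability — the generator draws all replicates from one
parameterized community.

## Pipeline, QC and reproducibility

The pipeline treats the baseline as a first-class time point (`time_h = 0`)
rather than a separate file, which makes the pooling rules above natural.
The QC report resolves every item to pass/fail/not-evaluable: (i) the
per-case mean F/B ratio at baseline and endpoint must stay at or below the
dysbiosis threshold 2; (ii) archaeal taxa present at baseline must persist
at the endpoint (absence of archaea marks the item not-evaluable, not
failed); (iii) Good's coverage must be stable between baseline and endpoint
(ANOVA p > 0.05 — note this is a null test and fails in ≈5 % of healthy
datasets by construction); (iv) observed-OTU richness is reported. Result
bundles include a manifest with a hash of the analysis config (output
location excluded) and are byte-identical under identical config and seed.

## Problem sizes

Defaults are sized to the study design they emulate: 32 fermentation cases
(4 arms × 4 time points × 2 biological replicates), ~40–150 taxa, ~27 VOCs,
sequencing depth 50 000. Monte-Carlo checks in the test suite use 100 seeds
for effect recovery, 20–30 seeds × 50–100 variables for null calibrations,
and 50 random 8-leaf trees for the UniFrac oracle — small enough to run the
whole suite in under two minutes on one CPU while keeping standard errors
well below the asserted tolerances.

## Known limitations

* "MANOVA" percentages are a partial eta-squared interpretation (above).
* Spearman p-values with ties always use the t approximation, even at n ≤ 9.
* UniFrac requires a user-supplied rooted tree with branch lengths; no tree
  inference is provided.
* The published figure-level magnitudes (absolute qPI values, normalized VOC
  magnitudes, endpoint F/B values) depend on unpublished replicate-level
  data; the synthetic scenario reproduces their orderings and signs, not
  their numbers.
* Compositionally-aware correlation (SparCC-style) and network inference are
  out of scope.
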