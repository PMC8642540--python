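# Methods

This note documents the statistical procedures implemented in `metaboqc`,
the modelling choices behind the synthetic-data generator, and the numerical
conventions that make results reproducible bit for bit.

## Post-processing chain

The chain runs in a fixed order: blank filter → dilution filter → drift
correction → CV filter → redundancy filter → log2.  The order matters in two
places.  Drift correction precedes the CV filter because the pooled-QC CV is
only meaningful once the systematic intensity trend along the injection order
has been removed; and all filters operate on the raw intensity scale because
the 3× blank ratio and the 30% CV convention are defined on raw intensities —
log2 is an explicit, flagged, final step.

**Blank filter.**  A feature is kept iff mean(biological) ≥ 3 × mean(blank).
Missing values are ignored in both means; a blank row that is entirely
missing counts as background 0 (the feature is kept).  Equality passes: only
a strictly smaller biological mean discards.

**Dilution filter.**  Pearson correlation between intensity and the inverse
dilution factor over the pooled-QC dilution series, threshold 0.7.  A feature
with zero variance across the series has undefined correlation and is
discarded — a signal blind to an 8-fold dilution is not quantitative.  The
filter is skipped (with a warning) when fewer than three distinct dilution
points exist, since not every acquisition includes a dilution series.

**Drift correction.**  Per feature, intensity is regressed on injection order
by loess over the reference injections — pooled QCs by default, biological
samples as the alternative for sequences where the pooled QCs track the drift
poorly.  The smoother is a tricube-weighted local polynomial of degree 2 with
span 1.0 (both configurable); with the typical 10–30 reference points a
smaller span would chase noise.  Correction is multiplicative:
intensities are divided by the fitted curve and rescaled so that the median
of the corrected reference samples equals the median of the raw reference
samples exactly.  (Dividing by the curve and multiplying by the raw median
alone preserves that median only approximately under noise; the explicit
rescaling makes the median-preservation property exact without changing the
behaviour on clean data.)  Outside the reference injection range the fit is
held at the nearest fitted value, and the curve is floored at 10⁻⁶ × the
reference median before division.  Features with fewer than 5 observed
reference values are left uncorrected and noted in the report.

**CV filter.**  CV = sd/mean over observed values.  Discard iff pooled-QC
CV > 0.30, or pooled-QC CV > biological CV, or fewer than 3 observed pool
values (too few replicates to judge reliability).

**Redundancy filter.**  Isotopes, adducts and in-source fragments of one
metabolite are collapsed by building a graph with an edge between two
features iff all three criteria hold: biological-profile Pearson r > 0.9,
|ΔRT| < 6 s, and |Δm/z| matching a reference list within 0.005 Da.  The
shipped reference list covers the ¹³C isotope spacing (1.00336 Da), Na/H and
K/H exchange, NH₄⁺, water loss, formic and acetic acid adducts and Cl⁻; it is
a plain editable table.  Connected components form redundancy groups; the
member with the highest median biological intensity survives (tie → lowest
m/z, as the monoisotopic/unmodified ion is conventionally the lightest).

## Quality metrics

All five scores live on a 0–100 scale, computed on the dataset state "drift
corrected but CV filter not yet applied" so that the metrics describe the
data a user will actually analyse while still reporting the unfiltered CV
distribution.

Sample inclusion: blanks are always excluded; the pooled-QC dilution series
is excluded as well because its intensities vary by design and would be read
as drift.  Biological samples and pooled QCs enter all metrics.

*Drift Spearman* tests each feature's intensity against injection order
(Spearman).  P-values use the exact permutation null for n ≤ 8 untied
observations and the t-approximation otherwise; Benjamini–Hochberg at 5% FDR
decides significance.  Features with fewer than 4 observed values are
excluded from the denominator.

*Drift PCA* measures how much of the injection-order direction lies inside
the space of the first three PCA score vectors (features centered and scaled
to unit variance; missing values mean-imputed for the PCA only, never written
back).  cos²α is the least-squares R² of the centered order vector on the
score basis.  Note the finite-sample floor: for a random order direction the
expected cos²α is 3/(n−1), so even drift-free data scores
100·(1 − 3/(n−1)) in expectation — about 94.8 at n = 59 injections.  Scores
should be compared against that null level, not against 100.

*QC spread* computes Mahalanobis distances of the 3-D PCA scores to the
common centroid, with the covariance estimated from all included samples (a
common metric for QCs and samples), and scores the farthest pooled QC against
the farthest biological sample, clamped below at 0.

*QC CV* is the fraction of features (≥ 3 observed pool values) with pooled-QC
CV ≤ 0.30, boundary inclusive; the cumulative %-features-vs-CV curve is
returned alongside.

*QC ICC* bins features by log2 median pooled-QC intensity into 10 equal-width
bins and reports ICC(A,1) — two-way random effects, absolute agreement,
single rater, computed from the ANOVA mean squares
(MS_R − MS_E) / (MS_R + (k−1)MS_E + (k/n)(MS_C − MS_E)) — for the most
populated bin.  Equal-width (not equal-count) binning is what makes "the bin
containing most compounds" a meaningful notion of the most probable
abundance.  Negative ICC estimates (possible with the ANOVA estimator) are
clamped to 0.

*Spiked standards*: per standard, z-scores across biological samples;
|z| > 3 flags a (sample, standard) pair; the per-standard CV summary is
reported with the flags.

## Reference ranges (rr95)

Transformation selection tries identity → log → sqrt → inverse, in order of
interpretability and prevalence, skipping transforms undefined for the data
(log needs positives, sqrt non-negatives, inverse non-zeros), and accepts the
first with Shapiro–Wilk p ≥ 0.05.  If a transform is accepted the range is
mean ± 2 sd on the transformed scale, back-transformed (bounds swap under the
order-reversing inverse; a sqrt lower bound below zero clamps to 0); the
inverse branch raises if the transformed range crosses zero, where the
original-scale range would be unbounded.  Otherwise the bounds are the 2.5th
and 97.5th percentiles with linear (type-7) interpolation, stated explicitly
so bounds reproduce exactly across implementations.  Ranges are computed per
sex by default (a pooled-sex mode exists); cohorts below 120 animals carry a
small-n warning following the CLSI EP28 recommendation.

Screening: a variable is discarded iff the project-cohort mean (per sex,
original scale) falls *strictly* outside the historical range for either sex;
a mean exactly on a bound passes.  The PCA overlay fits centered/scaled PCA
on the historical cohort only, projects the project animals, and tests 2-D
convex-hull membership — a deliberately coarse multivariate sanity check, not
an outlier test with calibrated error rates.

## Synthetic-data generator

The generator emulates a single-batch acquisition: solvent blanks first, the
pooled-QC dilution series, then biological samples bracketed by pooled QCs
every `qc_every` injections (defaults: 42 biological samples, QC every 5,
3 blanks, dilution factors 1/2/4/8).  Feature baselines are lognormal over
roughly four decades (10^3.5–10^7.5), making the ICC intensity binning
meaningful.  Technical noise is multiplicative lognormal with CV 5% on pooled
QCs, blanks and dilutions; biological samples carry 25% between-sample
variation plus genotype/sex fold-changes on 10% of ordinary features.
Pooled-QC levels are the mean of the biological expectations, and the
dilution series scales as 1/factor.

Signal drift multiplies every injection by a per-feature curve
g(order) = exp(±log(1+A)·s(t)/max|s|) with s(t) = t + (b/2)t² + (c/3)t³,
|b| ≤ 0.4, |c| ≤ 0.3, so each curve is smooth and strictly monotone with
random curvature and direction, and max|g−1| equals the configured amplitude
A (default 0.30).  Monotone drift is the regime the Spearman-based metric is
designed to detect, and matches the slow sensitivity decay seen along real
sequences; oscillatory drifts are not simulated.

Planted structure is constructed with deliberate margins so recovery tests
are sharp rather than borderline: blank-dominated features receive blank
background at bio/blank ratio 1.5 (they fail the 3× rule even when ±30%
drift shifts the means), all other features at ratio 20.  Redundancy
satellites copy their representative's profile times a 0.3–0.7 intensity
ratio and a small (1.5% CV) coupling noise, share retention time within
±2.5 s, and sit at a reference-list m/z offset ±0.0004 Da.  Spiked standards
are modelled as pre-extraction internal standards: they scale with the
dilution series, show no drift, and carry slightly larger replicate CV (2×
technical) in the biological samples than in the pooled QC aliquots — which
lets them traverse all five filters like genuine compounds and keeps the
truth-predicted final feature count exact.

Preclinical cohorts default to the scale of a large historical-control
database — 1112 historical animals (573 males / 539 females), 15 project
animals, 200 variables, one third lognormal (sdlog 0.3–0.6) and the rest
normal (relative sd 8–15%) — with each variable's generating family recorded
so transformation selection can be scored.  An optional mean shift on chosen
project variables plants reference-range violations.

What the generator does *not* emulate: missing values and detector
saturation, multi-batch structure, retention-time drift, correlated feature
blocks beyond the planted redundancy groups, heavy-tailed biological
outliers, and oscillatory or step-change drift.  Passing tests therefore
demonstrate the correctness of the procedures under their stated
assumptions, not robustness to every failure mode of real acquisitions.

## Problem sizes used in validation

Routine tests run at the study-default scale (42 biological samples).  The
drift-efficacy check runs the generator at 150 biological samples (~182
injections): the Drift PCA null expectation 100·(1 − 3/(n−1)) is ≈ 98.3
there, so a ≥ 95 score after correction is attributable to the correction
itself rather than to chance projection — at the 42-sample default the null
expectation (≈ 94) sits below that bar for any correction method.  Null
calibrations use 500 features × 60 samples and 400 order permutations;
rr95 coverage uses cohorts of 1000 and transformation recovery ~500 animals
per sex.

## Known limitations

- The loess smoother refits at every evaluation point (no interpolation
  shortcut); adequate for per-batch sequences, not tuned for thousands of
  reference injections.
- The redundancy representative is chosen by intensity, not by annotation
  status; an annotated ion can be discarded in favour of a brighter adduct.
- ICC bins with fewer than 3 features are skipped; datasets with extreme
  abundance skew may report the metric from a thin modal bin.
- The dilution filter assumes intensities linear in 1/dilution; saturating
  detectors violate this and would be over-filtered.
- Reference ranges assume the historical cohort is itself clean; no robust
  or bootstrap refinements are implemented.
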