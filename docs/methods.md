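# Methods

`cementochron` infers life history from annual increments in dental
cementum.  Cementum is deposited continuously through life and is not
remodeled, so a tooth root carries one growth layer group (GLG) per
year: a thick "light" (denser, favorable-season) increment and a thin
"dark" one.  Counting light increments gives an age at death; the
radial widths of successive GLGs track somatic growth rate; and the
spatial texture of the tissue changes when growth truncates at sexual
maturity.  The package implements that chain of inference — image to
increment series to growth model to comparative statistics — plus a
synthetic-image generator that provides ground truth for every stage.

## Image model and preprocessing

Tomographic slices are combined into **virtual thin sections** by
averaging 10 aligned slices (mean, rounded half-up to 8-bit; half-up
rounding is platform-stable).  Averaging attenuates uncorrelated noise
by √10 while annual banding, which is coherent across adjacent slices,
is preserved.

Annotated cementum regions are **straightened** by resampling along
local normals of the inner-boundary polyline (bilinear interpolation;
normals intersected with the outer boundary using exact segment
geometry).  Each straightened column keeps its own radial step in μm,
so widths remain exact where the cementum is locally thicker.  The
interpolation scheme and the reconciliation of unequal inner/outer arc
lengths are our choices; sub-voxel localization downstream makes the
result insensitive to them at the ±0.5 voxel level.

Two bright artifacts bracket every real transect: the hyaline layer at
the cementum-dentine junction and the phase fringe at the outer
cementum-air boundary.  Both would defeat any brightness threshold, so
`trim_boundary_artifacts` crops leading/trailing runs of rows whose
mean exceeds 225/255 before transects are extracted — the operational
equivalent of measuring "between the hyaline layer and the outer
boundary".

Regions containing **cellular voids** (lacunae of cellular cementum,
whose incrementation is unreliable) are detected as connected dark
blobs (< 40 gray, ≥ 6 px) and rejected for width analysis.

## Increment detection

Mean grayscale is taken over eight evenly spaced, 10-pixel-thick radial
transects per section.  Each transect is split into **five segments of
equal sample count** (remainder to the last); a candidate increment is
a maximal run of samples exceeding its segment's mean + 1 SD.  The
segmentation makes the threshold locally adaptive: brightness and band
amplitude both drift with radial depth.

Three choices the rule itself does not fix:

* **Runs near segment boundaries** are judged — and extended — against
  the threshold of the segment containing the run's maximum, so a band
  is not split where segments happen to meet.
* **Sub-voxel position** is the grayscale-weighted centroid of the run;
  unbiased under symmetric noise, and exact for symmetric bands.
* **Degenerate-segment guard**: segments whose SD is below 0.25× the
  whole-profile SD contribute no peaks.  The final year of a
  short-lived specimen is mostly featureless dark tissue; its segment
  mean + SD sits just above the noise floor and would otherwise turn
  noise wiggles into extra "years".  A constant profile reports zero
  peaks with an explicit degenerate flag.

Peaks closer than 2 voxels merge into the higher one.  Widths are
peak-to-peak distances; the interval beyond the last peak (the final,
possibly incomplete year) is never reported as a width.  A specimen's
**life span** is the mode of GLG counts across its (up to 72)
transects, ties resolved upward — under noise, missed peaks are more
common than spurious ones after merging.

Cohorts are filtered to preservational categories a/b and to taxa with
≥ 3 genus-level (or ≥ 5 ordinal-level) specimens.  Pooling averages
widths within specimens first, then across specimens, and reports only
years represented by ≥ 3 individuals.

## Mass-specific growth rates and allometry

Wider-bodied taxa deposit absolutely wider increments.  Widths are
normalized into **msGR** by dividing by the ratio of the
mass-predicted first-year width to that of a 1 g reference, using the
extant-therian calibration

    log10 w1(μm) = 0.270 · exp(0.340 · log10 M(g)) + 0.564.

The normalization strategy is pluggable (`MsgrRatioStrategy`); direct
division by mass is available as an alternative reading of
"mass-specific".  Metabolic rate is estimated from maximum life span
with clade-specific regressions (log10 msSMR = −0.237·log10 L − 0.083
for mammals; −0.83·log10 L − 0.31 for reptiles); dentary length from
lm1 length as 10.184·lm1 + 8.026.  Logs are base-10 throughout.
Dentary-to-mass coefficients are configuration, not constants, because
they belong to external comparative datasets.

## Growth-pattern modeling

Per-year msGR series are fitted to ten curve families (linear,
quadratic, Gaussian, exponential, 4-parameter decreasing Hill sigmoid,
von Bertalanffy, 3-parameter logistic, Gompertz, power, logarithmic) by
bounded least squares with 20 Latin-hypercube multi-starts per family
(tolerance 1e-9, ties by RSS).  AIC is the Gaussian-likelihood form
`n·ln(RSS/n) + 2k`, `k = p + 1`, without small-sample correction —
matching common desktop statistics software; models within ΔAIC < 2
are treated as ties and resolved by r².  Families with more parameters
than points are skipped; non-convergent fits are flagged and excluded
from selection.

Identifiability caveat: over a ≤ 12-year window at realistic noise, a
*monotone* quadratic is statistically confusable with 2-parameter decay
families (power, logarithmic); the family is reliably recovered only
when its interior minimum (decline, then late-life rise) falls inside
the observed window.  The synthetic quadratic benchmark is therefore
parameterized with an interior minimum.

**Growth-rate truncation** (the maturity proxy) is the maximal
contiguous run of years, containing the steepest year-to-year msGR
drop, whose drops are at least θ = 2/3 as steep as the steepest;
`min_age` is the run's first year, `max_age` the year the decline lands
on.  θ = 2/3 is fixed by the rule's worked reference case (series
8, 8, 8, 5, 3, 3 → window years 3–5, i.e. drops −3 and −2 both
qualify).  Monotone non-decreasing series return no window; a strictly
uniform decline returns the full run flagged non-sigmoidal.  Maturity
ranges add the extreme offsets (extant maturity age − truncation onset)
from a calibration table, floored at zero.

## Texture analysis

Grayscale is treated as a height field; 21 standard areal texture
measures (amplitude, spatial, hybrid, functional; formulas in
`texture_measures.md`) are computed per patch.  Juvenile/adult patch
pairs share the shorter radial extent and twice that width (clamped to
the region), excluding the hyaline layer (juvenile side) and the final
year (adult side).  Measures are screened by per-dataset one-way ANOVA
(retained iff p < 0.05 in *every* dataset), z-scored, and ordinated by
SVD-based PCA (correlation-matrix equivalent; component signs fixed by
the largest loading).  Stage separation is judged by convex-hull
overlap in the PC1–PC2 plane: overlap = area(∩)/area(∪), "distinct"
below 0.05 (our threshold — the underlying published comparison is
visual).  Collinear score sets fall back to segment overlap.

The hull-overlap statistic needs enough points: hulls of fewer than
~12 points per stage underestimate their stage's true support and can
be disjoint by chance.  Discrimination benchmarks therefore use 20
specimens per cohort.

## Phylogenetic statistics

PGLS uses the Brownian-motion covariance (shared root-to-tip path
lengths), solved by Cholesky whitening; on a star phylogeny it reduces
exactly to OLS.  r² is computed on the whitened scale.  Nonlinear
phylogenetic regression fits exponential (`a·e^{b·x} + c`) or linear
means with BM or stationary-OU (`exp(−α·d)`) error correlation by
profile maximum likelihood (Nelder-Mead over mean parameters and
log α), compared by AIC; a rejection-ABC comparison (default 500 draws
per model, uniform perturbations around the ML estimates, RMS tip
distance, 5% acceptance) is provided as a secondary check because the
reference procedure's priors and distance kernel are unpublished.
Phylogenetic ANCOVA F-tests nested GLS models (interaction term for
slope homogeneity; group term under a common slope) and reports partial
η².  Pooled two-group comparisons use one-way ANOVA with pooled-SD
Cohen's d and per-group Shapiro-Wilk W (reported, never used as a
gate).  Tip names are matched case-insensitively with spaces and
underscores normalized.

## Synthetic data: what it does and does not emulate

The generator renders straightened cementum with: raised-cosine light
bands (amplitude contrast·127 over a mid-gray base) whose
center-to-center spacings equal the growth schedule's annual widths;
a 0.25 dark:light width ratio; a 3-voxel hyaline layer and phase
fringe; optional elliptical voids at a stated areal density; smooth
per-column band jitter with amplitude 1.5 μm/(1 + anisotropy);
additive Gaussian noise; and an optional post-maturity shift in
contrast/anisotropy/noise.  Cohorts draw life spans from a discrete
uniform on [2, n_years] (death censoring) and individual growth scale
from a lognormal with 10% CV — without that variability, all specimens
would share band geometry in phase, and stage comparisons would detect
the shared layout rather than texture.  Brownian trait simulation draws
multivariate normal tip values with covariance σ²·C from the
shared-path matrix.

Not emulated: tomographic physics (ring artifacts, phase-retrieval
halos beyond the single bright fringe), diagenesis, resorption, angular
drift in deposition, intra-annual sub-banding.  A green synthetic test
establishes that the algorithms recover a stated, idealized signal
model at stated noise — not that any particular fossil measurement is
correct.

Default texture values (contrast 0.5, anisotropy 2, noise SD 8 on
8-bit data) were chosen once as a mid-grade preservation analog; image
quality categories in real data are qualitative, so no empirical noise
calibration exists.

## Numerical choices

* 8-bit conversions round half-up.
* Peak merging radius: 2 voxels.  Bands narrower than ~2 voxels are
  unresolvable by construction.
* PCA drops zero-variance measures and reduces components under rank
  deficiency, with notices.
* Singular phylogenetic covariances (duplicate zero-length tips) raise
  immediately with guidance rather than being jittered.
* All randomness flows from per-call seeds through
  `numpy.random.default_rng`; fixed seeds give byte-identical images
  and CSVs.

## Known limitations

* The consensus count degrades for specimens whose late-life widths
  fall below ~2 voxels — a resolution limit, not a statistical one.
* The truncation rule reports a single window; bimodal declines
  (e.g. a juvenile dip plus a maturity truncation) return only the
  steeper one.
* The ABC comparison is a qualitative cross-check; its acceptance
  quantile and priors are conventions, and posterior shares should not
  be over-read.
* Straightening assumes locally smooth boundaries; hairpin ROI
  geometry can drop columns (warned, and an error above 20%).
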