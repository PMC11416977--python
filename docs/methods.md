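# Methods

## Synthetic cohorts

The generator produces the statistical structure the analysis pipeline
assumes, not anatomically realistic CT.  A phantom is a `grid_shape`
(default 32³, 1 mm isotropic) volume with an i.i.d. Gaussian lung
background (mean −800 HU, SD 30 HU) and an ellipsoidal tumor (semi-axes
8/10/12 mm, mean 40 HU).  The intra-tumor texture is a stationary Gaussian
random field: white noise smoothed with a Gaussian kernel whose width is
the texture correlation length (3 mm default), rescaled analytically (by
the l2 norm of the smoothing kernel) so the marginal voxel SD equals
`texture_contrast` (40 HU default).  This is the simplest field with a
tunable, analytically checkable second-order structure; it has none of the
scanner noise, partial-volume or anatomical heterogeneity of real CT, so
passing tests demonstrate correctness of the pipeline, not clinical
performance.

Infiltration fractions use nested Beta draws — CD3 ~ Beta(4, 6), CD8 =
CD3 · Beta(3, 3), TRM = CD8 · Beta(2, 3) — which enforces TRM ≤ CD8 ≤ CD3
per case by construction and gives flow-cytometry-plausible percentages
(CD3 ≈ 40%, CD8 ≈ 20%, TRM ≈ 8% on average).  No published distributions
exist for these marginals; the Betas are a stand-in choice, not an
inference.  Latent standardized scores use the analytic product-Beta
moments, so standardization does not depend on the realized cohort and
per-case substreams (one `SeedSequence` spawn per case) guarantee that
adding a case never perturbs earlier cases.

Coupling: the tumor mean is shifted by `effect_size ×
texture_contrast × z_CD8` HU and the texture amplitude scaled by
`exp(0.1 · effect_size · z_CD3)`.  `effect_size = 0` is an exact null —
the image stream is independent of the labels.  The immunotherapy cohort
draws a favorable-vs-poor response from a logistic link on z_CD8
(intercept 1.1, slope 1.0, matching a ≈75% favorable rate), splits
favorable into CR/PR and poor into SD/PD at the observed 8:76 and 18:10
ratios, and draws PFS from an exponential proportional-hazards model with
baseline median 10.3 months and log-hazard `survival_link × z_CD8`
(default log 0.218, the strong protective CD8 effect the pipeline is
designed to detect).  Censoring is an independent exponential time
calibrated so the expected censored fraction at z = 0 equals
`censoring_rate` (default 0.02), truncated at a 24-month administrative
horizon; `censoring_rate = 0` disables censoring entirely.

## Feature extraction

Discretization is fixed-bin-width (default 25 HU) anchored at the ROI
minimum, applied per image (each wavelet sub-band is discretized on its
own scale).  The wavelet bank is a single-level undecimated separable
Coiflet-1 transform with symmetric boundary extension; sub-band keys apply
letter-by-letter to the (z, y, x) axes.  Directional families (GLCM,
GLRLM) build one matrix per unique distance-1 3-D direction (13) and
average feature values over directions; GLSZM and GLDM use
26-connectivity; NGTDM averages over in-ROI 26-neighbors (voxels with no
in-ROI neighbor are excluded from the table).  GLDM dependence is the
count of 26-neighbors within `alpha` (default 0) gray levels; the
emphasis formulas use dependence size = count + 1 so the isolated-voxel
(count 0) column is well defined.

Degenerate values are never NaN: on a constant ROI, GLCM Correlation and
MCC are 1, entropies are 0, NGTDM Coarseness is capped at 10⁶, first-order
Skewness/Kurtosis are 0.  These conventions make every downstream matrix
finite.  Shape features are meshed by marching cubes on the one-voxel-
padded, slightly Gaussian-smoothed (σ = 0.8 voxel) binary mask: the
smoothed iso-surface removes voxelization facets, which is what makes a
digitized ball's sphericity come out near 1 (≈0.99 at radius 10 voxels)
instead of the ≈0.91 of a raw binary mesh.  A fallback to the raw
indicator handles masks too small to survive smoothing.

Two known limits of the mask-invariance ideal: wavelet filtering mixes in
a neighborhood of the ROI, so wavelet-band features depend on voxels just
outside the mask (within the filter support of the cropped region) — this
matches how production extractors behave; and CT display windowing is
exposed (`ExtractionConfig.window`) but off by default, since windowing
belongs to the segmentation display context and would silently saturate
first-order statistics if applied to extraction inputs.

## Reliability filtering

ICC(2,1) — two-way random effects, absolute agreement, single measurement
— from the ANOVA mean squares, with the convention that a zero-variance
table scores 1.  The retention rule is strict (ICC > 0.80).  The second
rater is emulated by a boundary jitter of the mask (15% of the outer
shell added, 15% of the inner boundary removed), which perturbs
boundary-sensitive features much more than interior texture, as real
re-segmentation does.

## Modeling choices

Z-scores use the population (1/n) SD so the worked example is exact.
Median ties go to the low group.  Pearson deduplication uses |r| > 0.99
and keeps the earlier feature in manifest order.  RFE uses an L2 logistic
base model and eliminates one feature per round; Relief uses 3 nearest
hits/misses and all cases as anchors.  The SVM scores through a logistic
squash of its decision value; all other classifiers score with the
positive-class probability.  Grid ties break by fewer features, then
canonical selector/classifier order.  The auto-encoder classifier that
some exploration tools list is excluded: it has no reproducible
definition, leaving nine classifiers in the default grid.

The integrated transfer model refits the winning TIME classifier on the
full surgical cohort using the union of the TIME-retained and
response-retained features (intersection and TIME-only are available as
options), normalizes immunotherapy cases with surgical-cohort parameters,
and thresholds at the Youden point of the surgical-cohort scores.  This is
one concrete reading of a one-sentence description of the original
combination rule; the choice is logged in the result object.

An important caveat the null tests surfaced: selecting the argmax
test-set AUC over even a small grid is optimistically biased (a mean
"best" AUC of ≈0.56–0.62 on pure-noise cohorts with 15-case test sets).
Null-calibration checks therefore evaluate one fixed configuration;
leaderboard winners should be read with this selection effect in mind —
it is a property of the explore-and-pick-the-best workflow itself.

## Statistics

AUC is the Mann–Whitney concordance with half credit for ties; variance
and the paired two-model comparison use DeLong placement values, with a
degenerate (zero-variance) difference reported as p = 1 with a warning.
The optimal cutoff maximizes sensitivity + specificity over midpoint
thresholds, ties to the lowest.  Contingency tests use Pearson chi-square
without continuity correction, falling back to Fisher's exact test when
any expected cell count is below 5.  Kaplan–Meier estimation and the
log-rank/Breslow (Wilcoxon, at-risk-weighted) tests are delegated to
lifelines; "mean progression time ± x" is reported as the restricted mean
survival time (area under the KM curve to the largest observed time) with
the standard KM-mean standard error, computed directly from the step
function.  The Cox model is an in-package Newton–Raphson maximization of
the Breslow partial likelihood (gradient tolerance 1e-8, centered
covariates, monotone-likelihood guard), cross-checked against lifelines
on tie-free data; ties are rare under the continuous-time generator.

## Validation problem sizes

The test-suite and acceptance-script simulations are sized for a
single-CPU desk run: texture oracle fuzzing uses grids up to 5³ against
plain-loop enumeration (1e-9 relative tolerance); type-I-error
calibration uses 500 replicates at n = 100; the planted-effect
end-to-end check uses one 120-case cohort at full 851-feature extraction;
null checks use ten 100-case cohorts with a reduced 3-image feature set
(chance behavior does not depend on feature count); hazard-ratio recovery
uses twenty 400-case cohorts fit on the latent covariate.  Determinism is
checked by byte-comparing two complete study reports from the same
configuration.
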