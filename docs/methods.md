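# Methods

## The mismatch model

The pipeline quantifies, per region of interest (ROI), how far each
participant's neuronal metabolism deviates from what their local tau burden
predicts.  For ROI *j* the cohort-level coupling is

    FDG_ij = α_j + β_j · log(tau_ij) + ε_ij ,

with FDG and tau in SUVR units.  Tau is log-transformed because regional
tau SUVR is right-skewed; the natural logarithm is used (the base only
rescales β_j and leaves residuals unchanged).  The fit is an M-estimate
with Tukey's bisquare ψ (tuning constant 4.685, ~95% Gaussian efficiency),
scale estimated by normalized median absolute deviation, at most 50 IRLS
iterations with coefficient tolerance 1e-8 (statsmodels RLM).  Gross
outliers therefore receive zero weight and cannot drag the line.  A
constant predictor or fewer than 10 complete pairs is a degenerate fit and
is refused.

The mismatch residual r_ij = FDG_ij − (α_j + β_j log tau_ij) is positive
when metabolism exceeds the tau-predicted level (resilience direction) and
negative otherwise (susceptibility direction).

## Discretization

Residuals are coded per ROI: +1 if r_ij > 0.6·SD_j, −1 if r_ij < −0.6·SD_j,
else 0.  Two choices are deliberate:

- **SD_j is the ordinary sample SD** of the robust-fit residuals, not the
  robust MAD scale.  Under a Gaussian residual law the rule flags
  P(Z > 0.6) ≈ 27.4% of points on each side — the "farthest quarter"
  reading of the cutpoint — whereas the MAD scale would flag ~42%.  The
  robust scale is retained on every `RoiFit` for sensitivity analyses.
- **Strict inequality at the boundary**: a residual exactly at 0.6 SD
  codes 0.

Missing residuals (a participant missing either modality at an ROI) code 0:
a neutral value that fabricates no direction.  The count is reported.

## Clustering and model-order selection

Participants are clustered on the code vectors with Ward's minimum-variance
criterion (squared-Euclidean Lance–Williams form, scipy linkage).  The test
suite verifies the merge sequence against an exhaustive greedy
minimum-variance oracle on small fixtures.  Two model-order criteria are
computed over k ∈ [2, 10]:

- silhouette: k maximizing the mean silhouette width (Euclidean metric);
- elbow: k maximizing the second difference
  WSS(k−1) − 2·WSS(k) + WSS(k+1) of the within-cluster sum of squares.
  The elbow criterion is named in the literature without a formula; the
  maximum-curvature second difference is this package's formalization.
  Note it is dominated by the large WSS drop at small k whenever a coarse
  partition exists, so it tends to suggest smaller k than silhouette; the
  pipeline uses the silhouette choice and reports both curves.

Ties in either criterion resolve to the smallest k.  Degenerate input (all
rows identical) refuses selection.

Archetype naming operates on the **continuous** residuals (clustering on
the discretized codes, labeling on the residual magnitudes): the cluster
with the smallest mean |residual| across ROIs is *canonical*; every other
cluster is *resilient* (mean residual > 0) or *susceptible*, qualified
*limbic* or *cortical* by whichever region class carries the larger mean
magnitude; two cortical clusters sharing a direction split into *high* and
*low* by magnitude rank.  The high/low distinction is a formalization of
what is likely a continuum; it is deterministic but not canonical.

## Stability validation

Ten folds each draw 52% of the cohort without replacement (mirroring a
150-of-289 design), re-run regression → discretization → Ward clustering at
the reference k, and are matched to the reference clusters by
maximum-agreement one-to-one assignment (Hungarian algorithm on the
contingency table; rectangular when a fold loses a cluster).  Regressions
are refit inside each fold — the validation exercises the whole procedure,
not just the clustering.  A participant's majority-vote identity across the
folds that sampled them is compared with their reference identity;
majority ties break toward the reference identity (logged), and
participants never sampled are excluded from the denominator.  Mismatches
are classified as same-direction (e.g. high → low cortical resilient) or
cross-direction shifts.

## Copathology markers

- Cingulate island ratio: FDG_PCC / mean(FDG_precuneus, FDG_cuneus).
- I/MTL/FSO ratio: FDG_IT / mean(FDG_MTL, FDG_FSO), where MTL is the mean
  of entorhinal, parahippocampal, hippocampus and amygdala ROIs and FSO
  the mean of the frontal supraorbital ROIs.
- MTL asymmetry: |L − R| / (L + R) on the left/right MTL composites.

The ratio denominators are arithmetic means of their constituents; "ratio
of X/Y/Z" leaves the composition ambiguous, so the mean form is declared,
configurable to a sum, and recorded in the output metadata.  Bilateral
regions are averaged across hemispheres before ratio computation.  Amyloid
status is A+ iff florbetapir composite ≥ 1.11 or florbetaben composite
≥ 1.08 (boundaries inclusive); CSF Aβ42 < 980 pg/ml (strict) is used only
when no PET composite exists.

## Group statistics

Cross-sectional comparisons are likelihood-ratio tests between nested
linear models (outcome ~ group + covariates vs. outcome ~ covariates, both
ML; χ² with #groups − 1 df).  Default covariates: sex, age, education,
A status, inferior temporal tau SUVR.  Pairwise comparisons against the
canonical group refit on the two-group subset (a declared choice; contrasts
within the full model are the alternative) and are Benjamini–Hochberg
adjusted at FDR 0.05.  Frequency tables use Pearson χ² without continuity
correction.

Longitudinal trajectories use a random-intercept linear mixed model fit by
maximum likelihood (not REML, so nested comparisons stay coherent): fixed
effects are baseline score, time from scan, cluster, cluster × time, plus
covariates; the score at the first visit is the baseline covariate and
later visits are outcomes.  Each cluster's annual slope is the time
coefficient plus its interaction coefficient (identically zero for the
reference cluster by treatment coding); decline-rate differences are judged
by Wald tests of the interaction coefficients, BH-adjusted.

## The synthetic cohort generator

The generator emulates the *statistical structure* the analysis assumes,
not any particular cohort:

- 104 gray-matter ROIs as 52 bilateral pairs with limbic / cortical /
  subcortical classes and composite tags for the marker formulas.
- Per-ROI coupling: α_j ∈ [1.15, 1.45], β_j ∈ [−0.55, −0.25] (every ROI
  loses metabolism with tau), log tau ~ Normal with higher mean in limbic
  regions (earlier tau accumulation), measurement noise σ_j = 0.015 FDG
  SUVR.
- Six archetypes with **regionally patterned residual offsets** (FDG-SUVR
  units): canonical 0 everywhere; high cortical resilient +0.20 on
  anterior neocortex; low cortical resilient +0.15 on posterior neocortex;
  limbic resilient +0.20 on limbic ROIs and +0.15 on temporal neocortex;
  cortical susceptible −0.18 on anterior neocortex; limbic susceptible
  −0.15 on limbic ROIs and −0.20 on posterior neocortex.  Mixing weights
  0.28/0.21/0.17/0.08/0.16/0.10 keep canonical largest and limbic
  resilient rarest.
- Copathology signatures as targeted extra offsets: +0.08 posterior
  cingulate sparing in cortical susceptible (cingulate island), −0.06 on
  left MTL (asymmetry) and −0.08 on FSO regions (I/MTL/FSO) in limbic
  susceptible.
- Covariates drawn independently of archetype (age ~ N(74, 8²), education
  ~ N(16, 2.6²), sex Bernoulli(0.5)); amyloid composites bimodal around
  the tracer cutoffs (florbetapir 80%, florbetaben 15%, CSF-only 5%).
- Longitudinal scores: score_it = b_i + slope_a(i)·t + e_it over visits
  {0, 0.5, 1, 1.5, 2} years, b_i ~ N(16, 6²), e_it ~ N(0, 1.2²); slopes
  (points/year) canonical +0.8, high cortical resilient −0.07, low
  cortical and limbic resilient +0.6, cortical susceptible +2.4, limbic
  susceptible +3.9.

Two generator design choices deserve emphasis.  First, the archetype
offsets are *patterned* (each archetype occupies a distinct regional
support) rather than uniform within a region class.  Uniform class-wide
offsets place all six group centroids along a single resilient–susceptible
axis; on such one-dimensional geometry mean silhouette width is maximized
at k = 2 regardless of noise level, and a uniform +0.10 offset sits exactly
at the 0.6 SD cutpoint, making that group's codes irreducibly ambiguous.
Near-orthogonal supports, with positive and negative patterns weighted so
each ROI's offset mixture is near zero mean (keeping the canonical group on
the regression line), make the six groups mutually distinguishable — which
is also the more faithful emulation of group-specific regional residual
topographies.  Second, the measurement noise (0.015 SUVR) is deliberately
small relative to the planted between-archetype heterogeneity, which then
dominates the total per-ROI residual SD (~0.08–0.13, a realistic FDG
residual scale); these two choices together were calibrated once, before
the test suite was frozen, so that the planted partition is recoverable but
the clustering problem is not trivial (clusters still overlap through
stray codes near the cutpoints).

What the generator does **not** emulate: spatial correlation between
neighboring ROIs, covariate–archetype confounding (hooks exist but default
off), tau–archetype dependence, scanner or site effects, missing data, and
visit-schedule irregularity.  Passing tests therefore demonstrate that the
pipeline recovers structure of this planted form — they do not certify
behavior under real-data nuisances such as atlas misregistration or
partial-volume effects.

## Numerical and reproducibility choices

- All randomness flows from explicit seeds through `numpy` Generators;
  identical configuration + seed reproduces byte-identical CSVs.
- Ward/fcluster labels are relabeled by first occurrence, PCA component
  signs are fixed by making each component's largest-magnitude loading
  positive, and assignment/argmax ties break toward smallest indices, so
  every stage is deterministic given row order.
- Mixed models that fail to converge are reported with a warning rather
  than silently accepted; degenerate regressions abort with the offending
  ROI list.
- Pipeline outputs carry the configuration hash in a `#` header comment.

## Known limitations

- The archetype taxonomy assumes exactly one canonical cluster and at most
  two same-direction cortical clusters; more exotic solutions get numeric
  name suffixes.
- The elbow formalization is crude (see above); silhouette is the
  operative criterion.
- Cross-sectional pairwise tests refit per pair, so their covariate
  estimates differ slightly from the omnibus model's.
- The stability protocol subsamples participants only; ROI subsampling is
  out of scope.
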