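# tnmismatch

Residual-based subtyping of the mismatch between tau pathology (T) and
neuronal metabolism (N_M) in aging and Alzheimer's disease cohorts.

Tau tangle burden normally predicts local hypometabolism, but individuals
deviate: some retain more metabolism than their tau burden predicts
(*resilient*), others less (*susceptible*), and the regional pattern of
those deviations carries information about mixed pathologies and prognosis.
`tnmismatch` implements the full analysis as a tested pipeline:

1. **Mismatch residuals** — for each ROI *j*, a robust regression across
   participants, FDG_ij = α_j + β_j · log(tau_ij) + ε_ij, fit by
   iteratively reweighted least squares with Tukey bisquare weights
   (c = 4.685, MAD scale).  The residual r_ij = FDG_ij − (α_j + β_j ·
   log tau_ij), in FDG-SUVR units, is the T/N_M mismatch.
2. **Discretization** — r_ij is coded +1 / −1 if it lies more than
   0.6 residual-SDs above / below the regression line, else 0 (for
   Gaussian residuals this flags the farthest ~27% of points on each side).
3. **Clustering** — Ward minimum-variance agglomeration of the code
   vectors; the number of clusters is chosen by mean silhouette width and
   by the elbow (maximum second difference) of the within-cluster sum of
   squares over k ∈ [2, 10].  Clusters are named from their continuous
   residual profiles: *canonical* (smallest mean |residual|), then
   limbic/cortical × resilient/susceptible, with high/low qualifying two
   cortical clusters of the same direction.
4. **Stability** — the entire procedure (regression, discretization,
   clustering) is re-run on random subsamples (default: 10 folds of 52%),
   fold clusters are matched to the reference solution by
   maximum-agreement assignment, and each participant's majority-vote
   identity is compared with their reference identity.
5. **Copathology markers** — cingulate island ratio
   (PCC / mean(precuneus, cuneus) FDG), I/MTL/FSO ratio
   (inferior temporal / mean(MTL, FSO composites) FDG), MTL asymmetry
   |L−R|/(L+R), and amyloid status (florbetapir ≥ 1.11 or
   florbetaben ≥ 1.08 composite SUVR; CSF Aβ42 < 980 pg/ml fallback).
6. **Group statistics** — covariate-adjusted likelihood-ratio tests with
   Benjamini–Hochberg control (FDR 0.05), χ² frequency tests, and
   random-intercept linear mixed models whose per-group annual slope is
   the time coefficient plus the group × time interaction.

A seeded synthetic cohort generator (`tnmismatch.simulate`) produces data
with this exact structure — 104 bilateral gray-matter ROIs, six planted
participant archetypes with regional residual offsets, covariates, bimodal
amyloid composites and longitudinal ADAS-Cog-like scores — so every stage
is testable without access to any imaging archive.

## Worked example

The `analysis/` scripts run the study end to end on a generated cohort
(n = 300, seed 42):

```bash
python analysis/01_generate_cohort.py
python analysis/02_fit_mismatch.py
python analysis/03_cluster_and_validate.py
python analysis/04_derived_markers.py
python analysis/05_group_statistics.py
```

Key output (abridged):

```
silhouette selects k=6; elbow curvature suggests k=2
recovered groups:
canonical                  90
high_cortical_resilient    63
cortical_susceptible       53
low_cortical_resilient     44
limbic_susceptible         26
limbic_resilient           24
adjusted Rand index vs planted archetypes: 1.000
10-fold 52%-subsample stability: 100.0% majority-identity match
...
annual decline slopes (ADAS-Cog-like points/year):
                         slope  slope_se  p_adjusted
canonical                0.813     0.108         NaN
cortical_susceptible     2.008     0.141       0.000
high_cortical_resilient -0.086     0.129       0.000
limbic_resilient         0.610     0.210       0.391
limbic_susceptible       3.639     0.202       0.000
low_cortical_resilient   0.443     0.155       0.063
groups with decline differing from canonical (BH-adjusted):
['cortical_susceptible', 'high_cortical_resilient', 'limbic_susceptible']
```

Silhouette analysis recovers the six planted archetypes exactly (ARI 1.0);
cluster identities are stable under 52% subsampling; the susceptible
groups decline fastest, the high cortical resilient group is flat, and the
copathology markers are elevated precisely in the groups that plant them
(cingulate island ratio in cortical susceptible, I/MTL/FSO ratio and MTL
asymmetry in limbic susceptible).

The same pipeline runs on real data from CSV tables (see the schemas in
`tnmismatch.io`) via the `tnm` command line tool:

```bash
tnm generate --n 300 --seed 7 --outdir cohort   # or bring your own CSVs
tnm run --indir cohort --outdir results/run
tnm demo --n 200 --seed 7                        # generate + run in one step
```

## Layout

- `src/tnmismatch/` — library: `rois`, `simulate`, `mismatch`, `cluster`,
  `stability`, `markers`, `stats`, `io`, `pipeline`, `cli`
- `analysis/` — numbered narrative drivers reproducing the study flow
- `tests/` — unit, property and end-to-end acceptance tests
- `docs/methods.md` — modeling assumptions, parameter choices, limitations
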