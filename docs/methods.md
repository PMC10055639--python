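# Methods note

This note records the statistical model, the main parameter choices with
their rationale, what the synthetic-data generator does and does not
emulate, and the numerical decisions that affect results.

## Statistical model

### Edgewise group contrast

For each unique region pair (i, j), the Fisher-z connectivity of scan s
from rat k is modeled as

    z_s = β0 + β1·sex_k + b_k + ε_s,   b_k ~ N(0, σ_b²),  ε_s ~ N(0, σ_e²)

a linear mixed model with a rat-level random intercept, which accounts
for repeated scans of the same animal. The fit is restricted maximum
likelihood (REML), profiled down to a one-dimensional bounded search over
the variance ratio λ = σ_b²/σ_e². Because every rat's covariance block is
equicorrelated, V⁻¹ is applied through per-rat group sums, making one fit
cost about a millisecond; the full 2016-edge contrast runs in seconds.
The implementation is verified in the test suite against
`statsmodels.MixedLM` (exact REML agreement) — the fast path is a
performance re-derivation, not an approximation.

Degrees of freedom use the **between-within rule**: the sex effect varies
between animals, so df = n_rats − 2. In balanced designs this equals the
Satterthwaite value; when the REML solution sits at the λ = 0 boundary
the test collapses to ordinary least squares with df = n_scans − 2.
Calibration was measured on null cohorts before any thresholds were
frozen: empirical type-I error at p < 0.05 was 0.047–0.053 across master
seeds (n = 10 000 each), inside the exact binomial 99 % envelope.

A constant response (possible for integer-valued nodal degrees) makes
the t statistic undefined; such tests return NaN and are excluded from
the FDR family rather than counted as evidence.

Multiplicity is controlled by Benjamini–Hochberg FDR over the unique
edges (or regions/nodes, per analysis), step-up with the cumulative
minimum so q ≥ p always holds.

### Per-region classification

Scans are classified by sex from one region's connectivity profile (its
matrix row, diagonal excluded) with an RBF-kernel SVM (C = 1). The kernel
width uses the median heuristic γ = 1/(2·median‖x−x′‖²) computed on the
training fold only; features are standardized with training-fold
statistics only. Accuracy is stratified k-fold cross-validation averaged
over repeats; significance is a label-permutation null in which the full
repeated-CV procedure is rerun per permutation, with the add-one
estimator p = (1 + #{null ≥ observed})/(n_perm + 1).

Default folds split **scans**, so two scans of one rat can straddle a
split — this mirrors the common field practice whose optimism the rat-
grouped splitter (`group_by_rat`) quantifies; the test suite demonstrates
the leakage directionally on a cohort with rat-specific but sex-free
signatures.

### Network topology

Matrices are binarized by keeping the strongest signed-z edges at fixed
densities 0.10–0.30 (step 0.05); ties break lexicographically by edge
index so edge sets are deterministic and nested across densities. Metrics:
global efficiency (mean inverse shortest path, unreachable pairs
contribute zero), characteristic path length over reachable pairs, mean
clustering coefficient, Newman modularity maximized by seeded Louvain
(best of 10 restarts), degree assortativity (undefined — NaN with reason —
for regular graphs), and small-worldness σ = (C/C_r)/(L/L_r) with both
null terms averaged over the **same** set of degree-preserving rewired
graphs (10·m attempted swaps each). Group contrasts reuse the edgewise
mixed model per density; nodal degree is FDR-corrected within density.

### Ward clustering

Connectivity profiles are clustered by Ward linkage on Euclidean
distances between matrix rows with the self-connection **zeroed** (not
deleted). Zeroing keeps profile coordinates aligned across regions, so
relabeling regions permutes the partition exactly — deleting the diagonal
entry would misalign coordinates between rows and break that invariance.
The dendrogram is cut at a requested k (default 7); no height rule is
inferred.

## Parameters (units, defaults, rationale)

| parameter | default | rationale |
|---|---|---|
| head radius r | 5 mm | rat head scale for converting radians to arc displacement |
| FD threshold | 0.2 mm | awake-rodent scrubbing convention; neighbors also removed |
| initial discard | 10 volumes | T1 steady-state approach |
| max removed fraction | 0.15 | scans losing more are unusable |
| ICA components | 50 | enough to isolate structured physiological noise at this resolution |
| smoothing FWHM | 1 mm | ≈2 voxels at 0.5 mm isotropic; σ = FWHM/(2√(2 ln 2))/voxel size |
| bandpass | 0.01–0.1 Hz | resting-state band; order-4 Butterworth, zero-phase (`sosfiltfilt`) |
| TR | 1 s | acquisition rate assumed by the filter design |
| CV | 10-fold × 5 repeats | accuracy variance reduction at cohort sizes of tens of scans |
| permutations | 1000 | p floor ≈ 0.001, adequate for 64-region FDR |
| densities | 0.10–0.30 / 0.05 | sparse-to-moderate graphs where binary metrics are informative |
| dendrogram k | 7 | required parameter; no automatic height cut |

## The synthetic generator

### What it emulates

- **Population structure**: regions belong to systems (the planted
  clusters); within-system baseline correlation r = 0.35; sex effects of
  ±0.3 on the z scale planted on known edges (male-elevated between two
  systems, female-elevated within one system). The planted correlation
  matrix is repaired to positive definite by eigenvalue clipping plus
  diagonal rescaling.
- **Dynamics**: latent region series are AR(1) (φ = 0.3) with the planted
  stationary covariance via its Cholesky factor.
- **Nuisance**: spatially smooth noise components with AR(1)
  timecourses, loaded weakly on brain voxels and strongly on the WM/CSF
  slabs, so mask-based and ICA-based cleanup have something real to find.
- **Motion**: a random-walk drift (steps 0.005 mm translation, 0.001 rad
  rotation) plus persistent step displacements of 0.5 mm at recorded
  volumes, so FD exceeds the 0.2 mm threshold exactly at the logged spike
  volumes — scrubbing is testable against ground truth.
- **Anatomy**: a 32×32×8 grid (0.5 mm voxels) with 64 mirrored L/R
  parcels, homotopic pairs sharing a system, and disjoint WM/CSF slabs. A
  split-atlas variant halves each parcel to emulate a 128-parcel
  unilateral parcellation through the identical code path.
- Two access levels: the **voxel path** (full 4-D scans for pipeline
  testing) and a **latent path** drawing per-scan z matrices directly
  (population + rat offset sd 0.1 + edge noise sd 0.045 ≈ 1/√(T−3)),
  which makes statistical calibration experiments cheap.

### What it does not emulate

- No scanner artifacts beyond the modeled components: no spin-history
  effects of motion on intensity, no slice timing, no distortion, no
  hardware drift; motion corrupts the motion *log*, not the images.
- Smoothing at 1 mm FWHM leaks signal between **adjacent** parcels on
  this grid, inflating neighbor correlations relative to the planted
  matrix; recovery checks therefore correlate patterns rather than
  demand exact equality.
- Estrus labels are assigned at random to female scans; no hormonal
  effect is planted, so the estrus contrast is a true-null exercise by
  construction.
- Amplitudes are arbitrary units; no physiologic BOLD amplitude model.

### The generator is a fixed study design

Generator parameters (effect size 0.3, rat sd 0.1, baseline 0.35, motion
scales) define the simulated study conditions. They were chosen from the
study design being modeled and frozen before validation outcomes were
inspected; validation thresholds were never adjusted by re-tuning the
generator.

## Numerical decisions

- Fisher z = arctanh(r); |r| = 1 raises instead of clipping — a perfectly
  correlated pair is an upstream error, and clipping would silently cap
  test statistics. Planted generator correlations with |r| ≥ 0.995 are
  rejected as outside the usable range.
- FastICA component signs follow the positive-skew convention and
  components are energy-ordered, making decompositions reproducible.
- Noise-component labeling, when no manual label file is supplied, is a
  heuristic: |correlation with FD| > 0.3 or majority loading outside the
  brain mask. The generator emits ground-truth nuisance timecourses
  (not component indices, which FastICA does not preserve a priori).
- Bandpass gain contracts are asserted in the steady-state center of the
  filtered window because zero-phase filtering has edge transients.
- `small_worldness` uses one shared null-graph set for both C_r and L_r;
  separate draws would add avoidable variance to σ.
- All seeds derive from one master seed via 4-byte BLAKE2 substream
  hashes (< 2³¹), named per stage and scan, so stages are reproducible in
  isolation and no two streams collide by construction of their names.

## Problem sizes used in validation

Calibration: 12 rats/sex × 2 scans, 200 edges × 50 replicates (10 000
null tests). Power: 20 rats/sex × 2 scans, 64 regions, 10 seeds.
Classifier null: 50 single-region simulations, 99 permutations each.
End-to-end: 3 rats/sex × 2 scans, 300 volumes, 32×32×8 voxel grid, run
twice and compared byte-for-byte. These sizes were chosen to make the
statistical assertions sharp within a desk-scale compute budget.
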