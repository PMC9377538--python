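# Methods

This note documents the models, defaults and design choices behind
`wmfnet`, and what its simulation-based validation does and does not
show.

## Synthetic cohort model

The generator (`wmfnet.cohort`) produces a two-group resting-state fMRI
cohort on a small 3-D grid with a nested ellipsoidal tissue geometry: a
central CSF ventricle, a deep white-matter core, a superficial
white-matter shell, a gray-matter cortex and outer CSF.  Soft tissue
probability maps come from smoothing the hard compartments (sigma 0.7
voxels) plus per-subject jitter (SD 0.04), so subject-level maximum-
probability labels disagree near boundaries and the > 60 % group-mask
rule has something to decide.

**Networks.** White matter is partitioned into `k_true` contiguous
networks: the deep core is one network (mirroring the "deep network"
typically found last in white-matter parcellations, ~45 % of WM voxels),
and the shell is divided into `k_true − 1` parcels grown by randomised
multi-source Dijkstra expansion from farthest-point seeds
(6-connectivity), which yields irregular but compact, contiguous
parcels.  Gray matter is partitioned the same way into
`n_gm_networks = 8` parcels.

**Signals.** Each network has a band-limited (0.01–0.1 Hz) unit-variance
latent time course; latents across the `k + g` networks are mixed by the
Cholesky factor of a joint correlation matrix: weak white-matter
inter-network coupling (0.15 ± seeded jitter; 0.10 for the deep core),
weak gray–gray coupling (0.10), and a 0.70 coupling between each shell
white-matter network and a gray-matter partner — so white/gray-matter
correspondence is strong for superficial networks and absent for the
deep core, as reported for real white-matter parcellations.  The group-1
covariance adds `effect_z` (default 0.3, a free simulation parameter — no
effect size is available to copy) to a configurable set of edges in the
Fisher-z domain, with projection back to the nearest unit-diagonal PSD
matrix; with `effect_z = 0` the groups are exactly exchangeable.

**Within-network heterogeneity.** A voxel's series is its network latent
plus a *heterogeneity* term: 16 smooth spatial random fields (Gaussian
kernel, sigma 2 voxels) with independent band-limited time courses,
weighted 0.45 on the shell and 0.8 in the deep core (deep white matter
has lower BOLD coherence), plus white noise (`noise_sd = 0.2`).  The
field loadings are whitened *per network* so each network's internal
profile cloud is isotropic.  This term is what makes stability selection
behave like real data: without it, partitions at K above the planted
number differ between node folds only on the one cluster that splits,
and the pair-counting Dice stays above 0.95 for every K — the
largest-K-above-threshold rule would then always return the top of the
scanned range.  With isotropic continuum structure inside each network,
a clustering forced to split a network has no preferred seam; the split
direction is decided by fold-specific node sampling, and Dice collapses
(empirically from ~1.0 at the planted K to 0.6–0.8 immediately above it)
while remaining ~1.0 at the planted K.

**Motion and clinical scores.** Motion is a 6-parameter random walk
(translation step SD 0.02 mm, rotation 0.00015 rad at scale 1).  The
patient-like group's scale is 1.375× the control scale, and every
subject's scale is further multiplied by lognormal(0, 0.35) noise, giving
mean-FD distributions that differ in mean but overlap within groups
(coefficient of variation ≈ 0.36, as in the emulated study summary
table).  The overlap matters: a near-deterministic group difference in
mean FD would make the motion covariate collinear with the group factor
and absorb genuine FC effects.  BOLD data carry no motion artifact (no
MRI physics is simulated); nuisance regression is validated with
injected structured regressors instead.  Clinical scores are normal
draws with group means/SDs from the emulated study (e.g. MMSE
27.06 ± 1.84 vs 29.17 ± 0.92), truncated to instrument ranges; sex is
Bernoulli with the study's group ratios; disease duration exists only in
the patient-like group.

What the generator does **not** emulate: scanner drift and physiological
noise spectra, spatial autocorrelation of thermal noise, motion-induced
signal artifacts, susceptibility dropout, and anatomical variability
beyond boundary jitter.  Passing tests therefore demonstrate the
correctness and calibration of the *analysis* under the stated
statistical model, not robustness to every real-world artifact.

## Preprocessing

Fixed order: drop the first 10 volumes → motion summaries and FD spikes →
nuisance regression → band-pass → within-mask smoothing.  FD follows the
summed-absolute-differences convention with rotations converted on a
50 mm sphere (the radius is a parameter; the convention's usual choice is
the default).  Relative RMS motion is the frame-to-frame RMS over the
three translation axes only.  FD spikes (> 1, threshold configurable) are
entered as one-hot regressors; spike detection uses motion *after*
volume dropping.  The nuisance design is intercept, linear trend, 24
motion regressors (6 parameters, their backward differences, both sets
squared), and the mean CSF signal; white-matter and global means are
deliberately excluded.  Rank-deficient designs are repaired by
pivoted-QR column pruning with a warning rather than failing (spike
columns can collide with trend columns on short series).  The band-pass
is an ideal rectangular FFT filter after linear detrending (zero-phase
by construction); smoothing uses normalised convolution (mask-smoothed
denominator) so no signal leaks across compartment boundaries.  Subjects
whose trace exceeds 2 mm translation or 2° rotation are excluded at the
cohort level.

## Clustering and stability

The interchanging grid keeps in-mask voxels with even (x, y) on even
z-slices and odd (x, y) on odd slices (~1 in 4).  Correlation profiles
use exact Pearson via row standardisation; numerically constant voxel
series are flagged, zeroed, excluded from clustering (label 0) and
skipped in network averaging.  Profiles are averaged per group and then
across the two group means, so unequal group sizes do not bias the
average toward the larger group.

Correlation-distance k-means standardises rows to zero mean and unit
norm, making squared Euclidean distance an affine image of 1 − r, and
runs a well-tested Euclidean optimiser (scikit-learn KMeans, best of 10
replicates by inertia).  Labels are canonicalised by descending cluster
size (ties by smallest member index).  Stability analysis partitions
node columns into 4 near-equal seeded random folds (a fold count whose
pair-count 6 keeps the Dice average stable); every fold is clustered at
every K with the same replicate setting; agreement is the Dice
coefficient of co-assignment pair sets, computed from the label
contingency table (the V×V adjacency relations are never materialised).
The selected K is the largest with mean Dice strictly above 0.85; when
nothing qualifies the result is an explicit "no stable K", never a
fallback.  Layers are assigned by ranking networks on mean Euclidean
distance to gray matter and cutting ranks into ⌈K/3⌉/⌈K/3⌉/rest
(distance ties share the more superficial layer); an explicit layer map
can override the tertile rule, since published splits (e.g. 9/3/1 for 13
networks) are not tertiles.

## Group inference

Edges are tested with OLS `z ~ intercept + group + covariates`
(categorical covariates 0/1-coded); with no covariates the statistic
reduces exactly to the pooled two-sample t.  The default permutation
scheme is Freedman–Lane (covariates regressed out once, residual rows
permuted, nuisance fit added back), preserving nuisance structure; raw
label permutation is available, including exact enumeration of all
distinct group assignments for small samples.  p-values use the add-one
estimator and never return 0.

NBS: an edge is suprathreshold when its permutation p is below the
primary threshold (default 0.05, the only level the emulated analysis
states) — equivalently, when its |t| exceeds the per-edge null quantile,
applied identically to observed and permuted statistics.  Suprathreshold
edges are split by effect sign under two-sided testing (so decreases are
reported, not discarded), connected components are found by union-find,
and each observed component's edge count is referred to the permutation
distribution of the maximal component size.  Calibration: over repeated
null cohorts the fraction with any significant component sits at or
below the nominal 0.05 (empirically ≈ 0.03–0.06 over 200 cohorts).  A
caveat inherent to size-based NBS: at a liberal primary threshold the
null maximal component is often 2–3 edges on a 13-node graph, so small,
concentrated effects — however strong — are not size-rare; detecting
them requires a stricter primary threshold (the parameter is exposed),
while spatially extended effects are what p < 0.05 is sensitive to.

Demographics utilities reproduce summary-statistic tests: pooled-variance
two-sample t from printed means/SDs and the 2×2 Pearson chi-square
(continuity correction optional).

## Clinical association

Partial correlation residualises both variables on the covariates plus
intercept and applies the t-approximation with df = n − q − 2.  Only
edges in NBS-significant components are tested by default (an all-edges
mode exists); FDR is Benjamini–Hochberg, pooled across all tested
(edge, score) pairs (per-score families are a configuration choice).

## Validation scale and determinism

The acceptance script exercises the pipeline at desk scale chosen to
keep a full run within minutes on one CPU: 200 null cohorts × 1,000
permutations for the NBS error rate, and one 34-subject cohort on a
28×28×20 grid (~4,200 white-matter voxels, ~1,050 nodes, 200 volumes)
for the K = 2..22 stability sweep.  All randomness descends from a
single seed through a `SeedSequence` tree — cohorts, fold assignment,
k-means replicates and permutations — so identical seeds reproduce every
number bit for bit, and pipeline outputs are byte-identical across
reruns with the same configuration.

## Known limitations

* Slice-timing, realignment, segmentation and nonlinear normalisation
  are out of scope; inputs are assumed aligned on a common grid.
* The generator's stability cliff above the planted K is a consequence
  of its isotropic within-network heterogeneity; real data may have
  genuine sub-network structure, in which case the stability rule
  selects the finest *reproducible* scale rather than a "true" K.
* Fisher-z group effects are injected homogeneously across a network
  pair; spatially heterogeneous effects within a network are not
  modelled.
* The clinical-association stage inherits the small patient sample of
  the emulated design (n = 16); its null behaviour is validated, its
  power is not.
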