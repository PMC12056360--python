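# Methods

This note records the models, defaults, and design choices behind
`strokeconn`, and what the synthetic validation does and does not show.

## The analysis model

The scientific object is the relationship between resting-state
functional connectivity and lower-limb clinical performance in a chronic
stroke cohort.  Two complementary analyses are implemented.

**Edgewise association.**  For subject *s*, ROI pair (i, j), connectivity
is the sample Pearson correlation of the denoised BOLD series over
unscrubbed frames, Fisher-transformed: `z_s(i,j) = atanh(r_s(i,j))`.
For each edge and each clinical measure a simple linear model is fitted
across subjects and the slope t-score reported.  The t of the slope in a
simple regression equals the correlation t, so the direction of the
regression (z on measure vs. measure on z) does not affect the p-value;
z is treated as the response for interpretability.  The p-values of all
edges within one network for one measure form one multiple-testing
family, adjusted by Benjamini–Hochberg step-up FDR with significance at
adjusted p < 0.05.  No covariates enter the edgewise model.  Because
some measures improve downward (GAIT coordination score, Timed Up and
Go), displayed t-scores are multiplied by −1 for those measures so a
positive value always reads "better function, higher connectivity".

**Nodal graph-metric regression.**  Each subject's correlation matrix is
binarized at thresholds τ ∈ {0.15, 0.16, …, 0.50} (edge present iff
r > τ, strictly; negative correlations never create edges).  Nodal
global efficiency, clustering coefficient, and betweenness centrality
are computed at every τ and summarized by the trapezoidal AUC over the
grid, giving one threshold-free feature per node and metric.  Each
clinical outcome is then regressed on the nodal AUCs of one network, one
metric at a time, by the stability elastic-net procedure below.

## Preprocessing

Order is fixed: outlier detection → confound regression → band-pass →
scrubbing.  Defaults: framewise-displacement threshold 0.9 mm,
global-signal threshold 5 SD, band 0.008–0.09 Hz, scrubbing by frame
deletion, subjects with > 50 % flagged frames marked unusable.  The
filter is a zero-phase FFT-domain brick-wall (forward transform, zero
out-of-band bins, inverse transform); with in-band retention ≥ 0.9 and
stop-band leakage ≤ 0.1 it satisfies the pipeline's filtering contract
without imposing a filter family.  A high cut of 0.9 Hz is physically
unreachable at TR = 3 s (Nyquist 0.167 Hz); the default is the standard
0.09 Hz resting-state cut and both cuts are configurable.

Hemisphere standardization (all lesions mapped to one side) is applied
at the matrix level as the homologue row/column permutation, which is
equivalent to voxel-space flipping once signals have been reduced to
bilateral ROI pairs, and is an involution by construction.

## Stability elastic net

Per outcome and metric: complete cases only; the outcome is Shapiro–Wilk
tested and Box-Cox transformed when p < 0.05 (maximum-likelihood λ; a
recorded shift makes non-positive data positive).  Features (nodal AUCs)
and the outcome are standardized inside the fit, so the shared penalty
range is meaningful across outcomes measured in seconds, m/s, or score
points, and coefficients are comparable for the percentage ranking.  The
candidate grid is 10 mixing values α linear in [0.05, 1] crossed with 10
penalty strengths λ log-spaced in [0.0002, 0.36] (the range spans three
decades, so log spacing samples it evenly); 5-fold CV RMSE picks the
candidate, which is refitted on the full data.  The CV fit is repeated
20 times with re-drawn fold assignments (seed = base_seed + repeat);
selection means a nonzero coefficient in that repeat's chosen model; the
strong set is selection in ≥ 18 of 20 repeats.  Mean coefficients over
the repeats where selected are ranked proportionally (largest |β| =
100 %), and the direction of each strong association is the sign of the
raw Pearson correlation between the feature and the untransformed
outcome.  GE, CC, and BC enter three separate models per outcome rather
than one joint model, keeping each feature block homogeneous.

A known operating characteristic, measured by the acceptance machinery:
because the 20 repeats share the same data and differ only in fold
assignment, a noise feature whose sample correlation with the outcome
exceeds the entry threshold of even the sparsest grid candidate
(α = 1, λ = 0.36) is selected in every repeat.  At n = 37 with ~21 noise
features this happens in roughly half of null datasets, so the procedure
as specified retains some false features under the null and its
false-selection rate with planted effects sits near 0.2 rather than
below 0.1.  Sensitivity for planted effects of standardized size 0.8 at
R² ≈ 0.6 is high (≈ 0.95).  Users should read strong sets as
high-sensitivity shortlists, not FDR-controlled discoveries.

## Graph metrics: numerical conventions

Shortest paths by BFS (hop counts); disconnected pairs have d = ∞ and
contribute 1/∞ = 0 to GE; betweenness uses Brandes' dependency
accumulation with fractional counting of tied shortest paths, sums over
unordered pairs excluding the node, skips disconnected pairs, and
normalizes by (n−1)(n−2)/2 so values lie in [0, 1]; CC of nodes with
degree < 2 is 0.  Thresholding uses Pearson r (not z) with strict ">".
AUC is trapezoidal.  These are the standard conventions of the
brain-connectivity literature; all are cross-checked exactly against
networkx and against brute-force path enumeration on small graphs.

## Lesion load

`LL = Σ_k overlap_k · max_area / area_k` over axial slices with nonzero
CST, where `area_k` is the CST voxel count and `overlap_k` the
lesion∩CST count in slice k.  The weight is the simplest function giving
higher weight to narrower tract portions; it is pluggable
(`weight_fn`) for alternative narrowness weightings.  Masks are assumed
binary and co-registered; the axial axis is auto-detected from the NIfTI
affine (superior–inferior code) with an override.

## Synthetic cohorts

The generator emulates the statistical structure the analyses assume,
not fMRI physics.  Each subject's series is multivariate normal with an
exchangeable base correlation (default 0.25, positive-definite for any
network size used).  A planted *edge* (i, j, effect) shifts that
subject's true correlation at (i, j) by a latent trait
δ_s ~ N(0, 0.15²); the subject's true Fisher z at the edge then enters
the clinical score.  A planted *node* scales the node's whole
off-diagonal row/column by 1 + γ_s (γ_s ~ N(0, 0.3²), clipped), moving
its thresholded graph metrics coherently; the node's true metric AUC
enters the score.  Planted contributions are standardized across the
cohort before being combined, so effect sizes are on a common scale, and
Gaussian noise with configurable SD is added; a slope signal-to-noise
ratio of 5 corresponds to noise_sd = 0.2 at unit effect.  Lower-is-
better measures are simulated by negating the score, with the direction
flag carried in the clinical table.  Any perturbation that breaks
positive definiteness is rejected with a diagnostic rather than
repaired.  Default cohort dimensions are 37 subjects, 24 ROIs, 200
frames at TR = 3 s, matching the study scale the pipeline targets.
Framewise-displacement traces are |N(0.2, 0.05)| mm with independent
spikes above 0.9 mm at a configurable rate.

The generator does **not** model hemodynamics, spatial structure,
physiological noise spectra, scanner differences, or realistic lesion
geometry.  Passing tests therefore demonstrate that the statistical
machinery is correct and calibrated under its own assumptions
(multivariate-normal signals, linear effects, independent noise), not
that the pipeline is robust to the artifacts of real fMRI.

A direct design-matrix generator (`simulate_feature_outcome`: standard
normal features, linear outcome) isolates the elastic-net machinery from
the imaging chain for the operating-characteristic measurements.

## Problem sizes in the test and acceptance runs

Oracle equivalence uses 1000 random graphs of 3–7 nodes (exhaustive
brute-force betweenness on every tenth graph).  FDR calibration uses 200
null cohorts of 37 subjects × 24 ROIs × 200 frames; edge recovery 100
such cohorts; the stability characteristics 50 planted and 50 null
replicates of the full 20-repeat procedure; Box-Cox recovery 100
replicates at n = 500 per λ.  These sizes give Monte-Carlo standard
errors comfortably below the margins being tested while keeping a full
run in the minutes range on one CPU.

## Known limitations

- The Zhu-style slice weighting is one member of a family; the exact
  published weighting is not reproduced here, only its defining property
  (narrow slices weigh more).
- Edgewise models take no nuisance covariates (age, scanner, lesion
  load); a scanner covariate would be a natural extension.
- The stability procedure's false-selection behaviour is inherent to
  CV-minimum selection with fold-reshuffling-only replication (see
  above); subsample-based stability selection would control it but is a
  different procedure.
- Whole-graph (as opposed to nodal) metrics, weighted-graph metrics, and
  density-based thresholding are out of scope.
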