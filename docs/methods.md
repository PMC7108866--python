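# Methods

`crossrep` implements a representational-analysis pipeline for multi-subject
ROI pattern data: winner-take-all selectivity maps with a cluster-constrained
permutation null, cross-validated pairwise-decoding dissimilarity matrices
(DSMs), representational similarity analysis (RSA) within and between groups,
partial correlations with stimulus-derived model DSMs, inter-subject
correlation, and representational connectivity. Because the class of studies
it targets uses restricted human fMRI data, the package ships a synthetic-data
generator that plants a known representational geometry and topography, and
every stage is validated against that planted truth.

## The analysis model

**Patterns and conditions.** The unit of data is a beta pattern: one response
amplitude per voxel per stimulus per run, as produced by a standard GLM. The
default design has 24 stimuli in 8 categories (3 exemplars each), nested in 4
superordinate categories (human, animal, manipulable, big objects/places),
5 runs, and three groups of 16/16/17 subjects. Category order — and hence the
order of the 28-entry vectorized upper triangle of every 8x8 DSM — is fixed
study-wide.

**Selectivity maps.** A voxel's label is the condition with the largest
run-averaged beta (winner takes all); exact ties go to the lowest condition
index and are logged. Group maps average betas across subjects before the
argmax. Maps are compared between groups by a symmetric two-way scheme: the
Spearman correlation of each subject's integer-coded map with the other
group's average map, averaged over subjects, computed in both directions, and
the two direction means averaged. The integer label coding (a fixed study-wide
assignment of categories to integers) is a declared convention: rank
correlations on categorical codes depend on it, and an indicator-map variant
can be obtained by correlating per-category binary maps instead.

**The constrained permutation null.** Because label maps are spatially
smooth, naive voxel-wise permutation overstates significance. The null
instead fixes each map's connected same-label clusters (6-connectivity by
default; 18/26 configurable) and assigns a uniformly random condition to each
cluster, preserving the spatial structure exactly. A map with c clusters and
k conditions supports k^c distinct assignments; subjects whose maps support
fewer assignments than the permutation budget are excluded with a warning
rather than silently retained. p-values use the add-one estimator
p = (1 + #{null >= observed}) / (n_perm + 1), so p is never exactly 0 and
never smaller than 1/(n_perm+1). The default budget is 10,000 permutations;
tests and the bundled pipeline use 500.

**Decoding DSMs.** Each unordered category pair is decoded with a linear
support-vector classifier (LIBSVM via scikit-learn, C = 1, raw betas as
features, no scaling or feature selection — all knobs exposed in
`ClassifierConfig` and recorded in output provenance) under leave-one-run-out
cross-validation: per fold, train on 12-vs-12 exemplar patterns, test on the
held-out run's 3-vs-3. Accuracy is averaged over folds; the 28 accuracies form
a symmetric zero-diagonal DSM. Decoding accuracy is used as the dissimilarity
index (rather than correlation distance) because cross-validated estimates do
not inflate under pure noise — two undrivable conditions decode at chance.

**RSA.** Group-to-group DSM similarity uses the same symmetric two-way
Spearman scheme on vectorized DSMs, with a condition-relabeling null: each
iteration draws an independent random category permutation per subject and
recomputes the whole statistic on the relabeled data, *rebuilding the group
averages from the permuted subject vectors*. The rebuild matters: permuting
a precomputed group average wholesale (a natural shortcut) breaks the
dependence between the two direction terms that flows through each
subject's contribution to its own group's mean, and simulation under a true
null shows that variant rejects at ~13% for a nominal 5% level, while the
full-recomputation null is calibrated (5.2% over 1500 replicates). The
rebuild form is the standard condition-label randomization test: relabel
within each subject, then recompute the statistic end to end. Differences between two group
pairs that share a group are tested by shuffling subjects between the two
non-shared groups (two-tailed). Model comparisons use partial Spearman
correlation: all vectors are rank-transformed and the target/brain
correlation is computed on residuals after regressing out the nuisance
model's ranks; significance comes from relabeling the brain vector's
conditions, one-tailed against the positive tail (a negative observed
correlation yields p >= 0.5 — "significant negativity" is never reported).
Fisher's r-to-z is applied before any *parametric* test on correlations;
permutation tests use raw r.

**Inter-subject correlation.** All subjects' DSM vectors are correlated
pairwise (Spearman), giving an n_subjects x n_subjects matrix. Within-group
summaries average the upper half of each diagonal block (diagonal excluded);
between-group summaries average the full off-diagonal block. Block means are
ranked and tested by permuting group labels. A singleton group's within-mean
is undefined and flagged.

**Hierarchical clustering.** The DSM is treated directly as inter-category
distances; an agglomerative tree (single linkage by default, matching the
default of the numerical environment this analysis style originated in;
average/complete configurable) is cut at k = 2, 3, 4. Cuts of one tree are
nested by construction.

**Representational connectivity.** A decoding DSM is extracted in each seed
ROI and in each parcel covering the rest of the brain; the Spearman
correlation of every seed DSM with every target DSM forms a seeds x targets
profile (3 x 27 in the reference configuration). "z-normalization" is
interpreted as Fisher r-to-z followed by standardization within subject and
seed across targets; both steps are independently toggleable because the
choice is a convention, and the within-seed variant makes profiles invariant
to seed-wise affine rescaling of raw correlations. Profiles are compared
between groups with the two-way scheme; the null shuffles (seed, target)
entry labels per subject, again rebuilding the group-average profiles from
the permuted subject vectors.

**Model DSMs.**

* *Pitch*: fundamental frequency is estimated by windowed normalized
  autocorrelation. The window is two periods of the pitch floor (60 Hz
  default, so 33 ms windows; ceiling 2000 Hz default), hopped by half a
  window. Autocorrelations are made unbiased by dividing out the rectangular
  window taper (otherwise peak lags bias short and pitch estimates high by
  ~1%). Candidate lags are local maxima; among candidates within 5% of the
  global maximum the shortest lag wins (suppressing octave-down errors on
  harmonic-rich sounds), refined by parabolic interpolation. A window is
  voiced if its best peak exceeds 0.45; a signal with no voiced window
  returns an "unvoiced" marker distinct from an error. The category DSM is
  the absolute difference of category mean pitches, which satisfies the
  triangle inequality by construction.
* *HMAX C1*: S1 is the magnitude of the correlation with zero-mean,
  unit-norm Gabor filters at 4 orientations and 16 scales (sizes 7-37 px in
  steps of 2; sigma = 0.0036 s^2 + 0.35 s + 0.18, wavelength sigma/0.8,
  aspect ratio 0.3 — the canonical parameterization). Responses within half
  a filter of the image border are discarded, so a constant image yields
  exactly zero S1 everywhere. C1 takes the elementwise max over adjacent
  scale pairs and then a spatial max over scale-dependent neighborhoods
  (8-22 px, 50% overlap), within orientation; all unit responses are
  concatenated into one vector per image, category vectors are image means,
  and the DSM entry is 1 - Pearson correlation. An 8-scale reduced bank is
  provided for fast tests. Local contrast normalization of S1 is omitted;
  only the correlation-based geometry of C1 vectors is consumed downstream.
* *Behavioral*: stimulus-pair dissimilarity is 7 - rating (the simplest
  order-reversing map; only ordinal structure is used downstream). The
  category-level entry averages all stimulus pairs spanning a category pair;
  within-category pairs only inform the excluded diagonal. Group DSMs
  average per-rater DSMs.

**Shared inference machinery.** Benjamini-Hochberg FDR adjustment (via
statsmodels) is applied within the family declared by each analysis call —
by default, all contrasts of one call. One-sample and two-sample t-tests and
the repeated-measures ANOVA wrapper delegate to scipy/statsmodels; a
zero-variance sample is flagged degenerate rather than raising.

## The synthetic-data generator

The generator emulates post-GLM beta patterns on a 10x10x10 voxel grid with
named ROI masks; it simulates no hemodynamics, temporally autocorrelated
scanner noise, motion, or GLM estimation, and its noise is i.i.d. Gaussian
per (stimulus, run, voxel). What passing tests therefore demonstrate is the
*correctness and calibration of the analysis machinery* — recovery of a
planted geometry, nominal false-positive rates — not robustness to the
structured noise of real fMRI.

**Planted geometry.** The requested 8x8 geometry is built from an explicit
7-dimensional point configuration (guaranteeing Euclidean embeddability):
4 superordinate centers at mutual distances ~0.95-1.27 in a 3-D subspace,
each superordinate's two categories split 0.55-0.75 apart along a dedicated
axis, plus small per-category jitter so all 28 distances are distinct.
A non-embeddable user-supplied geometry (negative Gram eigenvalue) is
rejected with a diagnostic.

**Prototype construction.** Classical MDS embeds the requested geometry into
voxel space along orthonormal directions chosen orthogonal to the
selectivity-cluster indicator functions (scaled by `geometry_scale`, default
0.8). A per-superordinate selectivity bump (defaults 0.25/0.35/0.45/0.55) is
added on that superordinate's clusters; amplitudes are deliberately spread so
the bump component itself carries rankable between-superordinate structure.
Because bump and geometry live in orthogonal subspaces, realized prototype
distances decompose cleanly. Where the geometry component erodes a voxel's
noiseless 4-way winner margin below 0.15, that voxel's bump is raised to
restore it. The **planted truth stored for oracles is the realized outcome**:
`true_dsm` is the noiseless prototype distance matrix and `true_label_maps`
are the argmax labels of the noiseless prototypes (at both 4- and 8-category
granularity), so zero-noise recovery is exact by construction and
Spearman-based recovery targets are self-consistent.

**Layout.** `VOTC` (the target ROI) is 8 selectivity clusters of 2x2x1
voxels — two non-adjacent clusters per superordinate — so every map offers
at least 8 relabelable units (4^8 = 65,536 constrained assignments, enough
for a 10,000-permutation budget even on clean maps). `EVC` mirrors the
layout with a category-relabeled geometry, standing in for structure
unrelated to the planted categorical one. Remaining grid voxels host
whole-brain parcels (default 10 x 25 voxels) carrying the geometry at
amplitude 0.8 or pure noise, alternating — the substrate for connectivity
analyses. Groups differ by per-ROI SNR multipliers (defaults mirror the
qualitative ordering visual > blind-auditory > sighted-auditory, with no
signal in the sighted-auditory control's EVC) and optionally by a category
permutation of the prototypes, which plants a genuinely distinct geometry
and topography at identical SNR.

**Scale and SNR.** Patterns are `effect_size x prototype + N(0, noise_sd)`
with defaults effect 3, noise 1 ("high SNR" = ratio 3). The absolute scale
of bumps and geometry was chosen once so that, at the default SNR, pairwise
decoding accuracies span an informative range (~0.6-0.99 rather than pinning
at 1.0) while the winner-take-all map remains recoverable — the same tension
a real experiment resolves through ROI size and trial counts. Per-subject
noise-level SNR is a free parameter of the generator, not calibrated to any
empirical dataset. Determinism: every generator is a pure function of
(parameters, seed); per-subject streams derive from the master seed by a
fixed entropy scheme, and identical calls are bit-identical.

**Other planted assets.** Behavioral ratings are an affine map of planted
similarity plus Gaussian noise, rounded and clipped to the 1-7 scale (276
pairs per rater for 24 stimuli). Rounding necessarily ties some of the 28
category-pair values onto 7 levels, so the noiseless integer-rating DSM
correlates with the planted geometry at rho ~0.95 rather than exactly 1; a
continuous-rating mode (`integer=False`) recovers rho = 1 exactly and is the
form used for exactness tests. Audio tones (sine, band-limited sawtooth,
harmonic complex) are RMS-normalized with the synthesis f0 kept as oracle
metadata. Texture images are oriented gratings with seeded phase plus
low-pass noise.

## Numerical choices and degenerate inputs

* Spearman correlations use midranks throughout; a constant vector yields a
  flagged degenerate result (NaN or 0 by documented convention) rather than
  an exception, except where the operation's contract demands an error
  (constant feature vectors in 1-Pearson DSMs, constant vectors in partial
  correlation).
* A variable fully explained by the partial-correlation control (residual
  norm below 1e-9 of the rank-vector norm) has no residual association and
  returns 0.
* Connectivity z-scoring treats a seed whose correlations are all equal
  within 1e-10 relative tolerance as carrying no profile information (zeros).
* Winner-take-all ties break to the lowest condition index, logged.
* Permutation p-values: add-one estimator; two-tailed tests double the
  smaller tail, capped at 1.
* All file round-trips (DSM TSV, dataset TSV) use round-trip float parsing
  and are bit-exact.

## Problem sizes used in the shipped tests and acceptance script

Recovery runs use the default 10^3-voxel grid with the 32-voxel VOTC ROI,
16 subjects, and 500 permutations; chance calibration uses 50 zero-effect
subjects; permutation-p uniformity uses 200 replicates at 500 permutations;
the t-test level check uses 100 independent 16-subject null groups;
connectivity discrimination uses 3 groups of 6 subjects on 5 parcels. These
sizes were chosen as the smallest at which the planted effects and nominal
levels are stably measurable.

## Known limitations

* The noise model is white; spatial and temporal noise correlations of real
  fMRI are out of scope, as are hemodynamics, motion, GLM estimation,
  surface-based analysis and anatomical parcellation (masks are inputs).
* No noise-ceiling ("reliability of the correlational pattern") estimate is
  provided; it is a possible extension.
* The Spearman-on-label-maps convention (integer codes vs indicator maps) is
  a declared choice; results depend on it and both variants are exposed.
* The selectivity-map group comparison relabels the clusters of the subject
  maps *and* of the group-average maps independently (the average map cannot
  be rebuilt from relabeled cluster assignments, since it derives from
  averaged betas); unlike the DSM/profile nulls it therefore inherits the
  mild anticonservativity of wholesale-average permutation, and its p-values
  should be read as approximate. The planted-signal checks it supports are
  far from the threshold regime.
* HMAX is implemented through C1 only (no S2/C2), and the pitch tracker is a
  single-candidate-per-window autocorrelation method, adequate for clean
  synthetic stimuli rather than adverse recordings.
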