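# Methods

## Data model and conventions

Every object lives on exactly one `VoxelGrid` — integer dimensions
(nx, ny, nz) plus a 4×4 voxel-to-world affine in RAS+ mm. Flat voxel
indices are 0-based and x-fastest (Fortran-style over (x, y, z)); the same
convention applies to the container, masks, and maps, so indices are
portable across all artifacts. Grids are equal when dimensions match and
affines agree within 1e-4 mm elementwise; mismatched grids are a hard
error everywhere, and no resampling is ever performed — all inputs are
assumed registered to one template space upstream.

An `AcquisitionMatrix` stores one acquisition's BOLD timeseries (arbitrary
units) for its *valid* voxels only. Validity is operational: a voxel is
valid when its series is all-finite and not constant. Constancy is judged
by relative spread (peak-to-peak ≤ 1e-12 of the series magnitude) rather
than exact variance, because a constant series that has passed through I/O
or reshaping can acquire round-off noise of order 1e-16. This is the
package's definition of "signal could be calculated"; acquisition software
upstream may use a different rule, so coverage counts on real data should
be interpreted with that in mind.

A `StatMap` carries one float per voxel with NaN as the explicit no-data
marker plus a per-voxel contribution count `n_per_voxel` (0 exactly at
no-data voxels). Any per-voxel statistic with fewer than 2 contributing
acquisitions is no-data, never zero: signal dropout must remain
distinguishable from true null connectivity.

## Seed mapping

The seed series in each acquisition is the unweighted mean of the seed's
valid voxel rows (no coverage weighting — the simplest defensible rule).
Acquisitions where no seed voxel is valid, or where the seed mean is
constant, are skipped at group level with a logged warning; at
single-acquisition level these are errors.

The group mean-r map averages raw correlation coefficients (not
back-transformed Fisher z), matching the convention of reporting an
"average correlation coefficient". The group t-map, by contrast, applies
the Fisher transform z = artanh(r) per acquisition by default before the
one-sample t-test against zero, because z is variance-stabilized and
closer to normal; testing raw r is available via `space="raw_r"` since the
choice is a convention, not a theorem. Degrees of freedom vary per voxel
with coverage (df = n_v − 1), which gives correct small-sample behavior at
partially covered voxels.

Numerical guards: |r| is clipped to 1 − 1e-7 before arctanh so that
numerically perfect correlations (a single-voxel seed with itself) produce
a large finite z (≈ 8.4) rather than infinity; voxels whose z values have
exactly zero variance across acquisitions (e.g. duplicated data) are
no-data with a logged count.

Thresholding is strict (value > threshold, default 2.8) and one-sided
positive by default, with `abs_greater` available; a value exactly at the
threshold is excluded. No-data voxels are never members.

## Coverage

The coverage mask contains the voxels valid in at least `min_fraction`
(default 0.8) of acquisitions. The comparison is exact-rational
(count · q ≥ n · p for min_fraction = p/q), so with 77 acquisitions a voxel
valid in 62 (80.5%) is included and one valid in 61 (79.2%) is excluded,
with no float-boundary ambiguity at exactly 80%. Acquisitions with
differing volume counts are accepted with a warning (correlation is
per-acquisition), anticipating datasets that grow across protocols.

## Two-connectome comparison

At every voxel covered by ≥ 2 acquisitions in each group (optionally
intersected with a restrict mask such as the coverage mask), per-acquisition
Fisher-z connectivity values are compared with a two-sided Welch
(unequal-variance) t-test; Welch is the default because normative
connectomes of very different sizes (tens vs hundreds of acquisitions) make
pooled variance inappropriate. The p-values are corrected across all tested
voxels by Benjamini–Hochberg step-up FDR (independence/PRDS variant) at
q = 0.05. Swapping the groups flips t-signs and preserves p-values and the
significant set exactly.

## Outcome models

VTA–ROI connectivity is the mean, over ROI voxels with at least one
contributing acquisition, of the VTA-seeded group mean-r map — i.e. the
same seed-map workflow used everywhere else. The alternative reading
(mean over all VTA-voxel × ROI-voxel correlations per acquisition, then
averaged) is available as `method="pairwise"` for comparison; the two are
similar but not identical on correlated data, and the r-map route is the
default because it matches the package's mapping workflow. Bilateral VTAs
form one seed mask per patient.

Outcome models are ordinary least squares with intercept, one predictor
per ROI. Predictions are in-sample fitted values by default (a
leave-one-out mode exists); R is Pearson(predicted, actual), which for OLS
with intercept equals the multiple correlation coefficient, so for a
single predictor the p-value of that correlation coincides with the
slope's p-value (verified in the tests). Rank-deficient designs raise an
error naming the collinear ROIs. Repeated fits on one connectome may pass
a precomputed connectivity matrix; its entries are deterministic and the
cached path is tested equal to recomputation.

## Synthetic data

The generator emulates the structure of a normative rs-fMRI dataset, with
defaults matching the emulated acquisition protocol: 77 acquisitions of
175 volumes. Voxel v's series in one acquisition is

    sum_k a_k · s_k(t) · [v ∈ mask_k] + eps_v(t)

where each network's latent s_k is a unit-variance white Gaussian series
drawn independently per acquisition (normative aggregation is across
subjects, not one shared session), and eps_v is exactly stationary AR(1)
noise with parameter φ (default 0.3 — rs-fMRI noise is autocorrelated, so
tests must not rely on i.i.d. assumptions) and innovation sd σ (default
1, arbitrary units). Overlapping network masks add. The expected
within-network correlation is a² / (a² + σ²/(1−φ²));
`amplitude_for_within_r` inverts this, and the default planted scene (a
contiguous 200-voxel block on a 20×20×10, 2-mm grid with a 10-voxel seed
sub-block) uses the amplitude for r = 0.5. The desk-scale grid keeps full
pipelines at seconds per connectome; the generator accepts any grid,
including full template scale, but the tests do not use it. Dropout masks
remove each member voxel from an acquisition's valid set independently
with the stated probability. Everything is reproducible from
(config, seed); per-acquisition streams are seeded on (seed, index) so
acquisitions are independent and order-insensitive.

Simulated DBS cohorts place 2×2×2 VTA blocks sliding across the planted
network's edge so that true VTA–network connectivity varies across
patients, and draw outcomes as intercept + β·connectivity + N(0, σ²);
`noise_sd_for_target_r` chooses σ to hit a stated population
predicted-vs-actual R (0.3 in the recovery checks, with β = 5 and n = 50).

What the generator does *not* emulate: hemodynamic response shapes,
physiological (cardiac/respiratory) noise, subject motion, scanner drift,
spatial smoothness of the noise field, or between-subject anatomical
variability. Passing tests therefore demonstrate the correctness of the
estimators and their calibration under a known covariance structure — not
performance on real scanner data, whose artifacts live upstream of this
package's inputs.

## Calibration checks and their design

The null t-map calibration compares the fraction of background voxels with
t > 2.8 against the one-sided Student-t tail at df = 76. Voxels inside the
seed mask are excluded from this fraction: the seed mean is partly composed
of each seed voxel's own series, so their part-whole correlation is real
signal, not a null effect. The FDR check compares independent connectomes
drawn from the same generative model, where every rejection is false by
construction; the realized false-discovery proportion over 20 replicate
pairs is required to stay at q up to three binomial standard errors, and
self-comparison must reject nothing (identical groups give zero mean
difference at every voxel).

## File formats

NIfTI-1 masks are read liberally (any nonzero voxel is a member) to
tolerate atlas dialects, and written canonically as uint8 {0, 1}. Float
maps are written as float32 with NaN marking no-data, the convention
neuroimaging viewers expect. The connectome ships as a single hierarchical
HDF5 container (format version string, grid, per-acquisition id + voxel
indices + data, optional coverage mask); an unknown version or truncated
file raises without returning a partial object, and writes suppress HDF5
timestamps so identical content yields byte-identical files. A
one-matrix-per-file NIfTI export exists for interoperability. Reading
MATLAB-native matrix storage from other toolchains is a documented
extension point, not implemented.

## Known limitations

- No spatial smoothing, nuisance regression, filtering, or registration:
  inputs must be preprocessed and template-registered upstream.
- No permutation inference or cluster-extent correction; inference is
  voxelwise parametric with BH-FDR.
- Repeat acquisitions from the same subject are treated as exchangeable
  with all others in group statistics.
- The synthetic cohort's VTA geometry is schematic (axis-aligned blocks),
  chosen to produce a controlled spread of connectivity values rather than
  realistic electrode fields.
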