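# Methods

`meglabel` assigns anatomical atlas labels to MEG equivalent current dipoles
(ECDs) on a patient's native T1-weighted MRI. This note documents the model
and procedure, the parameters that matter, the synthetic data the tests run
on, the numerical choices, and the known limits of what the tests show.

## The labeling chain

A fitted dipole lives in the MEG **HEAD** coordinate frame. To name the brain
region under it, three transforms are chained:

1. **Coregistration** (HEAD → WORLD): the rigid/affine MEG–MRI alignment,
   read from a canonical text file that declares its frames and the unit of
   the HEAD coordinates (mm or m). A missing declaration is a parse error —
   a silently wrong unit or frame is the most dangerous failure mode of this
   kind of pipeline, so it is made impossible to express.
2. **Voxelization** (WORLD → VOXEL): the inverse of the T1's NIfTI
   voxel-to-world affine, followed by rounding to the nearest voxel centre.
   Labels are categorical, so there is no sub-voxel interpolation of codes.
3. **Atlas lookup**: atlases are integer-coded label volumes in a standard
   template space paired with a plain-text lookup table
   (`<code> "<region name>"`). Each atlas is *reverse-normalized* — resampled
   onto the native grid through the native→template normalization with
   nearest-neighbour interpolation — and the dipole's voxel is read out.
   Code 0, or a code absent from the table, means **unlabeled**: the normal
   outcome for dipoles in white matter or CSF under a grey-matter
   parcellation, not an error.

Every coordinate object is tagged with its frame (HEAD, WORLD, VOXEL,
TEMPLATE), and transform composition checks the tags, so an illegal chain
fails loudly at construction time.

All world coordinates are RAS+ millimetres; voxel indices are 0-based with
index *i* at the centre of voxel *i* (NIfTI affine semantics). Rounding is
nearest-integer with ties to even (`np.rint`).

## Dipole acceptance (sECD criteria)

Dipoles are filtered by the standard clinical single-ECD criteria before
labeling. Defaults, with their boundary semantics:

| criterion | default | semantics |
|---|---|---|
| reduced chi-square | < 2 | strict |
| goodness of fit | ≥ 80 % | inclusive |
| confidence volume | < 1000 mm³ | strict |
| dipole strength Q | 100–500 nAm | inclusive both ends |

A dipole missing an optional statistic (chi-square, confidence volume) is
judged only on the criteria it carries. Rejections report the *first* failing
criterion in the fixed order chi2 → gof → cv → strength, so reasons are
deterministic. Every input dipole ends in exactly one disposition — accepted,
rejected(reason), or excluded(reason) — and the summary counts are conserved
by construction (`total = accepted + rejected + excluded`; per atlas,
`labeled + unlabeled + out_of_fov = accepted`). Exclusion by expert judgment
(e.g. a dipole deep in CSF) has no automatable rule; it is expressed only as
an explicit list of dipole ids.

## Built-in affine normalization

In production the native→template normalization usually comes from an
external tool (a FLIRT-style affine matrix or a nonlinear displacement
field), which the package ingests from files. For self-contained operation it
also estimates a 12-parameter affine (3 translations, 3 rotations, 3 scales,
3 shears) itself, by maximizing normalized cross-correlation (NCC) between
the template and the resampled native image. NCC is appropriate because both
channels are T1-weighted; mutual information is an extension point.

The search is deterministic and proceeds in three stages:

1. **Moment matching.** Intensity centroids and second-moment matrices are
   matched in closed form. Background is suppressed by soft-thresholding
   weights at 10 % of the dynamic range — without this, noisy background
   voxels dominate the covariance by sheer count and corrupt the scale
   estimate. Matching moments determines the affine only up to an orthogonal
   factor *W* in whitened space: every candidate has the linear part
   `cov_f^1/2 · W · cov_m^-1/2`.
2. **Rotation capture.** *W* is searched over a fixed rotation-vector grid
   (±15° ball, 3° steps; 515 candidates), scoring NCC with the fixed grid
   subsampled at stride 2. Two facts force this design, both measured during
   development: (a) the NCC surface has false rotation minima with basins
   only a few degrees wide, so a purely local optimizer stalls; and (b)
   candidates must stay *inside* the moment-matched family — composing a
   rotation onto the `W = I` member drags a spurious stretch along and the
   true pose is never on that path.
3. **Powell refinement.** A residual 12-parameter affine about the fixed
   centroid is refined with Powell's derivative-free direction-set method,
   first on the stride-2 grid, then at full resolution. Scales and shears are
   parametrized in percent so all parameters move on comparable scales
   (mm / degrees / %). Coarse levels use plain grid decimation, **not** a
   blurred pyramid: smoothing erases the thin shell structure that identifies
   the pose, and on the test phantom a Gaussian pyramid's coarse-level global
   optimum sits at a wrong pose.

If the refined solution scores worse than the initialization at full
resolution, the initialization is returned and the result is flagged
non-converged. Degenerate (constant) inputs and non-overlapping volumes raise
immediately.

Resampling maps each target voxel centre through the given world transform
and samples the source (trilinear for intensities, nearest-neighbour —
mandatory — for labels and masks); voxels falling outside the source field of
view become 0, the reserved no-label code. Displacement fields store one mm
offset vector per target voxel (zero field = identity) and follow the same
sampling contract.

## Normalization QC

The skull-overlay check is quantified as the Dice coefficient between the
subject's head mask and the template head mask carried into native space,
plus boundary-distance summaries from a Euclidean distance transform. The
failure threshold (default Dice < 0.85) is this package's operating proxy for
"the overlay visibly does not match"; it is a configurable convention, not an
externally validated cut-off. The rendered QC artifact is the classic
tri-planar view (coronal / sagittal / axial) with the one-voxel skull outline
(mask minus its 6-connected erosion) and dipole markers; radiological
orientation mirrors the left–right axis of the axial and coronal panels only.
Snapshots are a QC artifact, not a measurement surface — tests assert marker
geometry, never pixels.

## Validation statistics

Ground truth comes from multiple raters; a rater may give a set of acceptable
labels (a dipole in a sulcus may legitimately belong to either adjacent
gyrus). The consensus label is the one endorsed by at least *k* of *n* raters
(default 2 of 3, a 66 % floor); ties among qualifying labels mean no
consensus, and such dipoles are excluded from concordance. Concordance is
exact string match of the pipeline label against the consensus set. Two
denominators are reported explicitly and kept distinct: concordant % over
*labeled* dipoles, unlabeled % over *all considered* dipoles. Every
percentage is stored with its integer numerator and denominator so rounding
is auditable. Method discrepancy between two runs (e.g. two normalization
methods) categorizes each dipole as same-label / different-label /
only-one-labeled / both-unlabeled; the discrepancy rate counts the middle two
categories.

## Synthetic data: what it emulates and what it does not

The test fixture generator builds, from a single seed, everything a subject
folder contains — so the whole pipeline is testable with no downloads and
with known answers at every stage.

* **Phantom head** (default 64³ voxels at 2 mm): concentric ellipsoids
  ("brain" semi-axes 40/34/30 mm, a 3 mm CSF gap, 6 mm skull, 5 mm scalp,
  distinct intensity levels) plus two off-centre intensity features inside
  the brain that break mirror and rotational symmetry — without them the
  affine pose would be unidentifiable. Additive Gaussian noise (default
  SD 2 on a 0–150 intensity scale for generated subjects) is seeded.
* **Toy atlas**: the brain mask partitioned into k contiguous
  nearest-centroid regions (codes 1..k, names `region_1..k`), optionally with
  the deepest interior fraction (default 15 %) left as code 0 to emulate the
  unlabeled white-matter core of a grey-matter atlas.
* **Ground-truth transforms**: a seeded affine normalization (translations
  ≤ 10 mm, rotations ≤ 10°, scales 0.9–1.1) and a seeded rigid
  coregistration, written in the canonical file dialects. The native T1 is
  the template carried through the normalization, plus noise — so the true
  normalization is known exactly.
* **Dipole sets**: planted at region-interior voxel centres (≥ 1 voxel from
  any region boundary) and back-transformed into the HEAD frame. Interior
  snapping guarantees that with the true transforms the pipeline recovers
  the planted label for **100 %** of accepted dipoles; under an *estimated*
  normalization, registration error is therefore the only possible error
  source. Fit statistics either all pass the sECD criteria or, in `mixed`
  mode, the first four dipoles each violate exactly one criterion.

What passing these tests does **not** show: performance on real MRI
(bias fields, MP2RAGE background noise, pathology and resection cavities,
genuinely nonlinear anatomy-to-template mappings), on real atlas
parcellations with hundreds of small regions, or on real MEGIN exports (the
`.dip` dialect here follows the classic text layout but has not been
validated against vendor files). Registration accuracy on the phantom —
20/20 seeded perturbations recovered with head bounding-box corner error
below 2 mm in the shipped test — is an upper bound on what to expect from
clinical images.

## Numerical and design choices

* Frame tags make illegal transform chains unrepresentable; same-frame
  transforms must be identities.
* Readers reject rather than coerce: non-finite numbers, duplicate or zero
  lookup codes, missing unit/frame declarations, malformed rows (with their
  1-based line number) are all hard errors.
* `.dip` round trips are lossless to 1e-6 (fixed-precision formatting,
  byte-stable); lookup tables round-trip exactly.
* FLIRT-style matrices are converted from the scaled-voxel convention
  (indices × voxel size, x flipped when the voxel-to-world determinant is
  positive) into plain WORLD→TEMPLATE mm transforms; the moving and fixed
  grid geometries are required because the matrix is meaningless without
  them.
* Nearest-labeled fallback search (the automated version of dragging the
  cursor to the nearest grey matter) works in world mm so anisotropic grids
  behave correctly, has a default radius of 10 mm, breaks ties by distance,
  then smaller code, then lexicographic voxel index — and is always recorded
  separately from the direct lookup, never substituted for it.
* Label volumes may contain codes missing from the lookup table: such voxels
  are reported as unlabeled with a warning, not an error.
* FIF containers are not parsed; the pipeline contract is the canonical
  coregistration text file, and a converter from vendor formats is an
  extension point outside the tested surface.
* Reports contain no timestamps; two runs on identical inputs are
  byte-identical, and the run log records configuration, package version and
  SHA-256 input checksums.

## Problem sizes in the shipped tests

The default test suite uses the 64³ / 2 mm phantom, toy atlases with 3–6
regions, subjects with 10–48 dipoles, 10 random affines for the resampling
oracle, 20 seeded perturbations for registration recovery and 50 randomized
fixtures for the conservation properties. These sizes keep the full suite in
the minutes range on one CPU while exercising every code path; nothing in the
method depends on them.
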