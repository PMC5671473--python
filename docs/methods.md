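# Methods

## Model and assumptions

The geometric transfer matrix models each ROI's observed mean SUVR as a
known linear mixture of true ROI means: the mixing weight ω_ij is the
mean, over the voxels of ROI *i*, of ROI *j*'s binary indicator
convolved with the scanner point-spread function.  Assumptions:

- the PSF is a stationary 3-D Gaussian of user-supplied FWHM (a single
  isotropic value, or a 3-vector for anisotropic scanners);
- activity is constant within each ROI;
- every voxel outside the modeled ROIs carries **zero** activity.  This
  is the load-bearing assumption: ventricles are deliberately left
  unmodeled (they are assumed tau-free), but any *real* signal outside
  the model — choroid plexus, meninges, extra-cortical hotspots —
  violates it and biases neighbouring estimates.  The ROI-construction
  stages exist to give every such source its own ROI.

Out-of-field activity is likewise assumed zero, so all smoothing uses
zero-padded boundaries and one shared implementation serves both the
mask-adjudication kernels and the GTM forward model; the residual
diagnostic can therefore never be inflated by a kernel mismatch.

The fit diagnostic is computed from the *calculated pre-PVC* image
(corrected means painted into their ROIs, re-smoothed by the PSF):
residual = pre-PVC − SUVR, and per ROI PVCnstd = std(residual)/
mean(SUVR).  The global score is the unweighted mean of PVCnstd over
the anatomical indices 1–77 that are present; the standard deviation is
population (ddof = 0) by default, configurable, since either convention
is defensible.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| scanner PSF FWHM | user input (6 in phantoms) | mm | GTM forward model, ECH searchable masks |
| mask smoothing FWHM | 8 | mm | cerebellar and choroid adjudication |
| choroid SUVR threshold | 1.0 | SUVR | high/low seeding |
| choroid contiguity | ≥ 100 | voxels | seed filter (inclusive) |
| ECH SUVR threshold | 1.6 (1.3 / 1.9 variants) | SUVR | hotspot definition |
| ECH cluster size | > 500 | voxels | strict; 500 is rejected |
| reference-scan threshold / size | 1.6 / > 500 | SUVR / voxels | reference cleaning |
| tissue probability cut | 0.3 | — | CSF/bone class gates |
| tissue SUVR floor / split | 0.1 / 1.0 | SUVR | low: (0.1, 1), high: ≥ 1 |
| connectivity | 26 | — | all connected components (6/18 available) |
| condition-number limit | 1e8 | — | switch to least-squares pseudo-inverse |

Voxel-count thresholds are resolution-dependent constants kept at their
published values; at coarser grids they correspond to larger physical
volumes.

## Design choices where the procedure was open

- **Tie-breaking.**  Cerebellar adjudication ties (equal or both-zero
  smoothed masks) go to the *superior* side, keeping ambiguous voxels
  out of the reference denominator.  Choroid ties go to *high*:
  over-estimating off-target choroid signal is the safer error for the
  hippocampal estimates it protects.  Modal-neighbor ties in the stray
  gray step go to the smallest label.  All three rules exist for
  determinism; byte-identical reruns are asserted in the tests.
- **Cluster label order.**  Hotspot labels count up from 85 in
  descending cluster size, ties by the lexicographically smallest
  bounding-box corner.
- **Label slots.**  The superior cerebellar gray takes index 77, and
  the inferior reference is carried as index 78 — the only free slot
  below the published 79–85+ block.  Cerebellar gray passes through the
  remap under an internal code (998), and configuration 1's un-split
  whole choroid uses 999, both far above any plausible hotspot count.
- **"Closer to bone than brain"** is operationalized exactly as the
  smoothed-mask comparison, not a distance transform.
- **Unknown FreeSurfer codes** map to 0 rather than erroring; real
  segmentations contain codes outside the grouping table.  The table is
  also loadable from TSV for other segmentation dialects.
- **Braak composites** are voxel-count-weighted by default (a composite
  is a union of voxels); an unweighted mean-of-means option exists.
- **Stray gray assignment** iterates to convergence (default cap 10
  passes) because one pass leaves interior strays with all-zero
  neighborhoods; a strict single-pass mode is available.
- **Hotspot painting** only fills voxels still unassigned, so a
  detected cluster can never overwrite an anatomical ROI; the
  searchable region is extracerebral by construction, so this matters
  only at its margins.
- **Tissue ROIs without the high/low split** (configurations 4 and 5)
  use the same class predicates with the SUVR split removed, i.e. one
  CSF ROI and one bone+meninges ROI over SUVR > 0.1.
- **Configurations 9 and 10** inherit the reference scan from 8 and
  vary only the hotspot threshold.
- **Ill-conditioning.**  ω is solved directly below a 2-norm condition
  number of 1e8 and by least squares above it (tiny ROIs beside large
  ones can make ω near-singular); the report flags the fallback.

## The phantom: what it emulates, and what it does not

All inputs are generated synthetically on a 64³ grid of 2 mm voxels —
small enough that every test runs in seconds while leaving ≥3 PSF
sigmas between unrelated structures.  The head is geometric: a cortical
shell in four sector ROIs around a white core; a ventricle block with
bimodal choroid slabs (high 1.5 ventral, low 0.7 dorsal) flush against
the hippocampi; a wide cerebellar ellipsoid split by a smaller
mirror-symmetric lobule atlas (the symmetry makes the designed
inferior/superior split provably recoverable, and the atlas-coverage
ring reproduces real aparc/SUIT disagreement); a CSF gap and a
skull/meninges shell.

Off-target features mirror the phenomena the pipeline targets:

- an **extra-cortical hotspot** as a conformal soft-tissue cap (SUVR
  3.5, ~1700 voxels) directly abutting the lateral cortical surface —
  hotspots follow the inner skull table, so they contaminate cortex
  over a broad parallel interface, which is precisely what makes their
  omission costly;
- **meningeal binding** (1.5) as the high bone+meninges compartment
  over a faint (0.2) skull/CSF background.  CSF truth is spatially
  uniform, so the SUVR-driven CSF high/low split only ever partitions
  constant-truth voxels;
- optionally, a **reference hotspot** (SUVR 3.0, ~620 voxels) inside
  the inferior cerebellum, sized to survive the reference-mean
  inflation it itself causes before the scan removes it.

The PET is the PSF-smoothed piecewise-constant truth plus optional
additive Gaussian noise (default sd 0.05 in reference units, a
realistic post-smoothing noise level for a 20-minute acquisition).
Under this construction the configuration sweep reproduces the
qualitative ordering the ROI design is built on: each added off-target
ROI class absorbs real unmodeled signal, and tissue ROIs without a
hotspot ROI make the fit worse because the hotspot's activity is
averaged into, and smeared across, a whole-head tissue class.

What the phantom does **not** emulate: anatomical realism, Poisson/
reconstruction noise correlations, segmentation errors, motion, or
PET–MRI misregistration.  Passing tests therefore demonstrate the
correctness of the construction rules, the linear algebra, and the
direction and mechanism of the configuration comparison — not clinical
effect sizes.  Human-cohort quantities (group PVCnstd levels, cohort
correlations) are outside what desk-scale synthetic data can certify.

## Monte-Carlo recovery experiment

`recovery_experiment` fixes the geometry and the ROI model (built from
the ground-truth label volume, merged or filtered by the
configuration's flags — e.g. no hotspot ROI, merged tissue classes) and
feeds each noisy repetition's observed means through the GTM solve.
This isolates the linear estimator: with the model fixed, its bias
under zero-mean noise is zero to second order, which the experiment
verifies per ROI against Monte-Carlo error (100 repetitions by
default).  Re-deriving the ROIs per repetition would add
threshold-jitter variance that belongs to the segmentation stages, not
the estimator; full-pipeline runs on noisy data remain available
through `run_subject`.  The SUVR normalization cancels exactly in the
truth comparison and is skipped inside the experiment.

## Known limitations

- World-space resampling is out of scope: all inputs must already share
  one grid (affines compared at 1e-4 per element).
- The choroid and tissue high/low boundaries are displaced by up to a
  voxel layer where the PSF moves the observed SUVR across the
  threshold; the partitions remain exact as partitions, and GTM
  absorbs constant-truth misassignment, but class-boundary voxels
  between compartments of different true activity are genuinely
  ambiguous at scanner resolution.
- Voxel-wise PVC methods (Müller-Gärtner, RBV), PSF estimation, and
  noise-covariance propagation of the GTM estimates are not
  implemented.
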