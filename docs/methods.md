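# Methods

This note documents the models, the numerical choices and the limits of
what the synthetic pipeline can show.  Everything quantitative stated here
is computed by the test suite or by `scripts/acceptance.py`.

## Thorax phantom

The phantom is a stylized thorax, not an anthropomorphic one: an elliptic
body cylinder (default half-axes 130 × 95 mm at the full 128 × 128 × 64
grid, 2.6 mm isotropic) with a 9 mm subcutaneous fat shell, a shoulder cut
(air above ~0.38 of the axial extent, giving the body outline a genuine
axial edge), two lung ellipsoids clipped to the interior and to the space
above the diaphragm, a left-ventricular annulus (inner/outer radii
18/28 mm, 65 mm long axis, long axis along z) of soft tissue with blood
pool inside, a liver-like hot compartment below the diaphragm, and two arm
cylinders near the lateral field-of-view edge.  Organ placement scales
with the grid extent, so shorter grids (16/32 slices) are proportionally
shortened thoraxes with the clinical in-plane matrix retained.

Lung ellipsoid axes are rescaled by a fixed-point iteration until the
rasterized lung volume matches the configured target within 2 %;
generation fails if the final volume misses the target by more than 15 %.
The default target is 2.6 L at the full grid, the scale of expiratory
breath-hold attenuation maps.  The generation seed drives only small
jitter fields: a lung-volume scale ~N(1, 0.05) clipped to [0.9, 1.1] and
±2 mm lung-centre offsets.  Everything else is a deterministic function of
the configuration, so phantoms are bit-reproducible per (config, seed).

Activity is piecewise constant per compartment.  Defaults (relative to
body soft tissue = 1): myocardium 8, blood 1.5, liver 3, lung 0.5 for the
perfusion-like study and 9 / 2 / 4.5 / 0.4 for the metabolism-like study.
The myocardium is required to be the hottest compartment.

What the phantom deliberately omits: cardiac and respiratory motion during
the emission acquisition (only inter-scan misalignment is modeled), bone,
anatomical texture, organ-shape variability beyond the jitter above, and
any attenuation value not in the four-class table.  Passing tests
therefore demonstrate correctness of the operators and the direction and
rough magnitude of artifact-induced biases, not their patient-level
distribution.

## Artifact injectors

Regions are specified in world millimetres and rasterized
centre-inclusive.  Susceptibility voids (sternal STN, implant-related SMA)
set fat/soft voxels in the region to background; LSTI and FSTI swap
lung↔soft and fat↔soft inside the region (both involutions); PMA converts
lung voxels in a transaxial band above the diaphragm to soft tissue;
truncation clears all tissue beyond a lateral half-plane.  Injectors are
local (voxels outside the region are untouched) and always return the
changed-voxel mask alongside the new map.

Misalignment is a rigid translation of the delivered map, quantized to
whole voxels (round half away from zero) to preserve the four-class
structure — no interpolation ever touches a μ-map.  Shifts are capped at
30 mm.

## Projection and reconstruction

Geometry is 2-D parallel-beam, slice by slice: 210 angles uniform over
[0, π), radial bin spacing equal to the in-plane voxel size, bin count
covering the image diagonal (made even so axis-aligned rays pass through
voxel-centre rows).  Line integrals are computed with a vectorized Siddon
tracer — exact intersection lengths of each ray with the voxel grid — and
assembled into a cached sparse system matrix.  Path lengths are converted
mm→cm inside the projector so μ in cm⁻¹ composes directly.  Because the
integrals are exact for the piecewise-constant image model, attenuation
factors reproduce closed-form a·L·exp(−μt) values to machine precision.

Attenuation enters as precomputed per-LOR factors (ACF sinogram).  The
reconstruction is multiplicative EM over interleaved angular subsets
(21 subsets of 10 angles by default) with per-subset sensitivity images;
the protocol default is 3 iterations, 21 subsets and a 5 mm FWHM Gaussian
post-filter (σ = FWHM/2.3548 per axis), applied last.  Scatter, randoms,
resolution modeling, time of flight and 3-D projectors are out of scope:
attenuation-correction bias survives this simplification, which is what
the analysis measures.

The EM start image is a clipped filtered backprojection (ramp filter on
the attenuation-corrected data, backprojected, floored at 10⁻³ of its
maximum so no voxel is stuck at zero by the multiplicative updates); a
uniform start is available via `init="uniform"`.  The FBP start
accelerates convergence of hot, thin structures: with it, 20 unsubsetted
noiseless iterations recover the myocardial ring mean to within ~3 %,
which the acceptance suite checks at the 5 % level.  EM monotonicity of
the Poisson log-likelihood holds from any positive start and is asserted
per full iteration.

Poisson noise is applied in count space: each bin is replaced by a draw
with mean bin × count_scale and rescaled, preserving the expectation.  The
cohort default count_scale = 10⁵ represents high-count static cardiac
acquisitions.

## Correction operators

**Susceptibility fill.**  Each artifact voxel receives the most frequent
tissue class among its six face-adjacent voxels; voxels whose neighbours
are all artifactual wait for the next pass, so surrounding tissue
propagates inward wavefront by wavefront (synchronous passes: assignments
become visible as neighbours only in the following pass).  Ties break by
the fixed priority soft > fat > lung > background, chosen because
artifacts occur inside the body where soft tissue dominates.  The fill
depends only on the labels outside the mask, hence is idempotent, and
restores a single-class surrounding exactly.  A mask covering the whole
volume has no seed neighbours and is rejected.

**Rigid re-alignment.**  Translation-only (clinical misalignment reports
are axial offsets in mm): an exhaustive integer-voxel search over ±10 mm
transaxially and ±20 mm axially maximizes the Dice overlap between the
nonAC-PET support (≥ 5 % of maximum) and the μ > 0 body mask, with ties
broken toward the smallest shift so an aligned map yields (0, 0, 0).
Axial identifiability comes from the phantom's shoulder edge inside the
field of view; offsets large enough to push that edge outside the volume
are not recoverable, which the misalignment table reports honestly as
recovery error.

**Truncation completion.**  Voxels that are background in the μ-map but
inside the nonAC-PET body support are assigned soft-tissue μ; nothing else
changes.  The support is the 5 %-of-maximum mask reduced to its largest
connected component — where connectivity is judged on a morphologically
closed copy (4 face-connected closing iterations) so arms separated from
the trunk by a narrow air gap count as the same body — and then eroded by
3 voxels.  The erosion absorbs reconstruction blur and nonAC haze spilling
past the body outline, making the operator a strict no-op on untruncated
maps while still restoring the truncated arm cores.  This operator is a
deliberately simple stand-in for joint activity/attenuation estimation;
it recovers tissue presence, not tissue class.

## Quantitation

Relative difference is computed ratio-first
(`100 · (corrected/original)`), so identical images give exactly 100 %.
The validity mask requires the denominator to reach 1 % of the original's
maximum (configurable); RD is undefined elsewhere.  Myocardial statistics
use the 42 %-of-regional-maximum threshold segmentation inside a box
around the LV (from phantom ground truth in pipeline mode); "SUV" means
reconstructed activity in arbitrary units, since only ratios are
reported.  Lung volume is the lung-voxel count times the voxel volume
(1.7576 × 10⁻⁵ L per 2.6 mm voxel); the test–retest incoherence flag
fires strictly above 10 % deviation of the volume ratio from 1.

The 17-segment polar map divides the LV long axis into basal/mid/apical
zones (30 % each from the base) plus an apical cap (final 10 %), with
6/6/4/1 angular sectors.  Because the LV model is an open cylinder, the
apical cap is sampled on the annulus like the other zones.  Segment values
are sector means normalized to a polar-map maximum of 100 (hence invariant
to global rescaling); a segment below 50 counts as reduced, defect extent
is the reduced fraction of the 17 segments, scar means reduced in both
perfusion and metabolism, hibernating means reduced in perfusion with
preserved metabolism.  The 50 % threshold and segment-level scoring are
declared simplifications of proprietary clinical scorers; absolute
clinical scores are not reproduced.  Scar/hibernating need two tracer
studies, so they are computed by `viability_scores(perfusion, metabolism)`
rather than stored on a single polar map.

## Cohort simulation

Each synthetic subject has one true anatomy, two emission scans
(perfusion- and metabolism-like) and one acquired attenuation map per
scan.  Acquired maps differ from truth by a fresh breath-hold lung-volume
scale ~N(1, 0.10) truncated to [0.75, 1.30] (giving test–retest volume
ratios with spread ~0.2 and range within 0.6–1.4), independently drawn
artifacts (defaults: STN 0.25, SMA 0.30, truncation 1.0, LSTI 0.05,
FSTI 0.10, PMA 0.35 per scan), and a rigid axial misalignment with
per-scan probability 0.55/0.70 and offset ~N(7, 4) mm truncated to
[−18, 12] mm.  Artifact co-occurrence is independent Bernoulli per kind —
a declared simplification.  These prevalences are simulation inputs
mirroring reported clinical frequencies, not reproduction targets: a
20-subject cohort's tables are cohort-specific and the runner reports
descriptive statistics only, without hypothesis tests.

The correction chain runs cumulatively (fill → align → detruncate), each
stage is reconstructed (with caching of identical maps) and quantified
against the original-map reconstruction.  The whole study is a pure
function of (CohortConfig, master seed): per-subject seeds come from a
`SeedSequence` spawn and every random draw goes through them.

Default problem sizes: unit and acceptance tests use the clinical
128 × 128 in-plane matrix with 16–64 slices; the bundled cohort runs use
three subjects at 32 slices.  These sizes keep full runs on a laptop-class
single core in minutes while preserving organ proportions; the in-plane
matrix is never scaled down because the lung-volume bounds of the phantom
configuration assume clinical cross-sections.

## Known limitations

* The 2-D projector ignores axial cross-talk; artifacts in one slice
  cannot bias another, which slightly understates misalignment effects.
* The detruncation surrogate restores soft tissue only and depends on the
  nonAC support; limbs with no tracer signal would not be recovered.
* Tissue-inversion artifacts are corrected only implicitly (the fill
  operates on explicit masks); like the clinical practice it models, PMA
  bands are detected but not corrected.
* The polar-map scorer is segment-level and threshold-based; its absolute
  scores are not comparable to clinical software output.
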