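# petmrac

Artifacts in four-class MR-based attenuation maps and their impact on
myocardial PET quantification, studied end to end on synthetic thorax
phantoms.

## The problem

Integrated PET/MR systems correct cardiac PET emission data with segmented
MR attenuation maps: every voxel is classified as background, lung, fat or
soft tissue and assigned a fixed linear attenuation coefficient at 511 keV
(lung: 0.0224 cm⁻¹).  These maps are fragile.  Metal near the heart
(sternal wires, stents, valve replacements) punches air-valued
susceptibility voids into the map; the narrow MR field of view truncates
the arms; segmentation can invert lung/soft or fat/soft tissue; and
breathing between the MR map and the PET acquisition misaligns the two,
all of which bias the reconstructed myocardial uptake — enough, in the
worst cases, to flip a clinical read.

This package provides a fully synthetic, reproducible analogue of that
assessment for people developing or validating attenuation-correction QA
tools: a digital thorax phantom with a hot left-ventricular (LV) ring, an
attenuated parallel-beam projector with ordered-subset EM (OSEM)
reconstruction (3 iterations, 21 subsets, 5 mm Gaussian post-filter),
injectors for each artifact class, the three standard retrospective
corrections, and the quantitation chain used to score their effect.

## The method in brief

* **μ-map model** — voxelwise lookup μ(x) ∈ {0, 0.0224, 0.0854, 0.1000} cm⁻¹
  for background, lung, fat, soft tissue.
* **Emission model** — per line of response L:
  `y(L) = (∫_L a dl) · exp(−∫_L μ dl)`, computed with an exact Siddon
  ray tracer; reconstruction is multiplicative EM over interleaved angular
  subsets with the attenuation factors in the system model.
* **Corrections** — susceptibility voids are filled with the most frequent
  tissue class among the six face-adjacent voxels, propagated inward;
  misalignment is undone by an exhaustive integer-voxel translation search
  maximizing the Dice overlap of the nonAC-PET body support and the μ > 0
  body mask; truncated tissue inside the PET support is completed with
  soft-tissue μ.
* **Quantitation** — relative-difference maps
  `RD = (PET_corrected / PET_original) × 100 %`, myocardial statistics over
  a 42 %-of-maximum threshold segmentation, lung volume as
  (lung-voxel count) × (voxel volume) with a > 10 % test–retest
  incoherence flag, and a simplified 17-segment polar map with defect
  extent, scar and hibernating scores.

## Worked example

```python
from petmrac import (
    GridSpec, PhantomConfig, ArtifactSpec, Sphere,
    generate_phantom, inject_artifact, labels_to_mu,
    forward_project, reconstruct_osem, ReconProtocol,
    fill_susceptibility, relative_difference, segment_myocardium,
    lung_volume,
)

cfg = PhantomConfig.default(GridSpec((128, 128, 16)))
labels, activity = generate_phantom(cfg, seed=5)
print(f"lung volume: {lung_volume(labels):.3f} L")

protocol = ReconProtocol()                      # 3 it, 21 subsets, 5 mm
mu_true = labels_to_mu(labels)
sino = forward_project(activity, mu_true, protocol)

# stent-like air cavity at the LV wall, then the majority-fill correction
cavity = ArtifactSpec("SMA", Sphere((-10.6, -20.5, 1.0), 12.0))
damaged, mask = inject_artifact(labels, cavity)
recon_bad = reconstruct_osem(sino, labels_to_mu(damaged), protocol)
filled, report = fill_susceptibility(damaged, mask)
recon_fix = reconstruct_osem(sino, labels_to_mu(filled), protocol)

myo = segment_myocardium(recon_fix, cfg.lv_geometry().search_box(cfg.grid))
rd = relative_difference(recon_fix, recon_bad)
print(f"filled {report.n_artifact} voxels in {report.n_passes} passes")
print(f"myocardial RD after correction: {rd.rd[myo & rd.mask].mean():.1f} %")
```

Output:

```
lung volume: 0.613 L
filled 313 voxels in 3 passes
myocardial RD after correction: 107.0 %
```

The quarter-length (16-slice) thorax holds ~0.6 L of lung; the full
64-slice phantom defaults to the clinical 2.6 L scale.  The RD above 100 %
is the signature of a susceptibility void next to the myocardium: the
artifactual map under-corrects attenuation, so repairing it raises the
reconstructed myocardial activity by ~7 %.

A full synthetic cohort (test–retest scans, random artifact prevalences,
misalignment, correction and scoring) runs with

```bash
petmrac study run --seed 1 --subjects 3 --out-dir scratch/study
```

and writes per-artifact frequency tables, myocardial RD summaries,
misalignment recovery and lung-volume test–retest tables as CSV plus a
JSON report.

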