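"""Phantom generation, artifact injectors and rigid map shifts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petmrac.geometry import Band, Box, HalfPlane, Sphere
from petmrac.grid import GridSpec
from petmrac.phantom import (
    ActivityRatios,
    ArtifactError,
    ArtifactSpec,
    PhantomConfig,
    PhantomError,
    generate_phantom,
    inject_artifact,
    quantize_shift,
    shift_map,
)
from petmrac.quant import lung_volume
from petmrac.volumes import BACKGROUND, FAT, LUNG, SOFT


class TestGeneratePhantom:
    def test_default_full_grid_lung_volume_in_cohort_range(self):
        """At the clinical grid the lungs land in the 2.6 +/- 0.7 L range."""
        labels, _ = generate_phantom(PhantomConfig.default(), seed=7)
        vol = lung_volume(labels)
        assert 1.9 <= vol <= 3.3
        assert abs(vol / 2.6 - 1.0) <= 0.15

    def test_all_four_classes_present_and_myocardium_hot(self, thorax16):
        labels, act = thorax16["labels"], thorax16["activity"]
        counts = labels.class_counts()
        assert all(counts[c] > 0 for c in (BACKGROUND, LUNG, FAT, SOFT))
        ring = thorax16["cfg"].lv_geometry().ring_mask(thorax16["grid"])
        assert np.all(labels.labels[ring] == SOFT)
        assert act.values[ring].min() == act.values.max()

    def test_deterministic_per_seed(self):
        cfg = PhantomConfig.default(GridSpec((128, 128, 16)))
        l1, a1 = generate_phantom(cfg, seed=3)
        l2, a2 = generate_phantom(cfg, seed=3)
        l3, _ = generate_phantom(cfg, seed=4)
        assert np.array_equal(l1.labels, l2.labels)
        assert np.array_equal(a1.values, a2.values)
        assert not np.array_equal(l1.labels, l3.labels)

    def test_zero_fat_shell_has_no_fat(self):
        cfg = PhantomConfig.default(GridSpec((128, 128, 16)), fat_shell_mm=0.0)
        labels, _ = generate_phantom(cfg, seed=1)
        assert labels.class_counts()[FAT] == 0

    def test_lv_ring_outside_body_rejected(self):
        cfg = PhantomConfig.default(
            GridSpec((128, 128, 16)), lv_center_mm=(-120.0, 8.0, 1.0)
        )
        with pytest.raises(PhantomError):
            generate_phantom(cfg, seed=1)

    def test_config_invariants(self):
        grid = GridSpec((128, 128, 16))
        with pytest.raises(PhantomError):
            PhantomConfig.default(grid, lv_inner_mm=30.0, lv_outer_mm=20.0)
        with pytest.raises(PhantomError):
            PhantomConfig.default(grid, lung_target_L=7.0)
        with pytest.raises(PhantomError):
            ActivityRatios(myocardium=1.0, blood=2.0)


class TestInjectArtifact:
    def test_sternotomy_void_clears_fat_and_soft_in_sphere(self, thorax16):
        labels, cfg = thorax16["labels"], thorax16["cfg"]
        sphere = Sphere(cfg.sternum_center_mm, 14.0)
        region = sphere.contains(labels.grid)
        applicable = region & np.isin(labels.labels, (FAT, SOFT))
        out, changed = inject_artifact(labels, ArtifactSpec("STN", sphere))
        assert np.array_equal(changed, applicable)
        assert np.all(out.labels[changed] == BACKGROUND)

    def test_injectors_are_local(self, thorax16):
        labels, cfg = thorax16["labels"], thorax16["cfg"]
        specs = {
            "STN": ArtifactSpec("STN", Sphere(cfg.sternum_center_mm, 12.0)),
            "FSTI": ArtifactSpec("FSTI", Box((-60, -60, -15), (60, 60, 15))),
            "LSTI": ArtifactSpec("LSTI", Box((20, -70, -15), (130, 80, 15))),
            "PMA": ArtifactSpec(
                "PMA", Band(cfg.diaphragm_z_mm, cfg.diaphragm_z_mm + 7.8)
            ),
            "TRUNCATION": ArtifactSpec(
                "TRUNCATION", HalfPlane(cfg.body_half_axes_mm[0] + 5.0)
            ),
        }
        for kind, spec in specs.items():
            out, changed = inject_artifact(labels, spec)
            region = spec.region.contains(labels.grid)
            assert np.array_equal(out.labels[~region], labels.labels[~region]), kind
            assert changed.sum() > 0
            assert set(np.unique(out.labels)) <= {0, 1, 2, 3}

    def test_tissue_swaps_are_involutions(self, thorax16):
        labels = thorax16["labels"]
        for kind, region in [
            ("FSTI", Box((-170, -170, -25), (170, 170, 25))),
            ("LSTI", Box((20, -70, -15), (130, 80, 15))),
        ]:
            spec = ArtifactSpec(kind, region)
            once, _ = inject_artifact(labels, spec)
            twice, _ = inject_artifact(once, spec)
            assert np.array_equal(twice.labels, labels.labels), kind

    def test_pma_band_shrinks_lung_volume_by_band_count(self, thorax16):
        labels, cfg = thorax16["labels"], thorax16["cfg"]
        band = Band(cfg.diaphragm_z_mm, cfg.diaphragm_z_mm + 3 * 2.6)
        in_band_lung = band.contains(labels.grid) & (labels.labels == LUNG)
        out, _ = inject_artifact(labels, ArtifactSpec("PMA", band))
        dv = lung_volume(labels) - lung_volume(out)
        expected = in_band_lung.sum() * labels.grid.voxel_volume_mm3 * 1e-6
        assert dv == pytest.approx(expected, abs=1e-12)

    def test_truncation_clears_everything_beyond_plane(self, thorax16):
        labels = thorax16["labels"]
        plane = HalfPlane(120.0, axis="x", direction=1)
        out, _ = inject_artifact(labels, ArtifactSpec("TRUNCATION", plane))
        region = plane.contains(labels.grid)
        assert np.all(out.labels[region] == BACKGROUND)

    def test_empty_applicable_tissue_raises(self, thorax16):
        corner = Sphere((160.0, 110.0, 0.0), 5.0)  # air outside the body
        with pytest.raises(ArtifactError, match="STN"):
            inject_artifact(thorax16["labels"], ArtifactSpec("STN", corner))

    def test_misalignment_not_injectable(self, thorax16):
        spec = ArtifactSpec("MISALIGNMENT", shift_mm=(0.0, 0.0, 10.0))
        with pytest.raises(ArtifactError):
            inject_artifact(thorax16["labels"], spec)

    def test_misalignment_spec_bounds(self):
        with pytest.raises(ArtifactError):
            ArtifactSpec("MISALIGNMENT", shift_mm=(0.0, 0.0, 31.0))
        with pytest.raises(ArtifactError):
            ArtifactSpec("STN")  # region required


class TestShiftMap:
    def test_zero_shift_is_identity(self, thorax16):
        out = shift_map(thorax16["mu"], (0.0, 0.0, 0.0))
        assert np.array_equal(out.mu, thorax16["mu"].mu)

    def test_18mm_moves_seven_voxels_cranially(self, thorax16):
        """18 mm on a 2.6 mm grid rounds to 7 whole voxels."""
        assert quantize_shift((0, 0, 18.0), (2.6, 2.6, 2.6)) == (0, 0, 7)
        out = shift_map(thorax16["mu"], (0.0, 0.0, 18.0))
        assert np.array_equal(out.mu[:, :, 7:], thorax16["mu"].mu[:, :, :-7])
        assert np.all(out.mu[:, :, :7] == 0.0)

    def test_round_half_away_from_zero(self):
        assert quantize_shift((1.3, -1.3, 0.0), (2.6, 2.6, 2.6)) == (1, -1, 0)

    @given(st.integers(-7, 7))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_shift_then_inverse_restores_interior(self, thorax16, k):
        mm = (0.0, 0.0, k * 2.6)
        neg = tuple(-v for v in mm)
        back = shift_map(shift_map(thorax16["mu"], mm), neg)
        nz = thorax16["grid"].shape[2]
        lo, hi = max(0, -k) + abs(k), nz - abs(k) - max(0, k)
        interior = slice(abs(k), nz - abs(k))
        assert np.array_equal(
            back.mu[:, :, interior], thorax16["mu"].mu[:, :, interior]
        )

    def test_rejects_nonfinite_and_oversized(self, thorax16):
        with pytest.raises(ValueError):
            shift_map(thorax16["mu"], (np.nan, 0, 0))
        with pytest.raises(ValueError):
            shift_map(thorax16["mu"], (0, 0, 31.0))
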