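"""Quantitation chain: RD maps, myocardium segmentation, lung volumes,
polar maps."""

import numpy as np
import pytest

from petmrac.geometry import LVGeometry
from petmrac.grid import GridSpec
from petmrac.quant import (
    QuantError,
    lung_volume,
    myo_stats,
    polar_map_17,
    relative_difference,
    segment_myocardium,
    viability_scores,
)
from petmrac.quant import test_retest as retest_report
from petmrac.volumes import LUNG, ActivityMap, TissueLabelMap


def _amap(values):
    grid = GridSpec(values.shape)
    return ActivityMap(grid, values)


class TestRelativeDifference:
    def test_identity_is_100_percent(self):
        rng = np.random.default_rng(0)
        x = _amap(rng.uniform(0, 5, (16, 16, 16)))
        rdm = relative_difference(x, x)
        assert rdm.mask.any()
        assert np.allclose(rdm.rd[rdm.mask], 100.0)

    def test_doubling_is_200_percent(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 5, (16, 16, 16))
        rdm = relative_difference(_amap(2 * x), _amap(x))
        assert np.allclose(rdm.rd[rdm.mask], 200.0)

    def test_matches_scalar_oracle_elementwise(self):
        rng = np.random.default_rng(2)
        orig = rng.uniform(0, 2, (16, 16, 16))
        corr = rng.uniform(0, 2, (16, 16, 16))
        rdm = relative_difference(_amap(corr), _amap(orig), floor=0.05)
        it = np.nditer(orig, flags=["multi_index"])
        for o in it:
            idx = it.multi_index
            if o >= 0.05 * orig.max():
                assert rdm.mask[idx]
                assert rdm.rd[idx] == pytest.approx(100.0 * corr[idx] / o)
            else:
                assert not rdm.mask[idx]

    def test_rejects_zero_original_and_bad_floor(self):
        z = _amap(np.zeros((16, 16, 16)))
        x = _amap(np.ones((16, 16, 16)))
        with pytest.raises(QuantError):
            relative_difference(x, z)
        with pytest.raises(QuantError):
            relative_difference(x, x, floor=0.0)


class TestSegmentMyocardium:
    def test_threshold_at_42_percent_of_regional_max(self):
        vals = np.zeros((16, 16, 16))
        vals[0, 0, 0], vals[0, 0, 1], vals[0, 0, 2] = 100.0, 50.0, 41.9
        region = np.zeros_like(vals, dtype=bool)
        region[0, 0, :3] = True
        mask = segment_myocardium(_amap(vals), region)
        assert mask[0, 0, 0] and mask[0, 0, 1] and not mask[0, 0, 2]
        assert mask.sum() == 2

    def test_recovers_ring_on_reconstruction(self, thorax16, recon_ac16):
        cfg, grid = thorax16["cfg"], thorax16["grid"]
        lv = cfg.lv_geometry()
        mask = segment_myocardium(recon_ac16, lv.search_box(grid))
        ring = lv.ring_mask(grid)
        inter = (mask & ring).sum()
        dice = 2 * inter / (mask.sum() + ring.sum())
        assert dice > 0.6

    def test_flat_region_raises(self):
        vals = np.ones((16, 16, 16))
        region = np.ones_like(vals, dtype=bool)
        with pytest.raises(QuantError):
            segment_myocardium(_amap(vals), region)


class TestMyoStats:
    def test_single_voxel_and_constant(self):
        vals = np.zeros((16, 16, 16))
        vals[3, 4, 5] = 2.5
        mask = vals > 0
        s = myo_stats(_amap(vals), mask)
        assert s.suv_mean == s.suv_max == 2.5 and s.n_voxels == 1

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 9, (16, 16, 16))
        mask = rng.random((16, 16, 16)) < 0.2
        s = myo_stats(_amap(vals), mask)
        sel = [vals[i, j, k] for i, j, k in zip(*np.nonzero(mask))]
        assert s.suv_mean == pytest.approx(float(np.mean(sel)))
        assert s.suv_max == max(sel)
        with pytest.raises(QuantError):
            myo_stats(_amap(vals), np.zeros_like(mask))


class TestLungVolume:
    def test_single_voxel_arithmetic(self):
        grid = GridSpec((16, 16, 16))
        lab = np.zeros(grid.shape, dtype=np.uint8)
        lab[0, 0, 0] = LUNG
        vol = lung_volume(TissueLabelMap(grid, lab))
        assert vol == pytest.approx(1.7576e-5, rel=1e-12)

    def test_linearity_in_voxel_count(self):
        grid = GridSpec((128, 128, 16))
        lab = np.zeros(grid.shape, dtype=np.uint8)
        flat = lab.reshape(-1)
        flat[:147928] = LUNG
        vol = lung_volume(TissueLabelMap(grid, flat.reshape(grid.shape)))
        assert vol == pytest.approx(2.600, abs=1e-3)

    def test_mu_map_counts_lung_coefficient(self, thorax16):
        assert lung_volume(thorax16["mu"]) == lung_volume(thorax16["labels"])


class TestTestRetest:
    @pytest.mark.parametrize(
        "v1,v2,ratio,flag",
        [
            (2.6, 2.6, 1.0, False),
            (2.86, 2.6, 1.1, False),  # boundary: not strictly greater
            (3.64, 2.6, 1.4, True),
            (1.56, 2.6, 0.6, True),
        ],
    )
    def test_ratio_and_incoherence_flag(self, v1, v2, ratio, flag):
        rep = retest_report(v1, v2)
        assert rep.ratio == pytest.approx(ratio)
        assert rep.incoherent is flag

    def test_zero_retest_rejected(self):
        with pytest.raises(QuantError):
            retest_report(2.6, 0.0)


def _ring_activity(grid, geom, value=10.0, sector_scale=None):
    """Uniform LV ring, optionally rescaling one angular sector."""
    X, Y, Z = grid.meshgrid()
    vals = np.zeros(grid.shape)
    vals[geom.ring_mask(grid)] = value
    if sector_scale is not None:
        lo, hi, frac_lo, frac_hi, s = sector_scale
        phi = np.broadcast_to(np.arctan2(Y - geom.center_mm[1], X - geom.center_mm[0]),
                              grid.shape)
        frac = np.broadcast_to((geom.base_z_mm - Z) / geom.extent_mm, grid.shape)
        sel = (phi >= lo) & (phi < hi) & (frac >= frac_lo) & (frac < frac_hi)
        vals[sel] *= s
    return ActivityMap(grid, vals)


@pytest.fixture(scope="module")
def lv_grid():
    grid = GridSpec((64, 64, 32))
    geom = LVGeometry((0.0, 0.0, 0.0), inner_mm=14.0, outer_mm=26.0, extent_mm=60.0)
    return grid, geom


class TestPolarMap:
    def test_uniform_ring_scores_100_everywhere(self, lv_grid):
        grid, geom = lv_grid
        pm = polar_map_17(_ring := _ring_activity(grid, geom), geom)
        assert np.allclose(pm.segments, 100.0)
        assert pm.defect_extent_pct == 0.0

    def test_one_dead_mid_sector_gives_one_defect_segment(self, lv_grid):
        """Zeroing one of six mid sectors leaves exactly 1/17 segments
        reduced: extent 5.9%."""
        grid, geom = lv_grid
        sector = (-np.pi, -np.pi + np.pi / 3, 0.30, 0.60, 0.0)
        pm = polar_map_17(_ring_activity(grid, geom, sector_scale=sector), geom)
        assert (pm.segments < 50.0).sum() == 1
        assert pm.defect_extent_pct == pytest.approx(100.0 / 17.0, abs=1e-9)

    def test_segments_invariant_to_global_rescale(self, lv_grid):
        grid, geom = lv_grid
        sector = (0.0, np.pi / 2, 0.0, 0.30, 0.3)
        a = polar_map_17(_ring_activity(grid, geom, sector_scale=sector), geom)
        b = polar_map_17(
            ActivityMap(grid, 7.3 * _ring_activity(grid, geom, sector_scale=sector).values),
            geom,
        )
        np.testing.assert_allclose(a.segments, b.segments, rtol=1e-12)

    def test_mismatch_scores_hibernating_not_scar(self, lv_grid):
        grid, geom = lv_grid
        sector = (-np.pi, -np.pi + np.pi / 3, 0.30, 0.60, 0.0)
        perf = polar_map_17(_ring_activity(grid, geom, sector_scale=sector), geom)
        met = polar_map_17(_ring_activity(grid, geom), geom)
        scores = viability_scores(perf, met)
        assert scores["hibernating_pct"] == pytest.approx(100.0 / 17.0)
        assert scores["scar_pct"] == 0.0
        both = viability_scores(perf, perf)
        assert both["scar_pct"] == pytest.approx(100.0 / 17.0)
        assert both["hibernating_pct"] == 0.0

    def test_geometry_outside_volume_raises(self, lv_grid):
        grid, geom = lv_grid
        far = LVGeometry((0.0, 0.0, 500.0), 14.0, 26.0, 60.0)
        with pytest.raises(QuantError):
            polar_map_17(_ring_activity(grid, geom), far)
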