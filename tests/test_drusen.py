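"""Drusen quantification against brute-force oracles and closed-form examples."""

import numpy as np
import pytest

from octlayers.drusen import (
    DrusenVolumeMask,
    drusen_height_profile,
    drusen_mask_bscan,
    drusen_volume,
    enface_projection,
    estimate_healthy_offset,
    filter_by_component_height,
    quantify_drusen,
    rectify,
)


# -- independent oracles ----------------------------------------------------

def offset_oracle(values, bin_width=1.0):
    """Histogram-mode healthy offset, computed the slow explicit way."""
    values = np.sort(np.asarray(values, dtype=float))
    lo = np.floor(values.min() / bin_width) * bin_width
    nbins = int(np.floor((values.max() - lo) / bin_width)) + 1
    counts = [0] * nbins
    member = []
    for v in values:
        i = min(int((v - lo) / bin_width), nbins - 1)
        counts[i] += 1
        member.append(i)
    mode = counts.index(max(counts))
    sel = [v for v, i in zip(values, member) if abs(i - mode) <= 1]
    return sum(sel) / len(sel)


def flood_fill_filter(enface, min_height, connectivity):
    """Component filter via explicit BFS flood fill on the en-face map."""
    enface = np.asarray(enface)
    d, w = enface.shape
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(db, dx) for db in (-1, 0, 1) for dx in (-1, 0, 1) if (db, dx) != (0, 0)]
    seen = np.zeros_like(enface, dtype=bool)
    keep = np.zeros_like(enface, dtype=bool)
    for b in range(d):
        for x in range(w):
            if enface[b, x] <= 0 or seen[b, x]:
                continue
            queue, comp = [(b, x)], []
            seen[b, x] = True
            while queue:
                cb, cx = queue.pop()
                comp.append((cb, cx))
                for db, dx in steps:
                    nb, nx = cb + db, cx + dx
                    if 0 <= nb < d and 0 <= nx < w and enface[nb, nx] > 0 and not seen[nb, nx]:
                        seen[nb, nx] = True
                        queue.append((nb, nx))
            if max(enface[c] for c in comp) >= min_height:
                for c in comp:
                    keep[c] = True
    return keep


# -- rectification ----------------------------------------------------------

class TestRectify:
    def test_constant_offset(self):
        bm = np.full(8, 100.0)
        elev = rectify(bm - 10.0, bm)
        np.testing.assert_array_equal(elev.e, 10.0)
        assert elev.valid.all()

    def test_equal_layers_give_zero(self):
        bm = np.linspace(50, 60, 5)
        np.testing.assert_array_equal(rectify(bm, bm).e, 0.0)

    def test_nan_marks_invalid_locally(self):
        bm = np.full(4, 100.0)
        rpe = bm - 10.0
        rpe[2] = np.nan
        elev = rectify(rpe, bm)
        assert not elev.valid[2] and elev.valid[[0, 1, 3]].all()
        np.testing.assert_array_equal(elev.e[[0, 1, 3]], 10.0)

    def test_negative_elevation_clamped(self, caplog):
        bm = np.full(3, 100.0)
        elev = rectify(bm + 2.0, bm)  # RPE below BM
        np.testing.assert_array_equal(elev.e, 0.0)

    def test_width_mismatch_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            rectify(np.zeros(4), np.zeros(5))

    def test_rigid_shift_invariance(self, rng):
        """The whole pipeline ignores rigid vertical shifts of both layers."""
        w = 64
        bm = 80.0 + 3.0 * np.sin(np.linspace(0, 3, w))
        bump = np.where(np.abs(np.arange(w) - 30) < 6, 5.0, 0.0)
        rpe = bm - 10.0 - bump
        base = quantify_drusen(rpe[None], bm[None], height=128)
        for _ in range(100):
            s = rng.uniform(-20, 20)
            shifted = quantify_drusen(rpe[None] + s, bm[None] + s, height=128)
            assert shifted.offset.d == pytest.approx(base.offset.d, abs=1e-9)
            np.testing.assert_array_equal(shifted.mask.enface, base.mask.enface)


# -- healthy offset ---------------------------------------------------------

class TestHealthyOffset:
    def test_worked_example_mode_with_empty_neighbors(self):
        elev = rectify(np.zeros(7), np.array([10, 10, 10, 14, 15, 10, 10.0]))
        assert estimate_healthy_offset(elev, bin_width=1.0).d == pytest.approx(10.0)

    def test_constant_elevation(self):
        elev = rectify(np.zeros(9), np.full(9, 7.25))
        assert estimate_healthy_offset(elev).d == pytest.approx(7.25)

    def test_no_valid_ascans_rejected(self):
        elev = rectify(np.full(3, np.nan), np.zeros(3))
        with pytest.raises(ValueError, match="valid"):
            estimate_healthy_offset(elev)

    def test_matches_bruteforce_oracle_on_random_profiles(self, rng):
        for _ in range(1000):
            vals = rng.uniform(0, 20, size=rng.integers(3, 40))
            elev = rectify(np.zeros(vals.size), vals)
            got = estimate_healthy_offset(elev, bin_width=1.0).d
            assert got == pytest.approx(offset_oracle(vals, 1.0), abs=1e-9)

    def test_recovery_with_minority_drusen_and_noise(self, rng):
        """< 50% drusen coverage + sigma <= 0.3 noise: d recovered within max(1, 3*sigma)."""
        w, d_true, sigma = 512, 11.0, 0.3
        e = np.full(w, d_true) + rng.normal(0, sigma, w)
        drusen_cols = rng.choice(w, size=int(0.4 * w), replace=False)
        e[drusen_cols] += rng.uniform(2, 15, drusen_cols.size)
        elev = rectify(np.zeros(w), e)
        got = estimate_healthy_offset(elev, bin_width=1.0).d
        assert abs(got - d_true) <= max(1.0, 3 * sigma)


# -- heights and voxelization ----------------------------------------------

class TestDrusenHeights:
    def test_subtract_and_clamp(self):
        elev = rectify(np.zeros(7), np.array([10, 10, 10, 14, 15, 10, 10.0]))
        np.testing.assert_array_equal(
            drusen_height_profile(elev, 10.0), [0, 0, 0, 4, 5, 0, 0])

    def test_at_or_below_offset_gives_zero(self):
        elev = rectify(np.zeros(4), np.full(4, 8.0))
        np.testing.assert_array_equal(drusen_height_profile(elev, 8.0), 0.0)
        np.testing.assert_array_equal(drusen_height_profile(elev, 12.0), 0.0)

    def test_single_ascan_voxel_rows(self):
        rpe = np.array([90.0])
        bm = np.array([104.0])
        mask = drusen_mask_bscan(rpe, bm, 10.0, height=128)
        assert mask[:, 0].sum() == 4
        assert mask[90:94, 0].all()  # rows 90..93 inclusive

    def test_empty_profile_empty_mask(self):
        bm = np.full(6, 100.0)
        assert not drusen_mask_bscan(bm - 10.0, bm, 10.0, 128).any()

    def test_column_sums_match_heights_within_rounding(self, rng):
        w = 32
        bm = np.full(w, 100.0) + rng.uniform(-2, 2, w)
        bump = np.maximum(0, rng.uniform(-5, 8, w))
        rpe = bm - 10.0 - bump
        mask = drusen_mask_bscan(rpe, bm, 10.0, height=128)
        np.testing.assert_allclose(mask.sum(axis=0), bump, atol=1.0)


class TestEnfaceAndFilter:
    def test_enface_examples(self):
        assert not enface_projection(np.zeros((3, 8, 8), dtype=bool)).any()
        vol = np.zeros((4, 10, 9), dtype=bool)
        vol[2, 3:7, 7] = True
        ef = enface_projection(vol)
        assert ef[2, 7] == 4 and ef.sum() == 4

    def test_enface_conserves_voxel_count(self, rng):
        vol = rng.random((3, 6, 5)) > 0.5
        assert enface_projection(vol).sum() == vol.sum()

    def test_inconsistent_widths_rejected(self):
        with pytest.raises(ValueError, match="width"):
            enface_projection([np.zeros((4, 5), dtype=bool), np.zeros((4, 6), dtype=bool)])

    def test_component_height_rule_is_component_level(self):
        # one component, peak height 2, with 1-px fringes: kept whole
        vol = np.zeros((1, 8, 5), dtype=bool)
        vol[0, 0, 1] = True           # fringe, height 1
        vol[0, 0:2, 2] = True         # peak, height 2
        vol[0, 0, 3] = True           # fringe, height 1
        kept = filter_by_component_height(DrusenVolumeMask(vol), min_height=2)
        np.testing.assert_array_equal(kept.voxels, vol)
        # a lone height-1 component is removed entirely
        solo = np.zeros((1, 8, 5), dtype=bool)
        solo[0, 0, 1] = True
        assert not filter_by_component_height(DrusenVolumeMask(solo), 2).voxels.any()

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle(self, connectivity, rng):
        for _ in range(1000):
            heights = rng.integers(0, 4, size=(16, 16))
            heights[rng.random((16, 16)) < 0.6] = 0
            vol = np.arange(8)[None, :, None] < heights[:, None, :]
            got = filter_by_component_height(
                DrusenVolumeMask(vol), min_height=2, connectivity=connectivity)
            expected_keep = flood_fill_filter(heights, 2, connectivity)
            np.testing.assert_array_equal(got.enface > 0, expected_keep)
            assert got.voxels.sum() == heights[expected_keep].sum()

    def test_filter_only_deletes(self, rng):
        heights = rng.integers(0, 3, size=(8, 8))
        vol = np.arange(6)[None, :, None] < heights[:, None, :]
        filtered = filter_by_component_height(DrusenVolumeMask(vol), 2)
        assert not (filtered.voxels & ~vol).any()
        surviving = filtered.enface
        from scipy import ndimage
        labels, n = ndimage.label(surviving > 0, structure=np.ones((3, 3)))
        for i in range(1, n + 1):
            assert surviving[labels == i].max() >= 2


class TestVolume:
    def test_volume_arithmetic(self):
        vol = np.zeros((2, 8, 8), dtype=bool)
        vol.ravel()[:10] = True
        v, n = drusen_volume(DrusenVolumeMask(vol, spacing=(4.0, 6.0, 120.0)))
        assert n == 10 and v == pytest.approx(28_800.0)

    def test_empty_mask(self):
        v, n = drusen_volume(DrusenVolumeMask(np.zeros((1, 4, 4), dtype=bool),
                                              spacing=(1, 1, 1)))
        assert v == 0.0 and n == 0

    def test_missing_spacing_warns(self):
        with pytest.warns(UserWarning, match="spacing"):
            v, n = drusen_volume(DrusenVolumeMask(np.ones((1, 2, 2), dtype=bool)))
        assert v is None and n == 4

    def test_filtering_never_increases_volume(self, rng):
        heights = rng.integers(0, 3, size=(6, 10))
        vol = np.arange(5)[None, :, None] < heights[:, None, :]
        mask = DrusenVolumeMask(vol, spacing=(2.0, 2.0, 10.0))
        v0, _ = drusen_volume(mask)
        v1, _ = drusen_volume(filter_by_component_height(mask, 2))
        assert v1 <= v0


class TestEndToEnd:
    def test_healthy_volume_is_empty(self):
        w = 64
        bm = np.tile(90.0 + 4 * np.sin(np.linspace(0, 2, w)), (4, 1))
        result = quantify_drusen(bm - 9.0, bm, height=128)
        assert not result.mask.voxels.any()
        assert result.offset.d == pytest.approx(9.0)

    def test_deterministic(self, rng):
        bm = np.tile(np.full(32, 100.0), (3, 1)) + rng.uniform(-1, 1, (3, 32))
        rpe = bm - 10.0 - np.maximum(0, rng.uniform(-4, 6, (3, 32)))
        a = quantify_drusen(rpe, bm, height=128, spacing=(4, 11, 120))
        b = quantify_drusen(rpe, bm, height=128, spacing=(4, 11, 120))
        np.testing.assert_array_equal(a.mask.voxels, b.mask.voxels)
        assert a.volume_um3 == b.volume_um3

    def test_legacy_polynomial_mode_runs(self, rng):
        w = 64
        bm = np.tile(np.full(w, 100.0), (2, 1))
        rpe = bm - 10.0
        rpe[0, 20:26] -= 6.0
        modern = quantify_drusen(rpe, bm, height=128)
        legacy = quantify_drusen(rpe, bm, height=128, legacy_polynomial_fit=True)
        assert modern.mask.voxels.any()
        assert legacy.mask.voxels.shape == modern.mask.voxels.shape
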