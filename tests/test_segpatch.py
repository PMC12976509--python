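"""Foreground segmentation, patch tiling/filtering and random sampling."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skimage import draw

from mitoscore import segpatch, simcell
from mitoscore.imaging_io import normalize_percentile
from mitoscore.segpatch import FieldUnusableError, Patch, filter_patches, sample_patches, tile_patches


def _brute_force_origins(h, w, size, stride):
    return [
        (r, c)
        for r in range(0, h - size + 1, stride)
        for c in range(0, w - size + 1, stride)
    ]


class TestTilePatches:
    def test_2048_field_yields_400_patches(self):
        img = np.zeros((2048, 2048), dtype=np.uint8)
        mask = np.ones_like(img, dtype=bool)
        patches = tile_patches(img, mask, patch_size=112, stride=100)
        assert len(patches) == 400
        assert patches[0].origin_rc == (0, 0)
        assert patches[-1].origin_rc == (1900, 1900)

    @given(
        h=st.integers(112, 400),
        w=st.integers(112, 400),
        size=st.integers(16, 112),
        stride=st.integers(10, 120),
    )
    @settings(max_examples=25, deadline=None)
    def test_origins_match_brute_force_enumeration(self, h, w, size, stride):
        img = np.zeros((h, w), dtype=np.uint8)
        patches = tile_patches(img, np.ones((h, w), bool), patch_size=size, stride=stride)
        assert [p.origin_rc for p in patches] == _brute_force_origins(h, w, size, stride)

    def test_exact_fit_single_patch(self):
        img = np.arange(112 * 112, dtype=np.uint16).reshape(112, 112)
        patches = tile_patches(img, np.ones((112, 112), bool))
        assert len(patches) == 1
        assert patches[0].origin_rc == (0, 0)
        np.testing.assert_array_equal(patches[0].pixels, img)

    def test_all_foreground_mask_gives_unit_fractions(self):
        patches = tile_patches(np.zeros((512, 512)), np.ones((512, 512), bool))
        assert all(p.fg_fraction == 1.0 for p in patches)

    def test_oversized_patch_rejected(self):
        with pytest.raises(ValueError):
            tile_patches(np.zeros((64, 64)), np.ones((64, 64), bool), patch_size=112)

    def test_retained_patches_re_check_mask_coverage(self):
        rng = np.random.default_rng(6)
        mask = rng.random((512, 512)) > 0.4
        img = rng.random((512, 512))
        kept = filter_patches(tile_patches(img, mask), min_fg=0.5)
        for p in kept:
            r, c = p.origin_rc
            assert mask[r : r + 112, c : c + 112].mean() >= 0.5


class TestFilterPatches:
    def _patch(self, fg):
        return Patch(pixels=np.zeros((4, 4)), origin_rc=(0, 0), fg_fraction=fg)

    def test_boundary_keeps_exactly_half(self):
        patches = [self._patch(f) for f in (0.49, 0.50, 0.51)]
        kept = filter_patches(patches, min_fg=0.5)
        assert [p.fg_fraction for p in kept] == [0.50, 0.51]

    def test_all_background_empty_result(self):
        assert filter_patches([self._patch(0.0)] * 5, min_fg=0.5) == []

    def test_zero_threshold_is_identity(self):
        patches = [self._patch(f) for f in (0.0, 0.3, 1.0)]
        assert filter_patches(patches, min_fg=0.0) == patches


class TestSamplePatches:
    def _pool(self, n):
        return [Patch(pixels=np.full((2, 2), i), origin_rc=(0, i), fg_fraction=1.0) for i in range(n)]

    def test_saturated_pool_returns_all(self):
        pool = self._pool(4)
        drawn = sample_patches(pool, k=4, seed=0)
        assert sorted(p.origin_rc for p in drawn) == [p.origin_rc for p in pool]

    def test_seed_determinism(self):
        pool = self._pool(40)
        a = [p.origin_rc for p in sample_patches(pool, k=4, seed=7)]
        b = [p.origin_rc for p in sample_patches(pool, k=4, seed=7)]
        c = [p.origin_rc for p in sample_patches(pool, k=4, seed=8)]
        assert a == b
        assert a != c

    def test_inclusion_probability_is_k_over_n(self):
        """Uniform sampling without replacement: each of 8 patches appears
        with frequency k/n = 0.5 over many draws."""
        pool = self._pool(8)
        counts = np.zeros(8)
        for s in range(10_000):
            for p in sample_patches(pool, k=4, seed=s):
                counts[p.origin_rc[1]] += 1
        np.testing.assert_allclose(counts / 10_000, 0.5, atol=0.02)

    def test_small_pool_samples_with_replacement_and_warns(self):
        pool = self._pool(2)
        with pytest.warns(UserWarning, match="replacement"):
            drawn = sample_patches(pool, k=4, seed=0)
        assert len(drawn) == 4

    def test_empty_pool_raises_with_field_id(self):
        with pytest.raises(FieldUnusableError) as exc:
            sample_patches([], k=4, seed=0, field_id="f42")
        assert exc.value.field_id == "f42"


class TestSegmentForeground:
    def test_all_zero_image_gives_empty_mask(self):
        mask = segpatch.segment_foreground(np.zeros((256, 256)))
        assert not mask.mask.any()

    def test_non_2d_rejected(self):
        with pytest.raises(ValueError):
            segpatch.segment_foreground(np.zeros((4, 4, 4)))

    def test_single_disc_one_component_with_analytic_area(self):
        img = np.zeros((256, 256))
        rr, cc = draw.disk((128, 128), 50.5)
        img[rr, cc] = 1.0
        mask = segpatch.segment_foreground(img, sigma=4, min_object_px=500)
        from scipy import ndimage

        labels, n = ndimage.label(mask.mask)
        assert n == 1
        assert abs(mask.mask.sum() - math.pi * 50**2) / (math.pi * 50**2) < 0.2

    def test_recovers_simulated_cell_footprints(self):
        """Coverage >= 95% of truth and Jaccard >= 0.7 on noiseless fields
        across the three phenotype conditions."""
        coverages, jaccards = [], []
        for phi, seed in [(p, s) for p in (0.15, 0.5, 0.85) for s in range(7)]:
            sim = simcell.simulate_field(
                simcell.MorphologySpec(phi=phi, seed=300 + seed, noise_level=0.0)
            )
            pred = segpatch.segment_foreground(normalize_percentile(sim.image)).mask
            inter = (pred & sim.truth_mask).sum()
            coverages.append(inter / sim.truth_mask.sum())
            jaccards.append(inter / (pred | sim.truth_mask).sum())
        assert min(coverages) >= 0.95
        assert min(jaccards) >= 0.7


def test_tile_filter_sample_is_pure_function_of_inputs(normalized_field, noiseless_field):
    mask = noiseless_field.truth_mask
    a = segpatch.patch_pool(normalized_field, mask)
    b = segpatch.patch_pool(normalized_field, mask)
    assert [p.origin_rc for p in a] == [p.origin_rc for p in b]
    sa = sample_patches(a, k=4, seed=5)
    sb = sample_patches(b, k=4, seed=5)
    assert [p.origin_rc for p in sa] == [p.origin_rc for p in sb]
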