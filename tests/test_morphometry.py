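"""Shape metrics, skeleton graphs and the classical baseline's behaviour."""

import math

import numpy as np
import pytest
from scipy import ndimage
from skimage import draw

from mitoscore import morphometry, simcell
from mitoscore.imaging_io import normalize_percentile
from mitoscore.morphometry import field_morphometry, segment_mitochondria, shape_metrics, skeleton_graph


def _disc_mask(radius, pad=20):
    side = 2 * radius + 2 * pad
    img = np.zeros((side, side), bool)
    rr, cc = draw.disk((side // 2, side // 2), radius + 0.5)
    img[rr, cc] = True
    return img


def _labelled(mask):
    return ndimage.label(mask, structure=np.ones((3, 3), int))[0]


class TestShapeMetrics:
    def test_disc_form_factor_and_aspect_ratio_near_one(self):
        (obj,) = shape_metrics(_labelled(_disc_mask(30)))
        assert obj.form_factor == pytest.approx(1.0, abs=0.05)
        assert obj.aspect_ratio == pytest.approx(1.0, abs=0.05)
        assert obj.reliable

    def test_rectangle_aspect_ratio_equals_side_ratio(self):
        mask = np.zeros((60, 120), bool)
        mask[20:40, 20:100] = True  # 20 x 80
        (obj,) = shape_metrics(_labelled(mask))
        assert obj.aspect_ratio == pytest.approx(4.0, abs=0.1)

    def test_rectangle_form_factor_matches_closed_form(self):
        # FF = (2(80+20))^2 / (4*pi*1600) = 1.989
        mask = np.zeros((60, 120), bool)
        mask[20:40, 20:100] = True
        (obj,) = shape_metrics(_labelled(mask))
        assert obj.form_factor == pytest.approx((2 * (80 + 20)) ** 2 / (4 * math.pi * 1600), abs=0.1)

    def test_one_pixel_wide_object_flagged_unreliable(self):
        mask = np.zeros((20, 20), bool)
        mask[10, 2:18] = True
        (obj,) = shape_metrics(_labelled(mask))
        assert not obj.reliable

    def test_form_factor_at_least_one_up_to_discretization(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            mask = np.zeros((80, 80), bool)
            r = rng.integers(4, 20)
            rr, cc = draw.ellipse(40, 40, r, rng.integers(r, 30))
            mask[rr, cc] = True
            for obj in shape_metrics(_labelled(mask)):
                if obj.reliable:
                    assert obj.form_factor >= 1.0 - 0.05
                    assert obj.aspect_ratio >= 1.0


class TestSkeletonGraph:
    def test_straight_segment_is_one_branch(self):
        mask = np.zeros((20, 70), bool)
        mask[10, 10:60] = True  # 50 px line
        g = skeleton_graph(mask)
        assert g.n_branches == 1
        assert g.n_junctions == 0
        assert g.n_endpoints == 2
        assert g.branch_lengths[0] == pytest.approx(49, abs=1)

    def test_plus_sign_has_four_branches_one_junction(self):
        mask = np.zeros((41, 41), bool)
        mask[20, 5:36] = True
        mask[5:36, 20] = True
        g = skeleton_graph(mask)
        assert g.n_branches == 4
        assert g.n_junctions == 1

    def test_disjoint_union_is_additive(self):
        a = np.zeros((30, 60), bool)
        a[10, 5:45] = True
        b = np.zeros((30, 60), bool)
        b[22, 10:30] = True
        ga, gb, gu = skeleton_graph(a), skeleton_graph(b), skeleton_graph(a | b)
        assert gu.n_branches == ga.n_branches + gb.n_branches
        assert gu.total_length == pytest.approx(ga.total_length + gb.total_length, abs=1e-9)

    def test_ring_is_single_closed_branch(self):
        mask = np.zeros((60, 60), bool)
        rr, cc = draw.disk((30, 30), 20.5)
        mask[rr, cc] = True
        rr, cc = draw.disk((30, 30), 12.5)
        mask[rr, cc] = False
        g = skeleton_graph(mask)
        assert g.n_junctions == 0
        assert g.n_branches == 1
        assert g.n_endpoints == 0

    def test_total_length_invariant_under_translation_and_rotation(self):
        mask = np.zeros((64, 64), bool)
        mask[20, 8:40] = True
        mask[20:45, 30] = True
        base = skeleton_graph(mask).total_length
        shifted = np.roll(np.roll(mask, 7, axis=0), 5, axis=1)
        rotated = np.rot90(mask)
        assert skeleton_graph(shifted).total_length == pytest.approx(base, abs=1.5)
        assert skeleton_graph(rotated).total_length == pytest.approx(base, abs=1.5)

    def test_empty_mask_empty_graph(self):
        g = skeleton_graph(np.zeros((10, 10), bool))
        assert g.n_branches == 0 and g.n_junctions == 0 and g.total_length == 0.0


class TestSegmentMitochondria:
    def test_all_zero_image_no_objects(self):
        assert segment_mitochondria(np.zeros((64, 64))).max() == 0

    def test_single_bright_disc_is_one_object(self):
        img = np.full((64, 64), 0.05)
        rr, cc = draw.disk((32, 32), 5.5)
        img[rr, cc] = 0.9
        labels = segment_mitochondria(img)
        assert labels.max() == 1

    def test_empty_mask_gives_empty_labelling(self):
        img = np.random.default_rng(9).random((64, 64))
        labels = segment_mitochondria(img, mask=np.zeros((64, 64), bool))
        assert labels.max() == 0

    def test_object_count_matches_simulated_puncta(self):
        """Hyperfission field: segmented object count within 5% of the
        number of well-separated rendered puncta (simulator ground truth)."""
        spec = simcell.MorphologySpec(phi=0.0, noise_level=0.0, seed=17)
        puncta = tuple(
            simcell.Punctum(center=(256.0 + 24.0 * dr, 256.0 + 24.0 * dc), radius=2.5)
            for dr in (-2, -1, 0, 1, 2)
            for dc in (-2, -1, 0, 1, 2)
        )
        geom = [simcell.CellGeometry(center=(256.0, 256.0), radius=70.0, puncta=puncta, tubules=())]
        sim = simcell.render_field(geom, spec)
        # sparse constructed field: stretch against the structure peak rather
        # than the default 99th percentile (which sits in the cytoplasm here)
        image = normalize_percentile(sim.image, 1, 99.9)
        labels = segment_mitochondria(image, sim.truth_mask)
        assert labels.max() == pytest.approx(len(puncta), rel=0.05)


@pytest.fixture(scope="module")
def continuum_rows():
    rows = []
    for phi in (0.0, 0.5, 1.0):
        for seed in range(8):
            sim = simcell.simulate_field(
                simcell.MorphologySpec(phi=phi, seed=400 + seed, noise_level=0.0)
            )
            row = field_morphometry(normalize_percentile(sim.image), sim.truth_mask)
            row["phi"] = phi
            rows.append(row)
    import pandas as pd

    return pd.DataFrame(rows)


class TestFieldMorphometry:
    def test_zero_objects_gives_nan_row(self):
        row = field_morphometry(np.zeros((64, 64)))
        assert row["object_count"] == 0
        assert np.isnan(row["form_factor_mean"])

    def test_fragmentation_gradient_in_classical_metrics(self, continuum_rows):
        by_phi = continuum_rows.groupby("phi").mean()
        assert by_phi.loc[1.0, "aspect_ratio_mean"] > by_phi.loc[0.0, "aspect_ratio_mean"]
        assert by_phi.loc[1.0, "mean_branch_length"] > by_phi.loc[0.0, "mean_branch_length"]
        assert by_phi.loc[1.0, "object_count"] < by_phi.loc[0.0, "object_count"]

    def test_classical_metrics_separate_fission_better_than_fusion(self, continuum_rows):
        """The traditional baseline's known weakness: hyperfission vs normal
        shows a much larger effect than hyperfusion vs normal."""

        def cohens_d(a, b):
            sp = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
            return abs(a.mean() - b.mean()) / sp

        g = dict(tuple(continuum_rows.groupby("phi")))
        d_fission = cohens_d(g[0.0]["object_count"], g[0.5]["object_count"])
        d_fusion = cohens_d(g[1.0]["aspect_ratio_mean"], g[0.5]["aspect_ratio_mean"])
        assert d_fission > d_fusion
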