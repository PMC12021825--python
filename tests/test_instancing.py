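"""Semantic-to-instance conversion: labeling, sheath splitting, pairing."""

import numpy as np
import pytest
from scipy import ndimage

from axonmorph import (InstancingParams, SemanticMask, apply_region_masks,
                       extract_instances, label_axons, pair_axon_myelin,
                       split_touching_myelin)
from conftest import draw_annulus


def _mask(arr, px=8.0, **kw):
    return SemanticMask(np.asarray(arr, dtype=np.uint8), px, **kw)


def _disc(canvas, cr, cc, r, code=1):
    yy, xx = np.mgrid[: canvas.shape[0], : canvas.shape[1]]
    canvas[np.hypot(yy - cr, xx - cc) <= r] = code
    return canvas


class TestLabelAxons:
    def test_two_disjoint_discs_are_two_components(self):
        canvas = np.zeros((100, 100))
        _disc(canvas, 25, 25, 10)
        _disc(canvas, 70, 70, 10)
        labels, qc = label_axons(_mask(canvas), min_area_px=50)
        assert labels.max() == 2
        assert qc == []

    def test_single_pixel_dropped_below_min_area(self):
        canvas = np.zeros((20, 20))
        canvas[10, 10] = 1
        labels, qc = label_axons(_mask(canvas), min_area_px=50)
        assert labels.max() == 0
        assert len(qc) == 1 and qc[0]["reason"] == "below_min_area"

    def test_diagonal_touch_is_one_component_under_8_connectivity(self):
        # two blocks meeting only at a corner
        canvas = np.zeros((40, 40))
        canvas[5:15, 5:15] = 1
        canvas[15:25, 15:25] = 1
        labels, _ = label_axons(_mask(canvas), min_area_px=10)
        assert labels.max() == 1


class TestSplitTouchingMyelin:
    def test_isolated_annulus_equals_plain_connected_components(self):
        canvas = np.zeros((80, 80))
        draw_annulus(canvas, 40, 40, 12, 22, lumen=False)
        labels, qc = split_touching_myelin(_mask(canvas), k_erode=2)
        plain, n = ndimage.label(canvas == 2, structure=np.ones((3, 3)))
        assert n == 1 and labels.max() == 1
        np.testing.assert_array_equal(labels > 0, plain > 0)
        assert qc == []

    def test_bridged_annuli_split_into_two_by_proximity(self):
        # two thick annuli joined by a thin 2-px bridge
        canvas = np.zeros((80, 160))
        draw_annulus(canvas, 40, 40, 12, 22, lumen=False)
        draw_annulus(canvas, 40, 110, 12, 22, lumen=False)
        canvas[39:41, 62:89] = 2  # bridge
        sem = _mask(canvas)
        plain, n_plain = ndimage.label(canvas == 2, structure=np.ones((3, 3)))
        assert n_plain == 1  # really merged before splitting
        labels, qc = split_touching_myelin(sem, k_erode=2, max_bridge_px=30)
        assert labels.max() == 2
        # brute-force oracle: each assigned pixel is nearer (geodesically,
        # here equal to Euclidean) to its own sheath's eroded remnant
        seeds = ndimage.binary_erosion(canvas == 2, np.ones((3, 3)), iterations=2)
        seed_lab, _ = ndimage.label(seeds, structure=np.ones((3, 3)))
        rr, cc = np.nonzero(labels)
        s1 = np.column_stack(np.nonzero(seed_lab == 1))
        s2 = np.column_stack(np.nonzero(seed_lab == 2))
        for r, c in zip(rr[::7], cc[::7]):  # subsample for speed
            d1 = np.min(np.hypot(s1[:, 0] - r, s1[:, 1] - c))
            d2 = np.min(np.hypot(s2[:, 0] - r, s2[:, 1] - c))
            if abs(d1 - d2) > 1.5:  # skip near-equidistant watershed line
                expected = 1 if d1 < d2 else 2
                assert labels[r, c] == expected

    def test_solid_blob_is_one_component(self):
        canvas = np.zeros((60, 60))
        _disc(canvas, 30, 30, 15, code=2)
        labels, qc = split_touching_myelin(_mask(canvas), k_erode=2)
        assert labels.max() == 1

    def test_fragmenting_erosion_does_not_multiply_sheaths(self):
        # thin ring (3 px wall): erosion by 2 fragments it into arcs; the
        # arcs must be merged back into a single sheath
        canvas = np.zeros((80, 80))
        draw_annulus(canvas, 40, 40, 19, 22, lumen=False)
        labels, qc = split_touching_myelin(_mask(canvas), k_erode=2)
        assert labels.max() == 1


class TestPairing:
    def test_annulus_around_disc_is_one_instance(self):
        canvas = np.zeros((80, 80))
        draw_annulus(canvas, 40, 40, 12, 22)
        inst, qc = extract_instances(_mask(canvas))
        assert len(inst) == 1
        i = inst[0]
        assert i.n_axon_px > 0 and i.n_myelin_px > 0
        assert not np.any(i.axon_mask & i.myelin_mask)

    def test_empty_lumen_gives_unpaired_flag(self):
        canvas = np.zeros((80, 80))
        draw_annulus(canvas, 40, 40, 12, 22, lumen=False)
        inst, qc = extract_instances(_mask(canvas))
        assert len(inst) == 0
        assert (qc.reason == "unpaired_sheath").sum() == 1

    def test_two_lumens_in_one_sheath_pairs_nearest_and_flags_extra(self):
        canvas = np.zeros((120, 120))
        draw_annulus(canvas, 60, 60, 30, 40, lumen=False)
        _disc(canvas, 60, 55, 8)   # nearer the sheath centroid
        _disc(canvas, 60, 80, 6)   # second lumen, off-center
        inst, qc = extract_instances(_mask(canvas))
        assert len(inst) == 1
        assert "multiple_axons_in_sheath" in inst[0].flags
        assert (qc.reason == "extra_axon_in_sheath").sum() == 1
        # the nearer-centroid lumen was chosen
        assert abs(inst[0].centroid[1] - 55) < 3

    def test_unmyelinated_axon_excluded(self):
        canvas = np.zeros((60, 60))
        _disc(canvas, 30, 30, 10)
        inst, qc = extract_instances(_mask(canvas))
        assert len(inst) == 0
        assert (qc.reason == "unmyelinated").sum() == 1

    def test_no_pixel_in_two_instances(self, small_phantom):
        from axonmorph import instance_label_map

        inst = small_phantom["instances"]
        shape = small_phantom["mask"].shape
        total_px = sum(i.n_axon_px + i.n_myelin_px for i in inst)
        lab = instance_label_map(inst, shape)
        assert (lab > 0).sum() == total_px  # no overlap lost any pixel
        sem = small_phantom["mask"].classes
        assert total_px <= ((sem == 1).sum() + (sem == 2).sum())


class TestRegionMasks:
    def _one_instance(self):
        canvas = np.zeros((80, 80))
        draw_annulus(canvas, 40, 40, 12, 22)
        inst, _ = extract_instances(_mask(canvas))
        return inst

    def test_centroid_outside_region_dropped(self):
        inst = self._one_instance()
        cc = np.zeros((80, 80), dtype=bool)  # nothing inside
        kept, qc = apply_region_masks(inst, cc_mask=cc)
        assert kept == []
        assert qc[0]["reason"] == "outside_region"

    def test_subregion_label_assigned_by_centroid(self):
        inst = self._one_instance()
        genu = np.zeros((80, 80), dtype=bool)
        genu[:, :60] = True
        body = np.zeros((80, 80), dtype=bool)
        body[:, 60:] = True
        kept, _ = apply_region_masks(inst, subregion_masks={"genu": genu,
                                                            "body": body})
        assert kept[0].subregion == "genu"

    def test_overlapping_subregions_error(self):
        inst = self._one_instance()
        a = np.ones((80, 80), dtype=bool)
        with pytest.raises(ValueError, match="overlap"):
            apply_region_masks(inst, subregion_masks={"genu": a, "body": a})


class TestPhantomConservation:
    def test_nontouching_phantom_count_exact(self, wt_area_phantom,
                                             wt_geom_phantom):
        for ph in (wt_area_phantom, wt_geom_phantom):
            assert len(ph["instances"]) == len(ph["truth"])

    def test_engineered_bridges_count_within_2_percent(self):
        # 8x7 = 56 annuli, outer boundaries 4 px apart, with 2-px bridges
        # joining half of the horizontal neighbours
        step, r_in, r_out = 48, 10, 20
        n_r, n_c = 8, 7
        canvas = np.zeros((step * n_r + 20, step * n_c + 20))
        centers = []
        for i in range(n_r):
            for j in range(n_c):
                cr, cc = 24 + i * step, 24 + j * step
                draw_annulus(canvas, cr, cc, r_in, r_out)
                centers.append((cr, cc))
        for i in range(n_r):
            for j in range(0, n_c - 1, 2):
                cr = 24 + i * step
                cc = 24 + j * step
                canvas[cr - 1: cr + 1, cc + r_out: cc + step - r_out + 1] = 2
        inst, qc = extract_instances(_mask(canvas))
        true_n = n_r * n_c
        assert abs(len(inst) - true_n) <= 0.02 * true_n

    def test_pixel_budget(self, small_phantom):
        sem = small_phantom["mask"].classes
        total = sum(i.n_axon_px + i.n_myelin_px
                    for i in small_phantom["instances"])
        assert total <= (sem == 1).sum() + (sem == 2).sum()
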