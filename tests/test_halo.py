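"""Segmentation and rounded-region detection."""

import numpy as np
import pytest

from haloquant.halo import (
    CircularMask,
    DetectionParams,
    SegmentationParams,
    blue_mask,
    detect_halos,
    pixel_count_in_circle,
)
from haloquant.screen import GridLayout

from helpers import count_in_circle_brute, disk_mask, disk_pixel_count


def lab_image(b_values, L=70.0, a=0.0):
    """Build a Lab image from a 2-D array of b* values."""
    b = np.asarray(b_values, dtype=float)
    lab = np.empty(b.shape + (3,))
    lab[..., 0], lab[..., 1], lab[..., 2] = L, a, b
    return lab


class TestBlueMask:
    @pytest.mark.parametrize(
        "b,expected",
        [(-10.0, True), (0.0, False), (-25.0, False), (-20.0, False), (-5.0, False)],
    )
    def test_band_membership_strict_bounds(self, b, expected):
        mask = blue_mask(lab_image(np.full((4, 5), b)))
        assert mask.all() == expected
        assert mask.any() == expected

    def test_extend_blue_drops_lower_bound(self):
        img = lab_image(np.full((3, 3), -25.0))
        assert not blue_mask(img).any()
        assert blue_mask(img, SegmentationParams(extend_blue=True)).all()

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            SegmentationParams(b_lo=-5.0, b_hi=-20.0)

    def test_matches_brute_force_threshold(self):
        rng = np.random.default_rng(3)
        params = SegmentationParams()
        for _ in range(10):
            b = rng.uniform(-40, 20, size=(30, 40))
            got = blue_mask(lab_image(b), params)
            want = np.array(
                [
                    [params.b_lo < bv < params.b_hi for bv in row]
                    for row in b
                ]
            )
            assert np.array_equal(got, want)


class TestDetectHalos:
    layout = GridLayout.regular(2, 2, 100)

    def test_single_disk_count_matches_rasterization_oracle(self):
        mask = disk_mask(50, 50, 20, 200, 200)
        regions = detect_halos(mask, self.layout)
        assert len(regions) == 1
        reg = regions[0]
        assert reg.pixel_count == disk_pixel_count(50, 50, 20, 200, 200)
        assert reg.pixel_count == pytest.approx(np.pi * 400, rel=0.02)
        assert reg.cell_id == "r0c0"
        assert reg.circularity >= 0.9

    def test_empty_mask_yields_no_regions(self):
        assert detect_halos(np.zeros((50, 50), dtype=bool), self.layout) == []

    def test_two_disks_two_cells(self):
        mask = disk_mask(50, 50, 15, 200, 200) | disk_mask(150, 150, 12, 200, 200)
        regions = detect_halos(mask, self.layout)
        assert {r.cell_id for r in regions} == {"r0c0", "r1c1"}
        by_cell = {r.cell_id: r for r in regions}
        assert by_cell["r0c0"].pixel_count == disk_pixel_count(50, 50, 15, 200, 200)
        assert by_cell["r1c1"].pixel_count == disk_pixel_count(150, 150, 12, 200, 200)

    def test_translation_equivariance(self):
        base = np.zeros((120, 120), dtype=bool)
        base[20:60, 20:60] = disk_mask(20, 20, 15, 40, 40)
        shifted = np.roll(base, (17, 9), axis=(0, 1))
        r0 = detect_halos(base, None)
        r1 = detect_halos(shifted, None)
        assert len(r0) == len(r1) == 1
        assert r1[0].pixel_count == r0[0].pixel_count
        assert r1[0].centroid[0] == pytest.approx(r0[0].centroid[0] + 9)
        assert r1[0].centroid[1] == pytest.approx(r0[0].centroid[1] + 17)

    def test_low_circularity_component_rejected(self):
        mask = np.zeros((100, 100), dtype=bool)
        mask[48:52, 5:95] = True  # a long thin bar
        assert detect_halos(mask, None) == []

    def test_small_component_rejected(self):
        mask = np.zeros((50, 50), dtype=bool)
        mask[20:23, 20:23] = True
        assert detect_halos(mask, None, DetectionParams(min_area_px=50)) == []

    def test_hole_filling_restores_disk_area(self):
        mask = disk_mask(30, 30, 18, 60, 60)
        full = int(mask.sum())
        mask[28:33, 28:33] = False  # small interior dropout
        regions = detect_halos(mask, None)
        assert len(regions) == 1
        assert regions[0].pixel_count == full

    def test_largest_region_wins_within_cell(self):
        mask = disk_mask(30, 30, 18, 100, 100) | disk_mask(70, 70, 8, 100, 100)
        layout = GridLayout.regular(1, 1, 100)
        regions = detect_halos(mask, layout)
        assert len(regions) == 1
        assert regions[0].pixel_count == disk_pixel_count(30, 30, 18, 100, 100)

    def test_grid_line_network_not_detected_as_halo(self):
        # thin lines enclosing the cells: huge perimeter, tiny area
        mask = np.zeros((200, 200), dtype=bool)
        for k in (100,):
            mask[:, k - 1 : k + 1] = True
            mask[k - 1 : k + 1, :] = True
        mask |= disk_mask(50, 50, 20, 200, 200)
        regions = detect_halos(mask, self.layout)
        assert len(regions) == 1
        assert regions[0].cell_id == "r0c0"
        assert regions[0].pixel_count == pytest.approx(
            disk_pixel_count(50, 50, 20, 200, 200), rel=0.02
        )


class TestPixelCountInCircle:
    def test_circle_congruent_with_disk(self):
        mask = disk_mask(40, 35, 17, 80, 80)
        n = pixel_count_in_circle(mask, CircularMask(center=(40, 35), radius=17))
        assert n == disk_pixel_count(40, 35, 17, 80, 80)

    def test_all_false_mask(self):
        mask = np.zeros((50, 50), dtype=bool)
        assert pixel_count_in_circle(mask, CircularMask(center=(25, 25), radius=10)) == 0

    def test_half_covered_rectangle_matches_brute_force(self):
        mask = np.zeros((60, 60), dtype=bool)
        mask[10:50, 10:50] = True
        circ = CircularMask(center=(10, 30), radius=18)
        got = pixel_count_in_circle(mask, circ)
        assert got == count_in_circle_brute(mask, 10, 30, 18)

    def test_monotone_in_radius(self):
        rng = np.random.default_rng(11)
        mask = rng.random((70, 70)) < 0.3
        counts = [
            pixel_count_in_circle(mask, CircularMask(center=(35, 35), radius=r))
            for r in range(3, 40, 4)
        ]
        assert counts == sorted(counts)

    def test_non_intersecting_circle_rejected(self):
        mask = np.zeros((50, 50), dtype=bool)
        with pytest.raises(ValueError):
            pixel_count_in_circle(mask, CircularMask(center=(200, 200), radius=5))
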