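"""Activation regions and region-proposal generation."""

import numpy as np
import pytest

from trapcount.classifiers import ConstantClassifier
from trapcount.config import PipelineConfig
from trapcount.geometry import Box
from trapcount.proposals import (
    area_filter,
    connected_components,
    generate_proposals,
    label_region_fg_bg,
    tuneup_boxes,
)
from trapcount.structures import ActivationRegion

from conftest import gt


def flood_fill_components(mask, connectivity):
    """Brute-force reference labelling: iterative flood fill."""
    mask = np.asarray(mask)
    h, w = mask.shape
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for r0 in range(h):
        for c0 in range(w):
            if mask[r0, c0] == 0 or seen[r0, c0]:
                continue
            stack, pixels = [(r0, c0)], []
            seen[r0, c0] = True
            while stack:
                r, c = stack.pop()
                pixels.append((r, c))
                for dr, dc in steps:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                        seen[rr, cc] = True
                        stack.append((rr, cc))
            rows = [p[0] for p in pixels]
            cols = [p[1] for p in pixels]
            comps.append(
                (
                    (min(cols), min(rows), max(cols) + 1, max(rows) + 1),
                    len(pixels),
                    (sum(cols) / len(cols), sum(rows) / len(rows)),
                )
            )
    comps.sort(key=lambda t: (t[0][0], t[0][1]))
    return comps


class TestConnectedComponents:
    def test_empty_mask(self):
        assert connected_components(np.zeros((5, 5), dtype=np.uint8)) == []

    def test_full_mask_single_region(self):
        regions = connected_components(np.ones((10, 10), dtype=np.uint8))
        assert len(regions) == 1
        assert regions[0].box == Box(0, 0, 10, 10)
        assert regions[0].pixel_count == 100

    def test_two_components_with_boxes(self):
        mask = np.zeros((10, 10), dtype=np.uint8)
        mask[1, 1] = mask[2, 1] = 1  # rows 1-2, col 1
        mask[7, 7] = 1
        regions = connected_components(mask, connectivity=8)
        assert [r.box for r in regions] == [Box(1, 1, 2, 3), Box(7, 7, 8, 8)]
        assert [r.pixel_count for r in regions] == [2, 1]

    def test_diagonal_connectivity_difference(self):
        mask = np.eye(4, dtype=np.uint8)
        assert len(connected_components(mask, connectivity=8)) == 1
        assert len(connected_components(mask, connectivity=4)) == 4

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle(self, connectivity, rng):
        for _ in range(25):
            mask = (rng.random((32, 32)) < 0.35).astype(np.uint8)
            regions = connected_components(mask, connectivity)
            expected = flood_fill_components(mask, connectivity)
            got = [(tuple(r.box), r.pixel_count, r.center) for r in regions]
            assert [(b, n) for b, n, _ in got] == [(b, n) for b, n, _ in expected]
            for (_, _, ca), (_, _, cb) in zip(got, expected):
                assert ca == pytest.approx(cb)

    def test_pixel_conservation(self, rng):
        mask = (rng.random((32, 32)) < 0.4).astype(np.uint8)
        regions = connected_components(mask, 8)
        assert sum(r.pixel_count for r in regions) == mask.sum()

    def test_bad_connectivity_rejected(self):
        with pytest.raises(ValueError):
            connected_components(np.zeros((3, 3)), connectivity=6)


def region(x0, y0, x1, y1, n=None):
    box = Box(x0, y0, x1, y1)
    return ActivationRegion(box=box, pixel_count=n or box.area, center=box.center)


class TestAreaFilter:
    def test_beta_zero_keeps_all(self):
        regions = [region(0, 0, 2, 2), region(5, 5, 15, 8)]
        assert area_filter(regions, 0) == regions

    def test_equality_survives(self):
        regions = [region(0, 0, 2, 2), region(0, 0, 6, 5), region(0, 0, 10, 10)]
        kept = area_filter(regions, 30)
        assert [r.box.area for r in kept] == [30, 100]

    def test_empty(self):
        assert area_filter([], 10) == []

    def test_monotone_in_beta(self, rng):
        regions = [
            region(0, 0, int(rng.integers(1, 20)), int(rng.integers(1, 20)))
            for _ in range(30)
        ]
        counts = [len(area_filter(regions, b)) for b in (0, 10, 50, 100, 500)]
        assert counts == sorted(counts, reverse=True)


class TestLabelRegionFgBg:
    def test_covering_gt_is_foreground(self):
        assert label_region_fg_bg(region(0, 0, 20, 20), [gt(5, 5, 10, 10)], 0.5) == "foreground"

    def test_no_gts_is_background(self):
        assert label_region_fg_bg(region(0, 0, 20, 20), [], 0.5) == "background"

    def test_all_below_threshold_is_background(self):
        # overlaps of 0.2 and 0.49 of the gt areas
        gts = [gt(0, 0, 10, 10), gt(0, 0, 100, 10)]
        r = region(0, 0, 10, 2)  # covers 20/100 of first
        assert label_region_fg_bg(r, [gts[0]], 0.5) == "background"
        r2 = region(0, 0, 49, 10)  # 490/1000 of second
        assert label_region_fg_bg(r2, [gts[1]], 0.5) == "background"
        assert label_region_fg_bg(r2, [gts[1]], 0.49) == "foreground"


class TestTuneupBoxes:
    def test_centered_box(self):
        assert tuneup_boxes((50, 50), [(20, 20)], (100, 100)) == [Box(40, 40, 60, 60)]

    def test_clipping_near_corner(self):
        assert tuneup_boxes((2, 2), [(20, 20)], (100, 100)) == [Box(0, 0, 12, 12)]

    def test_empty_scales(self):
        assert tuneup_boxes((10, 10), [], (100, 100)) == []

    def test_center_outside_rejected(self):
        with pytest.raises(ValueError):
            tuneup_boxes((150, 50), [(10, 10)], (100, 100))


class TestGenerateProposals:
    @pytest.fixture
    def scene(self):
        image = np.full((100, 100, 3), (230, 200, 40), dtype=np.uint8)
        image[40:60, 40:60] = (20, 20, 20)
        return image

    def test_uniform_image_no_proposals(self, config):
        image = np.full((64, 64, 3), (230, 200, 40), dtype=np.uint8)
        assert generate_proposals(image, config, classifier=ConstantClassifier("foreground")) == []

    def test_one_insect_k2_three_proposals(self, scene):
        cfg = PipelineConfig(tuneup_scales=[(24, 24), (32, 32)])
        props = generate_proposals(scene, cfg, classifier=ConstantClassifier("foreground"))
        assert len(props) == 3
        assert len({p.anchor for p in props}) == 1
        assert [p.scale_index for p in props] == [0, 1, 2]

    def test_closed_gate_no_proposals(self, scene, config):
        assert generate_proposals(scene, config, classifier=ConstantClassifier("background")) == []

    def test_training_mode_gates_by_overlap(self, scene, config):
        props = generate_proposals(scene, config, gts=[gt(40, 40, 60, 60, "others")])
        assert props
        assert generate_proposals(scene, config, gts=[gt(0, 0, 5, 5, "others")]) == []

    def test_boxes_within_bounds_and_per_region_count(self, scene, config):
        props = generate_proposals(scene, config, classifier=ConstantClassifier("foreground"))
        assert len(props) == 1 + len(config.tuneup_scales)
        for p in props:
            assert 0 <= p.box.xmin < p.box.xmax <= 100
            assert 0 <= p.box.ymin < p.box.ymax <= 100

    def test_requires_exactly_one_mode(self, scene, config):
        with pytest.raises(ValueError):
            generate_proposals(scene, config)
        with pytest.raises(ValueError):
            generate_proposals(
                scene, config, gts=[], classifier=ConstantClassifier("foreground")
            )
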