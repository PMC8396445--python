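"""Conventional NMS, the merging rule, and the improved NMS loop."""

import random

import pytest

from trapcount.geometry import Box, iou
from trapcount.structures import Detection
from trapcount.suppression import inms, merge, merge_overlapping, nms

from conftest import det


class TestNms:
    def test_single_detection_unchanged(self):
        d = det(0, 0, 10, 10)
        assert nms([d], 0.5) == [d]

    def test_duplicate_keeps_higher_confidence(self):
        hi = det(0, 0, 10, 10, confidence=0.9)
        lo = det(0, 0, 10, 10, confidence=0.7)
        assert nms([lo, hi], 0.5) == [hi]

    def test_greedy_chain(self):
        # A overlaps B and B overlaps C above threshold, but A and C
        # only weakly: greedy suppression keeps A and C
        a = det(0, 0, 20, 10, confidence=0.9)
        b = det(5, 0, 25, 10, confidence=0.8)
        c = det(10, 0, 30, 10, confidence=0.7)
        assert iou(a.box, b.box) == pytest.approx(0.6)
        assert iou(b.box, c.box) == pytest.approx(0.6)
        assert iou(a.box, c.box) == pytest.approx(1 / 3)
        assert nms([a, b, c], 0.5) == [a, c]


class TestMerge:
    def test_noisy_or_confidence(self):
        a = det(0, 0, 10, 10, confidence=0.5)
        b = det(0, 0, 10, 10, confidence=0.5)
        merged = merge(a, b)
        assert merged.box == Box(0, 0, 10, 10)
        assert merged.confidence == pytest.approx(0.75)

    def test_certain_detection_absorbs(self):
        a = det(0, 0, 10, 10, confidence=1.0)
        b = det(0, 0, 10, 10, confidence=0.3)
        assert merge(a, b).confidence == pytest.approx(1.0)

    def test_weighted_average_coordinates(self):
        a = det(0, 0, 10, 10, confidence=0.5)
        b = det(10, 0, 20, 10, confidence=0.5)
        assert merge(a, b).box == Box(5, 0, 15, 10)

    def test_unequal_weights_shift_towards_confident(self):
        a = det(0, 0, 10, 10, confidence=0.9)
        b = det(10, 0, 20, 10, confidence=0.1)
        assert merge(a, b).box == Box(1, 0, 11, 10)

    def test_label_mismatch_rejected(self):
        with pytest.raises(ValueError):
            merge(det(0, 0, 10, 10), det(0, 0, 10, 10, label="others"))


class TestInms:
    def test_single_survivor(self):
        d = det(0, 0, 10, 10, confidence=0.9)
        assert inms([d], gamma=0.5) == [d]
        assert inms([det(0, 0, 10, 10, confidence=0.3)], gamma=0.5) == []

    def test_merge_rescues_low_confidence_pair(self):
        # two half-confident views of one insect survive a gamma that
        # would kill either alone
        a = det(0, 0, 10, 10, confidence=0.5)
        b = det(1, 0, 11, 10, confidence=0.5)  # iou 9/11 ≈ 0.82
        out = inms([a, b], merge_iou_threshold=0.5, nms_iou_threshold=0.5, gamma=0.6)
        assert len(out) == 1
        assert out[0].confidence == pytest.approx(0.75)

    def test_error_suppression_scenario(self):
        """A confident wrong-class box inside a correct box would win
        conventional NMS; merging the correct-class duplicate first
        lifts its confidence above the impostor."""
        wrong = det(0, 0, 8, 8, label="others", confidence=0.8)
        right1 = det(0, 0, 10, 10, confidence=0.6)
        right2 = det(0, 0, 10, 10, confidence=0.6)
        # conventional NMS alone keeps the wrong-class box and kills a right one
        conventional = nms([wrong, right1, right2], 0.5)
        assert conventional[0].label == "others"
        out = inms(
            [wrong, right1, right2],
            merge_iou_threshold=0.5,
            nms_iou_threshold=0.5,
            gamma=0.5,
        )
        assert len(out) == 1
        assert out[0].label == "diamondback moth"
        assert out[0].confidence == pytest.approx(0.84)

    def test_empty_input(self):
        assert inms([]) == []


def random_detections(rnd, n, labels=("a", "b")):
    out = []
    for _ in range(n):
        x0, y0 = rnd.randrange(0, 30), rnd.randrange(0, 30)
        w, h = rnd.randrange(4, 20), rnd.randrange(4, 20)
        out.append(
            Detection(
                box=Box(x0, y0, x0 + w, y0 + h),
                label=rnd.choice(labels),
                confidence=round(rnd.uniform(0.1, 1.0), 3),
            )
        )
    return out


def reference_merge_loop(dets, threshold):
    """Independent re-implementation of the merge phase with explicit
    re-sorting from scratch each iteration."""

    def key(d):
        return (d.box.area, d.box.xmin, d.box.ymin, d.confidence, d.box.ymax, d.box.xmax, d.label)

    work = list(dets)
    held = []
    while work:
        work = sorted(work, key=key)
        b0, rest = work[0], work[1:]
        hit = None
        for i, bi in enumerate(rest):
            if bi.label == b0.label and iou(b0.box, bi.box) > threshold:
                hit = i
                break
        if hit is None:
            held.append(b0)
            work = rest
        else:
            rest[hit] = merge(b0, rest[hit])
            work = rest
    return held


class TestInmsProperties:
    def test_output_bounded_and_above_gamma(self):
        rnd = random.Random(0)
        for _ in range(50):
            dets = random_detections(rnd, rnd.randrange(0, 9))
            out = inms(dets, gamma=0.5)
            assert len(out) <= len(dets)
            assert all(d.confidence >= 0.5 for d in out)
            assert {d.label for d in out} <= {d.label for d in dets}

    def test_reduces_to_nms_without_same_class_overlap(self):
        # same-class boxes disjoint; cross-class overlaps only
        a = det(0, 0, 10, 10, label="a", confidence=0.9)
        b = det(2, 0, 12, 10, label="b", confidence=0.8)
        c = det(30, 30, 40, 40, label="a", confidence=0.7)
        dets = [a, b, c]
        expected = [d for d in nms(dets, 0.5) if d.confidence >= 0.5]
        assert inms(dets, 0.5, 0.5, 0.5) == expected

    def test_permutation_invariance(self):
        rnd = random.Random(1)
        for _ in range(30):
            dets = random_detections(rnd, 8)
            baseline = inms(dets, 0.4, 0.5, 0.3)
            for _ in range(3):
                shuffled = dets[:]
                rnd.shuffle(shuffled)
                assert inms(shuffled, 0.4, 0.5, 0.3) == baseline

    def test_merge_phase_idempotent(self):
        rnd = random.Random(2)
        for _ in range(100):
            dets = random_detections(rnd, rnd.randrange(0, 9))
            once = merge_overlapping(dets, 0.4)
            assert merge_overlapping(once, 0.4) == once

    def test_merge_phase_matches_reference(self):
        rnd = random.Random(3)
        for _ in range(200):
            dets = random_detections(rnd, rnd.randrange(0, 9))
            assert merge_overlapping(dets, 0.45) == reference_merge_loop(dets, 0.45)
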