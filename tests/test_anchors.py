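"""Anchor clustering, linear stretch, scale assignment, match statistics."""

import itertools

import numpy as np
import pytest

from pestdet.anchors import (
    AnchorSet,
    COCO_ANCHORS,
    StretchParams,
    assign_anchors_to_scales,
    cluster_anchors,
    linear_stretch,
    match_statistics,
    mean_best_iou,
    read_anchor_file,
    sweep_beta,
    write_anchor_file,
)
from pestdet.boxes import size_aligned_iou
from pestdet.synth import generate_box_sample
from pestdet.voc import AnnotatedImage, AnnotatedObject, BoundingBox, MAIZE_PEST_CLASSES


def _brute_force_cost(sizes: np.ndarray, k: int, metric: str) -> float:
    """Oracle over the clustering's full candidate family: centroid sets are
    either the means induced by *any* assignment or any k-subset of the data
    points (medoid initialisations kept by the monotone-cost rule); the cost
    charges every point to its nearest centroid."""
    n = len(sizes)

    def dist(p, c):
        if metric == "iou":
            return 1.0 - size_aligned_iou(p, c)
        return float(((p - c) ** 2).sum())

    def total(centroids):
        return sum(min(dist(p, c) for c in centroids) for p in sizes)

    best = np.inf
    for labels in itertools.product(range(k), repeat=n):
        labels = np.array(labels)
        centroids = [sizes[labels == j].mean(axis=0) for j in range(k)
                     if len(sizes[labels == j])]
        best = min(best, total(centroids))
    for subset in itertools.combinations(range(n), k):
        best = min(best, total(sizes[list(subset)]))
    return best


class TestCluster:
    def test_k_equals_n_gives_zero_cost(self):
        sizes = np.array([[10, 12], [30, 28], [55, 60]])
        aset, det = cluster_anchors(sizes, k=3, seed=0, return_details=True)
        assert det["cost"] == pytest.approx(0.0, abs=1e-12)
        assert sorted(map(tuple, aset.as_array())) == sorted(map(tuple, sizes * 1.0))

    @pytest.mark.parametrize("metric", ["iou", "euclidean"])
    @pytest.mark.parametrize("n,k", [(5, 2), (7, 3), (8, 3)])
    def test_matches_brute_force_optimum(self, metric, n, k):
        rng = np.random.default_rng(n * 10 + k)
        sizes = np.round(rng.uniform(5, 120, size=(n, 2)), 1)
        oracle = _brute_force_cost(sizes, k, metric)
        _, det = cluster_anchors(sizes, k=k, metric=metric, seed=1, n_init=50,
                                 return_details=True)
        assert det["cost"] == pytest.approx(oracle, rel=1e-6, abs=1e-9)

    def test_recovers_two_separated_clusters_within_1pct(self):
        mixture = [(10.0, 14.0, 0.05, 1.0), (40.0, 60.0, 0.05, 1.0)]
        sizes = generate_box_sample(400, mixture, seed=9)
        aset = cluster_anchors(sizes, k=2, seed=0)
        got = aset.as_array()
        expect = np.array([[10, 14], [40, 60]], dtype=float)
        assert np.all(np.abs(got - expect) / expect < 0.01)

    def test_cost_history_never_increases(self):
        sizes = generate_box_sample(
            300, [(8, 10, 0.3, 1.0), (25, 30, 0.3, 1.0), (60, 80, 0.3, 1.0)], seed=4
        )
        _, det = cluster_anchors(sizes, k=5, seed=2, n_init=1, return_details=True)
        hist = det["cost_history"]
        assert len(hist) >= 1
        assert all(b <= a + 1e-9 for a, b in zip(hist, hist[1:]))

    def test_input_validation(self):
        with pytest.raises(ValueError):
            cluster_anchors(np.array([[1.0, 1.0]]), k=2)
        with pytest.raises(ValueError):
            cluster_anchors(np.array([[0.0, 5.0], [2.0, 2.0]]), k=2)


class TestLinearStretch:
    def test_identity_at_neutral_params(self):
        aset = AnchorSet.from_array([(10, 20), (20, 10), (30, 15)])
        out = linear_stretch(aset, StretchParams(beta=1.0, first_scale=1.0))
        assert np.allclose(out.as_array(), aset.as_array())

    def test_hand_computed_example(self):
        # widths (10, 20, 30), heights (20, 10, 15), beta=7, first_scale=0.5
        aset = AnchorSet.from_array([(10, 20), (20, 10), (30, 15)])
        out = linear_stretch(aset, StretchParams(beta=7.0, first_scale=0.5))
        assert np.allclose(out.widths, [5.0, 107.5, 210.0])
        assert np.allclose(out.heights, [10.0, 53.75, 105.0])

    def test_aspect_ratios_preserved_exactly(self):
        aset = AnchorSet.from_array(COCO_ANCHORS)
        out = linear_stretch(aset, StretchParams(beta=3.5, first_scale=0.5))
        assert np.allclose(
            out.heights / out.widths, aset.heights / aset.widths, rtol=1e-12
        )

    def test_order_preserving_and_scale_equivariant(self):
        aset = AnchorSet.from_array(COCO_ANCHORS)
        params = StretchParams(beta=4.0, first_scale=0.5)
        out = linear_stretch(aset, params)
        assert np.all(np.diff(out.widths) >= 0)
        # stretch(c * A) == c * stretch(A)
        c = 2.5
        scaled = linear_stretch(AnchorSet.from_array(aset.as_array() * c), params)
        assert np.allclose(scaled.as_array(), out.as_array() * c, rtol=1e-12)

    def test_degenerate_spread_rejected(self):
        aset = AnchorSet.from_array([(10, 5), (10, 20)])
        with pytest.raises(ValueError):
            linear_stretch(aset, StretchParams(beta=2.0))


class TestSweep:
    def test_single_beta_one_row(self):
        aset = AnchorSet.from_array(COCO_ANCHORS)
        rows = sweep_beta(aset, betas=[7.0], evaluation=lambda a: 1.23)
        assert rows == [(7.0, 1.23)]

    def test_default_grid_is_one_to_ten(self):
        aset = AnchorSet.from_array(COCO_ANCHORS)
        rows = sweep_beta(aset, evaluation=lambda a: 0.0)
        assert [b for b, _ in rows] == [float(i) for i in range(1, 11)]

    def test_perfect_alignment_scores_one(self):
        # GT sizes constructed as the exact stretch output at beta=2
        aset = AnchorSet.from_array([(10, 20), (20, 10), (30, 15)])
        target = linear_stretch(aset, StretchParams(beta=2.0, first_scale=0.5))
        rows = dict(sweep_beta(aset, betas=[1.0, 2.0, 3.0],
                               evaluation=mean_best_iou(target.as_array())))
        assert rows[2.0] == pytest.approx(1.0)
        assert rows[1.0] < 1.0 and rows[3.0] < 1.0

    def test_failing_callback_recorded_as_missing(self):
        aset = AnchorSet.from_array([(10, 20), (20, 10)])

        def boom(a):
            raise RuntimeError("no score")

        rows = sweep_beta(aset, betas=[2.0], evaluation=boom)
        assert rows == [(2.0, None)]


class TestScaleAssignment:
    def test_coco_grouping(self):
        aset = AnchorSet.from_array(COCO_ANCHORS)
        groups = assign_anchors_to_scales(aset)
        assert groups[8] == ((10, 13), (16, 30), (33, 23))
        assert groups[32] == ((116, 90), (156, 198), (373, 326))

    def test_union_equals_input(self):
        aset = AnchorSet.from_array(COCO_ANCHORS)
        groups = assign_anchors_to_scales(aset)
        flat = set(groups[8]) | set(groups[16]) | set(groups[32])
        assert flat == set(aset.anchors)

    def test_groups_keep_ascending_area_order(self):
        aset = AnchorSet.from_array(COCO_ANCHORS)
        groups = assign_anchors_to_scales(aset)
        areas = [w * h for s in (8, 16, 32) for w, h in groups[s]]
        assert areas == sorted(areas)

    def test_requires_nine_anchors(self):
        with pytest.raises(ValueError):
            assign_anchors_to_scales(AnchorSet.from_array([(1, 1), (2, 2)]))


def _img_with_boxes(boxes, size=416):
    objs = [
        AnnotatedObject(5, MAIZE_PEST_CLASSES[5], BoundingBox(*b)) for b in boxes
    ]
    return AnnotatedImage("m.png", size, size, objs)


class TestMatchStatistics:
    def test_gt_equal_to_anchor_matches_at_high_threshold(self):
        aset = AnchorSet.from_array(COCO_ANCHORS)
        # (16, 30) sits in the stride-8 group; center the GT on a cell center
        img = _img_with_boxes([(92, 85, 108, 115)])  # 16x30 centered at (100, 100)
        report = match_statistics(aset, [img], input_size=416, iou_threshold=0.99)
        assert report.per_box[0] >= 1

    def test_duplication_multiplies_counts(self):
        aset = AnchorSet.from_array(COCO_ANCHORS)
        box = (90, 84, 110, 116)
        single = match_statistics(aset, [_img_with_boxes([box])], 416, 0.3)
        triple = match_statistics(aset, [_img_with_boxes([box] * 3)], 416, 0.3)
        assert triple.total_matches == 3 * single.total_matches
        assert len(triple.per_box) == 3

    def test_tiny_gt_vs_large_anchors_no_match(self):
        aset = AnchorSet.from_array([(200, 200), (300, 300)])
        img = _img_with_boxes([(100, 100, 104, 104)])
        report = match_statistics(aset, [img], 416, 0.5)
        assert report.total_matches == 0

    def test_whole_stride_translation_invariance(self):
        aset = AnchorSet.from_array(COCO_ANCHORS)
        base = (60, 52, 80, 84)
        a = match_statistics(aset, [_img_with_boxes([base])], 416, 0.3)
        shifted = tuple(v + d for v, d in zip(base, (96, 64, 96, 64)))  # 3 and 2 strides of 32
        b = match_statistics(aset, [_img_with_boxes([shifted])], 416, 0.3)
        assert a.per_box == b.per_box

    def test_histogram_totals(self):
        aset = AnchorSet.from_array(COCO_ANCHORS)
        img = _img_with_boxes([(10, 10, 30, 30), (100, 100, 180, 180)])
        report = match_statistics(aset, [img], 416, 0.4)
        assert sum(report.histogram.values()) == len(report.per_box) == 2


class TestAnchorFiles:
    def test_round_trip(self, tmp_path):
        aset = AnchorSet.from_array([(4, 6), (21, 39), (162, 216)])
        path = tmp_path / "anchors.txt"
        write_anchor_file(aset, path)
        assert read_anchor_file(path).anchors == aset.anchors
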