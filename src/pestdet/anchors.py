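"""Anchor-box clustering, linear stretching, and anchor-GT match statistics.

YOLOv3 regresses detections from nine template "anchor" boxes, three per
detection branch (strides 8, 16, 32 at a 416 input).  The templates come from
k-means clustering of the GT box sizes, with the YOLO convention of using
``1 - IoU`` between size-aligned boxes as the distance.

On a single-scene dataset such as light-trap imagery the clustered sizes are
tightly concentrated, so the nine anchors collapse into a narrow band and the
multi-scale head loses its purpose.  The linear stretch transform fixes this
by spreading the anchors apart: with anchors sorted by width ``x_1..x_k``,

    x_1' = first_scale * x_1          (default 0.5)
    x_k' = beta * x_k                 (beta is the stretch factor)
    x_i' = (x_i - x_1)/(x_k - x_1) * (x_k' - x_1') + x_1'     (interior i)
    y_i' = x_i' * y_i / x_i           (aspect ratio preserved exactly)

so the smallest anchor shrinks, the largest grows by ``beta``, and the rest
are placed by linear interpolation between the new endpoints.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from .boxes import iou_xyxy, size_aligned_iou
from .voc import AnnotatedImage

log = logging.getLogger(__name__)

__all__ = [
    "AnchorSet",
    "StretchParams",
    "MatchReport",
    "cluster_anchors",
    "linear_stretch",
    "sweep_beta",
    "mean_best_iou",
    "assign_anchors_to_scales",
    "match_statistics",
    "write_anchor_file",
    "read_anchor_file",
]

#: The canonical nine COCO anchors of YOLOv3 at a 416 input, ascending.
COCO_ANCHORS: tuple[tuple[float, float], ...] = (
    (10, 13), (16, 30), (33, 23), (30, 61), (62, 45),
    (59, 119), (116, 90), (156, 198), (373, 326),
)

#: Branch strides, smallest-receptive-field first.
BRANCH_STRIDES: tuple[int, int, int] = (8, 16, 32)


@dataclass(frozen=True)
class AnchorSet:
    """Ordered ``(width, height)`` anchor templates at input resolution."""

    anchors: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.anchors) < 2:
            raise ValueError("need at least 2 anchors")
        ws = [w for w, _ in self.anchors]
        if any(w <= 0 or h <= 0 for w, h in self.anchors):
            raise ValueError("anchor dimensions must be positive")
        if any(a > b for a, b in zip(ws, ws[1:])):
            raise ValueError("anchors must be sorted ascending by width")

    @classmethod
    def from_array(cls, arr: np.ndarray | Sequence[Sequence[float]]) -> "AnchorSet":
        arr = np.asarray(arr, dtype=np.float64).reshape(-1, 2)
        order = np.lexsort((arr[:, 1], arr[:, 0]))
        return cls(tuple((float(w), float(h)) for w, h in arr[order]))

    @property
    def k(self) -> int:
        return len(self.anchors)

    @property
    def widths(self) -> np.ndarray:
        return np.array([w for w, _ in self.anchors])

    @property
    def heights(self) -> np.ndarray:
        return np.array([h for _, h in self.anchors])

    def as_array(self) -> np.ndarray:
        return np.array(self.anchors, dtype=np.float64)


@dataclass(frozen=True)
class StretchParams:
    """Linear-stretch parameters: ``beta`` scales the largest anchor, and the
    smallest is scaled by ``first_scale`` (0.5 by default)."""

    beta: float = 7.0
    first_scale: float = 0.5

    def __post_init__(self) -> None:
        if self.beta <= 0 or self.first_scale <= 0:
            raise ValueError("beta and first_scale must be positive")


# ---------------------------------------------------------------------------
# Clustering


def _iou_kmeans_once(
    sizes: np.ndarray, k: int, init: np.ndarray, rng: np.random.Generator,
    max_iter: int = 300,
) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    n = len(sizes)
    centroids = sizes[init].astype(np.float64)
    labels = np.full(n, -1)
    history: list[float] = []
    prev_cost = np.inf
    prev_state = (centroids.copy(), labels.copy())
    for _ in range(max_iter):
        # assignment by max size-aligned IoU
        inter = np.minimum(sizes[:, None, 0], centroids[None, :, 0]) * np.minimum(
            sizes[:, None, 1], centroids[None, :, 1]
        )
        union = (
            sizes[:, 0] * sizes[:, 1]
        )[:, None] + (centroids[:, 0] * centroids[:, 1])[None, :] - inter
        dist = 1.0 - inter / union
        new_labels = dist.argmin(axis=1)
        cost = float(dist[np.arange(n), new_labels].sum())
        if cost > prev_cost + 1e-12:
            # mean update is a heuristic under the IoU metric; never let the
            # recorded cost rise — roll back and stop
            centroids, labels = prev_state
            break
        history.append(cost)
        prev_state = (centroids.copy(), new_labels.copy())
        if np.array_equal(new_labels, labels):
            labels = new_labels
            break
        labels, prev_cost = new_labels, cost
        for j in range(k):
            members = sizes[labels == j]
            if len(members):
                centroids[j] = members.mean(axis=0)
            else:
                centroids[j] = sizes[rng.integers(n)]
    return centroids, labels, history[-1] if history else prev_cost, history


def cluster_anchors(
    boxes: np.ndarray | Sequence[Sequence[float]],
    k: int = 9,
    metric: str = "iou",
    seed: int = 0,
    n_init: int = 10,
    return_details: bool = False,
):
    """Cluster GT ``(w, h)`` sizes into ``k`` anchors.

    ``metric="iou"`` runs Lloyd iterations under the ``1 - IoU`` distance of
    size-aligned boxes (the YOLOv3 convention); ``metric="euclidean"`` uses
    squared Euclidean distance on the raw ``(w, h)`` pairs via scikit-learn.
    ``n_init`` seeded restarts keep the best solution by total cost.
    """
    sizes = np.asarray(boxes, dtype=np.float64).reshape(-1, 2)
    if np.any(sizes <= 0):
        raise ValueError("zero or negative box size in clustering input")
    if len(sizes) < k:
        raise ValueError(f"need at least k={k} boxes, got {len(sizes)}")

    if metric == "euclidean":
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(sizes)
        anchors = AnchorSet.from_array(km.cluster_centers_)
        if return_details:
            return anchors, {"labels": km.labels_, "cost": float(km.inertia_), "cost_history": []}
        return anchors
    if metric != "iou":
        raise ValueError(f"unknown metric {metric!r}")

    rng = np.random.default_rng(seed)
    # exhaustive medoid initialisation when the problem is tiny, random
    # k-subsets otherwise
    from math import comb

    if comb(len(sizes), k) <= max(n_init, 64):
        from itertools import combinations

        inits = [np.array(c) for c in combinations(range(len(sizes)), k)]
    else:
        inits = [rng.choice(len(sizes), size=k, replace=False) for _ in range(n_init)]
    best = None
    for init in inits:
        centroids, labels, cost, history = _iou_kmeans_once(sizes, k, init, rng)
        if best is None or cost < best[2]:
            best = (centroids, labels, cost, history)
    centroids, labels, cost, history = best
    anchors = AnchorSet.from_array(centroids)
    if return_details:
        return anchors, {"labels": labels, "cost": cost, "cost_history": history}
    return anchors


def iou_clustering_cost(sizes: np.ndarray, centroids: np.ndarray) -> float:
    """Total ``1 - best IoU`` cost of ``sizes`` against ``centroids``."""
    sizes = np.asarray(sizes, dtype=np.float64).reshape(-1, 2)
    return float(
        sum(1.0 - max(size_aligned_iou(s, c) for c in centroids) for s in sizes)
    )


# ---------------------------------------------------------------------------
# Linear stretch


def linear_stretch(anchors: AnchorSet, params: StretchParams) -> AnchorSet:
    """Spread anchors apart by the two-sided linear stretch (see module docs)."""
    x = anchors.widths
    y = anchors.heights
    x1, xk = x[0], x[-1]
    if xk == x1:
        raise ValueError("degenerate anchor spread (all widths equal)")
    x1p = params.first_scale * x1
    xkp = params.beta * xk
    xp = (x - x1) / (xk - x1) * (xkp - x1p) + x1p
    xp[0], xp[-1] = x1p, xkp  # endpoints exact
    yp = xp * y / x
    return AnchorSet.from_array(np.column_stack([xp, yp]))


def mean_best_iou(boxes: np.ndarray | Sequence[Sequence[float]]) -> Callable[[AnchorSet], float]:
    """Score callback for :func:`sweep_beta`: mean over GT sizes of the best
    size-aligned IoU against any anchor."""
    sizes = np.asarray(boxes, dtype=np.float64).reshape(-1, 2)

    def score(anchors: AnchorSet) -> float:
        return float(
            np.mean([max(size_aligned_iou(s, a) for a in anchors.anchors) for s in sizes])
        )

    return score


def sweep_beta(
    anchors: AnchorSet,
    betas: Sequence[float] = tuple(range(1, 11)),
    evaluation: Callable[[AnchorSet], float] | None = None,
    first_scale: float = 0.5,
) -> list[tuple[float, float | None]]:
    """Apply the stretch for each ``beta`` and record the evaluation score.

    The default grid is the integer range 1..10.  A failing callback is
    recorded as a missing (``None``) entry rather than aborting the sweep.
    """
    if not betas:
        raise ValueError("betas must be non-empty")
    if evaluation is None:
        raise ValueError("an evaluation callback is required (e.g. mean_best_iou(gt_sizes))")
    rows: list[tuple[float, float | None]] = []
    for beta in betas:
        try:
            stretched = linear_stretch(anchors, StretchParams(beta=beta, first_scale=first_scale))
            rows.append((float(beta), float(evaluation(stretched))))
        except Exception as exc:  # noqa: BLE001 - sweep must survive bad betas
            log.warning("beta=%s failed: %s", beta, exc)
            rows.append((float(beta), None))
    return rows


def assign_anchors_to_scales(anchors: AnchorSet) -> dict[int, tuple[tuple[float, float], ...]]:
    """Split nine anchors over the three branches: smallest three to the
    stride-8 (small-target) branch, largest three to stride-32.

    "Smallest" is by area, the YOLO grouping convention (it reproduces the
    canonical COCO grouping, where a tall 30x61 anchor belongs to the middle
    branch although its width undercuts the stride-8 group's 33x23).
    """
    if anchors.k != 9:
        raise ValueError(f"scale assignment needs k=9 anchors, got {anchors.k}")
    by_area = sorted(anchors.anchors, key=lambda wh: (wh[0] * wh[1], wh[0]))
    return {8: tuple(by_area[0:3]), 16: tuple(by_area[3:6]), 32: tuple(by_area[6:9])}


# ---------------------------------------------------------------------------
# Match statistics


@dataclass
class MatchReport:
    """Per-GT-box counts of anchor templates matching above an IoU threshold."""

    per_box: list[int] = field(default_factory=list)
    iou_threshold: float = 0.5

    @property
    def total_matches(self) -> int:
        return sum(self.per_box)

    @property
    def histogram(self) -> dict[int, int]:
        hist: dict[int, int] = {}
        for c in self.per_box:
            hist[c] = hist.get(c, 0) + 1
        return dict(sorted(hist.items()))


def match_statistics(
    anchors: AnchorSet,
    data: Iterable[AnnotatedImage],
    input_size: int = 416,
    iou_threshold: float = 0.5,
) -> MatchReport:
    """Count, per GT box, the anchors that would be responsible for it.

    Each image's boxes are letterboxed to ``input_size``; for every branch
    the anchor templates are tiled at the grid cell containing the GT center
    (anchor centered on the cell center) and full positional IoU against the
    GT is thresholded.  More copies of a small target mean proportionally
    more matched anchors — the effect that makes copy-paste augmentation
    help small-object recall.
    """
    groups = assign_anchors_to_scales(anchors) if anchors.k == 9 else None
    per_box: list[int] = []
    for img in data:
        s = min(input_size / img.width, input_size / img.height)
        pad_x = (input_size - round(img.width * s)) // 2
        pad_y = (input_size - round(img.height * s)) // 2
        for obj in img.objects:
            b = obj.box
            gt = (
                b.xmin * s + pad_x,
                b.ymin * s + pad_y,
                b.xmax * s + pad_x,
                b.ymax * s + pad_y,
            )
            cx, cy = (gt[0] + gt[2]) / 2, (gt[1] + gt[3]) / 2
            count = 0
            if groups is not None:
                branch_iter = groups.items()
            else:
                branch_iter = [(stride, anchors.anchors) for stride in BRANCH_STRIDES]
            for stride, templates in branch_iter:
                grid = input_size // stride
                ci = min(int(cx // stride), grid - 1)
                cj = min(int(cy // stride), grid - 1)
                ax = (ci + 0.5) * stride
                ay = (cj + 0.5) * stride
                for w, h in templates:
                    anchor_box = (ax - w / 2, ay - h / 2, ax + w / 2, ay + h / 2)
                    if iou_xyxy(gt, anchor_box) > iou_threshold:
                        count += 1
            per_box.append(count)
    return MatchReport(per_box=per_box, iou_threshold=iou_threshold)


# ---------------------------------------------------------------------------
# Anchor files (Darknet cfg dialect: "w,h w,h ...")


def write_anchor_file(anchors: AnchorSet, path: str | Path) -> None:
    text = " ".join(f"{w:g},{h:g}" for w, h in anchors.anchors)
    Path(path).write_text(text + "\n")


def read_anchor_file(path: str | Path) -> AnchorSet:
    pairs = []
    for token in Path(path).read_text().split():
        w, h = token.split(",")
        pairs.append((float(w), float(h)))
    return AnchorSet.from_array(pairs)
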