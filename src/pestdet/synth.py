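"""Synthetic light-trap scene and box-size generators.

Real light-trap imagery has four statistical features that drive every
design choice in this toolkit: many small targets per image (per-class mean
relative scale of roughly 0.1-0.6 % of the image side), extreme class
imbalance (instance counts spanning about 108 to 53,000 across the nine
maize-pest classes), occasional inter-object occlusion, and tightly
concentrated box-size distributions.  The generators here reproduce those
*statistics* — not insect appearance — so every module is testable without
downloading anything.

Pests are rendered as textured ellipses with a per-class hue on a bright
noisy background (traps photograph insects against a light panel).  The
per-class hue means a trivial colour-threshold detector can produce
non-degenerate detections, which is all the evaluation module needs to be
exercised end to end.  Everything is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from PIL import Image

from .boxes import BoundingBox
from .voc import MAIZE_PEST_CLASSES, AnnotatedImage, AnnotatedObject, write_voc_annotation

__all__ = [
    "BlobClass",
    "SceneConfig",
    "ScenePool",
    "generate_scene",
    "generate_dataset",
    "generate_box_sample",
    "color_threshold_detector",
]


@dataclass(frozen=True)
class BlobClass:
    """Rendering recipe for one synthetic pest class.

    ``mean_rel_scale`` is the mean linear relative scale in percent:
    ``100 * sqrt(box_area / image_area)``.  ``weight`` is the relative
    abundance (need not be normalised).
    """

    class_id: int
    name: str
    color: tuple[int, int, int]
    mean_rel_scale: float
    scale_sigma: float = 0.25
    weight: float = 1.0


# Nine classes mirroring the collated maize-pest statistics: relative scales
# in the 0.11-0.57 % band and abundance weights spanning 108..53,347 (the
# rarest class is ~0.07 % of all instances).
_CLASS_STATS: tuple[tuple[int, float, float, tuple[int, int, int]], ...] = (
    (5, 0.394, 8880, (140, 70, 30)),
    (6, 0.281, 28014, (90, 120, 40)),
    (8, 0.130, 30339, (60, 60, 110)),
    (13, 0.570, 4279, (150, 40, 90)),
    (24, 0.398, 1686, (180, 140, 30)),
    (29, 0.334, 108, (40, 40, 40)),
    (31, 0.255, 11675, (100, 50, 50)),
    (32, 0.249, 53347, (120, 90, 60)),
    (36, 0.114, 6484, (70, 100, 100)),
)

DEFAULT_CLASSES: tuple[BlobClass, ...] = tuple(
    BlobClass(cid, MAIZE_PEST_CLASSES[cid], color, scale, weight=weight)
    for cid, scale, weight, color in _CLASS_STATS
)


@dataclass(frozen=True)
class SceneConfig:
    """Scene-level generation parameters.

    The defaults emulate the trap-image regime at a 1024-pixel canvas:
    a dozen small targets per image with the per-class size and abundance
    statistics above, a 10 % chance per object of being placed overlapping
    a previous one, and mild sensor noise on a bright background.
    """

    width: int = 1024
    height: int = 1024
    classes: tuple[BlobClass, ...] = DEFAULT_CLASSES
    objects_per_scene: int = 12
    occlusion_probability: float = 0.1
    noise_level: float = 8.0
    background_gray: int = 205

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("scene extent must be positive")
        weights = [c.weight for c in self.classes]
        if any(w < 0 for w in weights) or not any(w > 0 for w in weights):
            raise ValueError("abundance weights must be >= 0 and not all zero")
        if any(c.mean_rel_scale <= 0 for c in self.classes):
            raise ValueError("mean_rel_scale must be positive")

    @classmethod
    def small(cls, **overrides) -> "SceneConfig":
        """A 256-pixel variant with proportionally larger blobs, for unit
        tests where per-pixel work on a full-size canvas is not the point."""
        defaults = dict(
            width=256,
            height=256,
            classes=tuple(
                BlobClass(c.class_id, c.name, c.color, c.mean_rel_scale * 12,
                          c.scale_sigma, c.weight)
                for c in DEFAULT_CLASSES
            ),
            objects_per_scene=6,
        )
        defaults.update(overrides)
        return cls(**defaults)


def _render_blob(
    canvas: np.ndarray, box: BoundingBox, color: tuple[int, int, int], rng: np.random.Generator
) -> None:
    h, w = box.height, box.width
    yy, xx = np.mgrid[0:h, 0:w]
    a, b = max(w / 2.0, 0.5), max(h / 2.0, 0.5)
    mask = ((xx + 0.5 - w / 2) / a) ** 2 + ((yy + 0.5 - h / 2) / b) ** 2 <= 1.0
    texture = rng.normal(1.0, 0.18, size=(h, w, 1))
    patch = np.clip(np.array(color, dtype=np.float64) * texture, 0, 255)
    region = canvas[box.ymin : box.ymax, box.xmin : box.xmax]
    region[mask] = patch[mask].astype(canvas.dtype)


def generate_scene(
    config: SceneConfig, seed: int, image_name: str | None = None
) -> tuple[np.ndarray, AnnotatedImage]:
    """Render one synthetic trap scene with exact GT boxes.

    Deterministic: the same ``(config, seed)`` gives byte-identical pixels
    and annotation.  With probability ``occlusion_probability`` an object is
    deliberately placed overlapping a previous one, which downstream code
    must flag as sticky.
    """
    rng = np.random.default_rng(seed)
    W, H = config.width, config.height
    canvas = np.clip(
        rng.normal(config.background_gray, config.noise_level, size=(H, W, 3)), 0, 255
    ).astype(np.uint8)

    weights = np.array([c.weight for c in config.classes], dtype=np.float64)
    weights /= weights.sum()
    diag = float(np.sqrt(W * H))
    objects: list[AnnotatedObject] = []
    for _ in range(config.objects_per_scene):
        blob = config.classes[int(rng.choice(len(config.classes), p=weights))]
        # lognormal with unit mean so the configured scale is the true mean
        rel = blob.mean_rel_scale / 100.0 * float(
            np.exp(rng.normal(-blob.scale_sigma**2 / 2, blob.scale_sigma))
        )
        side = rel * diag
        ar = float(np.exp(rng.uniform(-0.3, 0.3)))
        bw = int(np.clip(round(side * ar), 2, W // 4))
        bh = int(np.clip(round(side / ar), 2, H // 4))
        if objects and rng.random() < config.occlusion_probability:
            prev = objects[int(rng.integers(len(objects)))].box
            cx = prev.center[0] + rng.uniform(-prev.width / 2, prev.width / 2)
            cy = prev.center[1] + rng.uniform(-prev.height / 2, prev.height / 2)
            x0 = int(np.clip(round(cx - bw / 2), 0, W - bw))
            y0 = int(np.clip(round(cy - bh / 2), 0, H - bh))
        else:
            x0 = int(rng.integers(0, W - bw + 1))
            y0 = int(rng.integers(0, H - bh + 1))
        box = BoundingBox(x0, y0, x0 + bw, y0 + bh)
        _render_blob(canvas, box, blob.color, rng)
        objects.append(AnnotatedObject(blob.class_id, blob.name, box))

    name = image_name or f"scene_{seed:08d}.png"
    return canvas, AnnotatedImage(name, W, H, objects)


@dataclass
class ScenePool:
    """A generated dataset held in memory, with a loader usable anywhere the
    toolkit expects to read image files by path."""

    images: list[AnnotatedImage] = field(default_factory=list)
    pixels: dict[str, np.ndarray] = field(default_factory=dict)

    def loader(self, path: str) -> np.ndarray:
        key = Path(path).name
        if key not in self.pixels:
            raise OSError(f"unknown synthetic image {path}")
        return self.pixels[key]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        (out / "images").mkdir(parents=True, exist_ok=True)
        (out / "annotations").mkdir(parents=True, exist_ok=True)
        for img in self.images:
            Image.fromarray(self.pixels[img.image_path]).save(out / "images" / img.image_path)
            write_voc_annotation(img, out / "annotations" / (Path(img.image_path).stem + ".xml"))


def generate_dataset(config: SceneConfig, n_scenes: int, seed: int) -> ScenePool:
    """Generate ``n_scenes`` scenes with per-scene seeds derived from ``seed``."""
    pool = ScenePool()
    for i in range(n_scenes):
        pix, img = generate_scene(config, seed=seed * 100_003 + i, image_name=f"scene_{seed}_{i:05d}.png")
        pool.images.append(img)
        pool.pixels[img.image_path] = pix
    return pool


def generate_box_sample(
    n: int,
    mixture: Sequence[tuple[float, float, float, float]],
    seed: int,
) -> np.ndarray:
    """Draw ``n`` GT box sizes from a log-normal ``(w, h)`` mixture.

    ``mixture`` rows are ``(mean_w, mean_h, spread, weight)``; the spread is
    the log-scale sigma and the draw is mean-corrected so the configured
    means are the true component means.  Zero spread collapses a component
    to its exact means.  Emulates the concentrated size scatter of trap GT.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    weights = np.array([m[3] for m in mixture], dtype=np.float64)
    weights /= weights.sum()
    comps = rng.choice(len(mixture), size=n, p=weights)
    out = np.empty((n, 2))
    for i, c in enumerate(comps):
        mw, mh, sigma, _ = mixture[c]
        out[i, 0] = mw * np.exp(rng.normal(-sigma**2 / 2, sigma))
        out[i, 1] = mh * np.exp(rng.normal(-sigma**2 / 2, sigma))
    return out


def color_threshold_detector(
    pixels: np.ndarray,
    classes: Sequence[BlobClass] = DEFAULT_CLASSES,
    tolerance: float = 60.0,
) -> list:
    """A deliberately naive per-class colour detector for evaluation tests.

    Connected components of pixels within ``tolerance`` (Euclidean RGB) of a
    class colour become detections, confidence scaled by component size.
    Returns :class:`pestdet.evaluation.Detection` objects.
    """
    from scipy import ndimage

    from .evaluation import Detection

    dets: list[Detection] = []
    img = pixels.astype(np.float64)
    for blob in classes:
        dist = np.linalg.norm(img - np.array(blob.color), axis=-1)
        mask = dist < tolerance
        labels, n = ndimage.label(mask)
        if not n:
            continue
        for sl in ndimage.find_objects(labels):
            h = sl[0].stop - sl[0].start
            w = sl[1].stop - sl[1].start
            if h < 2 or w < 2:
                continue
            conf = float(min(0.99, 0.3 + 0.1 * np.sqrt(h * w)))
            dets.append(
                Detection(
                    class_id=blob.class_id,
                    box=(sl[1].start, sl[0].start, sl[1].stop, sl[0].stop),
                    confidence=conf,
                )
            )
    return dets
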