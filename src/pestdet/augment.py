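"""Copy-paste instance augmentation for class balancing.

Light-trap datasets are extremely imbalanced: a common scarab species can
contribute tens of thousands of GT instances while a rare one has barely a
hundred.  The remedy implemented here crops instances of under-represented
classes out of their source images, filters blurry and "sticky" (overlapping)
crops, and pastes the survivors into low-density background images under two
placement constraints: a pasted box must not overlap any other box (IoU
exactly 0) and pasted objects are spread as far apart as practical.

The far-apart rule is realised by a farthest-candidate heuristic: a batch of
random valid positions is sampled and the one maximising the minimum center
distance to every existing and previously pasted box wins.  All randomness is
drawn from an explicit seeded generator, so augmented annotations are
byte-reproducible.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from PIL import Image
from scipy import ndimage

from .boxes import BoundingBox, iou
from .voc import AnnotatedImage, AnnotatedObject, write_voc_annotation

log = logging.getLogger(__name__)

__all__ = [
    "InstanceCrop",
    "PastePolicy",
    "PasteResult",
    "BalanceReport",
    "load_image",
    "laplacian_sharpness",
    "extract_instances",
    "filter_crops",
    "select_backgrounds",
    "paste_instances",
    "balance_dataset",
]

ImageLoader = Callable[[str], np.ndarray]


def load_image(path: str) -> np.ndarray:
    """Read an image file as an ``(H, W, 3)`` uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def laplacian_sharpness(patch: np.ndarray) -> float:
    """Variance of the Laplacian response over the grayscale patch.

    A flat (uniform-colour) patch scores 0; in-focus textured insects score
    high.  Used as a reproducible stand-in for manually discarding blurry
    crops.
    """
    gray = np.asarray(patch, dtype=np.float64)
    if gray.ndim == 3:
        gray = gray @ np.array([0.299, 0.587, 0.114])
    return float(np.var(ndimage.laplace(gray)))


@dataclass
class InstanceCrop:
    """A cropped pest patch plus provenance and quality scores."""

    pixels: np.ndarray
    class_id: int
    class_name: str
    source_image: str
    source_box: BoundingBox
    sharpness: float
    sticky: bool  # overlapped another GT box at extraction

    def __post_init__(self) -> None:
        h, w = self.pixels.shape[:2]
        if (w, h) != (self.source_box.width, self.source_box.height):
            raise ValueError("crop pixels do not match source box dimensions")
        if self.sharpness < 0:
            raise ValueError("sharpness must be non-negative")


@dataclass
class PastePolicy:
    max_attempts_per_instance: int = 10
    margin: int = 2
    flip_modes: tuple[str, ...] = ("horizontal", "vertical")
    candidate_count: int = 16
    background_max_objects: int = 5

    def __post_init__(self) -> None:
        if self.max_attempts_per_instance < 1 or self.candidate_count < 1:
            raise ValueError("max_attempts_per_instance and candidate_count must be >= 1")
        bad = set(self.flip_modes) - {"horizontal", "vertical"}
        if bad:
            raise ValueError(f"unknown flip modes {bad}")


def extract_instances(
    data: Iterable[AnnotatedImage],
    class_id: int,
    image_loader: ImageLoader = load_image,
) -> list[InstanceCrop]:
    """Crop every GT instance of ``class_id`` out of its source image.

    A crop is flagged ``sticky`` when its box has IoU > 0 with any other
    object in the same image (such crops carry pixels of a neighbour and are
    usually excluded from the paste bank).
    """
    bank: list[InstanceCrop] = []
    for img in data:
        wanted = [o for o in img.objects if o.class_id == class_id]
        if not wanted:
            continue
        try:
            pixels = image_loader(img.image_path)
        except OSError as exc:
            log.warning("skipping unreadable image %s (%s)", img.image_path, exc)
            continue
        for obj in wanted:
            box = obj.box.clipped(img.width, img.height)
            patch = pixels[box.ymin : box.ymax, box.xmin : box.xmax].copy()
            sticky = any(
                other is not obj and iou(box, other.box) > 0 for other in img.objects
            )
            bank.append(
                InstanceCrop(
                    pixels=patch,
                    class_id=obj.class_id,
                    class_name=obj.class_name,
                    source_image=img.image_path,
                    source_box=box,
                    sharpness=laplacian_sharpness(patch),
                    sticky=sticky,
                )
            )
    return bank


def filter_crops(
    bank: Sequence[InstanceCrop], min_sharpness: float = 0.0, exclude_sticky: bool = True
) -> list[InstanceCrop]:
    """Drop blurry and (optionally) sticky crops, preserving order."""
    if not bank:
        raise ValueError("empty crop bank")
    kept = [
        c
        for c in bank
        if c.sharpness >= min_sharpness and not (exclude_sticky and c.sticky)
    ]
    if not kept:
        log.warning("all %d crops filtered out", len(bank))
    return kept


def select_backgrounds(
    data: Iterable[AnnotatedImage], max_objects: int
) -> list[AnnotatedImage]:
    """Images with at most ``max_objects`` GT boxes, sparsest first."""
    eligible = [img for img in data if len(img.objects) <= max_objects]
    return sorted(eligible, key=lambda im: (len(im.objects), im.image_path))


@dataclass
class PasteResult:
    pixels: np.ndarray
    image: AnnotatedImage
    pasted: list[AnnotatedObject] = field(default_factory=list)
    skipped: list[InstanceCrop] = field(default_factory=list)


def _maybe_flip(patch: np.ndarray, policy: PastePolicy, rng: np.random.Generator) -> np.ndarray:
    for mode in policy.flip_modes:
        if rng.random() < 0.5:
            patch = patch[:, ::-1] if mode == "horizontal" else patch[::-1, :]
    return patch


def _min_center_distance(x: float, y: float, boxes: Sequence[BoundingBox]) -> float:
    if not boxes:
        return np.inf
    return min(np.hypot(x - b.center[0], y - b.center[1]) for b in boxes)


def paste_instances(
    background_pixels: np.ndarray,
    background: AnnotatedImage,
    crops: Sequence[InstanceCrop],
    policy: PastePolicy,
    rng_seed: int,
    *,
    new_image_path: str | None = None,
) -> PasteResult:
    """Paste ``crops`` into a background under non-overlap + spread rules.

    Each crop is independently flipped per the policy, then placed at the
    random non-overlapping position (of ``candidate_count`` samples per
    attempt) farthest from every existing box.  Crops for which no valid
    position is found within ``max_attempts_per_instance`` attempts are
    reported in ``skipped``; a crop that cannot fit at all raises.
    """
    rng = np.random.default_rng(rng_seed)
    canvas = np.array(background_pixels, copy=True)
    H, W = canvas.shape[:2]
    if (W, H) != (background.width, background.height):
        raise ValueError("background pixels do not match annotation extent")

    occupied = [o.box for o in background.objects]
    pasted: list[AnnotatedObject] = []
    skipped: list[InstanceCrop] = []
    m = policy.margin
    for crop in crops:
        ch, cw = crop.pixels.shape[:2]
        if cw > W - 2 * m or ch > H - 2 * m:
            raise ValueError(
                f"crop {cw}x{ch} cannot fit in {W}x{H} background with margin {m}"
            )
        patch = _maybe_flip(crop.pixels, policy, rng)
        placed: BoundingBox | None = None
        for _ in range(policy.max_attempts_per_instance):
            xs = rng.integers(m, W - m - cw + 1, size=policy.candidate_count)
            ys = rng.integers(m, H - m - ch + 1, size=policy.candidate_count)
            best_d = -1.0
            for x, y in zip(xs.tolist(), ys.tolist()):
                cand = BoundingBox(x, y, x + cw, y + ch)
                if any(iou(cand, b) > 0 for b in occupied):
                    continue
                d = _min_center_distance(*cand.center, occupied)
                if d > best_d:
                    best_d, placed = d, cand
            if placed is not None:
                break
        if placed is None:
            skipped.append(crop)
            continue
        canvas[placed.ymin : placed.ymax, placed.xmin : placed.xmax] = patch
        obj = AnnotatedObject(crop.class_id, crop.class_name, placed, provenance="pasted")
        occupied.append(placed)
        pasted.append(obj)

    out_path = new_image_path or background.image_path
    image = AnnotatedImage(out_path, W, H, list(background.objects) + pasted)
    return PasteResult(canvas, image, pasted, skipped)


@dataclass
class BalanceReport:
    """Outcome of a balancing run: new images plus achieved-count bookkeeping."""

    new_images: list[tuple[np.ndarray, AnnotatedImage]]
    achieved: dict[int, int]
    targets: dict[int, int]
    shortfall: dict[int, int]
    manifest: list[dict[str, str]]

    @property
    def reached_all_targets(self) -> bool:
        return all(v == 0 for v in self.shortfall.values())


def _current_counts(data: Iterable[AnnotatedImage]) -> dict[int, int]:
    counts: dict[int, int] = {}
    for img in data:
        for obj in img.objects:
            counts[obj.class_id] = counts.get(obj.class_id, 0) + 1
    return counts


def balance_dataset(
    data: Sequence[AnnotatedImage],
    banks: Mapping[int, Sequence[InstanceCrop]],
    targets: Mapping[int, int],
    policy: PastePolicy,
    seed: int,
    *,
    crops_per_image: int = 5,
    image_loader: ImageLoader = load_image,
    out_dir: str | Path | None = None,
) -> BalanceReport:
    """Raise per-class instance counts to ``targets`` by copy-paste.

    Only the training pool should be passed in: evaluation/test images must
    never receive pasted instances.  Backgrounds (sparse images) are reused
    round-robin, each use producing one new image from the *original*
    background pixels, until every deficit class reaches its target or no
    further progress is possible; the report then carries the explicit
    shortfall.
    """
    rng = np.random.default_rng(seed)
    counts = _current_counts(data)
    for cid, tgt in targets.items():
        if tgt < counts.get(cid, 0):
            raise ValueError(f"target {tgt} below current count for class {cid}")

    deficits = {cid: tgt - counts.get(cid, 0) for cid, tgt in targets.items()}
    backgrounds = select_backgrounds(data, policy.background_max_objects)
    new_images: list[tuple[np.ndarray, AnnotatedImage]] = []
    manifest: list[dict[str, str]] = []
    serial = 0
    stalled = False
    while any(d > 0 for d in deficits.values()) and backgrounds and not stalled:
        stalled = True
        for bg in backgrounds:
            todo = [cid for cid, d in deficits.items() if d > 0 and banks.get(cid)]
            if not todo:
                break
            # most-deficient classes first, round-robin within the image
            todo.sort(key=lambda c: -deficits[c])
            chosen: list[InstanceCrop] = []
            for i in range(min(crops_per_image, sum(deficits[c] for c in todo))):
                cid = todo[i % len(todo)]
                if deficits[cid] - sum(c.class_id == cid for c in chosen) <= 0:
                    continue
                bank = banks[cid]
                chosen.append(bank[int(rng.integers(len(bank)))])
            if not chosen:
                break
            try:
                bg_pixels = image_loader(bg.image_path)
            except OSError as exc:
                log.warning("skipping unreadable background %s (%s)", bg.image_path, exc)
                continue
            stem = Path(bg.image_path).stem
            name = f"{stem}_aug{serial:04d}.png"
            result = paste_instances(
                bg_pixels,
                bg,
                chosen,
                policy,
                rng_seed=int(rng.integers(2**31)),
                new_image_path=name,
            )
            if not result.pasted:
                continue
            serial += 1
            stalled = False
            new_images.append((result.pixels, result.image))
            for obj in result.pasted:
                deficits[obj.class_id] -= 1
            manifest.append(
                {
                    "new_image": name,
                    "background": bg.image_path,
                    "pasted": ";".join(
                        f"{o.class_id}@{o.box.as_tuple()}" for o in result.pasted
                    ),
                }
            )
            if all(d <= 0 for d in deficits.values()):
                break

    achieved = _current_counts(data)
    for _, img in new_images:
        for obj in img.objects:
            if obj.provenance == "pasted":
                achieved[obj.class_id] = achieved.get(obj.class_id, 0) + 1
    shortfall = {cid: max(0, d) for cid, d in deficits.items()}
    if any(shortfall.values()):
        log.warning("balance shortfall: %s", shortfall)

    if out_dir is not None:
        out = Path(out_dir)
        (out / "images").mkdir(parents=True, exist_ok=True)
        (out / "annotations").mkdir(parents=True, exist_ok=True)
        for pixels, img in new_images:
            Image.fromarray(pixels).save(out / "images" / img.image_path)
            write_voc_annotation(
                img, out / "annotations" / (Path(img.image_path).stem + ".xml")
            )
        with open(out / "manifest.csv", "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=["new_image", "background", "pasted"])
            w.writeheader()
            w.writerows(manifest)

    return BalanceReport(
        new_images=new_images,
        achieved={cid: achieved.get(cid, 0) for cid in targets},
        targets=dict(targets),
        shortfall=shortfall,
        manifest=manifest,
    )
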