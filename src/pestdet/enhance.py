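"""Online (batch-time) image enhancement.

Each training batch sees a freshly jittered view of every image: the content
is resized with a random scale and aspect distortion, optionally flipped, and
letterboxed onto a square gray canvas at the network input size, with the GT
boxes mapped through the same affine transform.  Different seeds therefore
give different inputs for the same source image, which is the whole point of
doing the enhancement online rather than materialising augmented files.

Boxes travel as float ``(N, 4)`` arrays of ``(xmin, ymin, xmax, ymax)`` so the
letterbox transform is exactly invertible; quantisation back to integer GT
boxes is the caller's concern.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from PIL import Image

__all__ = ["EnhancementParams", "LetterboxTransform", "letterbox", "random_enhance", "flip_horizontal"]


@dataclass
class EnhancementParams:
    """Knobs of the batch enhancement.

    ``gray_value`` 128 is the conventional mid-gray padding; the jitter
    ranges follow common YOLOv3 training practice and are deliberately
    configuration-exposed rather than baked in.
    """

    target_size: int = 416
    scale_range: tuple[float, float] = (0.25, 2.0)
    aspect_jitter: float = 0.3
    flip_probability: float = 0.5
    gray_value: int = 128

    def __post_init__(self) -> None:
        lo, hi = self.scale_range
        if not 0 < lo <= hi:
            raise ValueError("scale_range must satisfy 0 < low <= high")
        if not 0.0 <= self.flip_probability <= 1.0:
            raise ValueError("flip_probability must be in [0, 1]")
        if not 0 <= self.gray_value <= 255:
            raise ValueError("gray_value must be in [0, 255]")
        if self.target_size <= 0:
            raise ValueError("target_size must be positive")


@dataclass(frozen=True)
class LetterboxTransform:
    """Affine record ``x' = s*x + pad_x`` of a letterbox, for inversion."""

    scale: float
    pad_x: float
    pad_y: float

    def apply_boxes(self, boxes: np.ndarray) -> np.ndarray:
        boxes = np.asarray(boxes, dtype=np.float64).reshape(-1, 4)
        out = boxes * self.scale
        out[:, [0, 2]] += self.pad_x
        out[:, [1, 3]] += self.pad_y
        return out

    def invert_boxes(self, boxes: np.ndarray) -> np.ndarray:
        boxes = np.asarray(boxes, dtype=np.float64).reshape(-1, 4)
        out = boxes.copy()
        out[:, [0, 2]] -= self.pad_x
        out[:, [1, 3]] -= self.pad_y
        return out / self.scale


def letterbox(
    pixels: np.ndarray,
    boxes: np.ndarray | Sequence[Sequence[float]],
    target_size: int,
    gray_value: int = 128,
) -> tuple[np.ndarray, np.ndarray, LetterboxTransform]:
    """Aspect-preserving resize onto a square gray canvas.

    The content is scaled by ``s = min(target/w, target/h)`` and centered;
    the excess is filled with gray bars.  Boxes are mapped by the same
    transform, which is returned for inversion.
    """
    if target_size <= 0:
        raise ValueError("target_size must be positive")
    h, w = pixels.shape[:2]
    if h == 0 or w == 0:
        raise ValueError("empty image")
    s = min(target_size / w, target_size / h)
    new_w, new_h = max(1, round(w * s)), max(1, round(h * s))
    pad_x = (target_size - new_w) // 2
    pad_y = (target_size - new_h) // 2

    if (new_w, new_h) == (w, h):
        content = np.asarray(pixels)
    else:
        content = np.asarray(
            Image.fromarray(np.asarray(pixels)).resize((new_w, new_h), Image.BILINEAR)
        )
    shape = (target_size, target_size) + pixels.shape[2:]
    canvas = np.full(shape, gray_value, dtype=pixels.dtype)
    canvas[pad_y : pad_y + new_h, pad_x : pad_x + new_w] = content

    tf = LetterboxTransform(scale=s, pad_x=float(pad_x), pad_y=float(pad_y))
    out_boxes = tf.apply_boxes(np.asarray(boxes, dtype=np.float64).reshape(-1, 4))
    return canvas, out_boxes, tf


def flip_horizontal(pixels: np.ndarray, boxes: np.ndarray, width: int) -> tuple[np.ndarray, np.ndarray]:
    """Mirror pixels and boxes about the vertical axis of a ``width`` canvas."""
    boxes = np.asarray(boxes, dtype=np.float64).reshape(-1, 4)
    flipped = boxes.copy()
    flipped[:, 0] = width - boxes[:, 2]
    flipped[:, 2] = width - boxes[:, 0]
    return pixels[:, ::-1].copy(), flipped


def random_enhance(
    pixels: np.ndarray,
    boxes: np.ndarray | Sequence[Sequence[float]],
    params: EnhancementParams,
    rng_seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """One stochastic enhancement draw: scale + aspect jitter + flip + letterbox.

    The scale draw changes the resampling resolution of the content (texture
    detail), the aspect jitter distorts its geometry, and the final letterbox
    guarantees everything lands inside the square canvas.  Boxes that
    degenerate below one pixel on a side after the transform are dropped.
    Pure function of ``(input, params, seed)`` — no global RNG state.
    """
    rng = np.random.default_rng(rng_seed)
    boxes = np.asarray(boxes, dtype=np.float64).reshape(-1, 4)
    h, w = pixels.shape[:2]

    scale = rng.uniform(*params.scale_range)
    jx = rng.uniform(-params.aspect_jitter, params.aspect_jitter)
    jy = rng.uniform(-params.aspect_jitter, params.aspect_jitter)
    sx = scale * (1.0 + jx)
    sy = scale * (1.0 + jy)
    new_w, new_h = max(1, round(w * sx)), max(1, round(h * sy))

    if (new_w, new_h) != (w, h):
        content = np.asarray(
            Image.fromarray(np.asarray(pixels)).resize((new_w, new_h), Image.BILINEAR)
        )
        # exact factors after integer rounding, so boxes stay aligned
        fx, fy = new_w / w, new_h / h
        jittered = boxes.copy()
        jittered[:, [0, 2]] *= fx
        jittered[:, [1, 3]] *= fy
    else:
        content, jittered = np.asarray(pixels), boxes.copy()

    canvas, out_boxes, _ = letterbox(content, jittered, params.target_size, params.gray_value)

    if rng.random() < params.flip_probability:
        canvas, out_boxes = flip_horizontal(canvas, out_boxes, params.target_size)

    np.clip(out_boxes[:, [0, 2]], 0, params.target_size, out=out_boxes[:, [0, 2]])
    np.clip(out_boxes[:, [1, 3]], 0, params.target_size, out=out_boxes[:, [1, 3]])
    keep = (out_boxes[:, 2] - out_boxes[:, 0] >= 1.0) & (out_boxes[:, 3] - out_boxes[:, 1] >= 1.0)
    return canvas, out_boxes[keep]
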