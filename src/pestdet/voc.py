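"""Pascal VOC annotation I/O, collation, statistics and splitting.

The unit flowing through the toolkit is the :class:`AnnotatedImage`: an image
reference plus its class-labelled ground-truth (GT) boxes.  VOC XML files
store 1-based inclusive pixel coordinates; everything in memory is 0-based
half-open (see :mod:`pestdet.boxes`).

The nine maize-pest classes of the Pest24 light-trap dataset, by their
original index, are exposed as :data:`MAIZE_PEST_CLASSES`.
"""

from __future__ import annotations

import csv
import logging
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .boxes import BoundingBox

log = logging.getLogger(__name__)

__all__ = [
    "MAIZE_PEST_CLASSES",
    "ClassRegistry",
    "AnnotatedObject",
    "AnnotatedImage",
    "ClassSummary",
    "DatasetSummary",
    "VocFormatError",
    "read_voc_annotation",
    "write_voc_annotation",
    "collate_dataset",
    "summarize_dataset",
    "split_dataset",
]

#: Pest24 maize-pest classes kept in the collated dataset, keyed by the
#: dataset's original class index.
MAIZE_PEST_CLASSES: dict[int, str] = {
    5: "Armyworm",
    6: "Bollworm",
    8: "Athetis Lepigone",
    13: "Little Gecko",
    24: "Yellow Tiger",
    29: "Holotrichia Oblita",
    31: "Holotrichia Parallela",
    32: "Anomala Corpulenta",
    36: "Agriotes Fuscicollis Miwa",
}


class VocFormatError(ValueError):
    """Malformed or incomplete VOC XML."""


class ClassRegistry:
    """Bidirectional id <-> name map for the configured detection classes."""

    def __init__(self, id_to_name: Mapping[int, str]):
        if not id_to_name:
            raise ValueError("empty class registry")
        self.id_to_name = dict(id_to_name)
        self.name_to_id = {v: k for k, v in self.id_to_name.items()}
        if len(self.name_to_id) != len(self.id_to_name):
            raise ValueError("duplicate class names in registry")

    @classmethod
    def maize_pests(cls) -> "ClassRegistry":
        return cls(MAIZE_PEST_CLASSES)

    def __contains__(self, key: object) -> bool:
        return key in self.id_to_name or key in self.name_to_id

    def __len__(self) -> int:
        return len(self.id_to_name)

    def ids(self) -> list[int]:
        return sorted(self.id_to_name)

    def resolve(self, name_or_id: str | int) -> tuple[int, str]:
        if isinstance(name_or_id, int):
            return name_or_id, self.id_to_name[name_or_id]
        return self.name_to_id[name_or_id], name_or_id


@dataclass(frozen=True)
class AnnotatedObject:
    """One GT instance: class label, box, and whether it was pasted."""

    class_id: int
    class_name: str
    box: BoundingBox
    provenance: str = "original"  # "original" | "pasted"

    def __post_init__(self) -> None:
        if self.provenance not in ("original", "pasted"):
            raise ValueError(f"bad provenance {self.provenance!r}")


@dataclass
class AnnotatedImage:
    image_path: str
    width: int
    height: int
    objects: list[AnnotatedObject] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError(f"non-positive image extent for {self.image_path}")
        for obj in self.objects:
            if not obj.box.inside(self.width, self.height):
                raise ValueError(
                    f"box {obj.box} outside {self.width}x{self.height} image {self.image_path}"
                )

    def class_ids(self) -> set[int]:
        return {o.class_id for o in self.objects}

    def with_objects(self, objects: Sequence[AnnotatedObject]) -> "AnnotatedImage":
        return AnnotatedImage(self.image_path, self.width, self.height, list(objects))


# ---------------------------------------------------------------------------
# XML I/O


def _require(parent: ET.Element, tag: str, source: str) -> ET.Element:
    el = parent.find(tag)
    if el is None:
        raise VocFormatError(f"{source}: missing <{tag}> element")
    return el


def read_voc_annotation(
    xml_source: str | Path,
    class_registry: ClassRegistry,
    *,
    image_path: str | None = None,
) -> AnnotatedImage:
    """Parse one VOC XML file into an :class:`AnnotatedImage`.

    Objects whose class is not in ``class_registry`` are dropped (with a
    counted warning, mirroring the tag-removal traversal used to collate the
    source dataset).  Coordinates are converted from VOC's 1-based inclusive
    convention to the internal 0-based half-open one; boxes degenerate after
    conversion are skipped with a warning.
    """
    source = str(xml_source)
    try:
        root = ET.parse(str(xml_source)).getroot()
    except ET.ParseError as exc:
        raise VocFormatError(f"{source}: malformed XML ({exc})") from exc

    size = _require(root, "size", source)
    width = int(_require(size, "width", source).text or 0)
    height = int(_require(size, "height", source).text or 0)
    if image_path is None:
        fn = root.findtext("filename")
        image_path = fn if fn else Path(source).with_suffix(".png").name

    objects: list[AnnotatedObject] = []
    dropped_unknown = 0
    for obj_el in root.iter("object"):
        name = (obj_el.findtext("name") or "").strip()
        key: str | int = name
        if name not in class_registry:
            try:
                key = int(name)
            except ValueError:
                key = name
        if key not in class_registry:
            dropped_unknown += 1
            continue
        class_id, class_name = class_registry.resolve(key)
        bnd = _require(obj_el, "bndbox", source)
        xmin = int(round(float(_require(bnd, "xmin", source).text or "nan"))) - 1
        ymin = int(round(float(_require(bnd, "ymin", source).text or "nan"))) - 1
        xmax = int(round(float(_require(bnd, "xmax", source).text or "nan")))
        ymax = int(round(float(_require(bnd, "ymax", source).text or "nan")))
        if xmax <= xmin or ymax <= ymin:
            log.warning("%s: degenerate box for %s skipped", source, class_name)
            continue
        box = BoundingBox(max(xmin, 0), max(ymin, 0), min(xmax, width), min(ymax, height))
        prov = obj_el.findtext("provenance") or "original"
        objects.append(AnnotatedObject(class_id, class_name, box, prov))
    if dropped_unknown:
        log.warning("%s: dropped %d objects of unregistered classes", source, dropped_unknown)
    return AnnotatedImage(image_path, width, height, objects)


def write_voc_annotation(
    image: AnnotatedImage, out_path: str | Path | None = None
) -> str:
    """Serialize an :class:`AnnotatedImage` to VOC XML (1-based inclusive).

    Element order is deterministic and objects keep their input order, so
    identical inputs produce byte-identical files.  Returns the XML text;
    writes it to ``out_path`` when given.
    """
    for obj in image.objects:
        if not obj.box.inside(image.width, image.height):
            raise ValueError(f"box {obj.box} violates image extent, refusing to write")

    root = ET.Element("annotation")
    ET.SubElement(root, "folder").text = str(Path(image.image_path).parent) or "."
    ET.SubElement(root, "filename").text = Path(image.image_path).name
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(image.width)
    ET.SubElement(size, "height").text = str(image.height)
    ET.SubElement(size, "depth").text = "3"
    for obj in image.objects:
        el = ET.SubElement(root, "object")
        ET.SubElement(el, "name").text = obj.class_name
        ET.SubElement(el, "provenance").text = obj.provenance
        ET.SubElement(el, "difficult").text = "0"
        bnd = ET.SubElement(el, "bndbox")
        ET.SubElement(bnd, "xmin").text = str(obj.box.xmin + 1)
        ET.SubElement(bnd, "ymin").text = str(obj.box.ymin + 1)
        ET.SubElement(bnd, "xmax").text = str(obj.box.xmax)
        ET.SubElement(bnd, "ymax").text = str(obj.box.ymax)
    ET.indent(root)
    text = ET.tostring(root, encoding="unicode") + "\n"
    if out_path is not None:
        Path(out_path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# Collation, statistics, splitting


def collate_dataset(
    raw: Iterable[AnnotatedImage], keep_classes: set[int]
) -> list[AnnotatedImage]:
    """Keep only objects of ``keep_classes``; drop images left empty.

    This is the collation step that turns the raw light-trap annotations into
    the working dataset: foreign class tags are removed and images without
    any remaining target object are discarded.
    """
    if not keep_classes:
        raise ValueError("keep_classes must be non-empty")
    out: list[AnnotatedImage] = []
    dropped_images = 0
    for img in raw:
        kept = [o for o in img.objects if o.class_id in keep_classes]
        if kept:
            out.append(img.with_objects(kept))
        else:
            dropped_images += 1
    log.info("collate: kept %d images, removed %d without target objects", len(out), dropped_images)
    return out


@dataclass
class ClassSummary:
    """Per-class dataset statistics.

    ``avg_relative_scale_linear`` is the instance mean of
    ``100 * sqrt(box_area / image_area)`` (a linear size ratio);
    ``avg_relative_scale_area`` is the instance mean of the raw area ratio in
    percent.  The GT-size/image-size ratio can be read either way, so both
    are carried; the linear one is the default display value because its
    magnitude matches the 0.1-0.6 % range typical of light-trap targets.
    """

    image_count: int = 0
    instance_count: int = 0
    avg_relative_scale_linear: float = 0.0
    avg_relative_scale_area: float = 0.0

    def merged(self, other: "ClassSummary") -> "ClassSummary":
        n = self.instance_count + other.instance_count
        if n == 0:
            return ClassSummary(self.image_count + other.image_count, 0, 0.0, 0.0)
        wl = (
            self.avg_relative_scale_linear * self.instance_count
            + other.avg_relative_scale_linear * other.instance_count
        ) / n
        wa = (
            self.avg_relative_scale_area * self.instance_count
            + other.avg_relative_scale_area * other.instance_count
        ) / n
        return ClassSummary(self.image_count + other.image_count, n, wl, wa)


@dataclass
class DatasetSummary:
    """Per-class counts and scales; additive over disjoint dataset unions."""

    per_class: dict[int, ClassSummary] = field(default_factory=dict)

    @property
    def total_instances(self) -> int:
        return sum(c.instance_count for c in self.per_class.values())

    @property
    def total_images(self) -> int:
        # note: not the union image count -- an image can host several classes
        return sum(c.image_count for c in self.per_class.values())

    def __add__(self, other: "DatasetSummary") -> "DatasetSummary":
        merged: dict[int, ClassSummary] = {}
        for cid in set(self.per_class) | set(other.per_class):
            a = self.per_class.get(cid, ClassSummary())
            b = other.per_class.get(cid, ClassSummary())
            merged[cid] = a.merged(b)
        return DatasetSummary(merged)

    def to_csv(self, path: str | Path, registry: ClassRegistry | None = None) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(
                [
                    "class_id",
                    "class_name",
                    "images",
                    "instances",
                    "avg_relative_scale_linear_pct",
                    "avg_relative_scale_area_pct",
                ]
            )
            for cid in sorted(self.per_class):
                c = self.per_class[cid]
                name = registry.id_to_name.get(cid, "") if registry else ""
                w.writerow(
                    [
                        cid,
                        name,
                        c.image_count,
                        c.instance_count,
                        f"{c.avg_relative_scale_linear:.4f}",
                        f"{c.avg_relative_scale_area:.4f}",
                    ]
                )


def summarize_dataset(data: Iterable[AnnotatedImage]) -> DatasetSummary:
    """Tally per-class image and instance counts and average relative scales."""
    images: dict[int, int] = {}
    instances: dict[int, int] = {}
    lin: dict[int, float] = {}
    area: dict[int, float] = {}
    for img in data:
        img_area = img.width * img.height
        for cid in img.class_ids():
            images[cid] = images.get(cid, 0) + 1
        for obj in img.objects:
            cid = obj.class_id
            instances[cid] = instances.get(cid, 0) + 1
            ratio = obj.box.area / img_area
            lin[cid] = lin.get(cid, 0.0) + 100.0 * math.sqrt(ratio)
            area[cid] = area.get(cid, 0.0) + 100.0 * ratio
    per_class = {
        cid: ClassSummary(
            image_count=images.get(cid, 0),
            instance_count=n,
            avg_relative_scale_linear=lin[cid] / n,
            avg_relative_scale_area=area[cid] / n,
        )
        for cid, n in instances.items()
    }
    return DatasetSummary(per_class)


def split_dataset(
    data: Sequence[AnnotatedImage], train_fraction: float, seed: int
) -> tuple[list[AnnotatedImage], list[AnnotatedImage]]:
    """Deterministic train/validation partition (default protocol is 8:2).

    Images are ordered lexicographically by path before the seeded shuffle so
    the split does not depend on input ordering or filesystem enumeration.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    data = list(data)
    if len(data) < 2:
        raise ValueError("need at least 2 images to split")
    order = sorted(range(len(data)), key=lambda i: data[i].image_path)
    rng = np.random.default_rng(seed)
    rng.shuffle(order)
    n_train = int(math.floor(len(data) * train_fraction + 0.5))
    n_train = min(max(n_train, 1), len(data) - 1)
    train = [data[i] for i in order[:n_train]]
    val = [data[i] for i in order[n_train:]]
    return train, val
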