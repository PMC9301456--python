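"""Declarative YOLOv3 architecture specs with exact parameter accounting.

Two variants are built as layer graphs (no tensors, no framework):

* ``baseline`` — standard YOLOv3: Darknet-53 backbone (residual block
  multiplicities 1, 2, 8, 8, 4), an FPN neck with two upsample-concat
  merges, and three detection branches of five DBLs + one DBL + a biased
  1x1 detection conv.  A DBL is Conv + BatchNorm + LeakyReLU.
* ``improved`` — the small-target variant: the second residual block (128
  filters) is expanded from 2 to 4 units to retain more low-level location
  information, and in every branch two of the five pre-head DBLs are wrapped
  into a residual unit (two DBLs plus an identity skip) to enhance feature
  reuse.  The skip is parameter-free, so the head swap costs 0 parameters;
  the two extra 128-channel residual units cost exactly
  ``2 * (128*64*1*1 + 2*64 + 64*128*3*3 + 2*128) = 164,608``.

Counting conventions: a conv contributes ``in * out * k^2`` weights plus
``out`` biases only where a bias exists (detection convs; convs feeding a
BatchNorm are bias-free), and a BatchNorm contributes 2 trainable parameters
per channel (scale and shift; running statistics are buffers, not
parameters).  Downsampling is by stride-2 convolution only — there is no
pooling anywhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable

__all__ = [
    "LayerSpec",
    "ArchitectureSpec",
    "ParamCountReport",
    "build_yolov3_spec",
    "build_improved_spec",
    "count_parameters",
    "infer_shapes",
    "branch_output_shapes",
    "prune_to_branch",
    "freeze_schedule",
]

_KINDS = {"conv", "batch_norm", "leaky_relu", "residual_add", "upsample", "concat", "detect_head"}

#: Residual-unit multiplicities of the five Darknet-53 stages.
DARKNET53_BLOCKS: tuple[int, ...] = (1, 2, 8, 8, 4)
IMPROVED_BLOCKS: tuple[int, ...] = (1, 4, 8, 8, 4)


@dataclass(frozen=True)
class LayerSpec:
    name: str
    kind: str
    filters: int = 0
    kernel: int = 0
    stride: int = 1
    has_bias: bool = False
    inputs: tuple[str, ...] = ()
    block: str = ""
    section: str = ""  # "backbone" or "head" (neck+branches train with the head)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind in ("conv", "detect_head") and self.stride not in (1, 2):
            raise ValueError("conv stride must be 1 or 2")


@dataclass(frozen=True)
class ArchitectureSpec:
    layers: tuple[LayerSpec, ...]
    num_classes: int
    input_size: int = 416
    anchors_per_scale: int = 3
    head_names: tuple[str, str, str] = ()
    decode_branches: tuple[int, ...] = (1, 2, 3)
    variant: str = "baseline"

    def __post_init__(self) -> None:
        by_name = {l.name: l for l in self.layers}
        if len(by_name) != len(self.layers):
            raise ValueError("duplicate layer names")
        head_ch = self.anchors_per_scale * (self.num_classes + 5)
        for name in self.head_names:
            head = by_name[name]
            if head.filters != head_ch:
                raise ValueError(
                    f"head {name}: {head.filters} channels, expected {head_ch}"
                )
            if not head.has_bias or head.kernel != 1:
                raise ValueError("detection convs must be biased 1x1")
        for layer in self.layers:
            if layer.kind == "batch_norm":
                src = by_name[layer.inputs[0]]
                if src.kind == "conv" and src.has_bias:
                    raise ValueError(f"conv {src.name} feeding BN must be bias-free")

    @property
    def head_channels(self) -> int:
        return self.anchors_per_scale * (self.num_classes + 5)

    def layer(self, name: str) -> LayerSpec:
        for l in self.layers:
            if l.name == name:
                return l
        raise KeyError(name)

    def channels(self) -> dict[str, int]:
        """Per-layer output channel count (graph inference from RGB input)."""
        ch: dict[str, int] = {"input": 3}
        for layer in self.layers:
            if layer.kind in ("conv", "detect_head"):
                ch[layer.name] = layer.filters
            elif layer.kind == "concat":
                ch[layer.name] = sum(ch[i] for i in layer.inputs)
            else:
                ch[layer.name] = ch[layer.inputs[0]]
        return ch

    def to_json(self) -> str:
        return json.dumps(
            {
                "variant": self.variant,
                "num_classes": self.num_classes,
                "input_size": self.input_size,
                "anchors_per_scale": self.anchors_per_scale,
                "head_names": list(self.head_names),
                "decode_branches": list(self.decode_branches),
                "layers": [vars(l) | {"inputs": list(l.inputs)} for l in self.layers],
            },
            indent=1,
        )

    def to_darknet_cfg(self) -> str:
        """Export as a Darknet-style cfg dialect (for inspection/diffing)."""
        lines = [f"# pestdet {self.variant} num_classes={self.num_classes}", "[net]",
                 f"width={self.input_size}", f"height={self.input_size}", "channels=3", ""]
        for l in self.layers:
            if l.kind in ("conv", "detect_head"):
                lines += ["[convolutional]", f"# {l.name}",
                          f"filters={l.filters}", f"size={l.kernel}", f"stride={l.stride}",
                          f"batch_normalize={0 if l.has_bias else 1}",
                          "activation=linear" if l.kind == "detect_head" else "activation=leaky", ""]
            elif l.kind == "residual_add":
                lines += ["[shortcut]", f"# {l.name} from {l.inputs[1]}", ""]
            elif l.kind == "upsample":
                lines += ["[upsample]", f"# {l.name}", "stride=2", ""]
            elif l.kind == "concat":
                lines += ["[route]", f"# {l.name} layers {','.join(l.inputs)}", ""]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Graph builder


class _Builder:
    def __init__(self) -> None:
        self.layers: list[LayerSpec] = []
        self.current = "input"
        self._n = 0

    def add(self, kind: str, *, inputs: tuple[str, ...] | None = None, advance: bool = True, **kw) -> str:
        self._n += 1
        name = f"{kind}_{self._n:03d}"
        if inputs is None:
            inputs = (self.current,)
        self.layers.append(LayerSpec(name=name, kind=kind, inputs=inputs, **kw))
        if advance:
            self.current = name
        return name

    def dbl(self, filters: int, kernel: int, block: str, section: str, stride: int = 1) -> str:
        self.add("conv", filters=filters, kernel=kernel, stride=stride,
                 has_bias=False, block=block, section=section)
        self.add("batch_norm", block=block, section=section)
        return self.add("leaky_relu", block=block, section=section)

    def residual_unit(self, channels: int, block: str, section: str) -> str:
        """Two DBLs (1x1 bottleneck to channels/2, then 3x3 back) + skip."""
        skip = self.current
        self.dbl(channels // 2, 1, block, section)
        self.dbl(channels, 3, block, section)
        return self.add("residual_add", inputs=(self.current, skip), block=block, section=section)

    def head_residual_unit(self, channels: int, block: str, section: str) -> str:
        """Branch-head residual unit: 3x3 expansion then 1x1 back + skip."""
        skip = self.current
        self.dbl(channels * 2, 3, block, section)
        self.dbl(channels, 1, block, section)
        return self.add("residual_add", inputs=(self.current, skip), block=block, section=section)


def _build_backbone(b: _Builder, block_units: tuple[int, ...]) -> tuple[str, str, str]:
    """Darknet-53-shaped backbone; returns the stride-8/16/32 tap layers."""
    sec = "backbone"
    b.dbl(32, 3, "stem", sec)
    taps = []
    filters = 32
    for stage, units in enumerate(block_units, start=1):
        filters *= 2  # 64, 128, 256, 512, 1024
        block = f"stage{stage}"
        b.dbl(filters, 3, block, sec, stride=2)
        for _ in range(units):
            b.residual_unit(filters, block, sec)
        if stage >= 3:
            taps.append(b.current)
    return tuple(taps)  # (stride8 @256ch, stride16 @512ch, stride32 @1024ch)


def _build_branch(
    b: _Builder, channels: int, block: str, head_ch: int, improved: bool
) -> tuple[str, str]:
    """One detection branch; returns (tap-for-FPN-reduce, detect layer name).

    Baseline: five alternating DBLs (1x1 c, 3x3 2c, 1x1 c, 3x3 2c, 1x1 c).
    Improved: DBLs two and three become a residual unit over the same convs,
    leaving three plain DBLs plus one residual unit — identical parameters.
    """
    sec = "head"
    b.dbl(channels, 1, block, sec)
    if improved:
        b.head_residual_unit(channels, block, sec)
    else:
        b.dbl(channels * 2, 3, block, sec)
        b.dbl(channels, 1, block, sec)
    b.dbl(channels * 2, 3, block, sec)
    tap = b.dbl(channels, 1, block, sec)
    b.dbl(channels * 2, 3, block, sec)
    detect = b.add("detect_head", filters=head_ch, kernel=1, has_bias=True,
                   block=block, section=sec)
    return tap, detect


def _build(num_classes: int, variant: str, input_size: int = 416) -> ArchitectureSpec:
    if num_classes < 1:
        raise ValueError("num_classes must be >= 1")
    blocks = IMPROVED_BLOCKS if variant == "improved" else DARKNET53_BLOCKS
    improved = variant == "improved"
    head_ch = 3 * (num_classes + 5)

    b = _Builder()
    tap8, tap16, tap32 = _build_backbone(b, blocks)

    # branch 1 (stride 32)
    t1, d1 = _build_branch(b, 512, "branch1", head_ch, improved)
    # FPN merge to stride 16
    b.current = t1
    b.dbl(256, 1, "fpn1", "head")
    b.add("upsample", block="fpn1", section="head")
    b.add("concat", inputs=(b.current, tap16), block="fpn1", section="head")
    t2, d2 = _build_branch(b, 256, "branch2", head_ch, improved)
    # FPN merge to stride 8
    b.current = t2
    b.dbl(128, 1, "fpn2", "head")
    b.add("upsample", block="fpn2", section="head")
    b.add("concat", inputs=(b.current, tap8), block="fpn2", section="head")
    _, d3 = _build_branch(b, 128, "branch3", head_ch, improved)

    return ArchitectureSpec(
        layers=tuple(b.layers),
        num_classes=num_classes,
        input_size=input_size,
        head_names=(d1, d2, d3),
        variant=variant,
    )


def build_yolov3_spec(num_classes: int, input_size: int = 416) -> ArchitectureSpec:
    """Baseline YOLOv3: Darknet-53 (1,2,8,8,4) + FPN + three branches."""
    return _build(num_classes, "baseline", input_size)


def build_improved_spec(num_classes: int, input_size: int = 416) -> ArchitectureSpec:
    """Small-target variant: 4 units in the second residual block and a
    parameter-neutral DBL-to-residual swap in every branch head."""
    return _build(num_classes, "improved", input_size)


# ---------------------------------------------------------------------------
# Parameter counting


@dataclass
class ParamCountReport:
    total: int
    per_block: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.total == sum(self.per_block.values())

    def table(self) -> str:
        rows = [f"{blk:<10} {n:>12,}" for blk, n in self.per_block.items()]
        rows.append(f"{'total':<10} {self.total:>12,}")
        return "\n".join(rows)


def count_parameters(spec: ArchitectureSpec) -> ParamCountReport:
    """Exact trainable-parameter count under the module's conventions."""
    ch = spec.channels()
    per_block: dict[str, int] = {}
    for layer in spec.layers:
        if layer.kind in ("conv", "detect_head"):
            in_ch = ch[layer.inputs[0]] if layer.inputs[0] != "input" else 3
            n = in_ch * layer.filters * layer.kernel**2
            if layer.has_bias:
                n += layer.filters
        elif layer.kind == "batch_norm":
            n = 2 * ch[layer.name]
        else:
            n = 0
        if n:
            per_block[layer.block] = per_block.get(layer.block, 0) + n
    return ParamCountReport(total=sum(per_block.values()), per_block=per_block)


# ---------------------------------------------------------------------------
# Shape inference


def infer_shapes(spec: ArchitectureSpec, input_size: int | None = None) -> dict[str, tuple[int, int, int]]:
    """Per-layer ``(H, W, C)``; stride-2 convs halve, upsample doubles,
    concat sums channels.  ``input_size`` must be divisible by 32."""
    size = spec.input_size if input_size is None else input_size
    if size % 32 != 0:
        raise ValueError(f"input_size {size} not divisible by 32")
    ch = spec.channels()
    shapes: dict[str, tuple[int, int, int]] = {"input": (size, size, 3)}
    for layer in spec.layers:
        if layer.kind in ("conv", "detect_head"):
            h, w, _ = shapes[layer.inputs[0]]
            if layer.stride == 2:
                h, w = h // 2, w // 2
            shapes[layer.name] = (h, w, layer.filters)
        elif layer.kind == "upsample":
            h, w, c = shapes[layer.inputs[0]]
            shapes[layer.name] = (2 * h, 2 * w, c)
        elif layer.kind == "concat":
            hw = {shapes[i][:2] for i in layer.inputs}
            if len(hw) != 1:
                raise ValueError(f"concat {layer.name}: mismatched spatial dims {hw}")
            h, w = hw.pop()
            shapes[layer.name] = (h, w, ch[layer.name])
        elif layer.kind == "residual_add":
            ss = {shapes[i] for i in layer.inputs}
            if len(ss) != 1:
                raise ValueError(f"residual_add {layer.name}: mismatched shapes {ss}")
            shapes[layer.name] = ss.pop()
        else:
            shapes[layer.name] = shapes[layer.inputs[0]]
    return shapes


def branch_output_shapes(spec: ArchitectureSpec, input_size: int | None = None) -> tuple[tuple[int, int, int], ...]:
    """Shapes of the three detection heads (branch 1 = stride 32 first)."""
    shapes = infer_shapes(spec, input_size)
    return tuple(shapes[name] for name in spec.head_names)


# ---------------------------------------------------------------------------
# Branch pruning and freeze scheduling


def prune_to_branch(spec: ArchitectureSpec, branch: int = 3) -> ArchitectureSpec:
    """Restrict inference decoding to one branch (default 3, the stride-8
    small-target head).  The layer graph — and hence the parameter count —
    is untouched; only which heads get decoded changes.  Idempotent."""
    if branch not in (1, 2, 3):
        raise ValueError(f"branch must be 1, 2 or 3, got {branch}")
    return replace(spec, decode_branches=(branch,))


def freeze_schedule(
    spec: ArchitectureSpec, freeze_epochs: int, total_epochs: int = 100
) -> list[dict[str, bool]]:
    """Transfer-learning freeze plan: backbone layers non-trainable for the
    first ``freeze_epochs`` epochs (default protocol freezes for 50 of 100),
    everything trainable afterwards.  Pure data — no training loop here."""
    if freeze_epochs < 0:
        raise ValueError("freeze_epochs must be >= 0")
    plan = []
    for epoch in range(total_epochs):
        frozen = epoch < freeze_epochs
        plan.append(
            {l.name: not (frozen and l.section == "backbone") for l in spec.layers}
        )
    return plan
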