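"""Declarative 34-layer CNN blueprint and learnable-parameter audit.

The network stacks 8 convolution blocks (conv 3x3 same-padding stride 1,
batch normalization, ReLU), with 2x2/stride-2 max pooling after blocks
1-5 and 8, then a 512->2 fully connected layer, softmax, and a
classification stage.  Filter counts follow filters(n) = min(2^(n+2), 512)
for block n = 1..8, i.e. 8, 16, 32, 64, 128, 256, 512, 512.  Under the
layer-counting convention that counts the input, every activation and
pooling stage, softmax and classification, the base network has 34 layers
and 3,937,970 learnable parameters (3.9 million).

A published per-layer parameter table for this architecture prints
1,180,160 for the eighth convolution — a duplicate of the seventh row.
The eighth batch norm (1024 = 2 x 512 channels), the FC count
(1026 = 512*2 + 2) and the 3.9 M total all require conv block 8 to emit
512 channels, giving 3*3*512*512 + 512 = 2,360,320.  The audit reports
the discrepancy rather than silently adopting either number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

__all__ = [
    "LayerSpec",
    "ArchitectureSpec",
    "VARIANTS",
    "conv_filters",
    "build_architecture",
    "count_layer_params",
    "total_params",
    "spatial_trace",
    "fc_input_features",
    "TABLE_PUBLISHED_PARAMS",
    "AuditRow",
    "audit_against_table",
    "describe",
]

VARIANTS = ("augmentation_no_dropout", "dropout_no_augmentation")

N_CONV_BLOCKS = 8
POOL_AFTER_BLOCKS = (1, 2, 3, 4, 5, 8)
INPUT_SHAPE = (100, 100, 1)
KERNEL = (3, 3)
N_CLASSES = 2
DROPOUT_RATE = 0.2


@dataclass(frozen=True)
class LayerSpec:
    """One layer of the blueprint; only fields relevant to ``kind`` are set."""

    kind: str
    name: str
    filters: int = 0
    kernel: tuple[int, int] = KERNEL
    in_channels: int = 0
    channels: int = 0  # batchnorm
    pool: int = 2
    stride: int = 1
    rate: float = 0.0  # dropout
    in_features: int = 0
    out_features: int = 0

    def __post_init__(self) -> None:
        if self.kind == "conv2d" and self.kernel != KERNEL:
            raise ValueError("convolution kernel is fixed at 3x3")
        if self.kind == "dropout" and not (0.0 < self.rate < 1.0):
            raise ValueError("dropout rate must be in (0, 1)")
        if self.kind == "fully_connected" and self.out_features <= 0:
            raise ValueError("fully_connected needs out_features >= 1")


@dataclass(frozen=True)
class ArchitectureSpec:
    layers: tuple[LayerSpec, ...]
    input_shape: tuple[int, int, int] = INPUT_SHAPE
    variant: str = "augmentation_no_dropout"

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def by_kind(self, kind: str) -> list[LayerSpec]:
        return [l for l in self.layers if l.kind == kind]


def conv_filters(n: int) -> int:
    """Filter count of conv block n (1-based): 2^(n+2) capped at 512."""
    if n < 1:
        raise ValueError("conv block index is 1-based")
    return min(2 ** (n + 2), 512)


def build_architecture(variant: str = "augmentation_no_dropout") -> ArchitectureSpec:
    """Emit the ordered layer list for the requested experiment variant.

    The dropout variant inserts a rate-0.2 dropout layer between the final
    max pool and the fully connected layer (35 layers in total); the base
    variant has no dropout (34 layers).
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    layers: list[LayerSpec] = [LayerSpec("input", "Input")]
    in_ch = 1
    for n in range(1, N_CONV_BLOCKS + 1):
        out_ch = conv_filters(n)
        layers.append(
            LayerSpec("conv2d", f"Conv_{n}", filters=out_ch, in_channels=in_ch)
        )
        layers.append(LayerSpec("batchnorm", f"Batchnorm_{n}", channels=out_ch))
        layers.append(LayerSpec("relu", f"ReLU_{n}"))
        if n in POOL_AFTER_BLOCKS:
            layers.append(LayerSpec("maxpool", f"MaxPool_{n}"))
        in_ch = out_ch
    if variant == "dropout_no_augmentation":
        layers.append(LayerSpec("dropout", "Dropout", rate=DROPOUT_RATE))
    layers.append(
        LayerSpec(
            "fully_connected", "FC", in_features=fc_input_features(), out_features=N_CLASSES
        )
    )
    layers.append(LayerSpec("softmax", "Softmax"))
    layers.append(LayerSpec("classification", "Classification"))
    return ArchitectureSpec(tuple(layers), variant=variant)


def spatial_trace(input_hw: tuple[int, int] = INPUT_SHAPE[:2]) -> list[tuple[int, int]]:
    """Spatial size after each conv block: same-padding convs preserve size,
    each 2x2/stride-2 pool floors the halving (100->50->25->12->6->3->3->3->1)."""
    h, w = input_hw
    sizes = []
    for n in range(1, N_CONV_BLOCKS + 1):
        if n in POOL_AFTER_BLOCKS:
            h, w = h // 2, w // 2
        sizes.append((h, w))
    return sizes


def fc_input_features(input_hw: tuple[int, int] = INPUT_SHAPE[:2]) -> int:
    """Flattened feature count reaching the FC layer (512 for 100x100 input)."""
    h, w = spatial_trace(input_hw)[-1]
    return h * w * conv_filters(N_CONV_BLOCKS)


def count_layer_params(layer: LayerSpec) -> int:
    """Learnable parameters (weights + biases) of one layer.

    conv2d: kh*kw*in_channels*filters + filters; batchnorm: 2 per channel
    (scale and offset); fully_connected: in*out + out; all other kinds 0.
    """
    if layer.kind == "conv2d":
        if layer.filters <= 0 or layer.in_channels <= 0:
            raise ValueError(f"under-specified conv layer {layer.name!r}")
        kh, kw = layer.kernel
        return kh * kw * layer.in_channels * layer.filters + layer.filters
    if layer.kind == "batchnorm":
        if layer.channels <= 0:
            raise ValueError(f"under-specified batchnorm layer {layer.name!r}")
        return 2 * layer.channels
    if layer.kind == "fully_connected":
        if layer.in_features <= 0:
            raise ValueError(f"under-specified FC layer {layer.name!r}")
        return layer.in_features * layer.out_features + layer.out_features
    return 0


def total_params(arch: ArchitectureSpec) -> int:
    return sum(count_layer_params(l) for l in arch.layers)


# Published per-layer parameter accounting for this architecture.  The
# Conv_8 row is printed as 1,180,160 (identical to Conv_7); see module
# docstring for why the reconstructed network disagrees there.
TABLE_PUBLISHED_PARAMS: tuple[tuple[str, int], ...] = (
    ("Conv_1", 80),
    ("Batchnorm_1", 16),
    ("Conv_2", 1168),
    ("Batchnorm_2", 32),
    ("Conv_3", 4640),
    ("Batchnorm_3", 64),
    ("Conv_4", 18496),
    ("Batchnorm_4", 128),
    ("Conv_5", 73856),
    ("Batchnorm_5", 256),
    ("Conv_6", 295168),
    ("Batchnorm_6", 512),
    ("Conv_7", 1180160),
    ("Batchnorm_7", 1024),
    ("Conv_8", 1180160),
    ("Batchnorm_8", 1024),
    ("FC", 1026),
)


@dataclass(frozen=True)
class AuditRow:
    name: str
    computed: int
    published: int

    @property
    def match(self) -> bool:
        return self.computed == self.published


def audit_against_table(
    arch: ArchitectureSpec,
    published: Sequence[tuple[str, int]] = TABLE_PUBLISHED_PARAMS,
) -> list[AuditRow]:
    """Per-layer computed-vs-published comparison; mismatches flagged, not fatal."""
    by_name = {l.name: l for l in arch.layers}
    rows = []
    for name, pub in published:
        if name not in by_name:
            raise KeyError(f"published table names unknown layer {name!r}")
        rows.append(AuditRow(name, count_layer_params(by_name[name]), pub))
    return rows


def describe(arch: ArchitectureSpec) -> str:
    """Human-readable per-layer table with the audit column."""
    published = dict(TABLE_PUBLISHED_PARAMS)
    lines = [f"variant: {arch.variant}  layers: {arch.n_layers}", ""]
    lines.append(f"{'layer':<16}{'kind':<16}{'params':>12}  {'published':>10}  note")
    for layer in arch.layers:
        params = count_layer_params(layer)
        pub = published.get(layer.name)
        note = ""
        if pub is not None:
            note = "ok" if pub == params else f"MISMATCH (published {pub:,})"
        lines.append(f"{layer.name:<16}{layer.kind:<16}{params:>12,}  "
                     f"{(f'{pub:,}' if pub is not None else '-'):>10}  {note}")
    total = total_params(arch)
    lines.append("")
    lines.append(f"total learnable parameters: {total:,} ({total / 1e6:.1f} million)")
    return "\n".join(lines)
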