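"""Model family: truncated 50-layer residual backbone + "naive inception" head.

The family is a 50-layer bottleneck residual network whose final stages may
be dropped (``stages_included`` is a prefix of conv1..conv5), optionally
fused with a naive inception block — parallel 1x1, 3x3 and 5x5 convolutions
plus a passthrough 3x3 max-pool branch, channel-concatenated — and finished
by a flatten- or global-average-pool head with a 2-unit dense classifier.

Parameter accounting follows the convention that reproduces the classic
published ResNet50 totals exactly: every convolution carries a bias term and
each batch-norm layer contributes four parameters per channel (gamma, beta,
and the two moving statistics; the moving statistics are counted in full
totals but are never gradient-trained).

``find_reference_widths`` pins the inception branch widths against a total
parameter budget by exhaustive closed-form integer search: the widths are
not a free choice but the solution of an exact audit constraint.
"""

from __future__ import annotations

import functools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import nn

__all__ = [
    "STAGE_ORDER",
    "ArchitectureSpec",
    "FreezeConfig",
    "LayerParamRecord",
    "ModelGraph",
    "build_backbone",
    "build_naive_inception",
    "assemble_model",
    "count_parameters",
    "apply_freeze_config",
    "find_reference_widths",
    "PROPOSED_PARAMETER_BUDGET",
    "BASELINE_PARAMETER_TOTAL",
]

STAGE_ORDER = ("conv1", "conv2", "conv3", "conv4", "conv5")

#: Published parameter totals for the two audited architectures.
BASELINE_PARAMETER_TOTAL = 23_788_418
PROPOSED_PARAMETER_BUDGET = 3_649_506


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArchitectureSpec:
    """Complete structural description of one model in the family.

    stages_included must be a prefix of conv1..conv5. ``branch_widths``
    (F1, F3, F5) switches the naive-inception block on; ``None`` omits it
    (the plain-backbone baseline). ``conv_bias`` and ``head_batchnorm``
    apply to the inception/head section only — backbone convolutions always
    carry biases under the audit convention.

    The scale fields (stem_channels, stage_widths, blocks_per_stage,
    expansion) default to the standard 50-layer network; tests use a
    proportionally shrunk variant from :meth:`small`.
    """

    stages_included: tuple[str, ...] = ("conv1", "conv2", "conv3")
    branch_widths: tuple[int, int, int] | None = (64, 64, 64)
    head: str = "flatten"            # "flatten" | "gap"
    head_units: int = 2
    conv_bias: bool = True
    head_batchnorm: bool = False
    input_size: tuple[int, int, int] = (224, 224, 3)   # H, W, C
    stem_channels: int = 64
    stage_widths: tuple[int, int, int, int] = (64, 128, 256, 512)
    blocks_per_stage: tuple[int, int, int, int] = (3, 4, 6, 3)
    expansion: int = 4

    def __post_init__(self):
        if tuple(self.stages_included) != STAGE_ORDER[:len(self.stages_included)]:
            raise ValueError(
                f"stages_included must be a prefix of {STAGE_ORDER}, "
                f"got {self.stages_included}")
        if self.branch_widths is not None and min(self.branch_widths) < 1:
            raise ValueError("branch widths must be >= 1")
        if self.head not in ("flatten", "gap"):
            raise ValueError(f"unknown head {self.head!r}")
        if self.head_units < 2:
            raise ValueError("head_units must be >= 2")

    @classmethod
    def baseline(cls) -> "ArchitectureSpec":
        """Full 5-stage backbone, no inception, flatten + dense head."""
        return cls(stages_included=STAGE_ORDER, branch_widths=None,
                   head="flatten", head_batchnorm=False)

    @classmethod
    def small(cls, input_hw: tuple[int, int] = (64, 64),
              branch_widths: tuple[int, int, int] = (4, 4, 4),
              ) -> "ArchitectureSpec":
        """Proportionally shrunk conv1-conv3 model for CPU-scale experiments."""
        return cls(stages_included=("conv1", "conv2", "conv3"),
                   branch_widths=branch_widths, head="gap",
                   input_size=(input_hw[0], input_hw[1], 3),
                   stem_channels=8, stage_widths=(4, 8, 16, 32),
                   blocks_per_stage=(1, 1, 1, 1))


@dataclass(frozen=True)
class FreezeConfig:
    """Which architectural blocks receive gradient updates.

    The four configurations form a nested ladder: config 1 trains only the
    inception block and the dense head on top of a fully frozen backbone;
    each subsequent configuration additionally unfreezes the next-deepest
    backbone stage, and config 4 trains the whole network.
    """

    config_id: int
    trainable_blocks: frozenset[str] = field(default_factory=frozenset)

    _LADDER = {
        1: frozenset({"inception", "head"}),
        2: frozenset({"inception", "head", "conv3"}),
        3: frozenset({"inception", "head", "conv3", "conv2"}),
        4: frozenset({"inception", "head", "conv3", "conv2", "conv1"}),
    }

    @classmethod
    def from_id(cls, config_id: int) -> "FreezeConfig":
        if config_id not in cls._LADDER:
            raise ValueError(f"unknown freeze config id {config_id}; expected 1-4")
        return cls(config_id=config_id, trainable_blocks=cls._LADDER[config_id])


@dataclass
class LayerParamRecord:
    layer_name: str
    tensor_shapes: list[tuple[int, ...]]
    count: int
    trainable: bool


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def _bottleneck(cin: int, f: int, expansion: int, stride: int,
                project: bool, name: str, block: str) -> nn.Residual:
    fout = f * expansion
    main = nn.Sequential([
        nn.Conv2D(cin, f, 1, stride=stride, name=f"{name}.a", block=block),
        nn.BatchNorm2D(f, name=f"{name}.a_bn", block=block),
        nn.ReLU(name=f"{name}.a_relu", block=block),
        nn.Conv2D(f, f, 3, name=f"{name}.b", block=block),
        nn.BatchNorm2D(f, name=f"{name}.b_bn", block=block),
        nn.ReLU(name=f"{name}.b_relu", block=block),
        nn.Conv2D(f, fout, 1, name=f"{name}.c", block=block),
        nn.BatchNorm2D(fout, name=f"{name}.c_bn", block=block),
    ], name=f"{name}.main", block=block)
    shortcut = None
    if project:
        shortcut = nn.Sequential([
            nn.Conv2D(cin, fout, 1, stride=stride, name=f"{name}.sc", block=block),
            nn.BatchNorm2D(fout, name=f"{name}.sc_bn", block=block),
        ], name=f"{name}.shortcut", block=block)
    return nn.Residual(main, shortcut, name=name, block=block)


def build_backbone(spec: ArchitectureSpec) -> nn.Sequential:
    """Residual stem plus the bottleneck stages named in the spec.

    The stem (7x7 stride-2 convolution, batch-norm, ReLU, 3x3 stride-2
    max-pool) is tagged as block ``conv1``; stage k+1 is ``conv{k+1}``.
    """
    layers: list[nn.Layer] = [
        nn.Conv2D(spec.input_size[2], spec.stem_channels, 7, stride=2,
                  name="conv1.conv", block="conv1"),
        nn.BatchNorm2D(spec.stem_channels, name="conv1.bn", block="conv1"),
        nn.ReLU(name="conv1.relu", block="conv1"),
        nn.MaxPool2D(3, stride=2, padding="same", name="conv1.pool", block="conv1"),
    ]
    cin = spec.stem_channels
    for si, stage in enumerate(spec.stages_included[1:], start=0):
        f = spec.stage_widths[si]
        n_blocks = spec.blocks_per_stage[si]
        stride = 1 if stage == "conv2" else 2
        for b in range(n_blocks):
            layers.append(_bottleneck(
                cin, f, spec.expansion,
                stride=stride if b == 0 else 1,
                project=(b == 0),
                name=f"{stage}.block{b + 1}", block=stage))
            cin = f * spec.expansion
    return nn.Sequential(layers, name="backbone")


def build_naive_inception(in_channels: int, widths: tuple[int, int, int],
                          conv_bias: bool = True) -> nn.Concat:
    """Four parallel spatial-size-preserving branches, channel-concatenated.

    Branches: 1x1, 3x3 and 5x5 convolutions of widths (F1, F3, F5), plus a
    parameter-free passthrough 3x3 stride-1 same-padded max-pool, giving
    F1 + F3 + F5 + in_channels output channels.
    """
    f1, f3, f5 = widths
    return nn.Concat([
        nn.Conv2D(in_channels, f1, 1, bias=conv_bias,
                  name="inception.b1x1", block="inception"),
        nn.Conv2D(in_channels, f3, 3, bias=conv_bias,
                  name="inception.b3x3", block="inception"),
        nn.Conv2D(in_channels, f5, 5, bias=conv_bias,
                  name="inception.b5x5", block="inception"),
        nn.MaxPool2D(3, stride=1, padding="same",
                     name="inception.pool", block="inception"),
    ], name="inception", block="inception")


# ---------------------------------------------------------------------------
# model graph
# ---------------------------------------------------------------------------

class ModelGraph:
    """An assembled model: a layer graph with a softmax probability output."""

    def __init__(self, root: nn.Layer, spec: ArchitectureSpec):
        self.root = root
        self.spec = spec
        h, w, c = spec.input_size
        self.input_shape = (c, h, w)
        out = root.out_shape(self.input_shape)
        if out != (spec.head_units,):
            raise ValueError(f"head emits shape {out}, expected ({spec.head_units},)")
        self._initialized = False

    def layers(self):
        return list(self.root.walk())

    def layer_shape_list(self) -> list[tuple[str, str, tuple[tuple[int, ...], ...]]]:
        """(name, kind, parameter shapes) per leaf layer — structural fingerprint."""
        return [(layer.name, type(layer).__name__,
                 tuple(shape for _n, shape, _t in layer.param_specs()))
                for layer in self.root.walk()]

    def initialize(self, seed: int = 0) -> "ModelGraph":
        rng = np.random.default_rng(seed)
        for layer in self.root.walk():
            layer.initialize(rng)
        self._initialized = True
        return self

    def forward_logits(self, x_nchw: np.ndarray, training: bool = False) -> np.ndarray:
        if not self._initialized:
            raise RuntimeError("model not initialized; call initialize(seed)")
        return self.root.forward(x_nchw.astype(np.float32, copy=False), training)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        return self.root.backward(dlogits)

    def predict_proba(self, images_nhwc: np.ndarray) -> np.ndarray:
        """Class probabilities for a batch of H×W×3 images."""
        x = np.transpose(images_nhwc, (0, 3, 1, 2))
        return nn.softmax(self.forward_logits(x, training=False))

    def get_weights(self) -> dict[str, np.ndarray]:
        out = {}
        for layer in self.root.walk():
            for pname, arr in layer.params.items():
                out[f"{layer.name}/{pname}"] = arr.copy()
        return out


def assemble_model(spec: ArchitectureSpec) -> ModelGraph:
    """Backbone → optional naive inception → head → 2-class logits."""
    backbone = build_backbone(spec)
    c, h, w = backbone.out_shape((spec.input_size[2],) + spec.input_size[:2])
    layers: list[nn.Layer] = [backbone]
    channels = c
    if spec.branch_widths is not None:
        layers.append(build_naive_inception(c, spec.branch_widths, spec.conv_bias))
        channels = sum(spec.branch_widths) + c
    if spec.head_batchnorm:
        layers.append(nn.BatchNorm2D(channels, name="head.bn", block="head"))
    if spec.head == "flatten":
        layers.append(nn.Flatten(name="head.flatten", block="head"))
        in_features = channels * h * w
    else:
        layers.append(nn.GlobalAvgPool(name="head.gap", block="head"))
        in_features = channels
    layers.append(nn.Dense(in_features, spec.head_units,
                           name="head.dense", block="head"))
    return ModelGraph(nn.Sequential(layers, name="model"), spec)


# ---------------------------------------------------------------------------
# parameter audit
# ---------------------------------------------------------------------------

def count_parameters(model: ModelGraph, trainable_only: bool = False,
                     ) -> tuple[list[LayerParamRecord], int]:
    """Exact per-layer parameter audit of an assembled model.

    Full totals include the non-trainable batch-norm moving statistics;
    ``trainable_only`` counts only gradient-trained tensors of layers whose
    trainable flag is set.
    """
    records: list[LayerParamRecord] = []
    total = 0
    for layer in model.layers():
        specs = layer.param_specs()
        if not specs:
            continue
        shapes, count = [], 0
        for _pname, shape, grad_trained in specs:
            if trainable_only and not (layer.trainable and grad_trained):
                continue
            shapes.append(shape)
            count += int(np.prod(shape))
        if trainable_only and count == 0:
            records.append(LayerParamRecord(layer.name, [], 0, layer.trainable))
            continue
        records.append(LayerParamRecord(layer.name, shapes, count, layer.trainable))
        total += count
    return records, total


def audit_to_frame(records: list[LayerParamRecord]):
    import pandas as pd

    return pd.DataFrame({
        "layer": [r.layer_name for r in records],
        "shapes": [";".join("x".join(map(str, s)) for s in r.tensor_shapes)
                   for r in records],
        "count": [r.count for r in records],
        "trainable": [r.trainable for r in records],
    })


def apply_freeze_config(model: ModelGraph, cfg: FreezeConfig) -> ModelGraph:
    """Set per-layer trainable flags according to the freeze ladder."""
    if cfg.config_id not in FreezeConfig._LADDER:
        raise ValueError(f"unknown freeze config id {cfg.config_id}")
    for layer in model.layers():
        layer.trainable = layer.block in cfg.trainable_blocks
    return model


# ---------------------------------------------------------------------------
# closed-form width search
# ---------------------------------------------------------------------------

def _cf_conv(k: int, cin: int, cout: int, bias: bool = True) -> int:
    return k * k * cin * cout + (cout if bias else 0)


def _cf_bn(c: int) -> int:
    return 4 * c


def _cf_bottleneck(cin: int, f: int, expansion: int, project: bool) -> int:
    fout = f * expansion
    total = (_cf_conv(1, cin, f) + _cf_bn(f)
             + _cf_conv(3, f, f) + _cf_bn(f)
             + _cf_conv(1, f, fout) + _cf_bn(fout))
    if project:
        total += _cf_conv(1, cin, fout) + _cf_bn(fout)
    return total


def closed_form_backbone_count(spec: ArchitectureSpec) -> int:
    """Arithmetic parameter total of the backbone named by the spec."""
    total = _cf_conv(7, spec.input_size[2], spec.stem_channels) \
        + _cf_bn(spec.stem_channels)
    cin = spec.stem_channels
    for si, _stage in enumerate(spec.stages_included[1:]):
        f = spec.stage_widths[si]
        for b in range(spec.blocks_per_stage[si]):
            total += _cf_bottleneck(cin, f, spec.expansion, project=(b == 0))
            cin = f * spec.expansion
    return total


def _backbone_out_geometry(spec: ArchitectureSpec) -> tuple[int, int, int]:
    """(channels, H, W) emitted by the truncated backbone — stride arithmetic."""
    h, w = spec.input_size[:2]
    h, w = -(-h // 2), -(-w // 2)          # 7x7 stride-2 stem, same padding
    h, w = -(-h // 2), -(-w // 2)          # 3x3 stride-2 max-pool, same padding
    c = spec.stem_channels
    for si, stage in enumerate(spec.stages_included[1:]):
        if stage != "conv2":               # conv2 keeps stride 1
            h, w = -(-h // 2), -(-w // 2)
        c = spec.stage_widths[si] * spec.expansion
    return c, h, w


def closed_form_total(spec: ArchitectureSpec) -> int:
    """Arithmetic parameter total of the fully assembled model."""
    total = closed_form_backbone_count(spec)
    c, h, w = _backbone_out_geometry(spec)
    channels = c
    if spec.branch_widths is not None:
        f1, f3, f5 = spec.branch_widths
        total += (_cf_conv(1, c, f1, spec.conv_bias)
                  + _cf_conv(3, c, f3, spec.conv_bias)
                  + _cf_conv(5, c, f5, spec.conv_bias))
        channels = f1 + f3 + f5 + c
    if spec.head_batchnorm:
        total += _cf_bn(channels)
    in_features = channels * h * w if spec.head == "flatten" else channels
    total += (in_features + 1) * spec.head_units
    return total


@functools.lru_cache(maxsize=8)
def find_reference_widths(parameter_budget: int,
                          max_width: int = 512) -> ArchitectureSpec:
    """Pin (F1, F3, F5) and the head variant against an exact parameter budget.

    Exhaustively searches branch widths in [1, max_width] and the head
    variants (flatten vs global-average pooling, inception-conv bias on/off,
    head batch-norm off/on) of the conv1-conv3 truncated backbone, in
    lexicographic order, and returns the first spec whose closed-form total
    equals the budget exactly. Pure integer arithmetic — no model is built.
    """
    base = ArchitectureSpec(stages_included=("conv1", "conv2", "conv3"),
                            branch_widths=(1, 1, 1))
    backbone = closed_form_backbone_count(base)
    c, h, w = _backbone_out_geometry(base)
    if parameter_budget <= backbone:
        raise ValueError(
            f"budget {parameter_budget} does not exceed the truncated-backbone "
            f"count {backbone}; no inception head can fit")
    nearest: tuple[int, ArchitectureSpec] | None = None
    for head in ("flatten", "gap"):
        for conv_bias in (True, False):
            for head_bn in (False, True):
                b = 1 if conv_bias else 0
                c1, c3, c5 = c + b, 9 * c + b, 25 * c + b
                per_ch = (h * w if head == "flatten" else 1) * 2  # dense row
                per_ch += 4 if head_bn else 0                     # head bn
                # total = backbone + c1*F1 + c3*F3 + c5*F5
                #         + per_ch*(F1+F3+F5+c) + head_units bias + ...
                const = backbone + per_ch * c + 2
                rem0 = parameter_budget - const
                for f1 in range(1, max_width + 1):
                    rem1 = rem0 - (c1 + per_ch) * f1
                    if rem1 < (c3 + per_ch) + (c5 + per_ch):
                        break
                    for f3 in range(1, max_width + 1):
                        num = rem1 - (c3 + per_ch) * f3
                        den = c5 + per_ch
                        if num < den:
                            break
                        f5, residue = divmod(num, den)
                        if f5 > max_width:
                            continue
                        cand = replace(base, branch_widths=(f1, f3, f5),
                                       head=head, conv_bias=conv_bias,
                                       head_batchnorm=head_bn)
                        total = closed_form_total(cand)
                        diff = abs(total - parameter_budget)
                        if nearest is None or diff < nearest[0]:
                            nearest = (diff, cand)
                        if residue == 0:
                            return cand
    near_total = closed_form_total(nearest[1]) if nearest else None
    raise ValueError(
        f"no width/head configuration in [1,{max_width}]^3 matches budget "
        f"{parameter_budget} exactly; nearest achievable total is {near_total}")


def reference_spec() -> ArchitectureSpec:
    """The pinned proposed model: widths solved from the published budget."""
    return find_reference_widths(PROPOSED_PARAMETER_BUDGET)
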