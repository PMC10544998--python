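"""Staged classifier backbones and channel adapters.

Both the teacher and the student are treated as four ordered stage
blocks followed by a classification head, mirroring the shared
hierarchical layout of modern vision backbones (four downsampling
stages at 4x / 8x / 16x / 32x of the input resolution). Feature
distillation matches the output of each student stage, projected
through a learnable 1x1 channel adapter, against the corresponding
teacher stage output.

Any network expressible as a named :class:`~stagedistill.nn.Sequential`
can be partitioned with :func:`partition_backbone`; the composed staged
forward pass is exactly (bitwise) the original forward pass. The module
also provides miniature four-stage CNN stand-ins (tens of thousands of
parameters) that make the full distillation protocol testable on a CPU
in minutes; full-size backbones plug in through the same contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .losses import N_STAGES, tempered_softmax

__all__ = [
    "StageDescriptor",
    "StagedBackbone",
    "partition_backbone",
    "forward_with_features",
    "Adapter",
    "AdapterBank",
    "build_adapters",
    "miniature_backbone",
    "miniature_student",
    "miniature_teacher",
    "predict",
]


@dataclass
class StageDescriptor:
    """Per-stage output channel counts and downsampling factors."""

    channels: tuple[int, ...]
    downsample: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.channels) != N_STAGES or len(self.downsample) != N_STAGES:
            raise ValueError(f"descriptor must cover exactly {N_STAGES} stages")


@dataclass
class StagedBackbone:
    """A classifier split into 4 stage blocks plus a head.

    ``meta`` carries enough information to rebuild the architecture when
    loading a checkpoint (used by the miniature factories).
    """

    stages: list[nn.Sequential]
    head: nn.Sequential
    descriptor: StageDescriptor
    num_classes: int
    in_channels: int = 3
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.stages) != N_STAGES:
            raise ValueError(f"a staged backbone needs exactly {N_STAGES} stages")

    def forward(self, x: np.ndarray) -> np.ndarray:
        for stage in self.stages:
            x = stage.forward(x)
        return self.head.forward(x)

    def params(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for k, stage in enumerate(self.stages):
            for name, p in stage.params().items():
                out[f"stage{k}.{name}"] = p
        for name, p in self.head.params().items():
            out[f"head.{name}"] = p
        return out

    def grads(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for k, stage in enumerate(self.stages):
            for name, g in stage.grads().items():
                out[f"stage{k}.{name}"] = g
        for name, g in self.head.grads().items():
            out[f"head.{name}"] = g
        return out

    def zero_grad(self) -> None:
        for g in self.grads().values():
            g[...] = 0.0

    def set_params(self, values: dict[str, np.ndarray]) -> None:
        params = self.params()
        for name, p in params.items():
            if name not in values:
                raise KeyError(f"missing parameter {name!r}")
            p[...] = np.asarray(values[name], dtype=p.dtype)

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params().items()}


def forward_with_features(
    model: StagedBackbone, batch: np.ndarray
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Forward pass that also captures the 4 stage outputs.

    Returns ``(logits, features)`` where ``features[k]`` is the output
    of stage ``k`` (shallow to deep). Capture does not perturb the
    forward result: the logits equal ``head(stage4(...stage1(x)))``
    exactly.
    """
    x = np.asarray(batch, dtype=nn.DTYPE)
    if x.ndim != 4 or x.shape[1] != model.in_channels:
        raise ValueError(
            f"expected input of shape (batch, {model.in_channels}, H, W), got {x.shape}"
        )
    feats: list[np.ndarray] = []
    for stage in model.stages:
        x = stage.forward(x)
        feats.append(x)
    return model.head.forward(x), feats


def partition_backbone(
    network: nn.Sequential,
    stage_boundaries: list[str],
    *,
    num_classes: int | None = None,
    input_shape: tuple[int, int, int] = (3, 64, 64),
) -> StagedBackbone:
    """Cut a named sequential network into 4 stages plus a head.

    ``stage_boundaries`` lists, in order, the name of the last layer of
    each stage; everything after the fourth boundary becomes the head.
    The stage descriptor (channel counts, downsampling factors) is read
    off a probe forward pass on a zero input of ``input_shape``.
    """
    if len(stage_boundaries) != N_STAGES:
        raise ValueError(
            f"expected {N_STAGES} stage boundaries, got {len(stage_boundaries)}"
        )
    names = network.names
    positions = []
    for label in stage_boundaries:
        if label not in names:
            raise ValueError(f"boundary layer {label!r} not found in network")
        positions.append(names.index(label))
    if positions != sorted(positions) or len(set(positions)) != N_STAGES:
        raise ValueError("stage boundaries must be distinct and in network order")
    if positions[-1] == len(names) - 1:
        raise ValueError("no layers left after the last boundary to form a head")

    cuts = [0] + [p + 1 for p in positions]
    stages = [network.slice(names[a:b]) for a, b in zip(cuts[:-1], cuts[1:])]
    head = network.slice(names[cuts[-1] :])

    probe = np.zeros((1, *input_shape), dtype=nn.DTYPE)
    channels, down = [], []
    x = probe
    for stage in stages:
        x = stage.forward(x)
        channels.append(x.shape[1])
        down.append(input_shape[1] // x.shape[2])
    logits = head.forward(x)
    n_out = logits.shape[-1]
    if num_classes is not None and num_classes != n_out:
        raise ValueError(f"head produces {n_out} logits, expected {num_classes}")
    return StagedBackbone(
        stages=stages,
        head=head,
        descriptor=StageDescriptor(tuple(channels), tuple(down)),
        num_classes=n_out,
        in_channels=input_shape[0],
    )


# ---------------------------------------------------------------------------
# channel adapters (student stage-k -> teacher stage-k)
# ---------------------------------------------------------------------------

class Adapter:
    """Learnable pointwise (1x1 convolution) channel projection."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / in_channels)
        self.weight = (rng.standard_normal((out_channels, in_channels)) * std).astype(
            nn.DTYPE
        )
        self.bias = np.zeros(out_channels, dtype=nn.DTYPE)
        self.grad_weight = np.zeros_like(self.weight)
        self.grad_bias = np.zeros_like(self.bias)

    @property
    def in_channels(self) -> int:
        return self.weight.shape[1]

    @property
    def out_channels(self) -> int:
        return self.weight.shape[0]


class AdapterBank:
    """The 4 per-stage adapters, trained jointly with the student."""

    def __init__(self, adapters: list[Adapter]):
        if len(adapters) != N_STAGES:
            raise ValueError(f"expected {N_STAGES} adapters")
        self.adapters = adapters

    def __len__(self) -> int:
        return len(self.adapters)

    def __iter__(self):
        return iter(self.adapters)

    def __getitem__(self, k: int) -> Adapter:
        return self.adapters[k]

    def params(self) -> dict[str, np.ndarray]:
        out = {}
        for k, a in enumerate(self.adapters):
            out[f"adapter{k}.weight"] = a.weight
            out[f"adapter{k}.bias"] = a.bias
        return out

    def grads(self) -> dict[str, np.ndarray]:
        out = {}
        for k, a in enumerate(self.adapters):
            out[f"adapter{k}.weight"] = a.grad_weight
            out[f"adapter{k}.bias"] = a.grad_bias
        return out

    def zero_grad(self) -> None:
        for g in self.grads().values():
            g[...] = 0.0


def build_adapters(
    student: StagedBackbone, teacher: StagedBackbone, seed: int = 0
) -> AdapterBank:
    """Adapters mapping student stage channels to teacher stage channels.

    Channel counts are read from the two stage descriptors; adapters are
    created even when the counts already agree (the projection stays
    learnable, it is not an identity shortcut). Initialization is
    deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    return AdapterBank(
        [
            Adapter(cs, ct, rng)
            for cs, ct in zip(student.descriptor.channels, teacher.descriptor.channels)
        ]
    )


# ---------------------------------------------------------------------------
# miniature 4-stage CNN stand-ins
# ---------------------------------------------------------------------------

def _build_miniature(
    channels: tuple[int, int, int, int],
    num_classes: int,
    in_channels: int,
    convs_per_stage: int,
    seed: int,
) -> nn.Sequential:
    rng = np.random.default_rng(seed)
    net = nn.Sequential()
    # stem downsamples 4x with two stride-2 convolutions
    net.add("stem_conv1", nn.Conv2d(in_channels, channels[0], 3, 2, 1, rng))
    net.add("stem_relu1", nn.ReLU())
    net.add("stem_conv2", nn.Conv2d(channels[0], channels[0], 3, 2, 1, rng))
    net.add("stem_relu2", nn.ReLU())
    prev = channels[0]
    for k, ch in enumerate(channels[1:], start=2):
        net.add(f"s{k}_conv1", nn.Conv2d(prev, ch, 3, 2, 1, rng))
        net.add(f"s{k}_relu1", nn.ReLU())
        for j in range(2, convs_per_stage + 1):
            net.add(f"s{k}_conv{j}", nn.Conv2d(ch, ch, 3, 1, 1, rng))
            net.add(f"s{k}_relu{j}", nn.ReLU())
        prev = ch
    net.add("gap", nn.GlobalAvgPool())
    net.add("fc", nn.Linear(prev, num_classes, rng))
    return net


def miniature_backbone(
    channels: tuple[int, int, int, int] = (8, 16, 32, 64),
    num_classes: int = 5,
    in_channels: int = 3,
    convs_per_stage: int = 1,
    seed: int = 0,
    image_size: int = 64,
) -> StagedBackbone:
    """A tiny 4-stage CNN with the 4x/8x/16x/32x downsampling schedule."""
    net = _build_miniature(channels, num_classes, in_channels, convs_per_stage, seed)
    suffix = convs_per_stage
    boundaries = ["stem_relu2"] + [f"s{k}_relu{suffix}" for k in (2, 3, 4)]
    staged = partition_backbone(
        net,
        boundaries,
        num_classes=num_classes,
        input_shape=(in_channels, image_size, image_size),
    )
    staged.meta = {
        "factory": "miniature",
        "channels": list(channels),
        "num_classes": num_classes,
        "in_channels": in_channels,
        "convs_per_stage": convs_per_stage,
        "seed": seed,
        "image_size": image_size,
    }
    return staged


def miniature_student(seed: int = 0, num_classes: int = 5, image_size: int = 64) -> StagedBackbone:
    """Default desk-scale student: ~25k parameters, 1 conv per stage."""
    return miniature_backbone((8, 16, 32, 64), num_classes, 3, 1, seed, image_size)


def miniature_teacher(seed: int = 0, num_classes: int = 5, image_size: int = 64) -> StagedBackbone:
    """Default desk-scale teacher: wider and deeper than the student."""
    return miniature_backbone((12, 24, 48, 96), num_classes, 3, 2, seed, image_size)


def from_meta(meta: dict) -> StagedBackbone:
    """Rebuild a miniature backbone from checkpoint metadata."""
    if meta.get("factory") != "miniature":
        raise ValueError("can only rebuild miniature-factory backbones from metadata")
    return miniature_backbone(
        tuple(meta["channels"]),
        meta["num_classes"],
        meta["in_channels"],
        meta["convs_per_stage"],
        meta["seed"],
        meta.get("image_size", 64),
    )


def predict(model: StagedBackbone, images: np.ndarray) -> np.ndarray:
    """Predicted class indices: argmax of the softmax output per image.

    Ties break toward the lowest class index. (The softmax is monotone,
    so this equals the argmax over raw logits and is invariant to any
    positive temperature rescaling at inference.)
    """
    logits = model.forward(np.asarray(images, dtype=nn.DTYPE))
    probs = tempered_softmax(logits, 1.0)
    return np.argmax(probs, axis=-1)
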