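"""Encoder backbone f(.) and projection head g(.).

The backbone maps an image to a fixed-length feature vector; the projection
head maps features to the embedding z = g(f(t(x))) consumed by the
contrastive losses.  Probing uses backbone features (pre-projection), the
standard protocol for SimCLR-family methods: the projection head exists only
to shape the self-supervised objective.

The desk-scale backbone is a three-block strided convolutional network with
batch normalization and global average pooling, sized so a full pretraining
run completes in minutes on one CPU core.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import _nn
from .views import ThreeViewBatch, TwoViewBatch

__all__ = [
    "EncoderSpec",
    "ProjectionSpec",
    "EmbeddingBatch",
    "SmallConvEncoder",
    "ProjectionHead",
    "encode_project",
    "freeze_backbone",
    "save_checkpoint",
    "load_checkpoint",
    "nchw",
]


@dataclass(frozen=True)
class EncoderSpec:
    architecture: str = "small-conv"
    input_size: int = 32
    in_channels: int = 3
    widths: tuple[int, ...] = (16, 32, 64)

    @property
    def feature_dim(self) -> int:
        return self.widths[-1]


@dataclass(frozen=True)
class ProjectionSpec:
    hidden_dim: int = 64
    output_dim: int = 16


@dataclass
class EmbeddingBatch:
    """M x D projection vectors plus the layout/pair metadata of their views."""

    vectors: np.ndarray
    layout: str
    positive_pairs: list[tuple[int, int]] = field(default_factory=list)
    n_sources: int = 0

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be an M x D matrix")
        if not np.isfinite(self.vectors).all():
            raise ValueError("embeddings must be finite")
        if self.n_sources == 0 and self.positive_pairs:
            self.n_sources = len(self.positive_pairs)


def nchw(images: np.ndarray) -> np.ndarray:
    """(N,H,W,C) [0,1] image stack -> float64 (N,C,H,W) tensor."""
    return np.ascontiguousarray(np.asarray(images, dtype=float).transpose(0, 3, 1, 2))


class SmallConvEncoder:
    """Strided conv -> BN -> ReLU blocks, global average pooling on top."""

    def __init__(self, spec: EncoderSpec = EncoderSpec(),
                 rng: np.random.Generator | None = None):
        if spec.architecture != "small-conv":
            raise ValueError(f"unsupported architecture {spec.architecture!r}")
        rng = np.random.default_rng(rng)
        self.spec = spec
        layers: list[_nn.Layer] = []
        c_in = spec.in_channels
        for width in spec.widths:
            layers += [
                _nn.Conv2d(c_in, width, kernel=3, stride=2, pad=1, rng=rng),
                _nn.BatchNorm2d(width),
                _nn.ReLU(),
            ]
            c_in = width
        layers.append(_nn.GlobalAvgPool())
        self.net = _nn.Sequential(layers)
        self.frozen = False

    @property
    def feature_dim(self) -> int:
        return self.spec.feature_dim

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if x.shape[2] != self.spec.input_size or x.shape[3] != self.spec.input_size:
            raise ValueError(
                f"encoder expects {self.spec.input_size}x{self.spec.input_size} "
                f"inputs, got {x.shape[2]}x{x.shape[3]}")
        return self.net.forward(x, train=train and not self.frozen)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.net.backward(grad)

    def state_dict(self) -> dict[str, np.ndarray]:
        return self.net.state()

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        self.net.load_state(state)

    def checksum(self) -> str:
        return _nn.state_checksum(self.net)


class ProjectionHead:
    """Two-layer MLP g(.): feature_dim -> hidden -> output embedding."""

    def __init__(self, feature_dim: int, spec: ProjectionSpec = ProjectionSpec(),
                 rng: np.random.Generator | None = None):
        rng = np.random.default_rng(rng)
        self.spec = spec
        self.net = _nn.Sequential([
            _nn.Linear(feature_dim, spec.hidden_dim, rng=rng),
            _nn.ReLU(),
            _nn.Linear(spec.hidden_dim, spec.output_dim, rng=rng),
        ])

    def forward(self, x, train=True):
        return self.net.forward(x, train=train)

    def backward(self, grad):
        return self.net.backward(grad)

    def state_dict(self):
        return self.net.state()

    def load_state_dict(self, state):
        self.net.load_state(state)

    def checksum(self) -> str:
        return _nn.state_checksum(self.net)


def encode_project(views: ThreeViewBatch | TwoViewBatch,
                   encoder: SmallConvEncoder,
                   projector: ProjectionHead,
                   train: bool = False) -> EmbeddingBatch:
    """z = g(f(view)) for every slot, order-preserving, layout copied over."""
    x = nchw(views.samples)
    feats = encoder.forward(x, train=train)
    z = projector.forward(feats, train=train)
    return EmbeddingBatch(vectors=z, layout=views.layout,
                          positive_pairs=list(views.positive_pairs),
                          n_sources=views.n_sources)


def freeze_backbone(encoder: SmallConvEncoder) -> SmallConvEncoder:
    """Mark all encoder parameters untrainable (idempotent); returns the handle."""
    encoder.frozen = True
    encoder.net.set_trainable(False)
    return encoder


def save_checkpoint(path, encoder: SmallConvEncoder, projector: ProjectionHead,
                    config: dict | None = None) -> None:
    """Weights + spec + producing config, in a single .npz archive."""
    payload = {f"encoder/{k}": v for k, v in encoder.state_dict().items()}
    payload |= {f"projector/{k}": v for k, v in projector.state_dict().items()}
    meta = {
        "encoder_spec": {
            "architecture": encoder.spec.architecture,
            "input_size": encoder.spec.input_size,
            "in_channels": encoder.spec.in_channels,
            "widths": list(encoder.spec.widths),
        },
        "projection_spec": {
            "hidden_dim": projector.spec.hidden_dim,
            "output_dim": projector.spec.output_dim,
        },
        "config": config or {},
    }
    payload["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **payload)


def load_checkpoint(path) -> tuple[SmallConvEncoder, ProjectionHead, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"]))
        es = meta["encoder_spec"]
        spec = EncoderSpec(es["architecture"], es["input_size"], es["in_channels"],
                           tuple(es["widths"]))
        ps = meta["projection_spec"]
        encoder = SmallConvEncoder(spec)
        projector = ProjectionHead(spec.feature_dim,
                                   ProjectionSpec(ps["hidden_dim"], ps["output_dim"]))
        encoder.load_state_dict({k.split("/", 1)[1]: data[k] for k in data.files
                                 if k.startswith("encoder/")})
        projector.load_state_dict({k.split("/", 1)[1]: data[k] for k in data.files
                                   if k.startswith("projector/")})
    return encoder, projector, meta["config"]
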