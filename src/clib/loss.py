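"""Multi-view NT-Xent contrastive losses with exact positive/negative accounting.

Three variants share one masked softmax core:

* ``simclr_loss`` — two augmented views, positives ``(i, i+N)``, denominator
  over the other ``2N - 1`` samples.
* ``clib_loss`` — three views in block layout [originals | subjects |
  backgrounds]; only the 2N original/subject slots anchor, each with its
  counterpart as single positive, and the denominator runs over all other
  ``3N - 1`` samples (so the N backgrounds act as extra negatives only).
* ``clib_ablation_loss`` — the SimCLR construction plus a background block
  appended to every denominator (backgrounds never anchor).

Anchor losses are ``-log softmax`` terms computed with per-row max-shifted
log-sum-exp; totals are the mean over the anchor set, hence always >= 0
because the positive term is part of its own denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .model import EmbeddingBatch

__all__ = [
    "LossConfig",
    "LossValue",
    "cosine_similarity",
    "simclr_loss",
    "clib_loss",
    "clib_ablation_loss",
    "contrastive_loss",
    "drop_background",
    "loss_and_grad",
    "interleaved_to_block",
    "block_to_interleaved",
    "clib_loss_interleaved",
]

VARIANTS = ("simclr", "clib_ablation", "clib")


@dataclass(frozen=True)
class LossConfig:
    temperature: float = 0.07
    variant: str = "clib"

    def __post_init__(self):
        if not np.isfinite(self.temperature) or self.temperature <= 0:
            raise ValueError("temperature must be finite and positive")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")


@dataclass
class LossValue:
    total: float
    per_anchor: np.ndarray = field(repr=False)


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """sim(u, v) = u.v / (|u||v|); rejects zero vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for zero vectors")
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


def _normalize_rows(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    norms = np.linalg.norm(z, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero embedding row: cosine similarity undefined")
    return z / norms, norms


def _layout_indices(layout: str, n: int, m: int):
    """Positive partner per slot (-1 = not an anchor) and denominator mask."""
    pos = np.full(m, -1, dtype=int)
    for i in range(n):
        pos[i] = i + n
        pos[i + n] = i
    mask = ~np.eye(m, dtype=bool)  # everything except self
    if layout == "two_view":
        if m != 2 * n:
            raise ValueError("two_view layout requires 2N embeddings")
    elif layout in ("three_view", "two_view_bg"):
        if m != 3 * n:
            raise ValueError(f"{layout} layout requires 3N embeddings")
    else:
        raise ValueError(f"unknown layout {layout!r}")
    return pos, mask


def _core(z: np.ndarray, pos: np.ndarray, mask: np.ndarray, tau: float,
          want_grad: bool):
    zn, norms = _normalize_rows(np.asarray(z, dtype=float))
    m = zn.shape[0]
    anchors = np.where(pos >= 0)[0]
    logits = (zn @ zn.T) / tau
    neg_inf = np.full_like(logits, -np.inf)
    masked = np.where(mask, logits, neg_inf)
    lse = logsumexp(masked[anchors], axis=1)
    per_anchor = lse - logits[anchors, pos[anchors]]
    total = float(per_anchor.mean())
    if not want_grad:
        return total, per_anchor, None
    # dL/dlogits restricted to anchor rows: softmax minus one-hot positive.
    probs = np.exp(masked[anchors] - lse[:, None])
    g = np.zeros_like(logits)
    g[anchors] = probs
    g[anchors, pos[anchors]] -= 1.0
    g /= len(anchors) * tau
    dzn = (g + g.T) @ zn
    # back through row normalization
    dz = (dzn - (dzn * zn).sum(axis=1, keepdims=True) * zn) / norms
    return total, per_anchor, dz


def contrastive_loss(embeddings: EmbeddingBatch, config: LossConfig) -> LossValue:
    """Dispatch on the embedding layout; validates layout/variant consistency."""
    layout = embeddings.layout
    expected = {"simclr": "two_view", "clib_ablation": "two_view_bg",
                "clib": "three_view"}[config.variant]
    if layout != expected:
        raise ValueError(f"variant {config.variant!r} expects layout {expected!r}, "
                         f"got {layout!r}")
    pos, mask = _layout_indices(layout, embeddings.n_sources, len(embeddings.vectors))
    total, per_anchor, _ = _core(embeddings.vectors, pos, mask,
                                 config.temperature, want_grad=False)
    return LossValue(total=total, per_anchor=per_anchor)


def simclr_loss(embeddings: EmbeddingBatch, config: LossConfig | None = None) -> LossValue:
    config = config or LossConfig(variant="simclr")
    return contrastive_loss(embeddings, LossConfig(config.temperature, "simclr"))


def clib_loss(embeddings: EmbeddingBatch, config: LossConfig | None = None) -> LossValue:
    config = config or LossConfig(variant="clib")
    return contrastive_loss(embeddings, LossConfig(config.temperature, "clib"))


def clib_ablation_loss(embeddings: EmbeddingBatch,
                       config: LossConfig | None = None) -> LossValue:
    config = config or LossConfig(variant="clib_ablation")
    return contrastive_loss(embeddings, LossConfig(config.temperature, "clib_ablation"))


def drop_background(embeddings: EmbeddingBatch) -> EmbeddingBatch:
    """Delete the background block of a 3N batch, leaving the 2N two-view
    batch whose SimCLR loss the background-augmented variant reduces to."""
    if embeddings.layout not in ("two_view_bg", "three_view"):
        raise ValueError("no background block to drop")
    n = embeddings.n_sources
    return EmbeddingBatch(vectors=embeddings.vectors[: 2 * n],
                          layout="two_view",
                          positive_pairs=list(embeddings.positive_pairs),
                          n_sources=n)


def loss_and_grad(z: np.ndarray, layout: str, n_sources: int,
                  temperature: float) -> tuple[float, np.ndarray, np.ndarray]:
    """(total, per_anchor, dL/dz) for training; same math as the public losses."""
    pos, mask = _layout_indices(layout, n_sources, z.shape[0])
    total, per_anchor, dz = _core(z, pos, mask, temperature, want_grad=True)
    return total, per_anchor, dz


# ---------------------------------------------------------------------------
# interleaved layout: triples (original_k, subject_k, background_k) stored
# consecutively, the numbering convention of the total-loss summation.


def block_to_interleaved(n: int) -> np.ndarray:
    """Permutation p with interleaved[j] = block[p[j]]."""
    p = np.empty(3 * n, dtype=int)
    for k in range(n):
        p[3 * k] = k              # original
        p[3 * k + 1] = k + n      # subject
        p[3 * k + 2] = k + 2 * n  # background
    return p


def interleaved_to_block(n: int) -> np.ndarray:
    """Inverse permutation: block[j] = interleaved[q[j]]."""
    return np.argsort(block_to_interleaved(n))


def clib_loss_interleaved(z_interleaved: np.ndarray,
                          config: LossConfig | None = None) -> LossValue:
    """CLIB loss for embeddings stored as consecutive (original, subject,
    background) triples; delegates to the block computation through the fixed
    permutation, so the two layouts agree bit-for-bit."""
    m = z_interleaved.shape[0]
    if m % 3:
        raise ValueError("interleaved layout requires 3N rows")
    n = m // 3
    z_block = z_interleaved[interleaved_to_block(n)]
    emb = EmbeddingBatch(vectors=z_block, layout="three_view",
                         positive_pairs=[(i, i + n) for i in range(n)],
                         n_sources=n)
    return clib_loss(emb, config)
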