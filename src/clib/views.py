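"""Subject/background extraction and multi-view batch construction.

The extraction module splits an image into a *subject* (centered crop of
height ``floor(alpha*H)`` and width ``floor(beta*W)``) and a *background*
(the four corner rectangles of height ``floor(gamma*H)`` and width
``floor(delta*W)`` pieced together into a mosaic, each corner keeping its
quadrant).  The original image, the subject and the background form the
three views entering the contrastive objective: original and subject of the
same source are the only positive pair, the background is negative-only.

All rectangles use 0-based, half-open ``[start, end)`` coordinates, and all
ratio-derived sizes round with ``floor``; images are ``H x W x C`` float
arrays with intensities in ``[0, 1]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GeometryError",
    "ImageBatch",
    "CropGeometry",
    "AugmentationPolicy",
    "ThreeViewBatch",
    "TwoViewBatch",
    "extract_subject",
    "extract_background",
    "extract_pair",
    "build_three_view_batch",
    "build_two_view_batch",
    "resize_bilinear",
]


class GeometryError(ValueError):
    """Raised when crop ratios produce an empty or out-of-bounds rectangle."""


@dataclass
class ImageBatch:
    """N images of identical shape with optional labels and identifiers."""

    pixels: np.ndarray  # (N, H, W, C) in [0, 1]
    labels: np.ndarray | None = None
    ids: list | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 4:
            raise ValueError("pixels must be (N, H, W, C)")
        if self.pixels.shape[0] < 1:
            raise ValueError("need at least one image")
        if not np.isfinite(self.pixels).all():
            raise ValueError("pixel intensities must be finite")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("pixel intensities must lie in [0, 1]")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != len(self.pixels):
                raise ValueError("labels length mismatch")
        if self.ids is None:
            self.ids = list(range(len(self.pixels)))

    def __len__(self):
        return self.pixels.shape[0]

    @property
    def image_shape(self):
        return self.pixels.shape[1:]


@dataclass(frozen=True)
class CropGeometry:
    """Subject/background crop ratios and the common output size.

    ``alpha``/``beta`` are the height/width ratios of the centered subject
    crop; ``gamma``/``delta`` the per-corner ratios of the background mosaic.
    Defaults: gamma = delta = 0.25 (the most effective corner ratio) and
    alpha = beta = 0.5 = 1 - 2*gamma, the unique choice making subject and
    corner pixel sets disjoint.
    """

    alpha: float = 0.5
    beta: float = 0.5
    gamma: float = 0.25
    delta: float = 0.25
    output_size: tuple[int, int] = (32, 32)

    def __post_init__(self):
        if not (0 < self.alpha <= 1 and 0 < self.beta <= 1):
            raise GeometryError("subject ratios must lie in (0, 1]")
        if not (0 < self.gamma <= 0.5 and 0 < self.delta <= 0.5):
            raise GeometryError("corner ratios must lie in (0, 0.5]")

    def subject_box(self, h: int, w: int) -> tuple[int, int, int, int]:
        """Half-open (r0, r1, c0, c1) of the centered subject rectangle."""
        sh, sw = int(self.alpha * h), int(self.beta * w)
        if sh == 0 or sw == 0:
            raise GeometryError(f"subject crop rounds to zero for image {h}x{w}")
        r0, c0 = (h - sh) // 2, (w - sw) // 2
        return r0, r0 + sh, c0, c0 + sw

    def corner_size(self, h: int, w: int) -> tuple[int, int]:
        ch, cw = int(self.gamma * h), int(self.delta * w)
        if ch == 0 or cw == 0:
            raise GeometryError(f"corner crop rounds to zero for image {h}x{w}")
        return ch, cw

    def corner_boxes(self, h: int, w: int) -> list[tuple[int, int, int, int]]:
        """The four corner rectangles in order TL, TR, BL, BR."""
        ch, cw = self.corner_size(h, w)
        return [
            (0, ch, 0, cw),
            (0, ch, w - cw, w),
            (h - ch, h, 0, cw),
            (h - ch, h, w - cw, w),
        ]


def extract_subject(image: np.ndarray, geometry: CropGeometry) -> np.ndarray:
    """Centered subject crop; pixels are copied without resampling."""
    h, w = image.shape[:2]
    r0, r1, c0, c1 = geometry.subject_box(h, w)
    return image[r0:r1, c0:c1].copy()


def extract_background(image: np.ndarray, geometry: CropGeometry) -> np.ndarray:
    """Four-corner mosaic with quadrant-preserving placement."""
    h, w = image.shape[:2]
    ch, cw = geometry.corner_size(h, w)
    boxes = geometry.corner_boxes(h, w)
    mosaic = np.empty((2 * ch, 2 * cw) + image.shape[2:], dtype=image.dtype)
    slots = [(0, 0), (0, cw), (ch, 0), (ch, cw)]  # quadrant of each corner
    for (r0, r1, c0, c1), (mr, mc) in zip(boxes, slots):
        mosaic[mr : mr + ch, mc : mc + cw] = image[r0:r1, c0:c1]
    return mosaic


def extract_pair(image: np.ndarray, geometry: CropGeometry):
    """(subject, background) of a single image — the extraction module output."""
    return extract_subject(image, geometry), extract_background(image, geometry)


# ---------------------------------------------------------------------------
# resizing and stochastic augmentation


def resize_bilinear(image: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Bilinear resize of an HxWxC image (half-pixel centers, edges clamped)."""
    h, w = image.shape[:2]
    if (h, w) == (out_h, out_w):
        return image.copy()
    r = np.clip((np.arange(out_h) + 0.5) * h / out_h - 0.5, 0, h - 1)
    c = np.clip((np.arange(out_w) + 0.5) * w / out_w - 0.5, 0, w - 1)
    r0 = np.floor(r).astype(int)
    c0 = np.floor(c).astype(int)
    r1 = np.minimum(r0 + 1, h - 1)
    c1 = np.minimum(c0 + 1, w - 1)
    fr = (r - r0)[:, None, None]
    fc = (c - c0)[None, :, None]
    if image.ndim == 2:
        fr, fc = fr[..., 0], fc[..., 0]
    ia = image[np.ix_(r0, c0)]
    ib = image[np.ix_(r0, c1)]
    ic = image[np.ix_(r1, c0)]
    id_ = image[np.ix_(r1, c1)]
    top = ia * (1 - fc) + ib * fc
    bot = ic * (1 - fc) + id_ * fc
    return top * (1 - fr) + bot * fr


_LUMA = np.array([0.299, 0.587, 0.114])


def _to_gray(img: np.ndarray) -> np.ndarray:
    return img @ _LUMA


@dataclass
class AugmentationPolicy:
    """Stochastic view augmentation (the SimCLR recipe by default).

    Transforms, in order: random resized crop to the target size, horizontal
    flip, color jitter (brightness/contrast/saturation/hue applied in random
    order), random grayscale.  ``AugmentationPolicy.identity()`` disables all
    randomness and only resizes, which is bit-exact when no resize is needed.
    """

    crop_scale: tuple[float, float] = (0.2, 1.0)
    crop_ratio: tuple[float, float] = (3 / 4, 4 / 3)
    hflip_p: float = 0.5
    jitter_p: float = 0.8
    brightness: float = 0.4
    contrast: float = 0.4
    saturation: float = 0.4
    hue: float = 0.1
    grayscale_p: float = 0.2
    random_crop: bool = True

    @classmethod
    def identity(cls) -> "AugmentationPolicy":
        return cls(hflip_p=0.0, jitter_p=0.0, grayscale_p=0.0, random_crop=False)

    # -- individual transforms -------------------------------------------

    def _random_resized_crop(self, img, out_hw, rng):
        h, w = img.shape[:2]
        area = h * w
        for _ in range(10):
            target = area * rng.uniform(*self.crop_scale)
            log_r = rng.uniform(np.log(self.crop_ratio[0]), np.log(self.crop_ratio[1]))
            ratio = np.exp(log_r)
            cw = int(round(np.sqrt(target * ratio)))
            ch = int(round(np.sqrt(target / ratio)))
            if 0 < ch <= h and 0 < cw <= w:
                r0 = rng.integers(0, h - ch + 1)
                c0 = rng.integers(0, w - cw + 1)
                crop = img[r0 : r0 + ch, c0 : c0 + cw]
                return resize_bilinear(crop, *out_hw)
        return resize_bilinear(img, *out_hw)

    def _jitter(self, img, rng):
        ops = rng.permutation(4)
        for op in ops:
            if op == 0 and self.brightness:
                img = img * rng.uniform(1 - self.brightness, 1 + self.brightness)
            elif op == 1 and self.contrast:
                f = rng.uniform(1 - self.contrast, 1 + self.contrast)
                mean = _to_gray(img).mean()
                img = (img - mean) * f + mean
            elif op == 2 and self.saturation:
                f = rng.uniform(1 - self.saturation, 1 + self.saturation)
                gray = _to_gray(img)[..., None]
                img = gray + (img - gray) * f
            elif op == 3 and self.hue:
                img = _rotate_hue(img, rng.uniform(-self.hue, self.hue) * 2 * np.pi)
        return np.clip(img, 0.0, 1.0)

    def apply(self, img: np.ndarray, out_hw: tuple[int, int],
              rng: np.random.Generator) -> np.ndarray:
        """One stochastic draw of the policy, producing an out_hw image."""
        if self.random_crop:
            img = self._random_resized_crop(img, out_hw, rng)
        else:
            img = resize_bilinear(img, *out_hw)
        if self.hflip_p and rng.random() < self.hflip_p:
            img = img[:, ::-1].copy()
        if self.jitter_p and rng.random() < self.jitter_p:
            img = self._jitter(img, rng)
        if self.grayscale_p and rng.random() < self.grayscale_p:
            img = np.repeat(_to_gray(img)[..., None], img.shape[2], axis=2)
        return np.ascontiguousarray(np.clip(img, 0.0, 1.0))


# YIQ hue rotation: luma-preserving rotation of the chroma plane.
_RGB2YIQ = np.array([[0.299, 0.587, 0.114],
                     [0.596, -0.274, -0.322],
                     [0.211, -0.523, 0.312]])
_YIQ2RGB = np.linalg.inv(_RGB2YIQ)


def _rotate_hue(img: np.ndarray, angle: float) -> np.ndarray:
    yiq = img @ _RGB2YIQ.T
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
    return yiq @ rot.T @ _YIQ2RGB.T


# ---------------------------------------------------------------------------
# view batches


@dataclass
class ThreeViewBatch:
    """3N augmented samples in block layout [originals | subjects | backgrounds].

    Positive pairs link slot ``i`` (original) to ``i + N`` (its subject);
    background slots ``2N..3N-1`` are negatives only and never anchor, so
    every anchor has 1 positive and 3N - 2 negatives.
    """

    samples: np.ndarray  # (3N, h, w, C)
    positive_pairs: list[tuple[int, int]]
    source_ids: list
    layout: str = "three_view"
    n_sources: int = 0

    def __post_init__(self):
        if self.n_sources == 0:
            self.n_sources = len(self.samples) // 3
        n = self.n_sources
        if len(self.samples) != 3 * n:
            raise ValueError("three-view batch must hold exactly 3N samples")
        if self.positive_pairs != [(i, i + n) for i in range(n)]:
            raise ValueError("positive pairs must be (i, i+N)")

    @property
    def n_anchors(self) -> int:
        return 2 * self.n_sources

    @property
    def negatives_per_anchor(self) -> int:
        return 3 * self.n_sources - 2


@dataclass
class TwoViewBatch:
    """2N two-augmentation samples, optionally plus N negative-only backgrounds."""

    samples: np.ndarray
    positive_pairs: list[tuple[int, int]]
    source_ids: list
    layout: str = "two_view"  # or "two_view_bg"
    n_sources: int = 0

    def __post_init__(self):
        n = self.n_sources or len(self.positive_pairs)
        self.n_sources = n
        expected = 3 * n if self.layout == "two_view_bg" else 2 * n
        if len(self.samples) != expected:
            raise ValueError(f"{self.layout} batch must hold {expected} samples")

    @property
    def n_anchors(self) -> int:
        return 2 * self.n_sources

    @property
    def negatives_per_anchor(self) -> int:
        total = len(self.samples)
        return total - 2


def _coerce_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def build_three_view_batch(batch: ImageBatch, geometry: CropGeometry,
                           policy: AugmentationPolicy, seed=0) -> ThreeViewBatch:
    """Original / subject / background views, each augmented once.

    Augmentation draws happen in slot order (originals, then subjects, then
    backgrounds), so the result is reproducible from (inputs, geometry,
    policy, seed).
    """
    rng = _coerce_rng(seed)
    n = len(batch)
    out_hw = geometry.output_size
    views: list[np.ndarray] = []
    crops = [img for img in batch.pixels]
    crops += [extract_subject(img, geometry) for img in batch.pixels]
    crops += [extract_background(img, geometry) for img in batch.pixels]
    for crop in crops:
        views.append(policy.apply(crop, out_hw, rng))
    ids = batch.ids
    source_ids = [(sid, v) for v in ("original", "subject", "background") for sid in ids]
    return ThreeViewBatch(
        samples=np.stack(views),
        positive_pairs=[(i, i + n) for i in range(n)],
        source_ids=source_ids,
        n_sources=n,
    )


def build_two_view_batch(batch: ImageBatch, policy: AugmentationPolicy, seed=0,
                         with_background: bool = False,
                         geometry: CropGeometry | None = None) -> TwoViewBatch:
    """Two independent augmentations per source (the SimCLR construction).

    With ``with_background=True`` the background mosaics are appended as N
    extra negative-only slots (the background-augmented baseline variant);
    anchors stay restricted to the first 2N slots.
    """
    rng = _coerce_rng(seed)
    geometry = geometry or CropGeometry()
    n = len(batch)
    out_hw = geometry.output_size
    views = [policy.apply(img, out_hw, rng) for img in batch.pixels]
    views += [policy.apply(img, out_hw, rng) for img in batch.pixels]
    layout = "two_view"
    source_ids = [(sid, v) for v in ("aug1", "aug2") for sid in batch.ids]
    if with_background:
        views += [policy.apply(extract_background(img, geometry), out_hw, rng)
                  for img in batch.pixels]
        layout = "two_view_bg"
        source_ids += [(sid, "background") for sid in batch.ids]
    return TwoViewBatch(
        samples=np.stack(views),
        positive_pairs=[(i, i + n) for i in range(n)],
        source_ids=source_ids,
        layout=layout,
        n_sources=n,
    )
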