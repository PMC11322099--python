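"""Image-folder and configuration file I/O."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from .training import PretrainConfig
from .views import ImageBatch

__all__ = ["load_image_folder", "save_image_folder", "load_pretrain_config"]

_EXTENSIONS = {".png", ".jpg", ".jpeg"}


def load_image_folder(directory) -> ImageBatch:
    """Read a class-per-subdirectory image tree into an ImageBatch.

    Class indices follow the sorted subdirectory names; files are sorted
    within each class so the batch is stable across runs.
    """
    directory = Path(directory)
    class_dirs = sorted(d for d in directory.iterdir() if d.is_dir())
    if not class_dirs:
        raise FileNotFoundError(f"no class subdirectories under {directory}")
    pixels, labels, ids = [], [], []
    for k, sub in enumerate(class_dirs):
        files = sorted(p for p in sub.iterdir() if p.suffix.lower() in _EXTENSIONS)
        for p in files:
            arr = np.asarray(Image.open(p).convert("RGB"), dtype=float) / 255.0
            pixels.append(arr)
            labels.append(k)
            ids.append(str(p.relative_to(directory)))
    if not pixels:
        raise FileNotFoundError(f"no images under {directory}")
    shapes = {p.shape for p in pixels}
    if len(shapes) > 1:
        raise ValueError(f"images must share one shape, found {sorted(shapes)}")
    return ImageBatch(pixels=np.stack(pixels), labels=np.array(labels), ids=ids)


def save_image_folder(batch: ImageBatch, directory) -> None:
    directory = Path(directory)
    labels = batch.labels if batch.labels is not None else np.zeros(len(batch), int)
    for i, (img, label) in enumerate(zip(batch.pixels, labels)):
        sub = directory / f"class_{int(label):02d}"
        sub.mkdir(parents=True, exist_ok=True)
        arr = (np.clip(img, 0, 1) * 255).round().astype(np.uint8)
        Image.fromarray(arr).save(sub / f"img_{i:05d}.png")


def load_pretrain_config(path) -> PretrainConfig:
    """Flat key/value YAML mirroring PretrainConfig; unknown keys rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    fields = {f.name for f in dataclasses.fields(PretrainConfig)}
    unknown = set(raw) - fields
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "widths" in raw:
        raw["widths"] = tuple(raw["widths"])
    return PretrainConfig(**raw)
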