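"""Self-supervised pretraining loop and parameter-sweep harness.

Thin functional layer over :class:`~clib.estimators.ContrastiveEncoder`:
``pretrain`` runs one configured training job (optionally writing a
checkpoint of the lowest-loss epoch), ``lr_schedule`` exposes the cosine
learning-rate decay, and ``sweep`` reruns pretrain+evaluate across a grid
of corner ratios or temperatures.

Pretraining uses every sample with no train/validation split; model
selection is by training loss (the lowest-loss epoch is preserved).
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .estimators import ContrastiveEncoder, cosine_lr
from .model import save_checkpoint
from .views import AugmentationPolicy, ImageBatch

__all__ = ["PretrainConfig", "TrainingLog", "lr_schedule", "pretrain", "sweep"]


@dataclass(frozen=True)
class PretrainConfig:
    """Hyperparameters of one pretraining job.

    Defaults are desk-scale (32x32 inputs, small conv encoder, 30 epochs);
    ``paper_scale()`` returns the published-protocol preset (SGD, lr 0.01 ->
    0.0001, temperature 0.07, 500 backbone epochs).
    """

    variant: str = "clib"
    batch_size: int = 32
    epochs: int = 30
    optimizer: str = "sgd"
    initial_lr: float = 0.01
    final_lr: float = 0.0001
    momentum: float = 0.9
    temperature: float = 0.07
    alpha: float = 0.5
    gamma: float = 0.25
    image_size: int = 32
    widths: tuple[int, ...] = (16, 32, 64)
    proj_dim: int = 16
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not self.initial_lr >= self.final_lr > 0:
            raise ValueError("require initial_lr >= final_lr > 0")
        if self.optimizer != "sgd":
            raise ValueError("only SGD is supported")

    @classmethod
    def paper_scale(cls, **overrides) -> "PretrainConfig":
        return cls(epochs=500, **overrides)

    def to_estimator(self, augment: AugmentationPolicy | None = None
                     ) -> ContrastiveEncoder:
        return ContrastiveEncoder(
            variant=self.variant, image_size=self.image_size, alpha=self.alpha,
            gamma=self.gamma, temperature=self.temperature, epochs=self.epochs,
            batch_size=self.batch_size, learning_rate=self.initial_lr,
            final_lr=self.final_lr, momentum=self.momentum,
            widths=self.widths, proj_dim=self.proj_dim, augment=augment,
            random_state=self.seed)


@dataclass
class TrainingLog:
    epoch_loss: np.ndarray
    lr_trace: np.ndarray
    best_epoch: int
    best_loss: float
    checkpoint_path: str | None = None
    lines: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.lines:
            self.lines = [
                f"epoch={e} lr={lr:.6g} loss={loss:.6f}"
                for e, (lr, loss) in enumerate(zip(self.lr_trace, self.epoch_loss))
            ]


def lr_schedule(epoch: float, config: PretrainConfig) -> float:
    """Cosine decay from initial_lr (epoch 0) to final_lr (last epoch).

    ``epoch`` may be fractional to query the schedule between epochs; it must
    lie in [0, epochs - 1].
    """
    if not 0 <= epoch <= config.epochs - 1:
        raise ValueError(f"epoch {epoch} outside [0, {config.epochs - 1}]")
    return cosine_lr(epoch, config.epochs, config.initial_lr, config.final_lr)


def pretrain(dataset: ImageBatch | np.ndarray, config: PretrainConfig,
             augment: AugmentationPolicy | None = None,
             checkpoint_path=None) -> tuple[ContrastiveEncoder, TrainingLog]:
    """Run one self-supervised pretraining job; reproducible from config.seed."""
    pixels = dataset.pixels if isinstance(dataset, ImageBatch) else np.asarray(dataset)
    if len(pixels) == 0:
        raise ValueError("empty dataset")
    est = config.to_estimator(augment).fit(pixels)
    if checkpoint_path is not None:
        save_checkpoint(checkpoint_path, est.encoder_, est.projector_,
                        config=asdict(config))
    log = TrainingLog(epoch_loss=est.loss_curve_, lr_trace=est.lr_trace_,
                      best_epoch=est.best_epoch_, best_loss=est.best_loss_,
                      checkpoint_path=None if checkpoint_path is None
                      else str(checkpoint_path))
    return est, log


_SWEEP_FIELDS = {"ratio": "gamma", "gamma": "gamma",
                 "temperature": "temperature", "tau": "temperature",
                 "variant": "variant"}


def _legal(parameter: str, value) -> bool:
    if parameter == "gamma":
        return 0 < value <= 0.5
    if parameter == "variant":
        from .loss import VARIANTS

        return value in VARIANTS
    return value > 0  # temperature


def sweep(dataset: ImageBatch | np.ndarray, parameter: str, values,
          base_config: PretrainConfig, eval_hook) -> pd.DataFrame:
    """One full pretrain + evaluation per value, same seed throughout.

    ``parameter`` is ``"ratio"``/``"gamma"`` (corner crop ratio),
    ``"temperature"``/``"tau"``, or ``"variant"`` (loss/view construction);
    ``eval_hook(estimator, log) -> float``
    supplies the reported metric (e.g. a probe accuracy or final loss).
    Illegal values are skipped with a warning.  Duplicate values rerun.
    """
    if parameter not in _SWEEP_FIELDS:
        raise ValueError(f"unknown sweep parameter {parameter!r}")
    fld = _SWEEP_FIELDS[parameter]
    rows = []
    for value in values:
        if not _legal(fld, value):
            warnings.warn(f"skipping illegal {parameter} value {value!r}")
            continue
        cfg = replace(base_config, **{fld: value})
        est, log = pretrain(dataset, cfg)
        rows.append({"parameter": fld, "value": value,
                     "metric": float(eval_hook(est, log))})
    return pd.DataFrame(rows, columns=["parameter", "value", "metric"])
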