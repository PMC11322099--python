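"""Linear-probe evaluation of a pretrained backbone.

Protocol: the labeled dataset is split 1:1:8 into probe-train, validation
and test; a single linear classifier is trained on frozen backbone features
of center-resized full images (no subject/background extraction at
evaluation time); the epoch with the highest validation accuracy is kept;
the test set yields accuracy and macro-averaged precision/recall/F1.

Macro averaging is used because per-class averaging with equal class weight
is the convention that lets precision/recall/F1 fall well below accuracy on
imbalanced data; ``average="micro"`` is available as a switch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import train_test_split

from .estimators import ContrastiveEncoder, LinearProbe

__all__ = ["SplitSpec", "MetricsReport", "split_dataset", "train_probe",
           "compute_metrics", "evaluate"]


@dataclass(frozen=True)
class SplitSpec:
    train_frac: float = 0.1
    val_frac: float = 0.1
    test_frac: float = 0.8
    stratify: bool = True
    seed: int = 0

    def __post_init__(self):
        if not np.isclose(self.train_frac + self.val_frac + self.test_frac, 1.0):
            raise ValueError("split fractions must sum to 1")


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    per_class: pd.DataFrame = field(repr=False)
    confusion: np.ndarray = field(repr=False)


def split_dataset(labels, spec: SplitSpec = SplitSpec()):
    """Disjoint (train, val, test) index arrays covering all samples.

    Stratified per class when feasible; deterministic given ``spec.seed``.
    Classes with fewer than 3 members cannot appear in every subset — they
    are assigned best-effort with a warning from sklearn suppressed into a
    plain split.
    """
    labels = np.asarray(labels)
    idx = np.arange(len(labels))
    strat = labels if spec.stratify else None
    _, class_counts = np.unique(labels, return_counts=True)
    if spec.stratify and class_counts.min() < 3:
        import warnings

        warnings.warn("classes with fewer than 3 members cannot appear in "
                      "every subset; assigning best-effort")
    try:
        trainval, test = train_test_split(
            idx, test_size=spec.test_frac, stratify=strat, random_state=spec.seed)
        strat2 = labels[trainval] if spec.stratify else None
        val_share = spec.val_frac / (spec.train_frac + spec.val_frac)
        train, val = train_test_split(
            trainval, test_size=val_share, stratify=strat2,
            random_state=spec.seed + 1)
    except ValueError:
        # tiny classes break stratification: fall back to a plain shuffle
        import warnings

        warnings.warn("stratified split infeasible; using unstratified split")
        rng = np.random.default_rng(spec.seed)
        perm = rng.permutation(idx)
        n_tr = int(round(spec.train_frac * len(idx)))
        n_va = int(round(spec.val_frac * len(idx)))
        train, val, test = perm[:n_tr], perm[n_tr : n_tr + n_va], perm[n_tr + n_va :]
    return np.sort(train), np.sort(val), np.sort(test)


def train_probe(encoder: ContrastiveEncoder, X, y, train_idx, val_idx,
                epochs: int = 100, learning_rate: float = 0.01,
                final_lr: float = 0.0001, seed: int = 0) -> LinearProbe:
    """Train the linear read-out on frozen features; encoder is not touched."""
    X = np.asarray(X)
    y = np.asarray(y)
    feats_train = encoder.transform(X[train_idx])
    feats_val = encoder.transform(X[val_idx]) if len(val_idx) else None
    probe = LinearProbe(epochs=epochs, learning_rate=learning_rate,
                        final_lr=final_lr, random_state=seed)
    probe.fit(feats_train, y[train_idx],
              X_val=feats_val, y_val=None if feats_val is None else y[val_idx])
    return probe


def compute_metrics(y_true, y_pred, n_classes: int | None = None,
                    average: str = "macro") -> MetricsReport:
    """Accuracy plus averaged precision/recall/F1 and the per-class table.

    Classes absent from the predictions get precision 0 by convention.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("label vectors must have equal length")
    if n_classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    else:
        classes = np.arange(n_classes)
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    accuracy = float(np.trace(cm) / cm.sum())
    prec, rec, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, zero_division=0)
    per_class = pd.DataFrame({"class": classes, "precision": prec,
                              "recall": rec, "f1": f1, "support": support})
    if average == "macro":
        p, r, f = float(prec.mean()), float(rec.mean()), float(f1.mean())
    elif average == "micro":
        p = r = f = accuracy
    else:
        raise ValueError("average must be 'macro' or 'micro'")
    return MetricsReport(accuracy=accuracy, precision=p, recall=r, f1=f,
                         per_class=per_class, confusion=cm)


def evaluate(encoder: ContrastiveEncoder, probe: LinearProbe, X_test, y_test,
             n_classes: int | None = None, average: str = "macro") -> MetricsReport:
    """Frozen encoder + trained probe on the held-out test set."""
    y_test = np.asarray(y_test)
    feats = encoder.transform(np.asarray(X_test))
    y_pred = probe.predict(feats)
    missing = np.setdiff1d(np.unique(y_test), probe.classes_)
    if n_classes is None and len(missing):
        n_classes = int(max(y_test.max(), probe.classes_.max())) + 1
    return compute_metrics(y_test, y_pred, n_classes=n_classes, average=average)
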