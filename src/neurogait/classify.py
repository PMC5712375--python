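"""Binary intention classifier: standardized features into an RBF-kernel SVM.

One model is trained per subject, event type (start/stop) and protocol on
27-value feature vectors (9 electrodes x 3 bands).  Features are
standardized with statistics fitted on the training set only;
zero-variance features are dropped (and recorded) rather than divided by
zero.  Class weighting is balanced because pseudo-online non-active
windows contribute many more epochs than the 4-s active windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import joblib
import numpy as np
from sklearn.svm import SVC

from .core import ValidationError

__all__ = ["SvmConfig", "TrainedModel", "train", "classify_epoch", "classify", "save_model", "load_model"]


@dataclass(frozen=True)
class SvmConfig:
    C: float = 1.0
    gamma: str | float = "scale"  # 1 / (n_features * feature variance)
    class_weight: str | dict | None = "balanced"


@dataclass
class TrainedModel:
    """Scaler statistics plus the fitted SVM and its provenance metadata."""

    mean: np.ndarray
    scale: np.ndarray
    keep: np.ndarray  # boolean mask of non-degenerate features
    svc: SVC
    metadata: dict[str, Any] = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return len(self.mean)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValidationError(
                f"feature vector length {X.shape[1]} does not match model ({self.n_features})"
            )
        if not np.all(np.isfinite(X)):
            raise ValidationError("non-finite feature values")
        return ((X - self.mean) / self.scale)[:, self.keep]


def train(
    X: np.ndarray,
    y: np.ndarray,
    config: SvmConfig = SvmConfig(),
    metadata: dict[str, Any] | None = None,
) -> TrainedModel:
    """Fit the standardizer and RBF-SVM on labelled epoch features."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    if X.shape[0] != len(y):
        raise ValidationError("feature/label count mismatch")
    if not np.all(np.isfinite(X)):
        raise ValidationError("non-finite feature values in training data")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValidationError(f"training data contains a single class: {classes}")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    scale = np.where(keep, sd, 1.0)
    svc = SVC(
        C=config.C,
        kernel="rbf",
        gamma=config.gamma,
        class_weight=config.class_weight,
        random_state=0,
    )
    meta = dict(metadata or {})
    meta.setdefault("svm", {"C": config.C, "gamma": config.gamma, "class_weight": config.class_weight})
    meta["n_dropped_features"] = int(np.sum(~keep))
    model = TrainedModel(mean=mean, scale=scale, keep=keep, svc=svc, metadata=meta)
    svc.fit(model.transform(X), y)
    return model


def classify(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Deterministic 0/1 labels for a batch of feature vectors."""
    return model.svc.predict(model.transform(X)).astype(int)


def classify_epoch(model: TrainedModel, fv: np.ndarray) -> int:
    """Label one 27-value epoch feature vector."""
    return int(classify(model, np.atleast_2d(fv))[0])


def save_model(model: TrainedModel, path) -> None:
    joblib.dump(model, path)


def load_model(path) -> TrainedModel:
    model = joblib.load(path)
    if not isinstance(model, TrainedModel):
        raise ValidationError(f"{path} does not contain a TrainedModel")
    return model
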