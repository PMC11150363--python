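"""Support-vector-regression head on fused penultimate features.

The network's penultimate activation F_l (length dense_units, post-ELU,
dropout off) is concatenated with the sex code G and regressed onto age
with epsilon-insensitive kernel SVR, y = SVR(F_l (+) G).  Columns are
standardised by training-set statistics stored with the head, so a fitted
head is a self-contained predictor; zero-variance columns pass through
unscaled rather than dividing by zero.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from sklearn.svm import SVR

from .io_manifest import Cohort
from .network import TrainedModel
from .training import predict_ages


@dataclass
class FeatureMatrix:
    """Per-scan fused features (F_l then G) with matched target ages."""

    features: np.ndarray  # (n, dense_units + 1)
    ages: np.ndarray      # (n,)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.ages = np.asarray(self.ages, dtype=float)
        if self.features.ndim != 2 or len(self.features) != len(self.ages):
            raise ValueError(
                f"features {self.features.shape} and ages {self.ages.shape} do not align"
            )

    @property
    def n(self) -> int:
        return len(self.ages)


def extract_features(
    model: TrainedModel,
    data: tuple[np.ndarray, np.ndarray, np.ndarray],
    batch_size: int = 8,
) -> FeatureMatrix:
    """Inference-mode F_l (+) G rows for every scan in (volumes, sex, ages)."""
    x, sex, ages = data
    _, feats = predict_ages(model, x, sex, batch_size)
    fused = np.concatenate([feats, np.asarray(sex, dtype=feats.dtype).reshape(-1, 1)], axis=1)
    if fused.shape[1] != model.config.dense_units + 1:
        raise ValueError("feature width does not match dense_units + 1")
    return FeatureMatrix(features=fused, ages=np.asarray(ages, dtype=float))


@dataclass
class SVRHead:
    """A fitted SVR with its train-set standardisation statistics.

    Both the feature columns and the age target are standardised by
    training statistics (the target is mapped back to years at prediction
    time), so the conventional C and epsilon defaults act on unit-variance
    quantities regardless of the cohort's age spread.
    """

    svr: SVR
    mean: np.ndarray
    scale: np.ndarray  # per-column sd; zero-variance columns stored as 1.0
    age_mean: float = 0.0
    age_scale: float = 1.0

    def transform(self, features: np.ndarray) -> np.ndarray:
        features = np.asarray(features, dtype=float)
        if features.ndim == 1:
            features = features[None, :]
        if features.shape[1] != len(self.mean):
            raise ValueError(
                f"expected {len(self.mean)} feature columns, got {features.shape[1]}"
            )
        return (features - self.mean) / self.scale

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path: str | Path) -> "SVRHead":
        with open(path, "rb") as fh:
            obj = pickle.load(fh)
        if not isinstance(obj, cls):
            raise TypeError(f"{path} does not hold an SVRHead")
        return obj


def fit_svr(
    features: FeatureMatrix,
    kernel: str = "rbf",
    C: float = 1.0,
    epsilon: float = 0.1,
    gamma: str | float = "scale",
) -> SVRHead:
    """Standardise by train statistics and fit epsilon-insensitive SVR."""
    if features.n < 2:
        raise ValueError("need at least 2 training rows to fit the SVR head")
    mean = features.features.mean(axis=0)
    sd = features.features.std(axis=0)
    scale = np.where(sd > 0, sd, 1.0)  # constant columns are left unscaled
    age_sd = float(features.ages.std())
    head = SVRHead(svr=SVR(kernel=kernel, C=C, epsilon=epsilon, gamma=gamma),
                   mean=mean, scale=scale,
                   age_mean=float(features.ages.mean()),
                   age_scale=age_sd if age_sd > 0 else 1.0)
    y = (features.ages - head.age_mean) / head.age_scale
    head.svr.fit(head.transform(features.features), y)
    return head


def predict_svr(head: SVRHead, features: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Predicted ages, one per feature row."""
    mat = features.features if isinstance(features, FeatureMatrix) else np.asarray(features)
    return head.svr.predict(head.transform(mat)) * head.age_scale + head.age_mean
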