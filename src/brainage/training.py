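"""Training loop (Adam + MSE) and regression evaluation.

Training follows the fixed-epoch recipe: Adam at learning rate 7e-4
minimising mean squared error for a fixed number of epochs (no early
stopping), while the parameters with the best validation loss seen so far
are checkpointed and restored at the end.  Everything is seeded and runs
on one CPU, so a repeated run reproduces the loss history bit for bit.

Evaluation reports the standard brain-age panel per scan: MAE, RMSE,
Pearson and Spearman correlations, R^2, and a t-based 95% confidence
interval of the mean signed error.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import stats

from .io_manifest import Cohort, VolumeImage, read_volume
from .network import TrainedModel
from .preprocess import PreprocessConfig, preprocess_pipeline
from ._layers import Adam

logger = logging.getLogger("brainage")


@dataclass
class TrainSpec:
    """Optimiser/loss schedule: Adam, MSE, fixed epoch count."""

    learning_rate: float = 7e-4
    loss: str = "mse"
    epochs: int = 100
    batch_size: int = 8
    seed: int = 0
    init_output_bias: bool = True  # warm-start the final bias at the mean train age

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.loss != "mse":
            raise ValueError(f"unsupported loss {self.loss!r}")


@dataclass
class RegressionMetrics:
    """Per-scan regression quality of predicted vs chronological age."""

    mae: float
    rmse: float
    pcc: float
    srcc: float
    r2: float
    ci95: tuple[float, float]
    n: int

    def to_dict(self) -> dict:
        return {
            "mae": self.mae, "rmse": self.rmse, "pcc": self.pcc,
            "srcc": self.srcc, "r2": self.r2,
            "ci95": list(self.ci95), "n": self.n,
        }


# ---------------------------------------------------------------------------
# data plumbing


def load_cohort_arrays(
    cohort: Cohort,
    pre_cfg: Optional[PreprocessConfig] = None,
    masks: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read and preprocess every scan of a cohort into stacked arrays.

    Returns (volumes (n, D, H, W) float32, sex codes (n,), ages (n,)).
    When ``masks`` is true, a ground-truth mask file next to each scan
    (``<stem>_mask.nii.gz``, as the synthetic generator writes) is used for
    brain extraction if present.
    """
    pre_cfg = pre_cfg or PreprocessConfig()
    vols = []
    for rec in cohort.records:
        vol = read_volume(rec.scan_path)
        mask = None
        if masks and rec.scan_path.endswith(".nii.gz"):
            cand = Path(rec.scan_path[: -len(".nii.gz")] + "_mask.nii.gz")
            if cand.exists():
                mask = read_volume(cand).grid.astype(bool)
        out = preprocess_pipeline(vol, pre_cfg, mask=mask)
        vols.append(out.grid.astype(np.float32))
    x = np.stack(vols)
    return x, cohort.sexes(), cohort.ages()


def predict_ages(model: TrainedModel, x: np.ndarray, sex: np.ndarray,
                 batch_size: int = 8) -> tuple[np.ndarray, np.ndarray]:
    """Inference-mode predictions and penultimate features, batched."""
    preds, feats = [], []
    for start in range(0, len(x), batch_size):
        sl = slice(start, start + batch_size)
        p, f = model.forward_batch(
            x[sl].astype(np.float32)[..., None], sex[sl], train=False, cache=False
        )
        preds.append(p)
        feats.append(f)
    return np.concatenate(preds), np.concatenate(feats)


# ---------------------------------------------------------------------------
# training


def train(
    model: TrainedModel,
    train_set: tuple[np.ndarray, np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray, np.ndarray],
    spec: Optional[TrainSpec] = None,
) -> TrainedModel:
    """Fit the network in place; returns the same model with history filled.

    ``train_set``/``val_set`` are (volumes, sex, age) triples as produced by
    :func:`load_cohort_arrays`; they must be subject-disjoint (the caller
    splits by subject).  Per-epoch train/val MSE is recorded and the
    best-validation parameters are restored on return.
    """
    spec = spec or TrainSpec()
    xtr, gtr, ytr = train_set
    xva, gva, yva = val_set
    if len(xtr) == 0 or len(xva) == 0:
        raise ValueError("training and validation sets must be non-empty")
    xtr = xtr.astype(np.float32)
    xva = xva.astype(np.float32)

    if spec.init_output_bias:
        # start the final linear unit at the mean train age so the first
        # epochs refine structure instead of crawling out of a huge offset
        model.out.b.value[...] = np.float32(ytr.mean())

    rng = np.random.default_rng(spec.seed)
    model.dropout.rng = np.random.default_rng(spec.seed + 1)
    opt = Adam(model.params(), lr=spec.learning_rate)
    best_val = math.inf
    best_state = None
    n = len(xtr)
    for epoch in range(spec.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, spec.batch_size):
            idx = order[start:start + spec.batch_size]
            xb = xtr[idx][..., None]
            yb = ytr[idx]
            model.zero_grad()
            pred, _ = model.forward_batch(xb, gtr[idx], train=True)
            resid = pred - yb
            loss = float(np.mean(resid ** 2)) + model.l2_loss()
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {loss}; "
                    "lower the learning rate or check the inputs"
                )
            model.backward_batch(2.0 * resid / len(idx))
            opt.step()
            losses.append(loss)
        val_pred, _ = predict_ages(model, xva, gva, spec.batch_size)
        val_loss = float(np.mean((val_pred - yva) ** 2))
        model.history["train_loss"].append(float(np.mean(losses)))
        model.history["val_loss"].append(val_loss)
        logger.info("epoch %d: train %.3f val %.3f", epoch, np.mean(losses), val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_state = {k: v.copy() for k, v in model.state_dict().items()}
    if best_state is not None:
        model.load_state_dict(best_state)
    return model


# ---------------------------------------------------------------------------
# evaluation


def evaluate(chronological: np.ndarray, predicted: np.ndarray) -> RegressionMetrics:
    """Regression metrics on per-scan (chronological, predicted) age pairs."""
    y = np.asarray(chronological, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if y.shape != p.shape or y.ndim != 1:
        raise ValueError("chronological and predicted ages must be equal-length vectors")
    if len(y) < 2:
        raise ValueError("need at least 2 test scans")
    err = p - y
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err ** 2)))
    if np.ptp(p) == 0 or np.ptp(y) == 0:
        logger.warning("constant predictions or targets: correlation undefined")
        pcc = srcc = float("nan")
    else:
        pcc = float(stats.pearsonr(y, p).statistic)
        srcc = float(stats.spearmanr(y, p).statistic)
    ss_res = float(np.sum(err ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    se = err.std(ddof=1) / math.sqrt(len(err))
    if se > 0:
        lo, hi = stats.t.interval(0.95, df=len(err) - 1, loc=err.mean(), scale=se)
    else:
        lo = hi = float(err.mean())
    return RegressionMetrics(mae=mae, rmse=rmse, pcc=pcc, srcc=srcc, r2=r2,
                             ci95=(float(lo), float(hi)), n=len(y))


def evaluate_model(model: TrainedModel, test_set: tuple[np.ndarray, np.ndarray, np.ndarray],
                   batch_size: int = 8) -> RegressionMetrics:
    x, g, y = test_set
    pred, _ = predict_ages(model, x, g, batch_size)
    return evaluate(y, pred)


def mean_baseline_mae(train_ages: np.ndarray, test_ages: np.ndarray) -> float:
    """MAE of the constant mean-train-age predictor, the no-information floor."""
    return float(np.mean(np.abs(np.asarray(test_ages) - np.mean(train_ages))))
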