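"""Compact volumetric regressor: ONH volume -> 52 VF sensitivities.

The network is intentionally small and fully deterministic: a non-overlapping
3D average-pooling encoder (pool size defaulting to the occlusion patch size)
followed by a configurable dense head, trained with Adam on the
reliability-weighted mean-square-error loss

    L = mean_pt  w_pt * (pred_pt - target_pt)^2 ,

where w_pt is the inverse pointwise sensitivity SD among healthy eyes,
normalized to max 1.  Targets are centered at the training-set mean VF, so
the untrained model is exactly the cohort-mean predictor and any learning
improves on that baseline.  The occlusion analysis downstream treats the
model as a black box; nothing there depends on this architecture.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .preprocess import ProcessedVolume
from .vf_grid import N_POINTS, ReliabilityWeights, VFTest

__all__ = [
    "RegressorConfig",
    "TrainedRegressor",
    "weighted_mse",
    "train",
    "predict",
    "mean_baseline_mae",
]


@dataclass(frozen=True)
class RegressorConfig:
    """Training configuration.

    The clinical-scale schedule (200 epochs, batch 16, lr 2e-4, x0.1 step
    decay every 100 epochs) is preserved in the "paper" pipeline profile;
    the defaults here are the desk-scale profile used on the synthetic
    cohort.
    """

    pool_vox: tuple[int, int, int] = (4, 4, 4)
    hidden: tuple[int, ...] = ()  # dense hidden layer widths (ReLU)
    epochs: int = 150
    batch_size: int = 8
    lr_init: float = 5e-2
    lr_decay_factor: float = 0.1
    lr_decay_every: int = 100  # epochs per step-decay boundary
    # L2 penalty added to the loss (ridge).  With far fewer training pairs
    # than pooled features the unpenalized problem is underdetermined and the
    # minimum-loss solution spreads weight onto uninformative patches, which
    # destroys the spatial attribution of the downstream occlusion analysis;
    # shrinkage concentrates weight on reproducibly informative features.
    # The penalty enters the gradient (coupled), so Adam's stationary points
    # are exactly the minima of loss + weight_decay * ||W||^2.
    weight_decay: float = 1e-2
    val_fraction: float = 0.1
    seed: int = 0
    deterministic_mode: bool = True

    def __post_init__(self) -> None:
        if self.lr_init <= 0:
            raise ValueError("lr_init must be positive")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be non-negative")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if any(h < 1 for h in self.hidden):
            raise ValueError("hidden widths must be positive")


def weighted_mse(pred: np.ndarray, target: np.ndarray,
                 w: ReliabilityWeights | np.ndarray) -> float:
    """Reliability-weighted MSE: mean over points of w_pt (pred - target)^2.

    For batched inputs (n, 52) the mean is additionally taken over the batch.
    """
    p = np.asarray(pred, dtype=float)
    t = np.asarray(target, dtype=float)
    wv = w.w if isinstance(w, ReliabilityWeights) else np.asarray(w, dtype=float)
    if p.shape != t.shape or p.shape[-1] != wv.shape[-1]:
        raise ValueError("pred, target and weights must align on the point axis")
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(t))):
        raise ValueError("non-finite inputs to weighted_mse")
    return float(np.mean(wv * (p - t) ** 2))


def _pool_features(vol: np.ndarray, pool: tuple[int, int, int]) -> np.ndarray:
    nx, ny, nz = vol.shape
    px, py, pz = pool
    if nx % px or ny % py or nz % pz:
        raise ValueError(f"volume {vol.shape} not divisible by pool {pool}")
    return (vol.reshape(nx // px, px, ny // py, py, nz // pz, pz)
               .mean(axis=(1, 3, 5)).ravel())


@dataclass
class TrainedRegressor:
    """A trained volume -> 52 dB regressor (pure function at inference)."""

    params: list  # [(W, b), ...] hidden layers then output layer
    feat_mean: np.ndarray
    feat_std: np.ndarray
    target_mean: np.ndarray
    pool_vox: tuple[int, int, int]
    input_shape: tuple[int, int, int]
    config: RegressorConfig
    training_log: list = field(default_factory=list)  # per-epoch dict records

    @property
    def weights_checksum(self) -> str:
        h = hashlib.sha256()
        for W, b in self.params:
            h.update(np.ascontiguousarray(W).tobytes())
            h.update(np.ascontiguousarray(b).tobytes())
        return h.hexdigest()

    def _forward(self, X: np.ndarray) -> np.ndarray:
        A = X
        for W, b in self.params[:-1]:
            A = np.maximum(A @ W + b, 0.0)
        W, b = self.params[-1]
        return A @ W + b + self.target_mean

    def _features(self, vols: np.ndarray) -> np.ndarray:
        F = np.stack([_pool_features(v, self.pool_vox) for v in vols])
        return (F - self.feat_mean) / self.feat_std

    def predict(self, volume) -> np.ndarray:
        """Predict 52 sensitivities (dB) for one volume."""
        vol = volume.intensity if isinstance(volume, ProcessedVolume) else np.asarray(volume)
        if vol.shape != self.input_shape:
            raise ValueError(f"volume shape {vol.shape} != training shape {self.input_shape}")
        out = self._forward(self._features(vol[None]))[0]
        if not np.all(np.isfinite(out)):
            raise RuntimeError("non-finite prediction")
        return out

    def predict_many(self, volumes: np.ndarray) -> np.ndarray:
        vols = np.asarray(volumes)
        if vols.shape[1:] != self.input_shape:
            raise ValueError(f"volume shape {vols.shape[1:]} != training shape {self.input_shape}")
        return self._forward(self._features(vols))


def _init_params(n_in: int, hidden: Sequence[int], rng: np.random.Generator):
    """He-init hidden layers; zero-init output so training starts at the mean."""
    params = []
    prev = n_in
    for h in hidden:
        W = rng.normal(0.0, np.sqrt(2.0 / prev), size=(prev, h))
        params.append((W, np.zeros(h)))
        prev = h
    params.append((np.zeros((prev, N_POINTS)), np.zeros(N_POINTS)))
    return params


def train(pairs: Sequence[tuple[ProcessedVolume, VFTest]],
          config: RegressorConfig,
          w: ReliabilityWeights) -> TrainedRegressor:
    """Train the regressor on (volume, VF) pairs with Adam + step decay.

    The train/validation split is by eye (no leakage of an eye across the
    split).  The training log records per-epoch weighted-MSE training loss,
    learning rate, and validation MAE.
    """
    if not pairs:
        raise ValueError("need at least one training pair")
    rng = np.random.default_rng(config.seed)
    input_shape = pairs[0][0].intensity.shape

    eyes = sorted({v.eye_id for v, _ in pairs})
    perm = rng.permutation(len(eyes))
    n_val = int(round(config.val_fraction * len(eyes)))
    val_eyes = {eyes[i] for i in perm[:n_val]} if n_val else set()

    F = np.stack([_pool_features(v.intensity, config.pool_vox) for v, _ in pairs])
    Y = np.stack([t.sensitivities for _, t in pairs])
    is_val = np.array([v.eye_id in val_eyes for v, _ in pairs])
    Ftr, Ytr = F[~is_val], Y[~is_val]
    Fva, Yva = F[is_val], Y[is_val]
    if len(Ftr) == 0:
        raise ValueError("validation split left no training pairs")

    feat_mean = Ftr.mean(axis=0)
    # one global scale, not per-feature: per-feature standardization would
    # inflate the model's sensitivity to low-variance (uninformative) patches
    # and distort occlusion saliency; a single scale only conditions Adam
    feat_std = np.full(Ftr.shape[1], max(float((Ftr - feat_mean).std()), 1e-6))
    Xtr = (Ftr - feat_mean) / feat_std
    Xva = (Fva - feat_mean) / feat_std if len(Fva) else Fva
    target_mean = Ytr.mean(axis=0)
    wv = w.w

    params = _init_params(Xtr.shape[1], config.hidden, rng)
    # Adam state
    m = [(np.zeros_like(W), np.zeros_like(b)) for W, b in params]
    v = [(np.zeros_like(W), np.zeros_like(b)) for W, b in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    model = TrainedRegressor(params=params, feat_mean=feat_mean, feat_std=feat_std,
                             target_mean=target_mean, pool_vox=config.pool_vox,
                             input_shape=input_shape, config=config)

    n = len(Xtr)
    for epoch in range(config.epochs):
        lr = config.lr_init * config.lr_decay_factor ** (epoch // config.lr_decay_every)
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            Xb, Yb = Xtr[idx], Ytr[idx]

            # forward with caches
            acts = [Xb]
            A = Xb
            for W, b in params[:-1]:
                A = np.maximum(A @ W + b, 0.0)
                acts.append(A)
            Wo, bo = params[-1]
            pred = A @ Wo + bo + target_mean

            err = pred - Yb
            loss = float(np.mean(wv * err ** 2))
            if config.weight_decay:
                loss += config.weight_decay * sum(float((W ** 2).sum()) for W, _ in params)
            if not np.isfinite(loss):
                raise RuntimeError(f"divergent loss at epoch {epoch}")
            epoch_loss += loss * len(idx)

            # backward
            grad_out = 2.0 * wv * err / err.size  # dL/dpred
            grads = [None] * len(params)
            gW = acts[-1].T @ grad_out
            gb = grad_out.sum(axis=0)
            grads[-1] = (gW, gb)
            delta = grad_out @ Wo.T
            for li in range(len(params) - 2, -1, -1):
                delta = delta * (acts[li + 1] > 0)
                grads[li] = (acts[li].T @ delta, delta.sum(axis=0))
                if li > 0:
                    delta = delta @ params[li][0].T

            if config.weight_decay:
                grads = [(gW + 2.0 * config.weight_decay * W, gb)
                         for (gW, gb), (W, _) in zip(grads, params)]

            # Adam update
            step += 1
            for li, ((gW, gb), (W, b)) in enumerate(zip(grads, params)):
                mW, mb = m[li]
                vW, vb = v[li]
                mW = beta1 * mW + (1 - beta1) * gW
                mb = beta1 * mb + (1 - beta1) * gb
                vW = beta2 * vW + (1 - beta2) * gW ** 2
                vb = beta2 * vb + (1 - beta2) * gb ** 2
                m[li], v[li] = (mW, mb), (vW, vb)
                c1 = 1 - beta1 ** step
                c2 = 1 - beta2 ** step
                W_new = W - lr * (mW / c1) / (np.sqrt(vW / c2) + eps)
                b_new = b - lr * (mb / c1) / (np.sqrt(vb / c2) + eps)
                params[li] = (W_new, b_new)

        record = {"epoch": epoch, "lr": lr, "train_loss": epoch_loss / n}
        if len(Xva):
            pred_va = model._forward(Xva)
            record["val_mae"] = float(np.mean(np.abs(pred_va - Yva)))
        model.training_log.append(record)

    return model


def predict(model: TrainedRegressor, volume) -> np.ndarray:
    """Functional alias for model.predict."""
    return model.predict(volume)


def mean_baseline_mae(train_targets: np.ndarray, eval_targets: np.ndarray) -> float:
    """MAE of the cohort-mean predictor (the no-structure baseline)."""
    mean_vf = np.asarray(train_targets).mean(axis=0)
    return float(np.mean(np.abs(np.asarray(eval_targets) - mean_vf)))
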