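"""Training loop: Adam on binary cross-entropy with a warm-up/decay schedule.

The learning rate rises linearly from ``init_lr`` to ``max_lr`` over the
warm-up epochs, then decays exponentially so that it reaches ``final_lr``
exactly at the last scheduled training step (per-step scheduling). After each
epoch the validation AUC is computed; training stops early when it has not
improved for ``patience`` consecutive epochs, and the parameters from the
best-validation epoch are returned. All randomness (parameter init, batch
shuffling, dropout) flows from the single run seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import cmpnn
from .cmpnn import ModelConfig, ConfigurationError
from .evaluation import AUCUndefinedError, trapezoidal_auc
from .molgraph import batch_graphs, smiles_to_graph
from .nn.autodiff import Tensor, bce_with_logits


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization hyperparameters (defaults reproduce the published setup)."""

    epochs: int = 60
    batch_size: int = 50
    warmup_epochs: int = 2
    init_lr: float = 1e-4
    max_lr: float = 1e-3
    final_lr: float = 1e-4
    patience: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.init_lr > self.max_lr or self.final_lr > self.max_lr:
            raise ConfigurationError("init_lr and final_lr must not exceed max_lr")
        if self.patience > self.epochs:
            raise ConfigurationError("patience must not exceed epochs")


def learning_rate(step: int, tc: TrainingConfig, steps_per_epoch: int) -> float:
    """Learning rate at a global batch counter under warm-up + exponential decay."""
    if steps_per_epoch <= 0:
        raise ConfigurationError("steps_per_epoch must be positive")
    warmup_steps = tc.warmup_epochs * steps_per_epoch
    total_steps = tc.epochs * steps_per_epoch
    if step < warmup_steps:
        return tc.init_lr + (tc.max_lr - tc.init_lr) * step / warmup_steps
    last = total_steps - 1
    if last <= warmup_steps:
        return tc.max_lr
    gamma = (tc.final_lr / tc.max_lr) ** (1.0 / (last - warmup_steps))
    return tc.max_lr * gamma ** min(step - warmup_steps, last - warmup_steps)


class Adam:
    """Adam update rule with bias correction."""

    def __init__(self, params: dict[str, Tensor], beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            m_hat = self.m[k] / (1 - self.beta1**self.t)
            v_hat = self.v[k] / (1 - self.beta2**self.t)
            p.data -= lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def _to_graphs(records):
    graphs, labels = [], []
    for r in records:
        graphs.append(smiles_to_graph(r.smiles))
        labels.append(r.label)
    return graphs, np.asarray(labels, dtype=np.float64)


@dataclass
class TrainResult:
    params: dict[str, Tensor]
    config: ModelConfig
    log: pd.DataFrame          # epoch, train_loss, val_auc, lr
    best_epoch: int
    best_val_auc: float


def train(
    train_records,
    val_records,
    mc: ModelConfig | None = None,
    tc: TrainingConfig | None = None,
) -> TrainResult:
    """Fit the message passing network; returns best-validation parameters.

    Both splits must be non-empty and the validation split must contain both
    classes (otherwise validation AUC is undefined).
    """
    mc = mc or ModelConfig()
    tc = tc or TrainingConfig()
    train_graphs, y_train = _to_graphs(train_records)
    val_graphs, y_val = _to_graphs(val_records)
    if len(set(y_val.tolist())) < 2:
        raise AUCUndefinedError("validation split contains a single class")
    if len(set(y_train.tolist())) < 2:
        raise ValueError("training split contains a single class")

    rng = np.random.default_rng(tc.seed)
    params = cmpnn.init_parameters(
        mc, train_graphs[0].atom_feats.shape[1], train_graphs[0].edge_feats.shape[1], rng
    )
    optimizer = Adam(params)
    steps_per_epoch = max(1, math.ceil(len(train_graphs) / tc.batch_size))

    best_auc = -np.inf
    best_epoch = -1
    best_params = cmpnn.parameters_as_arrays(params)
    log_rows = []
    step = 0
    stale = 0
    for epoch in range(tc.epochs):
        order = rng.permutation(len(train_graphs))
        losses = []
        lr = learning_rate(step, tc, steps_per_epoch)
        for start in range(0, len(order), tc.batch_size):
            idx = order[start : start + tc.batch_size]
            batch = batch_graphs([train_graphs[i] for i in idx])
            logits = cmpnn.forward_batch(
                batch, params, mc, dropout_rng=rng if mc.dropout > 0 else None
            )
            loss = bce_with_logits(logits, y_train[idx][:, None])
            if not np.isfinite(loss.data):
                raise DivergenceError(f"non-finite loss at epoch {epoch}")
            optimizer.zero_grad()
            loss.backward()
            lr = learning_rate(step, tc, steps_per_epoch)
            optimizer.step(lr)
            losses.append(float(loss.data))
            step += 1

        val_scores = cmpnn.predict_proba(val_graphs, params, mc, tc.batch_size)
        val_auc = trapezoidal_auc(y_val.astype(int), val_scores)
        log_rows.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(losses)),
                "val_auc": val_auc,
                "lr": lr,
            }
        )
        if val_auc > best_auc:
            best_auc = val_auc
            best_epoch = epoch
            best_params = cmpnn.parameters_as_arrays(params)
            stale = 0
        else:
            stale += 1
            if stale >= tc.patience:
                break

    return TrainResult(
        params=cmpnn.arrays_as_parameters(best_params),
        config=mc,
        log=pd.DataFrame(log_rows),
        best_epoch=best_epoch,
        best_val_auc=float(best_auc),
    )


def save_checkpoint(path, result: TrainResult) -> None:
    """Serialize config + parameters; loading reproduces predictions exactly."""
    arrays = cmpnn.parameters_as_arrays(result.params)
    np.savez(
        path,
        __config__=np.frombuffer(
            json.dumps(asdict(result.config)).encode(), dtype=np.uint8
        ),
        **arrays,
    )


def load_checkpoint(path) -> tuple[dict[str, Tensor], ModelConfig]:
    with np.load(path) as data:
        cfg = json.loads(bytes(data["__config__"]).decode())
        params = {
            k: Tensor(data[k].copy(), requires_grad=True)
            for k in data.files
            if k != "__config__"
        }
    return params, ModelConfig(**cfg)
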