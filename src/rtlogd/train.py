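"""Two-stage training: retention-time pretraining, then logD/logP multitask.

Stage one fits a single-head model to chromatographic retention time with a
SmoothL1 objective — RT is abundant and strongly correlated with
lipophilicity, so the backbone learns broadly useful structure before it
ever sees a distribution coefficient. Stage two widens the model to two
heads (logD, logP) and fine-tunes on the combined lipophilicity data at a
learning rate reduced by ``finetune_lr_factor`` (default 10) to preserve
the pretrained weights. Each molecule contributes loss only for the labels
it actually has: with one label the other head is ignored; with both, the
two task losses are averaged. Early stopping for fine-tuning maximizes the
averaged squared Pearson correlation across the two validation tasks.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor
from .featurize import MolecularGraph, SplitAssignment
from .net import Model, ModelConfig, batch_graphs, build_model, widen_to_multitask

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TaskLabels:
    """Per-molecule lipophilicity labels; missing values simply absent."""

    logd: float | None = None
    logp: float | None = None

    def __post_init__(self) -> None:
        if self.logd is None and self.logp is None:
            raise ValueError("a training molecule needs at least one label")


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-3
    finetune_lr_factor: float = 10.0
    weight_decay: float = 1e-5
    batch_size: int = 128
    max_epochs: int = 100
    patience: int = 20
    smooth_l1_beta: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr <= 0 or self.finetune_lr_factor < 1 or self.patience < 1:
            raise ValueError("require lr > 0, finetune_lr_factor >= 1, patience >= 1")


# ---------------------------------------------------------------------------
# Losses and validation metric
# ---------------------------------------------------------------------------

def smooth_l1(pred: float, target: float, beta: float = 1.0) -> float:
    """SmoothL1: quadratic within beta of the target, linear outside."""
    if not (math.isfinite(pred) and math.isfinite(target)) or beta <= 0:
        raise ValueError("smooth_l1 needs finite inputs and beta > 0")
    d = abs(pred - target)
    return 0.5 * d * d / beta if d < beta else d - 0.5 * beta


def masked_multitask_loss(
    preds: tuple[float, float], labels: TaskLabels, beta: float = 1.0
) -> float:
    """Per-molecule loss: mean SmoothL1 over whichever labels are present."""
    losses = []
    if labels.logd is not None:
        losses.append(smooth_l1(preds[0], labels.logd, beta))
    if labels.logp is not None:
        losses.append(smooth_l1(preds[1], labels.logp, beta))
    return sum(losses) / len(losses)


def _smooth_l1_elementwise(pred: Tensor, target: np.ndarray, beta: float) -> Tensor:
    """Tensor SmoothL1 per element; the quadratic/linear switch is locally
    constant so it enters backprop as a fixed mask (the loss is C^1)."""
    d = pred - Tensor(target)
    absmask = np.sign(d.data)
    quad = (np.abs(d.data) < beta).astype(float)
    d_abs = d * Tensor(absmask)
    return Tensor(quad) * (d * d) * (0.5 / beta) + Tensor(1.0 - quad) * (d_abs - 0.5 * beta)


def _masked_batch_loss(
    preds: Tensor, targets: np.ndarray, mask: np.ndarray, beta: float
) -> Tensor:
    """Batch-mean of per-molecule masked multitask losses.

    ``targets``/``mask`` are (n, n_tasks); masked slots contribute zero
    regardless of their stored value. Per molecule, present-task losses are
    averaged, then averaged over the batch.
    """
    per_task = _smooth_l1_elementwise(preds, targets, beta)
    n_present = mask.sum(axis=1, keepdims=True)
    if (n_present == 0).any():
        raise ValueError("molecule with no labels in batch")
    weights = mask / n_present / mask.shape[0]
    return (per_task * Tensor(weights)).sum()


def avg_squared_pearson(
    preds: np.ndarray, targets: np.ndarray, mask: np.ndarray
) -> float:
    """Mean of squared Pearson r over tasks, each on its labeled molecules.

    Tasks with no labeled molecules at all (e.g. a logD-only dataset) are
    left out of the average; a task with one labeled molecule is an error.
    """
    scores = []
    for t in range(targets.shape[1]):
        sel = mask[:, t].astype(bool)
        if sel.sum() == 0:
            continue
        if sel.sum() < 2:
            raise ValueError(f"task {t}: need >= 2 labeled molecules")
        y, yhat = targets[sel, t], preds[sel, t]
        if y.std() == 0 or yhat.std() == 0:
            raise ValueError(f"task {t}: zero variance, correlation undefined")
        r = float(np.corrcoef(y, yhat)[0, 1])
        scores.append(r * r)
    if not scores:
        raise ValueError("no task has any labeled validation molecules")
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with L2 weight decay folded into the gradient."""

    def __init__(self, params: dict[str, Tensor], lr: float, weight_decay: float = 0.0,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.weight_decay = lr, weight_decay
        self.b1, self.b2, self.eps = betas[0], betas[1], eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# Training loops
# ---------------------------------------------------------------------------

def _snapshot(model: Model) -> dict:
    return {
        "w": {k: t.data.copy() for k, t in model.params.items()},
        "bn": (model.bn_running_mean.copy(), model.bn_running_var.copy()),
    }


def _restore(model: Model, snap: dict) -> None:
    for k, t in model.params.items():
        t.data = snap["w"][k].copy()
    model.bn_running_mean, model.bn_running_var = (
        snap["bn"][0].copy(), snap["bn"][1].copy()
    )


def pretrain_rt(
    graphs: list[MolecularGraph],
    rt_values: np.ndarray,
    model_config: ModelConfig,
    cfg: TrainConfig,
    val_fraction: float = 0.1,
) -> Model:
    """Train the single-head retention-time model; returns the best epoch.

    RT values are standardized internally (the network regresses z-scores;
    the scale is recorded in ``training_meta``). Validation is a seeded
    random split; early stopping minimizes validation SmoothL1 with the
    configured patience, returning the best-so-far model either way.
    """
    if len(graphs) == 0:
        raise ValueError("empty pretraining dataset")
    rt_values = np.asarray(rt_values, dtype=float)
    mu, sd = float(rt_values.mean()), float(rt_values.std() or 1.0)
    y = (rt_values - mu) / sd

    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(graphs))
    n_val = max(1, int(round(val_fraction * len(graphs))))
    val_idx, train_idx = order[:n_val], order[n_val:]

    model = build_model(
        ModelConfig(**{**model_config.__dict__, "n_heads_out": 1}), seed=cfg.seed
    )
    model.training_meta = {"seed": cfg.seed, "rt_mean": mu, "rt_sd": sd}
    opt = Adam(model.params, cfg.lr, cfg.weight_decay)
    val_batch = batch_graphs([graphs[i] for i in val_idx])
    y_val = y[val_idx]

    best = _snapshot(model)
    best_val, best_epoch, stale = np.inf, -1, 0
    for epoch in range(cfg.max_epochs):
        rng.shuffle(train_idx)
        train_loss = 0.0
        for lo in range(0, len(train_idx), cfg.batch_size):
            idx = train_idx[lo : lo + cfg.batch_size]
            batch = batch_graphs([graphs[i] for i in idx])
            model.zero_grad()
            preds = model.forward(batch, training=True, dropout_rng=rng)
            loss = _smooth_l1_elementwise(
                preds.reshape(-1, 1), y[idx].reshape(-1, 1), cfg.smooth_l1_beta
            ).mean()
            loss.backward()
            opt.step()
            train_loss += float(loss.data) * len(idx)
        preds_val = model.forward(val_batch).data.ravel()
        val_loss = float(np.mean([smooth_l1(p, t, cfg.smooth_l1_beta)
                                  for p, t in zip(preds_val, y_val)]))
        logger.info("pretrain epoch=%d train_loss=%.4f val_loss=%.4f",
                    epoch, train_loss / len(train_idx), val_loss)
        if val_loss < best_val - 1e-9:
            best_val, best_epoch, stale = val_loss, epoch, 0
            best = _snapshot(model)
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    else:
        logger.warning("pretraining hit max_epochs=%d without early stop", cfg.max_epochs)
    _restore(model, best)
    model.training_meta.update({"best_epoch": best_epoch, "best_val_loss": best_val})
    return model


def _labels_to_arrays(labels: list[TaskLabels]) -> tuple[np.ndarray, np.ndarray]:
    targets = np.zeros((len(labels), 2))
    mask = np.zeros((len(labels), 2))
    for i, lab in enumerate(labels):
        if lab.logd is not None:
            targets[i, 0], mask[i, 0] = lab.logd, 1.0
        if lab.logp is not None:
            targets[i, 1], mask[i, 1] = lab.logp, 1.0
    return targets, mask


def check_split_leakage(split: SplitAssignment) -> None:
    parts = split.partitions()
    names = list(parts)
    scaff = {k: {split.scaffold_of[i] for i in idx} for k, idx in parts.items()}
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            shared = scaff[names[a]] & scaff[names[b]]
            if shared:
                raise ValueError(
                    f"scaffold leakage between {names[a]} and {names[b]}: {sorted(shared)[:3]}"
                )


def finetune_multitask(
    pretrained: Model | None,
    graphs: list[MolecularGraph],
    labels: list[TaskLabels],
    split: SplitAssignment,
    cfg: TrainConfig,
    model_config: ModelConfig | None = None,
) -> Model:
    """Fine-tune (or train from scratch when ``pretrained`` is None).

    With a pretrained model the backbone weights are transferred, the heads
    are fresh, and the learning rate drops by ``finetune_lr_factor``.
    Early stopping maximizes the averaged squared Pearson correlation over
    the logD and logP validation molecules.
    """
    check_split_leakage(split)
    targets, mask = _labels_to_arrays(labels)

    if pretrained is not None:
        model = widen_to_multitask(pretrained) if pretrained.config.n_heads_out == 1 else pretrained
        lr = cfg.lr / cfg.finetune_lr_factor
    else:
        if model_config is None:
            raise ValueError("model_config required when training from scratch")
        model = build_model(
            ModelConfig(**{**model_config.__dict__, "n_heads_out": 2}), seed=cfg.seed
        )
        lr = cfg.lr
    opt = Adam(model.params, lr, cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed + 1)

    train_idx = np.array(split.train, dtype=np.int64)
    val_idx = np.array(split.valid, dtype=np.int64)
    val_batch = batch_graphs([graphs[i] for i in val_idx])

    best = _snapshot(model)
    best_score, best_epoch, stale = -np.inf, -1, 0
    for epoch in range(cfg.max_epochs):
        rng.shuffle(train_idx)
        for lo in range(0, len(train_idx), cfg.batch_size):
            idx = train_idx[lo : lo + cfg.batch_size]
            batch = batch_graphs([graphs[i] for i in idx])
            model.zero_grad()
            preds = model.forward(batch, training=True, dropout_rng=rng)
            loss = _masked_batch_loss(preds, targets[idx], mask[idx], cfg.smooth_l1_beta)
            loss.backward()
            opt.step()
        preds_val = model.forward(val_batch).data
        score = avg_squared_pearson(preds_val, targets[val_idx], mask[val_idx])
        logger.info("finetune epoch=%d val_avg_r2=%.4f", epoch, score)
        if score > best_score + 1e-9:
            best_score, best_epoch, stale = score, epoch, 0
            best = _snapshot(model)
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    _restore(model, best)
    model.training_meta.update(
        {"seed": cfg.seed, "best_epoch": best_epoch, "best_val_avg_r2": best_score,
         "pretrained": pretrained is not None}
    )
    return model
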