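"""Fine-tuning loop and evaluation metrics.

Trains a :class:`~bactgene.transformer.TransformerClassifier` with AdamW
under a linear warm-up / linear decay learning-rate schedule, minimizing the
two-class cross-entropy

    L = - sum_i y'_i log(y_i),

and evaluates with the standard confusion-matrix metrics

    Accuracy  = (TP + TN) / (TP + TN + FP + FN)
    Precision = TP / (TP + FP)
    Recall    = TP / (TP + FN)
    F1        = 2 * Precision * Recall / (Precision + Recall).

A fixed 0.5 threshold on the positive-class probability defines predicted
labels for metric computation; the annotation pipeline's final TIS call uses
argmax-within-group instead (see :mod:`bactgene.annotate`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .tokenizer import Vocabulary, encode_sequence
from .transformer import TransformerClassifier

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass
class TrainConfig:
    """Optimization hyperparameters.

    ``lr_peak`` defaults to the fine-tuning value 3e-5; training a
    randomly-initialized desk-scale model needs a larger peak (the desk
    presets use 1e-3).
    """

    lr_peak: float = 3e-5
    warmup_fraction: float = 0.1
    batch_size: int = 16
    epochs: int = 3
    seed: int = 0
    weight_decay: float = 0.01
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    #: stop when the epoch-over-epoch eval-F1 gain falls below this;
    #: negative disables early stopping
    early_stop_min_delta: float = 1e-3
    #: restore the parameters of the best-eval-F1 epoch after training
    restore_best: bool = False

    def __post_init__(self) -> None:
        if self.lr_peak <= 0:
            raise ValueError("lr_peak must be positive")
        if not (0 <= self.warmup_fraction < 1):
            raise ValueError("warmup_fraction must be in [0, 1)")


@dataclass(frozen=True)
class MetricReport:
    """Loss plus the four confusion-matrix metrics.

    When a denominator is zero (no predicted positives, or no true
    positives in the data) the affected metric is reported as 0.0 and
    ``degenerate`` names it.
    """

    loss: float
    accuracy: float
    precision: float
    recall: float
    f1: float
    confusion: tuple[int, int, int, int]  # TP, TN, FP, FN
    degenerate: tuple[str, ...] = ()


@dataclass
class ArrayDataset:
    """Tokenized examples as dense id/mask/label arrays."""

    ids: np.ndarray
    mask: np.ndarray
    labels: np.ndarray

    def __len__(self) -> int:
        return len(self.labels)


def examples_to_dataset(examples: Sequence, vocab: Vocabulary, stride: int,
                        max_len: int) -> ArrayDataset:
    """Tokenize examples carrying ``.seq`` and ``.label`` attributes."""
    n = len(examples)
    ids = np.zeros((n, max_len), dtype=np.int64)
    mask = np.zeros((n, max_len), dtype=np.int64)
    labels = np.zeros(n, dtype=np.int64)
    for i, ex in enumerate(examples):
        ts = encode_sequence(ex.seq, vocab, stride, max_len)
        ids[i], mask[i], labels[i] = ts.ids, ts.mask, ex.label
    return ArrayDataset(ids=ids, mask=mask, labels=labels)


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean two-class cross-entropy over a batch.

    ``labels`` may be one-hot (N, 2) or integer class indices (N,).
    Probabilities of zero at the true class are clamped at 1e-12 (logged).
    """
    probs = np.atleast_2d(probs)
    labels = np.asarray(labels)
    if labels.ndim == 1:
        onehot = np.zeros_like(probs)
        onehot[np.arange(len(labels)), labels] = 1.0
    else:
        onehot = labels
    true_p = (probs * onehot).sum(axis=-1)
    n_clamped = int((true_p < _EPS).sum())
    if n_clamped:
        logger.warning("cross_entropy: clamped %d zero probabilities",
                       n_clamped)
    return float(-np.log(np.maximum(true_p, _EPS)).mean())


def lr_schedule(step: int, total_steps: int, cfg: TrainConfig) -> float:
    """Linear 0 -> lr_peak over the warm-up, then linear lr_peak -> 0."""
    if total_steps <= 0:
        raise ValueError("total_steps must be positive")
    if not (0 <= step <= total_steps):
        raise ValueError(f"step {step} outside [0, {total_steps}]")
    warmup = int(round(cfg.warmup_fraction * total_steps))
    if warmup > 0 and step <= warmup:
        return cfg.lr_peak * step / warmup
    if warmup == 0 and step == 0:
        return 0.0
    return cfg.lr_peak * (total_steps - step) / (total_steps - warmup)


def metrics_from_confusion(tp: int, tn: int, fp: int, fn: int,
                           loss: float = 0.0) -> MetricReport:
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("empty confusion matrix")
    degenerate = []
    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        precision, degenerate = 0.0, degenerate + ["precision"]
    if tp + fn > 0:
        recall = tp / (tp + fn)
    else:
        recall, degenerate = 0.0, degenerate + ["recall"]
    if precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1, degenerate = 0.0, degenerate + ["f1"]
    return MetricReport(loss=loss, accuracy=(tp + tn) / total,
                        precision=precision, recall=recall, f1=f1,
                        confusion=(tp, tn, fp, fn),
                        degenerate=tuple(degenerate))


def evaluate(model: TransformerClassifier, dataset: ArrayDataset,
             batch_size: int = 64, threshold: float = 0.5) -> MetricReport:
    """Confusion-matrix metrics of thresholded positive-class probabilities."""
    if len(dataset) == 0:
        raise ValueError("cannot evaluate on an empty dataset")
    p_pos = model.classify_batch(dataset.ids, dataset.mask,
                                 batch_size=batch_size)
    pred = (p_pos >= threshold).astype(int)
    y = dataset.labels
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    probs = np.stack([1 - p_pos, p_pos], axis=1)
    return metrics_from_confusion(tp, tn, fp, fn,
                                  loss=cross_entropy(probs, y))


class AdamW:
    """Decoupled weight-decay Adam over a parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], cfg: TrainConfig):
        self.cfg = cfg
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray], lr: float) -> None:
        cfg = self.cfg
        self.t += 1
        bc1 = 1.0 - cfg.beta1 ** self.t
        bc2 = 1.0 - cfg.beta2 ** self.t
        for k, p in params.items():
            g = grads[k]
            self.m[k] = cfg.beta1 * self.m[k] + (1 - cfg.beta1) * g
            self.v[k] = cfg.beta2 * self.v[k] + (1 - cfg.beta2) * g * g
            update = (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2)
                                          + cfg.adam_eps)
            if p.ndim >= 2:  # decay weight matrices, not biases/LayerNorm
                update = update + cfg.weight_decay * p
            p -= lr * update


def train(model: TransformerClassifier, train_data: ArrayDataset,
          eval_data: Optional[ArrayDataset], cfg: TrainConfig,
          checkpoint_dir: Optional[str | Path] = None
          ) -> tuple[TransformerClassifier, list[MetricReport]]:
    """Fine-tune ``model`` in place; returns it with per-epoch reports.

    Each batch is trimmed to its longest real token count before the
    forward pass (padding carries no information, so this only saves
    compute). Training stops early once the epoch-over-epoch eval-F1 gain
    drops below ``early_stop_min_delta``; a NaN loss aborts with a
    diagnostic. Deterministic under ``cfg.seed``.
    """
    n = len(train_data)
    if n == 0:
        raise ValueError("empty training set")
    steps_per_epoch = int(np.ceil(n / cfg.batch_size))
    total_steps = steps_per_epoch * cfg.epochs
    optimizer = AdamW(model.params, cfg)
    reports: list[MetricReport] = []
    rng = np.random.default_rng(cfg.seed)
    prev_f1 = None
    best_f1 = -1.0
    best_params = None
    step = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        drop_rng = np.random.default_rng(cfg.seed * 100003 + epoch)
        epoch_losses = []
        for b in range(steps_per_epoch):
            sel = order[b * cfg.batch_size:(b + 1) * cfg.batch_size]
            bids, bmask = train_data.ids[sel], train_data.mask[sel]
            y = train_data.labels[sel]
            L = int(bmask.sum(1).max())
            cache = model.forward(bids[:, :L], bmask[:, :L], train=True,
                                  rng=drop_rng)
            probs = cache["probs"]
            loss = cross_entropy(probs, y)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: loss={loss} at epoch {epoch} "
                    f"step {b} (lr={lr_schedule(step, total_steps, cfg):g})")
            epoch_losses.append(loss)
            onehot = np.zeros_like(probs)
            onehot[np.arange(len(y)), y] = 1.0
            dlogits = (probs - onehot) / len(y)
            grads = model.backward(cache, dlogits.astype(probs.dtype))
            step += 1
            optimizer.step(model.params, grads,
                           lr_schedule(step, total_steps, cfg))
        train_loss = float(np.mean(epoch_losses))
        if eval_data is not None and len(eval_data):
            rep = evaluate(model, eval_data, batch_size=cfg.batch_size * 4)
        else:
            rep = MetricReport(loss=train_loss, accuracy=0.0, precision=0.0,
                               recall=0.0, f1=0.0, confusion=(0, 0, 0, 0),
                               degenerate=("no-eval-data",))
        logger.info("epoch %d: train loss %.4f, eval acc %.4f f1 %.4f",
                    epoch, train_loss, rep.accuracy, rep.f1)
        reports.append(rep)
        if checkpoint_dir is not None:
            Path(checkpoint_dir).mkdir(parents=True, exist_ok=True)
            model.save(Path(checkpoint_dir) / f"epoch{epoch}.npz")
        if cfg.restore_best and eval_data is not None and rep.f1 > best_f1:
            best_f1 = rep.f1
            best_params = {k: v.copy() for k, v in model.params.items()}
        if (cfg.early_stop_min_delta >= 0 and eval_data is not None
                and prev_f1 is not None
                and rep.f1 - prev_f1 < cfg.early_stop_min_delta):
            logger.info("early stop at epoch %d (F1 plateau)", epoch)
            break
        prev_f1 = rep.f1 if eval_data is not None else None
    if best_params is not None:
        model.params = best_params
    return model, reports


def seed_sweep(make_model, train_data: ArrayDataset,
               eval_data: ArrayDataset, cfg: TrainConfig,
               seeds: Sequence[int]) -> list[MetricReport]:
    """Re-train from scratch under each seed; returns final epoch reports.

    Useful for probing run-to-run variability (e.g. occasional loss spikes)
    without asserting any particular count.
    """
    out = []
    for s in seeds:
        c = TrainConfig(**{**cfg.__dict__, "seed": s})
        model = make_model(s)
        _, reports = train(model, train_data, eval_data, c)
        out.append(reports[-1])
    return out
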