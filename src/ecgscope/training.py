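"""Optimization loop: Adam, epoch-indexed learning-rate decay, label
smoothing, a joint verification+identification loss, per-epoch
validation, and patience-based early stopping.

The learning rate follows lr(epoch) = 0.000012 * exp(2 - 0.03*epoch)
+ 0.00008: it starts near 1.69e-4 and decays toward the 8e-5 floor.
Targets are smoothed with eps = 0.1 (verification 0.95/0.05; 32-class
identification 0.903125/0.003125).  Training stops when the validation
loss has not improved for 3 consecutive epochs, and the parameters from
the best-validation-loss epoch are returned.

The monitored "combined accuracy" is the arithmetic mean of the
verification TPR, the verification FPR, and the identification accuracy
— FPR enters raw, not as 1-FPR.  That mean is implemented literally
because it is the stated monitoring quantity; a corrected variant
mean(TPR, 1-FPR, accuracy) is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, no_grad
from .dataset import Dataset
from .model import ECGPairClassifier
from .nn import Adam

__all__ = [
    "TrainConfig", "TrainingHistory", "lr_schedule", "smooth_labels",
    "joint_loss", "combined_accuracy", "early_stop", "train",
    "verification_rates",
]

_LOG_EPS = 1e-7


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 512
    steps_per_epoch: int = 256
    max_epochs: int = 200
    adam_beta1: float = 0.9
    adam_beta2: float = 0.98
    adam_eps: float = 1e-9
    label_smoothing_eps: float = 0.1
    early_stop_patience: int = 3
    verification_weight: float = 1.0
    identification_weight: float = 1.0
    #: multiplies lr_schedule; the schedule's base rate is tied to the
    #: full-scale batch of 512, so small-batch desk runs scale it up
    lr_scale: float = 1.0
    grad_clip: float | None = None
    seed: int = 0

    def __post_init__(self):
        if min(self.batch_size, self.steps_per_epoch, self.max_epochs) <= 0:
            raise ValueError("batch_size, steps_per_epoch, max_epochs must be positive")
        if self.early_stop_patience < 1:
            raise ValueError("patience must be >= 1")
        if not 0 <= self.label_smoothing_eps < 1:
            raise ValueError("label_smoothing_eps must be in [0, 1)")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_combined_accuracy: list[float] = field(default_factory=list)
    val_id_accuracy: list[float] = field(default_factory=list)
    val_tpr: list[float] = field(default_factory=list)
    val_fpr: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)
    best_epoch: int = -1            # 0-based index into the lists

    @property
    def epochs_run(self) -> int:
        return len(self.train_loss)


def lr_schedule(epoch: int) -> float:
    """Learning rate for a 0-based epoch index; decays to the 8e-5 floor."""
    if epoch < 0:
        raise ValueError(f"epoch must be >= 0, got {epoch}")
    return 0.000012 * np.exp(2.0 - 0.03 * epoch) + 0.00008


def smooth_labels(target: np.ndarray, eps: float = 0.1,
                  num_classes: int | None = None) -> np.ndarray:
    """Label smoothing.

    Binary mode (num_classes None): 1 -> 1 - eps/2, 0 -> eps/2.
    K-class mode: integer labels -> (N, K) rows with 1 - eps + eps/K at
    the true class and eps/K elsewhere.
    """
    if not 0 <= eps < 1:
        raise ValueError("eps must be in [0, 1)")
    target = np.asarray(target)
    if num_classes is None:
        # formulated so the printed constants come out exact (0.95 / 0.05)
        return np.where(target > 0.5, 1.0 - eps / 2.0, eps / 2.0)
    out = np.full(target.shape + (num_classes,), eps / num_classes)
    np.put_along_axis(out, target.astype(np.intp)[..., None],
                      1.0 - eps * (num_classes - 1) / num_classes, axis=-1)
    return out


def joint_loss(verification_probs: Tensor, id_distribution: Tensor,
               labels: np.ndarray, eps: float = 0.1,
               verification_weight: float = 1.0,
               identification_weight: float = 1.0) -> Tensor:
    """Mean BCE over the h smoothed verification targets plus the
    cross-entropy of the identification distribution against the smoothed
    K-class target, combined with the given weights (default unit)."""
    b, h = verification_probs.shape
    labels = np.asarray(labels)
    ver_target = smooth_labels(
        (labels[:, None] == np.arange(h)[None, :]).astype(np.float64), eps)
    dtype = verification_probs.dtype
    t = Tensor(ver_target.astype(dtype))
    p = verification_probs
    bce = -(t * (p + _LOG_EPS).log()
            + (1.0 - t) * (1.0 - p + _LOG_EPS).log()).mean()
    id_target = Tensor(smooth_labels(labels, eps, num_classes=h).astype(dtype))
    ce = -(id_target * (id_distribution + _LOG_EPS).log()).sum(axis=-1).mean()
    return bce * verification_weight + ce * identification_weight


def combined_accuracy(ver_tpr: float, ver_fpr: float, id_acc: float,
                      corrected: bool = False) -> float:
    """Mean of verification TPR, verification FPR, and identification
    accuracy (the literal monitored quantity); corrected=True replaces
    FPR with 1-FPR so all three terms reward correctness."""
    for v in (ver_tpr, ver_fpr, id_acc):
        if not 0 <= v <= 1:
            raise ValueError("rates must lie in [0, 1]")
    fpr_term = (1.0 - ver_fpr) if corrected else ver_fpr
    return (ver_tpr + fpr_term + id_acc) / 3.0


def early_stop(val_losses: list[float], patience: int) -> tuple[int, bool]:
    """(best 0-based epoch, stop now?) after the last recorded epoch.

    Stops once the loss has not improved for `patience` consecutive
    epochs past the best one.
    """
    best = int(np.argmin(val_losses))
    return best, (len(val_losses) - 1 - best) >= patience


def verification_rates(probs: np.ndarray, labels: np.ndarray,
                       threshold: float = 0.5) -> tuple[float, float]:
    """TPR/FPR of thresholded verification over a batch: the true-label
    position is the genuine claim, every other position an impostor."""
    b, h = probs.shape
    genuine = probs[np.arange(b), labels]
    mask = np.ones_like(probs, dtype=bool)
    mask[np.arange(b), labels] = False
    impostor = probs[mask]
    tpr = float((genuine >= threshold).mean())
    fpr = float((impostor >= threshold).mean())
    return tpr, fpr


def _evaluate(model: ECGPairClassifier, data: Dataset, cfg: TrainConfig,
              batch_size: int = 64) -> dict:
    model.eval()
    losses, id_hits, n_seen = [], 0, 0
    tp = fp = gn = im = 0
    with no_grad():
        for start in range(0, len(data), batch_size):
            stop = min(start + batch_size, len(data))
            ver, dist = model.forward_tensors(data.scope[start:stop],
                                              data.query[start:stop])
            labels = data.labels[start:stop].astype(np.intp)
            loss = joint_loss(ver, dist, labels, cfg.label_smoothing_eps,
                              cfg.verification_weight, cfg.identification_weight)
            losses.append(float(loss.data) * (stop - start))
            n_seen += stop - start
            id_hits += int((dist.data.argmax(axis=1) == labels).sum())
            b = stop - start
            genuine = ver.data[np.arange(b), labels]
            mask = np.ones_like(ver.data, dtype=bool)
            mask[np.arange(b), labels] = False
            impostor = ver.data[mask]
            tp += int((genuine >= 0.5).sum())
            gn += genuine.size
            fp += int((impostor >= 0.5).sum())
            im += impostor.size
    model.train()
    tpr = tp / gn if gn else 0.0
    fpr = fp / im if im else 0.0
    id_acc = id_hits / n_seen
    return {"loss": sum(losses) / n_seen, "id_accuracy": id_acc,
            "tpr": tpr, "fpr": fpr,
            "combined": combined_accuracy(tpr, fpr, id_acc)}


def train(model: ECGPairClassifier, train_data: Dataset, val_data: Dataset,
          cfg: TrainConfig = TrainConfig(),
          log_fn=None) -> tuple[ECGPairClassifier, TrainingHistory]:
    """Optimize `model`; returns it holding the best-validation-loss
    parameters, with the per-epoch history.

    The training dataset is traversed in its stored order and repeated
    when exhausted.  Any overlap between training and validation
    identities (from dataset provenance) is rejected up front.
    """
    if len(train_data) == 0 or len(val_data) == 0:
        raise ValueError("datasets must be non-empty")
    _assert_disjoint_identities(train_data, val_data)
    model.train()
    model.reseed_dropout(cfg.seed + 1)
    optimizer = Adam(model.parameters(), lr=lr_schedule(0),
                     beta1=cfg.adam_beta1, beta2=cfg.adam_beta2,
                     eps=cfg.adam_eps)
    history = TrainingHistory()
    best_state: dict | None = None
    cursor = 0
    n = len(train_data)
    for epoch in range(cfg.max_epochs):
        lr = lr_schedule(epoch) * cfg.lr_scale
        optimizer.lr = lr
        epoch_losses = []
        for _ in range(cfg.steps_per_epoch):
            idx = (cursor + np.arange(cfg.batch_size)) % n
            cursor = (cursor + cfg.batch_size) % n
            ver, dist = model.forward_tensors(train_data.scope[idx],
                                              train_data.query[idx])
            loss = joint_loss(ver, dist, train_data.labels[idx].astype(np.intp),
                              cfg.label_smoothing_eps,
                              cfg.verification_weight, cfg.identification_weight)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} "
                    f"(last finite losses: {epoch_losses[-3:]})")
            optimizer.zero_grad()
            loss.backward()
            if cfg.grad_clip is not None:
                _clip_gradients(model, cfg.grad_clip)
            optimizer.step()
            epoch_losses.append(float(loss.data))
        metrics = _evaluate(model, val_data, cfg)
        history.train_loss.append(float(np.mean(epoch_losses)))
        history.val_loss.append(metrics["loss"])
        history.val_combined_accuracy.append(metrics["combined"])
        history.val_id_accuracy.append(metrics["id_accuracy"])
        history.val_tpr.append(metrics["tpr"])
        history.val_fpr.append(metrics["fpr"])
        history.learning_rate.append(lr)
        if log_fn is not None:
            log_fn({"epoch": epoch, "lr": lr,
                    "train_loss": history.train_loss[-1], **metrics})
        best, stop = early_stop(history.val_loss, cfg.early_stop_patience)
        if best == epoch:
            best_state = model.state_dict()
        if stop:
            break
    history.best_epoch = int(np.argmin(history.val_loss))
    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return model, history


def _assert_disjoint_identities(train_data: Dataset, val_data: Dataset) -> None:
    def idents(ds: Dataset) -> set[str]:
        out = set()
        for ex in ds.provenance:
            out.update(ref[1] for ref in ex["scope"])
            out.add(ex["query"][1])
        return out

    common = idents(train_data) & idents(val_data)
    if common:
        raise ValueError(
            f"training and validation identities overlap: {sorted(common)[:5]}")


def _clip_gradients(model: ECGPairClassifier, max_norm: float) -> None:
    total = 0.0
    grads = [p.grad for p in model.parameters() if p.grad is not None]
    for g in grads:
        total += float((g * g).sum())
    norm = np.sqrt(total)
    if norm > max_norm:
        scale = max_norm / (norm + 1e-12)
        for g in grads:
            g *= scale
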