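"""Training loop, optimizer, and checkpoint round-trips for the
subsequence classifiers."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .layers import Param, softmax
from .losses import bce_loss, reconstruction_loss, total_loss
from .models import AutoEncoder3D, BaseModel, ClassifierSpec, build_model

logger = logging.getLogger(__name__)


@dataclass
class LabeledWindowSet:
    """Binary-labeled (ns, 48, 48) windows: 1 = blink, 0 = no blink."""

    windows: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int64).reshape(-1)
        if self.windows.ndim != 4:
            raise ValueError("windows must have shape (n, ns, H, W)")
        if len(self.windows) != len(self.labels):
            raise ValueError("window and label counts differ")

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())


@dataclass
class TrainingConfig:
    """Optimization settings (adaptive-moment gradient descent)."""

    epochs: int = 30
    batch_size: int = 16
    learning_rate: float = 1e-3
    rng_seed: int = 0
    validation_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 <= self.validation_fraction < 1:
            raise ValueError("validation_fraction must lie in [0, 1)")


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _batch_losses(model: BaseModel, x: np.ndarray, labels: np.ndarray,
                  train: bool) -> tuple[float, np.ndarray, tuple]:
    """Forward pass; returns (objective, dlogits, extras for backward)."""
    onehot = np.zeros((len(labels), 2), dtype=np.float32)
    onehot[np.arange(len(labels)), labels] = 1.0
    if isinstance(model, AutoEncoder3D):
        logits, recon = model.forward_full(x, train=train)
        probs = softmax(logits)
        l_cls = bce_loss(probs[:, 1], labels)
        raw = x  # reconstruction targets stay on the raw 0-255 scale
        l_rec = reconstruction_loss(raw, recon)
        w_cls, w_rec = model.spec.loss_weights
        dlogits = w_cls * (probs - onehot) / len(labels)
        drecon = (w_rec * 2.0 * (recon - raw) / recon.size).astype(np.float32)
        return total_loss(l_cls, l_rec, model.spec.loss_weights), dlogits, (drecon,)
    logits = model.forward(x, train=train)
    probs = softmax(logits)
    l_cls = bce_loss(probs[:, 1], labels)
    dlogits = (probs - onehot) / len(labels)
    return l_cls, dlogits, ()


def evaluate_loss(model: BaseModel, data: LabeledWindowSet,
                  batch_size: int = 16) -> float:
    """Mean objective over a dataset without updating weights."""
    losses, weights = [], []
    for lo in range(0, len(data), batch_size):
        x = data.windows[lo : lo + batch_size][:, None]
        y = data.labels[lo : lo + batch_size]
        loss, _, _ = _batch_losses(model, x, y, train=False)
        losses.append(loss)
        weights.append(len(y))
    return float(np.average(losses, weights=weights))


def train_classifier(
    model: BaseModel | ClassifierSpec,
    data: LabeledWindowSet,
    cfg: TrainingConfig | None = None,
) -> tuple[BaseModel, dict]:
    """Train a classifier; returns (model, history).

    The autoencoder optimizes the weighted classification +
    reconstruction objective; the other architectures plain binary
    cross-entropy. ``history`` holds per-epoch mean training loss and
    validation loss. Fully deterministic given ``cfg.rng_seed`` (which
    also reseeds the model's dropout masks).
    """
    if cfg is None:
        cfg = TrainingConfig()
    if isinstance(model, ClassifierSpec):
        model = build_model(model)
    classes = np.unique(data.labels)
    if len(classes) < 2:
        raise ValueError(
            f"training data contains a single class ({classes.tolist()}); "
            "both blink and no-blink windows are required"
        )
    rng = np.random.default_rng(cfg.rng_seed)
    model.reseed_dropout(int(rng.integers(2**31)))

    order = rng.permutation(len(data))
    n_val = int(round(cfg.validation_fraction * len(data)))
    val_idx, train_idx = order[:n_val], order[n_val:]
    train_set = LabeledWindowSet(data.windows[train_idx], data.labels[train_idx])
    val_set = (
        LabeledWindowSet(data.windows[val_idx], data.labels[val_idx])
        if n_val
        else None
    )

    opt = Adam(model.params(), lr=cfg.learning_rate)
    history: dict = {"train_loss": [], "val_loss": []}
    for epoch in range(cfg.epochs):
        perm = rng.permutation(len(train_set))
        epoch_losses, epoch_sizes = [], []
        for lo in range(0, len(perm), cfg.batch_size):
            sel = perm[lo : lo + cfg.batch_size]
            x = train_set.windows[sel][:, None]
            y = train_set.labels[sel]
            model.zero_grad()
            loss, dlogits, extras = _batch_losses(model, x, y, train=True)
            model.backward(dlogits, *extras)
            opt.step()
            epoch_losses.append(loss)
            epoch_sizes.append(len(y))
        history["train_loss"].append(
            float(np.average(epoch_losses, weights=epoch_sizes))
        )
        if val_set is not None:
            history["val_loss"].append(evaluate_loss(model, val_set))
        logger.info(
            "epoch %d/%d: train loss %.4f%s",
            epoch + 1, cfg.epochs, history["train_loss"][-1],
            f", val loss {history['val_loss'][-1]:.4f}" if val_set else "",
        )
    return model, history


def window_accuracy(model: BaseModel, data: LabeledWindowSet,
                    cutoff: float = 0.5) -> float:
    """Fraction of windows classified correctly at the probability cutoff."""
    probs = model.predict_proba(data.windows)
    return float(((probs >= cutoff).astype(int) == data.labels).mean())


def save_checkpoint(model: BaseModel, path: str | Path) -> None:
    """Write weights (.npz) plus a YAML architecture manifest alongside."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    arrays = {f"p{i}": p.value for i, p in enumerate(model.params())}
    np.savez(path, **arrays)
    spec = model.spec
    manifest = {
        "architecture": spec.architecture,
        "ns": spec.ns,
        "latent_units": spec.latent_units,
        "dropout_rate": spec.dropout_rate,
        "loss_weights": list(spec.loss_weights),
        "head_units": list(spec.head_units),
        "rng_seed": spec.rng_seed,
        "n_params": model.n_params(),
    }
    manifest_path = path.with_suffix(path.suffix + ".yaml")
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=False))


def load_checkpoint(path: str | Path) -> BaseModel:
    """Rebuild a model from a checkpoint written by :func:`save_checkpoint`."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    manifest_path = path.with_suffix(path.suffix + ".yaml")
    if not manifest_path.exists():
        raise FileNotFoundError(f"missing architecture manifest {manifest_path}")
    manifest = yaml.safe_load(manifest_path.read_text())
    spec = ClassifierSpec(
        architecture=manifest["architecture"],
        ns=manifest["ns"],
        latent_units=manifest["latent_units"],
        dropout_rate=manifest["dropout_rate"],
        loss_weights=tuple(manifest["loss_weights"]),
        head_units=tuple(manifest["head_units"]),
        rng_seed=manifest.get("rng_seed", 0),
    )
    model = build_model(spec)
    with np.load(path) as archive:
        params = model.params()
        if len(archive.files) != len(params):
            raise ValueError(
                f"checkpoint has {len(archive.files)} arrays, model expects "
                f"{len(params)}"
            )
        for i, p in enumerate(params):
            value = archive[f"p{i}"]
            if value.shape != p.value.shape:
                raise ValueError(
                    f"parameter {i} shape mismatch: checkpoint "
                    f"{value.shape} vs model {p.value.shape}"
                )
            p.value[:] = value
    return model
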