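"""Training objectives: binary cross-entropy, reconstruction MSE, and
their weighted combination used by the autoencoder classifier."""

from __future__ import annotations

import numpy as np

EPS = 1e-7


def bce_loss(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean binary cross-entropy -[t log p + (1-t) log(1-p)].

    ``probs`` are blink probabilities, ``labels`` binary targets;
    probabilities are clamped to [EPS, 1-EPS] before taking logs.
    """
    probs = np.asarray(probs, dtype=np.float64).reshape(-1)
    labels = np.asarray(labels, dtype=np.float64).reshape(-1)
    if probs.shape != labels.shape:
        raise ValueError(
            f"probs and labels differ in length: {probs.shape} vs {labels.shape}"
        )
    p = np.clip(probs, EPS, 1.0 - EPS)
    return float(-np.mean(labels * np.log(p) + (1.0 - labels) * np.log(1.0 - p)))


def reconstruction_loss(inputs: np.ndarray, reconstructions: np.ndarray) -> float:
    """Mean squared error over all voxels of all windows."""
    inputs = np.asarray(inputs, dtype=np.float64)
    reconstructions = np.asarray(reconstructions, dtype=np.float64)
    if inputs.shape != reconstructions.shape:
        raise ValueError(
            f"shape mismatch: {inputs.shape} vs {reconstructions.shape}"
        )
    return float(np.mean((inputs - reconstructions) ** 2))


def total_loss(
    l_cls: float, l_rec: float, weights: tuple[float, float] = (0.9, 0.1)
) -> float:
    """Weighted sum ``w_cls * l_cls + w_rec * l_rec``.

    The default (0.9, 0.1) weights the classification branch far above
    reconstruction; equal weights make the reconstruction term converge
    first and starve the classifier.
    """
    w_cls, w_rec = weights
    return w_cls * l_cls + w_rec * l_rec
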