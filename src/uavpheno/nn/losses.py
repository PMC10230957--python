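"""Losses returning (scalar loss, gradient w.r.t. the first argument)."""

from __future__ import annotations

import numpy as np


def softmax_cross_entropy(logits: np.ndarray, onehot: np.ndarray):
    """Categorical cross entropy over per-pixel class logits.

    ``logits`` and ``onehot`` are (N, K, H, W); the loss is averaged over
    all pixels of the batch.
    """
    if logits.shape != onehot.shape:
        raise ValueError(f"shape mismatch {logits.shape} vs {onehot.shape}")
    m = logits.max(axis=1, keepdims=True)
    e = np.exp(logits - m)
    p = e / e.sum(axis=1, keepdims=True)
    n_pix = logits.shape[0] * logits.shape[2] * logits.shape[3]
    loss = float(-(onehot * np.log(p + 1e-12)).sum() / n_pix)
    grad = (p - onehot) / n_pix
    return loss, grad.astype(logits.dtype)


def mse_loss(pred: np.ndarray, target: np.ndarray):
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {target.shape}")
    diff = pred - target
    loss = float(np.mean(diff * diff))
    grad = (2.0 / diff.size) * diff
    return loss, grad.astype(pred.dtype)


def bce_with_logits(logits: np.ndarray, targets: np.ndarray):
    """Numerically stable binary cross entropy on raw logits (1-D)."""
    logits = np.asarray(logits, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.float64)
    # log(1 + e^x) without overflow
    softplus = np.where(logits > 0, logits + np.log1p(np.exp(-logits)),
                        np.log1p(np.exp(logits)))
    loss = float(np.mean(softplus - targets * logits))
    p = 1.0 / (1.0 + np.exp(-logits))
    grad = (p - targets) / logits.size
    return loss, grad
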