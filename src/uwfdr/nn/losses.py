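"""Loss functions with analytic gradients."""
from __future__ import annotations

from typing import Optional, Tuple

import numpy as np


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out.astype(z.dtype)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def weighted_cross_entropy(logits: np.ndarray, labels: np.ndarray,
                           class_weights: Optional[np.ndarray] = None,
                           ) -> Tuple[float, np.ndarray]:
    """Class-weighted softmax cross-entropy; returns (mean loss, dL/dlogits)."""
    n, k = logits.shape
    p = softmax(logits.astype(np.float64))
    if class_weights is None:
        class_weights = np.ones(k)
    wn = np.asarray(class_weights, dtype=np.float64)[labels]
    logp = np.log(np.clip(p[np.arange(n), labels], 1e-12, None))
    wsum = wn.sum()
    loss = float(-(wn * logp).sum() / wsum)
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    grad *= (wn / wsum)[:, None]
    return loss, grad.astype(np.float32)


def dice_loss_grad(logits: np.ndarray, truth: np.ndarray, eps: float = 1e-6,
                   ) -> Tuple[float, np.ndarray]:
    """Soft dice loss on sigmoid probabilities; returns (loss, dL/dlogits).

    ``loss = 1 - (2 sum(p t) + eps) / (sum(p) + sum(t) + eps)`` computed over
    the whole batch.
    """
    if logits.shape != truth.shape:
        raise ValueError(f"shape mismatch: {logits.shape} vs {truth.shape}")
    p = sigmoid(logits.astype(np.float64))
    t = truth.astype(np.float64)
    inter = (p * t).sum()
    denom = p.sum() + t.sum() + eps
    loss = 1.0 - (2.0 * inter + eps) / denom
    # d/dp of -(2 sum(pt)+eps)/denom
    dp = -(2.0 * t * denom - (2.0 * inter + eps)) / denom ** 2
    dz = dp * p * (1.0 - p)
    return float(loss), dz.astype(np.float32)
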