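"""Masked per-pixel cross-entropy for the three tissue classes.

Background (label 0) and any pixel outside the tissue mask are excluded:
they carry no annotation, so they contribute neither to the loss value nor
to its gradient.
"""

from __future__ import annotations

import numpy as np

__all__ = ["softmax", "masked_cross_entropy"]


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def masked_cross_entropy(
    logits: np.ndarray,
    labels: np.ndarray,
    mask: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over valid pixels and its gradient wrt the logits.

    logits: (B, K, H, W) scores for tissue classes 1..K (class k at index
    k-1); labels: (B, H, W) in {0..K}; mask: optional (B, H, W) tissue mask.
    Valid pixels are those inside the mask with a tissue label.
    """
    b, k, h, w = logits.shape
    valid = (labels >= 1) & (labels <= k)
    if mask is not None:
        valid &= mask.astype(bool)
    n = int(valid.sum())
    if n == 0:
        return 0.0, np.zeros_like(logits, dtype=np.float32)
    p = softmax(logits.astype(np.float64), axis=1)
    target = np.zeros_like(p)
    lab0 = np.where(valid, labels - 1, 0)
    np.put_along_axis(target, lab0[:, None], 1.0, axis=1)
    vm = valid[:, None].astype(np.float64)
    eps = 1e-12
    loss = -(target * np.log(p + eps) * vm).sum() / n
    grad = ((p - target) * vm / n).astype(np.float32)
    return float(loss), grad
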