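"""Softmax and the composite cross-entropy + soft-Dice segmentation loss."""

from __future__ import annotations

import numpy as np


def softmax(logits: np.ndarray) -> np.ndarray:
    """Channel-axis softmax for a (C, D, H, W) logit tensor."""
    z = logits - logits.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((n_classes,) + labels.shape, dtype=np.float32)
    for c in range(n_classes):
        out[c] = labels == c
    return out


def soft_dice_per_class(probs, target_onehot, foreground_only=True, eps=1e-6):
    """Soft Dice coefficient per class from probabilities and one-hot target."""
    c0 = 1 if foreground_only else 0
    p = probs[c0:].reshape(probs.shape[0] - c0, -1)
    t = target_onehot[c0:].reshape(p.shape)
    num = 2.0 * (p * t).sum(axis=1) + eps
    den = p.sum(axis=1) + t.sum(axis=1) + eps
    return num / den


def composite_loss_and_grad(logits, labels, class_weights=None, dice_weight=1.0):
    """Cross-entropy plus soft-Dice loss, with the gradient w.r.t. the logits.

    Cross-entropy is the voxel mean (optionally class-weighted by the target
    class); the Dice term is ``1 - mean`` soft Dice over foreground classes.

    Returns
    -------
    loss : float
    dlogits : ndarray, same shape as logits
    parts : dict with 'ce', 'dice_loss' and per-class 'soft_dice'
    """
    n_classes = logits.shape[0]
    probs = softmax(logits.astype(np.float64))
    t = one_hot(labels, n_classes).astype(np.float64)

    # --- cross-entropy ---
    if class_weights is None:
        w_vox = np.ones(labels.shape, dtype=np.float64)
    else:
        w = np.asarray(class_weights, dtype=np.float64)
        w_vox = w[labels]
    wsum = w_vox.sum()
    p_true = np.clip((probs * t).sum(axis=0), 1e-12, None)
    ce = float(-(w_vox * np.log(p_true)).sum() / wsum)
    dce_dz = w_vox[None] * (probs - t) / wsum

    # --- soft Dice over foreground classes ---
    nf = n_classes - 1
    pf = probs[1:].reshape(nf, -1)
    tf = t[1:].reshape(nf, -1)
    eps = 1e-6
    num = 2.0 * (pf * tf).sum(axis=1) + eps
    den = pf.sum(axis=1) + tf.sum(axis=1) + eps
    dice = num / den
    dice_loss = float(1.0 - dice.mean())
    # d(dice_c)/d(p_c(v)) = (2 t - dice) / den ; loss contributes -1/nf of it
    dldp = np.zeros_like(probs).reshape(n_classes, -1)
    dldp[1:] = -(2.0 * tf - dice[:, None]) / den[:, None] / nf
    # chain through softmax: dz_c = p_c * (g_c - sum_k p_k g_k)
    pflat = probs.reshape(n_classes, -1)
    inner = (pflat * dldp).sum(axis=0, keepdims=True)
    ddice_dz = (pflat * (dldp - inner)).reshape(probs.shape)

    loss = ce + dice_weight * dice_loss
    dlogits = (dce_dz + dice_weight * ddice_dz).astype(np.float32)
    parts = {"ce": ce, "dice_loss": dice_loss, "soft_dice": dice}
    return loss, dlogits, parts
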