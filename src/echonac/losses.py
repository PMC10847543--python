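"""Hybrid segmentation loss: region terms (BCE + Dice) and boundary terms
(active-contour + Hausdorff-distance surrogate).

Every term accepts either plain numpy arrays (returning a float, for
evaluation and testing) or autodiff :class:`~echonac.nn.Tensor` probability
maps (returning a Tensor, for training).  All terms reduce by the mean over
pixels (and over the batch), so values are comparable across resolutions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .nn import Tensor

BCE_EPS = 1e-7
_AC_EPS = 1e-8


@dataclass(frozen=True)
class LossWeights:
    """Non-negative weights of the four hybrid-loss terms."""

    w_bce: float = 1.0
    w_dice: float = 1.0
    w_ac: float = 0.5
    w_hd: float = 0.05

    def __post_init__(self):
        vals = (self.w_bce, self.w_dice, self.w_ac, self.w_hd)
        if any(v < 0 for v in vals):
            raise ValueError("loss weights must be non-negative")
        if not any(v > 0 for v in vals):
            raise ValueError("at least one loss weight must be positive")


def _prepare(prob, truth):
    """Validate shapes; return (Tensor prob, ndarray truth, was_array)."""
    was_array = not isinstance(prob, Tensor)
    p = Tensor(np.asarray(prob, dtype=np.float64)) if was_array else prob
    t = np.asarray(truth.data if isinstance(truth, Tensor) else truth, dtype=p.data.dtype)
    if p.data.shape != t.shape:
        raise ValueError(f"shape mismatch: prob {p.data.shape} vs truth {t.shape}")
    return p, t, was_array


def _ret(loss: Tensor, was_array: bool):
    return float(loss.data) if was_array else loss


def bce_loss(prob, truth):
    """Mean per-pixel binary cross-entropy, probabilities clipped to
    [eps, 1-eps] with eps=1e-7."""
    p, t, was_array = _prepare(prob, truth)
    pc = p.clip(BCE_EPS, 1.0 - BCE_EPS)
    loss = -(Tensor(t) * pc.log() + Tensor(1.0 - t) * (1.0 - pc).log()).mean()
    return _ret(loss, was_array)


def dice_loss(prob, truth, smooth: float = 1.0):
    """Soft Dice loss: 1 - (2*sum(p*t)+s) / (sum(p)+sum(t)+s)."""
    if smooth < 0:
        raise ValueError("smooth must be >= 0")
    p, t, was_array = _prepare(prob, truth)
    inter = (p * Tensor(t)).sum()
    denom = p.sum() + float(t.sum()) + smooth
    loss = 1.0 - (inter * 2.0 + smooth) / denom
    return _ret(loss, was_array)


def active_contour_loss(prob, truth, lambda_region: float = 1.0):
    """Chan-Vese-style boundary loss: mean forward-difference gradient
    magnitude of the probability map (length term) plus ``lambda_region``
    times the binary region-fit term with region constants c1=1, c2=0."""
    p, t, was_array = _prepare(prob, truth)
    # forward differences along the two trailing (spatial) axes
    nd = p.data.ndim
    row = [slice(None)] * nd
    col = [slice(None)] * nd
    row_hi, row_lo = row.copy(), row.copy()
    row_hi[nd - 2], row_lo[nd - 2] = slice(1, None), slice(None, -1)
    col_hi, col_lo = col.copy(), col.copy()
    col_hi[nd - 1], col_lo[nd - 1] = slice(1, None), slice(None, -1)
    dr = p[tuple(row_hi)] - p[tuple(row_lo)]
    dc = p[tuple(col_hi)] - p[tuple(col_lo)]
    # crop to the common (H-1, W-1) grid
    crop_r = [slice(None)] * nd
    crop_r[nd - 1] = slice(None, -1)
    crop_c = [slice(None)] * nd
    crop_c[nd - 2] = slice(None, -1)
    length = ((dr[tuple(crop_r)] ** 2 + dc[tuple(crop_c)] ** 2 + _AC_EPS) ** 0.5).mean()
    region = (p * Tensor((t - 1.0) ** 2) + (1.0 - p) * Tensor(t**2)).mean()
    loss = length + lambda_region * region
    return _ret(loss, was_array)


def _boundary_distance(mask: np.ndarray) -> np.ndarray:
    """Unsigned Euclidean distance to the foreground boundary; zero map for an
    empty mask (no boundary exists)."""
    fg = mask > 0.5
    if not fg.any() or fg.all():
        return np.zeros(mask.shape)  # no boundary exists
    inside = ndimage.distance_transform_edt(fg)
    outside = ndimage.distance_transform_edt(~fg)
    return inside + outside


def hausdorff_distance_loss(prob, truth, alpha: float = 2.0):
    """Distance-transform surrogate of the Hausdorff distance.

    mean over pixels of (p - t)^2 * (d_truth^alpha + d_pred^alpha), where
    d_* are unsigned distance transforms to the truth boundary and to the
    boundary of the thresholded prediction.  The distance maps are treated
    as constants, so the gradient flows through the squared disagreement.
    Zero when prediction equals truth; zero by convention when both are empty.
    """
    p, t, was_array = _prepare(prob, truth)
    pb = p.data >= 0.5
    if p.data.ndim == 2:
        weight = _boundary_distance(t) ** alpha + _boundary_distance(pb) ** alpha
    else:  # batched (..., H, W): per-plane transforms
        flat_t = t.reshape(-1, *t.shape[-2:])
        flat_p = pb.reshape(-1, *t.shape[-2:])
        weight = np.stack([
            _boundary_distance(ti) ** alpha + _boundary_distance(pi) ** alpha
            for ti, pi in zip(flat_t, flat_p)
        ]).reshape(t.shape)
    loss = ((p - Tensor(t)) ** 2 * Tensor(weight.astype(p.data.dtype))).mean()
    return _ret(loss, was_array)


def hybrid_loss(prob, truth, weights: LossWeights = LossWeights(),
                smooth: float = 1.0, lambda_region: float = 1.0,
                alpha: float = 2.0):
    """Weighted sum of BCE, Dice, active-contour and Hausdorff terms."""
    total = None
    for w, term in (
        (weights.w_bce, lambda: bce_loss(prob, truth)),
        (weights.w_dice, lambda: dice_loss(prob, truth, smooth)),
        (weights.w_ac, lambda: active_contour_loss(prob, truth, lambda_region)),
        (weights.w_hd, lambda: hausdorff_distance_loss(prob, truth, alpha)),
    ):
        if w > 0:
            piece = term() * w
            total = piece if total is None else total + piece
    return total
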