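"""Spatial-aware semantic refinement: polar-coordinate structure losses.

Fine-grained specimens such as *Cordyceps sinensis* have parts (head, eyes,
dorsal rings, leg groups) arranged along a body axis.  This module supervises
a backbone feature map to encode that layout: every spatial cell of an
``N x N`` feature grid is assigned polar coordinates ``(r, theta)`` relative
to the maximum-response reference cell, a small shared head predicts those
coordinates from the features, and two mask-weighted losses penalise

* radial error  — ``L_d``, the weighted mean squared error of ``r``, and
* angular error — ``L_a``, the weighted *variance* of the wrapped angle
  difference, which is invariant to a global rotation of the prediction.

Polar rather than Cartesian targets make the supervision robust to the
rotations and flips under which the specimens are photographed.

Coordinates are 0-based and row-major; ``(x, y)`` means (row, column).
Radial distances are normalised by the grid diagonal ``N * sqrt(2)`` so that
``r`` is in ``[0, 1]``; angles are mapped from ``atan2`` range to ``[0, 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor, concatenate
from .nn import Linear, Module

__all__ = [
    "SSRMLossParts", "compute_object_mask", "select_reference",
    "polar_targets", "PolarHead", "distance_loss", "angle_loss",
    "ssrm_image_loss", "ssrm_loss",
]

_EPS = 1e-12


@dataclass(frozen=True)
class SSRMLossParts:
    """Distance, angle and combined refinement losses (autodiff scalars)."""

    L_d: Tensor
    L_a: Tensor

    @property
    def L_ssrm(self) -> Tensor:
        return self.L_d + self.L_a


def compute_object_mask(f) -> np.ndarray:
    """Object-extent mask from a ``(C, H, W)`` feature map.

    Rectified channel mean, min–max normalised to ``[0, 1]``.  A degenerate
    (all-zero or constant) map falls back to the uniform mask so downstream
    weighted means stay defined.  The mask is a plain array: it weights the
    losses but deliberately receives no gradient.
    """
    arr = f.data if isinstance(f, Tensor) else np.asarray(f, dtype=float)
    if arr.ndim != 3:
        raise ValueError(f"expected (C, H, W) feature map, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("feature map contains non-finite values")
    m = np.maximum(arr.mean(axis=0), 0.0)
    lo, hi = m.min(), m.max()
    if hi - lo < _EPS:
        return np.full(m.shape, 1.0 / m.size)
    return (m - lo) / (hi - lo)


def select_reference(mask: np.ndarray) -> tuple[int, int]:
    """Cell of maximum mask response; ties go to smallest row, then column."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-d")
    x, y = np.unravel_index(int(np.argmax(mask)), mask.shape)
    return int(x), int(y)


def polar_targets(ref: tuple[int, int], n: int) -> tuple[np.ndarray, np.ndarray]:
    """Target polar grids ``(r, theta)`` of every cell about ``ref``.

    ``r[i, j] = sqrt((x-i)^2 + (y-j)^2) / (n*sqrt(2))`` (diagonal-normalised,
    hence in ``[0, 1]``); ``theta[i, j] = (atan2(y-j, x-i) + pi) / (2*pi)``
    wrapped into ``[0, 1)``.  The reference cell itself carries ``r = 0`` and
    ``theta = 0`` by convention.
    """
    x, y = ref
    if not (0 <= x < n and 0 <= y < n):
        raise ValueError(f"reference {ref} outside {n}x{n} grid")
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    dx = x - ii
    dy = y - jj
    r = np.sqrt(dx**2 + dy**2) / (n * np.sqrt(2.0))
    theta = np.mod((np.arctan2(dy, dx) + np.pi) / (2.0 * np.pi), 1.0)
    theta[x, y] = 0.0
    return r, theta


class PolarHead(Module):
    """Shared per-cell regressor of ``(r', theta')`` from refined features.

    For every grid cell the head sees the 2C vector formed by concatenating
    that cell's feature column with the reference cell's column, applies one
    shared affine map to two outputs and squashes them with a logistic
    sigmoid so predictions live in ``[0, 1]`` like the targets.
    """

    def __init__(self, channels: int, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        self.channels = channels
        self.fc = Linear(2 * channels, 2, rng=rng, dtype=dtype)

    def __call__(self, h: Tensor, ref: tuple[int, int]) -> tuple[Tensor, Tensor]:
        h = as_tensor(h)
        c, height, width = h.shape
        if c != self.channels:
            raise ValueError(f"head built for C={self.channels}, got C={c}")
        x, y = ref
        if not (0 <= x < height and 0 <= y < width):
            raise ValueError(f"reference {ref} outside {height}x{width} grid")
        flat = h.reshape(c, height * width)                    # (C, N^2)
        ref_col = flat[:, x * width + y].reshape(c, 1)
        ref_mat = ref_col * np.ones((1, height * width), dtype=h.dtype)
        stacked = concatenate([flat, ref_mat], axis=0)          # (2C, N^2)
        out = self.fc(stacked.T).sigmoid()                      # (N^2, 2)
        r_pred = out[:, 0].reshape(height, width)
        theta_pred = out[:, 1].reshape(height, width)
        return r_pred, theta_pred

    def forward_batch(self, h: Tensor, refs) -> tuple[Tensor, Tensor]:
        """Vectorised head over a batch: ``h`` is ``(B, C, N, N)``, ``refs``
        one reference cell per image.  Same math as calling the head image
        by image."""
        h = as_tensor(h)
        b, c, height, width = h.shape
        if c != self.channels:
            raise ValueError(f"head built for C={self.channels}, got C={c}")
        p = height * width
        flat = h.reshape(b, c, p)
        idx = np.array([x * width + y for x, y in refs])
        ref_cols = flat[np.arange(b), :, idx].reshape(b, c, 1)   # (B, C, 1)
        ref_mat = ref_cols * np.ones((1, 1, p), dtype=h.dtype)
        stacked = concatenate([flat, ref_mat], axis=1)           # (B, 2C, P)
        out = self.fc(stacked.transpose(0, 2, 1)).sigmoid()      # (B, P, 2)
        r_pred = out[:, :, 0].reshape(b, height, width)
        theta_pred = out[:, :, 1].reshape(b, height, width)
        return r_pred, theta_pred


def _check_mask(mask: np.ndarray, shape) -> np.ndarray:
    mask = np.asarray(mask, dtype=float)
    if mask.shape != tuple(shape):
        raise ValueError(f"mask shape {mask.shape} != grid shape {tuple(shape)}")
    if mask.min() < 0:
        raise ValueError("mask entries must be nonnegative")
    total = mask.sum()
    if total <= 0:
        raise ValueError("mask must have positive total weight")
    return mask


def distance_loss(r_pred, r_target: np.ndarray, mask: np.ndarray) -> Tensor:
    """Mask-weighted mean squared radial error ``L_d``."""
    r_pred = as_tensor(r_pred)
    mask = _check_mask(mask, r_pred.shape)
    diff = r_pred - np.asarray(r_target, dtype=float)
    return (Tensor(mask) * diff * diff).sum() / float(mask.sum())


def angle_loss(theta_pred, theta_target: np.ndarray, mask: np.ndarray) -> Tensor:
    """Mask-weighted variance of the wrapped angle error ``L_a``.

    The raw difference ``theta' - theta`` is wrapped by adding 1 where it is
    negative, so a constant angular offset (a global rotation of the
    prediction) shifts every cell equally and the variance — hence the loss —
    is unchanged.
    """
    theta_pred = as_tensor(theta_pred)
    mask = _check_mask(mask, theta_pred.shape)
    diff = theta_pred - np.asarray(theta_target, dtype=float)
    wrap = (diff.data < 0).astype(diff.dtype)   # indicator: constant w.r.t. grad
    delta = diff + Tensor(wrap)
    w = Tensor(mask / mask.sum())
    mean_delta = (w * delta).sum()
    centred = delta - mean_delta
    return (w * centred * centred).sum()


def ssrm_image_loss(r_pred, theta_pred, r_target, theta_target,
                    mask) -> SSRMLossParts:
    """Both polar losses for a single image / stage."""
    return SSRMLossParts(
        L_d=distance_loss(r_pred, r_target, mask),
        L_a=angle_loss(theta_pred, theta_target, mask),
    )


def ssrm_stage_loss(f_batch: np.ndarray, v_batch: Tensor,
                    head: PolarHead) -> SSRMLossParts:
    """Batch-accumulated polar losses for one tapped stage.

    ``f_batch`` (plain array ``(B, C, H, W)``) supplies the object masks and
    reference cells; ``v_batch`` (autodiff tensor, same grid) feeds the
    prediction head.  Equals the sum over images of the per-image losses.
    """
    b = f_batch.shape[0]
    n = f_batch.shape[2]
    dtype = v_batch.dtype if isinstance(v_batch, Tensor) else np.float64
    masks = np.empty((b, n * n), dtype=dtype)
    refs = []
    r_t = np.empty((b, n * n), dtype=dtype)
    th_t = np.empty((b, n * n), dtype=dtype)
    for i in range(b):
        m = compute_object_mask(f_batch[i])
        refs.append(select_reference(m))
        masks[i] = m.ravel()
        r, th = polar_targets(refs[-1], n)
        r_t[i], th_t[i] = r.ravel(), th.ravel()
    w = masks / masks.sum(axis=1, keepdims=True)   # per-image normalised
    r_pred, th_pred = head.forward_batch(v_batch, refs)
    r_pred = r_pred.reshape(b, n * n)
    th_pred = th_pred.reshape(b, n * n)
    w_t = Tensor(w)
    d = r_pred - Tensor(r_t)
    l_d = (w_t * d * d).sum()
    diff = th_pred - Tensor(th_t)
    wrap = (diff.data < 0).astype(diff.dtype)
    delta = diff + Tensor(wrap)
    mean_delta = (w_t * delta).sum(axis=1, keepdims=True)
    centred = delta - mean_delta
    l_a = (w_t * centred * centred).sum()
    return SSRMLossParts(L_d=l_d, L_a=l_a)


def ssrm_loss(parts: list[SSRMLossParts]) -> SSRMLossParts:
    """Accumulate per-image parts over a batch (sum, matching the outer sums
    of the per-image definitions)."""
    if not parts:
        raise ValueError("ssrm_loss needs at least one per-image term")
    total_d = parts[0].L_d
    total_a = parts[0].L_a
    for p in parts[1:]:
        total_d = total_d + p.L_d
        total_a = total_a + p.L_a
    return SSRMLossParts(L_d=total_d, L_a=total_a)
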