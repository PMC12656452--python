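"""Multi-scale collaborative perception: cross-scale complementary fusion.

Feature maps tapped at different backbone stages attend to parts of the
specimen at different granularities.  Treating each spatial location as a
C-dimensional "pixel", this module measures how *redundant* two pixels are
by their inner product and converts low similarity into high attention:
columns of a softmax over the **negated** similarity matrix weight how much
each source pixel contributes to each destination pixel.  Every destination
pixel thus receives a convex combination of source pixels dominated by the
ones carrying information it lacks, and the aggregate over all other scales
is folded back with strength ``gamma``:

    M        = X1^T X2                      (similarity)
    A_s1s2   = colsoftmax(-M^T)             (attention of scale 2 onto 1)
    Y_s1s2   = X2 A_s1s2                    (complement for scale 1 from 2)
    Y_i      = sum_{j != i} Y_si_sj
    Z_i      = X_i + gamma * Y_i            (fusion; default gamma = 2)

The module is parameter-free; only the channel projections that give all
scales a common C live in the surrounding network.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, as_tensor
from .nn import softmax

__all__ = ["similarity", "attention", "complementary", "aggregate", "fuse",
           "mcpm_fuse_all"]


def _swap_last(t: Tensor) -> Tensor:
    axes = list(range(t.ndim))
    axes[-1], axes[-2] = axes[-2], axes[-1]
    return t.transpose(*axes)


def similarity(x1, x2) -> Tensor:
    """Inner-product similarity ``M = X1^T X2`` between pixel columns.

    ``x1``: ``(C, P1)``, ``x2``: ``(C, P2)`` -> ``(P1, P2)``.  A leading
    batch axis is allowed on both arguments and carried through.
    """
    x1, x2 = as_tensor(x1), as_tensor(x2)
    if x1.shape[-2] != x2.shape[-2]:
        raise ValueError(
            f"scale features must share channels: {x1.shape[-2]} vs {x2.shape[-2]}")
    return _swap_last(x1) @ x2


def attention(m) -> tuple[Tensor, Tensor]:
    """Complementarity attention pair from a similarity matrix.

    Low similarity means high complementarity, so the softmax runs over the
    *negated* similarities; it is applied column-wise, making every column a
    distribution over source pixels.  Returns ``(A_s1s2, A_s2s1)`` where
    ``A_s1s2`` has shape ``(P2, P1)`` (columns indexed by pixels of scale 1).
    """
    m = as_tensor(m)
    a_12 = softmax(-_swap_last(m), axis=-2)
    a_21 = softmax(-m, axis=-2)
    return a_12, a_21


def complementary(x_source, a) -> Tensor:
    """Mix source pixels by attention columns: ``Y = X_source @ A``.

    Each output pixel (column of ``Y``) is the convex combination of the
    source pixels weighted by the corresponding attention column.
    """
    x_source, a = as_tensor(x_source), as_tensor(a)
    if x_source.shape[-1] != a.shape[-2]:
        raise ValueError(
            f"attention rows ({a.shape[-2]}) must match source pixels "
            f"({x_source.shape[-1]})")
    return x_source @ a


def aggregate(scales: list) -> list[Tensor]:
    """Total complementary information for every scale from all others.

    Each unordered pair is processed once — its similarity matrix yields the
    attentions for both directions — and ``Y_i`` sums the contributions of
    every ``j != i``.
    """
    scales = [as_tensor(x) for x in scales]
    if len(scales) < 2:
        raise ValueError("aggregation needs at least two scale features")
    ys: list[Tensor | None] = [None] * len(scales)
    for i in range(len(scales)):
        for j in range(i + 1, len(scales)):
            m = similarity(scales[i], scales[j])
            a_ij, a_ji = attention(m)
            y_i = complementary(scales[j], a_ij)
            y_j = complementary(scales[i], a_ji)
            ys[i] = y_i if ys[i] is None else ys[i] + y_i
            ys[j] = y_j if ys[j] is None else ys[j] + y_j
    return ys  # type: ignore[return-value]


def fuse(x, y, gamma: float = 2.0) -> Tensor:
    """Fold complementary information back: ``Z = X + gamma * Y``."""
    x, y = as_tensor(x), as_tensor(y)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch in fusion: {x.shape} vs {y.shape}")
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    return x + float(gamma) * y


def mcpm_fuse_all(scales: list, gamma: float = 2.0) -> list[Tensor]:
    """Full pipeline: one fused feature per scale."""
    ys = aggregate(scales)
    return [fuse(x, y, gamma) for x, y in zip(scales, ys)]
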