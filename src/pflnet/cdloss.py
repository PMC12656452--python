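"""Channel-decouple loss: per-class channel groups scored by masked max pooling.

Multiple classifier streams tend to converge on the same discriminative
region.  To push feature channels apart, the final feature map is projected
to exactly ``c * k`` channels so that each of the ``c`` classes owns a
contiguous group of ``k`` channels.  A class's score is computed by

1. multiplying its group element-wise with a fresh uniform ``[0, 1]`` random
   mask (so no single channel can dominate across evaluations),
2. taking the per-spatial-location maximum over the first ``xi`` masked
   channels of the group (cross-channel max pooling; ``xi = k`` by default),
3. averaging the maxima over all spatial locations.

Cross-entropy over the softmax of these ``c`` scores forces the channels
assigned to the true class — and only those — to fire somewhere in the
image, diversifying where the network looks.  The total objective adds this
term to the ordinary classifier cross-entropy with weight ``mu`` (default
0.3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor

__all__ = ["CDConfig", "group_channels", "sample_mask", "class_score",
           "cd_loss", "cd_batch_loss", "total_loss"]


@dataclass(frozen=True)
class CDConfig:
    """Channel-decouple hyperparameters.

    ``c``: number of classes; ``k``: channels per class (the projected
    feature map must have exactly ``c * k`` channels); ``xi``: how many
    masked channels participate in the cross-channel max (``None`` means all
    ``k``); ``mu``: weight of the decouple term in the total loss.
    """

    c: int
    k: int = 2
    xi: int | None = None
    mu: float = 0.3

    def __post_init__(self):
        if self.c < 2:
            raise ValueError("need at least two classes")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        xi = self.k if self.xi is None else self.xi
        if not 1 <= xi <= self.k:
            raise ValueError(f"xi must be in [1, k]; got xi={xi}, k={self.k}")
        if self.mu < 0:
            raise ValueError("mu must be nonnegative")

    @property
    def xi_eff(self) -> int:
        return self.k if self.xi is None else self.xi

    @property
    def channels(self) -> int:
        return self.c * self.k


def group_channels(f, cfg: CDConfig) -> list[Tensor]:
    """Split a ``(C, H, W)`` or ``(C, P)`` feature into ``c`` blocks of ``k``
    channels, each flattened to ``(k, W*H)``; class ``i`` owns channels
    ``[i*k, (i+1)*k)``."""
    f = as_tensor(f)
    if f.ndim == 3:
        c_total = f.shape[0]
        f = f.reshape(c_total, f.shape[1] * f.shape[2])
    elif f.ndim != 2:
        raise ValueError("feature must be (C, H, W) or (C, P)")
    if f.shape[0] != cfg.channels:
        raise ValueError(
            f"channel count {f.shape[0]} != c*k = {cfg.c}*{cfg.k} = {cfg.channels}")
    return [f[i * cfg.k:(i + 1) * cfg.k, :] for i in range(cfg.c)]


def sample_mask(shape, rng: np.random.Generator) -> np.ndarray:
    """I.i.d. uniform ``[0, 1]`` random mask, one element per feature entry."""
    return rng.uniform(0.0, 1.0, size=shape)


def class_score(group, mask: np.ndarray, xi: int) -> Tensor:
    """Masked cross-channel max score of one class group.

    ``group``: ``(k, P)``; element-wise mask multiply, per-location max over
    the first ``xi`` masked channels, then mean over the ``P`` locations.
    """
    group = as_tensor(group)
    k, _ = group.shape
    if not 1 <= xi <= k:
        raise ValueError(f"xi={xi} outside [1, {k}]")
    mask = np.asarray(mask, dtype=float)
    if mask.shape != group.shape:
        raise ValueError(f"mask shape {mask.shape} != group shape {group.shape}")
    masked = group * Tensor(mask)
    return masked[:xi, :].max(axis=0).mean()


def cd_loss(f, label: int, cfg: CDConfig,
            rng: np.random.Generator | int) -> Tensor:
    """Cross-entropy over softmaxed class scores for a single image.

    ``rng`` is either a seeded generator (advanced in place) or an integer
    seed; masks are resampled per call, so identical seeds give identical
    losses.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    groups = group_channels(f, cfg)
    if not 0 <= label < cfg.c:
        raise ValueError(f"label {label} outside [0, {cfg.c})")
    scores = [class_score(g, sample_mask(g.shape, rng), cfg.xi_eff)
              for g in groups]
    # stable log-softmax over the c scalar scores
    data = np.array([float(s) for s in scores])
    shift = float(data.max())
    exps = [(s - shift).exp() for s in scores]
    denom = exps[0]
    for e in exps[1:]:
        denom = denom + e
    return denom.log() - (scores[label] - shift)


def cd_batch_loss(fmap, labels, cfg: CDConfig,
                  rng: np.random.Generator) -> Tensor:
    """Mean channel-decouple loss over a batch, fully vectorised.

    ``fmap`` is ``(B, c*k, H, W)``; masks for all images and groups are
    drawn in one call, which consumes the generator in the same order as
    looping images and groups, so the result equals the mean of the
    per-image :func:`cd_loss` values for the same starting generator state.
    """
    from .nn import cross_entropy  # local import avoids a module cycle

    fmap = as_tensor(fmap)
    b, channels = fmap.shape[0], fmap.shape[1]
    if channels != cfg.channels:
        raise ValueError(
            f"channel count {channels} != c*k = {cfg.c}*{cfg.k} = {cfg.channels}")
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() >= cfg.c:
        raise ValueError("labels outside [0, c)")
    p = int(np.prod(fmap.shape[2:]))
    x = fmap.reshape(b, cfg.c, cfg.k, p)
    masks = rng.uniform(0.0, 1.0, size=(b, cfg.c, cfg.k, p)).astype(fmap.dtype)
    masked = x * Tensor(masks)
    scores = masked[:, :, :cfg.xi_eff, :].max(axis=2).mean(axis=2)  # (B, c)
    return cross_entropy(scores, labels)


def total_loss(ce, cd, mu: float = 0.3) -> Tensor:
    """Joint objective ``L = L_CE + mu * L_CD``."""
    if mu < 0:
        raise ValueError("mu must be nonnegative")
    return as_tensor(ce) + float(mu) * as_tensor(cd)
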