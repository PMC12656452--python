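"""Progressive feature-learning classifier: backbone taps, refinement, fusion.

The model wraps any staged convolutional backbone (a tiny 3-stage CNN ships
for CPU-scale work; the contract is simply an ordered list of stages, each
mapping the previous stage's output to a feature map).  The last
``n_tapped_stages`` feature maps are

1. refined by a per-stage 1x1 convolution whose output feeds the polar
   coordinate supervision (:mod:`pflnet.ssrm`),
2. projected to a common channel width and fused across scales by
   complementarity attention (:mod:`pflnet.mcpm`),
3. globally average-pooled and classified by per-stage two-layer heads plus
   one head over the concatenation of all pooled stage features,

while the final stage additionally feeds a ``c * k``-channel projection for
the channel-decouple loss (:mod:`pflnet.cdloss`).  The training objective is

    L = sum_heads L_CE + mu * L_CD + lambda_ssrm * (L_d + L_a)

with every term differentiated end-to-end through the autodiff core.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import cdloss as cd
from . import mcpm, ssrm
from .autodiff import Tensor, concatenate
from .config import PFLConfig
from .nn import (SGD, Conv2d, GroupNorm, Linear, Module, cosine_lr,
                 cross_entropy, softmax)

__all__ = [
    "TinyBackbone", "PFLNet", "LossBundle", "train_model", "evaluate",
    "predict", "save_checkpoint", "load_checkpoint", "normalize_images",
]


class TinyBackbone(Module):
    """Small staged CNN honouring the backbone contract.

    Stage 1 downsamples 4x (two stride-2 convolutions), later stages 2x
    each; with 96 px inputs and widths (16, 32, 64) the tapped grids are
    24, 12 and 6 cells wide.
    """

    def __init__(self, widths=(16, 32, 64), in_channels: int = 3,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.widths = tuple(widths)
        w0 = self.widths[0]
        self.stem_a = Conv2d(in_channels, w0, 3, stride=2, padding=1, rng=rng)
        self.norm_a = GroupNorm(w0)
        self.stem_b = Conv2d(w0, w0, 3, stride=2, padding=1, rng=rng)
        self.norm_b = GroupNorm(w0)
        self.stage_convs = [
            Conv2d(self.widths[i - 1], self.widths[i], 3, stride=2, padding=1,
                   rng=rng)
            for i in range(1, len(self.widths))
        ]
        self.stage_norms = [GroupNorm(w) for w in self.widths[1:]]

    @property
    def n_stages(self) -> int:
        return len(self.widths)

    def __call__(self, x: Tensor) -> list[Tensor]:
        h = self.norm_a(self.stem_a(x)).relu()
        feats = [self.norm_b(self.stem_b(h)).relu()]
        for conv, norm in zip(self.stage_convs, self.stage_norms):
            feats.append(norm(conv(feats[-1])).relu())
        return feats


@dataclass
class LossBundle:
    """All loss terms of one training step (autodiff scalars)."""

    ce_per_head: list
    cd: Tensor
    ssrm_d: Tensor
    ssrm_a: Tensor
    total: Tensor

    def to_floats(self) -> dict[str, float]:
        out = {f"ce_head_{i}": float(v) for i, v in enumerate(self.ce_per_head)}
        out.update(cd=float(self.cd), ssrm_d=float(self.ssrm_d),
                   ssrm_a=float(self.ssrm_a), total=float(self.total))
        return out


class PFLNet(Module):
    def __init__(self, cfg: PFLConfig, backbone: Module | None = None):
        self.cfg = cfg
        ss = np.random.SeedSequence(cfg.seed)
        rngs = [np.random.default_rng(s) for s in ss.spawn(6)]
        self.backbone = backbone or TinyBackbone(cfg.backbone_widths, rng=rngs[0])
        widths = list(self.backbone.widths)[-cfg.n_tapped_stages:]
        self.cd_cfg = cd.CDConfig(c=cfg.n_classes, k=cfg.k, xi=cfg.xi, mu=cfg.mu)
        self.ssrm_convs = [Conv2d(w, w, 1, rng=rngs[1]) for w in widths]
        self.ssrm_norms = [GroupNorm(w) for w in widths]
        self.polar_heads = [ssrm.PolarHead(w, rng=rngs[2]) for w in widths]
        self.projections = [Conv2d(w, cfg.common_channels, 1, rng=rngs[3])
                            for w in widths]
        hidden = cfg.classifier_hidden
        self.stage_heads = [
            _TwoLayerHead(cfg.common_channels, hidden, cfg.n_classes, rngs[4])
            for _ in widths
        ]
        self.cat_head = _TwoLayerHead(
            cfg.common_channels * len(widths), hidden, cfg.n_classes, rngs[4])
        self.cd_proj = Conv2d(widths[-1], self.cd_cfg.channels, 1, rng=rngs[5])

    # -------------------------------------------------------------- internals
    def _tapped(self, x: Tensor):
        feats = self.backbone(x)
        n = self.cfg.n_tapped_stages
        return feats[-n:]

    def _refine(self, tapped):
        """Stage-wise 1x1 refinement V = relu(norm(conv(F)))."""
        return [norm(conv(f)).relu()
                for conv, norm, f in zip(self.ssrm_convs, self.ssrm_norms,
                                         tapped)]

    def _pool_features(self, refined):
        """Project, (optionally) fuse across scales, globally pool.

        Returns a list of pooled ``(B, common_channels)`` tensors, one per
        tapped stage.
        """
        cfg = self.cfg
        projected = [proj(v).relu() for proj, v in zip(self.projections, refined)]
        if not cfg.use_mcpm:
            return [p.mean(axis=(2, 3)) for p in projected]
        scales = [p.reshape(p.shape[0], p.shape[1], p.shape[2] * p.shape[3])
                  for p in projected]
        fused = mcpm.mcpm_fuse_all(scales, gamma=cfg.gamma)
        return [z.mean(axis=2) for z in fused]

    # ---------------------------------------------------------------- forward
    def forward(self, x, return_features: bool = False):
        """Logits of every head for a normalised image batch.

        Returns ``(per_stage_logits, y_cat)`` — and the intermediate tapped /
        refined features when ``return_features`` is set.
        """
        x = x if isinstance(x, Tensor) else Tensor(x)
        tapped = self._tapped(x)
        refined = self._refine(tapped)
        pooled = self._pool_features(refined)
        logits = [head(p) for head, p in zip(self.stage_heads, pooled)]
        y_cat = self.cat_head(concatenate(pooled, axis=1))
        if return_features:
            return logits, y_cat, tapped, refined
        return logits, y_cat

    def __call__(self, x):
        return self.forward(x)

    # ------------------------------------------------------------------ losses
    def _ssrm_terms(self, tapped, refined):
        parts = [ssrm.ssrm_stage_loss(f.data, v, head)
                 for f, v, head in zip(tapped, refined, self.polar_heads)]
        return ssrm.ssrm_loss(parts)

    def _cd_term(self, refined, labels, rng: np.random.Generator) -> Tensor:
        fmap = self.cd_proj(refined[-1])
        return cd.cd_batch_loss(fmap, labels, self.cd_cfg, rng)

    def training_step(self, x, labels, rng: np.random.Generator | int,
                      optimizer: SGD | None = None) -> LossBundle:
        """Compute the joint objective on one batch; step if an optimizer is
        given.  ``rng`` seeds the channel-decouple masks."""
        cfg = self.cfg
        if isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(int(rng))
        labels = np.asarray(labels)
        logits, y_cat, tapped, refined = self.forward(x, return_features=True)
        ce_terms = [cross_entropy(lg, labels) for lg in logits]
        ce_terms.append(cross_entropy(y_cat, labels))
        total = ce_terms[0]
        for t in ce_terms[1:]:
            total = total + t
        zero = Tensor(np.zeros(()))
        if cfg.use_cd and cfg.mu > 0:
            cd_term = self._cd_term(refined, labels, rng)
            total = total + cfg.mu * cd_term
        else:
            cd_term = zero
        if cfg.use_ssrm and cfg.lambda_ssrm > 0:
            sp = self._ssrm_terms(tapped, refined)
            ssrm_d, ssrm_a = sp.L_d, sp.L_a
            # batch sum scaled to a per-image mean so the term's weight does
            # not grow with batch size
            total = total + (cfg.lambda_ssrm / len(labels)) * sp.L_ssrm
        else:
            ssrm_d = ssrm_a = zero
        if not np.isfinite(float(total)):
            bad = {name: float(v) for name, v in
                   [("cd", cd_term), ("ssrm_d", ssrm_d), ("ssrm_a", ssrm_a)]
                   + [(f"ce_{i}", t) for i, t in enumerate(ce_terms)]
                   if not np.isfinite(float(v))}
            raise FloatingPointError(f"non-finite loss terms: {bad}")
        if optimizer is not None:
            optimizer.zero_grad()
            total.backward()
            optimizer.step()
        return LossBundle(ce_per_head=ce_terms, cd=cd_term,
                          ssrm_d=ssrm_d, ssrm_a=ssrm_a, total=total)

    # -------------------------------------------------------------- optimiser
    def make_optimizer(self, total_steps: int) -> SGD:
        """Three parameter groups: backbone and new layers follow cosine
        annealing; the auxiliary concatenation head keeps a constant rate."""
        cfg = self.cfg
        sched = cosine_lr(total_steps)
        backbone_params = list(self.backbone.parameters())
        aux_params = list(self.cat_head.parameters())
        exclude = {id(p) for p in backbone_params} | {id(p) for p in aux_params}
        new_params = [p for p in self.parameters() if id(p) not in exclude]
        return SGD([
            {"params": backbone_params, "lr": cfg.lr_backbone, "schedule": sched},
            {"params": new_params, "lr": cfg.lr_new, "schedule": sched},
            {"params": aux_params, "lr": cfg.lr_aux, "schedule": None},
        ], momentum=cfg.momentum, weight_decay=cfg.weight_decay,
            max_grad_norm=cfg.max_grad_norm)


class _TwoLayerHead(Module):
    """Classifier head: two fully connected layers with a ReLU between."""

    def __init__(self, nin, hidden, nout, rng):
        self.fc1 = Linear(nin, hidden, rng=rng)
        self.fc2 = Linear(hidden, nout, rng=rng)

    def __call__(self, x):
        return self.fc2(self.fc1(x).relu())


# ---------------------------------------------------------------------------
# data plumbing, training loop, evaluation
# ---------------------------------------------------------------------------

def normalize_images(images: np.ndarray) -> np.ndarray:
    """uint8 ``(N, S, S, 3)`` -> float32 ``(N, 3, S, S)`` standardised."""
    x = images.astype(np.float32) / 255.0
    x = (x - 0.45) / 0.25
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


def _augment(x: np.ndarray, rng: np.random.Generator, pad: int = 6) -> np.ndarray:
    """Random horizontal flip and random crop after reflect padding."""
    b, _, h, w = x.shape
    out = np.empty_like(x)
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)), mode="reflect")
    offs = rng.integers(0, 2 * pad + 1, size=(b, 2))
    flips = rng.random(b) < 0.5
    for i in range(b):
        oy, ox = offs[i]
        crop = xp[i, :, oy:oy + h, ox:ox + w]
        out[i] = crop[:, :, ::-1] if flips[i] else crop
    return out


def predict(model: PFLNet, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """Class indices for normalised images.

    Default head: argmax of the mean softmax over all four heads; set
    ``predict_head='cat'`` in the config to use the concatenation head only.
    Ties resolve to the smallest class index.
    """
    from .autodiff import no_grad
    preds = []
    with no_grad():
        for lo in range(0, len(images), batch_size):
            chunk = images[lo:lo + batch_size]
            logits, y_cat = model.forward(chunk)
            if model.cfg.predict_head == "cat":
                probs = softmax(y_cat, axis=1).data
            else:
                heads = logits + [y_cat]
                probs = np.mean([softmax(lg, axis=1).data for lg in heads],
                                axis=0)
            preds.append(np.argmax(probs, axis=1))
    return np.concatenate(preds)


def evaluate(model: PFLNet, images: np.ndarray, labels: np.ndarray,
             batch_size: int = 64) -> float:
    """Top-1 accuracy in percent."""
    if len(images) == 0:
        raise ValueError("cannot evaluate on an empty dataset")
    preds = predict(model, images, batch_size)
    return 100.0 * float(np.mean(preds == np.asarray(labels)))


def train_model(cfg: PFLConfig, train_images: np.ndarray,
                train_labels: np.ndarray, augment: bool = True,
                log_fn=None) -> tuple[PFLNet, list[dict]]:
    """Train from scratch on normalised images; fully seeded.

    Returns the model and a per-epoch history of mean loss terms and
    learning rates.  Bit-identical across runs with the same config.
    """
    model = PFLNet(cfg)
    n = len(train_images)
    steps_per_epoch = max(1, (n + cfg.batch_size - 1) // cfg.batch_size)
    optimizer = model.make_optimizer(cfg.epochs * steps_per_epoch)
    ss = np.random.SeedSequence([cfg.seed, 0x5F1D])
    shuffle_rng, aug_rng, mask_rng = (np.random.default_rng(s)
                                      for s in ss.spawn(3))
    history = []
    order = np.arange(n)
    for epoch in range(cfg.epochs):
        shuffle_rng.shuffle(order)
        sums: dict[str, float] = {}
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            xb = train_images[idx]
            if augment:
                xb = _augment(xb, aug_rng)
            bundle = model.training_step(xb, train_labels[idx], mask_rng,
                                         optimizer)
            for key, val in bundle.to_floats().items():
                sums[key] = sums.get(key, 0.0) + val
        record = {"epoch": epoch,
                  **{k: v / steps_per_epoch for k, v in sums.items()},
                  "lr": optimizer.current_lrs()}
        history.append(record)
        if log_fn is not None:
            log_fn(record)
    return model, history


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: PFLNet, path) -> None:
    state = model.state_dict()
    np.savez(path, __config__=json.dumps(model.cfg.to_dict()), **state)


def load_checkpoint(path) -> PFLNet:
    with np.load(path, allow_pickle=False) as data:
        cfg = PFLConfig.from_dict(json.loads(str(data["__config__"])))
        state = {k: data[k] for k in data.files if k != "__config__"}
    model = PFLNet(cfg)
    model.load_state_dict(state)
    return model
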