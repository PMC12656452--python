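"""Procedural generator of fine-grained specimen images and tensor fixtures.

Real *Cordyceps sinensis* photographs show a centred, elongated larval body
on a standardised dark background, captured from four fixed angles; the
subspecies differ subtly in parts such as the head, the eyes, the dorsal
rings and the leg groups.  This module renders a cartoon analogue of that
protocol so the whole pipeline is testable without any download: a curved
segmented body with ``n_rings`` dark dorsal bands, a head disk with two eye
dots, and three pairs of leg stubs, drawn on a noisy near-black background
and presented in four discrete poses (back / foot / left / right).

A *class* is one fixed :class:`SpecimenSpec`; within-class variation comes
only from seeded jitter (translation, small rotation, brightness, pixel
noise).  Two presets ship: ``easy`` (large inter-class gaps, distinct body
hues, no rotation jitter) and ``hard`` (one shared hue, small geometric
gaps, rotation and photometric jitter) so that component ablations have
measurable headroom.  Every function is bit-deterministic given its seed.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "SpecimenSpec", "JitterSpec", "POSES", "make_class_specs",
    "render_specimen", "generate_arrays", "generate_dataset",
    "load_image_folder", "make_feature_fixture", "TRAIN_FRACTION",
]

POSES = ("back", "foot", "left", "right")
TRAIN_FRACTION = 0.7
_REF_SIZE = 96  # pixel-valued spec fields are expressed at this image size


@dataclass(frozen=True)
class SpecimenSpec:
    """Renderable parameters of one specimen class."""

    n_rings: int               # dorsal bands along the body
    head_ratio: float          # head diameter as a fraction of body length
    eye_offset: float          # eye separation from the midline, px at 96
    leg_spacing: float         # spacing between leg stubs, px at 96
    body_curvature: float      # bend of the body axis, radians
    base_hue: tuple            # body RGB in [0, 1]

    def __post_init__(self):
        if not 1 <= self.n_rings <= 12:
            raise ValueError("n_rings must be in [1, 12]")
        if not 0.10 <= self.head_ratio <= 0.40:
            raise ValueError("head_ratio outside renderable bounds [0.10, 0.40]")
        if not 0 < self.eye_offset <= 8:
            raise ValueError("eye_offset outside renderable bounds (0, 8] px")
        if not 3 <= self.leg_spacing <= 14:
            raise ValueError("leg_spacing outside renderable bounds [3, 14] px")
        if abs(self.body_curvature) > 0.35:
            raise ValueError("body_curvature outside renderable bounds")


@dataclass(frozen=True)
class JitterSpec:
    """Within-class nuisance variation (all sampled per image from the seed)."""

    max_shift_px: float = 2.0
    max_rot_deg: float = 0.0
    brightness: float = 0.03
    noise_sigma: float = 0.01


_EASY_JITTER = JitterSpec(max_shift_px=2.0, max_rot_deg=0.0,
                          brightness=0.03, noise_sigma=0.01)
_HARD_JITTER = JitterSpec(max_shift_px=2.0, max_rot_deg=3.0,
                          brightness=0.08, noise_sigma=0.02)

_EASY_HUES = [(0.75, 0.55, 0.30), (0.55, 0.30, 0.20), (0.35, 0.55, 0.30),
              (0.30, 0.40, 0.60), (0.66, 0.62, 0.25), (0.52, 0.35, 0.56)]


def make_class_specs(n_classes: int, preset: str = "easy") -> list[SpecimenSpec]:
    """One fixed spec per class; gaps between classes depend on the preset."""
    if n_classes < 2:
        raise ValueError("need at least two classes")
    specs = []
    if preset == "easy":
        for i in range(n_classes):
            specs.append(SpecimenSpec(
                n_rings=3 + (i % 6),
                head_ratio=0.18 + 0.03 * (i % 6),
                eye_offset=2.0 + 0.5 * (i % 6),
                leg_spacing=6.0 + (i % 6),
                body_curvature=0.04 * (i % 6),
                base_hue=_EASY_HUES[i % len(_EASY_HUES)],
            ))
    elif preset == "hard":
        # identical body hue for every class: discrimination must rely on
        # geometry (ring count, head size, eyes, legs, curvature) under
        # rotation / shift / photometric jitter
        for i in range(n_classes):
            specs.append(SpecimenSpec(
                n_rings=3 + (i % 6),
                head_ratio=0.18 + 0.03 * (i % 6),
                eye_offset=2.0 + 0.5 * (i % 6),
                leg_spacing=6.0 + (i % 6),
                body_curvature=0.04 * (i % 6),
                base_hue=(0.68, 0.52, 0.32),
            ))
    else:
        raise ValueError(f"unknown preset {preset!r} (use 'easy' or 'hard')")
    return specs


def _pose_transform(img: np.ndarray, pose: str) -> np.ndarray:
    if pose == "back":
        return img
    if pose == "foot":
        return img[::-1].copy()
    if pose == "left":
        return np.rot90(img, 1).copy()
    if pose == "right":
        return np.rot90(img, 3).copy()
    raise ValueError(f"unknown pose {pose!r}; expected one of {POSES}")


def render_specimen(spec: SpecimenSpec, pose: str = "back",
                    jitter_seed: int = 0, image_size: int = 96,
                    jitter: JitterSpec | None = None) -> np.ndarray:
    """Render one specimen image as ``(S, S, 3)`` uint8; bit-deterministic."""
    jitter = jitter or _EASY_JITTER
    s = int(image_size)
    scale = s / _REF_SIZE
    rng = np.random.default_rng(jitter_seed)

    shift = rng.uniform(-jitter.max_shift_px, jitter.max_shift_px, size=2) * scale
    rot = rng.uniform(-jitter.max_rot_deg, jitter.max_rot_deg)
    gain = 1.0 + rng.uniform(-jitter.brightness, jitter.brightness)

    cy = s / 2.0 + shift[0]
    cx = s / 2.0 + shift[1]
    length = 0.72 * s
    half = length / 2.0
    t0 = 0.09 * s

    ys, xs = np.mgrid[0:s, 0:s].astype(float)
    u = (xs - cx) / half                       # -1 (tail) .. +1 (head end)
    y_c = cy + math.tan(spec.body_curvature) * (xs - cx) ** 2 / half
    dy = ys - y_c
    taper = 0.55 + 0.45 * np.sqrt(np.clip(1.0 - u**2, 0.0, 1.0))
    thick = t0 * taper
    body = (np.abs(u) <= 1.0) & (np.abs(dy) <= thick)

    img = np.full((s, s, 3), 0.06)
    img += rng.normal(0.0, jitter.noise_sigma, size=img.shape)

    hue = np.asarray(spec.base_hue)
    shade = 1.0 - 0.25 * np.clip(np.abs(dy) / np.maximum(thick, 1e-9), 0, 1) ** 2
    img[body] = (hue[None, :] * shade[body, None])

    # dorsal rings: evenly spaced dark bands on the trunk (head region spared)
    u_lo, u_hi = -0.88, 0.42
    centers = u_lo + (np.arange(spec.n_rings) + 0.5) * (u_hi - u_lo) / spec.n_rings
    band_hw = max(0.26 * (u_hi - u_lo) / spec.n_rings, 1.4 / half)
    ring = body & (np.abs(u[..., None] - centers).min(axis=-1) < band_hw)
    img[ring] *= 0.38

    # three pairs of leg stubs below the body, spaced by leg_spacing
    leg_len = 0.07 * s
    leg_x0 = cx + 0.30 * length
    for leg_i in range(6):
        lx = leg_x0 - leg_i * spec.leg_spacing * scale
        lu = (lx - cx) / half
        if lu < -0.95:
            break
        ly = cy + math.tan(spec.body_curvature) * (lx - cx) ** 2 / half
        top = ly + t0 * (0.55 + 0.45 * math.sqrt(max(1 - lu**2, 0.0)))
        stub = (np.abs(xs - lx) <= max(1.1 * scale, 1.0)) & \
               (ys >= top - 1) & (ys <= top + leg_len)
        img[stub] = hue * 0.55

    # head disk and eye dots at the +u end
    r_h = spec.head_ratio * length / 2.0
    hx = cx + half - 0.6 * r_h
    hy = cy + math.tan(spec.body_curvature) * (hx - cx) ** 2 / half
    head = (xs - hx) ** 2 + (ys - hy) ** 2 <= r_h**2
    img[head] = hue * np.array([0.80, 0.62, 0.55])
    eye_r = max(1.8 * scale, 1.3)
    for sign in (-1, 1):
        ex = hx + 0.45 * r_h
        ey = hy + sign * spec.eye_offset * scale
        eye = (xs - ex) ** 2 + (ys - ey) ** 2 <= eye_r**2
        img[eye & head] = 0.03

    img = np.clip(img * gain, 0.0, 1.0)
    if jitter.max_rot_deg > 0 and abs(rot) > 1e-9:
        img = ndimage.rotate(img, rot, axes=(0, 1), reshape=False,
                             order=1, mode="constant", cval=0.06)
        img = np.clip(img, 0.0, 1.0)
    img = _pose_transform(img, pose)
    return np.round(img * 255.0).astype(np.uint8)


def generate_arrays(n_classes: int = 6, n_per_class: int = 100,
                    image_size: int = 96, seed: int = 0,
                    preset: str = "easy"):
    """Balanced in-memory dataset.

    Returns ``(images, labels, poses)`` with images ``(N, S, S, 3)`` uint8,
    integer labels and the pose tag of every image.  Poses cycle through the
    four capture angles so each class is covered from every angle.
    """
    specs = make_class_specs(n_classes, preset)
    jitter = _EASY_JITTER if preset == "easy" else _HARD_JITTER
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(n_classes * n_per_class)
    images, labels, poses = [], [], []
    idx = 0
    for ci, spec in enumerate(specs):
        for k in range(n_per_class):
            pose = POSES[k % len(POSES)]
            images.append(render_specimen(
                spec, pose=pose, jitter_seed=int(child_seeds[idx]),
                image_size=image_size, jitter=jitter))
            labels.append(ci)
            poses.append(pose)
            idx += 1
    return np.stack(images), np.asarray(labels), poses


def split_indices(labels: np.ndarray, seed: int,
                  train_fraction: float = TRAIN_FRACTION):
    """Disjoint per-class train/test indices by seeded shuffle."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        n_train = int(round(train_fraction * len(idx)))
        train.extend(idx[:n_train])
        test.extend(idx[n_train:])
    return np.sort(np.asarray(train)), np.sort(np.asarray(test))


def generate_dataset(out_dir, n_classes: int = 6, n_per_class: int = 100,
                     image_size: int = 96, seed: int = 0,
                     preset: str = "easy") -> list[dict]:
    """Write a class-per-directory image-folder tree plus a manifest.

    Layout: ``out_dir/{train,test}/class_<i>/<name>.png`` with a 70/30
    seeded split per class, and ``out_dir/manifest.csv`` with columns
    ``path,label,pose,seed``.  Refuses to overwrite an existing directory.
    """
    out = Path(out_dir)
    if out.exists():
        raise FileExistsError(f"output directory already exists: {out}")
    images, labels, poses = generate_arrays(
        n_classes, n_per_class, image_size, seed, preset)
    train_idx, test_idx = split_indices(labels, seed)
    in_train = np.zeros(len(labels), dtype=bool)
    in_train[train_idx] = True
    rows = []
    for i, (img, label, pose) in enumerate(zip(images, labels, poses)):
        part = "train" if in_train[i] else "test"
        rel = Path(part) / f"class_{label:02d}" / f"img_{i:05d}_{pose}.png"
        dest = out / rel
        dest.parent.mkdir(parents=True, exist_ok=True)
        Image.fromarray(img).save(dest)
        rows.append({"path": str(rel), "label": int(label),
                     "pose": pose, "seed": int(seed)})
    with open(out / "manifest.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["path", "label", "pose", "seed"])
        writer.writeheader()
        writer.writerows(rows)
    return rows


def load_image_folder(root):
    """Read a class-per-directory tree of PNG/JPEG images.

    Returns ``(images, labels, class_names)``; images ``(N, S, S, 3)`` uint8
    in path-sorted order, labels indexing the sorted class directory names.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset directory not found: {root}")
    class_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not class_dirs:
        raise FileNotFoundError(f"no class directories under {root}")
    images, labels = [], []
    names = [p.name for p in class_dirs]
    for ci, cdir in enumerate(class_dirs):
        for path in sorted(cdir.glob("*")):
            if path.suffix.lower() not in (".png", ".jpg", ".jpeg"):
                continue
            images.append(np.asarray(Image.open(path).convert("RGB")))
            labels.append(ci)
    if not images:
        raise FileNotFoundError(f"no images found under {root}")
    return np.stack(images), np.asarray(labels), names


def make_feature_fixture(c: int, h: int, w: int, seed: int = 0) -> np.ndarray:
    """Reproducible standard-normal ``(C, H, W)`` feature tensor for tests."""
    if min(c, h, w) < 1:
        raise ValueError("dimensions must be positive")
    return np.random.default_rng(seed).standard_normal((c, h, w))
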