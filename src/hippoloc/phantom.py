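"""Synthetic brain-phantom generator.

Produces seeded 3D grayscale volumes with a single bright ellipsoidal target
("hippocampus"), a paired binary mask, and a binary class label, emulating the
statistical structure the localization/classification pipeline assumes:

* volumes are ``depth x H x W`` with the mask supported on a contiguous slab
  of slices;
* the target fits inside the fixed agent box (50x65 at 256 resolution);
* the two classes differ only in within-target texture — class 0 (control-like)
  targets are smooth, class 1 (disease-like) targets carry multiplicative
  speckle and boundary attenuation of amplitude ``class_contrast``;
* the background is a smooth, deterministic pseudo-anatomy (head outline,
  ventricle-like dark lobes, low-frequency intensity fields) plus Gaussian
  noise, so that — as in real structural MRI — any crop-sized patch is
  informative about its own position in the image;
* the target sits at a stereotyped anatomical anchor with a small uniform
  jitter (``center_jitter``), mirroring the roughly fixed anatomical location
  of the hippocampus.  ``center_jitter=None`` places it uniformly over all
  valid positions instead.

Everything is deterministic given ``(config.seed, subject_id, label)``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "PhantomConfig",
    "VolumeSample",
    "PhantomDataset",
    "generate_volume",
    "generate_dataset",
    "target_texture_statistic",
    "FAST_PHANTOM_CONFIG",
    "DEFAULT_PHANTOM_CONFIG",
]


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the phantom cohort.

    ``target_halfaxes`` is ``(a, b, c)`` = half-axes along (depth, rows, cols)
    in voxels; the tight bounding box of the target is ``(2c+1) x (2b+1)``
    pixels in-plane, which must fit strictly inside ``box_size``.
    """

    volume_shape: tuple[int, int, int] = (40, 256, 256)
    target_halfaxes: tuple[int, int, int] = (10, 26, 20)
    mask_slab_fraction: float = 0.7
    class_contrast: float = 0.6
    noise_sd: float = 0.05
    seed: int = 0
    box_size: tuple[int, int, int] = (50, 65, 50)  # (width, height, depth)
    center_jitter: int | None = 12
    target_amplitude: float = 0.45
    border_margin: int = 5

    def __post_init__(self) -> None:
        d, h, w = self.volume_shape
        a, b, c = self.target_halfaxes
        bw, bh, bd = self.box_size
        if min(d, h, w) <= 0:
            raise ValueError(f"volume_shape must be positive, got {self.volume_shape}")
        if min(a, b, c) <= 0:
            raise ValueError(f"target_halfaxes must be positive, got {self.target_halfaxes}")
        if not (2 * c + 1 < bw and 2 * b + 1 < bh and 2 * a + 1 < bd + 1):
            raise ValueError(
                f"target of half-axes {self.target_halfaxes} does not fit strictly "
                f"inside the {bw}x{bh} (depth {bd}) agent box"
            )
        if not 0.0 < self.mask_slab_fraction <= 1.0:
            raise ValueError("mask_slab_fraction must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


DEFAULT_PHANTOM_CONFIG = PhantomConfig()

#: Reduced profile for fast CI: 128x128 slices, agent box 25x32, step 3.
FAST_PHANTOM_CONFIG = PhantomConfig(
    volume_shape=(12, 128, 128),
    target_halfaxes=(3, 13, 10),
    mask_slab_fraction=1.0,
    box_size=(25, 32, 12),
    center_jitter=6,
)


@dataclass
class VolumeSample:
    """One phantom subject: image voxels, binary mask, class label."""

    image: np.ndarray
    mask: np.ndarray
    label: int
    subject_id: str

    def __post_init__(self) -> None:
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask shapes differ")
        if not np.isfinite(self.image).all():
            raise ValueError("image contains non-finite intensities")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask must be binary")
        if self.mask.sum() == 0:
            raise ValueError("mask support is empty")


def _subject_rng(config: PhantomConfig, label: int, subject_id: str) -> np.random.Generator:
    sid = zlib.crc32(str(subject_id).encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence((config.seed, int(label), sid)))


def _pseudo_anatomy(h: int, w: int) -> np.ndarray:
    """Deterministic smooth brain-like background template in roughly [0, 1].

    Head outline (superellipse), a bright cortical rim, two dark ventricle-like
    lobes, and low-frequency sinusoidal intensity fields whose phases differ by
    axis so that local appearance encodes position.
    """
    yy, xx = np.meshgrid(np.linspace(-1, 1, h), np.linspace(-1, 1, w), indexing="ij")
    r = (np.abs(xx) / 0.85) ** 2.5 + (np.abs(yy) / 0.92) ** 2.5
    head = r < 1.0
    base = 0.45 - 0.12 * r
    base += 0.10 * np.sin(2.2 * np.pi * yy + 0.7) + 0.10 * np.sin(1.7 * np.pi * xx + 2.1)
    base += 0.08 * np.sin(1.3 * np.pi * (xx + yy) + 0.3)
    rim = (r > 0.72) & head
    base = np.where(rim, base + 0.18, base)
    for sx in (-0.22, 0.22):
        vent = ((xx - sx) / 0.16) ** 2 + ((yy + 0.12) / 0.30) ** 2 < 1.0
        base = np.where(vent, base - 0.22, base)
    img = np.where(head, base, 0.02)
    return gaussian_filter(img, sigma=2.0)


def _center_ranges(config: PhantomConfig) -> tuple[tuple[int, int], tuple[int, int], tuple[int, int]]:
    """Inclusive valid ranges for the target center along (z, y, x)."""
    d, h, w = config.volume_shape
    a, b, c = config.target_halfaxes
    m = config.border_margin
    slab_len = max(int(round(config.mask_slab_fraction * d)), 1)
    z0 = (d - slab_len) // 2
    z1 = z0 + slab_len - 1
    zr = (z0 + a, z1 - a)
    yr = (b + m, h - 1 - m - b)
    xr = (c + m, w - 1 - m - c)
    for lo, hi, axis in (zr + ("depth slab",), yr + ("rows",), xr + ("cols",)):
        if lo > hi:
            raise ValueError(
                f"target with half-axes {config.target_halfaxes} cannot fit inside "
                f"volume {config.volume_shape} along {axis} "
                f"(margin {m}, slab fraction {config.mask_slab_fraction})"
            )
    return zr, yr, xr


def _sample_center(config: PhantomConfig, rng: np.random.Generator) -> tuple[int, int, int]:
    (zlo, zhi), (ylo, yhi), (xlo, xhi) = _center_ranges(config)
    if config.center_jitter is None:
        return (
            int(rng.integers(zlo, zhi + 1)),
            int(rng.integers(ylo, yhi + 1)),
            int(rng.integers(xlo, xhi + 1)),
        )
    _, h, w = config.volume_shape
    anchor = ((zlo + zhi) // 2, int(round(0.58 * h)), int(round(0.42 * w)))
    j = config.center_jitter
    cz = int(np.clip(anchor[0] + rng.integers(-j, j + 1), zlo, zhi))
    cy = int(np.clip(anchor[1] + rng.integers(-j, j + 1), ylo, yhi))
    cx = int(np.clip(anchor[2] + rng.integers(-j, j + 1), xlo, xhi))
    return cz, cy, cx


def generate_volume(config: PhantomConfig, label: int, subject_id: str) -> VolumeSample:
    """Generate one phantom volume, deterministically per (seed, subject, label)."""
    if label not in (0, 1):
        raise ValueError(f"label must be 0 or 1, got {label!r}")
    rng = _subject_rng(config, label, subject_id)
    d, h, w = config.volume_shape
    a, b, c = config.target_halfaxes
    cz, cy, cx = _sample_center(config, rng)

    template = _pseudo_anatomy(h, w)
    gain = rng.uniform(0.93, 1.07)
    # depth profile fades the anatomy toward the top/bottom slices
    zprof = 0.75 + 0.25 * np.cos(np.linspace(-1, 1, d) * np.pi / 2) ** 2
    image = gain * zprof[:, None, None] * template[None, :, :]

    zz = (np.arange(d) - cz)[:, None, None] / a
    yy = (np.arange(h) - cy)[None, :, None] / b
    xx = (np.arange(w) - cx)[None, None, :] / c
    rho2 = zz**2 + yy**2 + xx**2
    mask = (rho2 <= 1.0).astype(np.uint8)

    bump = np.clip(1.0 - rho2, 0.0, None)
    if label == 0:
        texture = gaussian_filter(bump, sigma=1.5)
    else:
        speckle = gaussian_filter(rng.standard_normal(size=(d, h, w)), sigma=0.8)
        speckle /= max(speckle.std(), 1e-12)
        modul = 1.0 + config.class_contrast * speckle
        shell = (rho2 > (1.0 - 0.35) ** 2) & (rho2 <= 1.0)
        eroded = np.where(shell, 1.0 - 0.8 * config.class_contrast, 1.0)
        texture = gaussian_filter(bump * modul * eroded, sigma=0.6)
    image = image + config.target_amplitude * 1.8 * texture

    if config.noise_sd > 0:
        image = image + rng.normal(0.0, config.noise_sd, size=image.shape)
    return VolumeSample(
        image=image.astype(np.float32), mask=mask, label=label, subject_id=subject_id
    )


def target_texture_statistic(sample: VolumeSample) -> float:
    """Within-target intensity variance — the texture biomarker analogue."""
    vals = sample.image[sample.mask.astype(bool)]
    return float(vals.var())


@dataclass
class PhantomDataset:
    """A manifest of phantom subjects plus lazy volume materialization."""

    config: PhantomConfig
    manifest: pd.DataFrame  # columns: subject_id, label, split

    def load(self, subject_id: str) -> VolumeSample:
        row = self.manifest.loc[self.manifest.subject_id == subject_id]
        if len(row) != 1:
            raise KeyError(f"unknown subject_id {subject_id!r}")
        return generate_volume(self.config, int(row.label.iloc[0]), subject_id)

    def volumes(self, split: str | None = None) -> list[VolumeSample]:
        df = self.manifest if split is None else self.manifest[self.manifest.split == split]
        return [self.load(s) for s in df.subject_id]


def _split_counts(n: int, fractions: Sequence[float]) -> list[int]:
    raw = [f * n for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    rem = n - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)])  # largest remainder first
    for i in range(rem):
        counts[order[i]] += 1
    return counts


def generate_dataset(
    config: PhantomConfig,
    n_per_class: int,
    split_fractions: Sequence[float] = (0.78, 0.22),
    seed: int = 0,
    split_names: Sequence[str] | None = None,
) -> PhantomDataset:
    """Build a subject-level train/test manifest with requested class counts.

    Splitting is by subject, so no subject appears in more than one partition.
    Degenerate splits (any empty partition for either class) fail loudly.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    fr = np.asarray(split_fractions, dtype=float)
    if not np.isclose(fr.sum(), 1.0):
        raise ValueError(f"split fractions must sum to 1, got {split_fractions}")
    if split_names is None:
        split_names = ["train", "test"] if len(fr) == 2 else [f"split{i}" for i in range(len(fr))]
    rng = np.random.default_rng(seed)
    rows = []
    for label in (0, 1):
        counts = _split_counts(n_per_class, fr)
        if min(counts) == 0:
            raise ValueError(
                f"degenerate split: class {label} cannot cover partitions "
                f"{list(split_names)} with {n_per_class} subjects at fractions {list(fr)}"
            )
        ids = [f"C{label}-{i:04d}" for i in range(n_per_class)]
        perm = rng.permutation(n_per_class)
        start = 0
        for name, cnt in zip(split_names, counts):
            for j in perm[start : start + cnt]:
                rows.append((ids[j], label, name))
            start += cnt
    manifest = (
        pd.DataFrame(rows, columns=["subject_id", "label", "split"])
        .sort_values(["split", "label", "subject_id"], kind="stable")
        .reset_index(drop=True)
    )
    return PhantomDataset(config=config, manifest=manifest)
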