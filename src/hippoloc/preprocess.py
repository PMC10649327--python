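"""Volume-to-slice preprocessing: optimal-slice selection, Otsu thresholding of
the mask, largest-component bounding box, resizing and min-max normalization.

Coordinate conventions used throughout the package: 0-based, row-major; a
:class:`BoundingBox` covers the half-open pixel set
``[x, x+width) x [y, y+height)`` (and ``[z, z+depth)`` in 3D), so areas and
intersections are exact integer pixel counts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .phantom import VolumeSample

__all__ = [
    "BoundingBox",
    "SliceSample",
    "NormalizationStats",
    "select_optimal_slice",
    "otsu_threshold",
    "largest_contour_bbox",
    "resize_volume",
    "resize_slice",
    "minmax_normalize",
    "make_slice_dataset",
]


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box with integer, half-open extents."""

    x: int
    y: int
    width: int
    height: int
    z: int | None = None
    depth: int | None = None

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError(f"box must have positive width/height, got {self}")
        if (self.z is None) != (self.depth is None):
            raise ValueError("z and depth must be given together")
        if self.depth is not None and self.depth <= 0:
            raise ValueError("depth must be positive")

    @property
    def is_3d(self) -> bool:
        return self.z is not None

    @property
    def area(self) -> int:
        a = self.width * self.height
        return a * self.depth if self.is_3d else a

    def as_slices(self) -> tuple[slice, ...]:
        sl = (slice(self.y, self.y + self.height), slice(self.x, self.x + self.width))
        if self.is_3d:
            return (slice(self.z, self.z + self.depth),) + sl
        return sl

    def within(self, shape: Sequence[int]) -> bool:
        """True if fully inside an image of the given shape (H, W) or (D, H, W)."""
        if self.is_3d:
            d, h, w = shape
            if not (0 <= self.z and self.z + self.depth <= d):
                return False
        else:
            h, w = shape[-2:]
        return 0 <= self.x and self.x + self.width <= w and 0 <= self.y and self.y + self.height <= h


@dataclass
class SliceSample:
    """One normalized 2D slice with its ground-truth box and class label."""

    image: np.ndarray
    gt_box: BoundingBox
    label: int
    subject_id: str
    slice_index: int

    def __post_init__(self) -> None:
        if self.image.ndim != 2:
            raise ValueError("SliceSample image must be 2D")
        lo, hi = float(self.image.min()), float(self.image.max())
        if lo < 0.0 or hi > 1.0:
            raise ValueError(f"slice intensities must lie in [0,1]; got [{lo}, {hi}]")
        if not self.gt_box.within(self.image.shape):
            raise ValueError("gt_box lies outside image bounds")


@dataclass(frozen=True)
class NormalizationStats:
    vmin: float
    vmax: float

    def __post_init__(self) -> None:
        if not self.vmax > self.vmin:
            raise ValueError(f"degenerate normalization stats: min={self.vmin}, max={self.vmax}")

    @classmethod
    def from_arrays(cls, arrays: Sequence[np.ndarray]) -> "NormalizationStats":
        vmin = min(float(a.min()) for a in arrays)
        vmax = max(float(a.max()) for a in arrays)
        return cls(vmin, vmax)


def select_optimal_slice(mask_volume: np.ndarray) -> int:
    """Index of the slice with the highest mean mask intensity (ties -> lowest)."""
    mask_volume = np.asarray(mask_volume)
    if mask_volume.ndim != 3 or mask_volume.size == 0:
        raise ValueError("mask volume must be a non-empty 3D array")
    means = mask_volume.reshape(mask_volume.shape[0], -1).mean(axis=1)
    if not means.any():
        raise ValueError("all-zero mask volume: no target region present")
    return int(np.argmax(means))


def otsu_threshold(gray_image: np.ndarray) -> float:
    """Otsu's threshold by exhaustive between-class-variance maximization.

    Candidate thresholds are the distinct image values; the split is
    ``value > t``.  Ties resolve to the lowest candidate.  Maximizing the
    between-class variance  w0*w1*(mu0-mu1)^2  is equivalent to minimizing the
    within-class variance over the same splits.
    """
    vals = np.asarray(gray_image, dtype=float).ravel()
    levels, counts = np.unique(vals, return_counts=True)
    if levels.size < 2:
        raise ValueError("Otsu threshold undefined for a constant image")
    counts = counts.astype(float)
    n = vals.size
    csum = np.cumsum(counts)
    cmean = np.cumsum(counts * levels)
    total_mean = cmean[-1] / n
    # split after each level except the last (all-foreground split is empty)
    w0 = csum[:-1] / n
    mu0 = cmean[:-1] / csum[:-1]
    w1 = 1.0 - w0
    mu1 = (cmean[-1] - cmean[:-1]) / (n - csum[:-1])
    between = w0 * w1 * (mu0 - mu1) ** 2
    return float(levels[:-1][int(np.argmax(between))])


_STRUCT_2D = np.ones((3, 3), dtype=bool)  # 8-connectivity
_STRUCT_3D = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity


def largest_contour_bbox(binary_mask: np.ndarray) -> BoundingBox:
    """Tight box of the largest connected foreground component.

    8-connectivity in 2D, 26 in 3D; area ties resolve to the component whose
    first pixel comes earliest in row-major order.
    """
    m = np.asarray(binary_mask) > 0
    if not m.any():
        raise ValueError("empty mask: no foreground component")
    struct = _STRUCT_2D if m.ndim == 2 else _STRUCT_3D
    labels, nlab = ndimage.label(m, structure=struct)
    areas = np.bincount(labels.ravel())[1:]
    best_area = areas.max()
    candidates = np.flatnonzero(areas == best_area) + 1
    if len(candidates) > 1:
        flat = labels.ravel()
        first = [np.flatnonzero(flat == lab)[0] for lab in candidates]
        lab = int(candidates[int(np.argmin(first))])
    else:
        lab = int(candidates[0])
    idx = np.nonzero(labels == lab)
    if m.ndim == 2:
        ys, xs = idx
        return BoundingBox(
            x=int(xs.min()), y=int(ys.min()),
            width=int(xs.max() - xs.min() + 1), height=int(ys.max() - ys.min() + 1),
        )
    zs, ys, xs = idx
    return BoundingBox(
        x=int(xs.min()), y=int(ys.min()),
        width=int(xs.max() - xs.min() + 1), height=int(ys.max() - ys.min() + 1),
        z=int(zs.min()), depth=int(zs.max() - zs.min() + 1),
    )


def _scale_box(box: BoundingBox, sy: float, sx: float) -> BoundingBox:
    x0 = int(round(box.x * sx))
    y0 = int(round(box.y * sy))
    x1 = int(round((box.x + box.width) * sx))
    y1 = int(round((box.y + box.height) * sy))
    return replace(box, x=x0, y=y0, width=max(x1 - x0, 1), height=max(y1 - y0, 1))


def resize_slice(
    image: np.ndarray, target_hw: tuple[int, int], gt_box: BoundingBox | None = None
) -> tuple[np.ndarray, BoundingBox | None]:
    """Bilinear in-plane resize; the box is transformed by the same scale."""
    h, w = image.shape
    th, tw = target_hw
    if th <= 0 or tw <= 0:
        raise ValueError("target dimensions must be positive")
    if (h, w) == (th, tw):
        return image.copy(), gt_box
    out = _sk_resize(image.astype(float), (th, tw), order=1, anti_aliasing=False,
                     preserve_range=True)
    if gt_box is None:
        return out, None
    return out, _scale_box(gt_box, th / h, tw / w)


def _best_depth_window(weights: np.ndarray, depth: int) -> int:
    """Start of the contiguous window of length ``depth`` with maximal weight."""
    csum = np.concatenate([[0.0], np.cumsum(weights)])
    sums = csum[depth:] - csum[:-depth]
    return int(np.argmax(sums))


def resize_volume(
    volume: np.ndarray,
    target_shape: tuple[int, int, int],
    mask: np.ndarray | None = None,
    gt_box: BoundingBox | None = None,
) -> tuple[np.ndarray, np.ndarray | None, BoundingBox | None]:
    """Standardize a volume to ``(depth, H, W)``.

    Depth is reduced by keeping the contiguous window of the requested depth
    with the greatest total mask mass (total image intensity when no mask is
    given); in-plane resizing is bilinear, and the ground-truth box is mapped
    through the same scale factors.
    """
    d, h, w = volume.shape
    td, th, tw = target_shape
    if min(td, th, tw) <= 0:
        raise ValueError("target dimensions must be positive")
    if d < td:
        raise ValueError(f"volume depth {d} is shallower than requested depth {td}")
    weights = (mask.reshape(d, -1).sum(axis=1).astype(float) if mask is not None
               else volume.reshape(d, -1).sum(axis=1).astype(float))
    z0 = _best_depth_window(weights, td)
    vol = volume[z0 : z0 + td]
    msk = mask[z0 : z0 + td] if mask is not None else None
    if (h, w) != (th, tw):
        vol = _sk_resize(vol.astype(float), (td, th, tw), order=1, anti_aliasing=False,
                         preserve_range=True)
        if msk is not None:
            msk = (_sk_resize(msk.astype(float), (td, th, tw), order=0,
                              anti_aliasing=False, preserve_range=True) > 0.5).astype(np.uint8)
    box = None
    if gt_box is not None:
        box = _scale_box(gt_box, th / h, tw / w)
        if gt_box.is_3d:
            z = int(np.clip(gt_box.z - z0, 0, td - 1))
            dep = max(min(gt_box.z + gt_box.depth - z0, td) - z, 1)
            box = replace(box, z=z, depth=dep)
    return vol, msk, box


def minmax_normalize(array: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    """``(v - min) / (max - min)`` with clipping to [0, 1] for out-of-range values."""
    out = (np.asarray(array, dtype=float) - stats.vmin) / (stats.vmax - stats.vmin)
    return np.clip(out, 0.0, 1.0)


def make_slice_dataset(
    volumes: Sequence[VolumeSample],
    target_hw: tuple[int, int] = (256, 256),
    stats: NormalizationStats | None = None,
) -> list[SliceSample]:
    """Volume -> one preprocessed 2D slice each.

    Pipeline per volume: optimal-slice selection on the mask, Otsu threshold of
    the chosen mask slice, largest-component bounding box, in-plane resize,
    then min-max normalization.  ``stats`` should come from the training split
    (computed over the given volumes' selected slices when omitted).
    """
    picked: list[tuple[VolumeSample, int, np.ndarray, BoundingBox]] = []
    for vol in volumes:
        k = select_optimal_slice(vol.mask)
        mask_slice = vol.mask[k]
        thr = otsu_threshold(mask_slice) if len(np.unique(mask_slice)) > 1 else None
        binary = mask_slice > thr if thr is not None else mask_slice > 0
        box = largest_contour_bbox(binary)
        img, box = resize_slice(vol.image[k].astype(float), target_hw, box)
        picked.append((vol, k, img, box))
    if stats is None:
        stats = NormalizationStats.from_arrays([img for _, _, img, _ in picked])
    out = []
    for vol, k, img, box in picked:
        out.append(
            SliceSample(
                image=minmax_normalize(img, stats),
                gt_box=box,
                label=vol.label,
                subject_id=vol.subject_id,
                slice_index=k,
            )
        )
    return out
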