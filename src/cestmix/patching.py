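"""Shift-window patch extraction and crop-and-stitch aggregation.

Coordinates are 0-based, row-major; a patch at origin ``(r, c)`` covers the
half-open window ``[r, r+size) x [c, c+size)``.

The overlap between neighbouring patches is controlled by the stride::

    overlap = (1 - stride / size) * 100%

so the default stride of one quarter of the patch size yields 75% overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import CESTVolume


class GeometryError(ValueError):
    pass


class EmptyRegionError(ValueError):
    pass


@dataclass(frozen=True)
class PatchGrid:
    """Lattice of patch origins for a (size, stride) sliding window."""

    size: int
    stride: int
    origins: tuple[tuple[int, int], ...]
    bbox: tuple[int, int, int, int]  # (rmin, cmin, rmax, cmax) inclusive
    image_shape: tuple[int, int]

    @property
    def overlap(self) -> float:
        return overlap_fraction(self.size, self.stride)

    def __len__(self) -> int:
        return len(self.origins)


@dataclass
class PatchSet:
    """Patches cut from one patient's volume (plus optional label patches)."""

    patches: np.ndarray  # (n, size, size, C)
    origins: tuple[tuple[int, int], ...]
    labels: np.ndarray | None = None  # (n, size, size)
    masks: np.ndarray | None = None  # (n, size, size) bool, ROI membership
    patient_id: str | None = None

    def __len__(self) -> int:
        return self.patches.shape[0]


def overlap_fraction(size: int, stride: int) -> float:
    """Overlap percentage of a sliding window: ``(1 - stride/size) * 100``."""
    if size <= 0 or stride <= 0:
        raise ValueError("size and stride must be positive")
    if stride > size:
        raise ValueError(f"stride {stride} exceeds patch size {size}")
    return (1.0 - stride / size) * 100.0


def _axis_origins(lo: int, hi: int, size: int, stride: int, extent: int) -> list[int]:
    """Origins along one axis covering [lo, hi] (inclusive), clamped to image.

    Regular lattice at ``stride`` from ``lo``; a final clamped origin is
    appended when the far edge would otherwise be uncovered.
    """
    span = hi - lo + 1
    last = hi - size + 1  # origin whose window ends exactly at hi
    if span <= size:
        origins = [lo]
    else:
        origins = list(range(lo, last + 1, stride))
        if origins[-1] != last:
            origins.append(last)
    return [min(max(o, 0), extent - size) for o in origins]


def build_grid(
    region: np.ndarray | tuple[int, int, int, int],
    image_shape: tuple[int, int],
    size: int,
    stride: int,
) -> PatchGrid:
    """Build the patch lattice over a region's bounding box.

    ``region`` is a boolean mask or an inclusive bounding box
    ``(rmin, cmin, rmax, cmax)``.  A region smaller than one patch is
    inflated to ``size x size`` centered on it (clipped to the image), so
    every patient yields at least one patch.  Deterministic.
    """
    H, W = image_shape
    if size > H or size > W:
        raise GeometryError(f"patch size {size} exceeds image extent {image_shape}")
    overlap_fraction(size, stride)  # validates size/stride

    if isinstance(region, np.ndarray):
        mask = np.asarray(region, bool)
        if mask.shape != (H, W):
            raise GeometryError("region mask shape does not match image extent")
        if not mask.any():
            raise EmptyRegionError("empty region")
        rows = np.nonzero(mask.any(axis=1))[0]
        cols = np.nonzero(mask.any(axis=0))[0]
        bbox = (int(rows[0]), int(cols[0]), int(rows[-1]), int(cols[-1]))
    else:
        bbox = tuple(int(v) for v in region)
        if bbox[0] > bbox[2] or bbox[1] > bbox[3]:
            raise EmptyRegionError("empty bounding box")
        if bbox[2] >= H or bbox[3] >= W or bbox[0] < 0 or bbox[1] < 0:
            raise GeometryError("bounding box exceeds image extent")

    rmin, cmin, rmax, cmax = bbox
    # inflate small boxes to one full patch centred on the region
    if rmax - rmin + 1 < size:
        cy = (rmin + rmax) // 2
        rmin = min(max(cy - size // 2, 0), H - size)
        rmax = rmin + size - 1
    if cmax - cmin + 1 < size:
        cx = (cmin + cmax) // 2
        cmin = min(max(cx - size // 2, 0), W - size)
        cmax = cmin + size - 1

    r_orig = _axis_origins(rmin, rmax, size, stride, H)
    c_orig = _axis_origins(cmin, cmax, size, stride, W)
    origins = tuple((r, c) for r in r_orig for c in c_orig)
    return PatchGrid(
        size=size,
        stride=stride,
        origins=origins,
        bbox=(rmin, cmin, rmax, cmax),
        image_shape=(H, W),
    )


def extract_patches(
    volume: CESTVolume | np.ndarray,
    grid: PatchGrid,
    label_image: np.ndarray | None = None,
    roi_mask: np.ndarray | None = None,
    patient_id: str | None = None,
) -> PatchSet:
    """Cut one channel-complete patch per grid origin (pure cropping)."""
    data = volume.data if isinstance(volume, CESTVolume) else np.asarray(volume)
    H, W = data.shape[:2]
    if (H, W) != grid.image_shape:
        raise ValueError("grid image extent does not match volume")
    if label_image is not None and label_image.shape[:2] != (H, W):
        raise ValueError("label image shape does not match volume")
    if roi_mask is not None and roi_mask.shape[:2] != (H, W):
        raise ValueError("ROI mask shape does not match volume")
    s = grid.size
    patches = np.stack([data[r : r + s, c : c + s] for r, c in grid.origins])
    labels = (
        np.stack([label_image[r : r + s, c : c + s] for r, c in grid.origins])
        if label_image is not None
        else None
    )
    masks = (
        np.stack([roi_mask[r : r + s, c : c + s] for r, c in grid.origins])
        if roi_mask is not None
        else None
    )
    return PatchSet(
        patches=patches,
        origins=grid.origins,
        labels=labels,
        masks=masks,
        patient_id=patient_id,
    )


def aggregate_patches(
    predictions: np.ndarray,
    grid: PatchGrid,
    crop: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Stitch per-patch predictions into a full-image map.

    Each patch contributes its central ``(size - 2*crop)^2`` window; a side
    touching the image border or the grid bounding box keeps its uncropped
    edge there, so every covered pixel receives at least one contribution.
    Overlapping contributions are averaged.

    Returns ``(map, valid)`` where ``map`` is (H, W, ...) and ``valid`` flags
    pixels with at least one contribution (others are 0 in the map).
    """
    predictions = np.asarray(predictions, dtype=np.float64)
    if predictions.shape[0] != len(grid):
        raise ValueError("one prediction per grid origin required")
    s = grid.size
    if predictions.shape[1] != s or predictions.shape[2] != s:
        raise ValueError("prediction spatial shape must equal patch size")
    if crop < 0 or 2 * crop >= s:
        raise ValueError(f"crop must satisfy 0 <= crop < size/2, got {crop}")

    H, W = grid.image_shape
    rmin, cmin, rmax, cmax = grid.bbox
    trailing = predictions.shape[3:]
    acc = np.zeros((H, W) + trailing, dtype=np.float64)
    cnt = np.zeros((H, W), dtype=np.float64)

    for pred, (r, c) in zip(predictions, grid.origins):
        top = 0 if (r <= rmin or r == 0) else crop
        left = 0 if (c <= cmin or c == 0) else crop
        bottom = s if (r + s >= rmax + 1 or r + s == H) else s - crop
        right = s if (c + s >= cmax + 1 or c + s == W) else s - crop
        win = pred[top:bottom, left:right]
        acc[r + top : r + bottom, c + left : c + right] += win
        cnt[r + top : r + bottom, c + left : c + right] += 1.0

    valid = cnt > 0
    out = np.zeros_like(acc)
    out[valid] = acc[valid] / cnt[valid][(...,) + (None,) * len(trailing)]
    return out, valid
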