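"""Background-, eye- and ring-mask construction.

The artifact features are measured in air: a *background-mask* of voxels
entirely outside the head is derived from segmentation background maps
(cohort-averaged in normalized space, then mapped back to each native
space and thresholded).  The *eye-mask* restricts it to the region
directly in front of the eyes; the *ring-mask* to an axial slab around
the top of the head.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .core import MriqaError, TransformPair, VolumeGrid

__all__ = [
    "BinaryMask",
    "EyeBoxSpec",
    "DegenerateTransformError",
    "EmptyRegionError",
    "EmptySlabError",
    "ConstantVolumeError",
    "normalize_map",
    "average_background",
    "background_mask",
    "estimate_background_map",
    "build_eye_mask",
    "build_ring_mask",
]

MASK_KINDS = ("background", "eye", "ring")


class DegenerateTransformError(MriqaError):
    """The affine transform is singular (zero determinant)."""


class EmptyRegionError(MriqaError):
    """A requested region (eye boxes, mask) is empty or out of bounds."""


class EmptySlabError(MriqaError):
    """The ring-mask axial slab contains no slices."""


class ConstantVolumeError(MriqaError):
    """A constant volume carries no head/background contrast."""


@dataclass
class BinaryMask:
    """A boolean mask over the subject grid, tagged with its role."""

    data: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.dtype != bool:
            raise ValueError("mask data must be boolean")
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")
        if self.kind not in MASK_KINDS:
            raise ValueError(f"unknown mask kind {self.kind!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def count(self) -> int:
        return int(self.data.sum())


@dataclass
class EyeBoxSpec:
    """Bounding boxes of the two eye sockets in normalized space.

    Each box is ((x0, x1), (y0, y1), (z0, z1)) with half-open 0-based
    voxel ranges.  For real data these must be estimated once per
    normalized template and supplied via configuration; defaults exist
    only for the synthetic phantom geometry.
    """

    left: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    right: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]

    def __post_init__(self) -> None:
        for box in (self.left, self.right):
            for lo, hi in box:
                if hi <= lo:
                    raise ValueError(f"empty eye box range ({lo}, {hi})")

    @property
    def boxes(self):
        return (self.left, self.right)


def _check_transform(t: TransformPair) -> None:
    if t.is_degenerate:
        raise DegenerateTransformError("affine transform has zero determinant")


def _resample(
    data: np.ndarray, matrix: np.ndarray, shape, order: int, cval: float = 0.0
) -> np.ndarray:
    return ndimage.affine_transform(
        data,
        matrix=matrix[:3, :3],
        offset=matrix[:3, 3],
        output_shape=tuple(shape),
        order=order,
        mode="constant",
        cval=cval,
    )


def normalize_map(map_: VolumeGrid, t: TransformPair, cval: float = 0.0) -> VolumeGrid:
    """Resample a probability map onto the normalized grid (forward warp).

    Trilinear interpolation; output values are clipped back to [0, 1].
    ``cval`` fills points that pull from outside the native grid — use
    1.0 for background maps (beyond the imaged volume there is air).
    """
    _check_transform(t)
    # output voxel c' pulls from native coordinate H^-1 c'
    out = _resample(map_.data, t.inverse, t.target_shape, order=1, cval=cval)
    return VolumeGrid(np.clip(out, 0.0, 1.0))


def average_background(normalized_maps: Sequence[VolumeGrid]) -> VolumeGrid:
    """Voxelwise arithmetic mean of normalized background maps."""
    if len(normalized_maps) == 0:
        raise ValueError("need at least one normalized map")
    shapes = {m.shape for m in normalized_maps}
    if len(shapes) != 1:
        raise ValueError(f"maps have mismatched shapes: {shapes}")
    acc = np.zeros(normalized_maps[0].shape)
    for m in normalized_maps:
        acc += m.data
    return VolumeGrid(acc / len(normalized_maps))


def background_mask(
    avg: VolumeGrid, t: TransformPair, threshold: float = 0.5
) -> BinaryMask:
    """Map the averaged background back to native space and threshold it.

    The comparison is closed (``>= threshold``) so the boundary case is
    deterministic.
    """
    _check_transform(t)
    # native voxel c pulls from normalized coordinate H c; beyond the
    # normalized grid there is air, so out-of-bounds pulls read as 1
    shape = t.source_shape or t.target_shape
    native = _resample(avg.data, t.forward, shape, order=1, cval=1.0)
    return BinaryMask(native >= threshold, kind="background")


def estimate_background_map(vol: VolumeGrid) -> VolumeGrid:
    """Morphological fallback background map when no segmentation exists.

    Otsu-thresholds the volume, closes and hole-fills the head mask, and
    returns ``1 - head`` as a pseudo-probability map.  Assumes the head
    is brighter than air; inverted-contrast inputs produce a warning and
    unspecified output.
    """
    data = vol.data
    if data.max() == data.min():
        raise ConstantVolumeError("cannot estimate background of a constant volume")
    th = threshold_otsu(data)
    head = data > th
    if head.mean() > 0.5:
        warnings.warn(
            "more than half the volume classified as head; "
            "contrast may be inverted",
            stacklevel=2,
        )
    head = ndimage.binary_closing(head, iterations=2)
    head = ndimage.binary_fill_holes(head)
    return VolumeGrid((~head).astype(np.float64))


def _warp_box(box, inverse: np.ndarray):
    """Axis-aligned bounding box of a normalized-space box warped to native."""
    (x0, x1), (y0, y1), (z0, z1) = box
    corners = np.array(
        [
            [xx, yy, zz, 1.0]
            for xx in (x0, x1 - 1)
            for yy in (y0, y1 - 1)
            for zz in (z0, z1 - 1)
        ]
    )
    native = corners @ inverse.T
    lo = np.floor(native[:, :3].min(axis=0)).astype(int)
    hi = np.ceil(native[:, :3].max(axis=0)).astype(int) + 1
    return lo, hi


def build_eye_mask(
    bg: BinaryMask, boxes: EyeBoxSpec, t: TransformPair
) -> BinaryMask:
    """Intersect the background-mask with the anterior projection of the
    eye sockets.

    The (x, z) footprint of the warped eye boxes is extended along the
    coronal axis, but only strictly anterior of the first head voxel in
    each (x, z) column, so the mask captures the region directly in front
    of the eyes and nothing behind the head.
    """
    if bg.kind != "background":
        raise ValueError("bg must be a background-mask")
    _check_transform(t)
    nx, ny, nz = bg.shape
    footprint = np.zeros((nx, nz), dtype=bool)
    any_inside = False
    for box in boxes.boxes:
        lo, hi = _warp_box(box, t.inverse)
        x0, x1 = max(lo[0], 0), min(hi[0], nx)
        z0, z1 = max(lo[2], 0), min(hi[2], nz)
        if x1 > x0 and z1 > z0:
            footprint[x0:x1, z0:z1] = True
            any_inside = True
    if not any_inside:
        raise EmptyRegionError("eye boxes warp entirely outside the native grid")

    head = ~bg.data
    has_head = head.any(axis=1)  # (nx, nz)
    first_head_y = np.where(has_head, head.argmax(axis=1), ny)
    y_idx = np.arange(ny)[None, :, None]
    anterior = y_idx < first_head_y[:, None, :]
    mask = bg.data & anterior & footprint[:, None, :]
    return BinaryMask(mask, kind="eye")


def build_ring_mask(
    bg: BinaryMask,
    head_extent: tuple[int, int],
    lower_frac: float = 0.6,
    top_margin: int = 5,
) -> BinaryMask:
    """Restrict the background-mask to an axial slab around the upper head.

    The slab spans ``[z_min + lower_frac * (z_max - z_min), z_max -
    top_margin]`` of the head's axial extent: bounded below to stay clear
    of eye-movement ghosts and above to stay clear of axial wrap-around.
    """
    if bg.kind != "background":
        raise ValueError("bg must be a background-mask")
    z_min, z_max = head_extent
    z_lo = z_min + round(lower_frac * (z_max - z_min))
    z_hi = z_max - top_margin
    if z_lo > z_hi:
        raise EmptySlabError(
            f"ring slab empty: [{z_lo}, {z_hi}] from head extent {head_extent}"
        )
    mask = np.zeros_like(bg.data)
    mask[:, :, z_lo : z_hi + 1] = bg.data[:, :, z_lo : z_hi + 1]
    return BinaryMask(mask, kind="ring")
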