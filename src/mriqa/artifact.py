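"""Artifact-specific features measured in the air background.

ASF1 (eye movement): per axial slice of the eye-mask, the median of the
in-mask positive intensities along the coronal axis forms a noise-vector
over the sagittal axis; ASF1 is the maximum over slices of the summed
noise-vector.

ASF2 (ringing): the same noise-vector on the ring-mask, differenced with
itself at a 20-voxel sagittal offset (absolute difference over the
window); ASF2 is the maximum over slices of the summed difference.

ASF3 (aliasing): over a band of sagittal slices centered on the midline,
each slice is collapsed along the axial axis into a raw-vector over the
coronal axis; ASF3 is the maximum over slices of the raw-vector's
minimum.  A clean gap between the head and any wrapped-around anatomy
drives the minimum toward the background level, so a high ASF3 signals
anatomy folded onto the back of the head.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import MriqaError, VolumeGrid
from .masks import BinaryMask

__all__ = [
    "NoiseVector",
    "AliasRawVector",
    "EmptyArtifactMaskError",
    "noise_vector",
    "asf1_eye",
    "noise_vector_difference",
    "asf2_ring",
    "asf3_alias",
]

DEFAULT_WINDOW = 20
DEFAULT_HALF_WIDTH = 15


class EmptyArtifactMaskError(MriqaError):
    """An eye- or ring-mask needed by a feature is empty."""


@dataclass
class NoiseVector:
    """Median in-mask background intensity along x for one axial slice."""

    values: np.ndarray
    slice_index: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("noise vector must be 1D")
        if np.any(self.values < 0):
            raise ValueError("noise vector values must be >= 0")


@dataclass
class AliasRawVector:
    """Axial sum along z for one sagittal slice, indexed by y."""

    values: np.ndarray
    slice_index: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("raw vector must be 1D")
        if np.any(self.values < 0):
            raise ValueError("raw vector values must be >= 0")


def noise_vector(vol: VolumeGrid, mask: BinaryMask, z0: int) -> NoiseVector:
    """Median of positive in-mask voxels along y, for each x, at slice z0.

    Columns with no positive in-mask voxel yield 0 (the no-noise neutral
    element).  The median of an even count is the midpoint of the two
    central values.
    """
    if mask.kind not in ("eye", "ring"):
        raise ValueError("noise vectors are defined on eye- or ring-masks")
    nx, ny, nz = vol.shape
    if not 0 <= z0 < nz:
        raise IndexError(f"z0={z0} outside [0, {nz})")
    plane = vol.data[:, :, z0]
    sel = mask.data[:, :, z0] & (plane > 0)
    masked = np.ma.masked_array(plane, mask=~sel)
    med = np.ma.median(masked, axis=1).filled(0.0)
    return NoiseVector(np.asarray(med, dtype=np.float64), slice_index=z0)


def _mask_slices(mask: BinaryMask) -> np.ndarray:
    slices = np.where(mask.data.any(axis=(0, 1)))[0]
    if slices.size == 0:
        raise EmptyArtifactMaskError(f"{mask.kind}-mask is empty")
    return slices


def asf1_eye(vol: VolumeGrid, eye_mask: BinaryMask) -> float:
    """Eye-movement feature: max over axial slices of the summed
    noise-vector inside the eye-mask."""
    best = 0.0
    for z0 in _mask_slices(eye_mask):
        best = max(best, float(noise_vector(vol, eye_mask, int(z0)).values.sum()))
    return best


def noise_vector_difference(
    nv: NoiseVector, window: int = DEFAULT_WINDOW
) -> np.ndarray:
    """Absolute difference of the noise-vector with its window-shifted
    self, divided by the window; length is len(nv) - window."""
    v = nv.values
    if v.size <= window:
        raise ValueError(f"noise vector length {v.size} must exceed window {window}")
    return np.abs(v[window:] - v[:-window]) / window


def asf2_ring(
    vol: VolumeGrid, ring_mask: BinaryMask, window: int = DEFAULT_WINDOW
) -> float:
    """Ringing feature: max over ring-mask slices of the summed
    noise-vector difference."""
    if vol.shape[0] <= window:
        raise ValueError("sagittal extent must exceed the difference window")
    best = 0.0
    for z1 in _mask_slices(ring_mask):
        nv = noise_vector(vol, ring_mask, int(z1))
        best = max(best, float(noise_vector_difference(nv, window).sum()))
    return best


def asf3_alias(
    vol: VolumeGrid,
    midline: int | str = "auto",
    half_width: int = DEFAULT_HALF_WIDTH,
) -> float:
    """Aliasing feature: max over a sagittal band of min-over-y raw vectors.

    The band holds ``2 * half_width`` slices centered on ``midline``
    (``"auto"`` uses nx // 2).  Each slice's raw vector is the intensity
    sum along z per coronal position y; its minimum over the full y range
    is taken, and the maximum of those minima over the band is returned.
    """
    nx = vol.shape[0]
    xm = nx // 2 if midline == "auto" else int(midline)
    x_lo, x_hi = xm - half_width, xm + half_width
    if x_lo < 0 or x_hi > nx:
        raise ValueError(
            f"sagittal band [{x_lo}, {x_hi}) exceeds volume extent {nx}"
        )
    best = 0.0
    for x1 in range(x_lo, x_hi):
        raw = AliasRawVector(vol.data[x1].sum(axis=1), slice_index=x1)
        best = max(best, float(raw.values.min()))
    return best
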