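"""Volumetric quality features: intensity histogram (VF1), tissue-class
probability histograms (VF2), and the gray/white contrast score (VF3).

All histograms use 100 bins over [0, domain_max] with right-closed bins
(lo, hi]; the very first bin is additionally closed at zero so that
exact-zero voxels are counted and the histogram conserves the voxel
count.  Bin ``n`` (1-based) covers ((n-1) * delta, n * delta] with
``delta = domain_max / 100``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import MriqaError, TissueMapSet, VolumeGrid

__all__ = [
    "Histogram100",
    "ContrastStats",
    "AllZeroVolumeError",
    "EmptyClassMaskError",
    "vf1_histogram",
    "vf2_class_histogram",
    "gw_t_score",
]

N_BINS = 100


class AllZeroVolumeError(MriqaError):
    """The volume has no positive intensity, so no intensity range exists."""


class EmptyClassMaskError(MriqaError):
    """A thresholded tissue class mask contains no voxels."""


@dataclass
class Histogram100:
    """A 100-bin histogram over [0, domain_max]."""

    counts: np.ndarray
    bin_width: float
    domain_max: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_BINS,):
            raise ValueError("histogram must have exactly 100 bins")
        if np.any(self.counts < 0):
            raise ValueError("bin counts must be non-negative")

    @property
    def centers(self) -> np.ndarray:
        """Bin centers: (2n - 1) * delta / 2 for n = 1..100."""
        return (2 * np.arange(1, N_BINS + 1) - 1) * self.bin_width / 2.0


def _bin_counts(values: np.ndarray, domain_max: float) -> np.ndarray:
    """Right-closed binning of values in [0, domain_max] into 100 bins.

    Exact zeros land in bin 1 (closed lower edge); domain_max lands in
    bin 100.
    """
    delta = domain_max / N_BINS
    idx = np.ceil(values / delta).astype(np.int64) - 1
    idx = np.clip(idx, 0, N_BINS - 1)
    return np.bincount(idx.ravel(), minlength=N_BINS)


def vf1_histogram(vol: VolumeGrid) -> Histogram100:
    """Intensity histogram of the whole volume (feature VF1).

    The intensity range [0, I_max] is divided into 100 bins of width
    I_max / 100, where I_max is the volume's maximum intensity.  Counts
    sum to the total voxel count.
    """
    i_max = float(vol.data.max())
    if i_max <= 0:
        raise AllZeroVolumeError("volume is identically zero; no intensity range")
    counts = _bin_counts(vol.data, i_max)
    return Histogram100(counts, bin_width=i_max / N_BINS, domain_max=i_max)


def vf2_class_histogram(map_: VolumeGrid) -> Histogram100:
    """Probability histogram of one tissue map (feature VF2_c).

    The domain is fixed to [0, 1] (p_max = 1) regardless of the observed
    maximum, so bins are comparable across subjects and classes.
    """
    if map_.data.max() > 1.0:
        raise ValueError("probability map has values above 1")
    counts = _bin_counts(map_.data, 1.0)
    return Histogram100(counts, bin_width=1.0 / N_BINS, domain_max=1.0)


@dataclass
class ContrastStats:
    """Gray/white contrast statistics behind the gw_t_score (VF3)."""

    mu_gm: float
    mu_wm: float
    var_gm: float
    var_wm: float
    x1: float
    gw_t_score: float


def _masked_nonzero(vol: VolumeGrid, maps: TissueMapSet, cls: str) -> np.ndarray:
    mask = maps[cls].data >= 0.5
    if not mask.any():
        raise EmptyClassMaskError(f"thresholded {cls} mask is empty")
    vals = vol.data[mask]
    vals = vals[vals > 0]  # zeros inside the mask are mask artifacts, not tissue
    if vals.size == 0:
        raise EmptyClassMaskError(f"{cls} mask contains no positive intensities")
    return vals


def gw_t_score(
    vol: VolumeGrid, maps: TissueMapSet, mode: str = "intensity"
) -> ContrastStats:
    """Gray/white-matter contrast score (feature VF3).

    Binary GM and WM masks are formed by thresholding the probability
    maps at 0.5 and applied to the volume.  Two readings of the class
    statistics are provided:

    * ``mode="intensity"`` (default): mean and variance of the masked
      non-zero voxel *intensities* — the distribution-contrast reading.
      For well-separated classes with means m_WM, m_GM and standard
      deviations s, the score approaches
      (m_WM - m_GM) / sqrt(s_GM^2 + s_WM^2).
    * ``mode="literal"``: mean and variance of the 100 histogram bin
      *counts* of each masked image.  Note that the count mean is just
      (number of masked voxels) / 100, so the mean difference is
      independent of image contrast; this reading is kept for fidelity
      and comparison, not as the default.

    The score is x1 / sqrt(var_GM + var_WM) with x1 = mu_WM - mu_GM.
    """
    if mode not in ("intensity", "literal"):
        raise ValueError(f"unknown mode {mode!r}")
    stats = {}
    for cls in ("gm", "wm"):
        vals = _masked_nonzero(vol, maps, cls)
        if mode == "intensity":
            mu = float(vals.mean())
            var = float(vals.var())
        else:
            counts = _bin_counts(vals, float(vals.max())).astype(np.float64)
            mu = float(counts.mean())
            var = float(counts.var())
        stats[cls] = (mu, var)
    mu_gm, var_gm = stats["gm"]
    mu_wm, var_wm = stats["wm"]
    x1 = mu_wm - mu_gm
    denom = np.sqrt(var_gm + var_wm)
    if denom == 0:
        if x1 == 0:
            score = 0.0
        else:
            raise ZeroDivisionError("zero pooled variance with nonzero contrast")
    else:
        score = x1 / denom
    return ContrastStats(
        mu_gm=mu_gm,
        mu_wm=mu_wm,
        var_gm=var_gm,
        var_wm=var_wm,
        x1=x1,
        gw_t_score=float(score),
    )
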