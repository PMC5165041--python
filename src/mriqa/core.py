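"""Domain types, coordinate conventions, and volume / label-table I/O.

Coordinate convention used throughout the package (0-based voxel indices):

* axis 0 (``x``): sagittal index, left -> right
* axis 1 (``y``): coronal index, anterior -> posterior
* axis 2 (``z``): axial index, inferior -> superior

NIfTI files are reoriented on load so that these axis meanings hold
regardless of the on-disk orientation.  All published slice coordinates in
the field are conventionally 1-based; this package is 0-based internally
and converts at its boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "ARTIFACTS",
    "SEVERITIES",
    "STAGE1_COLORS",
    "FINAL_CATEGORIES",
    "TISSUE_CLASSES",
    "MriqaError",
    "VolumeFileMissingError",
    "VolumeHeaderError",
    "NonThreeDimensionalError",
    "LabelVocabularyError",
    "LabelConsistencyError",
    "MajorityTieError",
    "VolumeGrid",
    "TissueMapSet",
    "TransformPair",
    "QualityLabel",
    "FeatureVector",
    "read_volume",
    "write_volume",
    "read_label_table",
    "write_label_table",
    "majority_vote",
]

ARTIFACTS = (
    "eye_movement",
    "ringing",
    "aliasing",
    "grainy",
    "head_movement",
    "teeth_filling",
)
SEVERITIES = ("heavy", "moderate", "slight", "none")
STAGE1_COLORS = ("green", "yellow", "red")
FINAL_CATEGORIES = ("usable", "not-usable")
TISSUE_CLASSES = ("gm", "wm", "csf", "skull", "fat", "background")


class MriqaError(Exception):
    """Base class for package-specific errors."""


class VolumeFileMissingError(MriqaError, FileNotFoundError):
    """The requested volume file does not exist."""


class VolumeHeaderError(MriqaError):
    """The file exists but its header could not be parsed as NIfTI-1."""


class NonThreeDimensionalError(MriqaError):
    """The image on disk is not a 3D volume."""


class LabelVocabularyError(MriqaError):
    """A label value is outside the closed rating vocabulary."""


class LabelConsistencyError(MriqaError):
    """Stage-I color and the final usable/not-usable category disagree."""


class MajorityTieError(MriqaError):
    """A majority vote ended in an exact tie."""


@dataclass
class VolumeGrid:
    """A 3D scalar image on a voxel grid.

    ``data`` holds intensities in arbitrary scanner units, finite and
    non-negative.  ``meta`` is free-form bookkeeping (phantom geometry,
    provenance); it is never serialized.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise NonThreeDimensionalError(
                f"expected a 3D array, got ndim={self.data.ndim}"
            )
        if min(self.data.shape) < 1:
            raise ValueError("every axis must have at least one voxel")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must be finite")
        if self.data.min() < 0:
            raise ValueError("volume intensities must be >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def copy(self) -> "VolumeGrid":
        return VolumeGrid(self.data.copy(), self.voxel_size, dict(self.meta))


@dataclass
class TissueMapSet:
    """Per-subject tissue probability maps, one per class in TISSUE_CLASSES.

    Every voxel value lies in [0, 1] and all maps share the parent volume's
    shape.  The maps produced by unified segmentation (or by the phantom
    generator) additionally form a partition of unity, but that is not
    enforced here because thresholded or resampled maps may not.
    """

    maps: dict[str, VolumeGrid]

    def __post_init__(self) -> None:
        missing = set(TISSUE_CLASSES) - set(self.maps)
        if missing:
            raise ValueError(f"missing tissue classes: {sorted(missing)}")
        shapes = {m.shape for m in self.maps.values()}
        if len(shapes) != 1:
            raise ValueError(f"tissue maps have mismatched shapes: {shapes}")
        for name, m in self.maps.items():
            if m.data.min() < 0 or m.data.max() > 1:
                raise ValueError(f"map {name!r} has values outside [0, 1]")

    def __getitem__(self, cls: str) -> VolumeGrid:
        return self.maps[cls]

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.maps.values())).shape


@dataclass
class TransformPair:
    """Forward (native -> normalized) and inverse affine transforms.

    Both are 4x4 homogeneous matrices acting on voxel coordinates.
    ``target_shape`` is the normalized-grid size; ``source_shape`` the
    native-grid size (defaults to ``target_shape``).
    """

    forward: np.ndarray
    inverse: np.ndarray
    target_shape: tuple[int, int, int]
    source_shape: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        self.forward = np.asarray(self.forward, dtype=np.float64)
        self.inverse = np.asarray(self.inverse, dtype=np.float64)
        if self.forward.shape != (4, 4) or self.inverse.shape != (4, 4):
            raise ValueError("transforms must be 4x4 homogeneous matrices")
        if self.source_shape is None:
            self.source_shape = tuple(self.target_shape)  # type: ignore[assignment]
        resid = self.inverse @ self.forward - np.eye(4)
        if np.abs(resid).max() > 1e-6:
            raise ValueError("inverse is not the inverse of forward")

    @classmethod
    def identity(cls, shape: tuple[int, int, int]) -> "TransformPair":
        eye = np.eye(4)
        return cls(eye, eye.copy(), tuple(shape))

    @property
    def is_degenerate(self) -> bool:
        return abs(np.linalg.det(self.forward[:3, :3])) < 1e-12


@dataclass
class QualityLabel:
    """Visual-inspection label for one volume.

    ``stage1_color`` is the triage color (green / yellow / red);
    ``severity`` rates each recurring artifact on the 4-degree scale
    heavy / moderate / slight / none; ``final`` is the usable /
    not-usable category.  Green forces usable and red forces not-usable;
    only yellow volumes are decided by the rater committee.
    """

    subject_id: str
    stage1_color: str
    severity: dict[str, str]
    final: str

    def __post_init__(self) -> None:
        if self.stage1_color not in STAGE1_COLORS:
            raise LabelVocabularyError(
                f"{self.subject_id}: unknown stage-I color {self.stage1_color!r}"
            )
        if self.final not in FINAL_CATEGORIES:
            raise LabelVocabularyError(
                f"{self.subject_id}: unknown final category {self.final!r}"
            )
        for art in ARTIFACTS:
            sev = self.severity.get(art)
            if sev not in SEVERITIES:
                raise LabelVocabularyError(
                    f"{self.subject_id}: artifact {art!r} has severity {sev!r}, "
                    f"expected one of {SEVERITIES}"
                )
        if self.stage1_color == "green" and self.final != "usable":
            raise LabelConsistencyError(
                f"{self.subject_id}: green volumes must be usable"
            )
        if self.stage1_color == "red" and self.final != "not-usable":
            raise LabelConsistencyError(
                f"{self.subject_id}: red volumes must be not-usable"
            )


@dataclass
class FeatureVector:
    """All quality features for one subject.

    vf1: 100 intensity-histogram counts; vf2_*: 100 tissue-probability
    histogram counts per class; vf3: gray/white contrast t-like score;
    asf1..asf3: eye-movement, ringing and aliasing artifact features.
    """

    subject_id: str
    vf1: np.ndarray
    vf2_gm: np.ndarray
    vf2_wm: np.ndarray
    vf2_csf: np.ndarray
    vf3: float
    asf1: float
    asf2: float
    asf3: float

    def __post_init__(self) -> None:
        for name in ("vf1", "vf2_gm", "vf2_wm", "vf2_csf"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (100,):
                raise ValueError(f"{name} must have exactly 100 entries")
            if np.any(arr < 0) or not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} counts must be finite and >= 0")
            setattr(self, name, arr.astype(np.int64))
        for name in ("asf1", "asf2", "asf3"):
            val = float(getattr(self, name))
            if not np.isfinite(val) or val < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if not np.isfinite(self.vf3):
            raise ValueError("vf3 must be finite")


# ---------------------------------------------------------------------------
# Volume I/O
# ---------------------------------------------------------------------------

# Internally y runs anterior -> posterior; RAS+ stores y posterior ->
# anterior, so the y axis is flipped between disk and memory.


def read_volume(path: str | Path) -> VolumeGrid:
    """Read a NIfTI-1 volume and reorient it to the package convention.

    Small negative values (interpolation overshoot) are clamped to zero
    with a warning.  Raises :class:`VolumeFileMissingError`,
    :class:`VolumeHeaderError` or :class:`NonThreeDimensionalError`.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeFileMissingError(str(path))
    try:
        img = nib.load(str(path))
        img = nib.as_closest_canonical(img)
        data = np.asanyarray(img.dataobj, dtype=np.float64)
        zooms = img.header.get_zooms()[:3]
    except MriqaError:
        raise
    except Exception as exc:  # nibabel raises many concrete types
        raise VolumeHeaderError(f"{path}: unreadable NIfTI header ({exc})") from exc
    data = np.squeeze(data) if data.ndim > 3 and all(
        s == 1 for s in data.shape[3:]
    ) else data
    if data.ndim != 3:
        raise NonThreeDimensionalError(
            f"{path}: non-3D image (shape {data.shape})"
        )
    if data.min() < 0:
        warnings.warn(
            f"{path}: {int((data < 0).sum())} negative voxels clamped to 0",
            stacklevel=2,
        )
        data = np.clip(data, 0, None)
    data = data[:, ::-1, :].copy()  # RAS -> anterior-first y
    return VolumeGrid(data, voxel_size=tuple(float(z) for z in zooms))


def write_volume(vol: VolumeGrid, path: str | Path) -> None:
    """Write a VolumeGrid as NIfTI-1 in RAS+ orientation."""
    data = vol.data[:, ::-1, :]
    affine = np.diag(list(vol.voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(np.ascontiguousarray(data), affine), str(path))


# ---------------------------------------------------------------------------
# Label tables
# ---------------------------------------------------------------------------

LABEL_COLUMNS = ["subject_id", "stage1_color", *ARTIFACTS, "final"]


def read_label_table(path: str | Path) -> list[QualityLabel]:
    """Read a CSV of visual-inspection labels.

    Required columns: subject_id, stage1_color, one severity column per
    artifact, final.  Invariants of :class:`QualityLabel` are enforced
    per row; violations name the offending subject.
    """
    frame = pd.read_csv(path, dtype=str)
    missing = set(LABEL_COLUMNS) - set(frame.columns)
    if missing:
        raise LabelVocabularyError(f"label table missing columns {sorted(missing)}")
    labels = []
    for _, row in frame.iterrows():
        labels.append(
            QualityLabel(
                subject_id=str(row["subject_id"]),
                stage1_color=str(row["stage1_color"]),
                severity={a: str(row[a]) for a in ARTIFACTS},
                final=str(row["final"]),
            )
        )
    return labels


def write_label_table(labels: Sequence[QualityLabel], path: str | Path) -> None:
    rows = [
        {
            "subject_id": lab.subject_id,
            "stage1_color": lab.stage1_color,
            **{a: lab.severity[a] for a in ARTIFACTS},
            "final": lab.final,
        }
        for lab in labels
    ]
    pd.DataFrame(rows, columns=LABEL_COLUMNS).to_csv(path, index=False)


def majority_vote(votes: Iterable[str]) -> str:
    """Resolve a rater committee's usable / not-usable votes.

    Returns the category with strictly more votes; an exact tie raises
    :class:`MajorityTieError` (committees are odd-sized in practice).
    """
    votes = list(votes)
    if not votes:
        raise ValueError("empty vote list")
    bad = set(votes) - set(FINAL_CATEGORIES)
    if bad:
        raise LabelVocabularyError(f"unknown vote values {sorted(bad)}")
    n_usable = votes.count("usable")
    n_not = len(votes) - n_usable
    if n_usable == n_not:
        raise MajorityTieError(f"tie among {len(votes)} votes")
    return "usable" if n_usable > n_not else "not-usable"
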