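"""End-to-end feature extraction: volume + tissue maps -> FeatureVector.

The cohort path follows the published mask recipe: every subject's
background probability map is warped to normalized space, the maps are
averaged across the cohort, and the average is warped back to each
native space and thresholded into the subject's background-mask.  The
single-subject path degenerates to the same recipe with a cohort of one.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .artifact import asf1_eye, asf2_ring, asf3_alias
from .core import FeatureVector, QualityLabel, TissueMapSet, TransformPair, VolumeGrid
from .masks import (
    BinaryMask,
    EyeBoxSpec,
    average_background,
    background_mask,
    build_eye_mask,
    build_ring_mask,
    normalize_map,
)
from .phantom import phantom_eye_boxes
from .volumetric import gw_t_score, vf1_histogram, vf2_class_histogram

__all__ = [
    "head_z_extent",
    "extract_features",
    "extract_cohort_features",
    "features_to_frame",
    "default_phantom_eye_boxes",
]

FEATURE_COLUMNS = (
    ["subject_id", "vf3", "asf1", "asf2", "asf3"]
    + [f"vf1_{i:03d}" for i in range(100)]
    + [f"vf2{c}_{i:03d}" for c in ("gm", "wm", "csf") for i in range(100)]
)


def head_z_extent(maps: TissueMapSet) -> tuple[int, int]:
    """Axial extent of the head, from the background probability map."""
    head = maps["background"].data < 0.5
    zs = np.flatnonzero(head.any(axis=(0, 1)))
    if zs.size == 0:
        raise ValueError("no head voxels found in tissue maps")
    return int(zs[0]), int(zs[-1])


def default_phantom_eye_boxes(shape) -> EyeBoxSpec:
    left, right = phantom_eye_boxes(shape)
    return EyeBoxSpec(left=left, right=right)


def extract_features(
    vol: VolumeGrid,
    maps: TissueMapSet,
    transform: TransformPair,
    eye_boxes: EyeBoxSpec,
    bg: BinaryMask | None = None,
    subject_id: str = "",
    ring_lower_frac: float = 0.6,
    ring_top_margin: int = 5,
    window: int = 20,
    midline: int | str = "auto",
    half_width: int = 15,
    gw_mode: str = "intensity",
) -> FeatureVector:
    """Compute all six feature groups for one subject.

    ``bg`` is the subject's background-mask; when omitted it is derived
    from the subject's own background map (a cohort of one).
    """
    if bg is None:
        normalized = normalize_map(maps["background"], transform, cval=1.0)
        bg = background_mask(average_background([normalized]), transform)
    eye_mask = build_eye_mask(bg, eye_boxes, transform)
    ring_mask = build_ring_mask(
        bg, head_z_extent(maps), lower_frac=ring_lower_frac, top_margin=ring_top_margin
    )
    return FeatureVector(
        subject_id=subject_id,
        vf1=vf1_histogram(vol).counts,
        vf2_gm=vf2_class_histogram(maps["gm"]).counts,
        vf2_wm=vf2_class_histogram(maps["wm"]).counts,
        vf2_csf=vf2_class_histogram(maps["csf"]).counts,
        vf3=gw_t_score(vol, maps, mode=gw_mode).gw_t_score,
        asf1=asf1_eye(vol, eye_mask),
        asf2=asf2_ring(vol, ring_mask, window=window),
        asf3=asf3_alias(vol, midline=midline, half_width=half_width),
    )


def extract_cohort_features(
    cohort: Sequence[tuple],
    eye_boxes: EyeBoxSpec | None = None,
    **feature_params,
) -> tuple[pd.DataFrame, list[QualityLabel]]:
    """Extract features for a cohort with a shared averaged background.

    ``cohort`` holds (volume, maps, transform, label) tuples as produced
    by :func:`mriqa.phantom.generate_cohort`.  ``eye_boxes`` defaults to
    the phantom geometry of the normalized grid.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    normalized = [
        normalize_map(m["background"], t, cval=1.0) for _, m, t, _ in cohort
    ]
    avg = average_background(normalized)
    if eye_boxes is None:
        eye_boxes = default_phantom_eye_boxes(avg.shape)
    rows, labels = [], []
    for vol, maps, transform, label in cohort:
        bg = background_mask(avg, transform)
        fv = extract_features(
            vol,
            maps,
            transform,
            eye_boxes,
            bg=bg,
            subject_id=label.subject_id,
            **feature_params,
        )
        rows.append(fv)
        labels.append(label)
    return features_to_frame(rows), labels


def features_to_frame(features: Sequence[FeatureVector]) -> pd.DataFrame:
    """One row per subject in the extract CSV column layout."""
    records = []
    for fv in features:
        rec = {
            "subject_id": fv.subject_id,
            "vf3": fv.vf3,
            "asf1": fv.asf1,
            "asf2": fv.asf2,
            "asf3": fv.asf3,
        }
        rec.update({f"vf1_{i:03d}": int(v) for i, v in enumerate(fv.vf1)})
        for cls, arr in (("gm", fv.vf2_gm), ("wm", fv.vf2_wm), ("csf", fv.vf2_csf)):
            rec.update({f"vf2{cls}_{i:03d}": int(v) for i, v in enumerate(arr)})
        records.append(rec)
    return pd.DataFrame(records, columns=FEATURE_COLUMNS)
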