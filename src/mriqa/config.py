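"""YAML configuration with package defaults.

Keys mirror the module surfaces: ``masks.eye_boxes`` (per-eye normalized
bounding boxes, required for real data), ``masks.ring.lower_frac`` /
``masks.ring.top_margin``, ``asf.window`` / ``asf.midline`` /
``asf.half_width``, ``svm.kernel`` / ``svm.C`` / ``svm.gamma``, and
``histograms.normalize``.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

__all__ = ["DEFAULTS", "load_config"]

DEFAULTS: dict = {
    "masks": {
        "eye_boxes": None,  # [[ [x0,x1],[y0,y1],[z0,z1] ], ...]; phantom default used if None
        "ring": {"lower_frac": 0.6, "top_margin": 5},
    },
    "asf": {"window": 20, "midline": "auto", "half_width": 15},
    "svm": {"kernel": "rbf", "C": 1.0, "gamma": "median"},
    "histograms": {"normalize": False},
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML config file merged over the package defaults."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValueError(f"config root must be a mapping, got {type(user).__name__}")
    return _merge(DEFAULTS, user)
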