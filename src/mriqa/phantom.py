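"""Synthetic head phantoms with parametric artifact injection.

The phantom is an ellipsoidal head (skull/fat shell, CSF rim, gray-matter
shell, white-matter core, ventricles), two eye spheres protruding from the
anterior face, and a nose running from the head front to the anterior edge
of the grid.  Ground-truth tissue probability maps and the affine
registration to a common template accompany each phantom, so the full
feature pipeline can be exercised with known labels.

Artifact injection is done in image space: ghosting is modeled as shifted,
attenuated replicas of the bright source structure (eyes, upper skull rim)
and wrap-around aliasing as a modular copy of the anterior nose planes onto
the posterior edge of the field of view.  Image-space injection keeps the
support of every artifact analytically known, which is what the background
features measure; no MR physics is simulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .core import (
    ARTIFACTS,
    TISSUE_CLASSES,
    QualityLabel,
    TissueMapSet,
    TransformPair,
    VolumeGrid,
)

__all__ = [
    "PhantomSpec",
    "ArtifactSpec",
    "DEFAULT_TISSUE_MEANS",
    "generate_head_phantom",
    "inject_eye_movement",
    "inject_ringing",
    "inject_aliasing",
    "generate_cohort",
    "severity_from_amplitude",
    "phantom_eye_boxes",
]

# T1-weighted ordering: background << CSF < GM < WM < fat/skull.
DEFAULT_TISSUE_MEANS = {
    "background": 0.0,
    "csf": 50.0,
    "gm": 120.0,
    "wm": 180.0,
    "fat": 220.0,
    "skull": 240.0,
}

# Severity cutoffs for the synthetic label map: only the ordering matters.
SEVERITY_CUTOFFS = ((0.10, "none"), (0.35, "slight"), (0.65, "moderate"))

_LABEL_CODES = {name: i for i, name in enumerate(TISSUE_CLASSES)}


@dataclass
class PhantomSpec:
    """Parameters of the synthetic head.

    The default shape of 124x128x128 voxels matches a typical sagittal
    T1 acquisition with 124 sagittal slices.  ``noise_sd`` is additive
    Gaussian noise in scanner units (clipped at zero), roughly 2% of the
    white-matter mean by default.
    """

    shape: tuple[int, int, int] = (124, 128, 128)
    tissue_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_MEANS)
    )
    noise_sd: float = 3.0
    seed: int = 0
    softening_sigma: float = 0.7
    semi_scale: tuple[float, float, float] = (1.0, 1.0, 1.0)
    vent_scale: float = 1.0

    def __post_init__(self) -> None:
        m = self.tissue_means
        if not (m["wm"] > m["gm"] > m["csf"] > m["background"]):
            raise ValueError("tissue means must satisfy WM > GM > CSF > background")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if min(self.semi_scale) <= 0 or self.vent_scale <= 0:
            raise ValueError("scale factors must be positive")


@dataclass
class ArtifactSpec:
    """Per-subject artifact amplitudes, each in [0, 1] (grain unbounded)."""

    eye_amplitude: float = 0.0
    ring_amplitude: float = 0.0
    alias_amplitude: float = 0.0
    grain_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("eye_amplitude", "ring_amplitude", "alias_amplitude"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.grain_amplitude < 0:
            raise ValueError("grain_amplitude must be >= 0")


def _ellipsoid(coords, center, semi) -> np.ndarray:
    x, y, z = coords
    return (
        ((x - center[0]) / semi[0]) ** 2
        + ((y - center[1]) / semi[1]) ** 2
        + ((z - center[2]) / semi[2]) ** 2
    ) <= 1.0


def generate_head_phantom(
    spec: PhantomSpec | None = None,
) -> tuple[VolumeGrid, TissueMapSet, TransformPair]:
    """Build a head phantom with ground-truth maps and registration.

    Every subject is the affine image of one fixed template: the label
    geometry is evaluated on the template coordinates of each native
    voxel (the forward map of the per-subject head scaling), so the
    returned transform registers all subjects exactly.  Geometry needed
    by the injectors (eye centers, nose extent, head bounding
    coordinates, the hard label array) is stored in ``vol.meta``.
    """
    spec = spec or PhantomSpec()
    nx, ny, nz = spec.shape
    if min(spec.shape) < 32:
        raise ValueError(f"shape {spec.shape} too small: need >= 32 per axis")

    x, y, z = np.ogrid[0:nx, 0:ny, 0:nz]
    cx, cy, cz = 0.5 * nx, 0.45 * ny, 0.45 * nz
    sx, sy, sz = spec.semi_scale
    # template coordinates of each native voxel (forward affine)
    xw = cx + (x - cx) / sx
    yw = cy + (y - cy) / sy
    zw = cz + (z - cz) / sz
    coords = (xw, yw, zw)
    ax, ay, az = 0.32 * nx, 0.30 * ny, 0.38 * nz

    rho = np.sqrt(
        ((xw - cx) / ax) ** 2 + ((yw - cy) / ay) ** 2 + ((zw - cz) / az) ** 2
    )
    labels = np.full(spec.shape, _LABEL_CODES["background"], dtype=np.int8)
    shells = [
        (1.00, "skull"),
        (0.94, "fat"),
        (0.88, "csf"),   # subarachnoid CSF rim
        (0.82, "gm"),
        (0.62, "wm"),
    ]
    for radius, name in shells:
        labels[rho <= radius] = _LABEL_CODES[name]

    # Lateral ventricles inside the white-matter core (size varies beyond
    # the affine, emulating residual anatomical variability).
    v = spec.vent_scale
    for side in (-1, 1):
        vent = _ellipsoid(
            coords,
            (cx + side * 0.06 * nx, cy, cz),
            (0.05 * nx * v, 0.10 * ny * v, 0.08 * nz * v),
        )
        labels[vent] = _LABEL_CODES["csf"]

    # Eye spheres half-embedded in the anterior face at eye height.
    eye_radius = 0.05 * ny
    eye_centers = []
    for side in (-1, 1):
        ex, ez = cx + side * 0.13 * nx, cz
        inside = 1.0 - ((ex - cx) / ax) ** 2 - ((ez - cz) / az) ** 2
        ey = cy - ay * math.sqrt(max(inside, 0.0))
        eye = ((xw - ex) ** 2 + (yw - ey) ** 2 + (zw - ez) ** 2) <= eye_radius**2
        labels[eye] = _LABEL_CODES["fat"]
        # native-space center, for the ghost injector
        eye_centers.append(
            (
                float(cx + (ex - cx) * sx),
                float(cy + (ey - cy) * sy),
                float(cz + (ez - cz) * sz),
            )
        )

    # Nose: a blunt (quartic in y) protrusion running from the head front
    # to the anterior edge of the grid, so its coronal cross-sections stay
    # nearly constant until the tip.
    nose_semi = (0.16 * nx, 0.22 * ny, 0.08 * nz)
    nose = (
        ((xw - cx) / nose_semi[0]) ** 2
        + (yw / nose_semi[1]) ** 4
        + ((zw - 0.28 * nz) / nose_semi[2]) ** 2
    ) <= 1.0
    labels[nose & (labels == _LABEL_CODES["background"])] = _LABEL_CODES["fat"]

    means = np.array(
        [spec.tissue_means[name] for name in TISSUE_CLASSES], dtype=np.float64
    )
    data = means[labels]
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sd, size=spec.shape)
        data = np.clip(data, 0.0, None)

    head = labels != _LABEL_CODES["background"]
    head_y = np.where(head.any(axis=(0, 2)))[0]
    head_z = np.where(head.any(axis=(0, 1)))[0]
    nose_planes = np.where(
        (nose & head).any(axis=(0, 2))
    )[0]

    meta = {
        "phantom": True,
        "labels": labels,
        "eye_centers": eye_centers,
        "eye_radius": float(eye_radius * max(spec.semi_scale)),
        "nose_y_planes": (int(nose_planes.min()), int(nose_planes.max())),
        "head_y_max": int(head_y.max()),
        "head_z_extent": (int(head_z.min()), int(head_z.max())),
        "tissue_means": dict(spec.tissue_means),
        "noise_sd": spec.noise_sd,
    }
    vol = VolumeGrid(data, meta=meta)

    # Probabilities: the air/head boundary stays crisp (segmentation is
    # confident about air) while the head classes are softened against
    # each other and renormalized, so they partition unity exactly.
    maps = {}
    head_total = np.zeros(spec.shape)
    for name, code in _LABEL_CODES.items():
        if name == "background":
            continue
        m = (labels == code).astype(np.float64)
        if spec.softening_sigma > 0:
            m = ndimage.gaussian_filter(m, spec.softening_sigma, mode="nearest")
        maps[name] = m
        head_total += m
    safe_total = np.where(head & (head_total > 0), head_total, 1.0)
    for name in maps:
        maps[name] = VolumeGrid(
            np.clip(np.where(head, maps[name] / safe_total, 0.0), 0.0, 1.0)
        )
    maps["background"] = VolumeGrid((~head).astype(np.float64))
    tmaps = TissueMapSet(maps)

    # Native -> normalized: undo the per-subject head scaling about the
    # head center, so all subjects align on the template geometry.
    if spec.semi_scale == (1.0, 1.0, 1.0):
        transform = TransformPair.identity(spec.shape)
    else:
        center = np.array([cx, cy, cz])
        fwd = np.eye(4)
        fwd[:3, :3] = np.diag([1.0 / sx, 1.0 / sy, 1.0 / sz])
        fwd[:3, 3] = center - fwd[:3, :3] @ center
        inv = np.eye(4)
        inv[:3, :3] = np.diag([sx, sy, sz])
        inv[:3, 3] = center - inv[:3, :3] @ center
        transform = TransformPair(fwd, inv, spec.shape)
    return vol, tmaps, transform


def _require_phantom(vol: VolumeGrid) -> dict:
    if not vol.meta.get("phantom"):
        raise ValueError("injection requires a phantom from generate_head_phantom")
    return vol.meta


def inject_eye_movement(
    vol: VolumeGrid, maps: TissueMapSet, amp: float, seed: int = 0
) -> VolumeGrid:
    """Add eye-movement ghosting: attenuated replicas of the eye spheres
    displaced anteriorly along the coronal (phase-encode) axis.

    Replicas combine with the existing image by voxelwise maximum (the
    dominant-magnitude approximation), so ghosts appear in the air in
    front of the eyes without inflating already-bright tissue.  The
    injected background signal scales linearly with ``amp``; ``amp == 0``
    returns an unchanged copy.
    """
    if not 0.0 <= amp <= 1.0:
        raise ValueError("amp must lie in [0, 1]")
    meta = _require_phantom(vol)
    out = vol.copy()
    if amp == 0.0:
        return out
    nx, ny, nz = vol.shape
    x, y, z = np.ogrid[0:nx, 0:ny, 0:nz]
    source = np.zeros(vol.shape)
    r = meta["eye_radius"]
    for ex, ey, ez in meta["eye_centers"]:
        sphere = ((x - ex) ** 2 + (y - ey) ** 2 + (z - ez) ** 2) <= r**2
        source[sphere] = vol.data[sphere]

    rng = np.random.default_rng(seed)
    step = max(2, round(0.8 * r))
    ghost = np.zeros(vol.shape)
    for k in range(1, 7):
        dy = k * step + int(rng.integers(-1, 2))
        if dy >= ny:
            break
        shifted = np.zeros(vol.shape)
        shifted[:, : ny - dy, :] = (0.55**k) * source[:, dy:, :]
        ghost = np.maximum(ghost, shifted)
    out.data = np.maximum(vol.data, amp * ghost)
    return out


def inject_ringing(
    vol: VolumeGrid, maps: TissueMapSet, amp: float, seed: int = 0,
    gain: float = 0.35,
) -> VolumeGrid:
    """Add motion ringing: attenuated replicas of the bright skull/fat rim
    of the upper head, displaced laterally into the surrounding background
    of the upper axial slices.  ``gain`` sets the overall replica strength
    relative to the rim signal; replicas combine with the image by
    voxelwise maximum, as in :func:`inject_eye_movement`.
    """
    if not 0.0 <= amp <= 1.0:
        raise ValueError("amp must lie in [0, 1]")
    meta = _require_phantom(vol)
    out = vol.copy()
    if amp == 0.0:
        return out
    nx, ny, nz = vol.shape
    labels = meta["labels"]
    z_min, z_max = meta["head_z_extent"]
    z_lo = z_min + round((z_max - z_min) * 2.0 / 3.0)
    shell = np.isin(labels, [_LABEL_CODES["skull"], _LABEL_CODES["fat"]])
    shell[:, :, :z_lo] = False
    source = np.where(shell, vol.data, 0.0)

    rng = np.random.default_rng(seed)
    step = max(2, round(0.05 * nx))
    ghost = np.zeros(vol.shape)
    for k in range(1, 6):
        dx = k * step + int(rng.integers(-1, 2))
        if dx >= nx:
            break
        w = gain * 0.55**k
        shifted = np.zeros(vol.shape)
        shifted[: nx - dx, :, :] = w * source[dx:, :, :]
        shifted[dx:, :, :] = np.maximum(shifted[dx:, :, :], w * source[: nx - dx, :, :])
        ghost = np.maximum(ghost, shifted)
    out.data = np.maximum(vol.data, amp * ghost)
    return out


def inject_aliasing(vol: VolumeGrid, amp: float, overlay: bool = False) -> VolumeGrid:
    """Simulate wrap-around aliasing along the coronal axis.

    The anterior-most ``ceil(amp * ny * 0.2)`` coronal planes containing
    the nose are added back at the posterior side of the field of view.
    With ``overlay=False`` the wrapped nose stays at the posterior edge,
    leaving a band of untouched background between it and the head; with
    ``overlay=True`` the wrap is shifted so the nose signal lands on (and
    tiles up to the edge behind) the posterior head surface, leaving no
    clean background plane.  The wrapped signal is weighted by ``amp``,
    emulating coil-sensitivity falloff outside the field of view.
    """
    if not 0.0 <= amp <= 1.0:
        raise ValueError("amp must lie in [0, 1]")
    meta = _require_phantom(vol)
    out = vol.copy()
    nx, ny, nz = vol.shape
    w = math.ceil(amp * ny * 0.2)
    if w == 0:
        return out
    y0, y1 = meta["nose_y_planes"]
    w = min(w, y1 - y0 + 1)  # only planes that actually contain the nose
    # only object signal folds back; receiver noise in the air does not
    labels = meta["labels"][:, y0 : y0 + w, :]
    is_head = labels != _LABEL_CODES["background"]
    block = amp * np.where(is_head, vol.data[:, y0 : y0 + w, :], 0.0)
    if overlay:
        start = max(meta["head_y_max"] - 1, 0)
        for j, yy in enumerate(range(start, ny)):
            out.data[:, yy, :] = np.maximum(out.data[:, yy, :], block[:, j % w, :])
    else:
        out.data[:, ny - w :, :] = np.maximum(out.data[:, ny - w :, :], block)
    return out


def severity_from_amplitude(amp: float) -> str:
    """Map an injected amplitude to the 4-degree severity vocabulary."""
    for cutoff, name in SEVERITY_CUTOFFS:
        if amp < cutoff:
            return name
    return "heavy"


def phantom_eye_boxes(shape: Sequence[int], margin: float = 1.2):
    """Normalized-space eye-socket bounding boxes for the phantom geometry.

    Returns ((x0,x1),(y0,y1),(z0,z1)) half-open ranges per eye, suitable
    for :class:`mriqa.masks.EyeBoxSpec`.  Real data needs manually
    estimated boxes supplied through configuration.
    """
    nx, ny, nz = shape
    cx, cy, cz = 0.5 * nx, 0.45 * ny, 0.45 * nz
    ax, ay, az = 0.32 * nx, 0.30 * ny, 0.38 * nz
    r = 0.05 * ny * margin
    boxes = []
    for side in (-1, 1):
        ex, ez = cx + side * 0.13 * nx, cz
        inside = 1.0 - ((ex - cx) / ax) ** 2 - ((ez - cz) / az) ** 2
        ey = cy - ay * math.sqrt(max(inside, 0.0))
        boxes.append(
            (
                (int(max(ex - r, 0)), int(min(ex + r + 1, nx))),
                (int(max(ey - r, 0)), int(min(ey + r + 1, ny))),
                (int(max(ez - r, 0)), int(min(ez + r + 1, nz))),
            )
        )
    return boxes


def generate_cohort(
    n: int,
    usable_fraction: float,
    seed: int = 0,
    shape: tuple[int, int, int] | None = None,
    noise_sd: float | None = None,
) -> list[tuple[VolumeGrid, TissueMapSet, TransformPair, QualityLabel]]:
    """Generate a labeled cohort of phantoms with injected artifacts.

    ``round(n * usable_fraction)`` subjects are usable: all artifact
    amplitudes are drawn below the "none" cutoff.  The rest are
    not-usable: one artifact (chosen at random) is drawn in the "heavy"
    band, the other two anywhere below it.  Per-artifact severities
    follow :func:`severity_from_amplitude`; the stage-I color is green if
    every severity is none, red if any is heavy, yellow otherwise.

    Subjects additionally vary in head size (per-axis semi-axis scale,
    with the matching affine registration to the common template),
    ventricle size, per-class tissue contrast, and noise level, emulating
    the anatomical and scanner variability of a real cohort.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0.0 < usable_fraction < 1.0:
        raise ValueError("usable_fraction must lie strictly in (0, 1)")
    n_usable = round(n * usable_fraction)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n)
    rng = np.random.default_rng(ss.spawn(1)[0])

    cohort = []
    for i in range(n):
        child_seed = int(children[i].generate_state(1)[0] % 2**31)
        usable = i < n_usable
        if usable:
            amps = rng.uniform(0.0, SEVERITY_CUTOFFS[0][0], size=3)
        else:
            amps = rng.uniform(0.0, SEVERITY_CUTOFFS[2][0], size=3)
            amps[rng.integers(0, 3)] = rng.uniform(SEVERITY_CUTOFFS[2][0], 1.0)
        artifacts = ArtifactSpec(
            eye_amplitude=float(amps[0]),
            ring_amplitude=float(amps[1]),
            alias_amplitude=float(amps[2]),
            seed=child_seed,
        )
        eye_amp = artifacts.eye_amplitude
        ring_amp = artifacts.ring_amplitude
        alias_amp = artifacts.alias_amplitude

        means = {
            cls: base * rng.uniform(0.93, 1.07)
            for cls, base in DEFAULT_TISSUE_MEANS.items()
        }
        means["background"] = 0.0
        spec = PhantomSpec(
            seed=child_seed,
            tissue_means=means,
            semi_scale=tuple(rng.uniform(0.92, 1.08, size=3)),
            vent_scale=float(rng.uniform(0.8, 1.3)),
            noise_sd=float(rng.uniform(2.5, 3.5)),
        )
        if shape is not None:
            spec.shape = tuple(shape)
        if noise_sd is not None:
            spec.noise_sd = noise_sd
        vol, maps, tp = generate_head_phantom(spec)
        vol = inject_eye_movement(vol, maps, eye_amp, seed=child_seed)
        vol = inject_ringing(vol, maps, ring_amp, seed=child_seed + 1)
        # any visible wrap is assumed to reach the head (overlay scenario)
        vol = inject_aliasing(
            vol, alias_amp, overlay=alias_amp >= SEVERITY_CUTOFFS[0][0]
        )

        severity = {a: "none" for a in ARTIFACTS}
        severity["eye_movement"] = severity_from_amplitude(eye_amp)
        severity["ringing"] = severity_from_amplitude(ring_amp)
        severity["aliasing"] = severity_from_amplitude(alias_amp)
        sevs = set(severity.values())
        if sevs == {"none"}:
            color = "green"
        elif "heavy" in sevs:
            color = "red"
        else:
            color = "yellow"
        label = QualityLabel(
            subject_id=f"sub-{i:03d}",
            stage1_color=color,
            severity=severity,
            final="usable" if usable else "not-usable",
        )
        cohort.append((vol, maps, tp, label))
    return cohort
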