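"""Core containers for volumetric images, labelmaps and transforms.

Grid convention
---------------
All volumes are stored as ``(nx, ny, nz)`` arrays with isotropic (or
per-axis) voxel spacing in mm.  Axis 0 runs left->right, so the
midsagittal plane is the central ``x`` lattice plane; the *left*
hemisphere is ``x < nx // 2``.  Axis 1 runs posterior->anterior and
axis 2 inferior->superior.

Label classes
-------------
0 background, 1 choroid plexus (CP), 2 lateral posterior ventricle horn
(LPVH), 3 cavum septum pellucidum et vergae (CSPV), 4 cerebellum (CB).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import scipy.ndimage as ndi

BACKGROUND = 0
CP = 1
LPVH = 2
CSPV = 3
CB = 4
FOREGROUND_CLASSES = (CP, LPVH, CSPV, CB)
CLASS_NAMES = {BACKGROUND: "background", CP: "CP", LPVH: "LPVH", CSPV: "CSPV", CB: "CB"}
NUM_CLASSES = 5


def _as_spacing(spacing) -> tuple[float, float, float]:
    if np.isscalar(spacing):
        return (float(spacing),) * 3
    s = tuple(float(v) for v in spacing)
    if len(s) != 3:
        raise ValueError("spacing must be scalar or length-3")
    return s


@dataclass
class Volume3D:
    """A 3D scalar image with spacing, alignment state and gestational age."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.2, 1.2, 1.2)
    aligned: bool = True
    ga_weeks: float | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError("Volume3D expects a 3D array")
        self.spacing = _as_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def copy(self) -> "Volume3D":
        return Volume3D(self.data.copy(), self.spacing, self.aligned, self.ga_weeks)


@dataclass
class LabelMap:
    """Integer class grid on the same lattice as its image.

    ``provenance`` records how the labels were obtained: ``expert``
    (ground truth), ``atlas`` (template propagation) or ``predicted``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.2, 1.2, 1.2)
    provenance: str = "expert"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            self.data = self.data.astype(np.uint8)
        if self.data.ndim != 3:
            raise ValueError("LabelMap expects a 3D array")
        if self.data.size and int(self.data.max()) >= NUM_CLASSES:
            raise ValueError(f"label classes must be < {NUM_CLASSES}")
        self.spacing = _as_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def mask(self, cls: int) -> np.ndarray:
        return self.data == cls

    def classes(self) -> set[int]:
        return set(int(c) for c in np.unique(self.data))

    def copy(self) -> "LabelMap":
        return LabelMap(self.data.copy(), self.spacing, self.provenance)


@dataclass
class RigidTransform:
    """Rigid body transform: rotations (degrees, about x/y/z through the
    grid center) followed by a translation in mm."""

    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def rotation_matrix(self) -> np.ndarray:
        ax, ay, az = np.deg2rad(self.rotation_deg)
        cx, sx = np.cos(ax), np.sin(ax)
        cy, sy = np.cos(ay), np.sin(ay)
        cz, sz = np.cos(az), np.sin(az)
        rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return rz @ ry @ rx

    def matrix(self) -> np.ndarray:
        cached = getattr(self, "_matrix", None)
        if cached is not None:
            return cached
        m = np.eye(4)
        m[:3, :3] = self.rotation_matrix()
        m[:3, 3] = self.translation_mm
        return m

    def inverse(self) -> "RigidTransform":
        r = self.rotation_matrix()
        t = -r.T @ np.asarray(self.translation_mm, dtype=float)
        inv = RigidTransform.__new__(RigidTransform)
        inv.rotation_deg = None  # composite inverse: matrix is authoritative
        inv.translation_mm = tuple(t)
        inv._matrix = np.eye(4)
        inv._matrix[:3, :3] = r.T
        inv._matrix[:3, 3] = t
        return inv

    def as_matrix(self) -> np.ndarray:
        return getattr(self, "_matrix", None) if getattr(self, "_matrix", None) is not None else self.matrix()

    def is_identity(self, tol: float = 1e-9) -> bool:
        return bool(np.allclose(self.as_matrix(), np.eye(4), atol=tol))


def apply_rigid(arr: np.ndarray, t: RigidTransform, spacing, order: int, cval: float = 0.0) -> np.ndarray:
    """Resample ``arr`` under rigid transform ``t`` about the grid center.

    Uses the pull-back convention: output voxel ``v`` samples the input at
    ``M^{-1} v`` (physical coordinates), so ``t`` moves the *object* by
    its rotation and translation.
    """
    sp = np.asarray(_as_spacing(spacing))
    m = t.as_matrix()
    minv = np.linalg.inv(m)
    center = (np.asarray(arr.shape) - 1) / 2.0 * sp
    # voxel -> physical -> inverse transform -> physical -> voxel
    a = np.diag(1.0 / sp) @ minv[:3, :3] @ np.diag(sp)
    b = (minv[:3, :3] @ (-center) + minv[:3, 3] + center) / sp
    return ndi.affine_transform(
        arr.astype(np.float32 if order > 0 else arr.dtype),
        a, offset=b, order=order, mode="constant", cval=cval, prefilter=False,
    )


@dataclass
class DeformationField:
    """Dense displacement field in voxel units with its inverse.

    ``forward[..., k]`` is the displacement (pull-back convention) used to
    warp a *moving* image onto the reference grid:
    ``warped(x) = moving(x + forward(x))``.  ``inverse`` warps the other
    way; ``forward o inverse ~ id`` on the brain mask.
    """

    forward: np.ndarray
    inverse: np.ndarray | None = None
    source_id: str | None = None

    def __post_init__(self):
        if self.forward.ndim != 4 or self.forward.shape[-1] != 3:
            raise ValueError("displacement field must be (nx, ny, nz, 3)")


def warp(arr: np.ndarray, displacement: np.ndarray, order: int = 1, cval: float = 0.0) -> np.ndarray:
    """Warp ``arr`` by a voxel-unit displacement field (pull-back)."""
    nx, ny, nz = arr.shape
    grid = np.stack(
        np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"), axis=-1
    ).astype(np.float32)
    coords = (grid + displacement).transpose(3, 0, 1, 2)
    return ndi.map_coordinates(
        arr.astype(np.float32 if order > 0 else arr.dtype),
        coords, order=order, mode="constant", cval=cval, prefilter=False,
    )


@dataclass
class Template:
    """Mean-intensity template on the reference grid, optionally labelled."""

    intensity: Volume3D
    labels: LabelMap | None = None
    ga_bin: int | tuple[int, int] | None = None
    hemisphere: str = "n/a"  # left | right | fused | n/a
    member_ids: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# NIfTI / sidecar IO
# ---------------------------------------------------------------------------

def save_nifti(arr: np.ndarray, spacing, path: str | Path) -> None:
    sp = _as_spacing(spacing)
    affine = np.diag([sp[0], sp[1], sp[2], 1.0])
    nib.save(nib.Nifti1Image(np.asarray(arr), affine), str(path))


def load_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), spacing


def save_volume(vol: Volume3D, path: str | Path, sidecar: dict | None = None) -> None:
    save_nifti(vol.data, vol.spacing, path)
    meta = {"ga_weeks": vol.ga_weeks, "aligned": vol.aligned}
    if sidecar:
        meta.update(sidecar)
    Path(str(path).replace(".nii.gz", "").replace(".nii", "")).with_suffix(".json").write_text(
        json.dumps(meta, indent=2)
    )
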