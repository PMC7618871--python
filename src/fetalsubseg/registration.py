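"""Rigid resampling and diffeomorphic demons registration.

The deformable backend is SimpleITK's symmetric-forces diffeomorphic
demons, run over a small shrink pyramid.  All displacement fields are
exchanged with the rest of the package as ``(nx, ny, nz, 3)`` arrays in
*voxel* units with the pull-back convention of :func:`fetalsubseg.core.warp`:
``warped(x) = moving(x + d(x))`` resamples the moving image on the fixed
grid.  Inverse fields are computed by fixed-point iteration.
"""

from __future__ import annotations

import numpy as np
import scipy.ndimage as ndi
import SimpleITK as sitk

from .core import DeformationField, LabelMap, RigidTransform, Volume3D, apply_rigid, warp


def rigid_align(vol: Volume3D | LabelMap, t: RigidTransform, interp: str = "trilinear"):
    """Resample a volume under a rigid transform on its own grid.

    Nearest-neighbour interpolation is mandatory for labelmaps.  For a
    ``Volume3D`` the orientation state flips ``unaligned -> aligned``.
    """
    m = t.as_matrix()
    if abs(np.linalg.det(m[:3, :3])) < 1e-12:
        raise ValueError("transform is not invertible")
    if isinstance(vol, LabelMap):
        if interp != "nearest":
            raise ValueError("labelmaps must be resampled with nearest-neighbour interpolation")
        out = apply_rigid(vol.data, t, vol.spacing, order=0)
        return LabelMap(out, vol.spacing, vol.provenance)
    order = {"trilinear": 1, "nearest": 0}[interp]
    out = apply_rigid(vol.data, t, vol.spacing, order=order)
    return Volume3D(out, vol.spacing, aligned=True, ga_weeks=vol.ga_weeks)


# ---------------------------------------------------------------------------
# Demons
# ---------------------------------------------------------------------------

def _to_sitk(arr: np.ndarray) -> sitk.Image:
    # numpy (x, y, z) -> sitk with unit spacing so fields are in voxels
    return sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0).astype(np.float64)))


def _field_to_numpy(field: sitk.Image) -> np.ndarray:
    a = sitk.GetArrayFromImage(field)          # (z, y, x, [dx, dy, dz]) in sitk order
    a = a.transpose(2, 1, 0, 3)                # -> (x, y, z, [dx, dy, dz])
    return np.ascontiguousarray(a).astype(np.float32)


def demons_displacement(
    fixed: np.ndarray,
    moving: np.ndarray,
    iterations: tuple[int, ...] = (30, 20, 10),
    smoothing_sigma: float = 1.5,
    shrink_factors: tuple[int, ...] = (4, 2, 1),
) -> np.ndarray:
    """Register ``moving`` onto ``fixed``; returns a voxel-unit
    displacement field ``d`` with ``moving(x + d(x)) ~ fixed(x)``.

    Runs symmetric-forces diffeomorphic demons on a shrink pyramid, each
    level initialised with the upsampled field of the previous one.
    """
    if fixed.shape != moving.shape:
        raise ValueError("fixed and moving must share a grid")
    f_img, m_img = _to_sitk(fixed), _to_sitk(moving)

    filt = sitk.FastSymmetricForcesDemonsRegistrationFilter()
    filt.SetSmoothDisplacementField(True)
    filt.SetStandardDeviations(smoothing_sigma)

    field = None
    for shrink, iters in zip(shrink_factors, iterations):
        if shrink > 1:
            f_l = sitk.Shrink(f_img, [shrink] * 3)
            m_l = sitk.Shrink(m_img, [shrink] * 3)
        else:
            f_l, m_l = f_img, m_img
        filt.SetNumberOfIterations(int(iters))
        if field is None:
            field = filt.Execute(f_l, m_l)
        else:
            init = sitk.Resample(field, f_l, sitk.Transform(), sitk.sitkLinear)
            init = sitk.Cast(init, sitk.sitkVectorFloat64)
            field = filt.Execute(f_l, m_l, init)
    if field.GetSize() != f_img.GetSize():
        field = sitk.Resample(field, f_img, sitk.Transform(), sitk.sitkLinear)
    return _field_to_numpy(field)


def invert_displacement(d: np.ndarray, n_iter: int = 30, tol_vox: float = 0.1) -> np.ndarray:
    """Fixed-point inversion: solve ``d_inv(x) = -d(x + d_inv(x))``.

    Stops early once the max update falls below ``tol_vox``.
    """
    d_inv = -d.copy()
    for _ in range(n_iter):
        upd = np.stack([warp(d[..., k], d_inv, order=1) for k in range(3)], axis=-1)
        new = -upd
        delta = np.abs(new - d_inv).max()
        d_inv = new
        if delta < tol_vox:
            break
    return d_inv.astype(np.float32)


def make_deformation(fixed: np.ndarray, moving: np.ndarray, source_id: str | None = None,
                     **demons_kw) -> DeformationField:
    fwd = demons_displacement(fixed, moving, **demons_kw)
    return DeformationField(forward=fwd, inverse=invert_displacement(fwd), source_id=source_id)


def inversion_residual(field: DeformationField, mask: np.ndarray | None = None) -> float:
    """Max voxel norm of ``forward o inverse`` composed displacement on
    ``mask`` (identity check)."""
    if field.inverse is None:
        raise ValueError("field has no inverse")
    comp = np.stack(
        [warp(field.forward[..., k], field.inverse, order=1) for k in range(3)], axis=-1
    ) + field.inverse
    norm = np.linalg.norm(comp, axis=-1)
    if mask is not None:
        norm = norm[mask]
    return float(norm.max()) if norm.size else 0.0
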