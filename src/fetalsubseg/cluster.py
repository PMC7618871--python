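"""Cluster-based LPVH template construction.

The LPVH shows more within-week shape variation than the other
structures, so a single weekly template blurs it.  This module groups
images from two-week gestational windows by LPVH appearance: crops
around the LPVH are histogram-equalized, pairwise registered, and the
sum-of-squared-differences (SSD) over an LPVH region of interest forms
a distance matrix which is clustered with k-medoids (PAM with seeded
restarts).  Outliers are excluded before clustering and re-attached to
their nearest medoid afterwards; per-cluster templates are then built
including the outliers, annotated, and their LPVH labels propagated
back to the members.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage import exposure

from .core import LPVH, DeformationField, LabelMap, Template, Volume3D, warp
from .phantom import LPVH_MODES, CohortSample, PhantomConfig, brain_semiaxes_mm
from .registration import demons_displacement
from .templates import groupwise_template, mirror_x, vote_labels, week_bin

#: Two-week gestational windows tiling [18, 26]; the last window is a
#: single week.
DEFAULT_WINDOWS = ((18, 19), (20, 21), (22, 23), (24, 25), (26, 26))


@dataclass
class DistanceMatrix:
    values: np.ndarray
    member_ids: list[str]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class Clustering:
    assignments: dict[int, int]      # member index -> cluster index
    medoids: list[int]               # member index of each cluster's medoid
    cost: float
    n_c: int
    n_restarts: int
    seed: int


# ---------------------------------------------------------------------------
# Crops and distances
# ---------------------------------------------------------------------------

def default_lpvh_bbox(config: PhantomConfig, margin_mm: float = 6.0) -> tuple[slice, slice, slice]:
    """A fixed crop box (voxel slices) covering the left-hemisphere LPVH
    across the whole GA range and all shape modes, with a margin."""
    n, sp = config.grid_size, config.spacing_mm
    axes26 = np.array(brain_semiaxes_mm(26.0, config))
    center = np.array([-0.38, -0.55, 0.12]) * axes26
    # largest semi-axes over modes at the largest volume (0.3 cm^3)
    vol_mm3 = 300.0
    semi = np.zeros(3)
    for ratios in LPVH_MODES:
        r = np.array(ratios)
        s = (3 * vol_mm3 / (4 * np.pi * np.prod(r))) ** (1 / 3)
        semi = np.maximum(semi, r * s)
    half = semi + margin_mm
    c_vox = center / sp + (n - 1) / 2.0
    lo = np.maximum(np.floor(c_vox - half / sp).astype(int), 0)
    hi = np.minimum(np.ceil(c_vox + half / sp).astype(int) + 1, n)
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def prepare_crops(samples: list[CohortSample], bbox: tuple[slice, slice, slice]) -> list[Volume3D]:
    """Mirror right-hemisphere members across the midline, crop the fixed
    box and histogram-equalize intensities to [0, 1]."""
    out = []
    for s in samples:
        img = s.image.data
        if s.visible_hemisphere == "right":
            img = mirror_x(img)
        for sl, dim in zip(bbox, img.shape):
            if sl.start < 0 or sl.stop > dim:
                raise ValueError("bbox exceeds grid")
        crop = img[bbox].astype(np.float32)
        if crop.max() > crop.min():
            crop = exposure.equalize_hist(crop).astype(np.float32)
        else:
            crop = np.zeros_like(crop)
        out.append(Volume3D(crop, s.image.spacing, aligned=True, ga_weeks=s.ga_weeks))
    return out


def window_roi(samples: list[CohortSample], bbox: tuple[slice, slice, slice],
               dilate_vox: int = 2) -> np.ndarray:
    """LPVH region of interest within the crop: union of the members'
    ground-truth LPVH masks (mirrored like the crops), dilated."""
    roi = None
    for s in samples:
        m = s.labels.data == LPVH
        if s.visible_hemisphere == "right":
            m = mirror_x(m)
        m = m[bbox]
        roi = m if roi is None else (roi | m)
    if dilate_vox > 0:
        roi = ndi.binary_dilation(roi, iterations=dilate_vox)
    return roi


def pairwise_ssd(crops: list[Volume3D], roi_mask: np.ndarray,
                 member_ids: list[str] | None = None,
                 register: bool = True, demons_kw: dict | None = None) -> DistanceMatrix:
    """Directed SSD over the ROI after deforming crop j onto crop i,
    symmetrized as (D + D^T)/2 with a zero diagonal."""
    if len(crops) < 2:
        raise ValueError("need at least two crops")
    if not roi_mask.any():
        raise ValueError("empty ROI")
    demons_kw = demons_kw or {"iterations": (20, 10), "shrink_factors": (2, 1)}
    ids = member_ids or [f"m{i}" for i in range(len(crops))]
    n = len(crops)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            fixed, moving = crops[i].data, crops[j].data
            if register:
                disp = demons_displacement(fixed, moving, **demons_kw)
                moving = warp(moving, disp, order=1)
            d[i, j] = float(((fixed - moving) ** 2)[roi_mask].sum())
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids)


# ---------------------------------------------------------------------------
# k-medoids (PAM with seeded restarts)
# ---------------------------------------------------------------------------

def _assign(dvals: np.ndarray, medoids: list[int]) -> np.ndarray:
    # nearest medoid; ties -> medoid occurring first in sorted order
    med = np.array(sorted(medoids))
    return med[np.argmin(dvals[:, med], axis=1)]


def _assign_min_size(dvals: np.ndarray, medoids: list[int],
                     min_size: int) -> np.ndarray:
    """Nearest-medoid assignment with a deterministic minimal-cost repair
    so every cluster reaches ``min_size`` (moves the member whose
    reassignment increases the cost least; ties to the lowest index)."""
    labels = _assign(dvals, medoids)
    if min_size <= 1:
        return labels
    med = sorted(medoids)
    while True:
        sizes = {m: int((labels == m).sum()) for m in med}
        under = [m for m in med if sizes[m] < min_size]
        if not under:
            return labels
        target = under[0]
        best = None
        for i in range(len(labels)):
            cur = int(labels[i])
            if cur == target or sizes[cur] <= min_size or i in med:
                continue
            key = (dvals[i, target] - dvals[i, cur], i)
            if best is None or key < best:
                best = key
        if best is None:
            raise ValueError("min_size constraint is infeasible")
        labels[best[1]] = target


def _cost_of_labels(dvals: np.ndarray, labels: np.ndarray) -> float:
    return float(dvals[np.arange(len(labels)), labels].sum())


def _cost(dvals: np.ndarray, medoids: list[int], min_size: int = 1) -> float:
    labels = _assign_min_size(dvals, medoids, min_size)
    return _cost_of_labels(dvals, labels)


def _pam_single(dvals: np.ndarray, k: int, rng: np.random.Generator,
                min_size: int = 1) -> tuple[list[int], float]:
    n = dvals.shape[0]
    medoids = list(rng.choice(n, size=k, replace=False))
    cost = _cost(dvals, medoids, min_size)
    improved = True
    while improved:
        improved = False
        best = (cost, None, None)
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                cand = medoids[:mi] + [h] + medoids[mi + 1:]
                c = _cost(dvals, cand, min_size)
                if c < best[0] - 1e-12:
                    best = (c, mi, h)
        if best[1] is not None:
            cost = best[0]
            medoids[best[1]] = best[2]
            improved = True
    return sorted(medoids), cost


def k_medoids(D: DistanceMatrix, k: int, restarts: int = 500, min_size: int = 3,
              seed: int = 0) -> Clustering:
    """Best-of-restarts PAM clustering of a distance matrix.

    Cluster sizes are kept at or above ``min_size`` by a deterministic
    minimal-cost reassignment inside the swap search.  Deterministic
    under ``seed`` (restart ``r`` uses seed ``seed + r``); cost ties
    break toward the lowest sorted medoid index set.
    """
    n = D.n
    if k > n:
        raise ValueError("k larger than number of members")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    if k * min_size > n:
        raise ValueError("min_size constraint is infeasible for this k")
    best: tuple[float, tuple, np.ndarray] | None = None
    for r in range(restarts):
        rng = np.random.default_rng(seed + r)
        medoids, cost = _pam_single(D.values, k, rng, min_size)
        labels = _assign_min_size(D.values, medoids, min_size)
        key = (cost, tuple(medoids))
        if best is None or key < (best[0], best[1]):
            best = (cost, tuple(medoids), labels)
    cost, medoids, labels = best
    cluster_of_medoid = {m: ci for ci, m in enumerate(medoids)}
    assignments = {i: cluster_of_medoid[int(labels[i])] for i in range(n)}
    return Clustering(assignments=assignments, medoids=list(medoids), cost=cost,
                      n_c=k, n_restarts=restarts, seed=seed)


def handle_outliers(D: DistanceMatrix, n_sigma: float = 2.0) -> tuple[list[int], list[int]]:
    """Flag members whose median distance to the others exceeds the
    cohort mean + ``n_sigma`` std of those medians.

    Returns ``(core_ids, outlier_ids)`` as indices into ``D``.  Outliers
    are meant to be excluded before clustering and re-attached to their
    nearest medoid afterwards (see :func:`assign_outliers`).
    """
    n = D.n
    stats = np.array([np.median(np.delete(D.values[i], i)) for i in range(n)])
    thr = stats.mean() + n_sigma * stats.std()
    outliers = [i for i in range(n) if stats[i] > thr]
    if len(outliers) > 0.2 * n:
        warnings.warn("outlier rule excludes more than 20% of members; proceeding")
    core = [i for i in range(n) if i not in outliers]
    return core, outliers


def assign_outliers(D: DistanceMatrix, clustering: Clustering, core: list[int],
                    outliers: list[int]) -> dict[int, int]:
    """Attach each outlier to the cluster of its nearest medoid.

    ``clustering`` indexes the *core* submatrix; the returned assignment
    maps full-matrix indices to clusters.
    """
    full = {core[i]: c for i, c in clustering.assignments.items()}
    medoid_full = [core[m] for m in clustering.medoids]
    for o in outliers:
        dists = [D.values[o, m] for m in medoid_full]
        full[o] = int(np.argmin(dists))
    return full


def build_cluster_templates(
    samples: list[CohortSample],
    assignments: dict[int, int],
    n_clusters: int,
    min_size: int = 1,
    iters: int = 2,
    demons_kw: dict | None = None,
) -> tuple[list[Template], list[dict[str, DeformationField]]]:
    """Groupwise LPVH templates per cluster (outliers included), built
    from the full mirrored images; the LPVH is labelled by majority
    vote of the members' warped ground truth."""
    templates, fieldmaps = [], []
    for c in range(n_clusters):
        idx = [i for i, ci in assignments.items() if ci == c]
        if len(idx) < min_size:
            raise ValueError(f"cluster {c} below min size after outlier reassignment")
        members = [samples[i] for i in idx]
        vols = []
        for s in members:
            img = s.image.data
            if s.visible_hemisphere == "right":
                img = mirror_x(img)
            vols.append(Volume3D(img, s.image.spacing, aligned=True, ga_weeks=s.ga_weeks))
        tpl, fields = groupwise_template(vols, iters=iters,
                                         member_ids=[s.sample_id for s in members],
                                         demons_kw=demons_kw)
        warped = []
        for s, f in zip(members, fields):
            lab = s.labels.data == LPVH
            if s.visible_hemisphere == "right":
                lab = mirror_x(lab)
            warped.append(warp(lab.astype(np.uint8) * LPVH, f.forward, order=0))
        tpl.labels = LabelMap(vote_labels(warped), tpl.intensity.spacing, provenance="atlas")
        tpl.hemisphere = "left"
        templates.append(tpl)
        fieldmaps.append({f.source_id: f for f in fields})
    return templates, fieldmaps


# ---------------------------------------------------------------------------
# End-to-end clustered LPVH labels
# ---------------------------------------------------------------------------

def clustered_lpvh_labels(
    cohort: list[CohortSample],
    config: PhantomConfig,
    k: int = 3,
    restarts: int = 50,
    min_size: int = 1,
    seed: int = 0,
    windows: tuple[tuple[int, int], ...] = DEFAULT_WINDOWS,
    demons_kw: dict | None = None,
) -> dict[str, np.ndarray]:
    """LPVH atlas labels from cluster-based templates for every cohort
    member; returns binary LPVH masks in each member's own (aligned,
    unmirrored) space."""
    bbox = default_lpvh_bbox(config)
    out: dict[str, np.ndarray] = {}
    for lo, hi in windows:
        members = [s for s in cohort if lo <= week_bin(s.ga_weeks) <= hi]
        if not members:
            continue
        if len(members) < 2 or len(members) <= k:
            assignments = {i: 0 for i in range(len(members))}
            n_c = 1
        else:
            crops = prepare_crops(members, bbox)
            roi = window_roi(members, bbox)
            dmat = pairwise_ssd(crops, roi, member_ids=[s.sample_id for s in members],
                                demons_kw=demons_kw)
            core, outliers = handle_outliers(dmat)
            sub = DistanceMatrix(dmat.values[np.ix_(core, core)],
                                 [dmat.member_ids[i] for i in core])
            k_eff = min(k, max(1, len(core) // max(min_size, 1)))
            ms_eff = min(min_size, len(core) // k_eff)
            clus = k_medoids(sub, k_eff, restarts=restarts, min_size=ms_eff, seed=seed)
            assignments = assign_outliers(dmat, clus, core, outliers)
            n_c = k_eff
        tpls, fieldmaps = build_cluster_templates(members, assignments, n_c,
                                                  min_size=1, demons_kw=demons_kw)
        for i, s in enumerate(members):
            c = assignments[i]
            f = fieldmaps[c][s.sample_id]
            lab = warp(tpls[c].labels.data, f.inverse, order=0) == LPVH
            if s.visible_hemisphere == "right":
                lab = mirror_x(lab)
            out[s.sample_id] = lab
    return out
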