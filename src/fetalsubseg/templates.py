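"""Groupwise per-week templates, hemisphere fusion and atlas labels.

Templates are built per gestational week (GA rounded to the nearest
integer, ties rounding down) and per visible hemisphere, by groupwise
diffeomorphic demons registration: each member is registered to the
running mean, warped, and re-averaged.  The left and right hemisphere
templates are fused at the central sagittal lattice plane.  Template
labels are obtained by warping member ground-truth labels into template
space and majority voting; weak *atlas labels* for each member are then
produced by resampling the template labels through each member's
inverse deformation field (nearest neighbour).
"""

from __future__ import annotations

import numpy as np

from .core import CP, LPVH, NUM_CLASSES, DeformationField, LabelMap, Template, Volume3D, warp
from .phantom import CohortSample
from .registration import demons_displacement, invert_displacement


def week_bin(ga_weeks: float) -> int:
    """Round GA to the nearest integer week; exact halves round down."""
    return int(np.ceil(ga_weeks - 0.5))


def mirror_x(arr: np.ndarray) -> np.ndarray:
    """Reflect across the midsagittal (central sagittal lattice) plane."""
    return np.flip(arr, axis=0).copy()


# ---------------------------------------------------------------------------
# Groupwise registration
# ---------------------------------------------------------------------------

def _mean_pairwise_ssd(vols: list[np.ndarray]) -> float:
    n = len(vols)
    if n < 2:
        return 0.0
    tot, cnt = 0.0, 0
    for i in range(n):
        for j in range(i + 1, n):
            tot += float(((vols[i] - vols[j]) ** 2).sum())
            cnt += 1
    return tot / cnt


def groupwise_template(
    samples: list[Volume3D],
    iters: int = 2,
    member_ids: list[str] | None = None,
    demons_kw: dict | None = None,
) -> tuple[Template, list[DeformationField]]:
    """Build a mean-intensity template and per-member deformation fields.

    Iterating re-registers every member to the current mean; the update
    is kept only while the mean pairwise SSD of the deformed members
    does not increase (monotone-or-stop contract).
    """
    if not samples:
        raise ValueError("need at least one volume")
    shapes = {v.shape for v in samples}
    if len(shapes) != 1:
        raise ValueError("mixed grids")
    demons_kw = demons_kw or {}
    ids = member_ids or [f"m{i}" for i in range(len(samples))]
    data = [v.data.astype(np.float32) for v in samples]

    template = np.mean(data, axis=0)
    zero = np.zeros(data[0].shape + (3,), dtype=np.float32)
    best_fields = [zero.copy() for _ in data]
    best_warped = list(data)
    best_ssd = _mean_pairwise_ssd(best_warped)

    if len(data) > 1:
        for _ in range(iters):
            fields = [demons_displacement(template, m, **demons_kw) for m in data]
            warped = [warp(m, f, order=1) for m, f in zip(data, fields)]
            ssd = _mean_pairwise_ssd(warped)
            if ssd > best_ssd:
                break
            best_ssd, best_fields, best_warped = ssd, fields, warped
            template = np.mean(warped, axis=0)

    template = np.mean(best_warped, axis=0)
    tpl = Template(
        intensity=Volume3D(template, samples[0].spacing, aligned=True),
        member_ids=list(ids),
    )
    defs = [
        DeformationField(forward=f, inverse=invert_displacement(f), source_id=i)
        for f, i in zip(best_fields, ids)
    ]
    return tpl, defs


def vote_labels(labelmaps: list[np.ndarray]) -> np.ndarray:
    """Per-voxel majority vote over integer labelmaps; ties -> lowest class."""
    counts = np.zeros((NUM_CLASSES,) + labelmaps[0].shape, dtype=np.int16)
    for lm in labelmaps:
        for c in range(NUM_CLASSES):
            counts[c] += lm == c
    return np.argmax(counts, axis=0).astype(np.uint8)


def annotate_template(tpl: Template, fields: list[DeformationField],
                      member_labels: list[LabelMap]) -> Template:
    """Label a template by warping member labels into template space
    (nearest neighbour through the forward fields) and majority voting.

    Synthetic stand-in for manual template annotation: the phantom's
    ground truth plays the role of the annotator.
    """
    warped = [warp(lm.data, f.forward, order=0) for lm, f in zip(member_labels, fields)]
    tpl.labels = LabelMap(vote_labels(warped), tpl.intensity.spacing, provenance="atlas")
    return tpl


def fuse_hemispheres(left: Template, right: Template) -> Template:
    """Join the two hemisphere templates at the central sagittal plane:
    left-template voxels on the left half-lattice, right on the right."""
    if left.intensity.shape != right.intensity.shape:
        raise ValueError("grid mismatch")
    if left.hemisphere != "left" or right.hemisphere != "right":
        raise ValueError("expected hemisphere tags left/right")
    nx = left.intensity.shape[0]
    cut = nx // 2
    fused = left.intensity.data.copy()
    fused[cut:] = right.intensity.data[cut:]
    out = Template(
        intensity=Volume3D(fused, left.intensity.spacing, aligned=True),
        ga_bin=left.ga_bin,
        hemisphere="fused",
        member_ids=list(left.member_ids) + list(right.member_ids),
    )
    if left.labels is not None and right.labels is not None:
        lab = left.labels.data.copy()
        lab[cut:] = right.labels.data[cut:]
        out.labels = LabelMap(lab, left.labels.spacing, provenance="atlas")
    return out


def propagate_labels(tpl: Template, fields: list[DeformationField]) -> list[LabelMap]:
    """Resample template labels to each member through the inverse
    deformation field (nearest neighbour); provenance ``atlas``."""
    if tpl.labels is None:
        raise ValueError("template has no labels")
    out = []
    for f in fields:
        if f.inverse is None:
            raise ValueError("deformation field missing inverse")
        lab = warp(tpl.labels.data, f.inverse, order=0)
        out.append(LabelMap(lab, tpl.labels.spacing, provenance="atlas"))
    return out


# ---------------------------------------------------------------------------
# Cohort-level pipeline
# ---------------------------------------------------------------------------

def restrict_lateral_to_hemisphere(labels: LabelMap, visible_hemisphere: str) -> LabelMap:
    """Zero out CP/LPVH labels in the occluded hemisphere; the midline
    structures (CSPV, CB) are left untouched."""
    nx = labels.shape[0]
    cut = nx // 2
    data = labels.data.copy()
    occluded = slice(cut, None) if visible_hemisphere == "left" else slice(None, cut)
    region = data[occluded]
    region[(region == CP) | (region == LPVH)] = 0
    data[occluded] = region
    return LabelMap(data, labels.spacing, provenance=labels.provenance)


def build_week_templates(
    cohort: list[CohortSample],
    iters: int = 2,
    demons_kw: dict | None = None,
) -> tuple[dict[int, Template], dict[str, DeformationField]]:
    """One fused, labelled template per gestational week.

    Hemisphere templates are built from the members whose visible
    hemisphere matches; if one hemisphere has no members in a week the
    opposite template is mirrored across the midline.  Returns the
    templates keyed by week and the per-sample deformation fields.
    """
    weeks = sorted({week_bin(s.ga_weeks) for s in cohort})
    templates: dict[int, Template] = {}
    sample_fields: dict[str, DeformationField] = {}
    for wk in weeks:
        members = [s for s in cohort if week_bin(s.ga_weeks) == wk]
        hemi_tpl: dict[str, Template] = {}
        for hemi in ("left", "right"):
            group = [s for s in members if s.visible_hemisphere == hemi]
            if not group:
                continue
            tpl, fields = groupwise_template(
                [s.image for s in group], iters=iters,
                member_ids=[s.sample_id for s in group], demons_kw=demons_kw,
            )
            tpl.ga_bin = wk
            tpl.hemisphere = hemi
            annotate_template(tpl, fields, [s.labels for s in group])
            hemi_tpl[hemi] = tpl
            for f in fields:
                sample_fields[f.source_id] = f
        for hemi in ("left", "right"):
            if hemi not in hemi_tpl:
                other = hemi_tpl[{"left": "right", "right": "left"}[hemi]]
                mirrored = Template(
                    intensity=Volume3D(mirror_x(other.intensity.data),
                                       other.intensity.spacing, aligned=True),
                    labels=LabelMap(mirror_x(other.labels.data), other.labels.spacing,
                                    provenance="atlas") if other.labels is not None else None,
                    ga_bin=wk, hemisphere=hemi, member_ids=[],
                )
                hemi_tpl[hemi] = mirrored
        templates[wk] = fuse_hemispheres(hemi_tpl["left"], hemi_tpl["right"])
    return templates, sample_fields


def atlas_labels_for_cohort(
    cohort: list[CohortSample],
    templates: dict[int, Template],
    sample_fields: dict[str, DeformationField],
    restrict_lateral: bool = True,
) -> dict[str, LabelMap]:
    """Weak atlas labels for every cohort member, propagated from its
    week's fused template through the member's inverse field."""
    out: dict[str, LabelMap] = {}
    for s in cohort:
        tpl = templates[week_bin(s.ga_weeks)]
        field = sample_fields[s.sample_id]
        lab = propagate_labels(tpl, [field])[0]
        if restrict_lateral:
            lab = restrict_lateral_to_hemisphere(lab, s.visible_hemisphere)
        out[s.sample_id] = lab
    return out
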