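"""Post-processing and evaluation metrics.

Largest-connected-component filtering, Dice similarity coefficient,
95th-percentile Hausdorff distance on boundary voxels (millimetres,
symmetric max of the two directed percentiles) and signed/unsigned
relative volume differences, plus a per-class report writer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import CLASS_NAMES, FOREGROUND_CLASSES, LabelMap

#: Sentinel for an h95 comparison that is undefined (an empty mask).
H95_UNDEFINED = float("nan")

_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity not in _STRUCTS:
        raise ValueError("connectivity must be 6, 18 or 26")
    return _STRUCTS[connectivity]


def largest_component(mask: np.ndarray, connectivity: int = 26) -> np.ndarray:
    """Keep only the largest connected component of a binary mask.

    Size ties are broken in favour of the component containing the
    lexicographically smallest voxel coordinate.  An empty mask passes
    through unchanged.
    """
    mask = np.asarray(mask).astype(bool)
    labeled, n = ndimage.label(mask, structure=_connectivity_structure(connectivity))
    if n <= 1:
        return mask.copy()
    sizes = ndimage.sum_labels(mask, labeled, index=np.arange(1, n + 1))
    best = np.max(sizes)
    candidates = np.flatnonzero(sizes == best) + 1
    if len(candidates) == 1:
        keep = candidates[0]
    else:
        # scipy labels components in raster-scan order, so the smallest
        # label among the tied candidates contains the lexicographically
        # smallest voxel
        keep = candidates.min()
    return labeled == keep


def postprocess_labels(labels: LabelMap, connectivity: int = 26) -> LabelMap:
    """Apply ``largest_component`` to every foreground class."""
    out = np.zeros_like(labels.data)
    for c in FOREGROUND_CLASSES:
        out[largest_component(labels.data == c, connectivity)] = c
    return LabelMap(out, labels.spacing, provenance=labels.provenance)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """2|a∩b| / (|a|+|b|); both-empty pairs score 1.0 by convention."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch {a.shape} vs {b.shape}")
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (sa + sb)


def boundary_voxels(mask: np.ndarray, connectivity: int = 26) -> np.ndarray:
    """(N, 3) coordinates of foreground voxels with ≥1 background
    neighbour under the chosen connectivity (grid edges count as
    background)."""
    mask = np.asarray(mask).astype(bool)
    eroded = ndimage.binary_erosion(mask, structure=_connectivity_structure(connectivity),
                                    border_value=0)
    return np.argwhere(mask & ~eroded)


def _directed_p95(src: np.ndarray, dst: np.ndarray, spacing: np.ndarray) -> float:
    # nearest-dst distance for each src boundary voxel, 95th percentile
    diffs = (src[:, None, :] - dst[None, :, :]) * spacing[None, None, :]
    dmin = np.sqrt((diffs ** 2).sum(axis=2)).min(axis=1)
    return float(np.percentile(dmin, 95))


def hausdorff95(a: np.ndarray, b: np.ndarray,
                spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
                connectivity: int = 26) -> float:
    """Symmetric 95th-percentile Hausdorff distance in mm between the
    boundary-voxel sets of two masks.

    Either mask empty → ``H95_UNDEFINED`` (NaN) with a warning: the
    comparison is reported missing, never as zero.
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch {a.shape} vs {b.shape}")
    if not a.any() or not b.any():
        warnings.warn("hausdorff95 undefined for an empty mask", stacklevel=2)
        return H95_UNDEFINED
    sp = np.asarray(spacing_mm, dtype=float)
    ba = boundary_voxels(a, connectivity)
    bb = boundary_voxels(b, connectivity)
    return max(_directed_p95(ba, bb, sp), _directed_p95(bb, ba, sp))


def volume_differences(pred: np.ndarray, gt: np.ndarray) -> tuple[float, float]:
    """Signed and unsigned relative volume difference (V_pred−V_gt)/V_gt.

    Positive signed values indicate over-segmentation.
    """
    vp = int(np.asarray(pred).astype(bool).sum())
    vg = int(np.asarray(gt).astype(bool).sum())
    if vg == 0:
        raise ValueError("ground-truth mask is empty")
    signed = (vp - vg) / vg
    return signed, abs(signed)


@dataclass
class MetricsReport:
    """Per-class evaluation of one predicted labelmap against a reference."""

    post_processed: bool
    rows: list[dict] = field(default_factory=list)

    def to_csv(self, path: str) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            wr = csv.DictWriter(fh, fieldnames=["class", "name", "dsc", "h95_mm",
                                                "signed_rvd", "unsigned_rvd"])
            wr.writeheader()
            for row in self.rows:
                wr.writerow(row)

    def mean(self, key: str) -> float:
        vals = [r[key] for r in self.rows if np.isfinite(r[key])]
        return float(np.mean(vals)) if vals else float("nan")


def evaluate(pred: LabelMap, gt: LabelMap, post: bool = True,
             connectivity: int = 26) -> MetricsReport:
    """Per-foreground-class DSC, H95 and relative volume differences,
    optionally after largest-component post-processing."""
    if pred.shape != gt.shape:
        raise ValueError("prediction/reference grid mismatch")
    work = postprocess_labels(pred, connectivity) if post else pred
    report = MetricsReport(post_processed=post)
    for c in FOREGROUND_CLASSES:
        pm = work.data == c
        gm = gt.data == c
        if gm.any():
            srvd, urvd = volume_differences(pm, gm)
        else:
            srvd, urvd = float("nan"), float("nan")
        report.rows.append({
            "class": c,
            "name": CLASS_NAMES[c],
            "dsc": dice(pm, gm),
            "h95_mm": hausdorff95(pm, gm, pred.spacing, connectivity)
            if pm.any() and gm.any() else H95_UNDEFINED,
            "signed_rvd": srvd,
            "unsigned_rvd": urvd,
        })
    return report
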