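"""Volumetric growth-curve estimation from predicted labelmaps.

Turns segmentations of an analysis cohort into absolute (cm³) and
brain-relative structure volumes, fits per-structure polynomial growth
curves by ordinary least squares with a significance-gated quadratic
term (retained only when significant for *both* model tags), and
provides 95% OLS prediction intervals.

Whole-brain volume comes from registering a binary brain template mask
to each image with a similarity transform (rigid + isotropic scale) and
counting the warped mask voxels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage, stats

from .core import FOREGROUND_CLASSES, CLASS_NAMES, LabelMap, Volume3D
from .templates import week_bin


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------

def structure_volume(labels: LabelMap | np.ndarray, c: int,
                     spacing_mm: tuple[float, float, float] | None = None) -> float:
    """Voxel count of class ``c`` times voxel volume, in cm³."""
    if isinstance(labels, LabelMap):
        arr, spacing = labels.data, labels.spacing
    else:
        arr = np.asarray(labels)
        if spacing_mm is None:
            raise ValueError("spacing_mm required for a bare array")
        spacing = spacing_mm
    if c not in range(0, 5):
        raise ValueError(f"invalid class {c}")
    n = int((arr == c).sum())
    if n == 0:
        warnings.warn(f"class {c} absent from labelmap", stacklevel=2)
    voxel_mm3 = float(np.prod(spacing))
    return n * voxel_mm3 / 1000.0


def relative_volume(v: float, v_brain: float) -> float:
    """Structure volume as a fraction of whole-brain volume."""
    if v_brain <= 0:
        raise ValueError("v_brain must be positive")
    return v / v_brain


def template_mask_for_ga(masks: dict[int, np.ndarray], ga_weeks: float,
                         floor_week: int | None = None) -> np.ndarray:
    """Rounded-GA mask lookup; below the available (or configured floor)
    range the youngest available template is substituted."""
    if not masks:
        raise ValueError("empty mask table")
    wk = week_bin(ga_weeks)
    lo = min(masks) if floor_week is None else max(min(masks), floor_week)
    wk = min(max(wk, lo), max(masks))
    if wk not in masks:
        raise KeyError(f"no brain mask template for week {wk}")
    return masks[wk]


def _subject_brain_mask(image: np.ndarray) -> np.ndarray:
    """Approximate subject brain mask by Otsu thresholding, closing and
    largest-component selection (used only as the registration target)."""
    from skimage.filters import threshold_otsu

    smooth = ndimage.gaussian_filter(image.astype(np.float32), 1.0)
    mask = smooth > threshold_otsu(smooth)
    mask = ndimage.binary_closing(mask, structure=np.ones((3, 3, 3)), iterations=2)
    mask = ndimage.binary_fill_holes(mask)
    labeled, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(mask, labeled, index=np.arange(1, n + 1))
        mask = labeled == (int(np.argmax(sizes)) + 1)
    return mask


def whole_brain_volume(image: Volume3D, brain_template_mask: np.ndarray,
                       ga_weeks: float | None = None) -> float:
    """Whole-brain volume in cm³ by similarity registration of the
    template mask to the image.

    The template mask (smoothed) is registered to a smoothed subject
    brain mask derived from the image with a rigid + isotropic scale
    transform; the returned volume counts the warped mask voxels on the
    image grid.  Raises if registration fails to improve the cost.
    """
    del ga_weeks  # lookup happens in template_mask_for_ga; kept for provenance
    subject = _subject_brain_mask(image.data).astype(np.float32)
    moving = np.asarray(brain_template_mask).astype(np.float32)
    if subject.shape != moving.shape:
        raise ValueError("template mask grid does not match image grid")
    sp = image.spacing

    def to_sitk(arr):
        img = sitk.GetImageFromArray(np.ascontiguousarray(
            ndimage.gaussian_filter(arr, 1.0).transpose(2, 1, 0)))
        img.SetSpacing(tuple(float(s) for s in sp))
        return img

    fixed, mov = to_sitk(subject), to_sitk(moving)
    tx0 = sitk.CenteredTransformInitializer(
        fixed, mov, sitk.Similarity3DTransform(),
        sitk.CenteredTransformInitializerFilter.MOMENTS)

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-4, numberOfIterations=100)
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetInitialTransform(tx0, inPlace=False)
    final = reg.Execute(fixed, mov)

    def cost(tx):
        m = sitk.ImageRegistrationMethod()
        m.SetMetricAsMeanSquares()
        m.SetInterpolator(sitk.sitkLinear)
        m.SetInitialTransform(tx)
        return m.MetricEvaluate(fixed, mov)

    if cost(final) >= cost(sitk.Transform(3, sitk.sitkIdentity)):
        raise RuntimeError("brain mask registration did not improve the cost")

    mask_img = sitk.GetImageFromArray(np.ascontiguousarray(moving.transpose(2, 1, 0)))
    mask_img.SetSpacing(tuple(float(s) for s in sp))
    warped = sitk.Resample(mask_img, fixed, final, sitk.sitkNearestNeighbor, 0.0)
    n = float(sitk.GetArrayFromImage(warped).sum())
    return n * float(np.prod(sp)) / 1000.0


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

@dataclass
class VolumeRecord:
    sample_id: str
    ga_weeks: float
    volumes_cm3: dict[int, float]
    brain_volume_cm3: float
    model_tag: str

    @property
    def relative(self) -> dict[int, float]:
        return {c: relative_volume(v, self.brain_volume_cm3)
                for c, v in self.volumes_cm3.items()}


def records_from_predictions(samples, predictions: dict[str, LabelMap],
                             model_tag: str,
                             brain_masks: dict[int, np.ndarray] | None = None,
                             brain_volumes: dict[str, float] | None = None,
                             floor_week: int | None = None) -> list[VolumeRecord]:
    """Build VolumeRecords for a cohort from post-processed predictions.

    Whole-brain volumes are either supplied directly (``brain_volumes``)
    or estimated by registering the rounded-GA template mask from
    ``brain_masks`` to each image.
    """
    from .metrics import postprocess_labels

    out = []
    for s in samples:
        pred = postprocess_labels(predictions[s.sample_id])
        vols = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for c in FOREGROUND_CLASSES:
                vols[c] = structure_volume(pred, c)
        if brain_volumes is not None:
            vb = brain_volumes[s.sample_id]
        elif brain_masks is not None:
            tpl = template_mask_for_ga(brain_masks, s.ga_weeks, floor_week)
            vb = whole_brain_volume(s.image, tpl, s.ga_weeks)
        else:
            raise ValueError("provide brain_masks or brain_volumes")
        out.append(VolumeRecord(s.sample_id, float(s.ga_weeks), vols, vb, model_tag))
    return out


def records_to_csv(records: list[VolumeRecord], path: str) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        names = [CLASS_NAMES[c] for c in FOREGROUND_CLASSES]
        wr = csv.writer(fh)
        wr.writerow(["sample_id", "ga_weeks", "model_tag", "brain_cm3"]
                    + [f"{n}_cm3" for n in names] + [f"{n}_rel" for n in names])
        for r in records:
            wr.writerow([r.sample_id, r.ga_weeks, r.model_tag,
                         f"{r.brain_volume_cm3:.6g}"]
                        + [f"{r.volumes_cm3[c]:.6g}" for c in FOREGROUND_CLASSES]
                        + [f"{r.relative[c]:.6g}" for c in FOREGROUND_CLASSES])


# ---------------------------------------------------------------------------
# Growth-curve fitting
# ---------------------------------------------------------------------------

@dataclass
class GrowthFit:
    """One per-tag polynomial fit with OLS prediction intervals."""

    structure: int
    model_tag: str
    degree: int
    coefficients: np.ndarray
    residual_variance: float
    df_resid: int
    cov_params: np.ndarray
    quadratic_p_values: dict[str, float] = field(default_factory=dict)

    def _design(self, ga: np.ndarray) -> np.ndarray:
        ga = np.atleast_1d(np.asarray(ga, dtype=float))
        cols = [np.ones_like(ga), ga]
        if self.degree == 2:
            cols.append(ga ** 2)
        return np.stack(cols, axis=1)

    def predict(self, ga) -> np.ndarray:
        return self._design(ga) @ self.coefficients

    def pi_half_width(self, ga, level: float = 0.95) -> np.ndarray:
        """Half-width of the OLS prediction interval at each GA."""
        x = self._design(ga)
        var_mean = np.einsum("ij,jk,ik->i", x, self.cov_params, x)
        se = np.sqrt(self.residual_variance + var_mean)
        t = stats.t.ppf(0.5 + level / 2.0, self.df_resid)
        return t * se

    def prediction_interval(self, ga, level: float = 0.95):
        mean = self.predict(ga)
        hw = self.pi_half_width(ga, level)
        return mean - hw, mean + hw


def _ols(x: np.ndarray, y: np.ndarray, degree: int):
    import statsmodels.api as sm

    cols = [x]
    if degree == 2:
        cols.append(x ** 2)
    X = sm.add_constant(np.stack(cols, axis=1))
    return sm.OLS(y, X).fit()


def _quadratic_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided t-test p-value of the quadratic coefficient; degenerate
    (near-zero residual) fits report non-significant."""
    res = _ols(x, y, degree=2)
    scale_floor = 1e-12 * max(1.0, float(np.mean(y ** 2)))
    if not np.isfinite(res.scale) or res.scale < scale_floor:
        return 1.0
    p = float(res.pvalues[-1])
    return p if np.isfinite(p) else 1.0


def fit_growth_curve(records: list[VolumeRecord], structure: int,
                     alpha: float = 0.05, value: str = "absolute",
                     ) -> dict[str, GrowthFit]:
    """Per-tag growth fit for one structure with a shared quadratic gate.

    Fits ``v ~ b0 + b1·ga (+ b2·ga²)`` by OLS for each model tag; the
    quadratic term is retained only when its two-sided t-test p-value is
    below ``alpha`` for *every* tag present.  ``value`` selects absolute
    (cm³) or brain-relative volumes.
    """
    if value not in ("absolute", "relative"):
        raise ValueError("value must be 'absolute' or 'relative'")
    tags = sorted({r.model_tag for r in records})
    if not tags:
        raise ValueError("no records")
    data: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for tag in tags:
        rs = [r for r in records if r.model_tag == tag]
        if len(rs) < 10:
            raise ValueError(f"tag {tag}: need >= 10 records, got {len(rs)}")
        ga = np.array([r.ga_weeks for r in rs])
        if len({week_bin(g) for g in ga}) < 4:
            raise ValueError(f"tag {tag}: records must span >= 4 GA weeks")
        if value == "absolute":
            y = np.array([r.volumes_cm3[structure] for r in rs])
        else:
            y = np.array([r.relative[structure] for r in rs])
        data[tag] = (ga, y)

    pvals = {tag: _quadratic_p(ga, y) for tag, (ga, y) in data.items()}
    degree = 2 if all(p < alpha for p in pvals.values()) else 1

    fits = {}
    for tag, (ga, y) in data.items():
        res = _ols(ga, y, degree)
        fits[tag] = GrowthFit(
            structure=structure, model_tag=tag, degree=degree,
            coefficients=np.asarray(res.params, dtype=float),
            residual_variance=float(res.scale),
            df_resid=int(res.df_resid),
            cov_params=np.asarray(res.cov_params(), dtype=float),
            quadratic_p_values=dict(pvals),
        )
    return fits


def plot_growth_curves(records: list[VolumeRecord],
                       fits: dict[int, dict[str, GrowthFit]],
                       path: str, value: str = "absolute") -> None:
    """2x2 panel of per-structure scatter + fitted curves with 95% PI."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharex=True)
    ga_grid = np.linspace(min(r.ga_weeks for r in records),
                          max(r.ga_weeks for r in records), 50)
    for ax, c in zip(axes.ravel(), FOREGROUND_CLASSES):
        for tag in sorted({r.model_tag for r in records}):
            rs = [r for r in records if r.model_tag == tag]
            ga = [r.ga_weeks for r in rs]
            y = [r.volumes_cm3[c] if value == "absolute" else r.relative[c]
                 for r in rs]
            ax.scatter(ga, y, s=10, alpha=0.6, label=tag)
            fit = fits[c][tag]
            mean = fit.predict(ga_grid)
            lo, hi = fit.prediction_interval(ga_grid)
            ax.plot(ga_grid, mean, lw=1.5)
            ax.fill_between(ga_grid, lo, hi, alpha=0.15)
        ax.set_title(f"{CLASS_NAMES[c]} (deg {fits[c][tag].degree})")
        ax.set_xlabel("GA (weeks)")
        ax.set_ylabel("cm³" if value == "absolute" else "fraction of brain")
    axes[0, 0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
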