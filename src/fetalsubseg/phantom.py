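"""Synthetic ultrasound-like fetal brain phantoms.

Generates 3D volumes that emulate the salient properties of second
trimester fetal neurosonography: an ellipsoidal brain whose volume grows
with gestational age (GA), four subcortical structures (CP, LPVH, CSPV,
CB) whose volumes follow GA-dependent growth laws, speckle as unit-mean
multiplicative noise, acoustic shadowing of the hemisphere proximal to
the virtual transducer, and a random rigid pose emulating free-hand
acquisition.  The lateral structures (CP, LPVH) are rendered only in the
visible (distal) hemisphere; the midline structures (CSPV, CB) span the
midsagittal plane.

Every sample is fully determined by ``(ga_weeks, seed, config)`` and
carries voxel-accurate ground-truth labels, so atlas propagation,
network training and growth-curve estimation can all be validated
against known truth.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import scipy.ndimage as ndi

from .core import (
    BACKGROUND, CB, CP, CSPV, LPVH, FOREGROUND_CLASSES, CLASS_NAMES,
    LabelMap, RigidTransform, Volume3D, apply_rigid, load_nifti, save_nifti,
)

GA_MIN, GA_MAX = 18.0, 27.0


# ---------------------------------------------------------------------------
# Growth laws
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthLaw:
    """Volume of a structure as a polynomial in ``t = ga - 18`` weeks.

    If ``relative_to_brain`` the polynomial gives the volume *fraction*
    of the whole brain and is multiplied by the brain volume at that GA;
    a linear fraction times a linear brain volume makes the absolute
    volume quadratic in GA.
    """

    structure: int
    form: str  # "linear" | "quadratic" (shape of the *absolute* volume in GA)
    coefficients: tuple[float, ...]
    relative_to_brain: bool = False

    def __call__(self, ga_weeks: float, brain_volume_cm3: float | None = None) -> float:
        t = ga_weeks - 18.0
        v = float(np.polyval(self.coefficients[::-1], t))
        if self.relative_to_brain:
            if brain_volume_cm3 is None:
                brain_volume_cm3 = brain_volume(ga_weeks)
            v *= brain_volume_cm3
        return v


def brain_volume(ga_weeks: float) -> float:
    """Whole-brain volume in cm^3; linear from 33 (18 GW) to 105 (26 GW)."""
    return 33.0 + 9.0 * (ga_weeks - 18.0)


#: Default calibrations.  LPVH rises linearly 0.1 -> 0.3 cm^3 and CSPV
#: 0.01 -> 0.6 cm^3 over 18 -> 26 GW; the cerebellum holds 1.7 -> 2.3 %
#: of brain volume (quadratic absolute growth); the choroid plexus adds
#: only a little absolute volume, so its brain-relative share falls from
#: ~12 % at 18 GW to ~4 % at 26 GW.
DEFAULT_LAWS: dict[int, GrowthLaw] = {
    CP: GrowthLaw(CP, "linear", (4.0, 0.0375)),
    LPVH: GrowthLaw(LPVH, "linear", (0.1, 0.025)),
    CSPV: GrowthLaw(CSPV, "linear", (0.01, 0.07375)),
    CB: GrowthLaw(CB, "quadratic", (0.017, 0.00075), relative_to_brain=True),
}


def growth_model(ga_weeks: float, law: GrowthLaw, brain_volume_cm3: float | None = None) -> float:
    """Evaluate a growth law at ``ga_weeks``; volume in cm^3."""
    if not (GA_MIN <= ga_weeks <= GA_MAX):
        raise ValueError(f"ga_weeks={ga_weeks} outside supported range [{GA_MIN}, {GA_MAX}]")
    if not all(np.isfinite(law.coefficients)):
        raise ValueError("growth-law coefficients must be finite")
    v = law(ga_weeks, brain_volume_cm3)
    if v <= 0:
        raise ValueError(f"growth law predicts non-positive volume at {ga_weeks} GW")
    return v


# ---------------------------------------------------------------------------
# Phantom configuration and geometry
# ---------------------------------------------------------------------------

# centers as fractions of the brain semi-axes; axis ratios of each
# structure ellipsoid (scaled to the target volume).
_GEOMETRY = {
    CP: {"center": (0.42, 0.18, 0.0), "ratios": (0.95, 1.0, 0.95), "lateral": True},
    LPVH: {"center": (0.38, -0.55, 0.12), "ratios": (1.0, 1.4, 0.7), "lateral": True},
    CSPV: {"center": (0.0, 0.35, 0.15), "ratios": (0.45, 1.8, 0.5), "lateral": False},
    CB: {"center": (0.0, -0.55, -0.45), "ratios": (1.6, 0.8, 0.6), "lateral": False},
}

#: Discrete LPVH shape modes (axis ratios); volume is preserved across
#: modes so cluster-based templates have shape variation to recover.
LPVH_MODES = ((1.0, 1.4, 0.7), (0.7, 1.9, 0.55), (1.35, 0.9, 0.95))

_INTENSITY = {BACKGROUND: 0.05, "parenchyma": 0.45, CP: 0.85, LPVH: 0.15, CSPV: 0.12, CB: 0.75}

# paint order: large structures first so that small ones keep exact
# volume where ellipsoids abut (the sliver lost by CP/CB is < 1-2 %).
_PAINT_ORDER = (CP, CB, CSPV, LPVH)


@dataclass(frozen=True)
class PhantomConfig:
    grid_size: int = 64
    spacing_mm: float = 1.2
    shadow_strength: float = 0.35
    speckle_strength: float = 0.25  # std of unit-mean multiplicative noise
    smooth_sigma_vox: float = 0.5
    jitter: float = 0.02            # relative geometric inter-subject variability
    lpvh_n_modes: int = 3
    lpvh_mode: int | None = None    # fix the shape mode; None -> random per sample
    quality: float = 1.0            # >1 attenuates, <1 amplifies the corruptions
    max_rotation_deg: float = 15.0
    max_translation_mm: float = 5.0
    laws: dict = field(default_factory=lambda: dict(DEFAULT_LAWS))

    @property
    def extent_mm(self) -> float:
        return self.grid_size * self.spacing_mm


def paper_scale_config(**kw) -> PhantomConfig:
    """The full-resolution grid convention: 160^3 at 0.6 mm isotropic."""
    return PhantomConfig(grid_size=160, spacing_mm=0.6, **kw)


@dataclass
class CohortSample:
    """One synthetic subject: aligned image + ground-truth labels."""

    image: Volume3D
    labels: LabelMap
    ga_weeks: float
    visible_hemisphere: str       # "left" | "right"
    brain_mask: np.ndarray
    pose: RigidTransform
    seed: int
    sample_id: str = ""
    lpvh_mode: int = 0

    def unaligned_image(self) -> Volume3D:
        out = apply_rigid(self.image.data, self.pose, self.image.spacing, order=1,
                          cval=_INTENSITY[BACKGROUND])
        return Volume3D(out, self.image.spacing, aligned=False, ga_weeks=self.ga_weeks)

    def unaligned_labels(self) -> LabelMap:
        out = apply_rigid(self.labels.data, self.pose, self.labels.spacing, order=0)
        return LabelMap(out, self.labels.spacing, provenance=self.labels.provenance)


def brain_semiaxes_mm(ga_weeks: float, config: PhantomConfig) -> tuple[float, float, float]:
    """Ellipsoid semi-axes (mm) with ratios 1.25 : 1 : 0.92 matched to the
    brain-volume law.  At 26 GW the brain spans ~70 mm left-right, which
    fits the default 76.8 mm grid extent."""
    ratios = np.array([1.25, 1.0, 0.92])
    v_mm3 = brain_volume(ga_weeks) * 1000.0
    r = (3.0 * v_mm3 / (4.0 * np.pi * np.prod(ratios))) ** (1.0 / 3.0)
    return tuple(ratios * r)


def analytic_brain_mask(ga_weeks: float, config: PhantomConfig) -> np.ndarray:
    n, sp = config.grid_size, config.spacing_mm
    axes = brain_semiaxes_mm(ga_weeks, config)
    c = (n - 1) / 2.0
    x, y, z = np.meshgrid(*[(np.arange(n) - c) * sp] * 3, indexing="ij")
    return (x / axes[0]) ** 2 + (y / axes[1]) ** 2 + (z / axes[2]) ** 2 <= 1.0


def _ellipsoid_mask(n, sp, center_mm, semi_mm) -> np.ndarray:
    c = (n - 1) / 2.0
    x, y, z = np.meshgrid(*[(np.arange(n) - c) * sp] * 3, indexing="ij")
    return ((x - center_mm[0]) / semi_mm[0]) ** 2 + ((y - center_mm[1]) / semi_mm[1]) ** 2 \
        + ((z - center_mm[2]) / semi_mm[2]) ** 2 <= 1.0


def make_phantom(ga_weeks: float, seed: int, config: PhantomConfig = PhantomConfig(),
                 visible_hemisphere: str | None = None, sample_id: str = "") -> CohortSample:
    """Generate one deterministic synthetic subject at ``ga_weeks``."""
    if not (GA_MIN <= ga_weeks <= GA_MAX):
        raise ValueError(f"ga_weeks={ga_weeks} outside [{GA_MIN}, {GA_MAX}]")
    rng = np.random.default_rng(seed)
    n, sp = config.grid_size, config.spacing_mm

    axes = np.array(brain_semiaxes_mm(ga_weeks, config))
    if 2 * axes.max() > config.extent_mm * 0.98:
        raise ValueError("brain does not fit the configured grid")
    brain = analytic_brain_mask(ga_weeks, config)
    v_brain = brain_volume(ga_weeks)

    if visible_hemisphere is None:
        visible_hemisphere = "left" if rng.random() < 0.5 else "right"
    side = +1.0 if visible_hemisphere == "right" else -1.0  # +x is the right hemisphere

    lpvh_mode = config.lpvh_mode
    if lpvh_mode is None:
        lpvh_mode = int(rng.integers(config.lpvh_n_modes))

    labels = np.zeros((n, n, n), dtype=np.uint8)
    for cls in _PAINT_ORDER:
        geo = _GEOMETRY[cls]
        target_cm3 = growth_model(ga_weeks, config.laws[cls], v_brain)
        if target_cm3 >= v_brain:
            raise ValueError(f"{CLASS_NAMES[cls]} volume exceeds brain volume")
        ratios = np.array(LPVH_MODES[lpvh_mode] if cls == LPVH else geo["ratios"], dtype=float)
        ratios = ratios * (1.0 + config.jitter * rng.standard_normal(3))
        s = (3.0 * target_cm3 * 1000.0 / (4.0 * np.pi * np.prod(ratios))) ** (1.0 / 3.0)
        semi = ratios * s
        center = np.array(geo["center"], dtype=float)
        if geo["lateral"]:
            center[0] *= side
        center = center * axes
        center += config.jitter * axes * rng.standard_normal(3) * 0.5
        m = _ellipsoid_mask(n, sp, center, semi) & brain
        labels[m] = cls

    # piecewise-constant intensity image
    img = np.full((n, n, n), _INTENSITY[BACKGROUND], dtype=np.float32)
    img[brain] = _INTENSITY["parenchyma"]
    for cls in FOREGROUND_CLASSES:
        img[labels == cls] = _INTENSITY[cls]

    if config.smooth_sigma_vox > 0:
        img = ndi.gaussian_filter(img, config.smooth_sigma_vox)

    # acoustic shadowing: smooth attenuation ramp from the midline into
    # the hemisphere proximal to the virtual transducer (the occluded,
    # non-visible side).
    shadow = config.shadow_strength / max(config.quality, 1e-6)
    if shadow > 0:
        xs = np.arange(n, dtype=np.float32) - (n - 1) / 2.0
        depth = np.clip(-side * xs / (n / 2.0), 0.0, 1.0)  # 0 at midline -> 1 at far occluded edge
        ramp = 1.0 - shadow * (3 * depth**2 - 2 * depth**3)  # smoothstep
        img *= ramp[:, None, None]

    speckle = config.speckle_strength / max(config.quality, 1e-6)
    if speckle > 0:
        k = 1.0 / speckle**2
        img *= rng.gamma(shape=k, scale=1.0 / k, size=img.shape).astype(np.float32)

    pose = RigidTransform(
        rotation_deg=tuple(rng.uniform(-config.max_rotation_deg, config.max_rotation_deg, 3)),
        translation_mm=tuple(rng.uniform(-config.max_translation_mm, config.max_translation_mm, 3)),
    )

    return CohortSample(
        image=Volume3D(img, sp, aligned=True, ga_weeks=ga_weeks),
        labels=LabelMap(labels, sp, provenance="expert"),
        ga_weeks=float(ga_weeks),
        visible_hemisphere=visible_hemisphere,
        brain_mask=brain,
        pose=pose,
        seed=int(seed),
        sample_id=sample_id or f"ga{ga_weeks:.1f}_s{seed}",
        lpvh_mode=lpvh_mode,
    )


def make_cohort(n: int, ga_range: tuple[float, float] = (18.0, 26.0), seed: int = 0,
                config: PhantomConfig = PhantomConfig()) -> list[CohortSample]:
    """Generate ``n`` subjects with GAs evenly covering ``ga_range`` and
    visible hemispheres drawn ~50/50."""
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = ga_range
    if not (lo < hi):
        raise ValueError("empty GA range")
    rng = np.random.default_rng(seed)
    gas = np.linspace(lo, hi, n) if n > 1 else np.array([(lo + hi) / 2.0])
    seeds = rng.integers(0, 2**31 - 1, size=n)
    sides = np.where(rng.random(n) < 0.5, "left", "right")
    return [
        make_phantom(float(gas[i]), int(seeds[i]), config,
                     visible_hemisphere=str(sides[i]), sample_id=f"p{i:03d}")
        for i in range(n)
    ]


def write_cohort(samples: list[CohortSample], outdir: str | Path) -> Path:
    """Write images/labels as NIfTI-1, per-sample sidecar JSON and a
    cohort manifest CSV; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = outdir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "ga_weeks", "hemisphere", "seed"])
        for s in samples:
            save_nifti(s.image.data, s.image.spacing, outdir / f"{s.sample_id}_image.nii.gz")
            save_nifti(s.labels.data, s.labels.spacing, outdir / f"{s.sample_id}_labels.nii.gz")
            (outdir / f"{s.sample_id}.json").write_text(json.dumps({
                "ga_weeks": s.ga_weeks,
                "visible_hemisphere": s.visible_hemisphere,
                "seed": s.seed,
                "rotation_deg": list(np.atleast_1d(s.pose.rotation_deg)),
                "translation_mm": list(s.pose.translation_mm),
                "lpvh_mode": s.lpvh_mode,
            }, indent=2))
            w.writerow([s.sample_id, s.ga_weeks, s.visible_hemisphere, s.seed])
    return manifest


def load_cohort(outdir: str | Path) -> list[CohortSample]:
    """Read a cohort previously written by :func:`write_cohort`."""
    outdir = Path(outdir)
    manifest = outdir / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest.csv in {outdir}")
    samples: list[CohortSample] = []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            sid = row["id"]
            img, spacing = load_nifti(outdir / f"{sid}_image.nii.gz")
            lab, _ = load_nifti(outdir / f"{sid}_labels.nii.gz")
            meta = json.loads((outdir / f"{sid}.json").read_text())
            ga = float(meta["ga_weeks"])
            cfg = PhantomConfig(grid_size=img.shape[0], spacing_mm=float(spacing[0]))
            samples.append(CohortSample(
                image=Volume3D(img, spacing, aligned=True, ga_weeks=ga),
                labels=LabelMap(lab.astype(np.uint8), spacing, provenance="expert"),
                ga_weeks=ga,
                visible_hemisphere=meta["visible_hemisphere"],
                brain_mask=analytic_brain_mask(ga, cfg),
                pose=RigidTransform(tuple(meta["rotation_deg"]),
                                    tuple(meta["translation_mm"])),
                seed=int(meta["seed"]),
                sample_id=sid,
                lpvh_mode=int(meta.get("lpvh_mode", 0)),
            ))
    return samples


def label_volume_cm3(labels: LabelMap, cls: int) -> float:
    return float(np.count_nonzero(labels.data == cls)) * labels.voxel_volume_mm3 / 1000.0
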