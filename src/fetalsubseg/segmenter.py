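"""Multi-label 3D U-Net training and inference.

Training minimizes a combination of multi-class soft Dice (foreground
classes only) and voxel-mean cross-entropy, with Adam at learning rate
0.001.  Augmentation draws one random midline flip, rotation, translation
and an isotropic scale whose per-gestational-week bounds are derived from
the mean brain volume curve, so that a sample augmented at week ``w``
stays within the plausible size range of the modelled GA window.

Two label sources are supported: ``expert`` (ground-truth labelmaps, the
few-shot mode) and ``atlas`` (propagated template labels); the source and
the alignment state are recorded in every trained model.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .core import NUM_CLASSES, LabelMap, Volume3D
from .nn import Adam, UNet3D, softmax
from .templates import week_bin

EPS_DICE = 1e-5


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SegConfig:
    """Hyperparameters of one training run.

    The full-scale defaults are depth 5 with 16 initial feature maps;
    desk-scale experiments override ``depth``/``init_features`` and the
    ``iteration_budget``.
    """

    depth: int = 5
    init_features: int = 16
    num_classes: int = NUM_CLASSES
    lambda_ce: float = 1.0
    learning_rate: float = 0.001
    final_learning_rate: float | None = None  # exponential decay target
    warmup_iterations: int = 0                # linear ramp-up to learning_rate
    batch_size: int = 4
    iteration_budget: int | None = None
    label_source: str = "expert"
    aligned: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.label_source not in ("expert", "atlas"):
            raise ValueError("label_source must be 'expert' or 'atlas'")
        for name in ("depth", "init_features", "num_classes", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0 or self.lambda_ce < 0:
            raise ValueError("learning_rate must be positive, lambda_ce >= 0")
        if self.final_learning_rate is not None and self.final_learning_rate <= 0:
            raise ValueError("final_learning_rate must be positive when set")
        if self.warmup_iterations < 0:
            raise ValueError("warmup_iterations must be >= 0")


def default_iteration_budget(n_atlas_train: int, batch_size: int) -> int:
    """Budget equivalent to 100 epochs over the atlas-labelled set."""
    return 100 * math.ceil(n_atlas_train / batch_size)


# ---------------------------------------------------------------------------
# Eq. 2 scaling range and augmentation
# ---------------------------------------------------------------------------

def scaling_range(w: float, vbar: dict[int, float]) -> tuple[float, float]:
    """Per-week isotropic scaling bounds from the mean brain volume table.

    ``s_min = max((0.9 V̄(18)/V̄(w))^{1/3}, 1/1.5)`` and
    ``s_max = min((1.1 V̄(26)/V̄(w))^{1/3}, 1.5)``: the cube root converts
    a volume ratio into a linear scale factor, and the clip keeps any
    draw within [1/1.5, 1.5].
    """
    wk = w if w in vbar else week_bin(float(w))
    for key in (18, 26, wk):
        if key not in vbar:
            raise KeyError(f"vbar table missing week {key}")
        if vbar[key] <= 0:
            raise ValueError("brain volumes must be positive")
    v_w = vbar[wk]
    s_min = max((0.9 * vbar[18] / v_w) ** (1.0 / 3.0), 1.0 / 1.5)
    s_max = min((1.1 * vbar[26] / v_w) ** (1.0 / 3.0), 1.5)
    return float(s_min), float(s_max)


@dataclass
class AugmentationSpec:
    """Random-transform bounds: midline flip, rotation, translation and
    GA-aware isotropic scaling driven by the ``vbar`` brain-volume table."""

    flip_prob: float = 0.5
    rotation_max_deg: float = 30.0
    translation_max_vox: float = 10.0
    vbar: dict[int, float] = field(default_factory=dict)

    def scale_bounds(self, ga_weeks: float) -> tuple[float, float]:
        if not self.vbar:
            return 1.0, 1.0
        return scaling_range(ga_weeks, self.vbar)


def default_augmentation_spec(weeks: tuple[int, int] = (18, 26)) -> AugmentationSpec:
    from .phantom import brain_volume

    vbar = {w: brain_volume(float(w)) for w in range(weeks[0], weeks[1] + 1)}
    for w in (18, 26):
        vbar.setdefault(w, brain_volume(float(w)))
    return AugmentationSpec(vbar=vbar)


def _rotation_matrix(angles_deg: np.ndarray) -> np.ndarray:
    ax, ay, az = np.deg2rad(angles_deg)
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def _affine_resample(arr: np.ndarray, fwd: np.ndarray, shift_vox: np.ndarray,
                     order: int) -> np.ndarray:
    """Resample under the forward map y = fwd (x - c) + c + shift."""
    c = (np.asarray(arr.shape, dtype=float) - 1.0) / 2.0
    inv = np.linalg.inv(fwd)
    offset = c - inv @ (c + shift_vox)
    return ndimage.affine_transform(arr.astype(np.float32), inv, offset=offset,
                                    order=order, mode="constant", cval=0.0,
                                    prefilter=False)


def augment(sample: tuple[np.ndarray, np.ndarray, float], spec: AugmentationSpec,
            rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One random geometric draw applied identically to image and labels.

    The flip reflects across the midsagittal plane (axis 0); rotation
    angles, translations and the isotropic scale are drawn uniformly
    within the bounds of ``spec``.  The image is resampled trilinearly,
    the
    labels with nearest neighbour.
    """
    image, labels, ga = sample
    flip = rng.random() < spec.flip_prob
    angles = rng.uniform(-spec.rotation_max_deg, spec.rotation_max_deg, size=3)
    shift = rng.uniform(-spec.translation_max_vox, spec.translation_max_vox, size=3)
    s_min, s_max = spec.scale_bounds(ga)
    scale = rng.uniform(s_min, s_max)

    fwd = _rotation_matrix(angles) * scale
    if flip:
        fwd = fwd @ np.diag([-1.0, 1.0, 1.0])
    img_out = _affine_resample(image, fwd, shift, order=1)
    lab_out = _affine_resample(labels, fwd, shift, order=0).astype(labels.dtype)
    return img_out, lab_out


# ---------------------------------------------------------------------------
# Eq. 1 loss
# ---------------------------------------------------------------------------

def _one_hot(target: np.ndarray, num_classes: int) -> np.ndarray:
    eye = np.eye(num_classes, dtype=np.float32)
    return eye[target].transpose(0, 4, 1, 2, 3)


def combined_loss(probs: np.ndarray, target: np.ndarray, lambda_ce: float = 1.0,
                  eps: float = EPS_DICE) -> float:
    """``L_total = L_MD + lambda_ce * L_CE`` on probability grids.

    ``L_MD`` is one minus the mean soft Dice over the four foreground
    classes (intersection and sums aggregated over batch and voxels
    before the class mean); ``L_CE`` is the voxel-mean cross-entropy
    over all five classes.
    """
    if probs.ndim == 4:
        probs, target = probs[None], target[None]
    if probs.shape != target.shape:
        raise ValueError(f"shape mismatch {probs.shape} vs {target.shape}")
    axes = (0, 2, 3, 4)
    inter = (probs * target).sum(axis=axes)
    den = probs.sum(axis=axes) + target.sum(axis=axes)
    dice = (2.0 * inter + eps) / (den + eps)
    l_md = 1.0 - float(dice[1:].mean())
    n_vox = target.shape[0] * np.prod(target.shape[2:])
    logp = np.log(np.clip(probs, 1e-12, None))
    l_ce = -float((target * logp).sum()) / float(n_vox)
    return l_md + lambda_ce * l_ce


def _loss_and_grad(logits: np.ndarray, target: np.ndarray, lambda_ce: float,
                   eps: float = EPS_DICE) -> tuple[float, np.ndarray]:
    """Loss value and its analytic gradient with respect to the logits."""
    num_classes = logits.shape[1]
    p = softmax(logits)
    onehot = _one_hot(target, num_classes)
    n_vox = float(target.size)
    n_fg = num_classes - 1
    axes = (0, 2, 3, 4)

    inter = (p * onehot).sum(axis=axes)
    den = p.sum(axis=axes) + onehot.sum(axis=axes)
    num = 2.0 * inter + eps
    dice = num / (den + eps)
    l_md = 1.0 - float(dice[1:].mean())

    logp = np.log(np.clip(p, 1e-12, None))
    l_ce = -float((onehot * logp).sum()) / n_vox

    # dL_MD/dp_c = -(2 t_c (den_c+eps) - num_c) / ((den_c+eps)^2 (C-1)), c >= 1
    dLdp = np.zeros_like(p)
    for c in range(1, num_classes):
        d = den[c] + eps
        dLdp[:, c] = -(2.0 * onehot[:, c] * d - num[c]) / (d * d * n_fg)
    dot = (dLdp * p).sum(axis=1, keepdims=True)
    g_md = p * (dLdp - dot)
    g_ce = (p - onehot) / n_vox
    grad = (g_md + lambda_ce * g_ce).astype(logits.dtype)
    return l_md + lambda_ce * l_ce, grad


# ---------------------------------------------------------------------------
# Training and inference
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    net: UNet3D
    config: SegConfig
    loss_log: list[float]
    val_log: list[tuple[int, float]]
    grid_shape: tuple[int, int, int]
    spacing: tuple[float, float, float]

    @property
    def mode_tag(self) -> str:
        a = "aligned" if self.config.aligned else "unaligned"
        return f"{self.config.label_source}/{a}"


def _normalize(image: np.ndarray) -> np.ndarray:
    img = image.astype(np.float32)
    std = float(img.std())
    return (img - float(img.mean())) / (std if std > 0 else 1.0)


def _as_arrays(dataset) -> list[tuple[np.ndarray, np.ndarray, float]]:
    out = []
    for image, labels, ga in dataset:
        img = image.data if isinstance(image, Volume3D) else np.asarray(image)
        lab = labels.data if isinstance(labels, LabelMap) else np.asarray(labels)
        if img.shape != lab.shape:
            raise ValueError("image/label grid mismatch")
        out.append((img.astype(np.float32), lab.astype(np.uint8), float(ga)))
    return out


def train(dataset, config: SegConfig, spec: AugmentationSpec | None = None,
          spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
          val_every: int = 25) -> TrainedModel:
    """Run exactly ``config.iteration_budget`` Adam steps (one batch per
    iteration) on the dataset, independent of its size.

    In ``atlas`` mode 10% of the samples (at least one, when more than
    one is available) are held out and their loss is logged every
    ``val_every`` iterations; ``expert`` mode trains on everything.  The
    returned model carries the last-iteration weights and the full
    per-iteration loss log.
    """
    data = _as_arrays(dataset)
    if not data:
        raise ValueError("empty dataset")
    shapes = {d[0].shape for d in data}
    if len(shapes) != 1:
        raise ValueError("mixed grids in dataset")
    grid = data[0][0].shape
    div = 2 ** (config.depth - 1)
    if any(s % div for s in grid):
        raise ValueError(f"grid {grid} not divisible by 2^(depth-1)={div}; "
                         "use a smaller depth or a larger grid")
    budget = config.iteration_budget
    if budget is None:
        budget = default_iteration_budget(len(data), config.batch_size)
        config = replace(config, iteration_budget=budget)

    rng = np.random.default_rng(config.seed)
    idx = rng.permutation(len(data))
    val_idx: list[int] = []
    if config.label_source == "atlas" and len(data) > 1:
        n_val = max(1, int(round(0.1 * len(data))))
        val_idx = list(idx[:n_val])
    train_idx = [i for i in idx if i not in val_idx]

    net = UNet3D(depth=config.depth, init_features=config.init_features,
                 num_classes=config.num_classes, seed=config.seed)
    opt = Adam(net.params, lr=config.learning_rate)
    loss_log: list[float] = []
    val_log: list[tuple[int, float]] = []

    def make_batch(indices):
        imgs, labs = [], []
        for i in indices:
            img, lab, ga = data[i]
            if spec is not None:
                img, lab = augment((img, lab, ga), spec, rng)
            imgs.append(_normalize(img))
            labs.append(lab)
        return np.stack(imgs)[:, None], np.stack(labs)

    lr0 = config.learning_rate
    decay = 1.0
    if config.final_learning_rate is not None and budget > 1:
        decay = (config.final_learning_rate / lr0) ** (1.0 / (budget - 1))

    for it in range(budget):
        opt.lr = lr0 * decay**it
        if it < config.warmup_iterations:
            opt.lr *= (it + 1) / config.warmup_iterations
        picks = rng.choice(train_idx, size=config.batch_size,
                           replace=len(train_idx) < config.batch_size)
        x, y = make_batch(picks)
        net.zero_grad()
        logits = net.forward(x, train=True)
        loss, grad = _loss_and_grad(logits, y, config.lambda_ce)
        net.backward(grad)
        opt.step()
        loss_log.append(float(loss))
        if val_idx and (it % val_every == 0 or it == budget - 1):
            vx = np.stack([_normalize(data[i][0]) for i in val_idx])[:, None]
            vy = np.stack([data[i][1] for i in val_idx])
            vlogits = net.forward(vx, train=False)
            vloss, _ = _loss_and_grad(vlogits, vy, config.lambda_ce)
            val_log.append((it, float(vloss)))

    return TrainedModel(net=net, config=config, loss_log=loss_log,
                        val_log=val_log, grid_shape=grid, spacing=spacing)


def predict(model: TrainedModel, image) -> LabelMap:
    """Per-voxel argmax segmentation (ties break to the lowest class)."""
    if isinstance(image, Volume3D):
        arr, spacing = image.data, image.spacing
    else:
        arr, spacing = np.asarray(image), model.spacing
    if tuple(arr.shape) != tuple(model.grid_shape):
        raise ValueError(f"grid {arr.shape} does not match model grid "
                         f"{model.grid_shape}")
    x = _normalize(arr)[None, None]
    logits = model.net.forward(x, train=False)
    labels = np.argmax(logits[0], axis=0).astype(np.uint8)
    return LabelMap(labels, spacing, provenance="predicted")


def predict_probs(model: TrainedModel, image) -> np.ndarray:
    """Softmax class probabilities on the input grid (channels first)."""
    arr = image.data if isinstance(image, Volume3D) else np.asarray(image)
    x = _normalize(arr)[None, None]
    logits = model.net.forward(x, train=False)
    return softmax(logits)[0]


# ---------------------------------------------------------------------------
# Checkpoint IO
# ---------------------------------------------------------------------------

def save_checkpoint(model: TrainedModel, path: str) -> None:
    state = model.net.state_dict()
    arrays = {f"p{i}": v for i, v in enumerate(state["params"])}
    for i, (rm, rv) in enumerate(state["bn"]):
        arrays[f"bn{i}_mean"] = rm
        arrays[f"bn{i}_var"] = rv
    meta = {
        "config": vars(model.config),
        "grid_shape": list(model.grid_shape),
        "spacing": list(model.spacing),
        "n_params": len(state["params"]),
        "n_bn": len(state["bn"]),
        "loss_log": model.loss_log,
        "val_log": model.val_log,
    }
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str) -> TrainedModel:
    with np.load(path) as zf:
        meta = json.loads(bytes(zf["meta"]).decode())
        config = SegConfig(**meta["config"])
        net = UNet3D(depth=config.depth, init_features=config.init_features,
                     num_classes=config.num_classes, seed=config.seed)
        state = {
            "params": [zf[f"p{i}"] for i in range(meta["n_params"])],
            "bn": [(zf[f"bn{i}_mean"], zf[f"bn{i}_var"])
                   for i in range(meta["n_bn"])],
        }
    net.load_state_dict(state)
    return TrainedModel(net=net, config=config, loss_log=list(meta["loss_log"]),
                        val_log=[tuple(v) for v in meta["val_log"]],
                        grid_shape=tuple(meta["grid_shape"]),
                        spacing=tuple(meta["spacing"]))
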