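"""Train a small 3D U-Net on synthetic phantoms, predict and score a
held-out subject, and look at the gestational-age aware augmentation.

Training here runs without augmentation: on desk-scale grids (32 voxels
a side, minutes of CPU budget) random geometric transforms destabilize
the short optimization, so augmentation is reserved for full-resolution
problems.  The augmentation machinery itself is demonstrated at the end.

Run:  python examples/04_train_segmenter.py     (~5 min on one CPU)
"""

import numpy as np

from fetalsubseg.metrics import evaluate
from fetalsubseg.phantom import PhantomConfig, make_cohort
from fetalsubseg.segmenter import (
    SegConfig,
    augment,
    default_augmentation_spec,
    predict,
    save_checkpoint,
    train,
)

cfg = PhantomConfig(grid_size=32, spacing_mm=2.4)
cohort = make_cohort(10, (22.0, 26.0), seed=1, config=cfg)
held_out, training = cohort[4], [s for i, s in enumerate(cohort) if i != 4]

data = [(s.image.data, s.labels.data, s.ga_weeks) for s in training]
sc = SegConfig(depth=3, init_features=8, batch_size=2,
               iteration_budget=200, seed=0, learning_rate=0.01)
print(f"training {len(data)} subjects, {sc.iteration_budget} iterations "
      f"(depth {sc.depth}, {sc.init_features} features)")
model = train(data, sc)
print(f"loss {model.loss_log[0]:.3f} -> {model.loss_log[-1]:.3f}")

pred = predict(model, held_out.image.data)
report = evaluate(pred, held_out.labels, post=True)
print(f"\nheld-out subject {held_out.sample_id} (GA {held_out.ga_weeks:.1f}):")
for row in report.rows:
    print(f"  {row['name']:<6} DSC {row['dsc']:.2f}  "
          f"H95 {row['h95_mm']:.1f} mm  RVD {row['signed_rvd']:+.2f}")

save_checkpoint(model, "example_model.npz")
print("\ncheckpoint written to example_model.npz")

# ---- GA-aware augmentation --------------------------------------------------
# The isotropic scale is drawn from per-week bounds derived from the
# mean brain-volume table (cube root of a volume ratio, clipped to
# [1/1.5, 1.5]), so young brains are never shrunk below the youngest
# plausible size nor old brains grown past the oldest.
spec = default_augmentation_spec()
print("\nGA-aware scale bounds:")
for w in (18, 22, 26):
    lo, hi = spec.scale_bounds(float(w))
    print(f"  week {w}: scale in [{lo:.3f}, {hi:.3f}]")

s = training[0]
rng = np.random.default_rng(0)
img_aug, lab_aug = augment((s.image.data, s.labels.data, s.ga_weeks), spec, rng)
moved = int((lab_aug != s.labels.data).sum())
print(f"one augmented draw of {s.sample_id}: "
      f"{moved} of {lab_aug.size} label voxels changed")
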