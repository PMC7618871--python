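# fetalsubseg

Few-shot segmentation of subcortical structures in 3D fetal
neurosonography, evaluated end to end on a synthetic phantom cohort.

Between 18 and 26 gestational weeks (GW) four subcortical structures —
choroid plexus (CP), lateral posterior ventricle horn (LPVH), cavum
septi pellucidi et vergae (CSPV) and cerebellum (CB) — change size and
appearance rapidly, and expert annotations of 3D ultrasound are scarce.
This package implements a pipeline that gets a full segmentation model
from only a handful of annotated template images:

1. **Phantom cohort** (`fetalsubseg.phantom`) — synthetic
   ultrasound-like volumes with analytic growth laws, acoustic
   shadowing of one hemisphere, speckle, and known ground truth.
2. **Groupwise templates** (`fetalsubseg.templates`) — per-week
   templates by iterated diffeomorphic demons registration, hemisphere
   fusion across the midsagittal plane, and propagation of template
   labels onto every subject ("weak" atlas annotations).
3. **Cluster templates for the LPVH** (`fetalsubseg.cluster`) — the
   LPVH varies too much for one weekly template; subjects are clustered
   by cropped-region similarity (constrained k-medoids on an SSD
   distance matrix, with outlier handling) and get one template per
   cluster.
4. **3D U-Net segmenter** (`fetalsubseg.segmenter`, `fetalsubseg.nn`) —
   a from-scratch NumPy/numba U-Net trained with a summed soft-Dice +
   cross-entropy loss and gestational-age-aware augmentation, on either
   expert labels (few) or atlas labels (free, available for everyone).
5. **Metrics** (`fetalsubseg.metrics`) — Dice, 95th-percentile
   Hausdorff distance, relative volume differences, largest-component
   post-processing; verified against brute-force oracles.
6. **Growth curves** (`fetalsubseg.growth`) — structure volumes vs
   gestational age with significance-gated quadratic terms and 95%
   prediction intervals; whole-brain volume via similarity registration
   of an age-matched template.

See [docs/methods.md](docs/methods.md) for models, parameters and
numerical choices, and `examples/` for narrative walk-throughs of each
stage.

## Quick start

```python
from fetalsubseg.phantom import PhantomConfig, make_cohort
from fetalsubseg.templates import build_week_templates, atlas_labels_for_cohort
from fetalsubseg.segmenter import SegConfig, train, predict
from fetalsubseg.metrics import evaluate

cfg = PhantomConfig(grid_size=48, spacing_mm=1.6)
cohort = make_cohort(12, (22.0, 26.0), seed=0, config=cfg)

# weak atlas labels from per-week templates
templates, fields = build_week_templates(cohort)
atlas = atlas_labels_for_cohort(cohort, templates, fields)

# train on atlas labels, evaluate against ground truth
data = [(s.image.data, atlas[s.sample_id].data, s.ga_weeks) for s in cohort[:-1]]
model = train(data, SegConfig(depth=3, init_features=8, batch_size=2,
                              iteration_budget=200, learning_rate=0.01,
                              label_source="atlas"))
held_out = cohort[-1]
report = evaluate(predict(model, held_out.image.data), held_out.labels)
print(report.mean("dsc"))
```

The same pipeline is available as a CLI:

```bash
fetalseg phantom --n 12 --ga-min 22 --ga-max 26 --grid 48 --spacing 1.6 --seed 0 --out cohort/
fetalseg templates --cohort cohort/ --out templates/
fetalseg cluster --cohort cohort/ --k 3 --seed 0 --out lpvh/
fetalseg train --cohort cohort/ --labels expert --na 9 --out model.npz
fetalseg predict --model model.npz --in cohort/p000_image.nii.gz --out pred.nii.gz
fetalseg evaluate --pred pred.nii.gz --gt cohort/p000_labels.nii.gz --out report.csv
fetalseg curves --pred-dir preds/ --cohort cohort/ --out growth/
```

## Worked example

`python scripts/acceptance.py --seed 0 --out report.json` runs every
stage end to end on one CPU in about 15 minutes. Representative numbers
from that run (synthetic phantoms, reduced problem sizes):

- **Metric oracles** — `dice` matched a brute-force overlap count on
  100/100 random mask pairs; `hausdorff95` agreed with a
  brute-force all-pairs distance oracle to 0.0 maximum absolute difference.
- **Atlas-label fidelity** (12 phantoms, 48³/1.6 mm, GA 18–26) — mean
  DSC of propagated template labels vs ground truth: CP 0.99,
  LPVH 0.91, CSPV 0.78, CB 0.95.
- **Cluster templates** — with identical machinery and one full-range
  GA window, three LPVH cluster templates beat a single template:
  mean LPVH DSC 0.82 vs 0.79.
- **Training** (16 phantoms, 48³, depth-3 U-Net, 8 features, 200
  iterations) — held-out mean foreground DSC 0.77; a 2-sample run
  reduced its training loss by 87%, confirming the net can (over)fit.
- **Post-processing** — largest-component filtering never worsened H95
  or DSC on 20 predictions with injected spurious components.
- **Growth-fit recovery** — the generator's LPVH slope
  (0.025 cm³/week) fell inside the fitted 95% CI in 10/10 cohorts;
  the quadratic term was falsely admitted in 7% of linear replicates
  (α = 0.05).
- **Expert vs atlas labels** (28 phantoms, 24³, single net seed) —
  four models (expert/atlas labels × aligned/unaligned inputs) are
  trained and scored; the three-seed version of this experiment in
  `tests/test_acceptance.py` shows the expert-label model ahead on
  aligned inputs (mean DSC 0.59 vs 0.44) and the atlas-label model's
  H95 advantage growing when alignment is removed.

## Reproduction

- `python -m pytest -q tests/` runs the unit tests plus one acceptance
  test per property criterion (metric oracles, Eq.-2 scaling suite,
  clustering vs exhaustive search, atlas-label fidelity, scaled-down
  training, post-processing, growth-fit recovery, expert-vs-atlas
  directional experiment). One CPU, ≈20 minutes; everything is seeded.
- `python scripts/acceptance.py --seed 0 --out report.json` re-runs the
  pipeline end to end at desk scale and writes the main computed
  quantities as JSON.

All evaluation runs on synthetic phantoms at reduced problem sizes
(24³–64³ grids, small U-Nets); published absolute accuracy numbers on
clinical cohorts are out of scope by design. Design decisions and
their rationale are documented in the project notes and in
[docs/methods.md](docs/methods.md).
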