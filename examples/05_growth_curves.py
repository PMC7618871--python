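"""Fit growth curves (volume vs gestational age) from segmentations and
plot them with 95% prediction intervals.

Whole-brain volume is measured by similarity registration of a
gestational-age matched brain template to each subject.

Run:  python examples/05_growth_curves.py     (~2 min)
"""

import numpy as np

from fetalsubseg.core import CLASS_NAMES, FOREGROUND_CLASSES, LPVH
from fetalsubseg.growth import (
    fit_growth_curve,
    plot_growth_curves,
    records_from_predictions,
    records_to_csv,
)
from fetalsubseg.phantom import PhantomConfig, analytic_brain_mask, make_cohort

cfg = PhantomConfig(grid_size=48, spacing_mm=1.6)
cohort = make_cohort(14, (18.0, 26.0), seed=2, config=cfg)

# use ground-truth labels as stand-in predictions ("expert" tag)
preds = {s.sample_id: s.labels for s in cohort}
brain_masks = {w: analytic_brain_mask(float(w), cfg) for w in range(18, 27)}
records = records_from_predictions(cohort, preds, "expert",
                                   brain_masks=brain_masks)
records_to_csv(records, "example_volumes.csv")

for cls in FOREGROUND_CLASSES:
    fit = fit_growth_curve(records, cls, value="absolute")["expert"]
    kind = "quadratic" if fit.degree == 2 else "linear"
    lo, hi = fit.prediction_interval(22.0)
    print(f"{CLASS_NAMES[cls]:<6} {kind:<9} slope {fit.coefficients[1]:+.4f} "
          f"cm^3/week   95% PI at 22 GW: [{lo[0]:.3f}, {hi[0]:.3f}]")

fits = {cls: fit_growth_curve(records, cls) for cls in FOREGROUND_CLASSES}
plot_growth_curves(records, fits, "example_growth_curves.png")
print("\nwrote example_volumes.csv and example_growth_curves.png")
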