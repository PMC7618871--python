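import numpy as np
import pytest

from fetalsubseg.core import CB, CP, CSPV, LPVH, LabelMap
from fetalsubseg.growth import (
    GrowthFit,
    VolumeRecord,
    fit_growth_curve,
    records_from_predictions,
    relative_volume,
    structure_volume,
    template_mask_for_ga,
    whole_brain_volume,
)
from fetalsubseg.phantom import (
    PhantomConfig,
    analytic_brain_mask,
    brain_volume,
    make_phantom,
)


def _linear_records(rng=None, tags=("expert", "atlas"), n=12, noise=0.0,
                    b0=0.1, b1=0.025, structure=LPVH):
    rng = rng or np.random.default_rng(0)
    recs = []
    for tag in tags:
        for i in range(n):
            ga = 18.0 + 8.0 * i / (n - 1)
            v = b0 + b1 * (ga - 18.0)
            if noise:
                v = max(v + rng.normal(0, noise), 1e-6)
            vols = {c: 1.0 for c in (CP, LPVH, CSPV, CB)}
            vols[structure] = v
            recs.append(VolumeRecord(f"{tag}{i}", ga, vols, 60.0, tag))
    return recs


class TestVolumes:
    def test_structure_volume_examples(self):
        lab = np.zeros((12, 12, 12), np.uint8)
        lab.ravel()[:1000] = CP
        lm = LabelMap(lab, (1.0, 1.0, 1.0))
        assert structure_volume(lm, CP) == pytest.approx(1.0)
        lab2 = np.zeros((10, 10, 10), np.uint8)
        lab2.ravel()[:100] = CB
        assert structure_volume(LabelMap(lab2, (0.6, 0.6, 0.6)), CB) == \
            pytest.approx(0.0216)

    def test_absent_class_warns_zero(self):
        lm = LabelMap(np.zeros((4, 4, 4), np.uint8), (1, 1, 1))
        with pytest.warns(UserWarning):
            assert structure_volume(lm, CSPV) == 0.0

    def test_relative_volume(self):
        assert relative_volume(2.0, 100.0) == pytest.approx(0.02)
        assert relative_volume(0.0, 100.0) == 0.0
        with pytest.raises(ValueError):
            relative_volume(1.0, 0.0)

    def test_template_mask_lookup_floor(self):
        masks = {w: np.full((2, 2, 2), w) for w in (21, 22, 23)}
        assert template_mask_for_ga(masks, 22.3)[0, 0, 0] == 22
        # below-range GA falls back to the youngest available week
        assert template_mask_for_ga(masks, 18.0)[0, 0, 0] == 21
        assert template_mask_for_ga(masks, 30.0)[0, 0, 0] == 23


class TestWholeBrainVolume:
    def test_recovers_phantom_volume_within_5pct(self):
        cfg = PhantomConfig()
        s = make_phantom(23.0, seed=2, config=cfg)
        tpl = analytic_brain_mask(23.0, cfg)
        v = whole_brain_volume(s.image, tpl, 23.0)
        assert v == pytest.approx(brain_volume(23.0), rel=0.05)

    def test_grid_mismatch_error(self):
        cfg = PhantomConfig()
        s = make_phantom(22.0, seed=1, config=cfg)
        with pytest.raises(ValueError):
            whole_brain_volume(s.image, np.zeros((8, 8, 8)), 22.0)


class TestFitGrowthCurve:
    def test_exact_linear_recovery_degenerate_gate(self):
        fits = fit_growth_curve(_linear_records(), LPVH)
        for f in fits.values():
            assert f.degree == 1
            assert f.coefficients[1] == pytest.approx(0.025, abs=1e-9)
            assert f.coefficients[0] == pytest.approx(-0.35, abs=1e-9)
            assert all(p == 1.0 for p in f.quadratic_p_values.values())

    def test_quadratic_recovery(self):
        rng = np.random.default_rng(1)
        recs = []
        for tag in ("expert", "atlas"):
            ga = rng.uniform(18, 26, 50)
            y = 0.5 + 0.01 * ga + 0.02 * ga**2 + rng.normal(0, 0.05, 50)
            for i, (g, v) in enumerate(zip(ga, y)):
                recs.append(VolumeRecord(f"{tag}{i}", g,
                                         {CP: v, LPVH: 1, CSPV: 1, CB: 1},
                                         600.0, tag))
        fits = fit_growth_curve(recs, CP)
        f = fits["expert"]
        assert f.degree == 2
        se = np.sqrt(f.cov_params[2, 2])
        assert abs(f.coefficients[2] - 0.02) < 2.5 * se

    def test_gate_requires_both_tags(self):
        rng = np.random.default_rng(2)
        recs = []
        for tag, b2 in (("expert", 0.05), ("atlas", 0.0)):
            ga = rng.uniform(18, 26, 40)
            y = 0.5 + 0.01 * ga + b2 * ga**2 + rng.normal(0, 0.05, 40)
            for i, (g, v) in enumerate(zip(ga, y)):
                recs.append(VolumeRecord(f"{tag}{i}", g,
                                         {CP: v, LPVH: 1, CSPV: 1, CB: 1},
                                         600.0, tag))
        fits = fit_growth_curve(recs, CP)
        assert all(f.degree == 1 for f in fits.values())

    def test_insufficient_records_or_spread(self):
        with pytest.raises(ValueError):
            fit_growth_curve(_linear_records(n=5), LPVH)
        recs = []
        for i in range(12):
            recs.append(VolumeRecord(f"e{i}", 22.0 + 0.01 * i,
                                     {CP: 1, LPVH: 1, CSPV: 1, CB: 1},
                                     60.0, "expert"))
        with pytest.raises(ValueError):
            fit_growth_curve(recs, LPVH)

    def test_prediction_interval_coverage(self):
        rng = np.random.default_rng(3)
        hits, total = 0, 0
        for rep in range(20):
            ga = rng.uniform(18, 26, 30)
            y = 0.1 + 0.025 * (ga - 18) + rng.normal(0, 0.02, 30)
            recs = [VolumeRecord(f"s{i}", g, {LPVH: v, CP: 1, CSPV: 1, CB: 1},
                                 60.0, "expert")
                    for i, (g, v) in enumerate(zip(ga, y))]
            fit = fit_growth_curve(recs, LPVH)["expert"]
            g0 = rng.uniform(18, 26)
            y0 = 0.1 + 0.025 * (g0 - 18) + rng.normal(0, 0.02)
            lo, hi = fit.prediction_interval(g0)
            hits += int(lo[0] <= y0 <= hi[0])
            total += 1
        assert hits / total >= 0.85

    def test_relative_values_and_sum_below_one(self):
        cfg = PhantomConfig(grid_size=32, spacing_mm=2.4)
        s = make_phantom(24.0, seed=5, config=cfg)
        vols = {c: structure_volume(s.labels, c) for c in (CP, LPVH, CSPV, CB)}
        rec = VolumeRecord("p0", 24.0, vols, brain_volume(24.0), "expert")
        rel = rec.relative
        assert all(0.0 <= r < 1.0 for r in rel.values())
        assert sum(rel.values()) < 1.0

    def test_pi_half_width_positive(self):
        fits = fit_growth_curve(_linear_records(noise=0.02), LPVH)
        hw = fits["expert"].pi_half_width(np.array([19.0, 22.0, 25.0]))
        assert (hw > 0).all()
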