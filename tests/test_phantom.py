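import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fetalsubseg.core import CB, CP, CSPV, LPVH
from fetalsubseg.phantom import (
    DEFAULT_LAWS,
    GA_MAX,
    GA_MIN,
    PhantomConfig,
    brain_volume,
    growth_model,
    label_volume_cm3,
    load_cohort,
    make_cohort,
    make_phantom,
    write_cohort,
)

CFG = PhantomConfig()


def test_growth_model_endpoints():
    assert growth_model(18.0, DEFAULT_LAWS[LPVH]) == pytest.approx(0.1, rel=1e-6)
    assert growth_model(26.0, DEFAULT_LAWS[LPVH]) == pytest.approx(0.3, rel=1e-6)
    assert growth_model(18.0, DEFAULT_LAWS[CSPV]) == pytest.approx(0.01, rel=1e-6)
    assert growth_model(26.0, DEFAULT_LAWS[CSPV]) == pytest.approx(0.6, rel=1e-6)
    assert growth_model(22.0, DEFAULT_LAWS[LPVH]) == pytest.approx(0.2, rel=1e-6)


def test_growth_model_range_error():
    with pytest.raises(ValueError):
        growth_model(17.0, DEFAULT_LAWS[CP])
    with pytest.raises(ValueError):
        growth_model(28.0, DEFAULT_LAWS[CP])


@given(st.floats(min_value=GA_MIN, max_value=GA_MAX))
@settings(max_examples=50, deadline=None)
def test_growth_laws_positive_and_nondecreasing(ga):
    for cls, law in DEFAULT_LAWS.items():
        v = growth_model(ga, law)
        assert v > 0
        if ga + 0.25 <= GA_MAX:
            assert growth_model(ga + 0.25, law) >= v - 1e-12


def test_determinism():
    a = make_phantom(22.0, seed=7, config=CFG)
    b = make_phantom(22.0, seed=7, config=CFG)
    assert np.array_equal(a.image.data, b.image.data)
    assert np.array_equal(a.labels.data, b.labels.data)
    c = make_phantom(22.0, seed=8, config=CFG)
    assert not np.array_equal(a.image.data, c.image.data)


def test_label_volumes_match_growth_model():
    s = make_phantom(22.0, seed=1, config=CFG)
    for cls in (CP, LPVH, CSPV, CB):
        target = growth_model(22.0, DEFAULT_LAWS[cls], brain_volume(22.0))
        got = label_volume_cm3(s.labels, cls)
        # voxelization tolerance: one surface-voxel layer
        assert got == pytest.approx(target, rel=0.35), (cls, got, target)
    # the large structures should be tight
    assert label_volume_cm3(s.labels, CB) == pytest.approx(
        growth_model(22.0, DEFAULT_LAWS[CB], brain_volume(22.0)), rel=0.1)


def test_shadow_darkens_occluded_hemisphere():
    s = make_phantom(22.0, seed=2, config=CFG)
    nx = s.image.shape[0]
    cut = nx // 2
    brain = s.brain_mask
    left = s.image.data[:cut][brain[:cut]].mean()
    right = s.image.data[cut:][brain[cut:]].mean()
    if s.visible_hemisphere == "left":
        assert left > right
    else:
        assert right > left


def test_zero_shadow_equalizes_hemispheres():
    cfg = PhantomConfig(shadow_strength=0.0)
    means = {"left": [], "right": []}
    for seed in range(4):
        s = make_phantom(22.0, seed=seed, config=cfg)
        cut = s.image.shape[0] // 2
        means["left"].append(s.image.data[:cut][s.brain_mask[:cut]].mean())
        means["right"].append(s.image.data[cut:][s.brain_mask[cut:]].mean())
    assert np.mean(means["left"]) == pytest.approx(np.mean(means["right"]), rel=0.05)


def test_lateral_structures_only_in_visible_hemisphere():
    for seed in (3, 4, 5, 6):
        s = make_phantom(24.0, seed=seed, config=CFG)
        cut = s.labels.shape[0] // 2
        lateral = (s.labels.data == CP) | (s.labels.data == LPVH)
        if s.visible_hemisphere == "left":
            assert not lateral[cut:].any()
            assert lateral[:cut].any()
        else:
            assert not lateral[:cut].any()
            assert lateral[cut:].any()


def test_labels_inside_brain_mask():
    s = make_phantom(20.0, seed=9, config=CFG)
    assert not ((s.labels.data > 0) & ~s.brain_mask).any()


def test_make_cohort_coverage_and_seeding():
    cohort = make_cohort(9, (18.0, 26.0), seed=0, config=CFG)
    gas = sorted(s.ga_weeks for s in cohort)
    assert gas[0] == pytest.approx(18.0)
    assert gas[-1] == pytest.approx(26.0)
    hemis = {s.visible_hemisphere for s in cohort}
    assert hemis == {"left", "right"}
    again = make_cohort(9, (18.0, 26.0), seed=0, config=CFG)
    assert all(np.array_equal(a.image.data, b.image.data)
               for a, b in zip(cohort, again))
    with pytest.raises(ValueError):
        make_cohort(0, (18.0, 26.0), seed=0, config=CFG)


def test_cohort_roundtrip(tmp_path):
    cohort = make_cohort(3, (19.0, 25.0), seed=5, config=CFG)
    write_cohort(cohort, tmp_path)
    back = load_cohort(tmp_path)
    assert len(back) == 3
    for a, b in zip(cohort, back):
        assert a.sample_id == b.sample_id
        assert a.visible_hemisphere == b.visible_hemisphere
        assert a.ga_weeks == pytest.approx(b.ga_weeks)
        np.testing.assert_allclose(a.image.data, b.image.data, atol=1e-6)
        assert np.array_equal(a.labels.data, b.labels.data)
        np.testing.assert_allclose(a.pose.matrix(), b.pose.matrix(), atol=1e-9)
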