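from itertools import product

import numpy as np
import pytest

from fetalsubseg.core import LabelMap
from fetalsubseg.metrics import (
    H95_UNDEFINED,
    boundary_voxels,
    dice,
    evaluate,
    hausdorff95,
    largest_component,
    postprocess_labels,
    volume_differences,
)


def _oracle_boundary(mask):
    # independent definition: pad with background, test all 26 offsets
    padded = np.pad(mask, 1)
    pts = []
    for p in np.argwhere(mask):
        for off in product([-1, 0, 1], repeat=3):
            if off == (0, 0, 0):
                continue
            if not padded[tuple(p + np.array(off) + 1)]:
                pts.append(p)
                break
    return np.asarray(pts)


def _oracle_h95(a, b, spacing=(1.0, 1.0, 1.0)):
    # exhaustive all-pairs boundary distance table via cdist
    from scipy.spatial.distance import cdist

    sp = np.asarray(spacing, dtype=float)
    ba, bb = _oracle_boundary(a), _oracle_boundary(b)
    table = cdist(ba * sp, bb * sp)
    return max(np.percentile(table.min(axis=1), 95),
               np.percentile(table.min(axis=0), 95))


def test_dice_and_h95_match_bruteforce_oracles():
    rng = np.random.default_rng(7)
    checked_h95 = 0
    for _ in range(100):
        a = rng.random((12, 12, 12)) < 0.15
        b = rng.random((12, 12, 12)) < 0.15
        sa = {tuple(v) for v in np.argwhere(a)}
        sb = {tuple(v) for v in np.argwhere(b)}
        want = 1.0 if not sa and not sb else 2 * len(sa & sb) / (len(sa) + len(sb))
        assert dice(a, b) == want  # exact set arithmetic
        if sa and sb:
            assert hausdorff95(a, b) == pytest.approx(_oracle_h95(a, b), abs=1e-9)
            checked_h95 += 1
    assert checked_h95 >= 90


def test_dice_examples():
    a = np.zeros((4, 4, 4), bool)
    a[:2] = True
    assert dice(a, a) == 1.0
    b = np.zeros((4, 4, 4), bool)
    b[2:] = True
    assert dice(a, b) == 0.0
    assert dice(np.zeros((4, 4, 4), bool), np.zeros((4, 4, 4), bool)) == 1.0
    with pytest.raises(ValueError):
        dice(a, np.zeros((3, 3, 3), bool))


def test_h95_single_voxels_spacing():
    a = np.zeros((6, 6, 6), bool)
    b = np.zeros((6, 6, 6), bool)
    a[2, 2, 2] = True
    b[3, 2, 2] = True
    assert hausdorff95(a, b, (0.6, 0.6, 0.6)) == pytest.approx(0.6)
    assert hausdorff95(a, a, (0.6, 0.6, 0.6)) == 0.0


def test_h95_empty_sentinel_warns():
    a = np.zeros((4, 4, 4), bool)
    b = np.zeros((4, 4, 4), bool)
    b[1, 1, 1] = True
    with pytest.warns(UserWarning):
        out = hausdorff95(a, b)
    assert np.isnan(out) and np.isnan(H95_UNDEFINED)


def test_largest_component_and_ties():
    m = np.zeros((12, 12, 12), bool)
    m[0, 0, 0:10] = True  # 10 voxels
    m[6, 6, 0:3] = True   # 3 voxels
    out = largest_component(m)
    assert out[0, 0, 0] and not out[6, 6, 0]
    assert largest_component(np.zeros((4, 4, 4), bool)).sum() == 0
    # tie: two 5-voxel components; keep the one with the smallest voxel
    t = np.zeros((12, 12, 12), bool)
    t[0, 0, 0:5] = True
    t[8, 8, 4:9] = True
    kept = largest_component(t)
    assert kept[0, 0, 0] and not kept[8, 8, 4]


def test_largest_component_connectivity():
    m = np.zeros((6, 6, 6), bool)
    m[0, 0, 0] = True
    m[1, 1, 1] = True  # diagonal neighbour: connected at 26, not at 6
    assert largest_component(m, connectivity=26).sum() == 2
    assert largest_component(m, connectivity=6).sum() == 1
    with pytest.raises(ValueError):
        largest_component(m, connectivity=4)


def test_volume_differences_examples():
    gt = np.zeros((4, 4, 4), bool)
    gt[:2] = True
    pred = gt.copy()
    assert volume_differences(pred, gt) == (0.0, 0.0)
    pred2 = np.zeros_like(gt)
    assert volume_differences(pred2, gt) == (-1.0, 1.0)
    with pytest.raises(ValueError):
        volume_differences(pred, np.zeros_like(gt))


def test_postprocessing_property_spurious_components():
    """Injected far-away speckle: post-processing never worsens h95 or dice."""
    rng = np.random.default_rng(11)
    for _ in range(5):
        gt = np.zeros((24, 24, 24), np.uint8)
        gt[8:14, 8:14, 8:14] = 1
        pred = gt.copy()
        # spurious voxels far from the structure
        for _ in range(4):
            p = rng.integers(18, 24, size=3)
            pred[tuple(p)] = 1
        pm, gm = pred == 1, gt == 1
        h_before = hausdorff95(pm, gm)
        d_before = dice(pm, gm)
        post = largest_component(pm)
        assert hausdorff95(post, gm) <= h_before
        assert dice(post, gm) >= d_before


def test_evaluate_report(tmp_path):
    gt = np.zeros((16, 16, 16), np.uint8)
    gt[2:6, 2:6, 2:6] = 1
    gt[8:12, 8:12, 8:12] = 4
    pred = gt.copy()
    pred[14, 14, 14] = 1  # spurious CP island
    rep = evaluate(LabelMap(pred, (1, 1, 1)), LabelMap(gt, (1, 1, 1)), post=True)
    row_cp = rep.rows[0]
    assert row_cp["dsc"] == 1.0  # island removed by post-processing
    assert rep.post_processed
    csv_path = tmp_path / "report.csv"
    rep.to_csv(csv_path)
    assert csv_path.read_text().startswith("class,")
    # post=off keeps the island
    rep2 = evaluate(LabelMap(pred, (1, 1, 1)), LabelMap(gt, (1, 1, 1)), post=False)
    assert rep2.rows[0]["dsc"] < 1.0


def test_boundary_voxels_definition():
    m = np.zeros((5, 5, 5), bool)
    m[1:4, 1:4, 1:4] = True
    bd = {tuple(p) for p in boundary_voxels(m)}
    assert (2, 2, 2) not in bd  # interior voxel
    assert (1, 1, 1) in bd
    assert len(bd) == 26  # 3x3x3 cube minus its center


def test_postprocess_labels_multiclass():
    lab = np.zeros((10, 10, 10), np.uint8)
    lab[1:4, 1:4, 1:4] = 2
    lab[8, 8, 8] = 2  # island
    lab[5:7, 5:7, 5:7] = 3
    out = postprocess_labels(LabelMap(lab, (1, 1, 1)))
    assert out.data[8, 8, 8] == 0
    assert (out.data[1:4, 1:4, 1:4] == 2).all()
    assert (out.data[5:7, 5:7, 5:7] == 3).all()
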