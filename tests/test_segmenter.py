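import numpy as np
import pytest

import fetalsubseg.nn as nn
from fetalsubseg.core import LabelMap
from fetalsubseg.segmenter import (
    AugmentationSpec,
    SegConfig,
    TrainedModel,
    _loss_and_grad,
    augment,
    combined_loss,
    default_augmentation_spec,
    default_iteration_budget,
    load_checkpoint,
    predict,
    save_checkpoint,
    scaling_range,
    train,
)


def _onehot(target, n=5):
    return np.eye(n, dtype=np.float64)[target].transpose(3, 0, 1, 2)


class TestCombinedLoss:
    def test_perfect_prediction_zero(self):
        rng = np.random.default_rng(0)
        t = rng.integers(0, 5, size=(4, 4, 4))
        onehot = _onehot(t)
        assert combined_loss(onehot, onehot, 1.0, eps=0.0) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_ce_is_ln5(self):
        rng = np.random.default_rng(1)
        t = rng.integers(0, 5, size=(4, 4, 4))
        onehot = _onehot(t)
        uniform = np.full_like(onehot, 0.2)
        l_full = combined_loss(uniform, onehot, 1.0)
        l_md = combined_loss(uniform, onehot, 0.0)
        assert l_full - l_md == pytest.approx(np.log(5), abs=1e-9)

    def test_permutation_equivariance_foreground(self):
        rng = np.random.default_rng(2)
        t = rng.integers(0, 5, size=(5, 5, 5))
        p = rng.dirichlet(np.ones(5), size=(5, 5, 5)).transpose(3, 0, 1, 2)
        perm = [0, 3, 1, 4, 2]  # permute foreground classes only
        t_perm = np.array(perm)[t]
        p_perm = p[np.argsort(perm)]
        assert combined_loss(p, _onehot(t)) == pytest.approx(
            combined_loss(p_perm, _onehot(t_perm)), rel=1e-9)

    def test_decreases_toward_target_on_convex_path(self):
        rng = np.random.default_rng(3)
        t = rng.integers(0, 5, size=(4, 4, 4))
        onehot = _onehot(t)
        uniform = np.full_like(onehot, 0.2)
        losses = [combined_loss((1 - a) * uniform + a * onehot, onehot)
                  for a in np.linspace(0.0, 0.95, 8)]
        assert all(b < a for a, b in zip(losses, losses[1:]))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            combined_loss(np.zeros((5, 4, 4, 4)), np.zeros((5, 4, 4, 2)))

    def test_analytic_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(4)
        logits = rng.normal(size=(1, 5, 3, 3, 3))
        target = rng.integers(0, 5, size=(1, 3, 3, 3))
        _, grad = _loss_and_grad(logits, target, 1.0)
        eps = 1e-6
        for _ in range(20):
            idx = tuple(rng.integers(0, s) for s in logits.shape)
            lp, lm = logits.copy(), logits.copy()
            lp[idx] += eps
            lm[idx] -= eps
            fd = (_loss_and_grad(lp, target, 1.0)[0]
                  - _loss_and_grad(lm, target, 1.0)[0]) / (2 * eps)
            assert grad[idx] == pytest.approx(fd, rel=1e-4, abs=1e-9)


class TestScalingRange:
    VBAR = {w: 33.0 + 9.0 * (w - 18) for w in range(18, 27)}

    def test_week18_smin_branch(self):
        s_min, _ = scaling_range(18, self.VBAR)
        assert s_min == pytest.approx(0.9 ** (1 / 3))

    def test_week26_smax_branch(self):
        _, s_max = scaling_range(26, self.VBAR)
        assert s_max == pytest.approx(1.1 ** (1 / 3))

    def test_clip_branches(self):
        _, s_max = scaling_range(18, {18: 1.0, 26: 8.0})
        assert s_max == 1.5  # (8.8)^{1/3} ≈ 2.065 clipped
        s_min, _ = scaling_range(26, {18: 1.0, 26: 80.0})
        assert s_min == pytest.approx(1 / 1.5)

    def test_all_weeks_within_global_bounds(self):
        for w in range(18, 27):
            s_min, s_max = scaling_range(w, self.VBAR)
            assert 1 / 1.5 <= s_min <= s_max <= 1.5

    def test_invalid_volumes(self):
        with pytest.raises(ValueError):
            scaling_range(18, {18: -1.0, 26: 8.0})
        with pytest.raises(KeyError):
            scaling_range(18, {18: 1.0})


class TestAugment:
    def test_degenerate_draw_is_identity(self):
        spec = AugmentationSpec(flip_prob=0.0, rotation_max_deg=0.0,
                                translation_max_vox=0.0, vbar={})
        rng = np.random.default_rng(0)
        img = np.random.default_rng(1).random((12, 12, 12)).astype(np.float32)
        lab = (img > 0.8).astype(np.uint8)
        out_img, out_lab = augment((img, lab, 22.0), spec, rng)
        np.testing.assert_allclose(out_img, img, atol=1e-5)
        assert np.array_equal(out_lab, lab)

    def test_labels_never_invent_classes(self):
        spec = default_augmentation_spec()
        rng = np.random.default_rng(5)
        img = np.random.default_rng(6).random((12, 12, 12)).astype(np.float32)
        lab = np.zeros((12, 12, 12), np.uint8)
        lab[4:8, 4:8, 4:8] = 3
        for _ in range(5):
            _, out_lab = augment((img, lab, 22.0), spec, rng)
            assert set(np.unique(out_lab)) <= {0, 3}

    def test_scale_draws_within_bounds(self):
        vbar = {w: 33.0 + 9.0 * (w - 18) for w in range(18, 27)}
        spec = AugmentationSpec(vbar=vbar)
        s_min, s_max = spec.scale_bounds(18.0)
        rng = np.random.default_rng(7)
        draws = [rng.uniform(s_min, s_max) for _ in range(1000)]
        assert all(s_min <= d <= s_max for d in draws)
        assert s_min == pytest.approx(0.9 ** (1 / 3))


class TestTrainPredict:
    def _tiny_dataset(self, n=4, grid=16):
        rng = np.random.default_rng(8)
        data = []
        for i in range(n):
            lab = np.zeros((grid, grid, grid), np.uint8)
            c = 4 + (i % 2)
            lab[c:c + 6, c:c + 6, c:c + 6] = 1
            img = lab * 1.0 + rng.normal(0, 0.1, lab.shape)
            data.append((img.astype(np.float32), lab, 20.0 + i))
        return data

    def test_iteration_budget_exact_and_deterministic(self):
        data = self._tiny_dataset()
        cfg = SegConfig(depth=2, init_features=4, batch_size=2,
                        iteration_budget=5, seed=3)
        m1 = train(data, cfg)
        m2 = train(data, cfg)
        assert len(m1.loss_log) == 5
        assert m1.loss_log == pytest.approx(m2.loss_log, rel=1e-6)

    def test_default_budget_is_100_epochs(self):
        assert default_iteration_budget(9, 4) == 300
        assert default_iteration_budget(8, 4) == 200

    def test_empty_and_mixed_grids_error(self):
        with pytest.raises(ValueError):
            train([], SegConfig())
        data = self._tiny_dataset(2)
        bad = data + [(np.zeros((8, 8, 8), np.float32),
                       np.zeros((8, 8, 8), np.uint8), 20.0)]
        with pytest.raises(ValueError):
            train(bad, SegConfig(depth=2, init_features=4, iteration_budget=1))

    def test_grid_depth_divisibility_error(self):
        data = [(np.zeros((12, 12, 12), np.float32),
                 np.zeros((12, 12, 12), np.uint8), 20.0)]
        with pytest.raises(ValueError):
            train(data, SegConfig(depth=4, init_features=4, iteration_budget=1))

    def test_atlas_mode_holds_out_validation(self):
        data = self._tiny_dataset(6)
        cfg = SegConfig(depth=2, init_features=4, batch_size=2,
                        iteration_budget=4, seed=0, label_source="atlas")
        m = train(data, cfg)
        assert m.val_log  # validation loss recorded
        assert m.mode_tag == "atlas/aligned"

    def test_predict_shapes_ties_and_errors(self):
        data = self._tiny_dataset(2)
        cfg = SegConfig(depth=2, init_features=4, batch_size=2,
                        iteration_budget=2, seed=0)
        m = train(data, cfg)
        lab = predict(m, data[0][0])
        assert isinstance(lab, LabelMap)
        assert lab.shape == data[0][0].shape
        assert lab.provenance == "predicted"
        with pytest.raises(ValueError):
            predict(m, np.zeros((8, 8, 8), np.float32))
        # argmax tie rule: equal logits -> class 0
        assert int(np.argmax(np.zeros(5))) == 0

    def test_checkpoint_roundtrip(self, tmp_path):
        data = self._tiny_dataset(2)
        cfg = SegConfig(depth=2, init_features=4, batch_size=2,
                        iteration_budget=2, seed=1)
        m = train(data, cfg)
        p = tmp_path / "model.npz"
        save_checkpoint(m, p)
        back = load_checkpoint(p)
        assert isinstance(back, TrainedModel)
        np.testing.assert_array_equal(predict(m, data[0][0]).data,
                                      predict(back, data[0][0]).data)
        assert back.config.seed == 1

    def test_overfit_two_samples_reduces_loss(self):
        data = self._tiny_dataset(2)
        cfg = SegConfig(depth=2, init_features=8, batch_size=2,
                        iteration_budget=60, seed=0, learning_rate=0.003)
        m = train(data, cfg)
        start = np.mean(m.loss_log[:3])
        end = np.mean(m.loss_log[-3:])
        assert end < 0.5 * start
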