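"""Modified LeNet: shapes, gradients, augmentation, training contracts."""

import numpy as np
import pytest

from swallowtail import nn
from swallowtail.deepnet import (
    LeNet,
    augment,
    extract_deep_features,
    predict_image,
    saliency_map,
    train_cnn,
)
from swallowtail.localizer import PatchStack


def _stack(rng, case_id="c0"):
    return PatchStack(case_id, rng.uniform(0, 1, (4, 40, 40)), [])


class TestForwardShapes:
    def test_shape_chain_40_to_2(self):
        model = LeNet(seed=0)
        x = np.random.default_rng(0).normal(size=(3, 1, 40, 40))
        h1, _ = nn.conv_forward(x, model.w1, model.b1)
        assert h1.shape == (3, 6, 36, 36)
        p1, _ = nn.maxpool_forward(h1)
        assert p1.shape == (3, 6, 18, 18)
        h2, _ = nn.conv_forward(p1, model.w2, model.b2)
        assert h2.shape == (3, 16, 14, 14)
        p2, _ = nn.maxpool_forward(h2)
        assert p2.shape == (3, 16, 7, 7)
        logits, cache = model.forward(x)
        assert logits.shape == (3, 2)
        assert cache[-1].shape == (3, 200)  # the 1x200 feature layer

    def test_probabilities_form_a_simplex(self):
        model = LeNet(seed=1)
        probs = model.predict_proba(np.random.default_rng(1).uniform(0, 1, (5, 40, 40)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs >= 0).all()

    def test_zero_weight_model_is_indifferent(self):
        model = LeNet(seed=2)
        model.set_params([np.zeros_like(p) for p in model.params])
        model.trained = True
        assert predict_image(model, np.random.default_rng(2).uniform(0, 1, (40, 40))) == 0.5

    def test_monotone_in_pd_logit(self):
        model = LeNet(seed=3)
        model.trained = True
        patch = np.random.default_rng(3).uniform(0, 1, (40, 40))
        base = predict_image(model, patch)
        model.bf2[1] += 1.0  # raise the PD logit
        assert predict_image(model, patch) > base

    def test_wrong_patch_shape_rejected(self):
        model = LeNet(seed=4)
        model.trained = True
        with pytest.raises(ValueError, match="40"):
            predict_image(model, np.zeros((40, 41)))


class TestGradients:
    def test_parameter_gradients_match_finite_differences(self):
        model = LeNet(seed=5)
        rng = np.random.default_rng(5)
        x = rng.normal(size=(2, 1, 40, 40))
        y = np.array([0, 1])

        def loss_fn():
            logits, _ = model.forward(x)
            loss, _ = nn.softmax_xent(logits, y)
            return loss

        logits, cache = model.forward(x)
        _, dlogits = nn.softmax_xent(logits, y)
        grads, _ = model.backward(dlogits, cache)
        eps = 1e-6
        for p, g in zip(model.params, grads):
            flat = p.ravel()
            for idx in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss_fn()
                flat[idx] = orig - eps
                down = loss_fn()
                flat[idx] = orig
                fd = (up - down) / (2 * eps)
                assert g.ravel()[idx] == pytest.approx(fd, rel=1e-4, abs=1e-8)

    def test_input_gradient_matches_finite_differences(self):
        model = LeNet(seed=6)
        model.trained = True
        rng = np.random.default_rng(6)
        x = rng.normal(size=(1, 1, 40, 40))
        logits, cache = model.forward(x)
        cls = int(logits[0].argmax())
        dlogits = np.zeros_like(logits)
        dlogits[0, cls] = 1.0
        _, dx = model.backward(dlogits, cache, need_dx=True)
        eps = 1e-5
        for idx in rng.choice(1600, size=10, replace=False):
            r, c = divmod(int(idx), 40)
            x[0, 0, r, c] += eps
            up = model.forward(x)[0][0, cls]
            x[0, 0, r, c] -= 2 * eps
            down = model.forward(x)[0][0, cls]
            x[0, 0, r, c] += eps
            fd = (up - down) / (2 * eps)
            assert dx[0, 0, r, c] == pytest.approx(fd, rel=1e-4, abs=1e-9)


class TestAugment:
    def test_triples_the_input(self):
        out = augment(np.random.default_rng(7).uniform(0, 1, (40, 40)), seed=0)
        assert len(out) == 3
        assert all(a.shape == (40, 40) for a in out)

    def test_deterministic_for_fixed_seed(self):
        patch = np.random.default_rng(8).uniform(0, 1, (40, 40))
        a = augment(patch, seed=9)
        b = augment(patch, seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_identity_transform_returns_original(self):
        patch = np.random.default_rng(9).uniform(0, 1, (40, 40))
        out = augment(patch, seed=0, scale_range=(1.0, 1.0), rotation_range=(0.0, 0.0))
        for copy in out:
            np.testing.assert_allclose(copy, patch, atol=1e-10)


class TestTrainCnn:
    @pytest.fixture(scope="class")
    def tiny_training(self):
        rng = np.random.default_rng(10)
        stacks = []
        for i in range(10):
            label = "PD" if i % 2 else "HC"
            base = rng.uniform(0, 1, (4, 40, 40))
            if label == "PD":
                base[:, 10:20, 10:20] += 2.0  # strong synthetic signal
            stacks.append((PatchStack(f"c{i}", base, []), label))
        return stacks

    def test_case_level_fold_partition(self, tiny_training):
        bundle = train_cnn(tiny_training, n_folds=5, seed=0, epochs=2)
        folds = bundle.fold_assignments
        assert sorted(folds) == [f"c{i}" for i in range(10)]
        assert set(folds.values()) == set(range(5))
        counts = {f: list(folds.values()).count(f) for f in range(5)}
        assert all(v == 2 for v in counts.values())

    def test_reproducible_training(self, tiny_training):
        a = train_cnn(tiny_training, n_folds=5, seed=1, epochs=2)
        b = train_cnn(tiny_training, n_folds=5, seed=1, epochs=2)
        assert a.val_curves == b.val_curves
        for pa, pb in zip(a.model.params, b.model.params):
            np.testing.assert_array_equal(pa, pb)

    def test_best_epoch_is_argmax_of_validation_curve(self, tiny_training):
        bundle = train_cnn(tiny_training, n_folds=5, seed=2, epochs=4)
        for curve, best in zip(bundle.val_curves, bundle.best_epochs):
            assert curve[best] == max(curve)

    def test_fewer_cases_than_folds_rejected(self, tiny_training):
        with pytest.raises(ValueError, match="at least"):
            train_cnn(tiny_training[:3], n_folds=5, seed=0)

    def test_bundle_roundtrip(self, tiny_training, tmp_path):
        from swallowtail.deepnet import TrainedModelBundle

        bundle = train_cnn(tiny_training, n_folds=5, seed=3, epochs=2)
        bundle.save(str(tmp_path / "cnn"))
        loaded = TrainedModelBundle.load(str(tmp_path / "cnn"))
        patch = tiny_training[0][0].patches[0]
        assert predict_image(loaded.model, patch) == predict_image(bundle.model, patch)


class TestDeepFeatures:
    def test_dimensions_4_by_200(self):
        model = LeNet(seed=11)
        model.trained = True
        feats = extract_deep_features(model, _stack(np.random.default_rng(11)))
        assert feats.shape == (4, 200)

    def test_identical_patches_identical_rows(self):
        model = LeNet(seed=12)
        model.trained = True
        patch = np.random.default_rng(12).uniform(0, 1, (40, 40))
        stack = PatchStack("c", np.stack([patch] * 4), [])
        feats = extract_deep_features(model, stack)
        for row in feats[1:]:
            np.testing.assert_array_equal(row, feats[0])

    def test_untrained_model_rejected(self):
        with pytest.raises(ValueError, match="trained"):
            extract_deep_features(LeNet(seed=13), _stack(np.random.default_rng(13)))


class TestSaliency:
    def test_nonnegative_and_input_shaped(self):
        model = LeNet(seed=14)
        model.trained = True
        patch = np.random.default_rng(14).uniform(0, 1, (40, 40))
        sal = saliency_map(model, patch)
        assert sal.shape == (40, 40)
        assert (sal >= 0).all()

    def test_untrained_model_rejected(self):
        with pytest.raises(ValueError, match="trained"):
            saliency_map(LeNet(seed=15), np.zeros((40, 40)))
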