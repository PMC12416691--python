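"""Dual-output classifier: encoding, focal loss, backprop, training,
saliency, and interpretation sweeps."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from phantomqc import evaluate, learned, synth
from phantomqc._net import Flatten, Linear, SmallCNN
from phantomqc.layout import DEFAULT_LAYOUT, FIBER
from phantomqc.scores import Score

from conftest import tile_dataset

Z, H, F = Score.ZERO, Score.HALF, Score.FULL


class TestEncoding:
    def test_half_score_encodes_one_one(self):
        t = learned.encode_label(H)
        assert (t.exist, t.abnormal, t.abnormal_masked) == (1, 1, False)

    def test_full_score_encodes_one_zero(self):
        t = learned.encode_label(F)
        assert (t.exist, t.abnormal, t.abnormal_masked) == (1, 0, False)

    def test_zero_score_masks_abnormality(self):
        t = learned.encode_label(Z)
        assert t.exist == 0 and t.abnormal_masked

    def test_na_rejected(self):
        with pytest.raises(ValueError):
            learned.encode_label(Score.NA)

    @pytest.mark.parametrize("s", [Z, H, F])
    def test_roundtrip_via_hard_probabilities(self, s):
        t = learned.encode_label(s)
        thr = learned.DecisionThresholds(0.5, 0.5)
        assert learned.decode_prediction((t.exist, t.abnormal), thr) is s

    def test_decode_examples(self):
        thr = learned.DecisionThresholds(0.5, 0.5)
        assert learned.decode_prediction((0.9, 0.1), thr) is F
        assert learned.decode_prediction((0.9, 0.9), thr) is H
        assert learned.decode_prediction((0.2, 0.9), thr) is Z


class TestFocalLoss:
    def test_perfect_predictions_loss_vanishes(self):
        logits = np.array([[30.0, -30.0], [30.0, 30.0]])
        targets = np.array([[1, 0], [1, 1]], float)
        assert learned.masked_focal_loss(logits, targets) < 1e-8

    def test_gamma_zero_equals_hand_computed_bce(self):
        """3-sample batch checked against the binary cross-entropy
        formula written out by hand (masked abnormality term dropped
        from the mean)."""
        logits = np.array([[0.3, -1.2], [2.0, 0.5], [-0.7, 0.9]])
        targets = np.array([[1, 0], [1, 1], [0, 0]], float)
        mask = np.array([False, False, True])
        p = 1 / (1 + np.exp(-logits))
        hand = -(
            np.log(p[0, 0]) + np.log(1 - p[0, 1])
            + np.log(p[1, 0]) + np.log(p[1, 1])
            + np.log(1 - p[2, 0])
        ) / 5
        got = learned.masked_focal_loss(logits, targets, mask, gamma=0.0)
        assert got == pytest.approx(hand, rel=1e-12)

    def test_all_zero_batch_depends_only_on_existence_output(self):
        targets = np.zeros((4, 2))
        mask = np.ones(4, bool)
        rng = np.random.default_rng(0)
        base = rng.normal(size=(4, 2))
        other = base.copy()
        other[:, 1] = rng.normal(size=4)  # different abnormality logits
        a = learned.masked_focal_loss(base, targets, mask)
        b = learned.masked_focal_loss(other, targets, mask)
        assert a == pytest.approx(b, rel=1e-12)

    def test_gradient_matches_numeric(self):
        rng = np.random.default_rng(1)
        logits = rng.normal(size=(5, 2))
        targets = (rng.random((5, 2)) > 0.5).astype(float)
        mask = np.array([True, False, False, True, False])
        w = np.array([[1.3, 0.8], [0.9, 1.7]])
        _, grad = learned.masked_focal_loss(
            logits, targets, mask, gamma=2.0, weights=w, return_grad=True
        )
        eps = 1e-6
        for i in range(5):
            for j in range(2):
                lp = logits.copy(); lp[i, j] += eps
                lm = logits.copy(); lm[i, j] -= eps
                num = (
                    learned.masked_focal_loss(lp, targets, mask, 2.0, w)
                    - learned.masked_focal_loss(lm, targets, mask, 2.0, w)
                ) / (2 * eps)
                assert grad[i, j] == pytest.approx(num, abs=1e-7)

    def test_masked_samples_have_zero_abnormality_gradient(self):
        rng = np.random.default_rng(2)
        logits = rng.normal(size=(6, 2))
        targets = np.zeros((6, 2))
        mask = np.ones(6, bool)
        _, grad = learned.masked_focal_loss(
            logits, targets, mask, gamma=2.0, return_grad=True
        )
        np.testing.assert_array_equal(grad[:, 1], 0.0)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            learned.masked_focal_loss(np.zeros((0, 2)), np.zeros((0, 2)))


class TestNetwork:
    def test_backbone_size_and_determinism(self):
        net = SmallCNN(seed=3)
        assert 50_000 < net.n_params() < 150_000
        x = np.random.default_rng(0).random((2, 56, 56))
        a = net.forward(x)
        b = SmallCNN(seed=3).forward(x)
        np.testing.assert_array_equal(a, b)

    def test_parameter_gradients_match_numeric(self):
        net = SmallCNN(seed=0)
        rng = np.random.default_rng(1)
        x = rng.random((2, 56, 56))
        targets = np.array([[1, 0], [0, 0]], float)
        mask = np.array([False, True])
        _, dlog = learned.masked_focal_loss(
            net.forward(x), targets, mask, return_grad=True
        )
        net.backward(dlog)
        conv, fc = net.layers[1], net.layers[-1]
        eps = 1e-6
        for layer, name, idx in [(conv, "w", (1, 7)), (fc, "w", (0, 11)),
                                 (fc, "b", (1,))]:
            p = getattr(layer, name)
            orig = p[idx]
            p[idx] = orig + eps
            lp = learned.masked_focal_loss(net.forward(x), targets, mask)
            p[idx] = orig - eps
            lm = learned.masked_focal_loss(net.forward(x), targets, mask)
            p[idx] = orig
            num = (lp - lm) / (2 * eps)
            assert getattr(layer, "g" + name)[idx] == pytest.approx(num, abs=1e-6)

    def test_saliency_of_linear_scorer_is_weight_magnitude(self):
        """A flatten+linear 'network' has d(logit)/d(input) == w."""
        rng = np.random.default_rng(5)
        lin = Linear(56 * 56, 2, rng)
        net = SmallCNN(seed=0)
        net.layers = [Flatten(), lin]
        x = rng.random((1, 1, 56, 56))
        net.forward(x[:, 0])
        # forward expects (N, 56, 56); emulate clf.saliency's backward
        logits = net.forward(x[:, 0])
        seed = np.zeros_like(logits)
        seed[:, 0] = 1.0
        grad = net.backward(seed)
        np.testing.assert_allclose(
            np.abs(grad[0]), np.abs(lin.w[0].reshape(56, 56)), atol=1e-12
        )

    def test_zeroed_network_gives_zero_saliency(self):
        net = SmallCNN(seed=0)
        for layer in net.layers:
            if hasattr(layer, "params"):
                for name, _ in layer.params:
                    getattr(layer, name)[:] = 0.0
        x = np.random.default_rng(0).random((1, 56, 56))
        logits = net.forward(x)
        seed = np.zeros_like(logits)
        seed[:, 0] = 1.0
        assert np.abs(net.backward(seed)).max() == 0.0


class TestTraining:
    def test_same_seed_identical_loss_trajectories(self):
        X, y = tile_dataset(15, 5)
        a = learned.DualOutputClassifier(epochs=2, random_state=7).fit(X, y)
        b = learned.DualOutputClassifier(epochs=2, random_state=7).fit(X, y)
        assert a.loss_curve_ == b.loss_curve_
        assert a.val_loss_curve_ == b.val_loss_curve_

    def test_na_labels_dropped_single_class_warns(self):
        X = np.random.default_rng(0).random((30, 56, 56))
        y = [F] * 28 + [Score.NA] * 2
        with pytest.warns(UserWarning):
            clf = learned.DualOutputClassifier(
                epochs=1, augment=False, validation_fraction=0.0
            ).fit(X, y)
        assert clf.degenerate_outputs_ == ["exist", "abnormal"]

    def test_trained_model_separates_existence(self, trained_models):
        clf, Xte, yte = trained_models[0]
        keep = [i for i, s in enumerate(yte) if not s.is_na]
        probs = clf.predict_proba(Xte[keep])
        auc = evaluate.roc_existence(probs, [yte[i] for i in keep]).auc
        assert auc >= 0.95

    def test_save_load_roundtrip_predictions(self, trained_clf, tmp_path):
        path = tmp_path / "model.npz"
        trained_clf.save(path)
        back = learned.DualOutputClassifier.load(path)
        X = np.random.default_rng(0).random((4, 56, 56))
        np.testing.assert_allclose(
            back.predict_proba(X), trained_clf.predict_proba(X), atol=1e-12
        )
        assert back.thresholds_ == trained_clf.thresholds_


class TestSaliencyAndSweeps:
    def test_saliency_concentrates_on_the_fiber(self, trained_clf):
        spec_tiles, _ = synth.render_subimages(
            synth.PhantomSpec(
                lesions=synth.nominal_lesions(DEFAULT_LAYOUT, 66),
                blur_sigma=0.5, noise_sigma=0.003,
            )
        )
        tile = spec_tiles[DEFAULT_LAYOUT.cell_of(FIBER, 1)]
        sal = learned.saliency_map(trained_clf, tile, "exist")
        assert sal.shape == (56, 56)
        bg = np.median(tile.pixels)
        mask = ndi.binary_dilation(
            tile.pixels > bg + 0.25 * (tile.pixels.max() - bg), iterations=4
        )
        enrichment = (sal[mask].sum() / sal.sum()) / mask.mean()
        assert enrichment >= 1.3

    def test_display_ceiling_is_twice_pooled_percentile(self):
        maps = [np.full((8, 8), 0.1), np.full((8, 8), 0.3)]
        assert learned.saliency_display_max(maps) == pytest.approx(0.6, rel=0.01)

    def test_fiber_length_sweep_two_phase_response(self, trained_clf):
        sw = learned.interpretation_sweep(trained_clf, "fiber_length", steps=8)
        p_exist = sw.probs[:, 0]
        assert p_exist[-1] - p_exist[0] > 0.3
        assert np.all(np.diff(p_exist) > -0.1)  # essentially non-decreasing
        assert sw.decoded[-1] is F  # abnormality below threshold at full length
        assert not sw.above_threshold[-1, 1]

    def test_speck_sweep_reaches_half_then_full(self, trained_clf):
        sw = learned.interpretation_sweep(
            trained_clf, "speck_count_opacity", steps=13
        )
        u = sw.params
        assert sw.decoded[0] is Z
        assert all(s is F for s, v in zip(sw.decoded, u) if v >= 4.0)
        assert all(s in (H, F) for s, v in zip(sw.decoded, u) if v >= 2.0)

    def test_mass_deformation_raises_abnormality(self, trained_clf):
        sw = learned.interpretation_sweep(trained_clf, "mass_deformation", steps=8)
        assert sw.probs[-1, 1] - sw.probs[0, 1] > 0.2
        assert sw.decoded[0] is F
        assert sw.decoded[-1] is H

    def test_zero_step_sweep_returns_base_prediction(self, trained_clf):
        sw = learned.interpretation_sweep(trained_clf, "fiber_length", steps=0)
        assert sw.probs.shape == (1, 2)

    def test_unknown_manipulation_rejected(self, trained_clf):
        with pytest.raises(ValueError):
            learned.interpretation_sweep(trained_clf, "spin", steps=3)
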