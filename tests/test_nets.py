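"""Network contracts, loss oracles, and small training sanity checks."""

import numpy as np
import pytest

from ovaseg.errors import DegenerateInputError, ShapeError
from ovaseg.nets import (
    ClassifierConfig,
    SegmenterConfig,
    TrainConfig,
    TverskyParams,
    build_classifier,
    build_segmenter,
    classifier_logits,
    focal_tversky_loss,
    load_checkpoint,
    n_parameters,
    save_checkpoint,
    segmenter_probs,
    sigmoid_ce_loss,
    train_classifier,
    train_segmenter,
)
from ovaseg.nn.autograd import Tensor

# frozen reference parameter counts for the default architectures
N_PARAMS_CLASSIFIER = 10_825
N_PARAMS_SEGMENTER = 495_892


def tversky_oracle(pred, target, alpha, beta, gamma, smooth):
    """Brute-force soft-count evaluation, element by element."""
    tp = fn = fp = 0.0
    for p, t in zip(np.ravel(pred), np.ravel(target)):
        tp += p * t
        fn += (1 - p) * t
        fp += p * (1 - t)
    ti = (tp + smooth) / (tp + alpha * fn + beta * fp + smooth)
    return (1 - ti) ** (1 / gamma)


class TestFocalTverskyLoss:
    def test_perfect_prediction_loss_zero(self):
        t = np.zeros((8, 8))
        t[2:5, 2:5] = 1
        assert focal_tversky_loss(t, t, TverskyParams(smooth=1e-12)) == pytest.approx(0.0, abs=1e-9)

    def test_total_miss_loss_one(self):
        t = np.zeros((8, 8))
        t[1, 1] = 1
        assert focal_tversky_loss(np.zeros((8, 8)), t, TverskyParams(smooth=1e-12)) == pytest.approx(
            1.0, abs=1e-9
        )

    def test_hand_counts_case(self):
        # hard counts TP=2, FN=1, FP=1 -> TI = 2/2.8... with alpha=.8/beta=.2:
        # TI = 2 / (2 + .8 + .2) = 2/3; loss = (1/3)^(1/1.33)
        pred = np.array([1.0, 1, 0, 1, 0])
        target = np.array([1.0, 1, 1, 0, 0])
        expected = (1.0 / 3.0) ** (1.0 / 1.33)
        got = focal_tversky_loss(pred, target, TverskyParams(smooth=1e-12))
        assert got == pytest.approx(expected, abs=1e-9)
        assert got == pytest.approx(0.438, abs=1e-3)

    def test_matches_bruteforce_oracle_on_random_pairs(self, rng):
        p = TverskyParams()
        for _ in range(200):
            pred = rng.random((8, 8))
            target = (rng.random((8, 8)) > 0.5).astype(float)
            got = focal_tversky_loss(pred, target, p)
            want = tversky_oracle(pred, target, p.alpha, p.beta, p.gamma, p.smooth)
            assert got == pytest.approx(want, abs=1e-10)

    def test_range_and_fn_weighted_asymmetry(self, rng):
        p = TverskyParams()
        for _ in range(20):
            pred = rng.random((6, 6))
            target = (rng.random((6, 6)) > 0.5).astype(float)
            assert 0.0 <= focal_tversky_loss(pred, target, p) <= 1.0
        # with alpha > beta a false negative hurts more than a false positive
        target = np.zeros(10)
        target[:5] = 1
        miss_fn = target.copy()
        miss_fn[0] = 0  # one FN
        miss_fp = target.copy()
        miss_fp[5] = 1  # one FP
        assert focal_tversky_loss(miss_fn, target, p) > focal_tversky_loss(miss_fp, target, p)

    def test_symmetric_setting_matches_oracle(self, rng):
        p = TverskyParams(alpha=0.5, beta=0.5, gamma=1.0)
        pred = rng.random((8, 8))
        target = (rng.random((8, 8)) > 0.5).astype(float)
        want = tversky_oracle(pred, target, 0.5, 0.5, 1.0, p.smooth)
        assert focal_tversky_loss(pred, target, p) == pytest.approx(want, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            focal_tversky_loss(np.zeros((2, 2)), np.zeros((3, 3)))


class TestSigmoidCELoss:
    @pytest.mark.parametrize(
        "logit,label,expected",
        [
            (0.0, 1, np.log(2)),
            (-2.0, 0, np.log1p(np.exp(-2))),
            (2.0, 1, np.log1p(np.exp(-2))),
            (-50.0, 0, np.log1p(np.exp(-50))),
            (50.0, 1, np.log1p(np.exp(-50))),
        ],
    )
    def test_closed_form(self, logit, label, expected):
        assert sigmoid_ce_loss(logit, label) == pytest.approx(expected, abs=1e-12)

    def test_finite_at_huge_logits(self):
        assert np.isfinite(sigmoid_ce_loss(1e4, 0))
        assert sigmoid_ce_loss(1e4, 0) == pytest.approx(1e4)


class TestArchitectures:
    def test_classifier_emits_single_logit_per_slice(self, rng):
        model = build_classifier(ClassifierConfig(), seed=0)
        out = classifier_logits(model, rng.random((2, 512, 512)).astype(np.float32))
        assert out.shape == (2,)
        assert np.isfinite(out).all()

    def test_segmenter_emits_probability_map(self, rng):
        model = build_segmenter(seed=0)
        out = segmenter_probs(model, rng.random((2, 64, 64)).astype(np.float32))
        assert out.shape == (2, 64, 64)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_segmenter_rejects_indivisible_input(self, rng):
        model = build_segmenter(seed=0)
        with pytest.raises(ShapeError):
            model(Tensor(rng.random((1, 1, 50, 50)).astype(np.float32)))

    def test_parameter_counts_match_reference(self):
        assert n_parameters(build_classifier(ClassifierConfig(), seed=0)) == N_PARAMS_CLASSIFIER
        assert n_parameters(build_segmenter(SegmenterConfig(), seed=0)) == N_PARAMS_SEGMENTER

    def test_invalid_configs_rejected(self):
        from ovaseg.errors import DomainError

        with pytest.raises(DomainError):
            SegmenterConfig(level_features=(32, 16, 64, 128))
        with pytest.raises(DomainError):
            ClassifierConfig(dropout_p=1.5)


def _separable_pairs(rng, n=24, size=32):
    """Slices with/without a bright disc: a trivially separable task."""
    pairs = []
    yy, xx = np.mgrid[:size, :size]
    for i in range(n):
        img = rng.normal(0.1, 0.02, size=(size, size)).astype(np.float32)
        label = i % 2
        mask = np.zeros((size, size))
        if label:
            cy, cx = rng.integers(8, size - 8, size=2)
            disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= 16
            img[disc] = 1.0
            mask[disc] = 1.0
        pairs.append((img, label, mask))
    return pairs


class TestTraining:
    def test_classifier_learns_separable_task(self, rng):
        data = _separable_pairs(rng, n=32)
        pairs = [(img, lab) for img, lab, _ in data]
        model, history = train_classifier(
            pairs, TrainConfig(epochs=10, batch_size=8, seed=0), ClassifierConfig(input_size=32)
        )
        logits = classifier_logits(model, np.stack([p[0] for p in pairs]))
        acc = ((logits > 0) == np.array([p[1] for p in pairs])).mean()
        assert acc >= 0.95
        assert len(history["train_loss"]) == len(history["val_loss"])

    def test_same_seed_reproduces_validation_loss(self, rng):
        data = _separable_pairs(rng, n=12)
        pairs = [(img, lab) for img, lab, _ in data]
        cfg = TrainConfig(epochs=2, batch_size=4, seed=7)
        _, h1 = train_classifier(pairs, cfg, ClassifierConfig(input_size=32))
        _, h2 = train_classifier(pairs, cfg, ClassifierConfig(input_size=32))
        assert h1["val_loss"] == h2["val_loss"]

    def test_empty_and_single_class_sets_rejected(self):
        with pytest.raises(DegenerateInputError):
            train_classifier([], TrainConfig(epochs=1))
        ones = [(np.zeros((16, 16), np.float32), 1)] * 4
        with pytest.raises(DegenerateInputError):
            train_classifier(ones, TrainConfig(epochs=1), ClassifierConfig(input_size=16))

    def test_segmenter_rejects_empty_masks(self, rng):
        pairs = [(rng.random((16, 16)).astype(np.float32), np.zeros((16, 16)))]
        with pytest.raises(DegenerateInputError):
            train_segmenter(pairs, TrainConfig(epochs=1))

    def test_best_checkpoint_loss_is_running_minimum(self, rng):
        data = _separable_pairs(rng, n=16)
        pairs = [(img, mask) for img, lab, mask in data if lab]
        model, history = train_segmenter(
            pairs, TrainConfig(epochs=3, batch_size=4, seed=1), SegmenterConfig()
        )
        assert history["best_val_loss"] == pytest.approx(min(history["val_loss"]))

    def test_checkpoint_round_trip(self, rng, tmp_path):
        model = build_classifier(ClassifierConfig(input_size=32), seed=4)
        x = rng.random((3, 32, 32)).astype(np.float32)
        before = classifier_logits(model, x)
        save_checkpoint(model, tmp_path / "clf.npz", history={"val_loss": [1.0]}, seed=4)
        restored = load_checkpoint(tmp_path / "clf.npz")
        np.testing.assert_allclose(classifier_logits(restored, x), before, atol=1e-6)
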