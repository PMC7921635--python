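"""Oversampling, rotation augmentation, weighted metrics, desk classifier."""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from streetads.classify import (
    DeskClassifier,
    LabelledCropSet,
    TrainConfig,
    augment_rotate,
    balanced_subset_eval,
    oversample,
    per_class_prf,
    rotation_angle,
    weighted_prf,
)
from streetads.synthetic import billboard_texture, labelled_crop_set


def _set(counts: dict[str, int], seed: int = 0) -> LabelledCropSet:
    rng = np.random.default_rng(seed)
    crops, labels = [], []
    for lab, n in counts.items():
        for _ in range(n):
            crops.append(rng.integers(0, 255, (8, 8, 3)).astype(np.uint8))
            labels.append(lab)
    return LabelledCropSet(crops, labels)


class TestOversample:
    def test_balanced_set_counts_unchanged(self):
        out = oversample(_set({"food": 5, "other": 5}))
        assert out.class_counts() == {"food": 5, "other": 5}

    def test_minority_raised_to_majority(self):
        out = oversample(_set({"food": 10, "other": 100}))
        assert out.class_counts() == {"food": 100, "other": 100}

    def test_per_class_max_rule(self):
        out = oversample(_set({"food": 3, "alcohol": 7, "gambling": 7}))
        assert out.class_counts() == {"food": 7, "alcohol": 7, "gambling": 7}
        assert len(out.crops) == 21

    def test_original_samples_all_kept(self):
        data = _set({"food": 2, "other": 6})
        out = oversample(data, seed=3)
        ids = {id(c) for c in out.crops}
        assert all(id(c) in ids for c in data.crops)

    def test_deterministic_under_seed(self):
        data = _set({"food": 2, "other": 9})
        a = oversample(data, seed=5)
        b = oversample(data, seed=5)
        assert all(np.array_equal(x, y) for x, y in zip(a.crops, b.crops))

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="category"):
            LabelledCropSet([np.zeros((4, 4, 3), np.uint8)], ["vaping"])


class TestAugmentRotate:
    def test_zero_limit_is_identity(self):
        img = billboard_texture("food", 1, size=(32, 32))
        assert augment_rotate(img, 0.0, seed=4) is img

    def test_fixed_seed_repeats_angle(self):
        img = billboard_texture("food", 1, size=(32, 32))
        assert np.array_equal(augment_rotate(img, 30, 7), augment_rotate(img, 30, 7))

    def test_size_preserved(self):
        img = billboard_texture("alcohol", 2, size=(40, 56))
        assert augment_rotate(img, 30, 1).shape == img.shape

    def test_angle_distribution_uniform_within_limit(self):
        # Monte-Carlo: 10,000 seeded draws at limit 30
        angles = np.array([rotation_angle(30.0, s) for s in range(10_000)])
        assert angles.min() >= -30 and angles.max() <= 30
        assert abs(angles.mean()) < 1.0
        assert angles.std() == pytest.approx(30 / np.sqrt(3), rel=0.05)

    def test_negative_limit_rejected(self):
        with pytest.raises(ValueError):
            rotation_angle(-1.0, 0)


def _brute_force_weighted(preds, truths):
    """Independent confusion-matrix implementation of weighted P/R/F1."""
    labels = sorted(set(truths) | set(preds))
    n = len(truths)
    P = R = F = 0.0
    for lab in labels:
        tp = sum(1 for p, t in zip(preds, truths) if p == lab and t == lab)
        fp = sum(1 for p, t in zip(preds, truths) if p == lab and t != lab)
        fn = sum(1 for p, t in zip(preds, truths) if p != lab and t == lab)
        support = tp + fn
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        P += support / n * prec
        R += support / n * rec
        F += support / n * f1
    return P, R, F


class TestWeightedPRF:
    def test_perfect_predictions(self):
        out = weighted_prf(["food", "other"], ["food", "other"])
        assert (out.precision, out.recall, out.f1) == (1.0, 1.0, 1.0)

    def test_hand_built_confusion_matrix_case(self):
        truths = ["food", "food", "other", "other"]
        preds = ["food", "other", "other", "other"]
        # food: P=1, R=1/2, F=2/3; other: P=2/3, R=1, F=4/5; weights 1/2 each
        out = weighted_prf(preds, truths)
        assert out.precision == pytest.approx(0.5 * 1 + 0.5 * 2 / 3)
        assert out.recall == pytest.approx(0.75)
        assert out.f1 == pytest.approx(0.5 * 2 / 3 + 0.5 * 0.8)

    def test_single_class_predictor_on_balanced_classes(self):
        truths = ["food", "food", "other", "other"]
        preds = ["other"] * 4
        assert weighted_prf(preds, truths).recall == pytest.approx(0.5)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            weighted_prf([], [])

    @settings(max_examples=250, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["food", "alcohol", "gambling", "other"]),
                st.sampled_from(["food", "alcohol", "gambling", "other"]),
            ),
            min_size=1,
            max_size=40,
        )
    )
    def test_agrees_with_brute_force_oracle(self, pairs):
        preds = [p for p, _ in pairs]
        truths = [t for _, t in pairs]
        expected = _brute_force_weighted(preds, truths)
        out = weighted_prf(preds, truths)
        assert (out.precision, out.recall, out.f1) == pytest.approx(expected, abs=1e-12)


class TestDeskClassifier:
    def test_separates_synthetic_textures(self, quick_classifier):
        crops, labels = labelled_crop_set(n_per_category=5, seed=99)
        preds = [quick_classifier.predict(c)[0] for c in crops]
        scores = per_class_prf(preds, labels)
        assert all(s.f1 >= 0.95 for s in scores.values())

    def test_predict_deterministic_and_scored(self, quick_classifier):
        crop = billboard_texture("gambling", 123)
        a = quick_classifier.predict(crop)
        b = quick_classifier.predict(crop)
        assert a == b
        assert 0.0 <= a[1] <= 1.0

    def test_unfitted_predict_rejected(self):
        with pytest.raises(RuntimeError):
            DeskClassifier().predict(np.zeros((8, 8, 3), np.uint8))

    def test_train_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)
        with pytest.raises(ValueError):
            TrainConfig(rotation_limit_deg=200)


class TestBalancedSubsetEval:
    def test_single_subset_equals_direct_evaluation(self, quick_classifier):
        crops, labels = labelled_crop_set(n_per_category=6, seed=11)
        data = LabelledCropSet(crops, labels)
        pool = [i for i, l in enumerate(labels) if l == "other"]
        minority = [i for i, l in enumerate(labels) if l == "food"]
        out = balanced_subset_eval(quick_classifier, data, "food", "other", k_subsets=1, seed=0)
        idx = minority + pool  # pool size equals minority size -> whole pool used
        preds = [quick_classifier.predict(data.crops[i])[0] for i in idx]
        truths = [data.labels[i] for i in idx]
        direct = per_class_prf(preds, truths, labels=["food", "other"])
        for lab in ("food", "other"):
            assert out[lab].f1 == pytest.approx(direct[lab].f1)

    def test_deterministic_under_seed(self, quick_classifier):
        crops, labels = labelled_crop_set(n_per_category=8, seed=12)
        data = LabelledCropSet(crops, labels)
        a = balanced_subset_eval(quick_classifier, data, "food", "other", seed=5)
        b = balanced_subset_eval(quick_classifier, data, "food", "other", seed=5)
        assert a == b

    def test_separable_textures_score_highly(self, quick_classifier):
        crops, labels = labelled_crop_set(n_per_category=8, seed=13)
        out = balanced_subset_eval(
            quick_classifier, LabelledCropSet(crops, labels), "food", "other", k_subsets=5, seed=2
        )
        assert out["food"].f1 >= 0.95 and out["other"].f1 >= 0.95

    def test_pool_smaller_than_minority_rejected(self, quick_classifier):
        data = _set({"food": 5, "other": 3})
        with pytest.raises(ValueError, match="pool"):
            balanced_subset_eval(quick_classifier, data, "food", "other")
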