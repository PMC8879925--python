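import numpy as np
import pandas as pd
import pytest

from phenotyper import classify
from phenotyper.classify import (
    ConfusionMatrix,
    ExperimentDesign,
    InsufficientSubjectsError,
    InvalidDesignError,
    PredictionSet,
    assemble_dataset,
    confusion,
    evaluate,
    make_design,
    permutation_baseline,
    train_classifier,
)
from phenotyper.imaging import TrackImage
from phenotyper.nn import TrainConfig

DOSES = ("control", "100ug", "200ug")


def make_image(rng, label, fish_id, window_idx, size=16, bright=None):
    """Tiny synthetic image; `bright` places a class-specific blob."""
    px = np.zeros((size, size))
    px[rng.integers(size), rng.integers(size)] = 0.5
    if bright is not None:
        r, c = bright
        px[r:r + 4, c:c + 4] = 1.0
    return TrackImage(px, label, fish_id, window_idx)


def blob_image_set(rng, n_fish=6, n_seg=6, size=16):
    """Two separable classes: blob in opposite corners."""
    images = []
    for dose, corner in (("control", (0, 0)), ("200ug", (size - 4, size - 4))):
        for f in range(n_fish):
            for w in range(n_seg):
                images.append(make_image(rng, ("day1", dose), f"{dose}_f{f}", w,
                                         size=size, bright=corner))
    return images


class TestMakeDesign:
    def test_e1_all_classes(self):
        d = make_design("E1", doses=DOSES)
        assert len(d.train_classes) == 6
        assert d.train_classes == d.test_classes
        assert d.split_mode == "holdout"

    @pytest.mark.parametrize("did,day", [("E2A", "day1"), ("E2B", "day2")])
    def test_single_day_designs(self, did, day):
        d = make_design(did, doses=DOSES)
        assert all(c[0] == day for c in d.train_classes)
        assert d.train_classes == d.test_classes

    def test_cross_day_designs(self):
        a = make_design("E3A", doses=DOSES)
        b = make_design("E3B", doses=DOSES)
        assert all(c[0] == "day1" for c in a.train_classes)
        assert all(c[0] == "day2" for c in a.test_classes)
        assert a.train_classes == b.test_classes
        assert a.test_classes == b.train_classes
        assert a.match_on == "dose"

    def test_unknown_design(self):
        with pytest.raises(InvalidDesignError):
            make_design("E9")


class TestAssembleDataset:
    def _study_images(self, n_fish=10, n_seg=20):
        rng = np.random.default_rng(0)
        images = []
        for dose in DOSES:
            for f in range(n_fish):
                for day in ("day1", "day2"):
                    for w in range(n_seg):
                        images.append(make_image(rng, (day, dose), f"{dose}_f{f}", w))
        return images

    def test_e3a_counting(self):
        images = self._study_images(n_fish=10, n_seg=20)
        train, val = assemble_dataset(images, make_design("E3A", doses=DOSES))
        assert len(train) == 600 and len(val) == 600
        assert all(im.label[0] == "day1" for im in train)
        assert all(im.label[0] == "day2" for im in val)

    def test_holdout_no_fish_leakage(self):
        images = self._study_images()
        train, val = assemble_dataset(images, make_design("E1", doses=DOSES),
                                      holdout_frac=0.2, seed=0)
        train_fish = {im.fish_id for im in train}
        val_fish = {im.fish_id for im in val}
        assert train_fish.isdisjoint(val_fish)
        # 10 fish per dose, frac 0.2 -> 2 held out per dose
        assert len(val_fish) == 6

    def test_holdout_determinism(self):
        images = self._study_images(n_fish=5, n_seg=5)
        d = make_design("E1", doses=DOSES)
        a = assemble_dataset(images, d, seed=3)
        b = assemble_dataset(images, d, seed=3)
        assert [im.fish_id for im in a[1]] == [im.fish_id for im in b[1]]

    def test_insufficient_subjects(self):
        images = self._study_images(n_fish=1, n_seg=3)
        with pytest.raises(InsufficientSubjectsError):
            assemble_dataset(images, make_design("E1", doses=DOSES))

    def test_missing_class(self):
        rng = np.random.default_rng(0)
        images = [make_image(rng, ("day1", "control"), "f0", 0)]
        with pytest.raises(InvalidDesignError):
            assemble_dataset(images, make_design("E1", doses=DOSES))


class TestTrainAndEvaluate:
    def test_separable_classes_high_accuracy(self):
        rng = np.random.default_rng(1)
        images = blob_image_set(rng)
        d = make_design("E2A", doses=("control", "200ug"))
        train, val = assemble_dataset(images, d, holdout_frac=0.25, seed=0)
        model = train_classifier(train, TrainConfig(arch="tiny", epochs=6, seed=0))
        _, acc = evaluate(model, val)
        assert acc >= 0.9

    def test_training_determinism(self):
        rng = np.random.default_rng(2)
        images = blob_image_set(rng, n_fish=4, n_seg=4)
        d = make_design("E2A", doses=("control", "200ug"))
        train, val = assemble_dataset(images, d, seed=0)
        accs = []
        for _ in range(2):
            model = train_classifier(train, TrainConfig(arch="tiny", epochs=3, seed=7))
            _, acc = evaluate(model, val)
            accs.append(acc)
        assert accs[0] == accs[1]

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(3)
        images = blob_image_set(rng, n_fish=6, n_seg=6)
        # destroy the signal by shuffling labels across images
        labels = [im.label for im in images]
        rng.shuffle(labels)
        shuffled = [TrackImage(im.pixels, lab, im.fish_id, im.window_idx)
                    for im, lab in zip(images, labels)]
        d = make_design("E2A", doses=("control", "200ug"))
        train, val = assemble_dataset(shuffled, d, seed=0)
        model = train_classifier(train, TrainConfig(arch="tiny", epochs=3, seed=0))
        preds, acc = evaluate(model, val)
        bl = permutation_baseline(preds, reps=500, seed=0)
        lo, hi = np.quantile(bl.distribution, [0.005, 0.995])
        assert lo - 0.15 <= acc <= hi + 0.15

    def test_single_class_rejected(self):
        rng = np.random.default_rng(4)
        images = [make_image(rng, ("day1", "control"), f"f{f}", w)
                  for f in range(3) for w in range(3)]
        with pytest.raises(InvalidDesignError):
            train_classifier(images)

    def test_empty_validation_rejected(self):
        rng = np.random.default_rng(5)
        images = blob_image_set(rng, n_fish=2, n_seg=2)
        model = train_classifier(images, TrainConfig(arch="tiny", epochs=1, seed=0))
        with pytest.raises(ValueError):
            evaluate(model, [])


def preds_from_pairs(pairs):
    """pairs: list of (true, predicted) labels."""
    frame = pd.DataFrame({"true_class": [p[0] for p in pairs],
                          "predicted_class": [p[1] for p in pairs],
                          "fish_id": [f"f{i}" for i in range(len(pairs))]})
    return PredictionSet(frame)


class TestConfusion:
    def test_hand_tally(self):
        # true -> predicted: (A,A), (B,A), (B,B), (B,B)
        preds = preds_from_pairs([("A", "A"), ("B", "A"), ("B", "B"), ("B", "B")])
        cm = confusion(preds)
        assert cm.row_labels == ("A", "B") and cm.col_labels == ("A", "B")
        np.testing.assert_allclose(cm.values[:, 0], [1.0, 0.0])
        np.testing.assert_allclose(cm.values[:, 1], [1 / 3, 2 / 3])

    def test_perfect_predictions_identity(self):
        preds = preds_from_pairs([(l, l) for l in "ABCABC"])
        cm = confusion(preds)
        np.testing.assert_allclose(cm.values, np.eye(3))

    def test_columns_sum_to_one(self):
        rng = np.random.default_rng(0)
        pairs = [(rng.choice(list("ABC")), rng.choice(list("ABC"))) for _ in range(200)]
        cm = confusion(preds_from_pairs(pairs))
        np.testing.assert_allclose(cm.values.sum(axis=0), 1.0, atol=1e-9)

    def test_accuracy_equals_trace_mass(self):
        rng = np.random.default_rng(1)
        pairs = [(rng.choice(list("ABC")), rng.choice(list("ABC"))) for _ in range(100)]
        preds = preds_from_pairs(pairs)
        cm = confusion(preds)
        assert preds.accuracy == pytest.approx(np.trace(cm.counts) / cm.counts.sum())

    def test_empty_column_flagged(self):
        preds = preds_from_pairs([("A", "A"), ("B", "A")])
        cm = confusion(preds, col_labels=("A", "B", "C"))
        assert cm.empty_columns == ("C",)
        np.testing.assert_allclose(cm.values[:, 2], 0.0)

    def test_rectangular_cross_day(self):
        pairs = [(("day2", "control"), ("day1", "control")),
                 (("day2", "200ug"), ("day1", "200ug"))]
        frame = pd.DataFrame({"true_class": [p[0] for p in pairs],
                              "predicted_class": [p[1] for p in pairs],
                              "fish_id": ["f0", "f1"]})
        cm = confusion(PredictionSet(frame, match_on="dose"))
        assert cm.values.shape == (2, 2)
        assert all(r[0] == "day1" for r in cm.row_labels)
        assert all(c[0] == "day2" for c in cm.col_labels)


class TestPermutationBaseline:
    def test_mean_near_chance(self):
        rng = np.random.default_rng(0)
        pairs = [(rng.choice(list("ABCD")), rng.choice(list("ABCD"))) for _ in range(400)]
        bl = permutation_baseline(preds_from_pairs(pairs), reps=500, seed=0)
        assert bl.distribution.mean() == pytest.approx(0.25, abs=0.01)

    def test_determinism(self):
        preds = preds_from_pairs([("A", "A"), ("B", "A"), ("A", "B"), ("B", "B")] * 10)
        a = permutation_baseline(preds, reps=200, seed=5)
        b = permutation_baseline(preds, reps=200, seed=5)
        assert a.threshold == b.threshold
        np.testing.assert_array_equal(a.distribution, b.distribution)

    def test_perfect_predictions_significant(self):
        preds = preds_from_pairs([(l, l) for l in "ABC" * 20])
        bl = permutation_baseline(preds, reps=500, seed=0)
        assert bl.observed == 1.0
        assert bl.significant

    def test_invalid_reps(self):
        with pytest.raises(ValueError):
            permutation_baseline(preds_from_pairs([("A", "A")]), reps=0)
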