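"""Experiment assembly, CNN training, confusion matrices and permutation baselines.

Class labels are (day, dose) pairs. Five experiment designs are supported:

* ``E1``   — both days, all doses; subject-level holdout split.
* ``E2A``  — day 1 only; holdout split.
* ``E2B``  — day 2 only; holdout split.
* ``E3A``  — train on all day-1 classes, test on all day-2 classes.
* ``E3B``  — the reverse.

Holdout splits are by fish: every segment image of a given fish lands on
exactly one side of the split, so temporally autocorrelated segments can
never leak across. For the cross-day designs the trained label set differs
from the tested one, producing a rectangular confusion matrix; a prediction
is counted correct there when the dose component matches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imaging import TrackImage
from .nn import SoftmaxClassifier, TrainConfig

DESIGN_IDS = ("E1", "E2A", "E2B", "E3A", "E3B")


class InsufficientSubjectsError(ValueError):
    pass


class InvalidDesignError(ValueError):
    pass


@dataclass(frozen=True)
class ExperimentDesign:
    id: str
    train_classes: tuple[tuple[str, str], ...]
    test_classes: tuple[tuple[str, str], ...]
    split_mode: str  # "holdout" | "cross"

    @property
    def match_on(self) -> str:
        return "class" if self.split_mode == "holdout" else "dose"


def make_design(design_id: str, days: tuple[str, ...] = ("day1", "day2"),
                doses: tuple[str, ...] = ("control", "100ug", "200ug")) -> ExperimentDesign:
    d1 = days[0]
    d2 = days[1] if len(days) > 1 else None
    all_classes = tuple((day, dose) for day in days for dose in doses)
    day1 = tuple((d1, dose) for dose in doses)
    if d2 is None and design_id in ("E2B", "E3A", "E3B"):
        raise InvalidDesignError(f"design {design_id} needs two days")
    day2 = tuple((d2, dose) for dose in doses) if d2 is not None else ()
    if design_id == "E1":
        return ExperimentDesign("E1", all_classes, all_classes, "holdout")
    if design_id == "E2A":
        return ExperimentDesign("E2A", day1, day1, "holdout")
    if design_id == "E2B":
        return ExperimentDesign("E2B", day2, day2, "holdout")
    if design_id == "E3A":
        return ExperimentDesign("E3A", day1, day2, "cross")
    if design_id == "E3B":
        return ExperimentDesign("E3B", day2, day1, "cross")
    raise InvalidDesignError(f"unknown design {design_id!r}; expected one of {DESIGN_IDS}")


@dataclass
class PredictionSet:
    frame: pd.DataFrame  # columns: true_class, predicted_class, fish_id
    match_on: str = "class"

    def __len__(self) -> int:
        return len(self.frame)

    @staticmethod
    def _dose(label) -> str:
        return label[1] if isinstance(label, tuple) else label

    def matches(self, true_labels=None) -> np.ndarray:
        true = list(self.frame["true_class"]) if true_labels is None else list(true_labels)
        pred = list(self.frame["predicted_class"])
        if self.match_on == "dose":
            return np.array([self._dose(t) == self._dose(p) for t, p in zip(true, pred)])
        return np.array([t == p for t, p in zip(true, pred)])

    @property
    def accuracy(self) -> float:
        return float(self.matches().mean())


@dataclass
class ConfusionMatrix:
    """Column-normalized confusion: rows = predicted class, cols = true class."""

    values: np.ndarray
    counts: np.ndarray
    row_labels: tuple
    col_labels: tuple
    empty_columns: tuple = ()

    def to_frame(self) -> pd.DataFrame:
        fmt = lambda l: f"{l[0]}:{l[1]}" if isinstance(l, tuple) else str(l)
        return pd.DataFrame(self.values, index=[fmt(l) for l in self.row_labels],
                            columns=[fmt(l) for l in self.col_labels])


def assemble_dataset(
    images: list[TrackImage],
    design: ExperimentDesign,
    holdout_frac: float = 0.2,
    seed: int = 0,
) -> tuple[list[TrackImage], list[TrackImage]]:
    """Split images into (train, validation) per the experiment design."""
    by_label: dict[tuple, list[TrackImage]] = {}
    for im in images:
        by_label.setdefault(im.label, []).append(im)
    for cls in set(design.train_classes) | set(design.test_classes):
        if cls not in by_label:
            raise InvalidDesignError(f"class {cls} absent from the image set")

    if design.split_mode == "cross":
        train = [im for c in design.train_classes for im in by_label[c]]
        val = [im for c in design.test_classes for im in by_label[c]]
        return train, val

    rng = np.random.default_rng(seed)
    wanted = set(design.train_classes)
    pool = [im for im in images if im.label in wanted]
    # split by fish within each dose group so a fish's two days stay together
    fish_by_dose: dict[str, list[str]] = {}
    for im in pool:
        fish_by_dose.setdefault(im.label[1], [])
        if im.fish_id not in fish_by_dose[im.label[1]]:
            fish_by_dose[im.label[1]].append(im.fish_id)
    holdout_fish: set[str] = set()
    for dose in sorted(fish_by_dose):
        fish = sorted(fish_by_dose[dose])
        if len(fish) < 2:
            raise InsufficientSubjectsError(f"dose group {dose!r} has < 2 fish")
        n_hold = max(1, round(holdout_frac * len(fish)))
        if n_hold >= len(fish):
            n_hold = len(fish) - 1
        holdout_fish.update(rng.choice(fish, size=n_hold, replace=False))
    train = [im for im in pool if im.fish_id not in holdout_fish]
    val = [im for im in pool if im.fish_id in holdout_fish]
    return train, val


def train_classifier(train_images: list[TrackImage],
                     config: TrainConfig | None = None) -> SoftmaxClassifier:
    if config is None:
        config = TrainConfig()
    labels = [im.label for im in train_images]
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise InvalidDesignError("training set must contain at least 2 classes")
    x = np.stack([im.pixels for im in train_images])
    model = SoftmaxClassifier(classes, config)
    return model.fit(x, labels)


def evaluate(model: SoftmaxClassifier, val_images: list[TrackImage],
             match_on: str = "class") -> tuple[PredictionSet, float]:
    if not val_images:
        raise ValueError("validation set is empty")
    x = np.stack([im.pixels for im in val_images])
    preds = model.predict(x)
    frame = pd.DataFrame(
        {
            "true_class": [im.label for im in val_images],
            "predicted_class": preds,
            "fish_id": [im.fish_id for im in val_images],
        }
    )
    ps = PredictionSet(frame, match_on=match_on)
    return ps, ps.accuracy


def confusion(preds: PredictionSet, row_labels=None, col_labels=None) -> ConfusionMatrix:
    """Column-normalized confusion matrix from a prediction set.

    ``values[i, j]`` is the fraction of samples of true class j predicted as
    class i. Candidate classes absent from the predictions appear as flagged
    all-zero columns.
    """
    if len(preds) == 0:
        raise ValueError("prediction set is empty")
    truths = list(preds.frame["true_class"])
    predicted = list(preds.frame["predicted_class"])
    rows = tuple(sorted(set(predicted))) if row_labels is None else tuple(row_labels)
    cols = tuple(sorted(set(truths))) if col_labels is None else tuple(col_labels)
    ridx = {l: i for i, l in enumerate(rows)}
    cidx = {l: j for j, l in enumerate(cols)}
    counts = np.zeros((len(rows), len(cols)))
    for t, p in zip(truths, predicted):
        counts[ridx[p], cidx[t]] += 1.0
    col_sums = counts.sum(axis=0)
    empty = tuple(cols[j] for j in range(len(cols)) if col_sums[j] == 0)
    values = np.divide(counts, np.where(col_sums == 0, 1.0, col_sums)[None, :])
    return ConfusionMatrix(values=values, counts=counts, row_labels=rows,
                           col_labels=cols, empty_columns=empty)


@dataclass
class PermutationBaseline:
    threshold: float
    distribution: np.ndarray
    alpha: float
    observed: float
    significant: bool


def permutation_baseline(preds: PredictionSet, reps: int = 1000, alpha: float = 0.05,
                         seed: int = 0) -> PermutationBaseline:
    """Shuffled-label accuracy distribution against the *fixed* predictions.

    The threshold is the (1 - alpha) quantile of the permuted accuracies;
    the observed accuracy is significant iff it exceeds the threshold.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    # 1-D object array so tuple labels survive fancy indexing
    truths = np.empty(len(preds), dtype=object)
    truths[:] = list(preds.frame["true_class"])
    dist = np.empty(reps)
    for r in range(reps):
        shuffled = truths[rng.permutation(len(truths))]
        dist[r] = preds.matches(true_labels=list(shuffled)).mean()
    threshold = float(np.quantile(dist, 1.0 - alpha))
    observed = preds.accuracy
    return PermutationBaseline(threshold=threshold, distribution=dist, alpha=alpha,
                               observed=observed, significant=observed > threshold)
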