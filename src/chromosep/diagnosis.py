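"""Per-image SVM diagnosis test scored with sensitivity, PPV and F1.

For each image, 100 samples per class train a soft-margin RBF support vector
machine on the raw RGB features (rescaled to [0, 1]); the remaining samples
(1900 per class under the 2000-per-class protocol, 3800 in total) are
classified, and diagnosability is scored with the F1 measure — the harmonic
mean of sensitivity (recall of the cancer class) and positive predictive
value (precision).  Hyperparameters follow the long-standing soft-margin
defaults: C = 1 and the 1/(d·Var(X)) kernel-width heuristic.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np
from sklearn.svm import SVC

from .base import EvaluationError, SplitError, TrainingError
from .sampling import SampleSet

__all__ = ["SplitSpec", "ClassificationResult", "split_train_test",
           "train_classifier", "evaluate", "diagnose_image"]


@dataclasses.dataclass(frozen=True)
class SplitSpec:
    """Per-image train/test split: n training samples per class, seeded."""

    n_train_per_class: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_train_per_class < 1:
            raise SplitError("n_train_per_class must be >= 1")


@dataclasses.dataclass(frozen=True)
class ClassificationResult:
    """Confusion counts and derived scores; cancer is the positive class.

    When no sample is predicted positive (tp + fp = 0) or no positive exists,
    the affected rates and F1 are defined as 0 so degenerate classifiers
    score worst rather than erroring.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def f1(self) -> float:
        s, p = self.sensitivity, self.ppv
        return 2 * s * p / (s + p) if (s + p) > 0 else 0.0

    @property
    def n_test(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def split_train_test(cancer: SampleSet, noncancer: SampleSet, spec: SplitSpec
                     ) -> tuple[tuple[np.ndarray, np.ndarray],
                                tuple[np.ndarray, np.ndarray]]:
    """Split each class into train/test RGB arrays, without replacement.

    Returns ``((train_cancer, train_noncancer), (test_cancer, test_noncancer))``.
    Per class, ``n_train_per_class`` samples are drawn uniformly; the rest
    form the test set.  Deterministic under the spec seed; train and test are
    disjoint by construction.
    """
    k = spec.n_train_per_class
    for s in (cancer, noncancer):
        if s.n <= k:
            raise SplitError(f"class {s.label.value!r} has {s.n} samples; "
                             f"need more than n_train_per_class={k}")
    rng = np.random.default_rng(spec.seed)
    out_train, out_test = [], []
    for s in (cancer, noncancer):
        perm = rng.permutation(s.n)
        out_train.append(s.rgb[perm[:k]])
        out_test.append(s.rgb[perm[k:]])
    return (out_train[0], out_train[1]), (out_test[0], out_test[1])


def train_classifier(train_cancer: np.ndarray, train_noncancer: np.ndarray,
                     c: float = 1.0, gamma: "str | float" = "scale"
                     ) -> Callable[[np.ndarray], np.ndarray]:
    """Fit an RBF-kernel SVM on rescaled RGB features.

    Returns a decision function mapping an N×3 RGB array to predicted labels
    (1 = cancer, 0 = non-cancer).  Deterministic for fixed inputs.
    """
    if len(train_cancer) == 0 or len(train_noncancer) == 0:
        raise TrainingError("both training sets must be non-empty")
    x = np.vstack([train_cancer, train_noncancer]) / 255.0
    y = np.concatenate([np.ones(len(train_cancer), int),
                        np.zeros(len(train_noncancer), int)])
    if np.allclose(x, x[0]):
        raise TrainingError("degenerate training data: all samples identical")
    model = SVC(C=c, kernel="rbf", gamma=gamma)
    model.fit(x, y)

    def predict(rgb: np.ndarray) -> np.ndarray:
        return model.predict(np.asarray(rgb, float) / 255.0)

    return predict


def evaluate(predictions: Sequence[int], truths: Sequence[int]
             ) -> ClassificationResult:
    """Score predictions against truths (1 = cancer positive class)."""
    pred = np.asarray(predictions, int)
    true = np.asarray(truths, int)
    if pred.shape != true.shape:
        raise EvaluationError(f"length mismatch: {pred.shape} predictions vs "
                              f"{true.shape} truths")
    return ClassificationResult(
        tp=int(np.sum((pred == 1) & (true == 1))),
        fp=int(np.sum((pred == 1) & (true == 0))),
        tn=int(np.sum((pred == 0) & (true == 0))),
        fn=int(np.sum((pred == 0) & (true == 1))),
    )


def diagnose_image(cancer: SampleSet, noncancer: SampleSet, spec: SplitSpec,
                   c: float = 1.0, gamma: "str | float" = "scale"
                   ) -> ClassificationResult:
    """Run the full per-image diagnosis test: split, train, classify, score."""
    (tr_c, tr_n), (te_c, te_n) = split_train_test(cancer, noncancer, spec)
    predict = train_classifier(tr_c, tr_n, c=c, gamma=gamma)
    x_test = np.vstack([te_c, te_n])
    y_true = np.concatenate([np.ones(len(te_c), int), np.zeros(len(te_n), int)])
    return evaluate(predict(x_test), y_true)
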