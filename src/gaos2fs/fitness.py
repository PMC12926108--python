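"""Pluggable classifier-error evaluators used as the GA's fitness core.

A wrapper selector scores a candidate feature subset by the validation error
of an actual classifier trained on it.  Four classifiers are supported:
3-nearest-neighbours, a 6-tree random forest, a CART decision tree and a
linear-kernel SVM.  The evaluation protocol is either a single stratified
70/30 hold-out (``k = 0``) or stratified k-fold cross-validation
(``k >= 2``), optionally repeated with re-randomised splits.

The error for an empty feature set is the majority-class error, so the empty
subset can never masquerade as a perfect classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from ._utils import seed_to_int

__all__ = [
    "ClassifierSpec",
    "EvalProtocol",
    "majority_class_error",
    "classification_error",
    "make_evaluator",
]

_KINDS = ("knn3", "rf6", "cart", "svm_linear")


@dataclass
class ClassifierSpec:
    """Which classifier wraps the subset and its fixed settings.

    knn3: 3 neighbours; rf6: 6 trees; cart: default split rules;
    svm_linear: linear kernel.
    """

    kind: str = "knn3"
    neighbors: int = 3
    trees: int = 6

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}; choose from {_KINDS}")
        if self.neighbors < 1 or self.trees < 1:
            raise ValueError("classifier settings must be positive")

    def build(self, seed: int):
        if self.kind == "knn3":
            return KNeighborsClassifier(n_neighbors=self.neighbors)
        if self.kind == "rf6":
            return RandomForestClassifier(n_estimators=self.trees, random_state=seed)
        if self.kind == "cart":
            return DecisionTreeClassifier(random_state=seed)
        return SVC(kernel="linear", random_state=seed)


@dataclass
class EvalProtocol:
    """How the validation error is estimated.

    ``k = 0`` means one stratified 70/30 hold-out split; ``k >= 2`` means
    stratified k-fold.  ``repeats`` re-randomises the split(s) and averages.
    """

    k: int = 0
    repeats: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k == 1 or self.k < 0:
            raise ValueError("k must be 0 (hold-out) or >= 2 (k-fold)")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


def majority_class_error(y) -> float:
    """Error of always predicting the most frequent class."""
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    return 1.0 - counts.max() / y.shape[0]


def _check_stratifiable(y, n_splits: int) -> None:
    classes, counts = np.unique(y, return_counts=True)
    bad = classes[counts < n_splits]
    if bad.size:
        raise ValueError(
            f"class {bad[0]!r} has fewer than {n_splits} samples; "
            "stratified splitting is impossible"
        )


def classification_error(X, y, spec: ClassifierSpec | None = None,
                         protocol: EvalProtocol | None = None) -> float:
    """Mean misclassification rate of ``spec``'s classifier on columns of X.

    Deterministic given ``protocol.seed``; invariant to the column order of X
    for the distance- and margin-based classifiers.  An ``M x 0`` matrix
    returns the majority-class error.
    """
    spec = spec or ClassifierSpec()
    protocol = protocol or EvalProtocol()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be M x p with M matching the label length")
    if X.shape[1] == 0:
        return majority_class_error(y)
    if X.shape[0] < 10:
        raise ValueError("need at least 10 samples for stratified splitting")

    errors = []
    ss = np.random.SeedSequence(protocol.seed).spawn(protocol.repeats)
    for rep_ss in ss:
        rep_seed = seed_to_int(rep_ss)
        if protocol.k == 0:
            _check_stratifiable(y, 2)
            X_tr, X_te, y_tr, y_te = train_test_split(
                X, y, test_size=0.3, stratify=y, random_state=rep_seed
            )
            clf = spec.build(rep_seed)
            clf.fit(X_tr, y_tr)
            errors.append(float(np.mean(clf.predict(X_te) != y_te)))
        else:
            _check_stratifiable(y, protocol.k)
            skf = StratifiedKFold(n_splits=protocol.k, shuffle=True, random_state=rep_seed)
            for tr, te in skf.split(X, y):
                clf = spec.build(rep_seed)
                clf.fit(X[tr], y[tr])
                errors.append(float(np.mean(clf.predict(X[te]) != y[te])))
    return float(np.mean(errors))


def make_evaluator(y, spec: ClassifierSpec, protocol: EvalProtocol, seed: int):
    """Bind a seeded ``evaluator(X_sub, y)`` callable for the GA.

    The returned callable is a pure function of the submitted column matrix:
    the split seed is fixed up front, so fitness values do not depend on the
    order in which chromosomes are evaluated.
    """
    bound = EvalProtocol(k=protocol.k, repeats=protocol.repeats, seed=seed)

    def evaluator(X_sub, y_in):
        return classification_error(X_sub, y_in, spec, bound)

    return evaluator
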