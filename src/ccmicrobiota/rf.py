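"""Random-Forest group classification under repeated cross-validation.

Tests whether POST-sample community composition carries a signature of the
care group: a Random Forest is trained on relative abundances and its
accuracy estimated by repeated stratified k-fold cross-validation (default
10 folds x 10 repeats). Accuracy near 0.5 on a balanced two-group design
means the composition does not separate the groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import RepeatedStratifiedKFold

from .datamodel import AbundanceTable


@dataclass
class CvAccuracy:
    """Cross-validated accuracy: overall mean and per-repeat values."""

    mean_accuracy: float
    per_repeat_accuracies: np.ndarray
    folds: int
    repeats: int
    n_trees: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "mean_accuracy": self.mean_accuracy,
            "per_repeat_accuracies": [float(a) for a in self.per_repeat_accuracies],
            "folds": self.folds,
            "repeats": self.repeats,
            "n_trees": self.n_trees,
            "seed": self.seed,
        }


def classify_groups(
    X: AbundanceTable | pd.DataFrame | np.ndarray,
    labels,
    folds: int = 10,
    repeats: int = 10,
    n_trees: int = 500,
    max_features: str | float = "sqrt",
    seed: int = 0,
) -> CvAccuracy:
    """Repeated stratified k-fold Random-Forest classification accuracy.

    The forest is fitted on each training split only; per-repeat accuracy
    pools the held-out predictions of that repeat's folds, and the mean
    accuracy averages the repeats. Fully seeded and reproducible.
    """
    if isinstance(X, AbundanceTable):
        Xm = X.values
    elif isinstance(X, pd.DataFrame):
        Xm = X.to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    if Xm.shape[0] != y.size:
        raise ValueError("X and labels must have the same number of rows")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    if counts.min() < folds:
        raise ValueError(
            f"class {classes[np.argmin(counts)]!r} has {counts.min()} members, "
            f"fewer than {folds} folds; reduce the fold count"
        )

    cv = RepeatedStratifiedKFold(
        n_splits=folds, n_repeats=repeats, random_state=seed
    )
    correct = np.zeros(repeats)
    total = np.zeros(repeats)
    for split_idx, (train, test) in enumerate(cv.split(Xm, y)):
        rep = split_idx // folds
        clf = RandomForestClassifier(
            n_estimators=n_trees,
            max_features=max_features,
            random_state=seed + 7919 * split_idx,
            n_jobs=1,
        )
        clf.fit(Xm[train], y[train])
        pred = clf.predict(Xm[test])
        correct[rep] += np.sum(pred == y[test])
        total[rep] += test.size
    per_repeat = correct / total
    return CvAccuracy(
        mean_accuracy=float(per_repeat.mean()),
        per_repeat_accuracies=per_repeat,
        folds=folds,
        repeats=repeats,
        n_trees=n_trees,
        seed=seed,
    )
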