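"""Wrapped-classifier accuracy evaluation used by ATD and fusion.

All model selection (decorrelation curves, PCA rank, fusion weights) is
scored by stratified inner cross-validation of a margin classifier on the
training split only, so no information from held-out data leaks into the
fitted selectors.  The protocol is fully determined by its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC


@dataclass(frozen=True)
class AccuracyEvaluator:
    """Inner-CV accuracy of an RBF-kernel SVM with per-column standardization."""

    n_folds: int = 3
    seed: int = 0
    c: float = 1.0
    gamma: str | float = "scale"
    standardize: bool = True

    def make_classifier(self) -> Pipeline:
        steps = []
        if self.standardize:
            steps.append(("scale", StandardScaler()))
        steps.append(("svm", SVC(kernel="rbf", C=self.c, gamma=self.gamma,
                                 random_state=self.seed)))
        return Pipeline(steps)

    def evaluate(self, features, labels, groups=None) -> float:
        """Mean held-out accuracy over stratified inner folds.

        ``groups`` (e.g. trial ids) keeps sibling windows of one trial in
        the same fold; fold count adapts to the smallest class (or group
        count) so tiny toy problems remain evaluable.
        """
        X = np.asarray(features, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(labels)
        _, counts = np.unique(y, return_counts=True)
        n_folds = min(self.n_folds, counts.min())
        if groups is not None:
            groups = np.asarray(groups)
            n_folds = min(n_folds, len(np.unique(groups)))
        if n_folds < 2:
            raise ValueError(
                "need at least 2 samples per class (and 2 groups) to evaluate")
        if groups is None:
            splitter = StratifiedKFold(n_splits=n_folds, shuffle=True,
                                       random_state=self.seed)
            split = splitter.split(X, y)
        else:
            splitter = StratifiedGroupKFold(n_splits=n_folds, shuffle=True,
                                            random_state=self.seed)
            split = splitter.split(X, y, groups)
        accs = []
        for train_idx, test_idx in split:
            clf = self.make_classifier()
            clf.fit(X[train_idx], y[train_idx])
            accs.append(clf.score(X[test_idx], y[test_idx]))
        return float(np.mean(accs))
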