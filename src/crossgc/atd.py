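"""Adaptive two-stage decorrelation (ATD) feature extraction.

Connectivity feature tables are heavily redundant: many cells of a
causality network move together across windows.  ATD removes that
redundancy in two accuracy-guided stages:

Stage 1 (greedy decorrelation)
    Find the most-correlated feature pair in the (lower triangle of the)
    Pearson correlation matrix, delete one member, score the survivors
    with the wrapped classifier, and repeat until one feature remains.
    The retained size ``m`` is the argmax of that accuracy curve.

Stage 2 (adaptive principal components)
    Center the surviving features, eigendecompose their covariance
    (1/(n-1) normalisation), project on the top-p eigenvectors for every
    p, score each projection, and keep the rank ``k`` at the curve's
    argmax.

Ties in either argmax are broken toward fewer features.  The fitted
selector (surviving ids, per-feature means, orthonormal basis) is applied
unchanged to new data.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluate import AccuracyEvaluator

DELETE_RULES = ("first", "second", "random", "most_correlated")


@dataclass
class CorrelationMatrix:
    r: np.ndarray
    feature_ids: list[str]
    constant_columns: list[str] = field(default_factory=list)


def correlation_matrix(features, feature_ids=None) -> CorrelationMatrix:
    """Pearson correlation of feature columns over the samples.

    Constant columns cannot be correlated; they get r = 0 against every
    other feature (unit diagonal) and are flagged.
    """
    X = _as_matrix(features)
    n, m = X.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    if m < 2:
        raise ValueError("need at least 2 features")
    if feature_ids is None:
        feature_ids = _default_ids(features, m)
    const = np.ptp(X, axis=0) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X, rowvar=False)
    r[np.isnan(r)] = 0.0
    r[const, :] = 0.0
    r[:, const] = 0.0
    np.fill_diagonal(r, 1.0)
    np.clip(r, -1.0, 1.0, out=r)
    return CorrelationMatrix(r=r, feature_ids=list(feature_ids),
                             constant_columns=[feature_ids[i]
                                               for i in np.where(const)[0]])


def _as_matrix(features) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(dtype=float)
    return np.asarray(features, dtype=float)


def _default_ids(features, m) -> list[str]:
    if isinstance(features, pd.DataFrame):
        return [str(c) for c in features.columns]
    return [f"f{i}" for i in range(m)]


def _argmax_fewest(sizes: list[int], accs: list[float]) -> int:
    """Size with maximal accuracy; ties go to the smallest size."""
    best_acc = max(accs)
    return min(s for s, a in zip(sizes, accs) if a == best_acc)


@dataclass
class Stage1Result:
    deletion_order: list[int]      # original column indices, deletion order
    curve_sizes: list[int]
    curve_accuracy: list[float]
    m: int
    selected: list[int]            # original column indices, original order


@dataclass
class Stage2Result:
    center: np.ndarray
    eigenvalues: np.ndarray        # descending
    basis: np.ndarray              # m x m orthonormal, columns by eigenvalue
    curve_ranks: list[int]
    curve_accuracy: list[float]
    k: int


def stage1_decorrelate(features, labels, evaluator: AccuracyEvaluator,
                       rule: str = "first", signed_correlation: bool = False,
                       curve_stride: int = 1, groups=None) -> Stage1Result:
    """Greedy correlation-guided deletion with an accuracy curve.

    At each step the maximum (absolute, unless ``signed_correlation``)
    off-diagonal entry of the lower triangle of the *original* correlation
    matrix restricted to the survivors picks the redundant pair; ``rule``
    selects which member is deleted (default: the first, i.e. the
    earlier-index feature).  With ``curve_stride`` > 1 only every s-th
    subset size is scored, then the neighbourhood of the best scored size
    is refined at stride 1.
    """
    if rule not in DELETE_RULES:
        raise ValueError(f"unknown deletion rule {rule!r}; one of {DELETE_RULES}")
    X = _as_matrix(features)
    n, M = X.shape
    if M < 2:
        raise ValueError("need at least 2 features")
    cm = correlation_matrix(features)
    score = cm.r.copy() if signed_correlation else np.abs(cm.r)
    # keep only the strict lower triangle as candidates
    score[np.triu_indices(M)] = -np.inf
    mean_abs = np.abs(cm.r).copy()
    np.fill_diagonal(mean_abs, 0.0)
    rng = np.random.default_rng(evaluator.seed)

    alive = np.ones(M, dtype=bool)
    deletion_order: list[int] = []
    eval_cache: dict[int, float] = {}

    def _evaluate_size(size: int, survivors_at) -> float:
        if size not in eval_cache:
            idx = survivors_at(size)
            eval_cache[size] = evaluator.evaluate(X[:, idx], labels, groups)
        return eval_cache[size]

    # fixed deletion path, computed once
    work = score.copy()
    alive_count = M
    while alive_count > 1:
        flat = np.argmax(work)
        v, u = divmod(int(flat), M)  # row v > col u in the lower triangle
        if rule == "first":
            d = u
        elif rule == "second":
            d = v
        elif rule == "random":
            d = int(rng.choice([u, v]))
        else:  # most_correlated: higher mean |r| with the other survivors
            others = alive.copy()
            others[[u, v]] = False
            mu = mean_abs[u, others].mean() if others.any() else 0.0
            mv = mean_abs[v, others].mean() if others.any() else 0.0
            d = u if mu >= mv else v
        deletion_order.append(d)
        alive[d] = False
        work[d, :] = -np.inf
        work[:, d] = -np.inf
        alive_count -= 1

    all_idx = np.arange(M)

    def survivors_at(size: int) -> np.ndarray:
        dead = set(deletion_order[:M - size])
        return all_idx[[i not in dead for i in all_idx]]

    sizes = list(range(M, 0, -1))
    stride = max(1, int(curve_stride))
    for s in sizes:
        if (M - s) % stride == 0 or s == 1:
            _evaluate_size(s, survivors_at)
    # bracket refinement: halve the stride around the best size so the
    # argmax is located to +-1 with O(log stride) extra evaluations
    step = stride
    while step > 1:
        step //= 2
        best = _argmax_fewest(list(eval_cache), list(eval_cache.values()))
        for s in (best - step, best + step):
            if 1 <= s <= M:
                _evaluate_size(s, survivors_at)
    curve_sizes = sorted(eval_cache, reverse=True)
    curve_acc = [float(eval_cache[s]) for s in curve_sizes]
    m = int(_argmax_fewest(curve_sizes, curve_acc))
    return Stage1Result(deletion_order=[int(i) for i in deletion_order],
                        curve_sizes=[int(s) for s in curve_sizes],
                        curve_accuracy=curve_acc, m=m,
                        selected=[int(i) for i in survivors_at(m)])


def stage2_pca(features_m, labels, evaluator: AccuracyEvaluator,
               curve_stride: int = 1, groups=None) -> Stage2Result:
    """Accuracy-guided principal-component projection of the survivors."""
    B = _as_matrix(features_m)
    n, m = B.shape
    if n < 2 or m < 1:
        raise ValueError("need at least 2 samples and 1 feature")
    center = B.mean(axis=0)
    Bc = B - center
    S = (Bc.T @ Bc) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(S)
    desc = np.argsort(eigvals)[::-1]
    eigvals = eigvals[desc]
    eigvecs = eigvecs[:, desc]
    eval_cache: dict[int, float] = {}

    def _evaluate_rank(p: int) -> float:
        if p not in eval_cache:
            eval_cache[p] = evaluator.evaluate(Bc @ eigvecs[:, :p], labels, groups)
        return eval_cache[p]

    stride = max(1, int(curve_stride))
    for p in range(1, m + 1):
        if (p - 1) % stride == 0 or p == m:
            _evaluate_rank(p)
    step = stride
    while step > 1:
        step //= 2
        best = _argmax_fewest(list(eval_cache), list(eval_cache.values()))
        for p in (best - step, best + step):
            if 1 <= p <= m:
                _evaluate_rank(p)
    ranks = sorted(eval_cache)
    accs = [eval_cache[p] for p in ranks]
    k = _argmax_fewest(ranks, accs)
    return Stage2Result(center=center, eigenvalues=eigvals, basis=eigvecs,
                        curve_ranks=ranks, curve_accuracy=accs, k=k)


class ATD:
    """Fitted two-stage decorrelation selector (fit/transform interface)."""

    def __init__(self, evaluator: AccuracyEvaluator | None = None,
                 rule: str = "first", signed_correlation: bool = False,
                 curve_stride: int = 1):
        self.evaluator = evaluator or AccuracyEvaluator()
        self.rule = rule
        self.signed_correlation = signed_correlation
        self.curve_stride = curve_stride

    def fit(self, features, labels, groups=None) -> "ATD":
        X = _as_matrix(features)
        self.feature_ids_ = _default_ids(features, X.shape[1])
        self.stage1_ = stage1_decorrelate(
            features, labels, self.evaluator, rule=self.rule,
            signed_correlation=self.signed_correlation,
            curve_stride=self.curve_stride, groups=groups)
        Xm = X[:, self.stage1_.selected]
        self.stage2_ = stage2_pca(Xm, labels, self.evaluator,
                                  curve_stride=self.curve_stride, groups=groups)
        self.selected_ids_ = [self.feature_ids_[i] for i in self.stage1_.selected]
        self.m_ = self.stage1_.m
        self.k_ = self.stage2_.k
        return self

    def transform(self, features) -> np.ndarray:
        """Column selection, stored-mean centering, top-k projection."""
        if not hasattr(self, "stage2_"):
            raise RuntimeError("ATD is not fitted")
        if isinstance(features, pd.DataFrame):
            missing = [c for c in self.selected_ids_ if c not in features.columns]
            if missing:
                raise ValueError(f"new data lacks fitted feature ids: {missing[:5]}"
                                 f"{'...' if len(missing) > 5 else ''}")
            Xm = features.loc[:, self.selected_ids_].to_numpy(dtype=float)
        else:
            X = np.asarray(features, dtype=float)
            if X.ndim == 1:
                X = X[None, :]
            if X.shape[1] != len(self.feature_ids_):
                raise ValueError(
                    f"expected {len(self.feature_ids_)} features, got {X.shape[1]}")
            Xm = X[:, self.stage1_.selected]
        Bc = Xm - self.stage2_.center
        return Bc @ self.stage2_.basis[:, :self.k_]

    def fit_transform(self, features, labels, groups=None) -> np.ndarray:
        return self.fit(features, labels, groups).transform(features)

    # -- plain-text serialization ------------------------------------------

    def to_dict(self) -> dict:
        return {
            "config": {
                "rule": self.rule,
                "signed_correlation": self.signed_correlation,
                "curve_stride": self.curve_stride,
                "evaluator": {
                    "n_folds": self.evaluator.n_folds,
                    "seed": self.evaluator.seed,
                    "c": self.evaluator.c,
                    "gamma": self.evaluator.gamma,
                    "standardize": self.evaluator.standardize,
                },
            },
            "feature_ids": self.feature_ids_,
            "stage1": {
                "deletion_order": self.stage1_.deletion_order,
                "curve_sizes": self.stage1_.curve_sizes,
                "curve_accuracy": self.stage1_.curve_accuracy,
                "m": self.stage1_.m,
                "selected": self.stage1_.selected,
            },
            "stage2": {
                "center": self.stage2_.center.tolist(),
                "eigenvalues": self.stage2_.eigenvalues.tolist(),
                "basis": self.stage2_.basis.tolist(),
                "curve_ranks": self.stage2_.curve_ranks,
                "curve_accuracy": self.stage2_.curve_accuracy,
                "k": self.stage2_.k,
            },
        }

    def save(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "ATD":
        with open(path) as fh:
            d = json.load(fh)
        cfg = d["config"]
        ev = AccuracyEvaluator(**cfg["evaluator"])
        obj = cls(evaluator=ev, rule=cfg["rule"],
                  signed_correlation=cfg["signed_correlation"],
                  curve_stride=cfg["curve_stride"])
        obj.feature_ids_ = d["feature_ids"]
        s1 = d["stage1"]
        obj.stage1_ = Stage1Result(
            deletion_order=s1["deletion_order"], curve_sizes=s1["curve_sizes"],
            curve_accuracy=s1["curve_accuracy"], m=s1["m"],
            selected=s1["selected"])
        s2 = d["stage2"]
        obj.stage2_ = Stage2Result(
            center=np.array(s2["center"]),
            eigenvalues=np.array(s2["eigenvalues"]),
            basis=np.array(s2["basis"]),
            curve_ranks=s2["curve_ranks"], curve_accuracy=s2["curve_accuracy"],
            k=s2["k"])
        obj.selected_ids_ = [obj.feature_ids_[i] for i in obj.stage1_.selected]
        obj.m_ = obj.stage1_.m
        obj.k_ = obj.stage2_.k
        return obj


def fit_atd(features, labels, evaluator: AccuracyEvaluator | None = None,
            **kwargs) -> ATD:
    """Functional wrapper: fit an :class:`ATD` selector."""
    return ATD(evaluator=evaluator, **kwargs).fit(features, labels)


def transform_atd(model: ATD, features) -> np.ndarray:
    return model.transform(features)
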