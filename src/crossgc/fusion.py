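"""Accuracy/size-weighted fusion of the per-measure feature blocks.

Each block i (SS, CS, SC, CC after ATD) gets a scalar weight

    w_i = p_i * R_i + (1 - p_i) * (1 - N_i / N_all),

trading its standalone accuracy R_i against its share of the total feature
count N_i / N_all; p_i in [0, 1] is searched on a 0.05 grid.  The fused
matrix is the horizontal concatenation of the blocks with every column of
block i scaled by w_i (blocks of different widths cannot be summed
elementwise, and column scaling is exactly how a block's influence on a
margin classifier is controlled).  Columns are standardized with
training-set statistics *before* weighting so the weights are the sole
importance control.
"""

from __future__ import annotations

import itertools
import json
import os
from dataclasses import dataclass, field

import numpy as np

from .evaluate import AccuracyEvaluator


def block_weight(p: float, accuracy: float, n_features: int, n_all: int) -> float:
    """Weight of one block given its trade-off parameter p."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError(f"accuracy must be in [0, 1], got {accuracy}")
    if n_features <= 0:
        raise ValueError("block must have at least one feature")
    if n_features > n_all:
        raise ValueError(f"block size {n_features} exceeds total {n_all}")
    return p * accuracy + (1.0 - p) * (1.0 - n_features / n_all)


@dataclass
class BlockSummary:
    """One post-ATD feature block with its standalone accuracy."""

    name: str
    features: np.ndarray  # samples x N_i
    accuracy: float

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim == 1:
            self.features = self.features[:, None]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]


@dataclass
class FusionModel:
    """Optimized per-block weights plus the statistics to apply them."""

    block_names: list[str]
    p: list[float]
    weights: list[float]
    accuracies: list[float]
    sizes: list[int]
    n_all: int
    achieved_accuracy: float
    standardize: bool = True
    column_means: list[np.ndarray] = field(default_factory=list)
    column_scales: list[np.ndarray] = field(default_factory=list)

    @property
    def q(self) -> list[float]:
        return [1.0 - pi for pi in self.p]

    def to_dict(self) -> dict:
        return {
            "block_names": self.block_names,
            "p": self.p,
            "weights": self.weights,
            "accuracies": self.accuracies,
            "sizes": self.sizes,
            "n_all": self.n_all,
            "achieved_accuracy": self.achieved_accuracy,
            "standardize": self.standardize,
            "column_means": [m.tolist() for m in self.column_means],
            "column_scales": [s.tolist() for s in self.column_scales],
        }

    def save(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "FusionModel":
        with open(path) as fh:
            d = json.load(fh)
        d["column_means"] = [np.array(m) for m in d["column_means"]]
        d["column_scales"] = [np.array(s) for s in d["column_scales"]]
        return cls(**d)

    def apply(self, block_features) -> np.ndarray:
        """Fuse new per-block matrices with the fitted scalers and weights."""
        mats = []
        for i, X in enumerate(block_features):
            X = np.asarray(X, dtype=float)
            if self.standardize:
                X = (X - self.column_means[i]) / self.column_scales[i]
            mats.append(self.weights[i] * X)
        return np.hstack(mats)


def _fit_scalers(blocks) -> tuple[list[np.ndarray], list[np.ndarray]]:
    means, scales = [], []
    for b in blocks:
        mu = b.features.mean(axis=0)
        sd = b.features.std(axis=0)
        sd[sd == 0] = 1.0
        means.append(mu)
        scales.append(sd)
    return means, scales


def fuse(blocks, weights, standardize: bool = True,
         scalers=None) -> np.ndarray:
    """Weighted concatenation of block feature matrices.

    ``scalers`` (means, scales) may be supplied to reuse training-set
    statistics; otherwise they are computed from the given blocks.
    """
    blocks = list(blocks)
    weights = list(weights)
    if len(weights) != len(blocks):
        raise ValueError("one weight per block required")
    n_rows = {b.features.shape[0] for b in blocks}
    if len(n_rows) != 1:
        raise ValueError(f"blocks have mismatched sample counts: {sorted(n_rows)}")
    if standardize:
        means, scales = scalers if scalers is not None else _fit_scalers(blocks)
    mats = []
    for i, b in enumerate(blocks):
        X = b.features
        if standardize:
            X = (X - means[i]) / scales[i]
        mats.append(weights[i] * X)
    return np.hstack(mats)


def _weights_for(p_vec, blocks, n_all) -> list[float]:
    return [block_weight(p, b.accuracy, b.n_features, n_all)
            for p, b in zip(p_vec, blocks)]


def optimize_fusion(blocks, labels, evaluator: AccuracyEvaluator,
                    search: str = "coordinate", step: float = 0.05,
                    standardize: bool = True, groups=None,
                    max_sweeps: int = 5) -> FusionModel:
    """Grid search of the per-block trade-off parameters p_i.

    ``search="joint"`` enumerates the full grid (21^B points at the default
    step); ``"coordinate"`` starts from the all-p=1 cascade point and
    optimizes one p_i at a time, cycling until no change.  Both are
    deterministic given the evaluator seed; ties prefer a smaller sum of
    p_i, then the lexicographically smaller vector.  The returned optimum
    is never worse than the all-p=1 cascade point, which is always scored.
    """
    blocks = list(blocks)
    if len(blocks) < 1:
        raise ValueError("need at least one block")
    n_all = sum(b.n_features for b in blocks)
    grid = np.round(np.arange(0.0, 1.0 + step / 2, step), 10)
    if grid[-1] != 1.0:
        grid = np.append(grid, 1.0)
    scalers = _fit_scalers(blocks) if standardize else None
    labels = np.asarray(labels)
    cache: dict[tuple, float] = {}

    def score(p_vec: tuple) -> float:
        if p_vec not in cache:
            w = _weights_for(p_vec, blocks, n_all)
            fused = fuse(blocks, w, standardize=standardize, scalers=scalers)
            cache[p_vec] = evaluator.evaluate(fused, labels, groups)
        return cache[p_vec]

    def better(cand: tuple, acc_c: float, best: tuple, acc_b: float) -> bool:
        if acc_c != acc_b:
            return acc_c > acc_b
        if sum(cand) != sum(best):
            return sum(cand) < sum(best)
        return cand < best

    ones = tuple(1.0 for _ in blocks)
    best_p, best_acc = ones, score(ones)
    if search == "joint":
        for p_vec in itertools.product(grid, repeat=len(blocks)):
            acc = score(p_vec)
            if better(p_vec, acc, best_p, best_acc):
                best_p, best_acc = p_vec, acc
    elif search == "coordinate":
        for _ in range(max_sweeps):
            changed = False
            for i in range(len(blocks)):
                for val in grid:
                    cand = best_p[:i] + (float(val),) + best_p[i + 1:]
                    acc = score(cand)
                    if better(cand, acc, best_p, best_acc):
                        best_p, best_acc = cand, acc
                        changed = True
            if not changed:
                break
    else:
        raise ValueError(f"unknown search mode {search!r}")

    weights = _weights_for(best_p, blocks, n_all)
    return FusionModel(
        block_names=[b.name for b in blocks],
        p=[float(v) for v in best_p],
        weights=[float(w) for w in weights],
        accuracies=[b.accuracy for b in blocks],
        sizes=[b.n_features for b in blocks],
        n_all=n_all,
        achieved_accuracy=best_acc,
        standardize=standardize,
        column_means=scalers[0] if scalers else [],
        column_scales=scalers[1] if scalers else [],
    )
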