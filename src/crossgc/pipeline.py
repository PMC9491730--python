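"""End-to-end orchestration: labels, evaluation protocol, reports, sweeps.

The full chain is segment -> band extraction -> hemisphere split -> GC
measure tables -> per-block ATD -> weighted fusion -> SVM, evaluated over
stratified grouped train/test resplits.  Windows cut from one trial share
its label and are kept on the same side of every split (sibling windows
are near-duplicates; separating them would leak).  All selector fitting
(ATD curves, fusion grid) happens strictly inside the training portion.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .atd import ATD
from .evaluate import AccuracyEvaluator
from .fusion import BlockSummary, optimize_fusion
from .gc_core import GCParams
from .measures import KINDS, assemble_feature_table
from .preprocess import extract_bands, segment, split_hemispheres
from .synthetic import SynthConfig, generate_dataset

log = logging.getLogger("crossgc")

EMOTION_CLASSES = ("LALV", "HALV", "LAHV", "HAHV")


def map_labels(valence: float, arousal: float) -> str:
    """Quadrant class from 1-9 valence/arousal scores, threshold 5.

    Scores strictly above 5 are "high"; 5 or below is "low".
    """
    for name, score in (("valence", valence), ("arousal", arousal)):
        if not 1 <= score <= 9:
            raise ValueError(f"{name} score {score} outside the 1-9 scale")
    a = "H" if arousal > 5 else "L"
    v = "H" if valence > 5 else "L"
    return f"{a}A{v}V"


@dataclass(frozen=True)
class PipelineConfig:
    """Every knob of the end-to-end run; seeded and fully deterministic."""

    window_s: float = 3.0
    hop_s: float = 1.5
    band_method: str = "fir"
    kinds: tuple[str, ...] = KINDS
    adjacent_only: bool = True
    gc_order: int | None = 16
    gc_max_order: int = 20
    intercept: bool = True
    both_directions: bool = False
    atd_rule: str = "first"
    signed_correlation: bool = False
    curve_stride: int = 1
    fusion_search: str = "coordinate"
    fusion_step: float = 0.05
    standardize_fusion: bool = True
    inner_folds: int = 3
    outer_splits: int = 5
    outer_eval_splits: int | None = None
    group_by_trial: bool = True
    svm_c: float = 1.0
    svm_gamma: str | float = "scale"
    seed: int = 0

    def gc_params(self) -> GCParams:
        return GCParams(order=self.gc_order, max_order=self.gc_max_order,
                        intercept=self.intercept)

    def evaluator(self) -> AccuracyEvaluator:
        return AccuracyEvaluator(n_folds=self.inner_folds, seed=self.seed,
                                 c=self.svm_c, gamma=self.svm_gamma)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("kinds",):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SplitResult:
    test_accuracy: float
    block_accuracies: dict[str, float]
    post_atd_sizes: dict[str, int]
    fusion_p: dict[str, float]
    fusion_weights: dict[str, float]
    confusion: np.ndarray


@dataclass
class PipelineReport:
    classes: list[str]
    mean_accuracy: float
    split_accuracies: list[float]
    pre_atd_counts: dict[str, int]
    splits: list[SplitResult]
    confusion: np.ndarray
    n_samples: int

    def summary(self) -> str:
        lines = [
            f"samples: {self.n_samples}  classes: {', '.join(self.classes)}",
            "pre-ATD feature counts: "
            + ", ".join(f"{k}={v}" for k, v in self.pre_atd_counts.items()),
            f"held-out accuracy: {self.mean_accuracy:.4f} over "
            f"{len(self.split_accuracies)} split(s) "
            f"({', '.join(f'{a:.4f}' for a in self.split_accuracies)})",
        ]
        if self.splits:
            s = self.splits[0]
            lines.append("post-ATD sizes (split 1): "
                         + ", ".join(f"{k}={v}" for k, v in s.post_atd_sizes.items()))
            lines.append("fusion weights (split 1): "
                         + ", ".join(f"{k}={w:.3f}" for k, w in s.fusion_weights.items()))
        lines.append("confusion matrix (rows=true):")
        lines.append(str(self.confusion))
        return "\n".join(lines)


def prepare_feature_tables(dataset, config: PipelineConfig):
    """Segment, band-decompose and compute the per-kind GC feature tables.

    Returns (tables, labels, groups): DataFrames per kind, a label Series,
    and the per-sample trial ids used for grouped splitting.
    """
    samples = []
    groups = []
    for rec, label in dataset:
        for win in segment(rec, config.window_s, config.hop_s):
            bs = extract_bands(win, method=config.band_method)
            bs.label = label
            samples.append((bs, label))
            groups.append(rec.trial_id)
    if not samples:
        raise ValueError("dataset produced no windows")
    partition = split_hemispheres(dataset[0][0].channel_names)
    log.info("computing GC tables for %d windows, kinds=%s",
             len(samples), config.kinds)
    tables, labels = assemble_feature_table(
        samples, partition, kinds=config.kinds,
        adjacent_only=config.adjacent_only, params=config.gc_params(),
        both_directions=config.both_directions)
    return tables, labels, np.asarray(groups)


def _outer_splits(y, groups, config: PipelineConfig):
    if config.group_by_trial:
        splitter = StratifiedGroupKFold(n_splits=config.outer_splits,
                                        shuffle=True, random_state=config.seed)
        folds = splitter.split(np.zeros(len(y)), y, groups)
    else:
        splitter = StratifiedKFold(n_splits=config.outer_splits, shuffle=True,
                                   random_state=config.seed)
        folds = splitter.split(np.zeros(len(y)), y)
    folds = list(folds)
    if config.outer_eval_splits is not None:
        folds = folds[:config.outer_eval_splits]
    return folds


def fit_split(tables, labels, groups, train_idx, config: PipelineConfig):
    """Fit ATD per block and the fusion model on one training portion."""
    evaluator = config.evaluator()
    y = np.asarray(labels)
    blocks, models = [], {}
    for kind in config.kinds:
        X = tables[kind].iloc[train_idx]
        atd = ATD(evaluator=evaluator, rule=config.atd_rule,
                  signed_correlation=config.signed_correlation,
                  curve_stride=config.curve_stride)
        atd.fit(X, y[train_idx], groups=groups[train_idx])
        Z = atd.transform(X)
        acc = evaluator.evaluate(Z, y[train_idx], groups=groups[train_idx])
        blocks.append(BlockSummary(name=kind, features=Z, accuracy=acc))
        models[kind] = atd
        log.info("  %s: %d -> %d features, standalone accuracy %.3f",
                 kind, X.shape[1], Z.shape[1], acc)
    fusion = optimize_fusion(blocks, y[train_idx], evaluator,
                             search=config.fusion_search,
                             step=config.fusion_step,
                             standardize=config.standardize_fusion,
                             groups=groups[train_idx])
    return models, blocks, fusion


def run_pipeline(dataset, config: PipelineConfig = PipelineConfig()) -> PipelineReport:
    """Execute the full chain and evaluate on held-out trials.

    ``dataset`` is a list of (Recording, label) pairs or a
    :class:`~crossgc.synthetic.SynthConfig` to generate one.
    """
    if isinstance(dataset, SynthConfig):
        dataset = generate_dataset(dataset)
    tables, labels, groups = prepare_feature_tables(dataset, config)
    return evaluate_tables(tables, labels, groups, config)


def evaluate_tables(tables, labels, groups,
                    config: PipelineConfig) -> PipelineReport:
    """Selector fitting, fusion and held-out scoring on precomputed tables."""
    y = np.asarray(labels)
    classes = sorted(np.unique(y))
    pre_counts = {k: int(t.shape[1]) for k, t in tables.items()}

    split_results: list[SplitResult] = []
    total_confusion = np.zeros((len(classes), len(classes)), dtype=int)
    for split_no, (train_idx, test_idx) in enumerate(
            _outer_splits(y, groups, config), start=1):
        log.info("outer split %d: %d train / %d test windows",
                 split_no, len(train_idx), len(test_idx))
        models, blocks, fusion = fit_split(tables, labels, groups, train_idx,
                                           config)
        fused_train = fusion.apply(
            [b.features for b in blocks])
        test_blocks = [models[k].transform(tables[k].iloc[test_idx])
                       for k in config.kinds]
        fused_test = fusion.apply(test_blocks)
        clf = config.evaluator().make_classifier()
        clf.fit(fused_train, y[train_idx])
        pred = clf.predict(fused_test)
        acc = float(np.mean(pred == y[test_idx]))
        conf = confusion_matrix(y[test_idx], pred, labels=classes)
        total_confusion += conf
        split_results.append(SplitResult(
            test_accuracy=acc,
            block_accuracies={b.name: b.accuracy for b in blocks},
            post_atd_sizes={b.name: b.n_features for b in blocks},
            fusion_p=dict(zip(fusion.block_names, fusion.p)),
            fusion_weights=dict(zip(fusion.block_names, fusion.weights)),
            confusion=conf,
        ))
        log.info("  held-out accuracy %.4f", acc)
    accs = [s.test_accuracy for s in split_results]
    return PipelineReport(
        classes=list(classes),
        mean_accuracy=float(np.mean(accs)),
        split_accuracies=accs,
        pre_atd_counts=pre_counts,
        splits=split_results,
        confusion=total_confusion,
        n_samples=len(y),
    )


def permutation_null(tables, labels, groups, config: PipelineConfig,
                     n_permutations: int = 100,
                     seed: int | None = None) -> np.ndarray:
    """Held-out accuracies of the classification stage under label shuffling.

    Trial labels are permuted at the group level (windows of one trial stay
    together), and the standardize+SVM classifier is refit on the cascade
    of the pre-ATD tables under the same stratified grouped resplits the
    pipeline uses for its observed statistic (mean over the same number of
    folds).  Under label exchange no selection step can add held-out
    signal, so this is the chance band for the pipeline's test accuracy.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    X = np.hstack([np.asarray(tables[k], dtype=float) for k in config.kinds])
    y = np.asarray(labels)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    group_label = {g: y[groups == g][0] for g in uniq}
    n_folds = (config.outer_eval_splits if config.outer_eval_splits is not None
               else config.outer_splits)
    out = []
    for i in range(n_permutations):
        perm = rng.permutation([group_label[g] for g in uniq])
        y_perm = np.array([perm[np.where(uniq == g)[0][0]] for g in groups])
        skf = StratifiedGroupKFold(n_splits=config.outer_splits, shuffle=True,
                                   random_state=int(rng.integers(2 ** 31)))
        accs = []
        for fold, (train_idx, test_idx) in enumerate(
                skf.split(X, y_perm, groups)):
            if fold >= n_folds:
                break
            clf = config.evaluator().make_classifier()
            clf.fit(X[train_idx], y_perm[train_idx])
            accs.append(clf.score(X[test_idx], y_perm[test_idx]))
        out.append(float(np.mean(accs)))
    return np.asarray(out)


def window_sweep(dataset, config: PipelineConfig, window_sizes) -> dict:
    """Re-run the pipeline per window size (hop = window / 2).

    Infeasible sizes (window longer than the shortest trial) are skipped
    with a warning.  Returns {window_s: {"accuracy": ..., "n_samples": ...}}.
    """
    if isinstance(dataset, SynthConfig):
        dataset = generate_dataset(dataset)
    min_dur = min(rec.duration_s for rec, _ in dataset)
    results: dict[float, dict] = {}
    for w in window_sizes:
        if w > min_dur:
            warnings.warn(
                f"window of {w} s exceeds the shortest trial ({min_dur} s); "
                "skipped", UserWarning, stacklevel=2)
            continue
        cfg = replace(config, window_s=float(w), hop_s=float(w) / 2.0)
        report = run_pipeline(dataset, cfg)
        results[float(w)] = {"accuracy": report.mean_accuracy,
                             "n_samples": report.n_samples}
    return results
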