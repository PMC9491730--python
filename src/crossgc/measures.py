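"""SS/CS/SC/CC Granger-causality adjacency structures and feature vectors.

Channels are grouped by hemisphere (L/R) and band (theta/alpha/beta/gamma).
A measure is a family of directed 14 x 14 blocks between two such groups:

* SS (same hemisphere, same frequency):   L(f)->L(f) and R(f)->R(f)
* CS (cross hemisphere, same frequency):  L(f)->R(f)
* SC (same hemisphere, cross frequency):  L(f1)->L(f2) and R(f1)->R(f2)
* CC (cross hemisphere, cross frequency): L(f1)->R(f2) and R(f1)->L(f2)

with f1 < f2 in band order for the cross-frequency kinds.  With 14
electrodes per hemisphere this yields 392 values per SS/SC/CC combination
and 196 per CS combination; SS keeps its degenerate same-channel diagonal
cells at the convention value 0 so the block dimensionality is preserved.
A ``both_directions`` switch adds the reverse blocks for users who want
every block read in both directions (doubling the counts).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gc_core import GCParams, _lag_matrix, select_order
from .preprocess import BAND_ORDER, BandSet, HemispherePartition

KINDS = ("SS", "CS", "SC", "CC")

#: Same-frequency combinations, one per band.
SAME_FREQ_COMBINATIONS = tuple((b, b) for b in BAND_ORDER)
#: Cross-frequency combinations, low band first.
CROSS_FREQ_COMBINATIONS = tuple(itertools.combinations(BAND_ORDER, 2))
#: Adjacent cross-frequency combinations retained by default.
ADJACENT_COMBINATIONS = (("theta", "alpha"), ("alpha", "beta"), ("beta", "gamma"))


@dataclass(frozen=True)
class MeasureKind:
    """One measure family applied to one band combination."""

    kind: str
    combination: tuple[str, str]

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown measure kind {self.kind!r}")
        f1, f2 = self.combination
        for f in (f1, f2):
            if f not in BAND_ORDER:
                raise ValueError(f"unknown band {f!r}")
        if self.kind in ("SS", "CS") and f1 != f2:
            raise ValueError(f"{self.kind} requires a same-frequency combination")
        if self.kind in ("SC", "CC"):
            if f1 == f2:
                raise ValueError(f"{self.kind} requires a cross-frequency combination")
            if BAND_ORDER.index(f1) > BAND_ORDER.index(f2):
                raise ValueError(
                    f"cross-frequency combination must be band-ordered low->high, "
                    f"got ({f1}, {f2})")

    def __str__(self) -> str:
        f1, f2 = self.combination
        return f"{self.kind}({f1}~{f2})" if f1 != f2 else f"{self.kind}({f1})"


def combinations_for(kind: str, adjacent_only: bool = False) -> list[MeasureKind]:
    """All band combinations of one kind, in canonical order."""
    if kind in ("SS", "CS"):
        combos = SAME_FREQ_COMBINATIONS
    else:
        combos = ADJACENT_COMBINATIONS if adjacent_only else CROSS_FREQ_COMBINATIONS
    return [MeasureKind(kind, c) for c in combos]


def count_gc_values(kind: str, electrodes_per_hemisphere: int) -> tuple[int, int]:
    """(values per combination, values over all combinations) for one kind."""
    if electrodes_per_hemisphere < 1:
        raise ValueError("electrodes_per_hemisphere must be >= 1")
    e2 = electrodes_per_hemisphere ** 2
    per = {"SS": 2 * e2, "CS": e2, "SC": 2 * e2, "CC": 2 * e2}[kind]
    n_comb = 4 if kind in ("SS", "CS") else 6
    return per, per * n_comb


def blocks_for(measure: MeasureKind,
               both_directions: bool = False) -> list[tuple[tuple[str, str], tuple[str, str]]]:
    """Directed (source group, target group) blocks of one measure.

    Groups are (hemisphere, band) pairs; block order is fixed so flattened
    feature vectors are bit-stable.
    """
    f1, f2 = measure.combination
    if measure.kind == "SS":
        blocks = [(("L", f1), ("L", f1)), (("R", f1), ("R", f1))]
    elif measure.kind == "CS":
        blocks = [(("L", f1), ("R", f1))]
    elif measure.kind == "SC":
        blocks = [(("L", f1), ("L", f2)), (("R", f1), ("R", f2))]
    else:  # CC
        blocks = [(("L", f1), ("R", f2)), (("R", f1), ("L", f2))]
    if both_directions and measure.kind != "SS":
        blocks = blocks + [(tgt, src) for src, tgt in blocks]
    return blocks


def group_label(group: tuple[str, str]) -> str:
    return f"{group[0]}({group[1]})"


@dataclass
class GCMeasureMatrix:
    """Computed directed GC blocks for one measure on one window."""

    measure: MeasureKind
    blocks: dict[tuple[tuple[str, str], tuple[str, str]], np.ndarray]
    partition: HemispherePartition
    both_directions: bool = False

    @property
    def value_count(self) -> int:
        return sum(b.size for b in self.blocks.values())

    def block_order(self):
        return blocks_for(self.measure, self.both_directions)


@dataclass
class FeatureVector:
    """Flattened measure matrix with a bijective cell index."""

    values: np.ndarray
    index: list[tuple[str, str, str, str]]  # (src group, src ch, tgt group, tgt ch)

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# fast cached engine

class _TargetCache:
    """Orthonormalized own-past design and univariate fit for one target.

    Band-limited components have nearly collinear lag columns, so the
    engine works with a QR basis of the design rather than normal
    equations: residual sums of squares are computed as norm deficits,
    which is numerically equivalent to a least-squares solve on the raw
    design.
    """

    __slots__ = ("order", "y", "q", "yty", "rss_uni")

    def __init__(self, series: np.ndarray, order: int, intercept: bool):
        trim = order
        self.order = order
        self.y = series[trim:]
        z = _lag_matrix(series, order, trim)
        n_eff = len(self.y)
        cols = [z]
        if intercept:
            cols.insert(0, np.ones((n_eff, 1)))
        self.q, _ = np.linalg.qr(np.hstack(cols))
        self.yty = float(self.y @ self.y)
        qty = self.q.T @ self.y
        self.rss_uni = max(self.yty - float(qty @ qty), 0.0)

    @property
    def rel_residual(self) -> float:
        return self.rss_uni / self.yty if self.yty > 0 else 0.0


class GCEngine:
    """Computes directed GC values over a BandSet with shared caches.

    ``order`` is a cap: a heavily oversampled narrow band (e.g. theta at
    128 Hz) is numerically perfectly predicted by its own past at high
    order, leaving no residual variance for a causality ratio, so per
    target series the engine uses the largest order <= cap whose
    univariate fit keeps a relative residual above ``residual_floor``.
    Per-series caches are shared across cells; results agree with
    :func:`granger_pair` to round-off wherever the pair is well
    conditioned (asserted in the test-suite).
    """

    def __init__(self, bandset: BandSet, order: int, intercept: bool = True,
                 residual_floor: float = 1e-8):
        if order < 1:
            raise ValueError("order must be >= 1")
        n = bandset.n_samples
        if n <= 3 * order:
            raise ValueError(
                f"windows of {n} samples too short for order={order}")
        self.bandset = bandset
        self.order = order
        self.intercept = intercept
        self.residual_floor = residual_floor
        self._targets: dict[tuple[str, str], _TargetCache] = {}
        self._lags: dict[tuple[str, str, int], np.ndarray] = {}

    def _component(self, channel: str, band: str) -> np.ndarray:
        x = self.bandset.get(channel, band)
        if np.ptp(x) == 0:
            raise ValueError(
                f"component ({channel}, {band}) is constant; "
                "autoregressive design is singular")
        return x

    def target_cache(self, channel: str, band: str) -> _TargetCache:
        key = (channel, band)
        if key not in self._targets:
            x = self._component(channel, band)
            cache = _TargetCache(x, self.order, self.intercept)
            if cache.rel_residual < self.residual_floor:
                lo, hi = 1, self.order  # largest well-posed order in [1, cap]
                while lo < hi:
                    mid = (lo + hi + 1) // 2
                    if _TargetCache(x, mid, self.intercept).rel_residual \
                            >= self.residual_floor:
                        lo = mid
                    else:
                        hi = mid - 1
                cache = _TargetCache(x, lo, self.intercept)
            self._targets[key] = cache
        return self._targets[key]

    def _source_lags(self, channel: str, band: str, order: int) -> np.ndarray:
        key = (channel, band, order)
        if key not in self._lags:
            x = self._component(channel, band)
            self._lags[key] = _lag_matrix(x, order, order)
        return self._lags[key]

    def f_value(self, source: tuple[str, str], target: tuple[str, str]) -> float:
        """F_{source -> target} for (channel, band) component pairs."""
        if source == target:
            return 0.0
        t = self.target_cache(*target)
        if t.rss_uni <= 0.0 or t.rel_residual < self.residual_floor:
            return 0.0
        b = self._source_lags(*source, t.order)
        col_norms = np.linalg.norm(b, axis=0)
        # project source lags out of the target's own-past column space,
        # with one reorthogonalization pass for stability
        for _ in range(2):
            b = b - t.q @ (t.q.T @ b)
        keep = np.linalg.norm(b, axis=0) > 1e-9 * np.maximum(col_norms, 1e-300)
        if not keep.any():
            return 0.0
        qb, _ = np.linalg.qr(b[:, keep])
        qty = qb.T @ t.y
        rss_biv = max(t.rss_uni - float(qty @ qty),
                      self.residual_floor ** 2 * t.yty)
        return float(np.log(t.rss_uni / rss_biv))


def _resolve_order(bandset: BandSet, partition: HemispherePartition,
                   measure: MeasureKind, params: GCParams) -> int:
    if params.order is not None:
        return params.order
    # representative pair: first electrode pair, the measure's first block
    (src_grp, tgt_grp) = blocks_for(measure)[0]
    src_ch = (partition.left if src_grp[0] == "L" else partition.right)[0]
    tgt_ch = (partition.left if tgt_grp[0] == "L" else partition.right)[0]
    if (src_ch, src_grp[1]) == (tgt_ch, tgt_grp[1]):
        tgt_ch = (partition.left if tgt_grp[0] == "L" else partition.right)[1]
    return select_order(bandset.get(src_ch, src_grp[1]),
                        bandset.get(tgt_ch, tgt_grp[1]),
                        params.max_order, params.intercept)


def compute_measure(bandset: BandSet, partition: HemispherePartition,
                    measure: MeasureKind, params: GCParams = GCParams(order=8),
                    both_directions: bool = False) -> GCMeasureMatrix:
    """All directed GC blocks of one measure on one band-decomposed window.

    With ``params.order=None`` a common order is chosen by BIC on one
    representative channel pair of the measure and reused for every cell
    (per-cell selection would make cells incomparable and is far costlier).
    """
    for band in measure.combination:
        if band not in bandset.components:
            raise ValueError(f"BandSet lacks band {band!r} needed by {measure}")
    for name in partition.left + partition.right:
        if name not in bandset.channel_names:
            raise ValueError(f"BandSet lacks channel {name!r}")
    order = _resolve_order(bandset, partition, measure, params)
    engine = GCEngine(bandset, order, params.intercept)
    hemi = {"L": partition.left, "R": partition.right}
    blocks: dict = {}
    for src_grp, tgt_grp in blocks_for(measure, both_directions):
        src_names = hemi[src_grp[0]]
        tgt_names = hemi[tgt_grp[0]]
        e = len(src_names)
        block = np.zeros((e, len(tgt_names)))
        for i, sc in enumerate(src_names):
            for j, tc in enumerate(tgt_names):
                block[i, j] = engine.f_value((sc, src_grp[1]), (tc, tgt_grp[1]))
        blocks[(src_grp, tgt_grp)] = block
    return GCMeasureMatrix(measure=measure, blocks=blocks, partition=partition,
                           both_directions=both_directions)


def flatten(matrix: GCMeasureMatrix) -> FeatureVector:
    """Deterministic row-major flattening with cell descriptors."""
    hemi = {"L": matrix.partition.left, "R": matrix.partition.right}
    values: list[float] = []
    index: list[tuple[str, str, str, str]] = []
    for key in matrix.block_order():
        src_grp, tgt_grp = key
        block = matrix.blocks[key]
        src_names = hemi[src_grp[0]]
        tgt_names = hemi[tgt_grp[0]]
        for i, sc in enumerate(src_names):
            for j, tc in enumerate(tgt_names):
                values.append(block[i, j])
                index.append((group_label(src_grp), sc, group_label(tgt_grp), tc))
    return FeatureVector(values=np.asarray(values), index=index)


def feature_names(measure: MeasureKind, partition: HemispherePartition,
                  both_directions: bool = False) -> list[str]:
    """Stable column names: kind|combination|src group:ch->tgt group:ch."""
    hemi = {"L": partition.left, "R": partition.right}
    names = []
    for src_grp, tgt_grp in blocks_for(measure, both_directions):
        for sc in hemi[src_grp[0]]:
            for tc in hemi[tgt_grp[0]]:
                names.append(f"{measure}|{group_label(src_grp)}:{sc}->"
                             f"{group_label(tgt_grp)}:{tc}")
    return names


def assemble_feature_table(samples, partition: HemispherePartition,
                           kinds=KINDS, adjacent_only: bool = True,
                           params: GCParams = GCParams(order=8),
                           both_directions: bool = False):
    """Per-kind sample x feature matrices over a band-decomposed dataset.

    ``samples`` is a sequence of (BandSet, label) pairs in sample order.
    For each kind the band combinations are concatenated horizontally
    (SS/CS: all four bands; SC/CC: the six cross pairs, or the three
    adjacent ones when ``adjacent_only``).  Returns (tables, labels) where
    ``tables`` maps kind -> DataFrame indexed by sample id and ``labels``
    is a Series aligned with the rows.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("no samples")
    lengths = {bs.n_samples for bs, _ in samples}
    if len(lengths) != 1:
        raise ValueError(
            f"inconsistent window lengths across samples: {sorted(lengths)}")
    sample_ids = []
    for bs, _ in samples:
        sid = f"{bs.trial_id}@{bs.window_start_s:g}s"
        sample_ids.append(sid)
    if len(set(sample_ids)) != len(sample_ids):
        sample_ids = [f"s{i:05d}" for i in range(len(samples))]
    labels = pd.Series([lab for _, lab in samples], index=sample_ids, name="label")

    tables: dict[str, pd.DataFrame] = {}
    for kind in kinds:
        measures = combinations_for(kind, adjacent_only)
        cols: list[str] = []
        for m in measures:
            cols.extend(feature_names(m, partition, both_directions))
        data = np.empty((len(samples), len(cols)))
        for row, (bs, _) in enumerate(samples):
            offset = 0
            for m in measures:
                fv = flatten(compute_measure(bs, partition, m, params,
                                             both_directions))
                data[row, offset:offset + len(fv)] = fv.values
                offset += len(fv)
        tables[kind] = pd.DataFrame(data, index=sample_ids, columns=cols)
    return tables, labels
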