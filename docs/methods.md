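# Methods

`crossgc` implements a directed-connectivity feature pipeline for
multichannel scalp recordings: pairwise Granger causality (GC) between
hemisphere x frequency channel groups, adaptive two-stage decorrelation
(ATD) of the resulting feature tables, and accuracy/size-weighted fusion
of the per-measure blocks, feeding an RBF-kernel SVM.  This note records
the model assumptions, the numerical choices, and what the synthetic
benchmark does and does not demonstrate.

## Pairwise Granger causality

For two scalar series X, Y, four regressions are fit by ordinary least
squares on the same trimmed sample at a common autoregressive order L:
each series on its own past (univariate), and each series on both pasts
(bivariate).  The causality from X to Y is

    F_{X->Y} = ln( sigma^2[Y | Y_past] / sigma^2[Y | Y_past, X_past] ),

the log-ratio of restricted to unrestricted residual variances, and
symmetrically for Y to X.  Because the models are nested and fit on the
same sample, F >= 0 up to round-off; small negative values from
near-singular fits are floored at zero with a warning.  An intercept is
included by default (configurable); F is invariant to affine rescaling of
either series.

**Order selection.** `select_order` minimises the bivariate model's BIC
over 1..max_order (default cap 20), with all candidates scored on the
sample trimmed at max_order so likelihoods are comparable; ties break
low.  One common order per pair is used for all four regressions — the
log-ratio is only an interpretable nested comparison at a common order.

**Degenerate fits.** A band-limited component sampled far above its
bandwidth (e.g. a 4–8 Hz component at 128 Hz) is numerically *perfectly*
predicted by its own past once L is large enough: the univariate relative
residual falls to ~1e-14 and the causality ratio becomes 0/0 noise.  BIC
does not protect against this — such components have no innovation floor,
so BIC keeps increasing L.  Two guards are used:

* `granger_pair` returns 0 for a direction whose univariate residual
  variance is below 1e-12 of the target's mean square (machine-precision
  fit: nothing left to attribute);
* the batch engine treats the configured order as a *cap* and, per target
  series, uses the largest L <= cap whose univariate relative residual
  stays above 1e-8 (binary search).  At 128 Hz this typically keeps
  L = cap for beta/gamma targets and lowers theta/alpha targets to ~5.

The batch engine computes residual sums of squares on a QR basis of the
lag design (norm deficits, one reorthogonalization pass) rather than by
normal equations: narrowband lag columns are nearly collinear and the
squared condition number of a Gram matrix destroys the estimate.  The QR
path agrees with the reference `granger_pair` to round-off wherever the
pair is well conditioned (asserted in the tests).

## Measures over hemisphere x frequency groups

Channels are the 14 symmetric left/right pairs of the 10–20 montage
(midline Fz/Cz/Pz/Oz excluded); bands are theta 4–8, alpha 8–12, beta
12–30, gamma 30–45 Hz.  The four measure families and their directed
14 x 14 blocks are

| kind | blocks                                | values per combination |
|------|---------------------------------------|------------------------|
| SS   | L(f)->L(f), R(f)->R(f)                | 2·14² = 392            |
| CS   | L(f)->R(f)                            | 14² = 196              |
| SC   | L(f1)->L(f2), R(f1)->R(f2)            | 392                    |
| CC   | L(f1)->R(f2), R(f1)->L(f2)            | 392                    |

with f1 < f2 in band order for the cross-frequency kinds; "adjacent"
means {theta–alpha, alpha–beta, beta–gamma}.  SS keeps its degenerate
same-channel diagonal at the convention value 0 so block dimensionality
is preserved (constant columns are later removed by ATD).  A
`both_directions` switch adds the reverse blocks for users who want every
pair read both ways; it doubles the counts and is off by default.
Flattening is block order then row-major, with a bijective cell index, so
feature columns are bit-stable.

## Band extraction

Default: zero-phase forward–backward FIR band-pass per band, filter
length targeting a 1.5 Hz transition but capped by the window length
(a 3 s window at 128 Hz gives ≈127 taps, ~1.7 Hz transitions).  A
rectangular spectral mask (`method="stft"`) is available behind a config
switch.  Both are linear and deterministic.  Zero-phase filtering keeps
windows time-aligned but smears a lagged dependence over the filter
width — one reason the default GC order cap is generous (16).

## Synthetic data

Each channel is a sum of four independent narrowband oscillators (white
noise through a zero-phase FIR with ~2 Hz transitions, normalised to unit
variance) plus white sensor noise (sd 0.2).  A coupling adds
`gain x (source band component delayed by lag)` to the target channel's
target-band component, optionally only for certain class labels.
Injection at component level makes ground truth exactly the quantity the
measures estimate.  Defaults: 28 paired channels, 128 Hz, 60 s trials.

Because the coupling is linear, a cross-band copy carries *source-band*
energy: after the broadband mixture is re-filtered downstream, the
coupling is visible only through the spectral overlap of the two band
filters at their shared edge.  Adjacent pairs (the ~2 Hz oscillator
transition plus the ~1.7 Hz analysis transition around e.g. 30 Hz for
beta–gamma) therefore carry a recoverable cross-frequency signal, distant
pairs essentially none — mirroring how cross-frequency effects
concentrate at neighbouring rhythms.  Consequences verified in the tests:

* on the *generated components* a coupling produces large F (the source's
  lagged value enters the target exactly), and F is strictly increasing
  in gain while the injected term is small; once it dominates the target,
  restricted and unrestricted residuals scale together and F saturates
  (~1.9 for the beta->gamma scenario), so the monotonicity property is
  asserted over gains 0–0.2;
* reverse-direction F is small but not exactly zero: the coupled target
  is a noisy window into source lags deeper than the AR order; the tests
  assert directional dominance (reverse < 0.2 x forward);
* after mixing and re-extraction on 3 s windows the coupled cell's F is
  modest (~0.08 vs a ~0.015 null at order 16) — a realistic effect size
  for the classification benchmark rather than a giveaway.

The generator does not emulate ocular/muscle artifacts, volume
conduction, 1/f background, or nonstationarity; passing tests show the
pipeline recovers *linear lagged band-to-band structure*, not that it
handles real recordings' confounds.

## ATD

Stage 1 computes the Pearson correlation matrix of the feature columns
once (constant columns get r = 0 and are flagged), then repeatedly takes
the maximum-|r| entry of the lower triangle among the survivors and
deletes the first member of the pair (the survivor submatrix is taken
from the original matrix — no recomputation drift).  All four deletion
rules described in the field (first, second, random, most-correlated) are
available; they perform near-identically, so the simplest is the
default.  Absolute correlation is used because an anti-correlated feature
is equally redundant; a `signed_correlation` flag restores the literal
reading.  Accuracy after each deletion is scored by stratified inner
cross-validation (grouped by trial) of a standardize+SVM classifier on
the training split only; the retained size m is the curve argmax, ties
toward fewer features.

Stage 2 centers the m survivors, eigendecomposes their covariance
(1/(n-1)), scores the projection onto the top-p eigenvectors for each p,
and keeps the argmax rank k (ties toward fewer).  The fitted selector
(ids, means, basis) is applied unchanged to new data.

With M up to ~1600, scoring every subset size costs O(M) classifier
fits.  `curve_stride` s scores every s-th size and then locates the
argmax to ±1 by bracket refinement (halving steps), O(M/s + log s) fits.
The default is 1 (exact curve); the large built-in studies use s = 8.

## Fusion

Block i (a post-ATD measure family) gets weight
w_i = p_i R_i + (1-p_i)(1 - N_i/N_all), trading standalone accuracy
against feature-count share; p_i is searched on a 0.05 grid.  Blocks of
different widths cannot be summed elementwise, so "weighted sum" is
realised as weighted concatenation: columns are standardized with
training statistics *first* (so w_i is the sole importance control on a
margin classifier), then scaled by w_i and concatenated.  Joint search
enumerates the full grid (21^B points); the default coordinate search
starts at the all-p=1 cascade point and cycles (<= 5 sweeps), so the
returned optimum is never worse than the plain cascade.  Ties prefer
smaller sum of p, then the lexicographically smaller vector.

## Evaluation protocol

Labels follow the valence/arousal quadrant rule (score > 5 is high, <= 5
low).  Windows inherit their trial's label and *stay with their trial* on
every split — sibling windows overlap in time and would otherwise leak.
The outer protocol is stratified grouped 5-fold (each fold an 80/20
resplit); ATD and fusion are fitted inside each training portion only
(byte-identity under test-row deletion is asserted in the tests).
Classifier: RBF SVM, C = 1, gamma = 'scale', per-column standardization
fit on the training side.

**Permutation benchmark.** The chance band for held-out accuracy permutes
labels at trial level and refits the classification stage (standardize +
SVM on the pre-ATD cascade) under the same grouped resplits, averaging
the same number of folds as the observed statistic.  Refitting the full
selector stack inside every permutation would be disproportionate; under
label exchange a selection step cannot add held-out signal, so the
reduced null is valid for the test statistic.  Permutation tests need
enough exchangeable units: with 60 s trials, ~200 windows per class is
only 10 trials, and the null's upper tail is inflated by partial
relabelings that retain genuine signal.  The built-in recovery study
therefore uses 22 x 15 s trials per class (198 windows per class, 44
exchangeable units) — same data volume, statistically meaningful null.

## Problem sizes of the built-in studies

The end-to-end recovery study runs the CC measure over the three adjacent
band pairs (1176 features) on 198 windows per class, GC order cap 16,
ATD stride 8, two outer folds, and a 100-permutation null; the
zero-coupling control is identical with the coupling removed.  Unit and
property tests use reduced montages, shorter trials and coarser grids
chosen so each exercises its contract rather than data volume.

## Known limitations

* GC on band-limited, zero-phase-filtered signals is intrinsically
  fragile (filtering is non-causal and removes innovation); the adaptive
  order cap and degenerate-fit guards make the estimates stable, but
  absolute F values should be compared only within a block, not across
  bands with different effective orders.
* Linear lagged coupling cannot move energy across disjoint bands;
  non-adjacent cross-frequency measures on this generator are null by
  construction.  Phase–amplitude style nonlinear coupling is out of
  scope.
* The fusion weight grid treats block accuracies R_i as fixed inputs
  measured by inner CV; with few trials those estimates are noisy and the
  selected p_i inherit that noise.
* EDF input is not implemented; recordings enter via the documented CSV
  dialect or in memory.
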