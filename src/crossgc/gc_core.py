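"""Pairwise Granger causality by nested autoregressive least squares.

For two scalar series X and Y, a univariate model predicts each series from
its own past and a bivariate model adds the other series' past at the same
order L.  The causality from X to Y is the log-ratio of restricted to
unrestricted residual variances,

    F_{X->Y} = ln( sigma^2_Y|Y_past / sigma^2_Y|Y_past,X_past ),

and symmetrically for Y to X.  With both models fit by ordinary least
squares on the same trimmed sample at a common order, the models are
nested, so both F values are nonnegative up to round-off.  The common order
is selected by minimising the bivariate model's Bayesian information
criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

_NEG_TOL = 1e-10


@dataclass(frozen=True)
class GCParams:
    """Estimation settings for pairwise GC.

    order=None selects the order per pair by BIC over [1, max_order];
    an integer fixes it.  The intercept makes the fit insensitive to
    offsets; population GC is unchanged either way for zero-mean signals.
    """

    order: int | None = None
    max_order: int = 20
    intercept: bool = True


@dataclass
class VarFit:
    """OLS fit of one regression equation at order L."""

    order: int
    coefficients: np.ndarray
    residual_variance: float
    n_effective: int


@dataclass
class GCPair:
    """Both directed GC values for one series pair."""

    f_x_to_y: float
    f_y_to_x: float
    order_used: int
    n_used: int


def _lag_matrix(x: np.ndarray, order: int, trim: int) -> np.ndarray:
    """Columns x(t-1) ... x(t-order) for t = trim .. n-1."""
    return np.column_stack([x[trim - i:len(x) - i] for i in range(1, order + 1)])


def _ols(design: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return coef, float(resid @ resid)


def _check_series(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if not np.isfinite(x).all():
        raise ValueError(f"series {name} contains NaN or infinite values")
    if np.ptp(x) == 0:
        raise ValueError(
            f"series {name} is constant; the autoregressive design is singular")
    return x


def _fit_equation(target: np.ndarray, lag_blocks: list[np.ndarray],
                  intercept: bool) -> VarFit:
    n_eff = len(target)
    cols = lag_blocks if not intercept else [np.ones((n_eff, 1))] + lag_blocks
    design = np.hstack(cols)
    coef, rss = _ols(design, target)
    order = lag_blocks[0].shape[1]
    return VarFit(order=order, coefficients=coef,
                  residual_variance=rss / n_eff, n_effective=n_eff)


def select_order(x: np.ndarray, y: np.ndarray, max_order: int = 20,
                 intercept: bool = True) -> int:
    """Order of the bivariate model minimising BIC, ties broken low.

    All candidate orders are scored on the sample trimmed at ``max_order``
    so their likelihoods are comparable.
    """
    x = _check_series(x, "x")
    y = _check_series(y, "y")
    n = len(x)
    if len(y) != n:
        raise ValueError("series must have equal length")
    if n <= 3 * max_order:
        raise ValueError(
            f"series of length {n} too short for max_order={max_order}; "
            f"need more than {3 * max_order} samples")
    trim = max_order
    n_eff = n - trim
    xt, yt = x[trim:], y[trim:]
    best_order, best_bic = 1, np.inf
    for L in range(1, max_order + 1):
        zx = _lag_matrix(x, L, trim)
        zy = _lag_matrix(y, L, trim)
        fit_x = _fit_equation(xt, [zx, zy], intercept)
        fit_y = _fit_equation(yt, [zx, zy], intercept)
        k = 2 * (2 * L + int(intercept))
        with np.errstate(divide="ignore"):
            bic = n_eff * (np.log(fit_x.residual_variance)
                           + np.log(fit_y.residual_variance)) + k * np.log(n_eff)
        if bic < best_bic:
            best_order, best_bic = L, bic
    return best_order


def _floor_f(value: float, direction: str) -> float:
    if value < -_NEG_TOL:
        warnings.warn(
            f"negative GC value {value:.3e} for {direction} floored at 0 "
            "(near-singular fit)", RuntimeWarning, stacklevel=3)
    return max(value, 0.0)


def granger_pair(x: np.ndarray, y: np.ndarray, order: int | None = None,
                 params: GCParams = GCParams()) -> GCPair:
    """Directed GC between two series at a common autoregressive order.

    All four regressions are fit by OLS on the same trimmed sample.  A pair
    of identical arrays returns the self-pair convention value 0 for both
    directions (self-causality at the same band is degenerate).
    """
    xa = np.asarray(x, dtype=float).ravel()
    ya = np.asarray(y, dtype=float).ravel()
    if len(xa) != len(ya):
        raise ValueError("series must have equal length")
    if np.array_equal(xa, ya):
        L = order if order is not None else 1
        return GCPair(0.0, 0.0, order_used=L, n_used=len(xa))
    xa = _check_series(xa, "x")
    ya = _check_series(ya, "y")
    if order is None:
        order = params.order
    if order is None:
        order = select_order(xa, ya, params.max_order, params.intercept)
    n = len(xa)
    if n <= 3 * order:
        raise ValueError(
            f"series of length {n} too short for order={order}; "
            f"need more than {3 * order} samples")
    trim = order
    xt, yt = xa[trim:], ya[trim:]
    zx = _lag_matrix(xa, order, trim)
    zy = _lag_matrix(ya, order, trim)
    uni_x = _fit_equation(xt, [zx], params.intercept)
    uni_y = _fit_equation(yt, [zy], params.intercept)
    biv_x = _fit_equation(xt, [zx, zy], params.intercept)
    biv_y = _fit_equation(yt, [zx, zy], params.intercept)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_xy = float(np.log(uni_y.residual_variance / biv_y.residual_variance))
        f_yx = float(np.log(uni_x.residual_variance / biv_x.residual_variance))
    # an own-past fit at machine precision leaves no residual variance to
    # attribute; the causality ratio is then 0/0 noise -> convention 0
    if uni_y.residual_variance <= 1e-12 * float(np.mean(yt ** 2)):
        f_xy = 0.0
    if uni_x.residual_variance <= 1e-12 * float(np.mean(xt ** 2)):
        f_yx = 0.0
    return GCPair(
        f_x_to_y=_floor_f(f_xy, "x->y"),
        f_y_to_x=_floor_f(f_yx, "y->x"),
        order_used=order,
        n_used=n - trim,
    )
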