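"""Quadratic-plateau (smooth-join knot) regression on a variance series.

Model
-----
The within-subject variance is assumed to fall along a quadratic as the
operator learns, then hold constant once skill has stabilised:

    var(I) = a + b*I + c*I**2        for I <= K   (learning phase)
    var(I) = P                       for I >  K   (plateau)

with c > 0 and a *smooth join* at the knot K: the curve is continuous and
has zero slope there, which forces K to be the quadratic's vertex,

    K = -b / (2c),        P = a - b**2 / (4c).

Under this constraint the model has three free parameters and can be
rewritten around the knot as

    var(I) = P + c * (I - K)**2 * 1[I <= K],

which is linear in (P, c) for any fixed K.  Fitting is therefore a profile
search: ordinary least squares in (P, c) at each candidate K on an integer
grid, keeping the K with the smallest residual sum of squares, optionally
polished by a bounded continuous minimisation between its grid neighbours.
This is globally reliable -- no starting values, no local minima missed on
the grid resolution -- and is trivially checked against brute force.

Candidate solutions with c <= 0 (no decreasing limb) are discarded; if no
candidate supports a decreasing quadratic the fit degenerates to a flat
line at the mean variance and is flagged.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .errors import DomainError, InsufficientDataError
from .records import SubjectSummary

#: two candidate knots whose RSS differ by less than this are tied;
#: the smaller knot wins (the more conservative learning-curve claim).
RSS_TIE_TOL = 1e-10


@dataclass(frozen=True)
class QuadraticPlateauFit:
    """Fitted smooth-join quadratic-plateau model.

    ``a``, ``b``, ``c`` are the below-knot quadratic coefficients; ``knot``
    is the continuous plateau onset K, ``knot_index`` its half-away-from-
    zero rounding to an integer subject index, and ``plateau`` the constant
    variance beyond K.  ``degenerate`` marks fits where the data supported
    no decreasing quadratic limb and a flat line was returned instead.
    """

    a: float
    b: float
    c: float
    knot: float
    knot_index: int
    plateau: float
    rss: float
    n_subjects: int
    degenerate: bool = False
    weighted: bool = False

    def predict(self, index):
        """Evaluate the fitted curve at ``index`` (scalar or array)."""
        return predict(self, index)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def predict(fit: QuadraticPlateauFit, index):
    """Piecewise evaluation: quadratic at or below the knot, plateau above."""
    idx = np.asarray(index, dtype=float)
    if np.any(idx < 1):
        raise DomainError("subject index must be >= 1")
    below = fit.a + fit.b * idx + fit.c * idx**2
    out = np.where(idx <= fit.knot, below, fit.plateau)
    return float(out) if np.isscalar(index) else out


def knot_from_coefficients(a: float, b: float, c: float) -> tuple[float, float]:
    """Knot and plateau implied by below-knot coefficients under a smooth join.

    Returns ``(K, P)`` with ``K = -b/(2c)`` (the quadratic's vertex) and
    ``P = a - b**2/(4c)`` (its value there).  Requires ``c > 0``.
    """
    if not c > 0:
        raise DomainError(f"quadratic coefficient must be positive, got c={c}")
    knot = -b / (2.0 * c)
    plateau = a - b * b / (4.0 * c)
    return knot, plateau


def _profile_ols(
    index: np.ndarray, y: np.ndarray, knot: float, weights: Optional[np.ndarray]
) -> tuple[float, float, float]:
    """OLS in (P, c) at fixed knot.  Returns (P, c, rss); c may be <= 0."""
    x = np.where(index <= knot, (index - knot) ** 2, 0.0)
    design = np.column_stack([np.ones_like(x), x])
    if weights is not None:
        w = np.sqrt(weights)
        coef, *_ = np.linalg.lstsq(design * w[:, None], y * w, rcond=None)
        resid = (y - design @ coef) * w
    else:
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
    plateau, curv = float(coef[0]), float(coef[1])
    return plateau, curv, float(resid @ resid)


def fit_quadratic_plateau(
    summaries: Union[Sequence[SubjectSummary], np.ndarray],
    knot_grid: Optional[tuple[int, int]] = None,
    refine: bool = True,
    weights: Optional[np.ndarray] = None,
) -> QuadraticPlateauFit:
    """Fit the smooth-join quadratic-plateau model to a variance series.

    Parameters
    ----------
    summaries : sequence of SubjectSummary, or an (index, variance) array
        The within-subject variance series ordered by subject index.
    knot_grid : (lo, hi), optional
        Inclusive integer range of candidate knots.  Default: from the
        second-smallest to the second-largest index, so both segments are
        always supported by data.
    refine : bool
        Polish the winning integer knot by bounded continuous minimisation
        between its grid neighbours (default True).
    weights : array, optional
        Observation weights for weighted least squares (e.g. inverse
        sampling variances).  Default None: unweighted, every subject's
        variance estimate counts equally.

    Raises
    ------
    InsufficientDataError : fewer than 4 points.
    ValueError : non-finite variances or an invalid grid.
    """
    if isinstance(summaries, np.ndarray):
        arr = np.asarray(summaries, dtype=float)
        index, y = arr[:, 0], arr[:, 1]
    else:
        index = np.array([s.subject_index for s in summaries], dtype=float)
        y = np.array([s.within_variance for s in summaries], dtype=float)
    if len(y) < 4:
        raise InsufficientDataError(f"need at least 4 subjects, got {len(y)}")
    if not np.all(np.isfinite(y)):
        raise ValueError("within-subject variances must be finite")
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != y.shape or np.any(weights < 0):
            raise ValueError("weights must be non-negative and match the series length")

    uniq = np.unique(index)
    if knot_grid is None:
        lo, hi = int(math.ceil(uniq[1])), int(math.floor(uniq[-2]))
    else:
        lo, hi = int(knot_grid[0]), int(knot_grid[1])
        if lo > hi:
            raise ValueError(f"empty knot grid {knot_grid}")

    best: Optional[tuple[float, float, float, float]] = None  # (rss, K, P, c)
    for k in range(lo, hi + 1):
        plateau, curv, rss = _profile_ols(index, y, float(k), weights)
        if curv <= 0:
            continue
        if best is None or rss < best[0] - RSS_TIE_TOL:
            best = (rss, float(k), plateau, curv)

    # flat-line fit for degeneracy detection: when no candidate beats a
    # constant (e.g. exactly constant data, where rounding can make the OLS
    # curvature spuriously positive), no decreasing limb is supported
    if weights is not None and weights.sum() > 0:
        flat_mean = float(np.average(y, weights=weights))
        flat_rss = float(weights @ (y - flat_mean) ** 2)
    else:
        flat_mean = float(y.mean())
        flat_rss = float(((y - flat_mean) ** 2).sum())

    if best is None or flat_rss <= best[0] + RSS_TIE_TOL * max(1.0, flat_rss):
        mean, rss = flat_mean, flat_rss
        knot = float(uniq[0])
        return QuadraticPlateauFit(
            a=mean, b=0.0, c=0.0, knot=knot, knot_index=_round_half_away(knot),
            plateau=mean, rss=rss, n_subjects=len(y), degenerate=True,
            weighted=weights is not None,
        )

    rss, knot, plateau, curv = best
    if refine:
        span_lo = max(knot - 1.0, float(lo))
        span_hi = min(knot + 1.0, float(hi))
        res = minimize_scalar(
            lambda k: _profile_ols(index, y, k, weights)[2],
            bounds=(span_lo, span_hi),
            method="bounded",
            options={"xatol": 1e-9},
        )
        p2, c2, r2 = _profile_ols(index, y, float(res.x), weights)
        if c2 > 0 and r2 < rss:
            rss, knot, plateau, curv = r2, float(res.x), p2, c2

    # back out the quadratic written in powers of I from (P, c, K)
    a = plateau + curv * knot**2
    b = -2.0 * curv * knot
    return QuadraticPlateauFit(
        a=a, b=b, c=curv, knot=knot, knot_index=_round_half_away(knot),
        plateau=plateau, rss=rss, n_subjects=len(y),
        degenerate=False, weighted=weights is not None,
    )


def fitted_curve_table(
    fit: QuadraticPlateauFit, summaries: Sequence[SubjectSummary]
) -> pd.DataFrame:
    """One row per subject: index, observed variance, fitted value, residual.

    This is the table behind a learning-curve plot: observed within-subject
    variance against chronological index with the fitted piecewise curve.
    """
    index = np.array([s.subject_index for s in summaries], dtype=float)
    observed = np.array([s.within_variance for s in summaries], dtype=float)
    fitted = predict(fit, index)
    return pd.DataFrame(
        {
            "subject_index": index.astype(int),
            "observed": observed,
            "fitted": fitted,
            "residual": observed - fitted,
        }
    )
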