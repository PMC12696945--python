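"""P-spline machinery: B-spline bases, difference penalties, knot placement
(including a privacy-preserving anonymized range) and local maximum-likelihood
smoothing-parameter updates.

The smoothing parameter ``lambda`` is estimated *locally*, inside the
backfitting step, as the fixed point of the random-effects variance ratio

    lambda = sigma_e^2 / sigma_b^2,
    sigma_e^2 = weighted RSS / (n - edf),
    sigma_b^2 = gamma' G gamma / (edf - order),
    edf       = tr[(Z'WZ + lambda G)^{-1} Z'WZ],

using only low-dimensional aggregates (never per-observation data), so the
same update runs unchanged on pooled and federated fits.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import BSpline
from scipy.optimize import brentq

from ._exceptions import DisclosureError, RangeError, SpecificationError

__all__ = [
    "bspline_basis",
    "difference_penalty",
    "default_knots",
    "greville_abscissae",
    "anonymized_range",
    "update_lambda_local_ml",
    "estimate_lambda",
    "lambda_for_df",
    "effective_df",
    "LAMBDA_MIN",
    "LAMBDA_MAX",
]

LAMBDA_MIN = 1e-7
LAMBDA_MAX = 1e7


def bspline_basis(x, knots, degree: int) -> np.ndarray:
    """Evaluate the B-spline basis matrix (n x q), q = len(knots) - degree - 1.

    Rows form a partition of unity on the interior domain
    ``[knots[degree], knots[-degree-1]]``; values outside it raise
    :class:`RangeError` (extrapolation policy is decided by the caller).
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(knots, dtype=float)
    if np.any(np.diff(t) < 0):
        raise SpecificationError("knots must be nondecreasing")
    lo, hi = t[degree], t[-degree - 1]
    bad = np.flatnonzero((x < lo) | (x > hi))
    if bad.size:
        raise RangeError(
            f"{bad.size} value(s) outside the knot-supported domain "
            f"[{lo:g}, {hi:g}]; first offender x={x[bad[0]]!r} at index {int(bad[0])}"
        )
    return BSpline.design_matrix(x, t, degree, extrapolate=False).toarray()


def difference_penalty(q: int, order: int) -> np.ndarray:
    """Penalty matrix G = D'D from order-th differences of adjacent coefficients."""
    if order >= q:
        raise SpecificationError(f"penalty order ({order}) must be < basis dimension ({q})")
    D = np.diff(np.eye(q), n=order, axis=0)
    return D.T @ D


def default_knots(xmin: float, xmax: float, n_intervals: int, degree: int) -> np.ndarray:
    """Equally spaced knots: ``n_intervals`` interior intervals plus ``degree``
    equally spaced extension knots on each side (no boundary multiplicity)."""
    if not xmin < xmax:
        raise SpecificationError(f"need xmin < xmax, got ({xmin!r}, {xmax!r})")
    if n_intervals < 1:
        raise SpecificationError("n_intervals must be >= 1")
    h = (xmax - xmin) / n_intervals
    return xmin + h * np.arange(-degree, n_intervals + degree + 1, dtype=float)


def greville_abscissae(knots, degree: int) -> np.ndarray:
    """Greville sites: the coefficient vector reproducing the identity x -> x."""
    t = np.asarray(knots, dtype=float)
    q = len(t) - degree - 1
    if degree == 0:
        return 0.5 * (t[:-1] + t[1:])
    return np.array([t[i + 1: i + degree + 1].mean() for i in range(q)])


def anonymized_range(node_minmax, granularity: float | None = None,
                     k_anonymity: int = 3):
    """Combine per-node (min, max, n) into an outward-rounded shared range.

    The reported bounds are multiples of ``granularity`` covering every node's
    observed range, so the exact extremes are not recoverable. Nodes with
    fewer than ``k_anonymity`` observations may not contribute extremes at all.
    ``granularity`` defaults to roughly 1/32 of the pooled range, rounded to
    one significant digit.
    """
    node_minmax = list(node_minmax)
    if not node_minmax:
        raise SpecificationError("anonymized_range needs at least one node")
    for entry in node_minmax:
        mn, mx, n = entry
        if n < k_anonymity:
            raise DisclosureError(
                f"node with n={n} below k-anonymity threshold {k_anonymity}"
            )
    gmin = min(e[0] for e in node_minmax)
    gmax = max(e[1] for e in node_minmax)
    if granularity is None:
        span = gmax - gmin
        if span <= 0:
            raise SpecificationError("degenerate covariate range")
        raw = span / 32.0
        mag = 10.0 ** np.floor(np.log10(raw))
        granularity = float(np.round(raw / mag) * mag)
    if granularity <= 0:
        raise SpecificationError("granularity must be > 0")
    g = float(granularity)
    fuzz = 1e-9 * max(1.0, abs(gmin), abs(gmax))
    amin = np.floor((gmin + fuzz) / g) * g
    amax = np.ceil((gmax - fuzz) / g) * g
    return float(amin), float(amax)


# ---------------------------------------------------------------------------
# smoothing-parameter estimation from aggregated statistics
# ---------------------------------------------------------------------------

def effective_df(ztwz: np.ndarray, G: np.ndarray, lam: float) -> float:
    """edf = tr[(Z'WZ + lam G)^{-1} Z'WZ], the trace of the smoother matrix."""
    return float(np.trace(np.linalg.solve(ztwz + lam * G, ztwz)))


def update_lambda_local_ml(ztwz, gamma, G, weighted_rss: float, n_eff: float,
                           lam: float, order: int):
    """One variance-ratio update of lambda; returns (new_lambda, capped_flag)."""
    ztwz = np.asarray(ztwz, dtype=float)
    G = np.asarray(G, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    pen = float(gamma @ G @ gamma)
    edf = effective_df(ztwz, G, lam)
    if pen <= 1e-12 * max(1.0, float(gamma @ gamma)):
        # fit already in the penalty null space: perfectly smooth
        return LAMBDA_MAX, True
    sigma_e2 = max(weighted_rss, 0.0) / max(n_eff - edf, 1.0)
    sigma_b2 = pen / max(edf - order, 1e-8)
    new_lam = sigma_e2 / max(sigma_b2, 1e-300)
    capped = not (LAMBDA_MIN <= new_lam <= LAMBDA_MAX)
    return float(np.clip(new_lam, LAMBDA_MIN, LAMBDA_MAX)), capped


def estimate_lambda(ztwz, ztwr, rtwr: float, G, n_eff: float, lam0: float,
                    order: int, max_iter: int = 30, rtol: float = 1e-3):
    """Fixed-point iteration for the local-ML lambda.

    All inputs are additive aggregates (cross-products and scalars), so the
    iteration runs client-side with no extra communication. Returns
    ``(lambda, capped_flag)``.
    """
    ztwz = np.asarray(ztwz, dtype=float)
    ztwr = np.asarray(ztwr, dtype=float)
    G = np.asarray(G, dtype=float)
    lam = float(np.clip(lam0, LAMBDA_MIN, LAMBDA_MAX))
    capped = False
    for _ in range(max_iter):
        gamma = np.linalg.solve(ztwz + lam * G, ztwr)
        wrss = float(rtwr - 2.0 * gamma @ ztwr + gamma @ ztwz @ gamma)
        new_lam, capped = update_lambda_local_ml(ztwz, gamma, G, wrss, n_eff, lam, order)
        if abs(new_lam - lam) <= rtol * max(lam, LAMBDA_MIN):
            lam = new_lam
            break
        lam = new_lam
    return lam, capped


def lambda_for_df(ztwz, G, target_df: float) -> float:
    """Solve edf(lambda) = target_df by monotone root search on log10(lambda)."""
    ztwz = np.asarray(ztwz, dtype=float)
    G = np.asarray(G, dtype=float)
    q = ztwz.shape[0]
    order = q - int(np.linalg.matrix_rank(G))
    target = float(np.clip(target_df, order + 1e-6, q))

    def f(loglam):
        return effective_df(ztwz, G, 10.0 ** loglam) - target

    lo, hi = np.log10(LAMBDA_MIN), np.log10(LAMBDA_MAX)
    flo, fhi = f(lo), f(hi)
    if flo <= 0:  # even the weakest penalty cannot reach the requested df
        return LAMBDA_MIN
    if fhi >= 0:
        return LAMBDA_MAX
    return float(10.0 ** brentq(f, lo, hi, xtol=1e-10, rtol=1e-12))
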