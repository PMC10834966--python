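"""Fractal descriptors of motor primitives.

Two complementary estimators:

* Higuchi's fractal dimension (HFD) — local roughness of the signal
  within cycles.  Subsampled curve lengths L_k are computed for lags
  k = 2..k_max and HFD is the slope of log(L_k) against log(1/k).
  A straight line gives 1; the estimator saturates at 2 for
  uncorrelated noise; Brownian-type signals give 1.5.

* Rescaled-range Hurst exponent (HE) — persistence of the signal
  across cycles.  For prefix lengths q = n, n/2, n/4, ... >= 2 the
  centered cumulative sum's range over the standard deviation (R/S) is
  computed, and HE is the least-squares slope of log(R/S) versus
  log(q) between q = 2 and q = q_inflex.  0.5 marks a memoryless
  series (up to the well-known small-sample upward bias of plain R/S),
  larger values persistence, smaller anti-persistence.

Both scale choices (k_max, q_inflex) default to the fixed pipeline
values 10 and 200; data-driven selection is available but off by
default so pipeline outputs stay reproducible.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "higuchi_curve",
    "higuchi_fd",
    "select_kmax",
    "rescaled_range_curve",
    "hurst_exponent",
    "select_qinflex",
]


def _slope(logx: np.ndarray, logy: np.ndarray) -> tuple[float, float]:
    """OLS slope and fit MSE of logy on logx."""
    A = np.vstack([logx, np.ones_like(logx)]).T
    coef, *_ = np.linalg.lstsq(A, logy, rcond=None)
    mse = float(np.mean((logy - A @ coef) ** 2))
    return float(coef[0]), mse


def higuchi_curve(series: np.ndarray, k_max: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Normalized Higuchi curve lengths L_k for k = 2..k_max.

    For each lag k and offset t0 in 1..k, the subsampled series
    H(t0), H(t0+k), H(t0+2k), ... has length
    (sum of absolute increments) * (n-1) / (floor((n-t0)/k) * k) / k,
    and L_k averages over the k offsets.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if n < 2 * k_max:
        raise ValueError(f"series length {n} too short for k_max={k_max}")
    if not np.isfinite(x).all():
        raise ValueError("series must be finite")
    ks = np.arange(2, k_max + 1)
    L = np.empty(len(ks))
    for i, k in enumerate(ks):
        acc = 0.0
        for t0 in range(1, k + 1):
            sub = x[t0 - 1::k]
            m = len(sub) - 1
            if m < 1:
                raise ValueError(f"series too short at k={k}")
            length = np.abs(np.diff(sub)).sum() * (n - 1) / (m * k) / k
            acc += length
        L[i] = acc / k
    return ks, L


def higuchi_fd(series: np.ndarray, k_max: int = 10) -> float:
    """Higuchi fractal dimension: slope of log(L_k) vs log(1/k), k = 2..k_max."""
    ks, L = higuchi_curve(series, k_max)
    if (L <= 0).any():
        raise ValueError("constant series: curve lengths are zero")
    slope, _ = _slope(np.log(1.0 / ks), np.log(L))
    return slope


def select_kmax(series: np.ndarray, k_limit: int = 300,
                rel_mse_tol: float = 1e-3, default: int = 10) -> int:
    """Largest k for which the log-log Higuchi curve stays linear.

    Linearity is judged by the relative fit MSE (residual MSE over the
    variance of log(L_k), i.e. 1 - R^2 of the fit) staying below
    ``rel_mse_tol`` for the curve over k = 2..k.  ``k_limit`` is capped
    at half the series length.  Falls back to ``default`` with a warning
    when no k >= 3 satisfies the criterion.
    """
    x = np.asarray(series, dtype=float)
    k_limit = min(k_limit, len(x) // 2)
    ks, L = higuchi_curve(x, k_limit)
    logk = np.log(1.0 / ks)
    logL = np.log(L)
    best = None
    for upto in range(2, len(ks) + 1):  # curve over k = 2..ks[upto-1]
        lx, ly = logk[:upto], logL[:upto]
        _, mse = _slope(lx, ly)
        var = float(np.var(ly))
        rel = mse / var if var > 0 else 0.0
        if rel < rel_mse_tol:
            best = int(ks[upto - 1])
    if best is None or best < 3:
        warnings.warn("no linear Higuchi range found; using default k_max")
        return default
    return best


def rescaled_range_curve(series: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(q, R/S) points for prefix lengths q = n, n/2, n/4, ... >= 2.

    For each q: take the first q samples, subtract their mean, cumulate,
    and divide the range of the cumulative series by the (population)
    standard deviation of the centered prefix.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("series too short")
    qs = []
    q = n
    while q >= 2:
        qs.append(q)
        q //= 2
    rs = np.empty(len(qs))
    for i, q in enumerate(qs):
        seg = x[:q]
        S = seg.std()
        if S == 0:
            raise ValueError(f"constant prefix of length {q}: S_q is zero")
        c = np.cumsum(seg - seg.mean())
        rs[i] = (c.max() - c.min()) / S
    return np.array(qs), rs


def hurst_exponent(series: np.ndarray, q_min: int = 2, q_inflex: int = 200) -> float:
    """Rescaled-range Hurst exponent.

    Slope of log(R/S) on log(q) over the prefix-halving q values with
    q_min <= q <= q_inflex.  The raw slope is reported without clipping
    to [0, 1].
    """
    x = np.asarray(series, dtype=float)
    if len(x) < q_inflex:
        raise ValueError(f"series length {len(x)} shorter than q_inflex={q_inflex}")
    qs, rs = rescaled_range_curve(x)
    keep = (qs >= q_min) & (qs <= q_inflex)
    if keep.sum() < 2:
        raise ValueError("fewer than 2 rescaled-range points in the fit window")
    slope, _ = _slope(np.log(qs[keep]), np.log(rs[keep]))
    return slope


def select_qinflex(qs: np.ndarray, rs: np.ndarray,
                   curvature_tol: float = 0.05) -> int:
    """q at the maximal-curvature point of the log-log R/S curve.

    Curvature is measured by second differences of log(R/S) over
    log(q) at interior points.  When the curve is linear throughout
    (maximal curvature below ``curvature_tol``) there is no inflexion
    and the maximal q is returned with a warning.
    """
    qs = np.asarray(qs, dtype=float)
    rs = np.asarray(rs, dtype=float)
    order = np.argsort(qs)
    qs, rs = qs[order], rs[order]
    if len(qs) < 4:
        warnings.warn("fewer than 4 rescaled-range points; no inflexion search")
        return int(qs[-1])
    ly = np.log(rs)
    lx = np.log(qs)
    # slopes of adjacent segments; curvature = change of slope at each interior q
    seg = np.diff(ly) / np.diff(lx)
    curv = np.abs(np.diff(seg))
    if curv.max() < curvature_tol:
        warnings.warn("log-log R/S curve is linear; returning maximal q")
        return int(qs[-1])
    return int(qs[1 + int(np.argmax(curv))])
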