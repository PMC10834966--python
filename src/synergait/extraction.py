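"""Muscle-synergy extraction by Gaussian non-negative matrix factorization.

The cycle matrix ``V`` (muscles x time) is factorized as ``V ~ W H`` with
multiplicative updates

    H <- H * (W' V) / (W' W H)
    W <- W * (V H') / (W H H')

which monotonically decrease the squared reconstruction error.  The
iteration stops when the reconstruction R^2 changes by less than 0.01%
over a trailing 20-iteration window.  The factorization is repeated from
several random initializations and the best restart kept; the number of
synergies is chosen as the smallest rank in the most linear tail of the
R^2-versus-rank curve, found by iteratively pruning the lowest rank until
the linear-regression mean squared error drops below 1e-4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SynergyDecomposition",
    "RankCurve",
    "compute_r2",
    "nmf_factorize",
    "best_of_restarts",
    "rank_curve",
    "select_rank",
    "max_rank",
]


@dataclass
class SynergyDecomposition:
    """One NMF solution: modules W (m x r), primitives H (r x n)."""

    W: np.ndarray
    H: np.ndarray
    rank: int
    r2: float
    n_iterations: int
    seed: int
    r2_trace: np.ndarray = field(repr=False, default=None)

    def normalized(self) -> "SynergyDecomposition":
        """Scale each module column to max 1, compensating in H.

        The product ``W H`` is unchanged; only the scale indeterminacy of
        the factorization is fixed for reporting.
        """
        s = self.W.max(axis=0)
        s = np.where(s > 0, s, 1.0)
        return SynergyDecomposition(
            W=self.W / s, H=self.H * s[:, None], rank=self.rank,
            r2=self.r2, n_iterations=self.n_iterations, seed=self.seed,
            r2_trace=self.r2_trace,
        )


@dataclass
class RankCurve:
    """Best-restart R^2 per candidate rank, plus the selection trace."""

    ranks: np.ndarray
    r2_values: np.ndarray
    decompositions: list[SynergyDecomposition] = field(repr=False, default_factory=list)
    r_selected: int | None = None
    pruning_trace: list[tuple[int, float]] = field(default_factory=list)

    def best(self, rank: int | None = None) -> SynergyDecomposition:
        rank = self.r_selected if rank is None else rank
        for d in self.decompositions:
            if d.rank == rank:
                return d
        raise KeyError(f"no decomposition stored for rank {rank}")


def compute_r2(V: np.ndarray, V_R: np.ndarray) -> float:
    """Coefficient of determination 1 - SSE/SST over all matrix entries."""
    V = np.asarray(V, dtype=float)
    V_R = np.asarray(V_R, dtype=float)
    if V.shape != V_R.shape:
        raise ValueError("V and V_R must have the same shape")
    sst = float(((V - V.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError("constant V: SST is zero")
    sse = float(((V - V_R) ** 2).sum())
    return 1.0 - sse / sst


def max_rank(n_muscles: int) -> int:
    """Candidate-rank cap: 75% of the number of monitored muscles."""
    return int(round(0.75 * n_muscles))


def nmf_factorize(V: np.ndarray, rank: int, seed: int, *,
                  tol: float = 1e-4, window: int = 20,
                  max_iter: int = 10_000, relative: bool = True,
                  eps: float = 1e-12) -> SynergyDecomposition:
    """Multiplicative-update NMF from one random initialization.

    ``tol`` is the R^2-change stopping threshold over a trailing
    ``window`` iterations (0.01% default); relative change by default,
    absolute with ``relative=False``.  W and H start i.i.d. uniform(0, 1]
    from ``seed``; a small ``eps`` guards the update denominators.
    """
    V = np.asarray(V, dtype=float)
    if (V < 0).any():
        raise ValueError("V must be non-negative")
    m, n = V.shape
    if not (1 <= rank <= m):
        raise ValueError(f"rank must lie in [1, {m}]")
    if not (V > 0).any():
        raise ValueError("V must have a positive entry")
    rng = np.random.default_rng(seed)
    W = 1.0 - rng.uniform(0.0, 1.0, (m, rank))   # uniform on (0, 1]
    H = 1.0 - rng.uniform(0.0, 1.0, (rank, n))
    v_sq = float((V ** 2).sum())
    sst = v_sq - V.size * float(V.mean()) ** 2
    trace = np.empty(max_iter)
    it = 0
    for it in range(max_iter):
        H *= (W.T @ V) / ((W.T @ W) @ H + eps)
        HHt = H @ H.T
        W *= (V @ H.T) / (W @ HHt + eps)
        # SSE via the Gram trick: ||V - WH||^2 = ||V||^2 - 2<W'V, H> + <W'W, HH'>
        WtV = W.T @ V
        sse = v_sq - 2.0 * float(np.sum(WtV * H)) + float(np.sum((W.T @ W) * HHt))
        trace[it] = 1.0 - sse / sst
        if it >= window:
            prev, cur = trace[it - window], trace[it]
            delta = abs(cur - prev)
            if relative:
                delta /= max(abs(prev), eps)
            if delta < tol:
                break
    n_it = it + 1
    return SynergyDecomposition(W=W, H=H, rank=rank, r2=float(trace[it]),
                                n_iterations=n_it, seed=seed,
                                r2_trace=trace[:n_it].copy())


def _restart_seeds(base_seed: int, n: int) -> np.ndarray:
    ss = np.random.SeedSequence(base_seed)
    return ss.generate_state(n) % (2 ** 31)


def best_of_restarts(V: np.ndarray, rank: int, n_restarts: int = 5,
                     base_seed: int = 0, **kwargs) -> SynergyDecomposition:
    """Run ``n_restarts`` factorizations and keep the highest-R^2 one.

    Restart seeds derive deterministically from ``base_seed``.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    best = None
    for s in _restart_seeds(base_seed, n_restarts):
        d = nmf_factorize(V, rank, int(s), **kwargs)
        if best is None or d.r2 > best.r2:
            best = d
    return best


def rank_curve(V: np.ndarray, r_max: int | None = None, *,
               n_restarts: int = 5, base_seed: int = 0,
               **kwargs) -> RankCurve:
    """Best-of-restarts R^2 for every candidate rank 1..r_max."""
    m = V.shape[0]
    if r_max is None:
        r_max = max_rank(m)
    if r_max > m:
        raise ValueError("r_max cannot exceed the number of muscles")
    ranks = np.arange(1, r_max + 1)
    decs = []
    for r in ranks:
        decs.append(best_of_restarts(V, int(r), n_restarts=n_restarts,
                                     base_seed=base_seed + int(r), **kwargs))
    return RankCurve(ranks=ranks, r2_values=np.array([d.r2 for d in decs]),
                     decompositions=decs)


def _linear_fit_mse(x: np.ndarray, y: np.ndarray) -> float:
    A = np.vstack([x, np.ones_like(x)]).T
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(np.mean((y - A @ coef) ** 2))


def select_rank(curve: RankCurve | tuple, mse_threshold: float = 1e-4) -> int:
    """Smallest rank in the most linear tail of the R^2 curve.

    Fit a simple linear regression to the remaining (rank, R^2) points;
    if its MSE is below ``mse_threshold`` stop, otherwise drop the
    lowest-rank point and refit, until two points remain.  Returns the
    lowest surviving rank (the minimum number of synergies beyond which
    reconstruction quality only improves linearly/marginally).
    """
    if isinstance(curve, RankCurve):
        xs = list(map(float, curve.ranks))
        ys = list(map(float, curve.r2_values))
    else:
        xs, ys = list(map(float, curve[0])), list(map(float, curve[1]))
    if len(xs) < 2:
        raise ValueError("at least 2 points are required")
    trace = []
    while True:
        mse = _linear_fit_mse(np.array(xs), np.array(ys))
        trace.append((len(xs), mse))
        if mse < mse_threshold or len(xs) == 2:
            break
        xs.pop(0)
        ys.pop(0)
    selected = int(xs[0])
    if isinstance(curve, RankCurve):
        curve.r_selected = selected
        curve.pruning_trace = trace
    return selected
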