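"""Functional classification of extracted synergies.

Averaged motor primitives are k-means-clustered for k = 1..11 (20
centroid initializations per k, lowest within-cluster variance kept);
the cluster count is chosen by the same linear-regression pruning rule
used for the synergy rank.  Motor modules are then clustered with the
same imposed k.  Synergies whose primitive cluster and module cluster
agree (after maximal-overlap matching of the two labelings) are
fundamental; discordant ones are combined (a mixture of simpler
synergies) and carry no functional label.  Fundamental clusters are
named by the temporal order of their mean center of activity over the
cycle: braking, push-off, early flight, late flight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .extraction import select_rank

__all__ = [
    "VarianceCurve",
    "SynergyClassification",
    "cluster_primitives",
    "select_n_clusters",
    "cluster_modules",
    "concordance_and_label",
    "FUNDAMENTAL_NAMES",
]

FUNDAMENTAL_NAMES = ("braking", "push-off", "early-flight", "late-flight")


@dataclass
class VarianceCurve:
    """Within-cluster variance (normalized by total variance) per k."""

    ks: np.ndarray
    variance: np.ndarray
    labels_per_k: dict[int, np.ndarray] = field(repr=False, default_factory=dict)
    k_selected: int | None = None


@dataclass
class SynergyClassification:
    """Per-synergy cluster assignment, concordance and functional label."""

    primitive_cluster: np.ndarray
    module_cluster: np.ndarray     # mapped onto primitive-cluster ids
    fundamental: np.ndarray        # bool per synergy
    label: list[str]               # functional name or "combined"
    score: np.ndarray              # (FWHM + CoA in points) / 200, diagnostic
    n_clusters: int
    bimodal: np.ndarray | None = None


def _best_kmeans(X: np.ndarray, k: int, n_init: int, seed: int) -> KMeans:
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, algorithm="lloyd")
    return km.fit(X)


def cluster_primitives(mean_primitives: np.ndarray,
                       k_range: tuple[int, int] = (1, 11),
                       n_init: int = 20, seed: int = 0) -> VarianceCurve:
    """Best-of-``n_init`` k-means over a range of cluster counts.

    ``mean_primitives`` is (n_synergies, 200).  The variance curve is
    the within-cluster sum of squares normalized by the total sum of
    squares (so the k = 1 value is 1 and the curve is comparable to the
    1e-4 pruning threshold regardless of signal scale).
    """
    X = np.atleast_2d(np.asarray(mean_primitives, dtype=float))
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 primitives to cluster")
    lo, hi = k_range
    ks = np.arange(lo, min(hi, n) + 1)
    total_ss = float(((X - X.mean(axis=0)) ** 2).sum())
    var = np.empty(len(ks))
    labels = {}
    for i, k in enumerate(ks):
        km = _best_kmeans(X, int(k), n_init, seed + int(k))
        var[i] = km.inertia_ / total_ss if total_ss > 0 else 0.0
        labels[int(k)] = km.labels_.copy()
    return VarianceCurve(ks=ks, variance=var, labels_per_k=labels)


def select_n_clusters(curve: VarianceCurve, mse_threshold: float = 1e-4) -> int:
    """Cluster count by the linear-regression pruning rule (same as rank)."""
    k = select_rank((curve.ks, curve.variance), mse_threshold=mse_threshold)
    curve.k_selected = k
    return k


def cluster_modules(modules: np.ndarray, k_imposed: int,
                    n_init: int = 20, seed: int = 0) -> np.ndarray:
    """k-means labels of module weight vectors with an imposed k.

    ``modules`` is (n_synergies, m muscles) — one row per synergy.
    """
    X = np.atleast_2d(np.asarray(modules, dtype=float))
    if k_imposed > X.shape[0]:
        raise ValueError("more clusters than module vectors")
    return _best_kmeans(X, k_imposed, n_init, seed).labels_.copy()


def concordance_and_label(primitive_labels: np.ndarray,
                          module_labels: np.ndarray,
                          coa_deg: np.ndarray,
                          fwhm_points: np.ndarray,
                          bimodal: np.ndarray | None = None,
                          ) -> SynergyClassification:
    """Match the two clusterings and assign functional labels.

    Module clusters are mapped onto primitive clusters by maximal
    membership overlap (Hungarian assignment on the contingency table).
    A synergy is fundamental when its mapped module cluster equals its
    primitive cluster, combined otherwise.  Fundamental clusters are
    named in order of their circular-mean CoA (braking first); with a
    cluster count other than 4 the names are ``cluster-1`` .. ``cluster-k``
    in the same CoA order.  The per-synergy score
    (FWHM + CoA converted to points) / 200 is kept as a diagnostic.
    """
    p = np.asarray(primitive_labels)
    q = np.asarray(module_labels)
    coa = np.asarray(coa_deg, dtype=float)
    fwhm = np.asarray(fwhm_points, dtype=float)
    if not (len(p) == len(q) == len(coa) == len(fwhm)):
        raise ValueError("labelings and metrics must cover the same synergies")
    k = int(max(p.max(), q.max())) + 1
    # contingency: overlap[i, j] = #synergies in primitive cluster i & module cluster j
    overlap = np.zeros((k, k))
    for a, b in zip(p, q):
        overlap[a, b] += 1
    rows, cols = linear_sum_assignment(-overlap)
    mapping = {int(c): int(r) for r, c in zip(rows, cols)}
    q_mapped = np.array([mapping[int(b)] for b in q])
    fundamental = p == q_mapped

    # circular mean CoA per primitive cluster, ordered over the cycle
    order_key = []
    for c in range(k):
        members = coa[p == c]
        if len(members) == 0:
            order_key.append(np.inf)
            continue
        ang = np.radians(members)
        mean_ang = np.degrees(np.arctan2(np.sin(ang).sum(), np.cos(ang).sum())) % 360
        order_key.append(mean_ang)
    order = np.argsort(order_key)
    if k == len(FUNDAMENTAL_NAMES):
        names = {int(c): FUNDAMENTAL_NAMES[i] for i, c in enumerate(order)}
    else:
        names = {int(c): f"cluster-{i + 1}" for i, c in enumerate(order)}
    label = [names[int(c)] if fund else "combined"
             for c, fund in zip(p, fundamental)]
    score = (fwhm + coa / 360.0 * 200.0) / 200.0
    return SynergyClassification(
        primitive_cluster=p, module_cluster=q_mapped, fundamental=fundamental,
        label=label, score=score, n_clusters=k,
        bimodal=None if bimodal is None else np.asarray(bimodal, dtype=bool),
    )
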