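"""Linear descriptors of motor modules and motor primitives.

* co-contribution index (CI): balance between anterior and posterior
  mobilizing muscles at a joint, from the module weights;
* center of activity (CoA): circular-mean angle of the averaged
  primitive over the cycle (0 deg = touchdown, 360 deg = next touchdown);
* full width at half maximum (FWHM): number of cycle points on which the
  min-subtracted primitive exceeds half its maximum;
* per-point exceedance and overlap frequencies across cycles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DEFAULT_JOINT_MAP",
    "PrimitiveMetricSet",
    "co_contribution_index",
    "center_of_activity",
    "full_width_half_max",
    "half_max_indicator",
    "exceedance_frequency",
    "overlap_frequency",
    "count_half_max_runs",
    "is_bimodal",
    "primitive_metrics",
]

#: joint -> (anterior mobilizing muscles, posterior mobilizing muscles)
DEFAULT_JOINT_MAP: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "hip": (("RF",), ("GM",)),
    "knee": (("RF", "VL", "VM"), ("STSM", "BF")),
    "ankle": (("TA",), ("GaM", "GaL", "SOL", "PL")),
}


@dataclass
class PrimitiveMetricSet:
    """Per-synergy linear metrics on the 200-point cycle grid."""

    coa_deg: np.ndarray          # (r,), in [0, 360)
    fwhm_points: np.ndarray      # (r,), integer counts
    exceedance_freq: np.ndarray  # (r, 200), per-point fraction of cycles
    overlap_freq: np.ndarray     # (200,), fraction of cycles with >= 2 synergies
    bimodal: np.ndarray          # (r,), bool


def co_contribution_index(module_column: np.ndarray,
                          muscle_names: tuple[str, ...],
                          joint: str,
                          joint_map: dict | None = None) -> float:
    """CI = mean(anterior weights) / (mean(anterior) + mean(posterior)).

    1 when only anterior muscles contribute, 0 when only posterior,
    0.5 when both groups contribute equally.
    """
    joint_map = DEFAULT_JOINT_MAP if joint_map is None else joint_map
    ant_names, post_names = joint_map[joint]
    if set(ant_names) & set(post_names):
        raise ValueError("anterior and posterior groups must be disjoint")
    idx = {name: i for i, name in enumerate(muscle_names)}
    w = np.asarray(module_column, dtype=float)
    ant = float(np.mean([w[idx[n]] for n in ant_names]))
    post = float(np.mean([w[idx[n]] for n in post_names]))
    if ant + post == 0:
        raise ValueError(f"both muscle groups have zero mean weight at the {joint}")
    return ant / (ant + post)


def center_of_activity(mean_primitive: np.ndarray) -> float:
    """Circular center of mass of the primitive, in degrees [0, 360).

    Point t maps to angle 360 * (t - 1) / p, p the cycle length, so
    point 1 is the touchdown at 0 degrees.  The angle of the resultant
    vector (sum of cos/sin weighted by activity) is taken with the
    two-argument arctangent, covering all four quadrants.
    """
    h = np.asarray(mean_primitive, dtype=float)
    if (h < 0).any():
        raise ValueError("primitive must be non-negative")
    p = len(h)
    theta = 2.0 * np.pi * np.arange(p) / p
    A = float(np.sum(np.cos(theta) * h))
    B = float(np.sum(np.sin(theta) * h))
    if A == 0 and B == 0:
        raise ValueError("all-zero primitive has no center of activity")
    return float(np.degrees(np.arctan2(B, A)) % 360.0)


def half_max_indicator(primitive: np.ndarray) -> np.ndarray:
    """Boolean mask of points strictly exceeding half the min-subtracted max."""
    h = np.asarray(primitive, dtype=float)
    lo = h.min()
    hi = h.max()
    if hi <= lo:
        raise ValueError("constant primitive has no half-maximum")
    return (h - lo) > (hi - lo) / 2.0


def full_width_half_max(mean_primitive: np.ndarray) -> int:
    """Number of cycle points exceeding half the maximum after min-subtraction."""
    return int(half_max_indicator(mean_primitive).sum())


def exceedance_frequency(per_cycle_primitives: np.ndarray) -> np.ndarray:
    """Fraction of cycles in which each point exceeds that cycle's half-max.

    ``per_cycle_primitives`` is (C cycles, p points); the half-maximum
    rule (min-subtracted, strict) is applied within each cycle.
    """
    P = np.atleast_2d(np.asarray(per_cycle_primitives, dtype=float))
    ind = np.vstack([half_max_indicator(P[c]) for c in range(P.shape[0])])
    return ind.mean(axis=0)


def overlap_frequency(indicators: np.ndarray) -> np.ndarray:
    """Fraction of cycles with >= 2 synergies above half-max at each point.

    ``indicators`` is boolean (r synergies, C cycles, p points), the
    per-cycle half-max indicators of each synergy.
    """
    ind = np.asarray(indicators, dtype=bool)
    if ind.ndim != 3 or ind.shape[0] < 2:
        raise ValueError("need per-cycle indicators for at least 2 synergies")
    return (ind.sum(axis=0) >= 2).mean(axis=0)


def count_half_max_runs(mean_primitive: np.ndarray) -> int:
    """Number of contiguous above-half-max runs, counted circularly."""
    ind = half_max_indicator(mean_primitive)
    if ind.all():
        return 1
    # rotate so the series starts below half-max; runs then never wrap
    start = int(np.flatnonzero(~ind)[0])
    ind = np.roll(ind, -start)
    return int(np.sum(ind[1:] & ~ind[:-1]) + ind[0])


def is_bimodal(mean_primitive: np.ndarray) -> bool:
    """True when the averaged primitive has more than one half-max run."""
    return count_half_max_runs(mean_primitive) > 1


def primitive_metrics(H: np.ndarray, n_points: int = 200) -> PrimitiveMetricSet:
    """All primitive metrics for a (r, n_points * C) primitive matrix.

    CoA and FWHM are computed on the across-cycle average primitive;
    exceedance and overlap frequencies on the per-cycle primitives.
    """
    H = np.atleast_2d(np.asarray(H, dtype=float))
    r, n = H.shape
    if n % n_points:
        raise ValueError("primitive length must be a multiple of the cycle grid")
    C = n // n_points
    cycles = H.reshape(r, C, n_points)
    mean_prim = cycles.mean(axis=1)
    coa = np.array([center_of_activity(mean_prim[j]) for j in range(r)])
    fwhm = np.array([full_width_half_max(mean_prim[j]) for j in range(r)])
    exceed = np.vstack([exceedance_frequency(cycles[j]) for j in range(r)])
    ind = np.stack([
        np.vstack([half_max_indicator(cycles[j, c]) for c in range(C)])
        for j in range(r)
    ])
    overlap = overlap_frequency(ind) if r >= 2 else np.zeros(n_points)
    bimodal = np.array([is_bimodal(mean_prim[j]) for j in range(r)])
    return PrimitiveMetricSet(coa_deg=coa, fwhm_points=fwhm,
                              exceedance_freq=exceed, overlap_freq=overlap,
                              bimodal=bimodal)
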