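"""From raw force + EMG recordings to time-normalized cycle tensors.

The processing chain mirrors standard running-sEMG practice: gait events
from a 50 N threshold on the vertical ground-reaction force; an EMG
envelope via band-pass (10-500 Hz), high-pass (50 Hz), full-wave
rectification and low-pass (20 Hz), each stage a 4th-order zero-phase
Butterworth; each touchdown-to-touchdown cycle resampled to 200 points
(100 stance + 100 flight); per-muscle amplitude normalization to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "RawRecording",
    "GaitEvents",
    "SpatiotemporalParams",
    "EmgCycleTensor",
    "detect_gait_events",
    "spatiotemporal_params",
    "filter_emg",
    "normalize_amplitude",
    "time_normalize",
    "select_last_cycles",
]

N_POINTS = 200
N_STANCE = 100


@dataclass
class RawRecording:
    """A synchronized multi-muscle EMG + normal force recording."""

    emg: np.ndarray              # (m, n_samples)
    emg_rate: float
    force: np.ndarray            # (n_force_samples,)
    force_rate: float
    muscle_names: tuple[str, ...]
    condition: str = ""
    signal_type: str = "raw"     # "raw" or "envelope" (already rectified/smoothed)

    def __post_init__(self) -> None:
        self.emg = np.atleast_2d(np.asarray(self.emg, dtype=float))
        self.force = np.asarray(self.force, dtype=float)
        if self.emg_rate <= 0 or self.force_rate <= 0:
            raise ValueError("sampling rates must be positive")
        if not np.isfinite(self.emg).all() or not np.isfinite(self.force).all():
            raise ValueError("non-finite samples in recording")
        if self.emg.shape[0] != len(self.muscle_names):
            raise ValueError("EMG rows must match muscle_names")


@dataclass
class GaitEvents:
    """Touchdown / toe-off sample indices on the force timebase.

    Events alternate touchdown -> toe-off; ``toeoffs[i] > touchdowns[i]``.
    With K touchdowns there are K - 1 complete touchdown-to-touchdown
    cycles.
    """

    touchdowns: np.ndarray
    toeoffs: np.ndarray

    def __post_init__(self) -> None:
        self.touchdowns = np.asarray(self.touchdowns, dtype=int)
        self.toeoffs = np.asarray(self.toeoffs, dtype=int)
        if len(self.touchdowns) != len(self.toeoffs):
            raise ValueError("touchdowns and toeoffs must pair up")
        if (np.diff(self.touchdowns) <= 0).any() or (np.diff(self.toeoffs) <= 0).any():
            raise ValueError("event indices must be strictly increasing")
        if (self.toeoffs <= self.touchdowns).any():
            raise ValueError("each toe-off must follow its touchdown")

    @property
    def n_cycles(self) -> int:
        return max(len(self.touchdowns) - 1, 0)


@dataclass
class SpatiotemporalParams:
    """Per-cycle stance time, flight time and stride frequency (s, s, Hz)."""

    stance_time: np.ndarray
    flight_time: np.ndarray
    stride_frequency: np.ndarray


@dataclass
class EmgCycleTensor:
    """Per-muscle, per-cycle activity on the 200-point cycle grid.

    ``values`` has shape (m muscles, 200 points, C cycles); points 1-100
    cover stance, 101-200 flight.  ``matrix`` is the (m, 200*C) column
    concatenation of cycles fed to the factorization.
    """

    values: np.ndarray
    muscle_names: tuple[str, ...]
    condition: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[1] != N_POINTS:
            raise ValueError("values must be (m, 200, C)")

    @property
    def n_muscles(self) -> int:
        return self.values.shape[0]

    @property
    def n_cycles(self) -> int:
        return self.values.shape[2]

    @property
    def matrix(self) -> np.ndarray:
        """(m, 200*C) view with cycles concatenated in time order."""
        return self.values.transpose(0, 2, 1).reshape(self.n_muscles, -1)

    @classmethod
    def from_matrix(cls, V: np.ndarray, muscle_names, condition: str = "") -> "EmgCycleTensor":
        V = np.asarray(V, dtype=float)
        m, n = V.shape
        if n % N_POINTS:
            raise ValueError("matrix columns must be a multiple of 200")
        vals = V.reshape(m, n // N_POINTS, N_POINTS).transpose(0, 2, 1)
        return cls(vals, tuple(muscle_names), condition)


def detect_gait_events(force: np.ndarray, threshold_N: float = 50.0,
                       rate: float | None = None,
                       debounce_s: float | None = 0.05) -> GaitEvents:
    """Detect touchdowns and toe-offs from the normal force.

    A touchdown is the first sample at-or-above ``threshold_N`` after a
    below-threshold sample, a toe-off the first sample back below it.
    Incomplete leading (recording starts mid-stance) and trailing
    (stance not finished) half-cycles are dropped.  Crossing pairs closer
    than ``debounce_s`` (requires ``rate``) are merged to guard against
    chatter at the threshold; pass ``debounce_s=None`` to disable.
    """
    force = np.asarray(force, dtype=float)
    if force.ndim != 1 or len(force) < 2:
        raise ValueError("force must be a 1-D series of length >= 2")
    above = force >= threshold_N
    ups = np.flatnonzero(~above[:-1] & above[1:]) + 1
    downs = np.flatnonzero(above[:-1] & ~above[1:]) + 1
    if len(ups) == 0 or len(downs) == 0:
        raise ValueError("force never crosses the detection threshold")
    # drop a leading stance with no observed touchdown
    downs = downs[downs > ups[0]]
    # pair each touchdown with the next toe-off; drop trailing unfinished stance
    tds, tos = [], []
    j = 0
    for td in ups:
        while j < len(downs) and downs[j] <= td:
            j += 1
        if j == len(downs):
            break
        tds.append(td)
        tos.append(downs[j])
    if not tds:
        raise ValueError("no complete stance phase found")
    tds = np.array(tds)
    tos = np.array(tos)
    if debounce_s is not None and rate is not None:
        min_gap = debounce_s * rate
        keep = np.ones(len(tds), dtype=bool)
        last_to = tos[0]
        for i in range(1, len(tds)):
            if tds[i] - last_to < min_gap:   # spurious re-contact: merge
                keep[i] = False
            else:
                last_to = tos[i]
        # merging a spurious pair extends the previous stance to its toe-off
        merged_tos = []
        cur = None
        for i in range(len(tds)):
            if keep[i]:
                if cur is not None:
                    merged_tos.append(cur)
                cur = tos[i]
            else:
                cur = tos[i]
        merged_tos.append(cur)
        tds = tds[keep]
        tos = np.array(merged_tos)
    return GaitEvents(touchdowns=tds, toeoffs=tos)


def spatiotemporal_params(events: GaitEvents, rate: float) -> SpatiotemporalParams:
    """Per-cycle stance/flight duration and stride frequency.

    stance = toe-off - touchdown; flight = next touchdown - toe-off;
    stride frequency = 1 / (stance + flight).  Requires >= 2 complete
    touchdowns (>= 1 full cycle, >= 2 for the spec'd minimum).
    """
    if events.n_cycles < 2:
        raise ValueError("at least 2 complete cycles are required")
    td = events.touchdowns
    to = events.toeoffs
    stance = (to[:-1] - td[:-1]) / rate
    flight = (td[1:] - to[:-1]) / rate
    return SpatiotemporalParams(
        stance_time=stance,
        flight_time=flight,
        stride_frequency=1.0 / (stance + flight),
    )


def _sos(order: int, cutoff, rate: float, btype: str):
    return signal.butter(order, cutoff, btype=btype, fs=rate, output="sos")


def filter_emg(raw_emg: np.ndarray, rate: float, order: int = 4) -> np.ndarray:
    """Raw sEMG to a non-negative linear envelope.

    Cascade: band-pass 10-500 Hz, high-pass 50 Hz, full-wave
    rectification, low-pass 20 Hz; every filter a Butterworth of the
    given order applied forward-backward (zero phase).  Small negative
    excursions introduced by the final zero-phase low-pass are clipped
    at zero.
    """
    if rate <= 1000:
        raise ValueError("sampling rate must exceed 1000 Hz (500 Hz band edge)")
    x = np.atleast_2d(np.asarray(raw_emg, dtype=float))
    x = signal.sosfiltfilt(_sos(order, (10.0, 500.0), rate, "bandpass"), x, axis=-1)
    x = signal.sosfiltfilt(_sos(order, 50.0, rate, "highpass"), x, axis=-1)
    x = np.abs(x)
    x = signal.sosfiltfilt(_sos(order, 20.0, rate, "lowpass"), x, axis=-1)
    out = np.clip(x, 0.0, None)
    return out if np.asarray(raw_emg).ndim > 1 else out[0]


def normalize_amplitude(envelope: np.ndarray,
                        muscle_names: tuple[str, ...] | None = None) -> np.ndarray:
    """Per-muscle min-subtraction and division by the maximum.

    Operates row-wise over whatever sample axis layout is passed
    ((m, samples) or (m, 200, C)); after it every muscle spans exactly
    [0, 1] within the processed condition.
    """
    x = np.asarray(envelope, dtype=float)
    flat = x.reshape(x.shape[0], -1)
    lo = flat.min(axis=1)
    hi = flat.max(axis=1)
    bad = hi <= lo
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        name = muscle_names[i] if muscle_names else f"channel {i}"
        raise ValueError(f"degenerate (constant) EMG channel: {name}")
    shape = (x.shape[0],) + (1,) * (x.ndim - 1)
    return (x - lo.reshape(shape)) / (hi - lo).reshape(shape)


def time_normalize(envelope: np.ndarray, events: GaitEvents,
                   emg_rate: float, force_rate: float,
                   muscle_names: tuple[str, ...] = (),
                   condition: str = "") -> EmgCycleTensor:
    """Resample each cycle to 200 points (100 stance + 100 flight).

    Stance spans [touchdown, toe-off) and flight [toe-off, next
    touchdown), each mapped half-open onto 100 linearly interpolated
    points so the 200 points tile the cycle without duplication.
    """
    env = np.atleast_2d(np.asarray(envelope, dtype=float))
    m, n = env.shape
    C = events.n_cycles
    if C < 1:
        raise ValueError("at least one complete cycle is required")
    ratio = emg_rate / force_rate
    t = np.arange(n, dtype=float)
    out = np.empty((m, N_POINTS, C))
    for c in range(C):
        a = events.touchdowns[c] * ratio
        b = events.toeoffs[c] * ratio
        e = events.touchdowns[c + 1] * ratio
        if b - a < 2 or e - b < 2:
            raise ValueError(f"cycle {c}: stance or flight shorter than 2 EMG samples")
        if e > n:
            raise ValueError(f"cycle {c}: events extend past the EMG signal")
        xs = a + (b - a) * np.arange(N_STANCE) / N_STANCE
        xf = b + (e - b) * np.arange(N_STANCE) / N_STANCE
        grid = np.concatenate([xs, xf])
        for i in range(m):
            out[i, :, c] = np.interp(grid, t, env[i])
    names = tuple(muscle_names) if muscle_names else tuple(f"m{i}" for i in range(m))
    return EmgCycleTensor(out, names, condition)


def select_last_cycles(tensor: EmgCycleTensor, k: int = 60) -> EmgCycleTensor:
    """Keep the last ``k`` cycles (steady-state portion), order preserved."""
    C = tensor.n_cycles
    if C < k:
        raise ValueError(f"only {C} cycles available, {k} requested")
    return EmgCycleTensor(tensor.values[:, :, C - k:], tensor.muscle_names,
                          tensor.condition)
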