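"""Synthetic running EMG and ground-reaction-force generator.

Produces multi-muscle surface-EMG envelopes as a non-negative mixture
``V = W H`` of time-invariant motor modules (``W``, muscles x synergies)
and bump-shaped periodic motor primitives (``H``), tiled over running
cycles, together with a periodic vertical force trace whose threshold
crossings delimit the cycles.  The generator keeps full ground truth so
that downstream recovery (factorization rank, module weights, primitive
timing and width, persistence) can be scored exactly.

Cycle-to-cycle variability has two independent knobs:

* ``noise_sigma`` — additive Gaussian noise truncated at zero, acting on
  the local roughness of the signal;
* ``persistence_H`` with ``modulation_amp`` — each cycle's bump amplitude
  is modulated by fractional Gaussian noise with a target Hurst
  exponent, acting on the global, across-cycle structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Bump",
    "SyntheticGroundTruth",
    "SyntheticRecording",
    "DEFAULT_MUSCLES",
    "make_primitive",
    "make_fgn",
    "generate_cycle_matrix",
    "generate_recording",
    "default_ground_truth",
]

#: Right lower-limb muscles monitored in the running protocol, in
#: recording order: tibialis anterior, gastrocnemius medialis/lateralis,
#: soleus, peroneus longus, vastus medialis/lateralis, rectus femoris,
#: biceps femoris, semitendinosus+semimembranosus, gluteus maximus.
DEFAULT_MUSCLES = (
    "TA", "GaM", "GaL", "SOL", "PL", "VM", "VL", "RF", "BF", "STSM", "GM",
)

N_POINTS = 200  # points per time-normalized gait cycle (100 stance + 100 flight)


@dataclass(frozen=True)
class Bump:
    """One Gaussian activation bump on the 200-point cycle grid.

    ``center`` is a 1-based cycle point in [1, 200]; ``width`` is the full
    width at half maximum in cycle points; ``amplitude`` is non-negative.
    """

    center: float
    width: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not (1 <= self.center <= N_POINTS):
            raise ValueError(f"bump center {self.center} outside [1, {N_POINTS}]")
        if not (2 <= self.width <= N_POINTS - 1):
            raise ValueError(f"bump width {self.width} outside [2, {N_POINTS - 1}]")
        if self.amplitude < 0:
            raise ValueError("bump amplitude must be non-negative")


@dataclass
class SyntheticGroundTruth:
    """Generating parameters for one synthetic recording."""

    modules: np.ndarray                  # (m, r), non-negative, column max 1
    primitives: list[list[Bump]]         # one bump list per synergy
    n_cycles: int = 60
    noise_sigma: float = 0.05            # additive noise, fraction of unit amplitude
    persistence_H: float = 0.75          # Hurst exponent of amplitude modulation
    modulation_amp: float = 0.10         # sd of per-cycle amplitude factor
    seed: int = 0
    muscle_names: tuple[str, ...] = DEFAULT_MUSCLES
    stance_s: float = 0.20
    flight_s: float = 0.15
    emg_rate: float = 2000.0
    force_rate: float = 100.0
    condition: str = "SIM"

    def __post_init__(self) -> None:
        self.modules = np.asarray(self.modules, dtype=float)
        if self.modules.ndim != 2:
            raise ValueError("modules must be a 2-D (muscles x synergies) array")
        if (self.modules < 0).any():
            raise ValueError("module weights must be non-negative")
        m, r = self.modules.shape
        if r != len(self.primitives):
            raise ValueError(
                f"{r} module columns but {len(self.primitives)} primitive bump lists"
            )
        if m != len(self.muscle_names):
            raise ValueError("modules rows must match muscle_names")
        colmax = self.modules.max(axis=0)
        if (colmax <= 0).any():
            raise ValueError("every synergy needs at least one positive weight")
        self.modules = self.modules / colmax  # per-synergy max weight = 1
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if not (0 < self.persistence_H < 1):
            raise ValueError("persistence_H must lie in (0, 1)")

    @property
    def n_muscles(self) -> int:
        return self.modules.shape[0]

    @property
    def n_synergies(self) -> int:
        return self.modules.shape[1]


@dataclass
class SyntheticRecording:
    """A generated recording plus the truth that produced it."""

    emg: np.ndarray          # (m, n_emg_samples), non-negative envelope
    force: np.ndarray        # (n_force_samples,), Newtons
    emg_rate: float
    force_rate: float
    muscle_names: tuple[str, ...]
    touchdowns: np.ndarray   # force-timebase sample indices, length n_cycles + 1
    toeoffs: np.ndarray      # force-timebase sample indices, length n_cycles + 1
    truth: SyntheticGroundTruth


def make_primitive(bumps: list[Bump] | tuple[Bump, ...], n_points: int = N_POINTS) -> np.ndarray:
    """Evaluate a sum of circularly wrapped Gaussian bumps on the cycle grid.

    The cycle is periodic (point 200 is adjacent to point 1), so a bump
    centered near either end wraps across the boundary.  ``width`` is the
    FWHM of each bump, hence sigma = width / (2 sqrt(2 ln 2)).
    """
    if len(bumps) == 0:
        raise ValueError("at least one bump is required")
    t = np.arange(1, n_points + 1, dtype=float)
    out = np.zeros(n_points)
    for b in bumps:
        if b.width <= 0:
            raise ValueError("bump width must be positive")
        d = np.abs(t - b.center)
        d = np.minimum(d, n_points - d)  # circular distance
        sigma = b.width / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        out += b.amplitude * np.exp(-(d ** 2) / (2.0 * sigma ** 2))
    return out


def make_fgn(n: int, H: float, seed: int | np.random.Generator) -> np.ndarray:
    """Sample zero-mean, unit-variance fractional Gaussian noise.

    Uses circulant embedding of the fGn autocovariance
    ``gamma(k) = (|k-1|^{2H} - 2|k|^{2H} + |k+1|^{2H}) / 2``
    (Davies-Harte construction).  For H = 0.5 this reduces to white
    noise; the lag-1 autocorrelation is ``2^{2H-1} - 1``.
    """
    if not (0 < H < 1):
        raise ValueError("H must lie in (0, 1)")
    if n < 16:
        raise ValueError("n must be >= 16")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = np.arange(n + 1, dtype=float)
    gamma = 0.5 * (np.abs(k - 1) ** (2 * H) - 2 * k ** (2 * H) + (k + 1) ** (2 * H))
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    lam = np.fft.fft(row).real
    # tiny negative eigenvalues can appear from roundoff; clip them
    lam = np.maximum(lam, 0.0)
    m = 2 * n
    z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    x = np.fft.fft(np.sqrt(lam / m) * z).real[:n]
    return x


def _modulation_factors(truth: SyntheticGroundTruth, n_cycles: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Per-synergy, per-cycle amplitude factors around 1 with target Hurst H."""
    r = truth.n_synergies
    if truth.modulation_amp == 0:
        return np.ones((r, n_cycles))
    fac = np.empty((r, n_cycles))
    for j in range(r):
        g = make_fgn(max(n_cycles, 16), truth.persistence_H, rng)[:n_cycles]
        fac[j] = 1.0 + truth.modulation_amp * g
    return np.clip(fac, 0.05, None)


def generate_cycle_matrix(truth: SyntheticGroundTruth,
                          rng: np.random.Generator | None = None,
                          n_cycles: int | None = None,
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Build the noiseless cycle-grid factorization target.

    Returns ``(V0, H_full)`` where ``H_full`` is (r, 200 * n_cycles): each
    synergy's bump primitive tiled over cycles with per-cycle amplitude
    modulation, and ``V0 = modules @ H_full``.  With ``modulation_amp = 0``
    this is exactly ``W H`` with ``H`` the tiled template primitives.
    """
    n_cycles = truth.n_cycles if n_cycles is None else n_cycles
    rng = np.random.default_rng(truth.seed) if rng is None else rng
    templates = np.vstack([make_primitive(b) for b in truth.primitives])  # (r, 200)
    fac = _modulation_factors(truth, n_cycles, rng)                        # (r, C)
    # (r, C, 200) -> (r, C*200) with cycles concatenated in time order
    H_full = (templates[:, None, :] * fac[:, :, None]).reshape(truth.n_synergies, -1)
    V0 = truth.modules @ H_full
    return V0, H_full


def generate_recording(truth: SyntheticGroundTruth) -> SyntheticRecording:
    """Generate a synchronized force + EMG-envelope recording.

    The force trace is a train of half-sine stance pulses (peak 1.5 kN)
    separated by zero-force flight, preceded by half a flight of lead-in.
    One extra stance pulse is appended beyond ``n_cycles`` so that exactly
    ``n_cycles`` complete touchdown-to-touchdown cycles are delimited by
    the n_cycles + 1 detected touchdowns.

    The EMG is the module-mixed primitive train laid out in real time
    (stance points 1-100 spanning the stance duration, flight points
    101-200 the flight duration) plus truncated additive Gaussian noise,
    clipped at zero.  Deterministic given ``truth.seed``.
    """
    rng = np.random.default_rng(truth.seed)
    n_pulses = truth.n_cycles + 1

    f_stance = int(round(truth.stance_s * truth.force_rate))
    f_flight = int(round(truth.flight_s * truth.force_rate))
    f_lead = f_flight // 2
    pulse = 1500.0 * np.sin(np.pi * (np.arange(f_stance) + 0.5) / f_stance)
    force = np.zeros(f_lead + n_pulses * (f_stance + f_flight))
    touchdowns = np.empty(n_pulses, dtype=int)
    toeoffs = np.empty(n_pulses, dtype=int)
    for c in range(n_pulses):
        a = f_lead + c * (f_stance + f_flight)
        force[a:a + f_stance] = pulse
        touchdowns[c] = a
        toeoffs[c] = a + f_stance

    ratio = truth.emg_rate / truth.force_rate
    e_stance = int(round(f_stance * ratio))
    e_flight = int(round(f_flight * ratio))
    e_lead = int(round(f_lead * ratio))

    _, H_full = generate_cycle_matrix(truth, rng=rng, n_cycles=n_pulses)
    r = truth.n_synergies
    H_cycles = H_full.reshape(r, n_pulses, N_POINTS)

    # lay the 200-point cycle grid out in real time: 100 stance points over
    # the stance samples, 100 flight points over the flight samples
    half = N_POINTS // 2
    xs = np.arange(e_stance) * (half / e_stance)          # in [0, 100)
    xf = half + np.arange(e_flight) * (half / e_flight)   # in [100, 200)
    grid = np.arange(N_POINTS, dtype=float)
    act = np.zeros((r, e_lead + n_pulses * (e_stance + e_flight)))
    for c in range(n_pulses):
        a = e_lead + c * (e_stance + e_flight)
        for j in range(r):
            cyc = H_cycles[j, c]
            act[j, a:a + e_stance] = np.interp(xs, grid, cyc)
            act[j, a + e_stance:a + e_stance + e_flight] = np.interp(xf, grid, cyc)

    emg = truth.modules @ act
    if truth.noise_sigma > 0:
        emg = emg + truth.noise_sigma * rng.standard_normal(emg.shape)
    emg = np.clip(emg, 0.0, None)

    return SyntheticRecording(
        emg=emg,
        force=force,
        emg_rate=truth.emg_rate,
        force_rate=truth.force_rate,
        muscle_names=truth.muscle_names,
        touchdowns=touchdowns,
        toeoffs=toeoffs,
        truth=truth,
    )


def default_ground_truth(seed: int = 0, *, n_cycles: int = 60,
                         noise_sigma: float = 0.05,
                         persistence_H: float = 0.75,
                         modulation_amp: float = 0.10,
                         bimodal: bool = False,
                         condition: str = "SIM") -> SyntheticGroundTruth:
    """The packaged four-synergy running preset.

    Modules follow the canonical functional grouping of treadmill-running
    synergies: braking (quadriceps, weight acceptance in early stance),
    push-off (triceps surae + peroneus in late stance), early flight
    (tibialis anterior dorsiflexion with rectus femoris), and late flight
    (hamstrings + gluteus preparing touchdown).  Primitive bumps place
    each synergy's main activation accordingly on the 200-point grid
    (points 1-100 stance, 101-200 flight).

    With ``bimodal=True`` the late-flight synergy gets a second bump
    around touchdown, emulating a bimodal primitive profile.
    """
    m = len(DEFAULT_MUSCLES)
    W = np.zeros((m, 4))
    idx = {name: i for i, name in enumerate(DEFAULT_MUSCLES)}
    for mus, w in (("VM", 1.0), ("VL", 0.9), ("RF", 0.7), ("GM", 0.3)):
        W[idx[mus], 0] = w                                # braking
    for mus, w in (("GaM", 1.0), ("GaL", 0.85), ("SOL", 0.9), ("PL", 0.6)):
        W[idx[mus], 1] = w                                # push-off
    for mus, w in (("TA", 1.0), ("RF", 0.5), ("PL", 0.2)):
        W[idx[mus], 2] = w                                # early flight
    for mus, w in (("BF", 0.9), ("STSM", 1.0), ("GM", 0.8)):
        W[idx[mus], 3] = w                                # late flight
    prims = [
        [Bump(25, 40)],
        [Bump(60, 45)],
        [Bump(115, 50)],
        [Bump(175, 30), Bump(25, 25, 0.8)] if bimodal else [Bump(180, 40)],
    ]
    return SyntheticGroundTruth(
        modules=W, primitives=prims, n_cycles=n_cycles,
        noise_sigma=noise_sigma, persistence_H=persistence_H,
        modulation_amp=modulation_amp, seed=seed, condition=condition,
    )
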