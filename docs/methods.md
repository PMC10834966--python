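# Methods

This note documents the models and procedures the package implements,
the defaults and why they were chosen, the numerical conventions, and
what the synthetic-data generator does and does not emulate.

## Signal model

Surface EMG from m muscles during treadmill running is summarized, per
condition, as a non-negative cycle matrix `V` (m rows, 200·C columns):
each of the C gait cycles is time-normalized to 200 points (100 stance,
100 flight) and amplitude-normalized per muscle to [0, 1].  Muscle
synergies are the factors of the low-rank approximation

    V ≈ V_R = W H

with `W` (m × r) the time-invariant motor modules (relative muscle
weights per synergy) and `H` (r × 200·C) the time-varying motor
primitives.  The working assumption is that locomotor output is built
from a small set of such modules; r is chosen from the data (below).

## Preprocessing

1. **Gait events.** Touchdown is the first force sample at-or-above
   50 N following a below-threshold sample; toe-off the first sample
   back below.  Incomplete leading/trailing half-cycles are dropped.
   Crossing pairs closer than 50 ms are merged (debounce, disableable):
   insole/force-plate traces chatter near threshold; the generator's
   clean pulses are unaffected.
2. **Envelope.** Band-pass 10–500 Hz, high-pass 50 Hz, full-wave
   rectification, low-pass 20 Hz.  Every stage is a 4th-order Butterworth
   applied forward–backward (zero phase, `sosfiltfilt`).  Applying the
   same design to all three filters is standard envelope practice; the
   final low-pass can produce tiny negative excursions after
   rectification, which are clipped at zero.
3. **Time normalization.** Stance `[touchdown, toe-off)` and flight
   `[toe-off, next touchdown)` are each linearly resampled to 100
   points, half-open so the 200 points tile the cycle without
   duplication.  Cycle points are 1-based (1..200) in all reports.
4. **Cycle selection and amplitude normalization.** The last 60 cycles
   are kept (steady state).  Amplitude normalization (per-muscle
   min-subtraction, division by the maximum, within a condition) is
   applied to the cycle tensor *after* time normalization: the two
   operations commute for affine per-muscle maps, and this order makes
   the tensor bounds exact (min 0, max 1 per muscle).

Spatiotemporal parameters are per cycle: stance = toe-off − touchdown,
flight = next touchdown − toe-off, stride frequency = 1/(stance+flight).

## Synergy extraction

Gaussian NMF by multiplicative updates,

    H ← H ⊙ (WᵀV) ⁄ (WᵀW H),    W ← W ⊙ (V Hᵀ) ⁄ (W H Hᵀ),

with `1e-12` added to the denominators (guards division by zero while
preserving the monotone decrease of the squared error to numerical
tolerance).  `W`, `H` start i.i.d. uniform(0, 1] from the restart seed.
Reconstruction quality is `R² = 1 − SSE/SST` over all entries, computed
every iteration via the Gram identity
`‖V−WH‖² = ‖V‖² − 2⟨WᵀV, H⟩ + ⟨WᵀW, HHᵀ⟩`.

**Stopping.** Iterations stop when the R² change over the trailing 20
iterations is below 0.01%.  This is interpreted as *relative* change
(|R²ᵢ − R²ᵢ₋₂₀|/R²ᵢ₋₂₀ < 1e-4); an absolute mode is available
(`relative=False`).  A safety cap of 10,000 iterations applies.

**Restarts and rank sweep.** Each rank is factorized 5 times from
seeds derived deterministically from a base seed (`SeedSequence`), and
the highest-R² restart kept.  Candidate ranks run from 1 to
round(0.75·m) — 8 for the 11-muscle montage — since extracting as many
synergies as muscles would not reduce dimensionality.

**Rank selection.** The R²-vs-rank curve is iteratively pruned: fit a
simple linear regression, stop if its MSE < 1e-4, otherwise drop the
lowest-rank point and refit, until two points remain.  The selected
rank is the smallest rank in the surviving (most linear) tail — the
minimum number of synergies beyond which reconstruction only improves
marginally.  The regression is on the raw R² scale.  For reporting, W
columns are rescaled to max 1 with the inverse scale moved into H
(the product is unchanged; only the scale indeterminacy is fixed).

## Linear metrics

* **Co-contribution index.**  CI = mean(anterior) / (mean(anterior) +
  mean(posterior)) per joint, from the module weights.  Joint groups:
  hip RF | GM; knee RF, VL, VM | STSM, BF; ankle TA | GaM, GaL, SOL,
  PL.  CI is scale-invariant and undefined when both groups are zero.
* **Center of activity.**  The cycle is a circle: point t maps to angle
  θ_t = 360·(t−1)/200 (point 1 = touchdown = 0°).  With the averaged
  primitive H̄, A = Σ cosθ_t·H̄_t and B = Σ sinθ_t·H̄_t; CoA is the
  two-argument arctangent of (B, A) reported in [0, 360).  The
  two-argument form is required for angles outside the first quadrant.
* **FWHM.**  After subtracting the minimum, the number of points
  *strictly* exceeding half the maximum (ties at exactly half are out).
* **Exceedance / overlap frequencies.**  The half-max rule is applied
  within each cycle (per-cycle minima and maxima — a configurable but
  deliberate reading); the exceedance frequency of a synergy at a point
  is the fraction of cycles exceeding, and the overlap frequency the
  fraction of cycles in which at least two synergies exceed
  simultaneously.  CoA/FWHM use the cycle-averaged primitive;
  frequencies use per-cycle primitives.
* **Bimodality.**  A primitive with more than one contiguous
  above-half-max run (counted circularly, so a run across the cycle
  boundary is one run) is flagged bimodal.  CoA/FWHM are still computed
  and reported; exclusion decisions are left to the consumer.

## Fractal metrics

Both metrics are computed on the full concatenated primitive (all 60
cycles, 12,000 points), not the cycle average: the Hurst exponent is
about structure *across* cycles, and 12,000 ≫ the 200-sample fit limit.

**Higuchi fractal dimension.**  For k = 2..k_max and offsets t₀ = 1..k,
the subsampled series H(t₀), H(t₀+k), … has normalized length
`(Σ|increments|)·(n−1)/(⌊(n−t₀)/k⌋·k)/k`; L_k averages over offsets, and
HFD is the OLS slope of log L_k on log(1/k).  k_max defaults to the
fixed pipeline value 10; `select_kmax` finds the largest k keeping the
log-log curve linear (relative fit MSE < 1e-3) when data-driven
selection is wanted.  Calibration facts, all verified by the test
suite: a straight line gives 1.000; Brownian motion gives ≈ 1.5;
**i.i.d. Gaussian noise gives ≈ 2.0** — for uncorrelated samples the
mean absolute increment is lag-independent, so L_k ∝ k⁻² exactly.  The
often-quoted "1.5 for random Gaussian noise" is the value for
*integrated* noise (a random walk), via the fBm relation D = 2 − H; it
is not attainable for i.i.d. noise under this estimator.

**Rescaled-range Hurst exponent.**  For prefix lengths q = n, n/2, n/4,
… ≥ 2 (integer halving): center the first q samples, cumulate, and
divide the range of the cumulative series by the population standard
deviation of the centered prefix (the classical R/S convention; at
q = 2 this gives R/S = 1 identically).  HE is the OLS slope of
log(R/S) on log(q) for q in [2, q_inflex], q_inflex defaulting to the
fixed pipeline value 200; `select_qinflex` locates the
maximal-curvature point of the log-log curve by second differences and
falls back to the maximal q (with a warning) when the curve is linear,
as it is for exactly self-affine series.  The raw slope is reported
without clipping to [0, 1].  Plain R/S carries the well-documented
small-sample (Anis–Lloyd) bias: over the short prefixes the fit window
imposes, white noise measures ≈ 0.60 rather than the asymptotic 0.5,
and anti-persistent series are pulled toward 0.5 (fGn with H = 0.3,
n = 4096 measures ≈ 0.41).  The package implements the uncorrected
procedure on purpose — the estimator is the analysis method, bias and
all — and the test suite records these measured values; comparisons
between conditions remain valid because the bias is shared.

## Functional classification

Averaged primitives (per condition, pooled over participants) are
k-means clustered for k = 1..11 with 20 centroid initializations per k,
keeping the lowest within-cluster variance (scikit-learn's Lloyd
algorithm).  The variance curve is normalized by the total sum of
squares so the k = 1 value is 1 and the 1e-4 pruning threshold from the
rank selection applies unchanged; the cluster count is selected by the
identical pruning rule.  Modules are then clustered with the same
imposed k.  The two labelings are matched by maximal membership overlap
(Hungarian assignment on the contingency table); a synergy whose
primitive cluster and mapped module cluster agree is *fundamental*,
otherwise *combined* (a mixture of simpler synergies; excluded from
functional naming).  Fundamental clusters are named by the temporal
order of their circular-mean CoA — braking, push-off, early flight,
late flight when k = 4, generic `cluster-i` otherwise.  The scalar
score (FWHM + CoA converted to points)/200 is kept per synergy as a
diagnostic; overlap matching, not the score, is the concordance
mechanism, because a single scalar cannot align two labelings
operationally.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
not running biomechanics:

* **Primitives** are sums of circularly wrapped Gaussian bumps on the
  200-point grid, parameterized by center (cycle point), FWHM (points)
  and amplitude.  Gaussian bumps make CoA and FWHM directly checkable
  against the generating parameters.
* **Modules** in the packaged preset follow the canonical functional
  grouping of running synergies — braking (VM, VL, RF), push-off (GaM,
  GaL, SOL, PL), early flight (TA, RF), late flight (BF, STSM, GM) —
  with near-disjoint muscle groups, which keeps the planted rank
  identifiable.  A bimodal variant adds a second, well-separated bump
  to the late-flight primitive.
* **Variability.**  Per-cycle bump amplitudes are modulated by
  1 + 0.1·fGn(H) — fractional Gaussian noise sampled exactly by
  circulant embedding (Davies–Harte) — giving a controllable
  across-cycle persistence target (default H = 0.75, in line with the
  long-range persistence commonly reported for human stride-to-stride
  variability; the 10% modulation amplitude is a free design choice, not
  a claim about data).  Additive Gaussian noise (sd `noise_sigma`,
  default 0.05 of unit amplitude) is truncated at zero and controls
  local roughness independently.
* **Force** is a train of half-sine stance pulses (peak ≈ 1.5 kN, 0.20 s)
  separated by 0.15 s of zero-force flight; only its 50 N threshold
  crossings matter.  One extra pulse is appended beyond `n_cycles`
  because n complete touchdown-to-touchdown cycles require n+1
  touchdowns.
* **Signal class.**  The generated EMG is an *envelope-style*
  non-negative signal (the mixture itself plus truncated noise).  It
  carries no >50 Hz content, so the raw-EMG filter cascade would
  destroy it; dataset metadata records `signal_type: envelope` and the
  pipeline skips the cascade for such inputs (`apply_filters` config:
  auto/always/never).  Consequently the generator does not exercise the
  filter stage — that stage is validated separately on constructed
  raw-like signals (sinusoids, carriers, noise).

What passing tests on this generator do **not** show: robustness to
non-stationary electrode artifacts, crosstalk between channels,
force-plate drift, non-Gaussian EMG statistics, or modules that change
within a condition.  Real-data behavior on those axes is untested.

## Seeding and determinism

Every random draw derives from one integer master seed through
`numpy.random.SeedSequence` fan-out (per-participant generation seeds,
per-rank/per-restart NMF seeds, clustering seed); all derived seeds are
kept below 2³¹.  Re-running the pipeline with the same inputs and seed
reproduces every CSV byte-identically.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| force threshold | 50 N | touchdown/toe-off detection |
| debounce | 50 ms | merge threshold chatter (off: `None`) |
| cycles analyzed | 60 | steady-state tail of each condition |
| cycle grid | 200 pts (100+100) | stance + flight |
| NMF restarts | 5 | random re-initializations per rank |
| NMF stop | 0.01% over 20 iter | relative R² change |
| max rank | round(0.75·m) | 8 for 11 muscles |
| rank-selection MSE | 1e-4 | linear-tail pruning threshold |
| k_max | 10 | Higuchi lag limit |
| q_inflex | 200 | R/S fit limit |
| k-means | k=1..11, 20 inits | primitive/module clustering |

## Problem sizes used in the validation suites

The packaged validation runs use the preset scale: 11 muscles, 4
synergies, 60 cycles (12,000-column matrices), 10 generator seeds for
rank-recovery checks, 50 series for the fractal calibration means, 20
seeds per fGn recovery point, and a 4-participant dataset for the
end-to-end run — sizes at which every reported mean is stable to well
inside its stated tolerance.

## Known limitations

* The amplitude normalization is per condition, so absolute amplitudes
  are not comparable across conditions (by design).
* Plain R/S and Higuchi estimates carry the estimator biases discussed
  above; no bias correction is applied.
* Combined-synergy decomposition is out of scope; combined synergies
  are flagged and left unlabeled.
* The CLI stage commands exchange CSV intermediates and re-derive
  nothing; the library pipeline is the canonical path.
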