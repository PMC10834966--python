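# synergait

Muscle-synergy analysis of treadmill-running surface EMG: non-negative
matrix factorization of multi-muscle cycle matrices into motor modules
and motor primitives, linear and fractal descriptors of the primitives,
and functional classification of the extracted synergies — together
with a ground-truthed synthetic-data generator for validating every
stage.

**Who it is for.**  Researchers in neuromechanics and motor control who
record multi-channel sEMG and ground-reaction force during locomotion
and want a tested, reproducible pipeline from raw signals to per-synergy
metrics.

## The model

Per condition, the preprocessed EMG of m muscles over C gait cycles
(each time-normalized to 200 points: 100 stance + 100 flight) forms a
non-negative matrix V (m × 200·C), factorized as

    V ≈ V_R = W H

by Gaussian NMF with multiplicative updates
`H ← H ⊙ (WᵀV)/(WᵀW H)` and `W ← W ⊙ (V Hᵀ)/(W H Hᵀ)`.
`W` holds the time-invariant muscle weights of each synergy (motor
modules), `H` the time-varying activations (motor primitives).
Reconstruction quality is R² = 1 − SSE/SST; the iteration stops when R²
changes by less than 0.01% over 20 iterations; each rank is refit from
5 random restarts and the number of synergies is the smallest rank in
the most linear tail of the R²-vs-rank curve (iterative pruning until
the linear-fit MSE < 1e-4, ranks capped at 75% of the muscle count).

Per synergy the package computes:

* **CI** — co-contribution index, mean anterior / (anterior + posterior)
  module weight at the hip, knee and ankle (1 = purely anterior, 0 =
  purely posterior);
* **CoA** — center of activity, the circular-mean angle of the averaged
  primitive over the cycle (0° = touchdown);
* **FWHM** — points on which the min-subtracted primitive exceeds half
  its maximum, plus per-point exceedance and overlap frequencies across
  cycles;
* **HFD** — Higuchi fractal dimension (local roughness, lags 2..10);
* **HE** — rescaled-range Hurst exponent (across-cycle persistence,
  prefix halving, slope fitted for q in [2, 200]).

Synergies are classified functionally by dual k-means (primitives, then
modules with the same imposed k); concordant synergies are fundamental
(braking, push-off, early flight, late flight, named by CoA order) and
discordant ones combined.

See `docs/methods.md` for the full procedure, defaults and estimator
caveats.

## Worked example

```
$ python examples/05_full_pipeline.py
participant  synergy  rank    r2  coa_deg  fwhm_points  ci_ankle   hfd  hurst        label
        P01        1     4 0.985  105.573           42     0.000 1.289  1.013     push-off
        P01        2     4 0.985  201.550           54     0.926 1.439  0.955 early-flight
        P01        3     4 0.985  325.173           42     0.538 1.317  0.942  late-flight
        P01        4     4 0.985   44.991           36     0.000 1.283  0.972      braking
        P02        1     4 0.984  198.485           53     0.928 1.456  0.919 early-flight
        P02        2     4 0.984   49.165           38     0.000 1.331  0.966      braking
        P02        3     4 0.984  319.918           38     0.011 1.298  0.932  late-flight
        P02        4     4 0.984  111.354           40     0.016 1.280  1.001     push-off
```

Two synthetic participants are simulated from the four-synergy running
preset and pushed through the whole chain.  For every participant the
rank-selection rule finds the 4 planted synergies (R² ≈ 0.98 at rank 4),
each synergy is concordantly clustered from both its primitive and its
module (no "combined" label), and the labels follow the center of
activity over the cycle: braking peaks early in stance (CoA ≈ 45°),
push-off in late stance (≈ 105°), early flight just after toe-off
(≈ 200°), late flight before the next touchdown (≈ 320°).  The ankle CI
separates the tibialis-anterior-driven early-flight synergy (≈ 0.93,
anterior) from the triceps-surae push-off (≈ 0, posterior).  HFD ≈ 1.3
and HE ≈ 0.95 reflect the preset's mild additive noise and persistent
cycle-to-cycle amplitude modulation.

The other examples cover each capability in isolation: recording
simulation (`01`), extraction and module recovery (`02`), linear
metrics (`03`), fractal calibration (`04`).  A thin CLI wraps the same
library (`synergait simulate|preprocess|extract|metrics|classify|run`).

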