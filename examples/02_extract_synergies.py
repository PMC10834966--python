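"""Extract muscle synergies from a planted low-rank cycle matrix.

Plants a rank-4 mixture V = W H with 5% noise, runs the full rank sweep
(multiplicative-update NMF, best of 5 restarts per rank) and checks that
the selection rule finds the planted rank and the modules are recovered.
"""

from itertools import permutations

import numpy as np

from synergait import (default_ground_truth, generate_cycle_matrix,
                       rank_curve, select_rank)

truth = default_ground_truth(seed=0, noise_sigma=0.05)
rng = np.random.default_rng(0)
V0, _ = generate_cycle_matrix(truth, rng=rng)
V = np.clip(V0 + truth.noise_sigma * rng.standard_normal(V0.shape), 0, None)

curve = rank_curve(V, base_seed=0)
r = select_rank(curve)
print("rank :", " ".join(f"{k:6d}" for k in curve.ranks))
print("R^2  :", " ".join(f"{v:6.3f}" for v in curve.r2_values))
print(f"selected rank: {r} (planted: {truth.n_synergies})")

dec = curve.best(r).normalized()
A = dec.W / np.linalg.norm(dec.W, axis=0)
B = truth.modules / np.linalg.norm(truth.modules, axis=0)
C = B.T @ A
best = max(min(C[i, p[i]] for i in range(r)) for p in permutations(range(r)))
print(f"worst matched module cosine similarity: {best:.3f}")
# R^2 jumps until the planted rank then flattens; the pruning rule stops
# at the start of the linear tail, and each recovered module column
# matches a planted one almost perfectly.
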