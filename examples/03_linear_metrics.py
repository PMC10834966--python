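"""Linear descriptors of motor primitives and modules.

Computes center of activity (CoA), full width at half maximum (FWHM)
and the per-joint co-contribution index (CI) for the preset synergies.
"""

import numpy as np

from synergait import (DEFAULT_MUSCLES, co_contribution_index,
                       default_ground_truth, generate_cycle_matrix,
                       primitive_metrics)

truth = default_ground_truth(seed=0)
_, H = generate_cycle_matrix(truth)
met = primitive_metrics(H)

names = ("braking", "push-off", "early flight", "late flight")
print(f"{'synergy':<14}{'CoA [deg]':>10}{'FWHM [pts]':>11}"
      f"{'CI hip':>8}{'CI knee':>8}{'CI ankle':>9}")
for j, name in enumerate(names):
    ci = []
    for joint in ("hip", "knee", "ankle"):
        try:
            ci.append(f"{co_contribution_index(truth.modules[:, j], DEFAULT_MUSCLES, joint):.2f}")
        except ValueError:   # no anterior or posterior muscle active at this joint
            ci.append("--")
    print(f"{name:<14}{met.coa_deg[j]:>10.1f}{met.fwhm_points[j]:>11d}"
          f"{ci[0]:>8}{ci[1]:>8}{ci[2]:>9}")
print(f"max overlap frequency across the cycle: {met.overlap_freq.max():.2f}")
# CoA converts the bump centers to cycle angles (0 deg = touchdown);
# CI = 1 means purely anterior muscles at that joint, 0 purely posterior.
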