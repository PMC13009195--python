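"""Simulate the same reaching sequence with both planners.

Plans sequence 0 (start -> blue -> olive -> home) with the flat vpSOC(3)
controller and the hierarchical HiSeq controller, simulates a handful of
noisy trials with each, and prints the per-trial coarticulation features.
Takes a few seconds.
"""

import numpy as np

from reachseq import (
    PlantParams,
    default_layout,
    plan_sequence,
    simulate_vpsoc,
)
from reachseq.hiseq import build_hiseq_plan, make_shc_connectivity, simulate_hiseq
from reachseq.kinematics import trial_features

layout = default_layout()
geometry = layout.sequence_geometry(0)
plant = PlantParams(add_noise=8000.0)

print("sequence 0 waypoints (mm):")
for label, point in zip(["start", *[t.label for t in geometry.targets]],
                        geometry.waypoints()):
    print(f"  {label:6s} {point}")

# flat planning: one optimized trajectory through all three targets
matrices, cost, solution = plan_sequence(geometry, plant, h=(2.0, 2.0, 2.0), r=1e-6)
vp_trials = simulate_vpsoc(solution, matrices, geometry, plant, n_trials=5, seed=1)

# hierarchical planning: a 2-target block plus a return block, sequenced by
# the stable-heteroclinic-channel layer
plan = build_hiseq_plan(geometry, plant, h=(2.0, 2.0, 2.0), r=1e-6)
shc = make_shc_connectivity(len(plan.attractor_map))
hi_trials = simulate_hiseq(plan, shc, plant, n_trials=5, seed=1)

for name, trials in (("vpSOC(3)", vp_trials), ("HiSeq", hi_trials)):
    print(f"\n{name} trials:")
    print("  trial   hc1(mm)  tc1(mm)  maxcurv1  maxcurv2  peak(mm/s)")
    for tr in trials:
        f = trial_features(tr, geometry)
        print(
            f"  {tr.trial:5d}  {f['hc1']:8.2f} {f['tc1']:8.2f}"
            f"  {f['maxcurv1']:8.4f}  {f['maxcurv2']:8.4f}  {tr.peak_speed():9.0f}"
        )
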