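"""The mechanistic signature separating the two planners.

For a flat planner the whole sequence is one optimization problem: when a
dominant first-target weight and a lax control cost drive strong
anticipatory coarticulation (halfway cross far to the inside), the rest of
the trajectory is bent along with it, and curvature at the *second* target
collapses too.  The hierarchical planner's return block is planned
independently, so it keeps turning sharply at the second target no matter
how aggressive the first block has become.

This script fixes a dominant first-target weight (h1 = 25.7) and sweeps the
control cost r from stiff to lax, printing the anticipatory coarticulation
hc1 and the two per-target curvatures.  Takes ~1 minute.
"""

from reachseq import (
    PlantParams,
    default_layout,
    feature_point,
    plan_sequence,
    simulate_vpsoc,
)
from reachseq.hiseq import build_hiseq_plan, make_shc_connectivity, simulate_hiseq

layout = default_layout()
geometry = layout.sequence_geometry(0)
plant = PlantParams(add_noise=8000.0)


def simulate(model, r, h1=25.7114, h2=4.2602, n=12, seed=0):
    h = (h1, h2, h2)
    if model == "vpsoc3":
        matrices, _, sol = plan_sequence(geometry, plant, h=h, r=r)
        return simulate_vpsoc(sol, matrices, geometry, plant, n_trials=n, seed=seed)
    plan = build_hiseq_plan(geometry, plant, h=h, r=r)
    shc = make_shc_connectivity(len(plan.attractor_map))
    return simulate_hiseq(plan, shc, plant, n_trials=n, seed=seed)


for model in ("vpsoc3", "hiseq"):
    print(f"\n{model}: control-cost sweep at dominant h1 = 25.7, h2 = 4.26")
    print("        r   mean hc1   maxcurv1  maxcurv2")
    for r in (1e-6, 1e-5, 1.7e-4):
        fp = feature_point(simulate(model, r), geometry, label=f"r={r}")
        print(
            f"  {r:7.0e}  {fp.means['hc1']:9.2f}  {fp.means['maxcurv1']:9.4f}"
            f"  {fp.means['maxcurv2']:9.4f}"
        )

print(
    "\nAt r = 1.7e-4 both models coarticulate strongly (hc1 near -10 mm), but"
    "\nonly the flat planner lets the second-target turn collapse with it:"
    "\nthe hierarchical return block keeps maxcurv2 high.  This decoupling is"
    "\nthe signature the model-coverage classifier exploits."
)
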