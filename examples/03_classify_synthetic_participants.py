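"""End-to-end pipeline on a small synthetic cohort.

Generates four synthetic participants (two per planning model), simulates
compact coverage grids for both models on sequence 0, builds the coverage
regions, and classifies each participant's sequence-0 cell.  The printed
labels should recover the generating models.  Takes ~2-3 minutes; the
packaged full-size grids (``default_grid``) are what the study pipeline
uses, the ones here are trimmed for speed.
"""

from reachseq import (
    GridSpec,
    build_regions,
    classify_dataset,
    coverage_table,
    default_layout,
    feature_point,
    generate_cohort,
    recovery_cohort,
    simulate_grid,
)

layout = default_layout()
geometry = layout.sequence_geometry(0)

print("generating 4 synthetic participants (2 vpSOC(3), 2 HiSeq)...")
cohort = generate_cohort(recovery_cohort(seed=42, n_participants=4, n_trials=15),
                         layout=layout)

print("simulating compact coverage grids...")
vp_spec = GridSpec(
    model="vpsoc3", r_values=(2.5119e-7, 1.2589e-6, 6.3096e-6),
    h1_values=(1.15, 1.884, 3.0866, 5.0568, 8.2845, 13.5724),
    h2_values=(1.0, 2.0, 4.0), n_trials=20,
)
hi_spec = GridSpec(
    model="hiseq", r_values=(1e-6, 1e-5, 1.7e-4),
    h1_values=(0.3253, 1.1338, 3.9517, 13.7724, 25.7114, 48.0),
    h2_values=(1.2081, 2.2686, 4.2602), n_trials=10,
)
vp_table, vp_failed = simulate_grid(vp_spec, geometry)
hi_table, hi_failed = simulate_grid(hi_spec, geometry)
print(f"  vpsoc3: {len(vp_table)} cells ({len(vp_failed)} failed)")
print(f"  hiseq:  {len(hi_table)} cells ({len(hi_failed)} failed)")

vp_regions = build_regions(vp_table, "vpsoc3")
hi_regions = build_regions(hi_table, "hiseq")

truth = cohort.truth.set_index(["participant", "sequence"])
points, models = [], []
for (pid, sid), cell in sorted(cohort.trials.items()):
    points.append(feature_point(cell, geometry, label=pid))
    models.append(truth.loc[(pid, sid)]["model"])

labels = classify_dataset(points, vp_regions, hi_regions)
labels["truth"] = models

print("\nper-participant labels (sequence 0):")
print(labels[["label_cell", "truth", "vpsoc3_covered", "hiseq_covered", "label"]]
      .to_string(index=False))
print("\ncoverage table (percent of cells):")
print(coverage_table(labels).round(1).to_string(index=False))
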