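# reachseq

Flat versus hierarchical planning of sequential reaching movements:
simulation, kinematic coarticulation analysis, and model-coverage
classification.

When people reach through a sequence of targets, do they plan the whole
sequence as one fused trajectory, or compose it online from simpler
movements?  `reachseq` implements the two competing computational accounts
and the analysis pipeline that separates them from fingertip kinematics
alone:

- **vpSOC(3)** — *flat planning*: the entire three-target sequence is one
  finite-horizon stochastic optimal control problem with signal-dependent
  motor noise.  Each target is a via-point with its own precision weight
  `h_i`; a single control-cost weight `r` trades accuracy against effort.
- **HiSeq** — *hierarchical planning*: simple via-point controllers (a
  two-target block and a return block) are sequenced at run time by a
  generalized Lotka–Volterra system moving through a stable heteroclinic
  channel (SHC).  A monitor kicks the sequencing state from one saddle to
  the next when the hand reaches the current sub-goal; during the brief
  hand-off both controllers blend, which is what produces coarticulation
  around the intermediate target.

The discriminating signature is *decoupling*.  A flat planner bends the
whole trajectory together: drive it to coarticulate strongly into the first
target and the turn at the second target collapses too.  A hierarchical
planner's second block is planned independently, so it keeps turning
sharply no matter how aggressive the first block becomes.  The classifier
exploits this by simulating each model over a parameter grid, building the
region of kinematic features it can cover, and labeling observed cells by
which model's region their 99% confidence rectangle intersects.

## Worked example

```python
from reachseq import PlantParams, default_layout, plan_sequence, simulate_vpsoc
from reachseq.kinematics import trial_features

layout = default_layout()                  # canonical table of 5 targets
geometry = layout.sequence_geometry(0)     # start -> blue -> olive -> home
plant = PlantParams(add_noise=8000.0)

matrices, cost, solution = plan_sequence(geometry, plant, h=(2, 2, 2), r=1e-6)
trials = simulate_vpsoc(solution, matrices, geometry, plant, n_trials=5, seed=1)
print(trial_features(trials[0], geometry))
```

Output (one noisy trial):

```
{'trial': 0, 'sequence': '0', 'tag': 'vpsoc', 'hc1': 2.85, 'tc1': 1.86,
 'maxcurv1': 0.0445, 'maxcurv2': 0.0642, 'fusion1': 0.47, 'fusion2': 0.49}
```

`hc1` is the halfway coarticulation (signed lateral offset where the path
crosses the perpendicular at the midpoint of the start–target line, positive
toward the next target), `tc1` the transitional cross at the first target,
`maxcurv1/2` the peak absolute path curvature inside each target circle, and
`fusion1/2` how continuously the segments are executed (1 = fused
pass-through, 0 = full stop).

The `examples/` scripts tell the full story:

- `01_two_planners_one_sequence.py` — both planners on the same sequence;
- `02_decoupling_contrast.py` — the decoupling signature as a control-cost
  sweep (the flat planner's `maxcurv2` collapses with strong coarticulation,
  the hierarchical one's does not);
- `03_classify_synthetic_participants.py` — the end-to-end pipeline
  recovering the generating model of synthetic participants.

## Command line

Every stochastic subcommand requires an explicit `--seed`; all tables are
TSV with a provenance header.

```sh
reachseq synth    --seed 7 --out data/cohort --participants 20
reachseq features --data data/cohort --out features.tsv
reachseq stats    --features features.tsv --out stats.tsv
reachseq grid     --seed 0 --model vpsoc3 --out vpgrid.tsv
reachseq grid     --seed 0 --model hiseq  --out higrid.tsv
reachseq classify --data data/cohort --vpsoc-grid vpgrid.tsv \
                  --hiseq-grid higrid.tsv --out labels.tsv
```

## Layout of the package

| module | contents |
| --- | --- |
| `reachseq.plant` | discrete-time linear arm with signal-dependent noise |
| `reachseq.vpsoc` | via-point LQG solver (coupled controller/estimator) |
| `reachseq.hiseq` | SHC sequencing layer, monitor, hierarchical simulation |
| `reachseq.kinematics` | crossing measures, curvature, segmentation, fusion |
| `reachseq.stats` | normality-gated tests, correlation CIs, permutation bootstrap |
| `reachseq.classify` | parameter grids, coverage regions, cell labeling |
| `reachseq.synthetic` | canonical task layout, synthetic cohorts with ground truth |
| `reachseq.cli` | `reachseq` command-line front end |

Modeling conventions, parameter choices, and known limitations are
documented in `docs/methods.md`.
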