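"""Model-coverage classification.

Each planning model is simulated over a grid of its three free parameters
(control cost ``r`` and position-cost weights ``h1``, ``h2``); per-cell
kinematic features define the model's coverage regions in feature space, and
an observed participant-sequence cell is labeled by whether its 99% CI
rectangle intersects those regions on three criterion surfaces:

1. the mean hc1 interval,
2. the (hc1, maxcurv2) plane,
3. the (maxcurv1, maxcurv2) plane.

A cell is *covered* by a model when all three criteria intersect, and
*incompatible* with a model only when it is both uncovered and shows
coarticulation significantly different from zero; the overall label is one of
``both``, ``vpsoc_only``, ``hiseq_only``, ``neither``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
import shapely
from scipy import stats as sps
from shapely.geometry import MultiPoint, Point, box

from .geometry import SequenceGeometry
from .hiseq import build_hiseq_plan, make_shc_connectivity, simulate_hiseq
from .kinematics import trial_features
from .plant import PlantParams
from .stats import SignificanceResult, coarticulation_test
from .trajectory import Trajectory
from .vpsoc import plan_sequence, simulate_vpsoc

__all__ = [
    "GridSpec",
    "FeaturePoint",
    "CoverageRegion",
    "FEATURES",
    "CRITERIA",
    "default_grid",
    "matched_grids",
    "simulate_grid",
    "feature_point",
    "build_region",
    "build_regions",
    "classify_point",
    "classify_dataset",
    "coverage_table",
]

#: kinematic features summarized per cell
FEATURES = ("hc1", "tc1", "maxcurv1", "maxcurv2")
#: the three criterion surfaces used for coverage
CRITERIA = (("hc1",), ("hc1", "maxcurv2"), ("maxcurv1", "maxcurv2"))


@dataclass(frozen=True)
class GridSpec:
    """Parameter grid for one model: the cross product of r, h1, h2 values."""

    model: str  # "vpsoc3" | "hiseq"
    r_values: tuple[float, ...]
    h1_values: tuple[float, ...]
    h2_values: tuple[float, ...]
    n_trials: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("vpsoc3", "hiseq"):
            raise ValueError(f"unknown model '{self.model}'")
        if not (self.r_values and self.h1_values and self.h2_values):
            raise ValueError("all three value lists must be non-empty")
        if self.n_trials < 3:
            raise ValueError("need at least 3 trials per cell")

    @property
    def n_combinations(self) -> int:
        return len(self.r_values) * len(self.h1_values) * len(self.h2_values)

    def combinations(self):
        yield from product(self.r_values, self.h1_values, self.h2_values)


def default_grid(model: str) -> GridSpec:
    """Packaged default grids (306 vpSOC(3) / 1008 HiSeq combinations).

    The grid values are calibrated so that the simulated features span the
    ranges the models produce on the canonical geometry: log-spaced control
    costs and position weights from lax to aggressive, including (for HiSeq)
    the strongly anticipatory regime of large first-target weights.
    """
    if model == "vpsoc3":
        return GridSpec(
            model="vpsoc3",
            r_values=tuple(np.logspace(-8, -4.5, 6)),
            h1_values=tuple(np.round(np.logspace(np.log10(1.15), np.log10(16.0), 17), 4)),
            h2_values=(1.0, 2.0, 4.0),
            n_trials=120,
        )
    if model == "hiseq":
        return GridSpec(
            model="hiseq",
            r_values=(1e-8, 1e-7, 1e-6, 1e-5, 5e-5, 1.7e-4, 1e-3),
            h1_values=tuple(np.round(np.logspace(np.log10(0.05), np.log10(48.0), 12), 4)),
            h2_values=tuple(np.round(np.logspace(np.log10(0.25), np.log10(8.0), 12), 4)),
        )
    raise ValueError(f"unknown model '{model}'")


def matched_grids(n_trials: int = 20, seed: int = 0) -> tuple[GridSpec, GridSpec]:
    """Identical (r, h1, h2) grids for both models, for decoupling contrasts.

    Both models share the HiSeq first-target weight range, a coarse set of
    later-target weights, and control costs spanning stiff to lax -- the lax
    node sitting in HiSeq's decoupled regime.  Simulating both models over
    this common grid makes their within-grid feature correlations directly
    comparable.
    """
    h1 = tuple(np.round(np.logspace(np.log10(0.05), np.log10(48.0), 12), 4))
    h2 = (1.0, 2.0, 4.0)
    r = (1e-8, 1e-7, 1e-6, 1e-5, 1.7e-4)
    return (
        GridSpec(model="vpsoc3", r_values=r, h1_values=h1, h2_values=h2,
                 n_trials=n_trials, seed=seed),
        GridSpec(model="hiseq", r_values=r, h1_values=h1, h2_values=h2,
                 n_trials=n_trials, seed=seed),
    )


@dataclass(frozen=True)
class FeaturePoint:
    """Per-cell feature summary: means, SDs, and 99% CI half-widths."""

    label: str
    sequence: str
    n: int
    means: dict
    sds: dict
    ci99: dict
    significance: SignificanceResult | None = None

    def ci_box(self, fx: str, fy: str):
        """Axis-aligned 99% CI rectangle in the (fx, fy) plane."""
        return box(
            self.means[fx] - self.ci99[fx],
            self.means[fy] - self.ci99[fy],
            self.means[fx] + self.ci99[fx],
            self.means[fy] + self.ci99[fy],
        )

    def ci_interval(self, fx: str) -> tuple[float, float]:
        return (self.means[fx] - self.ci99[fx], self.means[fx] + self.ci99[fx])


def feature_point(
    trials: list[Trajectory],
    geometry: SequenceGeometry,
    label: str = "",
    min_valid: int = 3,
) -> FeaturePoint:
    """Summarize a cell of trials into a FeaturePoint.

    Trials whose feature extraction fails (never visiting a target, stuck
    sequencing) are dropped; fewer than ``min_valid`` valid trials raises.
    CI half-widths use the t distribution at n - 1 df and 99% coverage.
    """
    rows = []
    for tr in trials:
        if tr.meta.get("stuck"):
            continue
        try:
            rows.append(trial_features(tr, geometry))
        except ValueError:
            continue
    if len(rows) < min_valid:
        raise ValueError(
            f"cell '{label}': only {len(rows)}/{len(trials)} trials produced features"
        )
    df = pd.DataFrame(rows)
    n = len(df)
    tcrit = sps.t.ppf(0.995, n - 1)
    means = {f: float(df[f].mean()) for f in FEATURES}
    sds = {f: float(df[f].std(ddof=1)) for f in FEATURES}
    ci99 = {f: float(tcrit * sds[f] / np.sqrt(n)) for f in FEATURES}
    sig = coarticulation_test(df["hc1"].to_numpy())
    return FeaturePoint(
        label=label, sequence=geometry.sequence_id, n=n,
        means=means, sds=sds, ci99=ci99, significance=sig,
    )


def _simulate_cell(model, geometry, plant, r, h1, h2, n_trials, seed):
    h = (h1, h2, h2)
    if model == "vpsoc3":
        matrices, _, solution = plan_sequence(geometry, plant, h=h, r=r)
        return simulate_vpsoc(
            solution, matrices, geometry, plant, n_trials=n_trials, seed=seed, tag=model
        )
    plan = build_hiseq_plan(geometry, plant, h=h, r=r)
    shc = make_shc_connectivity(len(plan.attractor_map))
    return simulate_hiseq(plan, shc, plant, n_trials=n_trials, seed=seed, tag=model)


def simulate_grid(
    spec: GridSpec,
    geometry: SequenceGeometry,
    plant: PlantParams | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Simulate every grid cell on one sequence geometry.

    Returns a feature table (one row per successful cell: parameters plus
    mean/sd/ci99 of every feature) and a list of failure records; failed
    cells (solver non-convergence, degenerate trajectories) are excluded
    from the table, never fatal.
    """
    if plant is None:
        plant = PlantParams(add_noise=8000.0)
    master = np.random.default_rng(spec.seed)
    rows, failures = [], []
    for r, h1, h2 in spec.combinations():
        cell_seed = int(master.integers(2**63))
        label = f"{spec.model} r={r:g} h1={h1:g} h2={h2:g}"
        try:
            trials = _simulate_cell(
                spec.model, geometry, plant, r, h1, h2, spec.n_trials, cell_seed
            )
            fp = feature_point(trials, geometry, label=label)
        except (ValueError, FloatingPointError, np.linalg.LinAlgError) as exc:
            failures.append({"cell": label, "error": str(exc)})
            continue
        row = {
            "model": spec.model, "sequence": geometry.sequence_id,
            "r": r, "h1": h1, "h2": h2, "n": fp.n,
        }
        for f in FEATURES:
            row[f"mean_{f}"] = fp.means[f]
            row[f"sd_{f}"] = fp.sds[f]
            row[f"ci99_{f}"] = fp.ci99[f]
        rows.append(row)
    return pd.DataFrame(rows), failures


@dataclass(frozen=True)
class CoverageRegion:
    """Bounded region a model covers on one criterion surface.

    1-D criteria carry an interval; 2-D criteria a polygon built from the
    grid's cell means (concave hull, loosened until all generating points
    are contained; convex hull as fallback)."""

    model: str
    features: tuple[str, ...]
    geometry: object  # shapely geometry for 2-D, (lo, hi) for 1-D
    method: str = "concave"

    def covers(self, fp: FeaturePoint) -> bool:
        """Whether the point's 99% CI rectangle intersects the region."""
        if len(self.features) == 1:
            lo, hi = self.geometry
            a, b = fp.ci_interval(self.features[0])
            return a <= hi and b >= lo
        return bool(self.geometry.intersects(fp.ci_box(*self.features)))

    def contains_point(self, xy) -> bool:
        if len(self.features) == 1:
            lo, hi = self.geometry
            return lo <= xy[0] <= hi
        return bool(self.geometry.intersects(Point(*xy)))


def build_region(
    points: np.ndarray,
    model: str = "",
    features: tuple[str, ...] = (),
    ratio: float = 0.3,
) -> CoverageRegion:
    """Region from 2-D feature points: concave hull containing all points.

    The concave-hull ratio is relaxed toward 1 (the convex hull) until every
    generating point lies inside; degenerate collinear sets give a zero-width
    line region.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must have shape (n, 2)")
    if len(pts) < 3:
        raise ValueError("need at least 3 points")
    mp = MultiPoint([tuple(p) for p in pts])
    method = "concave"
    geom = None
    for rr in (ratio, 0.5, 0.75, 1.0):
        cand = shapely.concave_hull(mp, ratio=rr)
        if cand.geom_type == "Polygon" and all(
            cand.covers(Point(*p)) for p in pts
        ):
            geom = cand
            method = f"concave(ratio={rr})"
            break
    if geom is None:
        geom = mp.convex_hull  # may be a LineString for collinear input
        method = "convex"
    return CoverageRegion(model=model, features=features, geometry=geom, method=method)


def build_regions(feature_table: pd.DataFrame, model: str) -> dict[tuple[str, ...], CoverageRegion]:
    """All three criterion regions from a simulate_grid feature table."""
    df = feature_table[feature_table["model"] == model]
    if df.empty:
        raise ValueError(f"no rows for model '{model}'")
    regions: dict[tuple[str, ...], CoverageRegion] = {}
    hc = df["mean_hc1"].to_numpy()
    regions[("hc1",)] = CoverageRegion(
        model=model, features=("hc1",),
        geometry=(float(hc.min()), float(hc.max())), method="interval",
    )
    for pair in CRITERIA[1:]:
        pts = df[[f"mean_{pair[0]}", f"mean_{pair[1]}"]].to_numpy()
        regions[pair] = build_region(pts, model=model, features=pair)
    return regions


def classify_point(
    fp: FeaturePoint,
    vpsoc_regions: dict,
    hiseq_regions: dict,
    significance: SignificanceResult | None = None,
) -> dict:
    """Label one cell against both models' regions.

    Per criterion, a model covers the cell iff the CI rectangle (or interval)
    intersects its region; a model covers the cell overall iff all three
    criteria do.  Incompatibility with a model additionally requires
    significant coarticulation: an uncovered cell without significant hc1
    still counts as compatible.
    """
    sig = significance if significance is not None else fp.significance
    if sig is None:
        raise ValueError("a coarticulation significance result is required")
    out = {"label_cell": fp.label, "sequence": fp.sequence}
    covered = {}
    for name, regions in (("vpsoc3", vpsoc_regions), ("hiseq", hiseq_regions)):
        per = []
        for crit in CRITERIA:
            if crit not in regions:
                raise ValueError(f"missing {name} region for criterion {crit}")
            hit = regions[crit].covers(fp)
            out[f"{name}_{'_'.join(crit)}"] = hit
            per.append(hit)
        covered[name] = all(per)
        out[f"{name}_covered"] = covered[name]
    compat = {m: covered[m] or not sig.significant for m in covered}
    if compat["vpsoc3"] and compat["hiseq"]:
        label = "both"
    elif compat["vpsoc3"]:
        label = "vpsoc_only"
    elif compat["hiseq"]:
        label = "hiseq_only"
    else:
        label = "neither"
    out["significant_hc1"] = sig.significant
    out["label"] = label
    return out


def classify_dataset(
    points: list[FeaturePoint],
    vpsoc_regions: dict,
    hiseq_regions: dict,
) -> pd.DataFrame:
    """Classify a list of cells; one row per cell."""
    if not points:
        raise ValueError("no cells to classify")
    return pd.DataFrame(
        [classify_point(fp, vpsoc_regions, hiseq_regions) for fp in points]
    )


def coverage_table(labels: pd.DataFrame) -> pd.DataFrame:
    """Percentage of cells covered by each model, per criterion plus Total.

    Rows = the three criterion surfaces and 'Total' (all three); columns =
    vpSOC(3), HiSeq, Both.
    """
    if labels.empty:
        raise ValueError("empty classification table")
    rows = []
    for crit in CRITERIA:
        key = "_".join(crit)
        vp = labels[f"vpsoc3_{key}"].mean() * 100
        hi = labels[f"hiseq_{key}"].mean() * 100
        both = (labels[f"vpsoc3_{key}"] & labels[f"hiseq_{key}"]).mean() * 100
        rows.append({"criterion": key, "vpsoc3": vp, "hiseq": hi, "both": both})
    vp = labels["vpsoc3_covered"].mean() * 100
    hi = labels["hiseq_covered"].mean() * 100
    both = (labels["vpsoc3_covered"] & labels["hiseq_covered"]).mean() * 100
    rows.append({"criterion": "Total", "vpsoc3": vp, "hiseq": hi, "both": both})
    return pd.DataFrame(rows)
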