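import numpy as np
import pandas as pd
import pytest

from reachseq import GridSpec, default_grid, matched_grids, simulate_grid
from reachseq.classify import (
    CRITERIA,
    FEATURES,
    CoverageRegion,
    FeaturePoint,
    build_region,
    build_regions,
    classify_dataset,
    classify_point,
    coverage_table,
    feature_point,
)
from reachseq.stats import SignificanceResult


def make_point(hc1=0.0, tc1=0.0, mc1=0.05, mc2=0.05, ci=0.5, significant=True):
    means = dict(zip(FEATURES, (hc1, tc1, mc1, mc2)))
    sig = SignificanceResult(
        mean=hc1, n=20, normality_p=0.5, test="t", statistic=3.0,
        p_value=0.001 if significant else 0.5, significant=significant,
        alpha=0.01, sem=0.1,
    )
    return FeaturePoint(
        label="cell", sequence="0", n=20, means=means,
        sds={f: 1.0 for f in FEATURES}, ci99={f: ci for f in FEATURES},
        significance=sig,
    )


def square_regions(model, lo=-1.0, hi=1.0):
    pts = np.array([[lo, lo], [lo, hi], [hi, lo], [hi, hi], [0.0, 0.0]])
    return {
        ("hc1",): CoverageRegion(model, ("hc1",), (lo, hi), "interval"),
        ("hc1", "maxcurv2"): build_region(pts, model, ("hc1", "maxcurv2")),
        ("maxcurv1", "maxcurv2"): build_region(pts, model, ("maxcurv1", "maxcurv2")),
    }


def test_gridspec_validation():
    with pytest.raises(ValueError):
        GridSpec(model="nope", r_values=(1e-6,), h1_values=(1.0,), h2_values=(1.0,))
    with pytest.raises(ValueError):
        GridSpec(model="vpsoc3", r_values=(), h1_values=(1.0,), h2_values=(1.0,))
    with pytest.raises(ValueError):
        GridSpec(model="vpsoc3", r_values=(1e-6,), h1_values=(1.0,), h2_values=(1.0,),
                 n_trials=2)
    spec = GridSpec(model="vpsoc3", r_values=(1e-7, 1e-6), h1_values=(1.0, 2.0),
                    h2_values=(1.0,))
    assert spec.n_combinations == 4
    assert len(list(spec.combinations())) == 4


def test_default_grids():
    vp = default_grid("vpsoc3")
    hi = default_grid("hiseq")
    assert vp.n_combinations == 306
    assert hi.n_combinations == 1008
    with pytest.raises(ValueError):
        default_grid("nope")


def test_matched_grids_identical_parameters():
    vp, hi = matched_grids()
    assert vp.r_values == hi.r_values
    assert vp.h1_values == hi.h1_values
    assert vp.h2_values == hi.h2_values
    assert vp.model == "vpsoc3" and hi.model == "hiseq"


def test_build_region_contains_generators():
    rng = np.random.default_rng(0)
    pts = rng.normal(size=(40, 2))
    region = build_region(pts, "m", ("maxcurv1", "maxcurv2"))
    from shapely.geometry import Point

    assert all(region.geometry.covers(Point(*p)) for p in pts)


def test_build_region_collinear_fallback():
    pts = np.column_stack([np.arange(5.0), np.arange(5.0)])
    region = build_region(pts, "m", ("maxcurv1", "maxcurv2"))
    assert region.method == "convex"


def test_build_region_errors():
    with pytest.raises(ValueError):
        build_region(np.zeros((2, 2)))
    with pytest.raises(ValueError):
        build_region(np.zeros((5, 3)))


def test_region_covers_ci_rectangle():
    regions = square_regions("m")
    inside = make_point(hc1=0.0, mc1=0.0, mc2=0.0, ci=0.1)
    assert all(regions[c].covers(inside) for c in CRITERIA)
    # CI rectangle overlapping the region boundary still counts as covered
    touching = make_point(hc1=1.4, mc1=1.4, mc2=0.0, ci=0.5)
    assert regions[("hc1",)].covers(touching)
    far = make_point(hc1=5.0, mc1=5.0, mc2=5.0, ci=0.5)
    assert not any(regions[c].covers(far) for c in CRITERIA)


def test_classify_point_labels():
    vp = square_regions("vpsoc3", -1.0, 1.0)
    hi = square_regions("hiseq", 4.0, 6.0)
    in_vp = make_point(hc1=0.0, mc1=0.0, mc2=0.0, ci=0.1)
    assert classify_point(in_vp, vp, hi)["label"] == "vpsoc_only"
    in_hi = make_point(hc1=5.0, mc1=5.0, mc2=5.0, ci=0.1)
    assert classify_point(in_hi, vp, hi)["label"] == "hiseq_only"
    nowhere = make_point(hc1=10.0, mc1=10.0, mc2=10.0, ci=0.1)
    assert classify_point(nowhere, vp, hi)["label"] == "neither"
    # an uncovered cell without significant coarticulation stays compatible
    ns = make_point(hc1=10.0, mc1=10.0, mc2=10.0, ci=0.1, significant=False)
    assert classify_point(ns, vp, hi)["label"] == "both"


def test_classify_requires_significance():
    vp = square_regions("vpsoc3")
    hi = square_regions("hiseq")
    fp = make_point()
    object.__setattr__(fp, "significance", None)
    with pytest.raises(ValueError):
        classify_point(fp, vp, hi)


def test_feature_point_from_simulated_trials(geom0, plant):
    from reachseq import plan_sequence, simulate_vpsoc

    matrices, _, sol = plan_sequence(geom0, plant, h=(2.0, 2.0, 2.0), r=1e-6)
    trials = simulate_vpsoc(sol, matrices, geom0, plant, n_trials=8, seed=0)
    fp = feature_point(trials, geom0, label="cell")
    assert fp.n == 8
    assert set(fp.means) == set(FEATURES)
    assert all(fp.ci99[f] > 0 for f in FEATURES)
    assert fp.significance is not None
    with pytest.raises(ValueError, match="produced features"):
        feature_point(trials[:2], geom0, min_valid=3)


def test_simulate_grid_small(geom0, plant):
    spec = GridSpec(
        model="vpsoc3", r_values=(1e-6,), h1_values=(2.0, 4.0), h2_values=(2.0,),
        n_trials=5, seed=0,
    )
    table, failures = simulate_grid(spec, geom0, plant)
    assert len(table) + len(failures) == 2
    assert {"mean_hc1", "sd_hc1", "ci99_hc1", "mean_maxcurv2"} <= set(table.columns)


def test_build_regions_and_coverage_table(geom0, plant):
    spec = GridSpec(
        model="vpsoc3", r_values=(1e-7, 1e-6), h1_values=(1.5, 2.5, 4.0),
        h2_values=(2.0,), n_trials=5, seed=0,
    )
    table, _ = simulate_grid(spec, geom0, plant)
    regions = build_regions(table, "vpsoc3")
    assert set(regions) == set(CRITERIA)
    # grid cells classify as covered by the regions they generated
    from reachseq import simulate_vpsoc, plan_sequence

    matrices, _, sol = plan_sequence(geom0, plant, h=(2.5, 2.0, 2.0), r=1e-6)
    trials = simulate_vpsoc(sol, matrices, geom0, plant, n_trials=8, seed=1)
    fp = feature_point(trials, geom0, label="x")
    far = square_regions("hiseq", 100.0, 101.0)
    labels = classify_dataset([fp], regions, far)
    assert labels.iloc[0]["vpsoc3_covered"]
    cov = coverage_table(labels)
    assert list(cov["criterion"]) == ["hc1", "hc1_maxcurv2", "maxcurv1_maxcurv2", "Total"]
    assert cov.iloc[-1]["vpsoc3"] == 100.0
    with pytest.raises(ValueError):
        build_regions(table, "hiseq")
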