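import math

import numpy as np
import pandas as pd
import pytest

from osimc.spatial import (
    SpatialParams,
    composite_m2_imsc_distance,
    core_area_mm2,
    density_around,
    disc_intersection_area_um2,
    imsc_count_sum,
    median_pair_distance,
    neighbor_counts,
    pair_distances,
    spatial_metrics,
)
from osimc.abundance import MDSC_LABELS


def core_of(points):
    """points: list of (label, x, y)."""
    return pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(len(points))],
            "core_id": "k1",
            "x_um": [p[1] for p in points],
            "y_um": [p[2] for p in points],
            "phenotype": [p[0] for p in points],
        }
    )


# --- brute-force oracles ----------------------------------------------------


def brute_pairs(core, center, target, radius):
    tl = MDSC_LABELS if target == "MDSC" else (target,)
    cs = core[core["phenotype"] == center]
    ts = core[core["phenotype"].isin(tl)]
    out = []
    if center == target:
        pts = cs[["x_um", "y_um"]].to_numpy()
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                d = math.dist(pts[i], pts[j])
                if d <= radius:
                    out.append(d)
    else:
        for _, a in cs.iterrows():
            for _, b in ts.iterrows():
                d = math.hypot(a.x_um - b.x_um, a.y_um - b.y_um)
                if d <= radius:
                    out.append(d)
    return np.sort(np.array(out))


def brute_counts(core, target, params):
    tl = MDSC_LABELS if target == "MDSC" else (target,)
    cs = core[core["phenotype"] == params.center_label]
    ts = core[core["phenotype"].isin(tl)]
    counts = []
    for ci, a in cs.iterrows():
        n = 0
        for ti, b in ts.iterrows():
            if ti == ci:
                continue
            if math.hypot(a.x_um - b.x_um, a.y_um - b.y_um) <= params.radius:
                n += 1
        counts.append(n)
    return np.array(counts)


# --- worked examples --------------------------------------------------------


def test_simple_pair_geometry():
    core = core_of([("M2", 0, 0), ("M2", 30, 0)])
    assert pair_distances(core, "M2", "M2", 250).tolist() == [30.0]


def test_out_of_radius_pair_empty():
    core = core_of([("M2", 0, 0), ("mMDSC", 0, 300)])
    assert len(pair_distances(core, "M2", "MDSC", 250)) == 0


def test_median_of_three():
    core = core_of([("M2", 0, 0), ("Treg", 10, 0), ("Treg", 20, 0), ("Treg", 40, 0)])
    assert median_pair_distance(core, "M2", "Treg") == 20.0


def test_missing_policies():
    core = core_of([("M2", 0, 0)])
    for policy, want in (("zero", 0.0), ("radius_cap", 250.0)):
        p = SpatialParams(missing_policy=policy)
        assert median_pair_distance(core, "M2", "Treg", p) == want
    p = SpatialParams(missing_policy="missing")
    assert math.isnan(median_pair_distance(core, "M2", "Treg", p))


def test_composite_mean_of_medians():
    assert composite_m2_imsc_distance({"M2": 10, "MDSC": 20, "Treg": 30}) == 20.0
    assert composite_m2_imsc_distance({"M2": 0, "MDSC": 0, "Treg": 0}) == 0.0
    assert math.isnan(
        composite_m2_imsc_distance({"M2": 10, "MDSC": float("nan"), "Treg": 30})
    )


def test_density_worked_example():
    """5 targets around a single M2 in a 250 um disc = 25.46 cells/mm^2."""
    pts = [("M2", 0, 0)] + [("Treg", 10 * (i + 1), 0) for i in range(5)]
    dens = density_around(core_of(pts), "Treg")
    assert dens == pytest.approx(5 / (math.pi * 0.25**2), abs=0.01)
    assert dens == pytest.approx(25.46, abs=0.01)


def test_density_missing_without_centers():
    assert math.isnan(density_around(core_of([("Treg", 0, 0)]), "Treg"))


def test_imsc_count_sum_small():
    pts = (
        [("M2", 0, 0), ("M2", 5, 0), ("M2", 10, 0)]
        + [("mMDSC", 1, 1), ("pMDSC", 2, 2)]
        + [("Treg", 3, 3)]
    )
    # every cell within 250 of every other: per-M2 counts M2=2, MDSC=2, Treg=1
    assert imsc_count_sum(core_of(pts)) == 5.0


def test_core_area_matches_published_value():
    assert core_area_mm2(1000.0) == pytest.approx(0.785, abs=5e-4)


# --- oracle equivalence -----------------------------------------------------


def test_kdtree_matches_brute_force(make_core):
    rng = np.random.default_rng(42)
    params = SpatialParams()
    for _ in range(30):
        core = make_core(rng, int(rng.integers(5, 200)))
        for target in ("M2", "MDSC", "Treg"):
            d_fast = pair_distances(core, "M2", target, params.radius)
            d_slow = brute_pairs(core, "M2", target, params.radius)
            np.testing.assert_allclose(d_fast, d_slow, atol=1e-9)
            np.testing.assert_array_equal(
                neighbor_counts(core, target, params), brute_counts(core, target, params)
            )


def test_spatial_metrics_composite_matches_brute(make_core):
    rng = np.random.default_rng(7)
    core = make_core(rng, 150)
    sm = spatial_metrics(core).loc["core001"]
    meds = {
        t: float(np.median(brute_pairs(core, "M2", t, 250.0)))
        for t in ("M2", "MDSC", "Treg")
    }
    assert sm["dist_M2_IMSC"] == pytest.approx(np.mean(list(meds.values())), abs=1e-9)


# --- invariances ------------------------------------------------------------


def test_rigid_motion_invariance(make_core):
    rng = np.random.default_rng(5)
    core = make_core(rng, 120)
    theta = 0.7
    rot = np.array([[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]])
    moved = core.copy()
    xy = core[["x_um", "y_um"]].to_numpy() @ rot.T + np.array([123.4, -56.7])
    moved[["x_um", "y_um"]] = xy
    a = spatial_metrics(core)
    b = spatial_metrics(moved)
    pd.testing.assert_frame_equal(a, b, atol=1e-9, rtol=0)


def test_scaling_covariance(make_core):
    rng = np.random.default_rng(6)
    core = make_core(rng, 120)
    c = 2.5
    scaled = core.copy()
    scaled[["x_um", "y_um"]] *= c
    p1 = SpatialParams(radius=250.0)
    p2 = SpatialParams(radius=250.0 * c)
    d1 = pair_distances(core, "M2", "Treg", p1.radius)
    d2 = pair_distances(scaled, "M2", "Treg", p2.radius)
    np.testing.assert_allclose(d2, c * d1, atol=1e-9)
    dens1 = density_around(core, "Treg", p1)
    dens2 = density_around(scaled, "Treg", p2)
    assert dens2 == pytest.approx(dens1 / c**2, rel=1e-9)


def test_same_label_distances_symmetric(make_core):
    rng = np.random.default_rng(8)
    core = make_core(rng, 80)
    flipped = core.iloc[::-1].reset_index(drop=True)
    np.testing.assert_allclose(
        pair_distances(core, "M2", "M2", 250.0),
        pair_distances(flipped, "M2", "M2", 250.0),
        atol=1e-9,
    )


def test_clip_area_density_recovers_homogeneous_intensity():
    """CSR targets at 100 cells/mm^2: clipped density is unbiased near edges."""
    rng = np.random.default_rng(9)
    diameter, intensity = 1000.0, 100.0  # cells per mm^2
    n_mean = intensity * core_area_mm2(diameter)
    params = SpatialParams(clip_area=True)
    estimates = []
    for _ in range(50):
        n = rng.poisson(n_mean)
        r = diameter / 2 * np.sqrt(rng.uniform(size=n))
        th = rng.uniform(0, 2 * math.pi, n)
        pts = [("Treg", 500 + ri * math.cos(t), 500 + ri * math.sin(t)) for ri, t in zip(r, th)]
        # a handful of M2 centers placed like the targets
        rm = diameter / 2 * np.sqrt(rng.uniform(size=5))
        tm = rng.uniform(0, 2 * math.pi, 5)
        pts += [("M2", 500 + ri * math.cos(t), 500 + ri * math.sin(t)) for ri, t in zip(rm, tm)]
        estimates.append(
            density_around(
                core_of(pts), "Treg", params, core_center=(500, 500), core_diameter=diameter
            )
        )
    est = np.array(estimates)
    assert abs(est.mean() - intensity) < 3 * est.std(ddof=1) / math.sqrt(len(est))


def test_disc_intersection_limits():
    assert disc_intersection_area_um2(0.0, 100.0, 500.0) == pytest.approx(math.pi * 100**2)
    assert disc_intersection_area_um2(700.0, 100.0, 500.0) == 0.0
    half = disc_intersection_area_um2(500.0, 250.0, 500.0)
    assert 0 < half < math.pi * 250**2
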