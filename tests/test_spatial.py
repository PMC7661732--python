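import numpy as np
import pandas as pd
import pytest

from glycosync import Circle, Square
from glycosync.spatial import (
    UNASSIGNED,
    cluster_order_parameter,
    enhanced_synchrony,
    fit_phase_plane,
    phase_map,
    preselect_cells,
    segment_clusters,
    tessellate,
)


def random_positions(n, geom, seed=0):
    rng = np.random.default_rng(seed)
    xy = geom.sample(rng, n)
    return pd.DataFrame({"cell_id": np.arange(n), "x_um": xy[:, 0], "y_um": xy[:, 1]})


def blob_positions(centres, per_blob=6, spread=1.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for cx, cy in centres:
        rows.append(np.column_stack([
            rng.normal(cx, spread, per_blob), rng.normal(cy, spread, per_blob)
        ]))
    xy = np.vstack(rows)
    return pd.DataFrame({"cell_id": np.arange(len(xy)), "x_um": xy[:, 0], "y_um": xy[:, 1]})


def test_tessellation_partition_and_relative_density():
    geom = Circle(169.0)
    tess = tessellate(random_positions(232, geom, seed=1), geom)
    assert np.nanmean(tess.sigma) == pytest.approx(1.0, rel=1e-9)
    assert tess.S_um2.sum() == pytest.approx(geom.area_um2, rel=1e-9)


def test_tessellation_rejects_duplicate_positions():
    geom = Square(50.0)
    pos = random_positions(5, geom, seed=2)
    pos.loc[3, ["x_um", "y_um"]] = pos.loc[1, ["x_um", "y_um"]].to_numpy()
    with pytest.raises(ValueError, match="duplicate positions for cells 1 and 3"):
        tessellate(pos, geom)


def test_preselect_by_density_is_strict_median_cut():
    geom = Square(100.0)
    pos = random_positions(40, geom, seed=3)
    tess = tessellate(pos, geom)
    mask = preselect_cells(tess, "by_density")
    assert mask.sum() <= len(pos) // 2  # strict > median excludes the median itself
    assert np.all(tess.sigma[mask] > np.nanmedian(tess.sigma))


def test_preselect_by_distance():
    pos = pd.DataFrame(
        {
            "cell_id": [0, 1, 2],
            "x_um": [0.0, 4.0, 30.0],
            "y_um": [0.0, 0.0, 0.0],
        }
    )
    geom = Square(100.0)
    tess = tessellate(pos, geom)
    mask = preselect_cells(tess, "by_distance", r_max_um=6.0)
    assert mask.tolist() == [True, True, False]


def test_segment_two_blobs_exact():
    pos = blob_positions([(-20, 0), (20, 0)], per_blob=10, spread=1.0, seed=4)
    geom = Square(100.0)
    tess = tessellate(pos, geom)
    cs = segment_clusters(tess, pos, mode="by_distance")
    # 20 preselected cells -> round(20/10) = 2 clusters
    assert len(cs.labels) == 2
    lab = cs.assignments.to_numpy()
    assert len(set(lab[:10])) == 1 and len(set(lab[10:])) == 1
    assert lab[0] != lab[10]


def test_unselected_cells_are_unassigned():
    pos = blob_positions([(-20, 0), (20, 0)], per_blob=5, spread=1.0, seed=5)
    lone = pd.DataFrame({"cell_id": [99], "x_um": [0.0], "y_um": [45.0]})
    pos = pd.concat([pos, lone], ignore_index=True)
    geom = Square(100.0)
    tess = tessellate(pos, geom)
    cs = segment_clusters(tess, pos, mode="by_distance")
    assert cs.assignments.loc[99] == UNASSIGNED


def test_cluster_order_parameter_needs_two_members():
    with pytest.raises(ValueError, match="at least 2 members"):
        cluster_order_parameter(np.zeros((5, 3)), np.array([1]))


def test_enhanced_synchrony_relative_and_absolute_rules():
    t = np.arange(0, 100, 2.0)
    R = np.full(len(t), 0.5)
    R_c = np.full(len(t), 0.55)
    R_c[10:20] = 0.65  # exceeds R + 0.1 there
    rel = enhanced_synchrony(t, R_c, R, rule="relative")
    assert len(rel) == 1
    assert rel.iloc[0]["t_start"] == pytest.approx(t[10])
    assert rel.iloc[0]["persistence_s"] == pytest.approx(t[19] - t[10])
    absr = enhanced_synchrony(t, R_c, R, rule="absolute", absolute_threshold=0.6)
    assert len(absr) == 1
    with pytest.raises(ValueError, match="unknown rule"):
        enhanced_synchrony(t, R_c, R, rule="bogus")


def test_enhanced_synchrony_gap_merging():
    t = np.arange(0, 40, 2.0)
    R = np.zeros(len(t))
    R_c = np.zeros(len(t))
    R_c[2:5] = 1.0
    R_c[6:9] = 1.0
    split = enhanced_synchrony(t, R_c, R)
    merged = enhanced_synchrony(t, R_c, R, gap_tolerance_s=4.0)
    assert len(split) == 2 and len(merged) == 1


def test_phase_map_paints_polygons_and_masks_points():
    geom = Square(40.0)
    pos = pd.DataFrame(
        {"cell_id": [0, 1, 2], "x_um": [-10.0, 10.0, 0.0], "y_um": [-10.0, 10.0, 5.0]}
    )
    tess = tessellate(pos, geom)
    values = np.array([1.0, 2.0, 3.0])
    grid, extent = phase_map(values, pos, tess, geom, n_pixels=64)
    assert grid.shape == (64, 64)
    assert extent == (-20.0, 20.0, -20.0, 20.0)
    px = 40.0 / 64
    # pixel at cell 0's position carries its value
    ix = int((-10.0 + 20.0) / px)
    iy = int((-10.0 + 20.0) / px)
    assert grid[iy, ix] == 1.0
    # masked cell renders as a small disc, not its whole polygon
    grid_m, _ = phase_map(values, pos, tess, geom, mask=np.array([True, True, False]), n_pixels=64)
    assert np.count_nonzero(grid_m == 3.0) < np.count_nonzero(grid == 3.0)
    assert np.count_nonzero(grid_m == 3.0) > 0


def test_phase_map_512_default_resolution():
    geom = Circle(169.0)
    pos = random_positions(10, geom, seed=6)
    tess = tessellate(pos, geom)
    grid, extent = phase_map(np.arange(10.0), pos, tess, geom)
    assert grid.shape == (512, 512)
    assert (extent[1] - extent[0]) / grid.shape[1] == pytest.approx(169.0 / 512)
    # corners outside the circular field stay unpainted
    assert np.isnan(grid[0, 0]) and np.isnan(grid[-1, -1])


def test_fit_phase_plane_recovers_gradient():
    geom = Square(80.0)
    pos = random_positions(60, geom, seed=7)
    phi = 0.03 * pos["x_um"].to_numpy() - 0.01 * pos["y_um"].to_numpy() + 0.5
    a, b = fit_phase_plane(pos, phi)
    assert a == pytest.approx(0.03, abs=1e-9)
    assert b == pytest.approx(-0.01, abs=1e-9)
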