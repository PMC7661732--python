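"""Voronoi tessellation, spatial cluster detection and cluster synchrony.

Sedimented cells pack unevenly: some sit in locally dense clusters.  The
area S_i of the Voronoi polygon of each cell (clipped to the field of view)
gives a local cell-area density sigma~_i = 1/S_i, reported relative to the
population mean,

    sigma_i = sigma~_i / mean_j(sigma~_j),

so that mean(sigma_i) = 1 by construction.  Clusters are found by
preselecting cells (high density, or short nearest-neighbour distance) and
agglomeratively clustering their positions; each cluster's synchrony is
tracked by the cluster order parameter R_c(t) computed over its members.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.cluster.hierarchy import fcluster, linkage
from shapely.geometry import MultiPoint

from .geometry import Geometry
from .phase import _runs, order_parameter

DEFAULT_R_MAX_UM = 6.0
DEFAULT_RC_ABSOLUTE = 0.75
DEFAULT_RC_MARGIN = 0.1
UNASSIGNED = -1


@dataclass
class Tessellation:
    cell_ids: np.ndarray
    polygons: list  # shapely polygons clipped to the field of view
    S_um2: np.ndarray  # clipped polygon areas
    sigma_tilde: np.ndarray  # 1 / S_i
    sigma: np.ndarray  # relative cell area density, mean 1
    r: np.ndarray  # pairwise distance matrix, um
    field_area_um2: float


def tessellate(positions: pd.DataFrame, geometry: Geometry) -> Tessellation:
    """Voronoi tessellation of the cell centres, clipped to the field of view.

    Every polygon (including the unbounded outer ones) is intersected with
    the field region, so the clipped areas partition the field exactly.
    """
    xy = positions[["x_um", "y_um"]].to_numpy(dtype=float)
    if len(xy) < 3:
        raise ValueError("tessellation needs at least 3 cells")
    d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
    iu = np.triu_indices(len(xy), k=1)
    dup = np.argwhere((d[iu] < 1e-9))
    if len(dup):
        i, j = iu[0][dup[0][0]], iu[1][dup[0][0]]
        ids = positions["cell_id"].to_numpy()
        raise ValueError(f"duplicate positions for cells {ids[i]} and {ids[j]}")

    region = geometry.region
    raw = shapely.voronoi_polygons(MultiPoint(xy), extend_to=region)
    polys = list(raw.geoms)
    # voronoi_polygons returns polygons in arbitrary order: match each cell
    # to the polygon containing it
    tree = shapely.STRtree(polys)
    points = shapely.points(xy)
    cell_idx, poly_idx = tree.query(points, predicate="within")
    if len(cell_idx) != len(xy):
        raise RuntimeError("failed to match every cell to a Voronoi polygon")
    matched = [None] * len(xy)
    for ci, pi in zip(cell_idx, poly_idx):
        matched[ci] = polys[pi]

    clipped = [p.intersection(region) for p in matched]
    areas = np.array([p.area for p in clipped])
    empty = areas <= 0
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} cell(s) have an empty clipped Voronoi polygon; "
            "excluded from density statistics"
        )
    sigma_tilde = np.where(empty, np.nan, 1.0 / np.where(empty, 1.0, areas))
    sigma = sigma_tilde / np.nanmean(sigma_tilde)
    return Tessellation(
        cell_ids=positions["cell_id"].to_numpy(),
        polygons=clipped,
        S_um2=areas,
        sigma_tilde=sigma_tilde,
        sigma=sigma,
        r=d,
        field_area_um2=region.area,
    )


@dataclass
class ClusterSet:
    mode: str  # by_density | by_distance | conjunction
    assignments: pd.Series  # cell_id -> cluster label, UNASSIGNED if none
    labels: np.ndarray  # cluster labels with >= 2 members
    members: dict  # label -> integer row indices of member cells
    R_c: dict = field(default_factory=dict)  # label -> R_c(t)
    sync_episodes: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def M(self) -> dict:
        return {lab: len(idx) for lab, idx in self.members.items()}


def preselect_cells(
    tess: Tessellation, mode: str, r_max_um: float = DEFAULT_R_MAX_UM
) -> np.ndarray:
    """Boolean mask of cells that qualify for cluster membership.

    by_density: sigma_i strictly above the population median.
    by_distance: the cell's nearest neighbour lies within r_max_um.
    conjunction: both at once.
    """
    if mode == "by_density":
        med = np.nanmedian(tess.sigma)
        return tess.sigma > med
    r = tess.r.copy()
    np.fill_diagonal(r, np.inf)
    near = r.min(axis=1) <= r_max_um
    if mode == "by_distance":
        return near
    if mode == "conjunction":
        med = np.nanmedian(tess.sigma)
        return (tess.sigma > med) & near
    raise ValueError(f"unknown preselection mode {mode!r}")


def segment_clusters(
    tess: Tessellation,
    positions: pd.DataFrame,
    mode: str = "by_density",
    r_max_um: float = DEFAULT_R_MAX_UM,
    n_clusters: int | None = None,
) -> ClusterSet:
    """Group preselected cells into spatial clusters.

    Single-linkage agglomerative clustering of the preselected cells'
    positions, cut at ``n_clusters`` groups (default: one cluster per ~10
    preselected cells).  Singleton clusters are kept in the assignment but
    dropped from the reporting set (an order parameter over one cell is
    meaningless).
    """
    selected = preselect_cells(tess, mode, r_max_um)
    ids = positions["cell_id"].to_numpy()
    assignments = pd.Series(UNASSIGNED, index=ids, name="cluster", dtype=int)
    if selected.sum() < 2:
        warnings.warn("fewer than 2 cells preselected; no clusters formed")
        return ClusterSet(mode=mode, assignments=assignments, labels=np.array([], int), members={})

    xy = positions.loc[selected, ["x_um", "y_um"]].to_numpy(dtype=float)
    if n_clusters is None:
        n_clusters = max(1, round(selected.sum() / 10))
    n_clusters = min(n_clusters, len(xy))
    z = linkage(xy, method="single")
    labels = fcluster(z, t=n_clusters, criterion="maxclust")
    assignments.loc[ids[selected]] = labels

    sel_rows = np.flatnonzero(selected)
    members = {}
    for lab in np.unique(labels):
        rows = sel_rows[labels == lab]
        if len(rows) >= 2:
            members[int(lab)] = rows
    return ClusterSet(
        mode=mode,
        assignments=assignments,
        labels=np.array(sorted(members), dtype=int),
        members=members,
    )


def cluster_order_parameter(phi_wrapped: np.ndarray, member_rows: np.ndarray) -> np.ndarray:
    """R_c(t): Kuramoto order parameter restricted to one cluster's members."""
    if len(member_rows) < 2:
        raise ValueError("cluster order parameter needs at least 2 members")
    r_c, _ = order_parameter(np.atleast_2d(phi_wrapped)[member_rows])
    return r_c


def enhanced_synchrony(
    t: np.ndarray,
    R_c: np.ndarray,
    R: np.ndarray,
    rule: str = "relative",
    margin: float = DEFAULT_RC_MARGIN,
    absolute_threshold: float = DEFAULT_RC_ABSOLUTE,
    gap_tolerance_s: float = 0.0,
) -> pd.DataFrame:
    """Episodes where a cluster is better synchronized than the population.

    ``rule="relative"``: R_c >= R + margin (margin default 0.1);
    ``rule="absolute"``: R_c >= absolute_threshold (default 0.75).  Episodes
    are maximal exceedance intervals; runs separated by gaps no longer than
    ``gap_tolerance_s`` are merged.  Persistence is the episode duration.
    """
    t = np.asarray(t, dtype=float)
    if rule == "relative":
        above = np.asarray(R_c) >= np.asarray(R) + margin
    elif rule == "absolute":
        above = np.asarray(R_c) >= absolute_threshold
    else:
        raise ValueError(f"unknown rule {rule!r}")
    runs = _runs(above)
    if gap_tolerance_s > 0 and len(runs) > 1:
        dt = float(t[1] - t[0])
        merged = [runs[0]]
        for i0, i1 in runs[1:]:
            if (i0 - merged[-1][1]) * dt <= gap_tolerance_s:
                merged[-1] = (merged[-1][0], i1)
            else:
                merged.append((i0, i1))
        runs = merged
    rows = [
        {
            "t_start": t[i0],
            "t_end": t[i1 - 1],
            "persistence_s": t[i1 - 1] - t[i0],
            "mean_Rc": float(np.mean(np.asarray(R_c)[i0:i1])),
        }
        for i0, i1 in runs
    ]
    return pd.DataFrame(rows, columns=["t_start", "t_end", "persistence_s", "mean_Rc"])


def analyze_clusters(
    tess: Tessellation,
    positions: pd.DataFrame,
    phi_wrapped: np.ndarray,
    t: np.ndarray,
    R: np.ndarray,
    mode: str = "by_density",
    r_max_um: float = DEFAULT_R_MAX_UM,
    n_clusters: int | None = None,
    rule: str = "relative",
    margin: float = DEFAULT_RC_MARGIN,
    absolute_threshold: float = DEFAULT_RC_ABSOLUTE,
) -> ClusterSet:
    """Segment clusters and compute their R_c(t) and synchrony episodes."""
    cs = segment_clusters(tess, positions, mode, r_max_um, n_clusters)
    episode_frames = []
    for lab in cs.labels:
        r_c = cluster_order_parameter(phi_wrapped, cs.members[int(lab)])
        cs.R_c[int(lab)] = r_c
        ep = enhanced_synchrony(
            t, r_c, R, rule=rule, margin=margin, absolute_threshold=absolute_threshold
        )
        ep.insert(0, "cluster_label", int(lab))
        episode_frames.append(ep)
    episode_frames = [ep for ep in episode_frames if not ep.empty]
    if episode_frames:
        cs.sync_episodes = pd.concat(episode_frames, ignore_index=True)
    else:
        cs.sync_episodes = pd.DataFrame(
            columns=["cluster_label", "t_start", "t_end", "persistence_s", "mean_Rc"]
        )
    return cs


_MAP_QUANTITIES = ("phi", "delta_phi", "R_i", "f", "a_norm")


def phase_map(
    values: np.ndarray,
    positions: pd.DataFrame,
    tess: Tessellation,
    geometry: Geometry,
    mask: np.ndarray | None = None,
    n_pixels: int = 512,
    point_radius_px: int = 2,
):
    """Rasterize a per-cell quantity onto the field of view.

    Each cell's value is painted over its clipped Voronoi polygon; cells
    failing ``mask`` are drawn as small discs at their positions instead
    (mirroring maps where only cells of well-synchronized clusters are shown
    as polygons).  Returns (grid, extent): a (n_pixels, n_pixels) float
    array with NaN background, and the (xmin, xmax, ymin, ymax) extent.
    """
    values = np.asarray(values, dtype=float)
    xmin, ymin, xmax, ymax = geometry.bounds
    px = (xmax - xmin) / n_pixels
    grid = np.full((n_pixels, n_pixels), np.nan)
    xs = xmin + (np.arange(n_pixels) + 0.5) * px
    ys = ymin + (np.arange(n_pixels) + 0.5) * px
    xy = positions[["x_um", "y_um"]].to_numpy(dtype=float)
    if mask is None:
        mask = np.ones(len(values), dtype=bool)

    for i, poly in enumerate(tess.polygons):
        if not mask[i]:
            # point rendering: a small disc at the cell position
            cx = int((xy[i, 0] - xmin) / px)
            cy = int((xy[i, 1] - ymin) / px)
            r = point_radius_px
            x0, x1 = max(cx - r, 0), min(cx + r + 1, n_pixels)
            y0, y1 = max(cy - r, 0), min(cy + r + 1, n_pixels)
            grid[y0:y1, x0:x1] = values[i]
            continue
        if poly.is_empty:
            continue
        bx0, by0, bx1, by1 = poly.bounds
        ix = np.flatnonzero((xs >= bx0 - px) & (xs <= bx1 + px))
        iy = np.flatnonzero((ys >= by0 - px) & (ys <= by1 + px))
        if len(ix) == 0 or len(iy) == 0:
            continue
        gx, gy = np.meshgrid(xs[ix], ys[iy])
        inside = shapely.contains_xy(poly, gx.ravel(), gy.ravel()).reshape(gx.shape)
        sub = grid[np.ix_(iy, ix)]
        sub[inside] = values[i]
        grid[np.ix_(iy, ix)] = sub
    return grid, (xmin, xmax, ymin, ymax)


def fit_phase_plane(positions: pd.DataFrame, phi: np.ndarray) -> tuple[float, float]:
    """Least-squares plane fit phi ~ a*x + b*y + c; returns the gradient (a, b).

    Used as the travelling-wave diagnostic: for an imposed phase gradient the
    fitted (a, b) recovers the wave vector in rad/um.
    """
    xy = positions[["x_um", "y_um"]].to_numpy(dtype=float)
    A = np.column_stack([xy, np.ones(len(xy))])
    coef, *_ = np.linalg.lstsq(A, np.asarray(phi, dtype=float), rcond=None)
    return float(coef[0]), float(coef[1])
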