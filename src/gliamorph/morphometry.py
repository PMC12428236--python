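"""Per-cell skeleton morphometrics.

For each selected cell this module computes the eight standard
morphological parameters of 3D microglial analysis — cell volume, cell
territory (convex-hull volume), ramification index (territory / volume),
branchpoint and endpoint counts, and average / minimum / maximum branch
length — plus a distance-transform soma estimate and a 3D Sholl profile.

Skeletons are obtained by topology-preserving thinning of the binary cell
mask on the voxel lattice; all reported lengths and volumes use the
physical voxel spacing, so anisotropic stacks are handled without
resampling. The skeleton voxel graph (26-adjacency) is cleaned up in two
standard ways before measuring:

* within every 3-clique of mutually adjacent skeleton voxels the longest
  edge is dropped (staircase turns otherwise masquerade as junctions);
* adjacent branching voxels (degree >= 3) are merged into a single
  junction, since thinning often renders one anatomical bifurcation as a
  small cluster of branching voxels.

Spur branches shorter than a configurable prune length (default 2 µm) are
removed iteratively; they are thinning artifacts that would inflate
endpoint counts. A skeleton reduced to <= 1 voxel is flagged degenerate
and reported with zero counts and lengths, so such rows can be filtered
deliberately downstream.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage.morphology import skeletonize as _skeletonize_3d

from .config import PipelineConfig
from .segmentation import CellObject

__all__ = [
    "SkeletonGraph",
    "Branch",
    "BranchMetrics",
    "SomaEstimate",
    "MorphometricRecord",
    "cell_volume",
    "territory_volume",
    "ramification_index",
    "skeletonize",
    "branch_metrics",
    "soma",
    "sholl",
    "measure_cells",
    "MORPHOMETRY_COLUMNS",
]

MORPHOMETRY_COLUMNS = [
    "cell_id",
    "animal_id",
    "group",
    "cell_volume_um3",
    "territory_um3",
    "ramification_index",
    "branchpoints",
    "endpoints",
    "avg_branch_um",
    "min_branch_um",
    "max_branch_um",
    "soma_um3",
    "degenerate_skeleton",
]

# 26-neighborhood offsets, precomputed once
_OFFSETS = np.array(
    [o for o in itertools.product((-1, 0, 1), repeat=3) if o != (0, 0, 0)], dtype=np.int64
)


@dataclass
class Branch:
    """A skeleton path between two consecutive critical nodes."""

    path: list[tuple[int, int, int]]  # voxel coordinates, ends included
    length_um: float
    end_kinds: tuple[str, str]  # each 'endpoint', 'junction', or 'isolated'


@dataclass
class SkeletonGraph:
    """Spatial graph of a cell's medial skeleton with physical edge lengths."""

    graph: nx.Graph
    spacing: tuple[float, float, float]
    junctions: list[list[tuple[int, int, int]]]  # clustered branching voxels
    junction_degrees: list[int]  # branches leaving each junction cluster
    endpoints: list[tuple[int, int, int]]
    branches: list[Branch]
    degenerate: bool


@dataclass
class BranchMetrics:
    branchpoints: int
    endpoints: int
    avg_branch_um: float
    min_branch_um: float
    max_branch_um: float


@dataclass
class SomaEstimate:
    center_voxel: tuple[int, int, int]
    center_um: tuple[float, float, float]
    soma_volume_um3: float


@dataclass
class MorphometricRecord:
    """The eight morphological parameters plus soma volume and Sholl profile."""

    cell_id: int
    animal_id: str
    group_label: str
    cell_volume_um3: float
    territory_um3: float
    ramification_index: float
    branchpoints: int
    endpoints: int
    avg_branch_um: float
    min_branch_um: float
    max_branch_um: float
    soma_um3: float
    degenerate_skeleton: bool
    degenerate_territory: bool = False
    sholl: list[tuple[float, int]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# volumes


def cell_volume(cell: CellObject, spacing: tuple[float, float, float]) -> float:
    """Volume of the cell's voxels: count × dz·dy·dx (µm³)."""
    dz, dy, dx = spacing
    return cell.voxel_count * dz * dy * dx


def territory_volume(
    cell: CellObject, spacing: tuple[float, float, float]
) -> tuple[float, bool]:
    """Convex-hull volume of the cell's voxel centers in physical units.

    The territory is the maximal expansion of the cell: the volume of the
    convex polyhedron spanned by its voxel centers. Returns
    ``(volume_um3, degenerate)``; for cells whose centers are coplanar or
    collinear (no 3D hull) the cell volume is returned with the degenerate
    flag set, so the ramification index degrades to 1 rather than being
    undefined.
    """
    pts = cell.voxels * np.asarray(spacing)
    if len(pts) >= 4:
        try:
            return float(ConvexHull(pts).volume), False
        except QhullError:
            pass
    return cell_volume(cell, spacing), True


def ramification_index(territory_um3: float, volume_um3: float) -> float:
    """Territory volume divided by cell volume; >= 1 for a valid hull."""
    if volume_um3 <= 0:
        raise ValueError("cell volume must be positive")
    return territory_um3 / volume_um3


# ---------------------------------------------------------------------------
# skeleton extraction


def _physical_step(u: np.ndarray, v: np.ndarray, spacing: np.ndarray) -> float:
    return float(np.sqrt((((u - v) * spacing) ** 2).sum()))


def _build_voxel_graph(coords: np.ndarray, spacing: tuple[float, float, float]) -> nx.Graph:
    """26-adjacency graph over skeleton voxels with physical edge lengths."""
    sp = np.asarray(spacing, dtype=np.float64)
    index = {tuple(c): i for i, c in enumerate(coords)}
    g = nx.Graph()
    g.add_nodes_from(index.keys())
    for c in coords:
        ct = tuple(c)
        for off in _OFFSETS:
            nt = (ct[0] + off[0], ct[1] + off[1], ct[2] + off[2])
            if nt in index and nt > ct:  # each pair once
                g.add_edge(ct, nt, length=_physical_step(np.array(ct), np.array(nt), sp))
    return g


def _remove_triangle_diagonals(g: nx.Graph) -> None:
    """Drop the longest edge of every 3-clique of skeleton voxels.

    Staircase turns in a thinned path produce triangles whose diagonal
    edge makes an interior voxel look like a junction; removing the
    longest edge of each triangle restores a simple path. Removing one
    edge of a triangle can never disconnect the graph.
    """
    changed = True
    while changed:
        changed = False
        for u, v in list(g.edges()):
            if not g.has_edge(u, v):
                continue
            common = set(g[u]) & set(g[v])
            for w in common:
                tri = [(u, v), (u, w), (v, w)]
                tri = [e for e in tri if g.has_edge(*e)]
                if len(tri) < 3:
                    continue
                longest = max(tri, key=lambda e: (g.edges[e]["length"], sorted(e)))
                g.remove_edge(*longest)
                changed = True


def _junction_clusters(g: nx.Graph) -> list[list[tuple[int, int, int]]]:
    """Group branching voxels into anatomical junctions.

    Thinning renders one bifurcation as one or several branching voxels;
    voxels that are 26-adjacent, or bridged by a single intervening chain
    voxel, belong to the same junction (junctions closer than one voxel
    apart are not anatomically distinct)."""
    jnodes = [n for n in g.nodes if g.degree[n] >= 3]
    jset = set(jnodes)
    cg = nx.Graph()
    cg.add_nodes_from(jnodes)
    for u in jnodes:
        for v in g[u]:
            if v in jset:
                cg.add_edge(u, v)
            else:
                for w in g[v]:
                    if w != u and w in jset:
                        cg.add_edge(u, w)
    return [sorted(c) for c in nx.connected_components(cg)]


def _decompose(g: nx.Graph, spacing: tuple[float, float, float]) -> tuple[
    list[list[tuple[int, int, int]]], list[int], list[tuple[int, int, int]], list[Branch]
]:
    """Junction clusters, their branch degrees, endpoints, and branches."""
    clusters = _junction_clusters(g)
    cluster_of: dict[tuple[int, int, int], int] = {}
    for i, cl in enumerate(clusters):
        for n in cl:
            cluster_of[n] = i
    endpoints = sorted(n for n in g.nodes if g.degree[n] == 1)

    def kind(n: tuple[int, int, int]) -> str:
        if n in cluster_of:
            return "junction"
        if g.degree[n] == 1:
            return "endpoint"
        return "isolated" if g.degree[n] == 0 else "chain"

    sp = np.asarray(spacing, dtype=np.float64)

    def path_length(path: list[tuple[int, int, int]]) -> float:
        """Physical length of a voxel path, measured on a 3-point moving
        average of the coordinates (ends fixed). Plain voxel-step sums
        overestimate oblique runs by up to ~8% (staircase bias); the light
        smoothing removes most of it without shortening straight runs."""
        if len(path) < 2:
            return 0.0
        pts = np.asarray(path, dtype=np.float64) * sp
        if len(pts) > 2:
            smoothed = pts.copy()
            smoothed[1:-1] = (pts[:-2] + pts[1:-1] + pts[2:]) / 3.0
            pts = smoothed
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())

    branches: list[Branch] = []
    visited_edges: set[frozenset] = set()
    critical = [n for n in g.nodes if g.degree[n] != 2 or n in cluster_of]
    for start in critical:
        for nbr in g[start]:
            ek = frozenset((start, nbr))
            if ek in visited_edges:
                continue
            if start in cluster_of and nbr in cluster_of and cluster_of[start] == cluster_of[nbr]:
                visited_edges.add(ek)  # intra-cluster edge, not a branch
                continue
            path = [start, nbr]
            visited_edges.add(ek)
            prev, cur = start, nbr
            while kind(cur) == "chain":
                nxts = [n for n in g[cur] if n != prev]
                if not nxts:
                    break
                nxt = nxts[0]
                visited_edges.add(frozenset((cur, nxt)))
                path.append(nxt)
                prev, cur = cur, nxt
                if cur == start:  # closed loop
                    break
            if (
                len(path) <= 3
                and path[0] in cluster_of
                and path[-1] in cluster_of
                and cluster_of[path[0]] == cluster_of[path[-1]]
            ):
                continue  # short bridge inside one consolidated junction
            branches.append(
                Branch(path=path, length_um=path_length(path), end_kinds=(kind(path[0]), kind(path[-1])))
            )
    # pure cycles with no critical node (rare): walk them once
    seen = {n for br in branches for n in br.path}
    for comp in nx.connected_components(g):
        comp_nodes = list(comp)
        if any(n in seen for n in comp_nodes) or len(comp_nodes) < 3:
            continue
        if all(g.degree[n] == 2 for n in comp_nodes):
            cycle = nx.find_cycle(g.subgraph(comp_nodes))
            path = [e[0] for e in cycle] + [cycle[-1][1]]
            branches.append(Branch(path=path, length_um=path_length(path), end_kinds=("chain", "chain")))
    degrees = [0] * len(clusters)
    for br in branches:
        for end, k in zip((br.path[0], br.path[-1]), br.end_kinds):
            if k == "junction":
                degrees[cluster_of[end]] += 1
    return clusters, degrees, endpoints, branches


def _prune_spurs(g: nx.Graph, prune_length_um: float, spacing) -> None:
    """Iteratively remove endpoint-terminated branches shorter than the
    prune length, provided the other end is a junction (free-standing
    segments are kept)."""
    while True:
        clusters, _, _, branches = _decompose(g, spacing)
        cluster_nodes = {n for cl in clusters for n in cl}
        removed = False
        for br in branches:
            kinds = br.end_kinds
            if "endpoint" in kinds and "junction" in kinds and br.length_um < prune_length_um:
                # drop everything except the junction-side end voxel
                drop = [n for n in br.path if n not in cluster_nodes]
                if drop and all(g.has_node(n) for n in br.path):
                    g.remove_nodes_from(drop)
                    removed = True
        g.remove_nodes_from([n for n in g.nodes if g.degree[n] == 0])
        if not removed:
            break


def skeletonize(
    cell: CellObject,
    grid_shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    prune_length_um: float = 2.0,
) -> SkeletonGraph:
    """Thin a cell mask to a 1-voxel skeleton and build its branch graph.

    Coordinates in the returned graph are global (z, y, x) stack indices.
    """
    vox = cell.voxels
    lo = vox.min(axis=0)
    hi = vox.max(axis=0)
    pad = 1
    shape = tuple(hi - lo + 1 + 2 * pad)
    mask = np.zeros(shape, dtype=bool)
    local = vox - lo + pad
    mask[local[:, 0], local[:, 1], local[:, 2]] = True
    skel = _skeletonize_3d(mask)
    coords = np.argwhere(skel) + lo - pad
    if len(coords) == 0:
        # thinning of a tiny mask can vanish; fall back to the mask centroid voxel
        coords = vox[[0]]
    g = _build_voxel_graph(coords, spacing)
    _remove_triangle_diagonals(g)
    if prune_length_um > 0:
        _prune_spurs(g, prune_length_um, spacing)
    clusters, degrees, endpoints, branches = (
        _decompose(g, spacing) if g.number_of_nodes() > 1 else ([], [], [], [])
    )
    # compact blob remnants (e.g. the skeleton of a ball) carry no branch
    # information: an unbranched skeleton shorter than the prune length is
    # degenerate, as is anything reduced to <= 1 voxel
    total_length = sum(b.length_um for b in branches)
    if g.number_of_nodes() <= 1 or (not clusters and total_length < prune_length_um):
        return SkeletonGraph(
            graph=g, spacing=tuple(spacing), junctions=[], junction_degrees=[],
            endpoints=[], branches=[], degenerate=True,
        )
    return SkeletonGraph(
        graph=g,
        spacing=tuple(spacing),
        junctions=clusters,
        junction_degrees=degrees,
        endpoints=endpoints,
        branches=branches,
        degenerate=False,
    )


def branch_metrics(skel: SkeletonGraph) -> BranchMetrics:
    """Branchpoint/endpoint counts and branch-length summary.

    Branchpoints are junction clusters (adjacent branching voxels count
    once); endpoints are degree-1 voxels. A degenerate skeleton reports
    all zeros.
    """
    if skel.degenerate or not skel.branches:
        return BranchMetrics(0, 0, 0.0, 0.0, 0.0)
    lengths = [b.length_um for b in skel.branches]
    return BranchMetrics(
        branchpoints=len(skel.junctions),
        endpoints=len(skel.endpoints),
        avg_branch_um=float(np.mean(lengths)),
        min_branch_um=float(np.min(lengths)),
        max_branch_um=float(np.max(lengths)),
    )


# ---------------------------------------------------------------------------
# soma


def soma(
    cell: CellObject,
    spacing: tuple[float, float, float],
    soma_fraction: float = 0.5,
) -> SomaEstimate:
    """Locate the soma and estimate its volume via the distance transform.

    The soma center is the voxel maximizing the Euclidean distance
    transform of the cell mask (deepest interior point; ties resolved to
    the lowest (z, y, x)). The soma body is the set of cell voxels whose
    distance value is at least ``soma_fraction`` of the maximum,
    restricted to the connected component containing the center.
    """
    vox = cell.voxels
    lo = vox.min(axis=0)
    pad = 1
    shape = tuple(vox.max(axis=0) - lo + 1 + 2 * pad)
    mask = np.zeros(shape, dtype=bool)
    local = vox - lo + pad
    mask[local[:, 0], local[:, 1], local[:, 2]] = True
    edt = ndimage.distance_transform_edt(mask, sampling=spacing)
    dmax = edt.max()
    cand = np.argwhere(edt == dmax)
    center_local = tuple(cand[np.lexsort((cand[:, 2], cand[:, 1], cand[:, 0]))][0])
    body = mask & (edt >= soma_fraction * dmax)
    labels, _ = ndimage.label(body, structure=ndimage.generate_binary_structure(3, 3))
    comp = labels == labels[center_local]
    dz, dy, dx = spacing
    center_global = tuple(int(c) for c in (np.array(center_local) + lo - pad))
    return SomaEstimate(
        center_voxel=center_global,
        center_um=tuple(float(c * s) for c, s in zip(center_global, spacing)),
        soma_volume_um3=float(comp.sum()) * dz * dy * dx,
    )


# ---------------------------------------------------------------------------
# Sholl


def sholl(
    skel: SkeletonGraph,
    center_um: tuple[float, float, float],
    step_um: float,
    max_radius_um: float,
) -> list[tuple[float, int]]:
    """3D Sholl profile: skeleton-edge crossings of concentric spheres.

    For each radius r = step, 2·step, ... <= max_radius the count is the
    number of skeleton edges straddling the sphere of radius r about the
    center (an edge with endpoint distances d_lo < r <= d_hi crosses
    once). Distances are physical. A degenerate skeleton yields zeros.
    """
    if step_um <= 0:
        raise ValueError("Sholl step must be positive")
    radii = np.arange(step_um, max_radius_um + 1e-9, step_um)
    counts = np.zeros(len(radii), dtype=int)
    if not skel.degenerate:
        sp = np.asarray(skel.spacing)
        c = np.asarray(center_um)
        for u, v in skel.graph.edges():
            du = float(np.linalg.norm(np.asarray(u) * sp - c))
            dv = float(np.linalg.norm(np.asarray(v) * sp - c))
            lo, hi = min(du, dv), max(du, dv)
            counts += (lo < radii) & (radii <= hi)
    return [(float(r), int(n)) for r, n in zip(radii, counts)]


# ---------------------------------------------------------------------------
# assembly


def measure_cells(
    cells: list[CellObject],
    grid_shape: tuple[int, int, int],
    config: PipelineConfig,
    animal_id: str = "",
    group_label: str = "",
) -> list[MorphometricRecord]:
    """Compute all metrics for every *included* cell.

    Excluded cells appear only in the audit table, never here. If a thin
    cell's voxel-center hull is smaller than its voxel volume, the
    territory is clamped to the cell volume and flagged, so the
    ramification index is never silently < 1.
    """
    spacing = config.spacing
    records = []
    for cell in cells:
        if not cell.included:
            continue
        vol = cell_volume(cell, spacing)
        terr, degenerate_terr = territory_volume(cell, spacing)
        if terr < vol:
            terr, degenerate_terr = vol, True
        ri = ramification_index(terr, vol)
        skel = skeletonize(cell, grid_shape, spacing, prune_length_um=config.prune_length_um)
        bm = branch_metrics(skel)
        sm = soma(cell, spacing, soma_fraction=config.soma_fraction)
        profile = sholl(skel, sm.center_um, config.sholl_step_um, config.sholl_max_radius_um)
        records.append(
            MorphometricRecord(
                cell_id=cell.cell_id,
                animal_id=animal_id,
                group_label=group_label,
                cell_volume_um3=vol,
                territory_um3=terr,
                ramification_index=ri,
                branchpoints=bm.branchpoints,
                endpoints=bm.endpoints,
                avg_branch_um=bm.avg_branch_um,
                min_branch_um=bm.min_branch_um,
                max_branch_um=bm.max_branch_um,
                soma_um3=sm.soma_volume_um3,
                degenerate_skeleton=skel.degenerate,
                degenerate_territory=degenerate_terr,
                sholl=profile,
            )
        )
    return records


def records_to_frame(records: list[MorphometricRecord]) -> pd.DataFrame:
    """Morphometrics table with the canonical column layout."""
    return pd.DataFrame(
        [
            {
                "cell_id": r.cell_id,
                "animal_id": r.animal_id,
                "group": r.group_label,
                "cell_volume_um3": r.cell_volume_um3,
                "territory_um3": r.territory_um3,
                "ramification_index": r.ramification_index,
                "branchpoints": r.branchpoints,
                "endpoints": r.endpoints,
                "avg_branch_um": r.avg_branch_um,
                "min_branch_um": r.min_branch_um,
                "max_branch_um": r.max_branch_um,
                "soma_um3": r.soma_um3,
                "degenerate_skeleton": r.degenerate_skeleton,
            }
            for r in records
        ],
        columns=MORPHOMETRY_COLUMNS,
    )


def sholl_long_frame(records: list[MorphometricRecord]) -> pd.DataFrame:
    """Long-format Sholl table: (cell_id, radius_um, intersections)."""
    rows = [
        {"cell_id": r.cell_id, "radius_um": radius, "intersections": n}
        for r in records
        for radius, n in r.sholl
    ]
    return pd.DataFrame(rows, columns=["cell_id", "radius_um", "intersections"])
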