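"""Synthetic phantoms with known ground truth.

Two generators make every stage of the pipeline testable without any
image download:

* :func:`generate_phantom_stack` renders cells as a soma ball plus a
  random tree of capsule (cylinder + hemispherical caps) segments into a
  voxel grid, with constant background and optional additive Gaussian
  noise. Capsules admit analytic volumes, and the exact branch topology
  (branchpoints, endpoints, branch lengths, soma center) is recorded as
  ground truth. Branch growth is tip-based: from each active tip the
  direction is perturbed by a tortuosity angle and, below the maximum
  depth, the tip bifurcates with a configurable probability. A
  self-collision guard keeps non-adjacent capsules at a clearance of two
  branch radii plus two voxel diagonals, so distinct branches never fuse
  when voxelized — the recorded topology is exactly what is rendered.

* :func:`generate_feature_table` draws cell-by-parameter tables from
  per-archetype multivariate normals (diagonal covariance) for the three
  classic morphologies (amoeboid / intermediate / ramified), with hidden
  cluster labels. A treatment contrast is induced by shifting the
  archetype *mixing proportions* between groups — never the parameter
  values — which emulates a redistribution of cells across
  subpopulations rather than per-cell morphological change.

Everything is deterministic per seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .image_io import VoxelGrid

__all__ = [
    "PhantomSpec",
    "CellGroundTruth",
    "PlacementError",
    "default_spec",
    "generate_phantom_stack",
    "generate_single_cell_stack",
    "generate_feature_table",
    "ARCHETYPES",
    "FEATURE_ARCHETYPE_MEANS",
    "FEATURE_ARCHETYPE_SDS",
]

ARCHETYPES = ("amoeboid", "intermediate", "ramified")


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed without overlapping territories."""


@dataclass
class PhantomSpec:
    """Geometry and noise parameters for one phantom cell."""

    archetype: str
    soma_radius: float = 2.5  # µm
    n_primary_branches: int = 3
    max_branch_depth: int = 2
    bifurcation_prob: float = 0.5
    branch_segment_length: tuple[float, float] = (4.0, 0.6)  # mean, SD in µm
    branch_radius: float = 1.0  # µm
    tortuosity: float = 0.25  # radians per segment
    noise_sd: float = 0.0  # intensity units
    background_level: float = 100.0
    foreground_level: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"archetype must be one of {ARCHETYPES}")
        if not self.soma_radius > self.branch_radius > 0:
            raise ValueError("require soma_radius > branch_radius > 0")
        if self.archetype == "amoeboid" and self.max_branch_depth > 1:
            raise ValueError("amoeboid phantoms have max_branch_depth <= 1")
        if self.archetype == "ramified" and self.max_branch_depth < 3:
            raise ValueError("ramified phantoms have max_branch_depth >= 3")


_ARCHETYPE_DEFAULTS = {
    "amoeboid": dict(
        soma_radius=3.0, n_primary_branches=3, max_branch_depth=1, bifurcation_prob=0.0,
        branch_segment_length=(5.5, 0.5), branch_radius=1.2, tortuosity=0.2,
    ),
    "intermediate": dict(
        soma_radius=2.6, n_primary_branches=3, max_branch_depth=2, bifurcation_prob=0.6,
        branch_segment_length=(5.5, 0.6), branch_radius=1.1, tortuosity=0.25,
    ),
    "ramified": dict(
        soma_radius=2.4, n_primary_branches=4, max_branch_depth=3, bifurcation_prob=0.7,
        branch_segment_length=(5.5, 0.6), branch_radius=1.0, tortuosity=0.25,
    ),
}


def default_spec(archetype: str, seed: int = 0, **overrides) -> PhantomSpec:
    """A :class:`PhantomSpec` with the standard parameters per archetype."""
    params = dict(_ARCHETYPE_DEFAULTS[archetype])
    params.update(overrides)
    return PhantomSpec(archetype=archetype, seed=seed, **params)


@dataclass
class CellGroundTruth:
    """Exact topology and geometry of one generated cell."""

    cell_id: int
    archetype: str
    soma_center_um: tuple[float, float, float]  # global (z, y, x) µm
    soma_radius_um: float
    soma_volume_um3: float  # analytic 4/3 π r³
    branchpoints: int
    endpoints: int
    branch_lengths_um: list[float]  # between consecutive critical nodes, sorted
    degree_sum_excess: int  # Σ(degree − 2) over branchpoint nodes
    n_segments: int
    mask_voxel_count: int = 0
    capsule_volume_um3: float = 0.0  # analytic soma + capsule sum (overlaps not removed)

    def tree_identity_holds(self) -> bool:
        """endpoints == 2 + Σ(degree−2) over branchpoints, for acyclic trees."""
        return self.endpoints == 2 + self.degree_sum_excess

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# geometry helpers


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _perpendicular(v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A random unit vector perpendicular to v."""
    while True:
        r = rng.normal(size=3)
        p = r - np.dot(r, v) * v
        n = np.linalg.norm(p)
        if n > 1e-8:
            return p / n


def _rotate(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation of v about a unit axis."""
    return (
        v * np.cos(angle)
        + np.cross(axis, v) * np.sin(angle)
        + axis * np.dot(axis, v) * (1 - np.cos(angle))
    )


def _fibonacci_directions(n: int, rng: np.random.Generator) -> np.ndarray:
    """n roughly evenly spread unit vectors, randomly rotated."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    dirs = np.stack(
        [np.cos(phi), np.sin(phi) * np.sin(theta), np.sin(phi) * np.cos(theta)], axis=1
    )
    # random rotation: QR of a Gaussian matrix
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    return dirs @ q.T


def _segment_distance(p1: np.ndarray, q1: np.ndarray, p2: np.ndarray, q2: np.ndarray) -> float:
    """Minimum distance between segments [p1,q1] and [p2,q2]."""
    d1, d2 = q1 - p1, q2 - p2
    r = p1 - p2
    a, e, f = np.dot(d1, d1), np.dot(d2, d2), np.dot(d2, r)
    if a <= 1e-12 and e <= 1e-12:
        return float(np.linalg.norm(r))
    if a <= 1e-12:
        s, t = 0.0, np.clip(f / e, 0.0, 1.0)
    else:
        c = np.dot(d1, r)
        if e <= 1e-12:
            t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
        else:
            b = np.dot(d1, d2)
            denom = a * e - b * b
            s = np.clip((b * f - c * e) / denom, 0.0, 1.0) if denom > 1e-12 else 0.0
            t = (b * s + f) / e
            if t < 0.0:
                t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
            elif t > 1.0:
                t, s = 1.0, np.clip((b - c) / a, 0.0, 1.0)
    closest1 = p1 + s * d1
    closest2 = p2 + t * d2
    return float(np.linalg.norm(closest1 - closest2))


# ---------------------------------------------------------------------------
# tree growth


@dataclass
class _CellGeometry:
    spec: PhantomSpec
    tree: nx.Graph  # nodes: int ids with 'pos' (µm, local); soma center = 0
    segments: list[tuple[np.ndarray, np.ndarray]]
    bounding_radius: float


def _grow_cell(spec: PhantomSpec) -> _CellGeometry:
    """Grow the capsule tree for one cell in local coordinates (soma at 0)."""
    rng = np.random.default_rng(spec.seed)
    mean_len, sd_len = spec.branch_segment_length
    clearance = 2 * spec.branch_radius + 2.0  # µm; keeps voxelized branches separate

    tree = nx.Graph()
    tree.add_node(0, pos=np.zeros(3))
    segments: list[tuple[np.ndarray, np.ndarray]] = []
    seg_of_edge: list[tuple[int, int]] = []
    next_id = 1

    def draw_length() -> float:
        # lower clip keeps every terminal branch above the default 2 µm
        # spur-prune length even after junction-side erosion (~ branch
        # radius + 2 voxels) during thinning
        return float(np.clip(rng.normal(mean_len, sd_len), 4.8, mean_len + 2.5 * sd_len))

    def collides(p: np.ndarray, q: np.ndarray, parent_node: int, new_from: int) -> bool:
        for (a, b), (u, v) in zip(segments, seg_of_edge):
            if new_from in (u, v):  # adjacent segment shares a node: allowed to touch
                continue
            if _segment_distance(p, q, a, b) < clearance:
                return True
        # deep segments must not curl back into the soma
        if new_from != 0:
            if _segment_distance(p, q, np.zeros(3), np.zeros(3)) < spec.soma_radius + spec.branch_radius + 1.0:
                return True
        return False

    def try_place(from_node: int, direction: np.ndarray, depth: int) -> tuple[int, np.ndarray] | None:
        nonlocal next_id
        p = tree.nodes[from_node]["pos"]
        for _ in range(20):
            # primary branches run from the soma *center*; their free length
            # beyond the soma surface is the drawn segment length
            length = draw_length() + (spec.soma_radius if from_node == 0 else 0.0)
            q = p + direction * length
            if not collides(p, q, from_node, from_node):
                node = next_id
                next_id += 1
                tree.add_node(node, pos=q)
                tree.add_edge(from_node, node, length=length)
                segments.append((p.copy(), q.copy()))
                seg_of_edge.append((from_node, node))
                return node, direction
            # resample a nearby direction and retry
            axis = _perpendicular(direction, rng)
            direction = _unit(_rotate(direction, axis, rng.uniform(0.2, 0.7)))
        return None

    # primary branches leave the soma center in well-separated directions
    tips: list[tuple[int, np.ndarray, int]] = []  # (node, direction, depth)
    for d in _fibonacci_directions(spec.n_primary_branches, rng):
        placed = try_place(0, _unit(d), 1)
        if placed is not None:
            tips.append((placed[0], placed[1], 1))

    while tips:
        node, direction, depth = tips.pop(0)
        if depth >= spec.max_branch_depth:
            continue
        if rng.uniform() < spec.bifurcation_prob:
            axis = _perpendicular(direction, rng)
            for sign in (1.0, -1.0):
                angle = sign * rng.uniform(0.7, 1.0)  # ~40–57° per child
                child_dir = _unit(_rotate(direction, axis, angle))
                placed = try_place(node, child_dir, depth + 1)
                if placed is not None:
                    tips.append((placed[0], placed[1], depth + 1))
        else:
            axis = _perpendicular(direction, rng)
            bend = rng.normal(0.0, spec.tortuosity)
            cont_dir = _unit(_rotate(direction, axis, bend))
            placed = try_place(node, cont_dir, depth + 1)
            if placed is not None:
                tips.append((placed[0], placed[1], depth + 1))

    radius = spec.soma_radius
    for _, q in segments:
        radius = max(radius, float(np.linalg.norm(q)) + spec.branch_radius)
    return _CellGeometry(spec=spec, tree=tree, segments=segments, bounding_radius=radius)


def _truth_from_geometry(geom: _CellGeometry, cell_id: int, center_um: np.ndarray) -> CellGroundTruth:
    """Collapse degree-2 chain nodes and read off the critical-node topology."""
    tree = geom.tree
    spec = geom.spec
    deg = dict(tree.degree())
    branch_nodes = [n for n, d in deg.items() if d >= 3]
    end_nodes = [n for n, d in deg.items() if d == 1]
    # branch lengths between consecutive critical nodes (collapse deg-2 joints)
    lengths: list[float] = []
    visited: set[frozenset] = set()
    critical = [n for n, d in deg.items() if d != 2]
    for start in critical:
        for nbr in tree[start]:
            ek = frozenset((start, nbr))
            if ek in visited:
                continue
            visited.add(ek)
            total = tree.edges[start, nbr]["length"]
            prev, cur = start, nbr
            while deg[cur] == 2:
                nxt = [x for x in tree[cur] if x != prev][0]
                visited.add(frozenset((cur, nxt)))
                total += tree.edges[cur, nxt]["length"]
                prev, cur = cur, nxt
            lengths.append(float(total))
    # analytic volume: soma ball + cylinder part of each segment outside the
    # soma + one hemispherical cap per leaf tip; junction overlaps and the
    # omitted joint caps roughly cancel
    seg_volume = 0.0
    for a, b in geom.segments:
        L = float(np.linalg.norm(b - a))
        if np.allclose(a, 0.0):  # primary: the in-soma run is already counted
            L = max(L - spec.soma_radius, 0.0)
        seg_volume += np.pi * spec.branch_radius**2 * L
    n_leaves = sum(1 for n, d in deg.items() if d == 1 and n != 0)
    seg_volume += n_leaves * (2.0 / 3.0) * np.pi * spec.branch_radius**3
    return CellGroundTruth(
        cell_id=cell_id,
        archetype=spec.archetype,
        soma_center_um=tuple(float(c) for c in center_um),
        soma_radius_um=spec.soma_radius,
        soma_volume_um3=4.0 / 3.0 * np.pi * spec.soma_radius**3,
        branchpoints=len(branch_nodes),
        endpoints=len(end_nodes),
        branch_lengths_um=sorted(lengths),
        degree_sum_excess=int(sum(deg[n] - 2 for n in branch_nodes)),
        n_segments=len(geom.segments),
        capsule_volume_um3=float(4.0 / 3.0 * np.pi * spec.soma_radius**3 + seg_volume),
    )


# ---------------------------------------------------------------------------
# rendering


def _render_ball(mask: np.ndarray, center_um: np.ndarray, radius: float, spacing: np.ndarray) -> None:
    lo = np.maximum(np.floor((center_um - radius) / spacing - 1).astype(int), 0)
    hi = np.minimum(np.ceil((center_um + radius) / spacing + 1).astype(int), np.array(mask.shape) - 1)
    if np.any(lo > hi):
        return
    zz, yy, xx = np.meshgrid(
        *(np.arange(lo[i], hi[i] + 1) for i in range(3)), indexing="ij"
    )
    pts = np.stack([zz, yy, xx], axis=-1) * spacing
    d2 = ((pts - center_um) ** 2).sum(axis=-1)
    mask[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] |= d2 <= radius**2


def _render_capsule(
    mask: np.ndarray, a_um: np.ndarray, b_um: np.ndarray, radius: float, spacing: np.ndarray
) -> None:
    lo_um = np.minimum(a_um, b_um) - radius
    hi_um = np.maximum(a_um, b_um) + radius
    lo = np.maximum(np.floor(lo_um / spacing - 1).astype(int), 0)
    hi = np.minimum(np.ceil(hi_um / spacing + 1).astype(int), np.array(mask.shape) - 1)
    if np.any(lo > hi):
        return
    zz, yy, xx = np.meshgrid(
        *(np.arange(lo[i], hi[i] + 1) for i in range(3)), indexing="ij"
    )
    pts = np.stack([zz, yy, xx], axis=-1) * spacing
    d = b_um - a_um
    L2 = float(np.dot(d, d))
    rel = pts - a_um
    t = np.clip((rel @ d) / L2, 0.0, 1.0) if L2 > 0 else np.zeros(pts.shape[:-1])
    closest = a_um + t[..., None] * d
    d2 = ((pts - closest) ** 2).sum(axis=-1)
    mask[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] |= d2 <= radius**2


def render_tubes(
    segments: list[tuple],
    radius_um: float,
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    balls: list[tuple] | None = None,
) -> np.ndarray:
    """Voxelize explicit capsule segments (and optional balls) into a mask.

    ``segments`` are ((z, y, x), (z, y, x)) endpoint pairs in µm; ``balls``
    are ((z, y, x), radius) pairs. Useful for fixture phantoms with
    hand-chosen geometry (straight rods, Y-shapes).
    """
    spacing_arr = np.asarray(spacing, dtype=np.float64)
    mask = np.zeros(shape, dtype=bool)
    for a, b in segments:
        _render_capsule(mask, np.asarray(a, float), np.asarray(b, float), radius_um, spacing_arr)
    for c, r in balls or []:
        _render_ball(mask, np.asarray(c, float), r, spacing_arr)
    return mask


def render_cell_mask(
    geom: _CellGeometry, center_um: np.ndarray, shape: tuple[int, int, int], spacing
) -> np.ndarray:
    spacing = np.asarray(spacing, dtype=np.float64)
    mask = np.zeros(shape, dtype=bool)
    _render_ball(mask, center_um, geom.spec.soma_radius, spacing)
    for a, b in geom.segments:
        _render_capsule(mask, a + center_um, b + center_um, geom.spec.branch_radius, spacing)
    return mask


# ---------------------------------------------------------------------------
# stack assembly


def generate_phantom_stack(
    specs: list[PhantomSpec],
    grid_shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    placement_seed: int = 0,
    max_placement_attempts: int = 1000,
) -> tuple[VoxelGrid, list[CellGroundTruth], np.ndarray]:
    """Render phantom cells into a stack with non-overlapping territories.

    Cells are placed by rejection sampling of soma centers such that their
    bounding spheres neither overlap each other nor leave the stack. After
    ``max_placement_attempts`` consecutive failures a
    :class:`PlacementError` is raised.

    Returns ``(grid, truths, label_mask)`` where ``label_mask`` assigns
    each foreground voxel the 1-based index of its cell in ``specs``.
    """
    spacing_arr = np.asarray(spacing, dtype=np.float64)
    extent_um = (np.asarray(grid_shape) - 1) * spacing_arr
    rng = np.random.default_rng(placement_seed)

    geoms = [_grow_cell(spec) for spec in specs]
    centers: list[np.ndarray] = []
    for geom in geoms:
        r = geom.bounding_radius + float(spacing_arr.max())
        lo, hi = r, extent_um - r
        if np.any(lo > hi):
            raise PlacementError(
                f"cell with bounding radius {geom.bounding_radius:.1f} µm does not fit the grid"
            )
        placed = False
        for _ in range(max_placement_attempts):
            c = rng.uniform(lo, hi)
            prev_radii = [g.bounding_radius for g in geoms[: len(centers)]]
            if all(
                np.linalg.norm(c - c0) > r + r0 + 1.0
                for c0, r0 in zip(centers, prev_radii)
            ):
                centers.append(c)
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place cell {len(centers) + 1} after {max_placement_attempts} attempts"
            )

    label_mask = np.zeros(grid_shape, dtype=np.int32)
    truths = []
    for i, (geom, c) in enumerate(zip(geoms, centers), start=1):
        cell_mask = render_cell_mask(geom, c, grid_shape, spacing_arr)
        label_mask[cell_mask] = i
        truth = _truth_from_geometry(geom, i, c)
        truth.mask_voxel_count = int(cell_mask.sum())
        truths.append(truth)

    spec0 = specs[0]
    image = np.full(grid_shape, spec0.background_level, dtype=np.float64)
    image[label_mask > 0] = spec0.foreground_level
    if spec0.noise_sd > 0:
        noise_rng = np.random.default_rng(placement_seed + 7919)
        image += noise_rng.normal(0.0, spec0.noise_sd, size=grid_shape)
    data = np.clip(np.rint(image), 0, 65535).astype(np.uint16)
    grid = VoxelGrid(data=data, spacing=tuple(spacing), source_id=f"phantom(seed={placement_seed})")
    return grid, truths, label_mask


def generate_single_cell_stack(
    spec: PhantomSpec,
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5),
    margin_um: float = 2.0,
) -> tuple[VoxelGrid, CellGroundTruth, np.ndarray]:
    """One phantom centered in an auto-sized grid (for recovery tests)."""
    geom = _grow_cell(spec)
    spacing_arr = np.asarray(spacing, dtype=np.float64)
    r = geom.bounding_radius + margin_um
    shape = tuple(int(np.ceil(2 * r / s)) + 1 for s in spacing_arr)
    center = (np.asarray(shape) - 1) * spacing_arr / 2.0
    label_mask = render_cell_mask(geom, center, shape, spacing_arr).astype(np.int32)
    truth = _truth_from_geometry(geom, 1, center)
    truth.mask_voxel_count = int(label_mask.sum())
    image = np.full(shape, spec.background_level, dtype=np.float64)
    image[label_mask > 0] = spec.foreground_level
    if spec.noise_sd > 0:
        noise_rng = np.random.default_rng(spec.seed + 7919)
        image += noise_rng.normal(0.0, spec.noise_sd, size=shape)
    data = np.clip(np.rint(image), 0, 65535).astype(np.uint16)
    grid = VoxelGrid(data=data, spacing=tuple(spacing), source_id=f"phantom({spec.archetype},seed={spec.seed})")
    return grid, truth, label_mask


def write_truth(truths: list[CellGroundTruth], path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps([t.to_dict() for t in truths], indent=2))
    return path


# ---------------------------------------------------------------------------
# tabular feature mixtures

#: Per-archetype means of the eight parameters (columns as in morphometry).
FEATURE_ARCHETYPE_MEANS = pd.DataFrame(
    {
        "cell_volume_um3": [150.0, 300.0, 450.0],
        "territory_um3": [400.0, 1800.0, 4000.0],
        "ramification_index": [1.8, 4.5, 8.5],
        "branchpoints": [1.0, 5.0, 11.0],
        "endpoints": [3.0, 8.0, 14.0],
        "avg_branch_um": [3.0, 4.5, 6.0],
        "min_branch_um": [1.5, 2.0, 2.5],
        "max_branch_um": [5.0, 9.0, 13.0],
    },
    index=list(ARCHETYPES),
)

#: Common per-parameter SDs (archetype separations are >= 2 pooled SD on
#: most parameters, matching a well-separated subpopulation structure).
FEATURE_ARCHETYPE_SDS = pd.DataFrame(
    {
        "cell_volume_um3": [60.0, 60.0, 60.0],
        "territory_um3": [450.0, 450.0, 450.0],
        "ramification_index": [1.1, 1.1, 1.1],
        "branchpoints": [1.4, 1.4, 1.4],
        "endpoints": [2.0, 2.0, 2.0],
        "avg_branch_um": [0.7, 0.7, 0.7],
        "min_branch_um": [0.5, 0.5, 0.5],
        "max_branch_um": [1.6, 1.6, 1.6],
    },
    index=list(ARCHETYPES),
)


def generate_feature_table(
    n_per_archetype: tuple[int, int, int] = (80, 80, 80),
    archetype_means: pd.DataFrame | None = None,
    archetype_sds: pd.DataFrame | None = None,
    group_shift: float = 0.0,
    seed: int = 0,
    n_animals_per_group: int = 4,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Cell-by-parameter table with hidden archetype labels.

    Each cell's eight parameters are drawn from its archetype's diagonal
    multivariate normal. Cells are assigned to VEH/ATP groups; with
    ``group_shift`` s > 0 the assignment probability P(ATP | archetype)
    becomes (0.5 + s, 0.5, 0.5 − s) for (amoeboid, intermediate,
    ramified), shifting the ATP group toward amoeboid composition while
    leaving the parameter distributions untouched.

    Returns ``(table, true_labels)`` with labels 0/1/2 indexing
    (amoeboid, intermediate, ramified).
    """
    means = archetype_means if archetype_means is not None else FEATURE_ARCHETYPE_MEANS
    sds = archetype_sds if archetype_sds is not None else FEATURE_ARCHETYPE_SDS
    if (sds.to_numpy() <= 0).any():
        raise ValueError("archetype SDs must be strictly positive")
    if not 0.0 <= group_shift <= 0.5:
        raise ValueError("group_shift must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    p_atp = {"amoeboid": 0.5 + group_shift, "intermediate": 0.5, "ramified": 0.5 - group_shift}
    cell_id = 0
    for label, (arch, n) in enumerate(zip(ARCHETYPES, n_per_archetype)):
        mu = means.loc[arch].to_numpy(dtype=np.float64)
        sd = sds.loc[arch].to_numpy(dtype=np.float64)
        values = rng.normal(mu, sd, size=(n, len(mu)))
        in_atp = rng.uniform(size=n) < p_atp[arch]
        for v, atp in zip(values, in_atp):
            cell_id += 1
            group = "ATP" if atp else "VEH"
            animal = f"{group}-{rng.integers(1, n_animals_per_group + 1)}"
            rows.append([cell_id, animal, group, *v])
            labels.append(label)
    columns = ["cell_id", "animal_id", "group", *means.columns]
    df = pd.DataFrame(rows, columns=columns)
    return df, np.asarray(labels)
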