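"""SWC neuron morphometry and mitochondrial-distribution analysis.

Covers the reconstruction-based measurements: branch points, process
counts, compartment lengths, 3D Sholl intersections, rasterisation of the
reconstruction into a binary volume mask, shell-binned mitochondrial voxel
counts ("MitoSholl"), and branch-point-to-mitochondrion proximity.

Coordinates are SWC world coordinates in μm.  Shells are half-open
``[kΔ, (k+1)Δ)``; the Sholl center is the soma root node.  A Sholl crossing
is a strict sign change of (distance to center − R) within an edge, so a
node or tangency sitting exactly on a sphere contributes nothing — the same
answer a dense resampling of the edge would give.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .containers import VoxelStack
from .errors import InputError, ParseError, UndefinedResultError

SOMA, AXON, DENDRITE = 1, 2, 3
_TYPE_NAMES = {"soma": SOMA, "axon": AXON, "dendrite": DENDRITE}


@dataclass
class SWCMorphology:
    """A neuronal reconstruction: typed 3D nodes with radii, as a rooted tree.

    Arrays are aligned by node index (0-based, in file order).  ``parent``
    holds the *index* of the parent node, −1 for the root.  Invariants —
    exactly one root, parent-before-child ordering, finite coordinates —
    are enforced at construction.
    """

    ids: np.ndarray       # original SWC integer ids
    types: np.ndarray     # 1 soma, 2 axon, 3 dendrite
    xyz: np.ndarray       # (n, 3) μm
    radius: np.ndarray    # μm
    parent: np.ndarray    # index into arrays, -1 for root

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=int)
        self.types = np.asarray(self.types, dtype=int)
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        self.parent = np.asarray(self.parent, dtype=int)
        n = self.ids.size
        if n == 0:
            return
        if self.xyz.shape != (n, 3):
            raise InputError("xyz must be (n, 3)")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise InputError(f"morphology must have exactly one root, found {roots.size}")
        if np.any(self.parent >= np.arange(n)):
            raise InputError("parent must precede child")
        if not np.all(np.isfinite(self.xyz)):
            raise InputError("coordinates must be finite")
        unknown = set(np.unique(self.types)) - {SOMA, AXON, DENDRITE}
        if unknown:
            raise InputError(f"unknown SWC type codes: {sorted(unknown)}")

    @property
    def n_nodes(self) -> int:
        return self.ids.size

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    @property
    def soma_center(self) -> np.ndarray:
        """Sholl center: the root node's coordinate."""
        return self.xyz[self.root]

    def n_children(self) -> np.ndarray:
        counts = np.zeros(self.n_nodes, dtype=int)
        p = self.parent[self.parent >= 0]
        np.add.at(counts, p, 1)
        return counts

    def edges(self, compartment: str = "all") -> np.ndarray:
        """(child, parent) index pairs; an edge's compartment is its child's type."""
        child = np.flatnonzero(self.parent >= 0)
        if compartment != "all":
            child = child[self.types[child] == _TYPE_NAMES[compartment]]
        else:
            child = child[self.types[child] != SOMA]
        return np.column_stack([child, self.parent[child]])


# ---------------------------------------------------------------------------
# SWC I/O (standard 7-column text format)

def read_swc(path: str | Path) -> SWCMorphology:
    ids, types, xyz, radius, parent_ids = [], [], [], [], []
    lines_of = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise ParseError(f"expected 7 columns, got {len(parts)}", lineno)
            try:
                nid, ntype = int(parts[0]), int(parts[1])
                x, y, z, r = map(float, parts[2:6])
                pid = int(parts[6])
            except ValueError as exc:
                raise ParseError(str(exc), lineno) from None
            if ntype not in (SOMA, AXON, DENDRITE):
                raise ParseError(f"unknown type code {ntype}", lineno)
            if nid in lines_of:
                raise ParseError(f"duplicate node id {nid}", lineno)
            lines_of[nid] = lineno
            ids.append(nid); types.append(ntype)
            xyz.append((x, y, z)); radius.append(r); parent_ids.append(pid)
    index_of = {nid: i for i, nid in enumerate(ids)}
    parent = np.empty(len(ids), dtype=int)
    for i, pid in enumerate(parent_ids):
        if pid == -1:
            parent[i] = -1
        elif pid not in index_of:
            raise ParseError(f"node {ids[i]} references missing parent {pid}", lines_of[ids[i]])
        elif index_of[pid] >= i:
            raise ParseError(
                f"node {ids[i]} appears before its parent {pid}", lines_of[ids[i]]
            )
        else:
            parent[i] = index_of[pid]
    try:
        return SWCMorphology(np.array(ids), np.array(types), np.array(xyz),
                             np.array(radius), parent)
    except InputError as exc:
        raise ParseError(str(exc)) from None


def write_swc(morph: SWCMorphology, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for i in range(morph.n_nodes):
            pid = -1 if morph.parent[i] < 0 else morph.ids[morph.parent[i]]
            x, y, z = morph.xyz[i]
            fh.write(
                f"{morph.ids[i]} {morph.types[i]} {x:.6g} {y:.6g} {z:.6g} "
                f"{morph.radius[i]:.6g} {pid}\n"
            )


# ---------------------------------------------------------------------------
# Tree statistics

def _compartment_nodes(morph: SWCMorphology, compartment: str) -> np.ndarray:
    if compartment == "all":
        return morph.types != SOMA
    return morph.types == _TYPE_NAMES[compartment]


def branch_points(morph: SWCMorphology, compartment: str = "all") -> np.ndarray:
    """(k, 3) coordinates of non-soma nodes with ≥ 2 children.

    A node with more than two children still counts once.
    """
    sel = (morph.n_children() >= 2) & _compartment_nodes(morph, compartment)
    return morph.xyz[sel]


def count_processes(morph: SWCMorphology) -> int:
    """Number of unbranched segments of the condensed tree.

    Condensed-tree vertices are the root, branch points and tips; each
    non-root vertex terminates exactly one segment, so the count is
    ``#tips + #branch points`` (root excluded).
    """
    if morph.n_nodes <= 1:
        return 0
    nchild = morph.n_children()
    vertices = (nchild == 0) | (nchild >= 2)
    vertices[morph.root] = False
    return int(vertices.sum())


def total_length(morph: SWCMorphology, compartment: str = "all") -> float:
    """Summed parent–child Euclidean length (μm) over the compartment.

    ``all`` means axon + dendrite; edges whose child is a soma node carry
    no neurite length.
    """
    e = morph.edges(compartment)
    if e.size == 0:
        return 0.0
    d = morph.xyz[e[:, 0]] - morph.xyz[e[:, 1]]
    return float(np.linalg.norm(d, axis=1).sum())


# ---------------------------------------------------------------------------
# Sholl analysis

@dataclass
class ShollProfile:
    """Per-radius intersection (or voxel) counts at uniform radial step."""

    radii: np.ndarray   # μm; ring radii or shell lower bounds
    counts: np.ndarray

    def __post_init__(self):
        self.radii = np.asarray(self.radii, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.radii.size != self.counts.size:
            raise InputError("radii and counts must align")
        if np.any(self.counts < 0):
            raise InputError("counts must be non-negative")


def _edge_crossings(p0: np.ndarray, p1: np.ndarray, center: np.ndarray, r: float) -> int:
    """Number of strict sign changes of ‖p(t)−center‖−r for t in (0, 1)."""
    a = p0 - center
    v = p1 - p0
    # f(t) = |a + t v|^2 - r^2, a quadratic in t
    A = float(v @ v)
    B = 2.0 * float(a @ v)
    C = float(a @ a) - r * r
    if A == 0.0:
        return 0
    disc = B * B - 4 * A * C
    if disc <= 0:  # tangency (== 0) is not a crossing
        return 0
    sq = np.sqrt(disc)
    return sum(0.0 < t < 1.0 for t in ((-B - sq) / (2 * A), (-B + sq) / (2 * A)))


def sholl_intersections(
    morph: SWCMorphology,
    compartment: str = "all",
    step: float = 1.0,
    center: np.ndarray | None = None,
) -> ShollProfile:
    """3D Sholl profile: crossings of tree edges with concentric spheres.

    Spheres sit at radii ``step, 2·step, …`` out to the farthest node; an
    edge crossing a sphere twice contributes two.
    """
    if step <= 0:
        raise InputError("step must be positive")
    center = morph.soma_center if center is None else np.asarray(center, dtype=float)
    e = morph.edges(compartment)
    dmax = 0.0
    if morph.n_nodes:
        dmax = float(np.max(np.linalg.norm(morph.xyz - center, axis=1)))
    radii = np.arange(step, dmax + step, step)
    counts = np.zeros(radii.size, dtype=int)
    for child, parent in e:
        p0, p1 = morph.xyz[parent], morph.xyz[child]
        d0 = np.linalg.norm(p0 - center)
        d1 = np.linalg.norm(p1 - center)
        lo, hi = min(d0, d1), max(d0, d1)
        # only spheres whose radius can intersect the edge's distance range
        k0 = max(int(np.floor((lo - np.linalg.norm(p1 - p0)) / step)), 1)
        k1 = int(np.ceil(hi / step)) + 1
        for k in range(k0, min(k1, radii.size + 1)):
            counts[k - 1] += _edge_crossings(p0, p1, center, k * step)
    return ShollProfile(radii, counts)


# ---------------------------------------------------------------------------
# Volume mask and MitoSholl

def fill_volume_mask(
    morph: SWCMorphology,
    voxel_size: float,
    margin: float = 2.0,
    origin: tuple[float, float, float] | None = None,
    shape: tuple[int, int, int] | None = None,
) -> VoxelStack:
    """Rasterise the reconstruction into a binary stack.

    A voxel is set when its center lies within the local radius of the
    interpolated centerline (union of capsules over edges, radius linearly
    interpolated between nodes).  Zero-radius nodes are clamped to
    ``voxel_size / 2`` so thin neurites stay connected.  Pass ``origin``
    (z, y, x world μm) and ``shape`` to rasterise onto an existing grid,
    e.g. that of a matching mitochondrial stack.
    """
    if voxel_size <= 0:
        raise InputError("voxel_size must be positive")
    if morph.n_nodes == 0:
        return VoxelStack(np.zeros((1, 1, 1), dtype=bool), (voxel_size,) * 3)
    rmin = voxel_size / 2.0
    radius = np.maximum(morph.radius, rmin)
    if origin is None or shape is None:
        lo = morph.xyz.min(axis=0) - radius.max() - margin
        hi = morph.xyz.max(axis=0) + radius.max() + margin
        ext = np.ceil((hi - lo) / voxel_size).astype(int) + 1  # (x, y, z) extents
        nz, ny, nx = int(ext[2]), int(ext[1]), int(ext[0])
        origin = (float(lo[2]), float(lo[1]), float(lo[0]))
    else:
        nz, ny, nx = shape
    mask = np.zeros((nz, ny, nx), dtype=bool)

    def stamp_sphere(cx, cy, cz, r):
        # voxel index ranges covering the sphere
        i0 = np.floor(([cz, cy, cx] - np.array([origin[0], origin[1], origin[2]]) - r)
                      / voxel_size).astype(int)
        i1 = np.ceil(([cz, cy, cx] - np.array([origin[0], origin[1], origin[2]]) + r)
                     / voxel_size).astype(int)
        i0 = np.maximum(i0, 0)
        i1 = np.minimum(i1, [nz - 1, ny - 1, nx - 1])
        if np.any(i0 > i1):
            return
        zz = origin[0] + np.arange(i0[0], i1[0] + 1) * voxel_size
        yy = origin[1] + np.arange(i0[1], i1[1] + 1) * voxel_size
        xx = origin[2] + np.arange(i0[2], i1[2] + 1) * voxel_size
        Z, Y, X = np.meshgrid(zz, yy, xx, indexing="ij")
        inside = (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2 <= r * r
        mask[i0[0]:i1[0] + 1, i0[1]:i1[1] + 1, i0[2]:i1[2] + 1] |= inside

    # isolated root (e.g. bare soma) renders as a sphere
    nchild = morph.n_children()
    if nchild[morph.root] == 0 or morph.n_nodes == 1:
        x, y, z = morph.xyz[morph.root]
        stamp_sphere(x, y, z, radius[morph.root])
    for child in np.flatnonzero(morph.parent >= 0):
        parent = morph.parent[child]
        p0, p1 = morph.xyz[parent], morph.xyz[child]
        r0, r1 = radius[parent], radius[child]
        seg_len = float(np.linalg.norm(p1 - p0))
        n_steps = max(int(np.ceil(seg_len / (voxel_size / 2.0))), 1)
        for t in np.linspace(0.0, 1.0, n_steps + 1):
            p = p0 + t * (p1 - p0)
            stamp_sphere(p[0], p[1], p[2], r0 + t * (r1 - r0))
    return VoxelStack(mask, (voxel_size,) * 3, origin)


def shell_counts(
    stack: VoxelStack, center: np.ndarray, step: float = 1.0
) -> ShollProfile:
    """Positive-voxel counts per half-open radial shell [kΔ, (k+1)Δ)."""
    pos = stack.voxel_centers(stack.data.astype(bool))
    if pos.shape[0] == 0:
        return ShollProfile(np.array([0.0]), np.array([0]))
    d = np.linalg.norm(pos - np.asarray(center, dtype=float), axis=1)
    k = np.floor(d / step).astype(int)
    counts = np.bincount(k)
    radii = np.arange(counts.size) * step  # shell lower bounds
    return ShollProfile(radii, counts)


def mito_sholl(
    stack: VoxelStack,
    mask: VoxelStack,
    center: np.ndarray,
    step: float = 1.0,
    rolling_ball_radius: int = 50,
    median_size: int = 3,
    threshold_method: str = "otsu",
) -> ShollProfile:
    """Shell-binned mitochondrial voxel counts around the soma.

    Pipeline: per-slice rolling-ball background subtraction → median filter
    → binarisation → AND with the reconstruction volume mask → count
    positive voxel centers per 1-μm shell.  Pass a boolean ``stack`` to
    skip the intensity preprocessing (already-binarised input).
    """
    from .image_quant import binarize_stack  # local import avoids a cycle

    if stack.shape != mask.shape:
        raise InputError("stack and mask dimensions differ")
    if stack.voxel_size != mask.voxel_size:
        raise InputError("stack and mask voxel sizes differ")
    if stack.data.dtype == bool:
        binary = stack.data
    else:
        binary = binarize_stack(
            stack.data,
            rolling_ball_radius=rolling_ball_radius,
            median_size=median_size,
            method=threshold_method,
        )
    combined = VoxelStack(binary & mask.data.astype(bool), stack.voxel_size, stack.origin)
    return shell_counts(combined, center, step)


# ---------------------------------------------------------------------------
# Proximity analysis

@dataclass
class ProximityResult:
    """Minimum branch-point→mitochondrion distances (μm), one per branch point."""

    branch_points: np.ndarray     # (k, 3) world μm
    min_distances: np.ndarray     # (k,) μm
    normalized: np.ndarray | None = None  # a.u., filled by normalize_distances


def min_branch_mito_distance(
    branch_pts: np.ndarray, mito: VoxelStack
) -> ProximityResult:
    """Euclidean distance from each branch point to the nearest positive voxel.

    Distances use voxel centers with the stack's (possibly anisotropic)
    voxel size.  Ties are irrelevant to the value; the nearest voxel found
    first in linear index order would be reported.
    """
    branch_pts = np.atleast_2d(np.asarray(branch_pts, dtype=float))
    if branch_pts.shape[0] == 0:
        raise InputError("no branch points supplied")
    pos = mito.voxel_centers(mito.data.astype(bool))
    if pos.shape[0] == 0:
        raise UndefinedResultError("no positive mitochondrial voxels; distance undefined")
    tree = cKDTree(pos)
    d, _ = tree.query(branch_pts)
    return ProximityResult(branch_pts, np.asarray(d, dtype=float))


def normalize_distances(
    groups: dict[str, ProximityResult], reference_group: str
) -> dict[str, ProximityResult]:
    """Divide every group's distances by the reference group's mean.

    The reference group's normalized mean is exactly 1 by construction.
    """
    ref = groups[reference_group]
    ref_mean = float(np.mean(ref.min_distances))
    if ref_mean <= 0:
        raise InputError("reference group mean distance must be positive")
    return {
        name: ProximityResult(g.branch_points, g.min_distances,
                              g.min_distances / ref_mean)
        for name, g in groups.items()
    }


def prob_within_radius(result: ProximityResult, r: float = 1.0) -> float:
    """Fraction of branch points with a mitochondrion within ``r`` μm."""
    return float(np.mean(result.min_distances <= r))
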