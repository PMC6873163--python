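"""Neuron skeletons, dendritic branch ordering, and rasterization.

A :class:`NeuronSkeleton` is a rooted tree of 3D nodes with radii, in the
style of an SWC reconstruction: one or more soma nodes plus apical and
basal dendritic arbours.  Dendrites are decomposed into
:class:`CompartmentSegment` objects — maximal unbranched runs between
branch points — labelled with a centrifugal branch order: stems leaving
the soma are first order (1deg) and the order increments by one at every
branch point.  Pyramidal neurons have a single 1deg apical stem; the 1deg
apical segment is treated downstream as a distinct, perisomatic
compartment.

Rasterization sweeps capsules (spheres joined along edges) through an
anisotropic voxel grid to emulate the cytosolic cell-fill channel from
which the cell surface is reconstructed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage import measure

from .grid import VoxelGridSpec

SWC_TYPE_TO_COMPARTMENT = {1: "soma", 3: "basal", 4: "apical"}
COMPARTMENT_TO_SWC_TYPE = {"soma": 1, "basal": 3, "apical": 4}
COMPARTMENTS = ("soma", "apical", "basal")


@dataclass
class NeuronSkeleton:
    """Rooted tree of 3D nodes with radii and compartment tags.

    Parameters
    ----------
    node_ids : (n,) int array
        Unique node identifiers.
    positions : (n, 3) float array
        Node positions in um, axis order (z, y, x).
    radii : (n,) float array
        Node radii in um, all positive.
    parents : (n,) int array
        Parent node id per node, or -1 for the root.  Exactly one root.
    compartments : sequence of str
        Per-node tag: ``soma``, ``apical`` or ``basal``.
    """

    node_ids: np.ndarray
    positions: np.ndarray
    radii: np.ndarray
    parents: np.ndarray
    compartments: np.ndarray

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.radii = np.asarray(self.radii, dtype=np.float64)
        self.parents = np.asarray(self.parents, dtype=np.int64)
        self.compartments = np.asarray(self.compartments, dtype=object)
        n = len(self.node_ids)
        if n == 0:
            raise ValueError("skeleton has no nodes")
        if self.positions.shape != (n, 3):
            raise ValueError("positions must be (n, 3)")
        if len(set(self.node_ids.tolist())) != n:
            raise ValueError("node ids must be unique")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("node positions must be finite")
        if np.any(self.radii <= 0):
            raise ValueError("node radii must be positive")
        bad = set(self.compartments.tolist()) - set(COMPARTMENTS)
        if bad:
            raise ValueError(f"untagged or unknown compartments: {sorted(bad)}")
        roots = np.flatnonzero(self.parents == -1)
        if len(roots) != 1:
            raise ValueError(f"skeleton must have exactly one root, found {len(roots)}")
        self._id_to_row = {int(i): r for r, i in enumerate(self.node_ids)}
        known = set(self.node_ids.tolist()) | {-1}
        for p in self.parents.tolist():
            if int(p) not in known:
                raise ValueError(f"parent id {p} refers to no node")
        self._check_connected_acyclic(int(roots[0]))

    def _check_connected_acyclic(self, root_row: int) -> None:
        children = self.children_map()
        seen: set[int] = set()
        stack = [int(self.node_ids[root_row])]
        while stack:
            nid = stack.pop()
            if nid in seen:
                raise ValueError("cycle detected in skeleton")
            seen.add(nid)
            stack.extend(children.get(nid, ()))
        if len(seen) != len(self.node_ids):
            raise ValueError("skeleton is disconnected")

    # -- topology helpers -------------------------------------------------

    def row(self, node_id: int) -> int:
        return self._id_to_row[int(node_id)]

    @property
    def root_id(self) -> int:
        return int(self.node_ids[np.flatnonzero(self.parents == -1)[0]])

    def children_map(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {int(i): [] for i in self.node_ids}
        for nid, pid in zip(self.node_ids.tolist(), self.parents.tolist()):
            if pid != -1:
                out[int(pid)].append(int(nid))
        return out

    @property
    def soma_ids(self) -> list[int]:
        return [int(i) for i, c in zip(self.node_ids, self.compartments) if c == "soma"]

    def position_of(self, node_id: int) -> np.ndarray:
        return self.positions[self.row(node_id)]

    @property
    def soma_center(self) -> np.ndarray:
        """Centre of the cell body: the largest-radius soma node (smaller
        soma-tagged nodes are stem anchors, not the body itself)."""
        rows = [self.row(i) for i in self.soma_ids]
        if not rows:
            raise ValueError("skeleton has no soma nodes")
        best = rows[int(np.argmax(self.radii[rows]))]
        return self.positions[best]

    @property
    def soma_radius(self) -> float:
        rows = [self.row(i) for i in self.soma_ids]
        return float(self.radii[rows].max())

    def total_dendritic_length(self) -> float:
        """Sum of edge lengths over edges whose child is a dendritic node (um)."""
        total = 0.0
        for r, pid in enumerate(self.parents.tolist()):
            if pid == -1 or self.compartments[r] == "soma":
                continue
            total += float(
                np.linalg.norm(self.positions[r] - self.positions[self.row(pid)])
            )
        return total


@dataclass
class CompartmentSegment:
    """Maximal unbranched dendritic run with a centrifugal branch order.

    ``path`` starts at the attachment node (a soma node or the upstream
    branch point) so that concatenating all segments conserves total tree
    length.  ``lineage`` is ``apical`` or ``basal``; ``order`` >= 1.
    """

    segment_id: int
    lineage: str
    order: int
    node_ids: list[int]
    path: np.ndarray  # (m, 3) um
    arc_length: float = field(init=False)

    def __post_init__(self) -> None:
        self.path = np.asarray(self.path, dtype=np.float64)
        if self.path.shape[0] < 2:
            raise ValueError("segment needs at least two path points")
        self.arc_length = segment_arc_length(self.path)

    @property
    def label(self) -> str:
        return f"{self.lineage}{self.order}"


def segment_arc_length(path: np.ndarray) -> float:
    """Polyline length in um: sum of consecutive Euclidean inter-node distances."""
    pts = np.asarray(path, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("arc length needs a polyline of >= 2 points")
    d = np.diff(pts, axis=0)
    length = float(np.sqrt((d * d).sum(axis=1)).sum())
    if length <= 0:
        raise ValueError("segment has zero arc length")
    return length


def compute_branch_orders(skeleton: NeuronSkeleton) -> list[CompartmentSegment]:
    """Decompose the dendritic arbour into branch-ordered segments.

    Stems leaving the soma are order 1; the order increments by one at
    every branch point (a trifurcation increments once for all children).
    Every non-soma node belongs to exactly one segment, and the summed
    segment arc lengths equal the total dendritic tree length.
    """
    children = skeleton.children_map()
    comp = {int(i): c for i, c in zip(skeleton.node_ids, skeleton.compartments)}
    segments: list[CompartmentSegment] = []
    next_id = 0

    # (attach node, first dendritic node, order) work list, seeded at soma exits
    work: list[tuple[int, int, int]] = []
    for sid in skeleton.soma_ids:
        for ch in children[sid]:
            if comp[ch] != "soma":
                work.append((sid, ch, 1))
    if not work and any(c != "soma" for c in comp.values()):
        raise ValueError("dendritic nodes present but none attach to the soma")

    while work:
        attach, first, order = work.pop(0)
        lineage = comp[first]
        if lineage == "soma":
            raise ValueError("soma node inside a dendritic segment")
        node_path = [attach, first]
        cur = first
        while True:
            kids = [k for k in children[cur] if comp[k] != "soma"]
            if len(kids) == 1:
                cur = kids[0]
                node_path.append(cur)
            else:
                for k in kids:
                    work.append((cur, k, order + 1))
                break
        path = np.array([skeleton.position_of(i) for i in node_path])
        segments.append(
            CompartmentSegment(
                segment_id=next_id,
                lineage=lineage,
                order=order,
                node_ids=node_path,
                path=path,
            )
        )
        next_id += 1
    return segments


def nearest_segment(
    segments: list[CompartmentSegment], points: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest segment for each query point by distance to the segment polyline.

    Returns ``(segment_ids, distances)``; distances in um.  The attachment
    edge shared with the upstream segment belongs to both polylines; ties
    resolve to the lower segment id.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    best_d = np.full(len(pts), np.inf)
    best_id = np.full(len(pts), -1, dtype=np.int64)
    for seg in segments:
        d = _point_polyline_distance(pts, seg.path)
        better = d < best_d
        best_d[better] = d[better]
        best_id[better] = seg.segment_id
    return best_id, best_d


def _point_polyline_distance(points: np.ndarray, path: np.ndarray) -> np.ndarray:
    """Min distance from each point to a polyline (vectorized over edges)."""
    a = path[:-1]  # (m, 3)
    b = path[1:]
    ab = b - a
    ab2 = (ab * ab).sum(axis=1)  # (m,)
    ab2 = np.where(ab2 == 0, 1.0, ab2)
    # (n, m, 3) broadcast
    ap = points[:, None, :] - a[None, :, :]
    t = np.clip((ap * ab[None, :, :]).sum(axis=2) / ab2[None, :], 0.0, 1.0)
    closest = a[None, :, :] + t[:, :, None] * ab[None, :, :]
    d = np.linalg.norm(points[:, None, :] - closest, axis=2)
    return d.min(axis=1)


# -- rasterization --------------------------------------------------------


def rasterize_cell(skeleton: NeuronSkeleton, grid: VoxelGridSpec) -> np.ndarray:
    """Binary mask of the cell body: soma spheres plus dendritic capsules.

    Soma nodes are rendered as spheres of their radius; every edge is a
    capsule whose radius interpolates linearly between its end nodes.
    Distances are Euclidean in physical um, so the mask respects the grid's
    anisotropy.  Raises if any node lies outside the grid.
    """
    outside = ~grid.contains_point(skeleton.positions)
    if np.any(outside):
        bad = skeleton.node_ids[outside].tolist()
        raise ValueError(f"skeleton nodes outside grid: {bad}")
    mask = np.zeros(grid.shape, dtype=bool)
    for sid in skeleton.soma_ids:
        r = skeleton.row(sid)
        _stamp_capsule(
            mask, grid, skeleton.positions[r], skeleton.positions[r],
            skeleton.radii[r], skeleton.radii[r],
        )
    for r, pid in enumerate(skeleton.parents.tolist()):
        if pid == -1:
            continue
        pr = skeleton.row(pid)
        _stamp_capsule(
            mask, grid, skeleton.positions[pr], skeleton.positions[r],
            skeleton.radii[pr], skeleton.radii[r],
        )
    if not mask.any():
        raise ValueError("rasterized mask is empty")
    return mask


def _stamp_capsule(
    mask: np.ndarray,
    grid: VoxelGridSpec,
    p0: np.ndarray,
    p1: np.ndarray,
    r0: float,
    r1: float,
) -> None:
    """OR a capsule (cone-sphere swept between p0 and p1) into `mask`."""
    vs = np.asarray(grid.voxel_size)
    origin = np.asarray(grid.origin)
    rmax = max(r0, r1)
    lo = np.minimum(p0, p1) - rmax
    hi = np.maximum(p0, p1) + rmax
    i0 = np.maximum(np.floor((lo - origin) / vs - 0.5).astype(int), 0)
    i1 = np.minimum(
        np.ceil((hi - origin) / vs + 0.5).astype(int) + 1, np.asarray(grid.shape)
    )
    if np.any(i0 >= i1):
        return
    axes = [
        origin[a] + (np.arange(i0[a], i1[a]) + 0.5) * vs[a] for a in range(3)
    ]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([zz, yy, xx], axis=-1)
    d = pts - p0
    ab = p1 - p0
    ab2 = float(ab @ ab)
    if ab2 == 0:
        dist = np.linalg.norm(d, axis=-1)
        rad = r0
    else:
        t = np.clip((d @ ab) / ab2, 0.0, 1.0)
        closest = p0 + t[..., None] * ab
        dist = np.linalg.norm(pts - closest, axis=-1)
        rad = r0 + t * (r1 - r0)
    sub = dist <= rad
    mask[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] |= sub


def soma_surface_area(mask: np.ndarray, grid: VoxelGridSpec) -> float:
    """Surface area (um^2) of a binary mask via an isosurface mesh.

    Marching cubes at the 0.5 level with the grid's physical spacing;
    voxel-face counting (which overestimates curved surfaces) is used only
    when the mask is too small to mesh.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot measure surface area of an empty mask")
    if mask.sum() < 4:
        return _face_count_area(mask, grid)
    padded = np.pad(mask, 1).astype(np.float64)
    try:
        verts, faces, _, _ = measure.marching_cubes(
            padded, level=0.5, spacing=grid.voxel_size
        )
    except (ValueError, RuntimeError):
        return _face_count_area(mask, grid)
    if len(faces) == 0:
        return _face_count_area(mask, grid)
    return float(measure.mesh_surface_area(verts, faces))


def _face_count_area(mask: np.ndarray, grid: VoxelGridSpec) -> float:
    dz, dy, dx = grid.voxel_size
    face_area = {0: dy * dx, 1: dz * dx, 2: dz * dy}
    padded = np.pad(mask, 1)
    total = 0.0
    for axis in range(3):
        for shift in (1, -1):
            neighbor = np.roll(padded, shift, axis=axis)
            total += float(np.sum(padded & ~neighbor)) * face_area[axis]
    return total


# -- SWC I/O ---------------------------------------------------------------


def read_swc(path: str | Path) -> NeuronSkeleton:
    """Read a 7-column SWC skeleton (id, type, x, y, z, radius, parent).

    SWC stores coordinates as x, y, z in um; they are reordered into the
    package's (z, y, x) convention.  Type codes 1/3/4 map to
    soma/basal/apical; other codes are rejected.
    """
    ids, positions, radii, parents, comps = [], [], [], [], []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        f = line.split()
        if len(f) < 7:
            raise ValueError(f"malformed SWC line: {line!r}")
        nid, ntype = int(f[0]), int(f[1])
        x, y, z, radius = (float(v) for v in f[2:6])
        parent = int(f[6])
        if ntype not in SWC_TYPE_TO_COMPARTMENT:
            raise ValueError(f"unsupported SWC type code {ntype} on node {nid}")
        ids.append(nid)
        positions.append((z, y, x))
        radii.append(radius)
        parents.append(parent)
        comps.append(SWC_TYPE_TO_COMPARTMENT[ntype])
    if not ids:
        raise ValueError(f"no nodes found in SWC file {path}")
    return NeuronSkeleton(
        node_ids=np.array(ids),
        positions=np.array(positions),
        radii=np.array(radii),
        parents=np.array(parents),
        compartments=np.array(comps, dtype=object),
    )


def write_swc(skeleton: NeuronSkeleton, path: str | Path) -> None:
    """Write a skeleton as standard 7-column SWC (coordinates back to x, y, z)."""
    lines = ["# id type x y z radius parent (um; types: 1 soma, 3 basal, 4 apical)"]
    for r in range(len(skeleton.node_ids)):
        z, y, x = skeleton.positions[r]
        lines.append(
            f"{int(skeleton.node_ids[r])} "
            f"{COMPARTMENT_TO_SWC_TYPE[str(skeleton.compartments[r])]} "
            f"{x:.6g} {y:.6g} {z:.6g} {skeleton.radii[r]:.6g} "
            f"{int(skeleton.parents[r])}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
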