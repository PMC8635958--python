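"""Deformable 2D cell geometry: membrane ring + interior Delaunay network.

The cell is a simple closed polygon of membrane nodes (counterclockwise)
filled with interior "lamellipod" nodes.  All nodes are joined by the
Delaunay triangulation, clipped to the membrane polygon, and each triangle
corner carries a reference angle so that angular strain can be measured as
the cell deforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path
from scipy.spatial import Delaunay, QhullError

__all__ = [
    "CellMesh",
    "GeometryCache",
    "IntegrityError",
    "build_disk_mesh",
    "compute_geometry",
    "retriangulate",
    "angle_strain",
    "triangle_angles",
    "corner_keys",
    "polygon_area",
    "outward_normals",
]

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def shift_up(a: np.ndarray) -> np.ndarray:
    """Periodic shift so that out[i] = a[i+1] (np.roll(a, -1), faster)."""
    out = np.empty_like(a)
    out[:-1] = a[1:]
    out[-1] = a[0]
    return out


def shift_down(a: np.ndarray) -> np.ndarray:
    """Periodic shift so that out[i] = a[i-1] (np.roll(a, 1), faster)."""
    out = np.empty_like(a)
    out[1:] = a[:-1]
    out[0] = a[-1]
    return out


class IntegrityError(RuntimeError):
    """Fatal violation of a geometric or bookkeeping invariant."""


@dataclass
class CellMesh:
    """Membrane ring, interior nodes and their clipped Delaunay triangulation.

    ``triangles`` indexes the concatenation ``[membrane; interior]`` and is
    stored in canonical form: each row sorted ascending, rows lexsorted.
    ``reference_angles[t, j]`` is the rest angle at corner ``triangles[t, j]``
    captured when the (triangle, corner) pair was first created.
    """

    membrane: np.ndarray            # (Nm, 2) μm, CCW
    interior: np.ndarray            # (Ni, 2) μm
    triangles: np.ndarray           # (T, 3) int, canonical
    reference_angles: np.ndarray    # (T, 3) rad
    full_triangles: np.ndarray | None = None   # unclipped Delaunay (for Eq-2 adjacency)

    @property
    def n_membrane(self) -> int:
        return len(self.membrane)

    @property
    def n_interior(self) -> int:
        return len(self.interior)

    @property
    def points(self) -> np.ndarray:
        return np.vstack([self.membrane, self.interior])

    @property
    def corner_angles(self) -> np.ndarray:
        return triangle_angles(self.points, self.triangles)

    @property
    def segment_lengths(self) -> np.ndarray:
        """Arc length of membrane edge i (node i -> node i+1, periodic)."""
        d = shift_up(self.membrane) - self.membrane
        return np.hypot(d[:, 0], d[:, 1])

    @property
    def node_arc_lengths(self) -> np.ndarray:
        """Control-volume arc length attached to each membrane node.

        When the membrane is numerically a regular polygon (segment spread
        below 1e-12 relative, i.e. pure floating-point noise), the control
        volumes snap to exactly uniform so that a symmetric state is
        preserved bitwise instead of seeding the polarization instability
        with rounding error.
        """
        seg = self.segment_lengths
        mean = seg.mean()
        if np.ptp(seg) < 1e-12 * mean:
            return np.full(len(seg), mean)
        return 0.5 * (seg + shift_down(seg))

    def validate(self) -> None:
        """Raise :class:`IntegrityError` on any broken mesh invariant."""
        if polygon_area(self.membrane) <= 0:
            raise IntegrityError("membrane polygon is not counterclockwise")
        if not _polygon_is_simple(self.membrane):
            raise IntegrityError("membrane polygon self-intersects")
        inside = Path(self.membrane).contains_points(self.interior)
        if not inside.all():
            raise IntegrityError(
                f"{np.count_nonzero(~inside)} interior node(s) outside the membrane"
            )
        ang = self.corner_angles
        if np.abs(ang.sum(axis=1) - np.pi).max() > 1e-9:
            raise IntegrityError("triangle corner angles do not sum to π")


@dataclass
class GeometryCache:
    """Per-step geometric quantities derived from a :class:`CellMesh`."""

    normals: np.ndarray           # (Nm, 2) outward unit normals
    segment_lengths: np.ndarray   # (Nm,)
    perimeter: float
    area: float
    corner_angles: np.ndarray     # (T, 3)
    centroid: np.ndarray = field(default_factory=lambda: np.zeros(2))


def polygon_area(poly: np.ndarray) -> float:
    """Signed shoelace area; positive for counterclockwise orientation."""
    x, y = poly[:, 0], poly[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    return 0.5 * float(np.sum(x * yn - xn * y))


def polygon_centroid(poly: np.ndarray) -> np.ndarray:
    x, y = poly[:, 0], poly[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * cross.sum()
    cx = np.sum((x + xn) * cross) / (6.0 * a)
    cy = np.sum((y + yn) * cross) / (6.0 * a)
    return np.array([cx, cy])


def _polygon_is_simple(poly: np.ndarray) -> bool:
    """Brute-force segment-pair intersection test (n is small)."""
    n = len(poly)
    p = poly
    q = np.roll(poly, -1, axis=0)
    d = q - p
    for i in range(n - 2):
        # candidate partners: non-adjacent edges only
        j = np.arange(i + 2, n if i > 0 else n - 1)
        r = p[j] - p[i]
        den = d[i, 0] * d[j, 1] - d[i, 1] * d[j, 0]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (r[:, 0] * d[j, 1] - r[:, 1] * d[j, 0]) / den
            u = (r[:, 0] * d[i, 1] - r[:, 1] * d[i, 0]) / den
        hit = (den != 0) & (t > 0) & (t < 1) & (u > 0) & (u < 1)
        if hit.any():
            return False
    return True


def outward_normals(poly: np.ndarray) -> np.ndarray:
    """Unit outward normal at each vertex of a CCW polygon.

    The normal at node i is the normalized bisector normal of its two
    incident edges (average of the two edge normals), which points away
    from the interior for a CCW polygon.
    """
    edge = shift_up(poly) - poly
    ln = np.hypot(edge[:, 0], edge[:, 1])
    if np.any(ln <= 0):
        raise IntegrityError("zero-length membrane edge")
    # outward normal of edge (dx,dy) on a CCW polygon is (dy,-dx)/|e|
    en = np.c_[edge[:, 1], -edge[:, 0]] / ln[:, None]
    nrm = en + shift_down(en)
    mag = np.hypot(nrm[:, 0], nrm[:, 1])
    mag = np.where(mag < 1e-12, 1.0, mag)
    return nrm / mag[:, None]


def triangle_angles(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Corner angle (rad) at each vertex of each triangle, shape (T, 3)."""
    p = points[triangles]  # (T, 3, 2)
    out = np.empty((len(triangles), 3))
    for j in range(3):
        a = p[:, j]
        u = p[:, (j + 1) % 3] - a
        v = p[:, (j + 2) % 3] - a
        nu = np.hypot(u[:, 0], u[:, 1])
        nv = np.hypot(v[:, 0], v[:, 1])
        cosang = np.clip((u * v).sum(axis=1) / (nu * nv), -1.0, 1.0)
        out[:, j] = np.arccos(cosang)
    return out


def unique_edges(triangles: np.ndarray) -> np.ndarray:
    """Undirected Delaunay edge list (E, 2), deduplicated."""
    t = np.asarray(triangles, dtype=np.int64)
    e = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
    lo = e.min(axis=1)
    hi = e.max(axis=1)
    key = np.unique(lo << 32 | hi)
    return np.column_stack([key >> 32, key & 0xFFFFFFFF])


def _canonical(triangles: np.ndarray) -> np.ndarray:
    tri = np.sort(np.asarray(triangles, dtype=np.int64), axis=1)
    order = np.lexsort((tri[:, 2], tri[:, 1], tri[:, 0]))
    return tri[order]


def corner_keys(mesh: CellMesh) -> np.ndarray:
    """Stable int64 identity for every (triangle, corner) pair, shape (T, 3).

    The key encodes the sorted node triple plus the corner's own node id, so
    a corner persists across retriangulations iff the same three nodes still
    form a triangle.
    """
    n = mesh.n_membrane + mesh.n_interior
    tri = mesh.triangles
    tkey = (tri[:, 0] * n + tri[:, 1]) * n + tri[:, 2]
    return tkey[:, None] * n + tri


def _clipped_delaunay(
    points: np.ndarray, membrane: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(clipped, full) canonical triangle arrays: the Delaunay triangulation
    of all nodes and its restriction to triangles whose centroid lies inside
    the membrane polygon."""
    simplices = Delaunay(points).simplices
    cent = points[simplices].mean(axis=1)
    keep = Path(membrane).contains_points(cent)
    return _canonical(simplices[keep]), _canonical(simplices)


def build_disk_mesh(
    diameter: float, n_membrane: int, n_interior: int, seed: int
) -> CellMesh:
    """Construct the resting circular cell.

    Membrane nodes are equally spaced on the circle of the given diameter;
    interior nodes fill the disk quasi-uniformly on a sunflower (Fibonacci)
    spiral pulled in from the membrane by one membrane spacing and smoothed
    by three rounds of Delaunay-neighbor averaging.  A fixed 1e-9-scale
    jitter derived from ``seed`` breaks co-circular Delaunay ties so the
    construction is bit-reproducible.
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    if n_membrane < 8:
        raise ValueError("need at least 8 membrane nodes")
    if n_interior < 1:
        raise ValueError("need at least one interior node")

    radius = diameter / 2.0
    theta = 2.0 * np.pi * np.arange(n_membrane) / n_membrane
    membrane = radius * np.c_[np.cos(theta), np.sin(theta)]
    spacing = 2.0 * radius * np.sin(np.pi / n_membrane)

    if n_interior == 1:
        interior = np.zeros((1, 2))
    else:
        k = np.arange(n_interior)
        r = (radius - spacing) * np.sqrt((k + 0.5) / n_interior)
        a = k * GOLDEN_ANGLE
        interior = np.c_[r * np.cos(a), r * np.sin(a)]

    for attempt in range(5):
        rng = np.random.default_rng([seed, attempt])
        pts = np.vstack([membrane, interior])
        pts[n_membrane:] += 1e-9 * rng.standard_normal(interior.shape)
        try:
            # quasi-uniform smoothing: 3 rounds of neighbor averaging
            inter = pts[n_membrane:].copy()
            if n_interior > 1:
                for _ in range(3):
                    allpts = np.vstack([membrane, inter])
                    tri, _ = _clipped_delaunay(allpts, membrane)
                    inter = _neighbor_average(allpts, tri, n_membrane)
            allpts = np.vstack([membrane, inter])
            tri, full = _clipped_delaunay(allpts, membrane)
        except QhullError:
            continue
        mesh = CellMesh(
            membrane=membrane,
            interior=inter if n_interior > 1 else interior,
            triangles=tri,
            reference_angles=np.empty((len(tri), 3)),
            full_triangles=full,
        )
        mesh.reference_angles = mesh.corner_angles.copy()
        return mesh
    raise IntegrityError("degenerate Delaunay triangulation after 5 jitter attempts")


def _neighbor_average(
    points: np.ndarray, triangles: np.ndarray, n_boundary: int
) -> np.ndarray:
    """Move every interior node to the mean of its Delaunay neighbors."""
    n = len(points)
    e = unique_edges(triangles)
    adj = np.zeros((n, 2))
    deg = np.zeros(n)
    for a, b in ((e[:, 0], e[:, 1]), (e[:, 1], e[:, 0])):
        np.add.at(adj, a, points[b])
        np.add.at(deg, a, 1.0)
    deg = np.where(deg == 0, 1.0, deg)
    new = adj / deg[:, None]
    out = points[n_boundary:].copy()
    out[:] = new[n_boundary:]
    return out


def compute_geometry(mesh: CellMesh, with_angles: bool = True) -> GeometryCache:
    """Normals, arc lengths, perimeter, enclosed area and corner angles.

    ``with_angles=False`` skips the (comparatively expensive) corner-angle
    computation for callers that only need the polygon quantities.
    """
    area = polygon_area(mesh.membrane)
    if area <= 0:
        raise IntegrityError("membrane polygon is not counterclockwise")
    seg = mesh.segment_lengths
    return GeometryCache(
        normals=outward_normals(mesh.membrane),
        segment_lengths=seg,
        perimeter=float(seg.sum()),
        area=float(area),
        corner_angles=mesh.corner_angles if with_angles else None,
        centroid=polygon_centroid(mesh.membrane),
    )


def retriangulate(mesh: CellMesh) -> CellMesh:
    """Recompute the clipped Delaunay triangulation for the current positions.

    Reference angles are carried over for (triangle, corner) pairs whose node
    triple persists; corners of newly created triangles start strain-free
    (reference = current angle).
    """
    new_tri, full = _clipped_delaunay(mesh.points, mesh.membrane)
    new = CellMesh(
        membrane=mesh.membrane,
        interior=mesh.interior,
        triangles=new_tri,
        reference_angles=np.empty((len(new_tri), 3)),
        full_triangles=full,
    )
    cur = new.corner_angles
    new.reference_angles = cur.copy()

    old_keys = corner_keys(mesh).ravel()
    new_keys = corner_keys(new).ravel()
    order = np.argsort(old_keys)
    pos = np.searchsorted(old_keys, new_keys, sorter=order)
    pos = np.clip(pos, 0, len(old_keys) - 1)
    hit = old_keys[order[pos]] == new_keys
    ref = new.reference_angles.ravel()
    ref[hit] = mesh.reference_angles.ravel()[order[pos[hit]]]
    new.reference_angles = ref.reshape(-1, 3)
    return new


def angle_strain(mesh: CellMesh) -> np.ndarray:
    """Signed angular strain Δθ = current − reference per (triangle, corner)."""
    return mesh.corner_angles - mesh.reference_angles


def mesh_to_dict(mesh: CellMesh) -> dict:
    """JSON-serializable snapshot of the mesh."""
    return {
        "membrane": mesh.membrane.tolist(),
        "interior": mesh.interior.tolist(),
        "triangles": mesh.triangles.tolist(),
        "reference_angles": mesh.reference_angles.tolist(),
    }


def mesh_from_dict(d: dict) -> CellMesh:
    return CellMesh(
        membrane=np.asarray(d["membrane"], dtype=float),
        interior=np.asarray(d["interior"], dtype=float),
        triangles=_canonical(np.asarray(d["triangles"], dtype=np.int64)),
        reference_angles=np.asarray(d["reference_angles"], dtype=float),
    )
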