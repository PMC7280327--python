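"""Triangle-mesh data model, I/O, cleaning, smoothing and sphere fitting.

Meshes are stored as shared-vertex triangle soups (``TriMesh``). All geometry
is held in metres internally; readers convert declared file units.  The
cleaning step mirrors the standard pre-processing applied to segmented
anatomical surfaces: welding duplicated vertices, discarding degenerate
triangles and faces incident to non-manifold (over-shared) edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import trimesh as _trimesh
from scipy.spatial import cKDTree

from .errors import NumericalError, ValidationError

#: metres per declared unit
_UNIT_SCALE = {"m": 1.0, "mm": 1e-3, "cm": 1e-2}

DEFAULT_WELD_TOL = 1e-6  # m; below scan resolution, above float noise


@dataclass
class TriMesh:
    """Shared-vertex triangle mesh.

    Parameters
    ----------
    vertices : (n, 3) float array, metres.
    faces : (m, 3) int array of 0-based vertex indices.
    name : identifier used in error messages and exports.
    """

    vertices: np.ndarray
    faces: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValidationError(f"{self.name}: vertices must be (n, 3)")
        if self.faces.size and (self.faces.ndim != 2 or self.faces.shape[1] != 3):
            raise ValidationError(f"{self.name}: faces must be (m, 3)")
        if self.faces.size == 0:
            self.faces = self.faces.reshape(0, 3)
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValidationError(f"{self.name}: face index out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def edges(self) -> np.ndarray:
        """All face edges as sorted vertex pairs, one row per half-edge."""
        e = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        return np.sort(e, axis=1)

    def face_areas(self) -> np.ndarray:
        p = self.vertices[self.faces]
        return 0.5 * np.linalg.norm(
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
        )

    def face_normals(self) -> np.ndarray:
        p = self.vertices[self.faces]
        n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        nn = np.linalg.norm(n, axis=1, keepdims=True)
        nn[nn == 0] = 1.0
        return n / nn

    def copy(self) -> "TriMesh":
        return TriMesh(self.vertices.copy(), self.faces.copy(), self.name)


@dataclass
class BoundaryLoop:
    """Ordered cyclic sequence of vertex indices on a mesh boundary."""

    vertex_indices: np.ndarray

    def __post_init__(self) -> None:
        self.vertex_indices = np.asarray(self.vertex_indices, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.vertex_indices)

    def points(self, mesh: TriMesh) -> np.ndarray:
        return mesh.vertices[self.vertex_indices]

    def centroid(self, mesh: TriMesh) -> np.ndarray:
        return self.points(mesh).mean(axis=0)


@dataclass
class Sphere:
    center: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=np.float64)
        if not np.isfinite(self.radius) or self.radius <= 0:
            raise ValidationError("sphere radius must be positive")


# ---------------------------------------------------------------------------
# I/O


def load_mesh(path, fmt: str | None = None, units: str = "m") -> TriMesh:
    """Load an STL/OBJ/PLY triangle mesh.

    ``units`` declares the file's length unit ("m", "mm" or "cm"); positions
    are converted to metres. OBJ's 1-based indexing is handled by the reader.
    """
    path = str(path)
    if fmt is None:
        fmt = path.rsplit(".", 1)[-1].lower()
    if fmt not in ("stl", "obj", "ply"):
        raise ValidationError(f"unsupported mesh format: {fmt}")
    if units not in _UNIT_SCALE:
        raise ValidationError(f"unknown unit declaration: {units}")
    try:
        loaded = _trimesh.load(path, file_type=fmt, process=False, force="mesh")
    except Exception as exc:  # noqa: BLE001 - rewrap parser failures
        raise IOError(f"cannot read mesh {path!r}: {exc}") from exc
    vertices = np.asarray(loaded.vertices, dtype=np.float64) * _UNIT_SCALE[units]
    faces = np.asarray(loaded.faces, dtype=np.int64)
    if len(vertices) == 0 or len(faces) == 0:
        raise ValidationError(f"mesh {path!r} is empty")
    name = path.rsplit("/", 1)[-1].rsplit(".", 1)[0]
    return TriMesh(vertices, faces, name=name)


def save_mesh(mesh: TriMesh, path, fmt: str | None = None) -> None:
    """Write a mesh as STL (ASCII), OBJ or PLY (ASCII)."""
    path = str(path)
    if fmt is None:
        fmt = path.rsplit(".", 1)[-1].lower()
    tm = _trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
    if fmt == "stl":
        data = _trimesh.exchange.stl.export_stl_ascii(tm)
        with open(path, "w") as fh:
            fh.write(data)
    elif fmt == "obj":
        tm.export(path, file_type="obj")
    elif fmt == "ply":
        tm.export(path, file_type="ply", encoding="ascii")
    else:
        raise ValidationError(f"unsupported mesh format: {fmt}")


# ---------------------------------------------------------------------------
# Cleaning


def clean_mesh(mesh: TriMesh, weld_tol: float = DEFAULT_WELD_TOL) -> TriMesh:
    """Weld near-duplicate vertices and drop defective faces.

    Three defect classes are repaired: duplicated vertices (welded within
    ``weld_tol``), degenerate triangles (repeated indices or zero area) and
    faces incident to edges shared by more than two faces.  Unreferenced
    vertices are dropped and indices remapped.  Idempotent.
    """
    if mesh.n_vertices == 0 or mesh.n_faces == 0:
        raise ValidationError("clean_mesh: empty mesh")

    # union-find over all vertex pairs closer than weld_tol
    tree = cKDTree(mesh.vertices)
    pairs = tree.query_pairs(weld_tol, output_type="ndarray")
    parent = np.arange(mesh.n_vertices)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    rep = np.array([find(i) for i in range(mesh.n_vertices)])

    faces = rep[mesh.faces]
    # degenerate: repeated indices
    ok = (
        (faces[:, 0] != faces[:, 1])
        & (faces[:, 1] != faces[:, 2])
        & (faces[:, 2] != faces[:, 0])
    )
    faces = faces[ok]
    # degenerate: zero area
    p = mesh.vertices[faces]
    areas = 0.5 * np.linalg.norm(
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
    )
    faces = faces[areas > 1e-16]

    # faces incident to over-shared edges
    if len(faces):
        e = np.sort(
            np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]),
            axis=1,
        )
        uniq, inv, counts = np.unique(e, axis=0, return_inverse=True, return_counts=True)
        bad_edge = counts[inv] > 2  # per half-edge flag
        bad_face = bad_edge.reshape(3, -1).any(axis=0)
        faces = faces[~bad_face]

    if len(faces) == 0:
        raise ValidationError("clean_mesh: no faces left after cleaning")

    used = np.unique(faces)
    remap = np.full(mesh.n_vertices, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return TriMesh(mesh.vertices[used], remap[faces], name=mesh.name)


def smooth_mesh(mesh: TriMesh, iterations: int, factor: float = 0.5) -> TriMesh:
    """Taubin smoothing: a shrink step (+factor) and an inflate step per
    iteration, with boundary vertices held fixed.  Connectivity unchanged.

    The inflate coefficient is -(factor + 0.03), the classic pairing that
    keeps the overall volume nearly constant (lambda=0.5, mu=-0.53 at the
    default factor).
    """
    if iterations < 0:
        raise ValidationError("smooth_mesh: iterations must be >= 0")
    if not (0.0 < factor < 1.0):
        raise ValidationError("smooth_mesh: factor must be in (0, 1)")
    if iterations == 0:
        return mesh.copy()

    n = mesh.n_vertices
    e = mesh.edges()
    uniq, counts = np.unique(e, axis=0, return_counts=True)
    boundary_verts = np.unique(uniq[counts == 1])
    free = np.ones(n, dtype=bool)
    free[boundary_verts] = False

    # umbrella (uniform-weight) neighbour averaging
    i = np.concatenate([uniq[:, 0], uniq[:, 1]])
    j = np.concatenate([uniq[:, 1], uniq[:, 0]])
    deg = np.bincount(i, minlength=n).astype(float)
    deg[deg == 0] = 1.0

    v = mesh.vertices.copy()
    mu = -(factor + 0.03)
    for _ in range(iterations):
        for step in (factor, mu):
            avg = np.zeros_like(v)
            np.add.at(avg, i, v[j])
            avg /= deg[:, None]
            delta = avg - v
            v[free] += step * delta[free]
    return TriMesh(v, mesh.faces.copy(), name=mesh.name)


# ---------------------------------------------------------------------------
# Boundary extraction


def boundary_loops(mesh: TriMesh) -> list[BoundaryLoop]:
    """Closed, ordered vertex loops of each boundary component.

    Loops follow the orientation induced by the incident faces.  Raises if
    any edge is shared by more than two faces (non-manifold).
    """
    f = mesh.faces
    directed = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    und = np.sort(directed, axis=1)
    uniq, inv, counts = np.unique(und, axis=0, return_inverse=True, return_counts=True)
    if counts.max(initial=0) > 2:
        raise ValidationError("boundary_loops: mesh has non-manifold edges")
    boundary = directed[counts[inv] == 1]
    if len(boundary) == 0:
        return []

    nxt = {int(a): int(b) for a, b in boundary}
    if len(nxt) != len(boundary):
        raise ValidationError("boundary_loops: boundary is not a disjoint union of simple loops")
    loops: list[BoundaryLoop] = []
    seen: set[int] = set()
    for start in sorted(nxt):
        if start in seen:
            continue
        loop = [start]
        seen.add(start)
        cur = nxt[start]
        while cur != start:
            loop.append(cur)
            seen.add(cur)
            cur = nxt[cur]
        loops.append(BoundaryLoop(np.array(loop)))
    return loops


# ---------------------------------------------------------------------------
# Sphere fitting


def fit_sphere(points: np.ndarray) -> Sphere:
    """Algebraic least-squares sphere fit (joint-centre estimation).

    Solves ``|p|^2 = 2 c.p + (r^2 - |c|^2)`` linearly: exact on noiseless
    spherical data, deterministic, and translation-equivariant.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 4:
        raise ValidationError("fit_sphere: need >= 4 points of shape (n, 3)")
    centroid = pts.mean(axis=0)
    q = pts - centroid  # centring improves conditioning
    A = np.column_stack([2.0 * q, np.ones(len(q))])
    b = (q**2).sum(axis=1)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4:
        raise ValidationError("fit_sphere: points are coplanar or degenerate")
    c = sol[:3]
    r2 = sol[3] + (c**2).sum()
    if r2 <= 0 or not np.isfinite(r2):
        raise NumericalError("fit_sphere: non-positive squared radius")
    return Sphere(center=c + centroid, radius=float(np.sqrt(r2)))


# ---------------------------------------------------------------------------
# Point-to-surface distance (exact, vectorized over faces)


def closest_point_on_surface(
    mesh: TriMesh, points: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closest surface point, distance and face index for each query point.

    Exact point-to-triangle projection evaluated against every face; intended
    for the moderate mesh sizes of anatomical models rather than huge scans.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    tri = mesh.vertices[mesh.faces]  # (m, 3, 3)
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac = b - a, c - a

    out_pts = np.empty_like(pts)
    out_d = np.empty(len(pts))
    out_f = np.empty(len(pts), dtype=np.int64)

    for k, p in enumerate(pts):
        ap = p - a
        d1 = (ab * ap).sum(axis=1)
        d2 = (ac * ap).sum(axis=1)
        bp = p - b
        d3 = (ab * bp).sum(axis=1)
        d4 = (ac * bp).sum(axis=1)
        cp = p - c
        d5 = (ab * cp).sum(axis=1)
        d6 = (ac * cp).sum(axis=1)

        va = d3 * d6 - d5 * d4
        vb = d5 * d2 - d1 * d6
        vc = d1 * d4 - d3 * d2
        denom = va + vb + vc
        denom = np.where(np.abs(denom) < 1e-300, 1.0, denom)
        v = vb / denom
        w = vc / denom

        cand = a + v[:, None] * ab + w[:, None] * ac  # interior projection
        # vertex regions
        cand = np.where(((d1 <= 0) & (d2 <= 0))[:, None], a, cand)
        cand = np.where(((d3 >= 0) & (d4 <= d3))[:, None], b, cand)
        cand = np.where(((d6 >= 0) & (d5 <= d6))[:, None], c, cand)
        # edge AB
        vab = d1 / np.where(d1 - d3 == 0, 1.0, d1 - d3)
        on_ab = (d1 >= 0) & (d3 <= 0) & (vc <= 0)
        cand = np.where(on_ab[:, None], a + np.clip(vab, 0, 1)[:, None] * ab, cand)
        # edge AC
        vac = d2 / np.where(d2 - d6 == 0, 1.0, d2 - d6)
        on_ac = (d2 >= 0) & (d6 <= 0) & (vb <= 0)
        cand = np.where(on_ac[:, None], a + np.clip(vac, 0, 1)[:, None] * ac, cand)
        # edge BC
        num = d4 - d3
        den = (d4 - d3) + (d5 - d6)
        vbc = num / np.where(den == 0, 1.0, den)
        on_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
        cand = np.where(on_bc[:, None], b + np.clip(vbc, 0, 1)[:, None] * (c - b), cand)

        dist = np.linalg.norm(cand - p, axis=1)
        fi = int(np.argmin(dist))
        out_pts[k] = cand[fi]
        out_d[k] = dist[fi]
        out_f[k] = fi
    return out_pts, out_d, out_f


def surface_distance(mesh: TriMesh, points: np.ndarray) -> np.ndarray:
    """Unsigned distance from each point to the mesh surface."""
    return closest_point_on_surface(mesh, points)[1]
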