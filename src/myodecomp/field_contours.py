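"""Harmonic scalar field between the two attachment boundaries and isolines.

The field orders the muscle cross-sections from origin (value 0) to insertion
(value 1): a discrete Laplace equation is solved on the open surface with
Dirichlet conditions on the two boundary loops.  Isoline contours of the
field are then the cross-sections onto which template slices are mapped.

The Laplace operator uses cotangent weights with negative off-diagonal
weights clamped to zero, which preserves the discrete maximum principle on
imperfect (obtuse-triangle) meshes at a small cost in accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import NumericalError, ValidationError
from .mesh_core import BoundaryLoop, TriMesh, boundary_loops

DEFAULT_RESAMPLE = 64  # arc-length uniform points per contour


@dataclass
class FieldOnMesh:
    """Per-vertex scalar field in [0, 1] on an open mesh."""

    mesh: TriMesh
    values: np.ndarray
    origin_loop: BoundaryLoop
    insertion_loop: BoundaryLoop

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)


@dataclass
class ClosedContour:
    """Closed isoline polyline on the mesh surface.

    ``points`` is an ordered cyclic sequence (first point not repeated);
    orientation is counter-clockwise about the mean field-gradient direction
    after normalization (``winding`` = "ccw").
    """

    points: np.ndarray
    level: float
    winding: str = "ccw"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)

    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        return float(np.linalg.norm(d, axis=1).sum())

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


def _cotan_laplacian(mesh: TriMesh) -> sp.csr_matrix:
    """Cotangent-weight Laplacian, negative weights clamped to 0."""
    n = mesh.n_vertices
    f = mesh.faces
    p = mesh.vertices[f]
    ij, w = [], []
    for k in range(3):
        # edge opposite to corner k
        a = p[:, k]
        b = p[:, (k + 1) % 3]
        c = p[:, (k + 2) % 3]
        u, v = b - a, c - a
        cos = (u * v).sum(axis=1)
        sin = np.linalg.norm(np.cross(u, v), axis=1)
        sin[sin < 1e-300] = 1e-300
        cot = cos / sin
        ij.append(f[:, [(k + 1) % 3, (k + 2) % 3]])
        w.append(0.5 * cot)
    ij = np.concatenate(ij)
    w = np.concatenate(w)
    W = sp.coo_matrix((w, (ij[:, 0], ij[:, 1])), shape=(n, n))
    W = W + W.T  # symmetrize: w_ij = (cot alpha + cot beta)/2
    W = W.tocsr()
    W.data = np.maximum(W.data, 0.0)  # clamp for the maximum principle
    d = np.asarray(W.sum(axis=1)).ravel()
    return sp.diags(d) - W


def solve_field(
    mesh: TriMesh, origin_loop: BoundaryLoop, insertion_loop: BoundaryLoop
) -> FieldOnMesh:
    """Discrete harmonic interpolation: 0 on origin, 1 on insertion.

    The mesh must have exactly the two given boundary loops.  The reduced
    system is symmetric positive-definite and solved directly; the result is
    clipped to [0, 1] only to absorb last-digit round-off.
    """
    loops = boundary_loops(mesh)
    loop_sets = [frozenset(l.vertex_indices.tolist()) for l in loops]
    want = [
        frozenset(origin_loop.vertex_indices.tolist()),
        frozenset(insertion_loop.vertex_indices.tolist()),
    ]
    if sorted(loop_sets, key=sorted) != sorted(want, key=sorted):
        raise ValidationError(
            f"solve_field: mesh has {len(loops)} boundary loops; expected exactly "
            "the given origin and insertion loops"
        )

    n = mesh.n_vertices
    L = _cotan_laplacian(mesh).tocsr()
    values = np.zeros(n)
    fixed = np.zeros(n, dtype=bool)
    fixed[origin_loop.vertex_indices] = True
    values[insertion_loop.vertex_indices] = 1.0
    fixed[insertion_loop.vertex_indices] = True
    free = ~fixed
    if free.any():
        A = L[free][:, free].tocsc()
        b = -L[free][:, fixed] @ values[fixed]
        try:
            x = spla.spsolve(A, b)
        except Exception as exc:  # pragma: no cover - singular operator
            raise NumericalError(f"solve_field: sparse solve failed: {exc}") from exc
        if not np.all(np.isfinite(x)):
            raise NumericalError("solve_field: singular system")
        values[free] = x
    return FieldOnMesh(mesh, np.clip(values, 0.0, 1.0), origin_loop, insertion_loop)


# ---------------------------------------------------------------------------
# Isoline extraction (marching triangles)


def _face_gradients(field: FieldOnMesh, face_ids: np.ndarray) -> np.ndarray:
    """Per-face gradient of the piece-wise linear field."""
    f = field.mesh.faces[face_ids]
    p = field.mesh.vertices[f]
    v = field.values[f]
    n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    a2 = np.linalg.norm(n, axis=1, keepdims=True)
    a2[a2 == 0] = 1.0
    nh = n / a2
    grad = np.zeros((len(f), 3))
    for k in range(3):
        e = p[:, (k + 2) % 3] - p[:, (k + 1) % 3]  # edge opposite vertex k
        grad += v[:, k, None] * np.cross(nh, e)
    return grad / a2


def extract_isoline(field: FieldOnMesh, level: float) -> ClosedContour:
    """Marching-triangles isoline, returned as the largest closed loop.

    Vertices whose value equals the level exactly are perturbed by 1e-12 so
    every crossing lies strictly inside an edge.  If the level produces
    several loops the one with the largest perimeter is kept.
    """
    if not (0.0 < level < 1.0):
        raise ValidationError("extract_isoline: level must be in (0, 1)")
    vals = field.values.copy()
    vals[vals == level] += 1e-12

    f = field.mesh.faces
    fv = vals[f]
    below = fv < level
    n_below = below.sum(axis=1)
    crossed = (n_below == 1) | (n_below == 2)
    if not crossed.any():
        raise ValidationError(f"extract_isoline: no edges cross level {level}")

    face_ids = np.nonzero(crossed)[0]
    # for each crossed face, its two crossing edges (as sorted vertex pairs)
    segs: list[tuple[tuple[int, int], tuple[int, int]]] = []
    edge_point: dict[tuple[int, int], np.ndarray] = {}
    V = field.mesh.vertices
    for fi in face_ids:
        tri = f[fi]
        cross_edges = []
        for k in range(3):
            a, b = int(tri[k]), int(tri[(k + 1) % 3])
            va, vb = vals[a], vals[b]
            if (va - level) * (vb - level) < 0:
                key = (min(a, b), max(a, b))
                if key not in edge_point:
                    t = (level - va) / (vb - va)
                    if a > b:
                        # parametrize consistently from the smaller index
                        t = 1.0 - t
                    lo, hi = key
                    edge_point[key] = V[lo] + t * (V[hi] - V[lo])
                cross_edges.append(key)
        if len(cross_edges) == 2:
            segs.append((cross_edges[0], cross_edges[1]))

    # chain crossing edges into loops via shared faces
    adj: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for e1, e2 in segs:
        adj.setdefault(e1, []).append(e2)
        adj.setdefault(e2, []).append(e1)

    loops: list[list[tuple[int, int]]] = []
    visited: set[tuple[int, int]] = set()
    for start in adj:
        if start in visited or len(adj[start]) != 2:
            continue
        loop = [start]
        visited.add(start)
        prev, cur = start, adj[start][0]
        while cur != start and cur not in visited:
            loop.append(cur)
            visited.add(cur)
            nbrs = adj.get(cur, [])
            nxt = [e for e in nbrs if e != prev]
            if not nxt:
                break
            prev, cur = cur, nxt[0]
        if cur == start and len(loop) >= 3:
            loops.append(loop)
    if not loops:
        raise ValidationError(f"extract_isoline: no closed loop at level {level}")

    def perim(loop: list[tuple[int, int]]) -> float:
        pts = np.array([edge_point[e] for e in loop])
        d = np.diff(np.vstack([pts, pts[:1]]), axis=0)
        return float(np.linalg.norm(d, axis=1).sum())

    best = max(loops, key=perim)
    pts = np.array([edge_point[e] for e in best])

    # orientation: counter-clockwise about the mean field gradient
    g = _face_gradients(field, face_ids).mean(axis=0)
    gn = np.linalg.norm(g)
    if gn > 0:
        g = g / gn
        centred = pts - pts.mean(axis=0)
        area_vec = 0.5 * np.cross(centred, np.roll(centred, -1, axis=0)).sum(axis=0)
        if float(area_vec @ g) < 0:
            pts = pts[::-1]
    return ClosedContour(points=pts, level=float(level))


def resample_closed(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polyline to ``n`` arc-length uniform points,
    keeping the original starting point."""
    closed = np.vstack([points, points[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ValidationError("resample_closed: degenerate contour")
    target = np.linspace(0.0, total, n, endpoint=False)
    out = np.empty((n, 3))
    for d in range(3):
        out[:, d] = np.interp(target, s, closed[:, d])
    return out


def _align_to(prev: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Cyclically shift ``pts`` to minimize total distance to ``prev``
    (nearest-point correspondence; prevents twist along the stack)."""
    n = len(pts)
    best_shift, best_cost = 0, np.inf
    for s in range(n):
        cost = float(((np.roll(pts, -s, axis=0) - prev) ** 2).sum())
        if cost < best_cost:
            best_cost, best_shift = cost, s
    return np.roll(pts, -best_shift, axis=0)


def contour_stack(
    field: FieldOnMesh, n_points: int, resample: int = DEFAULT_RESAMPLE
) -> list[ClosedContour]:
    """Extract ``n_points`` contours at levels k/(n_points+1), k=1..n_points,
    ordered origin -> insertion, each resampled to ``resample`` points with
    index correspondence propagated between consecutive contours.

    The first contour is anchored at its sample of minimum angular coordinate
    about the origin->insertion centroid axis; subsequent contours are
    aligned to their predecessor by cyclic nearest-point matching.
    """
    if n_points < 1:
        raise ValidationError("contour_stack: n_points must be >= 1")
    levels = [(k + 1) / (n_points + 1) for k in range(n_points)]
    contours = []
    for lv in levels:
        try:
            c = extract_isoline(field, lv)
        except ValidationError as exc:
            raise ValidationError(f"contour_stack: level {lv}: {exc}") from exc
        contours.append(c)

    o_cent = field.origin_loop.centroid(field.mesh)
    i_cent = field.insertion_loop.centroid(field.mesh)
    axis = i_cent - o_cent
    an = np.linalg.norm(axis)
    axis = axis / an if an > 0 else np.array([0.0, 0.0, 1.0])
    ref = np.array([1.0, 0.0, 0.0])
    if abs(ref @ axis) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - (ref @ axis) * axis
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)

    out: list[ClosedContour] = []
    prev: np.ndarray | None = None
    for c in contours:
        pts = resample_closed(c.points, resample)
        if prev is None:
            rel = pts - o_cent
            ang = np.mod(np.arctan2(rel @ e2, rel @ e1), 2 * np.pi)
            pts = np.roll(pts, -int(np.argmin(ang)), axis=0)
        else:
            pts = _align_to(prev, pts)
        prev = pts
        out.append(ClosedContour(points=pts, level=c.level, winding=c.winding))
    return out
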