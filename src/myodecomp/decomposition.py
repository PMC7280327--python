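"""Muscle decomposition pipeline: from a closed muscle mesh plus two
attachment areas to an ordered set of polyline fibres.

Stages: project the attachment outlines onto the muscle surface and remove
the enclosed regions (giving an open surface with two boundaries), solve the
harmonic field between the boundaries, extract one contour per interior
fibre point, map template slices onto the contours with mean-value
coordinates, append attachment endpoints with the same barycentric
machinery, and finally apply a quadratic smoothing with fixed endpoints.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dfield

import numpy as np
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
from scipy.spatial import cKDTree

from .errors import StageError, ValidationError
from .field_contours import (
    DEFAULT_RESAMPLE,
    contour_stack,
    resample_closed,
    solve_field,
)
from .mesh_core import TriMesh, boundary_loops, closest_point_on_surface
from .template_mapping import (
    FiberTemplate,
    map_section,
    mvc_matrix,
    slice_template,
)

DEFAULT_CAPTURE_DISTANCE = 0.02  # m, landmark-to-mesh projection limit
DEFAULT_SMOOTHING_LAM = 1.0

_UNIT_SCALE = {"m": 1.0, "mm": 1e-3, "cm": 1e-2}


@dataclass
class AttachmentArea:
    """Origin or insertion area: an ordered closed outline of landmarks
    fixed on a bone."""

    name: str
    bone: str
    landmarks: np.ndarray

    def __post_init__(self) -> None:
        self.landmarks = np.asarray(self.landmarks, dtype=np.float64)
        if self.landmarks.ndim != 2 or self.landmarks.shape[1] != 3:
            raise ValidationError(f"attachment {self.name}: landmarks must be (k, 3)")
        if len(self.landmarks) < 3:
            raise ValidationError(f"attachment {self.name}: need >= 3 landmarks")

    @property
    def centroid(self) -> np.ndarray:
        return self.landmarks.mean(axis=0)


@dataclass
class SurfaceRegion:
    """Faces of the muscle mesh covered by a projected attachment."""

    faces: np.ndarray
    outline_vertices: np.ndarray  # ordered vertex loop on the mesh
    projected_points: np.ndarray


@dataclass
class Bindings:
    """Per fibre point: indices of the two nearest bones and their blending
    weights (filled by kinematics.assign_bones)."""

    bone_order: list
    bones: np.ndarray  # (F, P, 2) int
    weights: np.ndarray  # (F, P, 2) float, rows sum to 1


@dataclass
class FiberSet:
    """n_fibers x n_points ordered 3D fibre polylines (metres)."""

    points: np.ndarray
    muscle: str = ""
    bindings: Bindings | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 3 or self.points.shape[2] != 3:
            raise ValidationError("FiberSet points must be (n_fibers, n_points, 3)")
        if not np.all(np.isfinite(self.points)):
            raise ValidationError("FiberSet contains non-finite coordinates")

    @property
    def n_fibers(self) -> int:
        return self.points.shape[0]

    @property
    def n_points(self) -> int:
        return self.points.shape[1]

    @property
    def n_segments(self) -> int:
        return self.n_points - 1

    def lengths(self) -> np.ndarray:
        """Polyline length of every fibre."""
        seg = np.diff(self.points, axis=1)
        return np.linalg.norm(seg, axis=2).sum(axis=1)

    def replace_points(self, points: np.ndarray) -> "FiberSet":
        return FiberSet(points=points, muscle=self.muscle, bindings=self.bindings)

    def to_json(self) -> str:
        return json.dumps(
            {
                "muscle": self.muscle,
                "n_fibers": self.n_fibers,
                "n_segments": self.n_segments,
                "points": self.points.tolist(),
                "units": "m",
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "FiberSet":
        d = json.loads(text)
        scale = _UNIT_SCALE[d.get("units", "m")]
        return cls(points=np.asarray(d["points"]) * scale, muscle=d.get("muscle", ""))

    def to_csv(self) -> str:
        lines = ["fiber_id,point_id,x,y,z"]
        for fi in range(self.n_fibers):
            for pi in range(self.n_points):
                x, y, z = self.points[fi, pi]
                lines.append(f"{fi},{pi},{x:.9g},{y:.9g},{z:.9g}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Landmark file I/O


def load_landmarks(path) -> dict:
    """Read a landmark JSON file into AttachmentAreas grouped by name prefix.

    The file holds ``{"units": ..., "landmarks": [{"name", "bone",
    "position"}, ...]}``; landmark names like ``origin_03`` group into the
    area ``origin`` with ordering given by file order.
    """
    with open(path) as fh:
        d = json.load(fh)
    scale = _UNIT_SCALE[d.get("units", "m")]
    groups: dict[str, dict] = {}
    for lm in d["landmarks"]:
        prefix = lm["name"].rsplit("_", 1)[0] if "_" in lm["name"] else lm["name"]
        g = groups.setdefault(prefix, {"bone": lm["bone"], "positions": []})
        g["positions"].append(np.asarray(lm["position"], dtype=np.float64) * scale)
    return {
        name: AttachmentArea(name=name, bone=g["bone"], landmarks=np.array(g["positions"]))
        for name, g in groups.items()
    }


def save_landmarks(areas, path, units: str = "m") -> None:
    scale = 1.0 / _UNIT_SCALE[units]
    landmarks = []
    for area in areas:
        for k, p in enumerate(area.landmarks):
            landmarks.append(
                {
                    "name": f"{area.name}_{k:03d}",
                    "bone": area.bone,
                    "position": (np.asarray(p) * scale).tolist(),
                }
            )
    with open(path, "w") as fh:
        json.dump({"units": units, "landmarks": landmarks}, fh, indent=1)


# ---------------------------------------------------------------------------
# Attachment projection and removal


def project_attachment(
    muscle: TriMesh,
    area: AttachmentArea,
    capture_distance: float = DEFAULT_CAPTURE_DISTANCE,
) -> SurfaceRegion:
    """Project the attachment outline onto the muscle surface and collect
    the enclosed faces.

    Landmarks are projected to their closest surface points (erroring past
    ``capture_distance``), snapped to mesh vertices, joined by shortest
    edge paths into a closed outline, and the vertex component on the
    attachment side of the outline defines the region.
    """
    proj, dist, _ = closest_point_on_surface(muscle, area.landmarks)
    far = np.nonzero(dist > capture_distance)[0]
    if len(far):
        raise ValidationError(
            f"attachment {area.name}: landmark {int(far[0])} is "
            f"{dist[far[0]]:.4f} m from the mesh (capture distance "
            f"{capture_distance} m)"
        )

    tree = cKDTree(muscle.vertices)
    snapped = tree.query(proj)[1]
    snapped = np.asarray(snapped, dtype=np.int64)

    # weighted vertex graph for shortest paths along edges
    e = muscle.edges()
    uniq = np.unique(e, axis=0)
    w = np.linalg.norm(muscle.vertices[uniq[:, 0]] - muscle.vertices[uniq[:, 1]], axis=1)
    n = muscle.n_vertices
    G = sp.coo_matrix(
        (np.concatenate([w, w]), (np.concatenate([uniq[:, 0], uniq[:, 1]]),
                                  np.concatenate([uniq[:, 1], uniq[:, 0]]))),
        shape=(n, n),
    ).tocsr()

    outline: list[int] = []
    uniq_snapped = [int(s) for s in dict.fromkeys(snapped.tolist())]
    m = len(uniq_snapped)
    for k in range(m):
        a = uniq_snapped[k]
        b = uniq_snapped[(k + 1) % m]
        if a == b:
            continue
        _, pred = csgraph.dijkstra(
            G, indices=a, return_predecessors=True, directed=False
        )
        chain = [b]
        while chain[-1] != a:
            prev = pred[chain[-1]]
            if prev < 0:
                raise ValidationError(
                    f"attachment {area.name}: outline vertices are disconnected"
                )
            chain.append(int(prev))
        outline.extend(chain[::-1][:-1])  # a .. just before b
    outline_arr = np.array(list(dict.fromkeys(outline)), dtype=np.int64)
    if len(outline_arr) < 3:
        raise ValidationError(f"attachment {area.name}: projected outline degenerate")

    # components of the vertex graph with the outline removed
    keep = np.ones(n, dtype=bool)
    keep[outline_arr] = False
    mask = keep[uniq[:, 0]] & keep[uniq[:, 1]]
    sub = sp.coo_matrix(
        (np.ones(mask.sum()), (uniq[mask, 0], uniq[mask, 1])), shape=(n, n)
    )
    n_comp, labels = csgraph.connected_components(sub, directed=False)
    labels = labels.copy()
    labels[~keep] = -1
    comp_ids = [c for c in range(n_comp) if np.any(labels == c)]
    if len(comp_ids) < 2:
        raise ValidationError(
            f"attachment {area.name}: outline does not separate the surface"
        )
    # the enclosed side is the component nearest the attachment centroid
    best, best_d = None, np.inf
    for c in comp_ids:
        cent = muscle.vertices[labels == c].mean(axis=0)
        dcent = float(np.linalg.norm(cent - area.centroid))
        if dcent < best_d:
            best, best_d = c, dcent
    inside = labels == best

    fl = inside[muscle.faces]
    on_outline = ~keep[muscle.faces]
    region_faces = np.nonzero((fl | on_outline).all(axis=1) & fl.any(axis=1))[0]
    if len(region_faces) == 0:
        raise ValidationError(f"attachment {area.name}: projected region is empty")
    return SurfaceRegion(
        faces=region_faces, outline_vertices=outline_arr, projected_points=proj
    )


def remove_region(muscle: TriMesh, region_faces: np.ndarray) -> TriMesh:
    """Delete the region faces, keeping the mesh connected.

    Unreferenced vertices are dropped and indices remapped.  Raises if the
    removal disconnects the remaining surface (e.g. an annular region).
    """
    region_faces = np.asarray(region_faces, dtype=np.int64)
    if len(region_faces) == 0:
        raise ValidationError("remove_region: empty region")
    keep = np.ones(muscle.n_faces, dtype=bool)
    keep[region_faces] = False
    faces = muscle.faces[keep]
    if len(faces) == 0:
        raise ValidationError("remove_region: removal leaves no faces")

    # face connectivity via shared edges
    e = np.sort(
        np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]), axis=1
    )
    fid = np.tile(np.arange(len(faces)), 3)
    order = np.lexsort((e[:, 1], e[:, 0]))
    es, fs = e[order], fid[order]
    same = (np.diff(es, axis=0) == 0).all(axis=1)
    pairs = np.column_stack([fs[:-1][same], fs[1:][same]])
    A = sp.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
        shape=(len(faces), len(faces)),
    )
    n_comp, _ = csgraph.connected_components(A, directed=False)
    if n_comp > 1:
        raise ValidationError("remove_region: removal disconnects the mesh")

    used = np.unique(faces)
    remap = np.full(muscle.n_vertices, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return TriMesh(muscle.vertices[used], remap[faces], name=muscle.name)


# ---------------------------------------------------------------------------
# Fibre smoothing


def smooth_fibers(fibers: FiberSet, lam: float = DEFAULT_SMOOTHING_LAM) -> FiberSet:
    """Quadratic smoothing per fibre: minimize the sum of squared
    displacements plus ``lam`` times the squared second differences, with
    both endpoints fixed.  The normal equations are a small SPD tridiagonal-
    bandwidth system solved densely (n_points is small)."""
    if lam < 0:
        raise ValidationError("smooth_fibers: lam must be >= 0")
    if lam == 0 or fibers.n_points <= 2:
        return fibers.replace_points(fibers.points.copy())

    n = fibers.n_points
    m = n - 2  # interior points
    # second differences over all consecutive triples, split into
    # interior-column and endpoint-column blocks
    D_full = np.zeros((m, n))
    for k in range(m):
        D_full[k, k : k + 3] = (1.0, -2.0, 1.0)
    D_i = D_full[:, 1:-1]
    D_b = D_full[:, [0, -1]]

    A = np.eye(m) + lam * (D_i.T @ D_i)
    pts = fibers.points
    p_int = pts[:, 1:-1, :]  # (F, m, 3)
    p_b = pts[:, [0, -1], :]  # (F, 2, 3)
    rhs = p_int - lam * np.einsum("km,fmd->fkd", D_i.T @ D_b, p_b)
    sol = np.linalg.solve(A, rhs.reshape(fibers.n_fibers, m, 3).transpose(1, 0, 2).reshape(m, -1))
    out = pts.copy()
    out[:, 1:-1, :] = sol.reshape(m, fibers.n_fibers, 3).transpose(1, 0, 2)
    return fibers.replace_points(out)


# ---------------------------------------------------------------------------
# Attachment connection


def _fit_endpoints(
    seeds_lam: np.ndarray, outline3d: np.ndarray, ring: np.ndarray
) -> np.ndarray:
    """Endpoints from barycentric weights and an attachment outline, choosing
    the cyclic shift/orientation best aligned with the adjacent fibre ring."""
    best_pts, best_cost = None, np.inf
    for cand in (outline3d, outline3d[::-1]):
        for s in range(len(cand)):
            rolled = np.roll(cand, -s, axis=0)
            pts = seeds_lam @ rolled
            cost = float(((pts - ring) ** 2).sum())
            if cost < best_cost:
                best_cost, best_pts = cost, pts
    return best_pts


def connect_attachments(
    fibers: FiberSet,
    origin: AttachmentArea,
    insertion: AttachmentArea,
    template: FiberTemplate | None = None,
    resample: int = DEFAULT_RESAMPLE,
) -> FiberSet:
    """Fill the first/last fibre points with positions on the attachment
    areas, mapped from the template end faces through the same mean-value
    machinery used for the interior contours."""
    if template is None:
        from .template_mapping import make_parallel_template

        template = make_parallel_template(fibers.n_fibers)
    for area in (origin, insertion):
        # collinearity check on the outline
        lm = area.landmarks - area.centroid
        s = np.linalg.svd(lm, compute_uv=False)
        if s[1] < 1e-12 * max(s[0], 1e-30):
            raise ValidationError(f"attachment {area.name}: landmarks are collinear")

    end_sections = slice_template(template, [0.0, 1.0], resample=resample)
    lam0 = mvc_matrix(end_sections[0].fiber_points_2d, end_sections[0].boundary_polygon)
    lam1 = mvc_matrix(end_sections[1].fiber_points_2d, end_sections[1].boundary_polygon)

    out = fibers.points.copy()
    o_outline = resample_closed(origin.landmarks, resample)
    i_outline = resample_closed(insertion.landmarks, resample)
    out[:, 0, :] = _fit_endpoints(lam0, o_outline, fibers.points[:, 1, :])
    out[:, -1, :] = _fit_endpoints(lam1, i_outline, fibers.points[:, -2, :])
    return fibers.replace_points(out)


# ---------------------------------------------------------------------------
# Full pipeline


def decompose_muscle(
    muscle: TriMesh,
    origin: AttachmentArea,
    insertion: AttachmentArea,
    n_fibers: int = 100,
    n_segments: int = 15,
    template: FiberTemplate | None = None,
    smoothing_lam: float = DEFAULT_SMOOTHING_LAM,
    capture_distance: float = DEFAULT_CAPTURE_DISTANCE,
    resample: int = DEFAULT_RESAMPLE,
) -> FiberSet:
    """Decompose a muscle surface mesh into ``n_fibers`` polyline fibres of
    ``n_segments`` straight segments each (n_segments+1 points: one endpoint
    per attachment plus n_segments-1 interior contour points).

    Deterministic given identical inputs and configuration.
    """
    if n_fibers < 1:
        raise ValidationError("decompose_muscle: n_fibers must be >= 1")
    if n_segments < 2:
        raise ValidationError("decompose_muscle: n_segments must be >= 2")
    if template is None:
        from .template_mapping import make_parallel_template

        template = make_parallel_template(n_fibers)
    if template.n_fibers != n_fibers:
        raise ValidationError("decompose_muscle: template fibre count mismatch")

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(name, str(exc)) from exc

    region_o = stage("project_origin", project_attachment, muscle, origin,
                     capture_distance)
    region_i = stage("project_insertion", project_attachment, muscle, insertion,
                     capture_distance)
    all_faces = np.union1d(region_o.faces, region_i.faces)
    open_mesh = stage("remove_attachments", remove_region, muscle, all_faces)

    loops = stage("boundary_loops", boundary_loops, open_mesh)
    if len(loops) != 2:
        raise StageError(
            "boundary_loops", f"expected 2 boundary loops, found {len(loops)}"
        )
    d0 = np.linalg.norm(loops[0].centroid(open_mesh) - origin.centroid)
    d1 = np.linalg.norm(loops[1].centroid(open_mesh) - origin.centroid)
    loop_o, loop_i = (loops[0], loops[1]) if d0 <= d1 else (loops[1], loops[0])

    fld = stage("solve_field", solve_field, open_mesh, loop_o, loop_i)
    n_interior = n_segments - 1
    contours = stage("contour_stack", contour_stack, fld, n_interior, resample)
    levels = [c.level for c in contours]
    sections = stage("slice_template", slice_template, template, levels, resample)

    pts = np.empty((n_fibers, n_segments + 1, 3))
    for k, (sec, con) in enumerate(zip(sections, contours)):
        pts[:, k + 1, :] = stage("map_section", map_section, sec, con)
    pts[:, 0, :] = pts[:, 1, :]  # placeholders until attachment connection
    pts[:, -1, :] = pts[:, -2, :]

    fibers = FiberSet(points=pts, muscle=muscle.name)
    fibers = stage(
        "connect_attachments", connect_attachments, fibers, origin, insertion,
        template, resample,
    )
    fibers = stage("smooth_fibers", smooth_fibers, fibers, smoothing_lam)
    if np.any(fibers.lengths() <= 0):
        raise StageError("smooth_fibers", "zero-length fibre produced")
    return fibers
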