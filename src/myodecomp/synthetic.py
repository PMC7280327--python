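"""Synthetic muscles, bones and analytic oracles.

Everything the pipeline consumes can be generated here at anatomy-like
scales (lengths 0.1-0.4 m, radii 0.01-0.05 m): watertight tube/fusiform
muscle meshes with landmark rings on their end caps, a two-bone toy
skeleton articulated by a ball joint, and a planar hinge toy whose length
and moment arm have closed forms — the independent oracle for the
tendon-excursion method.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
import trimesh as _trimesh

from .decomposition import AttachmentArea, Bindings, FiberSet
from .errors import ValidationError
from .kinematics import BallJoint, Skeleton
from .mesh_core import TriMesh


@dataclass
class TubeSpec:
    """Parametric tube/fusiform muscle.

    ``centerline`` holds Bezier control points (metres); the radius profile
    is ``("constant", r)`` or ``("fusiform", r_min, r_max)`` with
    r(t) = r_min + (r_max - r_min) sin(pi t).  ``jitter`` adds seeded
    Gaussian vertex noise to exercise smoothing/robustness paths.
    """

    centerline: np.ndarray = dfield(
        default_factory=lambda: np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 0.2]])
    )
    radius: tuple = ("constant", 0.03)
    n_circumferential: int = 32
    n_axial: int = 20
    jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=np.float64)
        if self.n_circumferential < 8 or self.n_axial < 4:
            raise ValidationError("TubeSpec: resolutions must be >= 8 and >= 4")
        radii = self.radius[1:]
        if any(r <= 0 for r in radii):
            raise ValidationError("TubeSpec: radii must be positive")

    def radius_at(self, t: float) -> float:
        if self.radius[0] == "constant":
            return float(self.radius[1])
        if self.radius[0] == "fusiform":
            r_min, r_max = self.radius[1], self.radius[2]
            return float(r_min + (r_max - r_min) * np.sin(np.pi * t))
        raise ValidationError(f"TubeSpec: unknown radius profile {self.radius[0]!r}")


@dataclass
class HingeToy:
    """Planar two-segment toy: attachments at distances a and b from the
    hinge, rest included angle theta0 (degrees).  Closed forms:
    l = sqrt(a^2 + b^2 - 2ab cos(theta0 + theta)),
    |r| = a b sin(theta0 + theta) / l.
    """

    a: float = 0.1
    b: float = 0.1
    theta0: float = 90.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValidationError("HingeToy: a and b must be positive")


def _bezier(control: np.ndarray, t: np.ndarray) -> np.ndarray:
    pts = control[None, :, :] * np.ones((len(t), 1, 1))
    tt = t[:, None]
    while pts.shape[1] > 1:
        pts = (1 - tt[:, :, None]) * pts[:, :-1] + tt[:, :, None] * pts[:, 1:]
    return pts[:, 0, :]


def _bezier_tangent(control: np.ndarray, t: np.ndarray) -> np.ndarray:
    d = len(control) - 1
    if d == 0:
        raise ValidationError("centerline needs >= 2 control points")
    dctrl = d * np.diff(control, axis=0)
    tan = _bezier(dctrl, t) if len(dctrl) > 1 else np.tile(dctrl[0], (len(t), 1))
    n = np.linalg.norm(tan, axis=1, keepdims=True)
    if np.any(n < 1e-12):
        raise ValidationError("centerline has a stationary point")
    return tan / n


def make_tube_muscle(spec: TubeSpec) -> tuple[TriMesh, AttachmentArea, AttachmentArea]:
    """Closed watertight tube mesh with end caps plus attachment landmark
    rings on the cap perimeters.  Deterministic for a fixed seed.

    Cross-section frames are parallel-transported along the centerline so
    the surface carries no spurious twist.
    """
    nc, na = spec.n_circumferential, spec.n_axial
    t = np.linspace(0.0, 1.0, na + 1)
    centers = _bezier(spec.centerline, t)
    tangents = _bezier_tangent(spec.centerline, t)

    # parallel-transport frame
    ref = np.array([1.0, 0.0, 0.0])
    if abs(ref @ tangents[0]) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - (ref @ tangents[0]) * tangents[0]
    e1 /= np.linalg.norm(e1)
    frames = [e1]
    for k in range(1, len(t)):
        prev = frames[-1]
        tk = tangents[k]
        v = prev - (prev @ tk) * tk
        nv = np.linalg.norm(v)
        if nv < 1e-12:
            raise ValidationError("make_tube_muscle: frame transport degenerate")
        frames.append(v / nv)

    phi = 2 * np.pi * np.arange(nc) / nc
    rings = []
    radii = [spec.radius_at(tk) for tk in t]
    for k in range(len(t)):
        e1k = frames[k]
        e2k = np.cross(tangents[k], e1k)
        ring = (
            centers[k]
            + radii[k] * (np.cos(phi)[:, None] * e1k + np.sin(phi)[:, None] * e2k)
        )
        rings.append(ring)
    # self-intersection guard: ring radius vs local centerline curvature
    seg = np.diff(centers, axis=0)
    if np.any(np.linalg.norm(seg, axis=1) <= 0):
        raise ValidationError("make_tube_muscle: degenerate centerline")
    turn = (tangents[:-1] * tangents[1:]).sum(axis=1).clip(-1, 1)
    ang = np.arccos(turn)
    with np.errstate(divide="ignore"):
        curv_radius = np.where(ang > 0, np.linalg.norm(seg, axis=1) / np.maximum(ang, 1e-30), np.inf)
    if np.any(curv_radius < np.maximum(radii[:-1], radii[1:])):
        raise ValidationError("make_tube_muscle: centerline self-intersects at this radius")

    verts = np.concatenate(rings)  # (na+1)*nc
    if spec.jitter > 0:
        rng = np.random.default_rng(spec.seed)
        verts = verts + rng.normal(0.0, spec.jitter, size=verts.shape)
    faces = []
    for k in range(na):
        base0, base1 = k * nc, (k + 1) * nc
        for j in range(nc):
            j2 = (j + 1) % nc
            faces.append((base0 + j, base1 + j, base0 + j2))
            faces.append((base0 + j2, base1 + j, base1 + j2))
    # end caps: fan around the cap centre
    c0 = len(verts)
    c1 = len(verts) + 1
    verts = np.vstack([verts, centers[0], centers[-1]])
    for j in range(nc):
        j2 = (j + 1) % nc
        faces.append((c0, j, j2))  # orientation consistent with side faces
        base = na * nc
        faces.append((c1, base + j2, base + j))
    mesh = TriMesh(verts, np.array(faces), name="tube_muscle")

    origin = AttachmentArea(name="origin", bone="parent", landmarks=rings[0].copy())
    insertion = AttachmentArea(name="insertion", bone="child", landmarks=rings[-1].copy())
    return mesh, origin, insertion


def make_two_bone_skeleton(center=(0.0, 0.0, 0.0)) -> Skeleton:
    """Two box bones articulated by a ball joint at ``center``: the parent
    sits above the joint (pelvis-like, fixed), the child below (femur-like).
    """
    center = np.asarray(center, dtype=np.float64)

    def box(offset, extents=(0.08, 0.12, 0.08)):
        b = _trimesh.creation.box(extents=extents)
        return TriMesh(
            np.asarray(b.vertices) + center + np.asarray(offset),
            np.asarray(b.faces),
        )

    bones = {
        "parent": box((0.0, 0.12, 0.0)),
        "child": box((0.0, -0.12, 0.0)),
    }
    joint = BallJoint(center=center, parent="parent", child="child")
    return Skeleton(bones=bones, joint=joint)


def hinge_oracle(toy: HingeToy, theta_deg: float) -> tuple[float, float]:
    """Closed-form (length, moment-arm magnitude) of the hinge toy at
    deflection ``theta_deg`` from rest."""
    phi = np.deg2rad(toy.theta0 + theta_deg)
    if not (0.0 < np.rad2deg(phi) < 180.0):
        raise ValidationError("hinge_oracle: included angle must be in (0, 180) degrees")
    l = np.sqrt(toy.a**2 + toy.b**2 - 2 * toy.a * toy.b * np.cos(phi))
    r = toy.a * toy.b * np.sin(phi) / l
    return float(l), float(r)


def make_hinge_system(
    toy: HingeToy, center=(0.0, 0.0, 0.0)
) -> tuple[Skeleton, FiberSet]:
    """Skeleton plus a single two-point fibre realizing the hinge toy in the
    ball joint's flexion plane (rotation about +z).

    The parent-fixed endpoint sits at distance ``a`` along +y from the joint
    centre; the child-fixed endpoint at distance ``b`` such that the rest
    included angle is ``theta0`` and flexion (+z rotation) opens the angle.
    Bone boxes are placed along the two segments so nearest-bone binding is
    unambiguous.
    """
    center = np.asarray(center, dtype=np.float64)
    th0 = np.deg2rad(toy.theta0)
    u_p = np.array([0.0, 1.0, 0.0])
    u_d = np.array([-np.sin(th0), np.cos(th0), 0.0])
    P = center + toy.a * u_p
    D = center + toy.b * u_d

    def box(offset):
        b = _trimesh.creation.box(extents=(0.04, 0.04, 0.04))
        return TriMesh(np.asarray(b.vertices) + offset, np.asarray(b.faces))

    bones = {
        "parent": box(center + 1.5 * toy.a * u_p),
        "child": box(center + 1.5 * toy.b * u_d),
    }
    skeleton = Skeleton(bones=bones, joint=BallJoint(center=center, parent="parent", child="child"))
    # ranges wide enough for hinge sweeps
    skeleton.coord_ranges = {
        "flexion": (-89.0, 89.0),
        "adduction": (-89.0, 89.0),
        "rotation": (-89.0, 89.0),
    }

    points = np.array([[P, D]])
    binding = Bindings(
        bone_order=["parent", "child"],
        bones=np.array([[[0, 1], [0, 1]]]),
        weights=np.array([[[1.0, 0.0], [0.0, 1.0]]]),
    )
    fibers = FiberSet(points=points, muscle="hinge_toy", bindings=binding)
    return skeleton, fibers
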