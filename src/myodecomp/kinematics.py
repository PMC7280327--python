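"""Two-bone blending-weight kinematics for fibre points.

A ball-and-socket joint (three rotational degrees of freedom, e.g. the hip)
connects a fixed parent bone to a child bone.  Each fibre point is bound to
its two nearest bones and its posed position is the convex combination of
its two rigidly transformed images,

    V'_i = sum_j w_ij (R_j V_i + T_j),   w_i1 + w_i2 = 1,

with weights from a quadratic profile along the fibre,

    w_i1 = f(t) = a t^2 - (a + 1) t + 1,   t = (i - 1) / (n - 1),

so that f(0) = 1 and f(1) = 0: the endpoints move rigidly with their
attachment bones while interior points blend.  The single muscle-specific
parameter ``a`` sets how quickly a bone's influence fades along the fibre.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np

from .decomposition import Bindings, FiberSet
from .errors import ValidationError
from .mesh_core import TriMesh, surface_distance

#: muscle-specific weight parameters fitted in the source hip models
DEFAULT_WEIGHT_PARAMS = {
    "psoas": -0.042,
    "iliacus": -0.024,
    "gluteus_maximus": -0.042,
    "gluteus_medius": 0.0,
}

#: pose coordinate order and default ranges (degrees)
COORDINATES = ("flexion", "adduction", "rotation")
DEFAULT_COORD_RANGES = {
    "flexion": (-10.0, 60.0),
    "adduction": (-40.0, 40.0),
    "rotation": (-30.0, 30.0),
}


@dataclass
class RigidTransform:
    """Rotation + translation; applied as R x + T."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64)
        self.translation = np.asarray(self.translation, dtype=np.float64)
        R = self.rotation
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9) or not np.isclose(
            np.linalg.det(R), 1.0, atol=1e-9
        ):
            raise ValidationError("RigidTransform: rotation is not proper orthonormal")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation


@dataclass
class BallJoint:
    center: np.ndarray
    parent: str
    child: str
    rotation_order: str = "zxy"  # body-fixed: flexion Z, adduction X, rotation Y

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=np.float64)
        if not np.all(np.isfinite(self.center)):
            raise ValidationError("BallJoint: centre must be finite")


@dataclass
class Skeleton:
    """Named bone meshes in rest pose plus one ball-and-socket joint."""

    bones: dict
    joint: BallJoint
    coord_ranges: dict = dfield(default_factory=lambda: dict(DEFAULT_COORD_RANGES))

    def __post_init__(self) -> None:
        if self.joint.parent not in self.bones or self.joint.child not in self.bones:
            raise ValidationError("Skeleton: joint bones missing from bone dict")

    @property
    def bone_names(self) -> list:
        return list(self.bones)


@dataclass
class JointPose:
    """Hip-style pose: flexion, adduction, internal rotation in degrees."""

    flexion: float = 0.0
    adduction: float = 0.0
    rotation: float = 0.0

    def __post_init__(self) -> None:
        for name in COORDINATES:
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValidationError(f"JointPose: {name} must be finite")

    def coordinate(self, name: str) -> float:
        if name not in COORDINATES:
            raise ValidationError(f"unknown coordinate {name!r}")
        return float(getattr(self, name))


def weight_function(a: float, t) -> tuple:
    """Blending weights (w1, w2) of the origin- and insertion-side bones at
    relative fibre position ``t``; w1 = a t^2 - (a+1) t + 1, w2 = 1 - w1."""
    t = np.asarray(t, dtype=np.float64)
    if np.any(t < -1e-12) or np.any(t > 1 + 1e-12):
        raise ValidationError("weight_function: t must be in [0, 1]")
    w1 = a * t**2 - (a + 1.0) * t + 1.0
    return w1, 1.0 - w1


def _axis_rotation(axis: str, angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    if axis == "x":
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)
    if axis == "y":
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)
    if axis == "z":
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)
    raise ValidationError(f"unknown rotation axis {axis!r}")


def pose_transforms(skeleton: Skeleton, pose: JointPose) -> dict:
    """Rigid transform per bone for a pose: identity for the parent; for the
    child a body-fixed Z(flexion)-X(adduction)-Y(rotation) rotation about the
    joint centre (the centre is a fixed point of the child transform)."""
    for name in COORDINATES:
        lo, hi = skeleton.coord_ranges.get(name, (-180.0, 180.0))
        v = pose.coordinate(name)
        if not (lo - 1e-9 <= v <= hi + 1e-9):
            raise ValidationError(
                f"pose_transforms: {name}={v}° outside configured range [{lo}, {hi}]"
            )
    angles = {
        "z": np.deg2rad(pose.flexion),
        "x": np.deg2rad(pose.adduction),
        "y": np.deg2rad(pose.rotation),
    }
    R = np.eye(3)
    for ax in skeleton.joint.rotation_order:
        R = R @ _axis_rotation(ax, angles[ax])
    c = skeleton.joint.center
    child = RigidTransform(R, c - R @ c)
    out = {name: RigidTransform.identity() for name in skeleton.bones}
    out[skeleton.joint.child] = child
    return out


def assign_bones(fibers: FiberSet, skeleton: Skeleton, a: float = 0.0) -> FiberSet:
    """Bind every fibre point to its two nearest bones (rest-pose
    point-to-surface distance) with quadratic blending weights.

    w1 goes to the origin-side bone, identified per fibre as the bone
    nearest the first fibre point; t runs 0..1 from the fibre origin.
    """
    names = skeleton.bone_names
    if len(names) < 2:
        raise ValidationError("assign_bones: skeleton needs at least two bones")
    F, P = fibers.n_fibers, fibers.n_points
    flat = fibers.points.reshape(-1, 3)
    dists = np.stack(
        [surface_distance(skeleton.bones[n], flat) for n in names], axis=1
    )  # (F*P, n_bones)
    nearest2 = np.argsort(dists, axis=1, kind="stable")[:, :2].reshape(F, P, 2)

    t = np.arange(P) / (P - 1) if P > 1 else np.zeros(1)
    w1, w2 = weight_function(a, t)

    bones = np.empty((F, P, 2), dtype=np.int64)
    weights = np.empty((F, P, 2), dtype=np.float64)
    for fi in range(F):
        origin_bone = int(nearest2[fi, 0, 0])
        for pi in range(P):
            pair = list(nearest2[fi, pi])
            if origin_bone in pair:
                other = pair[0] if pair[1] == origin_bone else pair[1]
            else:
                other = pair[0]
            bones[fi, pi] = (origin_bone, other)
            weights[fi, pi] = (w1[pi], w2[pi])
    binding = Bindings(bone_order=names, bones=bones, weights=weights)
    return FiberSet(points=fibers.points.copy(), muscle=fibers.muscle, bindings=binding)


def update_fibers(fibers: FiberSet, transforms: dict) -> FiberSet:
    """Pose the fibre points: each becomes the weighted combination of its
    two rigidly transformed images.  The rest geometry is untouched."""
    if fibers.bindings is None:
        raise ValidationError("update_fibers: fibres have no bone bindings")
    b = fibers.bindings
    names = b.bone_order
    missing = [n for n in names if n not in transforms]
    if missing:
        raise ValidationError(f"update_fibers: missing transforms for {missing}")

    imgs = np.stack(
        [transforms[n].apply(fibers.points.reshape(-1, 3)) for n in names]
    )  # (n_bones, F*P, 3)
    F, P = fibers.n_fibers, fibers.n_points
    flat_idx = np.arange(F * P)
    bones = b.bones.reshape(-1, 2)
    weights = b.weights.reshape(-1, 2)
    img1 = imgs[bones[:, 0], flat_idx]
    img2 = imgs[bones[:, 1], flat_idx]
    # affine form: exact when both images coincide (e.g. identity transforms)
    out = img1 + weights[:, 1, None] * (img2 - img1)
    return FiberSet(
        points=out.reshape(F, P, 3), muscle=fibers.muscle, bindings=b
    )
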