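"""Straight-lines musculotendon paths with (conditional) via points.

The conventional multibody representation of a muscle: an ordered polyline
of path points fixed to bones, where a conditional via point participates
only while a joint coordinate lies within its active range.  Used as the
comparison model for the fibre decomposition; its moment arms are computed
geometrically (perpendicular-distance/cross-product form), which stays exact
where conditional points make the length non-smooth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import NumericalError, ValidationError
from .kinematics import JointPose, Skeleton, pose_transforms


@dataclass
class PathPoint:
    """A via point fixed to a bone, optionally conditional on a coordinate
    staying within [lo, hi] degrees (closed interval)."""

    bone: str
    local_position: np.ndarray
    condition: tuple | None = None  # (coordinate_name, (lo, hi))

    def __post_init__(self) -> None:
        self.local_position = np.asarray(self.local_position, dtype=np.float64)
        if self.condition is not None:
            _, (lo, hi) = self.condition
            if not lo < hi:
                raise ValidationError("PathPoint: condition range must have lo < hi")

    def is_active(self, pose: JointPose) -> bool:
        if self.condition is None:
            return True
        coord, (lo, hi) = self.condition
        return lo <= pose.coordinate(coord) <= hi


@dataclass
class PolylinePath:
    """Ordered path points origin -> insertion."""

    points: list
    name: str = ""

    def __post_init__(self) -> None:
        uncond = [p for p in self.points if p.condition is None]
        if len(uncond) < 2:
            raise ValidationError("PolylinePath: need >= 2 unconditional points")
        if self.points[0].condition is not None or self.points[-1].condition is not None:
            raise ValidationError("PolylinePath: first and last points must be unconditional")

    @classmethod
    def from_json(cls, text: str) -> "PolylinePath":
        d = json.loads(text)
        pts = []
        for p in d["points"]:
            cond = None
            if "condition" in p and p["condition"] is not None:
                c = p["condition"]
                cond = (c["coordinate"], (float(c["range"][0]), float(c["range"][1])))
            pts.append(PathPoint(bone=p["bone"], local_position=p["position"], condition=cond))
        return cls(points=pts, name=d.get("name", ""))

    def to_json(self) -> str:
        pts = []
        for p in self.points:
            d = {"bone": p.bone, "position": p.local_position.tolist()}
            if p.condition is not None:
                d["condition"] = {
                    "coordinate": p.condition[0],
                    "range": list(p.condition[1]),
                }
            pts.append(d)
        return json.dumps({"name": self.name, "points": pts})


def active_points(
    path: PolylinePath, skeleton: Skeleton, pose: JointPose
) -> tuple[np.ndarray, list]:
    """World-space positions of the path points active at ``pose``, plus the
    bone each retained point is fixed to."""
    transforms = pose_transforms(skeleton, pose)
    pts, bones = [], []
    for p in path.points:
        if p.is_active(pose):
            pts.append(transforms[p.bone].apply(p.local_position))
            bones.append(p.bone)
    if len(pts) < 2:
        raise ValidationError("active_points: fewer than 2 active points")
    return np.array(pts), bones


def path_length(points: np.ndarray) -> float:
    """Total Euclidean length of a world-space point sequence."""
    points = np.asarray(points, dtype=np.float64)
    if len(points) < 2:
        raise ValidationError("path_length: need >= 2 points")
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


def geometric_moment_arm(
    path: PolylinePath, skeleton: Skeleton, pose: JointPose, axis: np.ndarray
) -> float:
    """Moment arm of the joint-spanning segment about ``axis`` through the
    joint centre.

    With P the last parent-fixed and D the first child-fixed active point,
    u the unit vector from D toward P and c the joint centre:
    r = axis . ((D - c) x u).  Positive r means muscle tension generates a
    positive moment about the axis.
    """
    axis = np.asarray(axis, dtype=np.float64)
    an = np.linalg.norm(axis)
    if an == 0:
        raise ValidationError("geometric_moment_arm: zero axis")
    axis = axis / an

    pts, bones = active_points(path, skeleton, pose)
    parent, child = skeleton.joint.parent, skeleton.joint.child
    crossings = [
        k
        for k in range(len(bones) - 1)
        if {bones[k], bones[k + 1]} == {parent, child}
    ]
    if len(crossings) != 1:
        raise ValidationError(
            f"geometric_moment_arm: path must cross the joint exactly once "
            f"(found {len(crossings)} crossings)"
        )
    k = crossings[0]
    if bones[k] == parent:
        P, D = pts[k], pts[k + 1]
    else:
        P, D = pts[k + 1], pts[k]
    span = P - D
    ln = np.linalg.norm(span)
    if ln < 1e-12:
        raise NumericalError("geometric_moment_arm: zero-length spanning segment")
    u = span / ln
    c = skeleton.joint.center
    return float(axis @ np.cross(D - c, u))


def sweep_path_length(
    path: PolylinePath,
    skeleton: Skeleton,
    coordinate: str,
    grid_deg: np.ndarray,
) -> tuple[np.ndarray, list]:
    """Path length at every pose of a single-coordinate sweep, plus the pose
    indices where a conditional point toggles (length discontinuities)."""
    lengths = np.empty(len(grid_deg))
    active_counts = np.empty(len(grid_deg), dtype=int)
    for k, th in enumerate(grid_deg):
        pose = JointPose(**{coordinate: float(th)})
        pts, _ = active_points(path, skeleton, pose)
        lengths[k] = path_length(pts)
        active_counts[k] = len(pts)
    toggles = list(np.nonzero(np.diff(active_counts) != 0)[0] + 1)
    return lengths, toggles
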