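"""Fibre-architecture templates and generalized barycentric transfer.

A template is a unit cube holding a family of fibres expressed as Bezier
curves running from the origin face (z=0) to the insertion face (z=1).
Slicing the template with planes z=level yields per-fibre 2D points inside
the unit square; mean-value coordinates of those points with respect to the
square outline let the same points be re-expressed on any mesh contour with
matching sample count — the transfer that places fibres inside the muscle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
import math

import numpy as np

from .errors import ValidationError
from .field_contours import ClosedContour, DEFAULT_RESAMPLE


@dataclass
class FiberTemplate:
    """Unit-cube fibre family.

    ``fiber_curves`` holds, per fibre, an array of Bezier control points in
    [0,1]^3 with t=0 on the origin face (z=0) and t=1 on the insertion face.
    Only the ``parallel`` kind ships; curved Bezier templates are an
    extension hook.
    """

    n_fibers: int
    fiber_curves: list[np.ndarray]
    kind: str = "parallel"

    def __post_init__(self) -> None:
        self.fiber_curves = [np.asarray(c, dtype=np.float64) for c in self.fiber_curves]
        if self.n_fibers != len(self.fiber_curves):
            raise ValidationError("template: n_fibers mismatch")
        for c in self.fiber_curves:
            if c.min() < -1e-12 or c.max() > 1 + 1e-12:
                raise ValidationError("template: control points must lie in the unit cube")

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": self.kind,
                "n_fibers": self.n_fibers,
                "control_points": [c.tolist() for c in self.fiber_curves],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "FiberTemplate":
        d = json.loads(text)
        return cls(
            n_fibers=d["n_fibers"],
            fiber_curves=[np.asarray(c) for c in d["control_points"]],
            kind=d.get("kind", "parallel"),
        )


@dataclass
class TemplateSection:
    """One template slice: per-fibre 2D points and the square outline."""

    level: float
    fiber_points_2d: np.ndarray
    boundary_polygon: np.ndarray

    def __post_init__(self) -> None:
        self.fiber_points_2d = np.asarray(self.fiber_points_2d, dtype=np.float64)
        self.boundary_polygon = np.asarray(self.boundary_polygon, dtype=np.float64)


def make_parallel_template(n_fibers: int) -> FiberTemplate:
    """Template of vertical straight fibres seeded on a uniform interior grid.

    Seeds occupy a ceil(sqrt(n)) x ceil(sqrt(n)) grid at ((i+0.5)/m,
    (j+0.5)/m), truncated row-major to ``n_fibers``.
    """
    if n_fibers < 1:
        raise ValidationError("make_parallel_template: n_fibers must be >= 1")
    m = math.isqrt(n_fibers)
    if m * m < n_fibers:
        m += 1
    curves = []
    for idx in range(n_fibers):
        i, j = divmod(idx, m)
        x = (j + 0.5) / m
        y = (i + 0.5) / m
        curves.append(np.array([[x, y, 0.0], [x, y, 1.0]]))
    return FiberTemplate(n_fibers=n_fibers, fiber_curves=curves, kind="parallel")


def unit_square_outline(n: int = DEFAULT_RESAMPLE) -> np.ndarray:
    """Unit-square perimeter sampled at ``n`` arc-length uniform points,
    starting at (0,0) and walking counter-clockwise."""
    s = np.linspace(0.0, 4.0, n, endpoint=False)
    out = np.empty((n, 2))
    for k, t in enumerate(s):
        side, u = int(t), t - int(t)
        if side == 0:
            out[k] = (u, 0.0)
        elif side == 1:
            out[k] = (1.0, u)
        elif side == 2:
            out[k] = (1.0 - u, 1.0)
        else:
            out[k] = (0.0, 1.0 - u)
    return out


def _bezier_eval(control: np.ndarray, t: float) -> np.ndarray:
    """De Casteljau evaluation of a Bezier curve at parameter t."""
    pts = control.copy()
    while len(pts) > 1:
        pts = (1 - t) * pts[:-1] + t * pts[1:]
    return pts[0]


def _bezier_plane_crossing(control: np.ndarray, level: float) -> float:
    """Smallest t in [0,1] where the curve's z-component equals ``level``."""
    # z(t) is a polynomial in t of degree len(control)-1 (Bernstein basis)
    z = control[:, 2]
    n = len(z) - 1
    if n == 0:
        raise ValidationError("slice_template: degenerate fibre curve")
    # convert Bernstein coefficients to the power basis
    coeffs = np.zeros(n + 1)
    for i, zi in enumerate(z):
        for k in range(i, n + 1):
            coeffs[k] += (
                zi * math.comb(n, i) * math.comb(n - i, k - i) * (-1) ** (k - i)
            )
    coeffs[0] -= level
    roots = np.roots(coeffs[::-1]) if np.any(coeffs[1:]) else np.array([])
    real = [
        float(r.real)
        for r in np.atleast_1d(roots)
        if abs(r.imag) < 1e-10 and -1e-10 <= r.real <= 1 + 1e-10
    ]
    if not real:
        raise ValidationError(f"slice_template: fibre does not cross plane z={level}")
    return min(max(min(real), 0.0), 1.0)


def slice_template(
    template: FiberTemplate,
    levels,
    resample: int = DEFAULT_RESAMPLE,
) -> list[TemplateSection]:
    """Intersect every fibre curve with the planes z=level.

    Levels must be strictly increasing in (0,1) (the end faces are handled by
    the attachment-connection step).  The section boundary polygon is the
    unit-square outline at the contour resampling count so correspondence
    with mesh contours is index-to-index.
    """
    levels = list(levels)
    if any(not (0.0 <= l <= 1.0) for l in levels):
        raise ValidationError("slice_template: levels must be within [0, 1]")
    if any(b <= a for a, b in zip(levels, levels[1:])):
        raise ValidationError("slice_template: levels must be strictly increasing")
    outline = unit_square_outline(resample)
    sections = []
    for lv in levels:
        pts = np.empty((template.n_fibers, 2))
        for fi, curve in enumerate(template.fiber_curves):
            if np.allclose(curve[:, 2], curve[0, 2]):
                raise ValidationError("slice_template: fibre parallel to slicing planes")
            t = _bezier_plane_crossing(curve, lv)
            pts[fi] = _bezier_eval(curve, t)[:2]
        sections.append(
            TemplateSection(level=float(lv), fiber_points_2d=pts, boundary_polygon=outline)
        )
    return sections


def mean_value_coordinates(p: np.ndarray, polygon: np.ndarray) -> np.ndarray:
    """Mean-value coordinates of ``p`` with respect to a simple polygon.

    The weights are positive for star-shaped kernels, always sum to one and
    reproduce ``p`` as the weighted combination of the polygon vertices
    (linear precision).  ``p`` must be strictly inside.
    """
    p = np.asarray(p, dtype=np.float64)
    poly = np.asarray(polygon, dtype=np.float64)
    n = len(poly)
    if n < 3:
        raise ValidationError("mean_value_coordinates: polygon needs >= 3 vertices")
    d = poly - p
    r = np.linalg.norm(d, axis=1)
    if r.min() < 1e-12:
        raise ValidationError("mean_value_coordinates: point coincides with a vertex")
    if not _point_in_polygon(p, poly):
        raise ValidationError("mean_value_coordinates: point not strictly inside polygon")
    # angle subtended at p by each polygon edge
    d_next = np.roll(d, -1, axis=0)
    r_next = np.roll(r, -1)
    cross = d[:, 0] * d_next[:, 1] - d[:, 1] * d_next[:, 0]
    dot = (d * d_next).sum(axis=1)
    alpha = np.arctan2(cross, dot)
    if np.any(np.abs(np.abs(alpha) - np.pi) < 1e-12):
        raise ValidationError("mean_value_coordinates: point lies on a polygon edge")
    t = np.tan(alpha / 2.0)
    w = (np.roll(t, 1) + t) / r
    total = w.sum()
    if not np.isfinite(total) or total == 0:
        raise ValidationError("mean_value_coordinates: degenerate configuration")
    return w / total


def _point_in_polygon(p: np.ndarray, poly: np.ndarray) -> bool:
    """Ray-casting point-in-polygon test."""
    x, y = p
    inside = False
    n = len(poly)
    x0, y0 = poly[-1]
    for x1, y1 in poly:
        if (y1 > y) != (y0 > y):
            xi = x0 + (y - y0) / (y1 - y0) * (x1 - x0)
            if x < xi:
                inside = not inside
        x0, y0 = x1, y1
    return inside


def mvc_matrix(points: np.ndarray, polygon: np.ndarray) -> np.ndarray:
    """Mean-value coordinates of many points, stacked as rows."""
    return np.array([mean_value_coordinates(p, polygon) for p in np.atleast_2d(points)])


def map_section(section: TemplateSection, contour: ClosedContour) -> np.ndarray:
    """Transfer the section's fibre points onto a mesh contour.

    Each fibre point becomes sum_q lambda_q c_q with lambda its mean-value
    coordinates w.r.t. the template outline and c_q the index-corresponding
    contour samples.  Affine images of the outline are reproduced exactly
    (linear precision of mean-value coordinates).
    """
    if len(section.boundary_polygon) != len(contour.points):
        raise ValidationError(
            "map_section: contour sample count does not match template outline"
        )
    lam = mvc_matrix(section.fiber_points_2d, section.boundary_polygon)
    return lam @ contour.points
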