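import numpy as np
import pytest
import trimesh

from myodecomp.errors import ValidationError
from myodecomp.mesh_core import (
    TriMesh,
    boundary_loops,
    clean_mesh,
    closest_point_on_surface,
    fit_sphere,
    load_mesh,
    save_mesh,
    smooth_mesh,
)

# ---------------------------------------------------------------------------
# I/O


def _unit_cube():
    b = trimesh.creation.box(extents=(1, 1, 1))
    return TriMesh(np.asarray(b.vertices), np.asarray(b.faces), name="cube")


def test_load_obj_unit_cube(tmp_path):
    cube = _unit_cube()
    save_mesh(cube, tmp_path / "cube.obj")
    m = load_mesh(tmp_path / "cube.obj")
    assert m.n_vertices == 8
    assert m.n_faces == 12


def test_stl_roundtrip_positions_preserved_after_weld(tmp_path):
    cube = _unit_cube()
    save_mesh(cube, tmp_path / "cube.stl")
    m = clean_mesh(load_mesh(tmp_path / "cube.stl"))
    assert m.n_vertices == 8
    got = np.array(sorted(map(tuple, np.round(m.vertices, 9))))
    want = np.array(sorted(map(tuple, np.round(cube.vertices, 9))))
    np.testing.assert_allclose(got, want, atol=1e-6)


@pytest.mark.parametrize("fmt", ["stl", "obj", "ply"])
def test_roundtrip_all_formats(tmp_path, fmt):
    cube = _unit_cube()
    path = tmp_path / f"cube.{fmt}"
    save_mesh(cube, path)
    m = clean_mesh(load_mesh(path))
    assert m.n_faces == 12


def test_truncated_file_raises(tmp_path):
    path = tmp_path / "bad.ply"
    path.write_text("ply\nformat ascii 1.0\nelement vertex 100\n")
    with pytest.raises((IOError, ValidationError)):
        load_mesh(path)


def test_mm_units_scale_vertices(tmp_path):
    cube = _unit_cube()
    save_mesh(cube, tmp_path / "cube.obj")
    m = load_mesh(tmp_path / "cube.obj", units="mm")
    assert np.abs(m.vertices).max() == pytest.approx(5e-4)


# ---------------------------------------------------------------------------
# Cleaning


def test_clean_welds_coincident_vertices():
    v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1e-9, 0, 0], [1, 1, 0]], float)
    f = np.array([[0, 1, 2], [3, 1, 4]])
    m = clean_mesh(TriMesh(v, f))
    assert m.n_vertices == 4
    assert m.n_faces == 2


def test_clean_drops_degenerate_faces():
    v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [2, 0, 0]], float)
    f = np.array([[0, 1, 2], [0, 1, 1], [0, 1, 3]])  # repeated index + collinear
    m = clean_mesh(TriMesh(v, f))
    assert m.n_faces == 1


def test_clean_drops_overshared_edge_faces():
    # three faces sharing edge (0,1): all incident faces removed
    v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [5, 5, 5], [6, 5, 5], [5, 6, 5]], float)
    f = np.array([[0, 1, 2], [0, 1, 3], [0, 1, 4], [5, 6, 7]])
    m = clean_mesh(TriMesh(v, f))
    assert m.n_faces == 1


def test_clean_idempotent(cylinder):
    mesh, _, _ = cylinder
    once = clean_mesh(mesh)
    twice = clean_mesh(once)
    np.testing.assert_array_equal(once.faces, twice.faces)
    np.testing.assert_array_equal(once.vertices, twice.vertices)


def test_clean_everything_removed_raises():
    v = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float)
    f = np.array([[0, 1, 2]])  # zero area
    with pytest.raises(ValidationError):
        clean_mesh(TriMesh(v, f))


# ---------------------------------------------------------------------------
# Smoothing


def _noisy_sphere(seed=3, noise=0.01):
    s = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
    v = np.asarray(s.vertices)
    rng = np.random.default_rng(seed)
    v = v * (1 + rng.normal(0, noise, len(v)))[:, None]
    return TriMesh(v, np.asarray(s.faces))


def test_smooth_zero_iterations_identity(cylinder):
    mesh, _, _ = cylinder
    out = smooth_mesh(mesh, 0)
    np.testing.assert_array_equal(out.vertices, mesh.vertices)


def test_smooth_reduces_radial_noise():
    m = _noisy_sphere()
    rms_before = np.sqrt(((np.linalg.norm(m.vertices, axis=1) - 1.0) ** 2).mean())
    out = smooth_mesh(m, 20)
    rms_after = np.sqrt(((np.linalg.norm(out.vertices, axis=1) - 1.0) ** 2).mean())
    assert rms_after < rms_before
    np.testing.assert_array_equal(out.faces, m.faces)


def test_smooth_keeps_boundary_fixed(cylinder_field):
    open_mesh = cylinder_field.mesh
    loops = boundary_loops(open_mesh)
    out = smooth_mesh(open_mesh, 5)
    for loop in loops:
        np.testing.assert_array_equal(
            out.vertices[loop.vertex_indices], open_mesh.vertices[loop.vertex_indices]
        )


def test_smooth_factor_validation(cylinder):
    mesh, _, _ = cylinder
    with pytest.raises(ValidationError):
        smooth_mesh(mesh, 1, factor=1.5)


# ---------------------------------------------------------------------------
# Boundary loops


def test_closed_mesh_has_no_boundary():
    s = trimesh.creation.icosphere(subdivisions=2)
    assert boundary_loops(TriMesh(np.asarray(s.vertices), np.asarray(s.faces))) == []


def test_open_cylinder_has_two_loops(cylinder_field):
    loops = boundary_loops(cylinder_field.mesh)
    assert len(loops) == 2


def test_boundary_edge_count_matches_single_incidence(cylinder_field):
    mesh = cylinder_field.mesh
    e = mesh.edges()
    _, counts = np.unique(e, axis=0, return_counts=True)
    n_boundary_edges = int((counts == 1).sum())
    loops = boundary_loops(mesh)
    assert sum(len(l) for l in loops) == n_boundary_edges


def test_annulus_two_loops_with_correct_counts():
    # flat annulus: two rings of 16 vertices
    n = 16
    phi = 2 * np.pi * np.arange(n) / n
    inner = np.column_stack([0.5 * np.cos(phi), 0.5 * np.sin(phi), np.zeros(n)])
    outer = np.column_stack([np.cos(phi), np.sin(phi), np.zeros(n)])
    v = np.vstack([inner, outer])
    faces = []
    for j in range(n):
        j2 = (j + 1) % n
        faces.append((j, n + j, j2))
        faces.append((j2, n + j, n + j2))
    loops = boundary_loops(TriMesh(v, np.array(faces)))
    assert sorted(len(l) for l in loops) == [n, n]


def test_nonmanifold_raises():
    v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1]], float)
    f = np.array([[0, 1, 2], [0, 1, 3], [0, 1, 4]])
    with pytest.raises(ValidationError):
        boundary_loops(TriMesh(v, f))


# ---------------------------------------------------------------------------
# Sphere fitting


def _sphere_points(center, radius, n=200, seed=7):
    rng = np.random.default_rng(seed)
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    return np.asarray(center) + radius * u


def test_fit_sphere_exact():
    c0, r0 = np.array([0.01, 0.02, 0.03]), 0.025
    s = fit_sphere(_sphere_points(c0, r0))
    assert np.linalg.norm(s.center - c0) < 1e-9
    assert abs(s.radius - r0) < 1e-9


def test_fit_sphere_circumsphere_of_four_points():
    pts = np.array([[0.0, 0, 0], [0.04, 0, 0], [0, 0.05, 0], [0, 0, 0.03]])
    # independent oracle: solve |p - c|^2 = r^2 exactly via the 4x4 linear
    # system in (2c, r^2 - |c|^2)
    A = np.column_stack([2 * pts, np.ones(4)])
    b = (pts**2).sum(axis=1)
    sol = np.linalg.solve(A, b)
    c_exact = sol[:3]
    r_exact = np.sqrt(sol[3] + (c_exact**2).sum())
    s = fit_sphere(pts)
    np.testing.assert_allclose(s.center, c_exact, atol=1e-12)
    assert s.radius == pytest.approx(r_exact, abs=1e-12)


def test_fit_sphere_noisy_center_recovery():
    c0, r0 = np.array([0.01, 0.02, 0.03]), 0.025
    rng = np.random.default_rng(11)
    u = rng.normal(size=(200, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    pts = c0 + (r0 * (1 + rng.normal(0, 0.01, 200)))[:, None] * u
    s = fit_sphere(pts)
    assert np.linalg.norm(s.center - c0) < 0.005 * r0


def test_fit_sphere_coplanar_raises():
    pts = np.column_stack([np.random.default_rng(0).normal(size=(10, 2)), np.zeros(10)])
    with pytest.raises(ValidationError):
        fit_sphere(pts)


def test_fit_sphere_translation_equivariance():
    pts = _sphere_points([0, 0, 0], 0.04, seed=5)
    d = np.array([0.3, -0.2, 0.7])
    s1 = fit_sphere(pts)
    s2 = fit_sphere(pts + d)
    np.testing.assert_allclose(s2.center - s1.center, d, atol=1e-12)
    assert s1.radius == pytest.approx(s2.radius, abs=1e-12)


# ---------------------------------------------------------------------------
# Point-to-surface distance


def test_closest_point_on_box_faces_edges_corners():
    b = trimesh.creation.box(extents=(2, 2, 2))
    m = TriMesh(np.asarray(b.vertices), np.asarray(b.faces))
    pts = np.array([[2.0, 0, 0], [2.0, 2.0, 0], [2.0, 2.0, 2.0], [0.0, 0, 0]])
    _, d, _ = closest_point_on_surface(m, pts)
    np.testing.assert_allclose(
        d, [1.0, np.sqrt(2), np.sqrt(3), 1.0], atol=1e-12
    )
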