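import numpy as np
import pytest

from myodecomp.decomposition import (
    AttachmentArea,
    FiberSet,
    connect_attachments,
    decompose_muscle,
    load_landmarks,
    project_attachment,
    remove_region,
    save_landmarks,
    smooth_fibers,
)
from myodecomp.errors import StageError, ValidationError
from myodecomp.mesh_core import boundary_loops
from myodecomp.synthetic import TubeSpec, make_tube_muscle

from conftest import CYL_HEIGHT, CYL_RADIUS

# ---------------------------------------------------------------------------
# Attachment projection


def test_project_on_mesh_landmarks_selects_cap(cylinder):
    mesh, origin, _ = cylinder
    region = project_attachment(mesh, origin)
    centroids = mesh.vertices[mesh.faces[region.faces]].mean(axis=1)
    assert np.all(centroids[:, 2] < 1e-2 * CYL_HEIGHT)  # all on the z=0 cap
    # full cap: n_circumferential fan triangles
    assert len(region.faces) == 48


def test_project_offset_landmarks_same_region(cylinder):
    mesh, origin, _ = cylinder
    shifted = AttachmentArea(
        name="origin",
        bone=origin.bone,
        landmarks=origin.landmarks + np.array([0, 0, -0.001]),
    )
    r1 = project_attachment(mesh, origin)
    r2 = project_attachment(mesh, shifted)
    np.testing.assert_array_equal(np.sort(r1.faces), np.sort(r2.faces))


def test_project_far_landmark_raises(cylinder):
    mesh, origin, _ = cylinder
    far = AttachmentArea(
        name="origin",
        bone=origin.bone,
        landmarks=origin.landmarks + np.array([0, 0, -0.1]),
    )
    with pytest.raises(ValidationError):
        project_attachment(mesh, far, capture_distance=0.02)


# ---------------------------------------------------------------------------
# Region removal


def test_remove_both_caps_two_loops(cylinder):
    mesh, origin, insertion = cylinder
    ro = project_attachment(mesh, origin)
    ri = project_attachment(mesh, insertion)
    out = remove_region(mesh, np.union1d(ro.faces, ri.faces))
    assert len(boundary_loops(out)) == 2


def test_remove_one_cap_one_loop(cylinder):
    mesh, origin, _ = cylinder
    ro = project_attachment(mesh, origin)
    out = remove_region(mesh, ro.faces)
    assert len(boundary_loops(out)) == 1


def test_remove_annular_region_raises(cylinder):
    mesh, _, _ = cylinder
    # an annular band of side faces around the tube disconnects it
    centroids = mesh.vertices[mesh.faces].mean(axis=1)
    band = np.nonzero(
        (centroids[:, 2] > 0.45 * CYL_HEIGHT) & (centroids[:, 2] < 0.55 * CYL_HEIGHT)
    )[0]
    with pytest.raises(ValidationError):
        remove_region(mesh, band)


# ---------------------------------------------------------------------------
# Full decomposition


def test_cylinder_100x15_fiber_lengths_and_ordering(cylinder):
    mesh, origin, insertion = cylinder
    fibers = decompose_muscle(mesh, origin, insertion, n_fibers=100, n_segments=15)
    assert fibers.points.shape == (100, 16, 3)
    lengths = fibers.lengths()
    assert np.abs(lengths - CYL_HEIGHT).max() / CYL_HEIGHT < 0.02
    # interior points monotone along the field (axial) direction
    dz = np.diff(fibers.points[:, :, 2], axis=1)
    assert np.all(dz > 0)
    # fibres stay inside the cylinder (2% of radius tolerance)
    rad = np.linalg.norm(fibers.points[:, :, :2], axis=2)
    assert rad.max() < CYL_RADIUS * 1.02


def test_cylinder_single_fiber_on_axis(cylinder):
    mesh, origin, insertion = cylinder
    fibers = decompose_muscle(mesh, origin, insertion, n_fibers=1, n_segments=8)
    rad = np.linalg.norm(fibers.points[0, :, :2], axis=1)
    assert rad.max() < 0.01 * CYL_RADIUS


def test_decomposition_deterministic(cylinder):
    mesh, origin, insertion = cylinder
    f1 = decompose_muscle(mesh, origin, insertion, n_fibers=9, n_segments=6)
    f2 = decompose_muscle(mesh, origin, insertion, n_fibers=9, n_segments=6)
    np.testing.assert_array_equal(f1.points, f2.points)


def test_bent_tube_arc_lengths():
    """90-degree bend: each fibre's length matches the offset-curve closed
    form L_center + d * (pi/2), d the fibre's signed offset in the bend
    plane, within 5%."""
    R = 0.15
    ctrl = np.array([[R, 0, 0], [R, R, 0], [0, R, 0]])
    spec = TubeSpec(
        centerline=ctrl, radius=("constant", 0.02), n_circumferential=40, n_axial=40
    )
    mesh, origin, insertion = make_tube_muscle(spec)
    fibers = decompose_muscle(mesh, origin, insertion, n_fibers=25, n_segments=15)

    tt = np.linspace(0, 1, 20001)
    cl = (
        np.outer((1 - tt) ** 2, ctrl[0])
        + np.outer(2 * (1 - tt) * tt, ctrl[1])
        + np.outer(tt**2, ctrl[2])
    )
    L_center = np.linalg.norm(np.diff(cl, axis=0), axis=1).sum()

    lengths = fibers.lengths()
    for fi in range(fibers.n_fibers):
        pts = fibers.points[fi]
        # signed in-plane offset: distance from bend centre (origin) minus
        # local centerline radius, averaged along the fibre
        d = np.mean(np.linalg.norm(pts[:, :2], axis=1)) - np.mean(
            np.linalg.norm(cl[:, :2], axis=1)
        )
        expected = L_center + d * (np.pi / 2)
        assert abs(lengths[fi] - expected) / expected < 0.05


def test_decompose_validates_counts(cylinder):
    mesh, origin, insertion = cylinder
    with pytest.raises(ValidationError):
        decompose_muscle(mesh, origin, insertion, n_fibers=0, n_segments=15)
    with pytest.raises(ValidationError):
        decompose_muscle(mesh, origin, insertion, n_fibers=4, n_segments=1)


def test_stage_error_names_stage(cylinder):
    mesh, origin, insertion = cylinder
    far = AttachmentArea(
        name="origin", bone="parent", landmarks=origin.landmarks + np.array([0, 0, -1.0])
    )
    with pytest.raises(StageError, match="project_origin"):
        decompose_muscle(mesh, far, insertion, n_fibers=4, n_segments=4)


# ---------------------------------------------------------------------------
# Attachment connection


def test_connect_centered_fiber_hits_cap_centroid(cylinder):
    mesh, origin, insertion = cylinder
    fibers = decompose_muscle(mesh, origin, insertion, n_fibers=1, n_segments=8)
    np.testing.assert_allclose(
        fibers.points[0, 0], origin.landmarks.mean(axis=0), atol=1e-6
    )
    np.testing.assert_allclose(
        fibers.points[0, -1], insertion.landmarks.mean(axis=0), atol=1e-6
    )


def test_connect_endpoints_distinct_and_centered(cylinder):
    mesh, origin, insertion = cylinder
    fibers = decompose_muscle(mesh, origin, insertion, n_fibers=100, n_segments=15)
    starts = fibers.points[:, 0, :]
    assert len(np.unique(np.round(starts, 12), axis=0)) == 100
    mean_err = np.linalg.norm(starts.mean(axis=0) - origin.landmarks.mean(axis=0))
    assert mean_err < 0.05 * CYL_RADIUS


def test_connect_collinear_outline_raises(cylinder):
    mesh, origin, insertion = cylinder
    fibers = FiberSet(points=np.zeros((1, 4, 3)) + np.linspace(0, 1, 4)[None, :, None])
    bad = AttachmentArea(
        name="origin",
        bone="parent",
        landmarks=np.column_stack([np.linspace(0, 1, 5), np.zeros(5), np.zeros(5)]),
    )
    with pytest.raises(ValidationError):
        connect_attachments(fibers, bad, insertion)


# ---------------------------------------------------------------------------
# Fibre smoothing


def test_smooth_lam_zero_identity():
    rng = np.random.default_rng(0)
    fs = FiberSet(points=rng.normal(size=(3, 10, 3)))
    out = smooth_fibers(fs, 0.0)
    np.testing.assert_array_equal(out.points, fs.points)


def test_smooth_collinear_unchanged():
    line = np.linspace(0, 1, 12)[:, None] * np.array([1.0, 2.0, 3.0])
    fs = FiberSet(points=line[None])
    out = smooth_fibers(fs, 5.0)
    np.testing.assert_allclose(out.points, fs.points, atol=1e-12)


def test_smooth_matches_dense_qp_oracle():
    """Tridiagonal smoothing equals an independent dense least-squares
    solve of the same quadratic programme on random zig-zag fibres."""
    rng = np.random.default_rng(123)
    lam = 1.0
    for _ in range(50):
        n = int(rng.integers(5, 20))
        base = np.linspace(0, 0.2, n)[:, None] * np.array([0, 0, 1.0])
        zig = base + rng.normal(0, 0.005, (n, 3))
        fs = FiberSet(points=zig[None])
        out = smooth_fibers(fs, lam)

        m = n - 2
        D = np.zeros((m, n))
        for k in range(m):
            D[k, k : k + 3] = (1.0, -2.0, 1.0)
        for d in range(3):
            A = np.vstack([np.eye(m), np.sqrt(lam) * D[:, 1:-1]])
            b = np.concatenate(
                [zig[1:-1, d], -np.sqrt(lam) * (D[:, 0] * zig[0, d] + D[:, -1] * zig[-1, d])]
            )
            q = np.linalg.lstsq(A, b, rcond=None)[0]
            assert np.abs(q - out.points[0, 1:-1, d]).max() < 1e-10


def test_smooth_endpoints_always_fixed():
    rng = np.random.default_rng(5)
    pts = rng.normal(size=(4, 9, 3))
    fs = FiberSet(points=pts)
    out = smooth_fibers(fs, 3.0)
    np.testing.assert_array_equal(out.points[:, 0], pts[:, 0])
    np.testing.assert_array_equal(out.points[:, -1], pts[:, -1])


# ---------------------------------------------------------------------------
# Serialization


def test_fiberset_json_roundtrip():
    rng = np.random.default_rng(2)
    fs = FiberSet(points=rng.normal(size=(5, 7, 3)), muscle="toy")
    fs2 = FiberSet.from_json(fs.to_json())
    assert fs2.muscle == "toy"
    np.testing.assert_allclose(fs2.points, fs.points, atol=1e-12)


def test_fiberset_csv_header_and_rows():
    fs = FiberSet(points=np.zeros((2, 3, 3)))
    lines = fs.to_csv().strip().split("\n")
    assert lines[0] == "fiber_id,point_id,x,y,z"
    assert len(lines) == 1 + 2 * 3


def test_landmark_json_roundtrip(tmp_path, cylinder):
    _, origin, insertion = cylinder
    path = tmp_path / "lm.json"
    save_landmarks([origin, insertion], path, units="mm")
    areas = load_landmarks(path)
    assert set(areas) == {"origin", "insertion"}
    np.testing.assert_allclose(areas["origin"].landmarks, origin.landmarks, atol=1e-12)
    assert areas["insertion"].bone == insertion.bone
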