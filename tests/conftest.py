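import numpy as np
import pytest

from myodecomp.decomposition import project_attachment, remove_region
from myodecomp.field_contours import solve_field
from myodecomp.mesh_core import boundary_loops
from myodecomp.synthetic import HingeToy, TubeSpec, make_hinge_system, make_tube_muscle

CYL_HEIGHT = 0.2
CYL_RADIUS = 0.03


@pytest.fixture(scope="session")
def cylinder():
    """Closed straight tube muscle (H=0.2 m, r=0.03 m) with cap landmarks."""
    spec = TubeSpec(
        centerline=np.array([[0.0, 0.0, 0.0], [0.0, 0.0, CYL_HEIGHT]]),
        radius=("constant", CYL_RADIUS),
        n_circumferential=48,
        n_axial=30,
    )
    return make_tube_muscle(spec)


@pytest.fixture(scope="session")
def cylinder_field(cylinder):
    """Open cylinder (caps removed) with its harmonic field."""
    mesh, origin, insertion = cylinder
    ro = project_attachment(mesh, origin)
    ri = project_attachment(mesh, insertion)
    open_mesh = remove_region(mesh, np.union1d(ro.faces, ri.faces))
    loops = boundary_loops(open_mesh)
    d0 = np.linalg.norm(loops[0].centroid(open_mesh) - origin.centroid)
    d1 = np.linalg.norm(loops[1].centroid(open_mesh) - origin.centroid)
    lo, li = (loops[0], loops[1]) if d0 <= d1 else (loops[1], loops[0])
    return solve_field(open_mesh, lo, li)


@pytest.fixture(scope="session")
def hinge():
    """Hinge toy (a=b=0.1 m, rest angle 90 deg) with skeleton and fibre."""
    toy = HingeToy(a=0.1, b=0.1, theta0=90.0)
    skeleton, fibers = make_hinge_system(toy)
    return toy, skeleton, fibers
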