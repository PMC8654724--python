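import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

import tissuemech as tm


@pytest.fixture(scope="session")
def exp_force():
    """The standard exponential force parameter set (mu=50, s=1, c=10, r_A=1.5)."""
    return tm.ExpForceParams()


@pytest.fixture(scope="session")
def poly_force():
    return tm.PolyForceParams(c_r=2.0, c_a=1.0, r_R=1.0, r_A=1.5, n=1)


@pytest.fixture(scope="session")
def hex_sheet():
    """Small hexagonal cell sheet: centers, tessellation and vertex mesh."""
    dom = tm.Domain((0.0, 0.0), (10.0, 10.0))
    centers = tm.ic_2d_hex(tm.ICSpec2D(domain=dom, h=1.0))
    tess, mesh = tm.tessellate_2d(centers, dom)
    return dom, centers, tess, mesh


@pytest.fixture(scope="session")
def deep_interior_vertices(hex_sheet):
    """Vertices whose own incidence and all incident cells are interior."""
    _, _, tess, mesh = hex_sheet
    return [
        a for a in range(mesh.n_vertices)
        if not mesh.is_boundary[a]
        and all(not tess.boundary[k] for k in mesh.vertex_incident_cells[a])
    ]


def random_centers_2d(rng, n, dom):
    margin = 0.02 * min(dom.extents)
    lo = np.asarray(dom.lower) + margin
    hi = np.asarray(dom.upper) - margin
    return tm.CellCenters(rng.uniform(lo, hi, size=(n, 2)))
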