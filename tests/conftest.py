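"""Shared fixtures.

The expensive session fixtures (the full 20-model x 10-configuration
cohort sweep and the concentric-sphere oracle solve) are built lazily and
shared by every test that needs them.
"""

import numpy as np
import pytest

from torsodft import phantom as P
from torsodft import mesh as M
from torsodft import solver as S
from torsodft.geometry import Box, Sphere

COHORT_SEED = 1
COHORT_H = 2.5


@pytest.fixture(scope="session")
def base_phantom():
    """Healthy base anatomy of model 1."""
    return P.generate_base_anatomy(P.anatomy_params(0, seed=COHORT_SEED))


@pytest.fixture(scope="session")
def cohort():
    return P.build_cohort(5, seed=COHORT_SEED)


@pytest.fixture(scope="session")
def cohort_result(cohort):
    """Full study sweep: 20 models x 10 configurations at the desk h."""
    from torsodft.study import run_cohort
    res = run_cohort(cohort, h=COHORT_H)
    assert not res.failures, f"cohort solves failed: {res.failures}"
    return res


def make_slab(h=2.0, L=20.0, W=10.0):
    """Homogeneous slab with full-face plate electrodes at x=0 and x=L."""
    mesh = M.mesh_from_solids([("bath", Box((0, 0, 0), (L, W, W)))],
                              ["exterior", "bath"], h,
                              bounds=(np.zeros(3), np.array([L, W, W])))
    mesh.electrode_nodes["plate_hi"] = np.flatnonzero(mesh.nodes[:, 0] < 1e-9)
    mesh.electrode_nodes["plate_lo"] = np.flatnonzero(mesh.nodes[:, 0] > L - 1e-9)
    return mesh


def make_sphere_problem(a=5.0, b=50.0, h=1.25):
    """Concentric-sphere electrode problem on a voxel ball.

    Electrode node sets follow the package's capture rule: solids dilated
    by a quarter spacing (effective-radius correction).
    """
    mesh = M.mesh_from_solids([("bath", Sphere((0, 0, 0), b))],
                              ["exterior", "bath"], h)
    r = np.linalg.norm(mesh.nodes, axis=1)
    d = 0.25 * h
    mesh.electrode_nodes["inner"] = np.flatnonzero(r <= a + d)
    mesh.electrode_nodes["outer"] = np.flatnonzero(r >= b - h + d)
    return mesh, r


@pytest.fixture(scope="session")
def sphere_solution():
    sigma0 = 0.24725
    sig = S.ConductivityMap(region_sigma={"bath": sigma0})
    mesh, r = make_sphere_problem()
    K = S.assemble_stiffness(mesh, sig)
    sol = S.solve_shock(mesh, sig, {"inner": 10.0, "outer": 0.0}, K=K)
    S.electrode_currents(sol, mesh, sig, None, K=K)
    return {"mesh": mesh, "r": r, "sol": sol, "sigma": sig, "sigma0": sigma0,
            "a": 5.0, "b": 50.0, "h": 1.25}
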