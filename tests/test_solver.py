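"""FEM shock solver: tensors, exactness, convergence, conservation."""

import numpy as np
import pytest

from torsodft import mesh as M
from torsodft import solver as S
from torsodft.geometry import Box
from torsodft.phantom import ALL_LABELS

from conftest import make_slab, make_sphere_problem

SIGMA0 = 0.2
SIG = S.ConductivityMap(region_sigma={"bath": SIGMA0})


# ---------------------------------------------------------------------------
# myocardial tensor


def test_tensor_aligned_with_x_axis_is_diagonal():
    sig = S.ConductivityMap()
    T = S.myocardial_tensor([1.0, 0.0, 0.0], sig)
    sl, st = sig.sigma_long * 1e-3, sig.sigma_trans * 1e-3
    assert np.allclose(T, np.diag([sl, st, st]), atol=1e-15)


@pytest.mark.parametrize("seed", range(5))
def test_tensor_eigenvalues_match_requested_conductivities(seed):
    rng = np.random.default_rng(seed)
    f = rng.normal(size=3)
    f /= np.linalg.norm(f)
    sig = S.ConductivityMap()
    T = S.myocardial_tensor(f, sig)
    ev = np.sort(np.linalg.eigvalsh(T))
    sl, st = sig.sigma_long * 1e-3, sig.sigma_trans * 1e-3
    assert np.allclose(ev, [st, st, sl], atol=1e-12)
    assert np.isclose(np.trace(T), sl + 2 * st, atol=1e-15)
    # tensor acts as sigma_long on the fibre direction
    assert np.allclose(T @ f, sl * f, atol=1e-15)


def test_tensor_rejects_zero_fibre():
    with pytest.raises(S.SolverError):
        S.myocardial_tensor([0.0, 0.0, 0.0], S.ConductivityMap())


def test_effective_conductivity_modes():
    bulk = S.ConductivityMap()
    assert bulk.sigma_long == pytest.approx(0.174 + 0.625)
    assert bulk.sigma_trans == pytest.approx(0.019 + 0.236)
    extra = S.ConductivityMap(myocardium_mode="extracellular")
    assert extra.sigma_long == pytest.approx(0.625)
    assert extra.sigma_trans == pytest.approx(0.236)


def test_region_lookup_covers_all_phantom_labels_and_errors_on_unknown():
    sig = S.ConductivityMap()
    vals = sig.isotropic_lookup(ALL_LABELS)
    named = dict(zip(ALL_LABELS, vals))
    assert named["bath"] == pytest.approx(0.24725e-3)
    assert named["blood"] == pytest.approx(0.6667e-3)
    assert np.isnan(named["lv_wall"]) and np.isnan(named["rv_wall"])
    with pytest.raises(S.SolverError):
        sig.isotropic_lookup(["adipose"])


# ---------------------------------------------------------------------------
# slab / plate problems


def test_slab_solution_is_exactly_affine():
    mesh = make_slab(h=2.0, L=20.0)
    sol = S.solve_shock(mesh, SIG, {"plate_hi": 10.0, "plate_lo": 0.0})
    exact = 10.0 * (1.0 - mesh.nodes[:, 0] / 20.0)
    assert np.abs(sol.ve - exact).max() < 1e-12
    assert np.abs(sol.e_mag - 0.5).max() < 1e-12


def test_doubling_voltage_doubles_field_everywhere():
    mesh = make_slab(h=2.0)
    s10 = S.solve_shock(mesh, SIG, {"plate_hi": 10.0, "plate_lo": 0.0})
    s20 = S.solve_shock(mesh, SIG, {"plate_hi": 20.0, "plate_lo": 0.0})
    assert np.allclose(s20.ve, 2 * s10.ve, atol=1e-10)
    assert np.allclose(s20.e_vec, 2 * s10.e_vec, atol=1e-12)


def test_discrete_maximum_principle():
    mesh = make_slab(h=1.0, L=10.0, W=6.0)
    sol = S.solve_shock(mesh, SIG, {"plate_hi": 10.0, "plate_lo": 0.0})
    assert sol.ve.min() >= -1e-9
    assert sol.ve.max() <= 10.0 + 1e-9


def test_solution_invariant_under_node_relabeling():
    mesh = make_slab(h=2.0, L=8.0, W=4.0)
    sol = S.solve_shock(mesh, SIG, {"plate_hi": 10.0, "plate_lo": 0.0})
    rng = np.random.default_rng(0)
    perm = rng.permutation(mesh.n_nodes)
    inv = np.argsort(perm)
    pmesh = M.FEMesh(nodes=mesh.nodes[perm], tets=inv[mesh.tets],
                     labels=mesh.labels, label_names=mesh.label_names,
                     h=mesh.h, node_ijk=mesh.node_ijk[perm],
                     electrode_nodes={k: np.sort(inv[v]) for k, v in
                                      mesh.electrode_nodes.items()})
    psol = S.solve_shock(pmesh, SIG, {"plate_hi": 10.0, "plate_lo": 0.0})
    assert np.allclose(psol.ve[inv], sol.ve, atol=1e-9)


def test_missing_ground_raises():
    mesh = make_slab()
    with pytest.raises(S.SolverError):
        S.solve_shock(mesh, SIG, {"plate_hi": 10.0})
    with pytest.raises(S.SolverError):
        S.solve_shock(mesh, SIG, {"plate_hi": 10.0, "absent": 0.0})


# ---------------------------------------------------------------------------
# currents


def test_slab_current_and_conservation_machine_precision():
    mesh = make_slab(h=2.0, L=20.0, W=10.0)
    sol = S.solve_shock(mesh, SIG, {"plate_hi": 10.0, "plate_lo": 0.0})
    K = S.assemble_stiffness(mesh, SIG)
    cur = S.electrode_currents(sol, mesh, SIG, None, K=K)
    i_exact = SIGMA0 * 1e-3 * 100.0 * 10.0 / 20.0
    assert cur["plate_hi"] == pytest.approx(i_exact, rel=1e-12)
    assert abs(cur["plate_hi"] + cur["plate_lo"]) < 1e-12 * abs(cur["plate_hi"])


def test_surface_method_exact_on_volumetric_plates():
    """The surface-triangle integration is exact for lattice-aligned faces."""
    h, L, W = 2.0, 20.0, 12.0
    mesh = M.mesh_from_solids([("bath", Box((0, 0, 0), (L, W, W)))],
                              ["exterior", "bath"], h,
                              bounds=(np.zeros(3), np.array([L, W, W])))
    mesh.electrode_nodes["hi"] = np.flatnonzero(mesh.nodes[:, 0] <= h + 1e-9)
    mesh.electrode_nodes["lo"] = np.flatnonzero(mesh.nodes[:, 0] >= L - h - 1e-9)
    sol = S.solve_shock(mesh, SIG, {"hi": 10.0, "lo": 0.0})
    cur = S.electrode_currents(sol, mesh, SIG, None, method="surface")
    i_exact = SIGMA0 * 1e-3 * W * W * 10.0 / (L - 2 * h)
    assert cur["hi"] == pytest.approx(i_exact, rel=1e-10)
    assert cur["lo"] == pytest.approx(-i_exact, rel=1e-10)


def test_surface_method_requires_interior_elements():
    mesh = make_slab(h=2.0)  # plates are bare node sheets, no volume
    sol = S.solve_shock(mesh, SIG, {"plate_hi": 10.0, "plate_lo": 0.0})
    with pytest.raises(S.SolverError, match="no interior"):
        S.electrode_currents(sol, mesh, SIG, None, method="surface")


# ---------------------------------------------------------------------------
# convergence against the spherical-capacitor solution


def test_sphere_field_error_decreases_monotonically():
    a, b = 5.0, 20.0
    errs = []
    for h in (2.5, 1.25, 0.625):
        mesh, r = make_sphere_problem(a=a, b=b, h=h)
        sol = S.solve_shock(mesh, SIG, {"inner": 10.0, "outer": 0.0},
                            direct_threshold=40_000)
        mask = (r > a + 1.5 * h) & (r < b - 1.5 * h)
        exact = 10.0 * (1 / r[mask] - 1 / b) / (1 / a - 1 / b)
        errs.append(np.sqrt(np.mean((sol.ve[mask] - exact) ** 2)))
    assert errs[0] > errs[1] > errs[2]
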