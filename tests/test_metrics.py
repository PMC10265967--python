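"""Shock-efficacy metrics: DFT, energy, impedance, mean field."""

import numpy as np
import pytest

from torsodft import mesh as M
from torsodft import metrics as X
from torsodft import solver as S
from torsodft.geometry import Box
from torsodft.phantom import ALL_LABELS, LV_WALL, RV_WALL, SCAR

from conftest import make_slab

SIG = S.ConductivityMap(region_sigma={"bath": 0.2})


def myocardial_box_mesh(h=1.0, n=6):
    """Small lattice cube labeled entirely LV wall (for synthetic fields)."""
    L = n * h
    mesh = M.mesh_from_solids([(LV_WALL, Box((0, 0, 0), (L, L, L)))],
                              ["exterior", LV_WALL], h,
                              bounds=(np.zeros(3), np.full(3, L)))
    return mesh


def fake_solution(mesh, e_mag, v_applied=10.0):
    e = np.asarray(e_mag, float) * np.ones(mesh.n_elements)
    evec = np.zeros((mesh.n_elements, 3))
    evec[:, 0] = e
    return S.FieldSolution(ve=np.zeros(mesh.n_nodes), e_vec=evec, e_mag=e,
                           v_applied=v_applied, dirichlet={}, residual=0.0)


# ---------------------------------------------------------------------------
# volume-weighted percentile


@pytest.mark.parametrize("seed", range(6))
def test_weighted_percentile_matches_sort_accumulate_oracle(seed):
    rng = np.random.default_rng(seed)
    n = rng.integers(10, 500)
    v = rng.uniform(0, 10, n)
    w = rng.uniform(0.1, 3.0, n)
    frac = rng.uniform(0.02, 0.3)
    got = X.weighted_low_percentile(v, w, frac)

    # brute-force oracle: walk the sorted values until the mass is reached
    order = np.argsort(v)
    acc = 0.0
    expect = v[order[-1]]
    for i in order:
        acc += w[i]
        if acc >= frac * w.sum():
            expect = v[i]
            break
    assert got == pytest.approx(expect, abs=1e-9)
    # definition check: at most `frac` of the mass lies strictly below
    assert w[v < got].sum() <= frac * w.sum() + 1e-9


# ---------------------------------------------------------------------------
# DFT


def test_dft_scaling_identity():
    """Field exactly at threshold under the test voltage -> DFT = 10 V."""
    mesh = myocardial_box_mesh()
    crit = X.DFTCriterion()
    sol = fake_solution(mesh, e_mag=crit.threshold_v_per_mm, v_applied=10.0)
    assert X.compute_dft(sol, mesh, crit) == pytest.approx(10.0)


def test_dft_uses_volume_weighted_5th_percentile():
    mesh = myocardial_box_mesh(n=4)
    rng = np.random.default_rng(1)
    e = rng.uniform(0.2, 2.0, mesh.n_elements)
    sol = fake_solution(mesh, 1.0)
    sol.e_mag = e
    crit = X.DFTCriterion()
    g05 = X.weighted_low_percentile(e, mesh.volumes(), 0.05)
    assert X.compute_dft(sol, mesh, crit) == pytest.approx(
        10.0 * crit.threshold_v_per_mm / g05, rel=1e-12)


def test_dft_excludes_scar_from_the_mass():
    mesh = myocardial_box_mesh(n=4)
    labels = list(ALL_LABELS)
    mesh.label_names = labels
    mesh.labels = np.full(mesh.n_elements, labels.index(LV_WALL), np.int32)
    # scar elements carry a tiny field; excluding them raises the percentile
    scar_ids = np.arange(mesh.n_elements // 2)
    sol = fake_solution(mesh, 1.0)
    sol.e_mag = np.ones(mesh.n_elements)
    sol.e_mag[scar_ids] = 1e-4
    dft_with = X.compute_dft(sol, mesh)
    mesh.labels[scar_ids] = labels.index(SCAR)
    dft_without = X.compute_dft(sol, mesh)
    assert dft_without < dft_with


def test_dft_requires_myocardium():
    mesh = make_slab(h=2.0)
    sol = fake_solution(mesh, 1.0)
    with pytest.raises(ValueError):
        X.compute_dft(sol, mesh)


def test_dft_invariant_to_test_voltage():
    """Recomputing from a 20 V solve gives the same threshold (linearity)."""
    mesh = myocardial_box_mesh()
    mesh.electrode_nodes["hi"] = np.flatnonzero(mesh.nodes[:, 0] < 1e-9)
    mesh.electrode_nodes["lo"] = np.flatnonzero(mesh.nodes[:, 0] > 6 - 1e-9)
    sig = S.ConductivityMap()
    crit = X.DFTCriterion()
    dfts = []
    for v in (10.0, 20.0):
        sol = S.solve_shock(mesh, sig, {"hi": v, "lo": 0.0}, v_applied=v)
        dfts.append(X.compute_dft(sol, mesh, crit))
    assert dfts[0] == pytest.approx(dfts[1], rel=1e-9)


# ---------------------------------------------------------------------------
# energy / impedance / mean field


def test_energy_formula():
    assert X.dft_energy(0.0) == 0.0
    v = 123.4
    assert X.dft_energy(2 * v) == pytest.approx(4 * X.dft_energy(v))
    # direct formula oracle at V = 1000: 0.5 * 100e-6 * 1000^2 = 50 J
    assert X.dft_energy(1000.0) == pytest.approx(50.0)
    with pytest.raises(ValueError):
        X.dft_energy(-1.0)


def test_slab_impedance_exact_and_voltage_invariant():
    mesh = make_slab(h=2.0, L=20.0, W=10.0)
    r_exact = 20.0 / (0.2e-3 * 100.0)
    vals = []
    for v in (10.0, 40.0):
        sol = S.solve_shock(mesh, SIG, {"plate_hi": v, "plate_lo": 0.0},
                            v_applied=v)
        vals.append(X.compute_impedance(sol, mesh, SIG, None))
    assert vals[0] == pytest.approx(r_exact, rel=1e-12)
    assert vals[0] == pytest.approx(vals[1], rel=1e-12)


def test_mean_field_uniform_and_oracle():
    mesh = myocardial_box_mesh()
    sol = fake_solution(mesh, 0.5)
    assert X.mean_e_field(sol, mesh) == pytest.approx(0.5)
    rng = np.random.default_rng(2)
    sol.e_mag = rng.uniform(0, 1, mesh.n_elements)
    vols = mesh.volumes()
    oracle = float((sol.e_mag * vols).sum() / vols.sum())
    assert X.mean_e_field(sol, mesh) == pytest.approx(oracle, rel=1e-12)
    # linear in the applied voltage
    sol2 = fake_solution(mesh, 0.5)
    sol2.e_mag = 3 * sol.e_mag
    assert X.mean_e_field(sol2, mesh) == pytest.approx(3 * oracle, rel=1e-12)


def test_coverage_fraction():
    mesh = myocardial_box_mesh(n=4)
    sol = fake_solution(mesh, 1.0)
    sol.e_mag = np.linspace(0, 1, mesh.n_elements)
    cov = X.coverage_fraction(sol, mesh)
    above = sol.e_mag >= X.DFTCriterion().threshold_v_per_mm
    vols = mesh.volumes()
    assert cov == pytest.approx(vols[above].sum() / vols.sum())


def test_criterion_validation():
    with pytest.raises(ValueError):
        X.DFTCriterion(mass_fraction=1.0)
    with pytest.raises(ValueError):
        X.DFTCriterion(threshold_v_per_cm=0.0)
    assert X.DFTCriterion().threshold_v_per_mm == pytest.approx(0.5)
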