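"""Synthetic cohort generator: dimensional targets, labels, determinism."""

import json

import numpy as np
import pytest

from torsodft import phantom as P


@pytest.mark.parametrize("index", range(5))
def test_healthy_dimensions_hit_reference_table(index):
    """Measured LVEDD and wall thickness equal the per-model targets."""
    dims = P.BASE_HEART_DIMENSIONS[index]
    ph = P.generate_base_anatomy(P.anatomy_params(index, seed=3))
    assert ph.measure_lvedd() == pytest.approx(dims["lvedd"], abs=1e-5)
    assert ph.measure_wall_thickness() == pytest.approx(dims["wall"], abs=1e-5)


@pytest.mark.parametrize("index", range(5))
def test_pathologies_hit_targets_and_order(index):
    dims = P.BASE_HEART_DIMENSIONS[index]
    base = P.generate_base_anatomy(P.anatomy_params(index, seed=3))
    hcm = P.apply_pathology(base, P.Pathology(kind="hcm"))
    dcm = P.apply_pathology(base, P.Pathology(kind="dcm"))
    # HCM: wall thickened into the blood pool to its target
    assert hcm.measure_wall_thickness() == pytest.approx(dims["hcm_wall"], abs=1e-5)
    assert hcm.measure_wall_thickness() > base.measure_wall_thickness()
    # HCM wall grows inward: the cavity shrinks, the epicardium stays
    assert hcm.measure_lvedd() < base.measure_lvedd()
    # DCM: cavity dilated to its target at the equator, wall preserved
    assert dcm.measure_lvedd() == pytest.approx(dims["dcm_lvedd"], abs=1e-5)
    assert dcm.measure_lvedd() > base.measure_lvedd()
    assert dcm.measure_wall_thickness() == pytest.approx(dims["wall"], abs=1e-4)


def test_healthy_pathology_is_identity(base_phantom):
    assert P.apply_pathology(base_phantom, P.Pathology(kind="healthy")) \
        is base_phantom


def test_pathology_requires_healthy_base(base_phantom):
    hcm = P.apply_pathology(base_phantom, P.Pathology(kind="hcm"))
    with pytest.raises(P.PhantomError):
        P.apply_pathology(hcm, P.Pathology(kind="dcm"))


def test_unknown_kind_and_territory_rejected():
    with pytest.raises(P.PhantomError):
        P.Pathology(kind="fibrotic").validate()
    with pytest.raises(P.PhantomError):
        P.Pathology(kind="icm", scar_territory="PDA").validate()


def test_impossible_wall_rejected():
    with pytest.raises(P.PhantomError):
        P.AnatomyParams(lvedd=20.0, lv_wall_thickness=10.0).validate()


def test_same_seed_gives_identical_phantoms():
    a = P.anatomy_params(2, seed=11)
    b = P.anatomy_params(2, seed=11)
    assert a == b
    pa = P.generate_base_anatomy(a)
    pb = P.generate_base_anatomy(b)
    pts = np.random.default_rng(0).uniform(-1, 1, (20000, 3)) * [115, 85, 160]
    assert np.array_equal(pa.label_at(pts), pb.label_at(pts))


def test_every_interior_point_gets_exactly_one_label(base_phantom):
    """Painter's algorithm partitions the torso: one label per point."""
    rng = np.random.default_rng(4)
    pts = rng.uniform(-1, 1, (200000, 3)) * np.asarray(
        base_phantom.params.torso_semi)
    skin = base_phantom.solids[0][1]
    ids = base_phantom.label_at(pts)
    inside = skin.contains(pts)
    assert np.all(ids[inside] > 0)          # nothing unlabeled inside
    assert np.all(ids[~inside] == 0)        # nothing labeled outside


def test_all_conductivity_regions_present(cohort):
    """Healthy models carry every region except scar; ICM adds scar."""
    rng = np.random.default_rng(5)
    pts = rng.uniform(-1, 1, (400000, 3)) * [115, 85, 160]
    healthy, icm = cohort[0], cohort[3]
    seen = {healthy.labels[i] for i in set(healthy.label_at(pts).tolist())}
    assert seen >= set(P.ALL_LABELS) - {P.SCAR, P.EXTERIOR}
    seen_icm = {icm.labels[i] for i in set(icm.label_at(pts).tolist())}
    assert P.SCAR in seen_icm


def test_lv_wall_volume_matches_ellipsoid_shell_oracle(base_phantom):
    """Voxel volume of the epi-minus-cavity shell vs the closed form."""
    lm = base_phantom.landmarks
    cav, epi = lm["lv_cavity"], lm["lv_epi"]
    # closed-form prolate shell volume: 4/3 pi (a_e^2 c_e - a_c^2 c_c)
    v_exact = 4 / 3 * np.pi * (epi.a**2 * epi.c - cav.a**2 * cav.c)
    h = 1.0
    lo, hi = epi.bounds()
    axes = [np.arange(a + h / 2, b, h) for a, b in zip(lo, hi)]
    g = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    inside = epi.contains(g) & ~cav.contains(g)
    v_vox = inside.sum() * h**3
    assert v_vox == pytest.approx(v_exact, rel=0.05)
    # the labeled LV wall is the shell minus small vessel/valve punctures
    v_label = base_phantom.label_volume(P.LV_WALL, h=1.5)
    assert 0.85 * v_exact < v_label <= v_vox * 1.01


def test_scar_contained_in_lv_wall(cohort):
    icm = next(c for c in cohort if c.pathology.kind == "icm")
    lm = icm.landmarks
    rng = np.random.default_rng(6)
    center = lm["scar_center"]
    pts = center + rng.uniform(-30, 30, (50000, 3))
    ids = icm.label_at(pts)
    scar_pts = pts[ids == icm.label_index(P.SCAR)]
    assert len(scar_pts) > 100
    assert np.all(lm["lv_epi"].contains(scar_pts))
    assert not np.any(lm["lv_cavity"].contains(scar_pts))


def test_cohort_composition_and_manifest(tmp_path):
    cohort = P.build_cohort(5, seed=9)
    assert len(cohort) == 20
    variants = [c.pathology.kind for c in cohort]
    assert variants == list(P.VARIANTS) * 5
    small = P.build_cohort(1, seed=9)
    assert [c.pathology.kind for c in small] == list(P.VARIANTS)
    # determinism: identical manifests for identical seeds
    m1 = P.cohort_manifest(P.build_cohort(2, seed=5))
    m2 = P.cohort_manifest(P.build_cohort(2, seed=5))
    assert m1 == m2
    path = tmp_path / "cohort.json"
    P.write_manifest(cohort, path)
    loaded = json.loads(path.read_text())
    assert len(loaded) == 20
    assert {row["variant"] for row in loaded} == set(P.VARIANTS)
    assert all(row["model_id"] for row in loaded)
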