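"""ICD configuration catalogue and lead placement."""

import numpy as np
import pytest

from torsodft import electrodes as E
from torsodft import phantom as P


@pytest.fixture(scope="module")
def configs():
    return E.enumerate_study_configurations()


def test_study_set_is_the_ten_figure_configurations(configs):
    assert len(configs) == 10
    names = {c.name for c in configs}
    assert names == {
        "left_apical", "right_apical", "right_apical_svc", "right_apical_cs",
        "right_apical_svc_cs", "left_septal", "right_septal",
        "right_septal_svc", "right_septal_cs", "right_septal_svc_cs",
    }
    # extra ground coils are only ever added to right-sided-can setups
    for c in configs:
        if c.can_side == "left":
            assert c.extra_coils == ()


def test_configuration_validation():
    with pytest.raises(ValueError):
        E.ICDConfiguration(can_side="sternal")
    with pytest.raises(ValueError):
        E.ICDConfiguration(rv_position="outflow")
    with pytest.raises(ValueError):
        E.ICDConfiguration(extra_coils=("LV",))


def test_electrode_counts_and_roles(base_phantom, configs):
    for cfg in configs:
        es = E.build_configuration(cfg, base_phantom)
        shocks = [e for e in es.electrodes if e.role == "shock"]
        assert len(shocks) == 1            # exactly one shock coil
        assert len(es.grounds) == 1 + len(cfg.extra_coils)
        assert es.shock.name.startswith("rv_coil")


def test_standard_lead_dimensions(base_phantom):
    es = E.build_configuration(
        E.ICDConfiguration("right", "apical", ("SVC", "CS")), base_phantom)
    by_name = {e.name: e for e in es.electrodes}
    assert by_name["rv_coil_apical"].solid.length == pytest.approx(80.0, abs=0.5)
    assert by_name["rv_coil_apical"].solid.radius == pytest.approx(1.0)
    assert by_name["svc_coil"].solid.length == pytest.approx(80.0, abs=0.5)
    assert by_name["cs_coil"].solid.length == pytest.approx(40.0, abs=0.5)
    can = by_name["can_right"].solid
    assert can.radius == pytest.approx(30.0)
    assert can.length == pytest.approx(13.0)


def test_coils_sit_in_blood_and_can_in_bath(cohort, configs):
    """Electrode solids never intersect myocardial wall labels."""
    wall_ids = {c.label_index(lab) for c in cohort[:1]
                for lab in (P.LV_WALL, P.RV_WALL, P.SCAR)}
    for ph in cohort[:8]:
        for cfg in configs:
            es = E.build_configuration(cfg, ph)
            for el in es.electrodes:
                labs = ph.label_at(el.axis_points)
                assert not set(labs.tolist()) & wall_ids, \
                    f"{el.name} touches myocardium in {ph.name}"


def test_apical_and_septal_coils_are_geometrically_distinct(base_phantom):
    """Both coils drape along the septum; they differ in longitudinal span:
    the apical coil reaches the apex, the septal one is centred mid-septum."""
    lm = base_phantom.landmarks
    R = lm["frame"]
    hc = np.asarray(lm["heart_center"])
    api = E.build_configuration(E.ICDConfiguration("right", "apical"),
                                base_phantom).shock
    sep = E.build_configuration(E.ICDConfiguration("right", "septal"),
                                base_phantom).shock

    def local(el):
        return (el.axis_points - hc) @ R

    # apical extends clearly lower along the long axis than septal
    assert local(api)[:, 2].min() < local(sep)[:, 2].min() - 4.0

    # septal coil centred near 50% of the apex-to-base RV span
    rv_lo = lm["rv_center_local"][2] - lm["rv_semi"][2]
    rv_hi = lm["rv_center_local"][2] + lm["rv_semi"][2]
    mid = 0.5 * (rv_lo + rv_hi)
    sep_mid = local(sep)[:, 2].mean()
    assert abs(sep_mid - mid) < 0.15 * (rv_hi - rv_lo)

    def epi_gap(el):
        loc = local(el)
        rho = np.linalg.norm(loc[:, :2], axis=1)
        return rho - np.asarray(lm["lv_epi"].radius_at(loc[:, 2]))

    # the septal coil runs at the fixed septal clearance
    assert epi_gap(sep).mean() == pytest.approx(E.SEPTAL_CLEARANCE, abs=0.5)
    assert epi_gap(api).min() > E.SEPTAL_CLEARANCE - 0.5


def test_left_and_right_cans_mirror(base_phantom):
    left = E.build_configuration(E.ICDConfiguration("left", "apical"),
                                 base_phantom)
    right = E.build_configuration(E.ICDConfiguration("right", "apical"),
                                  base_phantom)
    cl = next(e for e in left.electrodes if e.name == "can_left").solid
    cr = next(e for e in right.electrodes if e.name == "can_right").solid
    assert cl.p0[0] > 0 > cr.p0[0]
    assert np.isclose(abs(cl.p0[0]), abs(cr.p0[0]))


def test_capture_solid_dilation():
    """Thin coils are inflated for node capture; fat cans barely change."""
    pts = np.array([[0, 0, 0], [0, 0, 80.0]])
    coil = E.Electrode("c", "shock", E.Tube(pts, E.COIL_RADIUS), "blood", pts)
    cap = coil.capture_solid(h=2.5)
    assert cap.radius == pytest.approx(2.0)   # 0.8 * h floor
    cap_fine = coil.capture_solid(h=0.5)
    assert cap_fine.radius == pytest.approx(E.COIL_RADIUS + 0.125)


def test_placement_error_on_hostile_geometry(base_phantom):
    """A coil that cannot stay inside its target region raises."""
    tiny = P.AnatomyParams(lvedd=26.0, lv_wall_thickness=8.0,
                           hcm_wall_thickness=12.9, dcm_lvedd=40.0)
    ph = P.generate_base_anatomy(tiny)
    with pytest.raises(E.PlacementError):
        E.build_configuration(E.ICDConfiguration("right", "apical"), ph)
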