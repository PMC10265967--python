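"""Synthetic torso/heart phantoms for defibrillation-field studies.

A phantom is an ordered list of labeled analytic solids resolved with a
painter's algorithm: at any point the label of the *last* containing solid
wins, so every point inside the torso maps to exactly one region. The
cohort generator produces five base anatomies, each in four cardiac
variants (healthy, hypertrophic, dilated, ischaemic), standing in for a
CT-derived torso cohort.

Regions carry the conductivity classes of a resistive volume-conductor
torso: inner body (bath), skin, bones, kidneys, liver, stomach, spleen,
lungs, atrial walls, great-vessel walls, blood pools (pools and valves
share one label), LV/RV myocardium and, for the ischaemic variant, scar.

All lengths are millimetres. The torso frame is x = patient left,
y = anterior, z = superior.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    BulgedEllipsoid,
    Cylinder,
    Difference,
    Ellipsoid,
    Intersection,
    Solid,
    Sphere,
    orthonormal_frame,
)

# ---------------------------------------------------------------------------
# Region labels

EXTERIOR = "exterior"
BATH = "bath"
SKIN = "skin"
BONE = "bones"
KIDNEY = "kidneys"
LIVER = "liver"
STOMACH = "stomach"
SPLEEN = "spleen"
LUNG = "lungs"
LA_WALL = "la_wall"
RA_WALL = "ra_wall"
AORTA_WALL = "aorta_wall"
SVC_WALL = "svc_wall"
BLOOD = "blood"  # all blood pools and valves (one conductivity class)
LV_WALL = "lv_wall"
RV_WALL = "rv_wall"
SCAR = "scar"

#: every label a phantom may emit, exterior first (index 0).
ALL_LABELS = [
    EXTERIOR, BATH, SKIN, BONE, KIDNEY, LIVER, STOMACH, SPLEEN, LUNG,
    LA_WALL, RA_WALL, AORTA_WALL, SVC_WALL, BLOOD, LV_WALL, RV_WALL, SCAR,
]

MYOCARDIUM_LABELS = (LV_WALL, RV_WALL)

VARIANTS = ("healthy", "hcm", "dcm", "icm")
SCAR_TERRITORIES = ("LAD", "LCx", "RCA")

# Reference heart dimensions for the five base anatomies (mm):
# healthy LVEDD, healthy wall thickness, DCM LVEDD target, HCM wall target.
BASE_HEART_DIMENSIONS = (
    {"lvedd": 48.0, "wall": 13.5, "dcm_lvedd": 68.0, "hcm_wall": 19.5},
    {"lvedd": 45.0, "wall": 11.7, "dcm_lvedd": 65.0, "hcm_wall": 20.0},
    {"lvedd": 42.0, "wall": 12.5, "dcm_lvedd": 62.0, "hcm_wall": 22.0},
    {"lvedd": 46.0, "wall": 12.0, "dcm_lvedd": 65.0, "hcm_wall": 18.0},
    {"lvedd": 54.0, "wall": 11.0, "dcm_lvedd": 74.0, "hcm_wall": 17.0},
)


class PhantomError(ValueError):
    """Raised for geometrically impossible anatomy parameters."""


@dataclass(frozen=True)
class AnatomyParams:
    """Parameters of one base (healthy) torso anatomy."""

    seed: int = 0
    torso_semi: tuple[float, float, float] = (110.0, 80.0, 155.0)
    skin_thickness: float = 5.0
    heart_center: tuple[float, float, float] = (28.0, 8.0, 0.0)
    heart_axis: tuple[float, float, float] = (0.45, 0.30, -0.84)  # apex direction
    lvedd: float = 48.0
    lv_wall_thickness: float = 13.5
    rv_wall_thickness: float = 3.5
    atrial_wall_thickness: float = 2.0
    aorta_wall_thickness: float = 2.0
    lv_long_axis_ratio: float = 1.65  # cavity long semi-axis / cavity radius
    hcm_wall_thickness: float = 19.5
    dcm_lvedd: float = 68.0
    organ_shift: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def validate(self) -> None:
        if self.lvedd <= 0:
            raise PhantomError("lvedd must be positive")
        for name in ("lv_wall_thickness", "rv_wall_thickness",
                     "atrial_wall_thickness", "aorta_wall_thickness",
                     "skin_thickness"):
            if getattr(self, name) <= 0:
                raise PhantomError(f"{name} must be positive")
        if self.lv_wall_thickness >= self.lvedd / 2:
            raise PhantomError("LV wall thickness >= LVEDD/2 leaves no cavity")
        if self.hcm_wall_thickness >= (self.lvedd / 2 + self.lv_wall_thickness):
            raise PhantomError("HCM wall target consumes the whole cavity")
        if np.any(np.asarray(self.torso_semi) <= 0):
            raise PhantomError("torso semi-axes must be positive")


@dataclass(frozen=True)
class Pathology:
    """Cardiac variant applied to a base anatomy."""

    kind: str = "healthy"
    scar_territory: str = "LAD"
    scar_radius: float = 25.0
    target_wall_thickness: float | None = None  # overrides params.hcm_wall_thickness
    target_lvedd: float | None = None  # overrides params.dcm_lvedd

    def validate(self) -> None:
        if self.kind not in VARIANTS:
            raise PhantomError(f"unknown pathology kind {self.kind!r}")
        if self.kind == "icm":
            if self.scar_territory not in SCAR_TERRITORIES:
                raise PhantomError(f"unknown scar territory {self.scar_territory!r}")
            if self.scar_radius <= 0:
                raise PhantomError("scar radius must be positive")


@dataclass
class TorsoPhantom:
    """One labeled torso: ordered solids plus landmarks for lead placement."""

    params: AnatomyParams
    pathology: Pathology
    solids: list[tuple[str, Solid]]
    landmarks: dict
    name: str = ""

    labels: list[str] = field(default_factory=lambda: list(ALL_LABELS))

    def label_index(self, label: str) -> int:
        return self.labels.index(label)

    def label_at(self, pts: np.ndarray) -> np.ndarray:
        """Painter's-algorithm label ids (index into ``labels``) per point."""
        pts = np.atleast_2d(np.asarray(pts, float))
        out = np.zeros(len(pts), dtype=np.int32)  # 0 == exterior
        for lab, solid in self.solids:
            idx = self.labels.index(lab)
            lo, hi = solid.bounds()
            cand = np.all((pts >= lo - 1e-9) & (pts <= hi + 1e-9), axis=1)
            if not cand.any():
                continue
            inside = solid.contains(pts[cand])
            sel = np.flatnonzero(cand)[inside]
            out[sel] = idx
        return out

    def label_name_at(self, pts: np.ndarray) -> list[str]:
        return [self.labels[i] for i in self.label_at(pts)]

    # -- measurements -----------------------------------------------------

    def _ray_exit(self, solid: Solid, origin, direction, t_max=200.0) -> float:
        """Distance from origin (inside solid) to the boundary along direction."""
        direction = np.asarray(direction, float)
        direction = direction / np.linalg.norm(direction)
        if not solid.contains(origin[None, :] if np.ndim(origin) == 1 else origin)[0]:
            raise PhantomError("measurement origin not inside solid")
        lo, hi = 0.0, t_max
        origin = np.asarray(origin, float)
        if solid.contains((origin + t_max * direction)[None, :])[0]:
            raise PhantomError("ray never exits solid")
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if solid.contains((origin + mid * direction)[None, :])[0]:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    def measure_lvedd(self) -> float:
        """Cavity diameter along the LV short axis through the equator."""
        lm = self.landmarks
        c = np.asarray(lm["heart_center"], float)
        d = lm["frame"][:, 1]  # short-axis direction clear of the RV
        cav = lm["lv_cavity"]
        return self._ray_exit(cav, c, d) + self._ray_exit(cav, c, -d)

    def measure_wall_thickness(self) -> float:
        """LV wall thickness along the same equatorial short axis."""
        lm = self.landmarks
        c = np.asarray(lm["heart_center"], float)
        d = lm["frame"][:, 1]
        r_endo = self._ray_exit(lm["lv_cavity"], c, d)
        r_epi = self._ray_exit(lm["lv_epi"], c, d)
        return r_epi - r_endo

    def label_volume(self, label: str, h: float = 1.0) -> float:
        """Voxel-count estimate of one region's volume at lattice spacing h."""
        want = self.labels.index(label)
        solids = [s for lab, s in self.solids if lab == label]
        if not solids:
            return 0.0
        lo = np.min([s.bounds()[0] for s in solids], axis=0) - h
        hi = np.max([s.bounds()[1] for s in solids], axis=0) + h
        axes = [np.arange(a + h / 2, b, h) for a, b in zip(lo, hi)]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        total = 0
        for chunk in np.array_split(grid, max(1, len(grid) // 500_000)):
            total += int(np.count_nonzero(self.label_at(chunk) == want))
        return total * h**3


# ---------------------------------------------------------------------------
# Construction


def _lv_shells(params: AnatomyParams, pathology: Pathology, center, R):
    """Cavity and epicardial solids for the requested variant."""
    r = params.lvedd / 2.0
    t = params.lv_wall_thickness
    c = params.lv_long_axis_ratio * r
    r_epi0, c_epi0 = r + t, c + t

    kind = pathology.kind
    if kind in ("healthy", "icm"):
        cav = BulgedEllipsoid(center, r, c, 0.0, R)
        epi = BulgedEllipsoid(center, r_epi0, c_epi0, 0.0, R)
    elif kind == "hcm":
        t_target = pathology.target_wall_thickness or params.hcm_wall_thickness
        if t_target >= r_epi0:
            raise PhantomError("HCM wall target consumes the whole cavity")
        # wall grows homogeneously into the blood pool; epicardium preserved
        cav = BulgedEllipsoid(center, r_epi0 - t_target, c_epi0 - t_target, 0.0, R)
        epi = BulgedEllipsoid(center, r_epi0, c_epi0, 0.0, R)
    elif kind == "dcm":
        lvedd_target = pathology.target_lvedd or params.dcm_lvedd
        if lvedd_target <= params.lvedd:
            raise PhantomError("DCM target LVEDD must exceed the healthy LVEDD")
        # full dilation at the equator tapering to zero at apex and base;
        # wall thickness at the equator preserved at the healthy value
        amp_cav = lvedd_target / (2.0 * r) - 1.0
        amp_epi = (lvedd_target / 2.0 + t) / r_epi0 - 1.0
        cav = BulgedEllipsoid(center, r, c, amp_cav, R)
        epi = BulgedEllipsoid(center, r_epi0, c_epi0, amp_epi, R)
    else:  # pragma: no cover - guarded by Pathology.validate
        raise PhantomError(f"unknown pathology kind {kind!r}")
    return cav, epi, r_epi0, c_epi0


def _build_phantom(params: AnatomyParams, pathology: Pathology) -> TorsoPhantom:
    params.validate()
    pathology.validate()

    ts = np.asarray(params.torso_semi, float)
    skin = Ellipsoid((0, 0, 0), ts)
    bath = Ellipsoid((0, 0, 0), ts - params.skin_thickness)

    hc = np.asarray(params.heart_center, float)
    apex_dir = np.asarray(params.heart_axis, float)
    apex_dir = apex_dir / np.linalg.norm(apex_dir)
    # local frame: z from apex to base, x toward the RV (patient right/anterior)
    R = orthonormal_frame(-apex_dir, (-1.0, 0.35, 0.0))

    cav, epi, r_e, c_e = _lv_shells(params, pathology, hc, R)

    # anterior direction expressed in the heart's local equatorial plane
    ant_local = R.T @ np.array([0.0, 1.0, 0.0])
    a2 = ant_local[:2] / np.linalg.norm(ant_local[:2])

    def world(local):
        return hc + R @ np.asarray(local, float)

    # right ventricle: a second shell whose septal side is clipped by the LV
    rv_center_local = np.array([0.95 * r_e, 0.0, -0.02 * c_e])
    rv_semi = np.array([0.62 * r_e, 0.55 * r_e, 0.92 * c_e])
    rv_cav = Ellipsoid(world(rv_center_local), rv_semi, R)
    rv_outer = Ellipsoid(world(rv_center_local), rv_semi + params.rv_wall_thickness, R)
    rv_blood = Difference(rv_cav, epi)

    # atria: thin spherical shells capping the base
    r_la, r_ra = 0.55 * r_e, 0.50 * r_e
    la_center = world([-0.35 * r_e - 0.30 * r_e * a2[0],
                       -0.30 * r_e * a2[1],
                       c_e + 0.55 * r_la])
    ra_center = world([0.78 * r_e, 0.0, c_e + 0.50 * r_ra])
    wa = params.atrial_wall_thickness
    la_wall, la_blood = Sphere(la_center, r_la), Sphere(la_center, r_la - wa)
    ra_wall, ra_blood = Sphere(ra_center, r_ra), Sphere(ra_center, r_ra - wa)

    # superior vena cava: a vertical-ish tube rising from the right atrium
    svc_dir = np.array([0.15, 0.0, 0.989])
    svc_dir = svc_dir / np.linalg.norm(svc_dir)
    svc_p0, svc_p1 = ra_center, ra_center + 98.0 * svc_dir
    svc_lumen_r = 7.5
    svc_wall = Cylinder(svc_p0, svc_p1, svc_lumen_r + params.aorta_wall_thickness)
    svc_lumen = Cylinder(svc_p0, svc_p1, svc_lumen_r)

    # ascending aorta out of the LV base
    ao_p0 = world([-0.10 * r_e, 0.0, 0.80 * c_e])
    ao_dir = np.array([-0.15, -0.10, 0.98])
    ao_dir = ao_dir / np.linalg.norm(ao_dir)
    ao_p1 = ao_p0 + 80.0 * ao_dir
    ao_lumen_r = 11.0
    ao_wall = Cylinder(ao_p0, ao_p1, ao_lumen_r + params.aorta_wall_thickness)
    ao_lumen = Cylinder(ao_p0, ao_p1, ao_lumen_r)
    # aortic-valve conduction path from the cavity into the aortic root
    valve = Cylinder(world([0.0, 0.0, 0.5 * (c_e - params.lv_wall_thickness)]),
                     ao_p0 + 15.0 * ao_dir, 7.0)

    # coronary-sinus course: an arc in the atrioventricular groove plane,
    # posterior to the LV base, just outside the epicardium
    z_cs = 0.72 * c_e
    r_arc = float(epi.radius_at(z_cs)) + 5.0
    phi0 = float(np.arctan2(-a2[1], -a2[0]))  # posterior azimuth
    half_span = 0.5 * 52.0 / r_arc
    phis = phi0 + np.linspace(-half_span, half_span, 25)
    cs_arc = np.array([world([r_arc * np.cos(p), r_arc * np.sin(p), z_cs])
                       for p in phis])

    sh = np.asarray(params.organ_shift, float)
    clip = Ellipsoid((0, 0, 0), ts - params.skin_thickness - 2.0)
    organs: list[tuple[str, Solid]] = [
        (BONE, Cylinder((0, -45, -95), (0, -45, 95), 11.0)),          # spine
        (BONE, Cylinder((0, 48, 20), (0, 48, 88), 7.0)),              # sternum
        (LUNG, Ellipsoid(np.array([-56, -16, 25]) + sh, (35, 46, 84))),
        (LUNG, Ellipsoid(np.array([66, -18, 25]) + sh, (29, 42, 80))),
        (LIVER, Ellipsoid(np.array([-38, 6, -85]) + sh, (42, 38, 40))),
        (STOMACH, Ellipsoid(np.array([35, 12, -85]) + sh, (28, 26, 32))),
        (SPLEEN, Ellipsoid(np.array([62, -18, -85]) + sh, (16, 20, 25))),
        (KIDNEY, Ellipsoid(np.array([-34, -30, -95]) + sh, (14, 12, 24))),
        (KIDNEY, Ellipsoid(np.array([34, -30, -95]) + sh, (14, 12, 24))),
    ]
    organs = [(lab, Intersection(sol, clip)) for lab, sol in organs]

    solids: list[tuple[str, Solid]] = [(SKIN, skin), (BATH, bath)]
    solids += organs
    # heart: all walls first, then all blood pools, so that pools meet
    # conductively at the junctions (SVC->RA, valves, etc.)
    solids += [
        (AORTA_WALL, ao_wall),
        (SVC_WALL, svc_wall),
        (LA_WALL, la_wall),
        (RA_WALL, ra_wall),
        (RV_WALL, rv_outer),
        (LV_WALL, epi),  # painted after the RV: the septum is LV myocardium
    ]
    solids += [
        (BLOOD, ao_lumen),
        (BLOOD, svc_lumen),
        (BLOOD, la_blood),
        (BLOOD, ra_blood),
        (BLOOD, rv_blood),  # RV pool explicitly clipped against the LV epi
        (BLOOD, cav),
        (BLOOD, valve),
    ]

    scar_center = None
    if pathology.kind == "icm":
        dir2d = {
            "LAD": a2,                      # anterior
            "LCx": np.array([-1.0, 0.0]),   # lateral free wall
            "RCA": -a2,                     # inferior/posterior
        }[pathology.scar_territory]
        z0 = -0.10 * c_e
        rho = 0.5 * (float(cav.radius_at(z0)) + float(epi.radius_at(z0)))
        scar_center = world([rho * dir2d[0], rho * dir2d[1], z0])
        scar = Difference(
            Intersection(Sphere(scar_center, pathology.scar_radius), epi), cav)
        solids.append((SCAR, scar))

    landmarks = {
        "frame": R,
        "heart_center": hc,
        "anterior2d": a2,
        "lv_cavity": cav,
        "lv_epi": epi,
        "r_epi0": r_e,
        "c_epi0": c_e,
        "rv_center_local": rv_center_local,
        "rv_semi": rv_semi,
        "rv_cavity": rv_cav,
        "rv_blood": rv_blood,
        "svc_axis": (svc_p0, svc_p1),
        "svc_lumen_radius": svc_lumen_r,
        "svc_lumen": svc_lumen,
        "cs_arc": cs_arc,
        "bath": bath,
        "torso_semi": ts,
        "scar_center": scar_center,
    }
    return TorsoPhantom(params=params, pathology=pathology, solids=solids,
                        landmarks=landmarks)


def generate_base_anatomy(params: AnatomyParams) -> TorsoPhantom:
    """Build the healthy base torso for one anatomy."""
    return _build_phantom(params, Pathology(kind="healthy"))


def apply_pathology(phantom: TorsoPhantom, pathology: Pathology) -> TorsoPhantom:
    """Rebuild a healthy base anatomy with a cardiac variant applied."""
    pathology.validate()
    if phantom.pathology.kind != "healthy":
        raise PhantomError("pathology must be applied to a healthy base phantom")
    if pathology.kind == "healthy":
        return phantom
    out = _build_phantom(phantom.params, pathology)
    out.name = phantom.name
    return out


def anatomy_params(index: int, seed: int = 0) -> AnatomyParams:
    """Parameters for base anatomy ``index`` (0-based).

    The first five anatomies take their heart dimensions from the reference
    table; further anatomies cycle through it. A per-anatomy jitter of the
    torso axes, heart pose and organ placement (seeded, a few percent /
    millimetres) makes anatomies distinct beyond their heart dimensions.
    """
    dims = BASE_HEART_DIMENSIONS[index % len(BASE_HEART_DIMENSIONS)]
    rng = np.random.default_rng([seed & 0x7FFFFFFF, index])
    u = lambda lo, hi, n=None: rng.uniform(lo, hi, n)
    base = AnatomyParams()
    torso = np.asarray(base.torso_semi) * (1.0 + u(-0.02, 0.02, 3))
    center = np.asarray(base.heart_center) + u(-2.0, 2.0, 3)
    axis = np.asarray(base.heart_axis) + u(-0.03, 0.03, 3)
    return AnatomyParams(
        seed=seed,
        torso_semi=tuple(torso),
        heart_center=tuple(center),
        heart_axis=tuple(axis / np.linalg.norm(axis)),
        lvedd=dims["lvedd"],
        lv_wall_thickness=dims["wall"],
        hcm_wall_thickness=dims["hcm_wall"],
        dcm_lvedd=dims["dcm_lvedd"],
        organ_shift=tuple(u(-3.0, 3.0, 3)),
    )


def build_cohort(n_anatomies: int = 5, seed: int = 0,
                 scar_radius: float = 25.0) -> list[TorsoPhantom]:
    """The study cohort: each anatomy in all four cardiac variants."""
    if n_anatomies < 1:
        raise PhantomError("need at least one anatomy")
    cohort: list[TorsoPhantom] = []
    for i in range(n_anatomies):
        params = anatomy_params(i, seed)
        base = generate_base_anatomy(params)
        territory = SCAR_TERRITORIES[i % len(SCAR_TERRITORIES)]
        for kind in VARIANTS:
            path = Pathology(kind=kind, scar_territory=territory,
                             scar_radius=scar_radius)
            ph = base if kind == "healthy" else apply_pathology(base, path)
            ph = dataclasses.replace(ph) if ph is base else ph
            ph.name = f"model{i + 1}_{kind}"
            cohort.append(ph)
    return cohort


def cohort_manifest(cohort: list[TorsoPhantom]) -> list[dict]:
    """JSON-serializable manifest: model id, variant, seed and parameters."""
    rows = []
    for ph in cohort:
        p = dataclasses.asdict(ph.params)
        p = {k: (list(v) if isinstance(v, tuple) else v) for k, v in p.items()}
        rows.append({
            "model_id": ph.name,
            "variant": ph.pathology.kind,
            "scar_territory": ph.pathology.scar_territory
            if ph.pathology.kind == "icm" else None,
            "scar_radius": ph.pathology.scar_radius
            if ph.pathology.kind == "icm" else None,
            "params": p,
        })
    return rows


def write_manifest(cohort: list[TorsoPhantom], path) -> None:
    with open(path, "w") as fh:
        json.dump(cohort_manifest(cohort), fh, indent=2)
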