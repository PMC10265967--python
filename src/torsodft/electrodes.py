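"""ICD electrode geometry: shock coil, ground can and optional extra coils.

The study set comprises transvenous configurations built from:

* an RV shock coil (2 mm diameter, 8 cm length) placed apically or at the
  mid-septum inside the RV blood pool;
* a pectoral can (6 cm diameter, 1.3 cm thickness) on the left or right
  upper chest, acting as ground;
* optional ground coils in the superior vena cava (2 mm x 8 cm) and along
  the coronary-sinus course at the posterior LV base (2 mm x 4 cm).

Electrodes are represented as analytic solids; the field solver applies
Dirichlet values on mesh nodes captured by each solid. Configurations not
using an electrode simply omit it, so an absent electrode leaves the
conductive medium untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import Cylinder, Solid, Tube
from .phantom import BATH, BLOOD, TorsoPhantom

COIL_RADIUS = 1.0        # mm (2 mm diameter)
RV_COIL_LENGTH = 80.0    # mm
SVC_COIL_LENGTH = 80.0   # mm
CS_COIL_LENGTH = 40.0    # mm
CAN_DIAMETER = 60.0      # mm
CAN_THICKNESS = 13.0     # mm

#: thin coils capture lattice nodes within max(radius, CAPTURE_FACTOR * h)
CAPTURE_FACTOR = 0.8

#: all capture solids are dilated by this fraction of the lattice spacing:
#: a staircase set of Dirichlet nodes acts as a conductor electrically
#: smaller than its nominal radius (a single lattice node behaves as a
#: sphere of radius ~0.3 h), so the capture boundary is pushed outward by
#: a quarter spacing to keep the discrete electrode size-consistent.
CAPTURE_DILATION = 0.25

SEPTAL_CLEARANCE = 4.5   # mm between a coil axis and the LV epicardium


class PlacementError(RuntimeError):
    pass


@dataclass
class Electrode:
    name: str
    role: str                  # "shock" | "ground"
    solid: Solid               # physical geometry
    expected_region: str       # phantom label the electrode must sit in
    axis_points: np.ndarray    # sample points used for placement validation

    def capture_solid(self, h: float) -> Solid:
        """Node-capture solid: the electrode dilated by the effective-radius
        correction, with a floor that keeps thin coils connected."""
        d = CAPTURE_DILATION * h
        if isinstance(self.solid, Tube):
            r = max(self.solid.radius + d, CAPTURE_FACTOR * h)
            return Tube(self.solid.points, r)
        if isinstance(self.solid, Cylinder):
            ax = self.solid.axis
            return Cylinder(self.solid.p0 - d * ax, self.solid.p1 + d * ax,
                            self.solid.radius + d)
        return self.solid


@dataclass(frozen=True)
class ICDConfiguration:
    """One ICD setup: can side, RV coil position and optional extra coils."""

    can_side: str = "left"          # "left" | "right"
    rv_position: str = "apical"     # "apical" | "septal"
    extra_coils: tuple[str, ...] = ()  # subset of ("SVC", "CS")

    def __post_init__(self):
        if self.can_side not in ("left", "right"):
            raise ValueError(f"unknown can side {self.can_side!r}")
        if self.rv_position not in ("apical", "septal"):
            raise ValueError(f"unknown RV coil position {self.rv_position!r}")
        extras = tuple(self.extra_coils)
        if any(e not in ("SVC", "CS") for e in extras):
            raise ValueError(f"unknown extra coil in {extras!r}")
        object.__setattr__(self, "extra_coils", extras)

    @property
    def name(self) -> str:
        parts = [self.can_side, self.rv_position]
        parts += [e.lower() for e in self.extra_coils]
        return "_".join(parts)


@dataclass
class ElectrodeSet:
    configuration: ICDConfiguration
    electrodes: list[Electrode] = field(default_factory=list)

    @property
    def shock(self) -> Electrode:
        return next(e for e in self.electrodes if e.role == "shock")

    @property
    def grounds(self) -> list[Electrode]:
        return [e for e in self.electrodes if e.role == "ground"]


def enumerate_study_configurations() -> list[ICDConfiguration]:
    """The ten configurations analysed in the study comparisons."""
    out = [
        ICDConfiguration("left", "apical"),
        ICDConfiguration("right", "apical"),
        ICDConfiguration("right", "apical", ("SVC",)),
        ICDConfiguration("right", "apical", ("CS",)),
        ICDConfiguration("right", "apical", ("SVC", "CS")),
        ICDConfiguration("left", "septal"),
        ICDConfiguration("right", "septal"),
        ICDConfiguration("right", "septal", ("SVC",)),
        ICDConfiguration("right", "septal", ("CS",)),
        ICDConfiguration("right", "septal", ("SVC", "CS")),
    ]
    return out


# ---------------------------------------------------------------------------
# placement


def _resample_polyline(pts: np.ndarray, s0: float, length: float,
                       n: int = 33) -> np.ndarray:
    """Sub-polyline of arc-length ``length`` starting at arc position s0."""
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s0 + length > s[-1] + 1e-9:
        raise PlacementError(
            f"polyline too short: need {s0 + length:.1f} mm of {s[-1]:.1f} mm")
    si = np.linspace(s0, s0 + length, n)
    out = np.empty((n, 3))
    for d in range(3):
        out[:, d] = np.interp(si, s, pts[:, d])
    return out


def _rv_coil_path(phantom: TorsoPhantom, position: str) -> np.ndarray:
    """Coil axis polyline inside the RV blood pool (heart-local x-z plane).

    The apical path hugs the RV free-wall side and starts at the apex; the
    septal path runs parallel to the septum at a fixed clearance from the
    LV epicardium, centred halfway between apex and base.
    """
    lm = phantom.landmarks
    R, hc = lm["frame"], np.asarray(lm["heart_center"])
    epi = lm["lv_epi"]
    rvc = lm["rv_center_local"]
    semi = lm["rv_semi"]
    margin = 2.5  # keep the capture tube inside the cavity
    sx, sz = semi[0] - margin, semi[2] - margin

    z = np.arange(rvc[2] - 0.985 * sz, rvc[2] + 0.985 * sz, 0.5)
    u = np.clip((z - rvc[2]) / sz, -1, 1)
    width = np.sqrt(1.0 - u * u)
    # a transvenous RV lead drapes along the septal aspect of the cavity;
    # both positions follow the septum at fixed clearance and differ only
    # in their longitudinal span (apex-reaching vs mid-septum-centred)
    x_septum = np.asarray(epi.radius_at(z)) + SEPTAL_CLEARANCE
    x_outer = rvc[0] + 0.95 * sx * width
    x_inner = rvc[0] - 0.95 * sx * width
    if position == "apical":
        x = np.maximum(x_septum, x_inner)
    elif position == "septal":
        x = x_septum
    else:
        raise ValueError(f"unknown RV coil position {position!r}")
    ok = (x <= x_outer + 1e-9) & (x >= x_inner - 1e-9)
    if not ok.any():
        raise PlacementError("RV cavity cannot host the coil at this clearance")
    # keep the longest contiguous feasible stretch
    idx = np.flatnonzero(ok)
    splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    idx = max(splits, key=len)
    pts_local = np.column_stack([x[idx], np.zeros(len(idx)), z[idx]])
    pts = hc + pts_local @ R.T

    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = seg.sum()
    if total < RV_COIL_LENGTH:
        raise PlacementError(
            f"RV blood pool too small for an {RV_COIL_LENGTH:.0f} mm coil "
            f"({total:.1f} mm available)")
    if position == "apical":
        s0 = 0.0  # coil ends at the apex
    else:
        s_mid = 0.5 * total  # centred at 50 % of the apex-to-base span
        s0 = min(max(0.0, s_mid - RV_COIL_LENGTH / 2), total - RV_COIL_LENGTH)
    return _resample_polyline(pts, s0, RV_COIL_LENGTH)


def _can_solid(phantom: TorsoPhantom, side: str) -> Cylinder:
    """Subcutaneous pectoral can, tangent to the chest surface.

    The disc sits just inside the inner-body (bath) ellipsoid on the upper
    chest, its normal along the local outward surface normal.
    """
    ph = phantom.params
    s = np.asarray(ph.torso_semi, float) - ph.skin_thickness
    sx = 1.0 if side == "left" else -1.0
    w = np.array([sx * 0.42, 0.58, 0.70])
    w /= np.linalg.norm(w)
    surf = w / np.sqrt(((w / s) ** 2).sum())     # surface point along w
    n = surf / s**2
    n /= np.linalg.norm(n)                       # outward ellipsoid normal
    center = surf - 15.0 * n                     # implant depth
    return Cylinder(center - 0.5 * CAN_THICKNESS * n,
                    center + 0.5 * CAN_THICKNESS * n, CAN_DIAMETER / 2)


def _validate(phantom: TorsoPhantom, electrode: Electrode) -> None:
    want = phantom.label_index(electrode.expected_region)
    got = phantom.label_at(electrode.axis_points)
    if not np.all(got == want):
        bad = {phantom.labels[i] for i in set(got.tolist()) if i != want}
        raise PlacementError(
            f"electrode {electrode.name!r} leaves its target region "
            f"{electrode.expected_region!r} (hits {sorted(bad)})")


def build_configuration(cfg: ICDConfiguration,
                        phantom: TorsoPhantom) -> ElectrodeSet:
    """Place the electrodes of one configuration into a phantom."""
    lm = phantom.landmarks
    electrodes: list[Electrode] = []

    rv_path = _rv_coil_path(phantom, cfg.rv_position)
    electrodes.append(Electrode(
        name=f"rv_coil_{cfg.rv_position}", role="shock",
        solid=Tube(rv_path, COIL_RADIUS), expected_region=BLOOD,
        axis_points=rv_path))

    can = _can_solid(phantom, cfg.can_side)
    # sample the can volume on a small grid for validation
    lo, hi = can.bounds()
    g = np.stack(np.meshgrid(*[np.linspace(a + 1, b - 1, 7) for a, b in
                               zip(lo, hi)], indexing="ij"), axis=-1).reshape(-1, 3)
    can_pts = g[can.contains(g)]
    electrodes.append(Electrode(
        name=f"can_{cfg.can_side}", role="ground", solid=can,
        expected_region=BATH, axis_points=can_pts))

    if "SVC" in cfg.extra_coils:
        p0, p1 = lm["svc_axis"]
        d = (p1 - p0) / np.linalg.norm(p1 - p0)
        a = p0 + 8.0 * d
        pts = np.linspace(a, a + SVC_COIL_LENGTH * d, 33)
        electrodes.append(Electrode(
            name="svc_coil", role="ground", solid=Tube(pts, COIL_RADIUS),
            expected_region=BLOOD, axis_points=pts))

    if "CS" in cfg.extra_coils:
        arc = lm["cs_arc"]
        seg = np.linalg.norm(np.diff(arc, axis=0), axis=1).sum()
        s0 = 0.5 * (seg - CS_COIL_LENGTH)
        pts = _resample_polyline(arc, s0, CS_COIL_LENGTH)
        electrodes.append(Electrode(
            name="cs_coil", role="ground", solid=Tube(pts, COIL_RADIUS),
            expected_region=BATH, axis_points=pts))

    for el in electrodes:
        _validate(phantom, el)
    return ElectrodeSet(configuration=cfg, electrodes=electrodes)
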