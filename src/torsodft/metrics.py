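"""Shock-efficacy metrics for one model x configuration solve.

The defibrillation threshold follows the critical-mass criterion: the
shock voltage at which 95% of the ventricular myocardium (LV plus RV
wall, volume-weighted, scar excluded) experiences an E-field magnitude of
at least 5 V/cm. Because the field problem is linear, the threshold is
obtained by scaling the applied test voltage by the ratio of the criterion
threshold to the 5th volume-percentile of the field.

Shock energy uses the capacitive-discharge relation E = C V^2 / 2 with
C = 100 uF; impedance is Ohm's law on the shock-electrode current.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import phantom as ph
from .mesh import FEMesh
from .solver import ConductivityMap, FieldSolution, electrode_currents

__all__ = [
    "DFTCriterion",
    "ShockMetrics",
    "compute_dft",
    "dft_energy",
    "compute_impedance",
    "mean_e_field",
    "coverage_fraction",
    "evaluate_shock",
]

#: device capacitance for the energy relation (farad)
CAPACITANCE = 100e-6

V_PER_CM_TO_V_PER_MM = 0.1


@dataclass(frozen=True)
class DFTCriterion:
    """Critical-mass defibrillation criterion."""

    threshold_v_per_cm: float = 5.0
    mass_fraction: float = 0.95
    test_voltage: float = 10.0

    def __post_init__(self):
        if not 0.0 < self.mass_fraction < 1.0:
            raise ValueError("mass fraction must lie in (0, 1)")
        if self.threshold_v_per_cm <= 0:
            raise ValueError("field threshold must be positive")

    @property
    def threshold_v_per_mm(self) -> float:
        return self.threshold_v_per_cm * V_PER_CM_TO_V_PER_MM


@dataclass
class ShockMetrics:
    model_id: str
    variant: str
    configuration: str
    dft_voltage: float        # V
    dft_energy: float         # J
    impedance: float          # ohm
    mean_e_field: float       # V/mm at the test voltage
    coverage: float           # myocardial volume fraction >= threshold
    extra: dict = field(default_factory=dict)


def _myocardium(mesh: FEMesh) -> np.ndarray:
    """Ventricular-myocardium mask: LV+RV wall, scar excluded."""
    mask = mesh.element_mask(*ph.MYOCARDIUM_LABELS)
    if not mask.any():
        raise ValueError("mesh contains no ventricular myocardium")
    return mask


def weighted_low_percentile(values: np.ndarray, weights: np.ndarray,
                            fraction: float) -> float:
    """Largest v such that the weight of {values < v} is at most ``fraction``.

    With fraction = 0.05 this is the field level exceeded by 95% of the
    tissue mass.
    """
    order = np.argsort(values)
    v = values[order]
    cum = np.cumsum(weights[order])
    target = fraction * cum[-1]
    i = int(np.searchsorted(cum, target, side="left"))
    return float(v[min(i, len(v) - 1)])


def compute_dft(sol: FieldSolution, mesh: FEMesh,
                criterion: DFTCriterion = DFTCriterion()) -> float:
    """Defibrillation threshold voltage by linear scaling of the solve."""
    mask = _myocardium(mesh)
    e = sol.e_mag[mask]
    w = mesh.volumes()[mask]
    g05 = weighted_low_percentile(e, w, 1.0 - criterion.mass_fraction)
    if g05 <= 0:
        raise ValueError("degenerate field: 5th percentile is zero")
    return sol.v_applied * criterion.threshold_v_per_mm / g05


def dft_energy(dft_voltage: float, capacitance: float = CAPACITANCE) -> float:
    """Capacitive-discharge shock energy (J)."""
    if dft_voltage < 0:
        raise ValueError("voltage must be nonnegative")
    return 0.5 * capacitance * dft_voltage**2


def compute_impedance(sol: FieldSolution, mesh: FEMesh,
                      sigma: ConductivityMap, electrodes,
                      K=None, method: str = "residual") -> float:
    """Shock impedance R = V / |I_shock| (ohm)."""
    if not sol.currents:
        electrode_currents(sol, mesh, sigma, electrodes, K=K, method=method)
    shock_names = [n for n, v in sol.dirichlet.items() if v != 0.0]
    i_shock = sum(sol.currents[n] for n in shock_names)
    if abs(i_shock) < 1e-300:
        raise ValueError("zero shock current")
    return sol.v_applied / abs(i_shock)


def mean_e_field(sol: FieldSolution, mesh: FEMesh) -> float:
    """Volume-weighted mean E-field magnitude over the myocardium (V/mm)."""
    mask = _myocardium(mesh)
    w = mesh.volumes()[mask]
    return float(np.sum(sol.e_mag[mask] * w) / np.sum(w))


def coverage_fraction(sol: FieldSolution, mesh: FEMesh,
                      criterion: DFTCriterion = DFTCriterion()) -> float:
    """Myocardial volume fraction at/above the field threshold."""
    mask = _myocardium(mesh)
    w = mesh.volumes()[mask]
    above = sol.e_mag[mask] >= criterion.threshold_v_per_mm
    return float(np.sum(w[above]) / np.sum(w))


def evaluate_shock(sol: FieldSolution, mesh: FEMesh, sigma: ConductivityMap,
                   electrodes, model_id: str = "", variant: str = "",
                   configuration: str = "", K=None,
                   criterion: DFTCriterion = DFTCriterion()) -> ShockMetrics:
    """All per-solve metrics in one record."""
    dft_v = compute_dft(sol, mesh, criterion)
    return ShockMetrics(
        model_id=model_id, variant=variant, configuration=configuration,
        dft_voltage=dft_v, dft_energy=dft_energy(dft_v),
        impedance=compute_impedance(sol, mesh, sigma, electrodes, K=K),
        mean_e_field=mean_e_field(sol, mesh),
        coverage=coverage_fraction(sol, mesh, criterion))
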