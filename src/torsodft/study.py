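"""Cohort runner and paired statistical comparison layer.

Runs every ICD configuration on every cohort model, collects per-solve
shock metrics into a long table, and compares configurations with paired
Wilcoxon signed-rank tests (pairing within model), reporting medians and
interquartile ranges. No multiple-testing correction is applied; each
comparison is reported with its raw two-sided p-value.

Within one model all configurations share the mesh, the stiffness matrix
and the multigrid hierarchy (electrodes enter only through Dirichlet node
sets), which makes the 20-model x 10-configuration sweep tractable on a
single CPU. Completed solves are cached on disk keyed by a content hash
of everything that determines the result.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .electrodes import ICDConfiguration, build_configuration, \
    enumerate_study_configurations
from .fibers import assign_fibers
from .mesh import capture_electrode_nodes, tetrahedralize
from .metrics import DFTCriterion, evaluate_shock
from .phantom import TorsoPhantom, build_cohort
from .solver import ConductivityMap, LatticeMultigrid, assemble_stiffness, \
    electrode_currents, solve_shock
from .stats import wilcoxon_signed_rank

log = logging.getLogger("torsodft.study")

METRIC_COLUMNS = ["dft_voltage_V", "dft_energy_J", "impedance_ohm",
                  "mean_e_field_V_per_mm", "coverage"]


@dataclass
class StudyResult:
    """Long metrics table plus any per-solve failures."""

    metrics: pd.DataFrame
    failures: list = field(default_factory=list)

    def write_csv(self, path: str) -> None:
        self.metrics.to_csv(path, index=False)


def _cache_key(phantom: TorsoPhantom, cfg_name: str, h: float,
               sigma: ConductivityMap, criterion: DFTCriterion,
               v_applied: float) -> str:
    payload = {
        "model": phantom.name,
        "params": dataclasses.asdict(phantom.params),
        "pathology": dataclasses.asdict(phantom.pathology),
        "config": cfg_name,
        "h": h,
        "sigma": {**{k: v for k, v in sigma.region_sigma.items()},
                  "il": sigma.sigma_il, "el": sigma.sigma_el,
                  "it": sigma.sigma_it, "et": sigma.sigma_et,
                  "mode": sigma.myocardium_mode},
        "criterion": dataclasses.asdict(criterion),
        "v": v_applied,
        "rev": 1,
    }
    blob = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:24]


def run_model(phantom: TorsoPhantom,
              configurations: list[ICDConfiguration] | None = None,
              h: float = 2.5, v_applied: float = 10.0,
              sigma: ConductivityMap | None = None,
              criterion: DFTCriterion = DFTCriterion(),
              cache_dir: str | None = None) -> tuple[list[dict], list]:
    """All configurations on one model; returns (metric rows, failures)."""
    if configurations is None:
        configurations = enumerate_study_configurations()
    sigma = sigma or ConductivityMap()

    pending = []
    rows, failures = [], []
    for cfg in configurations:
        key = None
        if cache_dir:
            key = os.path.join(cache_dir,
                               _cache_key(phantom, cfg.name, h, sigma,
                                          criterion, v_applied) + ".json")
            if os.path.exists(key):
                with open(key) as fh:
                    rows.append(json.load(fh))
                continue
        pending.append((cfg, key))
    if not pending:
        return rows, failures

    t0 = time.time()
    mesh = tetrahedralize(phantom, None, h=h)
    assign_fibers(mesh, phantom)
    K = assemble_stiffness(mesh, sigma)
    mg = None
    if mesh.n_nodes > 40_000:
        mg = LatticeMultigrid(K, mesh.node_ijk)
    log.info("%s: mesh %d nodes / %d tets, setup %.1fs", phantom.name,
             mesh.n_nodes, mesh.n_elements, time.time() - t0)

    for cfg, key in pending:
        try:
            t0 = time.time()
            es = build_configuration(cfg, phantom)
            mesh.electrode_nodes = {}
            capture_electrode_nodes(mesh, es)
            sol = solve_shock(mesh, sigma, es, v_applied, K=K, mg=mg)
            electrode_currents(sol, mesh, sigma, es, K=K)
            m = evaluate_shock(sol, mesh, sigma, es, model_id=phantom.name,
                               variant=phantom.pathology.kind,
                               configuration=cfg.name, K=K,
                               criterion=criterion)
            row = {
                "model_id": m.model_id, "variant": m.variant,
                "configuration": m.configuration,
                "dft_voltage_V": m.dft_voltage, "dft_energy_J": m.dft_energy,
                "impedance_ohm": m.impedance,
                "mean_e_field_V_per_mm": m.mean_e_field,
                "coverage": m.coverage,
                "residual": sol.residual,
                "i_shock_A": sol.currents[es.shock.name],
                "i_balance": abs(sum(sol.currents.values())),
            }
            log.info("%s x %s: DFT %.0f V (%.1f J), R %.1f ohm, %.1fs",
                     phantom.name, cfg.name, m.dft_voltage, m.dft_energy,
                     m.impedance, time.time() - t0)
            rows.append(row)
            if key:
                os.makedirs(cache_dir, exist_ok=True)
                with open(key, "w") as fh:
                    json.dump(row, fh)
        except Exception as err:  # individual solves fail without aborting
            log.warning("%s x %s failed: %s", phantom.name, cfg.name, err)
            failures.append((phantom.name, cfg.name, repr(err)))
    return rows, failures


def run_cohort(cohort: list[TorsoPhantom] | None = None,
               configurations: list[ICDConfiguration] | None = None,
               h: float = 2.5, v_applied: float = 10.0,
               sigma: ConductivityMap | None = None,
               criterion: DFTCriterion = DFTCriterion(),
               cache_dir: str | None = None,
               n_anatomies: int = 5, seed: int = 0) -> StudyResult:
    """One ShockMetrics row per (model, configuration)."""
    if cohort is None:
        cohort = build_cohort(n_anatomies, seed)
    rows, failures = [], []
    for phantom in cohort:
        r, f = run_model(phantom, configurations, h=h, v_applied=v_applied,
                         sigma=sigma, criterion=criterion,
                         cache_dir=cache_dir)
        rows += r
        failures += f
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["model_id", "configuration"]).reset_index(drop=True)
    return StudyResult(metrics=df, failures=failures)


def paired_wilcoxon(x, y) -> tuple[float, float]:
    """Wilcoxon signed-rank on paired samples: (W+, two-sided p)."""
    res = wilcoxon_signed_rank(x, y)
    return res.statistic, res.pvalue


def paired_metric(df: pd.DataFrame, metric: str, config_a: str,
                  config_b: str) -> tuple[np.ndarray, np.ndarray]:
    """Aligned per-model metric vectors for two configurations."""
    wide = df.pivot_table(index="model_id", columns="configuration",
                          values=metric)
    sub = wide[[config_a, config_b]].dropna()
    return sub[config_a].to_numpy(), sub[config_b].to_numpy()


def compare_configurations(df: pd.DataFrame,
                           pairs: list[tuple[str, str]],
                           metric: str = "dft_energy_J") -> pd.DataFrame:
    """Paired comparison records with medians, IQRs and signed-rank tests."""
    out = []
    for a, b in pairs:
        xa, xb = paired_metric(df, metric, a, b)
        stat, p = paired_wilcoxon(xa, xb)
        qa = np.percentile(xa, [25, 50, 75])
        qb = np.percentile(xb, [25, 50, 75])
        out.append({
            "config_a": a, "config_b": b, "metric": metric, "n_pairs": len(xa),
            "median_a": qa[1], "q1_a": qa[0], "q3_a": qa[2],
            "median_b": qb[1], "q1_b": qb[0], "q3_b": qb[2],
            "statistic": stat, "p_value": p,
        })
    return pd.DataFrame(out)


#: the pairwise comparisons mirrored from the study's figures
STUDY_PAIRS = [
    ("right_apical", "left_apical"),
    ("right_apical", "right_apical_svc"),
    ("right_apical", "right_apical_cs"),
    ("right_apical", "right_apical_svc_cs"),
    ("right_septal", "right_apical"),
    ("left_septal", "left_apical"),
    ("right_septal", "right_septal_svc"),
    ("right_septal", "right_septal_cs"),
    ("right_septal", "right_septal_svc_cs"),
]


def summarize(result: StudyResult) -> dict[str, pd.DataFrame]:
    """Per-configuration and per-variant median/Q1/Q3 summaries."""
    df = result.metrics
    if df.empty:
        raise ValueError("empty study result")

    def q(frame, by):
        g = frame.groupby(by)[["dft_energy_J", "impedance_ohm",
                               "mean_e_field_V_per_mm"]]
        med = g.median().add_suffix("_median")
        q1 = g.quantile(0.25).add_suffix("_q1")
        q3 = g.quantile(0.75).add_suffix("_q3")
        return med.join(q1).join(q3).sort_index(axis=1)

    have = set(df["configuration"])
    wide = df.pivot_table(index="model_id", columns="configuration",
                          values="dft_energy_J")
    pairs = [(a, b) for a, b in STUDY_PAIRS
             if {a, b} <= have and wide[[a, b]].dropna().shape[0] >= 5]
    return {
        "by_configuration": q(df, "configuration"),
        "by_variant": q(df, ["variant", "configuration"]),
        "comparisons": compare_configurations(df, pairs)
        if pairs else pd.DataFrame(),
    }
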