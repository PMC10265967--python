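# torsodft

Shock-field simulation of transvenous implantable cardioverter
defibrillator (ICD) configurations on synthetic torso phantoms.

The ICD generator ("can") is normally implanted in the left pectoral
area; infections, venous occlusion or prior surgery can force a
right-sided can and/or a mid-septal rather than apical position of the RV
shocking coil — both degrade the shock vector through the left ventricle
and raise the defibrillation threshold (DFT). Extra ground coils in the
superior vena cava (SVC) or coronary sinus (CS) can win that efficacy
back. `torsodft` quantifies these effects in silico for a cohort of
labeled torso models, for device researchers and computational
electrophysiologists who want the full pipeline — anatomy, mesh, field
solve, metrics, statistics — in reproducible Python.

## Model

During a shock, the torso is a resistive volume conductor. The package
solves the quasi-static problem

∇·(σ ∇Vₑ) = 0,  Vₑ = V on the shock coil, Vₑ = 0 on grounds, no-flux
on the torso surface,

with P1 finite elements on a region-labeled voxel tetrahedral mesh.
Organ regions are isotropic (bath 0.24725, lungs 0.0714, bones 0.05 S/m,
…); the ventricular myocardium carries the rank-1 anisotropic tensor
σ = σₜI + (σₗ−σₜ) f fᵀ about the rule-based fibre direction f (helix
angle +60°→−60° endo→epi).

Defibrillation success uses the **critical-mass criterion**: the DFT is
the shock voltage at which 95% of the ventricular myocardial mass sees
‖∇Vₑ‖ ≥ 5 V/cm, obtained by linearly rescaling a 10 V test solve:

DFT = 10 V × (5 V/cm) / g₀₅,  E = C·DFT²/2 (C = 100 µF),
R = V / I_shock.

The synthetic cohort is 5 base anatomies × 4 cardiac variants (healthy,
hypertrophic, dilated, ischaemic-with-scar), and the study set is 10
configurations: {left, right} can × {apical, septal} RV coil, plus SVC,
CS and SVC+CS ground-coil additions to the right-sided can.

## Worked example

```python
from torsodft.phantom import build_cohort
from torsodft.electrodes import ICDConfiguration
from torsodft.study import run_cohort

model = build_cohort(1, seed=1)[0]          # model1, healthy variant
configs = [ICDConfiguration("left", "apical"),
           ICDConfiguration("right", "apical"),
           ICDConfiguration("right", "apical", ("SVC", "CS"))]
res = run_cohort([model], configs, h=2.5)
cols = ["configuration", "dft_voltage_V", "dft_energy_J", "impedance_ohm"]
print(res.metrics[cols].round(1).to_string(index=False))
```

prints

```
      configuration  dft_voltage_V  dft_energy_J  impedance_ohm
        left_apical          244.8           3.0           34.5
       right_apical          338.0           5.7           35.5
right_apical_svc_cs          203.7           2.1           26.4
```

Moving the can to the right raises this model's DFT from 3.0 J to 5.7 J
(the shock vector misses more of the LV); adding SVC and CS ground coils
more than recovers it (2.1 J, below the conventional left-sided
configuration) while lowering the shock impedance. On the compact desk
phantom absolute energies are roughly half the clinical scale — the
cohort analysis interprets paired within-model contrasts, not absolute
values.

## Analysis pipeline

```bash
python analysis/01_build_cohort.py   --seed 1      # 20 models + manifest
python analysis/02_run_cohort.py    --seed 1      # 200 solves -> metrics.csv
python analysis/03_compare_configurations.py       # paired Wilcoxon tables
python analysis/04_variant_breakdown.py            # per-pathology view
```

Each script states what it found and writes its tables (and boxplots)
under `results/`. Intermediate solves are cached under
`scratch/solve_cache`, so reruns are incremental.

Meshes round-trip through openCARP text format (`.pts`/`.elem`/`.lon`,
0-based indices) and legacy ASCII VTK, so externally deposited cohorts in
those formats can be loaded (with a user-supplied label map) and pushed
through the same pipeline; see `torsodft.mesh.read_mesh` and
`fibers.assign_fibers_laplace`.

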