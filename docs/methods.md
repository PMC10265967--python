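# Methods

`torsodft` predicts the relative defibrillation efficacy of transvenous
ICD electrode configurations by solving the quasi-static shock-field
problem on labeled torso volumes and applying the critical-mass criterion.
This note records the model, the numerical choices, and what the synthetic
cohort does and does not emulate.

## Shock-field model

During a defibrillation shock the torso behaves as a resistive volume
conductor. The extracellular potential satisfies

    div( sigma(x) grad Ve ) = 0,

with Dirichlet values on the electrodes (shock coil at the applied
voltage, all grounds at 0 V) and no-flux conditions on the torso surface.
Every organ region carries a constant isotropic conductivity; the
ventricular myocardium carries the rank-1 anisotropic tensor

    sigma = sigma_t I + (sigma_l - sigma_t) f f^T,

with `f` the local unit fibre direction. The intra/extracellular
eigenvalue pairs are sigma_il = 0.174, sigma_el = 0.625 S/m along the
fibre and sigma_it = 0.019, sigma_et = 0.236 S/m transverse. How these
pairs combine into the *effective* tensor of a static solve is a genuine
modelling choice: the default sums them (`sigma_l = 0.799`,
`sigma_t = 0.255` S/m, the monodomain-bath-equivalent bulk tensor), and an
extracellular-only mode (0.625 / 0.236 S/m) is selectable via
`ConductivityMap(myocardium_mode="extracellular")`. This choice is
prominent because it scales the myocardial field level directly.

Two further conductivities are not tabulated anywhere and are package
assumptions, both configurable: great-vessel walls (aorta, SVC) at
0.25 S/m (atrial-wall-like tissue) and scar at 0.05 S/m (a poorly
conducting, bone-like region). Scar is modelled isotropic and carries no
fibres.

## Efficacy metrics

* **DFT (critical mass):** with the field solved at a 10 V test shock,
  let `g05` be the volume-weighted 5th percentile of ||grad Ve|| over the
  ventricular myocardium (LV + RV wall elements; atrial walls excluded;
  scar elements excluded, since the criterion targets excitable tissue).
  By linearity, `DFT = 10 V * (5 V/cm) / g05`. The percentile is
  volume-weighted rather than node-counted because "95% of the
  myocardium" is a tissue-mass statement; on the uniform lattice the two
  differ little, but the mass reading is the defensible one.
* **Energy:** `E = C V^2 / 2` with C = 100 uF.
* **Impedance:** `R = V / |I_shock|`. The default current extraction sums
  the stiffness-matrix reactions over an electrode's nodes (the
  variationally consistent discrete flux), which conserves charge to
  solver tolerance on any mesh. The alternative surface integration —
  electrode surface triangles times the tissue conductivity times the
  mean of the three recovered nodal fields — is implemented
  (`method="surface"`) and is exact for lattice-aligned electrode faces,
  but on stair-stepped voxel surfaces the jagged normals bias the flux by
  tens of percent, so it is not the default here.
* **Mean E-field:** volume-weighted mean of ||grad Ve|| over the same
  myocardial mass at the 10 V test shock.

## Synthetic cohort

The generator emulates a CT-derived torso cohort with analytic solids
resolved by a painter's algorithm (later solids overwrite earlier ones,
so every interior point has exactly one label). Each model provides:
skin shell, inner-body bath, spine and sternum, lungs, liver, stomach,
spleen, kidneys, and a heart assembled from a truncated prolate LV shell,
an RV shell clipped against the LV (the septum is LV tissue, the RV pool
is the remaining crescent), atrial shells capping the base, aorta and SVC
tubes with conductive lumens, and an aortic-valve conduction path.

Five base anatomies take their LV dimensions from reference values
(LVEDD 42-54 mm, wall 11-13.5 mm); a seeded jitter of a few percent on
torso axes, heart pose and organ placement makes anatomies distinct.
Four cardiac variants per anatomy:

* **healthy** — the base;
* **HCM** — wall thickened homogeneously *into* the blood pool to its
  per-model target (17-22 mm), epicardium preserved, so the cavity
  shrinks;
* **DCM** — cavity dilated to its per-model LVEDD target (62-74 mm) with
  a cosine-squared attenuation profile along the long axis (full dilation
  at the equator, zero at apex and base — the attenuation shape is a
  design choice), equatorial wall thickness preserved;
* **ICM** — a spheroidal transmural scar patch (default radius 25 mm,
  configurable) at an anterior (LAD), lateral (LCx) or inferior (RCA)
  territory position, constrained by construction to the LV wall.

Electrodes: RV shock coil (2 mm diameter, 8 cm) draping along the septal
aspect of the RV cavity at 4.5 mm clearance from the LV epicardium, as a
transvenous lead does, placed apically (spanning down to the apex) or
septally (centred at 50% of the apex-base span);
pectoral can (6 cm diameter, 1.3 cm) tangent to the chest surface under
the skin, left or right; optional SVC ground coil (2 mm x 8 cm) in the
SVC lumen and CS ground coil (2 mm x 4 cm) along a posterior
atrioventricular-groove arc. Configurations not using an electrode simply
omit it — there is no inactive-electrode material, so absence leaves the
conductive medium untouched.

**What the phantom does not emulate:** real segmentation detail
(trabeculation, papillary muscles, vessels beyond aorta/SVC), patient
variability beyond the jitter model, MRI-derived scar shapes (the
parametric patch replaces them), and true torso scale — the default chest
(half-axes 110 x 80 x 155 mm) is compact so that the full sweep runs on a
desk machine. Consequently absolute DFTs land near 230-400 V (2.5-8 J),
roughly half the clinical scale, and only *relative* configuration
effects (orderings, ratios, paired tests) are meaningful. Those
directional effects are exactly what the tests assert.

## Discretization and solver

* **Meshing:** a structured cubic lattice (default h = 2.5 mm) covers the
  torso; cells whose centroid lies inside are split into the six Kuhn
  tetrahedra sharing the cell diagonal. Boundaries are stair-stepped;
  the clinical-resolution alternative (sub-millimetre cardiac elements,
  boundary-conforming surfaces) is reachable by lowering `h` at the
  documented cost. All tets are congruent to six reference shapes, so
  element matrices are precomputed per shape.
* **Electrode capture:** electrode node sets come from point-in-solid
  tests against the electrode solid dilated by h/4. The dilation is the
  effective-radius correction for lattice Dirichlet sets: a staircase
  node set acts as a conductor electrically smaller than its nominal
  extent (a single node behaves as a sphere of radius ~0.3 h), and the
  quarter-spacing dilation restores size consistency — verified against
  the spherical-capacitor closed form, where potential and impedance then
  agree within 2% at h = 1.25 mm. Thin coils additionally keep a 0.8 h
  capture floor so their node chains stay connected.
* **Linear solve:** Dirichlet rows/columns are eliminated, keeping the
  system symmetric positive definite. Systems under 150k unknowns use a
  sparse direct factorization; larger lattice systems use conjugate
  gradients preconditioned by a geometric multigrid V-cycle (trilinear
  prolongation on the even sub-lattice, Galerkin-coarsened operators,
  damped-Jacobi smoothing), to a relative residual of 1e-8. The
  hierarchy is built once per model and sliced per configuration's
  Dirichlet set, so the 10-configuration sweep reuses one setup.
* **Field recovery:** element fields from the linear shape-function
  gradients; nodal fields (needed by the surface current rule) by
  volume-weighted averaging of incident elements, excluding
  electrode-interior elements whose constrained potential would dilute
  the surface field.
* **Fibres:** helix angle linear in transmural depth, +60 degrees at the
  endocardium to -60 at the epicardium (configurable; the cited rule
  family's apex-to-base variation is out of scope). For phantom meshes
  the depth comes from the analytic shells; for imported meshes from a
  Laplace-Dirichlet solve on the wall subgraph (endo 0, epi 1). Fibres
  are tangential to the wall by construction; walls thinner than the
  lattice fall back to circumferential orientation with a warning.

## Statistics

Configurations are compared within model (paired) by the Wilcoxon
signed-rank test: zero differences dropped, mid-ranks for ties, exact
null distribution by DP convolution for n <= 25, normal approximation
with tie and continuity correction above. The exact implementation is
kept in-package because the scipy reference silently switches to the
approximation when ties are present; scipy serves as a cross-check on
tie-free data, and full 2^n enumeration as the oracle for n <= 8.
Results are reported as median (IQR); raw two-sided p-values at the 0.05
level, with no multiple-testing correction (each comparison answers its
own question; this mirrors common practice for small paired cohorts and
is stated rather than hidden).

## Problem sizes used by the tests and the acceptance script

The default desk-scale study is 5 anatomies x 4 variants = 20 models,
10 configurations each (200 solves) at h = 2.5 mm (~0.39M nodes, ~2.2M
tets per model), about 35-40 s per model on one CPU. The sphere oracle
runs at h = 1.25 mm (~0.28M nodes). These sizes were chosen once as the
package's desk conditions; the full-resolution mode is a documented
option, not the default.

## Known limitations

* Stair-stepped boundaries bias thin-shell volumes (atrial walls and the
  3.5 mm RV wall are 1-2 cells thick at the default h); volume-fraction
  convergence is verified for the major regions only.
* The surface-triangle current rule degrades on voxel staircases (see
  above); impedances use the consistent residual flux by default.
* Absolute DFT/impedance values depend on torso scale and the effective
  myocardial tensor choice; only paired, within-cohort contrasts are
  interpreted.
* Biphasic waveform dynamics, membrane kinetics and time-dependent
  (bidomain) effects are outside the model: the criterion acts on the
  static field pattern.
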