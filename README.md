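# sucsim

Finite-element modelling of **subdural cortical stimulation (SuCS)** — electrical
stimulation delivered through disc electrodes placed directly on the cortical
surface, beneath the dura mater — on a parametric volume conductor of the
precentral gyrus.

The package is aimed at computational neurostimulation work: estimating how the
injected current spreads through cerebrospinal fluid, gray matter and white
matter, how electrode configuration (a 5-contact paddle array versus a single
contact) and white-matter anisotropy change the stimulated region, and how
voltage-controlled results convert to current-controlled stimulation.

## Model

Tissue is a passive resistive volume conductor. At stimulation frequencies the
quasi-static approximation holds, so the potential solves the conduction
boundary-value problem

```
∇·(σ ∇V) = 0            in Ω,
V = V₀                  on the driven contact surfaces,
V = 0                   on the grounded reference (slab sides and bottom),
σ ∇V · n = 0            on all other, insulated boundaries,
```

with σ a per-element symmetric positive-definite conductivity tensor (S/m).
White matter may be anisotropic along a fiber direction field: given an
eigensystem `S` (unit eigenvectors, longitudinal first), the tensor is
`σ = S diag(σ_long, σ_trans, σ_trans) Sᵀ`, with eigenvalues from either

- **volume-constraint normalization** of diffusion eigenvalues,
  `σᵢ = σ_iso · dᵢ / (d₁d₂d₃)^{1/3}` (determinant preserved at `σ_iso³`), or
- a **fixed longitudinal:transverse ratio** `r ∈ {2, 5, 10}`,
  `σ_long = r^{2/3} σ_iso`, `σ_trans = r^{-1/3} σ_iso` (same constraint),

with `σ_iso = 0.126 S/m` for white matter. Anisotropy strength is summarized by
the fractional anisotropy FA of the eigenvalues.

The solver uses first-order tetrahedral elements on a deterministic structured
hex-to-tet mesh; boundary currents are recovered with the variationally
consistent (reaction) flux. From one solve at 1 V the package derives:

- **impedance** `Z = V₀ / I` and the voltage↔current conversion (Ohm's law),
- **effective volume** — gray/white-matter volume with `|J| ≥ 2.5 A/m²`
  (the motor current-density threshold, MCT),
- **effective penetration depth** — distance from the contact centre, along
  the inward normal, to the farthest suprathreshold point,
- full amplitude sweeps (0.5–5 V in 0.5 V steps; 1–15 mA in 2 mA steps) by
  linear rescaling, without re-solving.

## Worked example

`examples/04_stimulation_metrics.py` solves a single 4 mm contact at 1 V on a
coarse slab and sweeps the voltage grid:

```
single 4 mm contact on the slab: impedance 126.7 ohm, output current 7.89 mA at 1 V
 amplitude  effective_volume_cm3  effective_depth_cm  output_current_mA
     0.500                 1.003               0.786              3.947
     1.000                 3.836               1.042              7.895
     ...
     5.000                54.454               3.053             39.475
```

Reading: at 1 V the model draws 7.89 mA through 126.7 Ω; the current density
exceeds the 2.5 A/m² motor threshold in 3.8 cm³ of gray/white matter, reaching
1.0 cm below the contact. Volume and depth grow monotonically with amplitude.
The other examples build the mesh and paddle (`01`), compare anisotropy models
(`02`), validate the solver against closed-form impedances (`03`), and contrast
paddle/single contacts and isotropic/1:10 white matter (`05`).

A thin CLI wraps the same pipeline:
`sucsim sweep config.yaml --outdir run/` writes a per-amplitude summary CSV, a
VTU field export, the archived config and a run log; other verbs:
`build-mesh`, `metrics`, `convergence`, `compare`.

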