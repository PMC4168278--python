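# Methods

## Geometry

The volume conductor is an extruded slab standing in for the region around the
precentral gyrus: a rectangular box (default 60 × 60 × 40 mm) with, from the
top down, a cerebrospinal-fluid (CSF) layer, a folded gray-matter (GM) sheet,
and white matter (WM). The fold is a smooth cosine-walled gyrus/sulcus profile
in the x–z plane, extruded along y: a flat crown plateau of `gyral_width`
(default 12 mm), walls descending `sulcal_depth` (15 mm) over half a
`sulcal_width` (3 mm) on each side, periodic with period
`gyral_width + sulcal_width`. The GM sheet is a constant vertical offset of
`gm_thickness` (2.5 mm) below the pial surface; the CSF layer above the crowns
is `csf_thickness` (2 mm) thick, and the sulci are CSF-filled. The exact crown
rounding and wall curvature of a real precentral gyrus are not reproduced; the
profile is an idealized stand-in with typical adult dimensions, and all
parameters are overridable.

Subdural contacts are 4 mm discs on the top surface, driven as equipotential
patches (no metal volume, no contact impedance); the 5-contact paddle is a
quincunx with the four corner contacts 10 mm (centre-to-centre) from the middle
contact, all driven together in voltage mode. There is no explicit dura layer:
the contacts are subdural by construction. The side and bottom surfaces of the
slab are grounded and play the role of the distant unipolar return; all other
boundaries are insulated.

## Meshing

Meshes are structured tensor-product hexahedral grids subdivided into 6
tetrahedra per cell (Kuhn triangulation): deterministic, conforming, exactly
tessellating the box, and with non-obtuse elements (so the discrete maximum
principle holds for isotropic conductivity). Region labels are assigned from
element centroids.

Two mesh-design choices matter for accuracy:

- the z grid conforms to the two flat interfaces under the crown (the pial
  plane and the GM/WM plane), so changing resolution never moves those
  material boundaries;
- the vertical spacing is graded toward the contact surface — CSF segment at
  `h/4`, GM segment at `h/2`, deep WM at `h` (default `h = 0.8 mm`) — because
  the disc-edge field is singular and the thin superficial layers carry the
  steepest gradients. Without this grading the near-rim solution (and the
  impedance itself) is visibly under-resolved at desk-scale element counts.

Electrode discs are discretized two ways, deliberately distinct: the *patch*
(contact area, current-integration surface) is the set of top facets whose
centroids fall inside the disc, while the *Dirichlet set* is the top-surface
nodes strictly inside the disc. Constraining every vertex of the selected
facets would bias the effective disc radius outward by O(h); with in-disc
nodes the half-space spreading-resistance benchmark converges to the analytic
value (−2.8 % at the default resolution, +0.4 % refined).

## Solver

First-order (P1) tetrahedral elements; element tensors are checked for
positive definiteness at assembly. Dirichlet constraints are enforced by
symmetric row/column elimination, so the reduced system stays symmetric
positive definite. Systems up to 40 000 unknowns are solved directly
(SuperLU); larger ones use Jacobi-preconditioned conjugate gradients at a
relative residual of 1e-8 with fixed ordering, making results run-to-run
deterministic. Coordinates are kept in mm with σ in S/m, so the stiffness
matrix has units of 10⁻³ S and `K·V` yields nodal currents in mA; electric
field and current density are converted to V/m and A/m² explicitly.

Boundary currents use the variationally consistent flux (the stiffness
reaction at constrained nodes), which is the Galerkin surface integral of
`J·n`: exact for linear fields and charge-conserving to solver tolerance. A
raw per-facet midpoint integration of the piecewise-constant element `J` is
available as an independent cross-check.

Validation oracles (in `sucsim.synthetic`):

- homogeneous bar, `R = L/(σA)` — exact to round-off (patch test);
- 4 mm disc on a half-space block, `R = 1/(4σa)` — the default block extends
  40 disc radii in every direction on a geometrically graded grid (0.4 mm near
  the disc, ratio 1.3 outward), since the grounded-truncation error of the
  analytic comparison scales like `2a/(πL)`.

## Conductivity

Isotropic defaults (S/m): WM 0.126, skull 0.01, scalp/body 0.465 (standard
model-family values); GM 0.276 and CSF 1.65 are literature defaults chosen
here (they are not fixed by the model family) and are overridable. White
matter anisotropy uses the volume-constraint convention throughout: both the
normalized and fixed-ratio models preserve `det σ = σ_iso³` per element, so
anisotropy redistributes conduction along the fibers without changing the
local "amount" of conductivity. Whether the fixed-ratio convention should
instead pin one eigenvalue at `σ_iso` is genuinely ambiguous in the source
material; the volume-preserving form is isolated in
`fixed_ratio_eigenvalues` so the convention can be swapped in one place. The
transverse eigenvectors are an arbitrary orthonormal completion (the two
transverse eigenvalues are equal, so the tensor is frame-independent about
the fiber axis).

## Synthetic fiber fields

The generator stands in for what a DTI pipeline would supply and covers every
WM element deterministically from a seed (default 20140917):

- `uniform` — constant direction;
- `u_fiber` — an idealized corona-radiata fan: the direction tilts about the
  extrusion axis by `45° · sin(2π(x − x_crown)/period)`, i.e. vertical under
  the crown and the sulcal floor, ±45° on the walls. The raw tangent field of
  the steep cosine fold changes direction too fast between neighbouring
  elements at desk-scale resolution; the fan is smooth by construction (worst
  neighbour jump ≈ 15° at h = 0.8 mm);
- `random_smooth` — a few low-order random Fourier modes, normalized.

Raw diffusion eigenvalues attached for the normalized model have the synthetic
prolate shape (1.2, 0.4, 0.4)·10⁻³; only their ratios matter after volume
constraint. None of this reproduces real tract anatomy (no corpus callosum or
internal capsule); passing tests demonstrate correctness of the machinery, not
anatomical fidelity of any particular fiber map.

## Metrics

The motor current-density threshold (MCT) defaults to 2.5 A/m², a value
established for motor cortex at 50 Hz; the 50 Hz qualifier is metadata — the
solver is quasi-static. Effective volume counts gray- and white-matter
elements with `|J| ≥ MCT` (inclusive at equality; CSF is excluded even though
it carries high current density, since the measure represents excitable
tissue; the eligible set is configurable). Effective depth is measured from
the middle contact's centre along the inward normal, as the farthest
suprathreshold point on the ray; the ray is resolved into exact element
crossing intervals (equivalent to crossing-plus-0.1 mm sampling for piecewise
constant `J`). A single threshold is used everywhere; region-dependent
thresholds and neuron/axon cable models are out of scope.

Both stimulation modes come from the 1 V solve by linearity: voltage mode
scales the field by the amplitude; current mode scales by
`I_target / I(1 V)`. Sweeps therefore cost one linear solve per configuration,
and the suprathreshold set at scale `k` is `{|J_1V| ≥ MCT/k}`.

## Convergence study

The refinement study multiplies the z-subdivision counts per segment by a
factor (default pair 1.0, 1.7 — about 1.7× the elements), keeping the x–y
grid, and with it the electrode Dirichlet patch, identical between levels, and
keeping the grid conforming to the flat interfaces. This isolates solution
convergence from electrode- and interface-re-discretization, the analog of
refining a boundary-conforming mesh around fixed electrode surfaces. The
coarse solution is linearly interpolated at fine nodes and the maximum
absolute difference is reported as a percentage of the applied voltage. On the
default slab with a single contact at 1 V this measures ≈ 0.5 %, with an
impedance drift of ≈ 0.2 % between levels.

## Numerical choices and degenerate inputs

- Threshold comparisons are inclusive (`≥`).
- Tie-breaks in electrode facet selection are geometric (centroid strictly
  inside the disc, with a 1e-12 relative tolerance at the rim for nodes).
- Empty suprathreshold sets give volume 0 and depth 0; a ray that misses the
  mesh, an empty electrode patch, an empty reference, overlapping contacts,
  non-positive eigenvalues, non-orthonormal frames and non-SPD tensors all
  raise with explicit messages.
- The discrete maximum principle is monitored with a 1e-6·V₀ tolerance; the
  structured non-obtuse elements keep isotropic solves within it. Strongly
  anisotropic tensors can in principle overshoot slightly; the helper
  `max_principle_violation` reports the excess.
- Problem sizes: the default slab solves ~2.0 M tetrahedra (~350 k nodes) in
  well under a minute per configuration; tests and examples use coarser
  desk-scale variants of the same geometry.

## Known limitations

- The slab is a deliberately simplified stand-in; results overestimate
  stimulation effects relative to realistic head/upper-body anatomy (the
  geometry family this model descends from shows exactly that bias).
- Quasi-static, purely resistive: no capacitive or electrode-interface
  effects, no frequency dependence.
- Structured meshing cannot conform to the curved sulcal walls; labels there
  are centroid-sampled, so wall interfaces carry O(h) geometric noise.
- The MCT activation criterion is a passive current-density threshold, not a
  neuron model; absolute volumes/depths should be read comparatively.
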