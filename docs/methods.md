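# Methods

## Scope and scenarios

`pfasim` is a forward model of bipolar-catheter pulsed-field ablation (PFA)
on *synthetic* tissue scenarios.  Patient-specific atrial geometry (CT-derived
meshes, rule-based fiber annotation) is deliberately out of scope: the
physical effects of interest — fiber-aligned lesion shaping and the
anisotropic-vs-isotropic (AC vs IC) comparison — are local to the catheter,
so a flat myocardial patch isolates them at desk scale.

Each scenario is a myocardial slab of homogeneous thickness (default 2.4 mm,
the mean human left-atrial wall) under a blood pool, with a straight
two-electrode catheter lying parallel to the endocardium: 7 F diameter
(1 F = 1/3 mm), 2 mm electrodes separated by a 2.5 mm plastic insulator,
pressed 0.5 mm into the tissue.  The catheter is modeled as a flat-ended
cylinder rather than a capsule: the ends sit far from the field region, and
the flat cylinder admits an exact slab-minus-cylinder-segment volume formula
used as the meshing oracle.  An "ostium" variant punches a trans-mural
circular hole beside the catheter, emulating a pulmonary-vein antrum.

Fiber fields are parametric per-element unit vectors: `UNIFORM` (in-plane at
an angle to the catheter), `CIRCUMFERENTIAL` (tangents of circles around a
given axis, as around a vein ostium), and `CROSSING_BUNDLES` (two oblique
uniform fields blended across a divide, as where epicardial and endocardial
bundle systems diverge on the posterior wall).  Transmural fiber rotation is
not modeled.

## Meshing

A structured hexahedral grid (default 400 µm edge, the resolution regime
standard for this problem class) with element-wise region assignment by
centroid classification against the analytic solids.  This is deliberately
dependency-light and byte-reproducible; the cost is a staircase
representation of the cylinder, whose consequences are discussed under
*Limitations*.  Region volumes agree with the closed-form CSG volumes to
0.04% at the 0.6 mm reference resolution and converge O(h).

## Conductivity model

Anisotropy split: sigma_l = 2 R sigma_i / (R+1), sigma_t = 2 sigma_i / (R+1),
so the longitudinal/transverse pair has ratio R and mean sigma_i.  Four
groups (R = 1.429, 3.75 for normal, 4.98, 6.25 for fibrillating myocardium)
share sigma_i = 0.0537 S/m, which is also the isotropic (IC) baseline.

Electroporation raises conductivity with the local field magnitude through a
logistic sigmoid centered at 58 kV/m (slope 3 kV/m, shift factor 10) from the
pre-poration baseline to sigma_1 = 0.281 S/m.  In AC mode the sigmoid is
applied *independently to sigma_l and sigma_t*, each converging to the single
scalar sigma_1 — post-poration tissue is treated as isotropic, consistent
with conductivity rising toward a common high-frequency-like value once the
membranes are porated.  The alternative (scaling the whole tensor by
sigma(E)/sigma_0, preserving R at every field level) was implemented and
rejected: on the slab scenarios it *reverses* the AC-vs-IC volume ordering
(anisotropic lesions become smaller, decreasingly so in R), contradicting the
qualitative behavior this package exists to reproduce.

A consequence worth stating plainly: because both principal values collapse
to sigma_1 above the ~50–70 kV/m transition band, and the 100 kV/m lesion
threshold lies *above* that band, the lesion interior is effectively
isotropic in both modes.  On a flat slab the AC-vs-IC differences are then
small in magnitude (0.02–0.4% in volume, 0.002–0.1 mm in extents at
1000–2000 V) though strictly systematic: AC > IC in every cell, growing
monotonically with R, with the lesion elongated along the fiber axis.  Large
percentage differences of the kind reported on patient anatomies require
curved thin walls and heterogeneous fiber fields interacting with the
sub-threshold anisotropic far field; a slab cannot and does not reproduce
their magnitude, only their sign structure.

Conductivity is memoryless (re-evaluated from the instantaneous |E|), blood
(0.99 S/m), electrode metal (4.6e6 S/m) and catheter plastic (1e-5 S/m) are
constant, and electroporation applies to myocardium only.

## Field solve

Trilinear hexahedral FEM with 2×2×2 Gauss quadrature; E, J, Q piecewise
constant per element (centroid gradient).  All electrode-cell nodes carry
Dirichlet values (amplitude on the left electrode, 0 on the right), which
renders the metal exactly equipotential; electrode elements are excluded from
assembly.  All other boundaries are natural (zero flux).

The sigma(E) nonlinearity is solved by Picard iteration with **Aitken dynamic
under-relaxation** (seed 0.7, clipped to [0.05, 1]).  A fixed relaxation
factor was tried first and stalls in a persistent two-cycle — elements in the
steep sigmoid transition flip between branches, with a residual plateau
proportional to the relaxation factor — while the Aitken secant update
annihilates the cycle and converges to the 1e-6 relative-change tolerance in
14–23 iterations on every reference case.  After convergence the system is
re-assembled once at the converged field so the stored (V, E, sigma, Q) are
mutually consistent to machine precision.

Linear systems: sparse LU below 20k free unknowns; above that, warm-started
Jacobi-preconditioned conjugate gradients (relative tolerance 1e-10) — on
the 30k-node reference slab this is ~70× faster than sparse LU, whose fill
is prohibitive for 3D operators.

Electrode current is the discrete reaction sum of K·V over the electrode's
Dirichlet nodes — the FEM-consistent surface integral of J·n; left and right
currents cancel to ~1e-13 relative on converged solutions (the 0.5%
conservation bound is enforced in tests).

Verification oracles: exact 1-D parallel-plate fields and currents; a
manufactured monopole solution (exact V0·a/r trace imposed on a voxelized
inner electrode and the outer box, interior reproduced within 2% — chosen
over a grounded outer box, which at desk scale sits close enough to distort
V by ~15% at r = 5a, and over a constant-potential staircase sphere, which
would alias the electrode radius at O(h)); and the anisotropic-to-isotropic
coordinate-stretch equivalence, which the hexahedral stiffness satisfies
identically (agreement ~1e-14, bound 1%).

## Pulse protocol

Defaults: 5 trains × 8 biphasic pulses, 100 µs pulse width and interval
(50% duty within a train), 198.4 ms between trains — exactly 1 s total with
4 ms cumulative on-time.  Amplitudes 1000/1500/2000 V for field metrics;
thermal runs default to 1000 V.  Because sigma(E) is memoryless and Q is
quadratic in V, one static solve serves every pulse; polarity alternation
affects only waveform plots.

## Bioheat stepping

Backward-Euler stepping of the Pennes equation with the gated source
(capacitance-lumped trilinear FEM diffusion + first-order upwind advection on
the structured node lattice).  Perfusion and metabolic terms are omitted
(negligible against the pulsed Joule source).  Blood motion is a prescribed
divergence-free profile (uniform plug, default 0.1 m/s — a typical mean
atrial velocity — or a linear shear obeying no-slip at the endocardium); node
velocities are zeroed on any node touching a non-blood element, enforcing
no-slip at interfaces.  Inflow nodes are held at 37 °C; all other boundaries
are insulated.  Default steps: 25 µs during trains, 2 ms during train
intervals; each step's source is weighted by its exact overlap with the
on-intervals, which makes the injected energy exact and yields a
machine-precision enthalpy balance in insulated runs.  `GATED` mode steps
the true schedule; `DUTY_AVERAGED` applies the 0.4% duty-scaled source
continuously.  A Courant guard (advective number ≤ 20) rejects step sizes
that would degrade the upwind scheme's accuracy.

Helper: Reynolds number rho·u·D/mu with a laminar flag (Re < 2000), for
checking that prescribed velocities are consistent with laminar atrial flow
(blood mu = 2.1e-3 kg/m/s).

## Lesion metrics

Element |E| is averaged to nodes (restricted to myocardium), giving a
piecewise-linear field on the Kuhn 6-tetrahedra decomposition of each
hexahedron (face-conforming across the structured grid).  Ablation volume
integrates the supra-threshold region exactly per tetrahedron (corner-cut
products for 1/3 vertices above, an exact convex-wedge decomposition for
2 above — validated against Monte-Carlo sampling of the same interpolant);
surface area does the analogous exact triangle clipping on the tagged
endocardial interface; the isosurface comes from marching tetrahedra, with
per-axis extents as max−min of its vertex coordinates (scenario axes; the
threshold is strict, default 1000 V/cm = 1e5 V/m).  Paired AC-vs-IC
differences carry the significance conventions: 1 mm for extents, 5% for
area/volume, 4 °C for temperature; aggregates are mean ± sample SD.

## Reference problem sizes

The test suite's reference slab uses the minimum admissible 26.4 mm lateral
extent at 0.6 mm resolution (27k cells) so the full four-group ×
three-amplitude AC/IC sweep solves in about a minute; geometry oracles also
run at 0.4–0.5 mm, and the refinement study spans 0.8→0.4 mm.  These sizes
are the package's validation choices; the physics modules accept any
admissible resolution.

## Known limitations

* **Staircase geometry.**  Voxelized cylinder surfaces create artificial
  edge corners where |E| is locally exaggerated (~4.8e5 V/m at 0.6 mm
  resolution, 1000 V).  Threshold metrics are insensitive (the lesion
  boundary lies in the smooth far field), but peak temperatures are not:
  together with the genuinely high field in the 2.5 mm tissue bridge beneath
  the insulator (~2–2.6e5 V/m, i.e. an adiabatic rise of tens of °C over the
  4 ms on-time) and the stagnant no-slip blood layer over the gap, the slab's
  myocardial maximum reaches ~90 °C at 1000 V — hotter than published
  patient-geometry simulations.  Peak-temperature magnitudes from this
  package should be read as scenario-specific, not clinical predictions;
  the AC-vs-IC temperature *difference* (the quantity of interest) is
  robustly insignificant (≪ 4 °C).
* **First-order boundary convergence.**  The ablation volume converges O(h)
  (staircase boundary): increments shrink from ~17% (0.8→0.6 mm) to ~2.7%
  (0.6→0.4 mm), with ~7% between 0.4 and 0.2 mm.  Comparative AC-vs-IC
  statements are far less resolution-sensitive since both modes share the
  identical mesh.
* **Slab extent artifacts.**  On a flat slab the lesion is transmural, so
  the wall-normal extent pins at the wall thickness (its amplitude
  correlation is undefined), and the catheter-axis extent saturates beyond
  the electrode tips (amplitude correlation ~0.98).  Volume and the
  transverse in-plane extent remain freely growing and correlate with
  amplitude at r > 0.99.
* **No CFD.**  Blood velocities are prescribed, not solved; pulsatile
  waveforms and pressure boundary conditions are not emulated.
* No thermal damage integrals (Arrhenius/CEM43), no temperature- or
  frequency-dependent material properties, no dynamic pore models, no
  transmural fiber rotation.
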