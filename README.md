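# pfasim

Forward simulator of catheter **pulsed-field ablation (PFA)** in myocardial
tissue, for computational electrophysiologists studying how the **anisotropic
electrical conductivity (AC)** induced by myocardial fiber orientation changes
lesion size and tissue heating compared with the usual **isotropic (IC)**
simplification.

PFA destroys myocardium by irreversible electroporation: tissue is ablated
where the pulsed electric field magnitude exceeds a threshold (here
1000 V/cm).  Because myocardium conducts ~1.4–6× better along the myocyte
bundles than across them, the field distribution — and therefore the lesion —
depends on the local fiber direction, which most computational PFA studies
ignore.

## Model

On synthetic tissue scenarios (a 2.4 mm myocardial slab with a blood pool and
a two-electrode 7 F catheter pressed 0.5 mm into the endocardium, with
parametric fiber patterns), `pfasim` solves the quasi-static conduction
problem

$$\nabla\cdot(\sigma(\mathbf{E})\,\nabla V) = 0$$

with the pulse amplitude on one electrode and ground on the other.  The
myocardial conductivity is a field-dependent tensor built from the unit fiber
direction $A = (\alpha,\beta,\gamma)$:

$$\sigma_a = \sigma_t I + (\sigma_l - \sigma_t)\,A A^{\mathsf T},
\qquad \sigma_l/\sigma_t = R,\qquad (\sigma_l+\sigma_t)/2 = \sigma_i,$$

where each principal value rises with the local field through the
electroporation sigmoid

$$\sigma(E) = \sigma_0 + \frac{\sigma_1 - \sigma_0}
{1 + 10\,e^{-(|\mathbf{E}| - 58{,}000)/3000}},$$

with $\sigma_0 = 0.0537$ S/m, $\sigma_1 = 0.281$ S/m.  Four anisotropy groups
($R$ = 1.429, 3.75, 4.98, 6.25; normal and fibrillating myocardium) share the
isotropic baseline $\sigma_i = \sigma_0$.  Joule heating
$Q = \mathbf{E}\cdot(\sigma\mathbf{E})$, gated by the biphasic pulse-train
protocol (5 trains × 8 pulses of 100 µs at 50% duty, 198.4 ms between trains,
1 s total), drives a Pennes bioheat solve

$$\rho c\,\partial T/\partial t = \nabla\cdot(k\nabla T) + Q\,g(t)
- \rho_b c_b\,\mathbf{u}\cdot\nabla T$$

with prescribed divergence-free blood velocity profiles.  Lesion metrics
(supra-threshold volume, endocardial surface area, isosurface and its
per-axis extents) and paired AC-vs-IC difference statistics follow.

Numerics: structured hexahedral trilinear FEM with Picard (Aitken-relaxed)
iteration for the $\sigma(E)$ nonlinearity, marching-tetrahedra isosurfaces
and sub-element threshold integrals, implicit upwind bioheat stepping.
Details in [docs/methods.md](docs/methods.md).

## Worked example

```python
from pfasim import (ScenarioConfig, build_slab_scenario, make_fiber_field,
                    ConductivityModel, solve_potential, compute_metrics,
                    total_electrode_current, paired_difference)

cfg = ScenarioConfig(lateral_extent=26.4e-3, resolution=0.6e-3,
                     blood_depth=6e-3)
mesh = build_slab_scenario(cfg)
fibers = make_fiber_field(mesh, "UNIFORM", {"theta": 0.0})

results = {}
for mode in ("AC", "IC"):
    model = ConductivityModel.from_group(4, mode)   # R = 6.25 / isotropic
    sol = solve_potential(mesh, fibers, model, amplitude=1000.0)
    m = compute_metrics(mesh, sol.e_mag, keep_isosurface=False)
    i_left = total_electrode_current(sol, "ELECTRODE_LEFT_SURFACE")
    results[mode] = m
    print(f"{mode}: {sol.picard_iterations} Picard iterations, "
          f"I = {i_left:.3f} A, lesion volume = {m.volume:.2f} mm^3, "
          f"endocardial area = {m.surface_area:.2f} mm^2, extents = "
          f"({m.extent_x:.2f}, {m.extent_y:.2f}, {m.extent_z:.2f}) mm")

d = paired_difference(results["AC"].volume, results["IC"].volume, "volume")
print(f"AC-vs-IC volume difference: {d.percent:+.3f}% "
      f"(significant: {d.significant})")
```

prints

```
AC: 21 Picard iterations, I = 6.690 A, lesion volume = 68.75 mm^3, endocardial area = 24.61 mm^2, extents = (8.38, 6.24, 2.40) mm
IC: 14 Picard iterations, I = 6.693 A, lesion volume = 68.62 mm^3, endocardial area = 24.56 mm^2, extents = (8.36, 6.23, 2.40) mm
AC-vs-IC volume difference: +0.182% (significant: False)
```

The 6.7 A electrode current and the ~69 mm³ lesion at 1000 V are the kind of
numbers a practitioner would sanity-check against bipolar PFA bench data.

The anisotropic lesion is consistently larger and elongated along the fiber
axis (extent 8.38 vs 8.36 mm), with the difference growing with the
anisotropy ratio — though on this flat-slab scenario the effect is far
smaller than on a patient atrium, because above the electroporation
transition both principal conductivities converge to the same post-poration
value (see the methods note).

The same sweep is available from the shell:

```bash
pfasim compare --config run.yaml --output out/
pfasim solve-field --amplitude 1000 --group 2 --mode AC --output out/
```

which writes metrics/paired-difference CSVs and VTK (`.vtu`) field files.

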