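# oculomech

Ocular tissue biomechanics under elevated intraocular pressure (IOP):

* **constitutive** — single/multi-term Ogden hyperelasticity combined with an
  exponential-kernel (Christensen-type) viscoelastic hereditary integral for
  incompressible uniaxial deformation; evaluated with an unconditionally
  stable exact-exponential recursion.
* **tensile** — closed-form forward simulation of uniaxial strip tension
  tests (force–displacement curves at prescribed crosshead rates) plus a CSV
  round trip and an RMS force-error kernel.
* **synthetic** — generators for study-like inputs: noisy multi-rate tensile
  curves for sclera (0.3/3/30/300 mm/s strips, 3.8 × 14.5 mm) and cornea
  (0.3/30 mm/s, 9.5 × 10 mm), synthetic lamina cribrosa (LC) morphometry
  tables, and the packaged 20-eye LC morphometry fixture.
* **inverse** — recovery of the four material constants (α, μ, β, G) from
  multi-rate curves with NSGA-II (one RMSE objective per loading rate),
  Sobol design-of-experiments initialization, log-scaled genotype for the
  decade-spanning moduli, and periodic memetic local-refinement bursts.
* **geometry** — parametric closed eyeball shell: icosphere globe with
  labelled cornea / anterior sclera / posterior sclera / elliptical LC
  regions and heterogeneous per-facet wall thickness; watertightness and
  mesh-quality (scaled Jacobian, minimum angle) reporting; legacy ASCII VTK
  and plain-text mesh I/O.
* **pressurize** — quasi-static equilibrium of the incompressible Ogden
  membrane shell under follower internal pressure at 10/30/60/100 mmHg,
  solved by minimizing total potential energy (elastic energy − p·enclosed
  volume) with an analytic gradient; von Mises equivalent stress/strain
  fields, per-region area-weighted summaries, and a transient ramp mode
  carrying the viscoelastic convolution.
* **report** — pipeline orchestration with YAML config, stage toggles,
  structured logging and a SHA-256 artifact manifest; LC summary statistics.

## CLI

```sh
oculomech simulate-curves --seed 0 --out curves/
oculomech fit --curves 'curves/curve_sclera_*.csv' --tissue sclera --seed 0 --out fit/
oculomech build-mesh --out eye.vtk
oculomech pressurize --mesh eye.vtk --iop 10,30,60,100 --out fields/
oculomech summarize
oculomech run-all --seed 0 --out pipeline_out/
```

## Key defaults and assumptions

* Strain convention for the viscoelastic convolution: engineering strain
  (λ − 1); logarithmic strain available per history.
* The uniaxial stress measure is Cauchy (true) stress; strip force uses the
  incompressible current area A₀/λ.
* Strip thicknesses (not measured inputs): sclera 1.7 mm, cornea 0.8 mm.
* Default tensile campaign amplitudes: peak stretch 1.05 (sclera) and 1.25
  (cornea), reproducing the reported order of peak forces (~16–30 N).
* Eye geometry is a parametric idealization (15 mm globe, 40° corneal cap,
  4.60 × 3.68 mm LC ellipse at the posterior pole, sclera thickness grading
  1.0 → 1.7 mm, cornea 0.8 → 1.0 mm toward the limbus, LC 0.4 mm).
* Steady-state pressurization uses the hyperelastic part only (the viscous
  kernel decays); the ramp mode includes it.
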