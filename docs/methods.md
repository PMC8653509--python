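# Methods

## Physical model

### Radial Darcy flow

The probe is treated as a line source of length L inside an effectively
infinite tissue: water flows radially through the membrane annulus
(r₁ → r₂) and into the tissue annulus it perfuses (r₂ → r₃). For
quasi-steady flow the flux through every cylindrical shell is the same, so
integrating Darcy's law dP/dr = q/(2πrLK(r)) over a piecewise-constant
permeability profile gives

    Δπ = q/(2πL) · [ ln(r₂/r₁)/K_mem + ln(r₃/r₂)/K_tissue ]
       = q · ln(r₃/r₁) / (2πL · K_total),

with K_total the log-weighted harmonic mean of the two permeabilities.
The driving pressure is purely osmotic: the probe fill matches the bath
salt (0.15 mol/L NaCl), so no net ion flux or electrical potential builds
up, and the hydrostatic gradient — measured independently with a needle
transducer at several multiples below the osmotic gradient — is dropped.
`swelling_pressure_from_flux` accepts an explicit hydrostatic offset for
transducer-paired use; it defaults to zero.

We work throughout in a single *hydraulic* permeability K ≡ k/μ
(m⁴ N⁻¹ s⁻¹). The calibration measures this lumped quantity directly, and
the tissue permeability law below is already in hydraulic form, so
viscosity never re-enters the downstream equations. A viscosity constant
(default 8.9 × 10⁻⁴ Pa·s, 0.15 M NaCl at 298.15 K) is exposed only for
converting user-supplied intrinsic (m²) permeabilities.

### Perfused radius and stretch

The perfused annulus volume is equated to the perfused fluid volume,
πL(r₃² − r₂²) = q·t, which assumes the fluid has no time to redistribute
within the 5 min reading (t defaults to 300 s). Because the osmotic load
is applied isotropically (equilibrium dialysis), the stretch entering the
confined-compression permeability law is taken as the radial stretch of a
sphere of constant density: λ = (m_f/m₀)^(1/3) from the wet masses at
excision and after equilibration. No 3D correction is attempted; this
substitution is the model's main structural approximation.

### Tissue permeability law

K_tissue(λ) = 1.59×10⁻¹⁵ · ((λ − 0.2)/0.8)^1.13 · exp(−0.02(λ² − 1)²),
an empirical strain-dependence for bovine NP tissue in confined
compression. It vanishes as λ → 0.2 (pore closure); we raise a hard
`ModelError` at λ ≤ 0.2 rather than clamping, since the law is
non-physical there and such a sample indicates a data problem.

### Gibbs-Donnan chain

With intra-tissue sodium c₊ (mol per litre of total tissue water) and bath
concentration c_ext, Donnan equilibrium (equal ion products) plus
electroneutrality give chloride c₋ = c_ext²/c₊, FCD c_f = c₊ − c₋, total
mobile ions c₊ + c₋, and the ionic swelling pressure
φRT(√(c_f² + 4c_ext²) − 2c_ext), with the NaCl osmotic coefficient
φ = 0.93 applied to internal and external ions alike. Osmolality uses the
dilute-solution identification mol/m³ ≡ mmol/L ≡ mOsm/kg H₂O, and
mEq/g TTW is numerically equal to mol/L TTW for a monovalent ion at water
density; both identifications are exact to the accuracy the rest of the
model works at. A measured c₊ < c_ext (possible under measurement noise)
implies a negative FCD; it is flagged and warned about, not rejected,
so noisy cohorts survive batch processing.

Normalization is to total tissue water throughout. Restricting to
extrafibrillar water would raise every Donnan quantity; no equation-level
treatment is included, and the `hydration` reported is (post-flux wet −
dry)/dry.

## Calibration and instrument conventions

Membrane permeability depends on the applied pressure, so probes are
calibrated in the same PEG solutions used to load the tissue and the
calibration table is keyed on (probe, pressure); a lookup at an
uncalibrated pressure falls back to the probe's nearest calibrated
pressure with a warning. Probes whose permeability sits far from the
cohort median can be flagged (`CalibrationTable.outlier_flags`) but are
never auto-excluded. The meniscus displacement rate is estimated by
ordinary least squares over all frames (an endpoint finite difference is
available via `slope_method: endpoints`); flux is slope × tubing
cross-section, with flux *into* the tissue positive.

PEG osmotic pressure is a virial polynomial in mass concentration with no
constant term. The published coefficient source is not reproduced here;
the shipped default set is a least-squares cubic through the five
(concentration, applied pressure) design points and is explicitly
non-authoritative — supply measured coefficients via config, or applied
pressures directly per calibration record, for quantitative work.

## Forward simulator

`simulate_cohort` emulates the study design: 5 applied pressures
(0.03/0.10/0.21/0.37/0.57 MPa from 5–25 % g/mL PEG) × 5 samples, seeded.
Generating choices, fixed as the package's reference conditions:

- **Equilibrium truth.** Each sample's swelling pressure equals its
  applied pressure, so true osmolality = (π_bath + P)/RT and the
  concordance between applied and recovered pressure is 1 by
  construction; recovered shortfall measures pipeline noise.
- **Ionic-only swelling.** True sodium is backed out of the true
  osmolality through the Donnan product, so the ionic route carries the
  whole swelling pressure and Donnan fractions are 1 in truth.
- **Hydration.** Linear in pressure through (0.03 MPa, 4.96) and
  (0.57 MPa, 1.64) g H₂O/g dry; excision hydration 5.2, making stretch
  ratios ≈0.99 at the lowest load and ≈0.75 at the highest.
- **Membrane permeability.** 2.0 → 0.8 × 10⁻¹⁸ m⁴ N⁻¹ s⁻¹, declining
  linearly with pressure. The scale keeps the perfused water at ~0.1–0.2 %
  of total tissue water over 5 min, consistent with a negligible-perturbation
  measurement; each sample gets its own probe, calibrated at its group's
  pressure, so calibration errors are independent across samples.
- **Noise.** Mean-one multiplicative lognormal on every flux reading
  (rel. SD 0.05, applied to calibration and each triplicate), on sodium
  (0.08), and on weighings (0.005); excision mass lognormal around 0.20 g
  (rel. SD 0.15). Only group-level spreads of real cohorts are known, so
  the split across sources is a modelling choice exposed as config knobs.

The simulator solves the implicit forward problem (r₃ depends on q,
q on r₃) by Brent root finding bracketed between zero and the
membrane-only flux, to ~1e-14 relative; the sequential inference chain is
its exact inverse, and the noise-free round trip is identity to better
than 1e-9 (tested). What the simulator does *not* emulate: non-ionic
(matrix/configurational) swelling, transient osmotic kinetics, spatial
heterogeneity within a sample, probe insertion damage, and
degeneration-dependent composition — so passing recovery tests show the
*inference machinery* is unbiased under the stated noise, not that the
model assumptions hold in real tissue.

## Statistics

Group tables report mean ± SD per applied pressure (SD set to 0 and
flagged for n = 1); the Δ-osmolality column is per-sample flux osmolality
minus the 0.21 MPa group mean. Linear/quadratic fits use ordinary least
squares with R² and the slope's t-test p-value (a constant response is
special-cased to slope 0, R² = 0). The diurnal extrapolation evaluates a
linear osmolality-vs-pressure fit at 0.2 and 0.6 MPa; the CLI default
fits per-sample data, with `--group-means` switching to group means.
Lin's concordance correlation is implemented directly from its definition
with population (1/n) moments — relevant at these small n, where the
(n−1) convention differs visibly. Spearman correlations use average ranks
for ties. No multiple-testing correction is applied. A two-way
(method × pressure) ANOVA of osmolality is available behind `--anova`;
post-hoc group lettering is not produced.

## Numerical conventions and edge cases

- Printed-table rounding is half-up (concentrations 2 dp, osmolalities
  integer); comparisons of a function-of-means against a mean-of-function
  use a 3 % tolerance, since the Donnan chain is nonlinear.
- All internal computation is SI; unit conversion only at I/O boundaries.
- Forward-flux root finding: relative tolerance 1e-14, failure to bracket
  raises `SolverError` with diagnostics.
- Degenerate inputs raise typed errors (`InvalidInputError`,
  `GeometryError`, `ModelError`, `CalibrationLookupError`) rather than
  returning sentinels; CSV readers collect per-row failures with file line
  numbers and continue.
- Outputs embed the config hash, package version and constants in JSON
  sidecars and contain no timestamps, so identical inputs re-run
  byte-identically (plots excepted).

## Scope and limitations

The quadratic sodium-vs-pressure and power-law FCD-vs-pressure fits are
available as generic fitting operations but are not validated reference
relations. Per-sample test sizes follow the 5 × 5 reference design; the
seeded recovery test asserts each group mean within 2 SEM of truth, a
t(4 df)-coverage event per group, and is run at the generator's default
seed. Transient diffusion–convection inside the tissue, anisotropic
permeability, annulus-fibrosus parameters, and EFW renormalization are out
of scope.
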