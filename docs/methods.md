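# Methods

## Scope and model

`deqct` quantifies spongiosa composition from two reconstructed CT volumes
acquired at different tube voltages.  Everything happens *after*
reconstruction, in Hounsfield units: no sinogram physics, no spectrum or
detector model.  The central object is the per-electron attenuation relative
to water,

    μ̄_m*(E) = μ̄*(E) / ρ_e*,

which for a fixed beam is modeled as a linear blend between water-like
(μ̄_m* = 1) and a pure power-law photoelectric-like term:

    μ̄_m*(E) = α(E) (1 − Z_eff*ⁿ) + Z_eff*ⁿ.

`n` is shared by both beams; `α(E)` is one scalar per beam.  Water satisfies
the identity μ̄_m* = 1 for every α, which anchors the whole relative system.
`Z_eff,H2O` is always computed from the water composition with the current
`n` — never hard-coded — so the identity holds for any exponent.

The decomposition stage treats a VOI as an immiscible mixture of 2–3 basis
materials (default: hydroxyapatite for bone mineral, peanut oil for yellow
marrow, a 50/50 water/pHEMA mass mixture for red marrow) and solves the
exact linear system of the two beam equations plus closure.

## Elemental cross sections

The attenuation table (Z = 1–30, 10–150 keV, 2 keV steps) is generated by
the package's own engine and shipped as text
(`src/deqct/data/elemental_mu_rho.tsv`, regenerable with
`scripts/generate_element_table.py`):

* **Photoabsorption** from the Cromer–Liberman imaginary anomalous factor
  f''(E) (`gemmi`), σ = 2 rₑ λ f''.
* **Coherent** scattering: Thomson cross section weighted by the squared
  IT92 atomic form factor.  The IT92 parametrization's constant term (for N
  and Cl, a near-zero-width Gaussian paired with a negative constant)
  represents core electrons and must decay at large momentum transfer; all
  terms with Gaussian width b < 0.1 are folded into a single asymptote damped
  by a hydrogenic 1s profile with screened charge Z − 0.3.
* **Incoherent** scattering: Klein–Nishina weighted by an incoherent
  scattering function S(q, Z) = Z (1 − (f/Z)^p).  The single exponent
  p = 1.54 was calibrated once against reference water attenuation values;
  independent hydrogen, aluminium and copper anchors then agree to ≤ 0.5%
  (mostly ≤ 0.2%) over 30–150 keV, and an ICRU-44 cortical-bone mixture to
  ≤ 0.4% over 50–100 keV.  These anchor values are frozen in
  `tests/test_xs.py`.

Energies below 10 keV are excluded: every K edge for Z ≤ 30 lies below, so
the tabulated region is smooth and log-log-linear interpolation between grid
points is essentially exact.  Elements above Z = 30 are out of scope (the
look-up inversion never needs them).

Atomic weights come from `gemmi`'s standard table.

## Calibration

* **n-fit** (theoretical): energies 50–100 keV step 1, n-grid 2–4 step 0.01,
  origin-constrained least squares per energy, total squared residual summed
  over energies and materials; ties break to the smallest n.  The default
  reference set is the seven-insert calibration phantom below.  On that set
  the residual curve is convex with a sharp minimum at n = 3.20.
* **α-fit** (measured): HU → μ̄_m* via (HU/1000 + 1)/ρ_e* with each
  material's nominal ρ_e*, then the same origin-constrained regression once
  per beam.  The regression has no intercept by construction (the fit
  variable already subtracts Z_eff*ⁿ).  Standard errors are reported with
  coverage factor k = 1.

The bundled benchmark (`data/dual_kvp_benchmark.tsv`) holds measured
μ̄_m* values of the seven inserts at 80/130 kVp on a SPECT/CT system; fitting
it yields α = 0.8975 ± 0.0011 (80 kVp) and 0.9492 ± 0.0006 (130 kVp), and the
forward model reproduces all fourteen measured cells to within ±1.6%.

## Phantom materials

The vendor's exact insert formulations are proprietary, so the defaults are
constructed from open data and are deliberately overridable via a YAML
material config (`data/default_materials.yaml` documents the schema):

* **Soft-tissue inserts** (adipose, breast, muscle, liver): ICRU Report 44
  real-tissue elemental compositions — the radiological targets the
  tissue-equivalent plastics are engineered to match.
* **Bone inserts**: the vendor-nominal description taken literally —
  hydroxyapatite (Ca₁₀(PO₄)₆(OH)₂, 3.0 g/cm³) at 200/800/1250 mg/cm³ in a
  water-equivalent base, at insert densities 1.16/1.53/1.82 g/cm³; the
  hydroxyapatite mass fraction is concentration/density.
* **Marrow surrogates**: peanut oil approximated by a triolein-like
  triglyceride (C₅₇H₁₀₄O₆, 0.915 g/cm³); pHEMA as its monomer composition
  (C₆H₁₀O₃, 1.15 g/cm³); the water/pHEMA basis is a 50/50 mass mixture at
  the volume-additive density 1.07 g/cm³.

Because the true insert chemistry is unknown, a fraction of a percent of
systematic disagreement against published calibrations must be expected;
with these defaults the fitted slopes sit 0.3–0.6% below the values reported
for the physical phantom — within the forward model's own ±2% envelope but
occasionally outside a ±0.005 absolute band on individual constants.

## ρ/Z estimation

The look-up table has exactly 30 rows (integer Z).  F(Z) is non-monotonic
near hydrogen/helium, so inversion is restricted to the largest monotone
sub-range containing water's Z_eff and reported with the table; spongiosa
targets (Z_eff ≈ 6–17) sit comfortably inside.  Interpolation is
piecewise-linear in both directions (F → Z and Z → μ̄_m,low*), which is
exactly invertible on monotone segments.  The discretization to integer-Z
nodes bounds the noise-free round-trip error at < 0.5% over Z_eff ∈ [6, 20];
that, not numerics, is the method's floor.  Out-of-range ratios raise an
error naming the admissible interval; `clamp=True` pins instead (intended
for noisy voxelwise maps).  Effective mass density comes from an ordinary
least-squares line fitted to (ρ_e,eff*, known density) pairs.

## Decomposition details

* The closure ΣVF = 1 is substituted, never fitted: a 3-material VOI gives
  an exact 2×2 solve, a 2-material VOI an overdetermined 1-unknown least
  squares over the two beam equations.
* **Fallback**: if any fraction is below −1e-10, the most negative member is
  pinned to zero and the reduced system re-solved, repeating until all
  fractions are non-negative (a single member left means VF = 1).  Pinned
  members are recorded.  The expected physiological pattern — no fat in a
  dense femoral head, no free water in a fatty shaft — emerges naturally on
  noisy data.
* **Conditioning**: the condition number of the stacked system is reported;
  a warning is emitted above 1e3 and an error above 1e12.  The fat and
  water surrogates are nearly collinear in (μ̄_low*, μ̄_high*), which makes
  the fat/water split the noise-amplifying part of the three-material
  problem (condition number ≈ 360 for the default basis).
* **C(Z)**: the beam-hardening factor multiplies the whole mixture sum at
  both beams, is exactly 1 for Z_eff ≤ 10, and defaults to identity above.
  The literature correction's functional form is not openly documented, so
  C ships as a configurable piecewise-linear curve plus
  `calibrate_c_curve`, which fits per-sample factors on references of known
  composition by minimizing the mixture-equation residual.
* **Measured basis**: alternatively, basis attenuations come from
  calibration vials — a single vial directly (HU/1000 + 1), or a
  hydroxyapatite concentration series extrapolated linearly to the pure
  mineral density (3000 mg/cm³), whose intercept doubles as the
  suspending-base member.
* BMD reference density (3000 mg/cm³) is a named constant, configurable per
  call.

## Synthetic phantoms

The generator operates at the reconstructed-HU level, exactly where the
estimator lives: region HU = forward parametrization of the mixture, plus
independent per-beam Gaussian HU noise (seeded `numpy` generator; scenes
without an explicit seed do not exist).  Default conditions mirror the
physical experiments: spine-phantom spongiosa at 50/100/200 mg/cm³
hydroxyapatite in water; vial racks with oil, water and 100/200/300 mg/cm³
mineral suspensions; femur-like head/neck/shaft mixtures
(0.22/0/0.78, 0.14/0.41/0.45, 0.01/0.99/0 bone/fat/water); 10 HU noise where
noise is studied.  What the generator does **not** emulate: beam-hardening
residuals (unless injected via C or HU offsets), partial-volume borders,
correlated noise between beams, scatter, and real trabecular texture — so
passing tests demonstrate correctness of the estimator chain, not clinical
accuracy on heterogeneous bone.

Problem sizes used in the shipped tests: 12³-voxel regions for identities
and workflows, 40³-voxel regions × 50 seeds for the noise study of BMD bias
(mean bias < 2 mg/cm³ at 10 HU noise).

## Known limitations

* No organic bone-matrix compartment: trabecular bone is reduced to its
  mineral, so part of the matrix is absorbed into the water/fat fractions.
* The fat/water separation degrades quickly with noise (near-collinear
  basis); condition-number reporting makes this visible but not smaller.
* Cross sections carry a few-tenths-percent model error; it largely cancels
  in water-relative ratios but is not zero, and the n-fit minimum position
  is sensitive to sub-percent energy-dependent bias.
* Default insert compositions are stand-ins for proprietary formulations
  (see above); users with vendor datasheets should supply them via config.
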