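# deqct

Post-reconstruction **d**ual-**e**nergy **q**uantitative **CT** for red-marrow
dosimetry: estimate the effective atomic number, effective mass density, and
the volume fractions of bone mineral, water-like (red marrow) and fat-like
(yellow marrow) material in spongiosa from two CT acquisitions at different
tube voltages (80 and 130 kVp by default).

Patient-specific absorbed-dose calculation for the red marrow needs the
patient's own trabecular-bone / red-marrow / yellow-marrow volume fractions to
select the right S values from parametrized skeletal dosimetry models.  This
package implements a phantom-calibrated method that delivers those fractions
from a standard dual-kVp (SPECT/)CT protocol — with **no knowledge of the
X-ray spectrum or detector response**: the entire polyenergetic physics of
each beam is absorbed into two fitted constants.

## The model

All quantities are relative to water (starred).  For a mixture with elemental
mass fractions `w_i`, effective atomic number

    Z_eff = [ Σ w_i Z_i^(n+1)/A_i  /  Σ w_i Z_i/A_i ]^(1/n)

and relative electron density `ρ_e* = ρ_m Σ w_i Z_i/A_i / (ρ_H2O Σ_H2O)`, the
attenuation per electron relative to water at beam E obeys

    μ̄_m*(E) = μ̄*(E)/ρ_e* = α(E) · (1 − Z_eff*ⁿ) + Z_eff*ⁿ ,   Z_eff*ⁿ = (Z_eff/Z_eff,H2O)ⁿ

with `n` and `α(E)` constants of the CT beam.  Calibration has two stages:

1. **n** — minimize, over a grid n ∈ [2, 4] (step 0.01), the summed squared
   residual of the origin-constrained regression of `μ̄_m*(E) − Z_eff*ⁿ` on
   `1 − Z_eff*ⁿ` across reference materials for monoenergies 50–100 keV
   (elemental cross sections via the bundled table).
2. **α(E₁), α(E₂)** — the same regression, once per tube voltage, on measured
   phantom attenuation `(HU/1000 + 1)/ρ_e*`.

Estimation then inverts a 30-row look-up table `F(Z) = μ̄_m,low*(Z)/μ̄_m,high*(Z)`:
a VOI's dual-kVp ratio yields `Z_eff`, the low-kVp column yields `ρ_e,eff*`, a
linear calibration maps it to mass density, and the volume fractions solve

    μ̄_eff,E* = C(Z_eff) · Σ_X VF_X μ̄_X,E*   (both beams),   Σ_X VF_X = 1

exactly, with a configurable beam-hardening factor `C(Z)` (identity ≤ Z 10)
and a fallback that pins negative fractions to zero (a VOI without fat, say,
lands outside the basis simplex under noise).  Bone mineral density is
`BMD = VF_bone × 3000 mg/cm³`.

Elemental photon cross sections (Z = 1–30, 10–150 keV) ship as a generated
table computed by the package's own engine (Cromer–Liberman photoabsorption
plus form-factor-weighted coherent/incoherent scattering, via `gemmi`),
accurate to a few tenths of a percent against standard reference values in
the diagnostic range; see `docs/methods.md`.

## Worked example

```sh
python examples/01_beam_calibration.py
```

```
exponent n            : 3.20  (residual minimum on the 2..4 grid)
alpha(E1), 80 kVp     : 0.8975 +- 0.0011 (k=1)
alpha(E2), 130 kVp    : 0.9492 +- 0.0006 (k=1)

material     measured80 calc80   measured130 calc130   err80%  err130%
adipose         0.964    0.960      0.982    0.980    -0.40    -0.18
breast          0.979    0.981      0.989    0.990     0.18     0.15
muscle          1.009    1.003      1.005    1.002    -0.59    -0.35
liver           1.009    1.004      1.003    1.002    -0.51    -0.11
bone_200        1.189    1.171      1.095    1.085    -1.53    -0.96
bone_800        1.547    1.538      1.271    1.266    -0.60    -0.38
bone_1250       1.708    1.719      1.350    1.356     0.65     0.45
```

The exponent lands at n = 3.20 and the two slopes reproduce every calibration
insert's measured attenuation to within ±1.6% at both voltages — two numbers
per beam capture the spectrum.  `examples/04_spine_phantom_bmd.py` then
recovers 50/100/200 mg/cm³ bone mineral density in a noisy synthetic spine
phantom to within a fraction of a mg/cm³, and
`examples/05_femur_decomposition.py` shows the three-material split with the
negative-fraction fallback on femur-like mixtures:

```
region  VF(bone)  VF(fat)  VF(water)  BMD mg/cm3  fallback
head      0.220    0.001     0.779      660.1   -
neck      0.140    0.410     0.450      420.0   -
shaft     0.010    0.990     0.000       30.0   water_phema
```

A thin CLI mirrors the stages (`deqct fit-beam | build-lut | rhoz |
decompose | simulate`); volumes are NIfTI or DICOM series, tables are TSV.

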