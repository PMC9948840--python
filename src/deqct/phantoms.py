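"""Built-in reference materials and calibration-phantom definitions.

The seven-insert electron-density calibration phantom (adipose, breast,
muscle, liver and three hydroxyapatite bone qualities) drives the beam
calibration.  Vendor datasheet compositions for the tissue-equivalent
plastics are not redistributable, so the defaults are constructed from
first principles and are overridable via a material config file:

* soft-tissue inserts carry ICRU Report 44 real-tissue elemental
  compositions (the radiological quantities the plastics are engineered to
  reproduce),
* bone inserts follow the vendor's own nominal description: hydroxyapatite
  at 200 / 800 / 1250 mg/cm^3 dispersed in a water-equivalent resin, at
  insert densities 1.16 / 1.53 / 1.82 g/cm^3 (hydroxyapatite mass fraction
  = concentration / insert density; remainder water-equivalent).

Also defined: the marrow surrogates used for spongiosa decomposition
(hydroxyapatite as bone mineral, peanut oil as yellow marrow / fat, a 50/50
water-pHEMA mixture as red marrow / water).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .materials import MaterialSpec

__all__ = [
    "BMD_REFERENCE_DENSITY_MG_CM3",
    "HYDROXYAPATITE",
    "PEANUT_OIL",
    "WATER_PHEMA",
    "cirs_inserts",
    "load_dual_kvp_benchmark",
    "spongiosa_basis",
]

#: Pure-hydroxyapatite density used to convert bone volume fraction to BMD.
BMD_REFERENCE_DENSITY_MG_CM3 = 3000.0

HYDROXYAPATITE = MaterialSpec.from_formula(
    "hydroxyapatite", "Ca10(PO4)6(OH)2", 3.0
)

#: Peanut oil approximated by its dominant triglyceride (triolein-like).
PEANUT_OIL = MaterialSpec.from_formula("peanut_oil", "C57H104O6", 0.915)

_PHEMA = MaterialSpec.from_formula("pHEMA", "C6H10O3", 1.15)


def _mix_by_mass(name: str, parts: list[tuple[MaterialSpec, float]], density: float) -> MaterialSpec:
    fractions: dict[str, float] = {}
    for mat, w in parts:
        for el, f in mat.mass_fractions.items():
            fractions[el] = fractions.get(el, 0.0) + w * f
    return MaterialSpec(name, fractions, density)


#: 50% water / 50% pHEMA by mass; density of the ideal (volume-additive) mix.
WATER_PHEMA = _mix_by_mass(
    "water_phema",
    [(MaterialSpec.from_formula("water", "H2O", 1.0), 0.5), (_PHEMA, 0.5)],
    1.0 / (0.5 / 1.0 + 0.5 / 1.15),
)

# ICRU 44 elemental mass fractions (percent by weight in the report).
_ICRU44 = {
    "adipose": (
        {"H": 11.4, "C": 59.8, "N": 0.7, "O": 27.8, "Na": 0.1, "S": 0.1, "Cl": 0.1},
        0.96,
    ),
    "breast": (
        {"H": 10.6, "C": 33.2, "N": 3.0, "O": 52.7, "Na": 0.1, "P": 0.1, "S": 0.2,
         "Cl": 0.1},
        0.99,
    ),
    "muscle": (
        {"H": 10.2, "C": 14.3, "N": 3.4, "O": 71.0, "Na": 0.1, "P": 0.2, "S": 0.3,
         "Cl": 0.1, "K": 0.4},
        1.06,
    ),
    "liver": (
        {"H": 10.2, "C": 13.9, "N": 3.0, "O": 71.6, "Na": 0.2, "P": 0.3, "S": 0.3,
         "Cl": 0.2, "K": 0.3},
        1.07,
    ),
}

# Bone inserts: (hydroxyapatite concentration mg/cm^3, insert density g/cm^3)
_BONE_INSERTS = {
    "bone_200": (200.0, 1.16),
    "bone_800": (800.0, 1.53),
    "bone_1250": (1250.0, 1.82),
}

_WATER_EQ = MaterialSpec.from_formula("water_equivalent_resin", "H2O", 1.0)


def _bone_insert(name: str, ha_mg_cm3: float, density: float) -> MaterialSpec:
    w_ha = ha_mg_cm3 / 1000.0 / density
    return _mix_by_mass(
        name, [(HYDROXYAPATITE, w_ha), (_WATER_EQ, 1.0 - w_ha)], density
    )


def cirs_inserts() -> dict[str, MaterialSpec]:
    """The seven calibration-phantom insert materials, in fixed order."""
    out: dict[str, MaterialSpec] = {}
    for name, (fractions, density) in _ICRU44.items():
        out[name] = MaterialSpec(name, fractions, density)
    for name, (conc, density) in _BONE_INSERTS.items():
        out[name] = _bone_insert(name, conc, density)
    return out


def spongiosa_basis() -> dict[str, MaterialSpec]:
    """Default three-material basis for spongiosa decomposition."""
    return {
        "hydroxyapatite": HYDROXYAPATITE,
        "peanut_oil": PEANUT_OIL,
        "water_phema": WATER_PHEMA,
    }


def load_dual_kvp_benchmark() -> pd.DataFrame:
    """Measured relative mass attenuation of the seven inserts at 80/130 kVp.

    A benchmark acquired on a SPECT/CT system (columns ``material``,
    ``mu_m_star_80``, ``mu_m_star_130``); the standard input for fitting the
    per-beam slopes alpha(E1), alpha(E2).
    """
    with resources.files("deqct.data").joinpath("dual_kvp_benchmark.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
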