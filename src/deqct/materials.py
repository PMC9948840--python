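"""Material mixtures and their water-relative radiological descriptors.

A material is a named elemental composition (chemical formula or explicit
mass fractions) plus a mass density.  Three derived quantities drive the
whole dual-energy pipeline, all expressed relative to water:

* the effective atomic number
  ``Z_eff = [sum_i w_i Z_i^(n+1)/A_i / sum_i w_i Z_i/A_i]^(1/n)``,
* the relative electron density
  ``rho_e* = rho_m sum_i w_i Z_i/A_i / (rho_H2O sum w Z/A of water)``,
* the monoenergetic mass attenuation relative to water via the elemental
  mixture rule ``sum_i w_i (mu/rho)_i(E)``.

The water reference (composition H2O at 1.000 g/cm^3) is computed with the
same machinery, never hard-coded, so changing the exponent ``n`` stays
self-consistent.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import xs
from .xs import ElementTable, atomic_mass, default_table

__all__ = [
    "MaterialSpec",
    "MaterialDerived",
    "WATER",
    "derive",
    "effective_atomic_number",
    "electron_density_relative",
    "load_materials",
    "mono_mass_attenuation_relative",
    "parse_formula",
    "water_zeff",
]

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)|(\()|(\))(\d*\.?\d*)")


def parse_formula(formula: str) -> dict[str, float]:
    """Parse a Hill-style chemical formula into element -> atom count.

    Supports nested parentheses and fractional indices, e.g.
    ``Ca10(PO4)6(OH)2`` or ``C0.5O0.5``.
    """
    if not formula or not formula.strip():
        raise ValueError("empty chemical formula")
    stack: list[dict[str, float]] = [{}]
    pos = 0
    for m in _TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at {formula[pos:]!r}")
        pos = m.end()
        sym, count, open_p, close_p, group_count = m.groups()
        if open_p:
            stack.append({})
        elif close_p:
            if len(stack) == 1:
                raise ValueError(f"unbalanced ')' in formula {formula!r}")
            group = stack.pop()
            mult = float(group_count) if group_count else 1.0
            for el, c in group.items():
                stack[-1][el] = stack[-1].get(el, 0.0) + c * mult
        else:
            xs.atomic_number(sym)  # raises for unknown symbols
            n = float(count) if count else 1.0
            stack[-1][sym] = stack[-1].get(sym, 0.0) + n
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r} at {formula[pos:]!r}")
    if len(stack) != 1:
        raise ValueError(f"unbalanced '(' in formula {formula!r}")
    if not stack[0]:
        raise ValueError(f"formula {formula!r} contains no elements")
    return stack[0]


def _mass_fractions_from_counts(counts: dict[str, float]) -> dict[str, float]:
    masses = {el: n * atomic_mass(el) for el, n in counts.items()}
    total = sum(masses.values())
    if total <= 0:
        raise ValueError("composition has zero total mass")
    return {el: m / total for el, m in masses.items()}


@dataclass(frozen=True)
class MaterialSpec:
    """A named chemical composition with mass density [g/cm^3]."""

    name: str
    mass_fractions: dict[str, float]
    density: float

    def __hash__(self):  # the mass-fraction dict is not hashable on its own
        return hash(
            (self.name, tuple(sorted(self.mass_fractions.items())), self.density)
        )

    def __post_init__(self):
        if self.density <= 0:
            raise ValueError(f"{self.name}: density must be positive")
        if not self.mass_fractions:
            raise ValueError(f"{self.name}: empty composition")
        total = sum(self.mass_fractions.values())
        if total <= 0:
            raise ValueError(f"{self.name}: mass fractions sum to zero")
        normalized = {el: w / total for el, w in self.mass_fractions.items() if w > 0}
        for el in normalized:
            xs.atomic_number(el)
        object.__setattr__(self, "mass_fractions", normalized)

    @classmethod
    def from_formula(cls, name: str, formula: str, density: float) -> "MaterialSpec":
        return cls(name, _mass_fractions_from_counts(parse_formula(formula)), density)


def effective_atomic_number(mass_fractions: dict[str, float], n: float) -> float:
    """Power-law effective atomic number with exponent ``n``."""
    if n <= 0:
        raise ValueError("exponent n must be positive")
    if not mass_fractions:
        raise ValueError("empty composition")
    num = 0.0
    den = 0.0
    for el, w in mass_fractions.items():
        z = xs.atomic_number(el)
        a = atomic_mass(el)
        num += w * z ** (n + 1.0) / a
        den += w * z / a
    return float((num / den) ** (1.0 / n))


def _electrons_per_gram(mass_fractions: dict[str, float]) -> float:
    return sum(
        w * xs.atomic_number(el) / atomic_mass(el) for el, w in mass_fractions.items()
    )


# Water reference: H2O at 1.000 g/cm^3
WATER = MaterialSpec.from_formula("water", "H2O", 1.000)


def water_zeff(n: float) -> float:
    """Effective atomic number of the water reference for exponent ``n``."""
    return effective_atomic_number(WATER.mass_fractions, n)


def electron_density_relative(
    mass_fractions: dict[str, float], density: float
) -> float:
    """Electron density relative to water at 1.000 g/cm^3 (dimensionless)."""
    if density <= 0:
        raise ValueError("density must be positive")
    if not mass_fractions:
        raise ValueError("empty composition")
    return (
        density
        * _electrons_per_gram(mass_fractions)
        / (WATER.density * _electrons_per_gram(WATER.mass_fractions))
    )


def mono_mass_attenuation(
    mass_fractions: dict[str, float], energy_kev, table: ElementTable | None = None
):
    """Absolute mixture mass attenuation [cm^2/g] at monoenergetic energies."""
    table = table or default_table()
    total = None
    for el, w in mass_fractions.items():
        term = w * np.asarray(table.mu_over_rho(el, energy_kev))
        total = term if total is None else total + term
    if np.isscalar(energy_kev):
        return float(total)
    return total


def mono_mass_attenuation_relative(
    mass_fractions: dict[str, float], energy_kev, table: ElementTable | None = None
):
    """Mixture mass attenuation divided by water's at the same energy."""
    table = table or default_table()
    mix = mono_mass_attenuation(mass_fractions, energy_kev, table)
    ref = mono_mass_attenuation(WATER.mass_fractions, energy_kev, table)
    return mix / ref


def mono_attenuation_per_electron_relative(
    mass_fractions: dict[str, float], energy_kev, table: ElementTable | None = None
):
    """Attenuation per electron relative to water, mu_bar*/rho_e* at monoenergies.

    This is the quantity the dual-energy parametrization is written in: the
    linear attenuation relative to water divided by the relative electron
    density, equal to the per-gram ratio rescaled by water's electrons per
    gram over the mixture's.
    """
    per_gram = mono_mass_attenuation_relative(mass_fractions, energy_kev, table)
    return per_gram * (
        _electrons_per_gram(WATER.mass_fractions) / _electrons_per_gram(mass_fractions)
    )


@dataclass(frozen=True)
class MaterialDerived:
    """Water-relative descriptors of one material for a given exponent n."""

    z_eff: float
    rho_e_star: float
    z_eff_star_n: float = field(default=float("nan"))


def derive(spec: MaterialSpec, n: float) -> MaterialDerived:
    z = effective_atomic_number(spec.mass_fractions, n)
    rho = electron_density_relative(spec.mass_fractions, spec.density)
    return MaterialDerived(z_eff=z, rho_e_star=rho, z_eff_star_n=(z / water_zeff(n)) ** n)


def load_materials(path: str | Path) -> dict[str, MaterialSpec]:
    """Read a material config file (YAML).

    Each entry: ``name`` plus ``density_g_cm3`` and either ``formula`` or
    ``mass_fractions`` (element -> weight; normalized on load).  Accepts
    either a mapping name -> record or a list of records with ``name`` keys.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if isinstance(raw, dict) and "materials" in raw:
        raw = raw["materials"]
    records: list[tuple[str, dict]] = []
    if isinstance(raw, dict):
        records = list(raw.items())
    elif isinstance(raw, list):
        records = [(r["name"], r) for r in raw]
    else:
        raise ValueError(f"unrecognized material config layout in {path}")
    out: dict[str, MaterialSpec] = {}
    for name, rec in records:
        density = float(rec["density_g_cm3"])
        if "formula" in rec:
            out[name] = MaterialSpec.from_formula(name, rec["formula"], density)
        elif "mass_fractions" in rec:
            out[name] = MaterialSpec(name, dict(rec["mass_fractions"]), density)
        else:
            raise ValueError(f"material {name!r}: needs 'formula' or 'mass_fractions'")
    return out
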