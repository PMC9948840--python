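"""Elemental photon mass-attenuation coefficients for the diagnostic energy range.

Total attenuation is assembled per atom from three channels:

* photoelectric absorption from the Cromer-Liberman imaginary anomalous
  scattering factor f''(E) (``sigma = 2 r_e lambda f''``),
* coherent (Rayleigh) scattering from the Thomson cross section weighted by
  the squared IT92 atomic form factor f(q),
* incoherent (Compton) scattering from the Klein-Nishina cross section
  weighted by the incoherent scattering function, modeled as
  ``S(q, Z) = Z * (1 - (f(q)/Z)^p)`` with a single universal exponent
  ``p = 1.54`` calibrated once against reference water attenuation values.

Anomalous factors and form factors both come from :mod:`gemmi`.  The IT92
form-factor parametrization carries a constant term representing the core
(K-shell) electrons; that term is given a hydrogenic 1s fall-off here so
f(q) -> 0 at large momentum transfer (the raw constant would otherwise
inflate the coherent integral at high energy).  Against independent
reference tabulations (H, Al, Cu, water; 30-150 keV) the assembled model
agrees to within about 0.5%, mostly within 0.2%.

A pre-generated table (Z = 1..30, 10-150 keV) ships with the package and is
the default data source; :func:`compute_mu_over_rho` regenerates it from
scratch (see ``scripts/generate_element_table.py``).  Interpolation on the
energy grid is log-log linear, which is essentially exact for the smooth,
edge-free cross sections above 10 keV (all K edges for Z <= 30 lie below).
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import gemmi
import numpy as np
import pandas as pd
from scipy.integrate import simpson

__all__ = [
    "Z_MAX",
    "ElementTable",
    "atomic_mass",
    "atomic_number",
    "compute_mu_over_rho",
    "default_table",
    "generate_table",
    "symbol_of",
]

R_E_CM = 2.8179403262e-13  # classical electron radius [cm]
HC_KEV_ANGSTROM = 12.3984198  # h*c [keV * Angstrom]
N_AVOGADRO = 6.02214076e23  # [1/mol]
ELECTRON_REST_KEV = 510.99895  # m_e c^2 [keV]

BOHR_RADIUS_ANGSTROM = 0.5292

#: Exponent of the incoherent scattering function S = Z(1 - (f/Z)^p),
#: calibrated once against reference water mass-attenuation values.
INCOHERENT_EXPONENT = 1.54

Z_MAX = 30
TABLE_ENERGIES_KEV = np.arange(10.0, 151.0, 2.0)
_FIXTURE = "elemental_mu_rho.tsv"


def atomic_number(symbol: str) -> int:
    z = gemmi.Element(symbol).atomic_number
    if z == 0:
        raise ValueError(f"unknown element symbol: {symbol!r}")
    return z


def symbol_of(z: int) -> str:
    return gemmi.Element(z).name


def atomic_mass(element: int | str) -> float:
    """Standard atomic weight A [g/mol] of an element (symbol or Z)."""
    el = gemmi.Element(element)
    if el.atomic_number == 0:
        raise ValueError(f"unknown element: {element!r}")
    return el.weight


def _photoelectric(z: int, energy_kev: float) -> float:
    """Photoabsorption cross section [cm^2/atom] via Cromer-Liberman f''."""
    _, fpp = gemmi.cromer_liberman(z=z, energy=energy_kev * 1000.0)
    wavelength_cm = HC_KEV_ANGSTROM / energy_kev * 1e-8
    return 2.0 * R_E_CM * wavelength_cm * fpp


def _form_factor(z: int, stol: np.ndarray) -> np.ndarray:
    """Atomic form factor f(q) vs sin(theta/2)/lambda [1/Angstrom].

    IT92 Gaussian part plus the constant (core-electron) term, the latter
    damped with a hydrogenic 1s profile so f decays at large q.
    """
    coefs = gemmi.Element(z).it92
    a = np.asarray(coefs.a)
    b = np.asarray(coefs.b)
    # Gaussians with b ~ 0 act as constants; fold them into the asymptote
    # (some fits, e.g. N and Cl, pair such a term with a large negative c).
    genuine = b >= 0.1
    asymptote = coefs.c + float(a[~genuine].sum())
    gauss = (
        a[genuine, None] * np.exp(-b[genuine, None] * stol[None, :] ** 2)
    ).sum(axis=0)
    z_k = max(z - 0.3, 1.0)  # screened nuclear charge seen by the 1s shell
    q = 4.0 * np.pi * stol
    f_1s = 1.0 / (1.0 + (q * BOHR_RADIUS_ANGSTROM / (2.0 * z_k)) ** 2) ** 2
    return gauss + asymptote * f_1s


def _scatter(z: int, energy_kev: float, npts: int = 1001) -> tuple[float, float]:
    """Coherent and incoherent cross sections [cm^2/atom] by angular quadrature."""
    theta = np.linspace(0.0, np.pi, npts)
    ct, st = np.cos(theta), np.sin(theta)
    stol = np.sin(theta / 2.0) * (energy_kev / HC_KEV_ANGSTROM)  # sin(th/2)/lambda [1/A]
    f = _form_factor(z, stol)

    d_thomson = 0.5 * R_E_CM**2 * (1.0 + ct**2)
    coherent = simpson(2.0 * np.pi * d_thomson * f**2 * st, x=theta)

    eps = energy_kev / ELECTRON_REST_KEV
    r = 1.0 / (1.0 + eps * (1.0 - ct))  # k'/k
    d_kn = 0.5 * R_E_CM**2 * r**2 * (r + 1.0 / r - st**2)
    s_incoh = z * (1.0 - (np.clip(f, 0.0, None) / z) ** INCOHERENT_EXPONENT)
    incoherent = simpson(2.0 * np.pi * d_kn * s_incoh * st, x=theta)
    return coherent, incoherent


def compute_mu_over_rho(
    z: int, energies_kev: np.ndarray, *, coherent: bool = True
) -> np.ndarray:
    """Mass attenuation coefficient mu/rho [cm^2/g] computed from scratch.

    ``coherent=False`` drops Rayleigh scattering from the total.
    """
    if not 1 <= z <= Z_MAX:
        raise ValueError(f"Z={z} outside supported range 1..{Z_MAX}")
    a = atomic_mass(z)
    out = np.empty(len(energies_kev))
    for i, e in enumerate(np.asarray(energies_kev, dtype=float)):
        coh, incoh = _scatter(z, e)
        sigma = _photoelectric(z, e) + incoh + (coh if coherent else 0.0)
        out[i] = sigma * N_AVOGADRO / a
    return out


def generate_table(
    energies_kev: np.ndarray = TABLE_ENERGIES_KEV,
    z_max: int = Z_MAX,
    *,
    coherent: bool = True,
) -> pd.DataFrame:
    """Build the elemental table (columns Z, symbol, A, energy_keV, mu_over_rho_cm2_g)."""
    frames = []
    for z in range(1, z_max + 1):
        frames.append(
            pd.DataFrame(
                {
                    "Z": z,
                    "symbol": symbol_of(z),
                    "A": atomic_mass(z),
                    "energy_keV": energies_kev,
                    "mu_over_rho_cm2_g": compute_mu_over_rho(
                        z, energies_kev, coherent=coherent
                    ),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


class ElementTable:
    """Log-log interpolating view over a per-element energy grid of mu/rho."""

    def __init__(self, table: pd.DataFrame):
        required = {"Z", "symbol", "A", "energy_keV", "mu_over_rho_cm2_g"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"element table missing columns: {sorted(missing)}")
        self._grids: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        self._mass: dict[int, float] = {}
        bounds = []
        for z, grp in table.groupby("Z"):
            grp = grp.sort_values("energy_keV")
            e = grp["energy_keV"].to_numpy(float)
            mu = grp["mu_over_rho_cm2_g"].to_numpy(float)
            if np.any(mu <= 0):
                raise ValueError(f"non-positive mu/rho for Z={z}")
            if np.any(np.diff(e) <= 0):
                raise ValueError(f"energy grid not strictly increasing for Z={z}")
            self._grids[int(z)] = (np.log(e), np.log(mu))
            self._mass[int(z)] = float(grp["A"].iloc[0])
            bounds.append((e[0], e[-1]))
        #: inclusive energy interval [keV] on which every element is defined
        self.energy_range = (
            max(b[0] for b in bounds),
            min(b[1] for b in bounds),
        )

    @classmethod
    def from_tsv(cls, path) -> "ElementTable":
        return cls(pd.read_csv(path, sep="\t"))

    @classmethod
    def bundled(cls) -> "ElementTable":
        with resources.files("deqct.data").joinpath(_FIXTURE).open() as fh:
            return cls(pd.read_csv(fh, sep="\t"))

    @property
    def atomic_numbers(self) -> list[int]:
        return sorted(self._grids)

    def atomic_mass(self, element: int | str) -> float:
        z = element if isinstance(element, int) else atomic_number(element)
        try:
            return self._mass[z]
        except KeyError:
            raise KeyError(f"element Z={z} not in table") from None

    def mu_over_rho(self, element: int | str, energy_kev) -> np.ndarray | float:
        """mu/rho [cm^2/g] at one or more energies (log-log interpolated)."""
        z = element if isinstance(element, int) else atomic_number(element)
        if z not in self._grids:
            raise KeyError(f"element Z={z} not in table")
        e = np.asarray(energy_kev, dtype=float)
        lo, hi = self.energy_range
        if np.any(e < lo) or np.any(e > hi):
            raise ValueError(
                f"energy {energy_kev} keV outside table range [{lo:g}, {hi:g}] keV"
            )
        log_e, log_mu = self._grids[z]
        result = np.exp(np.interp(np.log(e), log_e, log_mu))
        return float(result) if np.isscalar(energy_kev) else result


@lru_cache(maxsize=1)
def default_table() -> ElementTable:
    """The bundled elemental table (cached)."""
    return ElementTable.bundled()
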