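"""Dual-kVp beam calibration: the attenuation parametrization and its fit.

The parametrization expresses the mass attenuation of any material relative
to water at one beam as

    mu_m*(E) = alpha(E) * (1 - Zeff*^n) + Zeff*^n,

where ``Zeff*^n = (Zeff / Zeff_H2O)^n`` and ``alpha(E)``, ``n`` are
constants of the CT beam.  Water satisfies mu_m* = 1 identically.  The
calibration has two stages:

1. ``fit_n`` — a purely theoretical stage: over a monoenergetic grid
   (default 50..100 keV, 1 keV steps) and a grid of candidate exponents
   (default 2..4, step 0.01), regress ``mu_m*(E) - Zeff*^n`` on
   ``1 - Zeff*^n`` through the origin across a reference material set and
   pick the exponent minimizing the summed squared residual.
2. ``fit_alpha`` — a measured stage: convert phantom Hounsfield readings at
   each tube voltage to mu_m* via ``(HU/1000 + 1)/rho_e*`` and fit the same
   origin-constrained regression once per beam; the slope is alpha(E).

Both beams' alpha absorb the full polyenergetic spectrum, so no effective
beam energy in keV is ever needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .materials import (
    MaterialSpec,
    derive,
    mono_attenuation_per_electron_relative,
    water_zeff,
)
from .xs import ElementTable, default_table

__all__ = [
    "BeamCalibration",
    "NFitResult",
    "PhantomMeasurement",
    "fit_alpha",
    "fit_alpha_from_attenuation",
    "fit_beam",
    "fit_n",
    "hu_to_mu_m_star",
    "predict_mu_m_star",
]

DEFAULT_ENERGY_GRID_KEV = np.arange(50.0, 101.0, 1.0)
DEFAULT_N_GRID = np.round(np.arange(2.0, 4.0 + 1e-9, 0.01), 2)


def hu_to_mu_m_star(hu: float, rho_e_star: float) -> float:
    """Hounsfield units -> mass attenuation relative to water, (HU/1000+1)/rho_e*."""
    if rho_e_star <= 0:
        raise ValueError("rho_e_star must be positive")
    return (hu / 1000.0 + 1.0) / rho_e_star


def predict_mu_m_star(z_eff_star_n, alpha: float):
    """Forward parametrization: alpha*(1 - Zeff*^n) + Zeff*^n."""
    z = np.asarray(z_eff_star_n, dtype=float)
    if np.any(z <= 0):
        raise ValueError("Zeff*^n must be positive")
    out = alpha * (1.0 - z) + z
    return float(out) if np.isscalar(z_eff_star_n) else out


@dataclass(frozen=True)
class PhantomMeasurement:
    """Mean HU of one phantom material at both tube voltages."""

    material: MaterialSpec
    hu_low: float
    hu_high: float
    sd_low: float | None = None
    sd_high: float | None = None
    n_voxels: int | None = None

    def __post_init__(self):
        if self.hu_low < -1000 or self.hu_high < -1000:
            raise ValueError("HU below the air limit of -1000")
        if self.n_voxels is not None and self.n_voxels <= 0:
            raise ValueError("voxel count must be positive")


@dataclass(frozen=True)
class NFitResult:
    n: float
    n_grid: np.ndarray
    residuals: np.ndarray  # summed squared residual per candidate n


@dataclass(frozen=True)
class BeamCalibration:
    """Fitted dual-kVp beam model (exponent n and per-beam slopes alpha)."""

    kvp_low: float
    kvp_high: float
    n: float
    alpha_low: float
    alpha_high: float
    alpha_low_se: float = float("nan")
    alpha_high_se: float = float("nan")
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.kvp_low < self.kvp_high:
            raise ValueError("kvp_low must be below kvp_high")
        if not 0 < self.n:
            raise ValueError("exponent n must be positive")
        for a in (self.alpha_low, self.alpha_high):
            if not 0 < a < 2:
                raise ValueError(f"alpha {a} outside plausible range (0, 2)")

    @property
    def water_zeff(self) -> float:
        return water_zeff(self.n)

    def z_eff_star_n(self, z_eff) -> np.ndarray | float:
        """(Zeff / Zeff_H2O)^n for this beam's exponent."""
        return (np.asarray(z_eff, dtype=float) / self.water_zeff) ** self.n

    def save(self, path: str | Path) -> None:
        payload = {
            "kvp_low": self.kvp_low,
            "kvp_high": self.kvp_high,
            "n": self.n,
            "alpha_low": self.alpha_low,
            "alpha_high": self.alpha_high,
            "alpha_low_se": self.alpha_low_se,
            "alpha_high_se": self.alpha_high_se,
            "diagnostics": self.diagnostics,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "BeamCalibration":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)


def _origin_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope through the origin with its standard error (k=1)."""
    sxx = float(np.dot(x, x))
    if sxx <= 0:
        raise ValueError("degenerate regressor: all Zeff equal water's")
    slope = float(np.dot(x, y)) / sxx
    dof = len(x) - 1
    if dof > 0:
        resid = y - slope * x
        se = float(np.sqrt(np.dot(resid, resid) / dof / sxx))
    else:
        se = float("nan")
    return slope, se


def fit_n(
    reference_materials: list[MaterialSpec],
    energy_grid_kev: np.ndarray = DEFAULT_ENERGY_GRID_KEV,
    n_grid: np.ndarray = DEFAULT_N_GRID,
    table: ElementTable | None = None,
    mu: np.ndarray | None = None,
) -> NFitResult:
    """Select the exponent n minimizing the parametrization residual.

    For each candidate n, mu_m*(E) of every reference material (the
    per-electron attenuation relative to water, from the elemental mixture
    rule) is regressed on the origin-constrained linear relation at every
    energy of the grid; the summed squared residual over energies is the
    selection criterion.  Ties break to the smallest n.  ``mu`` (materials x
    energies) overrides the table-derived attenuation when supplied.
    """
    if len(reference_materials) < 3:
        raise ValueError("need at least 3 reference materials")
    if mu is None:
        table = table or default_table()
        mu = np.array(
            [
                mono_attenuation_per_electron_relative(
                    m.mass_fractions, energy_grid_kev, table
                )
                for m in reference_materials
            ]
        )  # (materials, energies)
    mu = np.asarray(mu, dtype=float)
    residuals = np.empty(len(n_grid))
    for i, n in enumerate(n_grid):
        zw = water_zeff(n)
        zn = np.array(
            [
                (derive(m, n).z_eff / zw) ** n
                for m in reference_materials
            ]
        )
        x = 1.0 - zn
        sxx = float(np.dot(x, x))
        if sxx <= 1e-12:
            raise ValueError("degenerate reference set: all Zeff equal")
        y = mu - zn[:, None]  # (materials, energies)
        slopes = x @ y / sxx  # per-energy alpha(E)
        resid = y - np.outer(x, slopes)
        residuals[i] = float(np.sum(resid**2))
    best = int(np.argmin(residuals))  # argmin takes the first (smallest n) on ties
    return NFitResult(n=float(n_grid[best]), n_grid=np.asarray(n_grid), residuals=residuals)


def fit_alpha_from_attenuation(
    materials: list[MaterialSpec], mu_m_star: np.ndarray, n: float
) -> tuple[float, float]:
    """Fit alpha for one beam from water-relative mass attenuation values.

    Returns (slope, standard error).  ``mu_m_star`` pairs with ``materials``.
    """
    zw = water_zeff(n)
    zn = np.array([(derive(m, n).z_eff / zw) ** n for m in materials])
    x = 1.0 - zn
    y = np.asarray(mu_m_star, dtype=float) - zn
    return _origin_slope(x, y)


def fit_alpha(
    measurements: list[PhantomMeasurement], n: float
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Fit (alpha_low, alpha_high) from phantom HU measurements.

    HU are converted to mu_m* with each material's nominal rho_e* before the
    origin-constrained regression.  Returns ((alpha_low, se), (alpha_high, se)).
    """
    if len(measurements) < 2:
        raise ValueError("need at least 2 phantom measurements")
    mats = [m.material for m in measurements]
    rho = np.array([derive(m, n).rho_e_star for m in mats])
    mu_low = (np.array([m.hu_low for m in measurements]) / 1000.0 + 1.0) / rho
    mu_high = (np.array([m.hu_high for m in measurements]) / 1000.0 + 1.0) / rho
    return (
        fit_alpha_from_attenuation(mats, mu_low, n),
        fit_alpha_from_attenuation(mats, mu_high, n),
    )


def fit_beam(
    measurements: list[PhantomMeasurement],
    kvp_low: float = 80.0,
    kvp_high: float = 130.0,
    reference_materials: list[MaterialSpec] | None = None,
    energy_grid_kev: np.ndarray = DEFAULT_ENERGY_GRID_KEV,
    n_grid: np.ndarray = DEFAULT_N_GRID,
    table: ElementTable | None = None,
) -> BeamCalibration:
    """Full calibration: fit n theoretically, then both alphas from HU data.

    ``reference_materials`` for the n stage default to the measured set.
    """
    refs = reference_materials or [m.material for m in measurements]
    nfit = fit_n(refs, energy_grid_kev, n_grid, table)
    (a_lo, se_lo), (a_hi, se_hi) = fit_alpha(measurements, nfit.n)
    return BeamCalibration(
        kvp_low=kvp_low,
        kvp_high=kvp_high,
        n=nfit.n,
        alpha_low=a_lo,
        alpha_high=a_hi,
        alpha_low_se=se_lo,
        alpha_high_se=se_hi,
        diagnostics={
            "n_grid_min": float(np.min(nfit.n_grid)),
            "n_grid_max": float(np.max(nfit.n_grid)),
            "n_residual": float(np.min(nfit.residuals)),
        },
    )
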