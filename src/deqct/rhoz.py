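"""Effective atomic number and effective density from paired HU readings.

Given a calibrated dual-kVp beam, a look-up table over integer Z = 1..30
stores, per element, the forward-parametrized attenuation at both beams and
their ratio ``F(Z) = mu_m*_low(Z) / mu_m*_high(Z)``.  A volume of interest
measured at both voltages yields ``mu_eff* = HU/1000 + 1`` per beam; the
ratio inverts F to the effective atomic number, and the low-beam column
then yields the relative effective electron density
``rho_e,eff* = mu_eff*_low / mu_m*_low(Z_eff)``.  A linear calibration
against materials of known mass density finally maps rho_e,eff* to an
effective mass density in g/cm^3.

F(Z) is non-monotonic near hydrogen/helium; inversion is restricted to the
largest monotone sub-range containing water's Z_eff (spongiosa targets sit
at Z_eff ~ 6-17).  Out-of-range ratios raise by default; ``clamp=True``
pins them to the admissible interval for noisy voxelwise use.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import BeamCalibration, predict_mu_m_star

__all__ = [
    "DensityCalibration",
    "LookupTable",
    "RhoZResult",
    "VOIMeasurement",
    "build_lookup",
    "calibrate_density",
    "estimate_rho_e",
    "estimate_rhoz",
    "estimate_zeff",
    "hu_to_mu_eff_star",
]


def hu_to_mu_eff_star(hu):
    """Mean VOI attenuation relative to water: HU/1000 + 1."""
    hu = np.asarray(hu, dtype=float)
    if np.any(hu < -1000):
        raise ValueError("HU below the air limit of -1000")
    out = hu / 1000.0 + 1.0
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class VOIMeasurement:
    """Mean HU over one volume of interest at both tube voltages."""

    label: str
    hu_low: float
    hu_high: float
    sd_low: float = float("nan")
    sd_high: float = float("nan")
    n_voxels: int = 1

    def __post_init__(self):
        if self.n_voxels < 1:
            raise ValueError("n_voxels must be >= 1")
        if self.hu_low < -1000 or self.hu_high < -1000:
            raise ValueError("HU below the air limit of -1000")


class LookupTable:
    """Per-element F(Z) and low-beam attenuation rows for one beam calibration."""

    def __init__(self, beam: BeamCalibration, z: np.ndarray, f_of_z: np.ndarray,
                 mu_m_star_low: np.ndarray, mu_m_star_high: np.ndarray):
        self.beam = beam
        self.z = np.asarray(z, dtype=float)
        self.f_of_z = np.asarray(f_of_z, dtype=float)
        self.mu_m_star_low = np.asarray(mu_m_star_low, dtype=float)
        self.mu_m_star_high = np.asarray(mu_m_star_high, dtype=float)
        if not (len(self.z) == len(self.f_of_z) == len(self.mu_m_star_low)):
            raise ValueError("inconsistent column lengths")
        self._lo, self._hi = self._monotone_range()

    def _monotone_range(self) -> tuple[int, int]:
        """Largest contiguous index range with strictly increasing F containing water."""
        df = np.diff(self.f_of_z)
        i_water = int(np.searchsorted(self.z, self.beam.water_zeff))
        lo = i_water
        while lo > 0 and df[lo - 1] > 0:
            lo -= 1
        hi = i_water
        while hi < len(self.z) - 1 and df[hi] > 0:
            hi += 1
        if hi - lo < 1:
            raise ValueError("F(Z) is not invertible around water's Z_eff")
        return lo, hi

    @property
    def invertible_z(self) -> tuple[float, float]:
        return float(self.z[self._lo]), float(self.z[self._hi])

    @property
    def invertible_f(self) -> tuple[float, float]:
        return float(self.f_of_z[self._lo]), float(self.f_of_z[self._hi])

    def zeff_from_ratio(self, f: float, clamp: bool = False) -> float:
        f_lo, f_hi = self.invertible_f
        if not f_lo <= f <= f_hi:
            if not clamp:
                raise ValueError(
                    f"attenuation ratio F={f:.4f} outside the invertible interval "
                    f"[{f_lo:.4f}, {f_hi:.4f}] "
                    f"(Z in [{self.invertible_z[0]:.0f}, {self.invertible_z[1]:.0f}])"
                )
            f = min(max(f, f_lo), f_hi)
        seg = slice(self._lo, self._hi + 1)
        return float(np.interp(f, self.f_of_z[seg], self.z[seg]))

    def mu_low_at(self, z_eff: float) -> float:
        z_lo, z_hi = self.invertible_z
        if not z_lo <= z_eff <= z_hi:
            raise ValueError(f"Z_eff {z_eff:.2f} outside table range [{z_lo}, {z_hi}]")
        seg = slice(self._lo, self._hi + 1)
        return float(np.interp(z_eff, self.z[seg], self.mu_m_star_low[seg]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Z": self.z.astype(int),
                "f_of_z": self.f_of_z,
                "mu_m_star_low": self.mu_m_star_low,
                "mu_m_star_high": self.mu_m_star_high,
            }
        )

    def save(self, path: str | Path) -> None:
        b = self.beam
        header = (
            f"# beam: kvp_low={b.kvp_low:g} kvp_high={b.kvp_high:g} n={b.n:g} "
            f"alpha_low={b.alpha_low:.6f} alpha_high={b.alpha_high:.6f}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            self.to_frame().to_csv(fh, sep="\t", index=False)


def build_lookup(beam: BeamCalibration, z_max: int = 30) -> LookupTable:
    """Tabulate F(Z) and per-beam attenuation for integer Z = 1..z_max."""
    z = np.arange(1, z_max + 1, dtype=float)
    zn = beam.z_eff_star_n(z)
    mu_low = predict_mu_m_star(zn, beam.alpha_low)
    mu_high = predict_mu_m_star(zn, beam.alpha_high)
    return LookupTable(beam, z, mu_low / mu_high, mu_low, mu_high)


def estimate_zeff(voi: VOIMeasurement, lut: LookupTable, clamp: bool = False) -> float:
    """Invert the VOI's dual-kVp attenuation ratio to an effective atomic number."""
    mu_low = hu_to_mu_eff_star(voi.hu_low)
    mu_high = hu_to_mu_eff_star(voi.hu_high)
    if mu_high == 0:
        raise ZeroDivisionError("high-kVp attenuation is zero (HU = -1000)")
    return lut.zeff_from_ratio(mu_low / mu_high, clamp=clamp)


def estimate_rho_e(voi: VOIMeasurement, z_eff: float, lut: LookupTable) -> float:
    """Relative effective electron density: mu_eff*_low / mu_m*_low(Z_eff)."""
    return hu_to_mu_eff_star(voi.hu_low) / lut.mu_low_at(z_eff)


@dataclass(frozen=True)
class DensityCalibration:
    """Line mapping relative effective electron density to mass density [g/cm^3]."""

    slope: float
    intercept: float
    r_value: float = float("nan")
    slope_se: float = float("nan")

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError("density calibration slope must be positive")

    def __call__(self, rho_e_eff_star: float) -> float:
        return self.slope * rho_e_eff_star + self.intercept


def calibrate_density(points: list[tuple[float, float]]) -> DensityCalibration:
    """OLS line through (rho_e_eff_star, known mass density) pairs."""
    if len(points) < 2:
        raise ValueError("need at least 2 calibration points")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if np.ptp(x) <= 0:
        raise ValueError("degenerate abscissae in density calibration")
    fit = stats.linregress(x, y)
    return DensityCalibration(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_value=float(fit.rvalue),
        slope_se=float(fit.stderr) if fit.stderr is not None else float("nan"),
    )


@dataclass(frozen=True)
class RhoZResult:
    label: str
    z_eff: float
    rho_e_eff_star: float
    rho_eff: float = float("nan")  # g/cm^3, present when a density calibration is given


def estimate_rhoz(
    voi: VOIMeasurement,
    lut: LookupTable,
    density_cal: DensityCalibration | None = None,
    clamp: bool = False,
) -> RhoZResult:
    """Full per-VOI estimate: Z_eff, rho_e,eff*, and (optionally) rho_eff."""
    z_eff = estimate_zeff(voi, lut, clamp=clamp)
    rho_e = estimate_rho_e(voi, z_eff, lut)
    rho_eff = density_cal(rho_e) if density_cal is not None else float("nan")
    return RhoZResult(voi.label, z_eff, rho_e, rho_eff)
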