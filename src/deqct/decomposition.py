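"""Two- and three-material volume-fraction decomposition of spongiosa.

The measured VOI attenuation pair is modeled as a volume-fraction-weighted
sum of basis-material attenuations at each beam,

    mu_eff*_E = C(Z_eff) * sum_X VF_X * mu_X*_E,      sum_X VF_X = 1,

solved exactly as a linear system (2x2 or 3x3 including the closure row).
Basis attenuations ``mu_X* = mu_m*(Z_eff_X) * rho_e*_X`` come either from
the beam parametrization ("computed") or from calibration-vial HU readings
("measured").  ``C(Z)`` is an empirical beam-hardening correction applied
above Z_eff = 10 (identity by default; configurable as a piecewise-linear
curve, with a helper to calibrate it on samples of known composition).

Non-physical solutions with a negative volume fraction — typical when a
basis member is effectively absent, e.g. no fat in a dense femoral head —
trigger a fallback: the most negative member is pinned to zero and the
reduced system re-solved, iterating until all fractions are non-negative.

Bone mineral density is the bone-mineral volume fraction times the
hydroxyapatite density (3000 mg/cm^3 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .calibration import BeamCalibration, predict_mu_m_star
from .materials import MaterialSpec, derive
from .phantoms import BMD_REFERENCE_DENSITY_MG_CM3
from .rhoz import VOIMeasurement, hu_to_mu_eff_star

__all__ = [
    "BasisMaterial",
    "CCurve",
    "DecompositionResult",
    "basis_attenuation",
    "basis_from_series",
    "basis_from_vial",
    "beam_hardening_factor",
    "bmd",
    "calibrate_c_curve",
    "decompose",
    "mass_fractions_from_volume",
]

COND_WARN = 1e3
COND_ERROR = 1e12


@dataclass(frozen=True)
class BasisMaterial:
    """One decomposition basis member with its per-beam attenuation vs water."""

    name: str
    mu_star_low: float
    mu_star_high: float
    density: float  # g/cm^3
    source: str = "computed"  # "computed" | "measured"

    def __post_init__(self):
        if self.mu_star_low <= 0 or self.mu_star_high <= 0:
            raise ValueError(f"{self.name}: attenuation must be positive")
        if self.source not in ("computed", "measured"):
            raise ValueError("source must be 'computed' or 'measured'")


def basis_attenuation(spec: MaterialSpec, beam: BeamCalibration) -> BasisMaterial:
    """Basis attenuation from chemistry: mu* = parametrization(Z_eff) x rho_e*."""
    d = derive(spec, beam.n)
    zn = d.z_eff_star_n
    return BasisMaterial(
        name=spec.name,
        mu_star_low=predict_mu_m_star(zn, beam.alpha_low) * d.rho_e_star,
        mu_star_high=predict_mu_m_star(zn, beam.alpha_high) * d.rho_e_star,
        density=spec.density,
        source="computed",
    )


def basis_from_vial(voi: VOIMeasurement, name: str, density: float) -> BasisMaterial:
    """Measured basis from a single calibration vial: mu* = HU/1000 + 1 per beam."""
    return BasisMaterial(
        name=name,
        mu_star_low=hu_to_mu_eff_star(voi.hu_low),
        mu_star_high=hu_to_mu_eff_star(voi.hu_high),
        density=density,
        source="measured",
    )


def basis_from_series(
    vials: list[VOIMeasurement],
    concentrations_mg_cm3: list[float],
    name: str,
    pure_density_mg_cm3: float = BMD_REFERENCE_DENSITY_MG_CM3,
    base_name: str = "base",
    base_density: float = 1.0,
) -> tuple[BasisMaterial, BasisMaterial]:
    """Measured basis from a concentration series of calibration vials.

    Per beam, HU is regressed on concentration; the line extrapolated to the
    pure-material density gives the pure-member attenuation, and the
    intercept (zero concentration) gives the suspending-base attenuation.
    Returns ``(pure_member, base_member)``.
    """
    if len(vials) < 2 or len(vials) != len(concentrations_mg_cm3):
        raise ValueError("need >= 2 vials with matching concentrations")
    c = np.asarray(concentrations_mg_cm3, dtype=float)
    if np.ptp(c) <= 0:
        raise ValueError("degenerate concentration series")
    mu_pure, mu_base = [], []
    for hu in (
        np.array([v.hu_low for v in vials]),
        np.array([v.hu_high for v in vials]),
    ):
        slope, intercept = np.polyfit(c, hu, 1)
        mu_pure.append(hu_to_mu_eff_star(slope * pure_density_mg_cm3 + intercept))
        mu_base.append(hu_to_mu_eff_star(intercept))
    pure = BasisMaterial(
        name, mu_pure[0], mu_pure[1], pure_density_mg_cm3 / 1000.0, "measured"
    )
    base = BasisMaterial(
        base_name, mu_base[0], mu_base[1], base_density, "measured"
    )
    return pure, base


class CCurve:
    """Piecewise-linear beam-hardening correction C(Z) for Z_eff > 10."""

    def __init__(self, z: np.ndarray, c: np.ndarray, threshold: float = 10.0):
        self.z = np.asarray(z, dtype=float)
        self.c = np.asarray(c, dtype=float)
        self.threshold = threshold
        if len(self.z) != len(self.c) or len(self.z) < 1:
            raise ValueError("malformed C(Z) curve")
        if np.any(np.diff(self.z) <= 0):
            raise ValueError("C(Z) curve abscissae must be strictly increasing")
        if np.any(self.c <= 0):
            raise ValueError("C(Z) values must be positive")

    def __call__(self, z_eff: float) -> float:
        if z_eff <= self.threshold:
            return 1.0
        return float(np.interp(z_eff, self.z, self.c))


def beam_hardening_factor(z_eff: float, curve: CCurve | None = None) -> float:
    """C(Z_eff): 1.0 at or below Z_eff = 10, the configured curve above."""
    if z_eff <= 0:
        raise ValueError("z_eff must be positive")
    if curve is None or z_eff <= 10.0:
        return 1.0
    return curve(z_eff)


def calibrate_c_curve(
    references: list[tuple[VOIMeasurement, dict[str, float], float]],
    basis: list[BasisMaterial],
    threshold: float = 10.0,
) -> CCurve:
    """Fit C(Z) on reference samples of known composition.

    ``references`` holds (VOI measurement, true volume fractions by basis
    name, Z_eff) triples.  For each sample the scalar C minimizing the
    squared residual of the mixture equations is C = (m.y)/(m.m) with
    m the modeled attenuation pair and y the measured pair; samples at or
    below the threshold are ignored (C = 1 there by definition).
    """
    zs, cs = [], []
    for voi, vf, z_eff in references:
        if z_eff <= threshold:
            continue
        model = np.array(
            [
                sum(vf.get(b.name, 0.0) * b.mu_star_low for b in basis),
                sum(vf.get(b.name, 0.0) * b.mu_star_high for b in basis),
            ]
        )
        meas = np.array(
            [hu_to_mu_eff_star(voi.hu_low), hu_to_mu_eff_star(voi.hu_high)]
        )
        zs.append(z_eff)
        cs.append(float(np.dot(model, meas) / np.dot(model, model)))
    if not zs:
        raise ValueError("no reference samples above the C(Z) threshold")
    order = np.argsort(zs)
    return CCurve(np.asarray(zs)[order], np.asarray(cs)[order], threshold)


@dataclass(frozen=True)
class DecompositionResult:
    """Per-VOI volume fractions and derived quantities."""

    label: str
    volume_fractions: dict[str, float]
    c_factor: float
    condition_number: float
    fallback: tuple[str, ...] = ()
    mass_fractions: dict[str, float] = field(default_factory=dict)
    mass_fraction_residual: float = float("nan")
    z_eff: float = float("nan")
    rho_eff: float = float("nan")
    bmd_mg_cm3: float = float("nan")


def _solve(mu: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, float]:
    """Solve the closure-constrained system for mu (2 x k) and the target pair.

    The closure sum(VF) = 1 is substituted exactly; the two attenuation
    equations are then solved exactly (k = 3) or by least squares (k = 2).
    """
    k = mu.shape[1]
    cond = float(np.linalg.cond(np.vstack([mu, np.ones(k)])))
    a = mu[:, :-1] - mu[:, [-1]]
    b = target - mu[:, -1]
    if a.shape[1] == 2:
        free = np.linalg.solve(a, b)
    else:
        free, *_ = np.linalg.lstsq(a, b, rcond=None)
    vf = np.append(free, 1.0 - free.sum())
    if cond > COND_ERROR:
        raise np.linalg.LinAlgError(
            f"basis attenuation matrix is numerically singular (cond={cond:.3g})"
        )
    if cond > COND_WARN:
        warnings.warn(
            f"ill-conditioned basis (cond={cond:.3g}); fractions are noise-sensitive",
            stacklevel=3,
        )
    return vf, cond


def decompose(
    voi: VOIMeasurement,
    basis: list[BasisMaterial],
    c_factor: float = 1.0,
    mineral: str | None = "hydroxyapatite",
    rho_eff: float | None = None,
    z_eff: float = float("nan"),
    negative_tolerance: float = 1e-10,
) -> DecompositionResult:
    """Solve the volume-fraction system for one VOI, with negative-VF fallback.

    The closure row (fractions summing to one) is enforced exactly.  When a
    solution carries a negative fraction beyond ``negative_tolerance``, the
    most negative member is pinned to zero and the reduced system re-solved
    (least squares once the system becomes overdetermined), iterating until
    all fractions are non-negative; pinned members are reported in
    ``fallback``.  ``rho_eff`` (g/cm^3) enables the volume->mass fraction
    conversion; ``mineral`` names the basis member whose volume fraction is
    scaled to bone mineral density.
    """
    if len(basis) not in (2, 3):
        raise ValueError("decomposition needs 2 or 3 basis materials")
    names = [b.name for b in basis]
    if len(set(names)) != len(names):
        raise ValueError("basis material names must be unique")
    target = np.array(
        [hu_to_mu_eff_star(voi.hu_low), hu_to_mu_eff_star(voi.hu_high)]
    ) / c_factor
    mu_all = np.array(
        [[b.mu_star_low for b in basis], [b.mu_star_high for b in basis]]
    )

    active = list(range(len(basis)))
    forced: list[str] = []
    cond = float("nan")
    while True:
        if len(active) == 1:
            vf_active = np.array([1.0])
            cond = 1.0
            break
        vf_active, cond = _solve(mu_all[:, active], target)
        neg = vf_active < -negative_tolerance
        if not neg.any():
            vf_active = np.clip(vf_active, 0.0, None)
            vf_active /= vf_active.sum()
            break
        worst = int(np.argmin(vf_active))
        forced.append(names[active[worst]])
        del active[worst]

    vf = {name: 0.0 for name in names}
    for idx, frac in zip(active, vf_active):
        vf[names[idx]] = float(frac)

    mf: dict[str, float] = {}
    mf_residual = float("nan")
    if rho_eff is not None:
        mf, mf_residual = mass_fractions_from_volume(
            vf, {b.name: b.density for b in basis}, rho_eff
        )

    result_bmd = float("nan")
    if mineral is not None and mineral in vf:
        result_bmd = bmd(vf[mineral])

    return DecompositionResult(
        label=voi.label,
        volume_fractions=vf,
        c_factor=c_factor,
        condition_number=cond,
        fallback=tuple(forced),
        mass_fractions=mf,
        mass_fraction_residual=mf_residual,
        z_eff=z_eff,
        rho_eff=rho_eff if rho_eff is not None else float("nan"),
        bmd_mg_cm3=result_bmd,
    )


def mass_fractions_from_volume(
    volume_fractions: dict[str, float],
    densities: dict[str, float],
    rho_eff: float,
) -> tuple[dict[str, float], float]:
    """MF_X = VF_X * rho_X / rho_eff; returns (fractions, |sum(MF) - 1|)."""
    if rho_eff <= 0:
        raise ValueError("rho_eff must be positive")
    mf = {}
    for name, vf in volume_fractions.items():
        rho = densities[name]
        if rho <= 0:
            raise ValueError(f"{name}: density must be positive")
        mf[name] = vf * rho / rho_eff
    return mf, abs(sum(mf.values()) - 1.0)


def bmd(
    volume_fraction_bone: float,
    mineral_density_mg_cm3: float = BMD_REFERENCE_DENSITY_MG_CM3,
) -> float:
    """Bone mineral density [mg/cm^3] from the bone-mineral volume fraction."""
    if not 0.0 <= volume_fraction_bone <= 1.0:
        raise ValueError("volume fraction must lie in [0, 1]")
    return volume_fraction_bone * mineral_density_mg_cm3
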