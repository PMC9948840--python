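"""Synthetic dual-energy phantoms with known ground truth.

The forward model lives exactly where the estimation method operates — at
the reconstructed-HU level: a region's attenuation pair is the
volume-fraction-weighted sum of its constituent materials' water-relative
attenuations under a given beam calibration, scaled by an optional
beam-hardening factor and converted to HU.  Voxel volumes add independent
Gaussian HU noise per acquisition (seeded; no wall-clock entropy), which
emulates reconstruction noise but not beam hardening, partial volume at
region borders, scatter, or texture from real trabecular microstructure.

Shipped scenes mirror the standard experimental layouts: ``cirs7`` (seven
calibration inserts), ``esp3`` (spine-phantom spongiosa at 50/100/200
mg/cm^3 hydroxyapatite), ``vial_rack`` (oil, water and hydroxyapatite
concentration vials), ``femur_toy`` (head/neck/shaft-like marrow-bone
mixtures).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import BeamCalibration
from .decomposition import basis_attenuation
from .materials import MaterialSpec, derive
from .imaging import ImagePair, Volume
from .phantoms import (
    HYDROXYAPATITE,
    PEANUT_OIL,
    WATER_PHEMA,
    cirs_inserts,
)

__all__ = [
    "PhantomScene",
    "Region",
    "SceneRender",
    "builtin_scene",
    "forward_hu",
    "mixture_truth",
    "render_scene",
]

AIR_HU = -1000.0


def forward_hu(
    mixture: dict[MaterialSpec, float] | list[tuple[MaterialSpec, float]],
    beam: BeamCalibration,
    c_factor: float = 1.0,
) -> tuple[float, float]:
    """HU pair of a volume-fraction mixture under a calibrated beam.

    ``mu_eff* = C * sum VF_X mu_X*`` per beam; ``HU = 1000 (mu_eff* - 1)``.
    """
    items = list(mixture.items()) if isinstance(mixture, dict) else list(mixture)
    total_vf = sum(vf for _, vf in items)
    if abs(total_vf - 1.0) > 1e-9:
        raise ValueError(f"volume fractions sum to {total_vf}, expected 1")
    mu_low = mu_high = 0.0
    for mat, vf in items:
        b = basis_attenuation(mat, beam)
        mu_low += vf * b.mu_star_low
        mu_high += vf * b.mu_star_high
    return (
        1000.0 * (c_factor * mu_low - 1.0),
        1000.0 * (c_factor * mu_high - 1.0),
    )


def mixture_truth(
    mixture: dict[MaterialSpec, float] | list[tuple[MaterialSpec, float]], n: float
) -> dict[str, float]:
    """Ground-truth Z_eff, rho_e*, and mass density of a volume-fraction mixture."""
    items = list(mixture.items()) if isinstance(mixture, dict) else list(mixture)
    rho_mix = sum(vf * m.density for m, vf in items)
    fractions: dict[str, float] = {}
    for m, vf in items:
        for el, w in m.mass_fractions.items():
            fractions[el] = fractions.get(el, 0.0) + vf * m.density * w / rho_mix
    mix = MaterialSpec("mixture", fractions, rho_mix)
    d = derive(mix, n)
    return {"z_eff": d.z_eff, "rho_e_star": d.rho_e_star, "density": rho_mix}


@dataclass(frozen=True)
class Region:
    """An axis-aligned primitive filled with a volume-fraction mixture."""

    label: int
    geometry: str  # "box" | "cylinder" | "sphere"
    center: tuple[float, float, float]  # voxel coordinates
    size: tuple[float, float, float]  # box: full extents; cyl/sphere: (r, r, half-h)
    mixture: tuple[tuple[str, float], ...]  # (material name, VF)

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        idx = np.indices(shape, dtype=float)
        d = [idx[k] - self.center[k] for k in range(3)]
        if self.geometry == "box":
            return np.all(
                [np.abs(d[k]) <= self.size[k] / 2.0 for k in range(3)], axis=0
            )
        if self.geometry == "cylinder":  # axis along z
            r2 = (d[0] / self.size[0]) ** 2 + (d[1] / self.size[1]) ** 2
            return (r2 <= 1.0) & (np.abs(d[2]) <= self.size[2])
        if self.geometry == "sphere":
            r2 = sum((d[k] / self.size[k]) ** 2 for k in range(3))
            return r2 <= 1.0
        raise ValueError(f"unknown geometry {self.geometry!r}")


@dataclass(frozen=True)
class PhantomScene:
    """Scene description: grid, regions, per-beam noise, and a mandatory seed."""

    shape: tuple[int, int, int]
    regions: tuple[Region, ...]
    materials: dict[str, MaterialSpec]
    noise_sd_hu: tuple[float, float] = (0.0, 0.0)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0
    background_hu: float = AIR_HU

    def __post_init__(self):
        labels = [r.label for r in self.regions]
        if len(set(labels)) != len(labels):
            raise ValueError("region labels must be unique")
        for r in self.regions:
            total = sum(vf for _, vf in r.mixture)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"region {r.label}: fractions sum to {total}")
            for name, _ in r.mixture:
                if name not in self.materials:
                    raise ValueError(f"region {r.label}: unknown material {name!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, materials: dict[str, MaterialSpec]) -> "PhantomScene":
        raw = yaml.safe_load(Path(path).read_text())
        regions = tuple(
            Region(
                label=int(r["label"]),
                geometry=r["geometry"],
                center=tuple(float(v) for v in r["center"]),
                size=tuple(float(v) for v in r["size"]),
                mixture=tuple((k, float(v)) for k, v in r["mixture"].items()),
            )
            for r in raw["regions"]
        )
        return cls(
            shape=tuple(int(v) for v in raw["shape"]),
            regions=regions,
            materials=materials,
            noise_sd_hu=tuple(float(v) for v in raw.get("noise_sd_hu", (0.0, 0.0))),
            spacing_mm=tuple(float(v) for v in raw.get("spacing_mm", (1.0, 1.0, 1.0))),
            seed=int(raw["seed"]),
            background_hu=float(raw.get("background_hu", AIR_HU)),
        )


@dataclass(frozen=True)
class SceneRender:
    pair: ImagePair
    mask: np.ndarray
    truth: pd.DataFrame = field(repr=False)


def render_scene(scene: PhantomScene, beam: BeamCalibration) -> SceneRender:
    """Voxelize a scene into a noisy dual-kVp image pair plus ground truth.

    Overlapping regions are resolved in listing order (later regions win).
    The truth table carries each region's volume fractions, Z_eff, rho_e*
    and mass density.
    """
    rng = np.random.default_rng(scene.seed)
    low = np.full(scene.shape, scene.background_hu, dtype=float)
    high = np.full(scene.shape, scene.background_hu, dtype=float)
    mask = np.zeros(scene.shape, dtype=np.int16)
    rows = []
    for region in scene.regions:
        mixture = [(scene.materials[nm], vf) for nm, vf in region.mixture]
        hu_low, hu_high = forward_hu(mixture, beam)
        sel = region.mask(scene.shape)
        low[sel] = hu_low
        high[sel] = hu_high
        mask[sel] = region.label
        truth = mixture_truth(mixture, beam.n)
        rows.append(
            {
                "label": region.label,
                "hu_low_true": hu_low,
                "hu_high_true": hu_high,
                **{f"vf_{nm}": vf for nm, vf in region.mixture},
                **truth,
            }
        )
    if scene.noise_sd_hu[0] > 0:
        low += rng.normal(0.0, scene.noise_sd_hu[0], scene.shape)
    if scene.noise_sd_hu[1] > 0:
        high += rng.normal(0.0, scene.noise_sd_hu[1], scene.shape)
    affine = np.diag([*scene.spacing_mm, 1.0])
    pair = ImagePair(
        low=Volume(low, affine, kvp=None), high=Volume(high, affine, kvp=None)
    )
    return SceneRender(pair=pair, mask=mask, truth=pd.DataFrame(rows))


def _esp_spongiosa_mixture(ha_mg_cm3: float) -> tuple[tuple[str, float], ...]:
    vf_ha = ha_mg_cm3 / 1000.0 / HYDROXYAPATITE.density
    return (("hydroxyapatite", vf_ha), ("water", 1.0 - vf_ha))


def builtin_scene(
    name: str,
    noise_sd_hu: tuple[float, float] = (0.0, 0.0),
    seed: int = 0,
    region_size: int = 12,
) -> PhantomScene:
    """Construct one of the shipped scenes: cirs7, esp3, vial_rack, femur_toy."""
    water = MaterialSpec.from_formula("water", "H2O", 1.0)
    mats: dict[str, MaterialSpec] = {
        "water": water,
        "hydroxyapatite": HYDROXYAPATITE,
        "peanut_oil": PEANUT_OIL,
        "water_phema": WATER_PHEMA,
        **cirs_inserts(),
    }
    s = region_size

    def grid_regions(mixtures: list[tuple[tuple[str, float], ...]]) -> tuple[Region, ...]:
        k = len(mixtures)
        shape_x = k * (s + 4) + 4
        return tuple(
            Region(
                label=i + 1,
                geometry="box",
                center=(4 + (s + 4) * i + s / 2.0, s / 2.0 + 2.0, s / 2.0 + 2.0),
                size=(float(s),) * 3,
                mixture=mix,
            )
            for i, mix in enumerate(mixtures)
        ), (shape_x, s + 4, s + 4)

    if name == "cirs7":
        mixtures = [((nm, 1.0),) for nm in cirs_inserts()]
    elif name == "esp3":
        mixtures = [_esp_spongiosa_mixture(c) for c in (50.0, 100.0, 200.0)]
    elif name == "vial_rack":
        mixtures = [
            (("peanut_oil", 1.0),),
            (("water", 1.0),),
            *(_ha_vial(c) for c in (100.0, 200.0, 300.0)),
        ]
    elif name == "femur_toy":
        mixtures = [
            (("hydroxyapatite", 0.22), ("water_phema", 0.78)),  # head: no fat
            (("hydroxyapatite", 0.14), ("peanut_oil", 0.41), ("water_phema", 0.45)),
            (("hydroxyapatite", 0.01), ("peanut_oil", 0.99)),  # shaft: almost all fat
        ]
    else:
        raise ValueError(f"unknown builtin scene {name!r}")
    regions, shape = grid_regions(mixtures)
    return PhantomScene(
        shape=shape,
        regions=regions,
        materials=mats,
        noise_sd_hu=noise_sd_hu,
        seed=seed,
    )


def _ha_vial(conc_mg_cm3: float) -> tuple[tuple[str, float], ...]:
    vf = conc_mg_cm3 / 1000.0 / HYDROXYAPATITE.density
    return (("hydroxyapatite", vf), ("water_phema", 1.0 - vf))
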