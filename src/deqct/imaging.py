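"""Reading paired CT volumes and extracting VOI statistics.

Volumes load from NIfTI files or DICOM series directories into Hounsfield
units (rescale slope/intercept applied for DICOM).  The two acquisitions of
a dual-energy pair must share the voxel grid exactly — no silent
resampling; a geometry mismatch is an error, because quantification across
misaligned grids would be meaningless.  Masks are integer NIfTI volumes on
the same grid; every positive label becomes one VOI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .rhoz import VOIMeasurement

__all__ = ["ImagePair", "Volume", "load_image_pair", "load_volume", "save_volume", "voi_stats"]

log = logging.getLogger(__name__)

GRID_ATOL_MM = 1e-3


@dataclass(frozen=True)
class Volume:
    """A 3-D HU array with its affine geometry and optional kVp metadata."""

    data: np.ndarray
    affine: np.ndarray
    kvp: float | None = None

    @property
    def spacing_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))


@dataclass(frozen=True)
class ImagePair:
    """Low- and high-kVp volumes on one common voxel grid."""

    low: Volume
    high: Volume

    def __post_init__(self):
        if self.low.data.shape != self.high.data.shape:
            raise ValueError(
                f"grid shape mismatch: {self.low.data.shape} vs {self.high.data.shape}"
            )
        if not np.allclose(self.low.affine, self.high.affine, atol=GRID_ATOL_MM):
            raise ValueError("image pair affines differ beyond 1e-3 mm")


def _load_nifti(path: Path, kvp: float | None) -> Volume:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if not np.isfinite(data).all():
        raise ValueError(f"{path}: non-finite voxel values")
    return Volume(data=data, affine=np.asarray(img.affine), kvp=kvp)


def _load_dicom_series(path: Path, kvp: float | None) -> Volume:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".dcm", ""))
    slices = []
    for f in files:
        if not f.is_file():
            continue
        ds = pydicom.dcmread(str(f))
        if hasattr(ds, "pixel_array"):
            slices.append(ds)
    if not slices:
        raise ValueError(f"no DICOM slices found under {path}")
    slices.sort(key=lambda ds: float(getattr(ds, "ImagePositionPatient", [0, 0, 0])[2]))
    positions = [float(getattr(ds, "ImagePositionPatient", [0, 0, i])[2])
                 for i, ds in enumerate(slices)]
    if len(positions) > 2:
        steps = np.diff(positions)
        if not np.allclose(steps, steps[0], atol=GRID_ATOL_MM):
            raise ValueError(f"{path}: inconsistent slice spacing {steps}")
    arrays = []
    for ds in slices:
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = getattr(ds, "RescaleIntercept", None)
        if intercept is None:
            log.warning("%s: missing RescaleIntercept, assuming 0", path)
            intercept = 0.0
        arrays.append(arr * slope + float(intercept))
    data = np.stack(arrays, axis=-1)
    ds0 = slices[0]
    dr, dc = (float(v) for v in getattr(ds0, "PixelSpacing", [1.0, 1.0]))
    dz = float(positions[1] - positions[0]) if len(positions) > 1 else 1.0
    affine = np.diag([dr, dc, dz, 1.0])
    affine[:3, 3] = [float(v) for v in getattr(ds0, "ImagePositionPatient", [0, 0, 0])]
    if kvp is None and hasattr(ds0, "KVP"):
        kvp = float(ds0.KVP)
    return Volume(data=data, affine=affine, kvp=kvp)


def load_volume(path: str | Path, kvp: float | None = None) -> Volume:
    """Load a CT volume in HU from a NIfTI file or a DICOM series directory."""
    path = Path(path)
    if path.is_dir():
        return _load_dicom_series(path, kvp)
    return _load_nifti(path, kvp)


def save_volume(volume: Volume, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(volume.data, volume.affine), str(path))


def load_image_pair(
    low_path: str | Path,
    high_path: str | Path,
    kvp_low: float | None = None,
    kvp_high: float | None = None,
) -> ImagePair:
    return ImagePair(
        low=load_volume(low_path, kvp_low), high=load_volume(high_path, kvp_high)
    )


def voi_stats(
    pair: ImagePair, mask: np.ndarray, label: int | None = None
) -> list[VOIMeasurement]:
    """Mean/SD/count of HU per mask label over both volumes.

    ``mask`` is an integer array on the image grid; each positive label
    yields one measurement (or only ``label`` when given).
    """
    mask = np.asarray(mask)
    if mask.shape != pair.low.data.shape:
        raise ValueError(
            f"mask grid {mask.shape} differs from image grid {pair.low.data.shape}"
        )
    labels = [label] if label is not None else sorted(
        int(v) for v in np.unique(mask) if v > 0
    )
    out = []
    for lab in labels:
        sel = mask == lab
        n = int(sel.sum())
        if n == 0:
            raise ValueError(f"mask label {lab} selects no voxels")
        lo = pair.low.data[sel]
        hi = pair.high.data[sel]
        out.append(
            VOIMeasurement(
                label=str(lab),
                hu_low=float(lo.mean()),
                hu_high=float(hi.mean()),
                sd_low=float(lo.std(ddof=1)) if n > 1 else 0.0,
                sd_high=float(hi.std(ddof=1)) if n > 1 else 0.0,
                n_voxels=n,
            )
        )
    return out
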