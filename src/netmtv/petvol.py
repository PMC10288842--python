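"""PET volume container, SUV computation and spherical reference VOIs.

A PET scan is represented as a 3D grid of standardized uptake values
(SUV, body-weight normalized, dimensionless) together with the physical
voxel spacing in mm.  Reference-tissue statistics (liver, bone, spleen)
are read out of fixed-volume spherical volumes of interest (VOIs):
a 5 ml sphere in the left liver lobe, a 3 ml sphere in the fifth lumbar
vertebra, a 5 ml sphere in the spleen.

Conventions
-----------
* Axis order is (x, y, z) = array axes (0, 1, 2); physical coordinates
  are in mm with the origin at the corner of voxel (0, 0, 0), so voxel
  ``(i, j, k)`` has its center at ``origin + (i + 0.5, j + 0.5, k + 0.5)
  * spacing``.
* VOI membership: a voxel belongs to a sphere iff its *center* lies
  within the sphere radius (no partial-volume weighting).
* The SD inside a VOI is the sample SD (n-1 denominator) by default,
  matching common workstation behaviour; switchable via ``ddof``.
* Tissue density is taken as 1 g/ml, and input volumes are assumed
  decay-corrected, as scanner software delivers them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import nibabel as nib
import numpy as np

__all__ = [
    "PetVolume",
    "SphereVOI",
    "ReferenceStats",
    "suv_from_activity",
    "voi_mask",
    "reference_stats",
    "read_volume",
    "write_volume",
    "write_mask",
]


class EmptyVOIError(ValueError):
    """Raised when a spherical VOI selects no voxel of the grid."""


@dataclass(frozen=True)
class PetVolume:
    """3D PET volume in SUV units with physical voxel spacing.

    Parameters
    ----------
    voxels
        3D array of SUV values; must be finite and non-negative.
    spacing
        Per-axis voxel edge length in mm, all components > 0.
    origin
        Physical coordinate (mm) of the corner of voxel (0, 0, 0).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=np.float64)
        if vox.ndim != 3:
            raise ValueError(f"voxels must be 3D, got ndim={vox.ndim}")
        if not np.all(np.isfinite(vox)):
            raise ValueError("SUV values must be finite")
        if np.any(vox < 0):
            raise ValueError("SUV values must be >= 0")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError(f"spacing must be 3 positive components, got {self.spacing}")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", sp)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in ml (spacing product in mm^3 / 1000)."""
        return float(np.prod(self.spacing)) / 1000.0

    def voxel_centers_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis physical center coordinates of every voxel (open grids)."""
        ax = []
        for n, s, o in zip(self.shape, self.spacing, self.origin):
            ax.append(o + (np.arange(n) + 0.5) * s)
        return np.ix_(ax[0], ax[1], ax[2])  # type: ignore[return-value]


@dataclass(frozen=True)
class SphereVOI:
    """Fixed-volume spherical volume of interest at a physical location.

    ``radius_mm`` is derived from the nominal volume:
    r = (3 V / 4 pi)^(1/3) with V in mm^3 (1 ml = 1000 mm^3).
    """

    center: tuple[float, float, float]
    volume_ml: float
    label: Literal["liver", "bone", "spleen", "other"] = "other"

    def __post_init__(self) -> None:
        if self.volume_ml <= 0:
            raise ValueError(f"volume_ml must be > 0, got {self.volume_ml}")
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))

    @property
    def radius_mm(self) -> float:
        return float((3.0 * self.volume_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0))


@dataclass(frozen=True)
class ReferenceStats:
    """SUV statistics inside a reference VOI."""

    suv_mean: float
    suv_max: float
    suv_sd: float
    n_voxels: int
    ddof: int = field(default=1, compare=False)

    def __post_init__(self) -> None:
        if self.n_voxels < 1:
            raise ValueError("n_voxels must be >= 1")
        if not (self.suv_max >= self.suv_mean >= 0):
            raise ValueError("require suv_max >= suv_mean >= 0")
        if self.suv_sd < 0:
            raise ValueError("suv_sd must be >= 0")


def suv_from_activity(
    activity_conc_kbq_ml: float, injected_activity_mbq: float, body_weight_kg: float
) -> float:
    """Body-weight standardized uptake value.

    SUV = C / (A / W) with tissue activity concentration C, injected
    activity A and body weight W; density 1 g/ml makes the result
    dimensionless.  With C in kBq/ml, A in MBq and W in kg the unit
    factors (1 MBq = 1000 kBq, 1 kg = 1000 g = 1000 ml at unit density)
    cancel, leaving ``C * W / A``.

    Linearity: the result is linear in C and W and inverse-linear in A.
    """
    if injected_activity_mbq <= 0 or body_weight_kg <= 0:
        raise ValueError("injected activity and body weight must be > 0")
    if activity_conc_kbq_ml < 0:
        raise ValueError("activity concentration must be >= 0")
    return activity_conc_kbq_ml * body_weight_kg / injected_activity_mbq


def voi_mask(volume: PetVolume, voi: SphereVOI) -> np.ndarray:
    """Boolean mask of voxels whose center lies inside the VOI sphere.

    Raises
    ------
    EmptyVOIError
        If the sphere contains no voxel center (e.g. entirely outside
        the grid).
    """
    cx, cy, cz = voi.center
    gx, gy, gz = volume.voxel_centers_mm()
    d2 = (gx - cx) ** 2 + (gy - cy) ** 2 + (gz - cz) ** 2
    mask = d2 <= voi.radius_mm**2
    if not mask.any():
        raise EmptyVOIError(
            f"{voi.label} VOI at {voi.center} (r={voi.radius_mm:.2f} mm) "
            "selects no voxel"
        )
    return mask


def reference_stats(volume: PetVolume, voi: SphereVOI, ddof: int = 1) -> ReferenceStats:
    """Mean / max / SD of SUV inside a spherical reference VOI.

    ``ddof=1`` (sample SD) is the default; pass ``ddof=0`` for the
    population convention.  A single-voxel VOI has SD 0 either way.
    """
    mask = voi_mask(volume, voi)
    vals = volume.voxels[mask]
    sd = 0.0 if vals.size <= ddof else float(np.std(vals, ddof=ddof))
    return ReferenceStats(
        suv_mean=float(vals.mean()),
        suv_max=float(vals.max()),
        suv_sd=sd,
        n_voxels=int(vals.size),
        ddof=ddof,
    )


# ---------------------------------------------------------------------------
# NIfTI I/O


def read_volume(path: str | Path) -> PetVolume:
    """Load a NIfTI-1 volume as a :class:`PetVolume`; spacing from the header."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    zooms = img.header.get_zooms()[:3]
    return PetVolume(voxels=data, spacing=tuple(float(z) for z in zooms))


def write_volume(volume: PetVolume, path: str | Path) -> None:
    affine = np.diag(list(volume.spacing) + [1.0])
    affine[:3, 3] = volume.origin
    nib.save(nib.Nifti1Image(volume.voxels.astype(np.float32), affine), str(path))


def write_mask(mask: np.ndarray, spacing: tuple[float, float, float], path: str | Path) -> None:
    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(path))
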