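"""Adaptive-threshold molecular tumor volume (MTV) segmentation.

Pathologic SSTR expression is defined relative to healthy liver uptake:
a voxel is tumor-suspicious when its SUV exceeds

    threshold = 1.5 * SUVmean_liver + 2 * SD_liver

("higher than" -> strict inequality; voxels exactly at the threshold are
background).  Supra-threshold voxels are grouped into connected
components (26-neighborhood by default, emulating single-click region
growth on a workstation), components dominated by a caller-supplied
exclusion mask (physiological uptake: kidneys, pituitary, spleen...) are
dropped, and the surviving components become lesions whose volumes sum
to the total MTV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .petvol import PetVolume, ReferenceStats

__all__ = [
    "Lesion",
    "SegmentationResult",
    "segmentation_threshold",
    "segment_mtv",
    "largest_lesion_metrics",
]


class EmptySegmentationError(ValueError):
    """Raised when per-lesion metrics are requested but no lesion exists."""


@dataclass(frozen=True)
class Lesion:
    """One connected supra-threshold component."""

    voxel_indices: np.ndarray  # (n, 3) int array of grid indices
    volume_ml: float
    suv_max: float
    suv_mean: float

    @property
    def n_voxels(self) -> int:
        return int(self.voxel_indices.shape[0])

    @property
    def seed_index(self) -> tuple[int, int, int]:
        """Lexicographically smallest voxel index; deterministic lesion anchor."""
        order = np.lexsort(self.voxel_indices.T[::-1])
        return tuple(int(v) for v in self.voxel_indices[order[0]])


@dataclass(frozen=True)
class SegmentationResult:
    lesions: tuple[Lesion, ...]
    threshold: float
    total_mtv_ml: float
    excluded_component_count: int
    metadata: dict = field(default_factory=dict, compare=False)


def segmentation_threshold(liver: ReferenceStats | None = None, *,
                           suv_mean: float | None = None,
                           suv_sd: float | None = None) -> float:
    """Liver-referenced SUV threshold: ``1.5 * mean + 2 * SD``.

    Accepts either a :class:`~netmtv.petvol.ReferenceStats` for the liver
    VOI or explicit ``suv_mean`` / ``suv_sd`` keywords.
    """
    if liver is not None:
        suv_mean, suv_sd = liver.suv_mean, liver.suv_sd
    if suv_mean is None or suv_sd is None:
        raise ValueError("provide liver stats or suv_mean and suv_sd")
    if suv_mean < 0 or suv_sd < 0:
        raise ValueError("liver SUV mean and SD must be >= 0")
    return 1.5 * suv_mean + 2.0 * suv_sd


_STRUCTS = {
    26: np.ones((3, 3, 3), dtype=bool),
    6: ndimage.generate_binary_structure(3, 1),
}


def segment_mtv(
    volume: PetVolume,
    threshold: float,
    exclusion_mask: np.ndarray | None = None,
    min_lesion_ml: float = 0.0,
    *,
    connectivity: int = 26,
    exclusion_overlap_fraction: float = 0.5,
) -> SegmentationResult:
    """Threshold the volume and extract lesions.

    Parameters
    ----------
    volume
        PET volume in SUV units.
    threshold
        SUV cut; voxels strictly above it are candidate tumor.
    exclusion_mask
        Optional boolean mask on the same grid flagging physiological
        uptake.  A component with more than ``exclusion_overlap_fraction``
        of its voxels inside the mask is dropped (and counted).
    min_lesion_ml
        Components smaller than this are discarded (default 0: keep all).
    connectivity
        26 (full neighborhood, default) or 6 (face neighbors).

    Returns
    -------
    SegmentationResult
        Lesions sorted by descending volume (ties: higher SUVmax first,
        then lexicographic seed index), total MTV, exclusion count.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if connectivity not in _STRUCTS:
        raise ValueError("connectivity must be 26 or 6")
    if exclusion_mask is not None:
        exclusion_mask = np.asarray(exclusion_mask, dtype=bool)
        if exclusion_mask.shape != volume.shape:
            raise ValueError(
                f"exclusion mask shape {exclusion_mask.shape} != volume {volume.shape}"
            )

    binary = volume.voxels > threshold  # strict: "higher than"
    labels, n_comp = ndimage.label(binary, structure=_STRUCTS[connectivity])
    vox_ml = volume.voxel_volume_ml

    lesions: list[Lesion] = []
    excluded = 0
    for lab in range(1, n_comp + 1):
        comp = labels == lab
        idx = np.argwhere(comp)
        if exclusion_mask is not None:
            overlap = np.count_nonzero(exclusion_mask[comp]) / idx.shape[0]
            if overlap > exclusion_overlap_fraction:
                excluded += 1
                continue
        vol_ml = idx.shape[0] * vox_ml
        if vol_ml < min_lesion_ml:
            continue
        vals = volume.voxels[comp]
        lesions.append(
            Lesion(
                voxel_indices=idx,
                volume_ml=vol_ml,
                suv_max=float(vals.max()),
                suv_mean=float(vals.mean()),
            )
        )

    lesions.sort(key=lambda L: (-L.volume_ml, -L.suv_max, L.seed_index))
    return SegmentationResult(
        lesions=tuple(lesions),
        threshold=float(threshold),
        total_mtv_ml=float(sum(L.volume_ml for L in lesions)),
        excluded_component_count=excluded,
        metadata={
            "connectivity": connectivity,
            "exclusion_overlap_fraction": exclusion_overlap_fraction,
            "min_lesion_ml": min_lesion_ml,
        },
    )


def largest_lesion_metrics(seg: SegmentationResult) -> tuple[float, float]:
    """(SUVmax, SUVmean) of the largest lesion by volume.

    Ties are broken toward the higher SUVmax, then the lexicographically
    smallest seed voxel index, so the choice is deterministic.
    """
    if not seg.lesions:
        raise EmptySegmentationError("segmentation contains no lesion")
    best = seg.lesions[0]  # already sorted with the documented tie-break
    return best.suv_max, best.suv_mean
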