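"""Inferior cerebellar gray reference region and SUVR normalization.

Tau tracers bind off-target in the dorsal cerebellum, so only the
inferior cerebellar gray serves as reference.  The cerebellar gray from
the anatomical segmentation is split into inferior and superior parts by
adjudication against smoothed binary masks built from the
reverse-normalized SUIT lobule atlas, PET is divided by the mean over
the inferior part, and — because isolated hotspots occasionally reach
into the reference itself — the reference can be scanned for large
supra-threshold clusters, which are excised and the SUVR renormalized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .volume_io import (
    DEFAULT_CONNECTIVITY,
    MASK_SMOOTH_FWHM_MM,
    LabeledVolume,
    ScalarVolume,
    VolumeGrid,
    assert_same_grid,
    component_masks,
    smooth_array,
)
from .roi_remap import CEREBELLUM_GRAY_CODES

log = logging.getLogger("taupvc")

#: SUIT lobule codes forming the inferior cerebellar gray.
SUIT_INFERIOR_INDICES = frozenset({6, *range(8, 29), 33, 34})

#: SUIT lobule codes forming the superior cerebellar gray.
SUIT_SUPERIOR_INDICES = frozenset({1, 2, 3, 4, 5, 7})

#: Edited label of the superior cerebellar gray (table row 77).
SUPERIOR_CEREBELLUM_LABEL = 77

#: Edited label of the inferior cerebellar reference.  The published
#: numbering fixes 79+ for choroid/tissue/hotspot ROIs and leaves 78 as
#: the only free slot.
INFERIOR_CEREBELLUM_LABEL = 78

#: Reference-hotspot scan defaults (SUVR units / voxels, strict >).
REFERENCE_HOTSPOT_THRESHOLD = 1.6
REFERENCE_HOTSPOT_MIN_VOXELS = 500


@dataclass
class CerebellarSplit:
    """Disjoint binary masks partitioning the cerebellar gray."""

    inferior_mask: np.ndarray
    superior_mask: np.ndarray

    def __post_init__(self) -> None:
        self.inferior_mask = np.asarray(self.inferior_mask, dtype=bool)
        self.superior_mask = np.asarray(self.superior_mask, dtype=bool)
        if (self.inferior_mask & self.superior_mask).any():
            raise ValueError("inferior and superior masks overlap")


@dataclass
class SuvrVolume:
    """PET normalized by the reference-region mean."""

    data: np.ndarray
    grid: VolumeGrid
    reference_mean: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != self.grid.shape:
            raise ValueError("SUVR data shape != grid shape")
        if not self.reference_mean > 0:
            raise ValueError(f"reference mean must be positive, got {self.reference_mean}")


def split_cerebellum(aparc: LabeledVolume,
                     suit: LabeledVolume,
                     mask_fwhm_mm: float = MASK_SMOOTH_FWHM_MM,
                     cerebellum_codes=CEREBELLUM_GRAY_CODES,
                     inferior_indices=SUIT_INFERIOR_INDICES,
                     superior_indices=SUIT_SUPERIOR_INDICES) -> CerebellarSplit:
    """Partition the aparc cerebellar gray into inferior/superior parts.

    Binary SUIT-derived masks are smoothed (8 mm FWHM by default) so every
    cerebellar-gray voxel — including those outside SUIT coverage — sees a
    nonzero value from at least one side; each voxel goes to the inferior
    part iff the smoothed inferior mask is strictly larger there.  Ties
    (including both sides zero) go to the superior part, keeping ambiguous
    voxels out of the reference denominator.
    """
    assert_same_grid([aparc, suit], names=["aparc", "suit"])
    cerebellum = np.isin(aparc.data, list(cerebellum_codes))
    if not cerebellum.any():
        raise ValueError("no cerebellar-gray voxels in the aparc volume")
    inf_raw = np.isin(suit.data, list(inferior_indices))
    sup_raw = np.isin(suit.data, list(superior_indices))
    if not (inf_raw.any() or sup_raw.any()):
        raise ValueError("SUIT volume contains no cerebellar lobule codes")
    vs = aparc.grid.voxel_size_mm
    sm_inf = smooth_array(inf_raw, vs, mask_fwhm_mm)
    sm_sup = smooth_array(sup_raw, vs, mask_fwhm_mm)
    inferior = cerebellum & (sm_inf > sm_sup)
    superior = cerebellum & ~inferior
    return CerebellarSplit(inferior, superior)


def normalize_suvr(pet: ScalarVolume, reference_mask: np.ndarray) -> SuvrVolume:
    """Divide PET by its mean over the reference mask."""
    reference_mask = np.asarray(reference_mask, dtype=bool)
    if not reference_mask.any():
        raise ValueError("reference mask is empty")
    ref_mean = float(pet.data[reference_mask].mean())
    if ref_mean <= 0:
        raise ValueError(f"reference mean must be positive, got {ref_mean}")
    return SuvrVolume(pet.data / ref_mean, pet.grid, ref_mean)


def scan_reference_hotspots(suvr: SuvrVolume,
                            inferior_mask: np.ndarray,
                            threshold: float = REFERENCE_HOTSPOT_THRESHOLD,
                            min_cluster_voxels: int = REFERENCE_HOTSPOT_MIN_VOXELS,
                            next_label: int = 85,
                            connectivity: int = DEFAULT_CONNECTIVITY,
                            ) -> tuple[np.ndarray, np.ndarray, SuvrVolume]:
    """Excise rare large hotspots from the reference and renormalize.

    Connected clusters of reference voxels with SUVR above ``threshold``
    and strictly more than ``min_cluster_voxels`` voxels are removed from
    the reference mask and each given the next free integer label
    (counting up after the highest hotspot label already assigned).  If
    any are found, the SUVR is renormalized to the mean over the cleaned
    reference; otherwise all outputs are returned unchanged.

    Returns ``(hotspot_labels, cleaned_mask, suvr)``.
    """
    inferior_mask = np.asarray(inferior_mask, dtype=bool)
    hot = inferior_mask & (suvr.data > threshold)
    hotspot_labels = np.zeros(suvr.data.shape, dtype=np.int32)
    cleaned = inferior_mask.copy()
    label = int(next_label)
    n_found = 0
    for comp in component_masks(hot, connectivity):
        if int(comp.sum()) > min_cluster_voxels:
            hotspot_labels[comp] = label
            cleaned &= ~comp
            label += 1
            n_found += 1
    if n_found == 0:
        return hotspot_labels, inferior_mask, suvr
    if not cleaned.any():
        raise ValueError("reference region empty after hotspot removal")
    log.info("scan_reference_hotspots: removed %d cluster(s) from the reference",
             n_found)
    rel_mean = float(suvr.data[cleaned].mean())
    renorm = SuvrVolume(suvr.data / rel_mean, suvr.grid,
                        suvr.reference_mean * rel_mean)
    return hotspot_labels, cleaned, renorm
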