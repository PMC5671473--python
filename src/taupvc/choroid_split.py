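"""Split the choroid plexus into high- and low-binding ROIs.

Choroid plexus binding is bimodal: the ventral portion next to the
hippocampus binds strongly (spilling into the hippocampal signal), the
dorsal portion weakly.  Voxels are seeded into the two classes by an
SUVR threshold at the reference level (1.0) with a contiguity filter,
and leftovers — small pockets below the contiguity cutoff — are
adjudicated by comparing the smoothed seed masks, yielding a total
partition of the choroid into labels 79 (high) and 80 (low).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .reference_region import SuvrVolume
from .volume_io import (
    DEFAULT_CONNECTIVITY,
    MASK_SMOOTH_FWHM_MM,
    component_masks,
    smooth_array,
)

log = logging.getLogger("taupvc")

CHOROID_HIGH_LABEL = 79
CHOROID_LOW_LABEL = 80


@dataclass(frozen=True)
class ChoroidPartition:
    """Parameters of the high/low choroid split."""

    high_label: int = CHOROID_HIGH_LABEL
    low_label: int = CHOROID_LOW_LABEL
    suvr_threshold: float = 1.0
    #: contiguity cutoff, inclusive ("at least 100 contiguous voxels").
    min_cluster_voxels: int = 100


def split_choroid(suvr: SuvrVolume,
                  choroid_mask: np.ndarray,
                  params: ChoroidPartition | None = None,
                  mask_fwhm_mm: float = MASK_SMOOTH_FWHM_MM,
                  connectivity: int = DEFAULT_CONNECTIVITY) -> np.ndarray:
    """Partition the choroid mask into high (79) / low (80) labels.

    Seeds are connected components of the thresholded SUVR within the
    choroid with at least ``min_cluster_voxels`` voxels.  Both seed masks
    are Gaussian-smoothed and every remaining choroid voxel joins the
    side with the larger smoothed value; ties (including both zero) go
    high, since over-estimating off-target choroid signal is the safer
    choice for protecting hippocampal estimates.  If neither class seeds
    at all, the whole choroid is labeled by direct thresholding with a
    warning.

    Returns an int32 label array that is nonzero exactly on the mask.
    """
    if params is None:
        params = ChoroidPartition()
    choroid_mask = np.asarray(choroid_mask, dtype=bool)
    if not choroid_mask.any():
        raise ValueError("choroid mask is empty")

    low_raw = choroid_mask & (suvr.data <= params.suvr_threshold)
    high_raw = choroid_mask & (suvr.data > params.suvr_threshold)
    low_seed = np.zeros(choroid_mask.shape, dtype=bool)
    high_seed = np.zeros(choroid_mask.shape, dtype=bool)
    for comp in component_masks(low_raw, connectivity):
        if int(comp.sum()) >= params.min_cluster_voxels:
            low_seed |= comp
    for comp in component_masks(high_raw, connectivity):
        if int(comp.sum()) >= params.min_cluster_voxels:
            high_seed |= comp

    out = np.zeros(choroid_mask.shape, dtype=np.int32)
    if not (low_seed.any() or high_seed.any()):
        log.warning("split_choroid: no seed component of either class; "
                    "falling back to direct thresholding")
        out[high_raw] = params.high_label
        out[low_raw] = params.low_label
        return out

    vs = suvr.grid.voxel_size_mm
    sm_high = smooth_array(high_seed, vs, mask_fwhm_mm)
    sm_low = smooth_array(low_seed, vs, mask_fwhm_mm)
    rest = choroid_mask & ~low_seed & ~high_seed
    high = high_seed | (rest & (sm_high >= sm_low))  # ties -> high
    low = low_seed | (rest & (sm_low > sm_high))
    out[high] = params.high_label
    out[low] = params.low_label
    return out
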