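"""CSF and bone+meninges tissue ROIs, and stray gray-voxel assignment.

After the anatomical remap, choroid split and hotspot detection, voxels
carrying tracer signal can still be unassigned — CSF, skull and
meninges, and occasional gray-matter voxels missed by the anatomical
segmentation.  Leaving them at 0 makes the GTM assume they have zero
activity, which biases neighbouring estimates.  This module classifies
the remainder into CSF low/high (81/82) and bone+meninges low/high
(83/84) from the tissue-probability maps and SUVR, then assigns stray
gray voxels the modal label of their 26-neighborhood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .reference_region import SuvrVolume
from .volume_io import LabeledVolume, ProbabilityVolume

log = logging.getLogger("taupvc")

CSF_LOW_LABEL = 81
CSF_HIGH_LABEL = 82
BONE_LOW_LABEL = 83
BONE_HIGH_LABEL = 84


@dataclass(frozen=True)
class TissueClassParams:
    suvr_floor: float = 0.1       # strict lower bound on all classes
    suvr_split: float = 1.0       # low < split, high >= split
    probability_cut: float = 0.3
    csf_low: int = CSF_LOW_LABEL
    csf_high: int = CSF_HIGH_LABEL
    bone_low: int = BONE_LOW_LABEL
    bone_high: int = BONE_HIGH_LABEL

    def __post_init__(self) -> None:
        if not self.suvr_floor < self.suvr_split:
            raise ValueError("suvr_floor must be below suvr_split")


def classify_csf_bone(edited: LabeledVolume,
                      c1: ProbabilityVolume,
                      c3: ProbabilityVolume,
                      c4: ProbabilityVolume,
                      c5: ProbabilityVolume,
                      suvr: SuvrVolume,
                      params: TissueClassParams | None = None,
                      split_high_low: bool = True) -> LabeledVolume:
    """Label unassigned voxels as CSF (81/82) or bone+meninges (83/84).

    Only voxels with ``edited == 0`` are touched (monotone refinement).
    CSF requires ``(c3 > 0.3 or c1 > 0.3) and c3 > 0 and c3 > c4+c5``
    — the gray-matter clause catches voxels the anatomical segmentation
    missed but the probabilistic one called gray.  Bone+meninges
    requires ``c4+c5 > 0.3 and c4+c5 > c3``.  Low means
    ``floor < SUVR < 1`` (strict both ends), high means ``SUVR >= 1``.
    With ``split_high_low=False`` each tissue becomes a single ROI
    (``SUVR > floor``) under its low label.
    """
    if params is None:
        params = TissueClassParams()
    data = edited.data
    free = data == 0
    c45 = c4.data + c5.data
    s = suvr.data
    cut = params.probability_cut

    csf_base = free & ((c3.data > cut) | (c1.data > cut)) \
        & (c3.data > 0) & (c3.data > c45)
    bone_base = free & (c45 > cut) & (c45 > c3.data)

    out = data.copy()
    if split_high_low:
        low = (s > params.suvr_floor) & (s < params.suvr_split)
        high = s >= params.suvr_split
        out[csf_base & low] = params.csf_low
        out[csf_base & high] = params.csf_high
        out[bone_base & low] = params.bone_low
        out[bone_base & high] = params.bone_high
    else:
        active = s > params.suvr_floor
        out[csf_base & active] = params.csf_low
        out[bone_base & active] = params.bone_low
    return LabeledVolume(out, edited.grid)


# 26-neighborhood offsets (all nonzero 3-D offsets in {-1,0,1}^3).
_NEIGHBOR_OFFSETS = [
    (dx, dy, dz)
    for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def _modal_nonzero_neighbor(labels: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Most common nonzero 26-neighbor label per coordinate (0 if none).

    Ties resolve to the smallest label (bincount argmax returns the first
    maximum), which keeps the pass deterministic.
    """
    padded = np.pad(labels, 1, mode="constant", constant_values=0)
    neigh = np.stack([
        padded[coords[:, 0] + dx + 1, coords[:, 1] + dy + 1, coords[:, 2] + dz + 1]
        for dx, dy, dz in _NEIGHBOR_OFFSETS
    ])  # (26, M)
    out = np.zeros(coords.shape[0], dtype=labels.dtype)
    for m in range(coords.shape[0]):
        vals = neigh[:, m]
        vals = vals[vals > 0]
        if vals.size:
            out[m] = np.bincount(vals).argmax()
    return out


def assign_stray_gray(edited: LabeledVolume,
                      c1: ProbabilityVolume,
                      c3: ProbabilityVolume,
                      c4: ProbabilityVolume,
                      c5: ProbabilityVolume,
                      suvr: SuvrVolume,
                      max_passes: int = 10,
                      single_pass: bool = False,
                      zero_tol: float = 1e-9) -> tuple[LabeledVolume, int]:
    """Assign stray gray voxels the modal label of their neighbors.

    A stray voxel has gray probability > 0.3, exactly zero probability of
    CSF, skull or meninges (below ``zero_tol`` for float-stored maps),
    SUVR > 0.1, and is still unassigned.  Assignments within one pass are
    computed from a snapshot, then applied simultaneously; passes repeat
    until nothing changes or ``max_passes`` is reached, because a single
    pass can leave interior strays with all-zero neighborhoods.  Voxels
    whose neighborhoods never contain a nonzero label stay 0.

    Returns the updated volume and the number of passes executed.
    """
    stray = (edited.data == 0) & (c1.data > 0.3) \
        & (c3.data <= zero_tol) & (c4.data <= zero_tol) & (c5.data <= zero_tol) \
        & (suvr.data > 0.1)
    labels = edited.data.copy()
    n_passes = 0
    limit = 1 if single_pass else max_passes
    while n_passes < limit:
        coords = np.argwhere(stray & (labels == 0))
        if coords.size == 0:
            break
        assigned = _modal_nonzero_neighbor(labels, coords)
        n_passes += 1
        if not (assigned > 0).any():
            break
        hit = assigned > 0
        labels[coords[hit, 0], coords[hit, 1], coords[hit, 2]] = assigned[hit]
    if n_passes:
        log.info("assign_stray_gray: %d pass(es)", n_passes)
    return LabeledVolume(labels, edited.grid), n_passes
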