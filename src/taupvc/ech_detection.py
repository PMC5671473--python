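"""Extra-cortical hotspot (ECH) detection.

Tau tracers bind in skull, meninges and soft tissue in subject-specific
spots.  A "searchable" region is built from the tissue-probability maps:
all clearly extracerebral bone/meninges (c4+c5 > 0.3), plus CSF-classed
voxels (c3 > 0.5) that lie closer to the bone mask than to the brain —
operationalized, as in the original method, by comparing the two
PSF-smoothed binary masks rather than a distance transform.  Within the
searchable region, connected clusters of voxels above the SUVR threshold
with strictly more than 500 voxels each become their own PVC ROI,
labeled 85, 86, ... in a deterministic order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reference_region import SuvrVolume
from .volume_io import (
    DEFAULT_CONNECTIVITY,
    LabeledVolume,
    ProbabilityVolume,
    PsfModel,
    assert_same_grid,
    component_masks,
    smooth_array,
)

log = logging.getLogger("taupvc")

FIRST_ECH_LABEL = 85


@dataclass(frozen=True)
class EchParams:
    """Thresholds of the ECH search (SUVR units, voxel counts)."""

    suvr_threshold: float = 1.6          # 1.3 and 1.9 are the explored variants
    min_cluster_voxels: int = 500        # strict: a cluster needs > 500 voxels
    c3_probability_cut: float = 0.5
    c45_mask_cut: float = 0.5
    c45_direct_cut: float = 0.3
    first_label: int = FIRST_ECH_LABEL
    connectivity: int = DEFAULT_CONNECTIVITY

    def __post_init__(self) -> None:
        if not self.suvr_threshold > 1:
            raise ValueError("ECH SUVR threshold must exceed 1")
        if self.min_cluster_voxels < 1:
            raise ValueError("min_cluster_voxels must be >= 1")


@dataclass(frozen=True)
class EchCluster:
    label: int
    n_voxels: int
    mean_suvr: float


@dataclass
class EchResult:
    searchable_mask: np.ndarray
    label_volume: np.ndarray           # int32, 0 outside clusters
    clusters: list[EchCluster] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def total_voxels(self) -> int:
        return sum(c.n_voxels for c in self.clusters)


def build_searchable_roi(c3: ProbabilityVolume,
                         c4: ProbabilityVolume,
                         c5: ProbabilityVolume,
                         aparc: LabeledVolume,
                         psf: PsfModel,
                         params: EchParams | None = None) -> np.ndarray:
    """Binary region in which hotspots are searched for.

    ``{c3 > 0.5 and smoothed(c4+c5 > 0.5) > smoothed(aparc != 0)}``
    union ``{c4+c5 > 0.3}``, both mask smoothings at the scanner PSF.
    """
    if params is None:
        params = EchParams()
    assert_same_grid([c3, c4, c5, aparc], names=["c3", "c4", "c5", "aparc"])
    vs = aparc.grid.voxel_size_mm
    c45 = c4.data + c5.data
    brain_mask = aparc.data != 0
    bone_mask = c45 > params.c45_mask_cut
    sm_brain = smooth_array(brain_mask, vs, psf.fwhm_mm)
    sm_bone = smooth_array(bone_mask, vs, psf.fwhm_mm)
    near_bone_csf = (c3.data > params.c3_probability_cut) & (sm_bone > sm_brain)
    return near_bone_csf | (c45 > params.c45_direct_cut)


def detect_ech(suvr: SuvrVolume,
               searchable: np.ndarray,
               params: EchParams | None = None) -> EchResult:
    """Find per-subject hotspot clusters and assign labels 85, 86, ...

    Components of ``searchable & (suvr > threshold)`` with strictly more
    than ``min_cluster_voxels`` voxels become ROIs.  Labels are assigned
    in descending cluster size, ties broken by the lexicographically
    smallest minimum corner, so outputs are reproducible.  Sub-threshold
    components are discarded; their voxels stay unassigned for the
    downstream tissue classification.
    """
    if params is None:
        params = EchParams()
    searchable = np.asarray(searchable, dtype=bool)
    probable = searchable & (suvr.data > params.suvr_threshold)
    label_volume = np.zeros(suvr.data.shape, dtype=np.int32)
    clusters: list[EchCluster] = []
    label = params.first_label
    for comp in component_masks(probable, params.connectivity):
        n = int(comp.sum())
        if n > params.min_cluster_voxels:
            label_volume[comp] = label
            clusters.append(EchCluster(label, n, float(suvr.data[comp].mean())))
            label += 1
    if clusters:
        log.info("detect_ech: %d cluster(s), %d voxels total",
                 len(clusters), sum(c.n_voxels for c in clusters))
    return EchResult(searchable, label_volume, clusters)


def clusters_table(result: EchResult, suvr: SuvrVolume) -> pd.DataFrame:
    """Per-cluster summary (label, n_voxels, mean_suvr, centroid in mm)."""
    rows = []
    for c in result.clusters:
        ijk = np.argwhere(result.label_volume == c.label)
        centroid_vox = ijk.mean(axis=0) if len(ijk) else np.full(3, np.nan)
        hom = np.append(centroid_vox, 1.0)
        centroid_mm = (suvr.grid.affine @ hom)[:3]
        rows.append({"label": c.label, "n_voxels": c.n_voxels,
                     "mean_suvr": c.mean_suvr,
                     "centroid_x_mm": centroid_mm[0],
                     "centroid_y_mm": centroid_mm[1],
                     "centroid_z_mm": centroid_mm[2]})
    return pd.DataFrame(rows, columns=["label", "n_voxels", "mean_suvr",
                                       "centroid_x_mm", "centroid_y_mm",
                                       "centroid_z_mm"])
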