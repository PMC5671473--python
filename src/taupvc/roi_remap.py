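"""Remap FreeSurfer aparc+aseg codes into the 77-index edited scheme.

The PVC model works on an "edited" label volume in which every ROI that
participates in the geometric transfer matrix carries one small integer:
1–76 for the grouped FreeSurfer cortical/subcortical regions, 77 for the
superior cerebellar gray (filled by the reference-region split), 78 for
the inferior cerebellar reference, 79/80 choroid high/low, 81–84 the
CSF and bone+meninges classes, and 85+ per-subject extra-cortical
hotspots.  Ventricles map to 0 and are assumed to have zero activity.

Braak-stage composites (I/II, III/IV, V/VI) are defined over the edited
indices and evaluated as voxel-count-weighted means by default.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import numpy as np

from .volume_io import LabeledVolume

log = logging.getLogger("taupvc")

#: FreeSurfer codes pooled into the cerebellar-gray pass-through.
CEREBELLUM_GRAY_CODES = frozenset({8, 47})

#: Internal label carrying cerebellar gray until the SUIT-based split
#: replaces it with 77 (superior) / 78 (inferior).  Far above any
#: plausible hotspot label so it can never collide.
RESERVED_CEREBELLUM_LABEL = 998

#: Internal label for the un-split whole choroid plexus (configuration 1).
WHOLE_CHOROID_LABEL = 999

#: FreeSurfer ventricle codes, unassigned (PVC value 0).
VENTRICLE_CODES = frozenset({4, 5, 14, 15, 24, 43, 44, 72})

#: Default FreeSurfer choroid-plexus codes (standard aseg convention).
DEFAULT_CHOROID_CODES = frozenset({31, 63})

# (edited index, FreeSurfer source codes, region name)
_DEFAULT_ROWS: list[tuple[int, tuple[int, ...], str]] = [
    (1, (1006,), "L Entorhinal"),
    (2, (2006,), "R Entorhinal"),
    (3, (17,), "L Hippocampus"),
    (4, (53,), "R Hippocampus"),
    (5, (1016,), "L Parahippocampal"),
    (6, (1007,), "L Fusiform"),
    (7, (1013,), "L Lingual"),
    (8, (18,), "L Amygdala"),
    (9, (2016,), "R Parahippocampal"),
    (10, (2007,), "R Fusiform"),
    (11, (2013,), "R Lingual"),
    (12, (54,), "R Amygdala"),
    (13, (1015,), "L Middle Temporal"),
    (14, (10,), "L Thalamus"),
    (15, (1002,), "L Caudal Anterior Cingulate"),
    (16, (1026,), "L Rostral Anterior Cingulate"),
    (17, (1023,), "L Posterior Cingulate"),
    (18, (1010,), "L Isthmus Cingulate"),
    (19, (1035,), "L Insula"),
    (20, (1009,), "L Inferior Temporal"),
    (21, (1033,), "L Temporal Pole"),
    (22, (2015,), "R Middle Temporal"),
    (23, (49,), "R Thalamus"),
    (24, (2002,), "R Caudal Anterior Cingulate"),
    (25, (2026,), "R Rostral Anterior Cingulate"),
    (26, (2023,), "R Posterior Cingulate"),
    (27, (2010,), "R Isthmus Cingulate"),
    (28, (2035,), "R Insula"),
    (29, (2009,), "R Inferior Temporal"),
    (30, (2033,), "R Temporal Pole"),
    (31, (1028,), "L Superior Frontal"),
    (32, (1012, 1014, 1032), "L Frontal Orbital"),
    (33, (1003, 1027), "L Middle Frontal"),
    (34, (1018, 1019, 1020), "L Pars Frontal"),
    (35, (11,), "L Caudate"),
    (36, (12,), "L Putamen"),
    (37, (1011,), "L Lateral Occipital"),
    (38, (1031,), "L Supramarginal"),
    (39, (1008,), "L Inferior Parietal"),
    (40, (1030,), "L Superior Temporal"),
    (41, (13,), "L Pallidum"),
    (42, (1029,), "L Superior Parietal"),
    (43, (1025,), "L Precuneus"),
    (44, (1001,), "L Banks STS"),
    (45, (26,), "L Accumbens"),
    (46, (1034,), "L Transverse Temporal"),
    (47, (2028,), "R Superior Frontal"),
    (48, (2012, 2014, 2032), "R Frontal Orbital"),
    (49, (2003, 2027), "R Middle Frontal"),
    (50, (2018, 2019, 2020), "R Pars Frontal"),
    (51, (50,), "R Caudate"),
    (52, (51,), "R Putamen"),
    (53, (2011,), "R Lateral Occipital"),
    (54, (2031,), "R Supramarginal"),
    (55, (2008,), "R Inferior Parietal"),
    (56, (2030,), "R Superior Temporal"),
    (57, (52,), "R Pallidum"),
    (58, (2029,), "R Superior Parietal"),
    (59, (2025,), "R Precuneus"),
    (60, (2001,), "R Banks STS"),
    (61, (58,), "R Accumbens"),
    (62, (2034,), "R Transverse Temporal"),
    (63, (1021,), "L Pericalcarine"),
    (64, (1022,), "L Postcentral"),
    (65, (1005,), "L Cuneus"),
    (66, (1024,), "L Precentral"),
    (67, (1017,), "L Paracentral"),
    (68, (2021,), "R Pericalcarine"),
    (69, (2022,), "R Postcentral"),
    (70, (2005,), "R Cuneus"),
    (71, (2024,), "R Precentral"),
    (72, (2017,), "R Paracentral"),
    (73, (2, 41, 251, 252, 253, 254, 255), "Hemispheric White"),
    (74, (7, 46), "Cerebellar White"),
    (75, (16,), "Brainstem"),
    (76, (28, 30, 60, 62, 77, 80, 85, 1000, 1004, 2000, 2004), "Other"),
    # Row 77 is populated by the reference-region split ("some of 8, 47").
    (77, (), "Superior Cerebellar Gray"),
]


@dataclass(frozen=True)
class RemapEntry:
    edited_index: int
    freesurfer_indices: frozenset[int]
    name: str


@dataclass(frozen=True)
class RemapTable:
    """Mapping from FreeSurfer aparc+aseg codes to edited indices 1–77."""

    entries: tuple[RemapEntry, ...]
    ventricle_indices: frozenset[int] = frozenset(VENTRICLE_CODES)

    def __post_init__(self) -> None:
        idx = sorted(e.edited_index for e in self.entries)
        if idx != list(range(1, 78)):
            raise ValueError("edited indices must be exactly 1..77 with no gaps")
        seen: dict[int, int] = {}
        for e in self.entries:
            for fs in e.freesurfer_indices:
                if fs in seen:
                    raise ValueError(f"FreeSurfer code {fs} appears in entries "
                                     f"{seen[fs]} and {e.edited_index}")
                seen[fs] = e.edited_index

    def lookup(self, freesurfer_code: int) -> int | None:
        """Edited index for a FreeSurfer code; 0 for ventricles; None if unknown."""
        if freesurfer_code in self.ventricle_indices:
            return 0
        for e in self.entries:
            if freesurfer_code in e.freesurfer_indices:
                return e.edited_index
        return None

    def name_of(self, edited_index: int) -> str:
        for e in self.entries:
            if e.edited_index == edited_index:
                return e.name
        raise KeyError(edited_index)

    def names(self) -> dict[int, str]:
        return {e.edited_index: e.name for e in self.entries}

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["edited_index", "freesurfer_indices", "name"])
            for e in self.entries:
                w.writerow([e.edited_index,
                            ",".join(str(i) for i in sorted(e.freesurfer_indices)),
                            e.name])
            w.writerow([0, ",".join(str(i) for i in sorted(self.ventricle_indices)),
                        "Ventricles"])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RemapTable":
        entries = []
        ventricles: frozenset[int] = frozenset()
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                codes = frozenset(
                    int(t) for t in row["freesurfer_indices"].split(",") if t.strip()
                )
                idx = int(row["edited_index"])
                if idx == 0:
                    ventricles = codes
                else:
                    entries.append(RemapEntry(idx, codes, row["name"]))
        return cls(tuple(entries), ventricles)


def default_remap_table() -> RemapTable:
    """The built-in 77-row grouping table (plus the ventricle row)."""
    return RemapTable(tuple(
        RemapEntry(i, frozenset(codes), name) for i, codes, name in _DEFAULT_ROWS
    ))


def _build_lut(table: RemapTable) -> np.ndarray:
    codes = [fs for e in table.entries for fs in e.freesurfer_indices]
    codes += list(table.ventricle_indices) + list(CEREBELLUM_GRAY_CODES)
    lut = np.zeros(max(codes) + 1, dtype=np.int32)
    for e in table.entries:
        for fs in e.freesurfer_indices:
            lut[fs] = e.edited_index
    for fs in table.ventricle_indices:
        lut[fs] = 0
    for fs in CEREBELLUM_GRAY_CODES:
        lut[fs] = RESERVED_CEREBELLUM_LABEL
    return lut


def remap_labels(aparc: LabeledVolume, table: RemapTable | None = None) -> LabeledVolume:
    """Apply the grouping table to an aparc+aseg label volume.

    Ventricles become 0; cerebellar-gray codes (8, 47) pass through under
    :data:`RESERVED_CEREBELLUM_LABEL` for the later SUIT split; any other
    code not in the table becomes 0 (real aparc+aseg files contain codes
    the model does not use), with the dropped count logged.
    """
    if table is None:
        table = default_remap_table()
    lut = _build_lut(table)
    data = aparc.data
    out = np.zeros(data.shape, dtype=np.int32)
    in_range = data < lut.size
    out[in_range] = lut[data[in_range]]
    known = np.zeros(lut.size, dtype=bool)
    known[np.flatnonzero(lut)] = True
    for fs in table.ventricle_indices:
        known[fs] = True
    known[0] = True
    unknown = (~in_range) | ~known[np.where(in_range, data, 0)]
    n_unknown = int(np.count_nonzero(unknown & (data != 0)))
    if n_unknown:
        log.info("remap_labels: %d voxels with FreeSurfer codes outside the "
                 "table set to 0", n_unknown)
    return LabeledVolume(out, aparc.grid)


# ---------------------------------------------------------------------------
# Braak composites
# ---------------------------------------------------------------------------

#: Braak I/II, III/IV and V/VI composites over the edited indices.
BRAAK_12 = frozenset(range(1, 5))
BRAAK_34 = frozenset(range(5, 31)) - {14, 23}
BRAAK_56 = frozenset(range(31, 73)) - {35, 36, 41, 45, 51, 52, 57, 61}


@dataclass(frozen=True)
class BraakComposite:
    braak_12: frozenset[int] = BRAAK_12
    braak_34: frozenset[int] = BRAAK_34
    braak_56: frozenset[int] = BRAAK_56

    def __post_init__(self) -> None:
        sets = (self.braak_12, self.braak_34, self.braak_56)
        if (self.braak_12 & self.braak_34 or self.braak_12 & self.braak_56
                or self.braak_34 & self.braak_56):
            raise ValueError("Braak composites must be pairwise disjoint")
        if not (self.braak_12 | self.braak_34 | self.braak_56) <= set(range(1, 73)):
            raise ValueError("Braak composites must lie within edited indices 1..72")


class BraakMeans(NamedTuple):
    braak_12: float
    braak_34: float
    braak_56: float


def braak_means(roi_means: Mapping[int, float],
                roi_voxel_counts: Mapping[int, int] | None = None,
                composite: BraakComposite | None = None,
                weighted: bool = True) -> BraakMeans:
    """Composite means over the three Braak stage groupings.

    By default each composite is treated as a union of voxels, i.e. the
    member-ROI means are weighted by their voxel counts; ``weighted=False``
    gives the unweighted mean of ROI means instead.  Members absent from
    ``roi_means`` are skipped with a warning; a composite with no members
    available raises ``ValueError``.
    """
    if composite is None:
        composite = BraakComposite()
    if weighted and roi_voxel_counts is None:
        raise ValueError("weighted Braak means need roi_voxel_counts")
    out = []
    for name, members in (("braak_12", composite.braak_12),
                          ("braak_34", composite.braak_34),
                          ("braak_56", composite.braak_56)):
        have = sorted(m for m in members if m in roi_means)
        missing = sorted(members - set(have))
        if missing:
            log.warning("braak_means: %s missing member ROIs %s", name, missing)
        if not have:
            raise ValueError(f"no member ROI means available for {name}")
        vals = np.array([roi_means[m] for m in have], dtype=float)
        if weighted:
            w = np.array([roi_voxel_counts.get(m, 0) for m in have], dtype=float)
            if w.sum() <= 0:
                raise ValueError(f"all voxel counts zero for {name}")
            out.append(float(np.average(vals, weights=w)))
        else:
            out.append(float(vals.mean()))
    return BraakMeans(*out)
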