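"""Per-subject pipeline orchestration and the ten ROI configurations.

The ROI-construction variants differ in whether the choroid plexus is
split, whether hotspots are detected (and at which SUVR threshold),
whether CSF/bone+meninges ROIs are added and split into high/low, and
whether the reference region is scanned for hotspots.  Configuration 8
(split choroid, hotspots at 1.6, split tissue ROIs, reference scan) is
the recommended final variant; running all ten on identical inputs and
comparing the global PVCnstd reproduces the configuration comparison
that motivated it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .choroid_split import ChoroidPartition, split_choroid
from .ech_detection import EchParams, EchResult, build_searchable_roi, clusters_table, detect_ech
from .gtm_pvc import (
    GtmModel,
    QcReport,
    build_transfer_matrix,
    calc_pre_pvc,
    pvc_image,
    residuals_and_pvcnstd,
    roi_means,
    solve_gtm,
)
from .reference_region import (
    INFERIOR_CEREBELLUM_LABEL,
    REFERENCE_HOTSPOT_MIN_VOXELS,
    REFERENCE_HOTSPOT_THRESHOLD,
    SUPERIOR_CEREBELLUM_LABEL,
    CerebellarSplit,
    SuvrVolume,
    normalize_suvr,
    scan_reference_hotspots,
    split_cerebellum,
)
from .roi_remap import (
    DEFAULT_CHOROID_CODES,
    RESERVED_CEREBELLUM_LABEL,
    WHOLE_CHOROID_LABEL,
    RemapTable,
    default_remap_table,
    remap_labels,
)
from .tissue_rois import TissueClassParams, assign_stray_gray, classify_csf_bone
from .volume_io import (
    DEFAULT_CONNECTIVITY,
    MASK_SMOOTH_FWHM_MM,
    LabeledVolume,
    ProbabilityVolume,
    PsfModel,
    ScalarVolume,
    assert_same_grid,
    write_volume,
)

log = logging.getLogger("taupvc")


@dataclass(frozen=True)
class RoiConfiguration:
    """One declarative ROI-construction variant."""

    config_id: int
    split_choroid: bool
    include_ech: bool
    ech_threshold: float
    include_tissue_rois: bool
    split_tissue_high_low: bool
    scan_reference: bool

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RoiConfiguration":
        return cls(**d)


def _cfg(cid, split_chor, ech, thr, tissue, split_tissue, scan):
    return RoiConfiguration(cid, split_chor, ech, thr, tissue, split_tissue, scan)


#: The ten published ROI configurations.  9 and 10 inherit the reference
#: scan from 8 and vary only the hotspot threshold.
CONFIG_PRESETS: dict[int, RoiConfiguration] = {
    1: _cfg(1, False, False, 1.6, False, False, False),
    2: _cfg(2, True, False, 1.6, False, False, False),
    3: _cfg(3, True, True, 1.6, False, False, False),
    4: _cfg(4, True, False, 1.6, True, False, False),
    5: _cfg(5, True, True, 1.6, True, False, False),
    6: _cfg(6, True, False, 1.6, True, True, False),
    7: _cfg(7, True, True, 1.6, True, True, False),
    8: _cfg(8, True, True, 1.6, True, True, True),
    9: _cfg(9, True, True, 1.3, True, True, True),
    10: _cfg(10, True, True, 1.9, True, True, True),
}


@dataclass
class PipelineParams:
    """Every tunable constant of the pipeline, at its published default."""

    mask_smooth_fwhm_mm: float = MASK_SMOOTH_FWHM_MM
    choroid_codes: frozenset[int] = DEFAULT_CHOROID_CODES
    choroid_suvr_threshold: float = 1.0
    choroid_min_voxels: int = 100
    ech_min_voxels: int = 500
    reference_hotspot_threshold: float = REFERENCE_HOTSPOT_THRESHOLD
    reference_hotspot_min_voxels: int = REFERENCE_HOTSPOT_MIN_VOXELS
    tissue_probability_cut: float = 0.3
    suvr_floor: float = 0.1
    stray_max_passes: int = 10
    stray_single_pass: bool = False
    connectivity: int = DEFAULT_CONNECTIVITY
    std_ddof: int = 0
    first_ech_label: int = 85

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["choroid_codes"] = sorted(self.choroid_codes)
        return d


@dataclass
class PipelineResult:
    """Everything one configuration produces for one subject."""

    config: RoiConfiguration
    edited: LabeledVolume
    suvr: SuvrVolume
    split: CerebellarSplit
    gtm: GtmModel
    qc: QcReport
    ech: EchResult | None
    reference_hotspot_labels: list[int]
    provenance: dict


def run_subject(aparc: LabeledVolume,
                suit: LabeledVolume,
                c1: ProbabilityVolume,
                c2: ProbabilityVolume,
                c3: ProbabilityVolume,
                c4: ProbabilityVolume,
                c5: ProbabilityVolume,
                pet: ScalarVolume,
                psf: PsfModel,
                config: RoiConfiguration | int = 8,
                params: PipelineParams | None = None,
                table: RemapTable | None = None,
                out_dir: str | Path | None = None) -> PipelineResult:
    """Run the full ROI-construction + GTM pipeline for one subject.

    Stages run in the fixed published order: anatomical remap →
    cerebellar split + SUVR → choroid split → hotspot detection →
    tissue ROIs + stray assignment → reference scan + renormalization →
    GTM solve → PVC / calculated pre-PVC images → residual QC.
    """
    if isinstance(config, int):
        config = CONFIG_PRESETS[config]
    if params is None:
        params = PipelineParams()
    if table is None:
        table = default_remap_table()
    volumes = [aparc, suit, c1, c2, c3, c4, c5, pet]
    names = ["aparc", "suit", "c1", "c2", "c3", "c4", "c5", "pet"]
    assert_same_grid(volumes, names=names)

    def stage(name):
        log.info("config %d: %s", config.config_id, name)

    # 1. anatomical remap (ventricles -> 0, cerebellar gray reserved)
    stage("remap labels")
    edited = remap_labels(aparc, table)

    # 2. cerebellar split and SUVR normalization
    stage("cerebellar split + SUVR")
    split = split_cerebellum(aparc, suit, params.mask_smooth_fwhm_mm)
    labels = edited.data.copy()
    labels[labels == RESERVED_CEREBELLUM_LABEL] = 0
    labels[split.superior_mask] = SUPERIOR_CEREBELLUM_LABEL
    labels[split.inferior_mask] = INFERIOR_CEREBELLUM_LABEL
    edited = LabeledVolume(labels, edited.grid)
    suvr = normalize_suvr(pet, split.inferior_mask)

    # 3. choroid plexus (split into 79/80, or kept whole)
    choroid_mask = np.isin(aparc.data, list(params.choroid_codes))
    if choroid_mask.any():
        if config.split_choroid:
            stage("choroid split")
            frag = split_choroid(
                suvr, choroid_mask,
                ChoroidPartition(suvr_threshold=params.choroid_suvr_threshold,
                                 min_cluster_voxels=params.choroid_min_voxels),
                params.mask_smooth_fwhm_mm, params.connectivity)
            labels = edited.data.copy()
            labels[choroid_mask] = frag[choroid_mask]
        else:
            stage("whole choroid")
            labels = edited.data.copy()
            labels[choroid_mask] = WHOLE_CHOROID_LABEL
        edited = LabeledVolume(labels, edited.grid)
    else:
        log.warning("no choroid-plexus voxels found (codes %s)",
                    sorted(params.choroid_codes))

    # 4. extra-cortical hotspots
    ech_result = None
    n_ech = 0
    if config.include_ech:
        stage("ECH detection")
        ech_params = EchParams(suvr_threshold=config.ech_threshold,
                               min_cluster_voxels=params.ech_min_voxels,
                               first_label=params.first_ech_label,
                               connectivity=params.connectivity)
        searchable = build_searchable_roi(c3, c4, c5, aparc, psf, ech_params)
        ech_result = detect_ech(suvr, searchable, ech_params)
        n_ech = ech_result.n_clusters
        if n_ech:
            labels = edited.data.copy()
            paint = (ech_result.label_volume > 0) & (labels == 0)
            labels[paint] = ech_result.label_volume[paint]
            edited = LabeledVolume(labels, edited.grid)

    # 5. tissue ROIs and stray gray voxels
    if config.include_tissue_rois:
        stage("tissue ROIs + stray gray")
        tissue_params = TissueClassParams(
            suvr_floor=params.suvr_floor,
            probability_cut=params.tissue_probability_cut)
        edited = classify_csf_bone(edited, c1, c3, c4, c5, suvr, tissue_params,
                                   split_high_low=config.split_tissue_high_low)
        edited, _ = assign_stray_gray(edited, c1, c3, c4, c5, suvr,
                                      max_passes=params.stray_max_passes,
                                      single_pass=params.stray_single_pass)

    # 6. reference hotspot scan (labels count up after the last ECH)
    reference_hotspots: list[int] = []
    if config.scan_reference:
        stage("reference hotspot scan")
        next_label = params.first_ech_label + n_ech
        hotspot_labels, cleaned, suvr = scan_reference_hotspots(
            suvr, split.inferior_mask,
            params.reference_hotspot_threshold,
            params.reference_hotspot_min_voxels,
            next_label, params.connectivity)
        if hotspot_labels.any():
            labels = edited.data.copy()
            labels[hotspot_labels > 0] = hotspot_labels[hotspot_labels > 0]
            edited = LabeledVolume(labels, edited.grid)
            split = CerebellarSplit(cleaned, split.superior_mask)
            reference_hotspots = sorted(
                int(v) for v in np.unique(hotspot_labels) if v > 0)

    # 7. GTM build + solve, PVC image, calculated pre-PVC, residual QC
    stage("GTM solve + QC")
    roi_labels = [int(v) for v in edited.labels()]
    model = build_transfer_matrix(edited, roi_labels, psf, suvr=suvr)
    model = solve_gtm(model)
    pvc = pvc_image(edited, model)
    pre = calc_pre_pvc(pvc, psf)
    roi_names = table.names()
    qc = residuals_and_pvcnstd(suvr, pre, edited, model=model,
                               names=roi_names, ddof=params.std_ddof)

    provenance = {
        "taupvc_version": _pkg_version,
        "config": config.to_dict(),
        "params": params.to_dict(),
        "psf_fwhm_mm": list(psf.fwhm_mm),
        "n_ech": n_ech,
        "reference_hotspot_labels": reference_hotspots,
        "reference_mean": suvr.reference_mean,
    }
    result = PipelineResult(config, edited, suvr, split, model, qc,
                            ech_result, reference_hotspots, provenance)
    if out_dir is not None:
        save_result(result, pet, psf, out_dir)
    return result


def save_result(result: PipelineResult, pet: ScalarVolume, psf: PsfModel,
                out_dir: str | Path) -> None:
    """Write edited labels, SUVR/PVC/pre-PVC/residual images and reports."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = result.edited.grid
    write_volume(result.edited, out / "edited_aparc_aseg.nii.gz")
    write_volume(ScalarVolume(result.suvr.data, grid), out / "suvr.nii.gz")
    pvc = pvc_image(result.edited, result.gtm)
    pre = calc_pre_pvc(pvc, psf)
    write_volume(pvc, out / "pvc.nii.gz")
    write_volume(pre, out / "calc_pre_pvc.nii.gz")
    write_volume(ScalarVolume(pre.data - result.suvr.data, grid),
                 out / "residual.nii.gz")
    result.qc.table.to_csv(out / "qc_report.tsv", sep="\t", index=False)
    means = result.qc.table[["label", "name", "n_voxels",
                             "observed_mean", "corrected_mean"]]
    means.to_csv(out / "roi_means.tsv", sep="\t", index=False)
    if result.ech is not None:
        clusters_table(result.ech, result.suvr).to_csv(
            out / "ech_clusters.tsv", sep="\t", index=False)
    manifest = dict(result.provenance)
    manifest["global_pvcnstd"] = result.qc.global_pvcnstd
    manifest["qc_labels"] = result.qc.qc_labels
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def compare_configurations(aparc, suit, c1, c2, c3, c4, c5, pet, psf,
                           configs=None,
                           params: PipelineParams | None = None,
                           table: RemapTable | None = None) -> pd.DataFrame:
    """Run several configurations on identical inputs.

    Returns one row per configuration with the global PVCnstd (averaged,
    unweighted, over the anatomical ROIs present), for the standard
    configuration comparison.
    """
    if configs is None:
        configs = list(CONFIG_PRESETS.values())
    rows = []
    for cfg in configs:
        if isinstance(cfg, int):
            cfg = CONFIG_PRESETS[cfg]
        res = run_subject(aparc, suit, c1, c2, c3, c4, c5, pet, psf,
                          config=cfg, params=params, table=table)
        rows.append({"config_id": cfg.config_id,
                     "global_pvcnstd": res.qc.global_pvcnstd,
                     "n_rois": res.gtm.n_rois,
                     "n_ech": res.ech.n_clusters if res.ech else 0})
    return pd.DataFrame(rows)
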