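"""Rousset geometric-transfer-matrix (GTM) partial volume correction.

The observed mean SUVR of ROI *i* is modeled as a known linear mixture
of the true ROI means: ``t_i = sum_j omega_ij c_j``, where
``omega_ij`` is the mean, over the voxels of ROI *i*, of ROI *j*'s
binary indicator smoothed by the scanner PSF.  Solving
``omega @ c = t`` recovers the PV-corrected means ``c``.  Voxels
labeled 0 are assumed to carry zero activity and contribute neither
rows nor columns.

The module also reconstructs the "calculated pre-PVC" image — corrected
means painted back into their ROIs and re-smoothed by the PSF — whose
residual against the original SUVR quantifies how well an ROI
configuration explains the data: the within-ROI standard deviation of
the residual, normalized by the ROI's mean SUVR (PVCnstd).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .reference_region import SuvrVolume
from .volume_io import LabeledVolume, PsfModel, ScalarVolume, smooth_array

log = logging.getLogger("taupvc")

#: 2-norm condition number above which the solve falls back to a
#: least-squares pseudo-inverse (tiny ROIs beside large ones can make
#: the transfer matrix near-singular).
CONDITION_LIMIT = 1e8

#: Edited indices over which the global PVCnstd is averaged by default
#: (the anatomical ROIs 1..77).
DEFAULT_QC_LABELS = tuple(range(1, 78))


@dataclass
class GtmModel:
    """Transfer matrix and per-ROI means for one label volume."""

    roi_labels: list[int]
    omega: np.ndarray
    observed_means: np.ndarray | None = None
    corrected_means: np.ndarray | None = None
    condition_number: float | None = None
    used_pseudoinverse: bool = False
    roi_voxel_counts: np.ndarray | None = None

    @property
    def n_rois(self) -> int:
        return len(self.roi_labels)

    def corrected_by_label(self) -> dict[int, float]:
        if self.corrected_means is None:
            raise ValueError("model not solved yet")
        return {lab: float(c) for lab, c in zip(self.roi_labels, self.corrected_means)}

    def observed_by_label(self) -> dict[int, float]:
        if self.observed_means is None:
            raise ValueError("observed means not set")
        return {lab: float(t) for lab, t in zip(self.roi_labels, self.observed_means)}


def roi_means(data: np.ndarray, edited: LabeledVolume,
              labels: Sequence[int]) -> np.ndarray:
    """Mean of a scalar field over each requested ROI."""
    out = np.empty(len(labels), dtype=float)
    flat = np.asarray(data, dtype=float).ravel()
    lab_flat = edited.data.ravel()
    for k, lab in enumerate(labels):
        idx = np.flatnonzero(lab_flat == lab)
        if idx.size == 0:
            raise ValueError(f"label {lab} absent from the volume")
        out[k] = flat[idx].mean()
    return out


def build_transfer_matrix(edited: LabeledVolume,
                          roi_labels: Sequence[int],
                          psf: PsfModel,
                          suvr: SuvrVolume | None = None) -> GtmModel:
    """Build omega for the given ROI set (optionally with observed means).

    Each ROI indicator is PSF-smoothed once; ``omega[i, j]`` is the mean
    of the smoothed indicator of ROI *j* over the voxels of ROI *i*.
    Requested labels absent from the volume are dropped with a warning
    (e.g. a subject with no hotspot).
    """
    if len(roi_labels) == 0:
        raise ValueError("roi_labels is empty")
    present = set(int(v) for v in np.unique(edited.data)) - {0}
    kept = [int(lab) for lab in roi_labels if int(lab) in present]
    dropped = [int(lab) for lab in roi_labels if int(lab) not in present]
    if dropped:
        log.warning("build_transfer_matrix: labels absent from volume, "
                    "dropped: %s", dropped)
    if not kept:
        raise ValueError("no requested ROI label is present in the volume")
    lab_flat = edited.data.ravel()
    indices = [np.flatnonzero(lab_flat == lab) for lab in kept]
    vs = edited.grid.voxel_size_mm
    n = len(kept)
    omega = np.empty((n, n), dtype=float)
    for j, lab in enumerate(kept):
        smoothed = smooth_array(edited.data == lab, vs, psf.fwhm_mm).ravel()
        for i in range(n):
            omega[i, j] = smoothed[indices[i]].mean()
    counts = np.array([idx.size for idx in indices])
    observed = None
    if suvr is not None:
        observed = roi_means(suvr.data, edited, kept)
    return GtmModel(kept, omega, observed_means=observed,
                    roi_voxel_counts=counts)


def solve_gtm(model: GtmModel,
              observed_means: np.ndarray | None = None,
              condition_limit: float = CONDITION_LIMIT) -> GtmModel:
    """Solve ``omega @ c = t`` for the corrected means.

    Well-conditioned systems are solved directly; above
    ``condition_limit`` (or on singularity) the solve switches to the
    least-squares pseudo-inverse and the model is flagged.  Corrected
    means may legitimately exceed observed means (spill-out recovery).
    """
    t = observed_means if observed_means is not None else model.observed_means
    if t is None:
        raise ValueError("observed means are required to solve the GTM")
    t = np.asarray(t, dtype=float)
    if t.shape != (model.n_rois,):
        raise ValueError(f"observed means shape {t.shape} != ({model.n_rois},)")
    cond = float(np.linalg.cond(model.omega))
    used_pinv = False
    if not np.isfinite(cond) or cond > condition_limit:
        log.warning("solve_gtm: condition number %.3g exceeds %.3g; using "
                    "least-squares pseudo-inverse", cond, condition_limit)
        c = np.linalg.lstsq(model.omega, t, rcond=None)[0]
        used_pinv = True
    else:
        c = np.linalg.solve(model.omega, t)
    return replace(model, observed_means=t, corrected_means=c,
                   condition_number=cond, used_pseudoinverse=used_pinv)


def pvc_image(edited: LabeledVolume, model: GtmModel) -> ScalarVolume:
    """Paint each ROI's corrected mean into its voxels (0 elsewhere)."""
    if model.corrected_means is None:
        raise ValueError("model not solved yet")
    lut_size = max(model.roi_labels) + 1
    lut = np.zeros(lut_size, dtype=float)
    for lab, c in zip(model.roi_labels, model.corrected_means):
        lut[lab] = c
    data = edited.data
    out = np.zeros(data.shape, dtype=float)
    in_range = data < lut_size
    out[in_range] = lut[data[in_range]]
    return ScalarVolume(out, edited.grid)


def calc_pre_pvc(pvc: ScalarVolume, psf: PsfModel) -> ScalarVolume:
    """Smooth the PVC image by the scanner PSF.

    If the ROI model and PSF explain the data, this reproduces the
    observed SUVR; the residual against it is the fit diagnostic.
    """
    return ScalarVolume(
        smooth_array(pvc.data, pvc.grid.voxel_size_mm, psf.fwhm_mm), pvc.grid
    )


@dataclass
class QcReport:
    """Per-ROI residual diagnostics and the global PVCnstd."""

    table: pd.DataFrame
    global_pvcnstd: float
    qc_labels: list[int]
    ddof: int = 0

    def pvcnstd_by_label(self) -> dict[int, float]:
        return dict(zip(self.table["label"], self.table["pvcnstd"]))


def residuals_and_pvcnstd(suvr: SuvrVolume,
                          pre: ScalarVolume,
                          edited: LabeledVolume,
                          labels: Sequence[int] | None = None,
                          model: GtmModel | None = None,
                          names: Mapping[int, str] | None = None,
                          qc_labels: Sequence[int] | None = None,
                          ddof: int = 0) -> QcReport:
    """Residual image statistics per ROI and the global PVCnstd.

    The residual is ``calculated pre-PVC − original SUVR``.  For each
    ROI, ``pvcnstd = std(residual) / mean(SUVR)`` (population standard
    deviation by default, ``ddof`` configurable).  The global score is
    the unweighted mean of pvcnstd over ``qc_labels`` (default: the
    anatomical indices 1..77 that are present).  ROIs whose mean SUVR is
    not positive get an undefined (NaN) pvcnstd and are excluded from
    the global mean with a warning.
    """
    residual = pre.data - suvr.data
    if labels is None:
        labels = [int(v) for v in edited.labels()]
    observed = model.observed_by_label() if model and model.observed_means is not None else {}
    corrected = model.corrected_by_label() if model and model.corrected_means is not None else {}
    rows = []
    for lab in labels:
        mask = edited.data == lab
        n = int(mask.sum())
        if n == 0:
            continue
        mean_suvr = float(suvr.data[mask].mean())
        res = residual[mask]
        res_std = float(res.std(ddof=ddof)) if n > ddof else np.nan
        if mean_suvr > 0 and np.isfinite(res_std):
            pvcnstd = res_std / mean_suvr
        else:
            log.warning("residuals_and_pvcnstd: ROI %d has non-positive mean "
                        "SUVR (%.3g); pvcnstd undefined", lab, mean_suvr)
            pvcnstd = np.nan
        rows.append({
            "label": lab,
            "name": names.get(lab, "") if names else "",
            "n_voxels": n,
            "observed_mean": observed.get(lab, mean_suvr),
            "corrected_mean": corrected.get(lab, np.nan),
            "residual_mean": float(res.mean()),
            "residual_std": res_std,
            "pvcnstd": pvcnstd,
        })
    table = pd.DataFrame(rows, columns=["label", "name", "n_voxels",
                                        "observed_mean", "corrected_mean",
                                        "residual_mean", "residual_std",
                                        "pvcnstd"])
    if qc_labels is None:
        qc_labels = DEFAULT_QC_LABELS
    present = [lab for lab in qc_labels if lab in set(table["label"])]
    vals = table.set_index("label").loc[present, "pvcnstd"].to_numpy()
    finite = vals[np.isfinite(vals)]
    global_score = float(finite.mean()) if finite.size else np.nan
    return QcReport(table, global_score, list(present), ddof)
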