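"""NIfTI I/O, shared-grid contracts, and the Gaussian PSF primitive.

Every stage of the partial-volume-correction pipeline assumes its inputs
live on one voxel grid (segmentations and PET already co-registered and
resliced upstream).  This module loads and validates those volumes, and
holds the single Gaussian-smoothing implementation used both for the
8 mm mask-adjudication kernels and for the scanner point-spread function
in the geometric-transfer-matrix forward model, so the residual
diagnostic can never be polluted by a kernel mismatch between the two.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import nibabel as nib
import numpy as np
from scipy import ndimage

log = logging.getLogger("taupvc")

#: Gaussian FWHM -> standard deviation.
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: Absolute per-element tolerance when comparing affines.
AFFINE_ATOL = 1e-4

#: FWHM (mm) of the kernel applied to binary masks during ROI adjudication
#: (cerebellar inferior/superior split, choroid high/low leftovers).
MASK_SMOOTH_FWHM_MM = 8.0

#: Default 3-D connected-component connectivity (face+edge+corner, the
#: MATLAB ``bwlabeln`` convention).  6 and 18 are also accepted.
DEFAULT_CONNECTIVITY = 26

#: Kernels narrower than this fraction of a voxel degenerate to identity.
_MIN_FWHM_VOXELS = 0.5

#: Truncation radius of the discrete Gaussian kernel, in standard
#: deviations (scipy's default; the brute-force oracle mirrors it).
KERNEL_TRUNCATE_SD = 4.0


class GridMismatchError(ValueError):
    """Two volumes that must share a grid do not."""


class VolumeValidationError(ValueError):
    """A volume's data violates the invariants of its declared type."""


# ---------------------------------------------------------------------------
# Grid and volume containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VolumeGrid:
    """Shape + voxel-to-world affine of one sampling grid."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise VolumeValidationError(f"grid shape must be 3 positive ints, got {self.shape}")
        affine = np.array(self.affine, dtype=float)
        if affine.shape != (4, 4) or not np.all(np.isfinite(affine)):
            raise VolumeValidationError("affine must be a finite 4x4 matrix")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise VolumeValidationError("affine is singular")
        object.__setattr__(self, "shape", shape)
        affine.flags.writeable = False
        object.__setattr__(self, "affine", affine)

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the rotation block)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def matches(self, other: "VolumeGrid", atol: float = AFFINE_ATOL) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol, rtol=0.0
        )


def default_grid(shape: Sequence[int] = (64, 64, 64),
                 voxel_size_mm: float | Sequence[float] = 2.0) -> VolumeGrid:
    """Axis-aligned grid centred at the world origin (phantom convention)."""
    vs = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float).ravel(), (3,))
    affine = np.diag(np.append(vs, 1.0))
    affine[:3, 3] = -vs * (np.asarray(shape, dtype=float) - 1) / 2.0
    return VolumeGrid(tuple(int(s) for s in shape), affine)


@dataclass
class BaseVolume:
    """A data array bound to a :class:`VolumeGrid`."""

    data: np.ndarray
    grid: VolumeGrid

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.shape != self.grid.shape:
            raise VolumeValidationError(
                f"data shape {self.data.shape} != grid shape {self.grid.shape}"
            )
        self._validate()

    def _validate(self) -> None:  # pragma: no cover - overridden
        pass


class LabeledVolume(BaseVolume):
    """Integer ROI codes per voxel; 0 means unassigned (PVC value 0)."""

    def _validate(self) -> None:
        if not np.issubdtype(self.data.dtype, np.integer):
            self.data = self.data.astype(np.int32)
        if self.data.min() < 0:
            raise VolumeValidationError("labels must be >= 0")

    def labels(self) -> np.ndarray:
        """Sorted nonzero label codes present in the volume."""
        u = np.unique(self.data)
        return u[u > 0]

    def counts(self) -> dict[int, int]:
        u, c = np.unique(self.data, return_counts=True)
        return {int(lab): int(n) for lab, n in zip(u, c) if lab > 0}


class ProbabilityVolume(BaseVolume):
    """Tissue probability map, values in [0, 1]."""

    _TOL = 1e-6

    def _validate(self) -> None:
        self.data = self.data.astype(float)
        lo, hi = float(self.data.min()), float(self.data.max())
        if lo < -self._TOL or hi > 1.0 + self._TOL:
            raise VolumeValidationError(
                f"probability values outside [0,1]: min={lo:.6g} max={hi:.6g}"
            )
        np.clip(self.data, 0.0, 1.0, out=self.data)


class ScalarVolume(BaseVolume):
    """Arbitrary finite scalar field (PET activity, SUVR, PVC images)."""

    def _validate(self) -> None:
        self.data = self.data.astype(float)
        if not np.all(np.isfinite(self.data)):
            raise VolumeValidationError("scalar volume contains non-finite values")


AnyVolume = Union[LabeledVolume, ProbabilityVolume, ScalarVolume]


@dataclass(frozen=True)
class PsfModel:
    """Scanner point-spread function as a 3-D Gaussian FWHM in mm."""

    fwhm_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        fw = np.broadcast_to(np.asarray(self.fwhm_mm, dtype=float).ravel(), (3,))
        if np.any(fw <= 0) or not np.all(np.isfinite(fw)):
            raise VolumeValidationError(f"PSF FWHM must be positive, got {self.fwhm_mm}")
        object.__setattr__(self, "fwhm_mm", tuple(float(f) for f in fw))

    @classmethod
    def isotropic(cls, fwhm_mm: float) -> "PsfModel":
        return cls((float(fwhm_mm),) * 3)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_LABEL_ROUND_TOL = 1e-6


def read_volume(path: str | Path, expect: str) -> AnyVolume:
    """Read a 3-D NIfTI-1 volume and validate it as the expected type.

    Parameters
    ----------
    path
        ``.nii`` or ``.nii.gz`` file.
    expect
        One of ``"label"``, ``"probability"``, ``"scalar"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeValidationError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    grid = VolumeGrid(data.shape, img.affine)
    if expect == "label":
        data = np.asarray(data, dtype=float)
        rounded = np.round(data)
        err = np.abs(data - rounded).max()
        if err >= _LABEL_ROUND_TOL:
            raise VolumeValidationError(
                f"{path}: non-integer label data (max deviation {err:.3g})"
            )
        return LabeledVolume(rounded.astype(np.int32), grid)
    if expect == "probability":
        return ProbabilityVolume(np.asarray(data, dtype=float), grid)
    if expect == "scalar":
        return ScalarVolume(np.asarray(data, dtype=float), grid)
    raise ValueError(f"expect must be label|probability|scalar, got {expect!r}")


def write_volume(volume: AnyVolume, path: str | Path) -> None:
    """Write a volume as NIfTI-1 (labels as int16/int32, scalars as float32)."""
    path = Path(path)
    if isinstance(volume, LabeledVolume):
        dtype = np.int16 if volume.data.max() <= np.iinfo(np.int16).max else np.int32
    else:
        dtype = np.float32
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=dtype), volume.grid.affine)
    img.header.set_data_dtype(dtype)
    img.to_filename(str(path))


def assert_same_grid(volumes: Sequence[AnyVolume | VolumeGrid],
                     names: Sequence[str] | None = None) -> None:
    """Check that all volumes share one grid; raise :class:`GridMismatchError`.

    Shapes must be equal and affines must agree within 1e-4 per element —
    world-space resampling is out of scope, inputs must be pre-resliced.
    """
    if len(volumes) < 2:
        raise ValueError("assert_same_grid needs at least two volumes")
    grids = [v if isinstance(v, VolumeGrid) else v.grid for v in volumes]
    if names is None:
        names = [f"volume[{i}]" for i in range(len(grids))]
    ref = grids[0]
    for name, g in zip(names[1:], grids[1:]):
        if g.shape != ref.shape:
            raise GridMismatchError(
                f"{name}: shape {g.shape} != {names[0]} shape {ref.shape}"
            )
        if not np.allclose(g.affine, ref.affine, atol=AFFINE_ATOL, rtol=0.0):
            delta = np.abs(g.affine - ref.affine).max()
            raise GridMismatchError(
                f"{name}: affine differs from {names[0]} (max |delta| = {delta:.3g})"
            )


# ---------------------------------------------------------------------------
# Gaussian smoothing
# ---------------------------------------------------------------------------

def _sigma_voxels(fwhm_mm, voxel_size_mm) -> np.ndarray:
    fw = np.broadcast_to(np.asarray(fwhm_mm, dtype=float).ravel(), (3,)).copy()
    vs = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float).ravel(), (3,))
    if np.any(fw <= 0):
        raise ValueError(f"FWHM must be positive, got {fwhm_mm}")
    sigma = fw * FWHM_TO_SIGMA / vs
    under = fw < _MIN_FWHM_VOXELS * vs
    if under.any():
        log.warning(
            "FWHM %s mm under-resolved on %s mm voxels; smoothing degenerates "
            "to identity on axes %s", fw, vs, np.flatnonzero(under)
        )
        sigma[under] = 0.0
    return sigma


def smooth_array(data: np.ndarray, voxel_size_mm, fwhm_mm) -> np.ndarray:
    """Separable Gaussian convolution with zero-padded boundaries.

    Masks (bool/int) are promoted to float 0/1 first.  Out-of-field
    activity is assumed zero, the GTM convention, so mass is conserved up
    to boundary loss.
    """
    sigma = _sigma_voxels(fwhm_mm, voxel_size_mm)
    out = np.asarray(data, dtype=float)
    if np.all(sigma == 0):
        return out.copy()
    return ndimage.gaussian_filter(
        out, sigma, mode="constant", cval=0.0, truncate=KERNEL_TRUNCATE_SD
    )


def gaussian_smooth(volume: BaseVolume, psf: PsfModel) -> ScalarVolume:
    """PSF-smooth a volume (scalar field or binary mask) on its own grid."""
    sm = smooth_array(volume.data, volume.grid.voxel_size_mm, psf.fwhm_mm)
    return ScalarVolume(sm, volume.grid)


# ---------------------------------------------------------------------------
# Connected components (shared by ECH, choroid and reference-scan stages)
# ---------------------------------------------------------------------------

def _structure(connectivity: int) -> np.ndarray:
    try:
        rank = {6: 1, 18: 2, 26: 3}[connectivity]
    except KeyError:
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    return ndimage.generate_binary_structure(3, rank)


def component_masks(mask: np.ndarray, connectivity: int = DEFAULT_CONNECTIVITY
                    ) -> list[np.ndarray]:
    """Connected components of a boolean mask, in deterministic order.

    Components are sorted by descending voxel count, ties broken by the
    lexicographically smallest (x, y, z) minimum corner, so cluster label
    assignment is reproducible run to run.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    lab, n = ndimage.label(mask, structure=_structure(connectivity))
    objects = ndimage.find_objects(lab)
    comps = []
    for i in range(1, n + 1):
        sl = objects[i - 1]
        local = lab[sl] == i
        size = int(local.sum())
        corner = tuple(int(s.start) for s in sl)
        comps.append((size, corner, sl, local))
    comps.sort(key=lambda t: (-t[0], t[1]))
    out = []
    for size, corner, sl, local in comps:
        full = np.zeros(mask.shape, dtype=bool)
        full[sl] = local
        out.append(full)
    return out
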