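"""CT volume and kidney-mask ingestion.

Volumes and masks are NIfTI images on a common grid. Arrays are indexed
``(slice, row, col)`` with axis 0 along the scanner z-axis; this is the axis
that defines the 2D planes used for in-plane texture analysis. Spacing is the
millimetre size of a voxel along each array axis, in the same order.

No resampling is performed: features are computed on the grid as stored.
Masks are treated as ground truth; exclusion of hilar vessels and renal
pelvis is the segmenter's responsibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "CTVolume",
    "SegmentationMask",
    "ROI",
    "GridError",
    "load_volume",
    "load_mask",
    "save_volume",
    "save_mask",
    "union_masks",
    "extract_roi",
    "roi_table",
]

# foreground rule for masks that arrive with fractional values (e.g. after
# resampling elsewhere): strictly greater than 0.5
FOREGROUND_THRESHOLD = 0.5


class GridError(ValueError):
    """Shapes or spacings of companion images do not match."""


@dataclass
class CTVolume:
    """A 3D CT image in Hounsfield units.

    Attributes
    ----------
    intensities : ndarray, shape (n_slices, n_rows, n_cols)
        Voxel values in HU.
    spacing : tuple of float
        Voxel size in mm along (slice, row, col).
    """

    intensities: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError(
                f"expected a 3D volume, got {self.intensities.ndim} dimensions"
            )
        if self.intensities.shape[0] < 1:
            raise ValueError("volume must contain at least one slice")
        n_bad = int(np.count_nonzero(~np.isfinite(self.intensities)))
        if n_bad:
            raise ValueError(f"volume contains {n_bad} non-finite voxels")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape


@dataclass
class SegmentationMask:
    """Binary kidney mask on the same grid as its companion volume."""

    labels: np.ndarray
    side: str  # "left" | "right" | "union"
    spacing: tuple[float, float, float]
    empty: bool = field(init=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels).astype(bool)
        if self.labels.ndim != 3:
            raise ValueError(f"expected a 3D mask, got {self.labels.ndim} dimensions")
        if self.side not in ("left", "right", "union"):
            raise ValueError(f"side must be left/right/union, got {self.side!r}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be positive")
        self.empty = not bool(self.labels.any())

    @property
    def n_foreground(self) -> int:
        return int(np.count_nonzero(self.labels))


@dataclass
class ROI:
    """The masked voxel set from which all features are computed."""

    coordinates: np.ndarray  # (n, 3) int (slice, row, col)
    values: np.ndarray  # (n,) HU
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (n, 3)")
        n = len(self.coordinates)
        if n < 1 or len(self.values) != n:
            raise ValueError("need at least one voxel and matching value count")
        uniq = np.unique(self.coordinates, axis=0)
        if len(uniq) != n:
            raise ValueError("ROI coordinates must be unique")

    def __len__(self) -> int:
        return len(self.values)


def _spacing_from_header(img: nib.Nifti1Image) -> tuple[float, float, float]:
    zooms = img.header.get_zooms()[:3]
    return tuple(float(z) for z in zooms)


def load_volume(path: str | Path) -> CTVolume:
    """Read a CT volume from a NIfTI file.

    The array axes are used as stored, with axis 0 taken as the slice (z)
    axis; intensity values pass through unchanged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path.name}: expected a 3D image, got {data.ndim}D")
    return CTVolume(intensities=data.astype(float), spacing=_spacing_from_header(img))


def load_mask(path: str | Path, side: str) -> SegmentationMask:
    """Read a kidney segmentation mask; any value > 0.5 is foreground.

    A warning is emitted when the file contains values outside {0, 1}
    (tolerated, e.g. fractional labels produced by resampling) so that
    reinterpretation is never silent.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim != 3:
        raise ValueError(f"{path.name}: expected a 3D mask, got {data.ndim}D")
    nonbinary = ~np.isin(data, (0.0, 1.0))
    if nonbinary.any():
        warnings.warn(
            f"{path.name}: {int(nonbinary.sum())} voxels outside {{0,1}}; "
            f"thresholding at {FOREGROUND_THRESHOLD}",
            stacklevel=2,
        )
    labels = data > FOREGROUND_THRESHOLD
    mask = SegmentationMask(labels=labels, side=side, spacing=_spacing_from_header(img))
    if mask.empty:
        warnings.warn(f"{path.name}: mask has no foreground voxels", stacklevel=2)
    return mask


def _affine_from_spacing(spacing) -> np.ndarray:
    return np.diag(list(spacing) + [1.0])


def save_volume(volume: CTVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(volume.intensities.astype(np.float32), _affine_from_spacing(volume.spacing))
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def save_mask(mask: SegmentationMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.labels.astype(np.uint8), _affine_from_spacing(mask.spacing))
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def _check_grid(a_shape, a_spacing, b_shape, b_spacing) -> None:
    if tuple(a_shape) != tuple(b_shape):
        raise GridError(f"shape mismatch: {tuple(a_shape)} vs {tuple(b_shape)}")
    if not np.allclose(a_spacing, b_spacing, rtol=0, atol=1e-6):
        raise GridError(f"spacing mismatch: {a_spacing} vs {b_spacing}")


def union_masks(left: SegmentationMask, right: SegmentationMask) -> SegmentationMask:
    """Merge the two per-kidney masks with a voxelwise logical OR."""
    _check_grid(left.labels.shape, left.spacing, right.labels.shape, right.spacing)
    merged = left.labels | right.labels
    if not merged.any():
        raise ValueError("both masks are empty: no parenchyma to analyse")
    return SegmentationMask(labels=merged, side="union", spacing=left.spacing)


def extract_roi(volume: CTVolume, mask: SegmentationMask) -> ROI:
    """Gather the foreground voxels of `mask` with their HU values."""
    _check_grid(volume.shape, volume.spacing, mask.labels.shape, mask.spacing)
    if mask.empty:
        raise ValueError("cannot extract an ROI from an empty mask")
    coords = np.argwhere(mask.labels)
    values = volume.intensities[mask.labels]
    return ROI(coordinates=coords, values=values, spacing=volume.spacing)


def roi_table(roi: ROI, patient_id: str) -> pd.DataFrame:
    """Tabular ROI export (one row per voxel) for debugging/provenance."""
    return pd.DataFrame(
        {
            "patient_id": patient_id,
            "slice": roi.coordinates[:, 0],
            "row": roi.coordinates[:, 1],
            "col": roi.coordinates[:, 2],
            "hu": roi.values,
        }
    )
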