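"""NIfTI volume/mask I/O and ROI time-series extraction.

Volumes and masks must share the exact voxel lattice; no resampling is
performed (inputs are assumed fully preprocessed). Voxel order within an
ROI is the canonical C-order (lexicographic) scan of the 3D grid, which
makes extraction invariant to how voxels happened to be stored on disk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from hippoclust.config import GridSpec
from hippoclust.errors import DegenerateROIError, FormatError, ShapeError

log = logging.getLogger(__name__)

MASK_NAMES = (
    "L_hipp",
    "R_hipp",
    "L_DG",
    "R_DG",
    "L_CA1sub",
    "R_CA1sub",
    "CEN",
    "SAL",
    "VIS",
    "SMN",
)

#: SD below which a voxel series is considered constant and dropped
ZERO_VARIANCE_SD = 1e-12


@dataclass
class ROIMask:
    """A named boolean voxel mask on a fixed grid."""

    name: str
    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ShapeError(f"mask {self.name!r}: expected 3D array, got {self.data.ndim}D")
        if not self.data.any():
            raise DegenerateROIError(f"mask {self.name!r} has no voxels")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class ROIMaskSet:
    """The ten analysis masks on one shared grid."""

    masks: dict[str, ROIMask]
    grid: GridSpec

    def __post_init__(self) -> None:
        missing = set(MASK_NAMES) - set(self.masks)
        if missing:
            raise ShapeError(f"mask set missing ROIs: {sorted(missing)}")
        for m in self.masks.values():
            if m.data.shape != self.grid.dimensions:
                raise ShapeError(
                    f"mask {m.name!r} shape {m.data.shape} != grid {self.grid.dimensions}"
                )

    def __getitem__(self, name: str) -> ROIMask:
        return self.masks[name]

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, mask in self.masks.items():
            write_volume(directory / f"{name}.nii.gz", mask.data.astype(np.uint8), self.grid)

    @classmethod
    def read(cls, directory: str | Path, grid: GridSpec) -> "ROIMaskSet":
        directory = Path(directory)
        masks = {}
        for name in MASK_NAMES:
            path = directory / f"{name}.nii.gz"
            if not path.exists():
                path = directory / f"{name}.nii"
            masks[name] = read_mask(path, name=name, expected_grid=grid)
        return cls(masks=masks, grid=grid)


@dataclass
class VoxelTimeSeriesMatrix:
    """Voxel-by-timepoint matrix for one ROI of one subject."""

    data: np.ndarray  # (V, T)
    mask_name: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ShapeError(f"time-series matrix must be 2D, got {self.data.ndim}D")
        if not np.isfinite(self.data).all():
            raise FormatError(f"ROI {self.mask_name!r}: non-finite values in time series")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


def write_volume(path: str | Path, data: np.ndarray, grid: GridSpec) -> None:
    """Write a 3D or 4D array as NIfTI-1 on the grid's affine."""
    img = nib.Nifti1Image(np.asarray(data), grid.affine)
    if data.ndim == 4:
        img.header.set_zooms((grid.voxel_size_mm,) * 3 + (grid.tr_seconds,))
    nib.save(img, str(path))


def read_volume(path: str | Path, expected_grid: GridSpec | None = None) -> np.ndarray:
    """Read a 4D BOLD volume; validates dimensionality and (optionally) grid."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ShapeError(f"{path}: expected 4D BOLD volume, got {data.ndim}D")
    if expected_grid is not None and data.shape[:3] != expected_grid.dimensions:
        raise ShapeError(
            f"{path}: spatial shape {data.shape[:3]} != expected {expected_grid.dimensions}"
        )
    return data


def read_mask(
    path: str | Path,
    name: str | None = None,
    expected_grid: GridSpec | None = None,
    threshold: float | None = None,
) -> ROIMask:
    """Read a 3D mask; probabilistic masks are binarized at ``threshold``.

    Without an explicit threshold, masks stored with non-binary values are
    binarized at 0.5 (maximum-probability convention); strictly binary
    masks pass through unchanged.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ShapeError(f"{path}: expected 3D mask, got {data.ndim}D")
    if expected_grid is not None and data.shape != expected_grid.dimensions:
        raise ShapeError(f"{path}: shape {data.shape} != expected {expected_grid.dimensions}")
    values = np.unique(data)
    if not np.all(np.isin(values, (0.0, 1.0))):
        if threshold is None:
            threshold = 0.5
        data = data > threshold
    if name is None:
        name = Path(path).name.split(".")[0]
    return ROIMask(name=name, data=data.astype(bool), affine=np.asarray(img.affine))


def extract_roi_timeseries(volume: np.ndarray, mask: ROIMask) -> VoxelTimeSeriesMatrix:
    """Extract the (V, T) voxel-by-time matrix under a mask.

    Rows follow the canonical C-order scan of the grid. Voxels with
    (numerically) zero variance are dropped with a logged count; an ROI
    in which every voxel is constant is an error.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 4:
        raise ShapeError(f"expected 4D volume, got {volume.ndim}D")
    if volume.shape[:3] != mask.data.shape:
        raise ShapeError(
            f"volume spatial shape {volume.shape[:3]} != mask {mask.name!r} {mask.data.shape}"
        )
    matrix = volume[mask.data]  # C-order over True voxels
    sd = matrix.std(axis=1, ddof=1)
    keep = sd > ZERO_VARIANCE_SD
    dropped = int((~keep).sum())
    if dropped == matrix.shape[0]:
        raise DegenerateROIError(f"ROI {mask.name!r}: all {dropped} voxels are constant")
    if dropped:
        log.warning("ROI %s: dropped %d zero-variance voxel(s)", mask.name, dropped)
    return VoxelTimeSeriesMatrix(data=matrix[keep], mask_name=mask.name)


def mean_timeseries(matrix: VoxelTimeSeriesMatrix) -> np.ndarray:
    """Unweighted voxel mean at each timepoint."""
    if matrix.n_voxels < 1:
        raise DegenerateROIError(f"ROI {matrix.mask_name!r}: empty time-series matrix")
    return matrix.data.mean(axis=0)
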