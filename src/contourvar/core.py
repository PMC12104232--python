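"""Domain types and volumetric plumbing shared by all pipeline stages.

The package operates on three kinds of objects living on a common regular
3D lattice: a :class:`VoxelGrid` (geometry), :class:`StructureMask` (binary
occupancy, e.g. a delineated GTV or organ at risk) and :class:`DoseGrid`
(absorbed dose in Gy per voxel).  Coordinate convention: voxel-center
sampling, 0-based indices, physical position = origin + index * spacing.
Masks are exchanged as volumetric images (NIfTI), never as contour polygons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "VoxelGrid",
    "StructureMask",
    "DoseGrid",
    "StructureSet",
    "MetricRecord",
    "METRIC_NAMES",
    "read_mask",
    "write_mask",
    "read_dose",
    "write_dose",
    "volume_cc",
    "resample_to",
    "expand_margin",
]

#: closed vocabulary for MetricRecord.metric_name
METRIC_NAMES = frozenset(
    {
        "dV_cc",
        "MMR",
        "CV",
        "DSC",
        "HD95_mm",
        "PDC_pct",
        "dPDC_pct",
        "dDdiff_pct",
        "EUD_gy",
        "TCP",
        "NTCP",
        "dTCP",
        "dNTCP",
        "Dmax_gy",
        "Dmean_gy",
        "D1cc_gy",
    }
)


@dataclass(frozen=True)
class VoxelGrid:
    """Regular 3D lattice with (possibly anisotropic) spacing in mm."""

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"shape must be a positive integer triple, got {self.shape}")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be a positive triple, got {self.spacing_mm}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(s) for s in self.origin_mm))

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing_mm
        return sx * sy * sz

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing_mm) + [1.0])
        aff[:3, 3] = self.origin_mm
        return aff

    def extent_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical bounding box spanned by voxel centers (lo, hi)."""
        lo = np.asarray(self.origin_mm, dtype=float)
        hi = lo + (np.asarray(self.shape) - 1) * np.asarray(self.spacing_mm)
        return lo, hi

    def index_coords_of(self, points_mm: np.ndarray) -> np.ndarray:
        """Continuous index coordinates of physical points (N, 3)."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        return (pts - np.asarray(self.origin_mm)) / np.asarray(self.spacing_mm)

    def physical_coords(self, index_array: np.ndarray) -> np.ndarray:
        """Physical coordinates (mm) of integer voxel indices (N, 3)."""
        idx = np.atleast_2d(np.asarray(index_array, dtype=float))
        return np.asarray(self.origin_mm) + idx * np.asarray(self.spacing_mm)

    @classmethod
    def from_affine(cls, shape, affine: np.ndarray) -> "VoxelGrid":
        spacing = tuple(float(np.linalg.norm(affine[:3, i])) for i in range(3))
        origin = tuple(float(x) for x in affine[:3, 3])
        return cls(tuple(int(s) for s in shape), spacing, origin)


@dataclass
class StructureMask:
    """Binary occupancy on a VoxelGrid (a delineated structure)."""

    grid: VoxelGrid
    occupancy: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy)
        if occ.shape != tuple(self.grid.shape):
            raise ValueError(
                f"occupancy shape {occ.shape} does not match grid {self.grid.shape}"
            )
        self.occupancy = occ.astype(bool)

    @property
    def n_voxels(self) -> int:
        return int(self.occupancy.sum())

    @property
    def volume_cc(self) -> float:
        return self.n_voxels * self.grid.voxel_volume_mm3 / 1000.0

    def is_empty(self) -> bool:
        return not self.occupancy.any()

    def occupied_coords_mm(self) -> np.ndarray:
        idx = np.argwhere(self.occupancy)
        return self.grid.physical_coords(idx)


@dataclass
class DoseGrid:
    """Scalar absorbed dose (Gy) per voxel on a VoxelGrid."""

    grid: VoxelGrid
    dose_gy: np.ndarray

    def __post_init__(self) -> None:
        dose = np.asarray(self.dose_gy, dtype=float)
        if dose.shape != tuple(self.grid.shape):
            raise ValueError(
                f"dose shape {dose.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(dose)):
            raise ValueError("dose contains non-finite values")
        if np.any(dose < 0):
            raise ValueError("dose contains negative values")
        self.dose_gy = dose


@dataclass
class StructureSet:
    """One observer's delineations, keyed by structure label, on one grid."""

    observer_id: str
    masks: dict[str, StructureMask] = field(default_factory=dict)

    def add(self, mask: StructureMask) -> None:
        if mask.label in self.masks:
            raise ValueError(f"duplicate structure label {mask.label!r}")
        if self.masks:
            ref = next(iter(self.masks.values())).grid
            if mask.grid != ref:
                raise ValueError("all masks in a StructureSet must share one grid")
        self.masks[mask.label] = mask

    def __getitem__(self, label: str) -> StructureMask:
        return self.masks[label]

    def __contains__(self, label: str) -> bool:
        return label in self.masks

    @property
    def labels(self) -> list[str]:
        return list(self.masks)

    @property
    def grid(self) -> VoxelGrid:
        return next(iter(self.masks.values())).grid


@dataclass
class MetricRecord:
    """One row of a long-format report table (one metric value per
    patient/observer/structure)."""

    patient_id: str
    observer_id: str
    structure_label: str
    metric_name: str
    value: float
    units: str = ""

    def __post_init__(self) -> None:
        if self.metric_name not in METRIC_NAMES:
            raise ValueError(
                f"unknown metric {self.metric_name!r}; allowed: {sorted(METRIC_NAMES)}"
            )


# ---------------------------------------------------------------------------
# I/O


def _load_volume(path) -> tuple[np.ndarray, VoxelGrid]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    grid = VoxelGrid.from_affine(data.shape, img.affine)
    return data, grid


def read_mask(path, label: str | None = None) -> StructureMask:
    """Read a binary structure mask from a NIfTI/NRRD-style volume.

    Occupancy convention: a voxel is occupied iff its value exceeds half the
    volume maximum, so {0,1}, {0,255} and probability maps all binarize
    consistently.  An all-zero volume yields a valid empty mask (warned).
    """
    data, grid = _load_volume(path)
    vmax = float(np.max(data)) if data.size else 0.0
    if vmax <= 0:
        warnings.warn(f"{path}: all-zero volume read as empty mask", stacklevel=2)
        occ = np.zeros(grid.shape, dtype=bool)
    else:
        occ = data > 0.5 * vmax
    if label is None:
        import os

        label = os.path.basename(str(path)).split(".")[0]
    return StructureMask(grid=grid, occupancy=occ, label=label)


def write_mask(mask: StructureMask, path) -> None:
    img = nib.Nifti1Image(mask.occupancy.astype(np.uint8), mask.grid.affine)
    nib.save(img, str(path))


def read_dose(path) -> DoseGrid:
    data, grid = _load_volume(path)
    return DoseGrid(grid=grid, dose_gy=np.asarray(data, dtype=float))


def write_dose(dose: DoseGrid, path) -> None:
    img = nib.Nifti1Image(dose.dose_gy.astype(np.float32), dose.grid.affine)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Geometry operations


def volume_cc(mask: StructureMask) -> float:
    """Structure volume in cc: occupied voxels x voxel volume (mm^3) / 1000."""
    return mask.volume_cc


def bbox_slices(occ: np.ndarray, pad_vox: tuple[int, int, int]) -> tuple[slice, slice, slice]:
    """Bounding-box slices of the True region, padded and clipped to the array.

    Distance-transform-based operators are local: computing them on a
    sufficiently padded bounding box is exact and much faster than on the
    full grid.  Raises on an all-False array.
    """
    if not occ.any():
        raise ValueError("cannot take the bounding box of an empty mask")
    slices = []
    for axis, pad in enumerate(pad_vox):
        other = tuple(i for i in range(occ.ndim) if i != axis)
        hit = np.any(occ, axis=other)
        lo = int(np.argmax(hit))
        hi = int(len(hit) - np.argmax(hit[::-1]))
        slices.append(slice(max(0, lo - int(pad)), min(len(hit), hi + int(pad))))
    return tuple(slices)


def resample_to(dose: DoseGrid, target: VoxelGrid) -> DoseGrid:
    """Trilinearly resample a dose grid onto a target grid.

    Target voxel centers outside the source extent get dose 0.  Disjoint
    physical extents are an error.
    """
    if dose.grid == target:
        return DoseGrid(grid=target, dose_gy=dose.dose_gy.copy())
    slo, shi = dose.grid.extent_mm()
    tlo, thi = target.extent_mm()
    if np.any(thi < slo) or np.any(tlo > shi):
        raise ValueError("target grid extent is disjoint from the dose grid extent")
    ii, jj, kk = np.meshgrid(
        np.arange(target.shape[0]),
        np.arange(target.shape[1]),
        np.arange(target.shape[2]),
        indexing="ij",
    )
    idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    pts = target.physical_coords(idx)
    src_idx = dose.grid.index_coords_of(pts)  # continuous index coords
    vals = ndimage.map_coordinates(
        dose.dose_gy, src_idx.T, order=1, mode="constant", cval=0.0
    )
    return DoseGrid(grid=target, dose_gy=vals.reshape(target.shape))


def expand_margin(mask: StructureMask, margin_mm: float) -> StructureMask:
    """Isotropic margin expansion via the exact Euclidean distance transform.

    A voxel is occupied in the result iff the Euclidean distance from its
    center to the nearest occupied voxel center (respecting anisotropic
    spacing) is <= margin_mm.  margin 0 is the identity; negative margins
    are rejected (erosion is a separate synthetic-module operator).
    """
    if margin_mm < 0:
        raise ValueError("margin must be nonnegative")
    if margin_mm == 0 or mask.is_empty():
        return StructureMask(grid=mask.grid, occupancy=mask.occupancy.copy(), label=mask.label)
    # the expansion is local: an exact EDT on the padded bounding box suffices
    pad = tuple(int(np.ceil(margin_mm / s)) + 1 for s in mask.grid.spacing_mm)
    box = bbox_slices(mask.occupancy, pad)
    dist = ndimage.distance_transform_edt(
        ~mask.occupancy[box], sampling=mask.grid.spacing_mm
    )
    occ = np.zeros(mask.grid.shape, dtype=bool)
    occ[box] = dist <= margin_mm + 1e-9
    return StructureMask(grid=mask.grid, occupancy=occ, label=mask.label)


def signed_distance_mm(mask: StructureMask) -> np.ndarray:
    """Signed Euclidean distance field (mm): negative inside, positive outside."""
    occ = mask.occupancy
    outside = ndimage.distance_transform_edt(~occ, sampling=mask.grid.spacing_mm)
    inside = ndimage.distance_transform_edt(occ, sampling=mask.grid.spacing_mm)
    return outside - inside
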