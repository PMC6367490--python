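"""Grid-aligned volume types, connected-component labelling and NIfTI I/O.

All downstream stages operate on three core containers:

``SuvImage``
    a 3-D scalar field of standardised uptake values (SUV, g/mL) on an
    anisotropic voxel grid,
``BinaryMask``
    a boolean field aligned to an image grid (a delineation), and
``LabeledLesions``
    an integer field assigning each foreground voxel to exactly one
    connected component (a lesion).

Physical coordinates follow the voxel-centre convention:
``x = origin + index * spacing`` with 0-based indices; all distances are
computed in millimetres, honouring anisotropic spacing.  Masks always live
on the exact grid of their source image — nothing in this package resamples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Grid",
    "SuvImage",
    "BinaryMask",
    "LabeledLesions",
    "VolumeFormatError",
    "GridMismatchError",
    "label_components",
    "connectivity_structure",
    "read_volume",
    "write_volume",
]


class VolumeFormatError(ValueError):
    """Raised when a volume on disk or in memory violates the format contract."""


class GridMismatchError(ValueError):
    """Raised when two volumes that must share a grid do not."""


@dataclass(frozen=True)
class Grid:
    """Voxel lattice: shape, per-axis spacing (mm) and physical origin (mm)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise VolumeFormatError("grids are strictly 3-D")
        if any(s <= 0 for s in self.spacing):
            raise VolumeFormatError(f"voxel spacing must be positive, got {self.spacing}")

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (spacing product / 1000)."""
        return float(np.prod(self.spacing)) / 1000.0

    def matches(self, other: "Grid", atol: float = 1e-4) -> bool:
        """True if shapes are identical and spacing/origin agree within `atol` mm."""
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def require_match(self, other: "Grid") -> None:
        if not self.matches(other):
            raise GridMismatchError(f"grid mismatch: {self} vs {other}")


def _as_grid_tuple(x) -> tuple:
    return tuple(float(v) for v in x)


@dataclass(frozen=True)
class SuvImage:
    """3-D standardised-uptake-value image.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        SUV in g/mL; finite and non-negative.
    spacing : (3,) sequence of float
        Voxel edge lengths in mm, all positive.
    origin : (3,) sequence of float
        Physical coordinate (mm) of the centre of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3:
            raise VolumeFormatError(f"SUV image must be 3-D, got ndim={values.ndim}")
        if not np.all(np.isfinite(values)):
            raise VolumeFormatError("SUV values must be finite")
        if np.any(values < 0):
            raise VolumeFormatError("SUV values must be non-negative")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", _as_grid_tuple(self.spacing))
        object.__setattr__(self, "origin", _as_grid_tuple(self.origin))
        # Grid construction validates spacing/shape.
        self.grid

    @property
    def grid(self) -> Grid:
        return Grid(tuple(self.values.shape), self.spacing, self.origin)

    @property
    def voxel_volume_ml(self) -> float:
        return self.grid.voxel_volume_ml


@dataclass(frozen=True)
class BinaryMask:
    """Boolean delineation on the grid of its source image."""

    values: np.ndarray
    grid: Grid

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=bool)
        if values.shape != tuple(self.grid.shape):
            raise GridMismatchError(
                f"mask shape {values.shape} does not match grid shape {self.grid.shape}"
            )
        object.__setattr__(self, "values", values)

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    @property
    def volume_ml(self) -> float:
        """Delineated volume in mL: voxel count times voxel volume."""
        return self.n_voxels * self.grid.voxel_volume_ml

    def is_empty(self) -> bool:
        return not bool(self.values.any())


@dataclass(frozen=True)
class LabeledLesions:
    """Partition of a foreground into connected components (lesion ids 1..N)."""

    labels: np.ndarray
    grid: Grid
    connectivity: int = 26
    n_lesions: int = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if not np.issubdtype(labels.dtype, np.integer):
            raise VolumeFormatError("lesion labels must be integer")
        if labels.shape != tuple(self.grid.shape):
            raise GridMismatchError("label shape does not match grid")
        object.__setattr__(self, "labels", labels)
        n = int(labels.max()) if labels.size else 0
        if self.n_lesions is None:
            object.__setattr__(self, "n_lesions", n)
        elif self.n_lesions != n:
            raise VolumeFormatError("n_lesions inconsistent with label field")

    def lesion_ids(self) -> list[int]:
        return list(range(1, self.n_lesions + 1))

    def mask_for(self, lesion_id: int) -> BinaryMask:
        return BinaryMask(self.labels == lesion_id, self.grid)

    def foreground(self) -> BinaryMask:
        return BinaryMask(self.labels > 0, self.grid)


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3x3x3 structuring element for a neighbourhood order (6, 18 or 26)."""
    order = {6: 1, 18: 2, 26: 3}.get(connectivity)
    if order is None:
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    return ndimage.generate_binary_structure(3, order)


def label_components(mask: BinaryMask, connectivity: int = 26) -> LabeledLesions:
    """Label connected components of a mask in deterministic scan order.

    An empty mask yields zero components (not an error).  Ids 1..N are
    assigned in ascending raster order of each component's first voxel.
    """
    labels, n = ndimage.label(mask.values, structure=connectivity_structure(connectivity))
    return LabeledLesions(labels.astype(np.int32), mask.grid, connectivity, n)


# ---------------------------------------------------------------------------
# NIfTI I/O

def _affine_from_grid(grid: Grid) -> np.ndarray:
    affine = np.diag(list(grid.spacing) + [1.0])
    affine[:3, 3] = grid.origin
    return affine


def _grid_from_img(img: nib.Nifti1Image) -> Grid:
    data_shape = img.shape
    if len(data_shape) != 3:
        raise VolumeFormatError(f"expected a 3-D volume, got shape {data_shape}")
    # spacing from the affine column norms: unlike the header pixdims these
    # are not silently "repaired" by nibabel, so degenerate files stay visible
    zooms = np.linalg.norm(img.affine[:3, :3], axis=0)
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise VolumeFormatError(f"non-positive or missing voxel spacing {tuple(zooms)}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return Grid(tuple(int(s) for s in data_shape), _as_grid_tuple(zooms), origin)


def read_volume(path, kind: str = "image") -> SuvImage | BinaryMask:
    """Read a 3-D NIfTI volume as a ``SuvImage`` (`kind="image"`) or
    ``BinaryMask`` (`kind="mask"`).

    Gzip-compressed files are handled transparently by nibabel.  Masks on
    disk are any-nonzero fields; images must be finite and non-negative.
    """
    img = nib.load(str(path))
    grid = _grid_from_img(img)
    data = np.asanyarray(img.dataobj)
    if kind == "image":
        return SuvImage(np.asarray(data, dtype=float), grid.spacing, grid.origin)
    if kind == "mask":
        return BinaryMask(np.asarray(data) != 0, grid)
    raise ValueError(f"kind must be 'image' or 'mask', got {kind!r}")


def write_volume(obj: SuvImage | BinaryMask | LabeledLesions, path) -> None:
    """Write a volume to NIfTI.

    Images are stored as float64, masks as 8-bit 0/1, label fields as int32;
    spacing and origin go into the affine/header so a round-trip preserves
    values and geometry within float tolerance.
    """
    if isinstance(obj, SuvImage):
        data, grid = obj.values.astype(np.float64), obj.grid
    elif isinstance(obj, BinaryMask):
        data, grid = obj.values.astype(np.uint8), obj.grid
    elif isinstance(obj, LabeledLesions):
        data, grid = obj.labels.astype(np.int32), obj.grid
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    img = nib.Nifti1Image(data, _affine_from_grid(grid))
    img.header.set_zooms(grid.spacing)
    nib.save(img, str(path))
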