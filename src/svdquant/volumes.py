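"""Volume containers, mask algebra and resampling.

Everything downstream works on three primitives:

``VolumeGrid``
    a 3D scalar image together with its voxel spacing (mm) and the 4x4
    voxel-to-world affine.  All volumes of one subject are expected to be
    coregistered onto one grid before analysis.

``BinaryMask``
    a boolean volume tied to the geometry of a reference grid.  All
    segmentation outputs are BinaryMasks; physical volume in mL is always
    computed from the header spacing (no through-plane interpolation), so a
    5 mm slice with a 1 mm gap contributes dz = 6 mm per voxel.

``AffineTransform``
    a world-to-world 4x4 map, as produced by rigid/affine registration.
    Transforms are stored as plain-text 4x4 matrices (whitespace separated,
    world coordinates, mapping native world -> target world).

Volumes are reoriented to the closest RAS orientation at load; the original
affine is retained for write-back.  Analyze 7.5 stores no orientation, so
such files are assumed to be in the protocol's axial orientation and a
warning is emitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import (
    DimensionalityError,
    FormatError,
    GridMismatchError,
    TransformError,
    ValidationError,
)

__all__ = [
    "VolumeGrid",
    "GridRef",
    "BinaryMask",
    "AffineTransform",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "combine_masks",
    "mask_volume_ml",
    "resample_mask",
    "resample_volume",
]

_GEOM_ATOL = 1e-4


def _spacing_from_affine(affine: np.ndarray) -> tuple[float, float, float]:
    return tuple(float(np.linalg.norm(affine[:3, i])) for i in range(3))


@dataclass
class VolumeGrid:
    """A 3D scalar image with physical geometry.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar image in arbitrary units. NaN is the missing-value sentinel.
    affine : ndarray, shape (4, 4)
        Voxel-to-world matrix (mm).
    spacing : tuple of float, optional
        Voxel size (dx, dy, dz) in mm; derived from the affine if omitted.
    modality_tag : str
        Free-text label (e.g. "FLAIR", "T2*W").
    """

    data: np.ndarray
    affine: np.ndarray
    spacing: tuple[float, float, float] | None = None
    modality_tag: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"expected a 3D volume, got {self.data.ndim}D shape {self.data.shape}"
            )
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValidationError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValidationError("affine is singular")
        if self.spacing is None:
            self.spacing = _spacing_from_affine(self.affine)
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    def grid_ref(self) -> "GridRef":
        return GridRef(shape=self.shape, spacing=self.spacing, affine=self.affine)

    def same_grid(self, other) -> bool:
        return self.grid_ref().matches(_as_grid_ref(other))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices (n, 3) to world mm coordinates."""
        ijk = np.atleast_2d(ijk)
        hom = np.c_[ijk, np.ones(len(ijk))]
        return (self.affine @ hom.T).T[:, :3]


@dataclass(frozen=True)
class GridRef:
    """Geometry identity of a grid: shape + spacing + affine."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    affine: np.ndarray = field(repr=False)

    def matches(self, other: "GridRef") -> bool:
        return (
            tuple(self.shape) == tuple(other.shape)
            and np.allclose(self.spacing, other.spacing, atol=_GEOM_ATOL)
            and np.allclose(self.affine, other.affine, atol=_GEOM_ATOL)
        )

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    def empty_volume(self, fill: float = 0.0, modality_tag: str = "") -> VolumeGrid:
        return VolumeGrid(
            np.full(self.shape, fill, dtype=float),
            affine=self.affine,
            spacing=self.spacing,
            modality_tag=modality_tag,
        )


def _as_grid_ref(obj) -> GridRef:
    if isinstance(obj, GridRef):
        return obj
    if isinstance(obj, (VolumeGrid, BinaryMask)):
        return obj.grid_ref() if isinstance(obj, VolumeGrid) else obj.grid
    raise TypeError(f"cannot interpret {type(obj)} as a grid")


@dataclass
class BinaryMask:
    """A boolean volume on a reference grid.

    All derived masks of one subject share one grid; set algebra between
    masks on different grids raises :class:`GridMismatchError`.
    """

    data: np.ndarray
    grid: GridRef

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.shape != tuple(self.grid.shape):
            raise GridMismatchError(
                f"mask shape {self.data.shape} != grid shape {self.grid.shape}"
            )

    @classmethod
    def from_volume(cls, vol: VolumeGrid, data: np.ndarray | None = None) -> "BinaryMask":
        return cls(vol.data.astype(bool) if data is None else data, vol.grid_ref())

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def volume_ml(self) -> float:
        return mask_volume_ml(self)

    def is_empty(self) -> bool:
        return not self.data.any()

    def _check_same_grid(self, other: "BinaryMask") -> None:
        if not self.grid.matches(other.grid):
            raise GridMismatchError("masks live on different grids")

    def __and__(self, other: "BinaryMask") -> "BinaryMask":
        return combine_masks("and", self, other)

    def __or__(self, other: "BinaryMask") -> "BinaryMask":
        return combine_masks("or", self, other)

    def __xor__(self, other: "BinaryMask") -> "BinaryMask":
        return combine_masks("xor", self, other)

    def __sub__(self, other: "BinaryMask") -> "BinaryMask":
        return combine_masks("subtract", self, other)

    def __invert__(self) -> "BinaryMask":
        return BinaryMask(~self.data, self.grid)


@dataclass(frozen=True)
class AffineTransform:
    """A world-to-world 4x4 affine map (native world -> target world)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise TransformError("transform must be a 4x4 matrix")
        if abs(np.linalg.det(m[:3, :3])) < 1e-12:
            raise TransformError("transform is singular")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))

    @classmethod
    def from_file(cls, path) -> "AffineTransform":
        m = np.loadtxt(path)
        return cls(m)

    def to_file(self, path) -> None:
        np.savetxt(path, self.matrix, fmt="%.10g")

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """Return the map `self after other` (apply `other` first)."""
        return AffineTransform(self.matrix @ other.matrix)

    def __matmul__(self, other: "AffineTransform") -> "AffineTransform":
        return self.compose(other)

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))

    def apply_points(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(xyz)
        hom = np.c_[xyz, np.ones(len(xyz))]
        return (self.matrix @ hom.T).T[:, :3]


# ---------------------------------------------------------------------------
# File IO
# ---------------------------------------------------------------------------

def read_volume(path, format: str | None = None, modality_tag: str = "") -> VolumeGrid:
    """Read a NIfTI-1 or Analyze 7.5 volume.

    The image is reoriented to the closest RAS convention.  Analyze 7.5
    headers carry no orientation; the file is assumed to already be in the
    protocol's axial orientation (a warning is issued).

    Parameters
    ----------
    path : path-like
    format : {"nifti", "analyze75", None}
        Autodetected from the suffix when None.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format is None:
        format = "analyze75" if path.suffix in (".hdr", ".img") else "nifti"
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several header error types
        raise FormatError(f"cannot parse {path} as an image: {exc}") from exc

    if format == "analyze75":
        if not isinstance(img, nib.AnalyzeImage):
            raise FormatError(f"{path} is not an Analyze 7.5 image")
        warnings.warn(
            "Analyze 7.5 stores no orientation; assuming the protocol's "
            "axial orientation",
            stacklevel=2,
        )
    elif isinstance(img, nib.Nifti1Image):
        img = nib.as_closest_canonical(img)
    else:
        raise FormatError(f"{path} is not a NIfTI-1 image")

    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise DimensionalityError(
            f"{path}: expected 3D data, got shape {data.shape}"
        )
    affine = img.affine if img.affine is not None else np.eye(4)
    zooms = img.header.get_zooms()[:3]
    return VolumeGrid(
        np.asarray(data, dtype=np.float64),
        affine=np.asarray(affine, dtype=float),
        spacing=tuple(float(z) for z in zooms),
        modality_tag=modality_tag,
    )


def write_volume(vol: VolumeGrid, path, dtype=np.float32) -> None:
    """Write a volume as NIfTI-1 (or Analyze 7.5 for .hdr/.img paths)."""
    path = Path(path)
    data = np.asarray(vol.data, dtype=dtype)
    if path.suffix in (".hdr", ".img"):
        img = nib.AnalyzeImage(data, vol.affine)
    else:
        img = nib.Nifti1Image(data, vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def read_mask(path, reference: GridRef | None = None) -> BinaryMask:
    """Read a uint8 mask image; optionally validate against a reference grid."""
    vol = read_volume(path)
    mask = BinaryMask(vol.data > 0.5, vol.grid_ref())
    if reference is not None and not mask.grid.matches(reference):
        raise GridMismatchError(f"mask {path} is not on the reference grid")
    return mask


def write_mask(mask: BinaryMask, path) -> None:
    vol = VolumeGrid(
        mask.data.astype(np.uint8),
        affine=mask.grid.affine,
        spacing=mask.grid.spacing,
    )
    write_volume(vol, path, dtype=np.uint8)


# ---------------------------------------------------------------------------
# Mask algebra and measurement
# ---------------------------------------------------------------------------

_MASK_OPS = {
    "and": np.logical_and,
    "or": np.logical_or,
    "xor": np.logical_xor,
    "subtract": lambda a, b: np.logical_and(a, np.logical_not(b)),
}


def combine_masks(op: str, a: BinaryMask, b: BinaryMask) -> BinaryMask:
    """Voxelwise boolean combination of two masks on one grid."""
    if op not in _MASK_OPS:
        raise ValueError(f"unknown op {op!r}; choose from {sorted(_MASK_OPS)}")
    a._check_same_grid(b)
    return BinaryMask(_MASK_OPS[op](a.data, b.data), a.grid)


def mask_volume_ml(mask: BinaryMask) -> float:
    """Physical volume of the true voxels in mL (header spacing; 1 mL = 1000 mm^3)."""
    return mask.n_voxels * mask.grid.voxel_volume_mm3 / 1000.0


def _index_map_matrix(
    source: GridRef, transform: AffineTransform, target: GridRef
) -> tuple[np.ndarray, np.ndarray]:
    """Matrix/offset mapping target voxel indices to source voxel indices.

    The world-to-world transform maps source(native) world -> target world,
    so pulling back a target voxel requires its inverse.
    """
    src_aff = np.asarray(source.affine)
    tgt_aff = np.asarray(target.affine)
    full = np.linalg.inv(src_aff) @ np.linalg.inv(transform.matrix) @ tgt_aff
    return full[:3, :3], full[:3, 3]


def resample_mask(
    mask: BinaryMask,
    transform: AffineTransform,
    target_grid: GridRef | VolumeGrid,
    method: str = "nearest",
    threshold: float = 0.5,
) -> BinaryMask:
    """Express a mask on a target grid under a world-to-world transform.

    ``method="nearest"`` preserves binarity exactly; ``"trilinear_threshold"``
    interpolates partial volumes and binarizes at ``threshold`` (0.5 is the
    unbiased cut), which aliases less for few-voxel objects.
    """
    target = _as_grid_ref(target_grid)
    if method not in ("nearest", "trilinear_threshold"):
        raise ValueError(f"unknown method {method!r}")
    if (
        mask.grid.matches(target)
        and np.allclose(transform.matrix, np.eye(4), atol=1e-12)
    ):
        return BinaryMask(mask.data.copy(), target)
    matrix, offset = _index_map_matrix(mask.grid, transform, target)
    if method == "nearest":
        out = ndimage.affine_transform(
            mask.data.astype(np.uint8), matrix, offset=offset,
            output_shape=target.shape, order=0, mode="constant", cval=0,
        ).astype(bool)
    else:
        interp = ndimage.affine_transform(
            mask.data.astype(np.float64), matrix, offset=offset,
            output_shape=target.shape, order=1, mode="constant", cval=0.0,
        )
        out = interp >= threshold
    return BinaryMask(out, target)


def resample_volume(
    vol: VolumeGrid,
    transform: AffineTransform,
    target_grid: GridRef | VolumeGrid,
    order: int = 1,
) -> VolumeGrid:
    """Resample a scalar volume onto a target grid (trilinear by default)."""
    target = _as_grid_ref(target_grid)
    matrix, offset = _index_map_matrix(vol.grid_ref(), transform, target)
    out = ndimage.affine_transform(
        np.asarray(vol.data, dtype=np.float64), matrix, offset=offset,
        output_shape=target.shape, order=order, mode="constant", cval=0.0,
    )
    return VolumeGrid(out, affine=target.affine, spacing=target.spacing,
                      modality_tag=vol.modality_tag)
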