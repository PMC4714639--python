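"""Standard-space mapping, lesion probability maps and volume distortion.

Feature masks are mapped to a common template grid with a world-to-world
affine and averaged across subjects into spatial probability maps.  Affine
mapping rescales volumes by |det| of the linear part — a typical
native-to-template map inflates lesions about 2.5x (about 1.36x per
dimension) — so probability maps serve only to study the *relative*
spatial distribution of disease markers; volumes are always reported from
native space, never from standard space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GridMismatchError, ValidationError
from .volumes import (
    AffineTransform,
    BinaryMask,
    GridRef,
    VolumeGrid,
    resample_mask,
)

__all__ = [
    "StandardSpaceResult",
    "to_standard",
    "probability_map",
    "volume_distortion",
    "synthetic_template_grid",
]

DISTORTION_NOTE = (
    "Affine standard-space mapping rescales volumes by |det|; probability "
    "maps are only for studying the relative spatial distribution of "
    "markers, never for measuring lesion size."
)


@dataclass
class StandardSpaceResult:
    """A standard-space mask with both native and standard volumes recorded.

    The native volume is the quantitative measurement; the standard-space
    volume exists only to document the distortion.
    """

    mask: BinaryMask
    native_volume_ml: float
    standard_volume_ml: float
    volumetric_factor: float
    note: str = DISTORTION_NOTE


def to_standard(
    mask: BinaryMask,
    transform: AffineTransform,
    template_grid: GridRef | VolumeGrid,
    method: str = "trilinear_threshold",
) -> StandardSpaceResult:
    """Resample a native mask onto the template grid.

    ``transform`` maps native world coordinates to template world
    coordinates.  Trilinear interpolation with a 0.5 cut is the default
    because nearest-neighbour aliases few-voxel lesions.
    """
    out = resample_mask(mask, transform, template_grid, method=method)
    return StandardSpaceResult(
        mask=out,
        native_volume_ml=mask.volume_ml,
        standard_volume_ml=out.volume_ml,
        volumetric_factor=volume_distortion(transform)[0],
    )


def probability_map(masks: list[BinaryMask]) -> VolumeGrid:
    """Voxelwise mean of binary masks on one template grid (values in [0,1])."""
    if not masks:
        raise ValidationError("need at least one mask")
    ref = masks[0].grid
    for m in masks[1:]:
        if not m.grid.matches(ref):
            raise GridMismatchError("probability map inputs on different grids")
    acc = np.zeros(ref.shape, dtype=float)
    for m in masks:
        acc += m.data
    acc /= len(masks)
    return VolumeGrid(acc, affine=ref.affine, spacing=ref.spacing,
                      modality_tag="probability")


def volume_distortion(transform: AffineTransform) -> tuple[float, float]:
    """(volumetric factor, per-dimension factor) of an affine map.

    The volumetric factor is |det| of the linear part; its cube root is the
    equivalent isotropic per-dimension scale.  Multiplicative under
    composition.
    """
    det = abs(float(np.linalg.det(transform.matrix[:3, :3])))
    return det, det ** (1.0 / 3.0)


def synthetic_template_grid(
    shape: tuple[int, int, int] = (91, 109, 91),
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0),
) -> GridRef:
    """A built-in standard-space grid for tests and examples.

    Mimics the geometry of a 2 mm isotropic adult template with a centered,
    RAS-oriented affine; real studies supply their own template grid.
    """
    affine = np.diag(list(spacing) + [1.0])
    affine[:3, 3] = -(np.asarray(shape) - 1) * np.asarray(spacing) / 2.0
    return GridRef(shape=tuple(shape), spacing=tuple(spacing), affine=affine)
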