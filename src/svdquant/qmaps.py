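"""Quantitative maps: variable-flip-angle T1 mapping and ROI statistics.

Two spoiled gradient-echo (SPGR/FSPGR) acquisitions at flip angles of 2 and
12 degrees with TR = 8.2 ms allow a closed-form per-voxel T1 estimate.  The
forward steady-state SPGR signal is

    S(alpha) = M0 sin(alpha) (1 - E) / (1 - E cos(alpha)),  E = exp(-TR/T1)

and from the signal ratio SR = S1/S2 of the two flip angles the two-point
inversion is

    E = (SR sin(a2) - sin(a1)) / (SR sin(a2) cos(a1) - sin(a1) cos(a2))
    T1 = -TR / ln(E)

Voxels whose E falls outside (0, 1) — noise, vessels, background — carry
the NaN missing sentinel and are excluded from all statistics, never
zero-filled.  An optional multiplicative B1 scale map corrects flip angles
when available (identity by default).

ROI statistics honor the protocol's partial-volume guard: the CSF mask is
dilated by one voxel in every direction and subtracted from each tissue
mask before averaging FA/MD/T1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .errors import ParameterError, ValidationError
from .volumes import BinaryMask, VolumeGrid

__all__ = [
    "VFAParams",
    "spgr_signal",
    "t1_from_vfa",
    "map_statistics",
    "validate_roi_template",
]


@dataclass(frozen=True)
class VFAParams:
    """Acquisition parameters of the variable-flip-angle pair.

    TR in ms; flip angles in degrees with 0 < alpha1 < alpha2 < 90.
    Protocol defaults: TR = 8.2 ms, 2 and 12 degrees.
    """

    TR: float = 8.2
    alpha1: float = 2.0
    alpha2: float = 12.0

    def __post_init__(self) -> None:
        if self.TR <= 0:
            raise ParameterError("TR must be positive")
        if not (0 < self.alpha1 < self.alpha2 < 90):
            raise ParameterError(
                f"need 0 < alpha1 < alpha2 < 90 degrees, got "
                f"({self.alpha1}, {self.alpha2})")


def spgr_signal(m0, t1, params: VFAParams, alpha: float):
    """Steady-state spoiled gradient-echo signal (forward model).

    Accepts scalars or arrays for ``m0`` and ``t1`` (ms).
    """
    t1 = np.asarray(t1, dtype=float)
    if np.any(t1 <= 0):
        raise ParameterError("T1 must be positive")
    a = math.radians(alpha)
    E = np.exp(-params.TR / t1)
    return m0 * math.sin(a) * (1.0 - E) / (1.0 - E * math.cos(a))


def t1_from_vfa(
    s1: VolumeGrid,
    s2: VolumeGrid,
    params: VFAParams | None = None,
    mask: BinaryMask | None = None,
    b1_scale: VolumeGrid | None = None,
) -> VolumeGrid:
    """Closed-form T1 map (ms) from the two-flip-angle SPGR pair.

    ``s1`` is the low-flip (alpha1) image, ``s2`` the high-flip (alpha2)
    image.  Nonphysical voxels (E outside (0,1), zero s2) become NaN.
    """
    params = params or VFAParams()
    if not s1.grid_ref().matches(s2.grid_ref()):
        raise ValidationError("the two flip-angle volumes are not coregistered")
    a1 = np.radians(params.alpha1)
    a2 = np.radians(params.alpha2)
    if b1_scale is not None:
        a1 = a1 * np.asarray(b1_scale.data, float)
        a2 = a2 * np.asarray(b1_scale.data, float)
    sin1, cos1 = np.sin(a1), np.cos(a1)
    sin2, cos2 = np.sin(a2), np.cos(a2)
    d1 = np.asarray(s1.data, float)
    d2 = np.asarray(s2.data, float)
    out = np.full(d1.shape, np.nan)
    dom = np.isfinite(d1) & np.isfinite(d2) & (d2 != 0)
    if mask is not None:
        dom &= mask.data
    with np.errstate(divide="ignore", invalid="ignore"):
        sr = d1 / np.where(d2 == 0, np.nan, d2)
        num = sr * sin2 - sin1
        den = sr * sin2 * cos1 - sin1 * cos2
        E = num / np.where(den == 0, np.nan, den)
        valid = dom & np.isfinite(E) & (E > 0) & (E < 1)
        out[valid] = -params.TR / np.log(E[valid])
    return VolumeGrid(out, affine=s1.affine, spacing=s1.spacing,
                      modality_tag="T1 (ms)")


def map_statistics(
    qmap: VolumeGrid,
    masks: dict[str, BinaryMask],
    csf: BinaryMask | None = None,
    csf_dilate_vox: int = 1,
    map_name: str = "",
) -> pd.DataFrame:
    """Per-mask statistics of a quantitative map with CSF-rim exclusion.

    The CSF mask is dilated by ``csf_dilate_vox`` voxels in each direction
    (box element) and subtracted from every mask before computing n, mean,
    sd and median.  NaN map voxels are excluded.  Masks emptied by the
    exclusion yield a row with n = 0 and a flag.
    """
    data = np.asarray(qmap.data, float)
    excl = None
    if csf is not None and csf_dilate_vox > 0 and not csf.is_empty():
        size = 2 * csf_dilate_vox + 1
        excl = ndimage.binary_dilation(csf.data, structure=np.ones((size,) * 3, bool))
    elif csf is not None:
        excl = csf.data
    rows = []
    name = map_name or qmap.modality_tag or "map"
    for roi, mask in masks.items():
        sel = mask.data.copy()
        if excl is not None:
            sel &= ~excl
        vals = data[sel]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            rows.append({"roi": roi, "map": name, "n": 0, "mean": np.nan,
                         "sd": np.nan, "median": np.nan,
                         "flag": "emptied by CSF exclusion"})
        else:
            rows.append({"roi": roi, "map": name, "n": int(vals.size),
                         "mean": float(vals.mean()), "sd": float(vals.std()),
                         "median": float(np.median(vals)), "flag": ""})
    return pd.DataFrame(rows, columns=["roi", "map", "n", "mean", "sd",
                                       "median", "flag"])


def validate_roi_template(
    template: VolumeGrid,
    area_range_mm2: tuple[float, float] = (10.0, 20.0),
    volume_range_mm3: tuple[float, float] = (40.0, 55.0),
    min_circularity: float = 0.6,
) -> pd.DataFrame:
    """Check an ROI label template against the protocol's geometry.

    Each ROI should be a single-slice circular region of about 15 mm^2
    in-plane area and 45-50 mm^3 volume.  ROIs outside the tolerated area
    or volume band, spanning several slices, or insufficiently circular
    (isoperimetric circularity 4*pi*A/P^2 below ``min_circularity``) are
    flagged.
    """
    lab = np.asarray(template.data)
    if not np.issubdtype(lab.dtype, np.integer):
        lab = np.round(lab).astype(np.int32)
    dx, dy, dz = template.spacing
    rows = []
    for roi in np.unique(lab):
        if roi == 0:
            continue
        sel = lab == roi
        coords = np.argwhere(sel)
        slices = np.unique(coords[:, 2])
        n_vox = int(sel.sum())
        area = max(np.sum(coords[:, 2] == z) for z in slices) * dx * dy
        volume = n_vox * dx * dy * dz
        flags = []
        if not (area_range_mm2[0] <= area <= area_range_mm2[1]):
            flags.append(f"in-plane area {area:.1f} mm^2 outside "
                         f"{area_range_mm2}")
        if not (volume_range_mm3[0] <= volume <= volume_range_mm3[1]):
            flags.append(f"volume {volume:.1f} mm^3 outside {volume_range_mm3}")
        if len(slices) > 1:
            flags.append(f"spans {len(slices)} slices")
        else:
            z = slices[0]
            sl = sel[:, :, z].astype(np.uint8)
            props = measure.regionprops(measure.label(sl))
            if props:
                p = max(props, key=lambda r: r.area)
                if p.perimeter > 0:
                    circ = 4 * np.pi * p.area / p.perimeter ** 2
                    if circ < min_circularity:
                        flags.append(f"circularity {circ:.2f} < {min_circularity}")
                elif p.area <= 2:
                    flags.append("degenerate (<= 2 voxels)")
        rows.append({"roi": int(roi), "n_voxels": n_vox,
                     "area_mm2": float(area), "volume_mm3": float(volume),
                     "n_slices": int(len(slices)),
                     "pass": not flags, "flags": "; ".join(flags)})
    return pd.DataFrame(rows, columns=["roi", "n_voxels", "area_mm2",
                                       "volume_mm3", "n_slices", "pass",
                                       "flags"])
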