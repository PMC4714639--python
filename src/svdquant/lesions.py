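"""Stroke lesion delineation and cavity/lacune detection.

Stroke lesions and tissue loss are delineated on FLAIR by thresholding
combined with region growing, optionally guided by a DWI image whose
suprathreshold regions provide the seeds.  Cavities are circular or ovoid
FLAIR hypointensities at CSF-like intensity, more than 3 mm in maximum
in-plane diameter and adjacent to (or inside) a stroke-lesion
hyperintensity; the 3-7 mm round subset is counted as lacunes.

Because slice spacing (typically 6 mm) dwarfs the 3-7 mm objects of
interest, all diameters are measured in-plane (maximum Feret diameter per
slice, maximized over slices).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .errors import ParameterError, ValidationError
from .volumes import BinaryMask, VolumeGrid

__all__ = [
    "LESION_CATEGORIES",
    "LesionLabel",
    "CavityReport",
    "region_grow",
    "delineate_lesion",
    "detect_cavities",
    "count_lacunes",
]

LESION_CATEGORIES = frozenset({
    "index_stroke", "old_stroke", "new_ischemic", "new_hemorrhagic",
    "tissue_loss", "cavity_index", "cavity_old", "cavity_new",
})

_CONNECTIVITY = {6: 1, 18: 2, 26: 3}


@dataclass
class LesionLabel:
    """One delineated lesion: category, mask and analyst annotations."""

    category: str
    mask: BinaryMask
    annotations: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.category not in LESION_CATEGORIES:
            raise ValidationError(
                f"unknown lesion category {self.category!r}; "
                f"choose from {sorted(LESION_CATEGORIES)}"
            )


@dataclass
class CavityReport:
    """Connected-component table of candidate cavities.

    ``table`` columns: component, category, n_voxels, volume_ml,
    max_diameter_mm (in-plane Feret), equivalent_diameter_mm, axis_ratio
    (in-plane minor/major), adjacent_to_lesion, mean_intensity, counted,
    annotation.  ``labels`` is the component label volume.
    """

    table: pd.DataFrame
    labels: VolumeGrid

    @property
    def count(self) -> int:
        return int(self.table["counted"].sum()) if len(self.table) else 0


# ---------------------------------------------------------------------------
# Region growing
# ---------------------------------------------------------------------------

def region_grow(
    image: VolumeGrid,
    seeds: list[tuple[int, int, int]],
    low: float,
    high: float,
    connectivity: int = 26,
) -> BinaryMask:
    """Maximal connected set containing the seeds with intensity in [low, high]."""
    if low > high:
        raise ParameterError(f"low {low} > high {high}")
    if connectivity not in _CONNECTIVITY:
        raise ParameterError("connectivity must be 6, 18 or 26")
    data = np.asarray(image.data, dtype=float)
    grid = image.grid_ref()
    for s in seeds:
        if not all(0 <= s[d] < data.shape[d] for d in range(3)):
            raise ParameterError(f"seed {s} outside the image")
    band = (data >= low) & (data <= high)
    struct = ndimage.generate_binary_structure(3, _CONNECTIVITY[connectivity])
    lab, _ = ndimage.label(band, structure=struct)
    wanted = {int(lab[tuple(s)]) for s in seeds} - {0}
    if not wanted:
        warnings.warn("no seed lies inside the intensity band; empty result",
                      stacklevel=2)
        return BinaryMask(np.zeros(data.shape, bool), grid)
    return BinaryMask(np.isin(lab, sorted(wanted)), grid)


def _component_diameter_mm(coords: np.ndarray, spacing) -> float:
    """Maximum in-plane Feret diameter (mm), maximized over slices."""
    best = 0.0
    for z in np.unique(coords[:, 2]):
        pts = coords[coords[:, 2] == z][:, :2].astype(float)
        pts = pts * np.asarray(spacing[:2])
        if len(pts) == 1:
            # a single voxel spans one voxel width
            best = max(best, float(max(spacing[:2])))
            continue
        # account for voxel extent: corners of each voxel footprint
        dx, dy = spacing[0] / 2.0, spacing[1] / 2.0
        corners = np.concatenate([pts + [sx, sy]
                                  for sx in (-dx, dx) for sy in (-dy, dy)])
        d = np.sqrt(((corners[:, None, :] - corners[None, :, :]) ** 2).sum(-1))
        best = max(best, float(d.max()))
    return best


def _component_axis_ratio(coords: np.ndarray) -> float:
    """In-plane minor/major axis ratio on the largest-area slice."""
    zs, counts = np.unique(coords[:, 2], return_counts=True)
    z = zs[np.argmax(counts)]
    pts = coords[coords[:, 2] == z][:, :2]
    sl = np.zeros(pts.max(axis=0) - pts.min(axis=0) + 3, dtype=np.uint8)
    sl[tuple((pts - pts.min(axis=0) + 1).T)] = 1
    props = measure.regionprops(sl)[0]
    if props.axis_major_length <= 0:
        return 1.0
    if props.axis_minor_length <= 0:
        # 1-voxel-thick lines digitize to zero minor axis
        return 1.0 if len(pts) == 1 else 0.0
    return float(props.axis_minor_length / props.axis_major_length)


# ---------------------------------------------------------------------------
# Lesion delineation
# ---------------------------------------------------------------------------

def delineate_lesion(
    flair: VolumeGrid,
    guide: VolumeGrid | None,
    category: str,
    low: float,
    high: float = np.inf,
    seeds: list[tuple[int, int, int]] | None = None,
    guide_threshold: float | None = None,
    fill_hole_diam_mm: float = 2.5,
    connectivity: int = 26,
) -> LesionLabel:
    """Delineate a stroke lesion on FLAIR by guided region growing.

    For the index stroke at baseline, ``guide`` is the DWI volume and seeds
    are derived from its suprathreshold regions (``guide_threshold``);
    otherwise explicit ``seeds`` are supplied.  Isointense interior holes up
    to ``fill_hole_diam_mm`` in diameter (necrotic or isointense cores of
    1-2 mm) are filled into the lesion.
    """
    if guide is None and not seeds:
        raise ParameterError("either a guide image or explicit seeds are required")
    annotations: list[str] = []
    seed_list = list(seeds) if seeds else []
    if guide is not None:
        thr = guide_threshold
        if thr is None:
            gd = guide.data[np.isfinite(guide.data)]
            thr = float(np.percentile(gd, 99.5))
        supra = np.argwhere(np.asarray(guide.data) >= thr)
        if len(supra) == 0:
            annotations.append("no suprathreshold region in guide image")
            return LesionLabel(category,
                               BinaryMask(np.zeros(flair.shape, bool),
                                          flair.grid_ref()),
                               annotations)
        seed_list.extend(map(tuple, supra))
    grown = region_grow(flair, seed_list, low, high, connectivity)
    if grown.is_empty():
        annotations.append("seeds outside the FLAIR intensity band")
        return LesionLabel(category, grown, annotations)

    # fill small interior isointense holes, slice-wise; hole size is judged
    # by in-plane equivalent diameter (area-based), the natural scale for
    # the 1-2 mm isointense cores
    filled = np.zeros_like(grown.data)
    for k in range(grown.data.shape[2]):
        filled[:, :, k] = ndimage.binary_fill_holes(grown.data[:, :, k])
    holes = filled & ~grown.data
    if holes.any():
        lab, n = ndimage.label(holes)
        keep = np.zeros_like(grown.data)
        px_area = flair.spacing[0] * flair.spacing[1]
        for comp in range(1, n + 1):
            coords = np.argwhere(lab == comp)
            area = max(np.sum(coords[:, 2] == z) for z in np.unique(coords[:, 2]))
            eq_diam = 2.0 * np.sqrt(area * px_area / np.pi)
            if eq_diam <= fill_hole_diam_mm:
                keep |= lab == comp
        grown = BinaryMask(grown.data | keep, grown.grid)
    return LesionLabel(category, grown, annotations)


# ---------------------------------------------------------------------------
# Cavities and lacunes
# ---------------------------------------------------------------------------

def detect_cavities(
    flair: VolumeGrid,
    lesion_masks: list[LesionLabel],
    csf_stats: tuple[float, float],
    min_diam_mm: float = 3.0,
    csf_band_sd: float = 2.0,
    search_mask: BinaryMask | None = None,
    baseline: bool = True,
    baseline_cavities: BinaryMask | None = None,
) -> CavityReport:
    """Detect CSF-intensity cavities related to stroke lesions.

    Candidate components are FLAIR voxels within ``csf_band_sd`` SDs of the
    CSF mean.  A component is *counted* when its maximum in-plane diameter
    exceeds ``min_diam_mm`` and it touches (26-connected, after one-voxel
    dilation) a stroke-lesion hyperintensity, inheriting the parent lesion's
    cavity category.  Undersized or off-intensity components are annotated,
    not counted.  Non-adjacent components are disregarded at baseline; at
    follow-up, components absent from ``baseline_cavities`` are labeled
    ``cavity_new`` and counted even without an adjacent lesion.
    """
    if csf_stats is None:
        raise ParameterError("csf_stats (mean, sd) are required")
    mu, sd = csf_stats
    grid = flair.grid_ref()
    data = np.asarray(flair.data, float)
    band = np.abs(data - mu) <= csf_band_sd * sd
    if search_mask is not None:
        band &= search_mask.data
    for lesion in lesion_masks:
        band &= ~lesion.mask.data
    struct = ndimage.generate_binary_structure(3, 3)
    lab, n = ndimage.label(band, structure=struct)
    cavity_cat = {"index_stroke": "cavity_index", "old_stroke": "cavity_old",
                  "new_ischemic": "cavity_new", "new_hemorrhagic": "cavity_new"}
    dilated = []
    for lesion in lesion_masks:
        dilated.append((cavity_cat.get(lesion.category, "cavity_old"),
                        ndimage.binary_dilation(lesion.mask.data, structure=struct)))
    rows = []
    vox_ml = grid.voxel_volume_mm3 / 1000.0
    for comp in range(1, n + 1):
        sel = lab == comp
        coords = np.argwhere(sel)
        diam = _component_diameter_mm(coords, grid.spacing)
        area_vox = max(np.sum(coords[:, 2] == z) for z in np.unique(coords[:, 2]))
        eq_diam = 2.0 * np.sqrt(area_vox * grid.spacing[0] * grid.spacing[1] / np.pi)
        ratio = _component_axis_ratio(coords)
        parent = next((cat for cat, dil in dilated if (sel & dil).any()), None)
        adjacent = parent is not None
        category, counted, note = parent or "", False, ""
        if not adjacent:
            if baseline:
                note = "not related to a stroke lesion at baseline; disregarded"
            else:
                is_new = (baseline_cavities is None
                          or not (sel & baseline_cavities.data).any())
                if is_new:
                    category = "cavity_new"
                    adjacent = False
                else:
                    note = "present at baseline but unrelated to a lesion"
        if diam <= min_diam_mm:
            note = f"diameter {diam:.1f} mm <= {min_diam_mm} mm; annotated only"
        elif category:
            counted = True
        rows.append({
            "component": comp, "category": category,
            "n_voxels": int(sel.sum()), "volume_ml": float(sel.sum() * vox_ml),
            "max_diameter_mm": diam, "equivalent_diameter_mm": float(eq_diam),
            "axis_ratio": ratio, "adjacent_to_lesion": adjacent,
            "mean_intensity": float(data[sel].mean()),
            "counted": counted, "annotation": note,
        })
    table = pd.DataFrame(rows, columns=[
        "component", "category", "n_voxels", "volume_ml", "max_diameter_mm",
        "equivalent_diameter_mm", "axis_ratio", "adjacent_to_lesion",
        "mean_intensity", "counted", "annotation"])
    labels = VolumeGrid(lab.astype(np.int32), affine=grid.affine,
                        spacing=grid.spacing, modality_tag="cavity-labels")
    return CavityReport(table=table, labels=labels)


def count_lacunes(
    report: CavityReport,
    diam_range_mm: tuple[float, float] = (3.0, 7.0),
    min_axis_ratio: float = 0.5,
) -> int:
    """Count counted cavities in the lacune band (3-7 mm, round/ovoid shape)."""
    if len(report.table) == 0:
        return 0
    t = report.table
    lo, hi = diam_range_mm
    sel = (t["counted"]
           & (t["max_diameter_mm"] >= lo) & (t["max_diameter_mm"] <= hi)
           & (t["axis_ratio"] >= min_axis_ratio))
    return int(sel.sum())
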