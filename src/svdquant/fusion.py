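"""Multispectral color-fusion segmentation.

Two or three coregistered structural sequences are normalized, assigned to
red/green(/blue) channels, and the resulting color image inside the
intracranial cavity is partitioned by minimum-variance quantization — a
deterministic recursive box split in color space.  Tissue classes are then
read off the quantized palette with simple color rules: e.g. white matter
hyperintensities appear *yellow* when FLAIR is mapped to green and the
T2*-weighted gradient echo to red (bright on FLAIR, mid-bright on T2*W),
while CSF and other "non-brain" contents appear dark on FLAIR.

The quantizer splits, at every step, the color box with the greatest total
within-box squared deviation, along its highest-variance channel, at the cut
that minimizes the summed within-box squared deviation of the two halves.
It is fully deterministic: identical input yields identical labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import (
    ConfigurationError,
    DegenerateContrastError,
    InclusionError,
    SegmentationError,
)
from .volumes import BinaryMask, VolumeGrid, combine_masks

__all__ = [
    "FusedColorVolume",
    "QuantizationResult",
    "ClusterRule",
    "DEFAULT_RULES",
    "segment_icv",
    "normalize_channel",
    "fuse_channels",
    "quantize_min_variance",
    "assign_clusters",
    "derive_tissue_masks",
]

CHANNEL_ROLES = ("red", "green", "blue")


@dataclass
class FusedColorVolume:
    """2-3 normalized channels with color roles, restricted to a domain mask.

    Channel values must lie in [0, 1] inside ``domain_mask`` and all
    channels must share the domain's grid.
    """

    channels: dict[str, VolumeGrid]
    domain_mask: BinaryMask

    def __post_init__(self) -> None:
        if not 2 <= len(self.channels) <= 3:
            raise ConfigurationError("fusion needs 2 or 3 channels")
        for role, vol in self.channels.items():
            if role not in CHANNEL_ROLES:
                raise ConfigurationError(f"unknown channel role {role!r}")
            if not vol.grid_ref().matches(self.domain_mask.grid):
                raise ConfigurationError(f"channel {role!r} is not on the domain grid")
            inside = vol.data[self.domain_mask.data]
            if inside.size and (np.nanmin(inside) < -1e-9 or np.nanmax(inside) > 1 + 1e-9):
                raise ConfigurationError(
                    f"channel {role!r} not normalized to [0,1] inside the domain"
                )

    @property
    def roles(self) -> tuple[str, ...]:
        return tuple(r for r in CHANNEL_ROLES if r in self.channels)

    def color_array(self) -> np.ndarray:
        """(n_domain_voxels, n_channels) color matrix in role order."""
        dom = self.domain_mask.data
        return np.column_stack([self.channels[r].data[dom] for r in self.roles])


@dataclass
class QuantizationResult:
    """Labels (0 = outside domain, 1..n_levels inside) plus the palette."""

    labels: VolumeGrid
    palette: np.ndarray          # (n_levels, n_channels) mean color per label
    n_levels: int
    roles: tuple[str, ...]

    def label_mask(self, labels, grid=None) -> BinaryMask:
        """Binary mask of the union of the given label ids."""
        wanted = np.isin(self.labels.data, np.atleast_1d(labels))
        return BinaryMask(wanted, self.labels.grid_ref())


@dataclass
class ClusterRule:
    """Palette color predicate naming a tissue class.

    ``bounds`` maps a channel role to an inclusive (lo, hi) interval the
    palette color must fall in.  Rules in a list are priority-ordered:
    earlier rules claim clusters first.
    """

    name: str
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def matches(self, color: np.ndarray, roles: tuple[str, ...]) -> bool:
        for role, (lo, hi) in self.bounds.items():
            if role not in roles:
                raise ConfigurationError(
                    f"rule {self.name!r} references channel {role!r} absent "
                    f"from the fusion ({roles})"
                )
            v = color[roles.index(role)]
            if not (lo <= v <= hi):
                return False
        return True


# Default color rules for the protocol's fusion pairs.  Thresholds are
# calibration parameters (no canonical printed values exist); override per
# study via the pipeline config.
DEFAULT_RULES: dict[str, list[ClusterRule]] = {
    # red = T2*W, green = FLAIR: CSF/veins/dura are FLAIR-dark
    "nonbrain": [ClusterRule("nonbrain", {"green": (0.0, 0.35)})],
    # red = T2*W, green = FLAIR: WMH are yellow (both channels high)
    "wmh": [ClusterRule("wmh", {"green": (0.62, 1.0), "red": (0.30, 1.0)})],
    # red = T1W, green = T2W: liquid is T1-dark / T2-bright
    "liquid": [ClusterRule("liquid", {"red": (0.0, 0.35), "green": (0.60, 1.0)})],
    # red = T1W, green = T2W: white matter is T1-bright / T2-mid
    "wm": [ClusterRule("wm", {"red": (0.55, 1.0), "green": (0.0, 0.55)})],
}


# ---------------------------------------------------------------------------
# ICV extraction
# ---------------------------------------------------------------------------

def segment_icv(
    t2star: VolumeGrid,
    threshold_fraction: float = 0.35,
    closing_radius_mm: float = 3.0,
) -> BinaryMask:
    """Extract the intracranial cavity from the T2*W GRE volume.

    The GRE sequence shows relatively uniform intensity across brain tissue
    and CSF against a dark background, so a single robust threshold followed
    by largest-component extraction, morphological closing and slice-wise
    hole filling recovers everything inside the inner skull table.

    Parameters
    ----------
    threshold_fraction : float
        Cut as a fraction of the robust (1st-99th percentile) intensity
        range above the robust minimum.
    closing_radius_mm : float
        Radius of the in-plane closing element, in mm.
    """
    data = np.asarray(t2star.data, dtype=float)
    finite = data[np.isfinite(data)]
    if finite.size == 0 or not np.any(finite > 0):
        raise SegmentationError("volume is empty or all-zero; cannot extract ICV")
    p1, p99 = np.percentile(finite, [1, 99])
    if p99 <= p1:
        raise SegmentationError("no intensity contrast for ICV extraction")
    thresh = p1 + threshold_fraction * (p99 - p1)
    fg = data > thresh
    if not fg.any():
        raise SegmentationError(
            f"threshold {thresh:.3g} (fraction {threshold_fraction}) left no voxels"
        )
    # largest 3D connected component
    lab, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        fg = lab == (1 + int(np.argmax(sizes)))
    # in-plane closing (slice spacing usually exceeds the closing radius)
    rx = max(1, int(round(closing_radius_mm / t2star.spacing[0])))
    ry = max(1, int(round(closing_radius_mm / t2star.spacing[1])))
    yy, xx = np.mgrid[-ry:ry + 1, -rx:rx + 1]
    disk = ((xx / rx) ** 2 + (yy / ry) ** 2) <= 1.0
    selem = disk[:, :, None]
    closed = ndimage.binary_closing(fg, structure=selem, iterations=1)
    closed |= fg
    # slice-wise hole fill
    out = np.zeros_like(closed)
    for k in range(closed.shape[2]):
        out[:, :, k] = ndimage.binary_fill_holes(closed[:, :, k])
    return BinaryMask(out, t2star.grid_ref())


# ---------------------------------------------------------------------------
# Channel normalization and fusion
# ---------------------------------------------------------------------------

def normalize_channel(
    vol: VolumeGrid,
    domain: BinaryMask,
    lo_pct: float = 1.0,
    hi_pct: float = 99.0,
) -> VolumeGrid:
    """Map the [P_lo, P_hi] intensity band inside the domain to [0, 1], clipped.

    Percentile scaling is robust to hot voxels; defaults 1-99.
    """
    if not (0 <= lo_pct < hi_pct <= 100):
        raise ConfigurationError(f"bad percentile band ({lo_pct}, {hi_pct})")
    if domain.is_empty():
        raise DegenerateContrastError("normalization domain is empty")
    inside = np.asarray(vol.data, dtype=float)[domain.data]
    inside = inside[np.isfinite(inside)]
    lo, hi = np.percentile(inside, [lo_pct, hi_pct])
    if hi <= lo:
        raise DegenerateContrastError(
            f"constant image inside domain (P{lo_pct}=P{hi_pct}={lo:.4g})"
        )
    scaled = np.clip((np.asarray(vol.data, dtype=float) - lo) / (hi - lo), 0.0, 1.0)
    return VolumeGrid(scaled, affine=vol.affine, spacing=vol.spacing,
                      modality_tag=vol.modality_tag)


def fuse_channels(
    domain: BinaryMask,
    lo_pct: float = 1.0,
    hi_pct: float = 99.0,
    **channels: VolumeGrid,
) -> FusedColorVolume:
    """Normalize each channel inside the domain and build a FusedColorVolume.

    Channels are passed as keyword arguments by role, e.g.
    ``fuse_channels(icv, red=t2s, green=flair)``.
    """
    norm = {role: normalize_channel(vol, domain, lo_pct, hi_pct)
            for role, vol in channels.items()}
    return FusedColorVolume(norm, domain)


# ---------------------------------------------------------------------------
# Minimum-variance quantization
# ---------------------------------------------------------------------------

def _box_sse(colors: np.ndarray) -> float:
    """Total squared deviation from the mean, summed over channels."""
    if len(colors) < 2:
        return 0.0
    return float(((colors - colors.mean(axis=0)) ** 2).sum())


def _split_box(colors: np.ndarray, idx: np.ndarray):
    """Split one box at the variance-minimizing cut along its widest-variance
    channel.  Returns (left_idx, right_idx) or None if the box cannot split.
    """
    sub = colors[idx]
    var = sub.var(axis=0)
    c = int(np.argmax(var))
    if var[c] <= 0:
        return None
    order = np.argsort(sub[:, c], kind="stable")
    sorted_vals = sub[order]
    n = len(sorted_vals)
    # candidate cuts only where the split-channel value changes, so equal
    # colors stay together and the result is deterministic
    change = np.flatnonzero(np.diff(sorted_vals[:, c]) > 0) + 1
    if change.size == 0:
        return None
    csum = np.cumsum(sorted_vals, axis=0)
    csum2 = np.cumsum(sorted_vals ** 2, axis=0)
    tot, tot2 = csum[-1], csum2[-1]
    k = change  # left part has k elements
    left_sse = (csum2[k - 1] - csum[k - 1] ** 2 / k[:, None]).sum(axis=1)
    nr = (n - k)[:, None]
    right_sse = ((tot2 - csum2[k - 1]) - (tot - csum[k - 1]) ** 2 / nr).sum(axis=1)
    best = int(np.argmin(left_sse + right_sse))
    kbest = int(k[best])
    return idx[order[:kbest]], idx[order[kbest:]]


def quantize_min_variance(fused: FusedColorVolume, n_levels: int = 16) -> QuantizationResult:
    """Partition the domain's colors into ``n_levels`` clusters.

    Recursive box split: at each step the box with the greatest total
    within-box squared deviation is split along its principal-variance
    channel at the cut minimizing the summed within-box squared deviation
    of the two halves.  Deterministic for fixed input.

    If the domain holds fewer distinct colors than ``n_levels`` the result
    has fewer levels and a warning is issued.
    """
    if n_levels < 2:
        raise ConfigurationError("n_levels must be >= 2")
    if fused.domain_mask.is_empty():
        raise ConfigurationError("fusion domain is empty")
    colors = fused.color_array()
    boxes: list[np.ndarray] = [np.arange(len(colors))]
    sses = [_box_sse(colors)]
    while len(boxes) < n_levels:
        j = int(np.argmax(sses))
        if sses[j] <= 0:
            warnings.warn(
                f"only {len(boxes)} distinct color clusters available; "
                f"requested {n_levels} levels",
                stacklevel=2,
            )
            break
        split = _split_box(colors, boxes[j])
        if split is None:
            sses[j] = 0.0
            continue
        left, right = split
        boxes[j] = left
        sses[j] = _box_sse(colors[left])
        boxes.append(right)
        sses.append(_box_sse(colors[right]))

    # order labels by mean luminance for stable, human-readable palettes
    means = np.array([colors[b].mean(axis=0) for b in boxes])
    order = np.argsort(means.sum(axis=1), kind="stable")
    label_flat = np.zeros(len(colors), dtype=np.int32)
    palette = np.empty_like(means)
    for new, old in enumerate(order):
        label_flat[boxes[old]] = new + 1
        palette[new] = means[old]

    label_vol = np.zeros(fused.domain_mask.grid.shape, dtype=np.int32)
    label_vol[fused.domain_mask.data] = label_flat
    labels = VolumeGrid(label_vol,
                        affine=fused.domain_mask.grid.affine,
                        spacing=fused.domain_mask.grid.spacing,
                        modality_tag="quantization-labels")
    return QuantizationResult(labels=labels, palette=palette,
                              n_levels=len(boxes), roles=fused.roles)


def assign_clusters(
    q: QuantizationResult,
    rules: list[ClusterRule],
    strict: bool = False,
) -> tuple[dict[str, BinaryMask], list[int]]:
    """Map quantization clusters to named tissue masks by palette color.

    Rules are priority-ordered: the first rule matching a cluster's palette
    color claims it.  With ``strict=True`` a cluster matched by more than
    one rule raises :class:`ConfigurationError` instead (rules must then be
    disjoint).  Returns the named masks plus the list of unassigned labels.
    """
    grid = q.labels.grid_ref()
    owner: dict[int, str] = {}
    for label in range(1, q.n_levels + 1):
        color = q.palette[label - 1]
        matched = [r.name for r in rules if r.matches(color, q.roles)]
        if strict and len(set(matched)) > 1:
            raise ConfigurationError(
                f"cluster {label} (color {np.round(color, 3)}) matched by "
                f"multiple rules {matched} with strict disjointness requested"
            )
        if matched:
            owner[label] = matched[0]
    masks: dict[str, BinaryMask] = {}
    for rule in rules:
        wanted = [lb for lb, name in owner.items() if name == rule.name]
        data = np.isin(q.labels.data, wanted) if wanted else np.zeros(grid.shape, bool)
        if rule.name in masks:
            data = masks[rule.name].data | data
        masks[rule.name] = BinaryMask(data, grid)
    unassigned = [lb for lb in range(1, q.n_levels + 1) if lb not in owner]
    return masks, unassigned


# ---------------------------------------------------------------------------
# Tissue bookkeeping
# ---------------------------------------------------------------------------

def derive_tissue_masks(
    icv: BinaryMask, nonbrain: BinaryMask, liquid: BinaryMask
) -> dict[str, BinaryMask]:
    """Derive CSF and brain-tissue masks from the fusion outputs.

    Non-brain contents (CSF + veins + sinuses + dura, FLAIR-dark) are
    subtracted from the ICV to give brain tissue; CSF is the liquid part of
    non-brain, i.e. non-brain minus its non-liquid structures.
    """
    if not combine_masks("subtract", nonbrain, icv).is_empty():
        raise InclusionError("nonbrain mask extends outside the ICV")
    csf = combine_masks("and", nonbrain, liquid)
    brain = combine_masks("subtract", icv, nonbrain)
    return {"csf": csf, "brain_tissue": brain}
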