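"""Seeded multi-contrast head phantom with ground truth.

Generates coregistered synthetic volumes for every sequence the pipeline
consumes — T1W, T2W, FLAIR, T2*W GRE, DWI, the two-flip-angle FSPGR pair,
FA and MD maps — together with ground-truth masks for every feature the
pipeline measures.  The phantom is a forward model of the protocol's
feature definitions: WMH are FLAIR-hyperintense at a prescribed z-level
above normal parenchyma, the pale grade still looks like white matter on
T1W/T2W while the intense grade does not, cavities carry CSF-like
intensity adjacent to a stroke hyperintensity, microbleeds and iron are
T2*-dark (iron iso/hyper on T1W, vessels dark on both), and the FSPGR
pair is synthesized through the true steady-state SPGR signal equation
from a T1 compartment map.

Intensities are class-constant plus noise (Gaussian by default; Rician
available since magnitude MRI noise is Rician) — the pipeline tests
contrast logic, not MR physics; only the FSPGR pair uses the exact
forward model.  Geometry is a set of nested ellipsoids (dura, CSF,
cortex, white matter core) with spherical deep gray structures, on an
anisotropic grid mimicking a 2D axial protocol (~0.94 mm in-plane, 6 mm
slice spacing).  Identical seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError
from .qmaps import VFAParams, spgr_signal
from .volumes import AffineTransform, BinaryMask, GridRef, VolumeGrid

__all__ = ["PhantomSpec", "PhantomResult", "generate_phantom"]

MODALITIES = ("t1w", "t2w", "flair", "t2s", "dwi", "fspgr2", "fspgr12",
              "fa", "md")

# class-mean intensity table per modality (arbitrary units; FA unitless,
# MD in 1e-3 mm^2/s, FSPGR synthesized from T1/M0)
DEFAULT_INTENSITIES: dict[str, dict[str, float]] = {
    #              bg   dura  csf  cortex deepgm  wm   less  intense lesion cavity mb  vessel iron
    "t1w":   dict(bg=5, dura=50, csf=30, cortex=120, deepgm=120, wm=150,
                  less=138, intense=60, lesion=80, cavity=30, mb=150,
                  vessel=25, iron=140),
    "t2w":   dict(bg=5, dura=40, csf=200, cortex=100, deepgm=100, wm=90,
                  less=92, intense=160, lesion=140, cavity=200, mb=88,
                  vessel=95, iron=95),
    "flair": dict(bg=5, dura=30, csf=25, cortex=105, deepgm=102, wm=100,
                  less=135, intense=210, lesion=165, cavity=25, mb=100,
                  vessel=40, iron=100),
    "t2s":   dict(bg=5, dura=140, csf=170, cortex=150, deepgm=148, wm=160,
                  less=170, intense=172, lesion=160, cavity=170, mb=30,
                  vessel=30, iron=95),
    "dwi":   dict(bg=5, dura=40, csf=60, cortex=100, deepgm=100, wm=95,
                  less=100, intense=105, lesion=185, cavity=50, mb=95,
                  vessel=90, iron=95),
    "fa":    dict(bg=0, dura=0.1, csf=0.05, cortex=0.20, deepgm=0.22,
                  wm=0.45, less=0.32, intense=0.25, lesion=0.20,
                  cavity=0.07, mb=0.40, vessel=0.15, iron=0.25),
    "md":    dict(bg=0, dura=1.0, csf=3.0, cortex=0.85, deepgm=0.80,
                  wm=0.70, less=0.95, intense=1.10, lesion=1.05,
                  cavity=2.8, mb=0.72, vessel=1.5, iron=0.80),
}

# T1 (ms) and proton density compartments driving the FSPGR pair
DEFAULT_T1_MS = dict(bg=1.0, dura=800.0, csf=4000.0, cortex=950.0,
                     deepgm=950.0, wm=600.0, less=1100.0, intense=1300.0,
                     lesion=1300.0, cavity=3500.0, mb=600.0, vessel=1500.0,
                     iron=700.0)
DEFAULT_M0 = dict(bg=0.0, dura=80.0, csf=100.0, cortex=90.0, deepgm=90.0,
                  wm=100.0, less=100.0, intense=100.0, lesion=100.0,
                  cavity=100.0, mb=100.0, vessel=100.0, iron=95.0)

# deep gray structures: name -> (center mm (x, y, z) for the left copy,
# radius mm).  The right copy mirrors x.
DEEP_GM_STRUCTURES = {
    "thalamus": ((-9.0, -8.0, 0.0), 6.5),
    "putamen": ((-22.0, 2.0, 0.0), 7.0),
    "pallidus": ((-14.0, 2.0, 0.0), 5.5),
    "caudate": ((-10.0, 14.0, 0.0), 6.0),
    "hippocampus": ((-24.0, -20.0, -6.0), 5.5),
}


@dataclass
class PhantomSpec:
    """Geometry, contrast and feature layout of the synthetic head.

    Defaults mirror the protocol's acquisition geometry (about 0.94 mm
    in-plane, 6 mm slice spacing from 5 mm slices + 1 mm gap) and a mild
    small-vessel-disease feature load: two-grade WMH of a few mL, one
    subcortical index stroke lesion with four intralesional cavities
    spanning the lacune band, three microbleeds, one vessel-like tube and
    bilateral pallidal iron deposits.
    """

    shape: tuple[int, int, int] = (96, 96, 20)
    spacing: tuple[float, float, float] = (0.9375, 0.9375, 6.0)
    seed: int = 0
    noise_model: str = "gaussian"          # or "rician"
    noise_sd_fraction: float = 0.02        # of each modality's intensity range
    intensities: dict[str, dict[str, float]] = field(
        default_factory=lambda: {m: dict(v) for m, v in DEFAULT_INTENSITIES.items()})
    t1_ms: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_T1_MS))
    m0: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_M0))
    vfa: VFAParams = field(default_factory=VFAParams)
    # head ellipsoid semi-axes (mm) and normalized shell radii
    head_semiaxes_mm: tuple[float, float, float] = (42.0, 44.0, 55.0)
    dura_inner: float = 0.96
    csf_inner: float = 0.90
    cortex_inner: float = 0.80
    # features
    include_wmh: bool = True
    include_lesion: bool = True
    cavity_diameters_mm: tuple[float, ...] = (2.0, 4.0, 5.0, 9.0)
    microbleed_centers_mm: tuple[tuple[float, float, float], ...] = (
        (-20.0, -14.0, -3.0), (20.0, -14.0, -3.0), (14.0, 18.0, -9.0))
    microbleed_radius_mm: float = 4.0
    include_vessel: bool = True
    iron_depth_sigma: float = 6.0
    iron_radius_mm: float = 3.0

    def __post_init__(self) -> None:
        if self.noise_model not in ("gaussian", "rician"):
            raise ValidationError(f"unknown noise model {self.noise_model!r}")
        if self.noise_sd_fraction < 0:
            raise ValidationError("noise_sd_fraction must be >= 0")


@dataclass
class PhantomResult:
    """Volumes, ground-truth masks, probability maps and transforms."""

    volumes: dict[str, VolumeGrid]
    truth: dict[str, BinaryMask]
    probmaps: dict[str, VolumeGrid]
    transforms: dict[str, AffineTransform]
    grid: GridRef
    spec: PhantomSpec

    @property
    def csf_stats(self) -> tuple[float, float]:
        """(mean, sd) of FLAIR over the true CSF mask."""
        vals = self.volumes["flair"].data[self.truth["csf"].data]
        return float(vals.mean()), float(vals.std())


def _world_coords(grid: GridRef) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    idx = np.indices(grid.shape, dtype=float)
    aff = np.asarray(grid.affine)
    x = aff[0, 0] * idx[0] + aff[0, 3]
    y = aff[1, 1] * idx[1] + aff[1, 3]
    z = aff[2, 2] * idx[2] + aff[2, 3]
    return x, y, z


def _ellipsoid(x, y, z, center, semi) -> np.ndarray:
    cx, cy, cz = center
    a, b, c = semi
    return (((x - cx) / a) ** 2 + ((y - cy) / b) ** 2
            + ((z - cz) / c) ** 2) <= 1.0


def _sphere(x, y, z, center, radius) -> np.ndarray:
    if radius <= 0:
        return np.zeros(x.shape, bool)
    return _ellipsoid(x, y, z, center, (radius, radius, radius))


def generate_phantom(spec: PhantomSpec | None = None) -> PhantomResult:
    """Build the phantom described by ``spec`` (deterministic per seed)."""
    spec = spec or PhantomSpec()
    shape = tuple(spec.shape)
    spacing = tuple(spec.spacing)
    affine = np.diag(list(spacing) + [1.0])
    affine[:3, 3] = -(np.asarray(shape) - 1) * np.asarray(spacing) / 2.0
    grid = GridRef(shape=shape, spacing=spacing, affine=affine)
    x, y, z = _world_coords(grid)
    a, b, c = spec.head_semiaxes_mm
    rnorm = np.sqrt((x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2)

    icv = rnorm <= 1.0
    dura = icv & (rnorm > spec.dura_inner)
    csf = icv & (rnorm > spec.csf_inner) & ~dura
    brain = icv & ~dura & ~csf
    cortex = brain & (rnorm > spec.cortex_inner)
    core = brain & ~cortex

    deep_gm = np.zeros(shape, bool)
    structures: dict[str, np.ndarray] = {}
    for name, (center, radius) in DEEP_GM_STRUCTURES.items():
        for side, sgn in (("l", 1.0), ("r", -1.0)):
            cx, cy, cz = center
            m = _sphere(x, y, z, (sgn * cx, cy, cz), radius) & core
            structures[f"{name}_{side}"] = m
            deep_gm |= m
    wm_anat = core & ~deep_gm

    # --- feature geometry (all carved to the anatomical WM compartment) ---
    def _carve(mask: np.ndarray, what: str) -> np.ndarray:
        m = mask & wm_anat
        if not m.any():
            raise ValidationError(f"feature {what!r} lies outside the brain "
                                  "white matter compartment")
        return m

    less = np.zeros(shape, bool)
    intense = np.zeros(shape, bool)
    if spec.include_wmh:
        # pale-only blob (left frontal) and a lesion complex with an intense
        # core inside a pale halo (right frontal / periventricular)
        less_blob = _ellipsoid(x, y, z, (-18.0, 27.0, 3.0), (7.0, 7.0, 5.0))
        halo = _ellipsoid(x, y, z, (12.0, 20.0, 0.0), (10.0, 9.0, 6.0))
        rim = _ellipsoid(x, y, z, (0.0, -24.0, -6.0), (8.0, 6.0, 4.0))
        core_int = _ellipsoid(x, y, z, (12.0, 20.0, 0.0), (5.0, 4.5, 3.5))
        less = _carve((less_blob | halo | rim) & ~core_int, "wmh")
        intense = _carve(core_int, "intense wmh")

    lesion = np.zeros(shape, bool)
    cavities: list[np.ndarray] = []
    cavity_all = np.zeros(shape, bool)
    if spec.include_lesion:
        lesion_blob = _ellipsoid(x, y, z, (-6.0, -18.0, 3.0), (14.0, 10.0, 5.0))
        lesion = _carve(lesion_blob, "index stroke lesion") & ~less & ~intense
        cavity_centers = ((3.0, -18.0, 3.0), (-2.0, -12.0, 3.0),
                          (-2.0, -24.0, 3.0), (-14.0, -18.0, 3.0))
        for diam, center in zip(spec.cavity_diameters_mm, cavity_centers):
            cav = _sphere(x, y, z, center, diam / 2.0) & lesion
            if not cav.any():
                raise ValidationError(
                    f"cavity of diameter {diam} mm fell outside the lesion")
            cavities.append(cav)
            cavity_all |= cav
        lesion &= ~cavity_all

    microbleeds = np.zeros(shape, bool)
    for center in spec.microbleed_centers_mm:
        mb = _carve(_sphere(x, y, z, center, spec.microbleed_radius_mm),
                    f"microbleed at {center}")
        microbleeds |= mb & ~less & ~intense & ~lesion & ~cavity_all

    vessel = np.zeros(shape, bool)
    if spec.include_vessel:
        # in-plane tube: radius 1.5 mm, running ~26 mm along y
        vessel = ((np.abs(x + 30.0) <= 1.5) & (np.abs(y) <= 13.0)
                  & (np.abs(z - 3.0) <= 1.0))
        vessel = _carve(vessel, "vessel") & ~microbleeds

    iron = np.zeros(shape, bool)
    for sname in ("pallidus_l", "pallidus_r"):
        center, _ = DEEP_GM_STRUCTURES["pallidus"]
        sgn = 1.0 if sname.endswith("_l") else -1.0
        # centered on a slice so the blob survives the 6 mm slice spacing
        blob = _sphere(x, y, z, (sgn * center[0], center[1], -3.0),
                       spec.iron_radius_mm) & structures[sname]
        iron |= blob

    wm_plain = wm_anat & ~(less | intense | lesion | cavity_all
                           | microbleeds | vessel)
    deep_gm_plain = deep_gm & ~iron

    # --- paint intensities --------------------------------------------------
    class_masks = [
        ("bg", ~icv), ("dura", dura), ("csf", csf), ("cortex", cortex),
        ("deepgm", deep_gm_plain), ("wm", wm_plain), ("less", less),
        ("intense", intense), ("lesion", lesion), ("cavity", cavity_all),
        ("mb", microbleeds), ("vessel", vessel), ("iron", iron),
    ]
    rng = np.random.default_rng(spec.seed)
    volumes: dict[str, VolumeGrid] = {}

    def _add_noise(img: np.ndarray, sd: float) -> np.ndarray:
        if sd <= 0:
            return img
        if spec.noise_model == "gaussian":
            return img + rng.normal(0.0, sd, img.shape)
        re = img + rng.normal(0.0, sd, img.shape)
        im = rng.normal(0.0, sd, img.shape)
        return np.sqrt(re ** 2 + im ** 2)

    for modality in ("t1w", "t2w", "flair", "t2s", "dwi", "fa", "md"):
        table = spec.intensities[modality]
        img = np.zeros(shape, float)
        for cls, mask in class_masks:
            img[mask] = table[cls]
        if modality == "t2s" and iron.any():
            # iron depth is expressed in units of the noise SD below the
            # structure mean (with a floor so zero-noise phantoms keep contrast)
            rng_range = max(table.values()) - min(table.values())
            sd = spec.noise_sd_fraction * rng_range
            depth = max(spec.iron_depth_sigma * sd, 10.0)
            img[iron] = table["deepgm"] - depth
        rng_range = max(table.values()) - min(table.values())
        img = _add_noise(img, spec.noise_sd_fraction * rng_range)
        volumes[modality] = VolumeGrid(img, affine=affine, spacing=spacing,
                                       modality_tag=modality)

    # FSPGR pair through the true SPGR forward model
    t1_map = np.full(shape, 1.0)
    m0_map = np.zeros(shape)
    for cls, mask in class_masks:
        t1_map[mask] = spec.t1_ms[cls]
        m0_map[mask] = spec.m0[cls]
    for name, alpha in (("fspgr2", spec.vfa.alpha1), ("fspgr12", spec.vfa.alpha2)):
        sig = spgr_signal(m0_map, t1_map, spec.vfa, alpha)
        sd = spec.noise_sd_fraction * (sig.max() - sig.min())
        volumes[name] = VolumeGrid(_add_noise(sig, sd), affine=affine,
                                   spacing=spacing, modality_tag=name)
    volumes["t1_true"] = VolumeGrid(np.where(icv, t1_map, np.nan),
                                    affine=affine, spacing=spacing,
                                    modality_tag="T1 truth (ms)")

    # --- truth masks ---------------------------------------------------------
    def _bm(m: np.ndarray) -> BinaryMask:
        return BinaryMask(m, grid)

    # veins count as non-brain intracranial content alongside CSF and dura
    nonbrain = dura | csf | vessel
    wmh = less | intense
    wm_gross = wm_plain | less | microbleeds     # the T1W/T2W "white matter" class
    truth = {
        "icv": _bm(icv), "dura": _bm(dura), "csf": _bm(csf),
        "nonbrain": _bm(nonbrain), "brain_tissue": _bm(brain & ~vessel),
        "cortex_gm": _bm(cortex), "deep_gm": _bm(deep_gm),
        "wm_gross": _bm(wm_gross), "nawm": _bm(wm_gross & ~wmh),
        "wmh": _bm(wmh), "wmh_less_intense": _bm(less),
        "wmh_intense": _bm(intense),
        "index_stroke": _bm(lesion), "cavities": _bm(cavity_all),
        "microbleeds": _bm(microbleeds), "vessel": _bm(vessel),
        "iron": _bm(iron),
        # everything the global T2* hypointensity threshold should find
        # within brain tissue (the vein is non-brain and never reaches it)
        "t2s_hypo_global": _bm(microbleeds),
    }
    for i, cav in enumerate(cavities):
        truth[f"cavity_{i}"] = _bm(cav)
    for name, m in structures.items():
        truth[f"struct_{name}"] = _bm(m)

    # probabilistic subcortical maps: eroding structures get p = 1 solid
    # blobs; the thalami get concentric probability levels
    probmaps: dict[str, VolumeGrid] = {}
    for name, m in structures.items():
        if name.startswith("thalamus"):
            center, radius = DEEP_GM_STRUCTURES["thalamus"]
            sgn = 1.0 if name.endswith("_l") else -1.0
            cx = (sgn * center[0], center[1], center[2])
            p = np.zeros(shape)
            p[_sphere(x, y, z, cx, radius) & core] = 0.2
            p[_sphere(x, y, z, cx, radius * 0.75) & core] = 0.6
            p[_sphere(x, y, z, cx, radius * 0.5) & core] = 1.0
        else:
            p = m.astype(float)
        probmaps[name] = VolumeGrid(p, affine=affine, spacing=spacing,
                                    modality_tag=f"probmap-{name}")

    # world-to-world transforms: identity native chain plus a two-step
    # follow-up chain and a native -> standard affine (the typical ~1.36x
    # per-dimension template inflation)
    rot = np.deg2rad(2.0)
    fu_to_t2w = np.eye(4)
    fu_to_t2w[:2, :2] = [[np.cos(rot), -np.sin(rot)], [np.sin(rot), np.cos(rot)]]
    fu_to_t2w[:3, 3] = [1.5, -1.0, 0.5]
    t2w_to_base = np.eye(4)
    t2w_to_base[:3, 3] = [-0.8, 0.6, -0.2]
    std = np.diag([1.36, 1.36, 1.36, 1.0])
    transforms = {
        "identity": AffineTransform.identity(),
        "followup_to_t2w": AffineTransform(fu_to_t2w),
        "t2w_to_baseline": AffineTransform(t2w_to_base),
        "to_standard": AffineTransform(std),
    }
    return PhantomResult(volumes=volumes, truth=truth, probmaps=probmaps,
                         transforms=transforms, grid=grid, spec=spec)
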