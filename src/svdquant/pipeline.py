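"""Per-subject workflow orchestration.

Runs the stages of the protocol in their documented order — ICV extraction,
color-fusion tissue segmentation, WMH partition and grading, stroke lesion
and cavity delineation, iron/microbleed detection, T1 mapping, ROI
statistics — with a YAML config, per-stage caching keyed on input hashes,
and a JSON provenance log.

The ICV is segmented once at baseline and reused for follow-up sessions.
All randomness lives in the phantom generator; the pipeline itself is
deterministic.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fusion, iron, lesions, qmaps, wmh
from .errors import ConfigurationError, SvdQuantError
from .fusion import ClusterRule, DEFAULT_RULES
from .phantom import PhantomSpec, generate_phantom
from .volumes import (
    BinaryMask,
    read_mask,
    read_volume,
    write_mask,
    write_volume,
)

__all__ = ["SubjectPipeline", "run_subject", "write_phantom_subject",
           "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "n_levels": 16,
    "normalize_percentiles": [1.0, 99.0],
    "icv": {"threshold_fraction": 0.35, "closing_radius_mm": 3.0},
    "rules": {},              # optional per-class [channel][lo, hi] overrides
    "cluster_overrides": {},  # optional per-class explicit cluster id lists
    "wmh": {"z_lo": 5.0, "intense_factor": 1.5},
    "rings": {"ring_width_vox": 2, "max_dist_mm": 10.0},
    "lesion": {"z_low": 10.0, "guide_z": 8.0},
    "cavities": {"min_diam_mm": 3.0, "lacune_band_mm": [3.0, 7.0]},
    "iron": {"fence_k": 1.5, "var_bound": 2.5, "threshold_fraction": 0.45,
             "size_range_vox": [5, 400]},
    "microbleeds": {"sphericity_min": 0.7, "max_diam_mm": 10.0},
    "stats": {"csf_dilate_vox": 1},
    "dice_floors": {"icv": 0.95, "nonbrain": 0.95, "brain_tissue": 0.95,
                    "csf": 0.90, "wm": 0.90, "wmh": 0.90,
                    "index_stroke": 0.90, "iron_subcortical": 0.80,
                    "iron_global": 0.80},
}

_MODALITY_FILES = {
    "t1w": "t1w.nii.gz", "t2w": "t2w.nii.gz", "flair": "flair.nii.gz",
    "t2s": "t2s.nii.gz", "dwi": "dwi.nii.gz", "fspgr2": "fspgr2.nii.gz",
    "fspgr12": "fspgr12.nii.gz", "fa": "fa.nii.gz", "md": "md.nii.gz",
}

# stage -> modalities it cannot run without
_STAGE_NEEDS = {
    "segment": ("t2s", "flair", "t1w", "t2w"),
    "wmh": ("flair", "t2s"),
    "lesions": ("flair", "dwi"),
    "iron": ("t2s", "t1w"),
    "t1map": ("fspgr2", "fspgr12"),
}


def _hash_arrays(*arrays, params=None) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    if params is not None:
        h.update(json.dumps(params, sort_keys=True, default=str).encode())
    return h.hexdigest()[:16]


def _merge(base: dict, override: dict) -> dict:
    out = {k: dict(v) if isinstance(v, dict) else v for k, v in base.items()}
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def _rules_for(name: str, config: dict) -> list[ClusterRule]:
    override = config.get("rules", {}).get(name)
    if override:
        return [ClusterRule(name, {ch: tuple(b) for ch, b in override.items()})]
    return DEFAULT_RULES[name]


def _robust_mean_sd(values: np.ndarray) -> tuple[float, float]:
    """Sigma-clipped (3 SD, two passes) mean and SD of a sample."""
    vals = np.asarray(values, float)
    vals = vals[np.isfinite(vals)]
    mu, sd = float(vals.mean()), float(vals.std())
    for _ in range(2):
        kept = vals[np.abs(vals - mu) <= 3 * sd]
        if kept.size < 2 or kept.size == vals.size:
            break
        vals = kept
        mu, sd = float(vals.mean()), float(vals.std())
    return mu, sd


def _dice(a: BinaryMask, b: BinaryMask) -> float:
    s = a.n_voxels + b.n_voxels
    return 2.0 * int((a.data & b.data).sum()) / s if s else 1.0


@dataclass
class SubjectPipeline:
    """Stage-by-stage execution for one subject directory.

    The directory holds the coregistered modalities as NIfTI files (see the
    ``phantom`` command for the layout); outputs and the provenance log go
    to ``<subject_dir>/derived``.
    """

    subject_dir: Path
    config: dict = field(default_factory=dict)
    baseline_icv: Path | None = None     # reuse the baseline ICV at follow-up

    def __post_init__(self) -> None:
        self.subject_dir = Path(self.subject_dir)
        self.config = _merge(DEFAULT_CONFIG, self.config)
        self.out_dir = self.subject_dir / "derived"
        self.out_dir.mkdir(exist_ok=True)
        self._provenance_path = self.out_dir / "provenance.json"
        self._provenance = (json.loads(self._provenance_path.read_text())
                            if self._provenance_path.exists() else {})
        self.volumes = {}
        for modality, fname in _MODALITY_FILES.items():
            path = self.subject_dir / fname
            if path.exists():
                self.volumes[modality] = read_volume(path, modality_tag=modality)
        if not self.volumes:
            raise ConfigurationError(f"no modality images in {self.subject_dir}")
        self.masks: dict[str, BinaryMask] = {}
        self.cache_hits: list[str] = []

    # -- infrastructure -----------------------------------------------------

    def _require(self, stage: str) -> None:
        missing = [m for m in _STAGE_NEEDS.get(stage, ())
                   if m not in self.volumes]
        if missing:
            raise ConfigurationError(
                f"stage {stage!r} blocked: missing modalities {missing}")

    def _stage_cached(self, stage: str, inputs, params, outputs: list[str]) -> bool:
        """True (and loads outputs) when the stage's inputs are unchanged."""
        key = _hash_arrays(*inputs, params=params)
        rec = self._provenance.get(stage)
        paths = [self.out_dir / f"{name}.nii.gz" for name in outputs]
        if rec and rec.get("hash") == key and all(p.exists() for p in paths):
            for name, p in zip(outputs, paths):
                self.masks[name] = read_mask(p)
            self.cache_hits.append(stage)
            return True
        self._provenance[stage] = {"hash": key, "params": params,
                                   "outputs": outputs}
        return False

    def _store(self, **named_masks: BinaryMask) -> None:
        for name, mask in named_masks.items():
            self.masks[name] = mask
            write_mask(mask, self.out_dir / f"{name}.nii.gz")

    def _flush_provenance(self) -> None:
        self._provenance_path.write_text(
            json.dumps(self._provenance, indent=2, default=str))

    # -- stages -------------------------------------------------------------

    def stage_segment(self) -> None:
        """ICV + fusion tissue segmentation (non-brain, CSF, brain, WM)."""
        self._require("segment")
        cfg = self.config
        lo, hi = cfg["normalize_percentiles"]
        inputs = [self.volumes[m].data for m in ("t2s", "flair", "t1w", "t2w")]
        params = {"icv": cfg["icv"], "n_levels": cfg["n_levels"],
                  "pct": [lo, hi], "rules": cfg["rules"],
                  "baseline_icv": str(self.baseline_icv)}
        outputs = ["icv", "nonbrain", "csf", "brain_tissue", "wm"]
        if self._stage_cached("segment", inputs, params, outputs):
            return
        if self.baseline_icv is not None:
            icv = read_mask(self.baseline_icv, reference=None)
        else:
            icv = fusion.segment_icv(self.volumes["t2s"], **cfg["icv"])
        nb_fused = fusion.fuse_channels(icv, lo, hi, red=self.volumes["t2s"],
                                        green=self.volumes["flair"])
        q_nb = fusion.quantize_min_variance(nb_fused, cfg["n_levels"])
        nb_masks, _ = fusion.assign_clusters(q_nb, _rules_for("nonbrain", cfg))
        nonbrain = nb_masks["nonbrain"]
        liq_fused = fusion.fuse_channels(icv, lo, hi, red=self.volumes["t1w"],
                                         green=self.volumes["t2w"])
        q_liq = fusion.quantize_min_variance(liq_fused, cfg["n_levels"])
        liq_masks, _ = fusion.assign_clusters(q_liq, _rules_for("liquid", cfg))
        tissues = fusion.derive_tissue_masks(icv, nonbrain, liq_masks["liquid"])
        brain = tissues["brain_tissue"]
        wm_fused = fusion.fuse_channels(brain, lo, hi, red=self.volumes["t1w"],
                                        green=self.volumes["t2w"])
        q_wm = fusion.quantize_min_variance(wm_fused, cfg["n_levels"])
        wm_masks, _ = fusion.assign_clusters(q_wm, _rules_for("wm", cfg))
        wm_mask = wm_masks["wm"]
        probmaps = self._load_probmaps()
        if probmaps:
            wm_mask = wmh.correct_wm_mask(wm_mask, probmaps)
        self._store(icv=icv, nonbrain=nonbrain, csf=tissues["csf"],
                    brain_tissue=brain, wm=wm_mask)

    def _load_probmaps(self):
        pm_dir = self.subject_dir / "probmaps"
        if not pm_dir.is_dir():
            return {}
        return {p.name.split(".")[0]: read_volume(p)
                for p in sorted(pm_dir.glob("*.nii.gz"))}

    def stage_lesions(self) -> list[lesions.LesionLabel]:
        """Index-stroke delineation on FLAIR guided by DWI."""
        self._require("lesions")
        cfg = self.config["lesion"]
        flair, dwi = self.volumes["flair"], self.volumes["dwi"]
        brain = self.masks["brain_tissue"]
        # thresholds sit well above the parenchyma distribution so the
        # grown region cannot percolate through suprathreshold noise
        # voxels and no noise voxel can become a seed
        mu, sd = _robust_mean_sd(flair.data[brain.data])
        mu_d, sd_d = _robust_mean_sd(dwi.data[brain.data])
        les = lesions.delineate_lesion(
            flair, dwi, "index_stroke", low=mu + cfg["z_low"] * sd,
            guide_threshold=mu_d + cfg["guide_z"] * sd_d)
        self._store(index_stroke=les.mask)
        return [les]

    def stage_wmh(self, lesion_masks: list[lesions.LesionLabel]) -> wmh.WMHPartition:
        """FLAIR-hyperintensity extraction, lesion removal, grade partition,
        NAWM and distance rings."""
        self._require("wmh")
        cfg = self.config
        lo, hi = cfg["normalize_percentiles"]
        brain = self.masks["brain_tissue"]
        fused = fusion.fuse_channels(brain, lo, hi, red=self.volumes["t2s"],
                                     green=self.volumes["flair"])
        q = fusion.quantize_min_variance(fused, cfg["n_levels"])
        hyper_masks, _ = fusion.assign_clusters(q, _rules_for("wmh", cfg))
        wmh_mask = hyper_masks["wmh"]
        for les in lesion_masks:
            wmh_mask = wmh_mask - les.mask
        part = wmh.partition_wmh(wmh_mask, self.masks["wm"])
        ring_map = wmh.contour_rings(part.wmh, part.nawm, **cfg["rings"])
        write_volume(ring_map.labels, self.out_dir / "wmh_rings.nii.gz",
                     dtype=np.int16)
        self._store(wmh=part.wmh, wmh_intense=part.intense,
                    wmh_less_intense=part.less_intense, nawm=part.nawm)
        self._ring_map = ring_map
        return part

    def stage_iron(self, lesion_masks) -> None:
        """Subcortical + global iron, artifact filtering, microbleed tally."""
        self._require("iron")
        cfg = self.config["iron"]
        probmaps = self._load_probmaps()
        structures = {name: BinaryMask(p.data > 0, p.grid_ref())
                      for name, p in probmaps.items()}
        grid = self.masks["brain_tissue"].grid
        if structures:
            seg = iron.detect_iron_subcortical(
                self.volumes["t2s"], self.volumes["t1w"], structures,
                fence_k=cfg["fence_k"])
            seg = iron.filter_artifacts(seg, self.volumes["t2s"],
                                        var_bound=cfg["var_bound"])
            seg.components.to_csv(self.out_dir / "iron_components.csv",
                                  index=False)
            self._store(iron_subcortical=seg.global_mask)
            deep_gm = BinaryMask(
                np.logical_or.reduce([s.data for s in structures.values()]),
                grid)
        else:
            deep_gm = BinaryMask(np.zeros(grid.shape, bool), grid)
            self._store(iron_subcortical=deep_gm)
        exclusions = deep_gm
        for les in lesion_masks:
            exclusions = exclusions | les.mask
        glob = iron.detect_iron_global(
            self.volumes["t2s"], self.masks["nawm"],
            tuple(cfg["size_range_vox"]), self.masks["brain_tissue"],
            exclusions=exclusions,
            threshold_fraction=cfg["threshold_fraction"])
        self._store(iron_global=glob,
                    iron=self.masks["iron_subcortical"] | glob)
        mb_cfg = self.config["microbleeds"]
        finds, tally = iron.count_microbleeds(
            glob, sphericity_min=mb_cfg["sphericity_min"],
            max_diam_mm=mb_cfg["max_diam_mm"])
        pd.DataFrame([{
            "component": f.component, "x_mm": f.center_mm[0],
            "y_mm": f.center_mm[1], "z_mm": f.center_mm[2],
            "equivalent_diameter_mm": f.equivalent_diameter_mm,
            "sphericity": f.sphericity, "region": f.region,
            "hemisphere": f.hemisphere} for f in finds]).to_csv(
                self.out_dir / "microbleeds.csv", index=False)
        tally.to_csv(self.out_dir / "microbleed_tally.csv")
        self.microbleed_findings = finds

    def stage_cavities(self, lesion_masks) -> lesions.CavityReport:
        csf_vals = self.volumes["flair"].data[self.masks["csf"].data]
        cfg = self.config["cavities"]
        report = lesions.detect_cavities(
            self.volumes["flair"], lesion_masks,
            (float(csf_vals.mean()), float(csf_vals.std())),
            min_diam_mm=cfg["min_diam_mm"], search_mask=self.masks["icv"])
        report.table.to_csv(self.out_dir / "cavities.csv", index=False)
        self.lacune_count = lesions.count_lacunes(
            report, tuple(cfg["lacune_band_mm"]))
        return report

    def stage_t1map(self):
        self._require("t1map")
        t1 = qmaps.t1_from_vfa(self.volumes["fspgr2"], self.volumes["fspgr12"],
                               mask=self.masks.get("icv"))
        write_volume(t1, self.out_dir / "t1_map.nii.gz")
        return t1

    def stage_statistics(self, t1_map) -> pd.DataFrame:
        """FA / MD / T1 statistics per tissue mask with CSF-rim exclusion."""
        stat_masks = {k: self.masks[k] for k in
                      ("nawm", "wmh_intense", "wmh_less_intense", "wmh")
                      if k in self.masks}
        frames = []
        dil = self.config["stats"]["csf_dilate_vox"]
        for name in ("fa", "md"):
            if name in self.volumes:
                frames.append(qmaps.map_statistics(
                    self.volumes[name], stat_masks, self.masks.get("csf"),
                    csf_dilate_vox=dil, map_name=name.upper()))
        if t1_map is not None:
            frames.append(qmaps.map_statistics(
                t1_map, stat_masks, self.masks.get("csf"),
                csf_dilate_vox=dil, map_name="T1"))
        stats = (pd.concat(frames, ignore_index=True) if frames
                 else pd.DataFrame())
        stats.to_csv(self.out_dir / "roi_stats.csv", index=False)
        return stats

    # -- reporting ----------------------------------------------------------

    def volume_report(self) -> pd.DataFrame:
        icv_ml = self.masks["icv"].volume_ml
        rows = []
        for name, mask in self.masks.items():
            rows.append({"class": name, "voxels": mask.n_voxels,
                         "volume_ml": round(mask.volume_ml, 3),
                         "pct_icv": round(100 * mask.volume_ml / icv_ml, 2)
                         if icv_ml else np.nan})
        report = pd.DataFrame(rows)
        report.to_csv(self.out_dir / "volumes.csv", index=False)
        return report

    def check_conservation(self) -> dict[str, float]:
        """Accounting identities, in voxels: brain + non-brain = ICV and
        intense + less-intense = WMH."""
        out = {}
        m = self.masks
        out["icv_minus_brain_minus_nonbrain"] = float(
            m["icv"].n_voxels - m["brain_tissue"].n_voxels
            - m["nonbrain"].n_voxels)
        if "wmh" in m:
            out["wmh_minus_grades"] = float(
                m["wmh"].n_voxels - m["wmh_intense"].n_voxels
                - m["wmh_less_intense"].n_voxels)
        return out

    def dice_vs_truth(self) -> pd.DataFrame:
        """Compare derived masks with any truth masks shipped alongside."""
        truth_dir = self.subject_dir / "truth"
        rows = []
        if truth_dir.is_dir():
            mapping = {"icv": "icv", "nonbrain": "nonbrain", "csf": "csf",
                       "brain_tissue": "brain_tissue", "wm": "wm_gross",
                       "wmh": "wmh", "index_stroke": "index_stroke",
                       "iron_subcortical": "iron",
                       "iron_global": "t2s_hypo_global"}
            floors = self.config["dice_floors"]
            for ours, theirs in mapping.items():
                tpath = truth_dir / f"{theirs}.nii.gz"
                if ours in self.masks and tpath.exists():
                    d = _dice(self.masks[ours], read_mask(tpath))
                    rows.append({"mask": ours, "dice": round(d, 4),
                                 "floor": floors.get(ours, np.nan),
                                 "pass": d >= floors.get(ours, 0.0)})
        report = pd.DataFrame(rows, columns=["mask", "dice", "floor", "pass"])
        report.to_csv(self.out_dir / "dice_vs_truth.csv", index=False)
        return report

    # -- full run -----------------------------------------------------------

    def run(self) -> dict:
        self.stage_segment()
        lesion_masks = (self.stage_lesions()
                        if "dwi" in self.volumes else [])
        self.stage_wmh(lesion_masks)
        cavity_report = self.stage_cavities(lesion_masks)
        self.stage_iron(lesion_masks)
        t1_map = (self.stage_t1map()
                  if "fspgr2" in self.volumes and "fspgr12" in self.volumes
                  else None)
        stats = self.stage_statistics(t1_map)
        volumes = self.volume_report()
        conservation = self.check_conservation()
        dice = self.dice_vs_truth()
        self._flush_provenance()
        summary = {
            "volumes": volumes, "conservation": conservation,
            "dice_vs_truth": dice, "cavity_count": cavity_report.count,
            "lacune_count": self.lacune_count,
            "microbleed_count": len(getattr(self, "microbleed_findings", [])),
            "stats": stats, "cache_hits": list(self.cache_hits),
        }
        with open(self.out_dir / "summary.json", "w") as fh:
            json.dump({k: v for k, v in summary.items()
                       if not isinstance(v, pd.DataFrame)}, fh, indent=2)
        return summary


def run_subject(config_path, subject_dir) -> dict:
    """Execute the full per-subject workflow (see :class:`SubjectPipeline`)."""
    config = {}
    if config_path is not None:
        with open(config_path) as fh:
            config = yaml.safe_load(fh) or {}
    return SubjectPipeline(Path(subject_dir), config).run()


def write_phantom_subject(subject_dir, spec: PhantomSpec | None = None) -> None:
    """Materialize a synthetic subject directory (images + truth masks)."""
    subject_dir = Path(subject_dir)
    subject_dir.mkdir(parents=True, exist_ok=True)
    ph = generate_phantom(spec)
    for modality, fname in _MODALITY_FILES.items():
        write_volume(ph.volumes[modality], subject_dir / fname)
    truth_dir = subject_dir / "truth"
    truth_dir.mkdir(exist_ok=True)
    for name, mask in ph.truth.items():
        write_mask(mask, truth_dir / f"{name}.nii.gz")
    pm_dir = subject_dir / "probmaps"
    pm_dir.mkdir(exist_ok=True)
    for name, pmap in ph.probmaps.items():
        write_volume(pmap, pm_dir / f"{name}.nii.gz")
    tf_dir = subject_dir / "transforms"
    tf_dir.mkdir(exist_ok=True)
    for name, tf in ph.transforms.items():
        tf.to_file(tf_dir / f"{name}.mat")
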