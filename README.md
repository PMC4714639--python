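# svdquant

Quantitative MRI assessment of cerebral small vessel disease (SVD).

Cerebral SVD shows on brain MRI as white matter hyperintensities (WMH),
lacunes, cerebral microbleeds, enlarged perivascular spaces, small
subcortical infarcts, mineral deposition and atrophy. Research studies need
all of these quantified consistently, per subject and per timepoint, from a
multi-sequence structural protocol (T1W, T2W, FLAIR, T2\*W gradient echo,
DWI-derived FA/MD maps, and a two-flip-angle FSPGR pair). `svdquant`
implements that quantification as a tested Python library with a thin
command-line front end, aimed at imaging scientists who analyse SVD and
stroke cohorts.

## What it computes

* **Tissue volumes by multispectral color fusion.** Two or three
  coregistered sequences are normalized to [0, 1], assigned to red/green/
  blue channels, and the color image inside the intracranial cavity is
  partitioned by deterministic **minimum-variance quantization** (recursive
  box split in color space). Tissue classes are read off the quantized
  palette: non-brain contents (CSF, veins, dura) are FLAIR-dark in the
  T2\*W/FLAIR fusion; WMH appear *yellow* (FLAIR mapped to green, T2\*W to
  red); white matter and liquid come from the T1W/T2W fusion. Brain tissue
  = ICV − non-brain; CSF = the liquid part of non-brain.
* **Two-grade WMH analysis.** Intense WMH (bright on FLAIR *and* T2W,
  outside the white matter class) vs less-intense WMH (pale halo, still
  classed as WM): `less = WMH ∧ WM`, `intense = WMH ∧ ¬WM`,
  `NAWM = WM ∧ ¬WMH`. An independent intensity-based grading uses the
  normal-parenchyma FLAIR statistics (less-intense ≳ 5 SD above the mean;
  intense ≥ 1.5× the less-intense mean). Concentric Chebyshev distance
  rings (2 voxels ≈ 1.88 mm wide, out to ~10 mm) profile NAWM integrity as
  a function of distance from the WMH.
* **Stroke lesions and cavities.** Threshold + region growing on FLAIR,
  seeded from the suprathreshold DWI regions for the index stroke; small
  isointense cores (1–2 mm) are filled. Cavities are CSF-intensity
  components > 3 mm maximum in-plane diameter adjacent to a stroke
  hyperintensity; the round 3–7 mm subset is counted as **lacunes**.
* **Iron and microbleeds on T2\*W.** Per-structure bivariate outlier
  fences (T2\* < Q1 − 1.5 IQR while T1W is *not* below its own lower
  fence — vessels are dark on both) plus artifact filtering by
  standardized-variance and T1W appearance; a global threshold below half
  the NAWM median elsewhere. Microbleeds are components with mesh
  **sphericity ψ = π^⅓(6V)^⅔ / A > 0.7** and diameter ≤ 10 mm, tallied per
  region × hemisphere.
* **Variable-flip-angle T1 mapping.** From the SPGR pair (TR = 8.2 ms,
  α = 2°/12°): with SR = S₁/S₂,
  `E = (SR·sin α₂ − sin α₁) / (SR·sin α₂·cos α₁ − sin α₁·cos α₂)` and
  `T1 = −TR / ln E`; nonphysical voxels become missing, never zero. ROI
  statistics of FA/MD/T1 subtract a one-voxel-dilated CSF mask first.
* **Spatial probability maps.** Masks mapped to a template grid by affine
  transforms and averaged voxelwise. The affine inflates volumes by |det|
  (≈ 2.5× for a typical 1.36×-per-dimension template fit), so the maps are
  for relative spatial distribution only — volumes are always native.
* **Visual rating capture.** Validated records for Fazekas (0–3 + 0–3),
  Wahlund, Potter EPVS, atrophy, basal-ganglia iron, BOMBS counts and
  Prins change scores, plus Spearman correlation, linear calibration and
  Bland–Altman agreement statistics.
* **Synthetic phantom.** A seeded multi-contrast head phantom with ground
  truth for every feature (the FSPGR pair synthesized through the true
  SPGR equation) replaces patient data in all tests.

## Worked example

```bash
svdquant phantom subject01 --seed 1 --noise 0.02   # synthetic subject + truth
svdquant run subject01                             # full workflow
```

prints (abridged):

```
"cavity_count": 3, "lacune_count": 2, "microbleed_count": 3
        class  voxels  volume_ml  pct_icv
          icv   80840    426.305   100.00
     nonbrain   22215    117.149    27.48
 brain_tissue   58625    309.155    72.52
          wmh     626      3.301     0.77
  wmh_intense      56      0.295     0.07
         mask   dice  floor  pass
          icv 1.0000   0.95  True
          wmh 1.0000   0.90  True
 index_stroke 1.0000   0.90  True
```

The volume table reports every derived mask in mL and as % of ICV (the
conservation identity brain + non-brain = ICV holds to the voxel); the
Dice table compares each stage against the phantom's ground truth. Of the
four implanted cavities (2/4/5/9 mm), three exceed the 3 mm rule and two
fall in the 3–7 mm lacune band; the three implanted microbleeds are
counted while the vessel-like tube fails the sphericity test. The
`examples/` directory holds one narrative script per capability
(`python examples/01_tissue_segmentation.py`, ...).

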