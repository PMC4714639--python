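# Methods

This note records the models, parameter choices and numerical decisions
behind `svdquant`, and what the synthetic test bed does and does not show.

## Geometry and containers

All volumes are 3D scalar arrays with a voxel spacing and a 4×4
voxel-to-world affine. NIfTI-1 input is reoriented to the closest RAS
convention at load; Analyze 7.5 carries no orientation and is assumed
axial (with a warning). Physical volume always comes from header spacing —
on the emulated 2D protocol a 5 mm slice with a 1 mm gap contributes
dz = 6 mm per voxel, and no through-plane interpolation is ever performed
implicitly. Masks resample with nearest-neighbour by default (preserves
binarity); trilinear interpolation with an unbiased 0.5 cut is used for
standard-space mapping, where nearest-neighbour aliases few-voxel lesions.
Transforms are world-to-world 4×4 matrices stored as plain text; the
registration *estimation* is out of scope — the package only applies given
transforms, including the two-step follow-up chain (follow-up → same-visit
T2W, then T2W → baseline), which composes by matrix product.

## Minimum-variance color quantization

The fusion segmenter normalizes each channel to [0, 1] by mapping the 1st
and 99th intensity percentiles inside the domain (robust to hot voxels),
then partitions the 2–3-channel color vectors of the domain voxels into
`n_levels` clusters (default 16 — few enough that clusters stay at tissue
scale) by a deterministic recursive box split: at each step the box with
the greatest total within-box squared deviation is split along its
highest-variance channel, at the cut that minimizes the summed squared
deviation of the two halves (computed in one pass from prefix sums;
candidate cuts only where the sort key changes, so equal colors never
separate and the result is reproducible bit-for-bit). Fewer distinct
colors than levels reduce the level count with a warning.

Cluster → tissue assignment is rule-based: each rule is a per-channel
interval on the palette (cluster-mean) color, and rules in a list claim
clusters in priority order. The default thresholds (non-brain: green ≤
0.35 of the T2\*W/FLAIR fusion; WMH: green ≥ 0.62 ∧ red ≥ 0.30; liquid:
red ≤ 0.35 ∧ green ≥ 0.60 of T1W/T2W; WM: red ≥ 0.55 ∧ green ≤ 0.55) are
**calibration parameters**: no canonical numbers exist for the analyst's
interactive cluster picking that they replace, so they were fixed once
against the phantom's contrast design and are exposed in the pipeline
config (including explicit per-case cluster lists as the escape hatch).

ICV extraction thresholds the T2\*W GRE volume (relatively uniform over
brain and CSF against dark background) at 0.35 of the robust 1–99%
intensity range, keeps the largest 3D component, closes in-plane with a
3 mm radius disk (slice spacing exceeds any useful 3D closing radius) and
fills holes slice-wise.

## WMH grades, NAWM and rings

The coincidence partition is exact set algebra and is asserted after every
run: `less = WMH ∧ WM`, `intense = WMH ∧ ¬WM`, `NAWM = WM ∧ ¬WMH`. Before
the partition the WM mask is corrected for subcortical gray structures:
putamen/pallidus/caudate probability maps are binarized at p > 0 and
eroded once with the 6-connected 3D diamond element; the thalami keep only
their maximum observed probability level (the "highest probability" rule
is configurable because the alternative reading — p = 1 exactly — differs
on maps that never reach 1); hippocampus and other boundary-corrected
maps are used as given.

The intensity-based grading computes the normal-parenchyma FLAIR mean and
SD over brain ∧ ¬WMH ∧ ¬lesions with two passes of 3-SD sigma-clipping
(residual CSF-like voxels — cavities, flow voids — otherwise inflate the
SD and shift the 5-SD cut). Less-intense WMH are WMH voxels with z ≥ 5;
the upper end of the descriptive "5–6 SD" band is treated as a
characterization, not a ceiling, so the default band is open above.
Intense WMH are defined relative to the *mean of the less-intense voxels*
(≥ 1.5×), which is circular; the implementation seeds a fixed point from
the 25th percentile of the supra-threshold FLAIR values (the pale halo
always dominates that quartile) and iterates to convergence — a one-shot
mean over all supra-threshold voxels misclassifies whenever the intense
core exceeds roughly 15% of the WMH.

Rings are built by iterated in-plane dilation with a square (Chebyshev)
element of half-width 2 voxels — in-plane because 6 mm slice spacing
dwarfs the ~1.88 mm ring width, Chebyshev because the construction is
defined in voxel steps; a disk element and 3D dilation are options. Ring k
therefore holds the voxels at Chebyshev distance ((k−1)·w, k·w] from the
WMH, intersected with NAWM; the ring count is ⌊max_dist / (w·dx)⌋, giving
the protocol's five ~2 mm rings up to ~10 mm.

## Focal lesions, cavities, lacunes

Region growing keeps the connected components (26-connected by default,
mirroring permissive manual outlining) of the intensity band that contain
a seed. In the pipeline the FLAIR band's lower bound sits at
mean + 10 SD of the sigma-clipped parenchyma distribution and DWI seeds at
mean + 8 SD: both thresholds must clear the extreme order statistics of
~10⁵ parenchyma voxels, otherwise isolated suprathreshold noise voxels
seed or percolate the growth. Interior isointense holes are filled when
their in-plane *equivalent* (area-based) diameter is ≤ 2.5 mm — the
natural scale for the 1–2 mm cores, and robust to the corner effects that
inflate Feret diameters of 2-voxel holes.

Cavity candidates are components within ±2 SD of the CSF FLAIR mean
("similar or equal to CSF" carries no printed number; 2 SD is the
configurable default). A component is counted when its maximum in-plane
Feret diameter (per-slice, corner-to-corner of the voxel footprints,
maximized over slices — through-plane diameters are meaningless at 6 mm
spacing) exceeds 3 mm *and* it touches a stroke-lesion hyperintensity
(26-connected contact after one-voxel dilation). Undersized or
off-intensity components are annotated, not counted; non-adjacent
components are disregarded at baseline and labeled new at follow-up.
Lacunes are the counted cavities with diameter in [3, 7] mm and in-plane
minor/major axis ratio ≥ 0.5.

## Iron and microbleeds

Subcortical detection applies Tukey fences per structure: flag voxels with
T2\* below Q1 − 1.5·IQR whose T1W is *not* below the T1W lower fence
(vessels and CSF are dark on both). This is a pluggable strategy — the
contract is structure-adaptive and bivariate. Artifact filtering removes
components whose within-component variance of the structure-standardized
T2\* exceeds 2.5 (smooth susceptibility gradients produce elongated
high-variance streaks; a compact deposit's standardized variance is near
the noise floor of ~1) or whose T1W class is hypointense. The 2.5 bound
has no canonical value; it was calibrated on phantom fixtures and is
declared non-normative. The fences assume the structure is mostly normal
tissue: when an implant occupies ~20% of a small structure the fence
shifts and sensitivity drops — visible in the full phantom's pallidi,
where recovery is ~0.89 Dice versus ≥ 0.95 in a clean structure.

Global detection thresholds at 0.45 × median NAWM T2\* (the fraction must
stay below 0.5 by contract) inside brain minus exclusion zones, keeping
components within a configured voxel-size range.

Sphericity uses volume from voxel counting and surface area from a
marching-cubes isosurface at level 0.5 of the lightly smoothed (σ = 0.5
voxel) indicator, after resampling anisotropic components to isotropy —
voxel-face counting overestimates area and biases ψ below threshold for
genuine spheres, while heavier smoothing shrinks small objects and pushes
ψ above 1. Digital spheres of radius 3–8 voxels measure within 5% of 1.
Components touching the volume boundary (no closed surface) and
components whose measured ψ exceeds 1.05 (below mesh resolution — the
shape cannot be assessed) are excluded from the count with a warning.
Microbleeds: ψ > 0.7 and equivalent diameter ≤ 10 mm (the conventional
microbleed/macrohemorrhage divide; larger irregular hypointensities are
hemorrhagic lesions), tallied per region × hemisphere, hemisphere from the
world x sign (RAS).

## T1 mapping

Forward model: S(α) = M0·sin α·(1 − E)/(1 − E·cos α), E = exp(−TR/T1).
Two-point inversion from SR = S₁/S₂ as in the README. The closed form is
anchored to the forward model by an exact round trip (≤ 10⁻⁶ relative
error over 200–5000 ms) and against an independent Bloch steady-state
iteration; published typesettings of this inversion are prone to sign
typos, so the round trip, not any printed formula, is the correctness
reference. Voxels with E outside (0, 1) (noise, background, zero S₂)
carry NaN and are excluded from all statistics — zero-filling would bias
tissue means. An optional B1 map scales both flip angles multiplicatively
(identity by default). Under Rician noise at SNR 50 the median recovered
T1 at 1000 ms is biased by < 2%.

ROI statistics subtract the CSF mask dilated by one voxel in each
direction before averaging, the standard guard against partial-volume
contamination at tissue/CSF borders. The ROI template validator expects
single-slice, near-circular ROIs of 10–20 mm² in-plane area and 40–55 mm³
volume — consistent on the ~3.2 mm-slice quantitative-map grid the
template is drawn on (15 mm² × 3.2 mm ≈ 48 mm³), not on the 6 mm
structural grid.

## Standard space

`to_standard` records native and standard-space volumes side by side and
the report schema never substitutes one for the other; `volume_distortion`
returns |det| of the linear part and its cube root. A 1.36×-per-dimension
affine yields 2.515× volumetric inflation, and the measured volume ratio
of a resampled sphere reproduces |det| within 3%. Composition fidelity of
the two-step registration chain holds to Dice ≥ 0.99 under adequate
sampling (voxels small relative to the object); on the native 6 mm-slice
grid two successive resamplings genuinely alias a small mask, which is why
the pipeline composes matrices before resampling wherever possible.

## The phantom: what it shows and what it does not

The phantom is nested ellipsoids (dura, CSF, cortex, WM core) with
spherical deep-gray structures on a 96×96×20 grid at 0.9375×0.9375×6 mm —
the emulated protocol geometry. Intensities are class-constant plus noise
(Gaussian default; Rician available as magnitude-MRI noise), at 2% of each
modality's intensity range by default; only the FSPGR pair goes through
the true SPGR equation. Feature load: a pale-only WMH blob, a halo+core
WMH complex and a pale rim (total ≈ 3.3 mL, ~0.8% of ICV), one
DWI-bright subcortical index lesion with four intralesional CSF-intensity
cavities of 2/4/5/9 mm, three 4 mm microbleeds, one in-plane vein-like
tube (counted as non-brain, as veins are), and bilateral pallidal iron at
−6 noise-SD on T2\* with iso/hyperintense T1W. All feature geometry is
carved to the white matter compartment, and truth masks satisfy the
partition and grade invariants by construction.

Passing on the phantom demonstrates the *contrast logic and rule
arithmetic* — class separability at realistic noise, exact set identities,
correct counting rules, exact T1 inversion. It does **not** demonstrate
robustness to partial volume effects, bias fields, registration error,
anatomical variability or pathology that violates the class-constant
assumption; the color-rule defaults in particular would need recalibration
per scanner and protocol, exactly as the interactive step they replace.

## Pipeline

Stage order: ICV (once, at baseline, reused at follow-up) → non-brain /
liquid / WM fusions → lesion delineation → WMH extraction and partition →
cavities → iron/microbleeds → T1 map → ROI statistics → reports. The
segmentation stage (the expensive one) caches on a hash of its input
arrays and parameters and is skipped on unchanged reruns; a JSON
provenance log records stage hashes and outputs. Accounting identities are
checked on every run: brain + non-brain = ICV to one voxel, and
intense + less-intense = WMH exactly. The acceptance script and the test
suite size every simulation (phantom grid, fixture counts, simulation
lengths) so a complete run stays in the tens of seconds on one CPU.
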