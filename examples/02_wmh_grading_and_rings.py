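"""Two-grade WMH quantification and NAWM distance rings.

White matter hyperintensities split into an intense core (bright on FLAIR
and T2W, outside the T1W/T2W white matter class) and a pale, less-intense
halo (still classed as white matter).  Concentric rings at increasing
distance from the WMH profile how the surrounding normal-appearing white
matter changes with proximity to the lesions.
"""

import warnings

from svdquant import PhantomSpec, generate_phantom, contour_rings, partition_wmh
from svdquant.qmaps import map_statistics

warnings.filterwarnings("ignore")

ph = generate_phantom(PhantomSpec(seed=0))
part = partition_wmh(ph.truth["wmh"], ph.truth["wm_gross"])

print("WMH volumes (mL):")
for name, ml in part.volumes_ml().items():
    print(f"  {name:13s}: {ml:8.2f}")
print("intense + less-intense equals total WMH exactly (set identity).")

rings = contour_rings(part.wmh, part.nawm, ring_width_vox=2, max_dist_mm=10.0)
print(f"\n{rings.n_rings} rings of ~{2 * 0.9375:.2f} mm around the WMH;")
ring_masks = {f"ring_{k}": rings.ring_mask(k)
              for k in range(1, rings.n_rings + 1)}
stats = map_statistics(ph.volumes["fa"], ring_masks, csf=ph.truth["csf"],
                       map_name="FA")
print("mean FA per ring (distance from WMH increases down the table):")
for _, row in stats.iterrows():
    print(f"  {row['roi']}: n={row['n']:5d}  FA={row['mean']:.3f}")
print("in patients a gradient here indicates a WMH penumbra in NAWM.")
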