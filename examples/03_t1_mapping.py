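"""Variable-flip-angle T1 mapping from the two-angle SPGR pair.

The phantom synthesizes its FSPGR volumes (2 and 12 degrees, TR 8.2 ms)
through the true steady-state SPGR signal equation, so the closed-form
two-point inversion should recover the tissue T1 values exactly in the
noiseless case.
"""

import numpy as np

from svdquant import PhantomSpec, generate_phantom, t1_from_vfa
from svdquant.qmaps import map_statistics

ph = generate_phantom(PhantomSpec(seed=0, noise_sd_fraction=0.0))
t1_map = t1_from_vfa(ph.volumes["fspgr2"], ph.volumes["fspgr12"],
                     mask=ph.truth["icv"])

masks = {"NAWM": ph.truth["nawm"], "deep GM": ph.truth["deep_gm"],
         "CSF": ph.truth["csf"], "WMH": ph.truth["wmh"]}
stats = map_statistics(t1_map, masks, map_name="T1")
print("recovered T1 (ms) per tissue (noiseless phantom):")
for _, row in stats.iterrows():
    print(f"  {row['roi']:8s}: median {row['median']:7.1f}  "
          f"(n={row['n']})")
truth = ph.volumes["t1_true"].data
err = np.nanmax(np.abs(t1_map.data - truth) / truth)
print(f"max relative error vs the generating T1 map: {err:.2e}")
print("values match the compartments the phantom was built from "
      "(white matter ~600, gray matter ~950, CSF ~4000 ms at 1.5T).")
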