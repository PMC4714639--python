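"""Intracranial and tissue volumes from multispectral color fusion.

Builds a synthetic head, extracts the intracranial cavity from the T2*W
gradient echo, classes non-brain contents (CSF, veins, dura) from the
T2*W/FLAIR color fusion and liquid from the T1W/T2W fusion, and prints the
resulting tissue volumes.
"""

import warnings

from svdquant import (
    PhantomSpec,
    derive_tissue_masks,
    fuse_channels,
    generate_phantom,
    quantize_min_variance,
    segment_icv,
    assign_clusters,
)
from svdquant.fusion import DEFAULT_RULES

warnings.filterwarnings("ignore")

ph = generate_phantom(PhantomSpec(seed=0))
icv = segment_icv(ph.volumes["t2s"])

# non-brain: FLAIR-dark clusters of the red=T2*W / green=FLAIR fusion
fused = fuse_channels(icv, red=ph.volumes["t2s"], green=ph.volumes["flair"])
q = quantize_min_variance(fused, n_levels=16)
nonbrain = assign_clusters(q, DEFAULT_RULES["nonbrain"])[0]["nonbrain"]

# liquid: T1-dark / T2-bright clusters of the T1W/T2W fusion
fused_liq = fuse_channels(icv, red=ph.volumes["t1w"], green=ph.volumes["t2w"])
q_liq = quantize_min_variance(fused_liq, n_levels=16)
liquid = assign_clusters(q_liq, DEFAULT_RULES["liquid"])[0]["liquid"]

tissues = derive_tissue_masks(icv, nonbrain, liquid)

print(f"ICV          : {icv.volume_ml:7.1f} mL")
print(f"non-brain    : {nonbrain.volume_ml:7.1f} mL "
      "(CSF + veins + dura, FLAIR-dark)")
print(f"CSF          : {tissues['csf'].volume_ml:7.1f} mL "
      "(liquid part of non-brain)")
print(f"brain tissue : {tissues['brain_tissue'].volume_ml:7.1f} mL "
      "(ICV minus non-brain)")
print()
print("brain + non-brain should equal the ICV exactly:",
      f"{tissues['brain_tissue'].volume_ml + nonbrain.volume_ml:.1f} mL")
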