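"""Visual rating capture and agreement with computational volumetry.

Ratings are expert inputs; the package validates them against their
published ranges and provides the statistics that link them to measured
volumes: Spearman rank correlation, a linear calibration (on
log-transformed volumes) and Bland-Altman limits of agreement.
"""

import numpy as np

from svdquant import (
    RatingRecord,
    bland_altman,
    fazekas_total,
    linear_calibration,
    rank_correlation,
)

record = RatingRecord("s01", fazekas_periventricular=2, fazekas_deep=3,
                      wahlund={"frontal": 2, "temporal": 1},
                      epvs={"basal_ganglia": 3},
                      atrophy_superficial=3, atrophy_deep=2,
                      basal_ganglia_iron=1,
                      bombs={"deep_wm_left": 1, "basal_ganglia_right": 2})
print(f"subject {record.subject}: Fazekas total = {record.fazekas_total()} "
      f"(0-6 scale), BOMBS total = {record.bombs_total()} microbleeds")

# simulated cohort: WMH volume grows with the total Fazekas score
rng = np.random.default_rng(0)
scores = rng.integers(0, 7, 200)
volumes = np.exp(0.8 + 0.45 * scores + rng.normal(0, 0.3, 200))  # mL

rho, p = rank_correlation(scores, volumes)
print(f"\nSpearman rho between score and WMH volume: {rho:.2f} (p={p:.2g})")

fit = linear_calibration(scores, volumes, log_transform=True)
print(f"log-linear calibration: slope {fit['slope']:.3f} per Fazekas point "
      f"(95% CI {fit['ci95'][0]:.3f}-{fit['ci95'][1]:.3f})")

# agreement between two lacune assessments
computational = rng.poisson(2.0, 50)
visual = computational + rng.integers(-1, 2, 50)
ba = bland_altman(computational, visual)
print(f"Bland-Altman: mean difference {ba['mean_difference']:+.2f} lacunes "
      f"(SD {ba['sd']:.2f}), limits of agreement "
      f"[{ba['lower_loa']:.2f}, {ba['upper_loa']:.2f}]")
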