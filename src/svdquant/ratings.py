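"""Visual rating scales: validated capture and agreement statistics.

Visual ratings are expert human inputs — this module never infers them
from images.  It validates each score against its published range, stores
records, computes derived totals on demand, and provides the agreement
statistics that link ratings to computational volumetry: Spearman rank
correlation, linear calibration (optionally on log-transformed volumes)
and Bland-Altman limits of agreement.

Scales captured per subject-timepoint:

* Fazekas periventricular and deep WMH, each 0-3 (total 0-6);
* Wahlund regional WMH, 0-3 in frontal, parieto-occipital, temporal,
  infratentorial and basal ganglia regions;
* Potter enlarged perivascular space score, 0-4 in midbrain, basal
  ganglia, hippocampi and centrum semiovale;
* superficial and deep atrophy, 1-6 against a normative age template;
* basal ganglia iron/mineral load, 0 (none) to 4 (much);
* BOMBS microbleed counts per region x hemisphere (non-negative);
* Prins WMH change scores at follow-up, stored as signed integers per
  region (the cited scale is not reprinted here; the default accepted
  range is -2..2 and marked provisional).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .errors import ValidationError

__all__ = [
    "RatingRecord",
    "WAHLUND_REGIONS",
    "EPVS_REGIONS",
    "fazekas_total",
    "rank_correlation",
    "linear_calibration",
    "bland_altman",
    "read_rating_records",
    "write_rating_records",
]

WAHLUND_REGIONS = ("frontal", "parieto_occipital", "temporal",
                   "infratentorial", "basal_ganglia")
EPVS_REGIONS = ("midbrain", "basal_ganglia", "hippocampi", "centrum_semiovale")
PRINS_RANGE = (-2, 2)  # provisional


def _check_range(name: str, value, lo: int, hi: int) -> int:
    try:
        v = int(value)
    except (TypeError, ValueError):
        raise ValidationError(f"{name}: {value!r} is not an integer score")
    if not lo <= v <= hi:
        raise ValidationError(f"{name}: {v} outside range [{lo}, {hi}]")
    return v


@dataclass
class RatingRecord:
    """One subject-timepoint's visual scores, range-validated on creation.

    Totals (e.g. the 0-6 Fazekas sum) are derived, never stored.
    """

    subject: str
    timepoint: str = "baseline"
    fazekas_periventricular: int | None = None
    fazekas_deep: int | None = None
    wahlund: dict[str, int] = field(default_factory=dict)
    epvs: dict[str, int] = field(default_factory=dict)
    atrophy_superficial: int | None = None
    atrophy_deep: int | None = None
    basal_ganglia_iron: int | None = None
    bombs: dict[str, int] = field(default_factory=dict)   # "region_hemisphere" -> count
    prins: dict[str, int] = field(default_factory=dict)   # follow-up change scores

    def __post_init__(self) -> None:
        if self.fazekas_periventricular is not None:
            self.fazekas_periventricular = _check_range(
                "fazekas_periventricular", self.fazekas_periventricular, 0, 3)
        if self.fazekas_deep is not None:
            self.fazekas_deep = _check_range("fazekas_deep", self.fazekas_deep, 0, 3)
        for region, score in self.wahlund.items():
            if region not in WAHLUND_REGIONS:
                raise ValidationError(f"unknown Wahlund region {region!r}")
            self.wahlund[region] = _check_range(f"wahlund[{region}]", score, 0, 3)
        for region, score in self.epvs.items():
            if region not in EPVS_REGIONS:
                raise ValidationError(f"unknown EPVS region {region!r}")
            self.epvs[region] = _check_range(f"epvs[{region}]", score, 0, 4)
        if self.atrophy_superficial is not None:
            self.atrophy_superficial = _check_range(
                "atrophy_superficial", self.atrophy_superficial, 1, 6)
        if self.atrophy_deep is not None:
            self.atrophy_deep = _check_range("atrophy_deep", self.atrophy_deep, 1, 6)
        if self.basal_ganglia_iron is not None:
            self.basal_ganglia_iron = _check_range(
                "basal_ganglia_iron", self.basal_ganglia_iron, 0, 4)
        for key, count in self.bombs.items():
            c = _check_range(f"bombs[{key}]", count, 0, 10**6)
            self.bombs[key] = c
        if self.prins and self.timepoint == "baseline":
            raise ValidationError("Prins change scores apply to follow-up only")
        for key, score in self.prins.items():
            self.prins[key] = _check_range(f"prins[{key}]", score, *PRINS_RANGE)

    def fazekas_total(self) -> int:
        if self.fazekas_periventricular is None or self.fazekas_deep is None:
            raise ValidationError("both Fazekas subscores are required for a total")
        return fazekas_total(self.fazekas_periventricular, self.fazekas_deep)

    def bombs_total(self) -> int:
        return sum(self.bombs.values())


def fazekas_total(periventricular: int, deep: int) -> int:
    """Total Fazekas WMH score (0-6): periventricular + deep."""
    p = _check_range("periventricular", periventricular, 0, 3)
    d = _check_range("deep", deep, 0, 3)
    return p + d


def rank_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation (midrank ties) with large-sample p-value."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) != len(y):
        raise ValidationError("inputs have different lengths")
    if len(x) < 3:
        raise ValidationError("need at least 3 pairs")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def linear_calibration(score, volume_ml, log_transform: bool = False):
    """Least-squares slope (with 95% CI) of volume on visual score.

    With ``log_transform`` the natural log of the volumes is fitted, which
    linearizes the typically exponential score-volume correspondence; all
    volumes must then be positive.
    """
    score = np.asarray(score, float)
    vol = np.asarray(volume_ml, float)
    if len(score) != len(vol):
        raise ValidationError("inputs have different lengths")
    if len(score) < 3:
        raise ValidationError("need at least 3 pairs")
    if np.var(score) == 0:
        raise ValidationError("score has zero variance; slope undefined")
    if log_transform:
        if np.any(vol <= 0):
            raise ValidationError("log transform requires positive volumes")
        vol = np.log(vol)
    res = stats.linregress(score, vol)
    # exact CI for tiny n degenerates; a noiseless fit has zero stderr
    tcrit = stats.t.ppf(0.975, df=len(score) - 2) if len(score) > 2 else np.nan
    half = tcrit * res.stderr
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "ci95": (float(res.slope - half), float(res.slope + half)),
        "p": float(res.pvalue),
        "log_transform": log_transform,
    }


def bland_altman(a, b) -> dict[str, float]:
    """Bland-Altman agreement: mean difference, SD and 1.96-SD limits."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) != len(b):
        raise ValidationError("inputs have different lengths")
    if len(a) < 2:
        raise ValidationError("need at least 2 pairs")
    d = a - b
    mean, sd = float(d.mean()), float(d.std(ddof=1))
    return {
        "mean_difference": mean,
        "sd": sd,
        "lower_loa": mean - 1.96 * sd,
        "upper_loa": mean + 1.96 * sd,
    }


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

_SCALARS = ("fazekas_periventricular", "fazekas_deep", "atrophy_superficial",
            "atrophy_deep", "basal_ganglia_iron")
_DICTS = ("wahlund", "epvs", "bombs", "prins")


def write_rating_records(records: list[RatingRecord], path) -> None:
    """Write records as CSV; dict-valued scales are JSON-encoded columns."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject", "timepoint", *_SCALARS, *_DICTS])
        for r in records:
            row = [r.subject, r.timepoint]
            row += ["" if getattr(r, f) is None else getattr(r, f)
                    for f in _SCALARS]
            row += [json.dumps(getattr(r, f), sort_keys=True) for f in _DICTS]
            writer.writerow(row)


def read_rating_records(path) -> list[RatingRecord]:
    """Read records back; invalid rows raise with a row-level diagnostic."""
    records = []
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh), start=2):
            try:
                kwargs = {"subject": row["subject"], "timepoint": row["timepoint"]}
                for f in _SCALARS:
                    kwargs[f] = int(row[f]) if row.get(f, "") != "" else None
                for f in _DICTS:
                    kwargs[f] = json.loads(row[f]) if row.get(f) else {}
                records.append(RatingRecord(**kwargs))
            except (ValidationError, ValueError, KeyError) as exc:
                raise ValidationError(f"{Path(path).name} line {i}: {exc}") from exc
    return records
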