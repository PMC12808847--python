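"""Average Oncogenic Score (AOS) and the four-tier driver grading.

Within one cohort, each of the five metric scores is Z-normalized across
the cohort's mutations; a mutation's AOS is the mean of its available
normalized metrics. Driver candidates are AOS outliers by two simultaneous
tests — the upper IQR fence (Q3 + 1.5·IQR) and |Z| > 2.5 (stricter than
±2 SD, ≈ the top 1%) — and are graded against a curated known-driver list:

=========  ==========  =============
grade      tests hit   known driver
=========  ==========  =============
1          both        yes
2A         both        no
2B         one         yes
3          one         no
none       neither     (any)
=========  ==========  =============
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .metrics import MetricProfile, upper_fence
from .pancancer import METRICS
from .types import ValidationError


@dataclass
class DriverCall:
    mutation: str
    cohort: str
    metric_scores: dict[str, Optional[float]]
    metric_z: dict[str, Optional[float]] = field(default_factory=dict)
    aos: Optional[float] = None
    iqr_flag: bool = False
    z_flag: bool = False
    known_driver: bool = False
    grade: str = "none"


def aos_scores(profiles: list[MetricProfile]) -> list[DriverCall]:
    """Z-normalize each metric across one cohort's mutations and average.

    Needs at least three mutations (normalization requires spread). Per
    metric, Z-scores use ddof=1 over non-missing values; a metric with zero
    spread contributes 0 for every mutation that has it. Missing metrics
    are excluded from the mean, so a mutation's AOS is the mean of its
    available normalized metrics; it is missing only when all five are.
    """
    cohorts = {p.cohort for p in profiles}
    if len(cohorts) != 1:
        raise ValidationError(f"aos_scores expects a single cohort, got {sorted(cohorts)}")
    if len(profiles) < 3:
        raise ValidationError("AOS needs >=3 mutations per cohort")
    raw = pd.DataFrame(
        {p.mutation: p.metric_vector() for p in profiles}, dtype=float
    ).T  # mutations × metrics
    z = pd.DataFrame(np.nan, index=raw.index, columns=raw.columns)
    for metric in METRICS:
        col = raw[metric]
        avail = col.dropna()
        if len(avail) < 2:
            continue
        sd = avail.std(ddof=1)
        if sd == 0:
            z.loc[avail.index, metric] = 0.0
        else:
            z.loc[avail.index, metric] = (avail - avail.mean()) / sd
    calls = []
    for p in profiles:
        mz = {m: (None if np.isnan(z.loc[p.mutation, m]) else float(z.loc[p.mutation, m]))
              for m in METRICS}
        avail = [v for v in mz.values() if v is not None]
        calls.append(
            DriverCall(
                mutation=p.mutation,
                cohort=p.cohort,
                metric_scores=p.metric_vector(),
                metric_z=mz,
                aos=float(np.mean(avail)) if avail else None,
            )
        )
    return calls


def flag_outliers(calls: list[DriverCall], z_mode: str = "two_sided") -> list[DriverCall]:
    """Set the IQR and Z outlier flags over one cohort's AOS distribution.

    ``iqr_flag``: AOS strictly above Q3 + 1.5·IQR. ``z_flag``: |Z| > 2.5
    (``z_mode="upper"`` restricts to the upper tail, matching an
    upper-outlier reading). With zero spread no flag is set. Requires at
    least four non-missing AOS values.
    """
    if z_mode not in ("two_sided", "upper"):
        raise ValidationError("z_mode must be 'two_sided' or 'upper'")
    aos = np.array([c.aos for c in calls if c.aos is not None], dtype=float)
    if aos.size < 4:
        raise ValidationError("outlier flags need >=4 AOS values")
    fence = upper_fence(aos)
    mean, sd = aos.mean(), aos.std(ddof=1)
    for c in calls:
        if c.aos is None:
            c.iqr_flag = c.z_flag = False
            continue
        c.iqr_flag = bool(c.aos > fence)
        if sd > 0:
            zz = (c.aos - mean) / sd
            c.z_flag = bool(zz > 2.5 if z_mode == "upper" else abs(zz) > 2.5)
        else:
            c.z_flag = False
    return calls


GRADE_TABLE = {
    (True, True): "1",
    (True, False): "2A",
    (False, True): "2B",
    (False, False): "3",
}


def grade_mutations(calls: list[DriverCall], known_drivers: Iterable[str]) -> list[DriverCall]:
    """Assign the four-tier grade from the two flags and known-driver status."""
    known = set(known_drivers)
    for c in calls:
        c.known_driver = c.mutation in known
        n_flags = int(c.iqr_flag) + int(c.z_flag)
        if n_flags == 0:
            c.grade = "none"
        else:
            c.grade = GRADE_TABLE[(n_flags == 2, c.known_driver)]
    return calls


def discover_drivers(
    profiles: list[MetricProfile],
    known_drivers: Iterable[str],
    z_mode: str = "two_sided",
) -> list[DriverCall]:
    """AOS → outlier flags → grades for one cohort's profiles."""
    return grade_mutations(flag_outliers(aos_scores(profiles), z_mode=z_mode), known_drivers)


def calls_to_frame(calls: list[DriverCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "mutation": c.mutation,
                "cohort": c.cohort,
                **{f"{m.lower()}_z": c.metric_z.get(m) for m in METRICS},
                "aos": c.aos,
                "iqr_flag": c.iqr_flag,
                "z_flag": c.z_flag,
                "known_driver": c.known_driver,
                "grade": c.grade,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["mutation", "cohort", "pb_z", "ep_z", "im_z", "pe_z", "ad_z",
                 "aos", "iqr_flag", "z_flag", "known_driver", "grade"],
    )
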