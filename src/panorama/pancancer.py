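"""Pan-cancer comparison of one mutation's metrics across cohorts.

Cohorts are ranked per metric and awarded integer points in graded blocks:
for 12 cohorts the top two receive 5, the next two 4, the middle four 3,
the next two 2 and the last two 1. A cohort where the metric's SignedFDR
family has no significant term (for PB: no directional log-rank hit) is
overridden to the minimum score of 1 regardless of rank.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .metrics import MetricProfile
from .types import ValidationError

METRICS = ("PB", "EP", "IM", "PE", "AD")

#: Cumulative rank-block fractions and the points of each block.
_BLOCK_FRACTIONS = (1 / 6, 2 / 6, 4 / 6, 5 / 6, 6 / 6)
_BLOCK_POINTS = (5, 4, 3, 2, 1)


def build_pancancer_matrix(profiles: list[MetricProfile]) -> pd.DataFrame:
    """Cohort × metric matrix of raw metric values for one mutation.

    PB enters as −log10 of its minimum endpoint p; EP/IM/PE as fractions of
    significant terms; AD as the outlier-site fraction. Missing metrics stay
    missing. Requires at least two cohorts, all for the same mutation.
    """
    if len(profiles) < 2:
        raise ValidationError("pan-cancer comparison needs >=2 cohorts")
    muts = {p.mutation for p in profiles}
    if len(muts) != 1:
        raise ValidationError(f"profiles mix mutations: {sorted(muts)}")
    names = [p.cohort for p in profiles]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate cohort names")
    rows = {p.cohort: p.metric_vector() for p in profiles}
    df = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    return df.reindex(index=names, columns=list(METRICS))


def rank_point_blocks(n: int) -> list[int]:
    """Block sizes for ``n`` ranked cohorts.

    For 12 cohorts this is the canonical (2, 2, 4, 2, 2); other counts use
    the same cumulative proportions (1/6, 1/6, 1/3, 1/6, 1/6) with block
    boundaries obtained by rounding the cumulative fractions.
    """
    bounds = [int(np.floor(n * f + 0.5)) for f in _BLOCK_FRACTIONS]
    bounds[-1] = n
    sizes = []
    prev = 0
    for b in bounds:
        b = max(b, prev)
        sizes.append(b - prev)
        prev = b
    return sizes


def allocate_rank_points(values: pd.Series, significance: pd.Series) -> pd.Series:
    """Assign rank points per cohort for one metric.

    ``values`` and ``significance`` are indexed by cohort name. Cohorts with
    a missing value get missing points; the rest are ranked by value
    descending (ties broken by cohort name ascending) and awarded block
    points. Any cohort whose significance flag is False is overridden to 1.
    """
    if not values.index.is_unique:
        raise ValidationError("duplicate cohort names")
    significance = significance.reindex(values.index)
    avail = values.dropna()
    points = pd.Series(np.nan, index=values.index, dtype=float)
    if len(avail):
        order = sorted(avail.index, key=lambda c: (-avail[c], c))
        sizes = rank_point_blocks(len(order))
        pos = 0
        for size, pts in zip(sizes, _BLOCK_POINTS):
            for c in order[pos:pos + size]:
                points[c] = pts
            pos += size
        override = avail.index[~significance.loc[avail.index].astype(bool)]
        points[override] = 1
    return points


def rank_pancancer(profiles: list[MetricProfile]) -> pd.DataFrame:
    """Tidy per-(cohort, metric) table of raw values and rank points.

    Directly plottable as a radar chart: columns mutation, cohort, metric,
    raw_value, points.
    """
    matrix = build_pancancer_matrix(profiles)
    sig = pd.DataFrame(
        {p.cohort: {m: p.significance.get(m, False) for m in METRICS} for p in profiles}
    ).T.reindex(matrix.index)
    recs = []
    mutation = profiles[0].mutation
    for metric in METRICS:
        pts = allocate_rank_points(matrix[metric], sig[metric])
        for cohort in matrix.index:
            recs.append(
                {
                    "mutation": mutation,
                    "cohort": cohort,
                    "metric": metric,
                    "raw_value": matrix.loc[cohort, metric],
                    "points": pts[cohort],
                }
            )
    return pd.DataFrame(recs)
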