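"""Mutant-vs-wild-type group statistics.

Every oncogenicity metric rests on the same comparison: split the cohort's
samples by the binary mutation status of one gene, then per feature of one
omics layer run a pooled two-sample Student's t-test on the complete cases,
convert p-values to FDR with Benjamini–Hochberg within that single
mutation × layer family, and summarize each feature as a *SignedFDR* —
sign(mutant mean − WT mean) · (−log10 FDR). Survival is compared with the
two-group log-rank test; pairwise mutation co-occurrence uses Fisher's
exact test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import Cohort, UndefinedStatistic, ValidationError

#: FDR values are clipped below at this floor before −log10 so signed scores
#: stay finite.
FDR_FLOOR = 1e-300

#: −log10(0.05); a SignedFDR at or above this marks positive significance.
SIGNED_FDR_CUTOFF = 1.301


@dataclass
class TTestResult:
    t_stat: float
    p: float
    degenerate: bool = False  # pooled SD was zero with unequal means


def two_sample_t(a: Sequence[float], b: Sequence[float], welch: bool = False) -> TTestResult:
    """Two-sided pooled-variance (Student's) two-sample t-test.

    Missing values are removed first; each group then needs at least two
    values or :class:`UndefinedStatistic` is raised. A pooled SD of zero
    yields t=0, p=1 when the means agree, and p=0 with the ``degenerate``
    flag when they differ. ``welch=True`` switches to the unequal-variance
    form.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise UndefinedStatistic("each group needs >=2 non-missing values")
    if not welch and a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return TTestResult(0.0, 1.0)
        return TTestResult(np.inf if a.mean() > b.mean() else -np.inf, 0.0, degenerate=True)
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return TTestResult(float(res.statistic), float(res.pvalue))


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR, preserving input order.

    Missing entries are excluded from the family and restored as missing.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    valid = ~np.isnan(p)
    pv = p[valid]
    if ((pv < 0) | (pv > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    if pv.size:
        out[valid] = multipletests(pv, method="fdr_bh")[1]
    return out


def signed_score(z_diff: float, fdr: float) -> float:
    """SignedFDR: sign of the mean difference times −log10(FDR); 0 if either
    the difference is zero or FDR is 1. FDR is floored at 1e−300."""
    if np.isnan(z_diff) or np.isnan(fdr):
        return np.nan
    if z_diff == 0:
        return 0.0
    return float(np.sign(z_diff) * -np.log10(max(fdr, FDR_FLOOR)))


@dataclass
class ComparisonTable:
    """Per-feature mutant-vs-WT statistics for one mutation × one layer.

    ``rows`` columns: feature, n_mut, n_wt, mean_mut, mean_wt, z_diff,
    t_stat, p, fdr, signed_fdr. Features failing the ≥2-per-group rule carry
    missing statistics and are outside the BH family.
    """

    mutation: str
    layer_kind: str
    rows: pd.DataFrame

    @property
    def testable(self) -> pd.DataFrame:
        return self.rows[self.rows["p"].notna()]

    @property
    def any_significant(self) -> bool:
        """True if any testable feature reaches the SignedFDR cutoff."""
        t = self.testable
        return bool(len(t)) and bool((t["signed_fdr"] >= SIGNED_FDR_CUTOFF).any())


def compare_layer(
    cohort: Cohort, mutation: str, layer: str, welch: bool = False
) -> ComparisonTable:
    """Mutant-vs-WT comparison of every feature of one (normalized) layer.

    Complete-case deletion per feature; features with fewer than two
    non-missing values in either group are reported with missing statistics
    and excluded from the BH family. Fewer than two mutant samples overall
    makes the mutation untestable (error).
    """
    om = cohort.layer(layer)
    if not om.normalized:
        raise ValidationError(f"layer {layer!r} must be Z-score normalized first")
    mut = cohort.mutations.mutant_mask(mutation)
    if mut.sum() < 2:
        raise UndefinedStatistic(
            f"mutation {mutation!r} has <2 mutant samples in cohort {cohort.name!r}"
        )
    vals = om.values.to_numpy(dtype=float)
    res = _vectorized_pooled_t(vals[:, mut], vals[:, ~mut], welch=welch)
    n_mut, n_wt, mean_mut, mean_wt, t_stat, p = res
    fdr = bh_adjust(p)
    z_diff = mean_mut - mean_wt
    with np.errstate(divide="ignore"):
        signed = np.sign(z_diff) * -np.log10(np.clip(fdr, FDR_FLOOR, None))
    signed = np.where(z_diff == 0, 0.0, signed)
    signed = np.where(np.isnan(fdr) | np.isnan(z_diff), np.nan, signed)
    rows = pd.DataFrame(
        {
            "feature": om.features,
            "n_mut": n_mut,
            "n_wt": n_wt,
            "mean_mut": mean_mut,
            "mean_wt": mean_wt,
            "z_diff": z_diff,
            "t_stat": t_stat,
            "p": p,
            "fdr": fdr,
            "signed_fdr": signed,
        }
    )
    return ComparisonTable(mutation=mutation, layer_kind=om.layer_kind, rows=rows)


def _vectorized_pooled_t(
    a: np.ndarray, b: np.ndarray, welch: bool = False
) -> tuple[np.ndarray, ...]:
    """Row-wise two-sample t over matrices with NaN-aware complete cases."""
    def moments(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        n = np.sum(~np.isnan(x), axis=1).astype(float)
        s = np.nansum(x, axis=1)
        mean = np.where(n > 0, s / np.maximum(n, 1), np.nan)
        ss = np.nansum((x - mean[:, None]) ** 2, axis=1)
        var = np.where(n > 1, ss / np.maximum(n - 1, 1), np.nan)
        return n, mean, var

    n1, m1, v1 = moments(a)
    n2, m2, v2 = moments(b)
    testable = (n1 >= 2) & (n2 >= 2)
    t = np.full(a.shape[0], np.nan)
    p = np.full(a.shape[0], np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        if welch:
            se2 = v1 / n1 + v2 / n2
            df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
            tt = (m1 - m2) / np.sqrt(se2)
        else:
            df = n1 + n2 - 2
            vp = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
            se2 = vp * (1 / n1 + 1 / n2)
            tt = (m1 - m2) / np.sqrt(se2)
        pp = 2 * stats.t.sf(np.abs(tt), df)
    # degenerate: zero pooled spread
    zero_se = testable & (se2 == 0)
    eq = zero_se & (m1 == m2)
    ne = zero_se & (m1 != m2)
    tt = np.where(eq, 0.0, tt)
    pp = np.where(eq, 1.0, pp)
    tt = np.where(ne, np.sign(m1 - m2) * np.inf, tt)
    pp = np.where(ne, 0.0, pp)
    t[testable] = tt[testable]
    p[testable] = pp[testable]
    m1 = np.where(n1 > 0, m1, np.nan)
    m2 = np.where(n2 > 0, m2, np.nan)
    return n1.astype(int), n2.astype(int), m1, m2, t, p


@dataclass
class SurvivalComparison:
    """Two-group log-rank result for one endpoint."""

    endpoint: str
    n_mut: int
    n_wt: int
    chi_sq: float
    p: float
    worse_in_mutant: bool  # observed mutant events exceed expectation under H0


def logrank_test(
    times_mut: Sequence[float],
    events_mut: Sequence[float],
    times_wt: Sequence[float],
    events_wt: Sequence[float],
    endpoint: str = "OS",
) -> SurvivalComparison:
    """Standard two-group log-rank test.

    chi² = (O_mut − E_mut)² / Var over the pooled distinct event times; p
    from χ²(1). ``worse_in_mutant`` is True when the mutant group observes
    more events than expected under the null. Raises
    :class:`UndefinedStatistic` when either group is empty or there are no
    events at all.
    """
    t1 = np.asarray(times_mut, dtype=float)
    e1 = np.asarray(events_mut, dtype=float).astype(int)
    t2 = np.asarray(times_wt, dtype=float)
    e2 = np.asarray(events_wt, dtype=float).astype(int)
    if len(t1) != len(e1) or len(t2) != len(e2):
        raise ValidationError("time and event vectors must have equal length")
    if len(t1) == 0 or len(t2) == 0:
        raise UndefinedStatistic("both groups need at least one subject")
    if e1.sum() + e2.sum() == 0:
        raise UndefinedStatistic("no events observed")

    event_times = np.unique(np.concatenate([t1[e1 == 1], t2[e2 == 1]]))
    o_mut = e_mut = var = 0.0
    for t in event_times:
        r1 = float(np.sum(t1 >= t))
        r2 = float(np.sum(t2 >= t))
        n = r1 + r2
        d1 = float(np.sum((t1 == t) & (e1 == 1)))
        d2 = float(np.sum((t2 == t) & (e2 == 1)))
        d = d1 + d2
        o_mut += d1
        e_mut += d * r1 / n
        if n > 1:
            var += d * (r1 / n) * (r2 / n) * (n - d) / (n - 1)
    if var > 0:
        chi = (o_mut - e_mut) ** 2 / var
        p = float(stats.chi2.sf(chi, 1))
    else:
        chi, p = 0.0, 1.0
    return SurvivalComparison(
        endpoint=endpoint,
        n_mut=len(t1),
        n_wt=len(t2),
        chi_sq=float(chi),
        p=p,
        worse_in_mutant=bool(o_mut > e_mut),
    )


def mutation_cooccurrence(m, fdr_cutoff: float = 0.05) -> pd.DataFrame:
    """Pairwise co-occurrence / mutual exclusivity across mutated genes.

    For each unordered gene pair a 2×2 sample-count table feeds a two-sided
    Fisher's exact test; odds ratios use the Haldane–Anscombe +0.5
    correction whenever a cell is zero; BH across all pairs. Labels:
    ``co_occurring`` (OR>1, FDR<cutoff), ``mutually_exclusive`` (OR<1,
    FDR<cutoff), else ``none``.
    """
    status = m.status.to_numpy(dtype=bool)
    genes = m.genes
    if len(genes) < 2:
        raise ValidationError("co-occurrence needs at least two genes")
    recs = []
    for i, j in combinations(range(len(genes)), 2):
        gi, gj = status[i], status[j]
        a = int(np.sum(gi & gj))
        b = int(np.sum(gi & ~gj))
        c = int(np.sum(~gi & gj))
        d = int(np.sum(~gi & ~gj))
        p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
        if min(a, b, c, d) == 0:
            orr = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
        else:
            orr = a * d / (b * c)
        recs.append((genes[i], genes[j], a, b, c, d, float(orr), p))
    out = pd.DataFrame(
        recs,
        columns=["gene_a", "gene_b", "n_both", "n_a_only", "n_b_only", "n_neither",
                 "odds_ratio", "p"],
    )
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    sig = out["fdr"] < fdr_cutoff
    out["label"] = "none"
    out.loc[sig & (out["odds_ratio"] > 1), "label"] = "co_occurring"
    out.loc[sig & (out["odds_ratio"] < 1), "label"] = "mutually_exclusive"
    return out
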