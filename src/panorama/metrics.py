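"""The five per-mutation oncogenicity metrics.

PB  Prognostic Biomarker — log-rank significance of mutant vs WT survival
    over any available endpoint; the flag requires the mutant group to do
    worse, the score is −log10 of the minimum endpoint p-value.
EP  Expression Perturbator — fraction of genes with SignedFDR ≥ 1.301 in
    the RNA layer (protein reported alongside).
IM  Immune Modulator — same fraction over immune-deconvolution scores.
PE  Pathway Effector — same fraction over pathway activity scores, per
    pathway layer plus a combined value.
AD  Actionable Driver — fraction of phosphosites whose SignedFDR exceeds
    the upper box-plot fence (Q3 + 1.5·IQR) of the mutation's own phospho
    comparison; each outlier is annotated with the parent gene's RNA and
    protein SignedFDR when available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .group_stats import (
    SIGNED_FDR_CUTOFF,
    ComparisonTable,
    SurvivalComparison,
    compare_layer,
    logrank_test,
)
from .types import Cohort, UndefinedStatistic, ValidationError


@dataclass
class ActionableSite:
    """A phosphosite whose signed score exceeds the upper IQR fence."""

    site: str
    signed_fdr_phospho: float
    fence: float
    signed_fdr_rna: Optional[float] = None
    signed_fdr_protein: Optional[float] = None

    @property
    def parent_gene(self) -> str:
        # phosphosite ids follow "GENE_residuePosition"
        return self.site.rsplit("_", 1)[0]


@dataclass
class MetricProfile:
    """All five oncogenicity scores for one mutation in one cohort.

    Scores of absent layers are ``None`` (never silently 0). ``significance``
    records, per metric, whether any term of that metric's own SignedFDR
    family reached the cutoff (for PB: the directional flag) — the
    pan-cancer ranking uses it for the minimum-score override.
    """

    mutation: str
    cohort: str
    pb_score: Optional[float] = None
    pb_flag: Optional[bool] = None
    pb_min_endpoint: Optional[str] = None
    pb_detail: dict[str, SurvivalComparison] = field(default_factory=dict)
    ep_score: Optional[float] = None
    ep_score_protein: Optional[float] = None
    im_score: Optional[float] = None
    pe_scores: dict[str, float] = field(default_factory=dict)
    ad_score: Optional[float] = None
    ad_fence: Optional[float] = None
    ad_targets: list[ActionableSite] = field(default_factory=list)
    significance: dict[str, bool] = field(default_factory=dict)

    @property
    def pe_score(self) -> Optional[float]:
        """Combined pathway-effector score: mean over available pathway layers."""
        vals = [v for v in self.pe_scores.values() if v is not None]
        return float(np.mean(vals)) if vals else None

    def metric_vector(self) -> dict[str, Optional[float]]:
        """The 5-vector feeding the pan-cancer matrix and the AOS."""
        return {
            "PB": self.pb_score,
            "EP": self.ep_score,
            "IM": self.im_score,
            "PE": self.pe_score,
            "AD": self.ad_score,
        }


def prognostic_biomarker(
    cohort: Cohort, mutation: str, alpha: float = 0.05
) -> tuple[float, bool, dict[str, SurvivalComparison], str]:
    """Log-rank comparison per available endpoint.

    Returns (pb_score, pb_flag, per-endpoint detail, endpoint of min p).
    pb_score = −log10 of the minimum p over endpoints, direction-agnostic;
    pb_flag = some endpoint has p < alpha with poorer outcome in mutants.
    """
    if cohort.clinical is None:
        raise UndefinedStatistic(f"cohort {cohort.name!r} has no clinical table")
    mut = cohort.mutations.mutant_mask(mutation)
    detail: dict[str, SurvivalComparison] = {}
    for ep in cohort.clinical.endpoints:
        t = cohort.clinical.data[f"{ep}_time"].to_numpy(dtype=float)
        e = cohort.clinical.data[f"{ep}_event"].to_numpy(dtype=float)
        ok = ~(np.isnan(t) | np.isnan(e))
        try:
            detail[ep] = logrank_test(
                t[ok & mut], e[ok & mut], t[ok & ~mut], e[ok & ~mut], endpoint=ep
            )
        except UndefinedStatistic:
            continue
    if not detail:
        raise UndefinedStatistic("no endpoint computable")
    min_ep = min(detail, key=lambda ep: detail[ep].p)
    pb_score = float(-np.log10(max(detail[min_ep].p, 1e-300)))
    pb_flag = any(sc.p < alpha and sc.worse_in_mutant for sc in detail.values())
    return pb_score, pb_flag, detail, min_ep


def proportion_significant(
    table: ComparisonTable, cutoff: float = SIGNED_FDR_CUTOFF
) -> float:
    """Fraction of testable features with SignedFDR at or above ``cutoff``."""
    t = table.testable
    if len(t) == 0:
        raise UndefinedStatistic("no testable feature in comparison table")
    return float((t["signed_fdr"] >= cutoff).sum() / len(t))


def upper_fence(values: np.ndarray) -> float:
    """Upper box-plot fence Q3 + 1.5·IQR (linear-interpolation quantiles)."""
    q1, q3 = np.quantile(values, [0.25, 0.75])
    return float(q3 + 1.5 * (q3 - q1))


def actionable_driver(
    cohort: Cohort,
    mutation: str,
    phospho_table: Optional[ComparisonTable] = None,
    rna_table: Optional[ComparisonTable] = None,
    protein_table: Optional[ComparisonTable] = None,
    phospho_layer: str = "phospho",
) -> tuple[float, list[ActionableSite], float]:
    """Outlier-level phosphosite upregulation score.

    Over the testable signed scores of the mutation's phospho comparison:
    sites strictly above Q3 + 1.5·IQR are upper outliers; the score is their
    count over the number of testable sites. Outliers are annotated with the
    parent gene's RNA/protein SignedFDR where those comparisons cover it.
    """
    if phospho_table is None:
        phospho_table = compare_layer(cohort, mutation, phospho_layer)
    t = phospho_table.testable
    if len(t) < 2:
        raise UndefinedStatistic("fewer than two testable phosphosites")
    signed = t["signed_fdr"].to_numpy(dtype=float)
    fence = upper_fence(signed)
    out = t[t["signed_fdr"] > fence]

    def lookup(table: Optional[ComparisonTable], gene: str) -> Optional[float]:
        if table is None:
            return None
        hit = table.rows.loc[table.rows["feature"] == gene, "signed_fdr"]
        if len(hit) == 0 or np.isnan(hit.iloc[0]):
            return None
        return float(hit.iloc[0])

    targets = []
    for _, row in out.iterrows():
        site = ActionableSite(
            site=row["feature"],
            signed_fdr_phospho=float(row["signed_fdr"]),
            fence=fence,
        )
        site.signed_fdr_rna = lookup(rna_table, site.parent_gene)
        site.signed_fdr_protein = lookup(protein_table, site.parent_gene)
        targets.append(site)
    targets.sort(key=lambda s: -s.signed_fdr_phospho)
    return len(targets) / len(t), targets, fence


def evaluate_mutation(
    cohort: Cohort, mutation: str, cutoff: float = SIGNED_FDR_CUTOFF
) -> MetricProfile:
    """Compute every metric the cohort's layers and clinical table support.

    Absent layers leave the corresponding metric missing. A cohort with no
    layers and no clinical table cannot be evaluated at all (error).
    """
    if not cohort.layers and cohort.clinical is None:
        raise ValidationError("cohort has neither omics layers nor clinical data")
    profile = MetricProfile(mutation=mutation, cohort=cohort.name)

    tables: dict[str, ComparisonTable] = {}
    for name in cohort.layers:
        tables[name] = compare_layer(cohort, mutation, name)

    if cohort.clinical is not None:
        try:
            (profile.pb_score, profile.pb_flag, profile.pb_detail,
             profile.pb_min_endpoint) = prognostic_biomarker(cohort, mutation)
            profile.significance["PB"] = bool(profile.pb_flag)
        except UndefinedStatistic:
            pass

    def prop(name: str) -> Optional[float]:
        if name not in tables:
            return None
        try:
            return proportion_significant(tables[name], cutoff)
        except UndefinedStatistic:
            return None

    profile.ep_score = prop("rna")
    profile.ep_score_protein = prop("protein")
    if profile.ep_score is not None:
        profile.significance["EP"] = tables["rna"].any_significant
    profile.im_score = prop("immune")
    if profile.im_score is not None:
        profile.significance["IM"] = tables["immune"].any_significant

    pathway_names = sorted(cohort.layers_of_kind("pathway"))
    pe_any = False
    for name in pathway_names:
        score = prop(name)
        if score is not None:
            profile.pe_scores[name] = score
            pe_any = pe_any or tables[name].any_significant
    if profile.pe_scores:
        profile.significance["PE"] = pe_any

    if "phospho" in tables:
        try:
            profile.ad_score, profile.ad_targets, profile.ad_fence = actionable_driver(
                cohort,
                mutation,
                phospho_table=tables["phospho"],
                rna_table=tables.get("rna"),
                protein_table=tables.get("protein"),
            )
            profile.significance["AD"] = tables["phospho"].any_significant
        except UndefinedStatistic:
            pass

    return profile


# ---------------------------------------------------------------------------
# tabular output

PROFILE_COLUMNS = [
    "mutation", "cohort", "pb_score", "pb_flag", "pb_min_endpoint",
    "ep_score", "ep_score_protein", "im_score", "pe_score_rna",
    "pe_score_protein", "ad_score", "n_ad_targets",
]


def profiles_to_frame(profiles: list[MetricProfile]) -> pd.DataFrame:
    """Flatten profiles to the documented table (+ per-metric significance)."""
    rows = []
    for p in profiles:
        rows.append(
            {
                "mutation": p.mutation,
                "cohort": p.cohort,
                "pb_score": p.pb_score,
                "pb_flag": p.pb_flag,
                "pb_min_endpoint": p.pb_min_endpoint,
                "ep_score": p.ep_score,
                "ep_score_protein": p.ep_score_protein,
                "im_score": p.im_score,
                "pe_score_rna": p.pe_scores.get("pathway_rna", p.pe_scores.get("pathway")),
                "pe_score_protein": p.pe_scores.get("pathway_protein"),
                "ad_score": p.ad_score,
                "n_ad_targets": len(p.ad_targets),
                "pe_score": p.pe_score,
                **{f"sig_{m.lower()}": p.significance.get(m) for m in
                   ("PB", "EP", "IM", "PE", "AD")},
            }
        )
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS + [
        "pe_score", "sig_pb", "sig_ep", "sig_im", "sig_pe", "sig_ad"])


def ad_targets_to_frame(profiles: list[MetricProfile]) -> pd.DataFrame:
    """Companion table of actionable phosphosites across profiles."""
    rows = []
    for p in profiles:
        for s in p.ad_targets:
            rows.append(
                {
                    "mutation": p.mutation,
                    "cohort": p.cohort,
                    "site": s.site,
                    "parent_gene": s.parent_gene,
                    "signed_fdr_phospho": s.signed_fdr_phospho,
                    "fence": s.fence,
                    "signed_fdr_rna": s.signed_fdr_rna,
                    "signed_fdr_protein": s.signed_fdr_protein,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["mutation", "cohort", "site", "parent_gene", "signed_fdr_phospho",
                 "fence", "signed_fdr_rna", "signed_fdr_protein"],
    )
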