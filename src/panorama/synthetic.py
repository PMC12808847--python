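"""Seeded synthetic cohorts with known planted truth.

The generator emulates the statistical structure the evaluation machinery
assumes: binary gene-level mutation status at a configurable frequency
(deterministic mutant count = round(frequency·n)), i.i.d. standard-normal
feature baselines for RNA / protein / phosphosites with additive mean
shifts planted in the mutant samples of designated features, immune
signature scores with optional planted shifts, pathway activity derived by
in-package ssGSEA over simulated gene sets, and exponential survival with
a per-mutation hazard ratio under uniform censoring.

Every data component draws from its own RNG stream derived from the master
seed, so enabling one layer never perturbs another; the full fixture is a
pure function of the configuration.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .cohort_io import assemble_cohort, write_matrix
from .preprocess import SsgseaConfig, ssgsea_scores
from .types import (
    ClinicalTable,
    Cohort,
    GeneSetCollection,
    MutationMatrix,
    OmicsMatrix,
    ValidationError,
)

_STREAMS = {"mutation": 0, "rna": 1, "protein": 2, "phospho": 3, "immune": 4,
            "survival": 5, "missing": 6, "sets": 7, "effects": 8}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


@dataclass
class MutationSpec:
    """One simulated mutation and its planted downstream effects.

    ``delta`` is added to the RNA and protein values of ``up_genes`` (and
    subtracted for ``down_genes``) in mutant samples; ``phospho_shift`` is
    added at ``phospho_outlier_sites``; ``immune_shift`` at
    ``immune_signatures``; ``hazard_ratio`` multiplies the mutant samples'
    event hazard. A mutation with all defaults is a planted passenger.
    """

    gene: str
    frequency: float
    up_genes: tuple[str, ...] = ()
    down_genes: tuple[str, ...] = ()
    delta: float = 0.0
    hazard_ratio: float = 1.0
    immune_shift: float = 0.0
    immune_signatures: tuple[str, ...] = ()
    phospho_outlier_sites: tuple[str, ...] = ()
    phospho_shift: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.frequency < 1:
            raise ValidationError("mutation frequency must be in (0, 1)")
        if self.hazard_ratio <= 0:
            raise ValidationError("hazard ratio must be positive")


@dataclass
class SimulationConfig:
    seed: int
    mutations: list[MutationSpec]
    n_samples: int = 200
    n_genes: int = 1000
    n_phospho_sites: int = 500
    n_immune_signatures: int = 20
    n_pathway_sets: int = 15
    pathway_set_size: int = 50
    baseline_hazard: float = 0.05
    censoring_horizon: float = 100.0
    endpoints: tuple[str, ...] = ("OS",)
    missing_fraction: float = 0.0
    with_immune: bool = True
    with_pathway: bool = True
    cohort_name: str = "SIM"

    def __post_init__(self) -> None:
        if self.n_samples < 20:
            raise ValidationError("n_samples must be >= 20")
        if self.baseline_hazard <= 0 or self.censoring_horizon <= 0:
            raise ValidationError("baseline_hazard and censoring_horizon must be positive")
        if not 0 <= self.missing_fraction < 1:
            raise ValidationError("missing_fraction must be in [0, 1)")

    @property
    def gene_names(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    @property
    def phospho_site_names(self) -> list[str]:
        genes = self.gene_names
        return [f"{genes[i % self.n_genes]}_S{i + 1}" for i in range(self.n_phospho_sites)]

    @property
    def immune_signature_names(self) -> list[str]:
        return [f"IMM{i:02d}" for i in range(1, self.n_immune_signatures + 1)]

    @property
    def sample_names(self) -> list[str]:
        width = len(str(self.n_samples))
        return [f"S{i:0{width}d}" for i in range(1, self.n_samples + 1)]


def simulate_survival(
    n_mut: int,
    n_wt: int,
    baseline_hazard: float,
    hazard_ratio: float,
    censoring_horizon: float,
    seed: Union[int, np.random.Generator],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Exponential event times with uniform censoring, per group.

    WT events have rate ``baseline_hazard``; mutant events rate
    ``baseline_hazard · hazard_ratio``. Censoring times are uniform on
    (0, horizon]; the observed time is the minimum and the event indicator
    marks an uncensored observation. Returns
    (times_mut, events_mut, times_wt, events_wt).
    """
    if baseline_hazard <= 0 or hazard_ratio <= 0 or censoring_horizon <= 0:
        raise ValidationError("hazards and horizon must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ev_mut = rng.exponential(1.0 / (baseline_hazard * hazard_ratio), n_mut)
    ev_wt = rng.exponential(1.0 / baseline_hazard, n_wt)
    c_mut = rng.uniform(0, censoring_horizon, n_mut)
    c_wt = rng.uniform(0, censoring_horizon, n_wt)
    t_mut = np.minimum(ev_mut, c_mut)
    t_wt = np.minimum(ev_wt, c_wt)
    return t_mut, (ev_mut <= c_mut).astype(int), t_wt, (ev_wt <= c_wt).astype(int)


def simulate_cohort(cfg: SimulationConfig) -> tuple[Cohort, dict]:
    """Generate a cohort and its planted-truth record from a configuration."""
    genes = cfg.gene_names
    sites = cfg.phospho_site_names
    sigs = cfg.immune_signature_names
    samples = cfg.sample_names
    gene_set = set(genes)
    site_set = set(sites)
    sig_set = set(sigs)
    for m in cfg.mutations:
        unknown = (set(m.up_genes) | set(m.down_genes)) - gene_set
        if unknown:
            raise ValidationError(f"{m.gene}: unknown effect gene(s) {sorted(unknown)[:3]}")
        if set(m.phospho_outlier_sites) - site_set:
            raise ValidationError(f"{m.gene}: unknown phosphosite in effect set")
        if set(m.immune_signatures) - sig_set:
            raise ValidationError(f"{m.gene}: unknown immune signature in effect set")

    # mutation status: exactly round(frequency · n) mutants per gene
    rng_mut = _rng(cfg.seed, "mutation")
    status = pd.DataFrame(0, index=[m.gene for m in cfg.mutations], columns=samples,
                          dtype=np.int8)
    masks: dict[str, np.ndarray] = {}
    for m in cfg.mutations:
        k = int(round(m.frequency * cfg.n_samples))
        idx = rng_mut.choice(cfg.n_samples, size=k, replace=False)
        mask = np.zeros(cfg.n_samples, dtype=bool)
        mask[idx] = True
        masks[m.gene] = mask
        status.loc[m.gene, :] = mask.astype(np.int8)
    mutations = MutationMatrix(status)

    def planted_matrix(stream: str, features: list[str],
                       shifts: dict[str, float]) -> np.ndarray:
        vals = _rng(cfg.seed, stream).standard_normal((len(features), cfg.n_samples))
        findex = {f: i for i, f in enumerate(features)}
        for m in cfg.mutations:
            for feat, delta in shifts.get(m.gene, {}).items():
                vals[findex[feat], masks[m.gene]] += delta
        return vals

    rna_shifts = {
        m.gene: {**{g: m.delta for g in m.up_genes}, **{g: -m.delta for g in m.down_genes}}
        for m in cfg.mutations
    }
    rna = planted_matrix("rna", genes, rna_shifts)
    protein = planted_matrix("protein", genes, rna_shifts)
    phospho = planted_matrix(
        "phospho", sites,
        {m.gene: {s: m.phospho_shift for s in m.phospho_outlier_sites}
         for m in cfg.mutations},
    )

    layers: dict[str, OmicsMatrix] = {
        "rna": OmicsMatrix(pd.DataFrame(rna, index=genes, columns=samples), "rna"),
        "protein": OmicsMatrix(pd.DataFrame(protein, index=genes, columns=samples),
                               "protein"),
        "phospho": OmicsMatrix(pd.DataFrame(phospho, index=sites, columns=samples),
                               "phospho"),
    }

    if cfg.with_immune and cfg.n_immune_signatures:
        imm = planted_matrix(
            "immune", sigs,
            {m.gene: {s: m.immune_shift for s in m.immune_signatures}
             for m in cfg.mutations},
        )
        layers["immune"] = OmicsMatrix(pd.DataFrame(imm, index=sigs, columns=samples),
                                       "immune")

    truth_sets: dict[str, list[str]] = {}
    if cfg.with_pathway and cfg.n_pathway_sets:
        rng_sets = _rng(cfg.seed, "sets")
        sets: dict[str, list[str]] = {}
        for i in range(1, cfg.n_pathway_sets + 1):
            members = rng_sets.choice(cfg.n_genes, size=cfg.pathway_set_size,
                                      replace=False)
            sets[f"SET{i:02d}"] = [genes[j] for j in sorted(members)]
        # one set per mutation with planted expression effects, so pathway
        # activity responds to the planted signal
        for m in cfg.mutations:
            if m.up_genes:
                sets[f"SET_{m.gene}"] = list(m.up_genes)
        truth_sets = {k: v for k, v in sets.items() if k.startswith("SET_")}
        layers["pathway_rna"] = ssgsea_scores(
            layers["rna"], GeneSetCollection(sets), SsgseaConfig()
        )

    clinical = None
    if cfg.endpoints:
        rng_surv = _rng(cfg.seed, "survival")
        log_hr = np.zeros(cfg.n_samples)
        for m in cfg.mutations:
            log_hr[masks[m.gene]] += np.log(m.hazard_ratio)
        hazard = cfg.baseline_hazard * np.exp(log_hr)
        cols = {}
        for ep in cfg.endpoints:
            ev = rng_surv.exponential(1.0 / hazard)
            cens = rng_surv.uniform(0, cfg.censoring_horizon, cfg.n_samples)
            cols[f"{ep}_time"] = np.minimum(ev, cens)
            cols[f"{ep}_event"] = (ev <= cens).astype(int)
        clinical = ClinicalTable(pd.DataFrame(cols, index=pd.Index(samples, name="sample")),
                                 time_unit="months")

    if cfg.missing_fraction > 0:
        rng_miss = _rng(cfg.seed, "missing")
        for key in ("rna", "protein", "phospho"):
            vals = layers[key].values.to_numpy()
            hole = rng_miss.random(vals.shape) < cfg.missing_fraction
            vals[hole] = np.nan
            layers[key] = OmicsMatrix(
                pd.DataFrame(vals, index=layers[key].values.index, columns=samples),
                layers[key].layer_kind,
            )

    cohort = assemble_cohort(cfg.cohort_name, mutations, layers, clinical,
                             samples=samples)
    truth = {
        "config": _config_dict(cfg),
        "pathway_truth_sets": truth_sets,
        "driver_genes": [m.gene for m in cfg.mutations if _has_effects(m)],
    }
    return cohort, truth


def _has_effects(m: MutationSpec) -> bool:
    return bool(m.up_genes or m.down_genes or m.phospho_outlier_sites
                or m.immune_shift or m.hazard_ratio != 1.0)


def _config_dict(cfg: SimulationConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["mutations"] = [dataclasses.asdict(m) for m in cfg.mutations]
    return d


def write_cohort(cohort: Cohort, truth: dict, outdir: Union[str, Path]) -> None:
    """Write the full cohort directory: MAF, layer TSVs, clinical, truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    recs = []
    for gene in cohort.mutations.genes:
        for sample in np.array(cohort.samples)[cohort.mutations.mutant_mask(gene)]:
            recs.append((gene, sample, "Missense_Mutation"))
    pd.DataFrame(
        recs, columns=["Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"]
    ).to_csv(outdir / "mutations.maf", sep="\t", index=False)
    for name, layer in cohort.layers.items():
        write_matrix(layer, outdir / f"{name}.tsv")
    if cohort.clinical is not None:
        df = cohort.clinical.data.copy()
        df.index.name = "sample"
        df.to_csv(outdir / "clinical.tsv", sep="\t")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# standard multi-cohort fixture with one planted driver per cohort

def driver_fixture_config(
    seed: int,
    cohort_index: int = 0,
    n_mutations: int = 10,
    n_samples: int = 200,
    n_genes: int = 1000,
    n_phospho_sites: int = 500,
    frequency: float = 0.2,
    delta: float = 1.5,
    up_fraction: float = 0.05,
    hazard_ratio: float = 3.0,
    phospho_fraction: float = 0.01,
    phospho_shift: float = 5.0,
    immune_shift: float = 1.0,
) -> SimulationConfig:
    """One cohort of the planted-driver study design.

    ``n_mutations`` mutations at the given frequency; the first is the
    planted driver, carrying an expression shift ``delta`` on
    ``up_fraction`` of the genes, a survival hazard ratio, planted phospho
    outliers on ``phospho_fraction`` of the sites, and an immune shift on a
    quarter of the immune signatures. The rest are passengers with no
    effects.
    """
    child_seed = int(np.random.SeedSequence([int(seed), cohort_index]).generate_state(1)[0]
                     % 2**31)
    base = SimulationConfig(seed=child_seed, mutations=[], n_samples=n_samples,
                            n_genes=n_genes, n_phospho_sites=n_phospho_sites)
    rng = _rng(child_seed, "effects")  # effect-set draws; independent of data streams
    genes = base.gene_names
    sites = base.phospho_site_names
    sigs = base.immune_signature_names
    n_up = max(1, int(round(up_fraction * n_genes)))
    n_ph = max(1, int(round(phospho_fraction * n_phospho_sites)))
    up = tuple(genes[i] for i in sorted(rng.choice(n_genes, n_up, replace=False)))
    ph = tuple(sites[i] for i in sorted(rng.choice(n_phospho_sites, n_ph, replace=False)))
    muts = [
        MutationSpec(
            gene="DRV01", frequency=frequency, up_genes=up, delta=delta,
            hazard_ratio=hazard_ratio, phospho_outlier_sites=ph,
            phospho_shift=phospho_shift, immune_shift=immune_shift,
            immune_signatures=tuple(sigs[: max(1, len(sigs) // 4)]),
        )
    ]
    muts += [MutationSpec(gene=f"PSG{i:02d}", frequency=frequency)
             for i in range(2, n_mutations + 1)]
    return dataclasses.replace(
        base, mutations=muts, cohort_name=f"COHORT{cohort_index:02d}"
    )
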