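"""Core containers for mutation-centric multi-omics cohort analysis.

A :class:`Cohort` bundles everything one cancer-type dataset contributes:
a binary gene × sample mutation matrix, one or more feature × sample omics
layers (RNA, protein, phosphosite, immune-deconvolution scores, pathway
activity scores), and an optional clinical survival table. All components
share a single ordered sample list, which is validated at assembly time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

#: Recognized omics layer kinds.
LAYER_KINDS = ("rna", "protein", "phospho", "immune", "pathway")

#: Recognized survival endpoints: overall, disease-specific, disease-free,
#: progression-free and relapse-free survival.
ENDPOINTS = ("OS", "DSS", "DFS", "PFS", "RFS")


class PanoramaError(Exception):
    """Base class for package errors."""


class FormatError(PanoramaError):
    """An input file violates its declared format."""


class EmptyInputError(PanoramaError):
    """An input yielded zero usable records."""


class ValidationError(PanoramaError):
    """Components are inconsistent (sample mismatch, bad parameter, ...)."""


class UndefinedStatistic(PanoramaError):
    """A statistic cannot be computed for this input (e.g. group too small)."""


@dataclass
class MutationMatrix:
    """Binary gene-level mutation status over an ordered sample list.

    ``status`` is a genes × samples DataFrame with values in {0, 1}; a sample
    without any qualifying variant in a gene is wild-type (0) for that gene.
    """

    status: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.status.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError("mutation status must be binary (0/1)")
        if not self.status.index.is_unique:
            raise ValidationError("duplicate gene symbols in mutation matrix")
        self.status = self.status.astype(np.int8)

    @property
    def genes(self) -> list[str]:
        return list(self.status.index)

    @property
    def samples(self) -> list[str]:
        return list(self.status.columns)

    @property
    def frequency(self) -> pd.Series:
        """Per-gene fraction of mutated samples (exact ratio over all samples)."""
        return self.status.sum(axis=1) / self.status.shape[1]

    def mutant_mask(self, gene: str) -> np.ndarray:
        """Boolean mask over samples: True where ``gene`` is mutated."""
        if gene not in self.status.index:
            raise ValidationError(f"gene {gene!r} not in mutation matrix")
        return self.status.loc[gene].to_numpy(dtype=bool)

    def reordered(self, samples: list[str]) -> "MutationMatrix":
        if set(samples) != set(self.status.columns):
            raise ValidationError("mutation matrix samples do not match cohort")
        return MutationMatrix(self.status[samples])


@dataclass
class OmicsMatrix:
    """A feature × sample matrix of real values with missing entries allowed.

    ``layer_kind`` records what the features are (genes, phosphosites,
    immune cell scores, pathway scores); ``normalized`` records whether
    per-feature Z-scoring has been applied.
    """

    values: pd.DataFrame
    layer_kind: str
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.layer_kind not in LAYER_KINDS:
            raise ValidationError(
                f"layer_kind {self.layer_kind!r} not one of {LAYER_KINDS}"
            )
        if not self.values.index.is_unique:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicate feature id {dup!r}")
        if self.values.shape[0] < 1:
            raise ValidationError("omics matrix needs at least one feature")
        if self.values.shape[1] < 2:
            raise ValidationError("omics matrix needs at least two samples")
        self.values = self.values.astype(float)

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def reordered(self, samples: list[str]) -> "OmicsMatrix":
        if set(samples) != set(self.values.columns):
            raise ValidationError(f"{self.layer_kind} layer samples do not match cohort")
        return OmicsMatrix(self.values[samples], self.layer_kind, self.normalized)


@dataclass
class ClinicalTable:
    """Survival endpoints per sample.

    ``data`` is indexed by sample id with columns ``<ENDPOINT>_time`` /
    ``<ENDPOINT>_event`` for any subset of OS, DSS, DFS, PFS, RFS. Times are
    non-negative (unit recorded but never converted — the log-rank test is
    unit-invariant); events are 1 = event observed, 0 = censored. Missing
    values are allowed per sample.
    """

    data: pd.DataFrame
    time_unit: str = "unspecified"

    def __post_init__(self) -> None:
        for ep in self.endpoints:
            t = self.data[f"{ep}_time"]
            e = self.data[f"{ep}_event"]
            if (t.dropna() < 0).any():
                raise FormatError(f"negative {ep}_time")
            bad = e.dropna()[~e.dropna().isin([0, 1])]
            if len(bad):
                raise FormatError(f"{ep}_event values must be 0/1, got {bad.iloc[0]!r}")

    @property
    def endpoints(self) -> list[str]:
        return [
            ep
            for ep in ENDPOINTS
            if f"{ep}_time" in self.data.columns and f"{ep}_event" in self.data.columns
        ]

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    def endpoint_arrays(self, endpoint: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Complete-case (time, event, sample-mask) arrays for one endpoint.

        The mask is over the table's own sample order and marks rows with both
        time and event present.
        """
        t = self.data[f"{endpoint}_time"].to_numpy(dtype=float)
        e = self.data[f"{endpoint}_event"].to_numpy(dtype=float)
        ok = ~(np.isnan(t) | np.isnan(e))
        return t[ok], e[ok].astype(int), ok

    def reordered(self, samples: list[str]) -> "ClinicalTable":
        if set(samples) != set(self.data.index):
            raise ValidationError("clinical table samples do not match cohort")
        return ClinicalTable(self.data.loc[samples], self.time_unit)


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. HALLMARK / KEGG collections from GMT files)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")
            # preserve order, drop duplicates
            self.sets[name] = list(dict.fromkeys(members))

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class SignatureWeights:
    """Gene × signature coefficient matrix for linear signature scoring."""

    weights: pd.DataFrame  # genes × signatures

    def __post_init__(self) -> None:
        if not self.weights.index.is_unique:
            raise FormatError("duplicate gene in signature weights")
        if not np.isfinite(self.weights.to_numpy()).all():
            raise FormatError("signature weights must be finite")

    @property
    def genes(self) -> list[str]:
        return list(self.weights.index)

    @property
    def signatures(self) -> list[str]:
        return list(self.weights.columns)


@dataclass
class Cohort:
    """One cancer-type dataset: mutations + omics layers + optional clinical.

    All components are stored in the cohort's sample order. Layer keys are
    free-form names (``rna``, ``protein``, ``phospho``, ``immune``,
    ``pathway_rna``, ...); each layer carries its kind in ``layer_kind``.
    """

    name: str
    samples: list[str]
    mutations: MutationMatrix
    layers: dict[str, OmicsMatrix]
    clinical: Optional[ClinicalTable] = None

    def __post_init__(self) -> None:
        self.mutations = self.mutations.reordered(self.samples)
        self.layers = {k: v.reordered(self.samples) for k, v in self.layers.items()}
        if self.clinical is not None:
            self.clinical = self.clinical.reordered(self.samples)

    def layer(self, name: str) -> OmicsMatrix:
        try:
            return self.layers[name]
        except KeyError:
            raise ValidationError(f"cohort {self.name!r} has no layer {name!r}") from None

    def layers_of_kind(self, kind: str) -> dict[str, OmicsMatrix]:
        return {k: v for k, v in self.layers.items() if v.layer_kind == kind}

    def with_layers(self, layers: dict[str, OmicsMatrix]) -> "Cohort":
        return replace(self, layers=layers)
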