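"""Readers and writers for cohort inputs and result tables.

Input dialects
--------------
MAF            tab-separated; required columns ``Hugo_Symbol``,
               ``Tumor_Sample_Barcode``, ``Variant_Classification``
               (header names remappable).
Matrix TSV     first column header ``feature``, remaining columns = sample ids.
Clinical TSV   column ``sample``, then ``<ENDPOINT>_time`` / ``<ENDPOINT>_event``
               pairs for any of OS, DSS, DFS, PFS, RFS.
GMT            standard MSigDB dialect: name TAB description TAB genes...
Weights TSV    first column ``gene``, remaining columns = signature names.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

from .types import (
    ENDPOINTS,
    ClinicalTable,
    Cohort,
    EmptyInputError,
    FormatError,
    GeneSetCollection,
    MutationMatrix,
    OmicsMatrix,
    SignatureWeights,
    ValidationError,
)

log = logging.getLogger("panorama")

#: Default gene-disrupting variant classes; silent/intronic classes excluded.
NON_SILENT_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
        "Translation_Start_Site",
        "Nonstop_Mutation",
    }
)

MAF_COLUMNS = {
    "gene": "Hugo_Symbol",
    "sample": "Tumor_Sample_Barcode",
    "variant": "Variant_Classification",
}


def load_mutations(
    maf_path: Union[str, Path],
    sample_universe: list[str],
    variant_filter: Union[str, Iterable[str]] = "default",
    column_map: Optional[dict[str, str]] = None,
) -> MutationMatrix:
    """Read a MAF file into a binary gene × sample mutation matrix.

    Samples in ``sample_universe`` with no qualifying record are wild-type
    (all-zero column). Records for samples outside the universe are dropped
    (count logged). Duplicate (gene, sample) records collapse to a single
    mutated status. Genes are sorted lexicographically.

    Parameters
    ----------
    variant_filter
        ``"default"`` keeps the non-silent classes, ``"all"`` keeps every
        record, otherwise an explicit set of Variant_Classification values.
    """
    cols = dict(MAF_COLUMNS)
    if column_map:
        cols.update(column_map)
    maf = pd.read_csv(maf_path, sep="\t", dtype=str, comment="#")
    missing = [c for c in cols.values() if c not in maf.columns]
    if missing:
        raise FormatError(f"MAF missing required column(s): {missing}")

    if variant_filter == "all":
        keep = maf
    else:
        classes = NON_SILENT_CLASSES if variant_filter == "default" else set(variant_filter)
        keep = maf[maf[cols["variant"]].isin(classes)]

    genes = keep[cols["gene"]].astype(str)
    samples = keep[cols["sample"]].astype(str)
    if (genes == "").any() or (samples == "").any():
        raise FormatError("empty gene symbol or sample barcode in MAF")

    universe = list(sample_universe)
    in_universe = samples.isin(set(universe))
    n_dropped = int((~in_universe).sum())
    if n_dropped:
        log.info("load_mutations: dropped %d record(s) outside sample universe", n_dropped)
    genes, samples = genes[in_universe], samples[in_universe]
    if len(genes) == 0:
        raise EmptyInputError(f"no parsable mutation records in {maf_path}")

    gene_order = sorted(set(genes))
    status = pd.DataFrame(0, index=gene_order, columns=universe, dtype=np.int8)
    gi = status.index.get_indexer(genes)
    si = status.columns.get_indexer(samples)
    status.values[gi, si] = 1
    return MutationMatrix(status)


def read_matrix(tsv_path: Union[str, Path], layer_kind: str) -> OmicsMatrix:
    """Read a feature × sample TSV; blank cells become missing values.

    Non-numeric cells and duplicate feature ids are format errors (reported
    with their location).
    """
    raw = pd.read_csv(tsv_path, sep="\t", index_col=0, dtype=str)
    if not raw.index.is_unique:
        dup = raw.index[raw.index.duplicated()][0]
        raise FormatError(f"{tsv_path}: duplicate feature id {dup!r}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna() & (raw.apply(lambda c: c.str.strip()) != "")
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{tsv_path}: non-numeric cell at feature {raw.index[r]!r}, "
            f"sample {raw.columns[c]!r}: {raw.iloc[r, c]!r}"
        )
    numeric.index = numeric.index.astype(str)
    numeric.columns = numeric.columns.astype(str)
    return OmicsMatrix(numeric, layer_kind=layer_kind, normalized=False)


def read_clinical(tsv_path: Union[str, Path], time_unit: str = "unspecified") -> ClinicalTable:
    """Read a clinical survival table with ``<ENDPOINT>_time/_event`` pairs.

    Only recognized endpoint pairs are loaded; other columns are ignored with
    a log line. Event values outside {0, 1, missing} and negative times are
    format errors.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    if "sample" not in df.columns:
        raise FormatError(f"{tsv_path}: missing 'sample' column")
    df = df.set_index("sample")
    df.index = df.index.astype(str)
    kept: dict[str, pd.Series] = {}
    for ep in ENDPOINTS:
        tc, ec = f"{ep}_time", f"{ep}_event"
        if tc in df.columns and ec in df.columns:
            kept[tc] = pd.to_numeric(df[tc], errors="raise")
            kept[ec] = pd.to_numeric(df[ec], errors="raise")
    ignored = [c for c in df.columns if c not in kept]
    if ignored:
        log.info("read_clinical: ignoring unrecognized column(s) %s", ignored)
    if not kept:
        raise EmptyInputError(f"{tsv_path}: no recognized endpoint column pairs")
    return ClinicalTable(pd.DataFrame(kept, index=df.index), time_unit=time_unit)


def read_gmt(path: Union[str, Path]) -> GeneSetCollection:
    """Read an MSigDB-dialect GMT file: name TAB description TAB member genes."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: expected >=3 tab-separated fields")
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if name in sets:
                raise FormatError(f"{path}: line {lineno}: duplicate set name {name!r}")
            if not genes:
                raise FormatError(f"{path}: line {lineno}: gene set {name!r} is empty")
            sets[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def read_signature_weights(path: Union[str, Path]) -> SignatureWeights:
    """Read a gene × signature weight TSV (first column ``gene``)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return SignatureWeights(df.astype(float))


def read_known_drivers(path: Union[str, Path]) -> set[str]:
    """Read a plain-text known-driver gene list, one symbol per line."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def assemble_cohort(
    name: str,
    mutations: MutationMatrix,
    layers: dict[str, OmicsMatrix],
    clinical: Optional[ClinicalTable] = None,
    samples: Optional[list[str]] = None,
) -> Cohort:
    """Build a :class:`Cohort`, verifying every component covers the same samples.

    The cohort sample order defaults to the mutation matrix order; components
    are reordered to it, and any set mismatch is an error.
    """
    if samples is None:
        samples = mutations.samples
    return Cohort(name=name, samples=list(samples), mutations=mutations,
                  layers=layers, clinical=clinical)


# ---------------------------------------------------------------------------
# cohort directory layout (as written by the simulator / consumed by the CLI)

LAYER_FILES = {
    "rna": ("rna.tsv", "rna"),
    "protein": ("protein.tsv", "protein"),
    "phospho": ("phospho.tsv", "phospho"),
    "immune": ("immune.tsv", "immune"),
    "pathway_rna": ("pathway_rna.tsv", "pathway"),
    "pathway_protein": ("pathway_protein.tsv", "pathway"),
    "pathway": ("pathway.tsv", "pathway"),
}


def load_cohort_dir(
    path: Union[str, Path],
    name: Optional[str] = None,
    variant_filter: Union[str, Iterable[str]] = "default",
) -> Cohort:
    """Load a cohort directory (``mutations.maf`` + layer TSVs + ``clinical.tsv``).

    The sample universe is taken from the first omics layer found; all other
    components must cover exactly the same samples.
    """
    path = Path(path)
    layers: dict[str, OmicsMatrix] = {}
    for key, (fname, kind) in LAYER_FILES.items():
        fp = path / fname
        if fp.exists():
            layers[key] = read_matrix(fp, layer_kind=kind)
    if not layers:
        raise EmptyInputError(f"{path}: no omics layer files found")
    samples = next(iter(layers.values())).samples
    maf = path / "mutations.maf"
    if not maf.exists():
        raise FormatError(f"{path}: missing mutations.maf")
    mutations = load_mutations(maf, samples, variant_filter=variant_filter)
    clinical = None
    if (path / "clinical.tsv").exists():
        clinical = read_clinical(path / "clinical.tsv")
    return assemble_cohort(name or path.name, mutations, layers, clinical, samples=samples)


# ---------------------------------------------------------------------------
# writers

def write_matrix(matrix: OmicsMatrix, path: Union[str, Path]) -> None:
    df = matrix.values.copy()
    df.index.name = "feature"
    df.to_csv(path, sep="\t")


def write_mutation_matrix(m: MutationMatrix, path: Union[str, Path]) -> None:
    df = m.status.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


def read_mutation_matrix(path: Union[str, Path]) -> MutationMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    return MutationMatrix(df)


def write_table(df: pd.DataFrame, path: Union[str, Path], parquet: bool = False) -> None:
    """Write a result table as TSV, optionally mirroring it as Parquet."""
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    if parquet:
        df.to_parquet(path.with_suffix(".parquet"), index=False)
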