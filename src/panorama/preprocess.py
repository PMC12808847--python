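"""Normalization, mutation-frequency filtering and derived score layers.

Feature-level Z-scoring follows the cohort convention: site-level for
phosphosites, gene-level for RNA and protein. Pathway activity layers are
derived by single-sample GSEA (ssGSEA) over gene-set collections; immune or
pathway layers may alternatively come from linear signature-weight scoring
or be supplied precomputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import (
    Cohort,
    EmptyInputError,
    GeneSetCollection,
    MutationMatrix,
    OmicsMatrix,
    SignatureWeights,
    ValidationError,
)

import logging

log = logging.getLogger("panorama")


def zscore_normalize(matrix: OmicsMatrix) -> tuple[OmicsMatrix, list[str]]:
    """Per-feature Z-score over non-missing entries (sample SD, ddof=1).

    Missing entries stay missing. Degenerate features — SD of 0 or fewer
    than two non-missing values — are set to all-zero and returned in the
    report list rather than raising.

    Returns
    -------
    (normalized matrix, list of degenerate feature ids)
    """
    if matrix.normalized:
        raise ValidationError("matrix is already normalized")
    vals = matrix.values.to_numpy(dtype=float)
    n = np.sum(~np.isnan(vals), axis=1)
    mean = np.nansum(vals, axis=1) / np.maximum(n, 1)
    sd = np.full(vals.shape[0], np.nan)
    ok = n >= 2
    if ok.any():
        sd[ok] = np.nanstd(vals[ok], axis=1, ddof=1)
    degenerate = (~ok) | (sd == 0)
    out = np.empty_like(vals)
    out[degenerate] = np.where(np.isnan(vals[degenerate]), np.nan, 0.0)
    good = ~degenerate
    out[good] = (vals[good] - mean[good, None]) / sd[good, None]
    report = [f for f, d in zip(matrix.features, degenerate) if d]
    norm = OmicsMatrix(
        pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns),
        layer_kind=matrix.layer_kind,
        normalized=True,
    )
    return norm, report


def normalize_cohort(cohort: Cohort) -> tuple[Cohort, dict[str, list[str]]]:
    """Z-score every not-yet-normalized layer of a cohort."""
    layers = {}
    reports: dict[str, list[str]] = {}
    for name, layer in cohort.layers.items():
        if layer.normalized:
            layers[name] = layer
        else:
            layers[name], reports[name] = zscore_normalize(layer)
    return cohort.with_layers(layers), reports


def filter_mutations_by_frequency(
    m: MutationMatrix, threshold: float = 0.05, inclusive: bool = True
) -> MutationMatrix:
    """Keep genes mutated in at least (``inclusive``) or more than ``threshold``
    of samples; gene order preserved. An empty result is valid (warned)."""
    if not 0 < threshold < 1:
        raise ValidationError("threshold must be in (0, 1)")
    freq = m.frequency
    keep = freq >= threshold if inclusive else freq > threshold
    if not keep.any():
        log.warning("filter_mutations_by_frequency: no gene passes %.3g", threshold)
    return MutationMatrix(m.status.loc[keep])


@dataclass
class SsgseaConfig:
    """ssGSEA parameters: rank-weight exponent and global range normalization.

    Defaults mirror the conventional single-sample GSEA settings
    (alpha = 0.25, scores divided by the global max − min).
    """

    alpha: float = 0.25
    normalize_range: bool = True

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValidationError("ssGSEA alpha must be >= 0")


def ssgsea_scores(
    matrix: OmicsMatrix, sets: GeneSetCollection, cfg: SsgseaConfig = SsgseaConfig()
) -> OmicsMatrix:
    """Single-sample gene-set enrichment scores (set × sample, kind=pathway).

    Per sample: features are ranked by value descending (ties broken by
    feature id ascending; missing values excluded from that sample's
    ranking). The enrichment score is the sum over rank positions of the
    difference between the weighted in-set ECDF (weights = rank^alpha,
    highest value has rank N, normalized to sum 1) and the uniform ECDF of
    the out-of-set features. A set covering every ranked feature scores 0.
    Sets with no overlap with the matrix are dropped with a warning; zero
    overlapping sets overall is an error.
    """
    features = np.asarray(matrix.features)
    feat_index = {f: i for i, f in enumerate(features)}
    usable: dict[str, np.ndarray] = {}
    for name, members in sets.sets.items():
        idx = np.array([feat_index[g] for g in members if g in feat_index], dtype=int)
        if idx.size == 0:
            log.warning("ssgsea_scores: set %r has no overlap with matrix; dropped", name)
            continue
        usable[name] = idx
    if not usable:
        raise EmptyInputError("no gene set overlaps the matrix features")

    # pre-sort rows lexicographically by feature id so that a stable argsort on
    # descending value breaks ties by id
    lex = np.argsort(features, kind="stable")
    vals = matrix.values.to_numpy(dtype=float)[lex]
    member_masks = {}
    for name, idx in usable.items():
        mask = np.zeros(len(features), dtype=bool)
        mask[idx] = True
        member_masks[name] = mask[lex]

    n_feat, n_samp = vals.shape
    scores = np.full((len(usable), n_samp), np.nan)
    set_names = list(usable)

    has_nan = np.isnan(vals).any()
    if not has_nan:
        order = np.argsort(-vals, axis=0, kind="stable")  # (F, S)
        n = n_feat
        w = (np.arange(n, 0, -1, dtype=float)) ** cfg.alpha  # rank N..1 by position
        for si, name in enumerate(set_names):
            ind = member_masks[name][order]  # (F, S) in rank order per sample
            k = int(member_masks[name].sum())
            if k == n:
                scores[si, :] = 0.0
                continue
            win = w[:, None] * ind
            p_in = np.cumsum(win, axis=0) / np.sum(win, axis=0, keepdims=True)
            p_out = np.cumsum(~ind, axis=0) / float(n - k)
            scores[si, :] = np.sum(p_in - p_out, axis=0)
    else:
        for j in range(n_samp):
            col = vals[:, j]
            valid = ~np.isnan(col)
            n = int(valid.sum())
            if n == 0:
                continue
            order = np.argsort(-col[valid], kind="stable")
            w = (np.arange(n, 0, -1, dtype=float)) ** cfg.alpha
            for si, name in enumerate(set_names):
                ind = member_masks[name][valid][order]
                k = int(ind.sum())
                if k == 0:
                    scores[si, j] = np.nan
                    continue
                if k == n:
                    scores[si, j] = 0.0
                    continue
                wsum = np.sum(w * ind)
                p_in = np.cumsum(w * ind) / wsum
                p_out = np.cumsum(~ind) / float(n - k)
                scores[si, j] = np.sum(p_in - p_out)

    if cfg.normalize_range:
        rng = np.nanmax(scores) - np.nanmin(scores)
        if rng > 0:
            scores = scores / rng

    return OmicsMatrix(
        pd.DataFrame(scores, index=set_names, columns=matrix.values.columns),
        layer_kind="pathway",
        normalized=False,
    )


def linear_signature_scores(
    matrix: OmicsMatrix, w: SignatureWeights, layer_kind: str = "pathway"
) -> tuple[OmicsMatrix, pd.Series]:
    """Weighted sums of Z-scored values per signature (coefficient scoring).

    ``score(sig, sample) = Σ_g weight(g, sig) · z(g, sample)`` over genes
    shared between the weight matrix and the input; missing values contribute
    0. Returns the score matrix and the per-signature count of genes used.
    """
    if not matrix.normalized:
        raise ValidationError("linear_signature_scores requires a normalized matrix")
    shared = [g for g in w.genes if g in set(matrix.features)]
    if not shared:
        raise EmptyInputError("no signature gene present in the matrix")
    ww = w.weights.loc[shared]  # genes × signatures
    xx = matrix.values.loc[shared].fillna(0.0)  # genes × samples
    scores = ww.T @ xx
    used = (ww != 0).sum(axis=0)
    used.name = "genes_used"
    return (
        OmicsMatrix(scores, layer_kind=layer_kind, normalized=False),
        used,
    )
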