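"""Normalization and feature-level summarization.

The pathway-level workflow expects peptidome/proteome intensities that have
been rolled up to protein level (geometric mean over a protein's peptides),
quantile normalised across samples and log2 transformed, in that order. The
factorization workflows additionally use per-feature standardization.
"""

from __future__ import annotations

import logging

import numpy as np

from .io import OmicsBlock, PeptideMap

logger = logging.getLogger("triomics")


def quantile_normalize(block: OmicsBlock) -> OmicsBlock:
    """Force every sample (column) to the same value distribution.

    The shared distribution is the across-sample mean of the order statistics;
    ties within a column receive the average of the tied order statistics
    (average-rank dialect). Idempotent up to floating point.
    """
    if block.n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    X = block.values
    ref = np.sort(X, axis=0).mean(axis=1)  # mean order statistics
    csum = np.concatenate([[0.0], np.cumsum(ref)])
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        vals = col[order]
        # tied runs share the mean of the reference over their rank span
        starts = np.concatenate([[0], np.where(np.diff(vals) != 0)[0] + 1,
                                 [vals.size]])
        assigned = np.empty_like(vals)
        for a, b in zip(starts[:-1], starts[1:]):
            assigned[a:b] = (csum[b] - csum[a]) / (b - a)
        out[order, j] = assigned
    return block.with_values(out)


def log2_transform(block: OmicsBlock, offset: float = 1.0,
                   force: bool = False) -> OmicsBlock:
    """Elementwise ``log2(value + offset)``; flips the scale flag to log2.

    A block already flagged log2 is returned unchanged (with a warning)
    unless ``force`` is set, in which case it is transformed again.
    """
    if offset < 0:
        raise ValueError("offset must be nonnegative")
    if block.scale == "log2" and not force:
        logger.warning("%s: already log2-scaled; returning unchanged "
                       "(use force=True to transform anyway)", block.omics_name)
        return block
    shifted = block.values + offset
    if np.any(shifted <= 0):
        bad = [block.feature_ids[i]
               for i in sorted(set(np.argwhere(shifted <= 0)[:, 0]))][:10]
        raise ValueError(f"nonpositive values after offset in features {bad}")
    return block.with_values(np.log2(shifted), scale="log2")


def summarize_peptides(block: OmicsBlock, pmap: PeptideMap) -> OmicsBlock:
    """Roll peptide rows up to one row per protein accession.

    On a linear-scale block the protein value is the geometric mean of its
    peptides per sample; on a log2 block the arithmetic mean of log2 values is
    used, which is the same quantity on the other scale. Peptides absent from
    the map are dropped (count logged). Output rows are sorted by accession.
    """
    groups: dict[str, list[int]] = {}
    for i, pep in enumerate(block.feature_ids):
        prot = pmap.protein_for(pep)
        if prot is not None:
            groups.setdefault(prot, []).append(i)
    n_unmapped = block.n_features - sum(len(v) for v in groups.values())
    if not groups:
        raise ValueError("no overlap between block features and peptide map")
    if n_unmapped:
        logger.info("%s: dropped %d peptides absent from the peptide map",
                    block.omics_name, n_unmapped)

    proteins = sorted(groups)
    out = np.empty((len(proteins), block.n_samples))
    if block.scale == "linear":
        if np.any(block.values <= 0):
            raise ValueError("geometric mean needs positive linear-scale values")
        logX = np.log(block.values)
        for r, prot in enumerate(proteins):
            out[r] = np.exp(logX[groups[prot]].mean(axis=0))
    else:
        for r, prot in enumerate(proteins):
            out[r] = block.values[groups[prot]].mean(axis=0)
    meta = dict(block.meta)
    meta["n_peptides_unmapped"] = n_unmapped
    return block.with_values(out, feature_ids=proteins, meta=meta)


def standardize(block: OmicsBlock) -> OmicsBlock:
    """Center each feature to mean 0 and scale to unit (population) variance.

    Features with variance below 1e-12 are left centered only; their ids are
    recorded under ``meta["constant_features"]``.
    """
    if block.n_samples < 2:
        raise ValueError("standardization needs at least 2 samples")
    X = block.values
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    flat = (sd[:, 0] ** 2) < 1e-12
    sd[flat] = 1.0
    meta = dict(block.meta)
    meta["constant_features"] = [block.feature_ids[i] for i in np.where(flat)[0]]
    return block.with_values((X - mu) / sd, meta=meta)
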