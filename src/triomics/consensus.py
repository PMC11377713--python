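"""Consensus feature selection across factorization methods.

From each method's chosen factor the top 5% of features by absolute weight
are taken per omics block; features selected by enough methods form the
consensus. If no feature reaches the required support the threshold is
relaxed one step at a time (recording the effective support used) - the
same pragmatic relaxation that lets miRNAs enter at two-of-three methods
when no miRNA is shared by all three. Selected peptides are then mapped to
proteins and miRNAs to their target genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import PeptideMap, TargetMap
from .jdr import Factorization


@dataclass
class ConsensusSelection:
    """Consensus for one omics block, with per-method provenance."""

    omics_name: str
    selected: list[str]
    support: dict[str, int]                 # feature -> number of methods
    effective_support: int
    per_method: dict[str, list[str]]        # method -> its top-fraction list
    fallback_used: bool = False
    mapped_proteins: list[str] | None = None
    mapped_genes: dict[str, list[str]] | None = None
    unmapped: list[str] = field(default_factory=list)


def top_fraction(feature_ids, weights, fraction: float = 0.05) -> list[str]:
    """Top ``ceil(fraction * p)`` features by |weight|.

    Stable sort by (|weight| descending, feature id ascending), so the
    selection is deterministic and invariant to positive rescaling of the
    weights.
    """
    ids = [str(f) for f in feature_ids]
    w = np.asarray(weights, dtype=float).ravel()
    if w.size == 0:
        raise ValueError("empty weight vector")
    if w.size != len(ids):
        raise ValueError("feature_ids and weights differ in length")
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    count = math.ceil(fraction * w.size)
    order = sorted(range(w.size), key=lambda i: (-abs(w[i]), ids[i]))
    return [ids[i] for i in order[:count]]


def consensus_select(per_method_sets: dict[str, set], required_support: int,
                     fallback: bool = True) -> tuple[set, int, dict]:
    """Features present in >= ``required_support`` method sets.

    If empty and ``fallback``, the support requirement is decremented (down
    to 2, then 1) until the selection is nonempty. Returns
    (selected set, effective support, per-feature support counts).
    """
    if not per_method_sets:
        raise ValueError("need at least one method set")
    counts: dict = {}
    for s in per_method_sets.values():
        for f in s:
            counts[f] = counts.get(f, 0) + 1
    support = min(required_support, len(per_method_sets))
    while True:
        sel = {f for f, c in counts.items() if c >= support}
        if sel or not fallback or support <= 1:
            return sel, support, counts
        support -= 1


def consensus_from_factorizations(
        factorizations: list[Factorization],
        chosen_factor: dict[str, int],
        fraction: float = 0.05,
        required_support: int | None = None,
        fallback: bool = True) -> dict[str, ConsensusSelection]:
    """Per-omics consensus over each method's chosen-factor weights.

    ``chosen_factor`` maps method name to the 1-based index of its better
    factor (from factor scoring). ``required_support`` defaults to the number
    of methods.
    """
    if not factorizations:
        raise ValueError("no factorizations")
    if required_support is None:
        required_support = len(factorizations)
    out: dict[str, ConsensusSelection] = {}
    omics = list(factorizations[0].W)
    for name in omics:
        per_method: dict[str, list[str]] = {}
        for fz in factorizations:
            j = chosen_factor[fz.method] - 1
            per_method[fz.method] = top_fraction(
                fz.feature_ids[name], fz.W[name][:, j], fraction)
        sel, eff, counts = consensus_select(
            {m: set(v) for m, v in per_method.items()}, required_support,
            fallback)
        out[name] = ConsensusSelection(
            omics_name=name, selected=sorted(sel),
            support={f: counts[f] for f in sorted(sel)},
            effective_support=eff, per_method=per_method,
            fallback_used=eff < min(required_support, len(factorizations)),
        )
    return out


def map_selection(selection: ConsensusSelection,
                  peptide_map: PeptideMap | None = None,
                  target_map: TargetMap | None = None) -> ConsensusSelection:
    """Complete a selection with protein accessions / target gene symbols.

    Peptide ids map to deduplicated protein accessions; miRNA ids map to the
    union of their target genes. Unmapped ids are listed, never fatal.
    """
    unmapped: list[str] = []
    if peptide_map is not None:
        prots: list[str] = []
        for pep in selection.selected:
            prot = peptide_map.protein_for(pep)
            if prot is None:
                unmapped.append(pep)
            else:
                prots.append(prot)
        selection.mapped_proteins = sorted(set(prots))
    if target_map is not None:
        genes: dict[str, list[str]] = {}
        for mir in selection.selected:
            if mir in target_map:
                genes[mir] = sorted(target_map.genes_for(mir))
            else:
                unmapped.append(mir)
        selection.mapped_genes = genes
    selection.unmapped = unmapped
    return selection


def selection_table(selections: dict[str, ConsensusSelection]) -> pd.DataFrame:
    """Long-format export: omics, feature, support, methods, mappings."""
    rows = []
    for name in sorted(selections):
        sel = selections[name]
        for f in sel.selected:
            methods = sorted(m for m, v in sel.per_method.items() if f in v)
            mapped = ""
            if sel.mapped_genes is not None and f in sel.mapped_genes:
                mapped = ";".join(sel.mapped_genes[f])
            rows.append({"omics": name, "feature_id": f,
                         "support": sel.support[f],
                         "methods": ";".join(methods),
                         "mapped": mapped,
                         "effective_support": sel.effective_support})
    return pd.DataFrame(rows, columns=["omics", "feature_id", "support",
                                       "methods", "mapped",
                                       "effective_support"])


def membership_matrix(selection: ConsensusSelection) -> pd.DataFrame:
    """0/1 feature x method membership matrix (UpSet-style input)."""
    feats = sorted({f for v in selection.per_method.values() for f in v})
    methods = sorted(selection.per_method)
    data = [[int(f in selection.per_method[m]) for m in methods] for f in feats]
    return pd.DataFrame(data, index=feats, columns=methods)
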