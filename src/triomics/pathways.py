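"""Pathway overrepresentation and miRNA->gene regulatory-link detection.

The pathway-level workflow: per omics a query gene set (significant genes;
for miRNAs, the targets of significant miRNAs) is tested against each
pathway with a one-sided hypergeometric test over the measured-gene
background. Pathways overrepresented in at least one omics are then scanned
for (miRNA, gene) pairs where the miRNA is significantly differentially
abundant, the gene is significant at peptidome (after protein rollup) or
proteome level, the gene is a recorded target of the miRNA, and the gene
belongs to a selected pathway. Each detected link carries a concordance
flag (same vs opposite direction of regulation).
"""

from __future__ import annotations

import pandas as pd
from scipy.stats import hypergeom

from .io import PathwayDB, PeptideMap, TargetMap


# ---------------------------------------------------------------------------
# overrepresentation
# ---------------------------------------------------------------------------

def ora(query: set, pathway_db: PathwayDB, background: set) -> pd.DataFrame:
    """One-sided hypergeometric overrepresentation per pathway.

    Pathway gene sets are intersected with the background first; pathways
    disjoint from the background are excluded. p = P(overlap >= observed)
    drawing |query| genes from the background.
    """
    query = set(query)
    background = set(background)
    if not background:
        raise ValueError("empty background")
    if not query:
        raise ValueError("empty query set")
    if not query <= background:
        raise ValueError("query must be a subset of the background")
    N, n = len(background), len(query)
    rows = []
    for pid in pathway_db:
        genes = pathway_db.genes(pid) & background
        if not genes:
            continue
        K = len(genes)
        k = len(query & genes)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"pathway_id": pid, "name": pathway_db.names[pid],
                     "pathway_size": K, "overlap": k, "query_size": n,
                     "background_size": N, "p_value": p})
    df = pd.DataFrame(rows, columns=["pathway_id", "name", "pathway_size",
                                     "overlap", "query_size",
                                     "background_size", "p_value"])
    return df.sort_values(["p_value", "pathway_id"]).reset_index(drop=True)


def _gene_sets_for_omics(de: pd.DataFrame, omics: str,
                         target_map: TargetMap | None,
                         peptide_map: PeptideMap | None,
                         protein_gene_map: dict | None) -> tuple[set, set]:
    """(query, background) gene sets for one omics DE table.

    miRNome: targets of significant miRNAs vs targets of all measured
    miRNAs. peptidome: features are protein accessions (post-rollup), mapped
    to genes through the peptide map. proteome: features mapped through
    ``protein_gene_map`` or taken as gene symbols directly.
    """
    sig = de.loc[de["significant"], "feature_id"]
    if omics == "miRNome":
        if target_map is None:
            raise ValueError("miRNome ORA needs a target map")
        bg = target_map.union_targets(de["feature_id"])
        q = target_map.union_targets(sig)
        return q, bg
    if omics == "peptidome" and peptide_map is not None:
        acc2gene = peptide_map.accession_gene_map()
        bg = {acc2gene[a] for a in de["feature_id"] if a in acc2gene}
        q = {acc2gene[a] for a in sig if a in acc2gene}
        return q, bg
    gmap = protein_gene_map or {}
    bg = {gmap.get(f, f) for f in de["feature_id"]}
    q = {gmap.get(f, f) for f in sig}
    return q, bg


def overrepresented_pathways(de_tables: dict[str, pd.DataFrame],
                             pathway_db: PathwayDB,
                             target_map: TargetMap | None = None,
                             peptide_map: PeptideMap | None = None,
                             protein_gene_map: dict | None = None,
                             alpha: float = 0.05
                             ) -> tuple[set, dict[str, pd.DataFrame]]:
    """Pathways with hypergeometric p < alpha in at least one omics.

    Omics with no significant features contribute nothing (their query is
    empty, so ORA is skipped for them). Returns the selected pathway id set
    and the per-omics enrichment tables.
    """
    selected: set = set()
    tables: dict[str, pd.DataFrame] = {}
    for omics in sorted(de_tables):
        de = de_tables[omics]
        q, bg = _gene_sets_for_omics(de, omics, target_map, peptide_map,
                                     protein_gene_map)
        if not q or not bg:
            continue
        table = ora(q, pathway_db, bg)
        tables[omics] = table
        selected |= set(table.loc[table["p_value"] < alpha, "pathway_id"])
    return selected, tables


# ---------------------------------------------------------------------------
# link detection
# ---------------------------------------------------------------------------

def _gene_stats(de_tables: dict[str, pd.DataFrame],
                peptide_map: PeptideMap | None,
                protein_gene_map: dict | None) -> dict[str, dict]:
    """gene -> {log2fc, p, source} for significant peptidome/proteome genes.

    When a gene is significant in both layers the proteome statistics are
    reported (direct protein measurement) and the evidence source is "both".
    """
    out: dict[str, dict] = {}
    if "peptidome" in de_tables:
        de = de_tables["peptidome"]
        acc2gene = peptide_map.accession_gene_map() if peptide_map else {}
        for row in de[de["significant"]].itertuples(index=False):
            gene = acc2gene.get(row.feature_id, row.feature_id)
            out[gene] = {"log2fc": row.log2fc, "p": row.p_value,
                         "source": "peptidome"}
    if "proteome" in de_tables:
        de = de_tables["proteome"]
        gmap = protein_gene_map or {}
        for row in de[de["significant"]].itertuples(index=False):
            gene = gmap.get(row.feature_id, row.feature_id)
            if gene in out:
                out[gene] = {"log2fc": row.log2fc, "p": row.p_value,
                             "source": "both"}
            else:
                out[gene] = {"log2fc": row.log2fc, "p": row.p_value,
                             "source": "proteome"}
    return out


def detect_links(de_tables: dict[str, pd.DataFrame],
                 target_map: TargetMap,
                 peptide_map: PeptideMap | None = None,
                 selected_pathways: set | None = None,
                 pathway_db: PathwayDB | None = None,
                 protein_gene_map: dict | None = None,
                 require_pathway: bool = True) -> pd.DataFrame:
    """All (miRNA, gene) pairs satisfying the four link predicates.

    miRNA significant; gene significant at peptidome or proteome level; the
    gene is a recorded target of the miRNA; and (if ``require_pathway``) the
    gene belongs to at least one selected pathway. ``concordant`` is True
    when miRNA and gene move in the same direction.
    """
    if "miRNome" not in de_tables:
        raise ValueError("miRNome DE table required")
    if require_pathway and (selected_pathways is None or pathway_db is None):
        raise ValueError("pathway filtering needs selected_pathways and pathway_db")

    gene_stats = _gene_stats(de_tables, peptide_map, protein_gene_map)
    mir_de = de_tables["miRNome"]
    sig_mirs = mir_de[mir_de["significant"]]

    membership: dict[str, list[str]] = {}
    if require_pathway:
        for pid in sorted(selected_pathways):
            for g in pathway_db.genes(pid):
                membership.setdefault(g, []).append(pid)

    rows = []
    for mrow in sig_mirs.itertuples(index=False):
        for gene in sorted(target_map.genes_for(mrow.feature_id)):
            if gene not in gene_stats:
                continue
            if require_pathway:
                pids = membership.get(gene)
                if not pids:
                    continue
            else:
                pids = sorted(p for p in (pathway_db or PathwayDB({}, {}))
                              if gene in pathway_db.genes(p)) if pathway_db else []
            gs = gene_stats[gene]
            rows.append({
                "mirna": mrow.feature_id, "gene": gene,
                "pathways": ";".join(pids),
                "mirna_log2fc": mrow.log2fc, "mirna_p": mrow.p_value,
                "gene_log2fc": gs["log2fc"], "gene_p": gs["p"],
                "gene_source": gs["source"],
                "concordant": bool(mrow.log2fc * gs["log2fc"] > 0),
            })
    cols = ["mirna", "gene", "pathways", "mirna_log2fc", "mirna_p",
            "gene_log2fc", "gene_p", "gene_source", "concordant"]
    return pd.DataFrame(rows, columns=cols).sort_values(
        ["mirna", "gene"]).reset_index(drop=True)


def extend_pathway(pathway_genes: set, target_map: TargetMap
                   ) -> list[tuple[str, str]]:
    """miRNA->gene edges restricted to genes inside one pathway."""
    edges = []
    for mir in sorted(target_map.targets):
        for gene in sorted(target_map.genes_for(mir) & set(pathway_genes)):
            edges.append((mir, gene))
    return edges


def pathway_link_analysis(de_tables: dict[str, pd.DataFrame],
                          pathway_db: PathwayDB,
                          target_map: TargetMap,
                          peptide_map: PeptideMap | None = None,
                          protein_gene_map: dict | None = None,
                          alpha: float = 0.05,
                          mode: str = "and") -> dict:
    """Full pathway-level workflow.

    ``mode="and"`` (default): links are confined to overrepresented
    pathways. ``mode="or"``: a pathway qualifies if it is overrepresented
    or contains a significant gene / a target of a significant miRNA, and
    links are confined to that wider set.
    """
    selected, tables = overrepresented_pathways(
        de_tables, pathway_db, target_map, peptide_map, protein_gene_map,
        alpha)
    if mode == "or":
        extra = set()
        for omics in sorted(de_tables):
            q, _ = _gene_sets_for_omics(de_tables[omics], omics, target_map,
                                        peptide_map, protein_gene_map)
            for pid in pathway_db:
                if q & pathway_db.genes(pid):
                    extra.add(pid)
        selected = selected | extra
    elif mode != "and":
        raise ValueError(f"unknown mode {mode!r}")

    links = detect_links(de_tables, target_map, peptide_map, selected,
                         pathway_db, protein_gene_map)
    linked = {pid for row in links.itertuples(index=False)
              for pid in row.pathways.split(";") if pid}
    extended = {pid: extend_pathway(pathway_db.genes(pid), target_map)
                for pid in sorted(linked)}
    return {"selected_pathways": selected, "enrichment": tables,
            "links": links, "linked_pathways": sorted(linked),
            "extended_edges": extended}
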