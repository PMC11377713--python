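"""Pipeline orchestration: one config, three workflows, reproducible outputs.

``run(config)`` executes simulate/load -> preprocess -> the enabled
workflows (factorization + factor scoring + consensus; multi-block sPLS-DA
+ similarity network; differential abundance + pathway links) and writes
every stage's tables plus a JSON run report. Every output file starts with
a comment line carrying the seed and a hash of the configuration, and two
runs with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .consensus import (consensus_from_factorizations, map_selection,
                        membership_matrix, selection_table)
from .diffexpr import differential_expression
from .factor_eval import scores_table, select_best
from .io import (MultiOmicsSet, PathwayDB, PeptideMap, TargetMap,
                 match_samples, read_annotation, read_block, read_gmt,
                 read_peptide_map, read_target_map, write_annotation,
                 write_block, write_gmt, write_peptide_map, write_target_map)
from .jdr import run_all, save_factorization
from .pathways import pathway_link_analysis
from .preprocess import log2_transform, quantile_normalize, summarize_peptides
from .simulate import SimConfig, simulate_knowledge, simulate_multiomics
from .splsda import (assemble_network, cross_block_similarity,
                     explained_variance, fit_block_splsda)

logger = logging.getLogger("triomics")

WORKFLOWS = ("jdr", "splsda", "pathway")

#: default keepX schedule: 50 features on component 1, 20 (miRNome) or
#: 10 (other blocks) on component 2, all features afterwards.
DEFAULT_KEEPX = {"component1": 50, "component2_mirna": 20, "component2_other": 10}


@dataclass
class RunConfig:
    """Everything a run needs; either ``simulate`` or ``inputs`` must be set."""

    outdir: str = "triomics_run"
    seed: int = 0
    workflows: tuple[str, ...] = ("jdr", "splsda", "pathway")
    simulate: SimConfig | None = None
    inputs: dict | None = None          # paths: blocks{name:path}, annotation,
                                        # gmt, target_map, peptide_map
    k: int = 2
    methods: tuple[str, ...] = ("jnmf", "mfa", "jica")
    n_runs: int = 1000
    fraction: float = 0.05
    required_support: int | None = None
    alpha: float = 0.05
    ncomp: int = 5
    keepX: dict | None = None
    similarity_threshold: float = 0.80
    design_weight: float = 1.0
    splsda_blocks: tuple[str, ...] | None = None
    pathway_mode: str = "and"
    log2_offset: float = 1.0

    def validate(self) -> None:
        if not self.workflows:
            raise ValueError("no workflow enabled")
        unknown = [w for w in self.workflows if w not in WORKFLOWS]
        if unknown:
            raise ValueError(f"unknown workflow(s): {unknown}")
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("exactly one of simulate/inputs must be set")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        # the output location is not a scientific parameter: runs of the
        # same configuration hash identically wherever they are written
        d = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        sim = raw.pop("simulate", None)
        cfg = cls(**{k: v for k, v in raw.items()
                     if k in {f.name for f in dataclasses.fields(cls)}})
        if sim is not None:
            sim_fields = {f.name for f in dataclasses.fields(SimConfig)}
            cfg.simulate = SimConfig(**{k: v for k, v in (sim or {}).items()
                                        if k in sim_fields})
        for name in ("workflows", "methods"):
            v = getattr(cfg, name)
            if isinstance(v, list):
                setattr(cfg, name, tuple(v))
        return cfg


# ---------------------------------------------------------------------------
# deterministic writers
# ---------------------------------------------------------------------------

def _header(config: RunConfig) -> str:
    return f"# seed={config.seed} config={config.config_hash()}\n"


def _write_df(df: pd.DataFrame, path: Path, config: RunConfig,
              index: bool = False, index_label: str | None = None) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, sep="\t", float_format="%.10g", index=index,
                  index_label=index_label)


# ---------------------------------------------------------------------------
# data acquisition
# ---------------------------------------------------------------------------

def _acquire(config: RunConfig, outdir: Path):
    """Simulate or load; returns (mset, pathway_db, target_map, peptide_map,
    truth-or-None)."""
    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate, seed=config.seed)
        mset, truth = simulate_multiomics(sim)
        pdb, tmap, pmap = simulate_knowledge(truth, sim)
        ddir = outdir / "data"
        ddir.mkdir(parents=True, exist_ok=True)
        for b in mset.blocks:
            write_block(b, ddir / f"{b.omics_name}.tsv")
        write_annotation(mset.labels, ddir / "annotation.tsv")
        write_gmt(pdb, ddir / "pathways.gmt")
        write_target_map(tmap, ddir / "target_map.tsv")
        write_peptide_map(pmap, ddir / "peptide_map.tsv")
        return mset, pdb, tmap, pmap, truth
    paths = config.inputs or {}
    blocks = [read_block(p, omics_name=name,
                         scale=paths.get("scales", {}).get(name, "linear"))
              for name, p in sorted(paths.get("blocks", {}).items())]
    annotation = read_annotation(paths["annotation"])
    mset = match_samples(blocks, annotation)
    pdb = read_gmt(paths["gmt"]) if "gmt" in paths else None
    tmap = read_target_map(paths["target_map"]) if "target_map" in paths else None
    pmap = read_peptide_map(paths["peptide_map"]) if "peptide_map" in paths else None
    return mset, pdb, tmap, pmap, None


# ---------------------------------------------------------------------------
# workflows
# ---------------------------------------------------------------------------

def run_jdr_workflow(config: RunConfig, mset: MultiOmicsSet, outdir: Path,
                     tmap: TargetMap | None, pmap: PeptideMap | None) -> dict:
    wdir = outdir / "jdr"
    fzs = run_all(mset, k=config.k, methods=config.methods, seed=config.seed)
    for fz in fzs:
        save_factorization(fz, wdir, header=_header(config))
    labels = [mset.labels.groups[s] for s in mset.sample_ids]
    scores, chosen = select_best(fzs, labels, n_runs=config.n_runs,
                                 seed=config.seed)
    _write_df(scores_table(scores), wdir / "factor_scores.tsv", config)

    chosen_factor = {c.method: c.factor_index for c in chosen}
    usable = [fz for fz in fzs if fz.method in chosen_factor]
    selections = consensus_from_factorizations(
        usable, chosen_factor, fraction=config.fraction,
        required_support=config.required_support)
    for name, sel in selections.items():
        if name == "miRNome" and tmap is not None:
            map_selection(sel, target_map=tmap)
        elif name == "peptidome" and pmap is not None:
            map_selection(sel, peptide_map=pmap)
        _write_df(membership_matrix(sel), wdir / f"membership_{name}.tsv",
                  config, index=True, index_label="feature_id")
    _write_df(selection_table(selections), wdir / "consensus.tsv", config)

    return {
        "best_method": chosen[0].method if chosen else None,
        "best_factor_accuracy": chosen[0].mean_accuracy if chosen else None,
        "chosen_factors": {c.method: c.factor_index for c in chosen},
        "method_accuracies": {c.method: c.mean_accuracy for c in chosen},
        "consensus_sizes": {n: len(s.selected)
                            for n, s in sorted(selections.items())},
        "consensus_effective_support": {n: s.effective_support
                                        for n, s in sorted(selections.items())},
    }


def run_splsda_workflow(config: RunConfig, mset: MultiOmicsSet, outdir: Path,
                        tmap: TargetMap | None, pmap: PeptideMap | None) -> dict:
    wdir = outdir / "splsda"
    names = list(config.splsda_blocks) if config.splsda_blocks \
        else mset.block_names[:2]
    sub = MultiOmicsSet([mset.block(n) for n in names], mset.labels)
    n = len(sub.sample_ids)
    ncomp = min(config.ncomp, n - 1)

    keepX = config.keepX
    if keepX is None:
        keepX = {}
        for b in sub.blocks:
            c2 = DEFAULT_KEEPX["component2_mirna"] if b.omics_name == "miRNome" \
                else DEFAULT_KEEPX["component2_other"]
            keepX[b.omics_name] = [min(DEFAULT_KEEPX["component1"], b.n_features),
                                   min(c2, b.n_features)] + [None] * (ncomp - 2)

    model = fit_block_splsda(sub, ncomp=ncomp, keepX=keepX,
                             design_weight=config.design_weight)
    for name in model.block_names:
        _write_df(pd.DataFrame(model.loadings[name],
                               index=model.feature_ids[name],
                               columns=[f"comp{h+1}" for h in range(ncomp)]),
                  wdir / f"loadings_{name}.tsv", config, index=True,
                  index_label="feature_id")
        _write_df(pd.DataFrame(model.scores[name], index=model.sample_ids,
                               columns=[f"comp{h+1}" for h in range(ncomp)]),
                  wdir / f"scores_{name}.tsv", config, index=True,
                  index_label="sample_id")
    _write_df(explained_variance(model), wdir / "explained_variance.tsv", config)

    edges = cross_block_similarity(model, ncomp_used=min(2, ncomp),
                                   threshold=config.similarity_threshold)
    edge_df = pd.DataFrame(
        [{"feature_i": e.feature_i, "block_i": e.block_i,
          "feature_j": e.feature_j, "block_j": e.block_j,
          "similarity": e.similarity} for e in edges],
        columns=["feature_i", "block_i", "feature_j", "block_j", "similarity"])
    _write_df(edge_df, wdir / "similarity_edges.tsv", config)
    network = assemble_network(edges, target_map=tmap, peptide_map=pmap)
    _write_df(network, wdir / "network_edges.tsv", config)
    return {"splsda_blocks": names, "ncomp": ncomp,
            "n_similarity_edges": len(edges),
            "n_network_edges": int(network.shape[0])}


def run_pathway_workflow(config: RunConfig, mset: MultiOmicsSet, outdir: Path,
                         pdb: PathwayDB | None, tmap: TargetMap | None,
                         pmap: PeptideMap | None) -> dict:
    if pdb is None or tmap is None:
        raise ValueError("pathway workflow needs a pathway database and target map")
    wdir = outdir / "pathway"
    labels = mset.labels.groups
    de_tables = {}
    for b in mset.blocks:
        blk = b
        if b.omics_name == "peptidome" and pmap is not None:
            blk = summarize_peptides(blk, pmap)
        if blk.scale == "linear":
            blk = quantile_normalize(blk)
            blk = log2_transform(blk, offset=config.log2_offset)
        de = differential_expression(blk, labels, alpha=config.alpha)
        de_tables[b.omics_name] = de
        _write_df(de, wdir / f"de_{b.omics_name}.tsv", config)

    result = pathway_link_analysis(de_tables, pdb, tmap, peptide_map=pmap,
                                   alpha=config.alpha, mode=config.pathway_mode)
    for omics, table in sorted(result["enrichment"].items()):
        _write_df(table, wdir / f"enrichment_{omics}.tsv", config)
    _write_df(result["links"], wdir / "links.tsv", config)
    ext_rows = [{"pathway_id": pid, "source": m, "target": g,
                 "edge_type": "mirna_target"}
                for pid, edges in sorted(result["extended_edges"].items())
                for m, g in edges]
    _write_df(pd.DataFrame(ext_rows, columns=["pathway_id", "source",
                                              "target", "edge_type"]),
              wdir / "extended_edges.tsv", config)
    return {
        "n_pathways_tested": len(pdb),
        "n_overrepresented": len(result["selected_pathways"]),
        "overrepresented": sorted(result["selected_pathways"]),
        "n_links": int(result["links"].shape[0]),
        "n_significant": {n: int(t["significant"].sum())
                          for n, t in sorted(de_tables.items())},
    }


def run(config: RunConfig) -> dict:
    """Execute the enabled workflows; returns (and writes) the run report."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mset, pdb, tmap, pmap, truth = _acquire(config, outdir)

    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "parameters": {k: v for k, v in config.to_dict().items()
                       if k != "outdir"},
        "n_samples": len(mset.sample_ids),
        "blocks": {b.omics_name: b.n_features for b in mset.blocks},
    }
    try:
        if "jdr" in config.workflows:
            report["jdr"] = run_jdr_workflow(config, mset, outdir, tmap, pmap)
        if "splsda" in config.workflows:
            report["splsda"] = run_splsda_workflow(config, mset, outdir,
                                                   tmap, pmap)
        if "pathway" in config.workflows:
            report["pathway"] = run_pathway_workflow(config, mset, outdir,
                                                     pdb, tmap, pmap)
    except Exception as exc:
        (outdir / "report.json").write_text(
            json.dumps(report, sort_keys=True, indent=1, default=str) + "\n")
        raise RuntimeError(f"workflow failed: {exc}") from exc

    (outdir / "report.json").write_text(
        json.dumps(report, sort_keys=True, indent=1, default=str) + "\n")
    return report
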