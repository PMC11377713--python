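"""Reading, writing and sample alignment for multi-omics abundance data.

The pipeline works on feature-by-sample abundance matrices (one per omics
layer: miRNome, peptidome, proteome), a two-level clinical annotation, and
three knowledge tables: pathway gene sets (GMT), a miRNA->target-gene table
(miRTarBase-style TSV) and a peptide->protein mapping table.

All tabular formats are plain delimited text so that synthetic and real data
flow through identical code paths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("triomics")

#: Cell contents treated as missing in abundance matrices.
MISSING_TOKENS = ("", "NA", "NaN", "nan", "N/A", "NULL", "null")

OMICS_NAMES = ("miRNome", "peptidome", "proteome", "custom")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class OmicsBlock:
    """One omics layer: a real-valued feature x sample abundance matrix.

    ``scale`` records whether values are raw ("linear") or log2 intensities;
    several operations (peptide rollup, differential abundance) are only
    meaningful on one of the two scales and check the flag.
    """

    omics_name: str
    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale: str = "linear"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        for kind, ids in (("feature", self.feature_ids), ("sample", self.sample_ids)):
            dup = _duplicates(ids)
            if dup:
                raise ValueError(f"duplicate {kind} ids: {sorted(dup)}")
        if not np.all(np.isfinite(self.values)):
            bad = [self.feature_ids[i] for i in
                   sorted(set(np.argwhere(~np.isfinite(self.values))[:, 0]))][:10]
            raise ValueError(f"non-finite values in features {bad}")
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids,
                            columns=self.sample_ids)

    def with_values(self, values: np.ndarray, *, scale: str | None = None,
                    feature_ids: list[str] | None = None,
                    meta: dict | None = None) -> "OmicsBlock":
        """Copy of the block with replaced values (and optionally ids/scale)."""
        return OmicsBlock(
            omics_name=self.omics_name,
            feature_ids=list(self.feature_ids if feature_ids is None else feature_ids),
            sample_ids=list(self.sample_ids),
            values=np.array(values, dtype=float),
            scale=self.scale if scale is None else scale,
            meta=dict(self.meta if meta is None else meta),
        )

    def subset_samples(self, sample_ids: list[str]) -> "OmicsBlock":
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise KeyError(f"samples not in block {self.omics_name}: {missing}")
        cols = [idx[s] for s in sample_ids]
        return OmicsBlock(self.omics_name, list(self.feature_ids),
                          list(sample_ids), self.values[:, cols],
                          self.scale, dict(self.meta))


@dataclass
class SampleAnnotation:
    """Mapping sample id -> group label with exactly two label levels."""

    groups: dict[str, str]

    def __post_init__(self) -> None:
        self.groups = {str(k): str(v) for k, v in self.groups.items()}
        if len(self.levels) != 2:
            raise ValueError(
                f"annotation must have exactly two group levels, got {self.levels}"
            )

    @property
    def levels(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.groups.values())))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.groups)

    def restrict(self, sample_ids: list[str]) -> "SampleAnnotation":
        missing = [s for s in sample_ids if s not in self.groups]
        if missing:
            raise KeyError(f"samples missing from annotation: {missing}")
        return SampleAnnotation({s: self.groups[s] for s in sample_ids})

    def binary(self, sample_ids: list[str]) -> np.ndarray:
        """0/1 vector, 1 for the lexicographically second level."""
        second = self.levels[1]
        return np.array([1 if self.groups[s] == second else 0
                         for s in sample_ids], dtype=int)


@dataclass
class MultiOmicsSet:
    """Ordered omics blocks sharing an identical, aligned sample list."""

    blocks: list[OmicsBlock]
    labels: SampleAnnotation

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("at least one block required")
        ref = self.blocks[0].sample_ids
        for b in self.blocks[1:]:
            if b.sample_ids != ref:
                raise ValueError(
                    f"block {b.omics_name} sample ids differ from {self.blocks[0].omics_name}"
                )
        if set(self.labels.groups) != set(ref):
            raise ValueError("annotation does not cover exactly the aligned samples")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.blocks[0].sample_ids)

    @property
    def block_names(self) -> list[str]:
        return [b.omics_name for b in self.blocks]

    def block(self, name: str) -> OmicsBlock:
        for b in self.blocks:
            if b.omics_name == name:
                return b
        raise KeyError(f"no block named {name!r}")

    def y(self) -> np.ndarray:
        return self.labels.binary(self.sample_ids)


@dataclass
class PathwayDB:
    """Pathway id -> (display name, set of member gene symbols)."""

    names: dict[str, str]
    gene_sets: dict[str, set[str]]

    def __post_init__(self) -> None:
        if set(self.names) != set(self.gene_sets):
            raise ValueError("names and gene_sets must share keys")
        for pid, genes in self.gene_sets.items():
            if not genes:
                raise ValueError(f"pathway {pid} has an empty gene set")

    def __len__(self) -> int:
        return len(self.gene_sets)

    def __iter__(self):
        return iter(sorted(self.gene_sets))

    def genes(self, pathway_id: str) -> set[str]:
        return self.gene_sets[pathway_id]

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for g in self.gene_sets.values():
            out |= g
        return out


@dataclass
class TargetMap:
    """miRNA id -> set of target gene symbols (miRTarBase-style)."""

    targets: dict[str, set[str]]

    def __post_init__(self) -> None:
        for mir, genes in self.targets.items():
            if not mir:
                raise ValueError("empty miRNA id")
            if not genes:
                raise ValueError(f"miRNA {mir} has an empty target set")

    def __contains__(self, mirna: str) -> bool:
        return mirna in self.targets

    def genes_for(self, mirna: str) -> set[str]:
        return self.targets.get(mirna, set())

    def union_targets(self, mirnas) -> set[str]:
        out: set[str] = set()
        for m in mirnas:
            out |= self.genes_for(m)
        return out


@dataclass
class PeptideEntry:
    protein: str
    gene: str
    sequence: str | None = None
    alternates: tuple[str, ...] = ()


@dataclass
class PeptideMap:
    """Peptide id -> (primary protein accession, gene symbol, optional sequence)."""

    entries: dict[str, PeptideEntry]

    def __post_init__(self) -> None:
        for pep, e in self.entries.items():
            if not e.protein:
                raise ValueError(f"peptide {pep} maps to an empty accession")

    def __contains__(self, peptide: str) -> bool:
        return peptide in self.entries

    def protein_for(self, peptide: str) -> str | None:
        e = self.entries.get(peptide)
        return e.protein if e else None

    def accession_gene_map(self) -> dict[str, str]:
        """Protein accession -> gene symbol (first gene seen wins, ids sorted)."""
        out: dict[str, str] = {}
        for pep in sorted(self.entries):
            e = self.entries[pep]
            out.setdefault(e.protein, e.gene)
        return out


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _duplicates(ids) -> set:
    seen, dup = set(), set()
    for i in ids:
        if i in seen:
            dup.add(i)
        seen.add(i)
    return dup


def primary_accession(feature_id: str, policy: str = "first") -> str | list[str]:
    """Split a multi-accession id like ``"P55285; Q9Y6N8; Q9ULB4"``.

    ``policy="first"`` keeps the first accession (the default downstream
    behaviour, matching the convention of keeping one representative per
    co-measured protein group); ``"all"`` returns the full list.
    """
    parts = [p.strip() for p in str(feature_id).split(";") if p.strip()]
    if not parts:
        raise ValueError(f"empty accession in {feature_id!r}")
    if policy == "first":
        return parts[0]
    if policy == "all":
        return parts
    raise ValueError(f"unknown accession policy {policy!r}")


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


# ---------------------------------------------------------------------------
# abundance matrices
# ---------------------------------------------------------------------------

def read_block(path, omics_name: str = "custom", *,
               scale: str = "linear",
               max_missing_fraction: float = 0.2,
               impute: str = "feature_min",
               missing_tokens=MISSING_TOKENS,
               accession_policy: str | None = None) -> OmicsBlock:
    """Read a feature x sample abundance matrix from delimited text.

    First column holds feature ids, the header row sample ids. Features with
    more than ``max_missing_fraction`` missing cells are dropped; remaining
    missing cells are imputed (default: the feature's observed minimum).
    Non-numeric cells beyond the missing tokens are a hard error reported with
    their feature/sample position.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str,
                      keep_default_na=False)
    dup = _duplicates(raw.index.tolist())
    if dup:
        raise ValueError(f"{path}: duplicate feature id(s) {sorted(dup)}")
    dup = _duplicates(raw.columns.tolist())
    if dup:
        raise ValueError(f"{path}: duplicate sample id(s) {sorted(dup)}")

    miss = raw.isin(set(missing_tokens))
    num = raw.mask(miss).apply(pd.to_numeric, errors="coerce")
    bad = num.isna() & ~miss
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric cell {raw.iat[i, j]!r} at feature "
            f"{raw.index[i]!r}, sample {raw.columns[j]!r}"
        )

    frac = miss.mean(axis=1)
    keep = frac <= max_missing_fraction
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("%s: dropped %d features with >%d%% missing values",
                    path.name, n_dropped, int(100 * max_missing_fraction))
    num = num.loc[keep]

    if num.isna().to_numpy().any():
        if impute == "feature_min":
            fill = num.min(axis=1)
        elif impute == "feature_mean":
            fill = num.mean(axis=1)
        else:
            try:
                fill = pd.Series(float(impute), index=num.index)
            except (TypeError, ValueError):
                raise ValueError(f"unknown imputation policy {impute!r}") from None
        num = num.apply(lambda row: row.fillna(fill[row.name]), axis=1)
        if num.isna().to_numpy().any():
            empty = num.index[num.isna().any(axis=1)].tolist()
            raise ValueError(f"{path}: features with no observed values: {empty}")

    feature_ids = [str(f) for f in num.index]
    if accession_policy == "first":
        feature_ids = [primary_accession(f, "first") for f in feature_ids]
        dup = _duplicates(feature_ids)
        if dup:
            raise ValueError(
                f"{path}: accession policy 'first' produced duplicate ids {sorted(dup)}"
            )
    return OmicsBlock(omics_name, feature_ids, [str(s) for s in num.columns],
                      num.to_numpy(dtype=float), scale,
                      meta={"n_features_dropped_missing": n_dropped})


def write_block(block: OmicsBlock, path, float_format: str = "%.12g") -> None:
    path = Path(path)
    df = block.to_frame()
    df.index.name = "feature_id"
    df.to_csv(path, sep=_sep_for(path), float_format=float_format)


# ---------------------------------------------------------------------------
# sample matching
# ---------------------------------------------------------------------------

def match_samples(blocks: list[OmicsBlock],
                  annotation: SampleAnnotation) -> MultiOmicsSet:
    """Align blocks on the sorted intersection of annotated sample ids.

    The shared ordering is the lexicographic sort of the intersection, which
    makes the result independent of input block order. Per-block sample counts
    before/after are logged.
    """
    if not blocks:
        raise ValueError("at least one block required")
    shared = set(blocks[0].sample_ids)
    for b in blocks[1:]:
        shared &= set(b.sample_ids)
    shared &= set(annotation.groups)
    if not shared:
        raise ValueError("no samples shared by all blocks and the annotation")
    order = sorted(shared)
    for b in blocks:
        logger.info("match_samples: %s %d -> %d samples",
                    b.omics_name, b.n_samples, len(order))
    matched = [b.subset_samples(order) for b in blocks]
    return MultiOmicsSet(matched, annotation.restrict(order))


def read_annotation(path, sample_col: str = "sample_id",
                    group_col: str = "group") -> SampleAnnotation:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    for col in (sample_col, group_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return SampleAnnotation(dict(zip(df[sample_col], df[group_col])))


def write_annotation(annotation: SampleAnnotation, path) -> None:
    df = pd.DataFrame({"sample_id": list(annotation.groups),
                       "group": list(annotation.groups.values())})
    df.to_csv(Path(path), sep=_sep_for(path), index=False)


# ---------------------------------------------------------------------------
# knowledge tables
# ---------------------------------------------------------------------------

def read_gmt(path) -> PathwayDB:
    """Read gene sets from standard GMT (id, description, genes...)."""
    names: dict[str, str] = {}
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs id, "
                                 f"description and at least one gene")
            pid = parts[0].strip()
            if pid in sets:
                raise ValueError(f"{path}:{lineno}: duplicate pathway id {pid!r}")
            genes = {g.strip() for g in parts[2:] if g.strip()}
            if not genes:
                raise ValueError(f"{path}:{lineno}: pathway {pid!r} has no genes")
            names[pid] = parts[1].strip()
            sets[pid] = genes
    return PathwayDB(names, sets)


def write_gmt(db: PathwayDB, path) -> None:
    with open(path, "w") as fh:
        for pid in db:
            genes = "\t".join(sorted(db.gene_sets[pid]))
            fh.write(f"{pid}\t{db.names[pid]}\t{genes}\n")


def read_target_map(path) -> TargetMap:
    """Read a miRNA->target TSV.

    Accepts both the plain dialect (columns ``miRNA``, ``target_gene``) and
    the miRTarBase hsa_MTI export dialect (``miRNA``, ``Target Gene``).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    cols = {c.lower().replace(" ", "_"): c for c in df.columns}
    mir_col = cols.get("mirna")
    gene_col = cols.get("target_gene")
    if mir_col is None or gene_col is None:
        raise ValueError(f"{path}: need columns miRNA and target_gene "
                         f"(or 'Target Gene'), got {list(df.columns)}")
    targets: dict[str, set[str]] = {}
    for i, (mir, gene) in enumerate(zip(df[mir_col], df[gene_col]), start=2):
        if not isinstance(mir, str) or not mir.strip() \
                or not isinstance(gene, str) or not gene.strip():
            raise ValueError(f"{path}: malformed row at line {i}")
        targets.setdefault(mir.strip(), set()).add(gene.strip())
    return TargetMap(targets)


def write_target_map(tmap: TargetMap, path) -> None:
    rows = [(m, g) for m in sorted(tmap.targets) for g in sorted(tmap.targets[m])]
    pd.DataFrame(rows, columns=["miRNA", "target_gene"]).to_csv(
        Path(path), sep=_sep_for(path), index=False)


def read_peptide_map(path, accession_policy: str = "first") -> PeptideMap:
    """Read a peptide->protein TSV (peptide_id, protein_accession,
    gene_symbol[, sequence]); multi-accession entries split on ';'."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    needed = ["peptide_id", "protein_accession", "gene_symbol"]
    for col in needed:
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    entries: dict[str, PeptideEntry] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        pep = str(getattr(row, "peptide_id", "")).strip()
        acc = getattr(row, "protein_accession", "")
        gene = str(getattr(row, "gene_symbol", "")).strip()
        if not pep or not isinstance(acc, str) or not acc.strip():
            raise ValueError(f"{path}: malformed row at line {i}")
        accs = primary_accession(acc, "all")
        seq = getattr(row, "sequence", None)
        seq = seq.strip() if isinstance(seq, str) and seq.strip() else None
        if accession_policy == "first":
            entries[pep] = PeptideEntry(accs[0], gene, seq, tuple(accs[1:]))
        else:
            entries[pep] = PeptideEntry(accs[0], gene, seq, tuple(accs[1:]))
    return PeptideMap(entries)


def write_peptide_map(pmap: PeptideMap, path) -> None:
    rows = []
    for pep in sorted(pmap.entries):
        e = pmap.entries[pep]
        rows.append((pep, e.protein, e.gene, e.sequence or ""))
    pd.DataFrame(rows, columns=["peptide_id", "protein_accession",
                                "gene_symbol", "sequence"]).to_csv(
        Path(path), sep=_sep_for(path), index=False)
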