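"""Synthetic matched multi-omics data with a planted two-group factor.

The generator emulates the study design the pipeline targets: three omics
blocks (miRNome, peptidome, proteome) measured on the same cohort of
18 + 13 = 31 samples, with a shared latent factor that separates the two
clinical groups and sparse per-block loadings. Alongside the abundance
matrices it emits consistent toy knowledge tables (pathways, miRNA targets,
peptide->protein map) with planted cross-omics regulatory links, so every
downstream stage - factorization, consensus selection, differential
abundance, pathway/link detection - can be exercised and scored against
ground truth without any external download.

Model, per block b (log2 scale):

    X_b = mu_b + W_b @ F.T + E_b

where column 1 of F carries the group effect (+effect_size/2 for group 1,
-effect_size/2 for group 2, plus standard-normal jitter), remaining factors
are standard normal, W_b is sparse with ``informative_fraction`` nonzero
entries of magnitude U(0.5, 1.5) and random sign, E_b is iid
N(0, noise_sd^2), and mu_b ~ U(4, 12) is a per-feature baseline intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import (MultiOmicsSet, OmicsBlock, PathwayDB, PeptideEntry,
                 PeptideMap, SampleAnnotation, TargetMap)


@dataclass
class SimConfig:
    """Study-design parameters of the generator.

    Defaults mirror the target design: 18 vs 13 samples and block sizes
    scaled down (~5x) from 503 miRNAs / 7302 peptides / 1662 proteins so a
    full pipeline run stays well under a minute.
    """

    n_group1: int = 18
    n_group2: int = 13
    n_mirna: int = 100
    n_peptide: int = 400
    n_protein: int = 150
    k_latent: int = 2
    effect_size: float = 2.0      # group separation on factor 1, in noise-SD units
    informative_fraction: float = 0.05
    noise_sd: float = 1.0         # Gaussian noise SD on the log2 scale
    peptides_per_protein: tuple[int, int] = (2, 5)
    group_names: tuple[str, str] = ("non-severe", "severe")
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_group1", "n_group2", "n_mirna", "n_peptide",
                     "n_protein", "k_latent"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.informative_fraction <= 1.0):
            raise ValueError("informative_fraction must be in (0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be nonnegative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        lo, hi = self.peptides_per_protein
        if lo < 1 or hi < lo:
            raise ValueError("invalid peptides_per_protein range")


@dataclass
class GroundTruth:
    """What was planted: labels, informative features, links, pathways."""

    labels: dict[str, str]
    informative: dict[str, set[str]] = field(default_factory=dict)
    signs: dict[str, dict[str, int]] = field(default_factory=dict)
    peptide_protein: dict[str, tuple[str, str]] = field(default_factory=dict)
    planted_links: list[tuple[str, str, bool]] = field(default_factory=list)
    informative_genes: set[str] = field(default_factory=set)
    hot_pathways: dict[str, set[str]] = field(default_factory=dict)
    factor_scores: np.ndarray | None = None


def _n_informative(fraction: float, p: int) -> int:
    return max(1, int(round(fraction * p)))


def _sparse_loadings(rng: np.random.Generator, p: int, k: int,
                     support1: np.ndarray, n_extra: int) -> np.ndarray:
    """Loading matrix: factor 1 on ``support1``, later factors on supports
    drawn from the complement, all entries sign-mixed U(0.5, 1.5)."""
    W = np.zeros((p, k))
    signs = rng.choice([-1.0, 1.0], size=support1.size)
    W[support1, 0] = signs * rng.uniform(0.5, 1.5, size=support1.size)
    pool = np.setdiff1d(np.arange(p), support1)
    for j in range(1, k):
        m = min(n_extra, pool.size)
        if m == 0:
            break
        sup = rng.choice(pool, size=m, replace=False)
        W[sup, j] = rng.choice([-1.0, 1.0], size=m) * rng.uniform(0.5, 1.5, size=m)
    return W


def simulate_multiomics(config: SimConfig) -> tuple[MultiOmicsSet, GroundTruth]:
    """Generate the three matched blocks plus ground truth. Deterministic
    under ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n1, n2 = config.n_group1, config.n_group2
    n = n1 + n2
    k = config.k_latent

    sample_ids = [f"NS{i + 1:03d}" for i in range(n1)] + \
                 [f"SV{i + 1:03d}" for i in range(n2)]
    g1, g2 = config.group_names
    labels = {s: (g1 if s.startswith("NS") else g2) for s in sample_ids}

    # shared factors: column 0 carries the group contrast
    F = rng.standard_normal((n, k))
    F[:, 0] += np.where(np.arange(n) < n1,
                        config.effect_size / 2.0, -config.effect_size / 2.0)

    truth = GroundTruth(labels=labels, factor_scores=F.copy())

    # --- miRNome -----------------------------------------------------------
    mir_ids = [f"hsa-miR-sim-{i + 1:04d}" for i in range(config.n_mirna)]
    n_inf = _n_informative(config.informative_fraction, config.n_mirna)
    sup = np.sort(rng.choice(config.n_mirna, size=n_inf, replace=False))
    W_mir = _sparse_loadings(rng, config.n_mirna, k, sup, n_inf)
    truth.informative["miRNome"] = {mir_ids[i] for i in sup}
    truth.signs["miRNome"] = {mir_ids[i]: int(np.sign(W_mir[i, 0])) for i in sup}

    # --- peptidome: peptides grouped into proteins, planted per protein ----
    pep_ids = [f"PEP{i + 1:04d}" for i in range(config.n_peptide)]
    lo, hi = config.peptides_per_protein
    proteins: list[list[int]] = []
    i = 0
    while i < config.n_peptide:
        size = int(rng.integers(lo, hi + 1))
        proteins.append(list(range(i, min(i + size, config.n_peptide))))
        i += size
    for pi, members in enumerate(proteins):
        acc, gene = f"QP{pi + 1:04d}", f"GQ{pi + 1:04d}"
        for m in members:
            truth.peptide_protein[pep_ids[m]] = (acc, gene)

    target_pep = _n_informative(config.informative_fraction, config.n_peptide)
    order = rng.permutation(len(proteins))
    W_pep = np.zeros((config.n_peptide, k))
    inf_pep: set[str] = set()
    sign_pep: dict[str, int] = {}
    covered = 0
    inf_protein_genes: list[tuple[str, int]] = []
    used_rows: list[int] = []
    for pi in order:
        if covered >= target_pep:
            break
        members = proteins[pi]
        s = int(rng.choice([-1, 1]))
        for m in members:
            W_pep[m, 0] = s * rng.uniform(0.5, 1.5)
            inf_pep.add(pep_ids[m])
            sign_pep[pep_ids[m]] = s
            used_rows.append(m)
        inf_protein_genes.append((f"GQ{pi + 1:04d}", s))
        covered += len(members)
    pool = np.setdiff1d(np.arange(config.n_peptide), np.array(used_rows))
    for j in range(1, k):
        m = min(target_pep, pool.size)
        supj = rng.choice(pool, size=m, replace=False)
        W_pep[supj, j] = rng.choice([-1.0, 1.0], size=m) * rng.uniform(0.5, 1.5, size=m)
    truth.informative["peptidome"] = inf_pep
    truth.signs["peptidome"] = sign_pep

    # --- proteome: feature ids are gene symbols (pre-mapped intensities) ---
    pro_ids = [f"GP{i + 1:04d}" for i in range(config.n_protein)]
    n_inf_p = _n_informative(config.informative_fraction, config.n_protein)
    sup_p = np.sort(rng.choice(config.n_protein, size=n_inf_p, replace=False))
    W_pro = _sparse_loadings(rng, config.n_protein, k, sup_p, n_inf_p)
    truth.informative["proteome"] = {pro_ids[i] for i in sup_p}
    truth.signs["proteome"] = {pro_ids[i]: int(np.sign(W_pro[i, 0])) for i in sup_p}

    gene_signs: dict[str, int] = {g: s for g, s in inf_protein_genes}
    gene_signs.update({pro_ids[i]: int(np.sign(W_pro[i, 0])) for i in sup_p})
    truth.informative_genes = set(gene_signs)

    blocks = []
    for name, ids, W in (("miRNome", mir_ids, W_mir),
                         ("peptidome", pep_ids, W_pep),
                         ("proteome", pro_ids, W_pro)):
        p = len(ids)
        mu = rng.uniform(4.0, 12.0, size=(p, 1))
        E = rng.normal(0.0, config.noise_sd, size=(p, n))
        X = mu + W @ F.T + E
        blocks.append(OmicsBlock(name, ids, list(sample_ids), X, scale="log2"))

    # planted regulatory links: informative miRNAs target informative genes
    gene_pool = sorted(gene_signs)
    for mir in sorted(truth.informative["miRNome"]):
        n_t = int(rng.integers(1, 3))
        picks = rng.choice(len(gene_pool), size=min(n_t, len(gene_pool)),
                           replace=False)
        for gi in np.sort(picks):
            gene = gene_pool[gi]
            concordant = truth.signs["miRNome"][mir] == gene_signs[gene]
            truth.planted_links.append((mir, gene, bool(concordant)))

    mset = MultiOmicsSet(blocks, SampleAnnotation(labels))
    return mset, truth


def simulate_knowledge(truth: GroundTruth,
                       config: SimConfig) -> tuple[PathwayDB, TargetMap, PeptideMap]:
    """Toy pathway / target / peptide-map tables consistent with the truth.

    The target map contains every planted (miRNA, gene) link plus decoy edges
    among non-informative features; the pathway database contains one "hot"
    pathway enriched for informative genes plus background pathways.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 9173])

    pmap = PeptideMap({pep: PeptideEntry(acc, gene)
                       for pep, (acc, gene) in sorted(truth.peptide_protein.items())})

    pep_genes = {g for _, g in truth.peptide_protein.values()}
    pro_genes = {f"GP{i + 1:04d}" for i in range(config.n_protein)}
    all_genes = sorted(pep_genes | pro_genes)
    decoy_genes = sorted(set(all_genes) - truth.informative_genes)

    # target map: planted links first, then decoys so every miRNA has >=1 target
    targets: dict[str, set[str]] = {}
    for mir, gene, _ in truth.planted_links:
        targets.setdefault(mir, set()).add(gene)
    mir_ids = [f"hsa-miR-sim-{i + 1:04d}" for i in range(config.n_mirna)]
    for mir in mir_ids:
        n_decoy = int(rng.integers(1, 5))
        picks = rng.choice(len(decoy_genes), size=min(n_decoy, len(decoy_genes)),
                           replace=False)
        for gi in np.sort(picks):
            targets.setdefault(mir, set()).add(decoy_genes[gi])
    tmap = TargetMap(targets)

    # pathways: one hot pathway enriched in informative genes + backgrounds
    names: dict[str, str] = {}
    sets: dict[str, set[str]] = {}
    inf = sorted(truth.informative_genes)
    n_hot = max(1, int(round(0.8 * len(inf))))
    hot = {inf[i] for i in np.sort(rng.choice(len(inf), size=n_hot, replace=False))}
    n_bg_in_hot = min(5, len(decoy_genes))
    hot |= {decoy_genes[i] for i in
            np.sort(rng.choice(len(decoy_genes), size=n_bg_in_hot, replace=False))}
    names["WPHOT001"] = "synthetic hot pathway"
    sets["WPHOT001"] = hot
    truth.hot_pathways = {"WPHOT001": set(hot)}

    n_background = 8
    for b in range(n_background):
        size = int(rng.integers(12, 21))
        picks = rng.choice(len(decoy_genes), size=min(size, len(decoy_genes)),
                           replace=False)
        pid = f"WPBG{b + 1:03d}"
        names[pid] = f"synthetic background pathway {b + 1}"
        sets[pid] = {decoy_genes[i] for i in np.sort(picks)}
    return PathwayDB(names, sets), tmap, pmap
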