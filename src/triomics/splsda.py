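"""Supervised (sparse) PLS discriminant analysis, single- and multi-block.

PLS-DA regresses a one-hot outcome on a standardized feature block through
successive latent components; sPLS-DA additionally soft-thresholds each
component's loading vector so that exactly ``keepX`` features stay nonzero.
The multi-block variant couples several omics blocks and the outcome, each
component maximizing the design-weighted sum of covariances between block
scores. Downstream utilities compute per-block explained variance, the
cross-block feature similarity network (product of correlations with the
averaged latent scores, summed over components; edges above a threshold,
default 0.80), and a three-layer network assembly combining similarity
edges, miRNA-target edges and peptide->protein mapping (with an optional
Smith-Waterman alignment fallback when sequences are available).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MultiOmicsSet, OmicsBlock, PeptideMap, TargetMap


@dataclass
class SimilarityEdge:
    feature_i: str
    block_i: str
    feature_j: str
    block_j: str
    similarity: float
    ncomp_used: int


@dataclass
class PLSModel:
    block_names: list[str]
    loadings: dict[str, np.ndarray]        # block -> features x H
    scores: dict[str, np.ndarray]          # block -> n x H
    y_loadings: np.ndarray                 # classes x H
    y_scores: np.ndarray | None
    keepX: dict[str, list[int]]
    ncomp: int
    explained_variance: dict[str, np.ndarray]  # block -> H percentages
    feature_ids: dict[str, list[str]]
    sample_ids: list[str]
    class_levels: tuple[str, str]
    train_labels: list[str] = field(default_factory=list)
    X0: dict[str, np.ndarray] = field(default_factory=dict)  # standardized inputs
    centers: dict[str, np.ndarray] = field(default_factory=dict)
    scales: dict[str, np.ndarray] = field(default_factory=dict)
    x_proj_loadings: dict[str, np.ndarray] = field(default_factory=dict)

    def cumulative_variance(self, block: str) -> np.ndarray:
        return np.cumsum(self.explained_variance[block])


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _standardize_cols(M: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = M.mean(axis=0)
    sd = M.std(axis=0, ddof=1)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return (M - mu) / sd, mu, sd


def _one_hot(labels, sample_ids) -> tuple[np.ndarray, tuple[str, str], list[str]]:
    lab = np.asarray([labels[s] for s in sample_ids]
                     if isinstance(labels, dict) else labels)
    levels = tuple(sorted(set(lab.tolist())))
    if len(levels) != 2:
        raise ValueError(f"labels must have two levels, got {levels}")
    Y = np.stack([(lab == lv).astype(float) for lv in levels], axis=1)
    return Y, levels, [str(v) for v in lab.tolist()]


def _sparsify(w: np.ndarray, keep: int, ids: list[str]) -> np.ndarray:
    """Soft threshold so exactly ``keep`` entries are nonzero.

    The threshold is the (keep+1)-th largest |w|; ties between kept and
    dropped entries are broken by feature id (ascending keeps priority).
    """
    p = w.size
    if keep < 1:
        raise ValueError("keepX must be >= 1")
    if keep >= p:
        return w.copy()
    order = sorted(range(p), key=lambda i: (-abs(w[i]), ids[i]))
    kept = order[:keep]
    lam = max(abs(w[i]) for i in order[keep:])
    out = np.zeros_like(w)
    mags = np.abs(w[kept]) - lam
    floor = max(mags.max() * 1e-9, 1e-12)
    mags = np.where(mags <= 0, floor, mags)
    out[kept] = np.sign(w[kept]) * mags
    return out


def _rank(M: np.ndarray) -> int:
    s = np.linalg.svd(M, compute_uv=False)
    return int(np.sum(s > s[0] * 1e-10)) if s.size and s[0] > 0 else 0


def _normalize_keepx(keepX, ncomp: int, p: int) -> list[int]:
    if keepX is None:
        return [p] * ncomp
    if isinstance(keepX, int):
        keepX = [keepX] * ncomp
    keepX = [p if k is None else int(k) for k in keepX]
    if len(keepX) < ncomp:
        keepX = keepX + [p] * (ncomp - len(keepX))
    keepX = keepX[:ncomp]
    for k in keepX:
        if k < 1:
            raise ValueError("keepX entries must be >= 1")
        if k > p:
            raise ValueError(f"keepX {k} exceeds feature count {p}")
    return keepX


# ---------------------------------------------------------------------------
# single-block (s)PLS-DA
# ---------------------------------------------------------------------------

def fit_splsda(block: OmicsBlock, labels, ncomp: int = 2,
               keepX=None, max_iter: int = 500, tol: float = 1e-9) -> PLSModel:
    """Sparse PLS-DA on one block (NIPALS with regression deflation).

    With ``keepX=None`` (all features every component) this is plain PLS-DA.
    Loadings are unit-norm before normalization-preserving sparsification;
    scores of successive components are mutually orthogonal.
    """
    X_raw = block.values.T  # n x p
    Xs, mu, sd = _standardize_cols(X_raw)
    Y, levels, lab = _one_hot(labels, block.sample_ids)
    Yc, _, _ = _standardize_cols(Y)
    rank = _rank(Xs)
    if ncomp > rank:
        raise ValueError(f"ncomp={ncomp} exceeds rank {rank}")
    ids = list(block.feature_ids)
    keepx = _normalize_keepx(keepX, ncomp, len(ids))

    X, Yd = Xs.copy(), Yc.copy()
    total_var = float(np.sum(Xs ** 2))
    W = np.zeros((len(ids), ncomp))
    T = np.zeros((Xs.shape[0], ncomp))
    C = np.zeros((Y.shape[1], ncomp))
    P = np.zeros((len(ids), ncomp))
    ev = np.zeros(ncomp)
    for h in range(ncomp):
        u = Yd[:, 0].copy()
        if np.allclose(u, 0):
            u = Yd[:, 1].copy()
        w = np.zeros(len(ids))
        for _ in range(max_iter):
            w_new = X.T @ u
            w_new = _sparsify(w_new, keepx[h], ids)
            nrm = np.linalg.norm(w_new)
            if nrm < 1e-15:
                raise ValueError("degenerate component (zero weight vector)")
            w_new /= nrm
            t = X @ w_new
            q = Yd.T @ t
            qn = np.linalg.norm(q)
            if qn > 0:
                q /= qn
            u_new = Yd @ q
            if np.linalg.norm(w_new - w) < tol:
                w = w_new
                break
            w, u = w_new, u_new
        t = X @ w
        tt = float(t @ t)
        p_load = X.T @ t / tt
        c = Yd.T @ t / tt
        ev[h] = 100.0 * tt * float(p_load @ p_load) / total_var
        X = X - np.outer(t, p_load)
        Yd = Yd - np.outer(t, c)
        W[:, h], T[:, h], C[:, h], P[:, h] = w, t, c, p_load

    name = block.omics_name
    return PLSModel(
        block_names=[name], loadings={name: W}, scores={name: T},
        y_loadings=C, y_scores=None, keepX={name: keepx}, ncomp=ncomp,
        explained_variance={name: ev}, feature_ids={name: ids},
        sample_ids=list(block.sample_ids), class_levels=levels,
        train_labels=lab,
        X0={name: Xs}, centers={name: mu}, scales={name: sd},
        x_proj_loadings={name: P},
    )


def fit_plsda(block: OmicsBlock, labels, ncomp: int = 2) -> PLSModel:
    """Plain PLS-DA (sPLS-DA with every feature kept each component)."""
    return fit_splsda(block, labels, ncomp=ncomp, keepX=None)


# ---------------------------------------------------------------------------
# multi-block sPLS-DA
# ---------------------------------------------------------------------------

def fit_block_splsda(mset: MultiOmicsSet, labels=None, ncomp: int = 5,
                     keepX: dict | None = None, design_weight: float = 1.0,
                     max_iter: int = 500, tol: float = 1e-9) -> PLSModel:
    """Multi-block sparse PLS-DA (DIABLO-style).

    Every block is connected to the outcome with weight 1; block-block
    connections carry ``design_weight`` (0 decouples the blocks so each
    reduces to its single-block sPLS-DA). Per component, block weight
    vectors are updated in turn to maximize the design-weighted sum of score
    covariances, sparsified to their keepX, and all blocks are deflated by
    regression on their own scores.
    """
    if len(mset.blocks) < 2:
        raise ValueError("multi-block sPLS-DA needs at least two blocks")
    if labels is None:
        labels = mset.labels.groups
    names = mset.block_names
    Y, levels, lab = _one_hot(labels, mset.sample_ids)
    Yc, _, _ = _standardize_cols(Y)

    Xs, mus, sds, ids, keepx, ranks = {}, {}, {}, {}, {}, {}
    for b in mset.blocks:
        Z, mu, sd = _standardize_cols(b.values.T)
        Xs[b.omics_name] = Z
        mus[b.omics_name], sds[b.omics_name] = mu, sd
        ids[b.omics_name] = list(b.feature_ids)
        ranks[b.omics_name] = _rank(Z)
        kx = (keepX or {}).get(b.omics_name)
        keepx[b.omics_name] = _normalize_keepx(kx, ncomp, b.n_features)
    max_ncomp = min(min(ranks.values()), len(mset.sample_ids) - 1)
    if ncomp > max_ncomp:
        raise ValueError(f"ncomp={ncomp} exceeds usable rank {max_ncomp}")

    X = {n: Xs[n].copy() for n in names}
    Yd = Yc.copy()
    total_var = {n: float(np.sum(Xs[n] ** 2)) for n in names}
    n_samples = len(mset.sample_ids)
    W = {n: np.zeros((len(ids[n]), ncomp)) for n in names}
    T = {n: np.zeros((n_samples, ncomp)) for n in names}
    P = {n: np.zeros((len(ids[n]), ncomp)) for n in names}
    EV = {n: np.zeros(ncomp) for n in names}
    C = np.zeros((Y.shape[1], ncomp))
    TY = np.zeros((n_samples, ncomp))

    for h in range(ncomp):
        # init from the outcome direction
        ty = Yd[:, 0].copy()
        if np.allclose(ty, 0):
            ty = np.ones(n_samples)
        t = {}
        w = {}
        for n in names:
            v = X[n].T @ ty
            nv = np.linalg.norm(v)
            w[n] = v / nv if nv > 0 else v
            t[n] = X[n] @ w[n]
        wy = Yd.T @ sum(t.values())
        nwy = np.linalg.norm(wy)
        wy = wy / nwy if nwy > 0 else wy
        ty = Yd @ wy

        for _ in range(max_iter):
            delta = 0.0
            for n in names:
                s = ty.copy()
                for m in names:
                    if m != n:
                        s += design_weight * t[m]
                v = X[n].T @ s
                v = _sparsify(v, keepx[n][h], ids[n])
                nv = np.linalg.norm(v)
                if nv < 1e-15:
                    raise ValueError(f"degenerate component in block {n}")
                v /= nv
                delta = max(delta, float(np.max(np.abs(v - w[n]))))
                w[n] = v
                t[n] = X[n] @ v
            wy_new = Yd.T @ sum(t.values())
            nwy = np.linalg.norm(wy_new)
            if nwy > 0:
                wy_new /= nwy
            delta = max(delta, float(np.max(np.abs(wy_new - wy))))
            wy = wy_new
            ty = Yd @ wy
            if delta < tol:
                break

        for n in names:
            tt = float(t[n] @ t[n])
            p_load = X[n].T @ t[n] / tt
            EV[n][h] = 100.0 * tt * float(p_load @ p_load) / total_var[n]
            X[n] = X[n] - np.outer(t[n], p_load)
            W[n][:, h], T[n][:, h], P[n][:, h] = w[n], t[n], p_load
        tyty = float(ty @ ty)
        if tyty > 0:
            c = Yd.T @ ty / tyty
            Yd = Yd - np.outer(ty, c)
            C[:, h] = c
        TY[:, h] = ty

    return PLSModel(
        block_names=list(names), loadings=W, scores=T, y_loadings=C,
        y_scores=TY, keepX=keepx, ncomp=ncomp, explained_variance=EV,
        feature_ids=ids, sample_ids=list(mset.sample_ids),
        class_levels=levels, train_labels=lab,
        X0={n: Xs[n] for n in names},
        centers=mus, scales=sds, x_proj_loadings=P,
    )


# ---------------------------------------------------------------------------
# model summaries
# ---------------------------------------------------------------------------

def explained_variance(model: PLSModel) -> pd.DataFrame:
    """Per-block per-component explained variance (%) with cumulative values."""
    rows = []
    for n in model.block_names:
        ev = model.explained_variance[n]
        cum = np.cumsum(ev)
        for h in range(model.ncomp):
            rows.append({"block": n, "component": h + 1,
                         "explained_pct": ev[h], "cumulative_pct": cum[h]})
    return pd.DataFrame(rows)


def cross_block_similarity(model: PLSModel, ncomp_used: int = 2,
                           threshold: float = 0.80,
                           selected_only: bool = True) -> list[SimilarityEdge]:
    """Cross-block feature similarity network.

    similarity(x in b, z in c) = sum_h cor(x, tbar_h) * cor(z, tbar_h) with
    tbar_h the across-block average component-h score. Only cross-block
    pairs with |similarity| > threshold are returned. By default only
    features with a nonzero loading in one of the used components enter
    (the variables the model actually selected).
    """
    if len(model.block_names) < 2:
        raise ValueError("similarity network needs a multi-block model")
    H = min(ncomp_used, model.ncomp)
    tbar = np.mean([model.scores[n][:, :H] for n in model.block_names], axis=0)
    tbar_c = tbar - tbar.mean(axis=0)
    tbar_sd = tbar_c.std(axis=0)
    tbar_sd = np.where(tbar_sd < 1e-15, 1.0, tbar_sd)

    cors: dict[str, np.ndarray] = {}
    feats: dict[str, list[str]] = {}
    n = len(model.sample_ids)
    for name in model.block_names:
        X = model.X0[name]
        if selected_only:
            mask = np.any(model.loadings[name][:, :H] != 0, axis=1)
        else:
            mask = np.ones(X.shape[1], dtype=bool)
        idx = np.where(mask)[0]
        Xc = X[:, idx] - X[:, idx].mean(axis=0)
        sd = Xc.std(axis=0)
        sd = np.where(sd < 1e-15, 1.0, sd)
        cors[name] = (Xc / sd).T @ (tbar_c / tbar_sd) / n
        feats[name] = [model.feature_ids[name][i] for i in idx]

    edges: list[SimilarityEdge] = []
    for i, b in enumerate(model.block_names):
        for c in model.block_names[i + 1:]:
            S = cors[b] @ cors[c].T
            for r, q in zip(*np.where(np.abs(S) > threshold)):
                edges.append(SimilarityEdge(feats[b][r], b, feats[c][q], c,
                                            float(S[r, q]), H))
    edges.sort(key=lambda e: (e.block_i, e.feature_i, e.block_j, e.feature_j))
    return edges


# ---------------------------------------------------------------------------
# network assembly
# ---------------------------------------------------------------------------

def _align_identity(peptide_seq: str, protein_seq: str) -> float:
    """Best local-alignment identity of a peptide over its own length
    (Smith-Waterman: match +2, mismatch -1, gap -2)."""
    from Bio import Align

    aligner = Align.PairwiseAligner(mode="local", match_score=2,
                                    mismatch_score=-1, open_gap_score=-2,
                                    extend_gap_score=-2)
    best = aligner.align(peptide_seq, protein_seq)
    if len(best) == 0:
        return 0.0
    aln = best[0]
    matches = 0
    for (s1, e1), (s2, e2) in zip(*aln.aligned):
        matches += sum(1 for a, b in zip(peptide_seq[s1:e1],
                                         protein_seq[s2:e2]) if a == b)
    return matches / len(peptide_seq)


def assemble_network(edges: list[SimilarityEdge],
                     target_map: TargetMap | None = None,
                     peptide_map: PeptideMap | None = None,
                     protein_sequences: dict[str, str] | None = None,
                     min_identity: float = 0.9) -> pd.DataFrame:
    """Assemble the three-layer miRNA / peptide / protein edge table.

    1. miRNA-peptide edges: the similarity edges themselves.
    2. miRNA-protein edges: known targets of the involved miRNAs.
    3. peptide-protein edges: the peptide map; peptides absent from the map
       but carrying a sequence are matched by local alignment against the
       provided protein sequences (accepted at >= ``min_identity`` identity
       over the peptide length).
    """
    rows = []
    mirnas, peptides = set(), set()
    for e in edges:
        rows.append({"source": e.feature_i, "target": e.feature_j,
                     "type": "similarity", "weight": e.similarity})
        for feat, blk in ((e.feature_i, e.block_i), (e.feature_j, e.block_j)):
            (mirnas if blk == "miRNome" else peptides).add(feat)

    if target_map is not None:
        for mir in sorted(mirnas):
            for gene in sorted(target_map.genes_for(mir)):
                rows.append({"source": mir, "target": gene,
                             "type": "mirna_target", "weight": 1.0})

    for pep in sorted(peptides):
        if peptide_map is not None and pep in peptide_map:
            entry = peptide_map.entries[pep]
            rows.append({"source": pep, "target": entry.protein,
                         "type": "peptide_protein", "weight": 1.0})
        elif protein_sequences:
            seq = (peptide_map.entries[pep].sequence
                   if peptide_map is not None and pep in peptide_map else pep)
            best_prot, best_id = None, 0.0
            for prot in sorted(protein_sequences):
                ident = _align_identity(seq, protein_sequences[prot])
                if ident > best_id:
                    best_prot, best_id = prot, ident
            if best_prot is not None and best_id >= min_identity:
                rows.append({"source": pep, "target": best_prot,
                             "type": "peptide_protein", "weight": best_id})
    return pd.DataFrame(rows, columns=["source", "target", "type", "weight"])


# ---------------------------------------------------------------------------
# prediction of held-out samples
# ---------------------------------------------------------------------------

def predict(model: PLSModel, blocks: dict[str, np.ndarray] | MultiOmicsSet
            ) -> list[str]:
    """Classify new samples by nearest class centroid of averaged block scores.

    New blocks are standardized with the training centers/scales, projected
    through the per-component deflation loop, block scores averaged, and each
    sample assigned to the class whose training-score centroid is nearest.
    """
    if isinstance(blocks, MultiOmicsSet):
        data = {b.omics_name: b.values.T for b in blocks.blocks}
    else:
        data = dict(blocks)
    scores = []
    for n in model.block_names:
        X = (data[n] - model.centers[n]) / model.scales[n]
        T = np.zeros((X.shape[0], model.ncomp))
        for h in range(model.ncomp):
            t = X @ model.loadings[n][:, h]
            X = X - np.outer(t, model.x_proj_loadings[n][:, h])
            T[:, h] = t
        scores.append(T)
    avg = np.mean(scores, axis=0)

    train_avg = np.mean([model.scores[n] for n in model.block_names], axis=0)
    levels = model.class_levels
    lab = np.asarray(model.train_labels)
    if lab.size != train_avg.shape[0]:
        raise ValueError("model carries no training labels; refit to predict")
    centroids = {lv: train_avg[lab == lv].mean(axis=0) for lv in levels}
    out = []
    for row in avg:
        d = {lv: float(np.linalg.norm(row - centroids[lv])) for lv in levels}
        out.append(min(d, key=lambda lv: (d[lv], lv)))
    return out
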