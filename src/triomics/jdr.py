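"""Joint dimensionality reduction of matched omics blocks.

Three representative method families decompose a multi-omics set into one
shared sample x k factor matrix F plus per-block feature x k weight matrices:

* ``jnmf``  - joint nonnegative matrix factorization (multiplicative updates
  minimizing the summed Frobenius reconstruction error; blocks are shifted to
  nonnegativity by per-feature minimum subtraction).
* ``mfa``   - multiple factor analysis: each standardized block is scaled by
  the reciprocal of its first singular value, blocks are concatenated
  feature-wise and a truncated SVD taken (covariance/SVD family).
* ``jica``  - joint ICA: feature-wise concatenation, whitening of the sample
  mode to k dimensions, symmetric fixed-point ICA with the tanh contrast.

An ``external`` adapter loads pre-computed factor/weight TSVs so that
factorizations from other tools can be scored by the same evaluation code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import MultiOmicsSet
from .preprocess import standardize

logger = logging.getLogger("triomics")

_EPS = 1e-12


@dataclass
class Factorization:
    """A method's joint factor matrix and per-block weight matrices."""

    method: str
    F: np.ndarray                      # samples x k
    W: dict[str, np.ndarray]           # block name -> features x k
    k: int
    sample_ids: list[str]
    feature_ids: dict[str, list[str]]
    objective_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = True
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.F.shape != (len(self.sample_ids), self.k):
            raise ValueError("F shape does not match samples x k")
        for name, Wb in self.W.items():
            if Wb.shape != (len(self.feature_ids[name]), self.k):
                raise ValueError(f"W[{name}] shape mismatch")

    def weights_frame(self, block: str) -> pd.DataFrame:
        return pd.DataFrame(self.W[block], index=self.feature_ids[block],
                            columns=[f"factor{j + 1}" for j in range(self.k)])

    def factors_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.F, index=self.sample_ids,
                            columns=[f"factor{j + 1}" for j in range(self.k)])


def _check_k(mset: MultiOmicsSet, k: int) -> None:
    n = len(mset.sample_ids)
    pmin = min(b.n_features for b in mset.blocks)
    if k > min(n, pmin):
        raise ValueError(f"k={k} exceeds min(samples, smallest block) = "
                         f"{min(n, pmin)}")


def _fix_signs(F: np.ndarray, Wcat: np.ndarray,
               slices: list[tuple[str, slice]]) -> None:
    """Flip factor signs so the largest-|weight| entry per factor is positive."""
    for j in range(F.shape[1]):
        i = int(np.argmax(np.abs(Wcat[:, j])))
        if Wcat[i, j] < 0:
            Wcat[:, j] *= -1.0
            F[:, j] *= -1.0


def _standardized_concat(mset: MultiOmicsSet, scale_blocks: bool):
    """Standardize features; optionally scale each block by 1/sigma_1."""
    parts, slices, start = [], [], 0
    for b in mset.blocks:
        Z = standardize(b).values
        if scale_blocks:
            s1 = np.linalg.svd(Z, compute_uv=False)[0]
            if s1 > 0:
                Z = Z / s1
        parts.append(Z)
        slices.append((b.omics_name, slice(start, start + b.n_features)))
        start += b.n_features
    return np.vstack(parts), slices


# ---------------------------------------------------------------------------
# joint NMF
# ---------------------------------------------------------------------------

def fit_jnmf(mset: MultiOmicsSet, k: int, max_iter: int = 500,
             tol: float = 1e-6, seed: int = 0) -> Factorization:
    """Joint NMF by multiplicative updates.

    Minimizes ``sum_b ||X_b - W_b F^T||_F^2`` with shared nonnegative F.
    Blocks are shifted to nonnegativity by subtracting each feature's minimum
    (shifts recorded in diagnostics). The objective is nonincreasing per
    iteration; iteration stops at relative objective change < ``tol``.
    """
    _check_k(mset, k)
    rng = np.random.default_rng(seed)
    names = mset.block_names
    Xs, shifts = [], {}
    for b in mset.blocks:
        # only features dipping below zero are shifted (by their minimum),
        # so already-nonnegative data is factorized as-is
        mn = np.minimum(b.values.min(axis=1, keepdims=True), 0.0)
        Xs.append(b.values - mn)
        shifts[b.omics_name] = mn[:, 0].tolist()
    n = len(mset.sample_ids)
    F = rng.uniform(0.1, 1.0, size=(n, k))
    Ws = [rng.uniform(0.1, 1.0, size=(X.shape[0], k)) for X in Xs]

    def objective() -> float:
        return float(sum(np.sum((X - Wb @ F.T) ** 2) for X, Wb in zip(Xs, Ws)))

    trace = [objective()]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        FtF = F.T @ F
        for i, X in enumerate(Xs):
            Ws[i] *= (X @ F) / (Ws[i] @ FtF + _EPS)
        num = np.zeros((n, k))
        den = np.zeros((k, k))
        for X, Wb in zip(Xs, Ws):
            num += X.T @ Wb
            den += Wb.T @ Wb
        F *= num / (F @ den + _EPS)
        trace.append(objective())
        if abs(trace[-2] - trace[-1]) <= tol * max(trace[-2], _EPS):
            converged = True
            break

    W = {name: Wb for name, Wb in zip(names, Ws)}
    return Factorization(
        method="jnmf", F=F, W=W, k=k, sample_ids=list(mset.sample_ids),
        feature_ids={b.omics_name: list(b.feature_ids) for b in mset.blocks},
        objective_trace=trace, n_iter=it, converged=converged,
        diagnostics={"nonnegativity_shifts": shifts, "seed": seed},
    )


# ---------------------------------------------------------------------------
# multiple factor analysis
# ---------------------------------------------------------------------------

def fit_mfa(mset: MultiOmicsSet, k: int) -> Factorization:
    """MFA-style joint SVD; reduces to PCA for a single block."""
    _check_k(mset, k)
    Z, slices = _standardized_concat(mset, scale_blocks=True)
    U, S, Vt = np.linalg.svd(Z.T, full_matrices=False)
    rank = int(np.sum(S > S[0] * 1e-12)) if S.size else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds rank {rank}")
    F = U[:, :k] * S[:k]
    Wcat = Vt[:k].T.copy()
    _fix_signs(F, Wcat, slices)
    W = {name: Wcat[sl] for name, sl in slices}
    return Factorization(
        method="mfa", F=F, W=W, k=k, sample_ids=list(mset.sample_ids),
        feature_ids={b.omics_name: list(b.feature_ids) for b in mset.blocks},
        objective_trace=[], n_iter=1, converged=True,
        diagnostics={"singular_values": S[:k].tolist()},
    )


# ---------------------------------------------------------------------------
# joint ICA
# ---------------------------------------------------------------------------

def _sym_decorrelate(B: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(B.T @ B)
    vals = np.clip(vals, _EPS, None)
    return B @ (vecs * (1.0 / np.sqrt(vals))) @ vecs.T


def fit_jica(mset: MultiOmicsSet, k: int, max_iter: int = 500,
             tol: float = 1e-6, seed: int = 0) -> Factorization:
    """Joint ICA: whitening of the sample mode + symmetric FastICA (tanh).

    Sources live in sample space (unit variance); the mixing estimate gives
    the per-feature weights. Non-convergence is returned with
    ``converged=False`` rather than raised.
    """
    _check_k(mset, k)
    Z, slices = _standardized_concat(mset, scale_blocks=False)
    n = Z.shape[1]
    D = Z.T  # samples x features; columns already centered
    U, S, Vt = np.linalg.svd(D, full_matrices=False)
    rank = int(np.sum(S > S[0] * 1e-12)) if S.size else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds rank {rank}")
    Xw = U[:, :k] * np.sqrt(n)  # whitened: cov = I (1/n convention)

    rng = np.random.default_rng(seed)
    B = _sym_decorrelate(rng.standard_normal((k, k)))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        G = np.tanh(Xw @ B)
        B_new = (Xw.T @ G) / n - B * (1.0 - G ** 2).mean(axis=0)
        B_new = _sym_decorrelate(B_new)
        delta = float(np.max(np.abs(np.abs(np.diag(B_new.T @ B)) - 1.0)))
        B = B_new
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("jica: not converged after %d iterations", max_iter)

    F = Xw @ B                       # unit-variance sources
    Wcat = (Z @ F) / n               # mixing estimate per feature
    _fix_signs(F, Wcat, slices)
    W = {name: Wcat[sl] for name, sl in slices}
    return Factorization(
        method="jica", F=F, W=W, k=k, sample_ids=list(mset.sample_ids),
        feature_ids={b.omics_name: list(b.feature_ids) for b in mset.blocks},
        objective_trace=[], n_iter=it, converged=converged,
        diagnostics={"seed": seed},
    )


# ---------------------------------------------------------------------------
# registry / adapters
# ---------------------------------------------------------------------------

METHODS = {
    "jnmf": lambda mset, k, seed: fit_jnmf(mset, k, seed=seed),
    "mfa": lambda mset, k, seed: fit_mfa(mset, k),
    "jica": lambda mset, k, seed: fit_jica(mset, k, seed=seed),
}


def run_all(mset: MultiOmicsSet, k: int = 2, methods=None,
            seed: int = 0) -> list[Factorization]:
    """Fit every registered method; per-method failures are logged, not fatal."""
    names = list(METHODS) if methods is None else list(methods)
    if not names:
        raise ValueError("empty method list")
    unknown = [m for m in names if m not in METHODS]
    if unknown:
        raise KeyError(f"unknown method(s): {unknown}")
    out = []
    for name in names:
        try:
            out.append(METHODS[name](mset, k, seed))
        except Exception as exc:  # noqa: BLE001 - isolation is the contract
            logger.error("method %s failed: %s", name, exc)
    return out


def save_factorization(fz: Factorization, outdir, prefix: str | None = None,
                       header: str = "") -> list[Path]:
    """Serialize as factors TSV + one weights TSV per block + JSON sidecar."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prefix = prefix or fz.method
    written = []
    fpath = outdir / f"{prefix}_factors.tsv"
    _write_tsv(fz.factors_frame(), fpath, header, index_label="sample_id")
    written.append(fpath)
    for name in fz.W:
        wpath = outdir / f"{prefix}_weights_{name}.tsv"
        _write_tsv(fz.weights_frame(name), wpath, header, index_label="feature_id")
        written.append(wpath)
    side = outdir / f"{prefix}_diagnostics.json"
    side.write_text(json.dumps({
        "method": fz.method, "k": fz.k, "n_iter": fz.n_iter,
        "converged": fz.converged,
        "objective_trace": fz.objective_trace,
        "diagnostics": fz.diagnostics,
    }, sort_keys=True, indent=1) + "\n")
    written.append(side)
    return written


def _write_tsv(df: pd.DataFrame, path: Path, header: str,
               index_label: str) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        df.to_csv(fh, sep="\t", float_format="%.12g", index_label=index_label)


def load_factorization(factors_path, weights_paths: dict[str, str],
                       method: str = "external") -> Factorization:
    """Adapter for factorizations computed elsewhere (factors/weights TSVs)."""
    fdf = pd.read_csv(factors_path, sep="\t", index_col=0, comment="#")
    W, feats = {}, {}
    for name, p in weights_paths.items():
        wdf = pd.read_csv(p, sep="\t", index_col=0, comment="#")
        W[name] = wdf.to_numpy(dtype=float)
        feats[name] = [str(i) for i in wdf.index]
    return Factorization(
        method=method, F=fdf.to_numpy(dtype=float), W=W, k=fdf.shape[1],
        sample_ids=[str(i) for i in fdf.index], feature_ids=feats,
    )
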