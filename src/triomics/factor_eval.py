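"""Scoring factors by repeated k-means clustering against clinical labels.

Each factor's sample scores are clustered 1000 times with 1-D two-cluster
Lloyd k-means (fresh random centroid inits from the data points); each run's
accuracy is the better of the two possible label<->cluster assignments. Per
factorization the factor with higher mean accuracy is kept, and methods are
ranked by that accuracy. The baseline is max(n1, n2)/n - the accuracy of
putting every sample in one cluster (58% for an 18/13 design).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .jdr import Factorization


@dataclass
class FactorScore:
    method: str
    factor_index: int           # 1-based
    mean_accuracy: float
    max_accuracy: float
    n_runs: int
    baseline: float

    def __post_init__(self) -> None:
        # NB: max_accuracy usually reaches the baseline (some run collapses to
        # one cluster) but a 2-cluster assignment can legitimately score below
        # max(n1, n2)/n, so only structural bounds are enforced here.
        if not (0.0 <= self.max_accuracy <= 1.0 + 1e-12):
            raise ValueError("max_accuracy outside [0, 1]")
        if self.mean_accuracy > self.max_accuracy + 1e-12:
            raise ValueError("mean_accuracy exceeds max_accuracy")


def _binary_labels(labels) -> np.ndarray:
    lab = np.asarray(labels)
    levels = sorted(set(lab.tolist()))
    if len(levels) != 2:
        raise ValueError(f"labels must have exactly two levels, got {levels}")
    return (lab == levels[1]).astype(int)


def clustering_accuracy(assignment, labels) -> float:
    """Best-of-two-mappings agreement between a <=2-cluster assignment and
    two-level labels. Always >= max(n1, n2)/n."""
    a = np.asarray(assignment)
    lab = np.asarray(labels)
    if a.shape[0] != lab.shape[0]:
        raise ValueError("assignment and labels differ in length")
    clusters = sorted(set(a.tolist()))
    if len(clusters) > 2:
        raise ValueError(f"more than two clusters: {clusters}")
    y = _binary_labels(lab)
    ab = (a == clusters[-1]).astype(int)
    n = y.size
    m = int(np.sum(ab == y))
    return max(m, n - m) / n


def evaluate_factor(values, labels, n_runs: int = 1000,
                    seed=0, method: str = "", factor_index: int = 1) -> FactorScore:
    """Run ``n_runs`` independent 1-D 2-means clusterings of one factor's
    sample scores and score each against the labels.

    Lloyd's algorithm with two distinct data points as initial centroids per
    run, ties to the lower-index cluster; a run whose clustering collapses to
    a single cluster scores the baseline. Constant factors score the baseline
    in every run.
    """
    v = np.asarray(values, dtype=float).ravel()
    y = _binary_labels(labels)
    n = v.size
    if n < 4:
        raise ValueError("need at least 4 samples")
    if y.shape[0] != n:
        raise ValueError("values and labels differ in length")
    counts = np.bincount(y, minlength=2)
    baseline = counts.max() / n

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    uniq = np.unique(v)
    if uniq.size < 2:
        return FactorScore(method, factor_index, baseline, baseline,
                           n_runs, baseline)

    # init: two distinct data-point centroids per run
    i1 = rng.integers(n, size=n_runs)
    i2 = rng.integers(n, size=n_runs)
    for _ in range(100):
        clash = v[i1] == v[i2]
        if not clash.any():
            break
        i2[clash] = rng.integers(n, size=int(clash.sum()))
    clash = v[i1] == v[i2]
    if clash.any():  # pathological duplicates; fall back to distinct values
        i1[clash], i2[clash] = 0, 1
        v_init = np.stack([np.full(n_runs, uniq[0]), np.full(n_runs, uniq[1])], 1)
        C = np.where(clash[:, None], v_init, np.stack([v[i1], v[i2]], 1))
    else:
        C = np.stack([v[i1], v[i2]], axis=1)  # (runs, 2)

    assign = np.zeros((n_runs, n), dtype=bool)
    for _ in range(100):
        d0 = np.abs(v[None, :] - C[:, 0, None])
        d1 = np.abs(v[None, :] - C[:, 1, None])
        new_assign = d1 < d0  # tie -> cluster 0 (lower index)
        if (new_assign == assign).all():
            break
        assign = new_assign
        n1c = assign.sum(axis=1)
        s1 = (v[None, :] * assign).sum(axis=1)
        s0 = v.sum() - s1
        nz1 = n1c > 0
        nz0 = n1c < n
        C[nz1, 1] = s1[nz1] / n1c[nz1]
        C[nz0, 0] = s0[nz0] / (n - n1c[nz0])

    m = (assign == (y[None, :] == 1)).sum(axis=1)
    acc = np.maximum(m, n - m) / n
    return FactorScore(method, factor_index, float(acc.mean()),
                       float(acc.max()), n_runs, baseline)


def select_best(factorizations: list[Factorization], labels,
                n_runs: int = 1000, seed: int = 0, top_m: int = 3
                ) -> tuple[list[FactorScore], list[FactorScore]]:
    """Score every factor of every factorization and rank methods.

    Per method the factor with the higher mean accuracy wins (ties to the
    lower factor index); methods are ranked by that accuracy (ties broken
    lexicographically by method name). Returns (all scores, top_m chosen).
    """
    if not factorizations:
        raise ValueError("no factorizations to evaluate")
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(sum(fz.k for fz in factorizations)))
    scores: list[FactorScore] = []
    best: dict[str, FactorScore] = {}
    for fz in factorizations:
        for j in range(fz.k):
            sc = evaluate_factor(fz.F[:, j], labels, n_runs=n_runs,
                                 seed=np.random.default_rng(next(children)),
                                 method=fz.method, factor_index=j + 1)
            scores.append(sc)
            cur = best.get(fz.method)
            if cur is None or sc.mean_accuracy > cur.mean_accuracy:
                best[fz.method] = sc
    ranked = sorted(best.values(),
                    key=lambda s: (-s.mean_accuracy, s.method))
    return scores, ranked[:top_m]


def scores_table(scores: list[FactorScore]) -> pd.DataFrame:
    """Method x factor accuracy table (percentages rounded to integers),
    mirroring the usual presentation of per-factor clustering accuracies."""
    rows = [{"method": s.method, "factor": s.factor_index,
             "mean_accuracy_pct": int(round(100 * s.mean_accuracy)),
             "max_accuracy_pct": int(round(100 * s.max_accuracy)),
             "baseline_pct": int(round(100 * s.baseline)),
             "n_runs": s.n_runs} for s in scores]
    return pd.DataFrame(rows).sort_values(["method", "factor"]).reset_index(drop=True)
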