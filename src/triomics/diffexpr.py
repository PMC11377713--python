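"""Per-feature two-group differential abundance.

Each feature is tested with a one-predictor logistic regression of group
membership on its (internally z-scored) abundance; the p-value comes from
the Wald test of the slope. The effect size reported alongside is the log2
fold change computed directly as the difference of group means on log2
data - a logistic slope is not a fold change, so the two statistics are
computed separately. Features with p < alpha are flagged significant; no
multiple-testing correction is applied by default (Benjamini-Hochberg is
available behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2, norm

from .io import OmicsBlock

#: |slope| on z-scored x beyond which complete separation is assumed.
SEPARATION_BOUND = 15.0


@dataclass
class LogisticFit:
    slope: float
    intercept: float
    se: float
    p_value: float
    separated: bool
    converged: bool


def _deviance(eta: np.ndarray, y: np.ndarray) -> float:
    # -2 log-likelihood of a Bernoulli GLM with logit link
    return float(2.0 * np.sum(np.logaddexp(0.0, eta) - y * eta))


def logistic_fit(x, y, max_iter: int = 100, tol: float = 1e-8) -> LogisticFit:
    """One-predictor logistic regression via IRLS, with intercept.

    ``x`` is z-scored internally for numerical stability. On complete
    separation (diverging slope) the fit is flagged and the p-value falls
    back to the likelihood-ratio test against the intercept-only model
    instead of the (meaningless) Wald test.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y differ in length")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    if len(set(y.tolist())) < 2:
        raise ValueError("both classes must be present")

    sd = x.std()
    if sd < 1e-12:
        return LogisticFit(0.0, float(np.log(y.mean() / (1 - y.mean()))),
                           np.inf, 1.0, False, True)
    z = (x - x.mean()) / sd
    X = np.column_stack([np.ones_like(z), z])
    beta = np.zeros(2)
    separated = False
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        adj = eta + (y - mu) / w
        XtW = X.T * w
        beta_new = np.linalg.solve(XtW @ X, XtW @ adj)
        step = float(np.max(np.abs(beta_new - beta)))
        beta = beta_new
        if abs(beta[1]) > SEPARATION_BOUND:
            separated = True
            break
        if step < tol:
            converged = True
            break

    eta = np.clip(X @ beta, -30.0, 30.0)
    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    cov = np.linalg.inv((X.T * w) @ X)
    se = float(np.sqrt(cov[1, 1]))
    if separated:
        p0 = y.mean()
        dev_null = _deviance(np.full_like(y, np.log(p0 / (1 - p0))), y)
        dev_fit = _deviance(eta, y)
        p = float(chi2.sf(max(dev_null - dev_fit, 0.0), df=1))
    else:
        p = float(2.0 * norm.sf(abs(beta[1] / se))) if se > 0 else 1.0
    return LogisticFit(float(beta[1]), float(beta[0]), se, p,
                       separated, converged)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(ranked, 0.0, 1.0)
    return out


def differential_expression(block: OmicsBlock, labels, alpha: float = 0.05,
                            adjust: str | None = None) -> pd.DataFrame:
    """One DEResult row per feature of a log2-scale block.

    ``log2fc`` is group2 mean minus group1 mean (groups are the two label
    levels in lexicographic order); ``p_value`` is the logistic Wald (or
    separation-fallback) p. ``adjust="bh"`` flags significance on
    BH-adjusted p-values instead of raw ones.
    """
    if block.scale != "log2":
        raise ValueError("differential expression expects a log2-scale block")
    lab = np.asarray([labels[s] for s in block.sample_ids]
                     if isinstance(labels, dict) else labels)
    levels = sorted(set(lab.tolist()))
    if len(levels) != 2:
        raise ValueError(f"labels must have two levels, got {levels}")
    y = (lab == levels[1]).astype(float)

    rows = []
    for i, fid in enumerate(block.feature_ids):
        x = block.values[i]
        fit = logistic_fit(x, y)
        log2fc = float(x[y == 1].mean() - x[y == 0].mean())
        rows.append({"feature_id": fid, "log2fc": log2fc,
                     "coef": fit.slope, "se": fit.se, "p_value": fit.p_value,
                     "separated": fit.separated})
    de = pd.DataFrame(rows)
    pcol = de["p_value"].to_numpy()
    de["p_adjusted"] = bh_adjust(pcol) if adjust == "bh" else pcol
    de["significant"] = de["p_adjusted"] < alpha if adjust == "bh" \
        else de["p_value"] < alpha
    de["omics"] = block.omics_name
    return de
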