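# triomics

Three-strategy integration of matched multi-omics data for a two-group
clinical contrast — built for cohorts where the same samples were profiled
on several molecular layers (e.g. miRNome, peptidome and proteome of
amniotic fluid, split into non-severe vs severe congenital kidney and
urinary tract anomalies) and the question is which molecules, and which
regulatory miRNA→gene relationships, separate the groups.

The package implements, as one tested pipeline with a synthetic-data
module replacing any external download:

1. **Joint dimensionality reduction + factor scoring.** Three
   representative factorization families (joint NMF, multiple factor
   analysis, joint ICA) decompose the blocks `X_b ≈ W_b F^T` into a shared
   sample×k factor matrix `F` and per-block weights `W_b` (k = 2 by
   default). Each factor is scored by 1000 runs of 1-D two-cluster k-means
   against the clinical labels, where a run's accuracy is
   `max(m, n−m)/n` over the two label↔cluster mappings and the baseline is
   `max(n1, n2)/n` (58% for an 18/13 design). The top 5% of features by
   |weight| per method are intersected across methods into a consensus,
   then mapped to proteins / target genes.
2. **Multi-block sparse PLS-DA.** DIABLO-style supervised decomposition of
   several blocks against the one-hot outcome with a per-component `keepX`
   sparsity schedule, per-block explained variance, a cross-block feature
   similarity network (`sim(x,z) = Σ_h cor(x, t̄_h)·cor(z, t̄_h)`,
   thresholded at 0.80) and a three-layer network assembly
   (similarity + miRNA targets + peptide→protein mapping with an optional
   Smith–Waterman fallback).
3. **Pathway-level link detection.** Peptides are rolled up to proteins by
   geometric mean, quantile normalised and log2 transformed; each feature
   is tested by one-predictor logistic regression (Wald p, log2FC as the
   difference of group means); pathways are screened by one-sided
   hypergeometric overrepresentation over the measured-gene background; and
   (miRNA, gene) links are reported where both partners are significant,
   the edge exists in the target map and the gene lies in an
   overrepresented pathway, with a same/opposite-direction flag.

See `docs/methods.md` for the full model description and design choices.

## Worked example

```python
from triomics import (SimConfig, simulate_multiomics, run_all, select_best,
                      scores_table)
from triomics.consensus import consensus_from_factorizations

mset, truth = simulate_multiomics(SimConfig(seed=42))   # 18+13 samples
labels = [mset.labels.groups[s] for s in mset.sample_ids]
fzs = run_all(mset, k=2)                                # jnmf, mfa, jica
scores, chosen = select_best(fzs, labels, n_runs=1000, seed=0)
print(scores_table(scores).to_string(index=False))
```

```
method  factor  mean_accuracy_pct  max_accuracy_pct  baseline_pct  n_runs
  jica       1                 61                61            58    1000
  jica       2                 87                87            58    1000
  jnmf       1                 91                94            58    1000
  jnmf       2                 91                94            58    1000
   mfa       1                 91                94            58    1000
   mfa       2                 56                58            58    1000
```

Every method carries the planted group signal on one of its two factors
(87–91% mean clustering accuracy against the 58% baseline; the other
factor sits near baseline). Consensus selection over the chosen factors
then recovers the planted features:

```python
cf = {c.method: c.factor_index for c in chosen}
sels = consensus_from_factorizations(fzs, cf, required_support=2)
for name, sel in sels.items():
    print(name, len(sel.selected), "features at support >=",
          sel.effective_support)
# miRNome 5 features at support >= 2
# peptidome 19 features at support >= 2
# proteome 8 features at support >= 2
```

The same pipeline is available from the shell, one subcommand per stage:

```bash
triomics run --seed 42 --outdir results/demo          # all three workflows
triomics simulate --seed 42 --outdir results/demo     # just the data
triomics jdr --seed 42 --outdir results/demo          # one workflow
```

`results/demo/report.json` collects the headline numbers (best method and
accuracy, consensus sizes, overrepresented pathways, link count), and every
TSV output starts with a `# seed=… config=…` header; runs with the same
configuration are byte-identical.

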