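# priorank

Prioritization of candidate cancer genes for targeted resequencing, with
PPV-based evaluation and cross-cohort consensus ranking of the
prioritization strategies.

## The problem

Sequencing whole cancer genomes across a large cohort is often not
affordable, so laboratories sequence a targeted panel of candidate genes in
many samples instead. That only pays off if the panel is enriched for genes
that actually carry somatic mutations. `priorank` is for researchers
designing such panels: it ranks genes by signals available *before* any
sequencing — public expression arrays, segmented copy-number profiles, and
the fitSNP differential-expression-ratio (DER) catalogue — and quantifies
how much each ranking beats random gene selection against a reference
mutation screen.

## The method

Four per-gene scores, each defining a ranking (descending):

| strategy | score |
|---|---|
| `fitsnp` | DER(g) ∈ [0,1], looked up from the fitSNP table |
| `expr_variance` | SD of logged expression of g across the cohort (n−1) |
| `dosage_sensitivity` | Spearman ρ between expression and gene-level copy number over matched samples |
| `loss_frequency` | fraction of samples with copy-number value < loss cutoff (default −0.15 log2-ratio) |

Gene-level copy number is projected from CBS segments: largest-overlap
segment wins, and an uncovered gene takes the nearest segment's value on the
same chromosome. Pairs of strategies combine by intersecting their top
lists (smallest shared depth reaching the requested size, ordered by rank
sum).

A ranking is judged by its positive predictive value at depth k,

PPV(k) = |top-k ∩ mutated| / k,

compared with the baseline PPV = (mutated genes)/(genes sequenced) of the
screen — the yield of random selection — on the cutoff ladder
500…10, plus yield curves (minimal k containing m mutated genes; random
baseline ceil(m/rate)). Across datasets, the strategies themselves are
ranked by consensus: the ordering minimizing the weighted Spearman footrule
Σ_d Σ_s w_d(s)·|π(s) − π_d(s)| with mean-PPV weights, solved exactly by
enumeration (≤8 strategies) or by a seeded cross-entropy search.

A synthetic cohort generator produces all five input layers with tunable
coupling between mutation status and each signal, so the whole pipeline is
testable end to end without any external download.

## Worked example

```python
from priorank import (
    CohortSpec, generate_cohort, FitSNPScorer, baseline_ppv,
    ppv_at_cutoffs, genes_to_find, baseline_genes_to_find, fold_change,
)

cohort = generate_cohort(CohortSpec(seed=7, n_genes=2000, der_shift=0.25))
scorer = FitSNPScorer().fit(cohort)
ranked = scorer.rank(universe=cohort.mutations.universe)

base = baseline_ppv(cohort.mutations)
result = ppv_at_cutoffs(ranked, cohort.mutations)
print(f"baseline PPV: {100 * base:.1f}%  "
      f"({cohort.mutations.n_mutated}/{cohort.mutations.n_genes_sequenced})")
for k in (500, 100, 25, 10):
    value = result.ppv_at_cutoff[k]
    print(f"top-{k:<4d} PPV {100 * value:5.1f}%   "
          f"fold vs baseline {fold_change(value, base):4.1f}")
need = genes_to_find(ranked, cohort.mutations, 10)
rand = baseline_genes_to_find(base, 10)
print(f"genes to sequence for 10 mutated: {need} (prioritized) vs {rand} (random)")
```

prints

```
baseline PPV: 4.1%  (82/2000)
top-500  PPV  12.2%   fold vs baseline  3.0
top-100  PPV  28.0%   fold vs baseline  6.8
top-25   PPV  52.0%   fold vs baseline 12.7
top-10   PPV  70.0%   fold vs baseline 17.1
genes to sequence for 10 mutated: 17 (prioritized) vs 244 (random)
```

The cohort was simulated with mutated genes' DER shifted upward
(`der_shift=0.25`), so the fitSNP ranking concentrates mutated genes at the
top: 28% of the top-100 genes are mutated against a 4.1% baseline (6.8-fold
enrichment), and 10 mutated genes are found within the first 17 ranked
genes instead of the ~244 random picks the baseline rate implies.

The same stages are available from the shell:

```bash
priorank simulate --spec specs.yaml --out data/
priorank score --strategy fitsnp --annotation data/colon/annotation.tsv \
    --mutations data/colon/mutations.tsv --der data/colon/der.tsv --out scores.tsv
priorank rank --scores scores.tsv --strategy fitsnp --out ranked.tsv
priorank evaluate --ranked ranked.tsv --mutations data/colon/mutations.tsv --out eval.tsv
priorank pipeline --config config.yaml --out report.json --seed 1
```

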