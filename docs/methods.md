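# Methods

## Problem setting

Targeted resequencing of tumor genomes needs a short list of candidate genes
chosen before any sequencing happens. `priorank` implements and evaluates
four per-gene prioritization strategies computed from data that typically
exist before a sequencing screen — expression microarrays, segmented
copy-number profiles, and the fitSNP differential-expression-ratio (DER)
lookup table — and measures each strategy by how strongly its top-ranked
genes are enriched for somatically mutated genes in a reference screen.

## Scores

For gene *g* in a cohort of samples:

* **fitSNP** — the DER value of *g*: the fraction of expression studies in
  which *g* was called differentially expressed among studies evaluating it.
  Consumed as a table in [0, 1]; genes absent from the table are excluded
  from the fitSNP ranking rather than imputed. An optional strict threshold
  (`min_der`, e.g. 0.55) restricts the ranking to high-DER genes.
* **Expression variance** — the sample standard deviation of *g*'s logged
  expression values, with the n−1 denominator. Unbiased-estimator
  convention chosen because cohorts here can be as small as 9 samples. The
  matrix must be pre-logged; `read_expression(log2_offset=c)` applies
  log2(x+c) for raw intensities (log2 is the microarray convention).
* **Dosage sensitivity** — the Spearman rank correlation between *g*'s
  expression and its gene-level copy-number value across matched samples
  (ids shared between the two layers; at least 3 required). Ranks use
  midranks for ties; a zero-variance vector on either side leaves the
  correlation undefined (NaN) and the gene is excluded from the ranking so
  undefined values cannot dilute the top of a list.
* **Copy-number-loss frequency** — the fraction of cohort samples whose
  gene-level copy-number value is strictly below a loss cutoff. The cutoff
  is a dataset property (platform and purity dependent); the default is
  −0.15 on the log2-ratio scale, and a value exactly at the cutoff is not a
  loss.

### Gene-level copy number from segments

Segmented profiles (CBS output, SEG dialect) are projected onto gene
coordinates: a gene takes the value of the segment with the largest overlap;
equal overlaps go to the segment with the smaller start; a gene covered by
no segment takes the value of the nearest segment on the same chromosome
(smallest interval gap, ties again by smaller start). The fallback never
crosses chromosomes — a sample with no segments on a gene's chromosome is an
error unless the cell is explicitly allowed to stay missing. Coordinates are
0-based half-open internally; 1-based inclusive input dialects are converted
at the file boundary and nowhere else.

## Ranking and combination

Genes are ranked in descending score order with a deterministic
lexicographic tie-break on gene id. Ranking is restricted by default to the
universe of genes the mutation screen sequenced, because PPV is undefined
outside it.

A **combined strategy** intersects the tops of two single-strategy lists:
the smallest depth *k* is found at which the two top-*k* sets share at least
*n* genes; the members of that intersection are ordered by the sum of their
positions in the two input lists (ties by gene id) and truncated to *n*.
This makes combined lists well-defined at every cutoff of the evaluation
ladder even though an intersection has no single natural order.

## Evaluation

* **PPV(k)** = |top-k ∩ mutated| / k, kept as an exact fraction (k·PPV is
  always an integer count).
* **Baseline PPV** = mutated genes / genes sequenced — the yield of random
  selection.
* **Cutoff ladder**: PPV is reported at 500, 400, 300, 200, 150, 100, 75,
  50, 25, 10; cutoffs longer than the list are flagged unavailable and the
  mean PPV is taken over the available ones.
* **Yield curves**: the minimal k containing m mutated genes (the rank of
  the m-th hit); the baseline analogue uses the deterministic expected-yield
  convention, the smallest k with k·rate ≥ m (= ceil(m/rate)).
* **Maximum PPV** scans all depths and returns the smallest k attaining the
  maximum; `min_k` excludes trivially small depths (a single lucky gene at
  k=1 is PPV 1.0).
* **PPV by score cutoff** evaluates PPV among genes scoring strictly above a
  threshold, optionally pooling several screens (a gene is a hit if mutated
  in any of them).

## Cross-dataset consensus

Each dataset orders the candidate strategies (10 strategies — 4 single and
6 pairwise combinations — plus the baseline pseudo-strategy) by mean PPV,
and the mean PPVs double as importance weights. The consensus ordering
minimizes the **weighted Spearman footrule**: the sum over datasets and
strategies of weight × |candidate position − observed position|. The
weighted footrule was chosen as the objective because it is the standard
brute-force rank-aggregation distance and is exactly minimizable at this
problem size; the unweighted variant is available behind a flag. Up to 8
items the optimum is found by full enumeration (lexicographically smallest
ordering on ties); beyond that a seeded cross-entropy Monte-Carlo search is
used, constrained never to return worse than the best observed ordering,
and tests pin heuristic == exhaustive on enumerable instances. Datasets
lacking a strategy (no matched expression + copy number, hence no dosage
sensitivity) are excluded from the consensus, which requires a common
strategy set.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
any particular tumor biology:

* **Mutation status** is gene-level Bernoulli(baseline rate). Per-sample
  multiplicities are drawn (1 + Poisson(0.1), so ~90% of mutated genes are
  single-sample hits) but are not used by any score.
* **DER** ~ Beta with mean 0.40 and concentration 5; mutated genes' mean is
  shifted by `der_shift`.
* **Expression** is normal on the log scale (i.e. log-normal intensities):
  per-gene mean ~ N(8, 2), per-gene SD ~ U(0.2, 0.8), with mutated genes'
  SD multiplied by `var_ratio`.
* **Copy number** is generated segment-wise per (sample, chromosome) with
  exponential segment lengths (mean 5 Mb) and background states loss/gain/
  neutral at 10%/5%/85%, with values N(−0.6, 0.1), N(0.45, 0.1) and
  N(0, 0.05). A mutated gene's loss probability is raised to the
  `loss_or`-scaled odds by inserting, with the complementary probability, a
  focal loss segment exactly covering the gene — so the per-gene loss
  probability equals the odds-scaled target exactly while the profile
  remains a valid non-overlapping segmentation.
* **Dosage coupling** mixes a mutated gene's expression in matched samples
  with its own standardized copy-number value: latent = c·z(CN) +
  sqrt(1−c²)·noise, giving a correlation of roughly c.

Defaults are a colon-like entity: 18000 genes on 22 chromosomes, 19
expression and 19 copy-number samples (all matched), baseline mutation rate
0.047, and all effect sizes at the null. All randomness flows from one
master seed through named child streams (`default_rng([seed, stream])`) for
annotation, mutation, copy number, DER and expression, so a bundle is
bit-reproducible and layers can be regenerated independently.

What the generator does **not** emulate: realistic genome coordinates or
gene density, recurrent focal drivers, hypermutated samples, subclonality,
inter-gene expression correlation, and probe-level noise. Passing
calibration and recovery tests therefore demonstrates that the pipeline's
mathematics behaves correctly under the assumed generative structure — not
that any strategy will enrich for mutations in a particular real tumor
entity.

## Numerical choices and degenerate inputs

* PPVs are exact fractions internally; percent output rounds to one decimal.
* Spearman correlations are computed vectorized (midranks, then
  Pearson on ranks) and clipped to [−1, 1] against rounding excursions;
  agreement with `scipy.stats.spearmanr` is pinned to 1e−12 in tests.
* Score ties in ranking, overlap ties in segment assignment and distance
  ties in aggregation all break deterministically (lexicographic / smaller
  start), so every pipeline output is reproducible byte-for-byte.
* An empty intersection when combining lists, a cutoff beyond the list, a
  DER value outside [0, 1], overlapping segments, or fewer than 2 (variance)
  or 3 (correlation) samples raise validation errors rather than produce
  silent defaults.
* Hypermutated-sample exclusion is an explicit input decision
  (`exclude_samples` in the run config), not automatic detection.

## Problem sizes used in tests

Calibration and recovery suites run 100 replicates of 2000-gene cohorts at
the colon-like rate (0.047) with 19 samples per layer; monotonicity grids
use 1200-gene cohorts over 5 seeds. These sizes keep the full statistical
suite to a few minutes while leaving every per-replicate quantity (PPV at
k = 100 over ~95 mutated genes) well resolved. The acceptance script runs
the six-entity simulated design at the published cohort dimensions
(18000–21000 genes, 9–77 samples per layer).

## Known limitations

* The loss-frequency score takes few distinct values in small cohorts
  (counts over n samples), so its rankings depend noticeably on the
  lexicographic tie-break — the same granularity problem that limits the
  strategy in practice.
* The consensus objective (weighted footrule with mean-PPV weights) is one
  reasonable formalisation of weighted rank aggregation; other objectives
  (weighted Kendall, Borda) could order strategies differently.
* Combined lists shorter than a requested cutoff are evaluated only at the
  cutoffs they reach; comparisons across strategies at a fixed cutoff can
  therefore rest on different list lengths when intersections are small.
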