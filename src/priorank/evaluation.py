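"""PPV and yield mathematics for judging a prioritization strategy.

The positive predictive value (PPV) of a ranked gene list at depth k is the
exact fraction of mutated genes among the first k genes; the baseline PPV is
the mutation screen's overall rate (mutated genes / genes sequenced), i.e.
the yield of picking genes at random.  A strategy is useful where its PPV
curve sits above the baseline — equivalently, where fewer genes must be
sequenced to net a given number of mutated genes.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np

from .types import (
    EvaluationResult,
    MutationSet,
    RankedList,
    ScoreTable,
    ValidationError,
    YieldCurve,
)

__all__ = [
    "DEFAULT_CUTOFFS",
    "ppv",
    "baseline_ppv",
    "genes_to_find",
    "baseline_genes_to_find",
    "ppv_at_cutoffs",
    "max_ppv",
    "fold_change",
    "yield_curve",
    "ppv_by_score_cutoff",
    "restrict_to_universe",
]

#: the standard ladder of top-list sizes at which PPV is reported
DEFAULT_CUTOFFS: tuple[int, ...] = (500, 400, 300, 200, 150, 100, 75, 50, 25, 10)


def restrict_to_universe(ranked: RankedList, mut: MutationSet) -> RankedList:
    """Drop ranked genes outside the screen's sequenced universe.

    A gene the screen never sequenced can be called neither mutated nor
    unmutated, so it cannot participate in a PPV.  No-op when the mutation
    set carries no explicit universe.
    """
    if mut.universe is None:
        return ranked
    return ranked.restrict(mut.universe)


def _mutation_indicator(ranked: RankedList, mut: MutationSet) -> np.ndarray:
    mutated = mut.mutated_genes
    return np.fromiter((g in mutated for g in ranked.genes), bool, len(ranked))


def ppv(ranked: RankedList, mut: MutationSet, k: int) -> float:
    """PPV of the top-k of a ranked list: |top-k ∩ mutated| / k."""
    if k <= 0:
        raise ValidationError("cutoff k must be positive")
    if k > len(ranked):
        raise ValidationError(
            f"cutoff {k} exceeds list length {len(ranked)}"
        )
    hits = sum(1 for g in ranked.top(k) if g in mut.mutated_genes)
    return hits / k


def baseline_ppv(mut: MutationSet) -> float:
    """Overall mutation rate of the screen: mutated / sequenced."""
    return mut.n_mutated / mut.n_genes_sequenced


def genes_to_find(ranked: RankedList, mut: MutationSet, m: int) -> int:
    """Minimal top-k containing m mutated genes (rank of the m-th hit)."""
    if m <= 0:
        raise ValidationError("m must be positive")
    hits = 0
    for rank, gene in enumerate(ranked.genes, start=1):
        if gene in mut.mutated_genes:
            hits += 1
            if hits == m:
                return rank
    raise ValidationError(
        f"list contains only {hits} mutated genes; {m} requested"
    )


def baseline_genes_to_find(rate: float, m: int) -> int:
    """Expected number of random genes to sequence for m mutated genes.

    The deterministic expected-yield convention: the smallest integer k with
    k * rate >= m, i.e. ceil(m / rate).
    """
    if not 0 < rate <= 1:
        raise ValidationError(f"baseline rate must be in (0, 1], got {rate}")
    if m <= 0:
        raise ValidationError("m must be positive")
    k = math.ceil(m / rate)
    # guard against ceil overshoot from floating division
    while (k - 1) * rate >= m:
        k -= 1
    return k


def yield_curve(
    ranked: RankedList, mut: MutationSet, max_m: int | None = None
) -> YieldCurve:
    """Genes-to-sequence curve for m = 1 .. max_m mutated genes.

    ``max_m`` defaults to every mutated gene the list contains.
    """
    indicator = _mutation_indicator(ranked, mut)
    hit_ranks = np.flatnonzero(indicator) + 1
    available = len(hit_ranks)
    if max_m is None:
        max_m = available
    if max_m > available:
        raise ValidationError(
            f"list contains {available} mutated genes; curve to {max_m} requested"
        )
    rate = baseline_ppv(mut)
    needed = {m: int(hit_ranks[m - 1]) for m in range(1, max_m + 1)}
    base = (
        {m: baseline_genes_to_find(rate, m) for m in range(1, max_m + 1)}
        if rate > 0
        else {}
    )
    return YieldCurve(genes_needed=needed, baseline_needed=base)


def ppv_at_cutoffs(
    ranked: RankedList,
    mut: MutationSet,
    cutoffs: Sequence[int] = DEFAULT_CUTOFFS,
    *,
    with_yield_curve: bool = False,
) -> EvaluationResult:
    """PPV at each ladder cutoff, with baseline and mean PPV.

    Cutoffs longer than the list are reported as unavailable (None) — a
    short combined list simply cannot be evaluated at depth 500 — and the
    mean is taken over the available cutoffs only.
    """
    indicator = _mutation_indicator(ranked, mut)
    cum_hits = np.cumsum(indicator)
    ppv_map: dict[int, float | None] = {}
    hits_map: dict[int, int | None] = {}
    for k in cutoffs:
        if k <= 0:
            raise ValidationError("cutoffs must be positive")
        if k > len(ranked):
            ppv_map[k] = None
            hits_map[k] = None
        else:
            hits = int(cum_hits[k - 1])
            ppv_map[k] = hits / k
            hits_map[k] = hits
    available = [v for v in ppv_map.values() if v is not None]
    if not available:
        raise ValidationError(
            f"no cutoff fits the list (length {len(ranked)})"
        )
    curve = None
    if with_yield_curve:
        curve = yield_curve(ranked, mut)
    return EvaluationResult(
        label=ranked.label,
        cutoffs=tuple(cutoffs),
        ppv_at_cutoff=ppv_map,
        n_mutated_at_cutoff=hits_map,
        baseline_ppv=baseline_ppv(mut),
        mean_ppv=float(np.mean(available)),
        yield_curve=curve,
    )


def max_ppv(
    ranked: RankedList, mut: MutationSet, min_k: int = 1
) -> tuple[int, float]:
    """Maximum PPV over all depths k, and the smallest k attaining it.

    ``min_k`` restricts the scan to depths >= min_k (a single lucky gene at
    k=1 gives PPV 1.0, which is rarely the interesting maximum).
    """
    if not 1 <= min_k <= len(ranked):
        raise ValidationError(
            f"min_k must be in [1, {len(ranked)}], got {min_k}"
        )
    indicator = _mutation_indicator(ranked, mut)
    cum_hits = np.cumsum(indicator)
    ks = np.arange(1, len(ranked) + 1)
    ppvs = cum_hits / ks
    window = slice(min_k - 1, None)
    best_idx = int(np.argmax(ppvs[window])) + (min_k - 1)
    return int(ks[best_idx]), float(ppvs[best_idx])


def fold_change(ppv_value: float, baseline: float) -> float:
    """PPV enrichment over baseline."""
    if baseline <= 0:
        raise ValidationError("baseline PPV must be positive for a fold change")
    return ppv_value / baseline


def ppv_by_score_cutoff(
    scores: ScoreTable,
    mutations: MutationSet | Iterable[MutationSet],
    thresholds: Sequence[float],
) -> dict[float, float | None]:
    """PPV among genes scoring strictly above each threshold.

    Accepts one mutation screen or several (screens of different tumor
    entities pooled: a gene counts as a hit if mutated in any screen, and
    every gene any screen sequenced can be evaluated).  Thresholds above
    the maximum score leave an empty gene set and are reported as None.
    """
    if isinstance(mutations, MutationSet):
        mutations = [mutations]
    mutated: set[str] = set()
    for mut in mutations:
        mutated |= mut.mutated_genes
    s = scores.defined
    out: dict[float, float | None] = {}
    for t in thresholds:
        selected = s[s > t]
        if selected.empty:
            out[t] = None
        else:
            hits = sum(1 for g in selected.index if g in mutated)
            out[t] = hits / len(selected)
    return out
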