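"""Turning score tables into ranked gene lists, singly and combined.

Ranking is always descending in score with a deterministic lexicographic
tie-break on gene id, so repeated runs and permuted inputs produce the same
list.  A combined strategy is the intersection of two single strategies'
top lists: the smallest shared depth k is found whose top-k intersection
reaches the requested size, and the intersection is ordered by rank sum.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

from .types import RankedList, ScoreTable, ValidationError

__all__ = ["rank_genes", "combine_strategies"]


def rank_genes(
    scores: ScoreTable, universe: Iterable[str] | None = None
) -> RankedList:
    """Rank genes in descending score order.

    Undefined (NaN) scores are excluded.  If ``universe`` is given the
    scores are first restricted to it — evaluation against a mutation
    screen is only meaningful over the genes that screen sequenced.
    Ties are broken lexicographically by gene id.
    """
    s = scores.defined
    if universe is not None:
        allowed = set(universe)
        s = s[s.index.isin(allowed)]
    if s.empty:
        raise ValidationError(
            f"no scored genes left to rank for strategy {scores.strategy!r}"
            + (" after universe restriction" if universe is not None else "")
        )
    frame = s.rename("score").rename_axis("gene_id").reset_index()
    frame = frame.sort_values(
        ["score", "gene_id"], ascending=[False, True], kind="mergesort"
    )
    genes = tuple(frame["gene_id"])
    ordered_scores = pd.Series(
        frame["score"].to_numpy(), index=list(genes), name="score"
    )
    return RankedList(scores.strategy, genes, ordered_scores)


def combine_strategies(
    list_a: RankedList, list_b: RankedList, n: int
) -> RankedList:
    """Intersect the tops of two ranked lists into a combined list of size n.

    The combined list is the intersection of the two top-k lists at the
    smallest depth k where that intersection reaches ``n`` genes.  Members
    are ordered by the sum of their (1-based) positions in the two input
    lists, ties broken by gene id, and the result is truncated to ``n``.
    """
    if n <= 0:
        raise ValidationError("combined list size n must be positive")
    pos_a = {g: i for i, g in enumerate(list_a.genes, start=1)}
    pos_b = {g: i for i, g in enumerate(list_b.genes, start=1)}
    common = set(pos_a) & set(pos_b)
    if len(common) < n:
        raise ValidationError(
            f"top-list intersection of {list_a.label!r} and {list_b.label!r} "
            f"can reach at most {len(common)} genes; {n} requested"
        )
    # gene g joins the intersection once k >= max(pos_a[g], pos_b[g])
    entry_depth = {g: max(pos_a[g], pos_b[g]) for g in common}
    k_star = sorted(entry_depth.values())[n - 1]
    members = [g for g, d in entry_depth.items() if d <= k_star]
    members.sort(key=lambda g: (pos_a[g] + pos_b[g], g))
    selected = tuple(members[:n])
    rank_sums = pd.Series(
        [pos_a[g] + pos_b[g] for g in selected], index=list(selected),
        name="rank_sum",
    )
    label = f"{list_a.label}+{list_b.label}"
    return RankedList(label, selected, rank_sums)
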