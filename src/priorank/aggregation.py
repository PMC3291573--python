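"""Cross-dataset consensus ranking of prioritization strategies.

Each dataset (tumor entity) orders the candidate strategies by performance
and supplies importance weights (mean PPV of the top-ranked genes in the
standard analysis).  The consensus is the ordering minimizing the weighted
Spearman footrule — the weight-scaled sum of positional displacements —
found exactly by enumeration for small strategy sets and by a seeded
cross-entropy Monte-Carlo search otherwise.
"""

from __future__ import annotations

import itertools
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .types import StrategyRanking, ValidationError

__all__ = ["weighted_footrule", "aggregate_rankings", "RankAggregator"]

#: largest strategy set enumerated exhaustively by default (8! = 40320)
EXHAUSTIVE_LIMIT = 8


def _check_consistent(observed: Sequence[StrategyRanking]) -> tuple[str, ...]:
    if not observed:
        raise ValidationError("no rankings to aggregate")
    items = frozenset(observed[0].ordering)
    for r in observed[1:]:
        if frozenset(r.ordering) != items:
            raise ValidationError(
                f"dataset {r.dataset_id} ranks a different strategy set "
                f"than {observed[0].dataset_id}"
            )
    return tuple(sorted(items))


def weighted_footrule(
    candidate: Sequence[str],
    observed: Sequence[StrategyRanking],
    *,
    use_weights: bool = True,
) -> float:
    """Weighted Spearman footrule distance of a candidate ordering.

    Sum over datasets and strategies of weight x |position in candidate -
    position in the dataset's ordering| (positions 1-based).  With
    ``use_weights=False`` all weights are 1 and this is the plain footrule
    summed over datasets.
    """
    items = _check_consistent(observed)
    if frozenset(candidate) != frozenset(items) or len(candidate) != len(items):
        raise ValidationError("candidate must be a permutation of the strategy set")
    cand_pos = {s: i for i, s in enumerate(candidate, start=1)}
    total = 0.0
    for r in observed:
        for s in items:
            w = r.weights[s] if use_weights else 1.0
            total += w * abs(cand_pos[s] - r.position(s))
    return total


def _distance_terms(
    observed: Sequence[StrategyRanking],
    items: tuple[str, ...],
    use_weights: bool,
) -> tuple[np.ndarray, np.ndarray]:
    weights = np.array(
        [
            [r.weights[s] if use_weights else 1.0 for s in items]
            for r in observed
        ]
    )
    positions = np.array([[r.position(s) for s in items] for r in observed])
    return weights, positions


def _distance(
    cand_pos: np.ndarray, weights: np.ndarray, positions: np.ndarray
) -> float:
    return float((weights * np.abs(cand_pos[None, :] - positions)).sum())


def _exhaustive(
    items: tuple[str, ...], weights: np.ndarray, positions: np.ndarray
) -> tuple[tuple[str, ...], float]:
    best: tuple[str, ...] | None = None
    best_d = np.inf
    n = len(items)
    idx = {s: i for i, s in enumerate(items)}
    # items is sorted, so permutations arrive in lexicographic order and
    # strict improvement keeps the lexicographically smallest optimum
    for perm in itertools.permutations(items):
        cand_pos = np.empty(n)
        for p, s in enumerate(perm, start=1):
            cand_pos[idx[s]] = p
        d = _distance(cand_pos, weights, positions)
        if d < best_d - 1e-12:
            best, best_d = perm, d
    assert best is not None
    return best, best_d


def _cross_entropy(
    items: tuple[str, ...],
    weights: np.ndarray,
    positions: np.ndarray,
    rng: np.random.Generator,
    n_iter: int,
    n_samples: int,
    elite_frac: float,
    smoothing: float,
) -> tuple[tuple[str, ...], float]:
    n = len(items)
    idx = {s: i for i, s in enumerate(items)}
    prob = np.full((n, n), 1.0 / n)  # prob[item, position]
    n_elite = max(1, int(round(elite_frac * n_samples)))
    best: tuple[str, ...] | None = None
    best_d = np.inf

    def sample_perm() -> list[int]:
        used = np.zeros(n, bool)
        perm = np.empty(n, int)
        for pos in range(n):
            p = np.where(used, 0.0, prob[:, pos])
            total = p.sum()
            if total <= 0:
                p = np.where(used, 0.0, 1.0)
                total = p.sum()
            perm[pos] = rng.choice(n, p=p / total)
            used[perm[pos]] = True
        return perm.tolist()

    for _ in range(n_iter):
        perms = [sample_perm() for _ in range(n_samples)]
        dists = []
        for perm in perms:
            cand_pos = np.empty(n)
            for p, item_i in enumerate(perm, start=1):
                cand_pos[item_i] = p
            dists.append(_distance(cand_pos, weights, positions))
        order = np.argsort(dists, kind="stable")
        elite = [perms[i] for i in order[:n_elite]]
        for i in order[: n_elite]:
            labels = tuple(items[j] for j in perms[i])
            if dists[i] < best_d - 1e-12 or (
                abs(dists[i] - best_d) <= 1e-12
                and best is not None
                and labels < best
            ):
                best, best_d = labels, dists[i]
        freq = np.zeros((n, n))
        for perm in elite:
            for pos, item_i in enumerate(perm):
                freq[item_i, pos] += 1
        freq /= n_elite
        prob = (1 - smoothing) * prob + smoothing * freq
    assert best is not None
    return best, best_d


def aggregate_rankings(
    observed: Sequence[StrategyRanking],
    mode: str = "auto",
    seed: int | None = 0,
    *,
    use_weights: bool = True,
    n_iter: int = 60,
    n_samples: int = 200,
    elite_frac: float = 0.1,
    smoothing: float = 0.7,
) -> tuple[tuple[str, ...], float]:
    """Consensus strategy ordering minimizing the weighted footrule.

    ``mode='exhaustive'`` enumerates all permutations (strategy sets of up
    to 8); ``'heuristic'`` runs a seeded cross-entropy search whose result
    is never worse than the best observed ordering; ``'auto'`` picks by
    problem size.  Returns (ordering, distance).
    """
    items = _check_consistent(observed)
    weights, positions = _distance_terms(observed, items, use_weights)
    n = len(items)
    if mode == "auto":
        mode = "exhaustive" if n <= EXHAUSTIVE_LIMIT else "heuristic"
    if mode == "exhaustive":
        if n > EXHAUSTIVE_LIMIT:
            raise ValidationError(
                f"exhaustive aggregation limited to {EXHAUSTIVE_LIMIT} "
                f"strategies, got {n}"
            )
        return _exhaustive(items, weights, positions)
    if mode != "heuristic":
        raise ValidationError(f"unknown aggregation mode: {mode!r}")
    rng = np.random.default_rng(seed)
    best, best_d = _cross_entropy(
        items, weights, positions, rng, n_iter, n_samples, elite_frac, smoothing
    )
    # the search can never report worse than the best observed ordering
    idx = {s: i for i, s in enumerate(items)}
    for r in observed:
        cand_pos = np.empty(n)
        for p, s in enumerate(r.ordering, start=1):
            cand_pos[idx[s]] = p
        d = _distance(cand_pos, weights, positions)
        if d < best_d - 1e-12 or (
            abs(d - best_d) <= 1e-12 and tuple(r.ordering) < best
        ):
            best, best_d = tuple(r.ordering), d
    return best, best_d


class RankAggregator(BaseEstimator):
    """Estimator facade over :func:`aggregate_rankings`.

    Parameters mirror the function; after :meth:`fit` the consensus ordering
    is in ``consensus_`` and its weighted footrule distance in ``distance_``.
    """

    def __init__(
        self,
        mode: str = "auto",
        use_weights: bool = True,
        n_iter: int = 60,
        n_samples: int = 200,
        elite_frac: float = 0.1,
        smoothing: float = 0.7,
        random_state: int | None = 0,
    ):
        self.mode = mode
        self.use_weights = use_weights
        self.n_iter = n_iter
        self.n_samples = n_samples
        self.elite_frac = elite_frac
        self.smoothing = smoothing
        self.random_state = random_state

    def fit(self, rankings: Sequence[StrategyRanking], y=None):
        consensus, distance = aggregate_rankings(
            rankings,
            mode=self.mode,
            seed=self.random_state,
            use_weights=self.use_weights,
            n_iter=self.n_iter,
            n_samples=self.n_samples,
            elite_frac=self.elite_frac,
            smoothing=self.smoothing,
        )
        self.consensus_ = consensus
        self.distance_ = distance
        self.n_strategies_ = len(consensus)
        return self
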