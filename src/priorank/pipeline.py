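"""End-to-end orchestration: score -> rank -> combine -> evaluate -> aggregate.

A run takes a collection of cohorts (real files or synthetic bundles),
evaluates every single strategy the cohort's layers allow plus every
pairwise combination, and aggregates the per-dataset strategy orderings
into a cross-dataset consensus.  Cohorts lacking a layer simply skip the
strategies needing it (with a logged warning) and are excluded from the
consensus, which requires a common strategy set.
"""

from __future__ import annotations

import itertools
import logging
from typing import Mapping, Sequence

from .aggregation import aggregate_rankings
from .evaluation import (
    DEFAULT_CUTOFFS,
    baseline_ppv,
    max_ppv,
    ppv_at_cutoffs,
    restrict_to_universe,
)
from .ranking import combine_strategies, rank_genes
from .scoring import make_scorer
from .simulate import CohortSpec, generate_multi_dataset
from .types import (
    Cohort,
    EvaluationResult,
    RankedList,
    Strategy,
    StrategyRanking,
    ValidationError,
)

__all__ = [
    "single_strategy_lists",
    "combined_strategy_lists",
    "evaluate_lists",
    "strategy_ranking",
    "run_pipeline",
    "cohorts_from_config",
]

logger = logging.getLogger("priorank")

BASELINE_LABEL = "baseline"


def single_strategy_lists(
    cohort: Cohort,
    *,
    restrict: bool = True,
    scorer_params: Mapping[str, dict] | None = None,
) -> dict[str, RankedList]:
    """Ranked list per single strategy the cohort's layers support.

    Strategies whose required layer is absent are skipped with a warning
    (a cohort without matched expression + copy number has no dosage
    sensitivity, mirroring how entity panels differ in practice).
    """
    scorer_params = scorer_params or {}
    universe = cohort.mutations.universe if restrict else None
    lists: dict[str, RankedList] = {}
    for strategy in Strategy.ALL:
        try:
            scorer = make_scorer(strategy, **scorer_params.get(strategy, {}))
            scorer.fit(cohort)
            lists[strategy] = scorer.rank(universe=universe)
        except ValidationError as exc:
            logger.warning(
                "dataset %s: skipping %s (%s)", cohort.dataset_id, strategy, exc
            )
    return lists


def combined_strategy_lists(
    singles: Mapping[str, RankedList],
    *,
    target_size: int = max(DEFAULT_CUTOFFS),
    dataset_id: str = "",
) -> dict[str, RankedList]:
    """Every pairwise intersection of the available single-strategy lists.

    Each combination targets ``target_size`` genes but settles for the
    largest achievable intersection; pairs whose lists share no genes are
    skipped with a warning.
    """
    combined: dict[str, RankedList] = {}
    for a, b in itertools.combinations(sorted(singles), 2):
        la, lb = singles[a], singles[b]
        achievable = len(set(la.genes) & set(lb.genes))
        n = min(target_size, achievable)
        if n == 0:
            logger.warning(
                "dataset %s: %s+%s lists are disjoint, skipping", dataset_id, a, b
            )
            continue
        merged = combine_strategies(la, lb, n)
        combined[f"{a}+{b}"] = merged
    return combined


def evaluate_lists(
    cohort: Cohort,
    lists: Mapping[str, RankedList],
    cutoffs: Sequence[int] = DEFAULT_CUTOFFS,
) -> dict[str, EvaluationResult]:
    """PPV ladder evaluation of each ranked list against the cohort screen."""
    results = {}
    for label, ranked in lists.items():
        usable = restrict_to_universe(ranked, cohort.mutations)
        dropped = len(ranked) - len(usable)
        if dropped:
            logger.info(
                "dataset %s: %d genes of %s outside the sequenced universe "
                "dropped before evaluation",
                cohort.dataset_id,
                dropped,
                label,
            )
        if len(usable) < min(cutoffs):
            logger.warning(
                "dataset %s: list %s too short to evaluate (%d genes)",
                cohort.dataset_id,
                label,
                len(usable),
            )
            continue
        results[label] = ppv_at_cutoffs(usable, cohort.mutations, cutoffs)
    return results


def strategy_ranking(
    dataset_id: str,
    results: Mapping[str, EvaluationResult],
    baseline: float,
) -> StrategyRanking:
    """Order strategies (plus the baseline pseudo-strategy) by mean PPV.

    The mean PPV doubles as the strategy's importance weight in the
    cross-dataset aggregation; the baseline enters with its own rate so a
    useless strategy can rank below random selection.
    """
    weights = {label: res.mean_ppv for label, res in results.items()}
    weights[BASELINE_LABEL] = baseline
    ordering = tuple(sorted(weights, key=lambda s: (-weights[s], s)))
    return StrategyRanking(dataset_id, ordering, weights)


def run_pipeline(
    cohorts: Sequence[Cohort],
    *,
    cutoffs: Sequence[int] = DEFAULT_CUTOFFS,
    combined_target_size: int | None = None,
    aggregation_mode: str = "auto",
    seed: int = 0,
    restrict: bool = True,
    scorer_params: Mapping[str, dict] | None = None,
) -> dict:
    """Full multi-dataset run; returns a JSON-serializable report.

    Deterministic for a fixed seed: scoring and evaluation are themselves
    deterministic and the seed only drives the heuristic aggregation search.
    """
    if combined_target_size is None:
        combined_target_size = max(cutoffs)
    report: dict = {"seed": seed, "cutoffs": list(cutoffs), "datasets": {}}
    rankings: list[StrategyRanking] = []
    for cohort in cohorts:
        singles = single_strategy_lists(
            cohort, restrict=restrict, scorer_params=scorer_params
        )
        combined = combined_strategy_lists(
            singles, target_size=combined_target_size, dataset_id=cohort.dataset_id
        )
        all_lists = {**singles, **combined}
        results = evaluate_lists(cohort, all_lists, cutoffs)
        base = baseline_ppv(cohort.mutations)
        ranking = strategy_ranking(cohort.dataset_id, results, base)
        rankings.append(ranking)
        entry = {
            "baseline_ppv": base,
            "n_mutated": cohort.mutations.n_mutated,
            "n_genes_sequenced": cohort.mutations.n_genes_sequenced,
            "strategies": {},
            "ordering": list(ranking.ordering),
        }
        for label, res in results.items():
            usable = restrict_to_universe(all_lists[label], cohort.mutations)
            k_star, best = max_ppv(usable, cohort.mutations)
            entry["strategies"][label] = {
                "mean_ppv": res.mean_ppv,
                "ppv_at_cutoff": {str(k): v for k, v in res.ppv_at_cutoff.items()},
                "n_mutated_at_cutoff": {
                    str(k): v for k, v in res.n_mutated_at_cutoff.items()
                },
                "max_ppv": best,
                "max_ppv_k": k_star,
                "list_length": len(usable),
            }
        report["datasets"][cohort.dataset_id] = entry

    # consensus over datasets that evaluated the full strategy set
    full_set = frozenset().union(*(frozenset(r.ordering) for r in rankings))
    complete = [r for r in rankings if frozenset(r.ordering) == full_set]
    excluded = [r.dataset_id for r in rankings if frozenset(r.ordering) != full_set]
    for dataset_id in excluded:
        logger.warning(
            "dataset %s lacks some strategies; excluded from aggregation",
            dataset_id,
        )
    aggregation: dict = {"excluded_datasets": excluded}
    if complete:
        consensus, distance = aggregate_rankings(
            complete, mode=aggregation_mode, seed=seed
        )
        aggregation.update(
            consensus=list(consensus),
            distance=distance,
            datasets_used=[r.dataset_id for r in complete],
        )
    else:
        aggregation.update(consensus=None, distance=None, datasets_used=[])
    report["aggregation"] = aggregation
    return report


def cohorts_from_config(config: Mapping) -> list[Cohort]:
    """Build cohorts from a run configuration.

    Either ``simulate: {specs: [{...CohortSpec fields...}]}`` or
    ``datasets: [{id, annotation, expression?, segments?, der?, mutations,
    loss_cutoff?, one_based?}]`` with file paths.
    """
    if "simulate" in config:
        specs = [CohortSpec(**raw) for raw in config["simulate"]["specs"]]
        return generate_multi_dataset(specs)
    if "datasets" not in config:
        raise ValidationError("config needs a 'simulate' or 'datasets' section")
    from . import io as pio

    cohorts = []
    for raw in config["datasets"]:
        one_based = bool(raw.get("one_based", False))
        genes = pio.read_gene_annotation(raw["annotation"], one_based=one_based)
        mutations = pio.read_mutations(raw["mutations"])
        expression = (
            pio.read_expression(
                raw["expression"], log2_offset=raw.get("log2_offset")
            )
            if raw.get("expression")
            else None
        )
        segments = (
            pio.read_segments(raw["segments"], one_based=one_based)
            if raw.get("segments")
            else None
        )
        der = pio.read_der_table(raw["der"]) if raw.get("der") else None
        exclude = set(raw.get("exclude_samples", []))
        if exclude and segments is not None:
            segments = [p for p in segments if p.sample_id not in exclude]
        if exclude and expression is not None:
            kept = [s for s in expression.sample_ids if s not in exclude]
            expression = type(expression)(expression.frame[kept])
        cohorts.append(
            Cohort(
                dataset_id=str(raw["id"]),
                genes=genes,
                mutations=mutations,
                expression=expression,
                segments=segments,
                der=der,
                loss_cutoff=float(raw.get("loss_cutoff", -0.15)),
            )
        )
    return cohorts
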