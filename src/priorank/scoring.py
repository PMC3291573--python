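"""The four per-gene prioritization scores.

Each strategy is an estimator in the scikit-learn style: construct with its
parameters, call :meth:`fit` on a :class:`~priorank.types.Cohort`, and read
the fitted per-gene scores from ``scores_`` / ``score_table_``.  Module-level
functions expose the same computations on bare matrices for scripting.

Strategies
----------
fitsnp
    The gene's fitSNP DER value, looked up from the supplied table.
expr_variance
    Sample standard deviation of the gene's logged expression values.
dosage_sensitivity
    Spearman rank correlation between expression and gene-level copy number
    across matched samples (dosage-sensitive genes respond to copy number).
loss_frequency
    Fraction of cohort samples whose gene-level copy-number value falls
    below a loss cutoff (the Knudson "first hit").
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator

from .types import (
    Cohort,
    DERTable,
    ExpressionMatrix,
    GeneAnnotation,
    GeneCopyNumberMatrix,
    RankedList,
    ScoreTable,
    SegmentProfile,
    Strategy,
    ValidationError,
)
from .ranking import rank_genes

__all__ = [
    "assign_segment_values",
    "expression_variance",
    "dosage_sensitivity",
    "loss_frequency",
    "der_score",
    "FitSNPScorer",
    "ExpressionVarianceScorer",
    "DosageSensitivityScorer",
    "LossFrequencyScorer",
    "make_scorer",
]


def _assign_one_chrom(
    gene_start: np.ndarray,
    gene_end: np.ndarray,
    seg_start: np.ndarray,
    seg_end: np.ndarray,
    seg_value: np.ndarray,
) -> np.ndarray:
    """Per-gene segment value for one (sample, chromosome).

    A gene takes the value of the segment with the largest overlap; ties go
    to the segment with the smaller start.  A gene overlapping no segment
    takes the value of the segment with the smallest interval gap (again
    ties to the smaller start).  Segments must be sorted by start so that
    first-occurrence argmax/argmin realises the tie-break.
    """
    overlap = np.minimum(gene_end[:, None], seg_end[None, :]) - np.maximum(
        gene_start[:, None], seg_start[None, :]
    )
    overlap = np.clip(overlap, 0, None)
    best = overlap.argmax(axis=1)
    covered = overlap.max(axis=1) > 0
    if not covered.all():
        gap = np.maximum(
            gene_start[:, None] - seg_end[None, :],
            seg_start[None, :] - gene_end[:, None],
        )
        nearest = gap.argmin(axis=1)
        best = np.where(covered, best, nearest)
    return seg_value[best]


def assign_segment_values(
    segments: Sequence[SegmentProfile],
    genes: GeneAnnotation,
    *,
    allow_missing_chrom: bool = False,
) -> GeneCopyNumberMatrix:
    """Project segmented copy-number profiles onto gene coordinates.

    Every gene in every sample receives a CBS value: the maximal-overlap
    segment's value, or — when no segment covers the gene — the value of the
    nearest segment on the same chromosome.  The fallback never crosses
    chromosomes: a sample with no segment at all on a gene's chromosome is
    an error unless ``allow_missing_chrom``, in which case the cell is NaN.
    """
    anno = genes.frame
    order = anno.sort_values(["chrom", "start"], kind="mergesort")
    values = np.full((len(anno), len(segments)), np.nan)
    gene_pos = {g: i for i, g in enumerate(anno.index)}
    by_chrom = {
        chrom: (
            grp["start"].to_numpy(),
            grp["end"].to_numpy(),
            np.array([gene_pos[g] for g in grp.index]),
        )
        for chrom, grp in order.groupby("chrom", sort=False)
    }
    for j, profile in enumerate(segments):
        seg_by_chrom = dict(tuple(profile.segments.groupby("chrom", sort=False)))
        for chrom, (gs, ge, rows) in by_chrom.items():
            seg = seg_by_chrom.get(chrom)
            if seg is None:
                if not allow_missing_chrom:
                    raise ValidationError(
                        f"sample {profile.sample_id} has no segments on "
                        f"chromosome {chrom} (required by {len(rows)} genes); "
                        "pass allow_missing_chrom=True to mark them missing"
                    )
                continue
            values[rows, j] = _assign_one_chrom(
                gs,
                ge,
                seg["start"].to_numpy(),
                seg["end"].to_numpy(),
                seg["value"].to_numpy(),
            )
    frame = pd.DataFrame(
        values, index=anno.index, columns=[p.sample_id for p in segments]
    )
    return GeneCopyNumberMatrix(frame)


def expression_variance(expr: ExpressionMatrix, *, ddof: int = 1) -> ScoreTable:
    """Per-gene sample standard deviation of logged expression."""
    if expr.n_samples < 2:
        raise ValidationError(
            f"expression variance needs >=2 samples, got {expr.n_samples}"
        )
    sd = expr.frame.std(axis=1, ddof=ddof)
    return ScoreTable(Strategy.EXPR_VARIANCE, sd.rename("score"))


def _spearman_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Spearman correlation of two (genes x samples) arrays.

    Average ranks for ties; rows where either vector has zero rank variance
    come back NaN (the correlation is undefined there).
    """
    rx = rankdata(x, axis=1).astype(float)
    ry = rankdata(y, axis=1).astype(float)
    rx -= rx.mean(axis=1, keepdims=True)
    ry -= ry.mean(axis=1, keepdims=True)
    num = np.einsum("ij,ij->i", rx, ry)
    den = np.sqrt(
        np.einsum("ij,ij->i", rx, rx) * np.einsum("ij,ij->i", ry, ry)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return np.clip(rho, -1.0, 1.0, out=rho, where=~np.isnan(rho))


def dosage_sensitivity(
    expr: ExpressionMatrix,
    cn: GeneCopyNumberMatrix,
    *,
    min_matched: int = 3,
) -> ScoreTable:
    """Spearman correlation of expression with copy number per gene.

    Samples are matched by id (intersection of the two matrices' columns,
    in expression order); genes present in both matrices are scored.
    """
    matched = [s for s in expr.sample_ids if s in set(cn.sample_ids)]
    if len(matched) < min_matched:
        raise ValidationError(
            f"dosage sensitivity needs >={min_matched} matched samples, "
            f"got {len(matched)}"
        )
    shared_genes = expr.gene_ids.intersection(cn.gene_ids)
    if shared_genes.empty:
        raise ValidationError("no genes shared between expression and copy number")
    e = expr.frame.loc[shared_genes, matched].to_numpy(float)
    c = cn.frame.loc[shared_genes, matched].to_numpy(float)
    rho = _spearman_rows(e, c)
    return ScoreTable(
        Strategy.DOSAGE_SENSITIVITY,
        pd.Series(rho, index=shared_genes, name="score"),
    )


def loss_frequency(
    cn: GeneCopyNumberMatrix, loss_cutoff: float = -0.15
) -> ScoreTable:
    """Fraction of samples with a copy-number value strictly below the cutoff.

    The cutoff is a log-ratio threshold and is dataset-specific (array
    platform and tumor purity move it); a value exactly at the cutoff does
    not count as a loss.
    """
    values = cn.frame.to_numpy(float)
    n_samples = values.shape[1]
    if n_samples == 0:
        raise ValidationError("copy-number matrix has no samples")
    losses = np.nansum(values < loss_cutoff, axis=1)
    freq = losses / n_samples
    return ScoreTable(
        Strategy.LOSS_FREQUENCY,
        pd.Series(freq, index=cn.gene_ids, name="score"),
    )


def der_score(
    der: DERTable,
    universe: Iterable[str],
    *,
    min_der: float | None = None,
) -> ScoreTable:
    """Restrict the fitSNP DER table to a gene universe.

    Genes absent from the table carry no score and are simply excluded from
    the fitSNP ranking.  ``min_der`` optionally keeps only genes with
    DER strictly above a threshold (0.55 is the cutoff proposed for
    disease-variant association in the original fitSNP work).
    """
    universe = pd.Index(list(universe))
    present = universe.intersection(der.values.index)
    if present.empty:
        raise ValidationError("no universe gene has a DER value")
    scores = der.values.loc[present].rename("score")
    if min_der is not None:
        scores = scores[scores > min_der]
        if scores.empty:
            raise ValidationError(f"no gene has DER > {min_der}")
    return ScoreTable(Strategy.FITSNP, scores)


class _CohortScorer(BaseEstimator):
    """Base class: fit on a Cohort, expose per-gene ``scores_``."""

    strategy: str = ""

    def fit(self, cohort: Cohort, y=None):
        score_table = self._score(cohort)
        self.score_table_ = score_table
        self.scores_ = score_table.scores
        self.n_genes_ = len(score_table)
        return self

    def _score(self, cohort: Cohort) -> ScoreTable:  # pragma: no cover
        raise NotImplementedError

    def rank(self, universe: Iterable[str] | None = None) -> RankedList:
        """Ranked gene list from the fitted scores (best first)."""
        if not hasattr(self, "score_table_"):
            raise ValidationError("scorer is not fitted")
        return rank_genes(self.score_table_, universe=universe)


class FitSNPScorer(_CohortScorer):
    """Rank genes by their fitSNP DER value.

    Parameters
    ----------
    min_der : float or None
        If set, genes with DER <= min_der are dropped before ranking.
    """

    strategy = Strategy.FITSNP

    def __init__(self, min_der: float | None = None):
        self.min_der = min_der

    def _score(self, cohort: Cohort) -> ScoreTable:
        if cohort.der is None:
            raise ValidationError(
                f"cohort {cohort.dataset_id}: no DER table supplied"
            )
        return der_score(cohort.der, cohort.genes.gene_ids, min_der=self.min_der)


class ExpressionVarianceScorer(_CohortScorer):
    """Rank genes by the standard deviation of their logged expression."""

    strategy = Strategy.EXPR_VARIANCE

    def __init__(self, ddof: int = 1):
        self.ddof = ddof

    def _score(self, cohort: Cohort) -> ScoreTable:
        if cohort.expression is None:
            raise ValidationError(
                f"cohort {cohort.dataset_id}: no expression matrix supplied"
            )
        return expression_variance(cohort.expression, ddof=self.ddof)


class DosageSensitivityScorer(_CohortScorer):
    """Rank genes by expression/copy-number Spearman correlation.

    Requires matched expression and copy-number samples (ids shared between
    the two layers); ``min_matched`` guards against meaningless correlations
    from too few pairs.
    """

    strategy = Strategy.DOSAGE_SENSITIVITY

    def __init__(self, min_matched: int = 3, allow_missing_chrom: bool = False):
        self.min_matched = min_matched
        self.allow_missing_chrom = allow_missing_chrom

    def _score(self, cohort: Cohort) -> ScoreTable:
        if cohort.expression is None or cohort.segments is None:
            raise ValidationError(
                f"cohort {cohort.dataset_id}: dosage sensitivity needs both "
                "expression and copy-number layers"
            )
        cn = assign_segment_values(
            cohort.segments,
            cohort.genes,
            allow_missing_chrom=self.allow_missing_chrom,
        )
        self.copy_number_ = cn
        return dosage_sensitivity(
            cohort.expression, cn, min_matched=self.min_matched
        )


class LossFrequencyScorer(_CohortScorer):
    """Rank genes by their frequency of copy-number loss in the cohort.

    ``loss_cutoff=None`` takes the cohort's own dataset-specific cutoff.
    """

    strategy = Strategy.LOSS_FREQUENCY

    def __init__(
        self,
        loss_cutoff: float | None = None,
        allow_missing_chrom: bool = False,
    ):
        self.loss_cutoff = loss_cutoff
        self.allow_missing_chrom = allow_missing_chrom

    def _score(self, cohort: Cohort) -> ScoreTable:
        if cohort.segments is None:
            raise ValidationError(
                f"cohort {cohort.dataset_id}: no copy-number layer supplied"
            )
        cn = assign_segment_values(
            cohort.segments,
            cohort.genes,
            allow_missing_chrom=self.allow_missing_chrom,
        )
        self.copy_number_ = cn
        cutoff = self.loss_cutoff if self.loss_cutoff is not None else cohort.loss_cutoff
        return loss_frequency(cn, loss_cutoff=cutoff)


def make_scorer(strategy: str, **params) -> _CohortScorer:
    """Instantiate the scorer for a strategy label (aliases accepted)."""
    strategy = Strategy.canonical(strategy)
    cls = {
        Strategy.FITSNP: FitSNPScorer,
        Strategy.EXPR_VARIANCE: ExpressionVarianceScorer,
        Strategy.DOSAGE_SENSITIVITY: DosageSensitivityScorer,
        Strategy.LOSS_FREQUENCY: LossFrequencyScorer,
    }[strategy]
    return cls(**params)
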