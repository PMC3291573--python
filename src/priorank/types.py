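"""Domain types shared across the prioritization pipeline.

All genomic coordinates are stored 0-based, half-open.  Tables are carried as
pandas objects inside thin validated wrappers, so every layer (annotation,
expression, segmented copy number, DER lookup, mutation screen) has a single
canonical in-memory form regardless of the file dialect it came from.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "Strategy",
    "GeneAnnotation",
    "ExpressionMatrix",
    "SegmentProfile",
    "GeneCopyNumberMatrix",
    "DERTable",
    "MutationSet",
    "ScoreTable",
    "RankedList",
    "YieldCurve",
    "EvaluationResult",
    "StrategyRanking",
    "Cohort",
]


class ValidationError(ValueError):
    """An input table violates a structural invariant."""


class Strategy:
    """Canonical labels for the four single prioritization strategies."""

    FITSNP = "fitsnp"
    EXPR_VARIANCE = "expr_variance"
    DOSAGE_SENSITIVITY = "dosage_sensitivity"
    LOSS_FREQUENCY = "loss_frequency"

    ALL = (FITSNP, EXPR_VARIANCE, DOSAGE_SENSITIVITY, LOSS_FREQUENCY)

    #: short aliases used on the command line
    ALIASES = {
        "fitsnp": FITSNP,
        "ev": EXPR_VARIANCE,
        "ds": DOSAGE_SENSITIVITY,
        "fcnl": LOSS_FREQUENCY,
    }

    @classmethod
    def canonical(cls, label: str) -> str:
        label = label.strip().lower()
        if label in cls.ALL:
            return label
        if label in cls.ALIASES:
            return cls.ALIASES[label]
        raise ValidationError(f"unknown strategy label: {label!r}")


def _require_unique(ids: pd.Index, what: str) -> None:
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups[:10]}")


@dataclass(frozen=True)
class GeneAnnotation:
    """Genomic coordinates per gene: the join key across all data layers.

    ``frame`` is indexed by gene_id with columns ``chrom`` (str), ``start``
    and ``end`` (int, 0-based half-open).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = {"chrom", "start", "end"} - set(df.columns)
        if missing:
            raise ValidationError(f"annotation missing columns: {sorted(missing)}")
        _require_unique(df.index, "gene_id")
        if (df["start"] < 0).any():
            bad = df.index[df["start"] < 0].tolist()
            raise ValidationError(f"negative start coordinates for genes {bad[:10]}")
        degenerate = df["start"] >= df["end"]
        if degenerate.any():
            bad = df.index[degenerate].tolist()
            raise ValidationError(
                f"start >= end (empty/inverted interval) for genes {bad[:10]}"
            )

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, int, int]]
    ) -> "GeneAnnotation":
        df = pd.DataFrame.from_records(
            list(records), columns=["gene_id", "chrom", "start", "end"]
        ).set_index("gene_id")
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        return cls(df)

    @property
    def gene_ids(self) -> pd.Index:
        return self.frame.index

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Logged gene-expression values, genes x samples.

    Values must already be on a log scale; the readers offer a log2(x+c)
    transform for raw matrices but the matrix itself carries no unit flag.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        _require_unique(self.frame.index, "gene_id")
        _require_unique(self.frame.columns, "sample_id")
        if self.frame.isna().any().any():
            n = int(self.frame.isna().sum().sum())
            raise ValidationError(
                f"expression matrix contains {n} missing values; "
                "impute or drop before constructing"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.frame.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.frame.columns

    @property
    def n_samples(self) -> int:
        return self.frame.shape[1]


@dataclass(frozen=True)
class SegmentProfile:
    """Piecewise-constant copy-number profile (CBS output) for one sample.

    ``segments`` has columns chrom, start, end, value and is sorted by
    (chrom, start).  Segments must not overlap within a chromosome.
    """

    sample_id: str
    segments: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.segments
        missing = {"chrom", "start", "end", "value"} - set(df.columns)
        if missing:
            raise ValidationError(f"segment table missing columns: {sorted(missing)}")
        if (df["start"] >= df["end"]).any():
            raise ValidationError(
                f"sample {self.sample_id}: segment with start >= end"
            )
        ordered = df.sort_values(["chrom", "start"], kind="mergesort")
        for chrom, grp in ordered.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if (starts[1:] < ends[:-1]).any():
                raise ValidationError(
                    f"overlapping segments in sample {self.sample_id}, "
                    f"chromosome {chrom}"
                )
        if not ordered.index.equals(df.index):
            object.__setattr__(self, "segments", ordered.reset_index(drop=True))

    @property
    def chromosomes(self) -> set[str]:
        return set(self.segments["chrom"].unique())


@dataclass(frozen=True)
class GeneCopyNumberMatrix:
    """Per-gene CBS values, genes x samples, every cell filled (or NaN only
    where a sample lacks the gene's chromosome and that was explicitly
    allowed)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        _require_unique(self.frame.index, "gene_id")
        _require_unique(self.frame.columns, "sample_id")

    @property
    def gene_ids(self) -> pd.Index:
        return self.frame.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.frame.columns


@dataclass(frozen=True)
class DERTable:
    """fitSNP differential expression ratios: gene_id -> DER in [0, 1].

    The DER of a gene is the fraction of expression studies in which the gene
    was called differentially expressed among the studies that evaluated it;
    it is consumed as a lookup table, never recomputed here.
    """

    values: pd.Series

    def __post_init__(self) -> None:
        _require_unique(self.values.index, "gene_id")
        v = self.values
        bad = v[(v < 0) | (v > 1) | v.isna()]
        if len(bad):
            raise ValidationError(
                f"DER values outside [0,1] (or missing) for genes "
                f"{bad.index.tolist()[:10]}"
            )

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class MutationSet:
    """The mutated genes of a sequencing screen plus the size of the screened
    universe, which together define the baseline PPV."""

    mutated_genes: frozenset[str]
    n_genes_sequenced: int
    sample_counts: Mapping[str, int] | None = None
    universe: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.n_genes_sequenced <= 0:
            raise ValidationError("n_genes_sequenced must be positive")
        if len(self.mutated_genes) > self.n_genes_sequenced:
            raise ValidationError(
                f"{len(self.mutated_genes)} mutated genes exceed the "
                f"{self.n_genes_sequenced} genes sequenced"
            )
        if self.universe is not None and not self.mutated_genes <= self.universe:
            extra = sorted(self.mutated_genes - self.universe)
            raise ValidationError(
                f"mutated genes outside the sequenced universe: {extra[:10]}"
            )

    @property
    def n_mutated(self) -> int:
        return len(self.mutated_genes)


_SCORE_RANGES: dict[str, tuple[float, float]] = {
    Strategy.FITSNP: (0.0, 1.0),
    Strategy.LOSS_FREQUENCY: (0.0, 1.0),
    Strategy.DOSAGE_SENSITIVITY: (-1.0, 1.0),
    Strategy.EXPR_VARIANCE: (0.0, np.inf),
}


@dataclass(frozen=True)
class ScoreTable:
    """One strategy's per-gene prioritization values.

    NaN marks an undefined score (e.g. a zero-variance correlation); such
    genes are excluded from ranking rather than pulled to a default value.
    """

    strategy: str
    scores: pd.Series

    def __post_init__(self) -> None:
        _require_unique(self.scores.index, "gene_id")
        lo, hi = _SCORE_RANGES.get(self.strategy, (-np.inf, np.inf))
        v = self.scores.dropna()
        # tiny numerical excursions from correlation arithmetic are clamped
        eps = 1e-9
        if ((v < lo - eps) | (v > hi + eps)).any():
            bad = v[(v < lo - eps) | (v > hi + eps)]
            raise ValidationError(
                f"{self.strategy} scores outside [{lo}, {hi}]: "
                f"{bad.index.tolist()[:10]}"
            )

    @property
    def defined(self) -> pd.Series:
        """Scores with undefined (NaN) entries removed."""
        return self.scores.dropna()

    def __len__(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class RankedList:
    """An ordered gene list, best candidate first."""

    label: str
    genes: tuple[str, ...]
    scores: pd.Series | None = None

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"ranked list {self.label!r} has duplicate genes")

    def top(self, k: int) -> tuple[str, ...]:
        if k < 0:
            raise ValidationError("k must be non-negative")
        return self.genes[:k]

    def __len__(self) -> int:
        return len(self.genes)

    def restrict(self, universe: Iterable[str]) -> "RankedList":
        """Drop genes outside ``universe``, preserving order."""
        allowed = set(universe)
        kept = tuple(g for g in self.genes if g in allowed)
        scores = self.scores.loc[list(kept)] if self.scores is not None else None
        return RankedList(self.label, kept, scores)


@dataclass(frozen=True)
class YieldCurve:
    """Minimal list length needed to capture m mutated genes, for each m."""

    genes_needed: Mapping[int, int]
    baseline_needed: Mapping[int, int]

    def __post_init__(self) -> None:
        for curve in (self.genes_needed, self.baseline_needed):
            ms = sorted(curve)
            ks = [curve[m] for m in ms]
            if any(b < a for a, b in zip(ks, ks[1:])):
                raise ValidationError("yield curve must be non-decreasing in m")


@dataclass(frozen=True)
class EvaluationResult:
    """PPV of one ranked list against one mutation screen, on the standard
    cutoff ladder, next to the screen's baseline."""

    label: str
    cutoffs: tuple[int, ...]
    ppv_at_cutoff: Mapping[int, float | None]
    n_mutated_at_cutoff: Mapping[int, int | None]
    baseline_ppv: float
    mean_ppv: float
    yield_curve: YieldCurve | None = None

    def available(self) -> dict[int, float]:
        return {k: v for k, v in self.ppv_at_cutoff.items() if v is not None}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k in self.cutoffs:
            ppv = self.ppv_at_cutoff[k]
            rows.append(
                {
                    "cutoff": k,
                    "n_mutated": self.n_mutated_at_cutoff[k],
                    "ppv": ppv,
                    "baseline_ppv": self.baseline_ppv,
                    "fold_change": (
                        ppv / self.baseline_ppv
                        if ppv is not None and self.baseline_ppv > 0
                        else None
                    ),
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class StrategyRanking:
    """One dataset's ordering of prioritization strategies, with per-strategy
    importance weights (mean PPVs in the standard analysis)."""

    dataset_id: str
    ordering: tuple[str, ...]
    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        if len(set(self.ordering)) != len(self.ordering):
            raise ValidationError(
                f"dataset {self.dataset_id}: strategy listed twice"
            )
        missing = set(self.ordering) - set(self.weights)
        if missing:
            raise ValidationError(
                f"dataset {self.dataset_id}: no weight for {sorted(missing)}"
            )
        if any(w < 0 for w in self.weights.values()):
            raise ValidationError(f"dataset {self.dataset_id}: negative weight")

    def position(self, item: str) -> int:
        """1-based position of ``item`` in this ordering."""
        return self.ordering.index(item) + 1


@dataclass
class Cohort:
    """One tumor entity's full input bundle.  Layers may be absent (None)
    when the corresponding data do not exist for the entity."""

    dataset_id: str
    genes: GeneAnnotation
    mutations: MutationSet
    expression: ExpressionMatrix | None = None
    segments: Sequence[SegmentProfile] | None = None
    der: DERTable | None = None
    loss_cutoff: float = -0.15
    extras: dict = field(default_factory=dict)
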