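"""Synthetic multi-omic tumor cohorts.

Generates the complete input bundle the pipeline consumes — gene annotation,
logged expression, segmented copy number, fitSNP DER table, mutation screen —
with controllable association between a gene's mutation status and each
prioritization signal:

* ``der_shift``   raises the Beta mean of mutated genes' DER values;
* ``var_ratio``   multiplies mutated genes' expression standard deviation;
* ``loss_or``     scales the odds that a mutated gene's locus is lost;
* ``dosage_coupling`` mixes a mutated gene's expression with its own
  copy-number value across matched samples.

At the null (shift 0, ratio 1, odds 1, coupling 0) every signal is
independent of mutation status, so any ranking is a random draw with respect
to the screen and PPV calibrates to the baseline rate.  Default cohort
dimensions follow the colon-cancer-like setting: ~19 profiled samples and a
4.7% baseline mutation rate over an 18000-gene screen.

All randomness flows from one master seed through named child streams
(``default_rng([seed, stream])``), so a fixed seed reproduces the bundle
bit-for-bit regardless of which layers are consumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .scoring import assign_segment_values
from .types import (
    Cohort,
    DERTable,
    ExpressionMatrix,
    GeneAnnotation,
    MutationSet,
    SegmentProfile,
    ValidationError,
)

__all__ = ["CohortSpec", "generate_cohort", "generate_multi_dataset"]

# named sub-stream indices under the master seed
_STREAM_ANNOTATION = 0
_STREAM_MUTATION = 1
_STREAM_COPY_NUMBER = 2
_STREAM_DER = 3
_STREAM_EXPRESSION = 4

ALL_LAYERS = ("expression", "copy_number", "der")


@dataclass(frozen=True, kw_only=True)
class CohortSpec:
    """Parameters of one synthetic tumor cohort.

    Effect sizes default to the null; cohort dimensions default to a
    colon-cancer-like entity (19 expression / 19 copy-number samples, all
    matched, baseline mutation rate 4.7% over 18000 genes).
    """

    seed: int
    dataset_id: str = "synthetic"
    n_genes: int = 18000
    n_samples_expr: int = 19
    n_samples_cn: int = 19
    n_matched: int = 19
    baseline_mutation_rate: float = 0.047
    # effect sizes (null defaults)
    der_shift: float = 0.0
    var_ratio: float = 1.0
    loss_or: float = 1.0
    dosage_coupling: float = 0.0
    # genome geometry
    n_chromosomes: int = 22
    gene_length_mean: float = 20_000.0
    gene_gap_mean: float = 30_000.0
    segment_length_mean: float = 5_000_000.0
    # background copy-number state rates and DER shape
    loss_base_prob: float = 0.10
    gain_base_prob: float = 0.05
    der_mean: float = 0.40
    der_concentration: float = 5.0
    loss_cutoff: float = -0.15
    layers: tuple[str, ...] = ALL_LAYERS

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValidationError("n_genes must be positive")
        if not 0 < self.baseline_mutation_rate < 1:
            raise ValidationError("baseline_mutation_rate must be in (0, 1)")
        if self.n_matched > min(self.n_samples_expr, self.n_samples_cn):
            raise ValidationError(
                "n_matched cannot exceed either layer's sample count"
            )
        if not -1 <= self.der_shift <= 1:
            raise ValidationError("der_shift must be in [-1, 1]")
        if self.var_ratio <= 0 or self.loss_or <= 0:
            raise ValidationError("var_ratio and loss_or must be positive")
        if not 0 <= self.dosage_coupling <= 1:
            raise ValidationError("dosage_coupling must be in [0, 1]")
        if not 0 < self.loss_base_prob < 1 or not 0 <= self.gain_base_prob < 1:
            raise ValidationError("background state probabilities out of range")
        unknown = set(self.layers) - set(ALL_LAYERS)
        if unknown:
            raise ValidationError(f"unknown layers: {sorted(unknown)}")


def _stream(spec: CohortSpec, index: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, index])


def _make_annotation(spec: CohortSpec) -> GeneAnnotation:
    rng = _stream(spec, _STREAM_ANNOTATION)
    per_chrom = np.full(spec.n_chromosomes, spec.n_genes // spec.n_chromosomes)
    per_chrom[: spec.n_genes % spec.n_chromosomes] += 1
    records = []
    gene_no = 0
    for c, count in enumerate(per_chrom, start=1):
        pos = 0
        for _ in range(count):
            gap = int(rng.exponential(spec.gene_gap_mean)) + 1
            length = int(rng.exponential(spec.gene_length_mean)) + 1000
            start = pos + gap
            end = start + length
            records.append((f"G{gene_no:05d}", f"chr{c}", start, end))
            pos = end
            gene_no += 1
    return GeneAnnotation.from_records(records)


def _make_mutations(spec: CohortSpec, genes: GeneAnnotation) -> MutationSet:
    rng = _stream(spec, _STREAM_MUTATION)
    flags = rng.random(len(genes)) < spec.baseline_mutation_rate
    mutated = frozenset(genes.gene_ids[flags])
    # per-sample multiplicity: most genes are hit in a single sample
    counts = {g: int(1 + rng.poisson(0.1)) for g in sorted(mutated)}
    return MutationSet(
        mutated_genes=mutated,
        n_genes_sequenced=len(genes),
        sample_counts=counts,
        universe=frozenset(genes.gene_ids),
    )


def _chromosome_extents(genes: GeneAnnotation) -> dict[str, int]:
    return {
        str(chrom): int(grp["end"].max()) + 10_000
        for chrom, grp in genes.frame.groupby("chrom", sort=False)
    }


def _override_interval(
    segs: list[list], start: int, end: int, value: float, state: str
) -> list[list]:
    """Replace [start, end) in a sorted non-overlapping segment list.

    Entries are [start, end, value, state]; overlapped portions are clipped
    and the focal interval inserted with the given value and state.
    """
    out: list[list] = []
    for s, e, v, st in segs:
        if e <= start or s >= end:
            out.append([s, e, v, st])
            continue
        if s < start:
            out.append([s, start, v, st])
        if e > end:
            out.append([end, e, v, st])
    out.append([start, end, value, state])
    out.sort(key=lambda seg: seg[0])
    return out


def _make_segments(
    spec: CohortSpec,
    genes: GeneAnnotation,
    mutations: MutationSet,
    sample_ids: Sequence[str],
) -> list[SegmentProfile]:
    rng = _stream(spec, _STREAM_COPY_NUMBER)
    extents = _chromosome_extents(genes)
    p0 = spec.loss_base_prob
    odds = spec.loss_or * p0 / (1 - p0)
    p_target = odds / (1 + odds)
    # complementary focal probabilities realising the odds-scaled target
    p_focal_loss = max(0.0, (p_target - p0) / (1 - p0))
    p_focal_rescue = max(0.0, (p0 - p_target) / p0) if p0 > 0 else 0.0
    mutated_by_chrom = {
        chrom: grp.loc[grp.index.isin(mutations.mutated_genes)]
        for chrom, grp in genes.frame.groupby("chrom", sort=False)
    }

    def loss_value() -> float:
        return float(rng.normal(-0.6, 0.1))

    def neutral_value() -> float:
        return float(rng.normal(0.0, 0.05))

    def gain_value() -> float:
        return float(rng.normal(0.45, 0.1))

    profiles = []
    for sample in sample_ids:
        rows = []
        for chrom, length in extents.items():
            segs: list[list] = []
            pos = 0
            while pos < length:
                seg_len = int(rng.exponential(spec.segment_length_mean)) + 50_000
                end = min(pos + seg_len, length)
                u = rng.random()
                if u < p0:
                    state, value = "loss", loss_value()
                elif u < p0 + spec.gain_base_prob:
                    state, value = "gain", gain_value()
                else:
                    state, value = "neutral", neutral_value()
                segs.append([pos, end, value, state])
                pos = end
            # focal events over mutated genes realise the per-gene loss odds
            for gene_id, row in mutated_by_chrom[chrom].iterrows():
                gs, ge = int(row["start"]), int(row["end"])
                covering = max(
                    (seg for seg in segs if seg[1] > gs and seg[0] < ge),
                    key=lambda seg: min(seg[1], ge) - max(seg[0], gs),
                )
                is_loss = covering[3] == "loss"
                if not is_loss and p_focal_loss > 0 and rng.random() < p_focal_loss:
                    segs = _override_interval(segs, gs, ge, loss_value(), "loss")
                elif is_loss and p_focal_rescue > 0 and rng.random() < p_focal_rescue:
                    segs = _override_interval(segs, gs, ge, neutral_value(), "neutral")
            for s, e, v, _ in segs:
                rows.append((chrom, s, e, v))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
        profiles.append(SegmentProfile(str(sample), df))
    return profiles


def _make_der(spec: CohortSpec, genes: GeneAnnotation, mutations: MutationSet) -> DERTable:
    rng = _stream(spec, _STREAM_DER)
    nu = spec.der_concentration
    mu0 = spec.der_mean
    mutated = np.fromiter(
        (g in mutations.mutated_genes for g in genes.gene_ids), bool, len(genes)
    )
    mu = np.where(mutated, np.clip(mu0 + spec.der_shift, 0.01, 0.99), mu0)
    values = rng.beta(mu * nu, (1 - mu) * nu)
    return DERTable(pd.Series(values, index=genes.gene_ids, name="der"))


def _make_expression(
    spec: CohortSpec,
    genes: GeneAnnotation,
    mutations: MutationSet,
    sample_ids: Sequence[str],
    matched_cn: pd.DataFrame | None,
) -> ExpressionMatrix:
    rng = _stream(spec, _STREAM_EXPRESSION)
    n_genes = len(genes)
    n_samples = len(sample_ids)
    mean = rng.normal(8.0, 2.0, n_genes)
    base_sd = rng.uniform(0.2, 0.8, n_genes)
    mutated = np.fromiter(
        (g in mutations.mutated_genes for g in genes.gene_ids), bool, n_genes
    )
    sd = np.where(mutated, base_sd * spec.var_ratio, base_sd)
    noise = rng.standard_normal((n_genes, n_samples))
    latent = noise
    if matched_cn is not None and spec.dosage_coupling > 0:
        c = np.where(mutated, spec.dosage_coupling, 0.0)[:, None]
        cn = matched_cn.loc[genes.gene_ids].to_numpy(float)
        cn_sd = cn.std(axis=1, ddof=0, keepdims=True)
        z = np.where(cn_sd > 0, (cn - cn.mean(axis=1, keepdims=True)) / np.where(cn_sd > 0, cn_sd, 1.0), 0.0)
        matched_cols = [i for i, s in enumerate(sample_ids) if s in matched_cn.columns]
        latent = noise.copy()
        latent[:, matched_cols] = (
            c * z + np.sqrt(1 - c**2) * noise[:, matched_cols]
        )
    values = mean[:, None] + sd[:, None] * latent
    frame = pd.DataFrame(values, index=genes.gene_ids, columns=list(sample_ids))
    return ExpressionMatrix(frame)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate one complete synthetic cohort per its spec.

    The same seed reproduces the same bundle exactly; distinct seeds give
    statistically independent cohorts.
    """
    genes = _make_annotation(spec)
    mutations = _make_mutations(spec, genes)

    matched_ids = [f"S{i:03d}" for i in range(spec.n_matched)]
    cn_ids = matched_ids + [
        f"C{i:03d}" for i in range(spec.n_samples_cn - spec.n_matched)
    ]
    expr_ids = matched_ids + [
        f"E{i:03d}" for i in range(spec.n_samples_expr - spec.n_matched)
    ]

    segments = None
    matched_cn_frame = None
    if "copy_number" in spec.layers:
        segments = _make_segments(spec, genes, mutations, cn_ids)
        if spec.n_matched > 0 and "expression" in spec.layers:
            matched_profiles = [p for p in segments if p.sample_id in matched_ids]
            matched_cn_frame = assign_segment_values(matched_profiles, genes).frame

    expression = None
    if "expression" in spec.layers:
        expression = _make_expression(
            spec, genes, mutations, expr_ids, matched_cn_frame
        )

    der = _make_der(spec, genes, mutations) if "der" in spec.layers else None

    return Cohort(
        dataset_id=spec.dataset_id,
        genes=genes,
        mutations=mutations,
        expression=expression,
        segments=segments,
        der=der,
        loss_cutoff=spec.loss_cutoff,
        extras={"spec": spec},
    )


def generate_multi_dataset(specs: Sequence[CohortSpec]) -> list[Cohort]:
    """Generate one cohort per spec (a multi-tumor-entity design).

    Entities lacking a layer (no matched expression/copy-number data, say)
    are expressed through each spec's ``layers`` and ``n_matched`` fields.
    Dataset ids must be unique.
    """
    ids = [s.dataset_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValidationError("dataset_id must be unique across specs")
    return [generate_cohort(s) for s in specs]
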