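import numpy as np
import pandas as pd
import pytest

from priorank.simulate import CohortSpec, generate_cohort
from priorank.types import (
    DERTable,
    ExpressionMatrix,
    GeneAnnotation,
    MutationSet,
    SegmentProfile,
)


@pytest.fixture(scope="session")
def small_null_cohort():
    """A small cohort with every signal independent of mutation status."""
    spec = CohortSpec(seed=20, n_genes=600, n_chromosomes=6)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_enriched_cohort():
    """A small cohort where every strategy's signal tracks mutation status."""
    spec = CohortSpec(
        seed=21,
        n_genes=600,
        n_chromosomes=6,
        der_shift=0.25,
        var_ratio=3.0,
        loss_or=4.0,
        dosage_coupling=0.8,
    )
    return generate_cohort(spec)


@pytest.fixture
def toy_annotation():
    return GeneAnnotation.from_records(
        [
            ("gA", "chr1", 100, 200),
            ("gB", "chr1", 2000, 2100),
            ("gC", "chr2", 50, 500),
        ]
    )


@pytest.fixture
def toy_profile():
    seg = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr2"],
            "start": [0, 1000, 0],
            "end": [1000, 5000, 2000],
            "value": [-0.3, 0.2, 0.05],
        }
    )
    return SegmentProfile("S0", seg)


def make_expression(values, gene_ids=None, sample_ids=None):
    values = np.asarray(values, float)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=sample_ids))


def make_mutation_set(mutated, n_sequenced, universe=None):
    return MutationSet(
        mutated_genes=frozenset(mutated),
        n_genes_sequenced=n_sequenced,
        universe=frozenset(universe) if universe is not None else None,
    )


def make_der(mapping):
    return DERTable(pd.Series(mapping, dtype=float))
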