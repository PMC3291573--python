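import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from priorank.scoring import (
    DosageSensitivityScorer,
    ExpressionVarianceScorer,
    FitSNPScorer,
    LossFrequencyScorer,
    assign_segment_values,
    der_score,
    dosage_sensitivity,
    expression_variance,
    loss_frequency,
    make_scorer,
)
from priorank.types import (
    GeneAnnotation,
    GeneCopyNumberMatrix,
    SegmentProfile,
    Strategy,
    ValidationError,
)

from conftest import make_der, make_expression


def profile(sample_id, rows):
    return SegmentProfile(
        sample_id,
        pd.DataFrame(rows, columns=["chrom", "start", "end", "value"]),
    )


class TestAssignSegmentValues:
    def test_containment_takes_covering_segment(self):
        genes = GeneAnnotation.from_records([("g", "chr1", 100, 200)])
        p = profile("s", [("chr1", 0, 1000, -0.3)])
        cn = assign_segment_values([p], genes)
        assert cn.frame.loc["g", "s"] == pytest.approx(-0.3)

    def test_equal_overlap_tie_goes_to_smaller_start(self):
        genes = GeneAnnotation.from_records([("g", "chr1", 90, 110)])
        p = profile("s", [("chr1", 0, 100, 0.1), ("chr1", 100, 500, -0.5)])
        cn = assign_segment_values([p], genes)
        assert cn.frame.loc["g", "s"] == pytest.approx(0.1)

    def test_uncovered_gene_takes_nearest_segment(self):
        genes = GeneAnnotation.from_records([("g", "chr1", 2000, 2100)])
        p = profile("s", [("chr1", 0, 1000, 0.2), ("chr1", 5000, 9000, -0.7)])
        cn = assign_segment_values([p], genes)
        # gap to [0,1000) is 1000 < 2900 to [5000,9000)
        assert cn.frame.loc["g", "s"] == pytest.approx(0.2)

    def test_missing_chromosome_is_error_by_default(self):
        genes = GeneAnnotation.from_records([("g", "chrX", 0, 100)])
        p = profile("s", [("chr1", 0, 1000, 0.0)])
        with pytest.raises(ValidationError, match="chrX"):
            assign_segment_values([p], genes)
        cn = assign_segment_values([p], genes, allow_missing_chrom=True)
        assert np.isnan(cn.frame.loc["g", "s"])

    def test_matches_brute_force_on_random_genomes(self):
        """Overlap-then-distance choice agrees with exhaustive scoring."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            n_genes = rng.integers(1, 50)
            n_segs = rng.integers(1, 10)
            starts = np.sort(rng.integers(0, 10_000, n_genes))
            genes = GeneAnnotation.from_records(
                [
                    (f"g{i}", "chr1", int(s), int(s) + int(rng.integers(1, 500)))
                    for i, s in enumerate(starts)
                ]
            )
            bounds = np.sort(rng.choice(np.arange(0, 12_000, 10), n_segs + 1, replace=False))
            rows = [
                ("chr1", int(bounds[i]), int(bounds[i + 1]), float(rng.normal()))
                for i in range(n_segs)
            ]
            p = profile("s", rows)
            cn = assign_segment_values([p], genes)
            for gid, row in genes.frame.iterrows():
                gs, ge = row["start"], row["end"]
                best = None
                for s, e, v in ((r[1], r[2], r[3]) for r in rows):
                    ov = max(0, min(ge, e) - max(gs, s))
                    gap = max(gs - e, s - ge) if ov == 0 else 0
                    key = (-ov, gap, s)
                    if best is None or key < best[0]:
                        best = (key, v)
                # overlap dominates; among non-overlapping, distance, then start
                expected = best[1]
                assert cn.frame.loc[gid, "s"] == pytest.approx(expected)


class TestExpressionVariance:
    def test_constant_gene_scores_zero(self):
        expr = make_expression([[5.0, 5.0, 5.0]])
        assert expression_variance(expr).scores.iloc[0] == 0.0

    def test_two_sample_closed_form(self):
        a, b = 3.0, 8.0
        expr = make_expression([[a, b]])
        assert expression_variance(expr).scores.iloc[0] == pytest.approx(
            abs(a - b) / np.sqrt(2)
        )

    def test_single_sample_rejected(self):
        with pytest.raises(ValidationError, match=">=2 samples"):
            expression_variance(make_expression([[1.0]]))

    def test_matches_two_pass_sd_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(200, 20))
        got = expression_variance(make_expression(x)).scores.to_numpy()
        means = x.mean(axis=1)
        oracle = np.sqrt(((x - means[:, None]) ** 2).sum(axis=1) / (x.shape[1] - 1))
        np.testing.assert_allclose(got, oracle, atol=1e-10)

    def test_scales_linearly_under_positive_scaling(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(50, 8))
        base = expression_variance(make_expression(x)).scores
        scaled = expression_variance(make_expression(3.5 * x)).scores
        np.testing.assert_allclose(scaled, 3.5 * base, rtol=1e-12)


def cn_matrix(values, gene_ids=None, sample_ids=None):
    values = np.asarray(values, float)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    return GeneCopyNumberMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    )


class TestDosageSensitivity:
    def test_monotone_increasing_gives_plus_one(self):
        expr = make_expression([[1.0, 2.0, 3.0, 4.0]])
        cn = cn_matrix([[-0.5, 0.0, 0.3, 0.9]])
        assert dosage_sensitivity(expr, cn).scores.iloc[0] == pytest.approx(1.0)

    def test_monotone_decreasing_gives_minus_one(self):
        expr = make_expression([[4.0, 3.0, 2.0, 1.0]])
        cn = cn_matrix([[-0.5, 0.0, 0.3, 0.9]])
        assert dosage_sensitivity(expr, cn).scores.iloc[0] == pytest.approx(-1.0)

    def test_zero_variance_vector_is_undefined(self):
        expr = make_expression([[2.0, 2.0, 2.0, 2.0]])
        cn = cn_matrix([[-0.5, 0.0, 0.3, 0.9]])
        assert np.isnan(dosage_sensitivity(expr, cn).scores.iloc[0])

    def test_too_few_matched_samples_rejected(self):
        expr = make_expression([[1.0, 2.0]], sample_ids=["a", "b"])
        cn = cn_matrix([[0.0, 1.0]], sample_ids=["a", "b"])
        with pytest.raises(ValidationError, match="matched samples"):
            dosage_sensitivity(expr, cn)

    def test_matches_scipy_spearman_with_ties(self):
        rng = np.random.default_rng(3)
        # coarse rounding forces ties so average ranks are exercised
        x = np.round(rng.normal(size=(40, 20)), 1)
        y = np.round(rng.normal(size=(40, 20)), 1)
        got = dosage_sensitivity(make_expression(x), cn_matrix(y)).scores.to_numpy()
        for i in range(40):
            expected = spearmanr(x[i], y[i]).statistic
            if np.isnan(expected):
                assert np.isnan(got[i])
            else:
                assert got[i] == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(30, 15))
        y = rng.normal(size=(30, 15))
        base = dosage_sensitivity(make_expression(x), cn_matrix(y)).scores
        warped = dosage_sensitivity(
            make_expression(np.exp(x)), cn_matrix(y**3)
        ).scores
        np.testing.assert_allclose(base, warped, atol=1e-12)


class TestLossFrequency:
    def test_all_samples_below_cutoff(self):
        cn = cn_matrix(np.full((1, 10), -0.9))
        assert loss_frequency(cn, -0.15).scores.iloc[0] == 1.0

    def test_partial_losses_counted_exactly(self):
        row = [-0.4, -0.4, -0.4] + [0.0] * 7
        cn = cn_matrix([row])
        assert loss_frequency(cn, -0.15).scores.iloc[0] == pytest.approx(0.3)

    def test_value_at_cutoff_is_not_a_loss(self):
        cn = cn_matrix([[-0.15, -0.15, -0.5, 0.0]])
        assert loss_frequency(cn, -0.15).scores.iloc[0] == pytest.approx(0.25)

    def test_scores_are_integer_fractions(self):
        rng = np.random.default_rng(5)
        cn = cn_matrix(rng.normal(scale=0.4, size=(30, 13)))
        freq = loss_frequency(cn, -0.15).scores.to_numpy()
        counts = freq * 13
        np.testing.assert_allclose(counts, np.round(counts), atol=1e-9)
        assert ((freq >= 0) & (freq <= 1)).all()


class TestDerScore:
    def test_restriction_to_universe(self):
        der = make_der({"a": 0.2, "b": 0.8, "c": 0.5, "d": 0.9})
        table = der_score(der, ["a", "b", "c", "e", "f"])
        assert set(table.scores.index) == {"a", "b", "c"}

    def test_threshold_keeps_strictly_greater(self):
        der = make_der({"a": 0.55, "b": 0.56, "c": 0.9})
        table = der_score(der, ["a", "b", "c"], min_der=0.55)
        assert set(table.scores.index) == {"b", "c"}

    def test_identity_on_full_table(self):
        der = make_der({"a": 0.2, "b": 0.8})
        table = der_score(der, ["a", "b"])
        pd.testing.assert_series_equal(
            table.scores.sort_index(), der.values.sort_index(),
            check_names=False,
        )

    def test_empty_intersection_rejected(self):
        der = make_der({"a": 0.2})
        with pytest.raises(ValidationError, match="no universe gene"):
            der_score(der, ["z"])


class TestScorerEstimators:
    @pytest.mark.parametrize(
        "alias, cls",
        [
            ("fitsnp", FitSNPScorer),
            ("ev", ExpressionVarianceScorer),
            ("ds", DosageSensitivityScorer),
            ("fcnl", LossFrequencyScorer),
        ],
    )
    def test_factory_resolves_aliases(self, alias, cls):
        assert isinstance(make_scorer(alias), cls)

    def test_fit_sets_sklearn_style_attributes(self, small_null_cohort):
        scorer = LossFrequencyScorer(loss_cutoff=-0.15)
        assert scorer.get_params()["loss_cutoff"] == -0.15
        scorer.fit(small_null_cohort)
        assert scorer.scores_.notna().all()
        assert scorer.n_genes_ == len(small_null_cohort.genes)
        ranked = scorer.rank()
        assert len(ranked) == scorer.n_genes_

    def test_unfitted_scorer_cannot_rank(self):
        with pytest.raises(ValidationError, match="not fitted"):
            FitSNPScorer().rank()

    def test_missing_layer_raises(self, small_null_cohort):
        import dataclasses

        bare = dataclasses.replace(
            small_null_cohort, expression=None, segments=None, der=None
        )
        for strategy in Strategy.ALL:
            with pytest.raises(ValidationError):
                make_scorer(strategy).fit(bare)
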