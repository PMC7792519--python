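"""Randomized singleton controls, chromosome bias, distance effects."""

import numpy as np
import pandas as pd
import pytest

from paralog_epidiv.io import GeneRecord
from paralog_epidiv.profiles import HMProfileMatrix
from paralog_epidiv.resampling import (
    chromosome_bias_test,
    distance_divergence_correlation,
    null_divergence_replicates,
    randomized_control_comparison,
    same_vs_different_chromosome_comparison,
    sample_singleton_pairs,
)


def _singletons(n, n_chrom=3):
    return [
        GeneRecord(f"g{i}", f"Chr{i % n_chrom + 1}", 1 + 2000 * i, 1000 + 2000 * i, "+")
        for i in range(n)
    ]


class TestSampleSingletonPairs:
    def test_deterministic_under_fixed_seed(self):
        genes = _singletons(50)
        r1 = sample_singleton_pairs(genes, 20, 5, seed=42)
        r2 = sample_singleton_pairs(genes, 20, 5, seed=42)
        for a, b in zip(r1.indices, r2.indices):
            np.testing.assert_array_equal(a, b)

    def test_different_seeds_differ(self):
        genes = _singletons(50)
        r1 = sample_singleton_pairs(genes, 20, 1, seed=1)
        r2 = sample_singleton_pairs(genes, 20, 1, seed=2)
        assert not np.array_equal(r1.indices[0], r2.indices[0])

    def test_members_distinct_and_constraint_honoured(self):
        genes = _singletons(30)
        chrom = {g.gene_id: g.chromosome for g in genes}
        reps = sample_singleton_pairs(
            genes, 50, 3, constraint="different_chromosomes", seed=0
        )
        for r in range(3):
            for a, b in reps.pairs(r):
                assert a != b
                assert chrom[a] != chrom[b]

    def test_single_chromosome_makes_constraint_unsatisfiable(self):
        genes = _singletons(10, n_chrom=1)
        with pytest.raises(ValueError, match="one chromosome"):
            sample_singleton_pairs(
                genes, 5, 2, constraint="different_chromosomes", seed=0
            )

    def test_default_replicate_count_is_ten_thousand(self):
        import inspect

        sig = inspect.signature(sample_singleton_pairs)
        assert sig.parameters["n_replicates"].default == 10_000

    def test_null_divergence_shapes_match_observed(self):
        genes = _singletons(40)
        rng = np.random.default_rng(3)
        matrix = HMProfileMatrix(
            "ORF",
            pd.DataFrame(
                rng.normal(size=(40, 10)),
                index=[g.gene_id for g in genes],
                columns=[f"m{i}" for i in range(10)],
            ),
        )
        reps = sample_singleton_pairs(genes, 25, 4, seed=1)
        nulls = null_divergence_replicates(reps, matrix)
        assert len(nulls) == 4 and all(len(v) == 25 for v in nulls)
        assert all(np.isfinite(v).all() for v in nulls)


class TestControlComparison:
    def test_identical_constant_samples_give_p_one(self):
        p, direction = randomized_control_comparison([1.0, 1.0], [1.0, 1.0, 1.0])
        assert p == 1.0 and direction == "equal"

    def test_shifted_down_observed_detected_as_lower(self):
        rng = np.random.default_rng(4)
        obs = rng.normal(0.4, 0.1, 300)
        null = rng.normal(0.8, 0.1, 3000)
        p, direction = randomized_control_comparison(obs, null)
        assert p < 1e-10 and direction == "lower"

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            randomized_control_comparison([], [1.0])


class TestChromosomeBias:
    def test_hand_computed_chi_square(self):
        dup = [True] * 60 + [False] * 40
        rnd = [True] * 50 + [False] * 50
        chi2, df, p = chromosome_bias_test(dup, rnd)
        assert chi2 == pytest.approx(2.0202020202, abs=1e-9)
        assert df == 1

    def test_identical_proportions_give_zero_statistic(self):
        dup = [True] * 30 + [False] * 70
        rnd = [True] * 60 + [False] * 140
        chi2, _, p = chromosome_bias_test(dup, rnd)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chromosome_bias_test([True, True], [True, True])

    def test_enriched_same_chromosome_pairs_detected(self, small_dataset):
        """The generator places duplicates on one chromosome more often
        than random singleton pairs; the chi-square must pick it up."""
        from paralog_epidiv.resampling import sample_singleton_pairs

        singles = small_dataset.singletons
        reps = sample_singleton_pairs(singles, len(small_dataset.pairs), 1, seed=9)
        chrom = {g.gene_id: g.chromosome for g in small_dataset.catalog}
        rnd_same = [chrom[a] == chrom[b] for a, b in reps.pairs(0)]
        chi2, df, p = chromosome_bias_test(
            [p_.same_chromosome for p_ in small_dataset.pairs], rnd_same
        )
        dup_rate = np.mean([p_.same_chromosome for p_ in small_dataset.pairs])
        assert dup_rate > np.mean(rnd_same)
        assert p < 1e-6


class TestDistanceAndStrata:
    def _records(self, n, rng, couple=False):
        dist = rng.uniform(1e3, 1e6, n)
        d = 0.2 + 1e-6 * dist if couple else rng.uniform(0, 2, n)
        return pd.DataFrame(
            {
                "mode": "tandem",
                "same_chromosome": True,
                "distance_bp": dist,
                "d_hm_orf": d,
            }
        )

    def test_independent_distance_uncorrelated(self):
        rng = np.random.default_rng(5)
        r, p, n = distance_divergence_correlation(self._records(2000, rng), "ORF")
        assert abs(r) < 0.05

    def test_linear_coupling_recovered(self):
        rng = np.random.default_rng(6)
        r, _, _ = distance_divergence_correlation(
            self._records(200, rng, couple=True), "ORF"
        )
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(7)
        rec = self._records(100, rng)
        rec["d_hm_orf"] = 0.3 + 5e-7 * rec["distance_bp"] + rng.normal(0, 0.2, 100)
        r, _, _ = distance_divergence_correlation(rec, "ORF")
        expected = np.corrcoef(rec["distance_bp"], rec["d_hm_orf"])[0, 1]
        assert r == pytest.approx(expected, abs=1e-12)

    def test_same_chromosome_stratum_with_lower_divergence_detected(self):
        rng = np.random.default_rng(8)
        rec = pd.DataFrame(
            {
                "same_chromosome": [True] * 300 + [False] * 300,
                "d_hm_orf": np.concatenate(
                    [rng.normal(0.4, 0.1, 300), rng.normal(0.7, 0.1, 300)]
                ),
                "d_hm_promoter": rng.uniform(0, 2, 600),
            }
        )
        out = same_vs_different_chromosome_comparison(rec)
        assert out["ORF"]["p_wilcoxon"] < 1e-10
        assert out["ORF"]["median_same"] < out["ORF"]["median_different"]
        assert "p_ttest" in out["ORF"]  # secondary test also emitted

    def test_tiny_stratum_skipped_with_warning(self):
        rec = pd.DataFrame(
            {"same_chromosome": [True, False, False], "d_hm_orf": [0.5, 0.6, 0.7]}
        )
        with pytest.warns(UserWarning, match="stratum"):
            out = same_vs_different_chromosome_comparison(rec, regions=("ORF",))
        assert out == {}
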