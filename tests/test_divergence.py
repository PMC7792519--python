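"""D_HM, per-mark paralog correlations, Mantel concordance, Ka/Ks coupling."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from paralog_epidiv.divergence import (
    MantelResult,
    compute_pair_table,
    correlate_divergence_with_substitution,
    divergence_by_mode,
    expected_pair_divergence,
    filter_pairs_by_kaks,
    mantel_concordance,
    pair_divergence,
    pairwise_profile_divergence,
    per_mark_pair_correlation,
)
from paralog_epidiv.io import DuplicatePair
from paralog_epidiv.profiles import HMProfileMatrix


def pearson_oracle(a, b):
    """Direct sum-formula Pearson correlation, independent of numpy.corrcoef."""
    n = len(a)
    sa, sb = sum(a), sum(b)
    saa = sum(x * x for x in a)
    sbb = sum(x * x for x in b)
    sab = sum(x * y for x, y in zip(a, b))
    num = n * sab - sa * sb
    den = math.sqrt((n * saa - sa * sa) * (n * sbb - sb * sb))
    return num / den


class TestPairDivergence:
    def test_identical_profiles_have_zero_divergence(self):
        a = [0.1, -1.2, 0.7, 2.0, -0.5, 0.3, 1.1, -0.9, 0.0, 0.4]
        assert pair_divergence(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_profiles_have_divergence_two(self):
        a = np.linspace(-1, 1, 10)
        assert pair_divergence(a, -a) == pytest.approx(2.0, abs=1e-12)

    def test_interleaved_ranks_example_matches_formula_oracle(self):
        a = list(range(1, 11))
        b = [2, 1, 4, 3, 6, 5, 8, 7, 10, 9]
        expected = 1 - pearson_oracle(a, b)  # = 2/33
        assert expected == pytest.approx(2 / 33, abs=1e-12)
        assert pair_divergence(a, b) == pytest.approx(expected, abs=1e-12)

    def test_pairwise_complete_marks(self):
        a = [1.0, 2.0, math.nan, 4.0, 5.0]
        b = [2.0, 4.0, 9.0, 8.0, 10.0]
        # NaN mark excluded; remaining marks exactly proportional
        assert pair_divergence(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_too_few_shared_marks_is_missing(self):
        assert math.isnan(pair_divergence([1, 2, math.nan], [1, 2, 3]))

    def test_zero_variance_profile_is_missing(self):
        assert math.isnan(pair_divergence([1, 1, 1, 1], [1, 2, 3, 4]))

    @given(
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=3, max_size=10).filter(
            lambda xs: np.std(xs) > 1e-3
        ),
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=10, max_size=10).filter(
            lambda xs: np.std(xs) > 1e-3
        ),
    )
    def test_symmetric_and_bounded(self, a, b):
        n = min(len(a), len(b))
        a, b = a[:n], b[:n]
        d1, d2 = pair_divergence(a, b), pair_divergence(b, a)
        assert d1 == pytest.approx(d2, abs=1e-12)
        assert 0.0 <= d1 <= 2.0

    @given(
        st.lists(st.floats(-3, 3, allow_nan=False), min_size=5, max_size=5).filter(
            lambda xs: np.std(xs) > 1e-3
        ),
        st.lists(st.floats(-3, 3, allow_nan=False), min_size=5, max_size=5).filter(
            lambda xs: np.std(xs) > 1e-3
        ),
        st.floats(0.1, 10),
        st.floats(-5, 5),
    )
    def test_invariant_under_common_positive_affine_rescaling(self, a, b, m, c):
        d0 = pair_divergence(a, b)
        d1 = pair_divergence(
            [m * x + c for x in a], [m * x + c for x in b]
        )
        assert d1 == pytest.approx(d0, abs=1e-6)

    def test_vectorised_path_matches_scalar(self):
        rng = np.random.default_rng(5)
        A = rng.normal(size=(40, 10))
        B = rng.normal(size=(40, 10))
        A[rng.random(A.shape) < 0.1] = np.nan
        vec = pairwise_profile_divergence(A, B)
        scalar = np.array([pair_divergence(a, b) for a, b in zip(A, B)])
        np.testing.assert_allclose(vec, scalar, atol=1e-12, equal_nan=True)


def _matrix_from_rows(rows, gene_ids, region="ORF", marks=None):
    marks = marks or [f"m{i}" for i in range(rows.shape[1])]
    return HMProfileMatrix(
        region, pd.DataFrame(rows, index=gene_ids, columns=marks)
    )


class TestPerMarkCorrelation:
    def test_self_pairs_give_unit_correlation(self):
        rng = np.random.default_rng(1)
        ids = [f"g{i}" for i in range(30)]
        matrix = _matrix_from_rows(rng.normal(size=(30, 4)), ids)
        df = pd.DataFrame(
            {"gene_a": ids[:15], "gene_b": ids[:15], "mode": "WGD"}
        )
        table = per_mark_pair_correlation(df, matrix)
        overall = table[table["mode"] == "all"]
        assert np.allclose(overall["r"], 1.0)

    def test_independent_profiles_have_near_zero_correlation(self):
        rng = np.random.default_rng(2)
        n = 2000
        ids = [f"g{i}" for i in range(2 * n)]
        matrix = _matrix_from_rows(rng.normal(size=(2 * n, 10)), ids)
        df = pd.DataFrame(
            {"gene_a": ids[:n], "gene_b": ids[n:], "mode": "WGD"}
        )
        table = per_mark_pair_correlation(df, matrix)
        assert (table.loc[table["mode"] == "all", "r"].abs() < 0.05).all()


class TestMantel:
    def _pairs_and_matrix(self, rho, n_pairs=300, n_marks=4, seed=0):
        rng = np.random.default_rng(seed)
        cov = np.full((n_marks, n_marks), 0.3)
        np.fill_diagonal(cov, 1.0)
        chol = np.linalg.cholesky(cov)
        a = rng.normal(size=(n_pairs, n_marks)) @ chol.T
        b = rho * a + np.sqrt(1 - rho**2) * rng.normal(size=(n_pairs, n_marks)) @ chol.T
        ids_a = [f"a{i}" for i in range(n_pairs)]
        ids_b = [f"b{i}" for i in range(n_pairs)]
        matrix = _matrix_from_rows(
            np.vstack([a, b]), ids_a + ids_b, marks=[f"m{i}" for i in range(n_marks)]
        )
        pairs = pd.DataFrame({"gene_a": ids_a, "gene_b": ids_b, "mode": "WGD"})
        return pairs, matrix

    def test_identical_sides_give_r_one(self):
        pairs, matrix = self._pairs_and_matrix(rho=1.0)
        res = mantel_concordance(pairs, matrix)
        assert res.r == pytest.approx(1.0, abs=1e-9)
        assert res.n_perm == "exhaustive"  # 4 marks

    def test_exhaustive_p_matches_brute_force_enumeration(self):
        pairs, matrix = self._pairs_and_matrix(rho=0.6, seed=3)
        res = mantel_concordance(pairs, matrix)
        # independent oracle: enumerate all 24 permutations directly
        ga = matrix.profiles(pairs["gene_a"])
        gb = matrix.profiles(pairs["gene_b"])
        ma = np.corrcoef(ga, rowvar=False)
        mb = np.corrcoef(gb, rowvar=False)
        iu = np.triu_indices(4, 1)
        r_obs = np.corrcoef(ma[iu], mb[iu])[0, 1]
        count = 0
        perms = list(itertools.permutations(range(4)))
        for perm in perms:
            p = np.array(perm)
            mp = mb[np.ix_(p, p)]
            r_perm = np.corrcoef(ma[iu], mp[iu])[0, 1]
            if abs(r_perm) >= abs(r_obs) - 1e-12:
                count += 1
        assert res.r == pytest.approx(r_obs, abs=1e-12)
        assert res.p == pytest.approx(count / len(perms), abs=1e-12)

    def test_sampled_p_for_larger_matrices_uses_add_one_estimate(self):
        pairs, matrix = self._pairs_and_matrix(rho=0.5, n_marks=7, seed=4)
        res = mantel_concordance(pairs, matrix, n_perm=999, seed=11)
        assert res.n_perm == 999
        assert 0 < res.p <= 1

    def test_agrees_with_skbio_mantel_statistic(self):
        """Independent cross-check against scikit-bio on distance matrices."""
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        pairs, matrix = self._pairs_and_matrix(rho=0.6, n_marks=6, seed=5)
        res = mantel_concordance(pairs, matrix, n_perm=999, seed=1)
        ma = np.corrcoef(matrix.profiles(pairs["gene_a"]), rowvar=False)
        mb = np.corrcoef(matrix.profiles(pairs["gene_b"]), rowvar=False)
        da = skbio_distance.DistanceMatrix(1 - np.round(ma, 12), validate=False)
        db = skbio_distance.DistanceMatrix(1 - np.round(mb, 12), validate=False)
        r_sk, p_sk, _ = skbio_distance.mantel(da, db, permutations=999)
        # 1 - r is an affine map, so the Mantel statistic is identical
        assert res.r == pytest.approx(r_sk, abs=1e-9)
        assert res.p == pytest.approx(p_sk, abs=0.08)

    def test_constant_matrix_rejected(self):
        ids = [f"g{i}" for i in range(6)]
        rows = np.tile(np.linspace(-1, 1, 3), (6, 1))
        matrix = _matrix_from_rows(rows + 1e-9 * 0, ids)
        pairs = pd.DataFrame(
            {"gene_a": ids[:3], "gene_b": ids[3:], "mode": "WGD"}
        )
        with pytest.raises(ValueError):
            mantel_concordance(pairs, matrix)

    def test_heatmap_combines_both_sides(self):
        pairs, matrix = self._pairs_and_matrix(rho=0.7, seed=6)
        res = mantel_concordance(pairs, matrix)
        ma = np.corrcoef(matrix.profiles(pairs["gene_a"]), rowvar=False)
        mb = np.corrcoef(matrix.profiles(pairs["gene_b"]), rowvar=False)
        heat = res.heatmap.to_numpy()
        iu, il = np.triu_indices(4, 1), np.tril_indices(4, -1)
        np.testing.assert_allclose(heat[iu], ma[iu], atol=1e-12)
        np.testing.assert_allclose(heat[il], mb[il], atol=1e-12)


class TestKaKsFilter:
    def _pair(self, ka, ks):
        return DuplicatePair("A", "B", "WGD", ka=ka, ks=ks)

    def test_strict_boundaries(self):
        assert filter_pairs_by_kaks([self._pair(0.49, 1.99)])
        assert not filter_pairs_by_kaks([self._pair(0.5, 1.0)])
        assert not filter_pairs_by_kaks([self._pair(0.1, 2.0)])

    def test_missing_rates_removed(self):
        assert not filter_pairs_by_kaks([self._pair(None, 1.0)])
        assert not filter_pairs_by_kaks([self._pair(0.1, None)])

    def test_dataframe_variant_matches(self):
        df = pd.DataFrame(
            {"ka": [0.49, 0.5, np.nan], "ks": [1.99, 1.0, 1.0]}
        )
        assert filter_pairs_by_kaks(df).index.tolist() == [0]


class TestSubstitutionCoupling:
    def test_exactly_linear_divergence_gives_unit_correlation(self):
        ka = np.linspace(0.01, 0.4, 50)
        df = pd.DataFrame(
            {"mode": "WGD", "ka": ka, "ks": ka * 3, "d_hm_orf": 0.1 + 2 * ka}
        )
        res = correlate_divergence_with_substitution(df, "ka", "ORF")
        assert res.loc[res["mode"] == "all", "r"].iloc[0] == pytest.approx(1.0)

    def test_shuffled_pairing_has_near_zero_correlation(self):
        rng = np.random.default_rng(7)
        n = 2000
        df = pd.DataFrame(
            {
                "mode": "WGD",
                "ka": rng.uniform(0, 0.4, n),
                "ks": rng.uniform(0, 1.9, n),
                "d_hm_orf": rng.uniform(0, 2, n),
            }
        )
        res = correlate_divergence_with_substitution(df, "ka", "ORF")
        assert abs(res.loc[res["mode"] == "all", "r"].iloc[0]) < 0.05


class TestDivergenceByMode:
    def test_single_mode_rejected(self):
        df = pd.DataFrame({"mode": ["WGD"] * 5, "d_hm_orf": np.linspace(0, 1, 5)})
        with pytest.raises(ValueError, match="modes"):
            divergence_by_mode(df, "ORF")

    def test_shifted_mode_detected_with_highest_median(self):
        rng = np.random.default_rng(8)
        frames = []
        for mode, loc in [("WGD", 0.5), ("tandem", 0.4), ("transposed", 0.9)]:
            frames.append(
                pd.DataFrame(
                    {"mode": mode, "d_hm_orf": rng.normal(loc, 0.1, 300).clip(0, 2)}
                )
            )
        res = divergence_by_mode(pd.concat(frames, ignore_index=True), "ORF")
        assert res["p"] < 1e-6
        summary = res["summary"].set_index("group")
        modes_only = summary.drop(index="duplicate")
        assert modes_only["median"].idxmax() == "transposed"

    def test_null_calibration_rejection_rate_near_alpha(self):
        """All modes from one distribution: omnibus p rejects at ~5%."""
        rng = np.random.default_rng(9)
        n_sims, rejections = 200, 0
        for _ in range(n_sims):
            df = pd.DataFrame(
                {
                    "mode": np.repeat(["WGD", "tandem", "proximal"], 40),
                    "d_hm_orf": rng.uniform(0, 2, 120),
                }
            )
            if divergence_by_mode(df, "ORF")["p"] < 0.05 :
                rejections += 1
        assert 0.005 <= rejections / n_sims <= 0.12


class TestClosedForm:
    def test_expected_divergence_limits(self):
        assert expected_pair_divergence(1.0) == pytest.approx(0.0)
        assert expected_pair_divergence(0.0) == pytest.approx(1.0)
        # bias shrinks with profile length
        short = expected_pair_divergence(0.5, n_marks=5)
        long_ = expected_pair_divergence(0.5, n_marks=100)
        assert abs(long_ - 0.5) < abs(short - 0.5)
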