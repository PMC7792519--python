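"""Generator correctness: determinism, invariants, parameter recovery."""

import filecmp

import numpy as np
import pandas as pd
import pytest

from paralog_epidiv.divergence import (
    compute_pair_table,
    expected_pair_divergence,
    per_mark_pair_correlation,
)
from paralog_epidiv.simulate import (
    ConfigurationError,
    SyntheticConfig,
    generate_dataset,
    write_dataset,
)


class TestConfigValidation:
    def test_tandem_pairs_require_same_chromosome(self):
        cfg = SyntheticConfig(
            n_pairs_by_mode={"tandem": 10},
            same_chromosome_prob_by_mode={
                "WGD": 0.3,
                "tandem": 0.5,
                "proximal": 1.0,
                "transposed": 0.1,
            },
        )
        with pytest.raises(ConfigurationError, match="tandem"):
            cfg.validate()

    def test_mark_names_must_be_ten_distinct(self):
        with pytest.raises(ConfigurationError, match="10 distinct"):
            SyntheticConfig(mark_names=("a",) * 10).validate()
        with pytest.raises(ConfigurationError, match="10 distinct"):
            SyntheticConfig(mark_names=("a", "b", "c")).validate()

    def test_mixture_must_sum_to_one(self):
        with pytest.raises(ConfigurationError, match="probability"):
            SyntheticConfig(
                go_type_mixture={"I": 0.5, "II": 0.5, "III": 0.5, "IV": 0.0, "V": 0.0}
            ).validate()

    def test_genome_must_hold_requested_pairs(self):
        with pytest.raises(ConfigurationError, match="genome"):
            SyntheticConfig(
                n_chromosomes=2,
                genes_per_chromosome=10,
                n_pairs_by_mode={"WGD": 100},
                same_chromosome_prob_by_mode={
                    "WGD": 0.3, "tandem": 1.0, "proximal": 1.0, "transposed": 0.1,
                },
            ).validate()

    def test_defaults_are_valid(self):
        SyntheticConfig().validate()


class TestGenerateDataset:
    def test_no_pairs_gives_singletons_only(self):
        cfg = SyntheticConfig(
            genes_per_chromosome=20,
            n_pairs_by_mode={m: 0 for m in ("WGD", "tandem", "proximal", "transposed")},
            samples_per_condition={"Normal": 4, "Stress": 0, "CM_mu": 0},
            seed=1,
        )
        ds = generate_dataset(cfg)
        assert ds.pairs == []
        assert all(g.duplication_class == "singleton" for g in ds.catalog)

    def test_same_seed_byte_identical_outputs(self, tmp_path, small_config):
        d1 = generate_dataset(small_config)
        d2 = generate_dataset(small_config)
        write_dataset(d1, tmp_path / "run1")
        write_dataset(d2, tmp_path / "run2")
        names = sorted(p.name for p in (tmp_path / "run1").iterdir())
        match, mismatch, errors = filecmp.cmpfiles(
            tmp_path / "run1", tmp_path / "run2", names, shallow=False
        )
        assert mismatch == [] and errors == []
        assert set(match) == set(names)

    def test_different_seed_changes_data(self, small_config):
        import dataclasses

        other = dataclasses.replace(small_config, seed=small_config.seed + 1)
        d1, d2 = generate_dataset(small_config), generate_dataset(other)
        assert not np.allclose(
            d1.hm_orf.values.to_numpy(), d2.hm_orf.values.to_numpy()
        )

    def test_dataset_invariants(self, small_dataset):
        small_dataset.validate()
        small_dataset.hm_orf.validate()
        small_dataset.hm_promoter.validate()

    def test_physical_layout_by_mode(self, small_dataset):
        by_id = {g.gene_id: g for g in small_dataset.catalog}
        for p in small_dataset.pairs:
            ga, gb = by_id[p.gene_a], by_id[p.gene_b]
            if p.mode in ("tandem", "proximal"):
                assert ga.chromosome == gb.chromosome
                index_gap = abs(ga.start - gb.start) // 2000
                if p.mode == "tandem":
                    assert index_gap == 1
                else:
                    assert 2 <= index_gap <= 10

    def test_transposed_mostly_on_different_chromosomes(self, small_dataset):
        same = [p.same_chromosome for p in small_dataset.pairs if p.mode == "transposed"]
        assert np.mean(same) < 0.5

    def test_expression_conditions_match_config(self, small_dataset, small_config):
        counts = small_dataset.conditions.value_counts().to_dict()
        assert counts == small_config.samples_per_condition
        assert list(small_dataset.expression.columns) == list(
            small_dataset.conditions.index
        )
        assert (small_dataset.expression.to_numpy() >= 0).all()


@pytest.fixture(scope="module")
def wgd_dataset():
    cfg = SyntheticConfig(
        genes_per_chromosome=900,
        n_pairs_by_mode={"WGD": 2000, "tandem": 0, "proximal": 0, "transposed": 0},
        pair_hm_correlation_by_mode={
            "WGD": 0.8, "tandem": 0.65, "proximal": 0.6, "transposed": 0.3,
        },
        pair_rho_jitter=0.0,
        promoter_rho_boost=0.0,
        samples_per_condition={"Normal": 0, "Stress": 0, "CM_mu": 0},
        seed=99,
    )
    return generate_dataset(cfg)


class TestParameterRecovery:
    def test_per_mark_correlation_recovers_rho(self, wgd_dataset):
        table = per_mark_pair_correlation(
            compute_pair_table(wgd_dataset.pairs), wgd_dataset.hm_orf
        )
        r = table.loc[table["mode"] == "all", "r"]
        assert ((r - 0.8).abs() < 0.05).all()
        # and the mean over marks is within 3 standard errors
        se = (1 - 0.8**2) / np.sqrt(2000)
        assert abs(r.mean() - 0.8) < 3 * se

    def test_mean_divergence_matches_closed_form(self, wgd_dataset):
        records = compute_pair_table(wgd_dataset.pairs, wgd_dataset.hm_orf)
        observed = records["d_hm_orf"].mean()
        expected = expected_pair_divergence(0.8, n_marks=10)
        assert observed == pytest.approx(expected, abs=0.02)

    def test_type_mixture_recovered_within_binomial_ci(self, small_dataset, small_config):
        truth_types = pd.Series(
            [t["functional_type"] for t in small_dataset.truth["pairs"]]
        )
        modes = pd.Series([t["mode"] for t in small_dataset.truth["pairs"]])
        for mode in ("WGD", "tandem"):
            mix = small_config.mixture_for(mode)
            sel = truth_types[modes == mode]
            n = len(sel)
            for t, p_expected in mix.items():
                observed = (sel == t).mean()
                half_width = 3 * np.sqrt(p_expected * (1 - p_expected) / n)
                assert abs(observed - p_expected) <= half_width + 1e-9, (mode, t)

    def test_kaks_increases_with_injected_divergence(self, small_dataset):
        truth = pd.DataFrame(small_dataset.truth["pairs"])
        ka = pd.Series([p.ka for p in small_dataset.pairs])
        d_true = truth["d_true"]
        assert np.corrcoef(ka, d_true)[0, 1] > 0.3
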