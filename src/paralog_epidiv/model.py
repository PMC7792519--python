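"""Model/Results interface tying the analysis stages together.

:class:`DuplicateHMDivergence` is built from the study's five inputs
(gene catalog, duplicate-pair lists, two HM profile matrices, an
expression matrix with condition labels, a gene→GO map); its
:meth:`~DuplicateHMDivergence.fit` runs the full analysis — per-pair
D_HM scores, per-mark paralog correlations, Mantel concordance,
randomized singleton controls, chromosome bias, Ka/Ks and expression
coupling, and GO-overlap functional classification — and returns a
:class:`DivergenceResults` carrying every statistic with its p-value and
sample size, a ``summary()`` table, and a JSON-ready report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import divergence as dv
from . import expression as ex
from . import functional as fn
from . import resampling as rs
from .io import (
    DuplicatePair,
    GeneRecord,
    annotate_pairs,
    read_gene_catalog,
    read_go_map,
    read_matrix,
    read_pair_lists,
    read_sample_conditions,
)
from .profiles import HMProfileMatrix

__all__ = ["DuplicateHMDivergence", "DivergenceResults"]


class DuplicateHMDivergence:
    """Histone-modification divergence analysis of duplicate gene pairs.

    Parameters
    ----------
    catalog
        Gene records with coordinates and duplication classes; genes not
        in any pair act as singletons for the randomized controls.
    pairs
        Duplicate pairs with modes and (optionally) Ka/Ks.
    hm_orf, hm_promoter
        Z-scored genes × marks profile matrices for the two regions.
    expression, conditions
        Optional FPKM-like matrix (genes × samples) and sample→condition
        labels; enables the expression-divergence stage.
    go_map
        Optional gene→GO-term map; enables the functional stage.
    ka_max, ks_max
        Strict upper bounds of the selection filter applied before
        relating D_HM to substitution rates (defaults Ka < 0.5, Ks < 2.0).
    """

    def __init__(
        self,
        catalog: Sequence[GeneRecord],
        pairs: Sequence[DuplicatePair],
        hm_orf: HMProfileMatrix,
        hm_promoter: HMProfileMatrix,
        expression: pd.DataFrame | None = None,
        conditions: pd.Series | None = None,
        go_map: Mapping[str, set] | None = None,
        *,
        ka_max: float = 0.5,
        ks_max: float = 2.0,
    ) -> None:
        if (expression is None) != (conditions is None):
            raise ValueError("expression and conditions must be supplied together")
        self.catalog = list(catalog)
        if pairs and any(p.same_chromosome is None for p in pairs):
            pairs = annotate_pairs(pairs, self.catalog)
        self.pairs = list(pairs)
        self.hm_orf = hm_orf
        self.hm_promoter = hm_promoter
        self.expression = expression
        self.conditions = conditions
        self.go_map = dict(go_map) if go_map is not None else None
        self.ka_max = ka_max
        self.ks_max = ks_max
        self.singletons = [
            g for g in self.catalog if g.duplication_class == "singleton"
        ]

    # -- constructors -------------------------------------------------

    @classmethod
    def from_dataset(cls, dataset, **kwargs) -> "DuplicateHMDivergence":
        """Build from a :class:`~paralog_epidiv.simulate.SyntheticDataset`."""
        return cls(
            dataset.catalog,
            dataset.pairs,
            dataset.hm_orf,
            dataset.hm_promoter,
            expression=dataset.expression,
            conditions=dataset.conditions,
            go_map=dataset.go_map,
            **kwargs,
        )

    @classmethod
    def from_files(
        cls,
        catalog: str,
        pairs_by_mode: Mapping[str, str],
        hm_orf: str,
        hm_promoter: str,
        expression: str | None = None,
        samples: str | None = None,
        go_map: str | None = None,
        catalog_format: str = "tsv",
        **kwargs,
    ) -> "DuplicateHMDivergence":
        """Read the five inputs from disk; enrichment matrices are
        z-scored per mark on load."""
        cat = read_gene_catalog(catalog, format=catalog_format)
        prs = read_pair_lists(pairs_by_mode)
        # tag catalog classes from the pair lists
        mode_of: dict[str, str] = {}
        for p in prs:
            mode_of[p.gene_a] = p.mode
            mode_of[p.gene_b] = p.mode
        from dataclasses import replace

        cat = [
            replace(g, duplication_class=mode_of.get(g.gene_id, "singleton"))
            for g in cat
        ]
        orf = HMProfileMatrix.from_enrichment(read_matrix(hm_orf), "ORF")
        prom = HMProfileMatrix.from_enrichment(read_matrix(hm_promoter), "promoter")
        expr = read_matrix(expression) if expression else None
        cond = read_sample_conditions(samples) if samples else None
        go = read_go_map(go_map) if go_map else None
        return cls(
            cat, prs, orf, prom, expression=expr, conditions=cond, go_map=go, **kwargs
        )

    # -- fitting ------------------------------------------------------

    def fit(
        self,
        n_randomizations: int = rs.DEFAULT_N_REPLICATES,
        mantel_permutations: int = 9999,
        seed: int | None = None,
        expression_condition: str = "Normal",
    ) -> "DivergenceResults":
        """Run every analysis stage and collect the results.

        Stages needing missing inputs (expression, GO) or unsatisfiable
        preconditions (no singletons, one chromosome) are skipped and
        listed in ``results.skipped``.
        """
        skipped: dict[str, str] = {}
        records = dv.compute_pair_table(self.pairs, self.hm_orf, self.hm_promoter)

        per_mark = pd.concat(
            [
                dv.per_mark_pair_correlation(records, self.hm_orf),
                dv.per_mark_pair_correlation(records, self.hm_promoter),
            ],
            ignore_index=True,
        )

        mantel: dict[str, dv.MantelResult] = {}
        for matrix in (self.hm_orf, self.hm_promoter):
            try:
                mantel[matrix.region] = dv.mantel_concordance(
                    records, matrix, n_perm=mantel_permutations, seed=seed
                )
            except ValueError as exc:
                skipped[f"mantel_{matrix.region}"] = str(exc)

        mode_tests = {}
        for region in ("ORF", "promoter"):
            try:
                mode_tests[region] = dv.divergence_by_mode(records, region)
            except ValueError as exc:
                skipped[f"divergence_by_mode_{region}"] = str(exc)

        filtered = dv.filter_pairs_by_kaks(records, self.ka_max, self.ks_max)
        kaks_corr = []
        for which in ("ka", "ks"):
            for region in ("ORF", "promoter"):
                if len(filtered) >= 3:
                    kaks_corr.append(
                        dv.correlate_divergence_with_substitution(
                            filtered, which, region
                        )
                    )
        kaks_corr_df = (
            pd.concat(kaks_corr, ignore_index=True) if kaks_corr else None
        )
        if kaks_corr_df is None:
            skipped["kaks_correlation"] = "fewer than 3 pairs pass the Ka/Ks filter"

        randomization: dict[str, rs.RandomizationResult] = {}
        chromosome_bias = None
        if len(self.singletons) >= 2 and len(records):
            matrices = {"ORF": self.hm_orf, "promoter": self.hm_promoter}
            for region, matrix in matrices.items():
                col = dv.region_column(region)
                obs = records[col].to_numpy(float)
                res = rs.randomization_analysis(
                    obs[np.isfinite(obs)],
                    self.singletons,
                    matrix,
                    n_replicates=n_randomizations,
                    constraint="none",
                    seed=seed,
                )
                randomization[region] = res
            # chromosome bias: duplicates vs one matched randomized replicate
            reps = rs.sample_singleton_pairs(
                self.singletons, len(records), 1, constraint="none", seed=seed
            )
            chrom = {g.gene_id: g.chromosome for g in self.catalog}
            rnd_same = [
                chrom[a] == chrom[b] for a, b in reps.pairs(0)
            ]
            try:
                chromosome_bias = rs.chromosome_bias_test(
                    records["same_chromosome"].to_list(), rnd_same
                )
            except ValueError as exc:
                skipped["chromosome_bias"] = str(exc)
            # constrained variant: different-chromosome pairs only
            diff_records = records[records["same_chromosome"] == False]  # noqa: E712
            if len(diff_records) and len({g.chromosome for g in self.singletons}) >= 2:
                for region, matrix in matrices.items():
                    col = dv.region_column(region)
                    obs = diff_records[col].to_numpy(float)
                    randomization[f"{region}_different_chromosomes"] = (
                        rs.randomization_analysis(
                            obs[np.isfinite(obs)],
                            self.singletons,
                            matrix,
                            n_replicates=n_randomizations,
                            constraint="different_chromosomes",
                            seed=seed,
                        )
                    )
            else:
                skipped["randomization_constrained"] = (
                    "no different-chromosome pairs or singletons span one chromosome"
                )
        else:
            skipped["randomization"] = "fewer than 2 singleton genes"

        try:
            distance_corr = {
                region: rs.distance_divergence_correlation(records, region)
                for region in ("ORF", "promoter")
            }
        except ValueError as exc:
            distance_corr = None
            skipped["distance_correlation"] = str(exc)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            chrom_comparison = rs.same_vs_different_chromosome_comparison(records)

        condition_tests = hm_expr_corr = None
        if self.expression is not None:
            records = ex.expression_divergence_table(
                records, self.expression, self.conditions
            )
            condition_tests = ex.compare_conditions(records)
            hm_expr_corr = pd.concat(
                [
                    ex.correlate_hm_with_expression(
                        records, region, expression_condition
                    )
                    for region in ("ORF", "promoter")
                ],
                ignore_index=True,
            )
        else:
            skipped["expression"] = "no expression matrix supplied"

        functional_assoc = functional_div = None
        if self.go_map is not None:
            records = fn.annotate_functional_types(records, self.go_map)
            try:
                functional_assoc = fn.type_by_mode_association(records)
            except ValueError as exc:
                skipped["functional_association"] = str(exc)
            functional_div = {
                region: fn.divergence_by_type(records, region)
                for region in ("ORF", "promoter")
            }
        else:
            skipped["functional"] = "no GO map supplied"

        return DivergenceResults(
            model=self,
            records=records,
            per_mark_correlations=per_mark,
            mantel=mantel,
            mode_tests=mode_tests,
            kaks_filtered_n=len(filtered),
            kaks_correlations=kaks_corr_df,
            randomization=randomization,
            chromosome_bias=chromosome_bias,
            distance_correlation=distance_corr,
            chromosome_comparison=chrom_comparison,
            condition_tests=condition_tests,
            hm_expression_correlation=hm_expr_corr,
            functional_association=functional_assoc,
            functional_divergence=functional_div,
            skipped=skipped,
            seed=seed,
            n_randomizations=n_randomizations,
            mantel_permutations=mantel_permutations,
            expression_condition=expression_condition,
        )


@dataclass
class DivergenceResults:
    """Fitted results of :class:`DuplicateHMDivergence`.

    ``records`` is the pair-level table (one row per duplicate pair with
    D_HM–O, D_HM–P, per-condition E and functional type where
    available); the remaining attributes hold the statistical tables and
    tests.  ``skipped`` maps stage names to the reason they were not run.
    """

    model: DuplicateHMDivergence
    records: pd.DataFrame
    per_mark_correlations: pd.DataFrame
    mantel: dict
    mode_tests: dict
    kaks_filtered_n: int
    kaks_correlations: pd.DataFrame | None
    randomization: dict
    chromosome_bias: tuple | None
    distance_correlation: dict | None
    chromosome_comparison: dict
    condition_tests: pd.DataFrame | None
    hm_expression_correlation: pd.DataFrame | None
    functional_association: dict | None
    functional_divergence: dict | None
    skipped: dict = dc_field(default_factory=dict)
    seed: int | None = None
    n_randomizations: int = rs.DEFAULT_N_REPLICATES
    mantel_permutations: int = 9999
    expression_condition: str = "Normal"

    # -- derived tables ----------------------------------------------

    def pvalue_table(self) -> pd.DataFrame:
        """All headline p-values, raw and Benjamini-Hochberg adjusted.

        The study reports raw p-values; the adjusted column is provided
        alongside and clearly labelled, never substituted.
        """
        rows: list[tuple[str, float]] = []
        for region, res in self.randomization.items():
            rows.append((f"randomization_{region}", res.comparison_p))
        if self.chromosome_bias is not None:
            rows.append(("chromosome_bias", self.chromosome_bias[2]))
        for region, t in self.mode_tests.items():
            rows.append((f"divergence_by_mode_{region}", t["p"]))
        for region, res in self.mantel.items():
            rows.append((f"mantel_{region}", res.p))
        for region, st in self.chromosome_comparison.items():
            rows.append((f"same_vs_different_chromosome_{region}", st["p_wilcoxon"]))
        if self.condition_tests is not None:
            for t in self.condition_tests.itertuples(index=False):
                if t.mode == "all":
                    rows.append(
                        (f"expression_{t.condition_a}_vs_{t.condition_b}", t.p)
                    )
        if self.functional_association is not None:
            rows.append(("wgd_type2_fisher", self.functional_association["fisher_p"]))
        df = pd.DataFrame(rows, columns=["test", "p_raw"]).dropna()
        if len(df):
            df["p_bh"] = multipletests(df["p_raw"], method="fdr_bh")[1]
        else:
            df["p_bh"] = pd.Series(dtype=float)
        return df

    def summary(self) -> str:
        """Plain-text summary of the fitted analysis."""
        lines = ["Duplicate-gene HM divergence analysis", "=" * 38]
        rec = self.records
        lines.append(f"pairs: {len(rec)}   singletons: {len(self.model.singletons)}")
        counts = rec["mode"].value_counts()
        lines.append(
            "by mode: "
            + ", ".join(f"{m}={int(counts.get(m, 0))}" for m in counts.index)
        )
        for region, col in (("ORF", "d_hm_orf"), ("promoter", "d_hm_promoter")):
            if col in rec.columns and rec[col].notna().any():
                lines.append(
                    f"median D_HM-{region[0]}: {np.nanmedian(rec[col]):.4f}"
                )
        for region, res in self.randomization.items():
            lines.append(
                f"randomized control [{region}]: observed median "
                f"{res.observed_median:.4f} is {res.direction} than null "
                f"(Wilcoxon p={res.comparison_p:.3g}, {res.n_replicates} replicates)"
            )
        if self.chromosome_bias is not None:
            chi2, df_, p = self.chromosome_bias
            lines.append(f"chromosome bias: chi2={chi2:.4f}, df={df_}, p={p:.3g}")
        for region, t in self.mode_tests.items():
            lines.append(
                f"divergence by mode [{region}]: Kruskal-Wallis H={t['H']:.2f}, "
                f"p={t['p']:.3g}"
            )
        for region, res in self.mantel.items():
            lines.append(
                f"Mantel concordance [{region}]: r={res.r:.3f}, p={res.p:.3g} "
                f"({res.n_perm} permutations)"
            )
        if self.kaks_correlations is not None:
            sub = self.kaks_correlations.query("mode == 'all'")
            for t in sub.itertuples(index=False):
                lines.append(
                    f"corr(D_HM-{t.region[0]}, {t.which.upper()}): r={t.r:.3f}, "
                    f"p={t.p:.3g} (n={t.n} after Ka/Ks filter)"
                )
        if self.hm_expression_correlation is not None:
            sub = self.hm_expression_correlation.query("mode == 'all'")
            for t in sub.itertuples(index=False):
                lines.append(
                    f"corr(D_HM-{t.region[0]}, E_{t.condition}): r={t.r:.3f}, "
                    f"p={t.p:.3g}"
                )
        if self.condition_tests is not None:
            for t in self.condition_tests.query("mode == 'all'").itertuples(
                index=False
            ):
                lines.append(
                    f"E {t.condition_a} vs {t.condition_b}: medians "
                    f"{t.median_a:.3f}/{t.median_b:.3f}, Wilcoxon p={t.p:.3g}"
                )
        if self.functional_association is not None:
            lines.append(
                "WGD vs single-gene x Type II: Fisher p="
                f"{self.functional_association['fisher_p']:.3g}"
            )
        if self.skipped:
            lines.append("skipped stages: " + ", ".join(sorted(self.skipped)))
        return "\n".join(lines)

    def to_report(self) -> dict:
        """JSON-serialisable report of every statistic, p, n and seed."""

        def _mantel(res: dv.MantelResult) -> dict:
            return {"r": res.r, "p": res.p, "n_perm": res.n_perm}

        report: dict = {
            "n_pairs": int(len(self.records)),
            "n_singletons": int(len(self.model.singletons)),
            "seed": self.seed,
            "parameters": {
                "n_randomizations": int(self.n_randomizations),
                "mantel_permutations": int(self.mantel_permutations),
                "ka_max": self.model.ka_max,
                "ks_max": self.model.ks_max,
                "expression_condition": self.expression_condition,
            },
            "pairs_by_mode": {
                str(k): int(v)
                for k, v in self.records["mode"].value_counts().items()
            },
            "median_d_hm": {
                region: (
                    float(np.nanmedian(self.records[col]))
                    if col in self.records and self.records[col].notna().any()
                    else None
                )
                for region, col in (("ORF", "d_hm_orf"), ("promoter", "d_hm_promoter"))
            },
            "randomization": {
                key: {
                    "p": res.comparison_p,
                    "direction": res.direction,
                    "observed_median": res.observed_median,
                    "null_median": float(np.median(res.replicate_medians)),
                    "empirical_replicate_p": res.empirical_replicate_p,
                    "n_replicates": res.n_replicates,
                    "constraint": res.constraint,
                }
                for key, res in self.randomization.items()
            },
            "chromosome_bias": (
                None
                if self.chromosome_bias is None
                else {
                    "chi2": self.chromosome_bias[0],
                    "df": self.chromosome_bias[1],
                    "p": self.chromosome_bias[2],
                }
            ),
            "mode_tests": {
                region: {"H": t["H"], "p": t["p"]}
                for region, t in self.mode_tests.items()
            },
            "mantel": {region: _mantel(res) for region, res in self.mantel.items()},
            "chromosome_comparison": self.chromosome_comparison,
            "distance_correlation": (
                None
                if self.distance_correlation is None
                else {
                    region: {"r": r, "p": p, "n": n}
                    for region, (r, p, n) in self.distance_correlation.items()
                }
            ),
            "kaks": (
                None
                if self.kaks_correlations is None
                else {
                    "n_filtered": int(self.kaks_filtered_n),
                    "correlations": self.kaks_correlations.to_dict("records"),
                }
            ),
            "expression": (
                None
                if self.condition_tests is None
                else {
                    "condition_tests": self.condition_tests.to_dict("records"),
                    "hm_correlation": self.hm_expression_correlation.to_dict(
                        "records"
                    ),
                }
            ),
            "functional": (
                None
                if self.functional_divergence is None
                else {
                    "association": (
                        None
                        if self.functional_association is None
                        else {
                            "fisher_p": self.functional_association["fisher_p"],
                            "odds_ratio": self.functional_association["odds_ratio"],
                            "table": {
                                str(m): {
                                    str(t): int(v) for t, v in row.items()
                                }
                                for m, row in self.functional_association["table"]
                                .to_dict("index")
                                .items()
                            },
                        }
                    ),
                    "divergence_by_type": {
                        region: {
                            "summary": d["summary"].to_dict("records"),
                            "tests": d["tests"].to_dict("records"),
                        }
                        for region, d in self.functional_divergence.items()
                    },
                }
            ),
            "per_mark_correlations": self.per_mark_correlations.to_dict("records"),
            "pvalues": self.pvalue_table().to_dict("records"),
            "skipped": dict(self.skipped),
        }
        return report

    # -- plotting ------------------------------------------------------

    def plot_divergence_by_mode(self, region: str = "ORF", ax=None):
        """Boxplot of D_HM by duplication mode (plus pooled duplicates)."""
        import matplotlib.pyplot as plt

        col = dv.region_column(region)
        if ax is None:
            _, ax = plt.subplots()
        groups, labels = [], []
        for mode in self.records["mode"].cat.categories:
            x = self.records.loc[self.records["mode"] == mode, col].dropna()
            if len(x):
                groups.append(x.to_numpy())
                labels.append(str(mode))
        pooled = self.records[col].dropna().to_numpy()
        if len(pooled):
            groups.append(pooled)
            labels.append("duplicate")
        ax.boxplot(groups, tick_labels=labels)
        ax.set_ylabel(f"D_HM ({region})")
        ax.set_xlabel("duplication mode")
        return ax
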