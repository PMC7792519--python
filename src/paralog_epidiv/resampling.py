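"""Randomized singleton-pair controls and chromosome-bias analysis.

The observed divergence of duplicate pairs is compared against a null of
randomly paired singleton genes: for each of ``n_replicates`` (10,000 in
the study design) randomizations, the same number of singleton pairs is
sampled uniformly, optionally constrained so both members lie on
different chromosomes, and the observed-vs-pooled-null distributions are
compared with a two-sided Wilcoxon rank-sum test.  Chromosome bias — the
tendency of duplicate pair members to share a chromosome more often than
random pairs — is tested with a Pearson chi-square on the 2 × 2 table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneRecord
from .profiles import HMProfileMatrix
from .divergence import pairwise_profile_divergence, region_column

__all__ = [
    "DEFAULT_N_REPLICATES",
    "SingletonPairReplicates",
    "RandomizationResult",
    "sample_singleton_pairs",
    "null_divergence_replicates",
    "randomized_control_comparison",
    "randomization_analysis",
    "chromosome_bias_test",
    "distance_divergence_correlation",
    "same_vs_different_chromosome_comparison",
]

DEFAULT_N_REPLICATES = 10_000

CONSTRAINTS = ("none", "different_chromosomes")


@dataclass
class SingletonPairReplicates:
    """Sampled singleton pairs: ``gene_ids[indices[r]]`` are replicate r's pairs.

    ``indices`` is a list of (n_pairs, 2) integer arrays into ``gene_ids``.
    Genes may recur within a replicate (pairs are sampled uniformly, not as
    a matching).
    """

    gene_ids: np.ndarray
    indices: list[np.ndarray]
    constraint: str
    seed: int | None

    def pairs(self, replicate: int) -> list[tuple[str, str]]:
        idx = self.indices[replicate]
        return [(self.gene_ids[i], self.gene_ids[j]) for i, j in idx]


@dataclass
class RandomizationResult:
    """Observed pair scores vs a randomized-singleton null ensemble."""

    observed: np.ndarray
    null_replicates: list[np.ndarray]
    comparison_p: float
    direction: str
    n_replicates: int
    constraint: str
    seed: int | None
    #: per-replicate empirical p (fraction of replicates whose median is
    #: at most the observed median) — diagnostic only
    replicate_medians: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def observed_median(self) -> float:
        return float(np.nanmedian(self.observed))

    @property
    def empirical_replicate_p(self) -> float:
        b = np.sum(self.replicate_medians <= self.observed_median)
        return float((b + 1) / (self.n_replicates + 1))


def sample_singleton_pairs(
    singletons: Sequence[GeneRecord],
    n_pairs: int,
    n_replicates: int = DEFAULT_N_REPLICATES,
    constraint: str = "none",
    seed: int | None = None,
) -> SingletonPairReplicates:
    """Sample ``n_replicates`` sets of ``n_pairs`` random singleton pairs.

    Pairs are unordered, members distinct; under
    ``constraint="different_chromosomes"`` the two members must lie on
    different chromosomes (an error if the singletons span only one).
    Deterministic for a fixed seed.
    """
    if constraint not in CONSTRAINTS:
        raise ValueError(f"constraint must be one of {CONSTRAINTS}")
    if len(singletons) < 2:
        raise ValueError("need >= 2 singleton genes to sample pairs")
    gene_ids = np.array([g.gene_id for g in singletons])
    chroms = np.array([g.chromosome for g in singletons])
    if constraint == "different_chromosomes" and len(set(chroms)) < 2:
        raise ValueError(
            "different-chromosome constraint unsatisfiable: "
            "all singletons lie on one chromosome"
        )
    rng = np.random.default_rng(seed)
    n_genes = len(gene_ids)
    indices = []
    for _ in range(n_replicates):
        i = rng.integers(n_genes, size=n_pairs)
        j = rng.integers(n_genes, size=n_pairs)
        bad = (i == j) if constraint == "none" else (chroms[i] == chroms[j])
        while bad.any():
            k = int(bad.sum())
            i[bad] = rng.integers(n_genes, size=k)
            j[bad] = rng.integers(n_genes, size=k)
            bad = (i == j) if constraint == "none" else (chroms[i] == chroms[j])
        indices.append(np.column_stack([i, j]))
    return SingletonPairReplicates(gene_ids, indices, constraint, seed)


def null_divergence_replicates(
    replicates: SingletonPairReplicates, matrix: HMProfileMatrix
) -> list[np.ndarray]:
    """D_HM score vector for every replicate of sampled singleton pairs."""
    profiles = matrix.profiles(replicates.gene_ids)
    return [
        pairwise_profile_divergence(profiles[idx[:, 0]], profiles[idx[:, 1]])
        for idx in replicates.indices
    ]


def randomized_control_comparison(observed, null_pooled) -> tuple[float, str]:
    """Two-sided Wilcoxon rank-sum test of observed vs pooled-null scores.

    Returns ``(p, direction)`` where direction says whether the observed
    median is lower or higher than the null median.  All values tied
    across both samples gives p = 1.
    """
    x = np.asarray(observed, float)
    y = np.asarray(null_pooled, float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0, "equal"
    p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    mx, my = np.median(x), np.median(y)
    direction = "lower" if mx < my else ("higher" if mx > my else "equal")
    return p, direction


def randomization_analysis(
    observed_scores,
    singletons: Sequence[GeneRecord],
    matrix: HMProfileMatrix,
    n_replicates: int = DEFAULT_N_REPLICATES,
    constraint: str = "none",
    seed: int | None = None,
) -> RandomizationResult:
    """Full randomized-control analysis for one region's D_HM scores."""
    observed = np.asarray(observed_scores, float)
    n_pairs = len(observed)
    reps = sample_singleton_pairs(
        singletons, n_pairs, n_replicates, constraint=constraint, seed=seed
    )
    nulls = null_divergence_replicates(reps, matrix)
    pooled = np.concatenate(nulls)
    p, direction = randomized_control_comparison(observed, pooled)
    medians = np.array([np.nanmedian(v) for v in nulls])
    return RandomizationResult(
        observed=observed,
        null_replicates=nulls,
        comparison_p=p,
        direction=direction,
        n_replicates=n_replicates,
        constraint=constraint,
        seed=seed,
        replicate_medians=medians,
    )


def chromosome_bias_test(duplicate_same, randomized_same) -> tuple[float, int, float]:
    """Pearson chi-square (df = 1, no continuity correction) for chromosome
    bias: {duplicate, randomized} × {same, different chromosome}.

    Arguments are boolean arrays (or sequences of objects with a
    ``same_chromosome`` attribute) flagging same-chromosome pairs.
    """

    def _as_bool(seq):
        arr = np.asarray(
            [getattr(v, "same_chromosome", v) for v in seq], dtype=object
        )
        if any(v is None for v in arr):
            raise ValueError("pairs must be annotated with same_chromosome")
        return arr.astype(bool)

    dup = _as_bool(duplicate_same)
    rnd = _as_bool(randomized_same)
    if len(dup) == 0 or len(rnd) == 0:
        raise ValueError("both pair sets must be nonempty")
    table = np.array(
        [
            [dup.sum(), (~dup).sum()],
            [rnd.sum(), (~rnd).sum()],
        ]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in the 2x2 chromosome-bias table")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


def distance_divergence_correlation(
    records: pd.DataFrame, region: str = "ORF"
) -> tuple[float, float, int]:
    """Pearson correlation between TSS-to-TSS distance and D_HM over
    same-chromosome pairs.  Returns (r, p, n); NaN r when degenerate."""
    col = region_column(region)
    sub = records[records["same_chromosome"] == True]  # noqa: E712
    x = sub["distance_bp"].to_numpy(float)
    y = sub[col].to_numpy(float)
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 3:
        raise ValueError("need >= 3 same-chromosome pairs with distance and D_HM")
    if x[ok].std() == 0 or y[ok].std() == 0:
        warnings.warn("constant distances or divergences; correlation undefined")
        return float("nan"), float("nan"), n
    r, p = stats.pearsonr(x[ok], y[ok])
    return float(r), float(p), n


def same_vs_different_chromosome_comparison(
    records: pd.DataFrame, regions: Sequence[str] = ("ORF", "promoter")
) -> dict[str, dict]:
    """Compare D_HM of same- vs different-chromosome pairs per region.

    Primary test is the two-sided Wilcoxon rank-sum; Student's t-test is
    also reported.  A region with an empty (or singleton) stratum is
    skipped with a warning.
    """
    out: dict[str, dict] = {}
    for region in regions:
        col = region_column(region)
        if col not in records.columns:
            continue
        same = records.loc[records["same_chromosome"] == True, col].to_numpy(float)  # noqa: E712
        diff = records.loc[records["same_chromosome"] == False, col].to_numpy(float)  # noqa: E712
        same = same[np.isfinite(same)]
        diff = diff[np.isfinite(diff)]
        if len(same) < 2 or len(diff) < 2:
            warnings.warn(f"{region}: a chromosome stratum has < 2 records; skipped")
            continue
        p_w = float(stats.mannwhitneyu(same, diff, alternative="two-sided").pvalue)
        p_t = float(stats.ttest_ind(same, diff, equal_var=False).pvalue)
        out[region] = {
            "p_wilcoxon": p_w,
            "p_ttest": p_t,
            "median_same": float(np.median(same)),
            "median_different": float(np.median(diff)),
            "n_same": len(same),
            "n_different": len(diff),
        }
    return out
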