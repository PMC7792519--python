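"""Histone-modification divergence between paralog pairs.

The divergence of a pair is D_HM = 1 − r, where r is the Pearson
correlation between the two genes' per-mark z-score profiles; D_HM lies
in [0, 2] (0 = identical profile shape, 2 = perfectly anti-correlated).
Subscripts O/P denote the ORF and promoter regions.  This module also
provides the per-mark paralog correlation table, a Mantel test for the
concordance of mark co-occurrence structure between pair members, the
Ka/Ks selection filter, and the D_HM–substitution-rate coupling.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import MODES, DuplicatePair
from .profiles import HMProfileMatrix

__all__ = [
    "MIN_SHARED_MARKS",
    "pair_divergence",
    "pairwise_profile_divergence",
    "compute_pair_table",
    "per_mark_pair_correlation",
    "MantelResult",
    "mantel_concordance",
    "filter_pairs_by_kaks",
    "correlate_divergence_with_substitution",
    "divergence_by_mode",
    "expected_pair_divergence",
]

#: Minimum number of marks finite in both profiles for D_HM to be defined.
MIN_SHARED_MARKS = 3

_REGION_COLUMN = {"ORF": "d_hm_orf", "promoter": "d_hm_promoter"}


def region_column(region: str) -> str:
    try:
        return _REGION_COLUMN[region]
    except KeyError:
        raise ValueError(f"region must be 'ORF' or 'promoter', got {region!r}") from None


def pairwise_profile_divergence(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise D_HM = 1 − Pearson r between two (n_pairs, n_marks) arrays.

    Marks missing in either member of a pair are excluded pairwise.  Rows
    with fewer than :data:`MIN_SHARED_MARKS` shared finite marks, or zero
    variance in either profile over the shared marks, yield NaN.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("profile arrays must have the same shape")
    mask = np.isfinite(a) & np.isfinite(b)
    n = mask.sum(axis=1)
    aw = np.where(mask, a, 0.0)
    bw = np.where(mask, b, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ma = aw.sum(axis=1) / n
        mb = bw.sum(axis=1) / n
        ac = np.where(mask, aw - ma[:, None], 0.0)
        bc = np.where(mask, bw - mb[:, None], 0.0)
        sa = np.einsum("ij,ij->i", ac, ac)
        sb = np.einsum("ij,ij->i", bc, bc)
        cov = np.einsum("ij,ij->i", ac, bc)
        r = cov / np.sqrt(sa * sb)
    d = 1.0 - r
    d[(n < MIN_SHARED_MARKS) | (sa <= 0) | (sb <= 0)] = np.nan
    return np.clip(d, 0.0, 2.0)


def pair_divergence(profile_a, profile_b) -> float:
    """D_HM for a single pair of per-mark z-score profiles."""
    return float(
        pairwise_profile_divergence(
            np.asarray(profile_a, dtype=float)[None, :],
            np.asarray(profile_b, dtype=float)[None, :],
        )[0]
    )


def compute_pair_table(
    pairs: Sequence[DuplicatePair],
    hm_orf: HMProfileMatrix | None = None,
    hm_promoter: HMProfileMatrix | None = None,
) -> pd.DataFrame:
    """Build the per-pair record table with D_HM–O and D_HM–P columns.

    Returned columns: gene_a, gene_b, mode, ka, ks, same_chromosome,
    distance_bp, d_hm_orf, d_hm_promoter.  Expression and functional
    columns are appended by the expression/functional modules.
    """
    df = pd.DataFrame(
        {
            "gene_a": [p.gene_a for p in pairs],
            "gene_b": [p.gene_b for p in pairs],
            "mode": pd.Categorical([p.mode for p in pairs], categories=MODES),
            "ka": [math.nan if p.ka is None else p.ka for p in pairs],
            "ks": [math.nan if p.ks is None else p.ks for p in pairs],
            "same_chromosome": [p.same_chromosome for p in pairs],
            "distance_bp": [
                math.nan if p.distance_bp is None else float(p.distance_bp)
                for p in pairs
            ],
        }
    )
    for matrix in (hm_orf, hm_promoter):
        if matrix is None:
            continue
        col = region_column(matrix.region)
        if df.empty:
            df[col] = pd.Series(dtype=float)
            continue
        df[col] = pairwise_profile_divergence(
            matrix.profiles(df["gene_a"]), matrix.profiles(df["gene_b"])
        )
    return df


def per_mark_pair_correlation(
    pairs: Sequence[DuplicatePair] | pd.DataFrame,
    matrix: HMProfileMatrix,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Per-mark Pearson correlation between pair members, across pairs.

    For every mark, the gene_a-side values are correlated with the
    gene_b-side values over all pairs with both finite (pairs oriented
    canonically, gene_a < gene_b).  Computed overall and per mode.
    Returns a tidy frame: region, mark, mode ('all' + each mode), r, p, n;
    degenerate marks (constant or too few pairs) get NaN r/p.
    """
    if isinstance(pairs, pd.DataFrame):
        df = pairs
    else:
        df = pd.DataFrame(
            {
                "gene_a": [p.gene_a for p in pairs],
                "gene_b": [p.gene_b for p in pairs],
                "mode": [p.mode for p in pairs],
            }
        )
    rows = []
    a_all = matrix.profiles(df["gene_a"]) if len(df) else np.empty((0, len(matrix.marks)))
    b_all = matrix.profiles(df["gene_b"]) if len(df) else np.empty((0, len(matrix.marks)))
    modes_present = [m for m in MODES if (df["mode"] == m).any()]
    for group in ["all", *modes_present]:
        sel = np.ones(len(df), bool) if group == "all" else (df["mode"] == group).to_numpy()
        for j, mark in enumerate(matrix.marks):
            x, y = a_all[sel, j], b_all[sel, j]
            ok = np.isfinite(x) & np.isfinite(y)
            n = int(ok.sum())
            if n < min_pairs or x[ok].std() == 0 or y[ok].std() == 0:
                r = p = math.nan
            else:
                r, p = stats.pearsonr(x[ok], y[ok])
            rows.append((matrix.region, mark, group, r, p, n))
    return pd.DataFrame(rows, columns=["region", "mark", "mode", "r", "p", "n"])


# ---------------------------------------------------------------------------
# Mantel concordance of mark co-occurrence structure


@dataclass
class MantelResult:
    """Mantel statistic between the gene_a-side and gene_b-side mark
    correlation matrices, with an empirical permutation p-value.

    ``heatmap`` combines both matrices the way the study displays them:
    upper triangle from gene A, lower triangle from gene B.
    ``n_perm`` is the permutation count, or the string ``"exhaustive"``.
    """

    r: float
    p: float
    n_perm: int | str
    heatmap: pd.DataFrame


def _mark_correlation_matrix(values: np.ndarray) -> np.ndarray:
    """Mark × mark Pearson correlations across genes (pairwise-complete)."""
    return pd.DataFrame(values).corr(min_periods=2).to_numpy()


def _triu_correlations(a_flat: np.ndarray, b_rows: np.ndarray) -> np.ndarray:
    """Pearson r between a fixed vector and each row of ``b_rows``."""
    ac = a_flat - a_flat.mean()
    bc = b_rows - b_rows.mean(axis=1, keepdims=True)
    denom = np.sqrt((ac @ ac) * np.einsum("ij,ij->i", bc, bc))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (bc @ ac) / denom


def mantel_concordance(
    pairs: Sequence[DuplicatePair] | pd.DataFrame,
    matrix: HMProfileMatrix,
    n_perm: int = 9999,
    exhaustive_max_marks: int = 5,
    seed: int | None = None,
) -> MantelResult:
    """Mantel test: do pair members share the same mark co-occurrence
    structure?

    Correlation matrices among marks are computed separately from the
    gene_a-side and gene_b-side profile rows; the Mantel r is the Pearson
    correlation of their upper-triangle entries.  Significance comes from
    simultaneous row/column permutations of the gene_b-side matrix:
    exhaustive enumeration of all k! permutations when the number of marks
    is at most ``exhaustive_max_marks``, otherwise ``n_perm`` sampled
    permutations with the add-one estimate p = (b + 1)/(m + 1), where b
    counts permutations with \\|r_perm\\| >= \\|r_obs\\| (two-sided).
    """
    if isinstance(pairs, pd.DataFrame):
        ga, gb = pairs["gene_a"], pairs["gene_b"]
    else:
        ga = [p.gene_a for p in pairs]
        gb = [p.gene_b for p in pairs]
    if len(ga) < 3:
        raise ValueError("need >= 3 pairs for the Mantel concordance test")
    marks = matrix.marks
    k = len(marks)
    if k < 3:
        raise ValueError("need >= 3 marks for the Mantel concordance test")
    ma = _mark_correlation_matrix(matrix.profiles(ga))
    mb = _mark_correlation_matrix(matrix.profiles(gb))
    if np.any(~np.isfinite(ma)) or np.any(~np.isfinite(mb)):
        raise ValueError("degenerate mark correlation matrix (undefined entries)")

    iu, ju = np.triu_indices(k, 1)
    a_flat = ma[iu, ju]
    if a_flat.std() == 0 or mb[iu, ju].std() == 0:
        raise ValueError("constant mark correlation matrix; Mantel r undefined")

    exhaustive = k <= exhaustive_max_marks
    if exhaustive:
        perms = np.array(list(itertools.permutations(range(k))))
        n_perm_out: int | str = "exhaustive"
    else:
        rng = np.random.default_rng(seed)
        perms = rng.permuted(np.tile(np.arange(k), (n_perm, 1)), axis=1)
        n_perm_out = n_perm

    # permuted upper triangles via fancy indexing: entry (i, j) of the
    # permuted matrix is mb[perm[i], perm[j]]
    b_rows = mb[perms[:, iu], perms[:, ju]]
    r_all = _triu_correlations(a_flat, b_rows)
    r_obs = float(_triu_correlations(a_flat, mb[iu, ju][None, :])[0])
    b_count = int(np.sum(np.abs(r_all) >= abs(r_obs) - 1e-12))
    if exhaustive:
        p = b_count / len(perms)  # exact null: identity included, no correction
    else:
        p = (b_count + 1) / (len(perms) + 1)

    heat = np.triu(ma, 1) + np.tril(mb, -1) + np.eye(k)
    heatmap = pd.DataFrame(heat, index=marks, columns=marks)
    return MantelResult(r=r_obs, p=float(p), n_perm=n_perm_out, heatmap=heatmap)


# ---------------------------------------------------------------------------
# Ka/Ks selection and coupling


def filter_pairs_by_kaks(pairs, ka_max: float = 0.5, ks_max: float = 2.0):
    """Retain pairs with finite Ka < ka_max and finite Ks < ks_max (strict).

    Pairs with a missing rate are removed.  Accepts either a sequence of
    :class:`DuplicatePair` or a pair table DataFrame.
    """
    if isinstance(pairs, pd.DataFrame):
        keep = (
            np.isfinite(pairs["ka"])
            & np.isfinite(pairs["ks"])
            & (pairs["ka"] < ka_max)
            & (pairs["ks"] < ks_max)
        )
        return pairs.loc[keep]
    return [
        p
        for p in pairs
        if p.ka is not None and p.ks is not None and p.ka < ka_max and p.ks < ks_max
    ]


def correlate_divergence_with_substitution(
    records: pd.DataFrame, which: str = "ka", region: str = "ORF"
) -> pd.DataFrame:
    """Pearson correlation of D_HM with Ka or Ks, per mode and overall.

    ``records`` should already be restricted by :func:`filter_pairs_by_kaks`.
    Returns a tidy frame: mode, which, region, r, p, n.
    """
    if which not in ("ka", "ks"):
        raise ValueError("which must be 'ka' or 'ks'")
    col = region_column(region)
    rows = []
    modes_present = [m for m in MODES if (records["mode"] == m).any()]
    for group in ["all", *modes_present]:
        sub = records if group == "all" else records[records["mode"] == group]
        x = sub[which].to_numpy(float)
        y = sub[col].to_numpy(float)
        ok = np.isfinite(x) & np.isfinite(y)
        n = int(ok.sum())
        if n < 3 or x[ok].std() == 0 or y[ok].std() == 0:
            warnings.warn(f"degenerate {which} vs D_HM vectors for mode {group!r}")
            r = p = math.nan
        else:
            r, p = stats.pearsonr(x[ok], y[ok])
        rows.append((group, which, region, r, p, n))
    return pd.DataFrame(rows, columns=["mode", "which", "region", "r", "p", "n"])


def divergence_by_mode(records: pd.DataFrame, region: str = "ORF") -> dict:
    """Kruskal-Wallis omnibus test of D_HM across duplication modes.

    Modes with fewer than 2 finite records are dropped with a warning;
    fewer than two remaining modes is an error.  Returns the H statistic,
    p-value (midranks with tie correction, as scipy computes it) and a
    per-group summary table that includes the pooled 'all duplicates'
    group.
    """
    col = region_column(region)
    groups: dict[str, np.ndarray] = {}
    for mode in MODES:
        x = records.loc[records["mode"] == mode, col].to_numpy(float)
        x = x[np.isfinite(x)]
        if 0 < len(x) < 2:
            warnings.warn(f"mode {mode!r} has < 2 records; dropped from omnibus test")
            continue
        if len(x):
            groups[mode] = x
    if len(groups) < 2:
        raise ValueError("need >= 2 duplication modes for the omnibus test")
    h, p = stats.kruskal(*groups.values())
    pooled = np.concatenate(list(groups.values()))
    summary_rows = []
    for name, x in [*groups.items(), ("duplicate", pooled)]:
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        summary_rows.append((name, len(x), float(np.mean(x)), q1, med, q3))
    summary = pd.DataFrame(
        summary_rows, columns=["group", "n", "mean", "q1", "median", "q3"]
    )
    return {"region": region, "H": float(h), "p": float(p), "summary": summary}


def expected_pair_divergence(rho: float, n_marks: int = 10) -> float:
    """Closed-form E[D_HM] under the bivariate-normal profile generator.

    For profiles of ``n_marks`` i.i.d. bivariate-normal marks with
    correlation ρ, the sample correlation r has
    E[r] ≈ ρ − ρ(1 − ρ²)/(2·n_marks) (first-order small-sample bias), so
    E[D_HM] ≈ 1 − E[r].
    """
    return 1.0 - (rho - rho * (1.0 - rho**2) / (2.0 * n_marks))
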