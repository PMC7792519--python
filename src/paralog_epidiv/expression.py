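"""Expression divergence of paralog pairs across perturbation conditions.

RNA-seq samples are grouped into three conditions: normal development
("Normal"), environmental stress ("Stress"), and mutations of chromatin
modifiers ("CM_mu").  Within a condition group, the expression divergence
of a pair is E = 1 − Pearson r between the two genes' log2(x + 1)
abundance vectors over the group's samples — the same 1 − r form as the
histone divergence D_HM, so both live on [0, 2].
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import MODES
from .divergence import pairwise_profile_divergence, region_column

__all__ = [
    "CONDITIONS",
    "condition_column",
    "validate_grouping",
    "expression_divergence",
    "expression_divergence_table",
    "compare_conditions",
    "correlate_hm_with_expression",
]

#: Condition groups in the order the study reports them.
CONDITIONS = ("Normal", "Stress", "CM_mu")


def condition_column(condition: str) -> str:
    return f"e_{condition.lower()}"


def validate_grouping(expression: pd.DataFrame, conditions: pd.Series) -> None:
    """Every expression-matrix sample must map to exactly one condition."""
    missing = [s for s in expression.columns if s not in conditions.index]
    if missing:
        raise ValueError(f"samples without a condition assignment: {missing[:5]}")
    bad = set(conditions.unique()) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown conditions {sorted(bad)}; expected {CONDITIONS}")


def _log_rows(expression: pd.DataFrame, gene_ids, samples) -> np.ndarray:
    return np.log2(expression.loc[list(gene_ids), list(samples)].to_numpy(float) + 1.0)


def expression_divergence(
    expression: pd.DataFrame, gene_a: str, gene_b: str, samples: Sequence[str]
) -> float:
    """E = 1 − Pearson r of log2(x + 1) abundances over one sample group.

    NaN when either gene's vector has zero variance over the group, or a
    gene is absent from the matrix (with a warning).
    """
    if len(samples) < 3:
        raise ValueError("need >= 3 samples in the condition group")
    for g in (gene_a, gene_b):
        if g not in expression.index:
            warnings.warn(f"gene {g!r} absent from expression matrix")
            return float("nan")
    rows = _log_rows(expression, [gene_a, gene_b], samples)
    return float(pairwise_profile_divergence(rows[:1], rows[1:])[0])


def expression_divergence_table(
    records: pd.DataFrame,
    expression: pd.DataFrame,
    conditions: pd.Series,
) -> pd.DataFrame:
    """Append per-condition E columns (e_normal, e_stress, e_cm_mu).

    Conditions with fewer than 3 samples are skipped with a warning.
    Pairs with a member missing from the expression matrix get NaN.
    """
    validate_grouping(expression, conditions)
    records = records.copy()
    present = records["gene_a"].isin(expression.index) & records["gene_b"].isin(
        expression.index
    )
    if not present.all():
        warnings.warn(
            f"{(~present).sum()} pairs have a member missing from the "
            "expression matrix; their E is NaN"
        )
    for cond in CONDITIONS:
        samples = conditions.index[conditions == cond]
        samples = [s for s in samples if s in expression.columns]
        col = condition_column(cond)
        if len(samples) < 3:
            warnings.warn(f"condition {cond!r} has < 3 samples; E not computed")
            records[col] = np.nan
            continue
        e = np.full(len(records), np.nan)
        if present.any():
            sub = records.loc[present]
            a = _log_rows(expression, sub["gene_a"], samples)
            b = _log_rows(expression, sub["gene_b"], samples)
            e[present.to_numpy()] = pairwise_profile_divergence(a, b)
        records[col] = e
    return records


def compare_conditions(records: pd.DataFrame, by_mode: bool = True) -> pd.DataFrame:
    """Pairwise Wilcoxon rank-sum tests of E between condition groups.

    Run overall and (optionally) stratified per duplication mode.  A
    condition with fewer than 2 finite values is dropped with a warning.
    Returns a tidy frame: mode, condition_a, condition_b, median_a,
    median_b, p, n_a, n_b.
    """
    groups = ["all"] + ([m for m in MODES if (records["mode"] == m).any()] if by_mode else [])
    rows = []
    for group in groups:
        sub = records if group == "all" else records[records["mode"] == group]
        vals = {}
        for cond in CONDITIONS:
            col = condition_column(cond)
            if col not in sub.columns:
                continue
            x = sub[col].to_numpy(float)
            x = x[np.isfinite(x)]
            if len(x) < 2:
                warnings.warn(f"condition {cond!r} ({group}): < 2 values; dropped")
                continue
            vals[cond] = x
        conds = list(vals)
        if len(conds) < 2 and group == "all":
            warnings.warn("fewer than two usable conditions; no tests run")
        for i, ca in enumerate(conds):
            for cb in conds[i + 1 :]:
                p = float(
                    stats.mannwhitneyu(vals[ca], vals[cb], alternative="two-sided").pvalue
                )
                rows.append(
                    (
                        group,
                        ca,
                        cb,
                        float(np.median(vals[ca])),
                        float(np.median(vals[cb])),
                        p,
                        len(vals[ca]),
                        len(vals[cb]),
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "mode",
            "condition_a",
            "condition_b",
            "median_a",
            "median_b",
            "p",
            "n_a",
            "n_b",
        ],
    )


def correlate_hm_with_expression(
    records: pd.DataFrame, region: str = "ORF", condition: str = "Normal"
) -> pd.DataFrame:
    """Pearson correlation of D_HM(region) with E(condition), per mode and
    overall.  Returns a tidy frame: mode, region, condition, r, p, n."""
    dcol = region_column(region)
    ecol = condition_column(condition)
    rows = []
    modes_present = [m for m in MODES if (records["mode"] == m).any()]
    for group in ["all", *modes_present]:
        sub = records if group == "all" else records[records["mode"] == group]
        x = sub[dcol].to_numpy(float)
        y = sub[ecol].to_numpy(float)
        ok = np.isfinite(x) & np.isfinite(y)
        n = int(ok.sum())
        if n < 3 or x[ok].std() == 0 or y[ok].std() == 0:
            warnings.warn(f"degenerate D_HM/E vectors for mode {group!r}")
            r = p = float("nan")
        else:
            r, p = stats.pearsonr(x[ok], y[ok])
        rows.append((group, region, condition, float(r), float(p), n))
    return pd.DataFrame(rows, columns=["mode", "region", "condition", "r", "p", "n"])
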