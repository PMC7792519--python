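"""GO-overlap functional-divergence classification of paralog pairs.

Each pair is assigned one of five types from the raw GO identifier sets
of its members (no ontology topology is used):

* Type I   — both annotated with exactly the same GO terms
* Type II  — annotated sets intersect but are unequal (partial sharing)
* Type III — both annotated, sets disjoint
* Type IV  — exactly one member annotated (either one)
* Type V   — neither member annotated

Emptiness is checked first, making the rules mutually exclusive and
total; the classification is symmetric in the two members.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io import MODES
from .divergence import region_column

__all__ = [
    "FUNCTIONAL_TYPES",
    "classify_pair_type",
    "annotate_functional_types",
    "type_by_mode_association",
    "divergence_by_type",
]

FUNCTIONAL_TYPES = ("I", "II", "III", "IV", "V")

#: Duplication modes counted as single-gene duplications (vs WGD).
SINGLE_GENE_MODES = ("tandem", "proximal", "transposed")


def classify_pair_type(go_a: Iterable[str], go_b: Iterable[str]) -> str:
    """Classify one pair's functional divergence from its two GO sets."""
    a, b = set(go_a), set(go_b)
    if not a and not b:
        return "V"
    if not a or not b:
        return "IV"
    if a == b:
        return "I"
    if a & b:
        return "II"
    return "III"


def annotate_functional_types(
    records: pd.DataFrame, go_map: Mapping[str, Iterable[str]]
) -> pd.DataFrame:
    """Append a ``functional_type`` column; absent genes count as unannotated."""
    records = records.copy()
    records["functional_type"] = pd.Categorical(
        [
            classify_pair_type(go_map.get(a, ()), go_map.get(b, ()))
            for a, b in zip(records["gene_a"], records["gene_b"])
        ],
        categories=FUNCTIONAL_TYPES,
    )
    return records


def type_by_mode_association(records: pd.DataFrame) -> dict:
    """Association between duplication mode and functional type.

    Returns the full mode × type count table plus a two-sided Fisher
    exact test on the 2 × 2 collapse {WGD, single-gene duplication} ×
    {Type II, other}.
    """
    if "functional_type" not in records.columns:
        raise ValueError("records lack a functional_type column")
    table = pd.crosstab(records["mode"], records["functional_type"], dropna=False)
    table = table.reindex(index=list(MODES), columns=list(FUNCTIONAL_TYPES), fill_value=0)
    is_wgd = records["mode"] == "WGD"
    is_ii = records["functional_type"] == "II"
    two_by_two = np.array(
        [
            [int((is_wgd & is_ii).sum()), int((is_wgd & ~is_ii).sum())],
            [int((~is_wgd & is_ii).sum()), int((~is_wgd & ~is_ii).sum())],
        ]
    )
    if (two_by_two.sum(axis=0) == 0).any() or (two_by_two.sum(axis=1) == 0).any():
        raise ValueError("empty margin in the WGD × Type-II table")
    odds, p = stats.fisher_exact(two_by_two, alternative="two-sided")
    return {
        "table": table,
        "two_by_two": two_by_two,
        "odds_ratio": float(odds),
        "fisher_p": float(p),
    }


def divergence_by_type(records: pd.DataFrame, region: str = "ORF") -> dict:
    """Per-type D_HM summaries and pairwise Wilcoxon rank-sum tests.

    Types with fewer than 2 finite records are dropped with a warning;
    with a single usable type only the summaries are returned.
    """
    col = region_column(region)
    groups: dict[str, np.ndarray] = {}
    for t in FUNCTIONAL_TYPES:
        x = records.loc[records["functional_type"] == t, col].to_numpy(float)
        x = x[np.isfinite(x)]
        if 0 < len(x) < 2:
            warnings.warn(f"functional type {t}: < 2 records; dropped from tests")
            continue
        if len(x):
            groups[t] = x
    summary_rows = []
    for t, x in groups.items():
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        summary_rows.append((t, len(x), float(np.mean(x)), q1, med, q3))
    summary = pd.DataFrame(
        summary_rows, columns=["type", "n", "mean", "q1", "median", "q3"]
    )
    test_rows = []
    types = list(groups)
    for i, ta in enumerate(types):
        for tb in types[i + 1 :]:
            p = float(
                stats.mannwhitneyu(groups[ta], groups[tb], alternative="two-sided").pvalue
            )
            test_rows.append((ta, tb, p))
    tests = pd.DataFrame(test_rows, columns=["type_a", "type_b", "p"])
    return {"region": region, "summary": summary, "tests": tests}
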