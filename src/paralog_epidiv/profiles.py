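"""Per-gene histone-modification profiles.

For each of the ten HM marks and each gene region (ORF and the 500 bp
promoter upstream of the TSS), the raw signal is the log2-transformed
average enrichment ratio, optionally divided per bin by a nucleosome
occupancy track.  Each mark column is then standardised across genes,
Z = (x − μ)/δ with a population (divide-by-n) standard deviation, so a
gene's 10-mark vector is its HM profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GeneRecord

__all__ = [
    "DegenerateColumnError",
    "GenomicInterval",
    "promoter_interval",
    "aggregate_region_signal",
    "zscore_transform",
    "HMProfileMatrix",
]

PROMOTER_WINDOW_BP = 500

REGIONS = ("ORF", "promoter")


class DegenerateColumnError(ValueError):
    """A mark column has zero variance and cannot be standardised."""


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive interval; ``length`` is 0 when start > end."""

    chromosome: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return max(0, self.end - self.start + 1)


def promoter_interval(gene: GeneRecord, window: int = PROMOTER_WINDOW_BP) -> GenomicInterval:
    """The promoter window immediately upstream of the strand-aware TSS.

    At most ``window`` bp, clipped at chromosome position 1; never overlaps
    the gene body.  A + strand gene starting at position 1 yields an empty
    interval.
    """
    if window < 0:
        raise ValueError("window must be nonnegative")
    if gene.strand == "+":
        end = gene.start - 1
        start = max(1, gene.start - window)
    else:
        start = gene.end + 1
        end = gene.end + window
    return GenomicInterval(gene.chromosome, start, end)


def aggregate_region_signal(bin_ratios, nucleosome_ratios=None) -> float:
    """log2 of the mean per-bin IP/input ratio over a region.

    When a nucleosome occupancy track is supplied, each bin ratio is
    divided by the matching nucleosome ratio before averaging (the
    normalisation cancels when both tracks are proportional).  Missing
    bins (NaN) are ignored; an all-missing region yields NaN.  Nonpositive
    ratios are rejected: the log-ratio scale has no meaning for them.
    """
    ratios = np.asarray(bin_ratios, dtype=float)
    if ratios.ndim != 1 or ratios.size == 0:
        raise ValueError("bin_ratios must be a non-empty 1-D sequence")
    if np.any(ratios[np.isfinite(ratios)] <= 0):
        raise ValueError("bin ratios must be strictly positive")
    if nucleosome_ratios is not None:
        nuc = np.asarray(nucleosome_ratios, dtype=float)
        if nuc.shape != ratios.shape:
            raise ValueError("nucleosome track must match the bin ratios in length")
        if np.any(~np.isfinite(nuc)) or np.any(nuc <= 0):
            raise ValueError("nucleosome ratios must be finite and strictly positive")
        ratios = ratios / nuc
    finite = ratios[np.isfinite(ratios)]
    if finite.size == 0:
        return math.nan
    return float(np.log2(finite.mean()))


def zscore_transform(column, name: str | None = None) -> np.ndarray:
    """Standardise one mark column across genes: Z = (x − μ)/δ.

    μ and δ (population SD) are computed over finite entries only; missing
    entries stay missing.  Requires at least two finite values and δ > 0.
    """
    x = np.asarray(column, dtype=float)
    finite = np.isfinite(x)
    label = f" {name!r}" if name else ""
    if finite.sum() < 2:
        raise DegenerateColumnError(
            f"column{label}: need >= 2 finite values to standardise"
        )
    mu = x[finite].mean()
    delta = x[finite].std(ddof=0)
    if delta == 0:
        raise DegenerateColumnError(f"column{label} is constant (zero variance)")
    z = np.full_like(x, np.nan)
    z[finite] = (x[finite] - mu) / delta
    return z


@dataclass
class HMProfileMatrix:
    """Genes × marks table of z-scored HM enrichment for one region.

    ``values`` is a DataFrame indexed by gene id with one column per mark;
    the study uses exactly 10 marks but the container does not require it
    (small matrices are useful for exhaustive permutation tests).
    """

    region: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"region must be one of {REGIONS}, got {self.region!r}")
        self.values = self.values.astype(float)

    @property
    def marks(self) -> list[str]:
        return list(self.values.columns)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @classmethod
    def from_enrichment(cls, enrichment: pd.DataFrame, region: str) -> "HMProfileMatrix":
        """Standardise each mark column of a raw enrichment table."""
        z = pd.DataFrame(index=enrichment.index)
        for col in enrichment.columns:
            z[col] = zscore_transform(enrichment[col].to_numpy(), name=str(col))
        return cls(region=region, values=z)

    def validate(self, atol: float = 1e-9) -> None:
        """Check the z-score invariant: per-mark mean 0, population SD 1."""
        for col in self.values.columns:
            x = self.values[col].to_numpy()
            finite = x[np.isfinite(x)]
            if finite.size < 2:
                continue
            if abs(finite.mean()) > atol or abs(finite.std(ddof=0) - 1) > atol:
                raise ValueError(f"mark {col!r} is not z-scored")

    def profiles(self, gene_ids) -> np.ndarray:
        """Profile rows for the given gene ids as a (n, n_marks) array."""
        return self.values.loc[list(gene_ids)].to_numpy()
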