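"""Readers and writers for the tabular inputs of the duplicate-gene analysis.

All on-disk formats are plain UTF-8, tab-delimited text with ``NA`` for
missing values.  Internally coordinates are 1-based inclusive (GFF3
convention); BED input is converted at the boundary.  Duplicate pairs are
unordered and canonicalised so that ``gene_a < gene_b`` lexicographically.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MODES",
    "DUPLICATION_CLASSES",
    "FormatError",
    "ConsistencyError",
    "GeneRecord",
    "DuplicatePair",
    "annotate_pairs",
    "read_gene_catalog",
    "write_gene_catalog",
    "read_pair_lists",
    "write_pair_lists",
    "read_matrix",
    "write_matrix",
    "read_go_map",
    "write_go_map",
    "read_sample_conditions",
    "write_sample_conditions",
]

#: Duplication modes, in the order the study reports them.
MODES = ("WGD", "tandem", "proximal", "transposed")
DUPLICATION_CLASSES = MODES + ("singleton",)

_NA = "NA"


class FormatError(ValueError):
    """A file violates the expected dialect (malformed row, bad value)."""


class ConsistencyError(ValueError):
    """Logically inconsistent inputs (e.g. one gene under two modes)."""


@dataclass(frozen=True)
class GeneRecord:
    """A gene with genomic coordinates and its duplication class.

    Coordinates are 1-based inclusive base pairs.  ``duplication_class``
    is one of the four duplication modes or ``"singleton"`` for genes not
    assigned to any mode.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    duplication_class: str = "singleton"

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise FormatError("gene_id must be non-empty")
        if self.start > self.end:
            raise FormatError(
                f"gene {self.gene_id!r}: start ({self.start}) > end ({self.end})"
            )
        if self.start < 1:
            raise FormatError(f"gene {self.gene_id!r}: start must be >= 1")
        if self.strand not in ("+", "-"):
            raise FormatError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.duplication_class not in DUPLICATION_CLASSES:
            raise FormatError(
                f"gene {self.gene_id!r}: unknown duplication class "
                f"{self.duplication_class!r}"
            )

    @property
    def tss(self) -> int:
        """Transcription start site: ``start`` on +, ``end`` on − strand."""
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class DuplicatePair:
    """An unordered paralog pair with optional substitution rates.

    ``ka``/``ks`` are nonsynonymous/synonymous substitution rates; ``None``
    means the estimate is missing (never silently coerced to 0).  The
    derived fields ``same_chromosome`` and ``distance_bp`` (TSS-to-TSS
    separation, same-chromosome pairs only) are filled by
    :func:`annotate_pairs`.
    """

    gene_a: str
    gene_b: str
    mode: str
    ka: float | None = None
    ks: float | None = None
    same_chromosome: bool | None = field(default=None, compare=False)
    distance_bp: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise FormatError(f"self-pair {self.gene_a!r}")
        if self.mode not in MODES:
            raise FormatError(f"unknown duplication mode {self.mode!r}")
        for name in ("ka", "ks"):
            v = getattr(self, name)
            if v is not None and (not np.isfinite(v) or v < 0):
                raise FormatError(
                    f"pair ({self.gene_a}, {self.gene_b}): {name} must be a "
                    f"finite nonnegative number, got {v!r}"
                )
        if self.gene_b < self.gene_a:  # canonical unordered representation
            a, b = self.gene_b, self.gene_a
            object.__setattr__(self, "gene_a", a)
            object.__setattr__(self, "gene_b", b)


def annotate_pairs(
    pairs: Sequence[DuplicatePair], catalog: Sequence[GeneRecord]
) -> list[DuplicatePair]:
    """Fill the derived ``same_chromosome`` / ``distance_bp`` fields.

    Raises :class:`ConsistencyError` if a pair references a gene absent
    from the catalog.
    """
    by_id = {g.gene_id: g for g in catalog}
    out = []
    for p in pairs:
        try:
            ga, gb = by_id[p.gene_a], by_id[p.gene_b]
        except KeyError as exc:
            raise ConsistencyError(
                f"pair ({p.gene_a}, {p.gene_b}) references uncataloged gene {exc}"
            ) from None
        same = ga.chromosome == gb.chromosome
        dist = abs(ga.tss - gb.tss) if same else None
        out.append(replace(p, same_chromosome=same, distance_bp=dist))
    return out


# ---------------------------------------------------------------------------
# gene catalog

_CATALOG_COLUMNS = [
    "gene_id",
    "chromosome",
    "start",
    "end",
    "strand",
    "duplication_class",
]


def _check_unique_ids(ids: Iterable[str]) -> None:
    seen: set[str] = set()
    for gid in ids:
        if gid in seen:
            raise FormatError(f"duplicate gene_id {gid!r} in catalog")
        seen.add(gid)


def read_gene_catalog(path: str | Path, format: str = "tsv") -> list[GeneRecord]:
    """Read a gene catalog in ``tsv``, ``bed`` or ``gff3`` dialect.

    BED coordinates (0-based half-open) are converted to the internal
    1-based inclusive convention.  For GFF3, rows with ``type == "gene"``
    are kept and the ``ID`` attribute provides the gene id.
    """
    path = Path(path)
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        except pd.errors.EmptyDataError:
            return []
        missing = [c for c in _CATALOG_COLUMNS[:5] if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing catalog columns {missing}")
        if "duplication_class" not in df.columns:
            df["duplication_class"] = "singleton"
        rows = df[_CATALOG_COLUMNS].itertuples(index=False)
        records = [
            GeneRecord(gid, chrom, int(start), int(end), strand, dup)
            for gid, chrom, start, end, strand, dup in rows
        ]
    elif format == "bed":
        records = []
        with open(path, encoding="utf-8") as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 6:
                    raise FormatError(f"{path}:{ln}: BED needs >= 6 columns")
                chrom, start, end, name, _score, strand = parts[:6]
                records.append(
                    GeneRecord(name, chrom, int(start) + 1, int(end), strand)
                )
    elif format == "gff3":
        records = []
        with open(path, encoding="utf-8") as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 9:
                    raise FormatError(f"{path}:{ln}: GFF3 needs 9 columns")
                chrom, _src, ftype, start, end, _score, strand, _phase, attrs = parts
                if ftype != "gene":
                    continue
                m = re.search(r"(?:^|;)ID=([^;]+)", attrs)
                if m is None:
                    raise FormatError(f"{path}:{ln}: gene row without ID attribute")
                records.append(
                    GeneRecord(m.group(1), chrom, int(start), int(end), strand)
                )
    else:
        raise ValueError(f"unknown catalog format {format!r}")
    _check_unique_ids(g.gene_id for g in records)
    return records


def write_gene_catalog(records: Sequence[GeneRecord], path: str | Path) -> None:
    """Write a catalog in the native TSV dialect (header, 1-based)."""
    df = pd.DataFrame(
        [
            (g.gene_id, g.chromosome, g.start, g.end, g.strand, g.duplication_class)
            for g in records
        ],
        columns=_CATALOG_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# duplicate pair lists (one headerless TSV per mode: gene_a  gene_b  [ka  ks])


def _parse_rate(token: str, where: str) -> float | None:
    if token in ("", _NA):
        return None
    try:
        return float(token)
    except ValueError:
        raise FormatError(f"{where}: non-numeric rate {token!r}") from None


def read_pair_lists(paths_by_mode: Mapping[str, str | Path]) -> list[DuplicatePair]:
    """Read per-mode pair files; each pair is tagged with its file's mode.

    A gene appearing under two different modes raises
    :class:`ConsistencyError` (each gene belongs to one mode at most).
    """
    pairs: list[DuplicatePair] = []
    mode_of_gene: dict[str, str] = {}
    for mode, path in paths_by_mode.items():
        if mode not in MODES:
            raise ValueError(f"unknown duplication mode {mode!r}")
        with open(path, encoding="utf-8") as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise FormatError(f"{path}:{ln}: need >= 2 columns")
                where = f"{path}:{ln}"
                ka = _parse_rate(parts[2], where) if len(parts) > 2 else None
                ks = _parse_rate(parts[3], where) if len(parts) > 3 else None
                pair = DuplicatePair(parts[0], parts[1], mode, ka=ka, ks=ks)
                for gid in (pair.gene_a, pair.gene_b):
                    prev = mode_of_gene.setdefault(gid, mode)
                    if prev != mode:
                        raise ConsistencyError(
                            f"gene {gid!r} appears under modes {prev!r} and {mode!r}"
                        )
                pairs.append(pair)
    return pairs


def write_pair_lists(
    pairs: Sequence[DuplicatePair], outdir: str | Path, prefix: str = "pairs"
) -> dict[str, Path]:
    """Write one ``<prefix>_<mode>.tsv`` per mode present; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for mode in MODES:
        rows = [p for p in pairs if p.mode == mode]
        if not rows:
            continue
        path = outdir / f"{prefix}_{mode}.tsv"
        with open(path, "w", encoding="utf-8") as fh:
            for p in rows:
                ka = _NA if p.ka is None else repr(p.ka)
                ks = _NA if p.ks is None else repr(p.ks)
                fh.write(f"{p.gene_a}\t{p.gene_b}\t{ka}\t{ks}\n")
        paths[mode] = path
    return paths


# ---------------------------------------------------------------------------
# numeric matrices (genes as rows, marks/samples as columns)


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes × columns numeric TSV (header row, gene ids as index).

    ``NA`` cells become NaN; any other non-numeric cell raises
    :class:`FormatError` naming the offending row and column.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    out = pd.DataFrame(index=df.index.astype(str))
    for col in df.columns:
        converted = pd.to_numeric(df[col].where(df[col] != _NA), errors="coerce")
        bad = converted.isna() & ~df[col].isin(("", _NA))
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise FormatError(
                f"{path}: non-numeric value {df.loc[row, col]!r} "
                f"at row {row!r}, column {col!r}"
            )
        out[col] = converted.astype(float)
    return out


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", na_rep=_NA, index_label="gene_id")


# ---------------------------------------------------------------------------
# gene -> GO term map (two columns, one association per row)


def read_go_map(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column ``gene_id<TAB>go_id`` TSV (with header) into a dict.

    Genes without rows are simply absent; callers query them as empty sets.
    """
    go: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if header and len(header.rstrip("\n").split("\t")) != 2:
            raise FormatError(f"{path}: GO map must have exactly two columns")
        for ln, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{ln}: GO map rows need two columns")
            go.setdefault(parts[0], set()).add(parts[1])
    return go


def write_go_map(go: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tgo_id\n")
        for gid in sorted(go):
            for term in sorted(go[gid]):
                fh.write(f"{gid}\t{term}\n")


# ---------------------------------------------------------------------------
# sample condition metadata


def read_sample_conditions(path: str | Path) -> pd.Series:
    """Read sample metadata TSV (sample_id, condition[, source_id]) as a Series."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "condition"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"{path}: duplicate sample_id {dup!r}")
    return pd.Series(
        df["condition"].to_numpy(), index=df["sample_id"], name="condition"
    )


def write_sample_conditions(conditions: pd.Series, path: str | Path) -> None:
    df = pd.DataFrame(
        {"sample_id": conditions.index, "condition": conditions.to_numpy()}
    )
    df.to_csv(path, sep="\t", index=False)
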