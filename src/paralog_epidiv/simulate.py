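"""Synthetic datasets with the statistical structure the analysis assumes.

The generator emulates the study design at the level the pipeline
consumes: a five-chromosome gene catalog, duplicate-pair lists for the
four duplication modes (whole-genome, tandem, proximal, transposed) with
Ka/Ks values, per-gene per-mark HM enrichment tables for ORF and
promoter regions, an FPKM-like expression matrix over three condition
groups (Normal / Stress / CM_mu), and a gene→GO map.  Default parameter
values mirror the study's printed design: 4,293 WGD + 2,130 tandem +
784 proximal + 904 transposed pairs (8,111 total) and 18 + 20 + 50 = 88
expression samples.

Generative model, per pair:

* HM profiles — each mark is bivariate normal on the z-score scale with
  a pair-level correlation ρ drawn around the mode's configured value;
  the promoter region gets a small positive ρ boost (promoter profiles
  are more conserved than ORF profiles).
* Ka grows linearly with the injected HM divergence (1 − ρ) via
  ``kaks_coupling``; Ks is a noisy multiple of Ka.
* Expression — the two genes share a common per-sample profile plus
  independent noise whose standard deviation scales with the condition's
  ``expression_divergence_shift`` and, through
  ``hm_expression_coupling``, with the pair's injected HM divergence.
* GO sets realise a functional type (I–V) sampled from a per-mode
  mixture; identifiers are synthetic ("GO:SYNTH:k"), no ontology
  topology.

The injected parameters are exposed in a ``truth`` record so recovery
tests can compare observed statistics against them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import (
    MODES,
    DuplicatePair,
    GeneRecord,
    annotate_pairs,
    write_gene_catalog,
    write_go_map,
    write_matrix,
    write_pair_lists,
    write_sample_conditions,
)
from .expression import CONDITIONS
from .functional import FUNCTIONAL_TYPES
from .profiles import HMProfileMatrix

__all__ = [
    "ConfigurationError",
    "DEFAULT_MARKS",
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_dataset",
    "write_dataset",
]


class ConfigurationError(ValueError):
    """An internally inconsistent :class:`SyntheticConfig`."""


#: The ten histone marks the study profiles.
DEFAULT_MARKS = (
    "H2Bub",
    "H3K4me1",
    "H3K4me2",
    "H3K4me3",
    "H3K9ac",
    "H3K9me2",
    "H3K27me1",
    "H3K27me3",
    "H3K36me3",
    "H3K14ac",
)

_GO_UNIVERSE_SIZE = 300


def _default_pairs() -> dict[str, int]:
    # printed pair counts: 8,111 total
    return {"WGD": 4293, "tandem": 2130, "proximal": 784, "transposed": 904}


def _default_rho() -> dict[str, float]:
    # qualitative ordering from the per-mark paralog correlation table:
    # tandem/proximal most similar, transposed least
    return {"WGD": 0.50, "tandem": 0.65, "proximal": 0.60, "transposed": 0.30}


def _default_same_chrom() -> dict[str, float]:
    return {"WGD": 0.30, "tandem": 1.0, "proximal": 1.0, "transposed": 0.10}


def _default_expr_shift() -> dict[str, float]:
    # CM_mu noisier than Normal ~ Stress (chromatin-modifier mutants
    # loosen coordinated expression of the pair)
    return {"Normal": 0.6, "Stress": 0.6, "CM_mu": 1.2}


def _default_samples() -> dict[str, int]:
    return {"Normal": 18, "Stress": 20, "CM_mu": 50}


def _default_go_mixture() -> dict[str, dict[str, float]]:
    # WGD enriched in partial sharing (Type II); single-gene duplications
    # increasingly disjoint/unannotated from tandem to transposed
    return {
        "WGD": {"I": 0.12, "II": 0.50, "III": 0.12, "IV": 0.13, "V": 0.13},
        "tandem": {"I": 0.30, "II": 0.25, "III": 0.12, "IV": 0.13, "V": 0.20},
        "proximal": {"I": 0.25, "II": 0.28, "III": 0.15, "IV": 0.14, "V": 0.18},
        "transposed": {"I": 0.18, "II": 0.30, "III": 0.20, "IV": 0.17, "V": 0.15},
    }


@dataclass
class SyntheticConfig:
    """Generative knobs for one synthetic dataset.

    Defaults are the study conditions: genome and pair counts, per-mode
    pair HM correlations, same-chromosome probabilities, condition group
    sizes, and couplings sized to reproduce the study's qualitative
    findings at their printed scale.
    """

    n_chromosomes: int = 5
    genes_per_chromosome: int = 5500
    n_pairs_by_mode: dict[str, int] = field(default_factory=_default_pairs)
    pair_hm_correlation_by_mode: dict[str, float] = field(default_factory=_default_rho)
    same_chromosome_prob_by_mode: dict[str, float] = field(
        default_factory=_default_same_chrom
    )
    kaks_coupling: float = 0.25
    expression_divergence_shift_by_condition: dict[str, float] = field(
        default_factory=_default_expr_shift
    )
    samples_per_condition: dict[str, int] = field(default_factory=_default_samples)
    go_type_mixture: Mapping = field(default_factory=_default_go_mixture)
    mark_names: tuple[str, ...] = DEFAULT_MARKS
    seed: int = 0
    # couplings beyond the headline knobs
    pair_rho_jitter: float = 0.15
    promoter_rho_boost: float = 0.10
    hm_expression_coupling: float = 1.0
    hm_shift_by_type: dict[str, float] | None = None
    # mark co-occurrence across genes: active marks correlate with each
    # other, repressive marks with each other, weak anti-correlation
    # between the groups (gives the concordant mark structure the Mantel
    # test measures)
    mark_cooccurrence: float = 0.45
    repressive_marks: tuple[str, ...] = ("H3K9me2", "H3K27me1", "H3K27me3")

    def mixture_for(self, mode: str) -> dict[str, float]:
        mix = self.go_type_mixture
        if mix and all(k in FUNCTIONAL_TYPES for k in mix):
            return dict(mix)  # one mixture for every mode
        return dict(mix[mode])

    def validate(self) -> None:
        if self.n_chromosomes < 1 or self.genes_per_chromosome < 0:
            raise ConfigurationError("genome dimensions must be positive")
        marks = tuple(self.mark_names)
        if len(marks) != 10 or len(set(marks)) != 10:
            raise ConfigurationError("mark_names must list exactly 10 distinct marks")
        for mode in MODES:
            n = self.n_pairs_by_mode.get(mode, 0)
            if n < 0:
                raise ConfigurationError(f"negative pair count for {mode}")
            rho = self.pair_hm_correlation_by_mode.get(mode, 0.0)
            if not -1.0 <= rho <= 1.0:
                raise ConfigurationError(f"pair correlation for {mode} outside [-1, 1]")
            p = self.same_chromosome_prob_by_mode.get(mode, 0.0)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"same-chromosome prob for {mode} outside [0, 1]")
            if mode in ("tandem", "proximal") and n > 0 and p < 1.0:
                raise ConfigurationError(
                    f"{mode} duplicates are local by definition; "
                    "same_chromosome_prob must be 1.0"
                )
            mix = self.mixture_for(mode)
            if set(mix) != set(FUNCTIONAL_TYPES):
                raise ConfigurationError(
                    f"go_type_mixture for {mode} must cover Types {FUNCTIONAL_TYPES}"
                )
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9 or any(v < 0 for v in mix.values()):
                raise ConfigurationError(
                    f"go_type_mixture for {mode} must be a probability vector"
                )
        for cond in CONDITIONS:
            if self.samples_per_condition.get(cond, 0) < 0:
                raise ConfigurationError(f"negative sample count for {cond}")
            if self.expression_divergence_shift_by_condition.get(cond, 0.0) < 0:
                raise ConfigurationError(f"negative expression shift for {cond}")
        if not 0.0 <= self.mark_cooccurrence < 1.0:
            raise ConfigurationError("mark_cooccurrence must lie in [0, 1)")
        n_genes = self.n_chromosomes * self.genes_per_chromosome
        needed = 2 * sum(self.n_pairs_by_mode.get(m, 0) for m in MODES)
        if needed > n_genes:
            raise ConfigurationError(
                f"{needed} genes required for the requested pairs but the "
                f"genome has only {n_genes}"
            )


@dataclass
class SyntheticDataset:
    """A self-consistent synthetic dataset plus its injected truth."""

    catalog: list[GeneRecord]
    pairs: list[DuplicatePair]
    hm_orf: HMProfileMatrix
    hm_promoter: HMProfileMatrix
    enrichment_orf: pd.DataFrame
    enrichment_promoter: pd.DataFrame
    expression: pd.DataFrame
    conditions: pd.Series
    go_map: dict[str, set[str]]
    truth: dict

    @property
    def singletons(self) -> list[GeneRecord]:
        return [g for g in self.catalog if g.duplication_class == "singleton"]

    def validate(self) -> None:
        ids = {g.gene_id for g in self.catalog}
        for p in self.pairs:
            if p.gene_a not in ids or p.gene_b not in ids:
                raise ValueError("pair references a gene absent from the catalog")
        for source in (
            self.hm_orf.gene_ids,
            self.hm_promoter.gene_ids,
            self.expression.index,
            self.go_map,
        ):
            for gid in source:
                if gid not in ids:
                    raise ValueError(f"gene {gid!r} absent from the catalog")
        mode_of: dict[str, str] = {}
        for p in self.pairs:
            for gid in (p.gene_a, p.gene_b):
                prev = mode_of.setdefault(gid, p.mode)
                if prev != p.mode:
                    raise ValueError(f"gene {gid!r} participates in two modes")


# ---------------------------------------------------------------------------


def _place_pairs(config: SyntheticConfig, rng: np.random.Generator):
    """Assign pair members to catalog slots honouring the physical layout:
    tandem = adjacent gene indices, proximal = within 10 indices, WGD and
    transposed on the same chromosome only with their configured
    probability."""
    n_chrom, m = config.n_chromosomes, config.genes_per_chromosome
    free = [np.ones(m, dtype=bool) for _ in range(n_chrom)]

    def take_random(c: int) -> int:
        open_idx = np.flatnonzero(free[c])
        i = int(open_idx[rng.integers(len(open_idx))])
        free[c][i] = False
        return i

    def chrom_with_free(exclude: int | None = None, need: int = 1) -> int:
        order = rng.permutation(n_chrom)
        for c in order:
            if c != exclude and free[c].sum() >= need:
                return int(c)
        raise ConfigurationError("ran out of free gene slots during placement")

    placements: list[tuple[str, int, int, int, int]] = []  # mode, ca, ia, cb, ib
    # local modes first: they need specific adjacency still available
    for mode in ("tandem", "proximal", "WGD", "transposed"):
        n = config.n_pairs_by_mode.get(mode, 0)
        p_same = config.same_chromosome_prob_by_mode.get(mode, 0.0)
        for _ in range(n):
            if mode in ("tandem", "proximal"):
                lo, hi = (1, 1) if mode == "tandem" else (2, 10)
                for attempt in range(10_000):
                    c = int(rng.integers(n_chrom))
                    d = int(rng.integers(lo, hi + 1))
                    i = int(rng.integers(0, m - d))
                    if free[c][i] and free[c][i + d]:
                        free[c][i] = free[c][i + d] = False
                        placements.append((mode, c, i, c, i + d))
                        break
                else:
                    raise ConfigurationError(
                        f"could not place a {mode} pair; genome too crowded"
                    )
            else:
                if rng.random() < p_same:
                    c = chrom_with_free(need=2)
                    i, j = take_random(c), take_random(c)
                    placements.append((mode, c, i, c, j))
                else:
                    ca = chrom_with_free()
                    i = take_random(ca)
                    cb = chrom_with_free(exclude=ca)
                    j = take_random(cb)
                    placements.append((mode, ca, i, cb, j))
    return placements


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate one dataset; identical config (incl. seed) ⇒ identical data."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_chrom, m = config.n_chromosomes, config.genes_per_chromosome
    marks = list(config.mark_names)
    n_genes = n_chrom * m

    # --- catalog layout: 1 kb genes every 2 kb along each chromosome
    gene_ids = np.array(
        [f"AT{c + 1}G{(i + 1) * 10:05d}" for c in range(n_chrom) for i in range(m)]
    )
    chrom_of = np.repeat([f"Chr{c + 1}" for c in range(n_chrom)], m)
    starts = np.tile(1 + 2000 * np.arange(m), n_chrom)
    strands = rng.choice(["+", "-"], size=n_genes)

    def flat(c: int, i: int) -> int:
        return c * m + i

    placements = _place_pairs(config, rng)
    n_pairs = len(placements)
    a_idx = np.array([flat(c, i) for _, c, i, _, _ in placements], dtype=int)
    b_idx = np.array([flat(c, i) for _, _, _, c, i in placements], dtype=int)
    pair_modes = np.array([mode for mode, *_ in placements])

    dup_class = np.full(n_genes, "singleton", dtype=object)
    dup_class[a_idx] = pair_modes
    dup_class[b_idx] = pair_modes

    catalog = [
        GeneRecord(
            gene_ids[k],
            chrom_of[k],
            int(starts[k]),
            int(starts[k]) + 999,
            strands[k],
            dup_class[k],
        )
        for k in range(n_genes)
    ]

    # --- injected pair-level parameters
    type_draws = np.empty(n_pairs, dtype=object)
    for mode in MODES:
        sel = pair_modes == mode
        if not sel.any():
            continue
        mix = config.mixture_for(mode)
        probs = np.array([mix[t] for t in FUNCTIONAL_TYPES])
        type_draws[sel] = rng.choice(FUNCTIONAL_TYPES, size=int(sel.sum()), p=probs / probs.sum())

    rho_base = np.array(
        [config.pair_hm_correlation_by_mode.get(mode, 0.0) for mode in pair_modes]
    )
    type_shift = np.zeros(n_pairs)
    if config.hm_shift_by_type:
        type_shift = np.array(
            [config.hm_shift_by_type.get(t, 0.0) for t in type_draws]
        )
    rho_orf = np.clip(
        rho_base + config.pair_rho_jitter * rng.standard_normal(n_pairs) + type_shift,
        -0.99,
        0.99,
    )
    rho_prom = np.clip(rho_orf + config.promoter_rho_boost, -0.99, 0.99)
    d_true = 1.0 - rho_orf

    # --- Ka/Ks coupled to the injected divergence
    ka = np.maximum(
        0.0, 0.03 + config.kaks_coupling * d_true + 0.06 * rng.standard_normal(n_pairs)
    )
    ks = np.maximum(
        ka, ka * rng.uniform(2.0, 5.0, size=n_pairs) + 0.1 * rng.standard_normal(n_pairs)
    )

    # --- HM enrichment: bivariate-normal latents with a two-block mark
    # covariance (active vs repressive co-occurrence), mark-specific
    # location/scale on the enrichment-ratio scale
    mark_loc = np.linspace(0.4, 2.2, len(marks))
    mark_scale = np.linspace(0.5, 1.2, len(marks))
    repressive = np.array([m in config.repressive_marks for m in marks])
    same_block = repressive[:, None] == repressive[None, :]
    sigma = np.where(same_block, config.mark_cooccurrence, -config.mark_cooccurrence / 3)
    np.fill_diagonal(sigma, 1.0)
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        raise ConfigurationError(
            "mark co-occurrence matrix is not positive definite"
        ) from None
    enrichment = {}
    for region, rho in (("ORF", rho_orf), ("promoter", rho_prom)):
        z = rng.standard_normal((n_genes, len(marks))) @ chol.T
        if n_pairs:
            eps = rng.standard_normal((n_pairs, len(marks))) @ chol.T
            z[b_idx] = rho[:, None] * z[a_idx] + np.sqrt(1 - rho[:, None] ** 2) * eps
        enrichment[region] = pd.DataFrame(
            mark_loc + mark_scale * z, index=gene_ids, columns=marks
        )

    hm_orf = HMProfileMatrix.from_enrichment(enrichment["ORF"], "ORF")
    hm_prom = HMProfileMatrix.from_enrichment(enrichment["promoter"], "promoter")

    # --- expression across condition groups
    sample_ids: list[str] = []
    sample_conditions: list[str] = []
    for cond in CONDITIONS:
        for k in range(config.samples_per_condition.get(cond, 0)):
            sample_ids.append(f"{cond}_{k + 1:02d}")
            sample_conditions.append(cond)
    n_samples = len(sample_ids)
    mu = rng.normal(5.0, 1.5, size=n_genes)
    latent = mu[:, None] + rng.standard_normal((n_genes, n_samples))
    if n_pairs and n_samples:
        shared = rng.standard_normal((n_pairs, n_samples))
        sigma_pair = 0.5 + config.hm_expression_coupling * d_true
        cond_arr = np.array(sample_conditions)
        sigma = np.empty((n_pairs, n_samples))
        for cond in CONDITIONS:
            cols = cond_arr == cond
            if cols.any():
                shift = config.expression_divergence_shift_by_condition.get(cond, 0.0)
                sigma[:, cols] = (shift * sigma_pair)[:, None]
        latent[a_idx] = mu[a_idx][:, None] + shared + sigma * rng.standard_normal(
            (n_pairs, n_samples)
        )
        latent[b_idx] = mu[b_idx][:, None] + shared + sigma * rng.standard_normal(
            (n_pairs, n_samples)
        )
    expression = pd.DataFrame(
        np.exp2(np.maximum(latent, 0.0)) - 1.0, index=gene_ids, columns=sample_ids
    )
    conditions = pd.Series(sample_conditions, index=sample_ids, name="condition")

    # --- GO annotation sets realising each pair's functional type
    universe = [f"GO:SYNTH:{k:04d}" for k in range(_GO_UNIVERSE_SIZE)]
    go_map: dict[str, set[str]] = {}

    def sample_terms(k: int, exclude: set[str] = frozenset()) -> set[str]:
        terms: set[str] = set()
        while len(terms) < k:
            t = universe[int(rng.integers(_GO_UNIVERSE_SIZE))]
            if t not in exclude:
                terms.add(t)
        return terms

    for p in range(n_pairs):
        ga, gb = gene_ids[a_idx[p]], gene_ids[b_idx[p]]
        t = type_draws[p]
        if t == "I":
            shared = sample_terms(int(rng.integers(2, 6)))
            go_map[ga] = set(shared)
            go_map[gb] = set(shared)
        elif t == "II":
            shared = sample_terms(int(rng.integers(1, 5)))
            extra_a = sample_terms(int(rng.integers(1, 4)), exclude=shared)
            extra_b = sample_terms(int(rng.integers(0, 4)), exclude=shared | extra_a)
            go_map[ga] = shared | extra_a
            go_map[gb] = shared | extra_b
        elif t == "III":
            sa = sample_terms(int(rng.integers(1, 5)))
            sb = sample_terms(int(rng.integers(1, 5)), exclude=sa)
            go_map[ga] = sa
            go_map[gb] = sb
        elif t == "IV":
            annotated = ga if rng.random() < 0.5 else gb
            go_map[annotated] = sample_terms(int(rng.integers(1, 5)))
        # Type V: neither annotated
    for k in np.flatnonzero(dup_class == "singleton"):
        if rng.random() < 0.7:
            go_map[gene_ids[k]] = sample_terms(int(rng.integers(1, 6)))

    pairs = [
        DuplicatePair(
            gene_ids[a_idx[p]],
            gene_ids[b_idx[p]],
            pair_modes[p],
            ka=float(ka[p]),
            ks=float(ks[p]),
        )
        for p in range(n_pairs)
    ]
    pairs = annotate_pairs(pairs, catalog)

    truth = {
        "seed": config.seed,
        "pair_hm_correlation_by_mode": dict(config.pair_hm_correlation_by_mode),
        "kaks_coupling": config.kaks_coupling,
        "hm_expression_coupling": config.hm_expression_coupling,
        "expression_divergence_shift_by_condition": dict(
            config.expression_divergence_shift_by_condition
        ),
        "pairs": [
            {
                # canonical unordered orientation, matching DuplicatePair
                "gene_a": str(min(gene_ids[a_idx[p]], gene_ids[b_idx[p]])),
                "gene_b": str(max(gene_ids[a_idx[p]], gene_ids[b_idx[p]])),
                "mode": str(pair_modes[p]),
                "rho_orf": float(rho_orf[p]),
                "rho_promoter": float(rho_prom[p]),
                "d_true": float(d_true[p]),
                "functional_type": str(type_draws[p]),
            }
            for p in range(n_pairs)
        ],
    }

    return SyntheticDataset(
        catalog=catalog,
        pairs=pairs,
        hm_orf=hm_orf,
        hm_promoter=hm_prom,
        enrichment_orf=enrichment["ORF"],
        enrichment_promoter=enrichment["promoter"],
        expression=expression,
        conditions=conditions,
        go_map=go_map,
        truth=truth,
    )


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write every input file the readers accept, plus a truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["catalog"] = outdir / "catalog.tsv"
    write_gene_catalog(dataset.catalog, paths["catalog"])

    for mode, p in write_pair_lists(dataset.pairs, outdir).items():
        paths[f"pairs_{mode}"] = p

    for region, enr in (
        ("orf", dataset.enrichment_orf),
        ("promoter", dataset.enrichment_promoter),
    ):
        paths[f"hm_{region}"] = outdir / f"hm_{region}_enrichment.tsv"
        write_matrix(enr, paths[f"hm_{region}"])

    paths["expression"] = outdir / "expression.tsv"
    write_matrix(dataset.expression, paths["expression"])
    paths["samples"] = outdir / "samples.tsv"
    write_sample_conditions(dataset.conditions, paths["samples"])

    paths["go_map"] = outdir / "go_map.tsv"
    write_go_map(dataset.go_map, paths["go_map"])

    paths["truth"] = outdir / "truth.json"
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(dataset.truth, fh, indent=1, sort_keys=True)
    return paths
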