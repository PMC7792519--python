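"""Pipeline orchestration: simulate → profile → divergence → resampling →
expression → functional, driven by a YAML config, with logging and a
machine-readable JSON report validated against a published schema.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from .io import (
    ConsistencyError,
    FormatError,
    read_gene_catalog,
    read_go_map,
    read_matrix,
    read_pair_lists,
    read_sample_conditions,
)
from .model import DuplicateHMDivergence
from .profiles import PROMOTER_WINDOW_BP
from .resampling import DEFAULT_N_REPLICATES
from .simulate import SyntheticConfig, generate_dataset, write_dataset

__all__ = [
    "PipelineConfig",
    "Diagnostic",
    "validate_inputs",
    "run_pipeline",
    "load_report_schema",
    "validate_report",
]

logger = logging.getLogger("paralog_epidiv")


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs.

    Exactly one of ``simulate`` (generator settings) or ``inputs`` (paths
    to the five on-disk inputs) must be provided.
    """

    outdir: str = "paralog_epidiv_out"
    seed: int | None = None
    simulate: SyntheticConfig | None = None
    inputs: dict[str, Any] | None = None
    promoter_window: int = PROMOTER_WINDOW_BP
    ka_max: float = 0.5
    ks_max: float = 2.0
    n_randomizations: int = DEFAULT_N_REPLICATES
    mantel_permutations: int = 9999
    expression_condition: str = "Normal"

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("config needs exactly one of 'simulate' or 'inputs'")
        if self.ka_max <= 0 or self.ks_max <= 0:
            raise ValueError("Ka/Ks thresholds must be positive")
        if self.n_randomizations < 1 or self.mantel_permutations < 1:
            raise ValueError("replicate counts must be >= 1")
        if self.promoter_window < 0:
            raise ValueError("promoter window must be nonnegative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(
            simulate=SyntheticConfig(**sim) if sim is not None else None,
            **raw,
        )
        return cfg


@dataclass
class Diagnostic:
    level: str  # "fatal" | "warning"
    message: str


def validate_inputs(paths: Mapping[str, Any]) -> list[Diagnostic]:
    """Cross-check id consistency among the five inputs.

    ``paths`` uses the same keys as the config ``inputs`` block: catalog,
    catalog_format, pairs (mode→path), hm_orf, hm_promoter, expression,
    samples, go_map.  Returns diagnostics; an empty list means clean.
    """
    diags: list[Diagnostic] = []
    try:
        catalog = read_gene_catalog(
            paths["catalog"], format=paths.get("catalog_format", "tsv")
        )
    except (OSError, FormatError, KeyError) as exc:
        return [Diagnostic("fatal", f"catalog unreadable: {exc}")]
    ids = {g.gene_id for g in catalog}

    pairs = []
    if paths.get("pairs"):
        try:
            pairs = read_pair_lists(paths["pairs"])
        except (OSError, FormatError) as exc:
            diags.append(Diagnostic("fatal", f"pair lists unreadable: {exc}"))
        except ConsistencyError as exc:
            diags.append(Diagnostic("fatal", f"duplication-class conflict: {exc}"))
    for p in pairs:
        for gid in (p.gene_a, p.gene_b):
            if gid not in ids:
                diags.append(
                    Diagnostic("fatal", f"pair references uncataloged gene {gid!r}")
                )

    for key in ("hm_orf", "hm_promoter", "expression"):
        if not paths.get(key):
            continue
        try:
            mat = read_matrix(paths[key])
        except (OSError, FormatError) as exc:
            diags.append(Diagnostic("fatal", f"{key} unreadable: {exc}"))
            continue
        orphans = [g for g in mat.index if g not in ids]
        if orphans:
            diags.append(
                Diagnostic(
                    "warning",
                    f"{key}: {len(orphans)} gene ids not in catalog "
                    f"(e.g. {orphans[0]!r})",
                )
            )
        if key.startswith("hm_"):
            missing = [g for g in ids if g not in set(mat.index)]
            if pairs and missing:
                pair_genes = {g for p in pairs for g in (p.gene_a, p.gene_b)}
                lost = pair_genes & set(missing)
                if lost:
                    diags.append(
                        Diagnostic(
                            "warning",
                            f"{key}: {len(lost)} pair genes lack HM profiles",
                        )
                    )
    if paths.get("samples") and paths.get("expression"):
        try:
            cond = read_sample_conditions(paths["samples"])
            expr_cols = pd.read_csv(
                paths["expression"], sep="\t", nrows=0
            ).columns[1:]
            unassigned = [s for s in expr_cols if s not in cond.index]
            if unassigned:
                diags.append(
                    Diagnostic(
                        "fatal",
                        f"samples without condition assignment: {unassigned[:5]}",
                    )
                )
        except (OSError, FormatError) as exc:
            diags.append(Diagnostic("fatal", f"sample metadata unreadable: {exc}"))
    if paths.get("go_map"):
        try:
            go = read_go_map(paths["go_map"])
            orphans = [g for g in go if g not in ids]
            if orphans:
                diags.append(
                    Diagnostic(
                        "warning",
                        f"go_map: {len(orphans)} gene ids not in catalog",
                    )
                )
        except (OSError, FormatError) as exc:
            diags.append(Diagnostic("fatal", f"go_map unreadable: {exc}"))
    return diags


def _build_model(config: PipelineConfig):
    if config.simulate is not None:
        sim = config.simulate
        if config.seed is not None:
            sim.seed = config.seed
        t0 = time.perf_counter()
        dataset = generate_dataset(sim)
        logger.info("simulate: %d genes, %d pairs (%.1fs)",
                    len(dataset.catalog), len(dataset.pairs),
                    time.perf_counter() - t0)
        return DuplicateHMDivergence.from_dataset(
            dataset, ka_max=config.ka_max, ks_max=config.ks_max
        ), dataset
    inputs = config.inputs
    diags = validate_inputs(inputs)
    fatal = [d for d in diags if d.level == "fatal"]
    for d in diags:
        logger.log(logging.ERROR if d.level == "fatal" else logging.WARNING, d.message)
    if fatal:
        raise ConsistencyError(
            "fatal input inconsistencies: " + "; ".join(d.message for d in fatal[:3])
        )
    model = DuplicateHMDivergence.from_files(
        catalog=inputs["catalog"],
        pairs_by_mode=inputs.get("pairs", {}),
        hm_orf=inputs["hm_orf"],
        hm_promoter=inputs["hm_promoter"],
        expression=inputs.get("expression"),
        samples=inputs.get("samples"),
        go_map=inputs.get("go_map"),
        catalog_format=inputs.get("catalog_format", "tsv"),
        ka_max=config.ka_max,
        ks_max=config.ks_max,
    )
    return model, None


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, write the outputs and return the JSON report.

    Outputs under ``config.outdir``: ``pair_records.tsv`` (one row per
    pair), ``per_mark_correlations.tsv`` (Table-1-style mark × mode ×
    region r/p), ``randomization.tsv``, ``report.json``.  With a
    simulate block, the generated inputs land under ``inputs/``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model, dataset = _build_model(config)
    if dataset is not None:
        write_dataset(dataset, outdir / "inputs")

    t0 = time.perf_counter()
    results = model.fit(
        n_randomizations=config.n_randomizations,
        mantel_permutations=config.mantel_permutations,
        seed=config.seed,
        expression_condition=config.expression_condition,
    )
    logger.info("fit: %.1fs", time.perf_counter() - t0)
    for stage, reason in results.skipped.items():
        logger.warning("stage %s skipped: %s", stage, reason)

    results.records.to_csv(
        outdir / "pair_records.tsv", sep="\t", index=False, na_rep="NA"
    )
    results.per_mark_correlations.to_csv(
        outdir / "per_mark_correlations.tsv", sep="\t", index=False, na_rep="NA"
    )
    rand_rows = []
    for key, res in results.randomization.items():
        rand_rows.append(
            {
                "analysis": key,
                "constraint": res.constraint,
                "n_replicates": res.n_replicates,
                "observed_median": res.observed_median,
                "null_median_of_medians": float(
                    pd.Series(res.replicate_medians).median()
                ),
                "wilcoxon_p": res.comparison_p,
                "direction": res.direction,
                "empirical_replicate_p": res.empirical_replicate_p,
                "seed": res.seed,
            }
        )
    pd.DataFrame(rand_rows).to_csv(
        outdir / "randomization.tsv", sep="\t", index=False, na_rep="NA"
    )
    if results.functional_association is not None:
        results.functional_association["table"].to_csv(
            outdir / "mode_by_type_counts.tsv", sep="\t", na_rep="NA"
        )

    report = _sanitize(results.to_report())
    validate_report(report)
    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, allow_nan=False)
    return report


def _sanitize(obj):
    """Make a report strictly JSON: numpy scalars to Python, NaN to null."""
    import math

    import numpy as np

    if isinstance(obj, dict):
        return {str(k): _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, (bool, np.bool_)):
        return bool(obj)
    if isinstance(obj, (int, np.integer)):
        return int(obj)
    if isinstance(obj, (float, np.floating)):
        f = float(obj)
        return f if math.isfinite(f) else None
    return obj


# ---------------------------------------------------------------------------
# report schema (subset of JSON Schema: type / properties / required / items)


def load_report_schema() -> dict:
    with resources.files("paralog_epidiv").joinpath("report_schema.json").open(
        encoding="utf-8"
    ) as fh:
        return json.load(fh)


_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "number": (int, float),
    "integer": int,
    "boolean": bool,
    "null": type(None),
}


def _check(instance, schema: dict, path: str, errors: list[str]) -> None:
    types = schema.get("type")
    if types is not None:
        allowed = types if isinstance(types, list) else [types]
        py = tuple(
            t for name in allowed for t in (
                _TYPES[name] if isinstance(_TYPES[name], tuple) else (_TYPES[name],)
            )
        )
        if not isinstance(instance, py) or (
            isinstance(instance, bool) and bool not in py
        ):
            errors.append(f"{path or '$'}: expected {allowed}, got {type(instance).__name__}")
            return
    if isinstance(instance, dict):
        for key in schema.get("required", []):
            if key not in instance:
                errors.append(f"{path or '$'}: missing required key {key!r}")
    for key, sub in schema.get("properties", {}).items():
        if isinstance(instance, dict) and key in instance:
            _check(instance[key], sub, f"{path}.{key}", errors)
    if "items" in schema and isinstance(instance, list):
        for i, item in enumerate(instance):
            _check(item, schema["items"], f"{path}[{i}]", errors)


def validate_report(report: dict, schema: dict | None = None) -> None:
    """Structural validation of a report against the published schema."""
    if schema is None:
        schema = load_report_schema()
    errors: list[str] = []
    _check(report, schema, "", errors)
    if errors:
        raise ValueError("report schema violations: " + "; ".join(errors[:5]))
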