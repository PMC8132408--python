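"""Config-driven orchestration of the whole screen.

``run_pipeline`` is the in-memory engine: both approaches, their
combination on the focal target species, GO enrichment of the candidate
lists, and the stage-contrast overlay on the combined candidates.
``run_all`` wraps it for file-based use: it loads every table named in a
YAML config, runs the engine, and writes gene-set TSVs, enrichment tables,
DE results, the key→count summary and a log under one run directory.

Every filter logs input size, output size and excluded-for-missing-data
counts: censoring (genes without phenotype or expression data) is a real
feature of this kind of screen and is surfaced, not hidden.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .de import classify_expression, ddct_quantity, nb_stage_test
from .enrichment import EnrichmentResult, enrich, reproduction_fraction
from .expression import AbsoluteLevel, ClassificationRule, parse_level
from .filters import (
    Approach2Result,
    CascadeResult,
    CombinationResult,
    combine_approaches,
    run_approach1,
    run_approach2,
)
from .gene_sets import GeneSet
from .orthology import map_forward
from .tables import (
    CountMatrix,
    CtTable,
    ExpressionTable,
    GoAnnotationSet,
    OrthologTable,
    PhenotypeTable,
    read_count_matrix,
    read_ct_table,
    read_expression_table,
    read_gene_list,
    read_go_annotations,
    read_ortholog_table,
    read_phenotype_table,
    write_gene_set_report,
    write_summary,
    _read_tsv,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised with the full list of config violations, not just the first."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__(
            "invalid configuration:\n" + "\n".join(f"- {v}" for v in violations)
        )


@dataclass
class RunConfig:
    source_species: str
    intermediate_species: str
    focal_target: str
    paths: dict[str, str]
    target_ortholog_paths: dict[str, str]
    rule: ClassificationRule
    min_absolute_level: AbsoluteLevel
    enrichment_alpha: float
    de_alpha: float
    expression_floor: float
    min_base_mean: float
    output_dir: str
    seed: int = 0


_REQUIRED_PATHS = (
    "source_expression",
    "source_orthologs",
    "intermediate_expression",
    "phenotypes",
    "curated_list",
    "go_annotations",
)
_OPTIONAL_PATHS = ("counts", "conditions", "ct_table")


def validate_config(path) -> RunConfig:
    """Parse and validate a YAML config; report every violation at once."""
    try:
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
    except OSError as exc:
        raise ConfigError([f"cannot read config file: {exc}"])
    violations: list[str] = []
    species = raw.get("species", {})
    inputs = raw.get("inputs", {})
    classification = raw.get("classification", {})
    enr = raw.get("enrichment", {})
    de = raw.get("de", {})

    for key in ("source", "intermediate", "focal_target"):
        if not species.get(key):
            violations.append(f"species.{key} is required")
    for key in _REQUIRED_PATHS:
        p = inputs.get(key)
        if not p:
            violations.append(f"inputs.{key} is required")
        elif not Path(p).exists():
            violations.append(f"inputs.{key}: no such file: {p}")
    targets = inputs.get("target_orthologs") or {}
    if not isinstance(targets, dict) or not targets:
        violations.append("inputs.target_orthologs must map species to paths")
        targets = {}
    for sp, p in targets.items():
        if not Path(p).exists():
            violations.append(f"inputs.target_orthologs.{sp}: no such file: {p}")
    focal = species.get("focal_target")
    if targets and focal and focal not in targets:
        violations.append(
            f"species.focal_target {focal!r} has no ortholog table"
        )
    for key in _OPTIONAL_PATHS:
        p = inputs.get(key)
        if p and not Path(p).exists():
            violations.append(f"inputs.{key}: no such file: {p}")

    alpha = enr.get("alpha", 0.05)
    if not (0 < float(alpha) < 1):
        violations.append(f"enrichment.alpha must lie in (0, 1); got {alpha}")
    de_alpha = de.get("alpha", 0.05)
    if not (0 < float(de_alpha) < 1):
        violations.append(f"de.alpha must lie in (0, 1); got {de_alpha}")
    floor = de.get("expression_floor", 5.0)
    if float(floor) < 0:
        violations.append(f"de.expression_floor must be >= 0; got {floor}")
    if not raw.get("output_dir"):
        violations.append("output_dir is required")

    rule = None
    try:
        rule = ClassificationRule(
            focal_tissue=classification.get("focal_tissue", "testis"),
            tolerated_tissues=frozenset(
                classification.get(
                    "tolerated_tissues", ["accessory_gland", "imaginal_disc"]
                )
            ),
            side_tissue_max_level=parse_level(
                classification.get("side_tissue_max_level", "moderately high")
            ),
            max_other_expressed=int(
                classification.get("max_other_expressed", 1)
            ),
        )
        min_level = parse_level(
            classification.get("min_absolute_level", "moderately high")
        )
    except ValueError as exc:
        violations.append(f"classification: {exc}")
        min_level = AbsoluteLevel.MODERATELY_HIGH
    if violations:
        raise ConfigError(violations)
    return RunConfig(
        source_species=species["source"],
        intermediate_species=species["intermediate"],
        focal_target=focal,
        paths={k: inputs[k] for k in _REQUIRED_PATHS}
        | {k: inputs[k] for k in _OPTIONAL_PATHS if inputs.get(k)},
        target_ortholog_paths=dict(targets),
        rule=rule,
        min_absolute_level=min_level,
        enrichment_alpha=float(alpha),
        de_alpha=float(de_alpha),
        expression_floor=float(floor),
        min_base_mean=float(de.get("min_base_mean", 1.0)),
        output_dir=str(raw["output_dir"]),
        seed=int(raw.get("seed", 0)),
    )


@dataclass
class PipelineResult:
    cascade: CascadeResult
    approach2: Approach2Result
    combination: CombinationResult
    enrichment: dict[str, list[EnrichmentResult]]
    de_results: pd.DataFrame | None
    expression_classes: pd.DataFrame | None
    ddct: pd.DataFrame | None
    summary: dict[str, int] = field(default_factory=dict)


def run_pipeline(
    source_expression: ExpressionTable,
    source_to_intermediate: OrthologTable,
    intermediate_expression: ExpressionTable,
    phenotypes: PhenotypeTable,
    target_tables: Mapping[str, OrthologTable],
    curated: GeneSet,
    annotations: GoAnnotationSet | None = None,
    counts: CountMatrix | None = None,
    ct_table: CtTable | None = None,
    focal_target: str | None = None,
    rule: ClassificationRule | None = None,
    min_level: AbsoluteLevel = AbsoluteLevel.MODERATELY_HIGH,
    enrichment_alpha: float = 0.05,
    de_alpha: float = 0.05,
    expression_floor: float = 5.0,
    min_base_mean: float = 1.0,
) -> PipelineResult:
    """Run both approaches, combine them, enrich, and overlay the DE stage.

    Stages whose inputs are absent (annotations, counts, Ct table) are
    skipped with a log message; everything feasible still runs.
    """
    rule = rule or ClassificationRule()
    focal = focal_target or next(iter(target_tables))
    if focal not in target_tables:
        raise ValueError(f"no ortholog table for focal target {focal!r}")

    cascade = run_approach1(
        source_expression,
        source_to_intermediate,
        intermediate_expression,
        phenotypes,
        target_tables,
        rule=rule,
        min_level=min_level,
    )
    approach2 = run_approach2(curated, target_tables)
    set_a = cascade.per_species_orthologs[focal]
    set_b = approach2.per_species_orthologs[focal]
    combination = combine_approaches(set_a, set_b)
    # the alternative intermediate-species overlap, surfaced separately
    fly_overlap = cascade.initial.members & curated.members

    summary: dict[str, int] = {}
    summary.update(cascade.summary())
    summary.update(
        {f"approach2_{k}": v for k, v in approach2.summary().items()}
    )
    summary.update(combination.summary())
    summary["n_intermediate_overlap"] = len(fly_overlap)

    enrichment_results: dict[str, list[EnrichmentResult]] = {}
    if annotations is not None:
        for name, gs in (
            ("initial", cascade.initial),
            ("filter23", cascade.after_relative_and_absolute),
            ("curated", curated),
        ):
            results = enrich(gs, annotations, alpha=enrichment_alpha)
            enrichment_results[name] = results
            n_repro, n_signif, frac = reproduction_fraction(
                results, enrichment_alpha
            )
            summary[f"enrichment_{name}_n_significant"] = n_signif
            summary[f"enrichment_{name}_n_reproduction"] = n_repro
    else:
        logger.warning("no GO annotations supplied; enrichment skipped")

    de_results = None
    expr_classes = None
    if counts is not None:
        de_results = nb_stage_test(
            counts, alpha=de_alpha, min_base_mean=min_base_mean
        )
        expr_classes = classify_expression(counts, floor=expression_floor)
        candidates = [
            g for g in combination.union.members
            if g in counts.counts.index
        ]
        summary["n_candidates_in_matrix"] = len(candidates)
        expressed = expr_classes.loc[candidates, "expressed_both"]
        expressed_ids = set(expressed[expressed].index)
        summary["n_expressed_both"] = len(expressed_ids)
        high = expr_classes.loc[sorted(expressed_ids), "level_class"].isin(
            ["high", "very high"]
        )
        summary["n_high_level"] = int(high.sum())
        mod = de_results.loc[sorted(expressed_ids), "modulation"]
        summary["n_modulated"] = int((mod != "unchanged").sum())
        summary["n_up"] = int((mod == "up").sum())
        summary["n_down"] = int((mod == "down").sum())
    else:
        logger.warning("no count matrix supplied; stage-contrast overlay skipped")

    ddct = None
    if ct_table is not None:
        ddct = ddct_quantity(ct_table)

    return PipelineResult(
        cascade=cascade,
        approach2=approach2,
        combination=combination,
        enrichment=enrichment_results,
        de_results=de_results,
        expression_classes=expr_classes,
        ddct=ddct,
        summary=summary,
    )


def _enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "term_name": r.term_name,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p_raw": r.p_raw,
                "p_adj": r.p_adj,
                "reproduction_related": r.reproduction_related,
            }
            for r in results
        ]
    )


def run_all(config: RunConfig) -> PipelineResult:
    """Load every table named in the config, run the engine, write outputs."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out / "run.log", mode="w")
    log_handler.setFormatter(
        logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    )
    root = logging.getLogger("testisscreen")
    root.addHandler(log_handler)
    root.setLevel(logging.INFO)
    try:
        source_expr = read_expression_table(
            config.paths["source_expression"], "numeric",
            species=config.source_species,
        )
        source_orth = read_ortholog_table(
            config.paths["source_orthologs"],
            config.source_species, config.intermediate_species,
        )
        inter_expr = read_expression_table(
            config.paths["intermediate_expression"], "ordinal",
            species=config.intermediate_species,
        )
        phenotypes = read_phenotype_table(config.paths["phenotypes"])
        target_tables = {
            sp: read_ortholog_table(p, config.intermediate_species, sp)
            for sp, p in config.target_ortholog_paths.items()
        }
        curated = read_gene_list(
            config.paths["curated_list"], config.intermediate_species,
            "curated_reproductive",
        )
        annotations = read_go_annotations(config.paths["go_annotations"])
        counts = None
        if "counts" in config.paths and "conditions" in config.paths:
            cond = _read_tsv(config.paths["conditions"])
            condition_map = dict(zip(cond["sample"], cond["condition"]))
            counts = read_count_matrix(config.paths["counts"], condition_map)
        ct_table = None
        if "ct_table" in config.paths:
            ct_table = read_ct_table(
                config.paths["ct_table"],
                reference_genes=("rpl6", "rpl7"),
                calibrator_sample="white",
            )
        result = run_pipeline(
            source_expr, source_orth, inter_expr, phenotypes, target_tables,
            curated, annotations, counts, ct_table,
            focal_target=config.focal_target,
            rule=config.rule,
            min_level=config.min_absolute_level,
            enrichment_alpha=config.enrichment_alpha,
            de_alpha=config.de_alpha,
            expression_floor=config.expression_floor,
            min_base_mean=config.min_base_mean,
        )
        write_outputs(result, out)
        return result
    finally:
        root.removeHandler(log_handler)
        log_handler.close()


def write_outputs(result: PipelineResult, out: Path) -> None:
    out = Path(out)
    gene_sets = [
        result.cascade.source_screened,
        result.cascade.initial,
        result.cascade.after_phenotype,
        result.cascade.after_relative,
        result.cascade.after_relative_and_absolute,
        result.combination.set_a.derive(
            "approach1_focal", result.combination.set_a.members, "rename"
        ),
        result.combination.set_b.derive(
            "approach2_focal", result.combination.set_b.members, "rename"
        ),
        result.combination.union,
        result.combination.overlap,
    ]
    write_gene_set_report(gene_sets, out / "gene_sets")
    enr_dir = out / "enrichment"
    enr_dir.mkdir(parents=True, exist_ok=True)
    for name, results in result.enrichment.items():
        _enrichment_frame(results).to_csv(
            enr_dir / f"{name}.tsv", sep="\t", index=False
        )
    if result.de_results is not None:
        de_dir = out / "de"
        de_dir.mkdir(parents=True, exist_ok=True)
        merged = result.de_results.join(
            result.expression_classes[["expressed_both", "level_class"]]
        )
        merged.to_csv(de_dir / "results.tsv", sep="\t", index_label="gene_id")
    if result.ddct is not None:
        result.ddct.to_csv(out / "ddct_quantities.tsv", sep="\t",
                           index_label="sample")
    write_summary(result.summary, out / "summary.tsv")
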