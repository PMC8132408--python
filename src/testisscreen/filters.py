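"""The two candidate-gene approaches as composable filter cascades.

Approach 1 starts from a source-species screen for testis-biased genes,
expands it into an intermediate species through orthology, and applies
three per-gene filters to the resulting ortholog set:

* **filter 1** — mutant-phenotype filter: keep genes whose mutants are
  sterile.  Reported as a PARALLEL branch of the cascade (the sterile
  subset is not nested inside the expression subsets).
* **filter 2** — relative testicular expression: keep genes classified
  exclusive or predominant in the focal tissue.
* **filter 3** — absolute testicular expression: of the filter-2 genes,
  keep those at or above a minimum absolute level (default moderately
  high).

Each retained subset is then expanded into the k target species, with a
presence-pattern summary (orthologs in all / none / some species).

Approach 2 starts from a curated reproductive gene list in the
intermediate species and goes straight to the target-species expansion.
The two approaches are finally combined on target-species gene IDs by
union, with the overlap reported via inclusion–exclusion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .expression import (
    AbsoluteLevel,
    ClassificationRule,
    RelativeCategory,
    classify_table,
    screen_source_species,
)
from .gene_sets import GeneSet
from .orthology import (
    PresenceSummary,
    map_forward,
    presence_matrix,
    sources_with_ortholog,
    summarize_presence,
)
from .tables import ExpressionTable, OrthologTable, PhenotypeTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# the three per-gene filters
# ---------------------------------------------------------------------------


def filter_by_phenotype(
    genes: GeneSet,
    phenotypes: PhenotypeTable,
    keep: frozenset[str] | set[str] = frozenset({"sterile"}),
) -> GeneSet:
    """Keep genes whose mutant fertility outcome is in ``keep``.

    Genes absent from the table or annotated ``unknown`` are excluded; the
    number of such data-censored genes is logged and recorded in
    provenance, since missing phenotype data is a major censoring source.
    """
    keep = frozenset(keep)
    kept = frozenset(
        g for g in genes.members if phenotypes.outcome(g) in keep
    )
    n_unknown = sum(
        1 for g in genes.members if phenotypes.outcome(g) == "unknown"
    )
    logger.info(
        "filter_by_phenotype: %d -> %d (%d without phenotype data)",
        len(genes), len(kept), n_unknown,
    )
    return genes.derive(
        f"{genes.label}_phenotype",
        kept,
        operation="filter_by_phenotype",
        params={"keep": ",".join(sorted(keep)), "n_unknown": n_unknown},
    )


def filter_by_relative(
    genes: GeneSet,
    table: ExpressionTable,
    rule: ClassificationRule,
    keep: Iterable[RelativeCategory] = (
        RelativeCategory.EXCLUSIVE,
        RelativeCategory.PREDOMINANT,
    ),
) -> GeneSet:
    """Keep genes whose relative expression category is in ``keep``.

    Genes missing from the expression table are excluded and logged (not
    fatal).  Per-category tallies of the retained genes are recorded in
    provenance.
    """
    keep_values = {RelativeCategory(c).value for c in keep}
    present = [g for g in genes.members if g in table.values.index]
    n_missing = len(genes) - len(present)
    if n_missing:
        logger.info(
            "filter_by_relative: %d gene(s) missing from expression table",
            n_missing,
        )
    cats = classify_table(
        ExpressionTable(
            species=table.species,
            values=table.values.loc[present],
            dialect=table.dialect,
        ),
        rule,
    )
    kept = frozenset(cats[cats.isin(keep_values)].index)
    tallies = {
        f"n_{c}": int((cats == c).sum())
        for c in sorted(keep_values)
    }
    return genes.derive(
        f"{genes.label}_relative",
        kept,
        operation="filter_by_relative",
        params={"keep": ",".join(sorted(keep_values)),
                "n_missing": n_missing, **tallies},
    )


def filter_by_absolute(
    genes: GeneSet,
    table: ExpressionTable,
    min_level: AbsoluteLevel = AbsoluteLevel.MODERATELY_HIGH,
    focal_tissue: str = "testis",
) -> GeneSet:
    """Keep genes whose focal-tissue absolute level is >= ``min_level``.

    For ordinal tables the level is the stored code; numeric tables are
    not supported here (absolute levels are a property of the ordinal
    dialect).  Genes missing from the table are excluded and logged.
    """
    if table.dialect != "ordinal":
        raise ValueError("absolute-level filter requires an ordinal table")
    if focal_tissue not in table.values.columns:
        raise ValueError(f"focal tissue {focal_tissue!r} missing from table")
    present = [g for g in genes.members if g in table.values.index]
    n_missing = len(genes) - len(present)
    if n_missing:
        logger.info(
            "filter_by_absolute: %d gene(s) missing from expression table",
            n_missing,
        )
    levels = table.values.loc[present, focal_tissue]
    kept = frozenset(levels[levels >= int(min_level)].index)
    return genes.derive(
        f"{genes.label}_absolute",
        kept,
        operation="filter_by_absolute",
        params={"min_level": min_level.name.lower(), "n_missing": n_missing},
    )


# ---------------------------------------------------------------------------
# cascade results
# ---------------------------------------------------------------------------


@dataclass
class CascadeResult:
    """All boxed gene lists of the approach-1 cascade."""

    source_screened: GeneSet          # source-species testis-biased genes
    sources_mapped: GeneSet           # those with >=1 intermediate ortholog
    initial: GeneSet                  # distinct intermediate orthologs
    after_phenotype: GeneSet          # filter 1 (parallel branch)
    after_relative: GeneSet           # filter 2
    after_relative_and_absolute: GeneSet  # filters 2 + 3
    per_species_orthologs: dict[str, GeneSet]  # of the 2+3 subset
    presence_initial: PresenceSummary  # presence of the initial orthologs
    presence_final: PresenceSummary    # presence of the 2+3 subset

    def __post_init__(self) -> None:
        if not self.after_relative_and_absolute.members <= self.after_relative.members:
            raise ValueError("filter-3 subset must nest inside filter-2 subset")
        if not self.after_relative.members <= self.initial.members:
            raise ValueError("filter-2 subset must nest inside the initial set")
        if not self.after_phenotype.members <= self.initial.members:
            raise ValueError("filter-1 subset must nest inside the initial set")

    def summary(self) -> dict[str, int]:
        out = {
            "n_source_screened": len(self.source_screened),
            "n_sources_with_ortholog": len(self.sources_mapped),
            "n_initial": len(self.initial),
            "n_filter1": len(self.after_phenotype),
            "n_filter2": len(self.after_relative),
            "n_filter23": len(self.after_relative_and_absolute),
            "presence_initial_in_all": self.presence_initial.in_all,
            "presence_initial_in_none": self.presence_initial.in_none,
            "presence_initial_in_some": self.presence_initial.in_some,
            "presence_final_in_all": self.presence_final.in_all,
            "presence_final_in_none": self.presence_final.in_none,
            "presence_final_in_some": self.presence_final.in_some,
        }
        for sp, gs in sorted(self.per_species_orthologs.items()):
            out[f"n_orthologs_{sp}"] = len(gs)
        return out


@dataclass
class Approach2Result:
    """Target-species expansion of the curated reproductive list."""

    curated: GeneSet
    per_species_orthologs: dict[str, GeneSet]
    presence: PresenceSummary

    def summary(self) -> dict[str, int]:
        out = {
            "n_curated": len(self.curated),
            "presence_in_all": self.presence.in_all,
            "presence_in_none": self.presence.in_none,
            "presence_in_some": self.presence.in_some,
        }
        for sp, gs in sorted(self.per_species_orthologs.items()):
            out[f"n_orthologs_{sp}"] = len(gs)
        return out


@dataclass
class CombinationResult:
    """Union/overlap of the two approaches on target-species gene IDs."""

    set_a: GeneSet
    set_b: GeneSet
    overlap: GeneSet = field(init=False)
    union: GeneSet = field(init=False)

    def __post_init__(self) -> None:
        if self.set_a.species != self.set_b.species:
            raise ValueError(
                "cannot combine gene sets from different species: "
                f"{self.set_a.species!r} vs {self.set_b.species!r}"
            )
        inter = self.set_a.members & self.set_b.members
        uni = self.set_a.members | self.set_b.members
        self.overlap = self.set_a.derive(
            "overlap", inter, "intersect", {"other": self.set_b.label}
        )
        self.union = self.set_a.derive(
            "combined", uni, "union", {"other": self.set_b.label}
        )
        assert len(self.union) == len(self.set_a) + len(self.set_b) - len(
            self.overlap
        )

    def summary(self) -> dict[str, int]:
        return {
            "n_set_a": len(self.set_a),
            "n_set_b": len(self.set_b),
            "n_overlap": len(self.overlap),
            "n_union": len(self.union),
        }


# ---------------------------------------------------------------------------
# the two approaches
# ---------------------------------------------------------------------------


def run_approach1(
    source_expression: ExpressionTable,
    source_to_intermediate: OrthologTable,
    intermediate_expression: ExpressionTable,
    phenotypes: PhenotypeTable,
    target_tables: Mapping[str, OrthologTable],
    rule: ClassificationRule | None = None,
    min_level: AbsoluteLevel = AbsoluteLevel.MODERATELY_HIGH,
    source_rule: ClassificationRule | None = None,
    source_genes: GeneSet | None = None,
) -> CascadeResult:
    """Run the full expression-conservation cascade (approach 1).

    Screens the source species for focal-tissue-biased genes (or accepts a
    pre-screened ``source_genes`` list), expands them into the intermediate
    species, applies the three filters, and expands each retained subset
    into every target species.
    """
    rule = rule or ClassificationRule()
    source_rule = source_rule or ClassificationRule(
        focal_tissue=rule.focal_tissue, tolerated_tissues=frozenset()
    )
    if source_genes is None:
        source_genes = screen_source_species(source_expression, source_rule)
    sources_mapped = sources_with_ortholog(source_genes, source_to_intermediate)
    initial = map_forward(source_genes, source_to_intermediate)
    initial = GeneSet(
        label="orthologs_initial",
        members=initial.members,
        species=initial.species,
        provenance=initial.provenance,
    )
    f1 = filter_by_phenotype(initial, phenotypes)
    f2 = filter_by_relative(initial, intermediate_expression, rule)
    f23 = filter_by_absolute(
        f2, intermediate_expression, min_level, rule.focal_tissue
    )
    per_species = {
        sp: map_forward(f23, tab) for sp, tab in target_tables.items()
    }
    presence_initial = summarize_presence(
        presence_matrix(initial, target_tables)
    )
    presence_final = summarize_presence(presence_matrix(f23, target_tables))
    return CascadeResult(
        source_screened=source_genes,
        sources_mapped=sources_mapped,
        initial=initial,
        after_phenotype=f1,
        after_relative=f2,
        after_relative_and_absolute=f23,
        per_species_orthologs=per_species,
        presence_initial=presence_initial,
        presence_final=presence_final,
    )


def run_approach2(
    curated: GeneSet,
    target_tables: Mapping[str, OrthologTable],
) -> Approach2Result:
    """Expand a curated reproductive gene list into the target species."""
    per_species = {
        sp: map_forward(curated, tab) for sp, tab in target_tables.items()
    }
    presence = summarize_presence(presence_matrix(curated, target_tables))
    return Approach2Result(
        curated=curated,
        per_species_orthologs=per_species,
        presence=presence,
    )


def combine_approaches(set_a: GeneSet, set_b: GeneSet) -> CombinationResult:
    """Combine the two approaches' target-species candidate sets."""
    return CombinationResult(set_a=set_a, set_b=set_b)
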