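"""Set algebra over many-to-many ortholog tables.

Forward mapping expands a gene set through its (co-)ortholog pairs into the
target species; presence matrices summarise, per gene, in which of the k
target species at least one ortholog exists.  All counts are over DISTINCT
gene identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .gene_sets import GeneSet
from .tables import OrthologTable


@dataclass
class PresencePattern:
    """Boolean genes × species matrix: ortholog present or not."""

    matrix: pd.DataFrame  # bool, genes x species (column order fixed)

    @property
    def species(self) -> list[str]:
        return list(self.matrix.columns)


@dataclass(frozen=True)
class PresenceSummary:
    in_all: int
    in_none: int
    in_some: int
    per_species: dict[str, int]

    @property
    def total(self) -> int:
        return self.in_all + self.in_none + self.in_some


def _check_species(genes: GeneSet, table: OrthologTable) -> None:
    if genes.species != table.source_species:
        raise ValueError(
            f"species mismatch: gene set is {genes.species!r} but table maps "
            f"from {table.source_species!r}"
        )


def map_forward(genes: GeneSet, table: OrthologTable) -> GeneSet:
    """Map a gene set through an ortholog table into the target species.

    Returns the set of distinct target gene IDs paired with any member
    (co-ortholog expansion: one source gene may contribute several targets).
    """
    _check_species(genes, table)
    targets = table.targets_of(genes.members)
    return genes.derive(
        f"{genes.label}_in_{table.target_species}",
        targets,
        operation="map_forward",
        params={
            "source_species": table.source_species,
            "target_species": table.target_species,
        },
        species=table.target_species,
    )


def sources_with_ortholog(genes: GeneSet, table: OrthologTable) -> GeneSet:
    """Subset of the gene set having at least one ortholog in the table."""
    _check_species(genes, table)
    mapped_sources = table.sources()
    kept = frozenset(g for g in genes.members if g in mapped_sources)
    return genes.derive(
        f"{genes.label}_with_{table.target_species}_ortholog",
        kept,
        operation="sources_with_ortholog",
        params={"target_species": table.target_species},
    )


def presence_matrix(
    genes: GeneSet, tables: Iterable[OrthologTable] | Mapping[str, OrthologTable]
) -> PresencePattern:
    """Per-gene boolean presence over the target species of the tables."""
    if isinstance(tables, Mapping):
        table_list = list(tables.values())
    else:
        table_list = list(tables)
    species = [t.target_species for t in table_list]
    if len(set(species)) != len(species):
        raise ValueError(f"duplicated target species in {species}")
    for t in table_list:
        _check_species(genes, t)
    order = sorted(genes.members)
    sources = {t.target_species: t.sources() for t in table_list}
    data = {
        sp: [g in src for g in order] for sp, src in sources.items()
    }
    matrix = pd.DataFrame(data, index=order, columns=species, dtype=bool)
    return PresencePattern(matrix=matrix)


def summarize_presence(pattern: PresencePattern) -> PresenceSummary:
    """Count genes with orthologs in all / none / some target species."""
    m = pattern.matrix
    if m.empty:
        return PresenceSummary(0, 0, 0, {s: 0 for s in pattern.species})
    row_sum = m.sum(axis=1)
    k = m.shape[1]
    in_all = int((row_sum == k).sum())
    in_none = int((row_sum == 0).sum())
    return PresenceSummary(
        in_all=in_all,
        in_none=in_none,
        in_some=int(m.shape[0] - in_all - in_none),
        per_species={s: int(m[s].sum()) for s in pattern.species},
    )
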