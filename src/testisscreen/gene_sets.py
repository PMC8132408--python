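"""Labeled gene-ID sets with an append-only provenance trail.

Every boxed gene list in the screen (the source-species screen, the ortholog
expansions, the filter-cascade subsets) is a :class:`GeneSet`.  Provenance
records which operation produced the set, with what parameters, and from how
many input genes, so a summary report can reconstruct the whole cascade.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Iterator, Mapping


@dataclass(frozen=True)
class ProvenanceStep:
    """One applied operation: name, parameters, and the input size it saw."""

    operation: str
    params: Mapping[str, Any]
    input_size: int

    def as_text(self) -> str:
        items = ";".join(f"{k}={v}" for k, v in sorted(self.params.items()))
        return f"{self.operation}({items})<-{self.input_size}"


@dataclass(frozen=True)
class GeneSet:
    """An immutable set of gene identifiers from one species.

    Parameters
    ----------
    label
        Human-readable name, e.g. ``"testis_screen"``.
    members
        Gene identifiers (opaque, case-sensitive strings).
    species
        Species label; set algebra across species is refused by the callers
        that care (ortholog mapping, set combination).
    provenance
        Append-only trail of the operations that produced this set.
    """

    label: str
    members: frozenset[str]
    species: str
    provenance: tuple[ProvenanceStep, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if any(not g for g in self.members):
            raise ValueError("gene set contains an empty gene identifier")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.members))

    def derive(
        self,
        label: str,
        members: frozenset[str] | set[str],
        operation: str,
        params: Mapping[str, Any] | None = None,
        species: str | None = None,
    ) -> "GeneSet":
        """Create a child set, extending the provenance trail."""
        step = ProvenanceStep(operation, dict(params or {}), len(self.members))
        return replace(
            self,
            label=label,
            members=frozenset(members),
            species=species if species is not None else self.species,
            provenance=self.provenance + (step,),
        )


def gene_set(members, species: str, label: str = "gene_set") -> GeneSet:
    """Convenience constructor from any iterable of gene IDs."""
    return GeneSet(label=label, members=frozenset(members), species=species)
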