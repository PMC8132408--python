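"""Typed readers and writers for every table dialect the screen consumes.

Canonical on-disk dialect: UTF-8, tab-separated, one header row, first
column = gene identifier.  Gene identifiers are opaque case-sensitive
strings (the screen mixes FBgn-, NV- and Mm-style IDs); no normalization is
attempted.  An Excel ingester is provided solely to convert spreadsheet
supplements into TSV before parsing.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .expression import AbsoluteLevel, level_name, parse_level
from .gene_sets import GeneSet

logger = logging.getLogger(__name__)

PHENOTYPE_OUTCOMES = ("sterile", "fertile", "unknown")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionTable:
    """Gene × tissue expression values for one species.

    ``values`` is a DataFrame indexed by gene ID with one column per tissue;
    numeric dialect holds non-negative floats (counts/TPM), ordinal dialect
    holds integer level codes on the eight-point absolute scale.
    """

    species: str
    values: pd.DataFrame
    dialect: str  # "numeric" | "ordinal"

    def __post_init__(self) -> None:
        if self.dialect not in ("numeric", "ordinal"):
            raise ValueError(f"unknown dialect {self.dialect!r}")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene identifier: {dup!r}")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate tissue labels")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative expression value")

    @property
    def tissues(self) -> list[str]:
        return list(self.values.columns)

    def profile(self, gene: str) -> dict[str, AbsoluteLevel] | dict[str, float]:
        row = self.values.loc[gene]
        if self.dialect == "ordinal":
            return {t: AbsoluteLevel(int(v)) for t, v in row.items()}
        return {t: float(v) for t, v in row.items()}


@dataclass
class OrthologTable:
    """Many-to-many ortholog pairs between two species.

    Co-orthologs are kept as plain pairs — every listed orthology
    relationship counts.  Source genes listed with an empty target field are
    retained in ``no_ortholog`` so "no ortholog found" is distinguishable
    from "never queried".
    """

    source_species: str
    target_species: str
    pairs: frozenset[tuple[str, str]]
    no_ortholog: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for s, t in self.pairs:
            if not s or not t:
                raise ValueError("empty gene identifier in ortholog pair")

    def targets_of(self, genes: Iterable[str]) -> frozenset[str]:
        wanted = set(genes)
        return frozenset(t for s, t in self.pairs if s in wanted)

    def sources(self) -> frozenset[str]:
        return frozenset(s for s, _ in self.pairs)


@dataclass
class PhenotypeTable:
    """Gene → mutant fertility outcome (sterile / fertile / unknown)."""

    outcomes: dict[str, str]

    def __post_init__(self) -> None:
        bad = {v for v in self.outcomes.values()} - set(PHENOTYPE_OUTCOMES)
        if bad:
            raise ValueError(
                f"unknown phenotype outcome(s) {sorted(bad)}; "
                f"accepted: {PHENOTYPE_OUTCOMES}"
            )

    def outcome(self, gene: str) -> str:
        return self.outcomes.get(gene, "unknown")


@dataclass(frozen=True)
class GoTerm:
    term_id: str
    name: str
    reproduction_related: bool
    genes: frozenset[str]


@dataclass
class GoAnnotationSet:
    """Flat gene→GO annotations over a whole-genome universe."""

    terms: dict[str, GoTerm]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for term in self.terms.values():
            stray = term.genes - self.universe
            if stray:
                raise ValueError(
                    f"term {term.term_id} annotates genes outside the "
                    f"universe, e.g. {sorted(stray)[:3]}"
                )


@dataclass
class CountMatrix:
    """Genes × samples integer read counts with a two-stage design."""

    counts: pd.DataFrame  # int, genes × samples
    conditions: dict[str, str]  # sample -> "stage1" | "stage2"

    def __post_init__(self) -> None:
        missing = set(self.counts.columns) - set(self.conditions)
        if missing:
            raise ValueError(
                f"sample(s) missing from condition map: {sorted(missing)}"
            )
        bad = set(self.conditions.values()) - {"stage1", "stage2"}
        if bad:
            raise ValueError(f"unknown condition label(s): {sorted(bad)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative count")
        for cond in ("stage1", "stage2"):
            if len(self.samples(cond)) < 2:
                raise ValueError(f"fewer than 2 samples for {cond}")

    def samples(self, condition: str) -> list[str]:
        return [
            s for s in self.counts.columns if self.conditions[s] == condition
        ]


@dataclass
class CtTable:
    """qPCR Ct values per (sample, gene) with reference genes and calibrator."""

    ct: pd.DataFrame  # samples × genes, float (NaN = not measured)
    reference_genes: tuple[str, ...]
    calibrator_sample: str

    def __post_init__(self) -> None:
        for ref in self.reference_genes:
            if ref not in self.ct.columns:
                raise ValueError(f"reference gene {ref!r} missing from table")
            if self.ct[ref].isna().any():
                sample = self.ct.index[self.ct[ref].isna()][0]
                raise ValueError(
                    f"missing reference Ct for {ref!r} in sample {sample!r}"
                )
        if self.calibrator_sample not in self.ct.index:
            raise ValueError(
                f"calibrator sample {self.calibrator_sample!r} missing"
            )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def read_expression_table(path, dialect: str, species: str = "") -> ExpressionTable:
    """Read a gene × tissue TSV in either the numeric or ordinal dialect.

    Ordinal cells hold level strings ("moderately high", ...); numeric
    cells hold non-negative numbers.  Duplicate gene rows and unknown level
    strings are hard errors.
    """
    raw = _read_tsv(path)
    if raw.shape[1] < 2:
        raise ValueError(f"{path}: expected a gene column plus >=1 tissue")
    gene_col = raw.columns[0]
    dup = raw[gene_col][raw[gene_col].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate gene identifier: {dup.iloc[0]!r}")
    raw = raw.set_index(gene_col)
    raw.index.name = None
    if dialect == "ordinal":
        values = raw.map(lambda s: int(parse_level(s)))
    elif dialect == "numeric":
        try:
            values = raw.astype(float)
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric expression value ({exc})")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return ExpressionTable(species=species, values=values, dialect=dialect)


def read_ortholog_table(
    path,
    source_species: str,
    target_species: str,
    separator: str = ";",
) -> OrthologTable:
    """Read a source→target ortholog TSV.

    Each row is ``source<TAB>targets`` where ``targets`` may list several
    co-orthologs joined by ``separator`` (BioMart export style) or be empty
    (no ortholog found — the source gene is kept in the no-ortholog
    register).  Extra columns beyond the second are treated as further
    target fields.
    """
    pairs: set[tuple[str, str]] = set()
    no_orth: set[str] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            raise ValueError(f"{path}: empty file")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 1 or not row[0].strip():
                raise ValueError(f"{path}:{lineno}: missing source gene ID")
            source = row[0].strip()
            targets = [
                t.strip()
                for cell in row[1:]
                for t in cell.split(separator)
                if t.strip()
            ]
            if targets:
                pairs.update((source, t) for t in targets)
            else:
                no_orth.add(source)
    no_orth -= {s for s, _ in pairs}
    return OrthologTable(
        source_species=source_species,
        target_species=target_species,
        pairs=frozenset(pairs),
        no_ortholog=frozenset(no_orth),
    )


def read_phenotype_table(path) -> PhenotypeTable:
    raw = _read_tsv(path)
    gene_col, out_col = raw.columns[0], raw.columns[1]
    dup = raw[gene_col][raw[gene_col].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: gene listed twice: {dup.iloc[0]!r}")
    outcomes = {
        g: o.strip().lower() for g, o in zip(raw[gene_col], raw[out_col])
    }
    return PhenotypeTable(outcomes=outcomes)


def read_go_annotations(path) -> GoAnnotationSet:
    """Read flat annotations: term_id, term_name, reproduction flag, gene_id.

    One row per (term, gene) pair.  Rows whose term_id is the literal
    ``universe`` enumerate unannotated universe members.
    """
    raw = _read_tsv(path)
    need = {"term_id", "term_name", "reproduction_related", "gene_id"}
    if not need.issubset(raw.columns):
        raise ValueError(f"{path}: expected columns {sorted(need)}")
    universe: set[str] = set(raw["gene_id"])
    terms: dict[str, GoTerm] = {}
    for term_id, grp in raw[raw["term_id"] != "universe"].groupby("term_id"):
        flag = str(grp["reproduction_related"].iloc[0]).strip().lower()
        terms[str(term_id)] = GoTerm(
            term_id=str(term_id),
            name=str(grp["term_name"].iloc[0]),
            reproduction_related=flag in ("1", "true", "yes"),
            genes=frozenset(grp["gene_id"]),
        )
    return GoAnnotationSet(terms=terms, universe=frozenset(universe))


def read_count_matrix(path, condition_map: Mapping[str, str]) -> CountMatrix:
    """Read a genes × samples count TSV; counts must be non-negative integers."""
    raw = _read_tsv(path)
    raw = raw.set_index(raw.columns[0])
    raw.index.name = None
    missing = set(raw.columns) - set(condition_map)
    if missing:
        raise ValueError(
            f"{path}: sample(s) absent from condition map: {sorted(missing)}"
        )
    values = raw.apply(pd.to_numeric, errors="raise")
    arr = values.to_numpy()
    if not np.allclose(arr, np.round(arr)):
        raise ValueError(f"{path}: non-integer count value")
    if (arr < 0).any():
        raise ValueError(f"{path}: negative count value")
    return CountMatrix(
        counts=values.astype(np.int64),
        conditions={s: condition_map[s] for s in values.columns},
    )


def read_gene_list(path, species: str, label: str) -> GeneSet:
    """Read a one-column (or first-column) gene list TSV into a GeneSet."""
    raw = _read_tsv(path)
    return GeneSet(
        label=label,
        members=frozenset(g for g in raw[raw.columns[0]] if g),
        species=species,
    )


def read_ct_table(
    path, reference_genes: Iterable[str], calibrator_sample: str
) -> CtTable:
    """Read a long-format Ct TSV with columns sample, gene, ct."""
    raw = pd.read_csv(path, sep="\t")
    need = {"sample", "gene", "ct"}
    if not need.issubset(raw.columns):
        raise ValueError(f"{path}: expected columns {sorted(need)}")
    wide = raw.pivot(index="sample", columns="gene", values="ct")
    return CtTable(
        ct=wide,
        reference_genes=tuple(reference_genes),
        calibrator_sample=calibrator_sample,
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_expression_table(table: ExpressionTable, path) -> None:
    df = table.values
    if table.dialect == "ordinal":
        out = df.map(lambda v: level_name(AbsoluteLevel(int(v))))
    else:
        out = df
    out.to_csv(path, sep="\t", index_label="gene_id")


def write_ortholog_table(
    table: OrthologTable, path, separator: str = ";"
) -> None:
    by_source: dict[str, list[str]] = {}
    for s, t in sorted(table.pairs):
        by_source.setdefault(s, []).append(t)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("source_gene\ttarget_genes\n")
        for s in sorted(set(by_source) | set(table.no_ortholog)):
            fh.write(f"{s}\t{separator.join(by_source.get(s, []))}\n")


def write_gene_set_report(gene_sets: Iterable[GeneSet], directory) -> list[Path]:
    """Write one TSV per gene set: gene ID plus the provenance trail."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for gs in gene_sets:
        trail = "|".join(step.as_text() for step in gs.provenance)
        path = directory / f"{gs.label}.tsv"
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("gene_id\tspecies\tprovenance\n")
            for g in sorted(gs.members):
                fh.write(f"{g}\t{gs.species}\t{trail}\n")
        written.append(path)
    return written


def write_summary(counts: Mapping[str, int], path) -> None:
    """Write the key→integer summary (the boxed counts of the screen)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("key\tvalue\n")
        for key, value in counts.items():
            fh.write(f"{key}\t{int(value)}\n")


def read_summary(path) -> dict[str, int]:
    raw = _read_tsv(path)
    return {k: int(v) for k, v in zip(raw["key"], raw["value"])}


# ---------------------------------------------------------------------------
# Excel ingestion (spreadsheet supplements -> TSV)
# ---------------------------------------------------------------------------


def detect_multivalue_separator(
    cells: Iterable[str], candidates: tuple[str, ...] = (";", ",", "|", "/")
) -> str:
    """Autodetect the separator used for multi-ortholog cells.

    Picks the candidate occurring in the largest number of cells; defaults
    to ";" when no candidate occurs at all.
    """
    scores = {c: 0 for c in candidates}
    for cell in cells:
        for c in candidates:
            if c in str(cell):
                scores[c] += 1
    best = max(scores, key=lambda c: scores[c])
    return best if scores[best] > 0 else ";"


def excel_to_tsv(xlsx_path, out_path, sheet=0) -> Path:
    """Convert one sheet of a spreadsheet supplement to canonical TSV."""
    df = pd.read_excel(xlsx_path, sheet_name=sheet, dtype=str).fillna("")
    out_path = Path(out_path)
    df.to_csv(out_path, sep="\t", index=False)
    return out_path
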