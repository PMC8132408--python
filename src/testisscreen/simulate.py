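"""Synthetic input bundles with a ground-truth manifest.

The generator emulates the statistical structure of the comparative
screen's inputs: a numeric (EST-style) gene × tissue table for a source
species with planted testis-exclusive and testis-predominant genes; an
ordinal tissue-expression table, mutant-phenotype annotations and GO
annotations for an intermediate species; many-to-many ortholog tables from
source to intermediate and from intermediate to each of k target species
(independent Bernoulli retention per species, geometric co-ortholog
expansion); a curated reproductive gene list; a negative-binomial two-stage
count matrix with planted fold changes for the focal target species; and a
qPCR Ct table with planted relative quantities.

Profiles are planted so that, at the default zero noise, the classifiers
recover the planted classes *exactly*; the manifest records every planted
set together with the cascade counts implied by the draws, so every
pipeline stage can be checked against ground truth without any external
download.

One pseudo-random stream per artifact, each seeded from the master seed by
a fixed offset, so adding one generator does not perturb the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .gene_sets import GeneSet
from .tables import (
    CountMatrix,
    CtTable,
    ExpressionTable,
    GoAnnotationSet,
    GoTerm,
    OrthologTable,
    PhenotypeTable,
    write_expression_table,
    write_ortholog_table,
)

_STREAMS = {
    "source_expression": 0,
    "source_orthology": 1,
    "intermediate_expression": 2,
    "phenotypes": 3,
    "target_orthology": 4,
    "curated": 5,
    "go": 6,
    "counts": 7,
    "ct": 8,
}

MODERATELY_HIGH = 4  # ordinal code of the absolute-level cutoff


@dataclass
class BundleConfig:
    """Scale and rates of the synthetic bundle (defaults = study scale)."""

    source_species: str = "mouse"
    intermediate_species: str = "fly"
    n_source_genes: int = 20000
    n_testis_exclusive: int = 273
    n_testis_predominant: int = 273
    source_tissues: tuple[str, ...] = (
        "testis", "brain", "liver", "kidney", "heart",
        "lung", "spleen", "muscle", "ovary", "intestine",
    )
    intermediate_tissues: tuple[str, ...] = (
        "testis", "accessory_gland", "imaginal_disc", "head", "gut",
        "ovary", "salivary_gland", "fat_body", "carcass", "digestive_system",
    )
    ortholog_p: float = 0.36          # source gene has >=1 intermediate ortholog
    coortholog_p: float = 0.57        # chance of each extra co-ortholog
    n_background_intermediate: int = 3000
    target_species: tuple[str, ...] = (
        "nasonia", "apis_mellifera", "bombus_terrestris",
        "bombus_impatiens", "atta_cephalotes", "solenopsis_invicta",
    )
    focal_target: str = "nasonia"
    retention_p: float = 0.5          # per-species ortholog retention
    target_coortholog_p: float = 0.1
    # intermediate relative-category proportions (rest = ubiquitous)
    p_exclusive: float = 0.09
    p_predominant: float = 0.15
    p_not_expressed: float = 0.25
    # mutant-phenotype proportions (rest = unknown)
    p_sterile: float = 0.055
    p_fertile: float = 0.31
    n_curated: int = 379
    curated_overlap_frac: float = 0.05
    # GO annotations
    n_go_terms: int = 100
    go_term_size: tuple[int, int] = (5, 150)
    reproduction_term_frac: float = 0.15
    # two-stage count matrix (focal target species)
    n_replicates: int = 3
    count_dispersion: float = 0.05
    n_de: int = 60
    de_log2fc: float = 2.0
    de_mean: float = 500.0
    p_count_silent: float = 0.35
    n_background_focal: int = 2000

    def validate(self) -> None:
        if self.p_exclusive + self.p_predominant + self.p_not_expressed > 1:
            raise ValueError("relative-category proportions exceed 1")
        if self.p_sterile + self.p_fertile > 1:
            raise ValueError("phenotype proportions exceed 1")
        for p in (self.ortholog_p, self.coortholog_p, self.retention_p,
                  self.target_coortholog_p, self.curated_overlap_frac,
                  self.p_count_silent):
            if not 0 <= p <= 1:
                raise ValueError(f"probability out of [0, 1]: {p}")
        if self.n_testis_exclusive + self.n_testis_predominant > self.n_source_genes:
            raise ValueError("planted testis genes exceed the source genome")
        if self.focal_target not in self.target_species:
            raise ValueError("focal target must be one of the target species")
        if "testis" not in self.source_tissues or "testis" not in self.intermediate_tissues:
            raise ValueError("both tissue panels must include 'testis'")


@dataclass
class TruthManifest:
    """Everything planted, plus the cascade counts the draws imply."""

    seed: int
    stream_seeds: dict[str, list[int]]
    planted_testis_specific: list[str]     # source species, exclusive+predominant
    planted_sterile: list[str]             # intermediate species
    retention_p: float
    coortholog_p: float
    planted_enriched_terms: list[str]
    planted_de: dict[str, float]           # focal-species gene -> true log2fc
    library_factors: dict[str, float]
    expected_counts: dict[str, int]
    expected_sets: dict[str, list[str]]
    ct_true_quantity: dict[str, dict[str, float]]

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


@dataclass
class Bundle:
    """In-memory synthetic bundle: every table the pipeline consumes."""

    config: BundleConfig
    source_expression: ExpressionTable
    source_to_intermediate: OrthologTable
    intermediate_expression: ExpressionTable
    phenotypes: PhenotypeTable
    target_tables: dict[str, OrthologTable]
    curated: GeneSet
    annotations: GoAnnotationSet
    counts: CountMatrix
    ct_table: CtTable
    manifest: TruthManifest

    def write(self, directory) -> Path:
        """Write every table plus the manifest; byte-identical per seed."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_expression_table(
            self.source_expression, directory / "source_expression.tsv"
        )
        write_ortholog_table(
            self.source_to_intermediate,
            directory / "orthologs_source_to_intermediate.tsv",
        )
        write_expression_table(
            self.intermediate_expression,
            directory / "intermediate_expression.tsv",
        )
        with open(directory / "phenotypes.tsv", "w", encoding="utf-8",
                  newline="\n") as fh:
            fh.write("gene_id\toutcome\n")
            for g in sorted(self.phenotypes.outcomes):
                fh.write(f"{g}\t{self.phenotypes.outcomes[g]}\n")
        for sp, tab in self.target_tables.items():
            write_ortholog_table(
                tab, directory / f"orthologs_intermediate_to_{sp}.tsv"
            )
        with open(directory / "curated_list.tsv", "w", encoding="utf-8",
                  newline="\n") as fh:
            fh.write("gene_id\n")
            for g in self.curated:
                fh.write(f"{g}\n")
        with open(directory / "go_annotations.tsv", "w", encoding="utf-8",
                  newline="\n") as fh:
            fh.write("term_id\tterm_name\treproduction_related\tgene_id\n")
            annotated: set[str] = set()
            for tid in sorted(self.annotations.terms):
                term = self.annotations.terms[tid]
                flag = "1" if term.reproduction_related else "0"
                for g in sorted(term.genes):
                    fh.write(f"{tid}\t{term.name}\t{flag}\t{g}\n")
                annotated |= term.genes
            for g in sorted(self.annotations.universe - annotated):
                fh.write(f"universe\tuniverse\t0\t{g}\n")
        self.counts.counts.to_csv(
            directory / "counts.tsv", sep="\t", index_label="gene_id"
        )
        with open(directory / "conditions.tsv", "w", encoding="utf-8",
                  newline="\n") as fh:
            fh.write("sample\tcondition\n")
            for s in self.counts.counts.columns:
                fh.write(f"{s}\t{self.counts.conditions[s]}\n")
        long = self.ct_table.ct.stack().reset_index()
        long.columns = ["sample", "gene", "ct"]
        long.to_csv(directory / "ct_table.tsv", sep="\t", index=False,
                    float_format="%.6f")
        self.manifest.to_json(directory / "manifest.json")
        return directory


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAMS[stream]])


# ---------------------------------------------------------------------------
# artifact generators
# ---------------------------------------------------------------------------


def _gen_source_expression(cfg: BundleConfig, seed: int):
    rng = _rng(seed, "source_expression")
    n = cfg.n_source_genes
    tissues = list(cfg.source_tissues)
    t_idx = tissues.index("testis")
    genes = [f"Mm{i:05d}" for i in range(n)]
    n_e, n_p = cfg.n_testis_exclusive, cfg.n_testis_predominant
    values = np.zeros((n, len(tissues)), dtype=np.int64)
    other_idx = [j for j in range(len(tissues)) if j != t_idx]
    for i in range(n):
        if i < n_e:  # testis-exclusive: silent everywhere else
            values[i, t_idx] = rng.integers(5, 500)
        elif i < n_e + n_p:  # predominant: strictly higher in testis
            t = int(rng.integers(10, 500))
            values[i, t_idx] = t
            k = int(rng.integers(2, len(other_idx) + 1))
            for j in rng.choice(other_idx, size=k, replace=False):
                values[i, j] = rng.integers(1, t)
        else:
            if rng.random() < 0.35:  # silent in testis
                for j in other_idx:
                    values[i, j] = rng.integers(0, 200)
            else:  # ubiquitous: at least two other tissues at/above testis
                t = int(rng.integers(1, 200))
                values[i, t_idx] = t
                hi = rng.choice(other_idx, size=2, replace=False)
                for j in hi:
                    values[i, j] = t + int(rng.integers(0, 100))
                for j in other_idx:
                    if j not in hi:
                        values[i, j] = rng.integers(0, 200)
    table = ExpressionTable(
        species=cfg.source_species,
        values=pd.DataFrame(values, index=genes, columns=tissues),
        dialect="numeric",
    )
    planted = genes[: n_e + n_p]
    return table, planted


def _gen_source_orthology(cfg: BundleConfig, seed: int, source_genes):
    rng = _rng(seed, "source_orthology")
    pairs: set[tuple[str, str]] = set()
    no_orth: set[str] = set()
    counter = 0
    mapping: dict[str, list[str]] = {}
    for g in source_genes:
        if rng.random() < cfg.ortholog_p:
            n_targets = 1
            while rng.random() < cfg.coortholog_p:
                n_targets += 1
            targets = [f"Dm{counter + j:05d}" for j in range(n_targets)]
            counter += n_targets
            mapping[g] = targets
            pairs.update((g, t) for t in targets)
        else:
            no_orth.add(g)
    table = OrthologTable(
        source_species=cfg.source_species,
        target_species=cfg.intermediate_species,
        pairs=frozenset(pairs),
        no_ortholog=frozenset(no_orth),
    )
    return table, mapping, counter


def _gen_intermediate_expression(cfg: BundleConfig, seed: int, genes):
    """Ordinal profiles with planted relative categories and testis levels."""
    rng = _rng(seed, "intermediate_expression")
    tissues = list(cfg.intermediate_tissues)
    t_idx = tissues.index("testis")
    tolerated = {"accessory_gland", "imaginal_disc"}
    tol_idx = [j for j, t in enumerate(tissues) if t in tolerated]
    side_idx = [
        j for j, t in enumerate(tissues)
        if t != "testis" and t not in tolerated
    ]
    n = len(genes)
    values = np.zeros((n, len(tissues)), dtype=np.int64)
    classes: dict[str, str] = {}
    levels: dict[str, int] = {}
    p_e, p_p, p_n = cfg.p_exclusive, cfg.p_predominant, cfg.p_not_expressed
    for i, g in enumerate(genes):
        u = rng.random()
        if u < p_e:
            cls = "exclusive"
            level = int(rng.integers(1, 8))
            values[i, t_idx] = level
            for j in tol_idx:
                values[i, j] = rng.integers(0, 8)
            if rng.random() < 0.5:  # one tolerated extra below moderately high
                j = int(rng.choice(side_idx))
                values[i, j] = rng.integers(1, MODERATELY_HIGH)
        elif u < p_e + p_p:
            cls = "predominant"
            level = int(rng.integers(3, 8))
            values[i, t_idx] = level
            for j in rng.choice(side_idx, size=3, replace=False):
                values[i, j] = rng.integers(1, level)
            for j in tol_idx:
                values[i, j] = rng.integers(0, level)
        elif u < p_e + p_p + p_n:
            cls = "not_expressed"
            level = 0
            for j in side_idx + tol_idx:
                values[i, j] = rng.integers(0, 8)
        else:
            cls = "ubiquitous"
            level = int(rng.integers(1, 7))
            values[i, t_idx] = level
            hi, lo = rng.choice(side_idx, size=2, replace=False)
            values[i, hi] = rng.integers(max(level, MODERATELY_HIGH), 8)
            values[i, lo] = rng.integers(1, 8)
            for j in tol_idx:
                values[i, j] = rng.integers(0, 8)
        classes[g] = cls
        levels[g] = level
    table = ExpressionTable(
        species=cfg.intermediate_species,
        values=pd.DataFrame(values, index=list(genes), columns=tissues),
        dialect="ordinal",
    )
    return table, classes, levels


def _gen_phenotypes(cfg: BundleConfig, seed: int, genes):
    rng = _rng(seed, "phenotypes")
    outcomes = {}
    for g in genes:
        u = rng.random()
        if u < cfg.p_sterile:
            outcomes[g] = "sterile"
        elif u < cfg.p_sterile + cfg.p_fertile:
            outcomes[g] = "fertile"
        else:
            outcomes[g] = "unknown"
    return PhenotypeTable(outcomes=outcomes)


def _gen_target_orthology(cfg: BundleConfig, seed: int, genes):
    rng = _rng(seed, "target_orthology")
    prefixes = {
        sp: "NV" if sp == cfg.focal_target else f"{sp[:2].upper()}x"
        for sp in cfg.target_species
    }
    tables: dict[str, OrthologTable] = {}
    mappings: dict[str, dict[str, list[str]]] = {}
    for sp in cfg.target_species:
        counter = 0
        pairs: set[tuple[str, str]] = set()
        no_orth: set[str] = set()
        mapping: dict[str, list[str]] = {}
        for g in genes:
            if rng.random() < cfg.retention_p:
                n_targets = 1
                while rng.random() < cfg.target_coortholog_p:
                    n_targets += 1
                targets = [
                    f"{prefixes[sp]}{counter + j:05d}" for j in range(n_targets)
                ]
                counter += n_targets
                mapping[g] = targets
                pairs.update((g, t) for t in targets)
            else:
                no_orth.add(g)
        tables[sp] = OrthologTable(
            source_species=cfg.intermediate_species,
            target_species=sp,
            pairs=frozenset(pairs),
            no_ortholog=frozenset(no_orth),
        )
        mappings[sp] = mapping
    return tables, mappings


def _gen_counts_for_bundle(cfg: BundleConfig, seed: int, focal_genes,
                           candidate_genes):
    """Two-stage NB counts for the focal species with planted fold changes."""
    rng = _rng(seed, "counts")
    genes = list(focal_genes)
    n = len(genes)
    silent = rng.random(n) < cfg.p_count_silent
    base = np.where(
        silent, 0.02, np.exp(rng.normal(3.5, 1.2, size=n))
    )
    gene_pos = {g: i for i, g in enumerate(genes)}
    candidates = [g for g in candidate_genes if g in gene_pos]
    expressed_candidates = [
        g for g in candidates if not silent[gene_pos[g]]
    ]
    n_de = min(cfg.n_de, len(expressed_candidates))
    de_genes = [
        str(g) for g in rng.choice(expressed_candidates, size=n_de,
                                   replace=False)
    ] if n_de else []
    signs = rng.choice([-1.0, 1.0], size=len(de_genes))
    planted: dict[str, float] = {}
    lfc = np.zeros(n)
    for g, s in zip(de_genes, signs):
        base[gene_pos[g]] = cfg.de_mean
        lfc[gene_pos[g]] = s * cfg.de_log2fc
        planted[g] = float(s * cfg.de_log2fc)
    reps = cfg.n_replicates
    samples = [f"stage1_r{i+1}" for i in range(reps)] + [
        f"stage2_r{i+1}" for i in range(reps)
    ]
    conditions = {s: ("stage1" if s.startswith("stage1") else "stage2")
                  for s in samples}
    lib = rng.uniform(0.7, 1.3, size=len(samples))
    disp = cfg.count_dispersion
    data = np.zeros((n, len(samples)), dtype=np.int64)
    for j, s in enumerate(samples):
        mu = base * lib[j]
        if conditions[s] == "stage2":
            mu = mu * np.power(2.0, lfc)
        lam = rng.gamma(shape=1.0 / disp, scale=mu * disp)
        data[:, j] = rng.poisson(lam)
    cm = CountMatrix(
        counts=pd.DataFrame(data, index=genes, columns=samples),
        conditions=conditions,
    )
    lib_factors = {s: float(f) for s, f in zip(samples, lib)}
    return cm, planted, lib_factors


def _gen_ct(cfg: BundleConfig, seed: int):
    rng = _rng(seed, "ct")
    samples = ["white", "red_eye", "bicolor", "black"]
    targets = [f"cand{i+1}" for i in range(5)]
    refs = ("rpl6", "rpl7")
    ref_shift = rng.uniform(-1, 1, size=len(samples))
    ct = pd.DataFrame(index=samples, columns=list(refs) + targets,
                      dtype=float)
    ct["rpl6"] = 18.0 + ref_shift
    ct["rpl7"] = 19.0 + ref_shift
    ref_mean = ct[list(refs)].mean(axis=1)
    truth: dict[str, dict[str, float]] = {}
    for g in targets:
        base_dct = float(rng.uniform(2, 8))
        q = {s: (1.0 if s == "white"
                 else float(np.power(2.0, rng.uniform(-2, 2))))
             for s in samples}
        for s in samples:
            ct.loc[s, g] = ref_mean[s] + base_dct - np.log2(q[s])
        truth[g] = q
    table = CtTable(ct=ct, reference_genes=refs, calibrator_sample="white")
    return table, truth


# ---------------------------------------------------------------------------
# the bundle
# ---------------------------------------------------------------------------


def generate_bundle(config: BundleConfig | None = None, seed: int = 0,
                    outdir=None) -> Bundle:
    """Generate a complete, internally consistent input bundle.

    Deterministic given ``seed``; pass ``outdir`` to also write every table
    and the manifest to disk.
    """
    cfg = config or BundleConfig()
    cfg.validate()

    source_expr, planted_source = _gen_source_expression(cfg, seed)
    source_orth, src_map, n_orth_targets = _gen_source_orthology(
        cfg, seed, list(source_expr.values.index)
    )
    intermediate_genes = [f"Dm{i:05d}" for i in range(
        n_orth_targets + cfg.n_background_intermediate)]
    inter_expr, classes, levels = _gen_intermediate_expression(
        cfg, seed, intermediate_genes
    )
    phenotypes = _gen_phenotypes(cfg, seed, intermediate_genes)
    target_tables, target_maps = _gen_target_orthology(
        cfg, seed, intermediate_genes
    )

    # curated reproductive list: a slice overlapping the screen's orthologs
    rng_cur = _rng(seed, "curated")
    initial = sorted(
        {t for g in planted_source for t in src_map.get(g, [])}
    )
    n_overlap = min(int(round(cfg.curated_overlap_frac * cfg.n_curated)),
                    len(initial))
    overlap = list(rng_cur.choice(initial, size=n_overlap, replace=False)) \
        if n_overlap else []
    rest_pool = sorted(set(intermediate_genes) - set(initial))
    n_rest = min(cfg.n_curated - n_overlap, len(rest_pool))
    rest = list(rng_cur.choice(rest_pool, size=n_rest, replace=False))
    curated = GeneSet(
        label="curated_reproductive",
        members=frozenset(overlap + rest),
        species=cfg.intermediate_species,
    )

    # expected cascade (plain set algebra over the draws)
    sources_mapped = [g for g in planted_source if g in src_map]
    f1 = sorted(g for g in initial if phenotypes.outcomes[g] == "sterile")
    f2 = sorted(
        g for g in initial if classes[g] in ("exclusive", "predominant")
    )
    f23 = sorted(g for g in f2 if levels[g] >= MODERATELY_HIGH)

    def _presence_counts(genes_):
        k = len(cfg.target_species)
        in_all = in_none = 0
        per = {sp: 0 for sp in cfg.target_species}
        for g in genes_:
            hits = [sp for sp in cfg.target_species if g in target_maps[sp]]
            if len(hits) == k:
                in_all += 1
            if not hits:
                in_none += 1
            for sp in hits:
                per[sp] += 1
        return in_all, in_none, len(genes_) - in_all - in_none, per

    pi_all, pi_none, pi_some, _ = _presence_counts(initial)
    pf_all, pf_none, pf_some, _ = _presence_counts(f23)
    a2_all, a2_none, a2_some, _ = _presence_counts(sorted(curated.members))

    def _targets(genes_, sp):
        return sorted(
            {t for g in genes_ for t in target_maps[sp].get(g, [])}
        )

    focal = cfg.focal_target
    set_a = _targets(f23, focal)
    set_b = _targets(sorted(curated.members), focal)
    union = sorted(set(set_a) | set(set_b))
    overlap_ab = sorted(set(set_a) & set(set_b))

    # GO annotations: one planted term = exactly the filter-2+3 subset
    rng_go = _rng(seed, "go")
    universe = frozenset(intermediate_genes)
    terms: dict[str, GoTerm] = {}
    planted_term_genes = frozenset(f23) if f23 else frozenset(
        list(curated.members)[:20]
    )
    planted_tid = "GO:PLANTED"
    terms[planted_tid] = GoTerm(
        term_id=planted_tid,
        name="planted reproduction process",
        reproduction_related=True,
        genes=planted_term_genes,
    )
    lo, hi = cfg.go_term_size
    for i in range(cfg.n_go_terms - 1):
        size = int(rng_go.integers(lo, hi + 1))
        members = frozenset(
            rng_go.choice(intermediate_genes, size=size, replace=False)
        )
        tid = f"GO:{i+1:07d}"
        terms[tid] = GoTerm(
            term_id=tid,
            name=f"background process {i+1}",
            reproduction_related=bool(
                rng_go.random() < cfg.reproduction_term_frac
            ),
            genes=members,
        )
    annotations = GoAnnotationSet(terms=terms, universe=universe)

    # focal-species count matrix over its whole gene universe
    focal_universe = sorted(
        {t for targets in target_maps[focal].values() for t in targets}
    ) + [f"NVbg{i:05d}" for i in range(cfg.n_background_focal)]
    counts, planted_de, lib_factors = _gen_counts_for_bundle(
        cfg, seed, focal_universe, union
    )
    ct_table, ct_truth = _gen_ct(cfg, seed)

    expected_counts = {
        "n_source_screened": len(planted_source),
        "n_sources_with_ortholog": len(sources_mapped),
        "n_initial": len(initial),
        "n_filter1": len(f1),
        "n_filter2": len(f2),
        "n_filter23": len(f23),
        "presence_initial_in_all": pi_all,
        "presence_initial_in_none": pi_none,
        "presence_initial_in_some": pi_some,
        "presence_final_in_all": pf_all,
        "presence_final_in_none": pf_none,
        "presence_final_in_some": pf_some,
        "approach2_in_all": a2_all,
        "approach2_in_none": a2_none,
        "approach2_in_some": a2_some,
        "n_curated": len(curated),
        "n_set_a": len(set_a),
        "n_set_b": len(set_b),
        "n_overlap": len(overlap_ab),
        "n_union": len(union),
    }
    for sp in cfg.target_species:
        expected_counts[f"n_orthologs_a1_{sp}"] = len(_targets(f23, sp))
        expected_counts[f"n_orthologs_a2_{sp}"] = len(
            _targets(sorted(curated.members), sp)
        )

    manifest = TruthManifest(
        seed=seed,
        stream_seeds={k: [seed, v] for k, v in _STREAMS.items()},
        planted_testis_specific=list(planted_source),
        planted_sterile=sorted(
            g for g, o in phenotypes.outcomes.items() if o == "sterile"
        ),
        retention_p=cfg.retention_p,
        coortholog_p=cfg.coortholog_p,
        planted_enriched_terms=[planted_tid],
        planted_de=planted_de,
        library_factors=lib_factors,
        expected_counts=expected_counts,
        expected_sets={
            "source_screen": sorted(planted_source),
            "initial": initial,
            "filter1": f1,
            "filter2": f2,
            "filter23": f23,
            "set_a": set_a,
            "set_b": set_b,
            "union": union,
            "overlap": overlap_ab,
        },
        ct_true_quantity=ct_truth,
    )
    bundle = Bundle(
        config=cfg,
        source_expression=source_expr,
        source_to_intermediate=source_orth,
        intermediate_expression=inter_expr,
        phenotypes=phenotypes,
        target_tables=target_tables,
        curated=curated,
        annotations=annotations,
        counts=counts,
        ct_table=ct_table,
        manifest=manifest,
    )
    if outdir is not None:
        bundle.write(outdir)
    return bundle


def generate_counts(
    n_genes: int,
    de_fraction: float,
    log2fc: float,
    dispersion: float,
    reps: int,
    seed: int,
    mean: float = 500.0,
    baseline_log_mean: float = 4.0,
    baseline_log_sd: float = 1.0,
) -> tuple[CountMatrix, dict[str, float]]:
    """Standalone two-stage NB count generator with planted fold changes.

    The first ``round(n_genes * de_fraction)`` genes carry a planted
    log2 fold change of ``±log2fc`` (alternating sign) at baseline mean
    ``mean``; the rest draw lognormal baselines.  Per-sample library-size
    multipliers are drawn uniform on [0.7, 1.3] and recorded in the truth
    dict under ``"__lib__<sample>"`` keys.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    rng = np.random.default_rng([seed, _STREAMS["counts"]])
    genes = [f"g{i:05d}" for i in range(n_genes)]
    n_de = int(round(n_genes * de_fraction))
    base = np.exp(rng.normal(baseline_log_mean, baseline_log_sd, size=n_genes))
    lfc = np.zeros(n_genes)
    truth: dict[str, float] = {}
    for i in range(n_de):
        base[i] = mean
        lfc[i] = log2fc if i % 2 == 0 else -log2fc
        truth[genes[i]] = float(lfc[i])
    samples = [f"stage1_r{i+1}" for i in range(reps)] + [
        f"stage2_r{i+1}" for i in range(reps)
    ]
    conditions = {s: ("stage1" if s.startswith("stage1") else "stage2")
                  for s in samples}
    lib = rng.uniform(0.7, 1.3, size=len(samples))
    data = np.zeros((n_genes, len(samples)), dtype=np.int64)
    for j, s in enumerate(samples):
        mu = base * lib[j]
        if conditions[s] == "stage2":
            mu = mu * np.power(2.0, lfc)
        lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
        data[:, j] = rng.poisson(lam)
    for s, f in zip(samples, lib):
        truth[f"__lib__{s}"] = float(f)
    cm = CountMatrix(
        counts=pd.DataFrame(data, index=genes, columns=samples),
        conditions=conditions,
    )
    return cm, truth
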