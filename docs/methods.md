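# Methods

## The screen

The package implements a two-pronged comparative screen for
testis-function candidate genes across three tiers of species: a source
species with quantitative per-tissue expression (EST/TPM style), an
intermediate species with ordinal per-tissue expression labels,
mutant-phenotype annotations and GO annotations, and k target species
known only through ortholog tables. The screen's unit of bookkeeping is a
`GeneSet` carrying an append-only provenance trail (operation, parameters,
input size), so every reported count can be traced to the operations that
produced it.

Orthology is taken as given: tables list (source gene, target gene) pairs,
many-to-many, and every listed pair counts — co-orthologs are not
distinguished from one-to-one orthologs, and no confidence scores are
modelled. Forward mapping returns distinct target IDs; presence patterns
record, per gene, in which target species at least one ortholog exists.

## Expression classification

Absolute expression is an eight-level ordinal scale
(none < very low < low < moderate < moderately high < high < very high <
extremely high). Numeric values are binned with seven strictly increasing
cutpoints; binning is monotone, zero maps to *none* and negative values
are errors. When no cutpoints are supplied the package calibrates octiles
of the positive values of the table at hand; ordinal input labels are
taken verbatim and never re-binned.

Relative classification against a focal tissue (default `testis`) is a
four-way partition:

* **not expressed** — focal level is *none*;
* **exclusive** — focal level above *none*; tolerated tissues (default
  accessory gland, imaginal disc) may show any level; at most
  `max_other_expressed` (default 1) further tissue may be expressed, each
  strictly below `side_tissue_max_level` (default *moderately high*);
* **predominant** — not exclusive, and the focal level is strictly above
  every other tissue's level. Ties are deliberately **not** predominant:
  "stronger than the other tissues" is read as a strict inequality, and
  the tie case falls through to ubiquitous;
* **ubiquitous** — everything else.

For numeric (source-species) tables the predominance comparison runs on
raw values and the exclusivity side-condition uses the numeric equivalent
of the ordinal bound; the source screen keeps exclusive + predominant
genes. The absolute-level filter is inclusive at its lower bound
(level ≥ *moderately high*), which also admits *extremely high*; the bound
is configurable.

## Filter cascade and combination

Filter 1 (mutant phenotype: keep `sterile`) is reported as a **parallel
branch** of the cascade rather than chained before filters 2–3, because
the sterile subset of the initial ortholog set is not in general nested in
the expression-based subsets. Genes without phenotype data count as
`unknown` and are excluded by filter 1, but their number is logged and
recorded in provenance — data censoring is a first-class output of this
kind of screen, not noise. Filters 2 and 3 are per-gene predicates, hence
contractive, idempotent, and commuting with each other; the test suite
asserts all three properties.

The two approaches are combined on **target-species** gene IDs (union with
inclusion–exclusion); the alternative intermediate-species overlap of the
two lists is surfaced separately in the summary
(`n_intermediate_overlap`).

## GO enrichment

One-sided over-representation only: for each term,
p = P(X ≥ k), X ~ Hypergeometric(N, K, n), evaluated through the scipy
survival function (log-space internally); Benjamini–Hochberg adjustment
across all tested terms via statsmodels, significance at adjusted
p < 0.05. Query genes outside the universe are dropped and logged. The
reproduction-related flag on terms is a curated input column — deciding
which terms are "reproduction-related" is editorial, and the package does
not attempt it. No GO-DAG propagation is performed; annotations are
treated as flat. In tests, both statistics are checked against independent
oracles (exhaustive enumeration of draws for every universe of size ≤ 12;
a sort-based step-up recomputation of BH on random p-vectors).

## Stage-contrast test

A deliberately simple, fully specified negative-binomial pipeline; exact
equivalence with any particular DE package is not a goal, and there is no
cross-gene dispersion shrinkage or multi-factor design support.

1. **Size factors** — median-of-ratios: factor_j = median over
   all-nonzero genes of count_gj / geometric-mean_g. Matches the
   median-of-ratios factors of DESeq2-style normalisation (cross-checked
   against pydeseq2 in the test suite).
2. **Dispersion** — per condition, method of moments
   α = (s² − m)/m² on normalised counts; the gene's working dispersion is
   the **larger** of the two condition estimates, floored at 1e−8. Taking
   the maximum deliberately biases the variance model upwards: at 3+3
   replicates the moment estimate is very noisy, and underestimating the
   variance is the failure mode that breaks error control.
3. **Wald-type test** — on d = ln((m₂+c)/(m₁+c)) with pseudocount c = 0.5
   normalised counts (avoids infinities at one-sided zeros), standard
   error from the NB variance m + αm² by the delta method, referred to a
   **t distribution with 2·(n₁+n₂−2) degrees of freedom**. This reference
   is a numerical design choice validated by simulation at the 3+3
   design: a normal reference is anti-conservative (the per-gene variance
   estimate is noisy), while t(n₁+n₂−2) combined with the max-dispersion
   rule is so conservative that genes with a 4-fold change at mean 500
   are missed; the doubled-df reference keeps the null mean
   false-discovery proportion of BH(0.05) at its nominal level (measured
   0.053 ± 0.013 over 300 null matrices of 2,000 genes) with raw p-values
   inside the 99% DKW band, at useful power.
4. **Calls** — BH across tested genes (base mean ≥ 1 by default);
   *up*/*down* when adjusted p < α with the corresponding fold-change
   sign, otherwise *unchanged*.

Scale invariance holds up to the pseudocount: doubling every count leaves
modulation calls unchanged and shifts log2 fold changes only through the
(fixed) pseudocount's diminishing weight, noticeable only at very low
counts.

Expression classes: `expressed_both` requires mean normalised count ≥
floor (default 5) in **both** stages; the five level classes (very low …
very high) default to the 20/40/60/80% quantiles of the expressed genes'
base means, or explicit cutpoints. The floor and cutpoints are
configurable because "expressed" and "high" have no universal definition
for a count matrix.

ΔΔCt: reference-gene Ct values are aggregated by arithmetic mean
(equivalent to the geometric mean of the linear quantities), the
calibrator sample's quantity is exactly 1, and a one-cycle difference is a
factor of 2.

## Synthetic bundles and what they do (not) show

`generate_bundle` plants structure that the classifiers recover exactly at
the default zero noise: profiles are constructed per class (e.g. a planted
predominant gene gets ≥ 2 other expressed tissues strictly below its
focal level, so it can be neither exclusive nor ubiquitous), orthology is
independent Bernoulli retention per target species with geometric
co-ortholog expansion, one planted GO term annotates exactly the
filters-2+3 candidate set, counts are gamma-Poisson (NB) with planted
±log2fc effects, and the Ct table encodes known relative quantities. The
manifest records every planted set plus the cascade counts implied by the
draws; a fixed seed regenerates byte-identical files (one RNG stream per
artifact, so adding a generator does not perturb the others).

Default scale (chosen once, as the study conditions the generator
emulates): 20,000 source genes with 273 + 273 planted exclusive/
predominant; ortholog retention 0.36 into the intermediate species with
mean co-ortholog expansion ≈ 2.3; six target species at retention 0.5
each (plus expansion 0.1); intermediate relative-class proportions
0.09 / 0.15 / 0.25 / rest (exclusive / predominant / not expressed /
ubiquitous); phenotype proportions 0.055 sterile / 0.31 fertile / rest
unknown; a 379-gene curated list overlapping the ortholog set by ~5%;
counts over the focal species' gene universe at dispersion 0.05, 3+3
replicates, 60 planted |log2fc| = 2 effects at mean 500, ~35% of genes
near-silent.

What passing on these bundles does **not** show: real tissue panels are
correlated and noisy, so exact planted-set recovery is an internal
consistency check, not a sensitivity claim; per-species ortholog retention
is phylogenetically correlated in reality, whereas the generator draws
species independently — the joint distribution of "in all" vs "in none"
counts in real data (where both can be large simultaneously) cannot be
matched by any single independent retention probability; and GO terms in
real annotations overlap and nest, while the generator draws them almost
independently.

## Problem sizes in tests and acceptance

Unit tests run on a reduced bundle (2,000 source genes, 120 planted); the
acceptance suite and `scripts/acceptance.py` use the default study scale
above, 200 null matrices of 2,000 genes for calibration, and the complete
enumeration oracle up to universe size 12. These sizes were chosen as the
smallest at which every measured property is stable.

## Known limitations

* Gene identifiers are opaque strings; no cross-database ID normalisation
  or symbol matching is attempted.
* No live database access of any kind; spreadsheet supplements are
  ingested via a one-shot Excel→TSV converter with separator
  autodetection for multi-ortholog cells.
* The stage test reports no shrunken fold changes and supports exactly
  two conditions.
* Enrichment reproduces plain hypergeometric + BH; ranking heuristics of
  specific web services (combined scores etc.) are out of scope, so term
  counts from such services are not comparable beyond order of magnitude.
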