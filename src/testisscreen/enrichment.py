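"""GO-term over-representation testing.

For a query gene set of size n drawn from a universe of N genes, of which K
carry a given term, observing k annotated genes in the query has upper-tail
probability P(X >= k) under X ~ Hypergeometric(N, K, n).  One p-value per
term, Benjamini–Hochberg adjusted across all tested terms; a term is called
enriched when the adjusted p falls below alpha (default 0.05).  Only
over-representation (upper tail) is tested.

The fraction of enriched terms flagged as reproduction-related is the
screen's figure of merit for how reproductive a gene list is; the flag is a
curated input column, not something inferred here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .gene_sets import GeneSet
from .tables import GoAnnotationSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's 2×2 upper-tail test against the genome universe."""

    term_id: str
    term_name: str
    k: int  # annotated genes in the query
    K: int  # term size in the universe
    n: int  # query size (after intersecting with the universe)
    N: int  # universe size
    p_raw: float
    p_adj: float
    reproduction_related: bool

    def __post_init__(self) -> None:
        if self.k > min(self.K, self.n):
            raise ValueError("k cannot exceed min(K, n)")


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    The survival function is evaluated in log space internally (scipy), so
    extreme tails are stable; k = 0 gives exactly 1.
    """
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"require 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if K > N or n > N:
        raise ValueError(f"require K, n <= N; got K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted


def enrich(
    query: GeneSet,
    annotations: GoAnnotationSet,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Test every annotated term for over-representation in the query.

    The query is intersected with the universe first (dropped members are
    logged); every term with at least one annotated gene is tested and the
    BH adjustment runs across all tested terms.  Results are sorted by raw
    p-value.
    """
    if not annotations.universe:
        raise ValueError("empty annotation universe")
    in_universe = query.members & annotations.universe
    dropped = len(query.members) - len(in_universe)
    if dropped:
        logger.info(
            "enrich: %d query gene(s) absent from the universe, dropped",
            dropped,
        )
    n = len(in_universe)
    N = len(annotations.universe)
    tested = [t for t in annotations.terms.values() if len(t.genes) >= 1]
    raw = []
    rows = []
    for term in tested:
        K = len(term.genes)
        k = len(term.genes & in_universe)
        p = hypergeom_upper_tail(k, K, n, N)
        raw.append(p)
        rows.append((term, k, K, p))
    adjusted = bh_adjust(raw) if raw else np.array([])
    results = [
        EnrichmentResult(
            term_id=term.term_id,
            term_name=term.name,
            k=k,
            K=K,
            n=n,
            N=N,
            p_raw=p,
            p_adj=float(p_adj),
            reproduction_related=term.reproduction_related,
        )
        for (term, k, K, p), p_adj in zip(rows, adjusted)
    ]
    results.sort(key=lambda r: (r.p_raw, r.term_id))
    return results


def reproduction_fraction(
    results: Sequence[EnrichmentResult], alpha: float = 0.05
) -> tuple[int, int, float | None]:
    """(reproduction-related, significant, fraction) among enriched terms.

    Returns ``None`` for the fraction when no term is significant.
    """
    significant = [r for r in results if r.p_adj < alpha]
    n_signif = len(significant)
    n_repro = sum(1 for r in significant if r.reproduction_related)
    if n_signif == 0:
        return 0, 0, None
    return n_repro, n_signif, n_repro / n_signif
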