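"""Hypergeometric over-representation analysis of gene sets.

For a query of n genes drawn from a universe of N, a term annotating K
genes with k of them in the query is scored with the upper-tail
hypergeometric probability P(X >= k); p values are BH-adjusted across
all terms passing the size filter.  The annotation is taken as already
propagated up the ontology graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

from scipy import stats

from .diffexpr import bh_adjust
from .model import ValidationError

logger = logging.getLogger("rnlseq")

__all__ = ["AnnotationMap", "EnrichmentRow", "hypergeom_enrich", "top_terms"]


@dataclass
class AnnotationMap:
    """term -> annotated genes, against a fixed gene universe."""

    terms: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValidationError("empty annotation universe")
        self.terms = {t: set(g) & self.universe for t, g in self.terms.items()}

    @classmethod
    def from_annotation(
        cls, terms: Mapping[str, Iterable[str]], universe: Iterable[str]
    ) -> "AnnotationMap":
        return cls({t: set(g) for t, g in terms.items()}, set(universe))


@dataclass(frozen=True)
class EnrichmentRow:
    term_id: str
    k: int  # overlap
    K: int  # term size
    n: int  # query size
    N: int  # universe size
    p_value: float
    p_adjusted: float
    fold_enrichment: float


def hypergeom_enrich(
    query: Iterable[str],
    annotation: AnnotationMap,
    min_term_size: int = 3,
    max_term_size: int = 500,
) -> list[EnrichmentRow]:
    """Score every size-eligible term against the query."""
    query = set(query)
    outside = query - annotation.universe
    if outside:
        logger.warning("%d query genes outside the universe dropped", len(outside))
        query &= annotation.universe
    if not query:
        return []
    N = len(annotation.universe)
    n = len(query)
    terms = {
        t: g
        for t, g in annotation.terms.items()
        if min_term_size <= len(g) <= max_term_size
    }
    rows = []
    for term in sorted(terms):
        genes = terms[term]
        K = len(genes)
        k = len(genes & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        p = min(p, 1.0)
        fe = (k / n) / (K / N) if K else 0.0
        rows.append((term, k, K, p, fe))
    p_adj = bh_adjust([r[3] for r in rows]) if rows else []
    return [
        EnrichmentRow(term_id=t, k=k, K=K, n=n, N=N, p_value=p, p_adjusted=float(q),
                      fold_enrichment=fe)
        for (t, k, K, p, fe), q in zip(rows, p_adj)
    ]


def top_terms(rows: list[EnrichmentRow], k: int = 25) -> list[EnrichmentRow]:
    """The k best-scoring terms: smallest adjusted p, ties broken by
    larger fold enrichment, then term id."""
    if k <= 0:
        raise ValidationError(f"top_terms needs k > 0, got {k}")
    ranked = sorted(rows, key=lambda r: (r.p_adjusted, -r.fold_enrichment, r.term_id))
    return ranked[:k]
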