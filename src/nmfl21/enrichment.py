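"""Hypergeometric over-representation testing for gene-set annotations.

Implements the upper-tail hypergeometric statistic used to judge selected
gene lists against annotation terms, with the conventional thresholds of
max P = 0.01 and a minimum overlap of 2 genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationCollection",
    "EnrichmentResult",
    "hypergeom_sf",
    "enrich",
    "DEFAULT_MAX_P",
    "DEFAULT_MIN_GENES",
]

#: Default significance cutoff for reported terms.
DEFAULT_MAX_P = 0.01
#: Default minimum overlap between query and term.
DEFAULT_MIN_GENES = 2


@dataclass(frozen=True)
class AnnotationCollection:
    """Named gene sets plus the background universe they are tested against.

    Term gene sets must be subsets of the background; member genes outside
    the background are dropped with a logged count.
    """

    terms: tuple[tuple[str, str, frozenset[str]], ...]
    background: frozenset[str]

    def __post_init__(self) -> None:
        background = frozenset(str(g) for g in self.background)
        seen_ids: set[str] = set()
        cleaned = []
        n_dropped = 0
        for term_id, term_name, genes in self.terms:
            if term_id in seen_ids:
                raise ValueError(f"duplicate term id: {term_id!r}")
            seen_ids.add(term_id)
            genes = frozenset(str(g) for g in genes)
            inside = genes & background
            n_dropped += len(genes) - len(inside)
            cleaned.append((str(term_id), str(term_name), inside))
        if n_dropped:
            logger.info("dropped %d term member genes outside the background", n_dropped)
        object.__setattr__(self, "terms", tuple(cleaned))
        object.__setattr__(self, "background", background)

    @classmethod
    def from_gene_sets(
        cls,
        gene_sets: dict[str, set[str]],
        background: set[str] | None = None,
        names: dict[str, str] | None = None,
    ) -> "AnnotationCollection":
        """Build a collection; background defaults to the union of all terms."""
        if background is None:
            background = set().union(*gene_sets.values()) if gene_sets else set()
        names = names or {}
        terms = tuple(
            (tid, names.get(tid, tid), frozenset(genes)) for tid, genes in gene_sets.items()
        )
        return cls(terms=terms, background=frozenset(background))


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's overlap counts and upper-tail hypergeometric P-value."""

    term_id: str
    term_name: str
    k: int
    n_query: int
    K: int
    N: int
    p_value: float
    p_bonferroni: float
    overlapping_gene_ids: tuple[str, ...] = field(default_factory=tuple)


def hypergeom_sf(k: int, n_query: int, K: int, N: int) -> float:
    """Upper-tail probability P(X >= k) of the hypergeometric distribution.

    ``X`` counts annotated genes in a size-``n_query`` draw without
    replacement from a background of ``N`` genes of which ``K`` carry the
    annotation.  The tail is summed exactly in log space via log-gamma, so
    values far below 1e-100 remain representable; no normal approximation
    is used.
    """
    for name, v in (("k", k), ("n_query", n_query), ("K", K), ("N", N)):
        if int(v) != v:
            raise ValueError(f"{name} must be an integer, got {v}")
    k, n_query, K, N = int(k), int(n_query), int(K), int(N)
    if not (0 <= k <= n_query <= N):
        raise ValueError(f"need 0 <= k <= n_query <= N, got k={k}, n_query={n_query}, N={N}")
    if not (0 <= K <= N):
        raise ValueError(f"need 0 <= K <= N, got K={K}, N={N}")
    if k > K:
        return 0.0
    if k == 0:
        return 1.0
    hi = min(n_query, K)
    j = np.arange(k, hi + 1)
    # log pmf(j) = log C(K, j) + log C(N-K, n_query-j) - log C(N, n_query)
    log_pmf = (
        _log_comb(K, j)
        + _log_comb(N - K, n_query - j)
        - _log_comb(N, np.array([n_query]))
    )
    p = float(np.exp(logsumexp(log_pmf)))
    return min(p, 1.0)


def _log_comb(n: int | np.ndarray, r: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)


def enrich(
    query: list[str],
    annotations: AnnotationCollection,
    max_p: float = DEFAULT_MAX_P,
    min_genes: int = DEFAULT_MIN_GENES,
) -> list[EnrichmentResult]:
    """Test every term for over-representation in ``query``.

    Query genes outside the background are dropped (with a logged count).
    Terms are kept when their overlap has at least ``min_genes`` genes and a
    raw P-value at most ``max_p``; results are sorted by ascending P-value.
    A Bonferroni-adjusted value (multiplier = number of terms tested) is
    reported alongside the raw one.
    """
    if not query:
        raise ValueError("query gene list is empty")
    if not annotations.background:
        raise ValueError("annotation background is empty")
    query_set = {str(g) for g in query}
    inside = query_set & annotations.background
    n_outside = len(query_set) - len(inside)
    if n_outside:
        logger.info("dropped %d query genes outside the background", n_outside)
    if not inside:
        raise ValueError("no query genes remain after restricting to the background")
    N = len(annotations.background)
    n_query = len(inside)
    n_terms = len(annotations.terms)
    results = []
    for term_id, term_name, genes in annotations.terms:
        overlap = inside & genes
        k = len(overlap)
        p = hypergeom_sf(k, n_query, len(genes), N)
        if k >= min_genes and p <= max_p:
            results.append(
                EnrichmentResult(
                    term_id=term_id,
                    term_name=term_name,
                    k=k,
                    n_query=n_query,
                    K=len(genes),
                    N=N,
                    p_value=p,
                    p_bonferroni=min(1.0, p * n_terms),
                    overlapping_gene_ids=tuple(sorted(overlap)),
                )
            )
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results
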