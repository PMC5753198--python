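"""Hypergeometric gene-list enrichment with a two-stage filter chain.

Sets are pre-filtered by type and size, tested against the query with a
hypergeometric upper tail over the corpus universe, BH-adjusted across all
tested sets, then post-filtered on similarity, overlap, normalized cohesion
and FDR. Defaults mirror a typical advanced-search configuration
(types=all, size 2-1000, similarity >= 0.1, overlap > 1, cohesion >= 100,
FDR <= 0.05); every threshold is overridable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom

from .corpus_io import Corpus, GeneSet, normalize_symbol

logger = logging.getLogger(__name__)

SIMILARITY_METRICS = ("cosine", "jaccard")


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``N`` population size, ``K`` successes in population, ``n`` draws,
    ``k`` observed successes.
    """
    if N < 0 or not (0 <= K <= N) or not (0 <= n <= N) or k < 0:
        raise ValueError(
            f"inconsistent hypergeometric parameters k={k}, K={K}, n={n}, N={N}"
        )
    if k == 0:
        return 1.0
    if k > min(K, n):
        return 0.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out.tolist()


def similarity(query: Iterable[str], gene_set: GeneSet, metric: str = "cosine") -> float:
    """Overlap similarity between a query and a set.

    ``cosine`` (Ochiai): |Q∩S| / sqrt(|Q|·|S|); ``jaccard``: |Q∩S| / |Q∪S|.
    """
    q = set(query)
    if not q:
        raise ValueError("similarity of an empty query is undefined")
    s = gene_set.members
    overlap = len(q & s)
    if metric == "cosine":
        return overlap / math.sqrt(len(q) * len(s))
    if metric == "jaccard":
        return overlap / len(q | s)
    raise ValueError(f"metric must be one of {SIMILARITY_METRICS}, got {metric!r}")


@dataclass
class FilterConfig:
    """Thresholds for the enrichment filter chain.

    ``pag_types`` and the size window act as pre-filters (before testing and
    BH); the remaining thresholds act on the computed statistics.
    ``min_overlap_exclusive=1`` means overlap must be strictly greater than 1.
    """

    pag_types: frozenset[str] = frozenset({"P", "A", "G"})
    size_min: int = 2
    size_max: int = 1000
    min_similarity: float = 0.1
    min_overlap_exclusive: int = 1
    min_ncoco: float = 100.0
    max_fdr: float = 0.05

    def __post_init__(self) -> None:
        if self.size_min > self.size_max:
            raise ValueError(
                f"size_min {self.size_min} > size_max {self.size_max}"
            )


@dataclass
class EnrichmentResult:
    set_id: str
    name: str
    pag_type: str
    size: int
    overlap: int
    similarity: float
    p_value: float
    fdr: float
    ncoco: float
    passed: bool


@dataclass
class EnrichmentReport:
    results: list[EnrichmentResult]
    n_tested: int  # BH denominator: sets surviving the pre-filters
    query_size: int  # query genes inside the universe
    unmapped: list[str]

    @property
    def passing(self) -> list[EnrichmentResult]:
        return [r for r in self.results if r.passed]


class EmptyQueryError(ValueError):
    pass


def enrich_query(
    query: Sequence[str],
    corpus: Corpus,
    ncoco_by_set: Mapping[str, float] | None = None,
    filters: FilterConfig | None = None,
    metric: str = "cosine",
) -> EnrichmentReport:
    """Score a query gene list against every pre-filtered corpus set.

    The p-value for a set of size K is the hypergeometric upper tail of
    drawing >= overlap query genes when |query ∩ universe| genes are drawn
    from the N-gene universe. BH adjustment runs across all tested sets.
    Query symbols outside the universe are dropped with a warning; a query
    with no mappable symbols raises :class:`EmptyQueryError` listing them.

    When ``ncoco_by_set`` is None the cohesion threshold is skipped.
    """
    filters = filters or FilterConfig()
    universe = corpus.universe
    q_raw = [normalize_symbol(g) for g in query]
    q = sorted({g for g in q_raw if g in universe})
    unmapped = sorted({g for g in q_raw if g not in universe})
    if not q:
        raise EmptyQueryError(
            "no query genes found in the corpus universe; unmapped symbols: "
            + ", ".join(unmapped)
        )
    if unmapped:
        logger.warning(
            "%d query symbol(s) outside the universe dropped: %s",
            len(unmapped),
            ", ".join(unmapped),
        )
    N = len(universe)
    n_draws = len(q)
    qset = set(q)

    tested = [
        gs
        for gs in corpus
        if gs.pag_type in filters.pag_types
        and filters.size_min <= gs.size <= filters.size_max
    ]
    overlaps = [len(qset & gs.members) for gs in tested]
    p_values = [
        hypergeom_upper_tail(k, gs.size, n_draws, N)
        for k, gs in zip(overlaps, tested)
    ]
    # guard against float underflow: BH requires p in (0, 1]
    p_values = [min(max(p, 1e-320), 1.0) for p in p_values]
    fdrs = bh_fdr(p_values) if p_values else []

    results: list[EnrichmentResult] = []
    for gs, k, p, f in zip(tested, overlaps, p_values, fdrs):
        sim = similarity(qset, gs, metric) if k else 0.0
        nc = float("nan") if ncoco_by_set is None else float(
            ncoco_by_set.get(gs.id, 0.0)
        )
        passed = (
            sim >= filters.min_similarity
            and k > filters.min_overlap_exclusive
            and f <= filters.max_fdr
            and (ncoco_by_set is None or nc >= filters.min_ncoco)
        )
        results.append(
            EnrichmentResult(
                set_id=gs.id,
                name=gs.name,
                pag_type=gs.pag_type,
                size=gs.size,
                overlap=k,
                similarity=sim,
                p_value=p,
                fdr=f,
                ncoco=nc,
                passed=passed,
            )
        )
    results.sort(key=lambda r: (r.fdr, r.p_value, r.set_id))
    return EnrichmentReport(
        results=results, n_tested=len(tested), query_size=n_draws, unmapped=unmapped
    )


def write_enrichment_csv(report: EnrichmentReport, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(
            "set_id,name,type,size,overlap,similarity,p_value,fdr,ncoco,passed\n"
        )
        for r in report.results:
            nc = "" if math.isnan(r.ncoco) else f"{r.ncoco:.10g}"
            fh.write(
                f"{r.set_id},{r.name},{r.pag_type},{r.size},{r.overlap},"
                f"{r.similarity:.10g},{r.p_value:.10g},{r.fdr:.10g},{nc},"
                f"{r.passed}\n"
            )
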