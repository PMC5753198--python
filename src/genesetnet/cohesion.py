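"""Within-set network cohesion scoring and size-bias normalization.

A set's cohesion score measures how improbably many of its theoretically
possible gene pairs (and trios) are covered by interaction-network edges
(and triangles), under a hypergeometric sampling null against the background
network. Because the raw score grows strongly with set size, a corpus-wide
polynomial trend of log2(score) versus log2(size) is fitted and removed,
yielding a size-normalized score comparable across sizes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom

from .corpus_io import Corpus, GeneSet, InteractionNetwork

#: floor applied to tail probabilities before taking -log10
PROB_FLOOR = 1e-320
_MAX_NEGLOG10 = 320.0  # == -log10(PROB_FLOOR)


class CohesionUndefinedError(ValueError):
    """Cohesion is undefined for singleton sets."""


def theoretical_pairs(n: int) -> int:
    """Number of unordered gene pairs in a set of size ``n``: n(n-1)/2."""
    if n < 0:
        raise ValueError(f"set size must be nonnegative, got {n}")
    return n * (n - 1) // 2


def theoretical_trios(n: int) -> int:
    """Number of unordered gene trios in a set of size ``n``: n(n-1)(n-2)/6."""
    if n < 0:
        raise ValueError(f"set size must be nonnegative, got {n}")
    return n * (n - 1) * (n - 2) // 6


def observed_pairs(
    gene_set: GeneSet, ppi: InteractionNetwork, min_confidence: float = 0.0
) -> int:
    """Count network edges with both endpoints in the set passing the cutoff."""
    members = gene_set.members
    return sum(
        1
        for a, b, _ in ppi.edges(min_confidence)
        if a in members and b in members
    )


def observed_trios(
    gene_set: GeneSet, ppi: InteractionNetwork, min_confidence: float = 0.0
) -> int:
    """Count triangles in the set's induced subgraph at the cutoff."""
    members = gene_set.members
    adj: dict[str, set[str]] = {}
    for a, b, _ in ppi.edges(min_confidence):
        if a in members and b in members:
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
    count = 0
    for a in adj:
        for b in adj[a]:
            if b <= a:
                continue
            # common neighbors ranked above b to count each triangle once
            count += sum(1 for c in adj[a] & adj[b] if c > b)
    return count


@dataclass(frozen=True)
class NetworkBackground:
    """Corpus-level network density summary used as the sampling null.

    ``n_genes`` is the universe size N; ``n_edges`` the number of network
    edges among universe genes passing the confidence cutoff; ``n_triangles``
    the number of triangles among them.
    """

    n_genes: int
    n_edges: int
    n_triangles: int

    @classmethod
    def from_network(
        cls,
        ppi: InteractionNetwork,
        universe: Iterable[str],
        min_confidence: float = 0.0,
    ) -> "NetworkBackground":
        uni = set(universe)
        adj: dict[str, set[str]] = {}
        n_edges = 0
        for a, b, _ in ppi.edges(min_confidence):
            if a in uni and b in uni:
                n_edges += 1
                adj.setdefault(a, set()).add(b)
                adj.setdefault(b, set()).add(a)
        n_tri = 0
        for a in adj:
            for b in adj[a]:
                if b <= a:
                    continue
                n_tri += sum(1 for c in adj[a] & adj[b] if c > b)
        return cls(n_genes=len(uni), n_edges=n_edges, n_triangles=n_tri)


def _neg_log10_upper_tail(k: int, M: int, K: int, n: int) -> float:
    """-log10 P(X >= k), X ~ Hypergeom(M, K, n), capped at 320."""
    if k <= 0:
        return 0.0
    if K <= 0 or n <= 0:
        # an empty background (or no draws) carries no signal
        return 0.0
    log_p = hypergeom.logsf(k - 1, M, K, n)  # natural log of P(X >= k)
    neg = -log_p / math.log(10)
    if not math.isfinite(neg):
        return _MAX_NEGLOG10
    return min(neg, _MAX_NEGLOG10)


def cohesion_from_counts(
    obs_pairs: int,
    theo_pairs: int,
    obs_trios: int,
    theo_trios: int,
    background: NetworkBackground,
    trio_weight: float = 1.0,
) -> float:
    """Cohesion score from coverage counts and a background summary.

    ``S2`` is -log10 of the upper-tail probability of covering at least
    ``obs_pairs`` of ``theo_pairs`` sampled pairs when the background holds
    ``n_edges`` covered pairs among C(N,2); ``S3`` is the analogue for trios
    over background triangles among C(N,3). Returns ``S2 + trio_weight*S3``;
    probabilities are floored at 1e-320 before the log.
    """
    N = background.n_genes
    m_pairs = theoretical_pairs(N)
    m_trios = theoretical_trios(N)
    s2 = _neg_log10_upper_tail(obs_pairs, m_pairs, background.n_edges, theo_pairs)
    s3 = _neg_log10_upper_tail(obs_trios, m_trios, background.n_triangles, theo_trios)
    return s2 + trio_weight * s3


def coco_score(
    gene_set: GeneSet,
    ppi: InteractionNetwork,
    background: NetworkBackground,
    min_confidence: float = 0.0,
    trio_weight: float = 1.0,
) -> float:
    """Cohesion score of one gene set against the background network."""
    if gene_set.size < 2:
        raise CohesionUndefinedError(
            f"set {gene_set.id!r} is a singleton; cohesion is undefined for n < 2"
        )
    if background.n_edges == 0:
        return 0.0
    n = gene_set.size
    return cohesion_from_counts(
        observed_pairs(gene_set, ppi, min_confidence),
        theoretical_pairs(n),
        observed_trios(gene_set, ppi, min_confidence),
        theoretical_trios(n),
        background,
        trio_weight,
    )


@dataclass
class CohesionRecord:
    """Per-set cohesion report row."""

    set_id: str
    n: int
    theoretical_pairs: int
    observed_pairs: int
    theoretical_trios: int
    observed_trios: int
    coco: float
    ncoco: float = float("nan")


@dataclass
class SizeNormalizer:
    """Polynomial trend of log2(cohesion) versus log2(size).

    ``coefficients`` are in ascending power order; ``reference_level`` is the
    corpus mean of fitted values, so normalized scores are re-anchored to the
    corpus-typical level rather than to 1.
    """

    degree: int
    coefficients: np.ndarray
    reference_level: float

    def trend(self, log2_n: float | np.ndarray) -> float | np.ndarray:
        return np.polynomial.polynomial.polyval(log2_n, self.coefficients)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "degree": self.degree,
                    "coefficients": [float(c) for c in self.coefficients],
                    "reference_level": self.reference_level,
                },
                indent=2,
            )
            + "\n",
            encoding="utf-8",
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SizeNormalizer":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            degree=int(d["degree"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            reference_level=float(d["reference_level"]),
        )


class FitError(ValueError):
    """Normalizer fit is impossible on the given records."""


def fit_size_normalizer(
    records: Sequence[CohesionRecord], degree: int = 3
) -> SizeNormalizer:
    """Least-squares fit of log2(score) on log2(size) over positive-score sets.

    Sets with zero cohesion (log undefined) and singletons are excluded.
    Requires at least ``degree + 2`` usable records and at least
    ``degree + 1`` distinct sizes.
    """
    if degree < 0:
        raise ValueError(f"degree must be >= 0, got {degree}")
    usable = [r for r in records if r.coco > 0 and r.n >= 2]
    if len(usable) < degree + 2:
        raise FitError(
            f"need >= {degree + 2} records with positive cohesion for a "
            f"degree-{degree} fit, got {len(usable)}"
        )
    x = np.log2([r.n for r in usable])
    y = np.log2([r.coco for r in usable])
    if len(np.unique(x)) < degree + 1:
        raise FitError(
            f"only {len(np.unique(x))} distinct sizes; a degree-{degree} fit "
            "is rank-deficient"
        )
    coeffs = np.polynomial.polynomial.polyfit(x, y, degree)
    fitted = np.polynomial.polynomial.polyval(x, coeffs)
    return SizeNormalizer(
        degree=degree, coefficients=coeffs, reference_level=float(fitted.mean())
    )


def ncoco_score(coco: float, n: int, normalizer: SizeNormalizer) -> float:
    """Size-normalized cohesion: 2^(log2(score) - trend(log2 n) + reference)."""
    if coco < 0:
        raise ValueError(f"cohesion score must be nonnegative, got {coco}")
    if n < 2:
        raise ValueError(f"normalized cohesion undefined for size {n} < 2")
    if normalizer is None:
        raise ValueError("normalizer has not been fitted")
    if coco == 0:
        return 0.0
    resid = math.log2(coco) - float(normalizer.trend(math.log2(n)))
    return float(2.0 ** (resid + normalizer.reference_level))


def score_corpus(
    corpus: Corpus,
    ppi: InteractionNetwork,
    min_confidence: float = 0.0,
    trio_weight: float = 1.0,
) -> list[CohesionRecord]:
    """Cohesion records for every non-singleton set in the corpus."""
    background = NetworkBackground.from_network(ppi, corpus.universe, min_confidence)
    out: list[CohesionRecord] = []
    for gs in corpus:
        if gs.size < 2:
            continue
        op = observed_pairs(gs, ppi, min_confidence)
        ot = observed_trios(gs, ppi, min_confidence)
        score = (
            0.0
            if background.n_edges == 0
            else cohesion_from_counts(
                op,
                theoretical_pairs(gs.size),
                ot,
                theoretical_trios(gs.size),
                background,
                trio_weight,
            )
        )
        out.append(
            CohesionRecord(
                set_id=gs.id,
                n=gs.size,
                theoretical_pairs=theoretical_pairs(gs.size),
                observed_pairs=op,
                theoretical_trios=theoretical_trios(gs.size),
                observed_trios=ot,
                coco=score,
            )
        )
    return out


def apply_normalizer(
    records: Sequence[CohesionRecord], normalizer: SizeNormalizer
) -> None:
    """Fill the ``ncoco`` field of every record in place."""
    for r in records:
        r.ncoco = ncoco_score(r.coco, r.n, normalizer)


def cp50(
    scores: Sequence[float], group_labels: Sequence[str] | None = None
) -> float | dict[str, float]:
    """Score at cumulative fraction 0.50 (median, lower interpolation).

    With ``group_labels``, returns a per-group dict; otherwise a scalar.
    """
    if group_labels is None:
        if len(scores) == 0:
            raise ValueError("cp50 of an empty score list")
        return float(np.percentile(np.asarray(scores, dtype=float), 50, method="lower"))
    if len(group_labels) != len(scores):
        raise ValueError("group_labels length must match scores")
    groups: dict[str, list[float]] = {}
    for s, g in zip(scores, group_labels):
        groups.setdefault(g, []).append(s)
    return {g: cp50(vals) for g, vals in sorted(groups.items())}


_CSV_HEADER = (
    "set_id,size,theoretical_pairs,observed_pairs,theoretical_trios,"
    "observed_trios,coco,ncoco"
)


def write_cohesion_csv(records: Sequence[CohesionRecord], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(_CSV_HEADER + "\n")
        for r in records:
            nc = "" if math.isnan(r.ncoco) else f"{r.ncoco:.10g}"
            fh.write(
                f"{r.set_id},{r.n},{r.theoretical_pairs},{r.observed_pairs},"
                f"{r.theoretical_trios},{r.observed_trios},{r.coco:.10g},{nc}\n"
            )


def read_cohesion_csv(path: str | Path) -> list[CohesionRecord]:
    records: list[CohesionRecord] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        header = fh.readline().strip()
        if header != _CSV_HEADER:
            raise ValueError(f"unexpected cohesion CSV header: {header!r}")
        for line in fh:
            f = line.rstrip("\n").split(",")
            records.append(
                CohesionRecord(
                    set_id=f[0],
                    n=int(f[1]),
                    theoretical_pairs=int(f[2]),
                    observed_pairs=int(f[3]),
                    theoretical_trios=int(f[4]),
                    observed_trios=int(f[5]),
                    coco=float(f[6]),
                    ncoco=float(f[7]) if f[7] else float("nan"),
                )
            )
    return records
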