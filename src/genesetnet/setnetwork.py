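"""Set-to-set networks from member overlap (m-type) and regulation (r-type).

m-type edges are undirected links between set pairs whose member overlap is
hypergeometrically surprising under a dual point-mass / upper-tail filter.
r-type edges are directed links emitted when the number of regulation edges
running from one set's exclusive members to another's is enriched against
the regulation network's overall density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from scipy.stats import hypergeom

from .corpus_io import Corpus, RegulationNetwork

#: probabilities are floored here before -log10
_PROB_FLOOR = 1e-320


@dataclass(frozen=True)
class SetEdge:
    """A scored set-to-set relationship.

    m-type edges are undirected and stored with ``source_id < target_id``;
    r-type edges are directed, source regulating target.
    ``k`` is the overlap size (m) or cross-set regulation edge count (r).
    """

    source_id: str
    target_id: str
    kind: str  # "m" | "r"
    k: int
    neg_log10_pmf: float
    neg_log10_tail: float

    @property
    def directed(self) -> bool:
        return self.kind == "r"


def _neg_log10(p: float) -> float:
    return -math.log10(max(p, _PROB_FLOOR))


def build_m_type(
    corpus: Corpus,
    pmf_threshold: float = 5.0,
    tail_threshold: float = 10.0,
) -> list[SetEdge]:
    """Overlap-based undirected edges between set pairs.

    For each unordered pair with overlap ``k >= 1`` compute
    ``V1 = -log10 PMF(k; N, |A|, |B|)`` and ``V2 = -log10 P(X >= k)``; an
    edge is emitted iff ``V1 > pmf_threshold`` and ``V2 > tail_threshold``.
    """
    if pmf_threshold < 0 or tail_threshold < 0:
        raise ValueError("thresholds must be nonnegative")
    N = len(corpus.universe)
    # candidate pairs via inverted index: only pairs sharing >= 1 gene
    index = corpus.membership_index()
    pairs: set[tuple[str, str]] = set()
    for ids in index.values():
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                pairs.add((a, b))
    edges: list[SetEdge] = []
    for a_id, b_id in sorted(pairs):
        a, b = corpus[a_id], corpus[b_id]
        k = len(a.members & b.members)
        v1 = _neg_log10(float(hypergeom.pmf(k, N, a.size, b.size)))
        v2 = _neg_log10(float(hypergeom.sf(k - 1, N, a.size, b.size)))
        if v1 > pmf_threshold and v2 > tail_threshold:
            edges.append(
                SetEdge(
                    source_id=a_id,
                    target_id=b_id,
                    kind="m",
                    k=k,
                    neg_log10_pmf=v1,
                    neg_log10_tail=v2,
                )
            )
    return edges


def build_r_type(
    corpus: Corpus,
    reg: RegulationNetwork,
    pmf_alpha: float = 0.05,
    tail_alpha: float = 0.05,
) -> list[SetEdge]:
    """Regulation-based directed edges between ordered set pairs.

    For an ordered pair (A, B), ``k`` counts regulation edges from A-only
    members to B-only members (shared genes excluded from both sides to
    avoid self-regulation inflation). The null draws
    ``|A\\B| * |B\\A|`` ordered gene pairs from the ``N(N-1)`` ordered pairs
    of the universe, of which ``E`` (total regulation edges within the
    universe) are regulation edges. A directed edge is emitted iff
    ``PMF(k) < pmf_alpha``, ``P(X >= k) < tail_alpha`` and ``k >= 1``.
    """
    if not (0 < pmf_alpha < 1 and 0 < tail_alpha < 1):
        raise ValueError("alphas must lie in (0, 1)")
    universe = corpus.universe
    reg_edges = [(u, v) for u, v in reg.edges if u in universe and v in universe]
    if not reg_edges:
        return []
    E = len(reg_edges)
    N = len(universe)
    n_pairs = N * (N - 1)
    index = corpus.membership_index()
    # candidate ordered set pairs: some regulation edge runs u in A, v in B
    candidates: set[tuple[str, str]] = set()
    for u, v in reg_edges:
        for a_id in index.get(u, ()):
            for b_id in index.get(v, ()):
                if a_id != b_id:
                    candidates.add((a_id, b_id))
    edges: list[SetEdge] = []
    for a_id, b_id in sorted(candidates):
        a, b = corpus[a_id], corpus[b_id]
        a_only = a.members - b.members
        b_only = b.members - a.members
        draws = len(a_only) * len(b_only)
        if draws == 0:
            continue
        k = sum(1 for u, v in reg_edges if u in a_only and v in b_only)
        if k < 1:
            continue
        pmf = float(hypergeom.pmf(k, n_pairs, E, draws))
        tail = float(hypergeom.sf(k - 1, n_pairs, E, draws))
        if pmf < pmf_alpha and tail < tail_alpha:
            edges.append(
                SetEdge(
                    source_id=a_id,
                    target_id=b_id,
                    kind="r",
                    k=k,
                    neg_log10_pmf=_neg_log10(pmf),
                    neg_log10_tail=_neg_log10(tail),
                )
            )
    return edges


def classify_and_count(
    edges: Sequence[SetEdge], corpus: Corpus
) -> dict[str, int]:
    """Tally directed edges by endpoint class (singleton ``s`` vs multi ``m``).

    Returns counts for the four ordered categories ``s->m``, ``m->m``,
    ``m->s`` and ``s->s``.
    """
    counts = {"s->m": 0, "m->m": 0, "m->s": 0, "s->s": 0}
    for e in edges:
        for sid in (e.source_id, e.target_id):
            if sid not in corpus:
                raise ValueError(f"edge endpoint {sid!r} not found in corpus")
        src = "s" if corpus[e.source_id].is_singleton else "m"
        tgt = "s" if corpus[e.target_id].is_singleton else "m"
        counts[f"{src}->{tgt}"] += 1
    return counts


GRAPH_FORMATS = ("graphml", "sif")


def export_graph(
    edges: Sequence[SetEdge],
    path: str | Path,
    fmt: str = "graphml",
    annotations: Mapping[str, Mapping[str, object]] | None = None,
) -> None:
    """Write the set network as GraphML or SIF with deterministic ordering.

    ``annotations`` maps set id to node attributes (e.g. type, size, degree,
    neg_log2_fdr); attributes are attached in GraphML output only.
    """
    if fmt not in GRAPH_FORMATS:
        raise ValueError(f"format must be one of {GRAPH_FORMATS}, got {fmt!r}")
    path = Path(path)
    nodes = sorted({e.source_id for e in edges} | {e.target_id for e in edges})
    ordered = sorted(edges, key=lambda e: (e.source_id, e.target_id, e.kind))
    if fmt == "sif":
        lines = [f"{e.source_id}\t{e.kind}\t{e.target_id}" for e in ordered]
        path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
        return
    import networkx as nx

    directed = any(e.directed for e in edges)
    g = nx.DiGraph() if directed else nx.Graph()
    for node in nodes:
        attrs = dict(annotations.get(node, {})) if annotations else {}
        g.add_node(node, **attrs)
    for e in ordered:
        g.add_edge(
            e.source_id,
            e.target_id,
            kind=e.kind,
            k=e.k,
            neg_log10_pmf=e.neg_log10_pmf,
            weight=e.neg_log10_tail,
        )
    nx.write_graphml(g, path, infer_numeric_types=True)


def write_edges_tsv(edges: Sequence[SetEdge], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("source\ttarget\tkind\tk\tneg_log10_pmf\tneg_log10_tail\n")
        for e in sorted(edges, key=lambda e: (e.kind, e.source_id, e.target_id)):
            fh.write(
                f"{e.source_id}\t{e.target_id}\t{e.kind}\t{e.k}\t"
                f"{e.neg_log10_pmf:.10g}\t{e.neg_log10_tail:.10g}\n"
            )
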