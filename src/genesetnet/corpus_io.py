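"""Reading, writing and validation of gene-set corpora and gene networks.

The on-disk formats are deliberately plain:

* GMT — one gene set per line: ``id<TAB>description<TAB>gene1<TAB>gene2...``.
  The set type (``P``/``A``/``G``) is encoded as a leading ``type=X`` token in
  the description field, since standard GMT has no type column.
* Network TSV — two or three tab-separated columns
  (``geneA``, ``geneB``[, ``confidence``]); ``#`` comments are skipped.
* Gene lists — one symbol per line.

All gene symbols are uppercased and whitespace-trimmed at ingest; every
downstream overlap computation is symbol-exact.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

logger = logging.getLogger(__name__)

PAG_TYPES = ("P", "A", "G")

_TYPE_TOKEN = re.compile(r"\btype=([PAG])\b\s*;?\s*")


class ParseError(ValueError):
    """Raised for malformed input files; message names the offending line."""


class ValidationError(ValueError):
    """Raised when parsed values violate a domain invariant."""


def normalize_symbol(symbol: str) -> str:
    return symbol.strip().upper()


@dataclass(frozen=True)
class GeneSet:
    """A single gene set: pathway (P), annotated list (A) or signature (G)."""

    id: str
    members: frozenset[str]
    name: str = ""
    pag_type: str = "G"
    source: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.id!r} has no members")
        if self.pag_type not in PAG_TYPES:
            raise ValidationError(
                f"gene set {self.id!r}: pag_type must be one of {PAG_TYPES}, "
                f"got {self.pag_type!r}"
            )

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def is_singleton(self) -> bool:
        return len(self.members) == 1

    def sorted_members(self) -> list[str]:
        return sorted(self.members)


@dataclass
class Corpus:
    """A collection of gene sets over a shared gene universe.

    The universe defaults to the union of all members and may be extended by
    an explicit background; it defines ``N`` for every hypergeometric test.
    """

    sets: list[GeneSet]
    background: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for gs in self.sets:
            if gs.id in seen:
                raise ValidationError(f"duplicate set id {gs.id!r} in corpus")
            seen.add(gs.id)
        self._by_id = {gs.id: gs for gs in self.sets}

    @property
    def universe(self) -> frozenset[str]:
        members: set[str] = set(self.background)
        for gs in self.sets:
            members.update(gs.members)
        return frozenset(members)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __contains__(self, set_id: str) -> bool:
        return set_id in self._by_id

    def __getitem__(self, set_id: str) -> GeneSet:
        return self._by_id[set_id]

    def gene_frequencies(self) -> dict[str, int]:
        """Number of corpus sets containing each gene."""
        freq: dict[str, int] = {}
        for gs in self.sets:
            for g in gs.members:
                freq[g] = freq.get(g, 0) + 1
        return freq

    def membership_index(self) -> dict[str, list[str]]:
        """gene -> sorted list of ids of sets containing it."""
        idx: dict[str, list[str]] = {}
        for gs in self.sets:
            for g in gs.members:
                idx.setdefault(g, []).append(gs.id)
        for ids in idx.values():
            ids.sort()
        return idx


@dataclass
class InteractionNetwork:
    """Undirected confidence-weighted interaction network.

    Edges are stored keyed by lexicographically ordered gene pairs; parallel
    inputs are collapsed keeping the maximum confidence, self-loops dropped.
    """

    _edges: dict[tuple[str, str], float] = field(default_factory=dict)
    dropped_self_loops: int = 0

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add_edge(self, a: str, b: str, confidence: float = 1.0) -> None:
        if not 0.0 <= confidence <= 1.0:
            raise ValidationError(
                f"confidence {confidence} for edge ({a},{b}) outside [0,1]"
            )
        if a == b:
            self.dropped_self_loops += 1
            return
        key = self._key(a, b)
        prev = self._edges.get(key)
        if prev is None or confidence > prev:
            self._edges[key] = confidence

    def has_edge(self, a: str, b: str, min_confidence: float = 0.0) -> bool:
        c = self._edges.get(self._key(a, b))
        return c is not None and c >= min_confidence

    def confidence(self, a: str, b: str) -> float | None:
        return self._edges.get(self._key(a, b))

    def edges(self, min_confidence: float = 0.0) -> Iterable[tuple[str, str, float]]:
        for (a, b), c in self._edges.items():
            if c >= min_confidence:
                yield a, b, c

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def nodes(self) -> set[str]:
        out: set[str] = set()
        for a, b in self._edges:
            out.add(a)
            out.add(b)
        return out

    def neighbors(self, gene: str, min_confidence: float = 0.0) -> set[str]:
        out = set()
        for (a, b), c in self._edges.items():
            if c < min_confidence:
                continue
            if a == gene:
                out.add(b)
            elif b == gene:
                out.add(a)
        return out

    def to_networkx(self, min_confidence: float = 0.0):
        import networkx as nx

        g = nx.Graph()
        for a, b, c in self.edges(min_confidence):
            g.add_edge(a, b, confidence=c)
        return g


@dataclass
class RegulationNetwork:
    """Directed regulator -> target edges (unweighted)."""

    _edges: set[tuple[str, str]] = field(default_factory=set)
    dropped_self_loops: int = 0

    def add_edge(self, regulator: str, target: str) -> None:
        if regulator == target:
            self.dropped_self_loops += 1
            return
        self._edges.add((regulator, target))

    @property
    def edges(self) -> set[tuple[str, str]]:
        return self._edges

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self._edges


def _parse_description(raw: str) -> tuple[str, str]:
    """Split an optional ``type=P|A|G`` token off a GMT description."""
    m = _TYPE_TOKEN.search(raw)
    if m is None:
        return "G", raw.strip()
    return m.group(1), _TYPE_TOKEN.sub("", raw, count=1).strip()


def read_gmt(path: str | Path, background: Iterable[str] | None = None) -> Corpus:
    """Read a GMT file into a :class:`Corpus`.

    Duplicate genes within a line are deduplicated, symbols uppercased, and
    the set type parsed from an optional ``type=P|A|G`` token in the
    description field (default ``G``).

    Raises
    ------
    ParseError
        If a line has fewer than three tab-separated fields or a set id
        repeats.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    seen_ids: set[str] = set()
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields "
                    f"(id, description, genes), got {len(fields)}"
                )
            set_id = fields[0].strip()
            if set_id in seen_ids:
                raise ParseError(f"{path}:{lineno}: duplicate set id {set_id!r}")
            seen_ids.add(set_id)
            pag_type, description = _parse_description(fields[1])
            members = frozenset(
                normalize_symbol(g) for g in fields[2:] if g.strip()
            )
            if not members:
                raise ParseError(f"{path}:{lineno}: set {set_id!r} has no genes")
            sets.append(
                GeneSet(
                    id=set_id,
                    name=set_id,
                    pag_type=pag_type,
                    description=description,
                    members=members,
                )
            )
    bg = frozenset(normalize_symbol(g) for g in background) if background else frozenset()
    return Corpus(sets=sets, background=bg)


def write_gmt(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus as GMT, members in sorted order (canonical form).

    The set type is embedded as a ``type=X`` description prefix so that
    ``read_gmt(write_gmt(c))`` is the identity.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for gs in corpus.sets:
            desc = f"type={gs.pag_type}"
            if gs.description:
                desc += f"; {gs.description}"
            fh.write("\t".join([gs.id, desc, *gs.sorted_members()]) + "\n")


def _network_rows(path: Path):
    with path.open("r", encoding="utf-8") as fh:
        first_data = True
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (2, 3):
                raise ParseError(
                    f"{path}:{lineno}: expected 2 or 3 tab-separated columns, "
                    f"got {len(fields)}"
                )
            if first_data and len(fields) == 3:
                # tolerate a header row: third column not numeric
                try:
                    float(fields[2])
                except ValueError:
                    first_data = False
                    continue
            first_data = False
            yield lineno, fields


def read_network(
    path: str | Path, directed: bool = False
) -> InteractionNetwork | RegulationNetwork:
    """Read a 2/3-column edge TSV.

    Undirected mode collapses ``(a,b)``/``(b,a)`` keeping the maximum
    confidence; a missing confidence column defaults to 1.0; self-loops are
    dropped with a logged count. Directed mode ignores confidences.
    """
    path = Path(path)
    net: InteractionNetwork | RegulationNetwork
    net = RegulationNetwork() if directed else InteractionNetwork()
    for lineno, fields in _network_rows(path):
        a = normalize_symbol(fields[0])
        b = normalize_symbol(fields[1])
        if directed:
            net.add_edge(a, b)
        else:
            conf = 1.0
            if len(fields) == 3:
                try:
                    conf = float(fields[2])
                except ValueError as exc:
                    raise ParseError(
                        f"{path}:{lineno}: bad confidence {fields[2]!r}"
                    ) from exc
                if not 0.0 <= conf <= 1.0:
                    raise ValidationError(
                        f"{path}:{lineno}: confidence {conf} outside [0,1]"
                    )
            net.add_edge(a, b, conf)
    if net.dropped_self_loops:
        logger.info(
            "read_network(%s): dropped %d self-loop(s)", path, net.dropped_self_loops
        )
    return net


def write_network(
    net: InteractionNetwork | RegulationNetwork, path: str | Path
) -> None:
    """Write an edge TSV in deterministic (sorted) order."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        if isinstance(net, RegulationNetwork):
            for a, b in sorted(net.edges):
                fh.write(f"{a}\t{b}\n")
        else:
            for a, b, c in sorted(net.edges()):
                fh.write(f"{a}\t{b}\t{c:.6g}\n")


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-symbol-per-line gene list (deduplicated, order preserved)."""
    path = Path(path)
    out: list[str] = []
    seen: set[str] = set()
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sym = normalize_symbol(line)
            if sym not in seen:
                seen.add(sym)
                out.append(sym)
    return out
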