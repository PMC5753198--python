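"""Deterministic synthetic corpora, networks and queries for testing.

Generates a gene-set collection with a log-uniform size distribution
(optionally spiked at a fixed size to mimic curated-signature inflation), a
scale-free-like interaction network with planted cohesive modules, and a
regulation network with planted cross-set regulation. Every output is a pure
function of the seed, so fixtures are reproduced byte-identically at test
time instead of being checked in.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np

from .cohesion import CohesionRecord, theoretical_pairs, theoretical_trios
from .corpus_io import (
    Corpus,
    GeneSet,
    InteractionNetwork,
    RegulationNetwork,
    write_gmt,
    write_network,
)


class SynthConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SynthConfig:
    seed: int = 0
    n_genes: int = 2000
    n_sets: int = 150
    size_min: int = 1
    size_max: int = 300
    singleton_fraction: float = 0.1
    spike_size: int = 200
    spike_fraction: float = 0.0
    ppi_attach: int = 3
    confidence_range: tuple[float, float] = (0.5, 1.0)
    planted_module_fraction: float = 0.2
    planted_density: float = 0.5
    planted_confidence_range: tuple[float, float] = (0.8, 1.0)
    regulation_edges: int = 500
    planted_regulation_pairs: tuple[tuple[int, int], ...] = ()
    planted_regulation_density: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.planted_module_fraction <= 1:
            raise SynthConfigError("planted_module_fraction must be in [0,1]")
        if not 0 <= self.planted_density <= 1:
            raise SynthConfigError("planted_density must be in [0,1]")
        if not 0 <= self.singleton_fraction <= 1:
            raise SynthConfigError("singleton_fraction must be in [0,1]")
        if self.size_min < 1 or self.size_max < self.size_min:
            raise SynthConfigError("need 1 <= size_min <= size_max")
        if self.size_max > self.n_genes:
            raise SynthConfigError("size_max cannot exceed n_genes")


@dataclass
class SynthData:
    corpus: Corpus
    ppi: InteractionNetwork
    regulation: RegulationNetwork
    truth: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        """Write GMT/TSV fixtures plus the truth-labels JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_gmt(self.corpus, outdir / "corpus.gmt")
        write_network(self.ppi, outdir / "ppi.tsv")
        write_network(self.regulation, outdir / "regulation.tsv")
        (outdir / "truth.json").write_text(
            json.dumps(self.truth, indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )


def _draw_sizes(cfg: SynthConfig, rng: np.random.Generator) -> list[int]:
    sizes: list[int] = []
    lo = math.log2(max(2, cfg.size_min))
    hi = math.log2(cfg.size_max) if cfg.size_max > 1 else lo
    for _ in range(cfg.n_sets):
        u = rng.random()
        if u < cfg.singleton_fraction and cfg.size_min == 1:
            sizes.append(1)
        elif u < cfg.singleton_fraction + cfg.spike_fraction:
            sizes.append(min(cfg.spike_size, cfg.n_genes))
        else:
            sizes.append(int(round(2.0 ** rng.uniform(lo, hi))))
    return sizes


def generate(cfg: SynthConfig) -> SynthData:
    """Build a corpus, interaction network, regulation network and truth labels.

    Planted cohesive sets receive extra high-confidence edges until their
    induced density reaches ``planted_density``; planted regulation pairs
    ``(i, j)`` receive regulation edges covering ``planted_regulation_density``
    of the ordered cross pairs from set ``i``'s exclusive members to set
    ``j``'s.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = np.array([f"G{i:05d}" for i in range(cfg.n_genes)])

    sizes = _draw_sizes(cfg, rng)
    sets: list[GeneSet] = []
    for i, size in enumerate(sizes):
        members = frozenset(rng.choice(genes, size=size, replace=False).tolist())
        pag_type = ("P", "A", "G")[int(rng.integers(3))]
        sets.append(
            GeneSet(
                id=f"SYN{i:05d}",
                name=f"SYN{i:05d}",
                pag_type=pag_type,
                source="synthetic",
                members=members,
            )
        )
    corpus = Corpus(sets=sets, background=frozenset(genes.tolist()))

    # scale-free-ish backbone via preferential attachment
    ba_seed = int(rng.integers(2**31 - 1))
    backbone = nx.barabasi_albert_graph(cfg.n_genes, cfg.ppi_attach, seed=ba_seed)
    ppi = InteractionNetwork()
    c_lo, c_hi = cfg.confidence_range
    for u, v in sorted(backbone.edges()):
        ppi.add_edge(str(genes[u]), str(genes[v]), float(rng.uniform(c_lo, c_hi)))

    # plant cohesive modules: top up induced edges to the target density
    regular = [gs for gs in sets if gs.size >= 3]
    n_planted = int(round(cfg.planted_module_fraction * len(regular)))
    planted = regular[:n_planted]  # deterministic choice
    p_lo, p_hi = cfg.planted_confidence_range
    for gs in planted:
        mem = gs.sorted_members()
        all_pairs = [
            (mem[i], mem[j])
            for i in range(len(mem))
            for j in range(i + 1, len(mem))
        ]
        target = math.ceil(cfg.planted_density * len(all_pairs))
        chosen = rng.choice(len(all_pairs), size=target, replace=False)
        for pi in sorted(chosen.tolist()):
            a, b = all_pairs[pi]
            ppi.add_edge(a, b, float(rng.uniform(p_lo, p_hi)))

    # regulation: random background plus planted dense cross-set blocks
    reg = RegulationNetwork()
    while reg.n_edges < cfg.regulation_edges:
        u, v = rng.choice(cfg.n_genes, size=2, replace=False)
        reg.add_edge(str(genes[u]), str(genes[v]))
    planted_reg: list[list[str]] = []
    for i, j in cfg.planted_regulation_pairs:
        a, b = sets[i], sets[j]
        a_only = sorted(a.members - b.members)
        b_only = sorted(b.members - a.members)
        cross = [(u, v) for u in a_only for v in b_only]
        if not cross:
            raise SynthConfigError(
                f"planted regulation pair ({i},{j}) has no cross pairs"
            )
        target = math.ceil(cfg.planted_regulation_density * len(cross))
        chosen = rng.choice(len(cross), size=target, replace=False)
        for ci in sorted(chosen.tolist()):
            reg.add_edge(*cross[ci])
        planted_reg.append([a.id, b.id])

    truth = {
        "planted_cohesive": sorted(gs.id for gs in planted),
        "planted_regulation": planted_reg,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(cfg).items()
        },
    }
    return SynthData(corpus=corpus, ppi=ppi, regulation=reg, truth=truth)


def synth_cohesion_records(
    seed: int,
    n_sets: int = 2000,
    size_min: int = 2,
    size_max: int = 1000,
    intercept: float = 1.0,
    slope: float = 1.5,
    sigma: float = 0.4,
) -> list[CohesionRecord]:
    """Cohesion records with a planted power-law size trend plus log-normal noise.

    ``log2(score) = intercept + slope * log2(size) + Normal(0, sigma)`` —
    a stand-in corpus for exercising the size normalizer where only the
    score-versus-size relationship matters.
    """
    rng = np.random.default_rng(seed)
    records: list[CohesionRecord] = []
    lo, hi = math.log2(size_min), math.log2(size_max)
    for i in range(n_sets):
        n = int(round(2.0 ** rng.uniform(lo, hi)))
        log2_coco = intercept + slope * math.log2(n) + rng.normal(0.0, sigma)
        records.append(
            CohesionRecord(
                set_id=f"SIM{i:05d}",
                n=n,
                theoretical_pairs=theoretical_pairs(n),
                observed_pairs=0,
                theoretical_trios=theoretical_trios(n),
                observed_trios=0,
                coco=float(2.0**log2_coco),
            )
        )
    return records


def reference_config(seed: int = 42) -> SynthConfig:
    """The reference configuration used by the CLI smoke pipeline and tests."""
    return SynthConfig(
        seed=seed,
        n_genes=800,
        n_sets=60,
        size_min=1,
        size_max=120,
        singleton_fraction=0.15,
        spike_fraction=0.05,
        spike_size=100,
        ppi_attach=3,
        planted_module_fraction=0.25,
        planted_density=0.5,
        regulation_edges=400,
        planted_regulation_pairs=((2, 5), (7, 11)),
        planted_regulation_density=0.6,
    )
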