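"""Corpus comparison and summary reports.

Fold changes are truncated (not rounded) to two decimals and percent
increase ratios floored to integers — the reproduction convention for
published version-comparison tables (3.0674 -> 3.06, 5.1896 -> 518%).
Both use integer arithmetic to dodge binary-float edge cases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .cohesion import CohesionRecord
from .corpus_io import Corpus
from .setnetwork import SetEdge, classify_and_count


def fold_change(new: int, old: int) -> float:
    """new/old truncated to two decimals."""
    if old <= 0:
        raise ValueError(f"fold change undefined for old count {old}")
    if new < 0:
        raise ValueError(f"counts must be nonnegative, got new={new}")
    return (100 * new // old) / 100


def increase_pct(new: int, old: int) -> int:
    """floor(100 * new / old) as an integer percent."""
    if old <= 0:
        raise ValueError(f"increase ratio undefined for old count {old}")
    if new < 0:
        raise ValueError(f"counts must be nonnegative, got new={new}")
    return 100 * new // old


@dataclass(frozen=True)
class CorpusComparison:
    category: str
    count_old: int
    count_new: int

    @property
    def fold_change(self) -> float:
        return fold_change(self.count_new, self.count_old)

    @property
    def increase_pct(self) -> int:
        return increase_pct(self.count_new, self.count_old)


def corpus_summary(
    corpus: Corpus,
    cohesion: Sequence[CohesionRecord] | None = None,
    m_edges: Sequence[SetEdge] | None = None,
    r_edges: Sequence[SetEdge] | None = None,
) -> dict[str, int]:
    """Category counts for a corpus and its derived artifacts."""
    singles = sum(1 for gs in corpus if gs.is_singleton)
    out: dict[str, int] = {
        "genes": len(corpus.universe),
        "sets": len(corpus),
        "singleton_sets": singles,
        "regular_sets": len(corpus) - singles,
    }
    if cohesion is not None:
        out["sets_with_cohesion"] = sum(1 for r in cohesion if r.coco > 0)
        out["sets_with_cohesion_ge_1"] = sum(1 for r in cohesion if r.coco >= 1)
        out["sets_with_ncoco_gt_1"] = sum(
            1 for r in cohesion if not math.isnan(r.ncoco) and r.ncoco > 1
        )
    if m_edges is not None:
        out["m_type_edges"] = len(m_edges)
    if r_edges is not None:
        out["r_type_edges"] = len(r_edges)
        counts = classify_and_count(r_edges, corpus)
        out["r_type_s_to_m"] = counts["s->m"]
        out["r_type_m_to_m"] = counts["m->m"]
        out["r_type_m_to_s"] = counts["m->s"]
        out["r_type_s_to_s"] = counts["s->s"]
    return out


def write_summary(summary: Mapping[str, int], path: str | Path, fmt: str = "csv") -> None:
    path = Path(path)
    if fmt == "csv":
        lines = ["category,count"] + [f"{k},{v}" for k, v in summary.items()]
    elif fmt == "markdown":
        lines = ["| category | count |", "| --- | --- |"] + [
            f"| {k} | {v} |" for k, v in summary.items()
        ]
    else:
        raise ValueError(f"format must be 'csv' or 'markdown', got {fmt!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def comparison_table(
    counts_old: Mapping[str, int], counts_new: Mapping[str, int]
) -> list[CorpusComparison]:
    """Pair up two summaries into comparison rows (shared categories only)."""
    rows = []
    for cat in counts_old:
        if cat in counts_new and counts_old[cat] > 0:
            rows.append(
                CorpusComparison(
                    category=cat,
                    count_old=counts_old[cat],
                    count_new=counts_new[cat],
                )
            )
    return rows
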