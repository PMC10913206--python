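"""Summary statistics over the compiled knowledge base.

Reports entity totals, the per-food and per-drug interaction-count
distributions (mean, quartiles, maximum), ranked top-k tables and the share
of all interactions the top-k entities account for.  Quartiles use linear
interpolation between order statistics; percentages are rounded half-up to
integers.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .kb import KnowledgeBase
from .mapping import round_half_up_pct


@dataclass
class Distribution:
    n: int
    mean: float  # reported to 1 decimal
    q1: float
    median: float
    q3: float
    max: int
    defined: bool = True


@dataclass
class KbStats:
    totals: dict[str, int]
    per_food: dict[str, int]
    per_drug: dict[str, int]
    dist: dict[str, Distribution]
    topk: dict[str, list[tuple[str, int]]]
    coverage_pct: dict[str, int]

    def as_dict(self) -> dict:
        return {
            "totals": dict(self.totals),
            "per_food": dict(self.per_food),
            "per_drug": dict(self.per_drug),
            "dist": {
                k: {
                    "n": d.n, "mean": d.mean, "q1": d.q1, "median": d.median,
                    "q3": d.q3, "max": d.max, "defined": d.defined,
                }
                for k, d in self.dist.items()
            },
            "topk": {k: [[lab, c] for lab, c in v] for k, v in self.topk.items()},
            "coverage_pct": dict(self.coverage_pct),
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.as_dict(), indent=2, ensure_ascii=False), encoding="utf-8"
        )


_UNDEFINED = Distribution(0, 0.0, 0.0, 0.0, 0.0, 0, defined=False)


def _distribution(counts: Sequence[int]) -> Distribution:
    if not counts:
        return _UNDEFINED
    arr = np.asarray(sorted(counts), dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])  # type-7 linear interpolation
    return Distribution(
        n=len(counts),
        mean=round(float(arr.mean()), 1),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        max=int(arr.max()),
    )


def top_k(counts: Mapping[str, int], k: int) -> list[tuple[str, int]]:
    """k largest entries; ties broken deterministically (count desc, label asc)."""
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]


def top_k_coverage(
    counts: Sequence[int] | Mapping[str, int], k: int, total_fdis: int
) -> tuple[int, int]:
    """(sum of the k largest counts, integer percent of all interactions).

    The percentage is round-half-up; a zero interaction total makes the
    percentage undefined (reported as -1 by convention here, flagged by the
    caller).
    """
    values = sorted(
        counts.values() if isinstance(counts, Mapping) else counts, reverse=True
    )
    if k > len(values):
        raise ValueError(f"k={k} exceeds the {len(values)} available counts")
    s = sum(values[:k])
    if total_fdis == 0:
        return s, -1
    if s > total_fdis:
        raise ValueError("top-k sum exceeds the interaction total")
    return s, round_half_up_pct(s, total_fdis)


def compute_stats(kb: KnowledgeBase, k: int = 10) -> KbStats:
    """Deterministic KB summary; an empty KB yields all-zero totals."""
    per_food: dict[str, int] = {}
    per_drug: dict[str, int] = {}
    for fdi in kb.fdis:
        per_food[fdi.food_curie] = per_food.get(fdi.food_curie, 0) + 1
        per_drug[fdi.drug_curie] = per_drug.get(fdi.drug_curie, 0) + 1

    label = {c: n.label for c, n in kb.concepts.items()}
    food_counts_by_label = {label.get(c, c): n for c, n in per_food.items()}
    drug_counts_by_label = {label.get(c, c): n for c, n in per_drug.items()}

    n_fdis = len(kb.fdis)
    totals = {
        "drugs": len(kb.nodes_of_kind("drug")),
        "foods_herbs": len(kb.nodes_of_kind("food")) + len(kb.nodes_of_kind("herb")),
        "fdis": n_fdis,
        "sources": len(kb.sources),
    }
    topk = {
        "foods": top_k(food_counts_by_label, min(k, len(food_counts_by_label))),
        "drugs": top_k(drug_counts_by_label, min(k, len(drug_counts_by_label))),
    }
    coverage: dict[str, int] = {}
    for kind in ("foods", "drugs"):
        if n_fdis and topk[kind]:
            _, pct = top_k_coverage(
                [c for _, c in topk[kind]], len(topk[kind]), n_fdis
            )
            coverage[kind] = pct
        else:
            coverage[kind] = 0
    return KbStats(
        totals=totals,
        per_food=per_food,
        per_drug=per_drug,
        dist={
            "foods": _distribution(list(per_food.values())),
            "drugs": _distribution(list(per_drug.values())),
        },
        topk=topk,
        coverage_pct=coverage,
    )


def render_markdown(stats: KbStats) -> str:
    """Markdown tables mirroring the usual summary layout."""
    lines = ["| Entity | Count |", "|---|---|"]
    for name, count in stats.totals.items():
        lines.append(f"| {name} | {count} |")
    for kind in ("foods", "drugs"):
        lines += [
            "",
            f"| {kind[:-1].capitalize()} | Interactions |",
            "|---|---|",
        ]
        total = 0
        for lab, c in stats.topk[kind]:
            lines.append(f"| {lab} | {c} |")
            total += c
        lines.append(f"| Total (percentage) | {total} ({stats.coverage_pct[kind]}%) |")
    return "\n".join(lines) + "\n"
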