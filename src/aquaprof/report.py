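"""Aggregation of profile results: coverage, flow tables and per-inventory
domain proportions."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .profiler import ProfileResult

__all__ = [
    "CoverageSummary",
    "coverage_summary",
    "sankey_flows",
    "domain_proportions",
    "DOMAIN_CATEGORIES",
]

DOMAIN_CATEGORIES = ("narcosis", "reactive", "specific", "unclassified")


@dataclass
class CoverageSummary:
    """Inventory-level classification statistics.

    A compound counts once towards every domain/group/subgroup it touches,
    so category counts may sum to more than ``n_classified``.
    """

    n_total: int
    n_classified: int
    n_unclassified: int
    pct_unclassified: float
    empty_input: bool
    histogram: dict[str, int]  # binned: "1", "2", "3+"
    alerts_per_compound: dict[int, int]  # full distribution
    per_domain: dict[str, int]
    per_group: dict[str, int]
    per_subgroup: dict[str, int]
    taxa_counts: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_classified": self.n_classified,
            "n_unclassified": self.n_unclassified,
            "pct_unclassified": self.pct_unclassified,
            "empty_input": self.empty_input,
            "histogram": dict(self.histogram),
            "alerts_per_compound": {str(k): v for k, v in sorted(self.alerts_per_compound.items())},
            "per_domain": dict(self.per_domain),
            "per_group": dict(self.per_group),
            "per_subgroup": dict(self.per_subgroup),
            "taxa_counts": dict(self.taxa_counts),
        }


def coverage_summary(results: Sequence[ProfileResult]) -> CoverageSummary:
    """Tally classification coverage over a set of profile results."""
    n_total = len(results)
    n_classified = sum(1 for r in results if r.matches)
    n_unclassified = n_total - n_classified
    per_domain: Counter = Counter()
    per_group: Counter = Counter()
    per_subgroup: Counter = Counter()
    taxa: Counter = Counter()
    dist: Counter = Counter()
    for r in results:
        if not r.matches:
            continue
        dist[len(r.matches)] += 1
        for name in {m.domain_name for m in r.matches}:
            per_domain[name] += 1
        for gid in {m.group_id for m in r.matches}:
            per_group[gid] += 1
        for sid in {m.subgroup_id for m in r.matches}:
            per_subgroup[sid] += 1
        for label in {t for m in r.matches for t in m.taxa}:
            taxa[label] += 1
    histogram = {
        "1": dist.get(1, 0),
        "2": dist.get(2, 0),
        "3+": sum(v for k, v in dist.items() if k >= 3),
    }
    return CoverageSummary(
        n_total=n_total,
        n_classified=n_classified,
        n_unclassified=n_unclassified,
        pct_unclassified=(100.0 * n_unclassified / n_total) if n_total else 0.0,
        empty_input=n_total == 0,
        histogram=histogram,
        alerts_per_compound=dict(dist),
        per_domain=dict(per_domain),
        per_group=dict(per_group),
        per_subgroup=dict(per_subgroup),
        taxa_counts=dict(taxa),
    )


def sankey_flows(
    results: Sequence[ProfileResult], inventory_name: str = "inventory"
) -> pd.DataFrame:
    """Flow table for a Sankey-style rendering of the classification cascade.

    Rows are ``(source_node, target_node, count)`` edges across the levels
    inventory → domain → group → subgroup.  Multi-membership is preserved:
    a compound matching two groups contributes one unit to each group edge,
    so lower-level totals may exceed the compound count at the level above.
    Unclassified compounds flow to a terminal ``unclassified`` node.
    """
    edges: Counter = Counter()
    for r in results:
        if not r.matches:
            edges[(inventory_name, "unclassified")] += 1
            continue
        for dom in {m.domain_name for m in r.matches}:
            edges[(inventory_name, dom)] += 1
        for dom, grp in {(m.domain_name, f"{m.group_id} {m.group_name}") for m in r.matches}:
            edges[(dom, grp)] += 1
        for grp, sub in {
            (f"{m.group_id} {m.group_name}", f"{m.subgroup_id} {m.subgroup_name}")
            for m in r.matches
        }:
            edges[(grp, sub)] += 1
    rows = [
        {"source_node": s, "target_node": t, "count": c}
        for (s, t), c in sorted(edges.items())
    ]
    return pd.DataFrame(rows, columns=["source_node", "target_node", "count"])


def domain_proportions(
    named_results: Mapping[str, Sequence[ProfileResult]],
    mode: str = "exclusive",
) -> pd.DataFrame:
    """Per-inventory Tier 1 domain proportions.

    ``mode="exclusive"`` (default): a compound is attributed to each domain
    it touches and the denominator is the number of compound-domain
    incidences, so each inventory's proportions sum to exactly 1.
    ``mode="multi_label"``: the denominator is the number of compounds, so
    proportions may sum to more than 1 when compounds span domains.
    """
    if mode not in ("exclusive", "multi_label"):
        raise ValueError(f"unknown mode {mode!r}")
    rows = []
    for name, results in named_results.items():
        if not len(results):
            raise ValueError(f"inventory {name!r} is empty")
        incidences: Counter = Counter()
        for r in results:
            if not r.matches:
                incidences["unclassified"] += 1
            else:
                for dom in {m.domain_name for m in r.matches}:
                    incidences[dom] += 1
        denom = sum(incidences.values()) if mode == "exclusive" else len(results)
        for category in DOMAIN_CATEGORIES:
            rows.append(
                {
                    "inventory_name": name,
                    "category": category,
                    "proportion": incidences.get(category, 0) / denom,
                }
            )
    return pd.DataFrame(rows, columns=["inventory_name", "category", "proportion"])
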