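"""Three-way comparison of OTU partitions.

The three engines' partitions over the same specimens are joined into
comparison units: connected components of the graph in which each method
contributes an edge between every pair of specimens it co-clusters. Every
OTU of every method lies entirely inside one unit, so units can be
categorized independently:

* FULL — all three induced sub-partitions identical;
* PARTIAL — exactly two identical (they define the majority sub-partition);
* DISCORDANT — all three pairwise different.

OTU bookkeeping follows the source protocol: a FULL unit contributes its
agreed OTU count, a PARTIAL unit its majority sub-partition's count, and a
DISCORDANT unit counts as a single OTU. The finest competing sub-partition
of a PARTIAL unit is carried forward as the split candidate for the
resolution stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import pandas as pd

from .seq_io import Partition

CATEGORIES = ("FULL", "PARTIAL", "DISCORDANT")


@dataclass
class ComparisonUnit:
    unit_id: int
    members: list[str]  # in input order
    sub_partitions: dict[str, frozenset[frozenset[str]]]
    category: str = ""
    majority: frozenset[frozenset[str]] | None = None
    split_candidate: frozenset[frozenset[str]] | None = None


@dataclass
class ConsensusReport:
    units: list[ComparisonUnit]
    methods: list[str]
    partitions: dict[str, Partition] = field(default_factory=dict)

    def counts(self, partial_rule: str = "majority") -> pd.DataFrame:
        return category_counts(self, partial_rule)

    def units_by_category(self, category: str) -> list[ComparisonUnit]:
        return [u for u in self.units if u.category == category]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "methods": self.methods,
            "units": [{
                "unit_id": u.unit_id,
                "members": u.members,
                "category": u.category,
                "sub_partitions": {m: [sorted(b) for b in sorted(p, key=sorted)]
                                   for m, p in u.sub_partitions.items()},
                "split_candidate": [sorted(b) for b in
                                    sorted(u.split_candidate, key=sorted)]
                if u.split_candidate else None,
            } for u in self.units],
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "ConsensusReport":
        payload = json.loads(Path(path).read_text())
        units = []
        for u in payload["units"]:
            subs = {m: frozenset(frozenset(b) for b in blocks)
                    for m, blocks in u["sub_partitions"].items()}
            unit = ComparisonUnit(u["unit_id"], u["members"], subs,
                                  u["category"])
            if u.get("split_candidate"):
                unit.split_candidate = frozenset(
                    frozenset(b) for b in u["split_candidate"])
            counts = {}
            for m, p in subs.items():
                counts.setdefault(p, []).append(m)
            for p, ms in counts.items():
                if len(ms) >= 2 and len(counts) > 1:
                    unit.majority = p
            if unit.category == "FULL":
                unit.majority = next(iter(subs.values()))
            units.append(unit)
        return cls(units, payload["methods"])

    def write_tsv(self, path: str | Path) -> pd.DataFrame:
        rows = []
        for u in self.units:
            per_method = {}
            for m, sub in u.sub_partitions.items():
                block_id = {sid: i + 1
                            for i, b in enumerate(sorted(sub, key=sorted))
                            for sid in b}
                per_method[m] = block_id
            for sid in u.members:
                row = {"unit": u.unit_id, "specimen_id": sid,
                       "category": u.category}
                for m in self.methods:
                    row[f"otu_{m}"] = per_method[m][sid]
                rows.append(row)
        df = pd.DataFrame(rows)
        df.to_csv(path, sep="\t", index=False)
        return df


def comparison_units(partitions: Sequence[Partition]) -> list[ComparisonUnit]:
    """Join exactly three partitions into comparison units."""
    if len(partitions) != 3:
        raise ValueError("exactly three partitions are required")
    specimen_sets = [frozenset(p.assignment) for p in partitions]
    if len(set(specimen_sets)) != 1:
        diff = sorted(specimen_sets[0] ^ specimen_sets[1] |
                      specimen_sets[0] ^ specimen_sets[2])
        raise ValueError(f"partitions cover different specimens: {diff}")
    order = partitions[0].id_order or sorted(specimen_sets[0])
    g = nx.Graph()
    g.add_nodes_from(order)
    for p in partitions:
        for members in p.groups().values():
            for a, b in zip(members, members[1:]):
                g.add_edge(a, b)
    methods = _unique_methods(partitions)
    units = []
    comps = sorted((sorted(c, key=order.index) for c in nx.connected_components(g)),
                   key=lambda c: order.index(c[0]))
    for uid, members in enumerate(comps, start=1):
        subs = {m: p.restrict(members) for m, p in zip(methods, partitions)}
        units.append(ComparisonUnit(uid, list(members), subs))
    return units


def _unique_methods(partitions: Sequence[Partition]) -> list[str]:
    methods = []
    for i, p in enumerate(partitions):
        name = p.method or f"method{i+1}"
        while name in methods:
            name = f"{name}_{i+1}"
        methods.append(name)
    return methods


def categorize(unit: ComparisonUnit) -> str:
    """Assign FULL / PARTIAL / DISCORDANT and record majority + candidate."""
    subs = list(unit.sub_partitions.values())
    distinct: dict[frozenset, int] = {}
    for s in subs:
        distinct[s] = distinct.get(s, 0) + 1
    if len(distinct) == 1:
        unit.category = "FULL"
        unit.majority = subs[0]
        unit.split_candidate = subs[0]
    elif len(distinct) == 3:
        unit.category = "DISCORDANT"
        unit.majority = None
        unit.split_candidate = max(subs, key=len)
    else:
        unit.category = "PARTIAL"
        unit.majority = next(p for p, c in distinct.items() if c == 2)
        # candidate split: the finest competing sub-partition
        unit.split_candidate = max(distinct, key=len)
    return unit.category


def build_report(partitions: Sequence[Partition]) -> ConsensusReport:
    units = comparison_units(partitions)
    for u in units:
        categorize(u)
    methods = _unique_methods(partitions)
    return ConsensusReport(units, methods,
                           {m: p for m, p in zip(methods, partitions)})


def category_counts(report: ConsensusReport,
                    partial_rule: str = "majority") -> pd.DataFrame:
    """Per-category OTU counts and percentages.

    ``partial_rule`` selects whether a PARTIAL unit contributes its
    majority or its finest sub-partition's OTU count.
    """
    if partial_rule not in ("majority", "finest"):
        raise ValueError("partial_rule must be 'majority' or 'finest'")
    counts = dict.fromkeys(CATEGORIES, 0)
    for u in report.units:
        if u.category == "FULL":
            counts["FULL"] += len(u.majority)
        elif u.category == "PARTIAL":
            chosen = u.majority if partial_rule == "majority" else u.split_candidate
            counts["PARTIAL"] += len(chosen)
        else:
            counts["DISCORDANT"] += 1
    total = sum(counts.values())
    return pd.DataFrame([
        {"category": c, "otus": counts[c],
         "percent": round(100.0 * counts[c] / total, 1) if total else 0.0}
        for c in CATEGORIES
    ])
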