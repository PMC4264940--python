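"""Resolution of conflicting OTUs and the final partition.

FULL-match units pass straight into the final partition and DISCORDANT
units collapse to a single OTU each. PARTIAL-match units are resolved on
the sympatry of sister OTUs: the candidate split's sister pairs are read
off a guide tree (innermost pair first); a pair sharing at least one
biogeographic region is kept as two OTUs, an allopatric pair is merged
(including the common case of a lone specimen allopatric from its
multi-member sister). Diagnostic nucleotides and monophyly are computed
for the audit trail but are deliberately not decision-bearing. A
sympatric call can hide microallopatry at finer spatial scales than the
region labels; decisions carry a warning to that effect rather than any
attempt to model it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from skbio import DistanceMatrix as SkbioDM
from skbio.tree import nj as skbio_nj

from .consensus import ConsensusReport
from .distances import DistanceMatrix
from .seq_io import Alignment, Partition, read_tree

MICROALLOPATRY_WARNING = ("sympatric by shared region label; may be "
                          "microallopatric at finer scales")


# ---------------------------------------------------------------------------
# Guide trees

def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree, midpoint-rooted for monophyly queries."""
    if len(dm) < 3:
        raise ValueError("need at least 3 specimens for NJ")
    sk = SkbioDM(dm.d, ids=dm.ids)
    unrooted = skbio_nj(sk)
    tree = read_tree(str(unrooted))
    tree.reroot_at_midpoint(update_bipartitions=True)
    return tree


def is_monophyletic(tree: dendropy.Tree, tips: set[str] | list[str]) -> bool:
    """True iff ``tips`` equals the full leaf set of its MRCA."""
    tips = set(tips)
    labels = {l.taxon.label for l in tree.leaf_node_iter()}
    unknown = tips - labels
    if unknown:
        raise KeyError(f"tips not in tree: {sorted(unknown)}")
    if len(tips) == 1:
        return True
    mrca = tree.mrca(taxa=[l.taxon for l in tree.leaf_node_iter()
                           if l.taxon.label in tips])
    clade = {l.taxon.label for l in mrca.leaf_iter()}
    return clade == tips


# ---------------------------------------------------------------------------
# Diagnostic characters

def diagnostic_sites(alignment: Alignment, group_a: set[str] | list[str],
                     group_b: set[str] | list[str]) -> list[tuple[int, str, str]]:
    """Pure diagnostic positions between two groups.

    A 1-based position qualifies iff the state sets observed in the two
    groups are disjoint; positions where either group shows N or '-' are
    ignored. Returns (position, states_in_a, states_in_b) tuples.
    """
    a, b = set(group_a), set(group_b)
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    if a & b:
        raise ValueError(f"groups overlap: {sorted(a & b)}")
    seqs_a = [alignment.get(s).sequence for s in sorted(a)]
    seqs_b = [alignment.get(s).sequence for s in sorted(b)]
    out = []
    for col in range(alignment.length):
        states_a = {s[col] for s in seqs_a}
        states_b = {s[col] for s in seqs_b}
        if states_a & {"N", "-"} or states_b & {"N", "-"}:
            continue
        if not (states_a & states_b):
            out.append((col + 1, "".join(sorted(states_a)),
                        "".join(sorted(states_b))))
    return out


# ---------------------------------------------------------------------------
# Sister pairs and sympatry

def sister_pairs(tree: dendropy.Tree,
                 groups: list[frozenset[str]]) -> list[tuple[frozenset[str], frozenset[str]]]:
    """Sister pairs among candidate sub-OTUs, innermost first.

    Groups are agglomerated by repeatedly pairing the two whose joint MRCA
    subtends the fewest of the unit's tips, mirroring how nested sisters
    are read off a guide tree (on a ladder, the innermost cherry first).
    A merged pair continues as one meta-group for the next round.
    """
    groups = [frozenset(g) for g in groups]
    labels = {l.taxon.label for l in tree.leaf_node_iter()}
    for g in groups:
        missing = set(g) - labels
        if missing:
            raise KeyError(f"sub-OTU members absent from tree: {sorted(missing)}")
    if len(groups) < 2:
        return []
    taxa = {l.taxon.label: l.taxon for l in tree.leaf_node_iter()}

    def mrca_size(tips: frozenset[str]) -> int:
        if len(tips) == 1:
            return 1
        node = tree.mrca(taxa=[taxa[t] for t in tips])
        return sum(1 for _ in node.leaf_iter())

    current = list(groups)
    pairs = []
    while len(current) > 1:
        best = None
        for i in range(len(current)):
            for j in range(i + 1, len(current)):
                size = mrca_size(current[i] | current[j])
                key = (size, sorted(current[i] | current[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        a, b = sorted((current[i], current[j]), key=lambda g: sorted(g))
        pairs.append((a, b))
        merged = current[i] | current[j]
        current = [g for idx, g in enumerate(current) if idx not in (i, j)]
        current.append(merged)
    return pairs


def sympatry(regions_a: set[str], regions_b: set[str]) -> bool:
    """Sister OTUs are sympatric iff their region sets intersect."""
    if not regions_a or not regions_b:
        raise ValueError("both OTUs need at least one region label")
    return bool(regions_a & regions_b)


# ---------------------------------------------------------------------------
# Resolution

@dataclass
class ResolutionDecision:
    unit_id: int
    pair: tuple[frozenset[str], frozenset[str]]
    regions_a: set[str]
    regions_b: set[str]
    sympatric: bool
    decision: str  # SPLIT_KEPT or MERGED
    singleton_merge: bool = False
    diagnostic_count: int = 0
    diagnostics_low_confidence: bool = False
    monophyly: tuple[bool, bool] = (True, True)
    warning: str = ""


@dataclass
class FinalPartition:
    partition: Partition
    bookkeeping: dict[str, int] = field(default_factory=dict)

    @property
    def n_otus(self) -> int:
        return self.partition.n_otus


def _region_set(members: frozenset[str], regions: dict[str, str | None],
                unit_id: int) -> set[str]:
    missing = [m for m in sorted(members) if not regions.get(m)]
    if missing:
        raise ValueError(f"missing region labels for specimens {missing} "
                         f"(comparison unit {unit_id})")
    return {regions[m] for m in members}


def resolve(report: ConsensusReport, tree: dendropy.Tree,
            alignment: Alignment, regions: dict[str, str | None] | None = None,
            ) -> tuple[FinalPartition, list[ResolutionDecision]]:
    """Resolve PARTIAL and DISCORDANT units into the final partition.

    ``regions`` maps specimen id to a biogeographic region label; defaults
    to the alignment's annotations. Required for every member of a PARTIAL
    unit; FULL and DISCORDANT units do not consult geography.
    """
    regions = regions if regions is not None else alignment.regions()
    final_groups: list[list[str]] = []
    decisions: list[ResolutionDecision] = []
    book = {"FULL": 0, "PARTIAL_SPLIT": 0, "PARTIAL_MERGED": 0,
            "DISCORDANT": 0}
    order = []
    for u in report.units:
        order.extend(u.members)
    for u in report.units:
        if u.category == "FULL":
            blocks = [sorted(b, key=u.members.index) for b in u.majority]
            final_groups.extend(blocks)
            book["FULL"] += len(blocks)
            continue
        if u.category == "DISCORDANT":
            final_groups.append(list(u.members))
            book["DISCORDANT"] += 1
            continue
        # PARTIAL: evaluate the candidate split's sister pairs
        candidate = [frozenset(b) for b in u.split_candidate]
        if len(candidate) == 1:
            final_groups.append(list(u.members))
            book["PARTIAL_MERGED"] += 1
            continue
        pairs = sister_pairs(tree, candidate)
        live: list[set[str]] = [set(g) for g in candidate]

        taxa = {l.taxon.label: l.taxon for l in tree.leaf_node_iter()}

        def span(tips: set[str]) -> int:
            if len(tips) == 1:
                return 1
            node = tree.mrca(taxa=[taxa[t] for t in tips])
            return sum(1 for _ in node.leaf_iter())

        for a, b in pairs:
            # sides of a nested pair may by now cover several live groups
            # (earlier kept splits) or share one (earlier merges)
            ia = {i for i, g in enumerate(live) if g & a}
            ib = {i for i, g in enumerate(live) if g & b}
            if ia & ib:
                continue  # an earlier decision already joined the sides
            ga = set().union(*(live[i] for i in ia))
            gb = set().union(*(live[i] for i in ib))
            ra = _region_set(frozenset(ga), regions, u.unit_id)
            rb = _region_set(frozenset(gb), regions, u.unit_id)
            symp = sympatry(ra, rb)
            diag = diagnostic_sites(alignment, ga, gb)
            low_conf = min(len(ga), len(gb)) == 1
            mono = (is_monophyletic(tree, ga), is_monophyletic(tree, gb))
            decision = ResolutionDecision(
                unit_id=u.unit_id, pair=(frozenset(ga), frozenset(gb)),
                regions_a=ra, regions_b=rb, sympatric=symp,
                decision="SPLIT_KEPT" if symp else "MERGED",
                singleton_merge=(not symp) and low_conf,
                diagnostic_count=len(diag),
                diagnostics_low_confidence=low_conf,
                monophyly=mono,
                warning=MICROALLOPATRY_WARNING if symp else "")
            decisions.append(decision)
            if not symp:
                # merge the allopatric sides, but never collapse an earlier
                # kept split: each side contributes its phylogenetically
                # closest live group (smallest joint clade on the guide
                # tree) and only those two are fused
                pa = min(ia, key=lambda i: (span(live[i] | gb),
                                            sorted(live[i])))
                pb = min(ib, key=lambda i: (span(live[i] | live[pa]),
                                            sorted(live[i])))
                merged = live[pa] | live[pb]
                live = [g for i, g in enumerate(live) if i not in (pa, pb)]
                live.append(merged)
        for g in live:
            final_groups.append(sorted(g, key=u.members.index))
        if len(live) > 1:
            book["PARTIAL_SPLIT"] += len(live)
        else:
            book["PARTIAL_MERGED"] += 1
        # a fully merged unit counts once; a kept split counts each OTU
    partition = Partition.from_groups(final_groups, "final", order)
    return FinalPartition(partition, book), decisions


def final_count(full: int, partial: int, discordant: int) -> int:
    """Total OTU count from per-category contributions."""
    for name, v in (("full", full), ("partial", partial),
                    ("discordant", discordant)):
        if v < 0:
            raise ValueError(f"negative {name} count")
    return full + partial + discordant


def write_decision_log(decisions: list[ResolutionDecision],
                       path: str | Path) -> pd.DataFrame:
    rows = []
    for d in decisions:
        rows.append({
            "unit": d.unit_id,
            "otu_a": ";".join(sorted(d.pair[0])),
            "otu_b": ";".join(sorted(d.pair[1])),
            "regions_a": ";".join(sorted(d.regions_a)),
            "regions_b": ";".join(sorted(d.regions_b)),
            "sympatric": d.sympatric,
            "decision": d.decision,
            "singleton_merge": d.singleton_merge,
            "diagnostic_sites": d.diagnostic_count,
            "diagnostics_low_confidence": d.diagnostics_low_confidence,
            "monophyletic_a": d.monophyly[0],
            "monophyletic_b": d.monophyly[1],
            "warning": d.warning,
        })
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df


# ---------------------------------------------------------------------------
# Accumulation curve

def otu_accumulation_curve(partition: Partition, n_permutations: int = 100,
                           seed: int = 0) -> pd.DataFrame:
    """Mean (+/- sd) cumulative OTU count over random specimen orderings."""
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    order = partition.id_order or sorted(partition.assignment)
    otus = np.array([partition.assignment[s] for s in order])
    n = len(otus)
    rng = np.random.default_rng(seed)
    curves = np.empty((n_permutations, n))
    for r in range(n_permutations):
        perm = rng.permutation(n)
        seen: set[int] = set()
        for i, idx in enumerate(perm):
            seen.add(int(otus[idx]))
            curves[r, i] = len(seen)
    return pd.DataFrame({
        "specimens": np.arange(1, n + 1),
        "mean_otus": curves.mean(axis=0),
        "sd_otus": curves.std(axis=0, ddof=0),
    })
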