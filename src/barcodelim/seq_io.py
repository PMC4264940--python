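"""Sequence, metadata, tree and partition I/O.

Everything downstream operates on three small containers:

* :class:`Alignment` — equal-length barcode sequences keyed by specimen id,
  optionally annotated with a taxon label and a biogeographic region.
* :class:`Partition` — an assignment of specimens to OTUs; the universal
  output type of the three delimitation engines.
* dendropy trees for every tree-shaped object (guide trees, genealogies).

Sequences may contain ``N`` or ``-``; how those are handled per pair is the
distance module's concern. Region labels are free strings supplied by the
user (no gazetteer is applied).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO

VALID_CHARS = set("ACGTN-")


class ParseError(ValueError):
    """Malformed input file."""


@dataclass
class SpecimenRecord:
    """One barcode record: id, aligned sequence, optional annotations."""

    specimen_id: str
    sequence: str
    taxon_label: str | None = None
    region: str | None = None
    latitude: float | None = None
    longitude: float | None = None

    def __post_init__(self) -> None:
        if not self.specimen_id:
            raise ValueError("specimen_id must be non-empty")
        if len(self.sequence) == 0:
            raise ValueError(f"empty sequence for specimen {self.specimen_id!r}")


class Alignment:
    """Ordered collection of equal-length :class:`SpecimenRecord`."""

    def __init__(self, records: Sequence[SpecimenRecord]):
        records = list(records)
        if not records:
            raise ParseError("no records")
        lengths = {len(r.sequence) for r in records}
        if len(lengths) > 1:
            bad = [r.specimen_id for r in records
                   if len(r.sequence) != len(records[0].sequence)]
            raise ParseError(f"unequal length sequences: {', '.join(bad)}")
        seen: set[str] = set()
        for r in records:
            if r.specimen_id in seen:
                raise ParseError(f"duplicate specimen id {r.specimen_id!r}")
            seen.add(r.specimen_id)
        self.records = records
        self.length = len(records[0].sequence)

    @property
    def ids(self) -> list[str]:
        return [r.specimen_id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, specimen_id: str) -> SpecimenRecord:
        for r in self.records:
            if r.specimen_id == specimen_id:
                return r
        raise KeyError(specimen_id)

    def subset(self, ids: Iterable[str]) -> "Alignment":
        wanted = set(ids)
        return Alignment([r for r in self.records if r.specimen_id in wanted])

    def regions(self) -> dict[str, str | None]:
        return {r.specimen_id: r.region for r in self.records}


@dataclass
class Partition:
    """Assignment of every specimen to exactly one OTU.

    OTU ids are canonicalized to 1..k in order of each OTU's first member
    as listed in ``id_order`` (the input order), which makes partitions
    comparable across engines and invariant to internal label choices.
    """

    assignment: dict[str, int]
    method: str = ""
    id_order: list[str] = field(default_factory=list)

    @classmethod
    def from_groups(cls, groups: Iterable[Iterable[str]], method: str,
                    id_order: Sequence[str]) -> "Partition":
        assignment: dict[str, int] = {}
        for label, members in enumerate(groups, start=1):
            for m in members:
                if m in assignment:
                    raise ValueError(f"specimen {m!r} assigned to two OTUs")
                assignment[m] = label
        p = cls(assignment, method, list(id_order))
        missing = set(id_order) - set(assignment)
        if missing:
            raise ValueError(f"specimens missing from partition: {sorted(missing)}")
        return p.canonicalize()

    def canonicalize(self) -> "Partition":
        order = self.id_order or sorted(self.assignment)
        relabel: dict[int, int] = {}
        for sid in order:
            old = self.assignment[sid]
            if old not in relabel:
                relabel[old] = len(relabel) + 1
        assignment = {sid: relabel[otu] for sid, otu in self.assignment.items()}
        return Partition(assignment, self.method, list(order))

    def groups(self) -> dict[int, list[str]]:
        order = self.id_order or sorted(self.assignment)
        out: dict[int, list[str]] = {}
        for sid in order:
            out.setdefault(self.assignment[sid], []).append(sid)
        return out

    def as_sets(self) -> frozenset[frozenset[str]]:
        return frozenset(frozenset(g) for g in self.groups().values())

    @property
    def n_otus(self) -> int:
        return len(set(self.assignment.values()))

    def restrict(self, ids: Iterable[str]) -> frozenset[frozenset[str]]:
        """Sub-partition induced on a subset of specimens."""
        wanted = set(ids)
        out: dict[int, set[str]] = {}
        for sid in wanted:
            out.setdefault(self.assignment[sid], set()).add(sid)
        return frozenset(frozenset(g) for g in out.values())

    def same_otu(self, a: str, b: str) -> bool:
        return self.assignment[a] == self.assignment[b]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    Ids are taken from the header up to the first whitespace; sequences are
    uppercased. Ragged lengths, duplicate ids and empty files are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise ParseError(f"{path}:{lineno}: expected FASTA header, got "
                                 f"{stripped[:30]!r}")
            break
        else:
            raise ParseError(f"{path}: no records")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - VALID_CHARS
        if bad:
            # IUPAC ambiguity codes other than N are conservatively folded to N
            seq = "".join(c if c in VALID_CHARS else "N" for c in seq)
        records.append(SpecimenRecord(rec.id, seq))
    if not records:
        raise ParseError(f"{path}: no records")
    return Alignment(records)


def write_fasta(alignment: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in alignment:
            fh.write(f">{r.specimen_id}\n{r.sequence}\n")


# ---------------------------------------------------------------------------
# Metadata

_LAT_ALIASES = ("lat", "latitude")
_LON_ALIASES = ("lon", "longitude")


def read_metadata(path: str | Path, alignment: Alignment) -> Alignment:
    """Attach taxon/region/coordinate annotations from a TSV table.

    The table must have a ``specimen_id`` column; ``taxon``, ``region``,
    ``lat``/``latitude`` and ``lon``/``longitude`` are optional. Rows whose
    id is absent from the alignment are reported as warnings and dropped;
    specimens without a row keep empty annotations.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    if "specimen_id" not in table.columns:
        raise ParseError(f"{path}: missing required column 'specimen_id'")
    known = set(alignment.ids)
    extra = [sid for sid in table["specimen_id"] if sid not in known]
    if extra:
        warnings.warn(f"metadata rows for unknown specimens dropped: {extra}")

    def col(row, names):
        for n in names:
            if n in table.columns and pd.notna(row[n]):
                return row[n]
        return None

    by_id = {row["specimen_id"]: row for _, row in table.iterrows()
             if row["specimen_id"] in known}
    new_records = []
    for r in alignment:
        row = by_id.get(r.specimen_id)
        if row is None:
            new_records.append(r)
            continue
        lat = col(row, _LAT_ALIASES)
        lon = col(row, _LON_ALIASES)
        new_records.append(replace(
            r,
            taxon_label=col(row, ("taxon", "taxon_label")) or r.taxon_label,
            region=col(row, ("region",)) or r.region,
            latitude=float(lat) if lat is not None else r.latitude,
            longitude=float(lon) if lon is not None else r.longitude,
        ))
    return Alignment(new_records)


# ---------------------------------------------------------------------------
# Haplotype collapsing

def collapse_haplotypes(alignment: Alignment) -> tuple[Alignment, dict[str, list[str]]]:
    """Merge string-identical sequences into one representative each.

    The representative is the first member in input order. Returns the
    collapsed alignment and a mapping ``representative_id -> member ids``
    that partitions the full specimen set.
    """
    reps: dict[str, str] = {}
    members: dict[str, list[str]] = {}
    kept = []
    for r in alignment:
        if r.sequence in reps:
            members[reps[r.sequence]].append(r.specimen_id)
        else:
            reps[r.sequence] = r.specimen_id
            members[r.specimen_id] = [r.specimen_id]
            kept.append(r)
    return Alignment(kept), members


def expand_partition(partition: Partition, members: Mapping[str, Sequence[str]],
                     id_order: Sequence[str]) -> Partition:
    """Expand a partition of haplotypes back to all specimens."""
    assignment = {}
    for rep, otu in partition.assignment.items():
        for sid in members[rep]:
            assignment[sid] = otu
    return Partition(assignment, partition.method, list(id_order)).canonicalize()


# ---------------------------------------------------------------------------
# Trees

def read_tree(source: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree (path or literal string)."""
    if isinstance(source, Path):
        text = source.read_text()
    else:
        text = str(source)
        try:
            if Path(text).exists():
                text = Path(text).read_text()
        except OSError:  # a Newick literal, not a path
            pass
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:  # dendropy raises several error types
        raise ParseError(f"invalid Newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise ParseError(f"duplicate tip labels: {sorted(dupes)}")
    tree.is_rooted = True
    return tree


def write_tree(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    newick = tree.as_string(schema="newick", suppress_rooting=True,
                            unquoted_underscores=True).strip()
    if path is not None:
        Path(path).write_text(newick + "\n")
    return newick


# ---------------------------------------------------------------------------
# OTU table

def write_otu_table(partitions: Mapping[str, Partition], path: str | Path,
                    categories: Mapping[str, str] | None = None,
                    final: Partition | None = None) -> pd.DataFrame:
    """One row per specimen: id, per-method OTU ids, category, final OTU id."""
    methods = list(partitions)
    specimen_sets = {m: frozenset(p.assignment) for m, p in partitions.items()}
    reference = specimen_sets[methods[0]]
    for m in methods[1:]:
        if specimen_sets[m] != reference:
            diff = sorted(specimen_sets[m] ^ reference)
            raise ValueError(f"partitions cover different specimens; "
                             f"symmetric difference: {diff}")
    order = partitions[methods[0]].id_order or sorted(reference)
    rows = []
    for sid in order:
        row = {"specimen_id": sid}
        for m in methods:
            row[f"otu_{m}"] = partitions[m].assignment[sid]
        if categories is not None:
            row["category"] = categories.get(sid, "")
        if final is not None:
            row["otu_final"] = final.assignment[sid]
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df


def read_partition_tsv(path: str | Path, method: str = "") -> Partition:
    """Read a two-column (specimen_id, otu) TSV into a Partition."""
    df = pd.read_csv(path, sep="\t", dtype={"specimen_id": str})
    if "specimen_id" not in df.columns or "otu" not in df.columns:
        raise ParseError(f"{path}: expected columns specimen_id, otu")
    assignment = {str(r.specimen_id): int(r.otu) for r in df.itertuples()}
    return Partition(assignment, method, [str(s) for s in df["specimen_id"]]
                     ).canonicalize()


def write_partition_tsv(partition: Partition, path: str | Path) -> None:
    order = partition.id_order or sorted(partition.assignment)
    with open(path, "w") as fh:
        fh.write("specimen_id\totu\n")
        for sid in order:
            fh.write(f"{sid}\t{partition.assignment[sid]}\n")
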