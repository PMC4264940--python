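"""Synthetic multi-species barcode datasets with known truth.

The generator emulates the statistical structure the delimitation protocol
assumes: a Yule species tree, an independent Kingman coalescent within each
species (censored at species boundaries, continuing in ancestral species),
K80 sequence evolution so that simulated divergences match the K2P
estimator in expectation, uneven per-species sampling that includes
singletons and doubletons (rarity is the norm in barcode surveys), and
per-species biogeographic region sets with a controllable fraction of
sympatric sister species.

All randomness flows through a single ``numpy.random.Generator`` seeded
from the config, so a seed fixes the full output byte-for-byte. Branch
lengths are in expected substitutions per site throughout; the expected
within-species pairwise divergence is ``theta``.

Two presets bracket the difficulty range: ``separated`` rescales the
species tree so the shallowest split sits well above the coalescent scale
(a clean barcode gap; all engines should agree), while ``hard`` pushes the
shallowest splits into the coalescent scale so the engines start to
disagree.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .seq_io import Alignment, Partition, SpecimenRecord, read_tree

PRESETS = {
    # min species split height (subst/site), theta.  "separated" keeps the
    # shallowest species split 25x above the coalescent scale (clean
    # barcode gap even in the tail); "hard" pushes it into the coalescent
    # scale so the engines start to disagree.
    "separated": {"min_split_height": 0.05, "theta": 0.002},
    "hard": {"min_split_height": 0.008, "theta": 0.004},
}


@dataclass
class SimConfig:
    n_species: int = 8
    yule_rate: float = 1.0
    theta: float = 0.004          # expected within-species pairwise diversity
    seq_length: int = 654
    kappa: float = 4.0            # transition/transversion rate ratio
    min_split_height: float = 0.05
    root_height: float = 0.2      # keeps divergences clear of saturation
    tips_per_species: int | None = 4   # fixed count; None -> rarity law
    rarity_q: float = 0.26        # geometric law: P(1)+P(2) ~ 0.46
    max_tips_per_species: int = 20
    sympatry_fraction: float = 0.5
    n_regions: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        for name in ("yule_rate", "theta", "seq_length", "kappa",
                     "min_split_height"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.sympatry_fraction <= 1):
            raise ValueError("sympatry_fraction must be in [0, 1]")


class _Node:
    __slots__ = ("label", "children", "height")

    def __init__(self, label=None, children=(), height=0.0):
        self.label = label
        self.children = list(children)
        self.height = height

    def newick(self) -> str:
        return self._nwk(parent_height=None) + ";"

    def _nwk(self, parent_height):
        if self.children:
            inner = ",".join(c._nwk(self.height) for c in self.children)
            s = f"({inner})"
        else:
            s = self.label
        if parent_height is not None:
            s += f":{parent_height - self.height:.12g}"
        return s

    def leaves(self):
        if not self.children:
            yield self
        else:
            for c in self.children:
                yield from c.leaves()


@dataclass
class TruthSet:
    partition: Partition
    species_tree: str     # Newick
    genealogy: str        # Newick
    regions: dict[str, str]
    species_regions: dict[str, set[str]] = field(default_factory=dict)


def simulate_species_tree(config: SimConfig,
                          rng: np.random.Generator | None = None) -> _Node:
    """Yule pure-birth tree conditioned on ``n_species`` tips.

    Simulated forward: exponential waiting times with rate k * yule_rate
    while k lineages exist, a uniformly chosen lineage splitting at each
    event; heights are then measured back from the present.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_species
    split_times = [0.0]  # time of the root split
    t = 0.0
    for k in range(2, n):
        t += rng.exponential(1.0 / (k * config.yule_rate))
        split_times.append(t)
    total = t + rng.exponential(1.0 / (n * config.yule_rate))
    heights = [total - s for s in split_times]  # descending: root first

    tips = [_Node(label=f"sp{i+1}") for i in range(n)]
    # root split
    lineages = [tips[0], tips[1]]
    next_tip = 2
    root = _Node(children=[tips[0], tips[1]], height=heights[0])
    parents = {id(tips[0]): root, id(tips[1]): root}
    for h in heights[1:]:
        i = int(rng.integers(len(lineages)))
        old = lineages[i]
        new_tip = tips[next_tip]
        next_tip += 1
        node = _Node(children=[old, new_tip], height=h)
        parent = parents[id(old)]
        parent.children[parent.children.index(old)] = node
        parents[id(node)] = parent
        parents[id(old)] = node
        parents[id(new_tip)] = node
        lineages[i] = old
        lineages.append(new_tip)
    # map split heights linearly onto [min_split_height, root_height]:
    # the shallowest split sits at the preset depth and the root stays
    # clear of distance-model saturation; Yule rank order is preserved
    internal = _internal_heights(root)
    lo, hi = min(internal), max(internal)
    a = config.min_split_height
    b = max(config.root_height, a)
    if hi > lo:
        _map_heights(root, lambda h: a + (h - lo) * (b - a) / (hi - lo))
    else:
        _map_heights(root, lambda h: a)
    return root


def _map_heights(node: _Node, f) -> None:
    if node.children:
        node.height = f(node.height)
        for c in node.children:
            _map_heights(c, f)


def _internal_heights(node: _Node) -> list[float]:
    out = []
    if node.children:
        out.append(node.height)
        for c in node.children:
            out.extend(_internal_heights(c))
    return out


def _scale_heights(node: _Node, scale: float) -> None:
    node.height *= scale
    for c in node.children:
        _scale_heights(c, scale)


def _sample_counts(config: SimConfig, rng: np.random.Generator) -> list[int]:
    if config.tips_per_species is not None:
        return [config.tips_per_species] * config.n_species
    q = config.rarity_q
    counts = []
    for _ in range(config.n_species):
        k = int(rng.geometric(q))
        counts.append(min(k, config.max_tips_per_species))
    return counts


def simulate_genealogy(species_tree: _Node, counts: list[int], theta: float,
                       rng: np.random.Generator) -> _Node:
    """Censored coalescent within the species tree.

    Within every species branch, lineages coalesce at rate
    C(n,2) / (theta/2) per unit branch length, so two lineages in the same
    species have expected divergence ~ theta. Lineages remaining at a
    species-tree node join the ancestral species' pool; above the root
    coalescence runs to a single lineage.
    """
    rate2 = 2.0 / theta  # pairwise coalescence rate

    def coalesce(pool: list[_Node], start: float, stop: float | None) -> list[_Node]:
        t = start
        pool = list(pool)
        while len(pool) > 1:
            n_lin = len(pool)
            rate = rate2 * n_lin * (n_lin - 1) / 2.0
            t_next = t + rng.exponential(1.0 / rate)
            if stop is not None and t_next > stop:
                return pool
            i, j = rng.choice(n_lin, size=2, replace=False)
            i, j = int(i), int(j)
            a, b = pool[i], pool[j]
            node = _Node(children=[a, b], height=t_next)
            pool = [p for k, p in enumerate(pool) if k not in (i, j)]
            pool.append(node)
            t = t_next
        return pool

    species = sorted(species_tree.leaves(), key=lambda l: l.label)
    pools: dict[int, list[_Node]] = {}
    for sp, k in zip(species, counts):
        pools[id(sp)] = [_Node(label=f"{sp.label}_{i+1}") for i in range(k)]

    def process(node: _Node, parent_height: float | None) -> list[_Node]:
        if node.children:
            pool = []
            for c in node.children:
                pool.extend(process(c, node.height))
        else:
            pool = pools[id(node)]
        return coalesce(pool, node.height, parent_height)

    remaining = process(species_tree, None)
    root = coalesce(remaining, species_tree.height, None)[0] if len(remaining) > 1 \
        else remaining[0]
    return root


def evolve_sequences(genealogy: _Node, seq_length: int, kappa: float,
                     rng: np.random.Generator) -> dict[str, str]:
    """K80 evolution along the genealogy; returns label -> sequence.

    Rates are normalized to one expected substitution per site per unit
    branch length. States: A, G (purines), C, T (pyrimidines).
    """
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    bases = np.array(list("AGCT"))
    transition_partner = np.array([1, 0, 3, 2])  # A<->G, C<->T
    tv_choices = np.array([[2, 3], [2, 3], [0, 1], [0, 1]])

    def step(parent_seq: np.ndarray, bl: float) -> np.ndarray:
        if bl <= 0:
            return parent_seq.copy()
        e1 = np.exp(-4.0 * beta * bl)
        e2 = np.exp(-2.0 * (alpha + beta) * bl)
        p_same = 0.25 + 0.25 * e1 + 0.5 * e2
        p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
        u = rng.random(len(parent_seq))
        child = parent_seq.copy()
        ts = (u >= p_same) & (u < p_same + p_ts)
        child[ts] = transition_partner[parent_seq[ts]]
        tv = u >= p_same + p_ts
        which = (rng.random(int(tv.sum())) < 0.5).astype(int)
        child[tv] = tv_choices[parent_seq[tv], which]
        return child

    out: dict[str, str] = {}
    root_seq = rng.integers(0, 4, size=seq_length)

    def walk(node: _Node, seq: np.ndarray, parent_height: float) -> None:
        child_seq = step(seq, parent_height - node.height)
        if node.children:
            for c in node.children:
                walk(c, child_seq, node.height)
        else:
            out[node.label] = "".join(bases[child_seq])

    walk(genealogy, root_seq, genealogy.height)
    return out


def _assign_regions(species_tree: _Node, config: SimConfig,
                    rng: np.random.Generator) -> dict[str, set[str]]:
    """Per-species region sets exercising the sympatry rule.

    Each species draws a private region; with probability
    ``sympatry_fraction`` a species additionally shares one region with
    its sister clade (making the sister pair sympatric), otherwise the
    pair stays allopatric.
    """
    species = sorted((l.label for l in species_tree.leaves()))
    pool = [f"R{i+1}" for i in range(max(config.n_regions, len(species)))]
    regions: dict[str, set[str]] = {}
    for i, sp in enumerate(species):
        regions[sp] = {pool[i]}  # private region; sympatry only by sharing

    def visit(node: _Node) -> list[str]:
        if not node.children:
            return [node.label]
        sides = [visit(c) for c in node.children]
        if rng.random() < config.sympatry_fraction:
            a = sides[0][int(rng.integers(len(sides[0])))]
            b = sides[1][int(rng.integers(len(sides[1])))]
            shared = sorted(regions[a])[0]
            regions[b].add(shared)
        return [s for side in sides for s in side]

    visit(species_tree)
    return regions


def generate_dataset(config: SimConfig | None = None, preset: str | None = None,
                     **overrides) -> tuple[Alignment, pd.DataFrame, TruthSet]:
    """End-to-end fixture: alignment, metadata table and truth.

    ``preset`` ('separated' or 'hard') sets the species-depth/theta
    regime; explicit config fields win over preset values.
    """
    config = config or SimConfig()
    if preset is not None:
        if preset not in PRESETS:
            raise ValueError(f"unknown preset {preset!r}")
        config = replace(config, **PRESETS[preset])
    if overrides:
        config = replace(config, **overrides)
    rng = np.random.default_rng(config.seed)
    sp_tree = simulate_species_tree(config, rng)
    counts = _sample_counts(config, rng)
    genealogy = simulate_genealogy(sp_tree, counts, config.theta, rng)
    seqs = evolve_sequences(genealogy, config.seq_length, config.kappa, rng)
    sp_regions = _assign_regions(sp_tree, config, rng)

    records = []
    regions: dict[str, str] = {}
    true_groups: dict[str, list[str]] = {}
    for label in sorted(seqs):
        species = label.rsplit("_", 1)[0]
        choices = sorted(sp_regions[species])
        region = choices[int(rng.integers(len(choices)))]
        regions[label] = region
        records.append(SpecimenRecord(label, seqs[label],
                                      taxon_label=species, region=region))
        true_groups.setdefault(species, []).append(label)
    alignment = Alignment(records)
    metadata = pd.DataFrame({
        "specimen_id": [r.specimen_id for r in records],
        "taxon": [r.taxon_label for r in records],
        "region": [r.region for r in records],
    })
    truth = TruthSet(
        partition=Partition.from_groups(true_groups.values(), "truth",
                                        alignment.ids),
        species_tree=sp_tree.newick(),
        genealogy=genealogy.newick(),
        regions=regions,
        species_regions=sp_regions)
    return alignment, metadata, truth


def simulate_coalescent_tree(n_tips: int, theta: float = 0.004,
                             seed: int = 0):
    """Single-population Kingman coalescent tree (a GMYC null dataset).

    Returns a dendropy tree with tips tip1..tipN and branch lengths in
    expected substitutions per site.
    """
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    rng = np.random.default_rng(seed)
    pool = [_Node(label=f"tip{i+1}") for i in range(n_tips)]
    rate2 = 2.0 / theta
    t = 0.0
    while len(pool) > 1:
        n_lin = len(pool)
        t += rng.exponential(1.0 / (rate2 * n_lin * (n_lin - 1) / 2.0))
        i, j = rng.choice(n_lin, size=2, replace=False)
        i, j = int(i), int(j)
        node = _Node(children=[pool[i], pool[j]], height=t)
        pool = [p for k, p in enumerate(pool) if k not in (i, j)]
        pool.append(node)
    return read_tree(pool[0].newick())


def write_dataset(alignment: Alignment, metadata: pd.DataFrame,
                  truth: TruthSet, outdir: str | Path) -> None:
    from .seq_io import write_fasta, write_partition_tsv
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(alignment, outdir / "alignment.fasta")
    metadata.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    write_partition_tsv(truth.partition, outdir / "truth.tsv")
    (outdir / "species_tree.nwk").write_text(truth.species_tree + "\n")
    (outdir / "genealogy.nwk").write_text(truth.genealogy + "\n")
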