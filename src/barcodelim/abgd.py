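"""Automatic Barcode Gap Discovery (ABGD).

Given a prior upper bound P on intraspecific divergence and a relative gap
width X, the method locates the barcode gap in the sorted pairwise
distances, partitions the specimens into connected components below the
gap, and recursively re-applies the procedure inside each component. A
geometric grid of priors produces the familiar scan table (initial and
recursive OTU counts per prior, per distance model).

Gap rule used here: sort the pairwise distances ascending; a candidate gap
between consecutive distances qualifies when (a) its lower edge is at least
the prior limit — the largest observed distance still attributable to
intraspecific divergence under P, i.e. the largest distance <= P — and
(b) its width exceeds X times the local spacing scale: the median
spacing between consecutive *distinct* distances within a sliding window
of max(3, ceil(0.1 * n_pairs)) ranks on either side of the candidate,
the candidate itself excluded. Ignoring tied ranks matters — pairwise
distances from finite sequences are quantized to multiples of 1/L, and a
tie-diluted scale would let a single quantum step in the sparse tail of
intraspecific divergences masquerade as the barcode gap; the median (not
the mean) keeps stray near-coincidences between distances from groups
diverging at different scales from shrinking the local scale. The first
qualifying gap (scanning ascending) is the barcode gap:
everything below it is treated as intraspecific. The recursive pass then
re-runs the same search inside each group, where gaps that were smeared
into the global distance continuum — different groups diverge at
different scales — become locally detectable, so recursion can only add
splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .distances import DistanceMatrix
from .seq_io import Partition

MIN_SPLIT_SIZE = 3  # groups smaller than this are never (re-)split


@dataclass
class AbgdParams:
    p_min: float = 0.001
    p_max: float = 0.1
    n_steps: int = 10
    X: float = 1.5
    model: str = "k2p"

    def __post_init__(self) -> None:
        if not (0 < self.p_min <= self.p_max < 1):
            raise ValueError("require 0 < P_min <= P_max < 1")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.X <= 0:
            raise ValueError("relative gap width X must be > 0")


@dataclass
class Gap:
    lower: float   # largest distance below the gap
    upper: float   # smallest distance above the gap
    width: float
    slope: float   # local slope the width was tested against

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lower + self.upper)


def prior_grid(p_min: float = 0.001, p_max: float = 0.1,
               n_steps: int = 10) -> np.ndarray:
    """Geometric series of n_steps priors from p_min to p_max inclusive."""
    if n_steps == 1:
        if p_min != p_max:
            raise ValueError("n_steps=1 requires P_min == P_max")
        return np.array([p_min])
    AbgdParams(p_min, p_max, n_steps)  # validate bounds
    k = np.arange(n_steps)
    return p_min * (p_max / p_min) ** (k / (n_steps - 1))


def _find_gap(sorted_d: np.ndarray, P: float, X: float) -> Gap | None:
    """Widest qualifying gap in ascending distances, or None."""
    m = len(sorted_d)
    if m < 2:
        return None
    window = max(3, ceil(0.1 * m))
    below = sorted_d[sorted_d <= P]
    prior_limit = float(below[-1]) if below.size else 0.0
    diffs = np.diff(sorted_d)
    tie_tol = 1e-9 * max(float(sorted_d[-1]), 1e-12)
    for i in range(m - 1):
        if sorted_d[i] < prior_limit:
            continue
        width = float(diffs[i])
        if width <= tie_tol:
            continue
        local = np.concatenate([diffs[max(0, i - window):i],
                                diffs[i + 1:i + 1 + window]])
        local = local[local > tie_tol]
        slope = float(np.median(local)) if local.size else 0.0
        if width > X * slope:
            return Gap(float(sorted_d[i]), float(sorted_d[i + 1]),
                       width, slope)
    return None


def infer_gap(dm: DistanceMatrix, P: float, X: float = 1.5) -> Gap | None:
    """Barcode gap for prior P, or None when no gap qualifies."""
    if len(dm) < MIN_SPLIT_SIZE:
        raise ValueError(f"need at least {MIN_SPLIT_SIZE} specimens")
    return _find_gap(np.sort(dm.condensed()), P, X)


def _components(d: np.ndarray, ids: Sequence[str], threshold: float) -> list[list[str]]:
    """Connected components of the graph with edges d <= threshold."""
    n = len(ids)
    adj = d <= threshold
    seen = np.zeros(n, dtype=bool)
    comps = []
    for s in range(n):
        if seen[s]:
            continue
        stack, comp = [s], []
        seen[s] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            nbrs = np.nonzero(adj[v] & ~seen)[0]
            seen[nbrs] = True
            stack.extend(int(x) for x in nbrs)
        comps.append(sorted(comp))
    return [[ids[i] for i in comp] for comp in comps]


def initial_partition(dm: DistanceMatrix, P: float, X: float = 1.5) -> Partition:
    """One-pass ABGD: components below the barcode gap (1 OTU if no gap)."""
    gap = infer_gap(dm, P, X)
    if gap is None:
        groups = [list(dm.ids)]
    else:
        groups = _components(dm.d, dm.ids, gap.lower)
    return Partition.from_groups(groups, "abgd", dm.ids)


def recursive_partition(dm: DistanceMatrix, P: float, X: float = 1.5) -> Partition:
    """ABGD with recursive re-splitting inside each group.

    Each group of size >= 3 is re-examined on its own sub-matrix with the
    same prior until no group splits further.
    """
    initial = initial_partition(dm, P, X)
    groups = [members for members in initial.groups().values()]
    final: list[list[str]] = []
    queue = list(groups)
    while queue:
        members = queue.pop(0)
        if len(members) < MIN_SPLIT_SIZE:
            final.append(members)
            continue
        sub = dm.submatrix(members)
        gap = _find_gap(np.sort(sub.condensed()), P, X)
        if gap is None:
            final.append(members)
            continue
        pieces = _components(sub.d, sub.ids, gap.lower)
        if len(pieces) == 1:
            final.append(members)
        else:
            queue.extend(pieces)
    return Partition.from_groups(final, "abgd", dm.ids)


@dataclass
class AbgdScan:
    """Table-1-style scan: OTU counts per model and prior."""

    params: AbgdParams
    rows: list[dict] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"model": r["model"], "P": r["P"],
             "n_initial": r["initial"].n_otus,
             "n_recursive": r["recursive"].n_otus}
            for r in self.rows
        ])

    def partition(self, model: str, P: float, stage: str = "initial") -> Partition:
        best = min(self.rows, key=lambda r: (r["model"] != model, abs(r["P"] - P)))
        if best["model"] != model:
            raise KeyError(f"model {model!r} not in scan")
        return best[stage]

    def write_tsv(self, path: str | Path) -> None:
        """Wide layout mirroring the published scan tables: one row per
        model and stage, priors as columns (descending)."""
        df = self.to_dataframe()
        priors = sorted(df["P"].unique(), reverse=True)
        with open(path, "w") as fh:
            fh.write("model\tstage\t" + "\t".join(f"{p:.3g}" for p in priors) + "\n")
            for model in df["model"].unique():
                for stage, colname in (("initial", "n_initial"),
                                       ("recursive", "n_recursive")):
                    sub = df[df["model"] == model].set_index("P")[colname]
                    cells = "\t".join(str(int(sub[p])) for p in priors)
                    fh.write(f"{model}\t{stage}\t{cells}\n")


def abgd_scan(dms: Mapping[str, DistanceMatrix],
              params: AbgdParams | None = None) -> AbgdScan:
    """Run initial + recursive ABGD for every model and every grid prior."""
    params = params or AbgdParams()
    grid = prior_grid(params.p_min, params.p_max, params.n_steps)
    scan = AbgdScan(params)
    for model, dm in dms.items():
        for P in grid:
            scan.rows.append({
                "model": model,
                "P": float(P),
                "initial": initial_partition(dm, P, params.X),
                "recursive": recursive_partition(dm, P, params.X),
            })
    return scan
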