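"""Pairwise genetic distances (p, JC69, K2P) and the barcode-gap histogram.

Distances are stored on the proportion scale (the BIN threshold "2.2%" is
0.022). Sites where either sequence has ``N`` or ``-`` are excluded per
pair (pairwise deletion). Transitions are A<->G and C<->T; everything else
is a transversion.

Model formulas, with p = mismatch proportion, P = transition proportion,
Q = transversion proportion over the compared sites:

* p-distance:  d = p
* JC69:        d = -(3/4) ln(1 - (4/3) p)
* K2P:         d = -(1/2) ln(1 - 2P - Q) - (1/4) ln(1 - 2Q)
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .seq_io import Alignment

MODELS = ("p", "jc69", "k2p")

# A=0, G=1 (purines); C=2, T=3 (pyrimidines); 4 = missing (N or gap)
_CODE = {"A": 0, "G": 1, "C": 2, "T": 3, "N": 4, "-": 4}


class SaturationError(ValueError):
    """Distance formula undefined (log argument <= 0) for a pair."""


def encode_alignment(alignment: Alignment) -> np.ndarray:
    """(n, L) uint8 matrix of nucleotide codes; 4 marks missing data."""
    n, L = len(alignment), alignment.length
    mat = np.empty((n, L), dtype=np.uint8)
    for i, rec in enumerate(alignment):
        mat[i] = [_CODE.get(c, 4) for c in rec.sequence]
    return mat


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray
    model: str

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("non-zero diagonal")
        if not np.all(np.isfinite(self.d)) or np.any(self.d < 0):
            raise ValueError("distances must be finite and >= 0")

    def __len__(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.ids), k=1)
        return self.d[iu]

    def pair(self, a: str, b: str) -> float:
        return float(self.d[self.ids.index(a), self.ids.index(b)])

    def submatrix(self, ids: list[str]) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(list(ids), self.d[np.ix_(idx, idx)], self.model)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)

    def write_phylip(self, path: str | Path) -> None:
        """Square PHYLIP-style matrix for interoperability."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for sid, row in zip(self.ids, self.d):
                fh.write(sid + "  " + " ".join(f"{v:.8f}" for v in row) + "\n")


def jc69_from_p(p: float | np.ndarray) -> float | np.ndarray:
    arg = 1.0 - 4.0 * np.asarray(p, dtype=float) / 3.0
    if np.any(arg <= 0):
        raise SaturationError("JC69 undefined for p >= 3/4")
    return -0.75 * np.log(arg)


def k2p_from_pq(P: float | np.ndarray, Q: float | np.ndarray) -> float | np.ndarray:
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    a1 = 1.0 - 2.0 * P - Q
    a2 = 1.0 - 2.0 * Q
    if np.any(a1 <= 0) or np.any(a2 <= 0):
        raise SaturationError("K2P undefined: 1-2P-Q or 1-2Q <= 0")
    return -0.5 * np.log(a1) - 0.25 * np.log(a2)


def pairwise_distances(alignment: Alignment, model: str = "k2p") -> DistanceMatrix:
    """Distance matrix under ``model`` with pairwise deletion of N/'-' sites."""
    model = model.lower()
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    if len(alignment) < 2:
        raise ValueError("need at least 2 sequences")
    mat = encode_alignment(alignment)
    valid = mat < 4
    purine = mat < 2  # meaningful only where valid
    n = len(alignment)
    d = np.zeros((n, n), dtype=float)
    ids = alignment.ids
    for i in range(n):
        comp = valid[i] & valid[i + 1:]
        ncomp = comp.sum(axis=1)
        zero = np.nonzero(ncomp == 0)[0]
        if zero.size:
            j = int(zero[0]) + i + 1
            raise ValueError(f"no comparable sites for pair "
                             f"({ids[i]!r}, {ids[j]!r})")
        diff = (mat[i] != mat[i + 1:]) & comp
        ndiff = diff.sum(axis=1)
        p = ndiff / ncomp
        if model == "p":
            row = p
        elif model == "jc69":
            sat = np.nonzero(p >= 0.75)[0]
            if sat.size:
                j = int(sat[0]) + i + 1
                raise SaturationError(f"JC69 saturated for pair "
                                      f"({ids[i]!r}, {ids[j]!r}): p={p[sat[0]]:.3f}")
            row = jc69_from_p(p)
        else:
            ts = (diff & (purine[i] == purine[i + 1:])).sum(axis=1)
            P = ts / ncomp
            Q = (ndiff - ts) / ncomp
            bad = np.nonzero((1 - 2 * P - Q <= 0) | (1 - 2 * Q <= 0))[0]
            if bad.size:
                j = int(bad[0]) + i + 1
                raise SaturationError(f"K2P saturated for pair "
                                      f"({ids[i]!r}, {ids[j]!r})")
            row = k2p_from_pq(P, Q)
        d[i, i + 1:] = row
        d[i + 1:, i] = row
    return DistanceMatrix(list(ids), d, model)


@dataclass
class DistanceHistogram:
    table: pd.DataFrame  # columns: bin_low, bin_high, count
    n_pairs: int
    mean: float

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def distance_histogram(dm: DistanceMatrix, bin_width: float = 0.005) -> DistanceHistogram:
    """Histogram of upper-triangle pairwise distances.

    Empty bins between the minimum and maximum are included, so a barcode
    gap is visible as a run of zero-count bins.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    vals = dm.condensed()
    lo = np.floor(vals.min() / bin_width) * bin_width
    hi = vals.max()
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width)))
    if lo + n_bins * bin_width <= hi:  # right edge must cover the max
        n_bins += 1
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(vals, bins=edges)
    table = pd.DataFrame({
        "bin_low": edges[:-1],
        "bin_high": edges[1:],
        "count": counts,
    })
    return DistanceHistogram(table, n_pairs=len(vals), mean=float(vals.mean()))
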