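"""General Mixed Yule-coalescent (GMYC) species delimitation.

An ultrametric gene tree is modelled as a Yule (pure-birth) diversification
process deep in the tree that switches, at a threshold height T, to
independent within-species coalescent processes. Branches crossing T define
the OTUs. The per-interval total event rate is

    b_i = lambda1 * k_i**p1 + lambda2 * sum_j [n_ij * (n_ij - 1)]**p2

where k_i counts species-level lineages in inter-event interval i (all
crossing branches above T; the constant number of OTUs below T) and n_ij
counts the gene lineages of within-species process j. With waiting times
x_i the log-likelihood is sum_i [ln b_i - b_i x_i] over event-terminated
intervals, minus b x for the final tip-ward interval. The null model is a
single process over the whole tree, b_i = lambda * [n_i (n_i - 1)]**p.

The threshold is profiled over candidate heights (midpoints between
consecutive distinct node heights); rate parameters are fitted by bounded
quasi-Newton optimization from deterministic multi-starts. The
likelihood-ratio statistic 2*(logL_GMYC - logL_null) is referred to a
chi-squared distribution with 3 degrees of freedom by convention (the
threshold is not counted as a free parameter); the reference distribution
is configurable. Confidence sets are all candidate thresholds within 2
log-likelihood units of the optimum.

A UPGMA builder is included so a distance matrix can be turned into an
ultrametric tree for end-to-end runs when no externally inferred
chronogram is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.optimize import minimize
from scipy.stats import chi2

from .distances import DistanceMatrix
from .seq_io import Partition, read_tree

_HEIGHT_TOL = 1e-9
_LOG_LAM_BOUNDS = (np.log(1e-8), np.log(1e8))
_P_BOUNDS = (1e-2, 10.0)


class UltrametricityError(ValueError):
    """Input tree is not ultrametric within tolerance."""


class _TreeIndex:
    """Read-only arrays over a rooted ultrametric dendropy tree."""

    def __init__(self, tree: dendropy.Tree, rtol: float = 1e-6):
        leaves = [l for l in tree.leaf_node_iter()]
        if len(leaves) < 3:
            raise ValueError("GMYC needs a tree with at least 3 tips")
        depth: dict[int, float] = {}
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                depth[id(node)] = 0.0
            else:
                bl = node.edge.length if node.edge.length is not None else 0.0
                depth[id(node)] = depth[id(node.parent_node)] + bl
        tip_depths = np.array([depth[id(l)] for l in leaves])
        self.root_height = float(tip_depths.max())
        if self.root_height <= 0:
            raise UltrametricityError("tree has zero height")
        if np.any(np.abs(tip_depths - self.root_height) >
                  rtol * self.root_height):
            raise UltrametricityError(
                "root-to-tip path lengths differ beyond tolerance; "
                "an ultrametric tree is required")
        self.tree = tree
        self.height = {id(n): max(0.0, self.root_height - depth[id(n)])
                       for n in tree.preorder_node_iter()}
        for l in leaves:
            self.height[id(l)] = 0.0
        self.leaves = leaves
        self.tip_labels = [l.taxon.label for l in leaves]
        # edges: one per non-root node (the edge to its parent)
        self.edge_nodes = [n for n in tree.preorder_node_iter()
                           if n.parent_node is not None]
        self.edge_child_h = np.array([self.height[id(n)] for n in self.edge_nodes])
        self.edge_parent_h = np.array(
            [self.height[id(n.parent_node)] for n in self.edge_nodes])
        self.internal_heights = np.array(sorted(
            (self.height[id(n)] for n in tree.preorder_internal_node_iter()),
            reverse=True))

    def stems_at(self, threshold: float) -> list[dendropy.Node]:
        """Child ends of the branches crossing height ``threshold``."""
        if not (0 < threshold < self.root_height):
            raise ValueError("threshold must lie strictly between the tips "
                             "and the root height")
        return [n for n, ch, ph in zip(self.edge_nodes, self.edge_child_h,
                                       self.edge_parent_h)
                if ch < threshold < ph]

    def leaf_labels_under(self, node: dendropy.Node) -> list[str]:
        return [l.taxon.label for l in node.leaf_iter()]


@dataclass
class BranchingIntervals:
    """Inter-event intervals from the root toward the tips.

    ``events[i]`` is the number of branching events terminating interval i
    (0 for the final interval ending at the tips), ``k[i]`` the
    diversification-process lineage count, and the pair
    (``coal_idx``, ``coal_n``) the flattened within-OTU lineage counts
    n >= 2 with their interval index. ``n_total[i]`` is the total number of
    branches crossing the interval (used by the null model).
    """

    x: np.ndarray
    events: np.ndarray
    k: np.ndarray
    coal_idx: np.ndarray
    coal_n: np.ndarray
    n_total: np.ndarray
    n_otus: int
    otu_groups: list[list[str]]
    threshold: float | None = None


def _intervals_for_stems(idx: _TreeIndex, stems: list[dendropy.Node],
                         threshold: float | None = None) -> BranchingIntervals:
    n_edges = len(idx.edge_nodes)
    owner = np.full(n_edges, -1, dtype=int)
    pos = {id(n): i for i, n in enumerate(idx.edge_nodes)}
    stem_parent_h = np.empty(len(stems))
    otu_groups = []
    for j, stem in enumerate(stems):
        # a root "stem" models the degenerate one-OTU configuration
        stem_parent_h[j] = (idx.height[id(stem.parent_node)]
                            if stem.parent_node is not None else np.inf)
        for node in stem.preorder_iter():
            if id(node) in pos:
                owner[pos[id(node)]] = j
        otu_groups.append(idx.leaf_labels_under(stem))
    heights = idx.internal_heights
    distinct = []
    for h in heights:  # descending; root first
        if not distinct or distinct[-1] - h > _HEIGHT_TOL * idx.root_height:
            distinct.append(float(h))
    boundaries = distinct + [0.0]
    m = len(boundaries) - 1
    x = np.empty(m)
    events = np.zeros(m, dtype=int)
    k = np.empty(m, dtype=int)
    n_total = np.empty(m, dtype=int)
    coal_idx: list[int] = []
    coal_n: list[int] = []
    for i in range(m):
        top, bottom = boundaries[i], boundaries[i + 1]
        x[i] = top - bottom
        # branching events at the interval's lower boundary
        if i + 1 < len(boundaries) - 0:
            events[i] = int(np.sum(np.abs(heights - bottom) <=
                                   _HEIGHT_TOL * idx.root_height + 1e-300))
        if i == m - 1:
            events[i] = int(np.sum(heights <= _HEIGHT_TOL * idx.root_height))
        hm = 0.5 * (top + bottom)
        crossing = (idx.edge_child_h < hm) & (idx.edge_parent_h > hm)
        n_total[i] = int(crossing.sum())
        k[i] = int(np.sum(crossing & (owner == -1)))
        if stems:
            k[i] += int(np.sum(stem_parent_h > hm))
            counts = np.bincount(owner[crossing & (owner >= 0)],
                                 minlength=len(stems))
            for j, c in enumerate(counts):
                if c >= 2:
                    coal_idx.append(i)
                    coal_n.append(int(c))
    return BranchingIntervals(
        x=x, events=events, k=k,
        coal_idx=np.array(coal_idx, dtype=int),
        coal_n=np.array(coal_n, dtype=float),
        n_total=n_total, n_otus=len(stems), otu_groups=otu_groups,
        threshold=threshold)


def branching_intervals(tree: dendropy.Tree, threshold: float) -> BranchingIntervals:
    """Interval bookkeeping for a single threshold height."""
    idx = _TreeIndex(tree)
    return _intervals_for_stems(idx, idx.stems_at(threshold), threshold)


def mixed_loglik(iv: BranchingIntervals, lambda1: float, p1: float,
                 lambda2: float, p2: float) -> float:
    """Log-likelihood of the mixed Yule + coalescent model."""
    if lambda1 <= 0 or lambda2 <= 0:
        raise ValueError("rates must be positive")
    b = lambda1 * np.power(iv.k, p1, dtype=float)
    if iv.coal_n.size:
        coal = np.power(iv.coal_n * (iv.coal_n - 1.0), p2)
        contrib = np.zeros_like(b)
        np.add.at(contrib, iv.coal_idx, coal)
        b = b + lambda2 * contrib
    with np.errstate(divide="ignore"):
        logb = np.where(b > 0, np.log(np.maximum(b, 1e-300)), 0.0)
    return float(np.sum(iv.events * logb) - np.sum(b * iv.x))


def null_loglik(iv: BranchingIntervals, lam: float, p: float) -> float:
    """Single-process null: b_i = lam * [n_i (n_i - 1)]**p over the tree."""
    if lam <= 0:
        raise ValueError("rate must be positive")
    b = lam * np.power(iv.n_total * (iv.n_total - 1.0), p)
    with np.errstate(divide="ignore"):
        logb = np.where(b > 0, np.log(np.maximum(b, 1e-300)), 0.0)
    return float(np.sum(iv.events * logb) - np.sum(b * iv.x))


def _optimize_mixed(iv: BranchingIntervals) -> tuple[np.ndarray, float]:
    total_events = float(iv.events.sum())
    yule_time = float(np.sum(iv.k * iv.x)) or 1.0
    coal1 = np.zeros_like(iv.x)
    if iv.coal_n.size:
        np.add.at(coal1, iv.coal_idx, iv.coal_n * (iv.coal_n - 1.0))
    coal_time = float(np.sum(coal1 * iv.x)) or 1.0
    l1 = max(total_events / yule_time, 1e-6)
    l2 = max(total_events / coal_time, 1e-6)
    starts = [
        np.array([np.log(l1), 1.0, np.log(l2), 1.0]),
        np.array([np.log(l1), 0.5, np.log(l2), 1.5]),
        np.array([0.0, 1.0, 0.0, 1.0]),
    ]

    def neg(v: np.ndarray) -> float:
        return -mixed_loglik(iv, np.exp(v[0]), v[1], np.exp(v[2]), v[3])

    bounds = [_LOG_LAM_BOUNDS, _P_BOUNDS, _LOG_LAM_BOUNDS, _P_BOUNDS]
    best = None
    for s in starts:
        res = minimize(neg, s, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("mixed-model optimization failed to converge")
    return best.x, -float(best.fun)


def _optimize_null(iv: BranchingIntervals) -> tuple[np.ndarray, float]:
    total_events = float(iv.events.sum())
    t = float(np.sum(iv.n_total * (iv.n_total - 1.0) * iv.x)) or 1.0
    starts = [np.array([np.log(max(total_events / t, 1e-6)), 1.0]),
              np.array([0.0, 0.5])]

    def neg(v: np.ndarray) -> float:
        return -null_loglik(iv, np.exp(v[0]), v[1])

    bounds = [_LOG_LAM_BOUNDS, _P_BOUNDS]
    best = None
    for s in starts:
        res = minimize(neg, s, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("null-model optimization failed to converge")
    return best.x, -float(best.fun)


@dataclass
class GmycFit:
    method: str
    lambda1: float
    p1: float
    lambda2: float
    p2: float
    thresholds: list[float]
    logL_gmyc: float
    logL_null: float
    LR: float
    p_value: float
    clusters: int
    entities: int
    clusters_ci: tuple[int, int]
    entities_ci: tuple[int, int]
    partition: Partition
    candidates: pd.DataFrame = field(repr=False, default=None)

    @property
    def threshold(self) -> float:
        return self.thresholds[0]

    @property
    def significance(self) -> str:
        for cut, stars in ((0.001, "***"), (0.01, "**"), (0.05, "*")):
            if self.p_value < cut:
                return stars
        return "ns"

    def report_row(self) -> dict:
        lo_c, hi_c = self.clusters_ci
        lo_e, hi_e = self.entities_ci
        return {
            "analysis": self.method,
            "clusters": f"{self.clusters} ({lo_c}-{hi_c})",
            "entities": f"{self.entities} ({lo_e}-{hi_e})",
            "logL_null": round(self.logL_null, 2),
            "logL_gmyc": round(self.logL_gmyc, 2),
            "LR": round(self.LR, 2),
            "significance": self.significance,
            "thresholds": ";".join(f"{t:.6g}" for t in self.thresholds),
        }


def likelihood_ratio_test(logL_null: float, logL_gmyc: float, df: int = 3,
                          tol: float = 1e-6) -> tuple[float, float]:
    """LR = 2*(logL_gmyc - logL_null) and its chi-squared p-value."""
    LR = 2.0 * (logL_gmyc - logL_null)
    if LR < -tol:
        raise ValueError(f"negative likelihood ratio ({LR:.4g}): "
                         "GMYC optimizer failed to reach the null optimum")
    LR = max(LR, 0.0)
    return LR, float(chi2.sf(LR, df))


def _candidate_thresholds(idx: _TreeIndex) -> list[float]:
    distinct = []
    for h in idx.internal_heights:
        if not distinct or distinct[-1] - h > _HEIGHT_TOL * idx.root_height:
            distinct.append(float(h))
    cands = [0.5 * (a + b) for a, b in zip(distinct, distinct[1:])]
    cands.append(0.5 * distinct[-1])
    return cands


def _partition_from_groups(groups: list[list[str]], tip_order: list[str]) -> Partition:
    return Partition.from_groups(groups, "gmyc", tip_order)


def fit_single_threshold(tree: dendropy.Tree | str | Path,
                         lr_df: int = 3) -> GmycFit:
    """Profile the threshold over all candidate heights and return the MLE.

    Intended for haplotype-collapsed data (identical sequences produce
    zero-length branches that carry no information about the transition).
    """
    if not isinstance(tree, dendropy.Tree):
        tree = read_tree(tree)
    idx = _TreeIndex(tree)
    null_iv = _intervals_for_stems(idx, [])
    _, logL_null = _optimize_null(null_iv)
    rows = []
    best = None
    for T in _candidate_thresholds(idx):
        stems = idx.stems_at(T)
        iv = _intervals_for_stems(idx, stems, T)
        params, logL = _optimize_mixed(iv)
        clusters = sum(1 for g in iv.otu_groups if len(g) > 1)
        entities = iv.n_otus
        rows.append({"threshold": T, "logL": logL,
                     "clusters": clusters, "entities": entities})
        if best is None or logL > best["logL"]:
            best = {"threshold": T, "logL": logL, "params": params,
                    "clusters": clusters, "entities": entities,
                    "groups": iv.otu_groups}
    cand = pd.DataFrame(rows)
    in_ci = cand[cand["logL"] >= best["logL"] - 2.0]
    LR, p_value = likelihood_ratio_test(logL_null, best["logL"], df=lr_df)
    v = best["params"]
    return GmycFit(
        method="single",
        lambda1=float(np.exp(v[0])), p1=float(v[1]),
        lambda2=float(np.exp(v[2])), p2=float(v[3]),
        thresholds=[best["threshold"]],
        logL_gmyc=best["logL"], logL_null=logL_null,
        LR=LR, p_value=p_value,
        clusters=best["clusters"], entities=best["entities"],
        clusters_ci=(int(in_ci["clusters"].min()), int(in_ci["clusters"].max())),
        entities_ci=(int(in_ci["entities"].min()), int(in_ci["entities"].max())),
        partition=_partition_from_groups(best["groups"], idx.tip_labels),
        candidates=cand)


def fit_multiple_threshold(tree: dendropy.Tree | str | Path,
                           max_thresholds: int = 10,
                           improvement_tol: float = 2.0,
                           lr_df: int = 3) -> GmycFit:
    """Greedy multiple-threshold fit.

    Starting from the single-threshold optimum, repeatedly splits the OTU
    whose subdivision at its crown most improves the log-likelihood, until
    the improvement drops to ``improvement_tol`` log-units or
    ``max_thresholds`` is reached. Entity counts can only grow relative to
    the single-threshold fit.
    """
    if not isinstance(tree, dendropy.Tree):
        tree = read_tree(tree)
    single = fit_single_threshold(tree, lr_df=lr_df)
    if max_thresholds <= 1:
        out = single
        out.method = "multiple"
        return out
    idx = _TreeIndex(tree)
    stems = idx.stems_at(single.threshold)
    thresholds = [single.threshold]
    logL = single.logL_gmyc
    params = np.array([np.log(single.lambda1), single.p1,
                       np.log(single.lambda2), single.p2])
    while len(thresholds) < max_thresholds:
        best_move = None
        for i, stem in enumerate(stems):
            if stem.is_leaf():
                continue
            children = stem.child_nodes()
            trial = stems[:i] + stems[i + 1:] + list(children)
            iv = _intervals_for_stems(idx, trial)
            p, l = _optimize_mixed(iv)
            if best_move is None or l > best_move["logL"]:
                best_move = {"stems": trial, "logL": l, "params": p,
                             "height": idx.height[id(stem)], "iv": iv}
        if best_move is None or best_move["logL"] - logL <= improvement_tol:
            break
        stems = best_move["stems"]
        logL = best_move["logL"]
        params = best_move["params"]
        thresholds.append(best_move["height"])
    final_iv = _intervals_for_stems(idx, stems)
    LR, p_value = likelihood_ratio_test(single.logL_null, logL, df=lr_df)
    groups = final_iv.otu_groups
    return GmycFit(
        method="multiple",
        lambda1=float(np.exp(params[0])), p1=float(params[1]),
        lambda2=float(np.exp(params[2])), p2=float(params[3]),
        thresholds=thresholds,
        logL_gmyc=logL, logL_null=single.logL_null,
        LR=LR, p_value=p_value,
        clusters=sum(1 for g in groups if len(g) > 1),
        entities=len(groups),
        clusters_ci=(sum(1 for g in groups if len(g) > 1),) * 2,
        entities_ci=(len(groups),) * 2,
        partition=_partition_from_groups(groups, idx.tip_labels),
        candidates=single.candidates)


def write_gmyc_report(fits: list[GmycFit], path: str | Path) -> pd.DataFrame:
    df = pd.DataFrame([f.report_row() for f in fits])
    df.to_csv(path, sep="\t", index=False)
    return df


# ---------------------------------------------------------------------------
# UPGMA stand-in tree builder

def upgma_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Average-linkage (UPGMA) ultrametric tree; node height = merge/2."""
    n = len(dm)
    if n < 2:
        raise ValueError("need at least 2 specimens")
    if n == 2:
        h = dm.d[0, 1] / 2.0
        newick = f"({_quote(dm.ids[0])}:{h},{_quote(dm.ids[1])}:{h});"
        return read_tree(newick)
    Z = linkage(dm.condensed(), method="average")
    heights = {i: 0.0 for i in range(n)}
    newicks = {i: _quote(dm.ids[i]) for i in range(n)}
    for row_i, (a, b, dist, _) in enumerate(Z):
        a, b = int(a), int(b)
        h = dist / 2.0
        node_id = n + row_i
        la = h - heights[a]
        lb = h - heights[b]
        newicks[node_id] = f"({newicks[a]}:{la:.12g},{newicks[b]}:{lb:.12g})"
        heights[node_id] = h
    return read_tree(newicks[2 * n - 2] + ";")


def _quote(label: str) -> str:
    if any(c in label for c in " ()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label
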