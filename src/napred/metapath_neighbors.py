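"""Meta-path enumeration and multi-scale neighbor-set extraction.

A meta-path of order k is a typed node sequence of length k+1 over the two
node types r (drug) and d (disease), e.g. "rrd".  For a node v and order k,
candidates are all nodes reachable from v by at least one order-k meta-path
whose every step traverses a nonzero off-diagonal edge of the heterogeneous
network U^m (diagonal self-similarity entries are not edges; walks may
revisit nodes, but v itself is never its own candidate).

Same-type candidates are ranked by direct similarity U[v, c] (descending,
ties by node index); cross-type candidates by the number of distinct walk
instances reaching them.  The top N_k of each ranking are retained, and for
k = 1 the node itself is prepended to its same-type list (counting toward
the N_k budget).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .network_construction import HeteroNetwork

logger = logging.getLogger("napred")

__all__ = ["MetaPathSet", "NeighborSets", "enumerate_metapaths",
           "extract_neighbor_sets", "all_neighbor_sets"]


@dataclass(frozen=True)
class MetaPathSet:
    """All order-k meta-paths starting from one node type."""

    order: int
    start_type: str  # "drug" | "disease"
    paths: tuple[str, ...]

    def __post_init__(self):
        first = "r" if self.start_type == "drug" else "d"
        assert all(len(p) == self.order + 1 and p[0] == first for p in self.paths)


@dataclass
class NeighborSets:
    """Retained neighbors of one node at one order in one network."""

    node: int
    order: int
    same_type: list[int]
    cross_type: list[int]
    same_scores: list[float] = field(default_factory=list)
    cross_scores: list[float] = field(default_factory=list)


def enumerate_metapaths(start_type: str, k: int) -> MetaPathSet:
    """All 2**k type strings of length k+1 from start_type, lexicographic."""
    if k < 1:
        raise ValueError(f"meta-path order must be >= 1, got {k}")
    if start_type not in ("drug", "disease"):
        raise ValueError(f"unknown start type {start_type!r}")
    first = "r" if start_type == "drug" else "d"
    paths = sorted(first + "".join(tail) for tail in product("dr", repeat=k))
    return MetaPathSet(k, start_type, tuple(paths))


def _typed_blocks(U: HeteroNetwork):
    """Binary step matrices between node types, diagonal excluded."""
    n_r = U.n_drugs
    B = (U.values != 0).astype(float)
    np.fill_diagonal(B, 0.0)
    return {
        ("r", "r"): B[:n_r, :n_r],
        ("r", "d"): B[:n_r, n_r:],
        ("d", "r"): B[n_r:, :n_r],
        ("d", "d"): B[n_r:, n_r:],
    }


def _walk_counts(U: HeteroNetwork, start_type: str, k: int):
    """Walk-instance counts from every start node, split by end type.

    Returns {end_type: matrix (n_start, n_end)} where entry (v, c) counts
    distinct order-k typed walks from v to c over all meta-paths.
    """
    blocks = _typed_blocks(U)
    mps = enumerate_metapaths(start_type, k)
    counts: dict[str, np.ndarray] = {}
    for path in mps.paths:
        M = blocks[(path[0], path[1])]
        for a, b in zip(path[1:], path[2:]):
            M = M @ blocks[(a, b)]
        end = path[-1]
        counts[end] = counts.get(end, 0) + M
    return counts


def _rank(scores: np.ndarray, candidates: np.ndarray, n_keep: int):
    """Indices of the top candidates by score desc, index asc (stable)."""
    order = np.lexsort((candidates, -scores[candidates]))
    kept = candidates[order][:n_keep]
    return list(map(int, kept)), [float(scores[c]) for c in kept]


def extract_neighbor_sets(U: HeteroNetwork, node: int, k: int,
                          n_k: int, _counts=None) -> NeighborSets:
    """Retained same-type and cross-type neighbors of ``node`` at order k."""
    if n_k < 1:
        raise ValueError(f"N_k must be >= 1, got {n_k}")
    n_r, n_total = U.n_drugs, U.n_drugs + U.n_diseases
    if not 0 <= node < n_total:
        raise ValueError(f"node index {node} out of range [0,{n_total})")
    is_drug = node < n_r
    start_type = "drug" if is_drug else "disease"
    local = node if is_drug else node - n_r
    counts = _counts[start_type] if _counts else _walk_counts(U, start_type, k)

    same_char = "r" if is_drug else "d"
    cross_char = "d" if is_drug else "r"
    same_counts = counts.get(same_char)
    cross_counts = counts.get(cross_char)
    same_row = same_counts[local] if same_counts is not None else None
    cross_row = cross_counts[local] if cross_counts is not None else None

    # similarity rows of U restricted to each type, in local indices
    sim_row = U.values[node]
    same_sim = sim_row[:n_r] if is_drug else sim_row[n_r:]
    cross_sim = sim_row[n_r:] if is_drug else sim_row[:n_r]
    del cross_sim

    same_list: list[int] = []
    same_scores: list[float] = []
    if same_row is not None:
        cand = np.flatnonzero(same_row > 0)
        cand = cand[cand != local]
        keep = n_k - 1 if k == 1 else n_k
        same_list, same_scores = _rank(same_sim, cand, keep)
    if k == 1:
        same_list = [local] + same_list
        same_scores = [float(U.values[node, node])] + same_scores

    cross_list: list[int] = []
    cross_scores: list[float] = []
    if cross_row is not None:
        cand = np.flatnonzero(cross_row > 0)
        cross_list, cross_scores = _rank(cross_row, cand, n_k)

    if len(same_list) <= (1 if k == 1 else 0) and not cross_list:
        degree = (U.values[node] != 0).sum() - (U.values[node, node] != 0)
        if degree == 0:
            logger.warning("node %d is isolated in network %d; neighbor sets "
                           "reduced to self/empty", node, U.m)
    return NeighborSets(node, k, same_list, cross_list, same_scores, cross_scores)


def all_neighbor_sets(U: HeteroNetwork, orders, n_k) -> dict:
    """Neighbor sets for every node and order; ``n_k`` maps order -> N_k."""
    out = {}
    for k in orders:
        counts = {t: _walk_counts(U, t, k) for t in ("drug", "disease")}
        for node in range(U.n_drugs + U.n_diseases):
            out[(node, k)] = extract_neighbor_sets(U, node, k, n_k[k],
                                                   _counts=counts)
    return out
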