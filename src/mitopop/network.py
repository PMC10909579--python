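"""Median-joining haplotype networks with maximum-parsimony pruning.

The median-joining construction (Bandelt, Forster & Roehl 1999) iterates two
steps: build the (epsilon-relaxed) minimum spanning network over the current
node set under Hamming distance, then add "median vectors" — site-wise
majority consensus sequences of triplets that are close in the network —
whenever they can shorten the network, until no further median is accepted.
Median vectors are unsampled putative haplotypes (Steiner points).

The maximum-parsimony post-processing of Polzin & Vahdati Daneshmand removes
every link (and any median vector stranded by that removal) that does not lie
on at least one minimum-length spanning structure connecting all sampled
haplotypes.  Among equally short structures, those using fewer median vectors
are preferred, so a retained median vector always has degree >= 3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .popstats import HaplotypeTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HaploNetwork:
    sequences: tuple[str, ...]       # node sequences over the analysed columns
    names: tuple[str, ...]
    sampled: tuple[bool, ...]
    counts: pd.DataFrame             # sampled-node rows x populations
    edges: tuple[tuple[int, int, int], ...]  # (i, j, substitution count)
    epsilon: int = 0

    def degree(self, node: int) -> int:
        return sum(node in (i, j) for i, j, _ in self.edges)

    @property
    def total_length(self) -> int:
        return sum(w for _, _, w in self.edges)

    def minimum_spanning_length(self) -> int:
        """Weight of an MST within the network (all nodes)."""
        import networkx as nx

        g = self.to_networkx()
        return int(sum(d["weight"] for _, _, d in
                       nx.minimum_spanning_edges(g, data=True)))

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph(epsilon=self.epsilon)
        for i, name in enumerate(self.names):
            g.add_node(name, kind="sampled" if self.sampled[i] else "median",
                       sequence=self.sequences[i])
        for i, j, w in self.edges:
            g.add_edge(self.names[i], self.names[j], weight=int(w))
        return g

    def edge_table(self) -> pd.DataFrame:
        rows = [{"node1": self.names[i], "node2": self.names[j], "weight": w,
                 "kind1": "sampled" if self.sampled[i] else "median",
                 "kind2": "sampled" if self.sampled[j] else "median"}
                for i, j, w in self.edges]
        return pd.DataFrame(rows, columns=["node1", "node2", "weight", "kind1", "kind2"])

    def node_table(self) -> pd.DataFrame:
        rows = []
        for i, name in enumerate(self.names):
            row = {"node": name,
                   "kind": "sampled" if self.sampled[i] else "median"}
            if self.sampled[i]:
                row.update(self.counts.loc[name].to_dict())
            rows.append(row)
        return pd.DataFrame(rows)


def _hamming(a: np.ndarray, b: np.ndarray) -> int:
    return int(np.count_nonzero(a != b))


def _distance_matrix(seqs: list[np.ndarray]) -> np.ndarray:
    k = len(seqs)
    d = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i + 1, k):
            d[i, j] = d[j, i] = _hamming(seqs[i], seqs[j])
    return d


class _UnionFind:
    def __init__(self, n):
        self.p = list(range(n))

    def find(self, i):
        while self.p[i] != i:
            self.p[i] = self.p[self.p[i]]
            i = self.p[i]
        return i

    def union(self, i, j):
        self.p[self.find(i)] = self.find(j)


def msn_edges(d: np.ndarray, epsilon: int = 0) -> list[tuple[int, int, int]]:
    """Edges of the epsilon-relaxed minimum spanning network.

    An edge of weight w is kept iff its endpoints are not already connected by
    edges of weight < w - epsilon (epsilon = 0 gives the classical minimum
    spanning network: the union of all MSTs).
    """
    k = d.shape[0]
    pairs = sorted(((int(d[i, j]), i, j) for i in range(k) for j in range(i + 1, k)))
    edges = []
    weights = sorted({w for w, _, _ in pairs})
    uf = _UnionFind(k)
    added_below = 0  # index into pairs of edges merged so far
    for w in weights:
        # merge all edges with weight < w - epsilon into the component structure
        while added_below < len(pairs) and pairs[added_below][0] < w - epsilon:
            _, i, j = pairs[added_below]
            uf.union(i, j)
            added_below += 1
        for wp, i, j in pairs:
            if wp == w and uf.find(i) != uf.find(j):
                edges.append((i, j, w))
    # drop duplicates while preserving order
    return list(dict.fromkeys(edges))


def _majority_median(u: np.ndarray, v: np.ndarray, w: np.ndarray):
    """Site-wise majority of three sequences; None where all three differ."""
    med = u.copy()
    eq_vw = v == w
    med[eq_vw] = v[eq_vw]
    # sites where u agrees with v or w already hold the majority value
    tie = (u != v) & (u != w) & (v != w)
    if tie.any():
        return None
    return med


def median_joining(haplotypes: HaplotypeTable, epsilon: int = 0) -> HaploNetwork:
    """Build the median-joining network of a haplotype table.

    Candidate medians are the site-wise majority sequences of triplets that
    form a path or triangle in the current minimum spanning network; in each
    round every new median whose connection cost is within ``epsilon`` of the
    round's best is added, and unsampled nodes that fall to degree <= 2 in the
    rebuilt network are discarded.  Triplets with a three-way conflict at any
    site yield no single median and are skipped.
    """
    if haplotypes.H < 1:
        raise ValueError("empty haplotype table")
    if len({len(s) for s in haplotypes.sequences}) > 1:
        raise ValueError("haplotypes of unequal length")
    core = haplotypes.core_sequences()
    seqs = [np.frombuffer(s.encode(), dtype=np.uint8).copy() for s in core]
    n_sampled = len(seqs)
    sampled_names = list(haplotypes.counts.index)

    if n_sampled == 1:
        return HaploNetwork(tuple(core), tuple(sampled_names), (True,),
                            haplotypes.counts.copy(), (), epsilon)

    while True:
        d = _distance_matrix(seqs)
        edges = msn_edges(d, epsilon)
        adj = {i: set() for i in range(len(seqs))}
        for i, j, _ in edges:
            adj[i].add(j)
            adj[j].add(i)
        existing = {s.tobytes() for s in seqs}
        candidates = {}
        for v in range(len(seqs)):
            for u, w in combinations(sorted(adj[v]), 2):
                med = _majority_median(seqs[u], seqs[v], seqs[w])
                if med is None:
                    logger.debug("triplet (%d,%d,%d) has a three-way site conflict; skipped",
                                 u, v, w)
                    continue
                key = med.tobytes()
                if key in existing:
                    continue
                cost = (_hamming(med, seqs[u]) + _hamming(med, seqs[v])
                        + _hamming(med, seqs[w]))
                if key not in candidates or cost < candidates[key][0]:
                    candidates[key] = (cost, med)
        if not candidates:
            break
        lam = min(c for c, _ in candidates.values())
        new = [m for c, m in candidates.values() if c <= lam + epsilon]
        before = len(seqs)
        seqs.extend(new)
        # prune unsampled nodes that the enlarged network does not need
        while True:
            d = _distance_matrix(seqs)
            edges = msn_edges(d, epsilon)
            deg = np.zeros(len(seqs), dtype=int)
            for i, j, _ in edges:
                deg[i] += 1
                deg[j] += 1
            drop = [i for i in range(n_sampled, len(seqs)) if deg[i] <= 2]
            if not drop:
                break
            seqs = [s for i, s in enumerate(seqs) if i not in set(drop)]
        if len(seqs) == before:
            break

    d = _distance_matrix(seqs)
    edges = tuple(msn_edges(d, epsilon))
    names = sampled_names + [f"mv{i + 1}" for i in range(len(seqs) - n_sampled)]
    sampled = (True,) * n_sampled + (False,) * (len(seqs) - n_sampled)
    return HaploNetwork(tuple(s.tobytes().decode() for s in seqs), tuple(names),
                        sampled, haplotypes.counts.copy(), edges, epsilon)


def _mst_weight_and_union(nodes: list[int], edges) -> tuple[int | None, set]:
    """MST weight over the induced subgraph, and the union of edges belonging
    to at least one MST (None if the subgraph is disconnected)."""
    node_set = set(nodes)
    sub = [(w, i, j) for i, j, w in edges if i in node_set and j in node_set]
    idx = {v: k for k, v in enumerate(nodes)}
    uf = _UnionFind(len(nodes))
    weight = 0
    n_merged = 0
    for w, i, j in sorted(sub):
        if uf.find(idx[i]) != uf.find(idx[j]):
            uf.union(idx[i], idx[j])
            weight += w
            n_merged += 1
    if n_merged != len(nodes) - 1:
        return None, set()
    # an edge is in some MST iff its endpoints are separated by lighter edges
    union = set()
    for w, i, j in sub:
        uf2 = _UnionFind(len(nodes))
        for w2, a, b in sub:
            if w2 < w:
                uf2.union(idx[a], idx[b])
        if uf2.find(idx[i]) != uf2.find(idx[j]):
            union.add((i, j, w))
    return weight, union


def mp_postprocess(net: HaploNetwork, max_medians: int = 18) -> HaploNetwork:
    """Keep only links lying on a minimum-length spanning structure.

    All subsets of median vectors are searched for the Steiner minimum; among
    optima, subsets with fewer medians win, and the union of all MSTs over all
    winning subsets is retained.  With more than ``max_medians`` median
    vectors the exhaustive search is skipped and the network returned as-is
    (with a warning).
    """
    sampled_idx = [i for i, s in enumerate(net.sampled) if s]
    median_idx = [i for i, s in enumerate(net.sampled) if not s]
    if not median_idx:
        base = set(range(len(net.names)))
        w, union = _mst_weight_and_union(sorted(base), net.edges)
        kept = union
    else:
        if len(median_idx) > max_medians:
            logger.warning("%d median vectors exceed the exhaustive search cap; "
                           "network returned unpruned", len(median_idx))
            return net
        best_w = None
        best_m = None
        optima = []
        for r in range(len(median_idx) + 1):
            for subset in combinations(median_idx, r):
                nodes = sorted(sampled_idx + list(subset))
                w, union = _mst_weight_and_union(nodes, net.edges)
                if w is None:
                    continue
                if best_w is None or (w, r) < (best_w, best_m):
                    best_w, best_m = w, r
                    optima = [union]
                elif (w, r) == (best_w, best_m):
                    optima.append(union)
        kept = set().union(*optima) if optima else set(net.edges)
    keep_nodes = sorted({i for i, j, _ in kept} | {j for _, j, _ in kept}
                        | set(sampled_idx))
    remap = {old: new for new, old in enumerate(keep_nodes)}
    new_edges = tuple(sorted((remap[i], remap[j], w) for i, j, w in kept))
    return HaploNetwork(
        tuple(net.sequences[i] for i in keep_nodes),
        tuple(net.names[i] for i in keep_nodes),
        tuple(net.sampled[i] for i in keep_nodes),
        net.counts.copy(), new_edges, net.epsilon)
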