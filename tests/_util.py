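"""Shared test helpers: random data factories and independent brute-force
oracles (deliberately naive; they must not share code with the package)."""

from __future__ import annotations

from itertools import combinations, product
from math import sqrt

import numpy as np

from mitopop.io import Alignment

BASES = "ACGT"
MISSING_CHARS = "N-"


def random_alignment(rng, n, L, missing=0.0, n_variable=None):
    """Random alignment; optionally only ``n_variable`` columns vary."""
    if n_variable is None:
        mat = rng.choice(list(BASES), size=(n, L))
    else:
        base = rng.choice(list(BASES), size=L)
        mat = np.tile(base, (n, 1))
        var_cols = rng.choice(L, size=n_variable, replace=False)
        for c in var_cols:
            alt = rng.choice([b for b in BASES if b != base[c]])
            carriers = rng.random(n) < rng.uniform(0.1, 0.9)
            mat[carriers, c] = alt
    if missing > 0:
        mat[rng.random(mat.shape) < missing] = "N"
    seqs = ["".join(row) for row in mat]
    return Alignment.from_seqs([f"s{i}" for i in range(n)], seqs)


# ---------------------------------------------------------------------------
# Naive oracles (plain Python double loops)
# ---------------------------------------------------------------------------

def oracle_site_counts(aln):
    """(S, parsimony_informative, singleton site list) by per-column scan."""
    S = pinf = 0
    singles = []
    for col in range(aln.length):
        calls = [s[col] for s in aln.seqs if s[col] in BASES]
        counts = {b: calls.count(b) for b in set(calls)}
        if len(counts) >= 2:
            S += 1
            if sum(1 for v in counts.values() if v >= 2) >= 2:
                pinf += 1
            else:
                singles.append(col)
    return S, pinf, singles


def oracle_pairwise(aln, i, j):
    d = comp = 0
    si, sj = aln.seqs[i], aln.seqs[j]
    for a, b in zip(si, sj):
        if a in BASES and b in BASES:
            comp += 1
            if a != b:
                d += 1
    return d, comp


def oracle_pi(aln):
    """Average pairwise per-site difference (pairwise deletion)."""
    vals = []
    for i, j in combinations(range(aln.n), 2):
        d, comp = oracle_pairwise(aln, i, j)
        vals.append(d / comp)
    return sum(vals) / len(vals)


def oracle_mean_pairwise(aln):
    vals = [oracle_pairwise(aln, i, j)[0] for i, j in combinations(range(aln.n), 2)]
    return sum(vals) / len(vals)


def oracle_haplotype_diversity(counts):
    n = sum(counts)
    return n / (n - 1) * (1 - sum((c / n) ** 2 for c in counts))


def oracle_r2(aln):
    """Direct recount of singletons and the R2 formula."""
    n = aln.n
    S, _, singles = oracle_site_counts(aln)
    if S == 0:
        return None
    U = [0] * n
    if n > 2:
        for col in singles:
            calls = [(i, s[col]) for i, s in enumerate(aln.seqs) if s[col] in BASES]
            counts = {}
            for _, b in calls:
                counts[b] = counts.get(b, 0) + 1
            for i, b in calls:
                if counts[b] == 1:
                    U[i] += 1
    kbar = oracle_mean_pairwise(aln)
    return sqrt(sum((u - kbar / 2) ** 2 for u in U) / n) / S


def oracle_mismatch_hist(aln):
    ds = [oracle_pairwise(aln, i, j)[0] for i, j in combinations(range(aln.n), 2)]
    out = [0] * (max(ds) + 1)
    for d in ds:
        out[d] += 1
    return out


# ---------------------------------------------------------------------------
# Exhaustive network oracle: quasi-median closure + Steiner search
# ---------------------------------------------------------------------------

def _hamming_str(a, b):
    return sum(x != y for x, y in zip(a, b))


def quasi_median_closure(seqs, cap=200):
    """Close a set of sequences under the quasi-median operation: for every
    triple and every site take the majority state, or all three states where
    all differ."""
    closure = set(seqs)
    changed = True
    while changed and len(closure) < cap:
        changed = False
        current = sorted(closure)
        for u, v, w in combinations(current, 3):
            options = []
            for a, b, c in zip(u, v, w):
                if a == b or a == c:
                    options.append((a,))
                elif b == c:
                    options.append((b,))
                else:
                    options.append((a, b, c))
            for combo in product(*options):
                s = "".join(combo)
                if s not in closure:
                    closure.add(s)
                    changed = True
        if len(closure) >= cap:
            raise RuntimeError("quasi-median closure exploded")
    return sorted(closure)


def _mst_info(nodes, weight_of):
    """(weight, union of edges in some MST) over a complete graph."""
    edges = sorted((weight_of(a, b), a, b) for a, b in combinations(nodes, 2))
    parent = {v: v for v in nodes}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    weight = 0
    merged = 0
    for w, a, b in edges:
        if find(a) != find(b):
            parent[find(a)] = find(b)
            weight += w
            merged += 1
    if merged != len(nodes) - 1:
        return None, set()
    union = set()
    for w, a, b in edges:
        parent2 = {v: v for v in nodes}

        def find2(v):
            while parent2[v] != v:
                parent2[v] = parent2[parent2[v]]
                v = parent2[v]
            return v

        for w2, a2, b2 in edges:
            if w2 < w:
                parent2[find2(a2)] = find2(b2)
        if find2(a) != find2(b):
            union.add((min(a, b), max(a, b), w))
    return weight, union


def steiner_oracle(sampled):
    """Minimum Steiner network over the quasi-median closure.

    Returns (weight, edge union, used nodes): minimum over subsets of closure
    points of the MST weight of sampled+subset; ties broken toward fewer
    added points; the edge union pools all MSTs of all optimal subsets.
    """
    closure = quasi_median_closure(sampled)
    extras = [s for s in closure if s not in set(sampled)]
    best = None
    optima = []
    # a minimum Steiner tree on k terminals needs at most k-2 extra points
    r_max = min(len(extras), max(len(sampled) - 2, 0))
    for r in range(r_max + 1):
        for subset in combinations(extras, r):
            nodes = list(sampled) + list(subset)
            w, union = _mst_info(nodes, _hamming_str)
            if w is None:
                continue
            if best is None or (w, r) < best:
                best = (w, r)
                optima = [union]
            elif (w, r) == best:
                optima.append(union)
    union = set().union(*optima)
    used = {a for a, _, _ in union} | {b for _, b, _ in union} | set(sampled)
    return best[0], union, used


def network_edge_set(net):
    """Canonical {(seq_a, seq_b, w)} with seq_a < seq_b for comparison."""
    out = set()
    for i, j, w in net.edges:
        a, b = sorted((net.sequences[i], net.sequences[j]))
        out.add((a, b, w))
    return out
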