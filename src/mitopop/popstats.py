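"""Site classification, haplotype collapsing, and diversity statistics.

Implements the DnaSP-style summary statistics for haploid sequence data:
segregating and parsimony-informative site counts, haplotype number ``H`` and
diversity ``h`` (with Nei's sampling variances), per-site nucleotide diversity
``pi``, rarefied haplotype richness ``H_R`` (FSTAT-style), and pairwise
difference matrices.

Missing data (``N`` or ``-``) are handled by either *complete deletion*
(columns with any missing call are dropped before comparing sequences; the
DnaSP default, used for haplotype collapsing and site counts) or *pairwise
deletion* (each pair compared over its jointly called sites; used for pi).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, sqrt

import numpy as np
import pandas as pd

from .io import Alignment, PopulationMap

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_MISSING = np.frombuffer(b"N-", dtype=np.uint8)


def _base_counts(matrix: np.ndarray) -> np.ndarray:
    """(4, L) counts of A, C, G, T per column, missing ignored."""
    return np.stack([(matrix == b).sum(axis=0) for b in _BASES])


@dataclass(frozen=True)
class SiteClassification:
    """Per-column categories: invariant | singleton | informative | uncalled."""

    categories: tuple[str, ...]

    @property
    def S(self) -> int:
        return sum(c in ("singleton", "informative") for c in self.categories)

    @property
    def parsimony_informative(self) -> int:
        return sum(c == "informative" for c in self.categories)

    @property
    def singleton_sites(self) -> tuple[int, ...]:
        return tuple(i for i, c in enumerate(self.categories) if c == "singleton")

    @property
    def segregating_sites(self) -> tuple[int, ...]:
        return tuple(i for i, c in enumerate(self.categories)
                     if c in ("singleton", "informative"))


def classify_sites(alignment: Alignment) -> SiteClassification:
    """Classify every column of the alignment, ignoring missing calls.

    A column is polymorphic iff >=2 distinct bases occur among the called
    sequences, parsimony-informative iff >=2 bases each occur >=2 times, and a
    singleton site iff it is polymorphic but not informative (every base but
    one occurs exactly once).  All-missing columns are "uncalled".
    """
    if alignment.n < 2:
        raise ValueError("site classification requires n >= 2 sequences")
    counts = _base_counts(alignment.matrix)
    n_called = counts.sum(axis=0)
    n_alleles = (counts > 0).sum(axis=0)
    n_major = (counts >= 2).sum(axis=0)
    cats = np.where(n_called == 0, "uncalled",
                    np.where(n_alleles < 2, "invariant",
                             np.where(n_major >= 2, "informative", "singleton")))
    return SiteClassification(tuple(cats.tolist()))


@dataclass(frozen=True)
class HaplotypeTable:
    """Distinct haplotypes with per-population sample counts.

    ``sequences`` are representative full-length sequences (one per
    haplotype); identity was established over ``retained_columns`` only.
    """

    sequences: tuple[str, ...]
    counts: pd.DataFrame            # haplotypes x populations
    members: tuple[tuple[str, ...], ...]
    retained_columns: tuple[int, ...]

    @property
    def H(self) -> int:
        return len(self.sequences)

    @property
    def total_counts(self) -> np.ndarray:
        return self.counts.sum(axis=1).to_numpy()

    def core_sequences(self) -> tuple[str, ...]:
        """Representative sequences restricted to the retained columns."""
        cols = list(self.retained_columns)
        return tuple("".join(s[c] for c in cols) for s in self.sequences)


def collapse_haplotypes(alignment: Alignment,
                        popmap: PopulationMap | None = None,
                        missing_policy: str = "complete") -> HaplotypeTable:
    """Group identical sequences into haplotypes.

    ``missing_policy="complete"`` drops every column containing any missing
    call before comparing (DnaSP default).  ``"pairwise"`` compares sequences
    over jointly called sites; because that relation is not transitive, each
    sequence greedily joins the first existing haplotype whose representative
    it matches with zero differences (input order), else founds a new one.
    """
    mat = alignment.matrix
    n, L = mat.shape
    missing = np.isin(mat, _MISSING)
    if missing_policy == "complete":
        keep = ~missing.any(axis=0)
        if not keep.any() and L > 0:
            raise ValueError(
                "complete deletion removed every column; consider missing_policy='pairwise'")
        core = mat[:, keep]
        retained = tuple(np.flatnonzero(keep).tolist())
        _, first, inverse = np.unique(core, axis=0, return_index=True, return_inverse=True)
        # renumber haplotypes by first occurrence so output order is stable
        order = np.argsort(first, kind="stable")
        rank = np.empty_like(order)
        rank[order] = np.arange(len(order))
        labels = rank[inverse]
    elif missing_policy == "pairwise":
        retained = tuple(range(L))
        reps: list[int] = []
        labels = np.empty(n, dtype=int)
        for i in range(n):
            for h, r in enumerate(reps):
                called = ~missing[i] & ~missing[r]
                if not np.any(mat[i, called] != mat[r, called]):
                    labels[i] = h
                    break
            else:
                labels[i] = len(reps)
                reps.append(i)
    else:
        raise ValueError(f"unknown missing_policy {missing_policy!r}")

    H = int(labels.max()) + 1 if n else 0
    pops = popmap.populations if popmap is not None else ("all",)
    counts = np.zeros((H, len(pops)), dtype=int)
    members: list[list[str]] = [[] for _ in range(H)]
    reps = [None] * H
    for i, sid in enumerate(alignment.ids):
        h = labels[i]
        members[h].append(sid)
        if reps[h] is None:
            reps[h] = alignment.sequence(sid)
        pop = popmap.sample_to_pop[sid] if popmap is not None else "all"
        counts[h, pops.index(pop)] += 1
    df = pd.DataFrame(counts, columns=list(pops),
                      index=[f"Hap{i + 1}" for i in range(H)])
    return HaplotypeTable(tuple(reps), df, tuple(tuple(m) for m in members), retained)


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    d: np.ndarray         # (n, n) int, pairwise difference counts
    compared: np.ndarray  # (n, n) int, jointly called sites per pair

    def __post_init__(self) -> None:
        assert self.d.shape == self.compared.shape
        assert np.array_equal(self.d, self.d.T) and np.all(np.diag(self.d) == 0)


def distance_matrix(alignment: Alignment) -> DistanceMatrix:
    """Pairwise Hamming counts over jointly called sites (pairwise deletion)."""
    mat = alignment.matrix
    n = alignment.n
    if n < 2:
        raise ValueError("distance matrix requires >= 2 sequences")
    called = ~np.isin(mat, _MISSING)
    d = np.zeros((n, n), dtype=np.int64)
    comp = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        joint = called[i] & called[i:]
        diff = (mat[i] != mat[i:]) & joint
        d[i, i:] = diff.sum(axis=1)
        comp[i, i:] = joint.sum(axis=1)
    d = d + d.T
    comp = comp + comp.T - np.diag(np.diag(comp))
    return DistanceMatrix(alignment.ids, d, comp)


def nucleotide_diversity(alignment: Alignment) -> tuple[float, float]:
    """Per-site nucleotide diversity pi with its sampling SD.

    pi is the average over all sequence pairs of (differences / jointly called
    sites); the SD comes from Nei's (1987) sampling-variance approximation

        V(pi) = (n+1) pi / (3 (n-1) L)  +  2 (n^2 + n + 3) pi^2 / (9 n (n-1))

    with L the mean number of jointly called sites per pair.
    """
    dm = distance_matrix(alignment)
    n = alignment.n
    iu = np.triu_indices(n, 1)
    comp = dm.compared[iu]
    if np.any(comp == 0):
        raise ValueError("a sequence pair shares zero called sites")
    pi = float(np.mean(dm.d[iu] / comp))
    L = float(np.mean(comp))
    var = (n + 1) * pi / (3 * (n - 1) * L) + \
        2 * (n ** 2 + n + 3) * pi ** 2 / (9 * n * (n - 1))
    return pi, sqrt(var)


def mean_pairwise_differences(alignment: Alignment) -> float:
    """Average pairwise difference count per locus (theta-pi input to Fu's Fs)."""
    dm = distance_matrix(alignment)
    iu = np.triu_indices(alignment.n, 1)
    return float(np.mean(dm.d[iu]))


def haplotype_diversity(hap_counts, n: int | None = None) -> tuple[float, float]:
    """Gene diversity h = n(1 - sum p_i^2)/(n-1) with Nei's (1987) variance.

        V(h) = 2/(n(n-1)) { 2(n-2)[sum p^3 - (sum p^2)^2] + sum p^2 - (sum p^2)^2 }
    """
    counts = np.asarray(hap_counts, dtype=float)
    total = int(counts.sum()) if n is None else int(n)
    if total < 2:
        raise ValueError("haplotype diversity requires n >= 2")
    p = counts / total
    sp2 = float(np.sum(p ** 2))
    sp3 = float(np.sum(p ** 3))
    h = total * (1.0 - sp2) / (total - 1)
    var = 2.0 / (total * (total - 1)) * (
        2.0 * (total - 2) * (sp3 - sp2 ** 2) + sp2 - sp2 ** 2)
    return h, sqrt(max(var, 0.0))


def haplotype_richness(hap_counts, g: int) -> float:
    """Rarefied haplotype richness: expected number of distinct haplotypes in
    a random subsample of size g, computed by exact hypergeometric rarefaction

        H_R = sum_h [ 1 - C(N - N_h, g) / C(N, g) ].
    """
    counts = [int(c) for c in hap_counts if c > 0]
    N = sum(counts)
    if not 1 <= g <= N:
        raise ValueError(f"rarefaction size g={g} outside [1, N={N}]")
    denom = comb(N, g)
    return float(sum(1.0 - comb(N - c, g) / denom for c in counts))


def diversity_table(alignment: Alignment, popmap: PopulationMap,
                    rarefaction_g: int | None = None,
                    aggregates: dict | None = None) -> pd.DataFrame:
    """Per-population summary with the usual columns
    (N, polymorphic sites, H, pi +/- SD, h +/- SD, H_R).

    ``aggregates`` maps an extra row name to the populations pooled into it
    (pooled samples, not averaged statistics).  Rarefaction defaults to the
    smallest population size among the non-aggregate rows.
    """
    pop_samples = {p: list(popmap.samples_in(p)) for p in popmap.populations}
    if rarefaction_g is None:
        rarefaction_g = min(len(s) for s in pop_samples.values())
    rows = {}
    entries = list(pop_samples.items())
    for name, pops in (aggregates or {}).items():
        pooled = [s for p in pops for s in pop_samples[p]]
        entries.append((name, pooled))
    for name, samples in entries:
        sub = alignment.subset(samples)
        sc = classify_sites(sub) if sub.n >= 2 else None
        ht = collapse_haplotypes(sub)
        pi, pi_sd = nucleotide_diversity(sub) if sub.n >= 2 else (float("nan"),) * 2
        h, h_sd = haplotype_diversity(ht.total_counts) if sub.n >= 2 else (float("nan"),) * 2
        g = min(rarefaction_g, sub.n)
        rows[name] = {
            "N": sub.n,
            "polymorphic_sites": sc.S if sc else 0,
            "parsimony_informative": sc.parsimony_informative if sc else 0,
            "H": ht.H,
            "pi": pi, "pi_sd": pi_sd,
            "h": h, "h_sd": h_sd,
            "H_R": haplotype_richness(ht.total_counts, g),
        }
    return pd.DataFrame(rows).T.convert_dtypes()
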