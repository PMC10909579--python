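"""Neutrality tests: Fu's Fs via the Ewens sampling formula, and the
Ramos-Onsins & Rozas R2 statistic, with coalescent-simulation p-values.

Fu's Fs uses the Ewens (1972) distribution of the number of distinct alleles
K in a sample of size n under the infinite-alleles model,

    P(K = k | theta) = |s(n, k)| theta^k / (theta (theta+1) ... (theta+n-1)),

where |s(n, k)| are unsigned Stirling numbers of the first kind.  With theta
estimated by the mean number of pairwise differences (theta_pi), the tail
probability S' = P(K >= k_obs) gives

    Fs = ln( S' / (1 - S') ).

Large negative Fs means more haplotypes than the neutral-equilibrium
expectation: the signature of recent expansion or hitchhiking.

R2 (Ramos-Onsins & Rozas 2002) compares per-sequence singleton loads U_i with
half the mean pairwise difference k-bar:

    R2 = sqrt( (1/n) sum_i (U_i - k_bar/2)^2 ) / S .

Both statistics are small under expansion, so the simulation p-values are
lower-tail: the proportion of constant-size coalescent samples (conditioned
on the observed number of segregating sites) whose statistic is <= observed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .io import Alignment
from .popstats import classify_sites, collapse_haplotypes, mean_pairwise_differences


@lru_cache(maxsize=64)
def _log_stirling_row(n: int) -> np.ndarray:
    """log |s(n, k)| for k = 0..n via |s(n+1,k)| = n|s(n,k)| + |s(n,k-1)|."""
    row = np.full(2, -np.inf)
    row[1] = 0.0  # |s(1,1)| = 1
    for m in range(1, n):
        new = np.full(m + 2, -np.inf)
        new[1:] = np.logaddexp(np.log(m) + np.append(row, -np.inf)[1:],
                               row[0:m + 1])
        row = new
    return row


def ewens_haplotype_pmf(n: int, theta: float) -> np.ndarray:
    """P(K = k) for k = 1..n under the Ewens sampling formula (log-space)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if theta <= 0:
        raise ValueError("theta must be > 0")
    if n == 1:
        return np.array([1.0])
    log_s = _log_stirling_row(n)[1:]
    k = np.arange(1, n + 1)
    log_denom = np.sum(np.log(theta + np.arange(n)))
    log_p = log_s + k * math.log(theta) - log_denom
    return np.exp(log_p)


@dataclass(frozen=True)
class FsResult:
    Fs: float
    S_prime: float           # tail probability P(K >= k_obs)
    k_obs: int
    theta_pi: float
    n: int
    flag: str | None = None  # "undefined (monomorphic)" when k_obs == 1


def fu_fs(n: int, k_obs: int, theta_pi: float) -> FsResult:
    """Fu's Fs from the sample size, observed haplotype count, and theta_pi."""
    if n < 2:
        raise ValueError("Fu's Fs requires n >= 2")
    if not 1 <= k_obs <= n:
        raise ValueError(f"k_obs={k_obs} outside [1, n={n}]")
    if k_obs == 1:
        return FsResult(math.inf, 1.0, k_obs, theta_pi, n, "undefined (monomorphic)")
    if theta_pi <= 0:
        raise ValueError("theta_pi must be > 0 when k_obs > 1")
    pmf = ewens_haplotype_pmf(n, theta_pi)
    s_prime = float(pmf[k_obs - 1:].sum())
    s_prime = min(max(s_prime, 1e-300), 1.0)
    if s_prime >= 1.0:
        return FsResult(-math.inf, 1.0, k_obs, theta_pi, n, "S' saturated")
    return FsResult(math.log(s_prime / (1.0 - s_prime)), s_prime, k_obs, theta_pi, n)


def fu_fs_from_alignment(alignment: Alignment) -> FsResult:
    ht = collapse_haplotypes(alignment)
    theta_pi = mean_pairwise_differences(alignment)
    return fu_fs(alignment.n, ht.H, theta_pi)


@dataclass(frozen=True)
class R2Result:
    R2: float
    U: tuple[int, ...]
    k_bar: float
    S: int
    n: int
    flag: str | None = None


def r2_statistic(alignment: Alignment) -> R2Result:
    """Ramos-Onsins & Rozas R2 from per-sequence singleton counts.

    A singleton site has a minor base carried by exactly one sequence; that
    sequence's U_i is incremented.  For n = 2 both bases at a variable site
    have count 1, so no singleton can be assigned and such sites are excluded
    from U (the statistic is still defined through S and k_bar).
    """
    n = alignment.n
    if n < 2:
        raise ValueError("R2 requires n >= 2")
    sc = classify_sites(alignment)
    if sc.S == 0:
        return R2Result(math.nan, (0,) * n, 0.0, 0, n, "undefined (S = 0)")
    U = np.zeros(n, dtype=int)
    mat = alignment.matrix
    if n > 2:
        for col in sc.singleton_sites:
            column = mat[:, col]
            bases, counts = np.unique(
                column[~np.isin(column, np.frombuffer(b"N-", dtype=np.uint8))],
                return_counts=True)
            for b, c in zip(bases, counts):
                if c == 1:
                    U[np.flatnonzero(column == b)[0]] += 1
    k_bar = mean_pairwise_differences(alignment)
    r2 = math.sqrt(float(np.mean((U - k_bar / 2.0) ** 2))) / sc.S
    return R2Result(r2, tuple(U.tolist()), k_bar, sc.S, n)


# ---------------------------------------------------------------------------
# Null simulations (constant-size coalescent conditioned on S)
# ---------------------------------------------------------------------------

def _coalescent_branches(n: int, rng: np.random.Generator):
    """Simulate a Kingman genealogy; return (branch lengths, descendant sets).

    Nodes 0..n-1 are leaves.  ``desc`` is a (2n-2, n) boolean matrix giving
    the leaves below each non-root node; branch i joins node i to its parent.
    """
    desc = np.zeros((2 * n - 1, n), dtype=bool)
    desc[np.arange(n), np.arange(n)] = True
    times = np.zeros(2 * n - 1)
    active = list(range(n))
    t = 0.0
    nxt = n
    parent_time = np.zeros(2 * n - 1)
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        desc[nxt] = desc[a] | desc[b]
        times[nxt] = t
        parent_time[a] = parent_time[b] = t
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    lengths = parent_time[: 2 * n - 2] - times[: 2 * n - 2]
    return lengths, desc[: 2 * n - 2]


def _fixed_s_sample(n: int, S: int, rng: np.random.Generator) -> np.ndarray:
    """(n, S) binary genotype matrix: S mutations multinomially placed on a
    constant-size coalescent genealogy, infinite sites."""
    lengths, desc = _coalescent_branches(n, rng)
    p = lengths / lengths.sum()
    counts = rng.multinomial(S, p)
    cols = np.repeat(np.arange(len(lengths)), counts)
    return desc[cols].T.astype(np.uint8)


def _stats_from_genotypes(G: np.ndarray):
    """(k_haplotypes, k_bar, U per sequence, S) from a 0/1 genotype matrix."""
    n, S = G.shape
    c = G.sum(axis=0)
    k_bar = float(np.sum(2.0 * c * (n - c)) / (n * (n - 1)))
    k = len(np.unique(G, axis=0))
    U = np.zeros(n, dtype=int)
    if n > 2:
        for s in np.flatnonzero(c == 1):
            U[np.flatnonzero(G[:, s] == 1)[0]] += 1
        for s in np.flatnonzero(c == n - 1):
            U[np.flatnonzero(G[:, s] == 0)[0]] += 1
    return k, k_bar, U, S


def simulate_null_statistics(kind: str, n: int, S_obs: int, n_sims: int,
                             seed=None) -> np.ndarray:
    """Null distribution of Fs or R2 under the fixed-S constant coalescent."""
    if S_obs <= 0:
        raise ValueError("null simulation requires S_obs >= 1")
    rng = np.random.default_rng(seed)
    out = np.empty(n_sims)
    for b in range(n_sims):
        G = _fixed_s_sample(n, S_obs, rng)
        k, k_bar, U, S = _stats_from_genotypes(G)
        if kind == "Fs":
            if k == 1 or k_bar <= 0:
                out[b] = math.inf
            else:
                out[b] = fu_fs(n, k, k_bar).Fs
        elif kind == "R2":
            out[b] = math.sqrt(float(np.mean((U - k_bar / 2.0) ** 2))) / S
        else:
            raise ValueError(f"unknown statistic kind {kind!r}")
    return out


def neutrality_pvalue(kind: str, observed: float, n: int, S_obs: int,
                      n_sims: int = 10_000, seed=None) -> float:
    """Lower-tail simulation p-value, with the (b+1)/(B+1) correction."""
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100")
    sims = simulate_null_statistics(kind, n, S_obs, n_sims, seed)
    b = int(np.sum(sims <= observed))
    return (b + 1) / (n_sims + 1)
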