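"""Hierarchical analysis of molecular variance (AMOVA) and pairwise Phi-ST.

Variance components follow the Excoffier, Smouse & Quattro (1992) least
squares decomposition of pairwise distances.  For haploid sequence data the
pairwise difference counts are used directly as squared Euclidean distances
(the Arlequin convention), so the fixation indices are the distance-based
Phi statistics; the exported tables label them F_ST as Arlequin does.

Hierarchy: groups > populations > individuals.  With a single group (or when
every population is its own group but only Phi_ST is requested) the design
reduces to the classical two-level AMOVA.

Significance is assessed by permutation:

* Phi_ST  — individuals permuted among populations (ignoring groups),
* Phi_CT  — whole populations permuted among groups,
* Phi_SC  — individuals permuted among populations within their group,

with p = (number of permuted statistics >= observed + 1) / (n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import PopulationMap
from .popstats import DistanceMatrix


@dataclass(frozen=True)
class AmovaResult:
    df: dict                 # level -> degrees of freedom
    ss: dict                 # level -> sum of squares
    sigma2: dict             # level -> variance component
    pct_variation: dict      # level -> percent of total variance
    phi: dict                # index name -> value (phi_ST always; phi_CT/phi_SC with groups)
    p_values: dict           # index name -> permutation p (may be empty)
    n_perm: int = 0
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for level in self.df:
            rows.append({
                "source": level,
                "df": self.df[level],
                "sum_of_squares": self.ss.get(level, float("nan")),
                "variance_component": self.sigma2.get(level, float("nan")),
                "pct_variation": self.pct_variation.get(level, float("nan")),
            })
        out = pd.DataFrame(rows)
        for name, val in self.phi.items():
            out.loc[out.index[-1], name] = val
            if name in self.p_values:
                out.loc[out.index[-1], f"p_{name}"] = self.p_values[name]
        return out


@dataclass(frozen=True)
class FstMatrix:
    populations: tuple[str, ...]
    fst: np.ndarray       # symmetric estimates
    p: np.ndarray         # symmetric permutation p-values

    def to_frame(self) -> pd.DataFrame:
        """Estimates below the diagonal, p-values above (Arlequin table layout)."""
        k = len(self.populations)
        out = np.full((k, k), np.nan)
        for i in range(k):
            for j in range(k):
                if i > j:
                    out[i, j] = self.fst[i, j]
                elif i < j:
                    out[i, j] = self.p[i, j]
        return pd.DataFrame(out, index=self.populations, columns=self.populations)


def _ss_within(d2: np.ndarray, idx: np.ndarray) -> float:
    """Sum of squares within one set of individuals: (1/n) sum_{i<j} d2."""
    sub = d2[np.ix_(idx, idx)]
    return float(sub.sum() / (2 * len(idx)))


def _components(d2: np.ndarray, pop_codes: np.ndarray, group_of_pop: np.ndarray):
    """Variance components for a (possibly degenerate) two/three-level design.

    pop_codes: per-individual population index 0..P-1
    group_of_pop: per-population group index 0..G-1
    Returns (df, ss, sigma2) dicts keyed by level name.
    """
    N = len(pop_codes)
    pops = np.unique(pop_codes)
    P = len(pops)
    groups = np.unique(group_of_pop)
    G = len(groups)
    all_idx = np.arange(N)
    grp_codes = group_of_pop[pop_codes]

    ss_total = _ss_within(d2, all_idx)
    ss_wp = sum(_ss_within(d2, np.flatnonzero(pop_codes == p)) for p in pops)
    ss_wg = sum(_ss_within(d2, np.flatnonzero(grp_codes == g)) for g in groups)
    ss_ap_wg = ss_wg - ss_wp          # among populations within groups
    ss_ag = ss_total - ss_wg          # among groups

    n_p = np.array([(pop_codes == p).sum() for p in pops], dtype=float)
    n_g = np.array([(grp_codes == g).sum() for g in groups], dtype=float)
    sum_np2_by_group = np.array(
        [sum(n_p[i] ** 2 for i in range(P) if group_of_pop[pops[i]] == g)
         for g in groups])

    df_wp = N - P
    df_ap = P - G
    df_ag = G - 1

    sigma_c = ss_wp / df_wp if df_wp > 0 else 0.0
    if G < P:
        n_prime = (N - float(np.sum(sum_np2_by_group / n_g))) / df_ap
        sigma_b = (ss_ap_wg / df_ap - sigma_c) / n_prime
    else:
        sigma_b = 0.0
    if G > 1:
        n_dblprime = (float(np.sum(sum_np2_by_group / n_g)) - float(np.sum(n_p ** 2)) / N) / df_ag
        n_triprime = (N - float(np.sum(n_g ** 2)) / N) / df_ag
        sigma_a = (ss_ag / df_ag - sigma_c - n_dblprime * sigma_b) / n_triprime
    else:
        sigma_a = 0.0

    df = {"among_groups": df_ag, "among_pops_within_groups": df_ap, "within_pops": df_wp}
    ss = {"among_groups": ss_ag, "among_pops_within_groups": ss_ap_wg, "within_pops": ss_wp}
    sigma2 = {"among_groups": sigma_a, "among_pops_within_groups": sigma_b,
              "within_pops": sigma_c}
    return df, ss, sigma2


def _phi_from_sigma(sigma2: dict) -> dict:
    a = sigma2["among_groups"]
    b = sigma2["among_pops_within_groups"]
    c = sigma2["within_pops"]
    total = a + b + c
    phi = {"phi_ST": (a + b) / total if total != 0 else 0.0}
    phi["phi_CT"] = a / total if total != 0 else 0.0
    phi["phi_SC"] = b / (b + c) if (b + c) != 0 else 0.0
    return phi


def amova(dist: DistanceMatrix, popmap: PopulationMap,
          n_perm: int = 10_000, seed: int | None = None) -> AmovaResult:
    """Hierarchical AMOVA on a pairwise difference matrix.

    With >=2 groups a full three-level analysis is returned (Phi_CT, Phi_SC,
    Phi_ST); with a single group the among-groups level is degenerate and only
    Phi_ST is reported.
    """
    ids = dist.ids
    pops = popmap.populations
    if len(pops) < 2:
        raise ValueError("AMOVA requires >= 2 populations")
    pop_index = {p: i for i, p in enumerate(pops)}
    pop_codes = np.array([pop_index[popmap.sample_to_pop[s]] for s in ids])
    groups = popmap.groups
    group_index = {g: i for i, g in enumerate(groups)}
    group_of_pop = np.array([group_index[popmap.pop_to_group[p]] for p in pops])
    if len(groups) == len(pops):
        # every population its own group (the default map): the group level is
        # vacuous, so analyse the classical two-level design instead
        groups = ("all",)
        group_of_pop = np.zeros(len(pops), dtype=int)
    d2 = dist.d.astype(float)

    df, ss, sigma2 = _components(d2, pop_codes, group_of_pop)
    phi = _phi_from_sigma(sigma2)
    G = len(groups)
    if G == 1:
        # two-level design: drop the vacuous group level
        df = {"among_pops": df["among_pops_within_groups"], "within_pops": df["within_pops"]}
        ss = {"among_pops": ss["among_pops_within_groups"], "within_pops": ss["within_pops"]}
        sigma2 = {"among_pops": sigma2["among_pops_within_groups"],
                  "within_pops": sigma2["within_pops"]}
        phi = {"phi_ST": phi["phi_ST"]}
        total = sum(sigma2.values())
        pct = {k: 100.0 * v / total if total != 0 else float("nan") for k, v in sigma2.items()}
    else:
        total = sum(sigma2.values())
        pct = {k: 100.0 * v / total if total != 0 else float("nan") for k, v in sigma2.items()}

    p_values: dict = {}
    if n_perm and n_perm > 0:
        rng = np.random.default_rng(seed)
        exceed = dict.fromkeys(phi, 0)
        for _ in range(n_perm):
            # phi_ST: individuals among populations, ignoring group structure
            perm_codes = rng.permutation(pop_codes)
            if G == 1:
                _, _, s2 = _components(d2, perm_codes, group_of_pop)
                if _phi_from_sigma(s2)["phi_ST"] >= phi["phi_ST"]:
                    exceed["phi_ST"] += 1
            else:
                _, _, s2 = _components(d2, perm_codes, group_of_pop)
                if _phi_from_sigma(s2)["phi_ST"] >= phi["phi_ST"]:
                    exceed["phi_ST"] += 1
                # phi_CT: whole populations among groups
                perm_gop = rng.permutation(group_of_pop)
                _, _, s2 = _components(d2, pop_codes, perm_gop)
                if _phi_from_sigma(s2)["phi_CT"] >= phi["phi_CT"]:
                    exceed["phi_CT"] += 1
                # phi_SC: individuals among populations within their group
                perm_within = pop_codes.copy()
                grp_codes = group_of_pop[pop_codes]
                for g in range(G):
                    sel = np.flatnonzero(grp_codes == g)
                    perm_within[sel] = rng.permutation(pop_codes[sel])
                _, _, s2 = _components(d2, perm_within, group_of_pop)
                if _phi_from_sigma(s2)["phi_SC"] >= phi["phi_SC"]:
                    exceed["phi_SC"] += 1
        p_values = {k: (v + 1) / (n_perm + 1) for k, v in exceed.items()}

    return AmovaResult(df, ss, sigma2, pct, phi, p_values, n_perm, seed)


def pairwise_fst(dist: DistanceMatrix, popmap: PopulationMap,
                 n_perm: int = 10_000, seed: int | None = None,
                 floor_at_zero: bool = False) -> FstMatrix:
    """Pairwise distance-based Phi_ST between every pair of populations.

    Each pair is analysed as a two-population AMOVA on the sub-matrix of
    distances, with individuals permuted between the two populations for the
    p-value.  Negative estimates are reported as computed unless
    ``floor_at_zero``.
    """
    ids = dist.ids
    pops = popmap.populations
    k = len(pops)
    if k < 2:
        raise ValueError("pairwise Fst requires >= 2 populations")
    rng = np.random.default_rng(seed)
    fst = np.zeros((k, k))
    pvals = np.ones((k, k))
    id_index = {s: i for i, s in enumerate(ids)}
    for a in range(k):
        for b in range(a + 1, k):
            samples = [id_index[s] for s in popmap.samples_in(pops[a])] + \
                      [id_index[s] for s in popmap.samples_in(pops[b])]
            n_a = len(popmap.samples_in(pops[a]))
            codes = np.array([0] * n_a + [1] * (len(samples) - n_a))
            sub = dist.d[np.ix_(samples, samples)].astype(float)
            gop = np.array([0, 0])
            _, _, s2 = _components(sub, codes, gop)
            est = _phi_from_sigma(s2)["phi_ST"]
            exceed = 0
            for _ in range(n_perm):
                _, _, s2p = _components(sub, rng.permutation(codes), gop)
                if _phi_from_sigma(s2p)["phi_ST"] >= est:
                    exceed += 1
            fst[a, b] = fst[b, a] = max(est, 0.0) if floor_at_zero else est
            pvals[a, b] = pvals[b, a] = (exceed + 1) / (n_perm + 1)
    return FstMatrix(pops, fst, pvals)
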