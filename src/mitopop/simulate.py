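"""Coalescent simulation of haploid sequence samples with known truth.

The engine is a structured Kingman coalescent run directly in *mutational
time*: a deme of scaled size theta coalesces any lineage pair at rate
1/theta, and mutations fall on the genealogy at rate 1/2 per branch per unit
time, so two lineages that coalesce at time t differ at Poisson(t) sites and
a constant deme of size theta has E[pairwise differences] = theta.  Mutations
follow the infinite-sites model, mapped to distinct uniform positions on a
sequence of length L.

Demographic events (backward in time) are instantaneous size changes,
per-deme exponential growth, deme mergers (population splits viewed
backward), and instantaneous founder bottlenecks of a given intensity.  The
invasion preset chains these into the serial-introduction history the
analysis modules are designed to detect: a deep-structured native source, a
first bottlenecked introduction, and a second introduction founded from the
first, each followed by expansion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import Alignment, PopulationMap


@dataclass(frozen=True)
class DemographicEvent:
    """Backward-time event.

    kind "resize": deme ``source`` takes size ``size`` (and growth ``growth``)
    at ``time``.  kind "merge": all lineages of ``source`` move into ``dest``;
    a founder ``bottleneck`` intensity >= 0 first coalesces lineage pairs at
    rate 1 per pair for that much pseudo-time (math.inf -> single founder).
    """

    kind: str
    time: float
    source: int
    dest: int = -1
    size: float = 1.0
    growth: float = 0.0
    bottleneck: float = 0.0


@dataclass
class ScenarioConfig:
    n: tuple[int, ...]                      # samples per deme
    L: int = 17_270                         # sequence length (bp)
    sizes: tuple[float, ...] = (1.0,)       # theta per deme
    growth: tuple[float, ...] | None = None
    events: tuple[DemographicEvent, ...] = ()
    migration_rate: float = 0.0             # per-lineage, mutational-time units
    missingness: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.sizes) != len(self.n):
            raise ValueError("sizes and n must have one entry per deme")
        if any(s <= 0 for s in self.sizes):
            raise ValueError("deme sizes must be > 0")
        if not 0 <= self.missingness < 1:
            raise ValueError("missingness must be in [0, 1)")
        times = [e.time for e in self.events]
        if any(t < 0 for t in times) or times != sorted(times):
            raise ValueError("event times must be >= 0 and sorted")


@dataclass(frozen=True)
class TruthRecord:
    """Genealogy and mutation map behind a simulated alignment."""

    parent: np.ndarray            # parent node index, -1 for the root
    node_time: np.ndarray
    branch_mutations: tuple[tuple[int, ...], ...]  # mutated sites per node branch
    positions: np.ndarray         # site position of every mutation
    params: dict

    def genealogy_distance(self, i: int, j: int) -> int:
        """Mutations on the tree path between leaves i and j."""
        anc_i = {}
        node, d = i, 0
        while node != -1:
            anc_i[node] = d
            d += len(self.branch_mutations[node])
            node = self.parent[node]
        node, d = j, 0
        while node not in anc_i:
            d += len(self.branch_mutations[node])
            node = self.parent[node]
        return d + anc_i[node]


class _Genealogy:
    """Incrementally built coalescent tree over a fixed leaf set."""

    def __init__(self, n_leaves: int):
        self.parent = [-1] * n_leaves
        self.time = [0.0] * n_leaves
        self.n_leaves = n_leaves

    def merge(self, a: int, b: int, t: float) -> int:
        node = len(self.parent)
        self.parent.append(-1)
        self.time.append(t)
        self.parent[a] = node
        self.parent[b] = node
        return node

    def finish(self):
        parent = np.array(self.parent)
        time = np.array(self.time)
        n_nodes = len(parent)
        lengths = np.zeros(n_nodes)
        nonroot = parent >= 0
        lengths[nonroot] = time[parent[nonroot]] - time[np.flatnonzero(nonroot)]
        desc = np.zeros((n_nodes, self.n_leaves), dtype=bool)
        desc[np.arange(self.n_leaves), np.arange(self.n_leaves)] = True
        for node in range(self.n_leaves, n_nodes):
            desc[node] = desc[parent == node].any(axis=0)
        return parent, time, lengths, desc


def _bottleneck(tree: _Genealogy, lineages: list[int], intensity: float,
                t: float, rng: np.random.Generator) -> list[int]:
    """Instantaneous founder bottleneck: pair coalescences at rate 1 for
    ``intensity`` units of pseudo-time (no real time elapses)."""
    if intensity == math.inf:
        while len(lineages) > 1:
            i, j = rng.choice(len(lineages), 2, replace=False)
            node = tree.merge(lineages[i], lineages[j], t)
            lineages = [x for k, x in enumerate(lineages) if k not in (i, j)] + [node]
        return lineages
    s = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        s += rng.exponential(2.0 / (k * (k - 1)))
        if s > intensity:
            break
        i, j = rng.choice(k, 2, replace=False)
        node = tree.merge(lineages[i], lineages[j], t)
        lineages = [x for m, x in enumerate(lineages) if m not in (i, j)] + [node]
    return lineages


def simulate_genealogy(cfg: ScenarioConfig, rng: np.random.Generator):
    """Run the structured coalescent; returns (parent, time, lengths, desc)."""
    n_total = sum(cfg.n)
    tree = _Genealogy(n_total)
    deme_of: dict[int, int] = {}
    leaf = 0
    for d, nd in enumerate(cfg.n):
        for _ in range(nd):
            deme_of[leaf] = d
            leaf += 1
    sizes = list(cfg.sizes)
    growth = list(cfg.growth) if cfg.growth else [0.0] * len(sizes)
    t_ref = [0.0] * len(sizes)
    alive = [True] * len(sizes)
    events = list(cfg.events)
    t = 0.0

    def coal_wait(d: int, k: int) -> float:
        """Waiting time to next coalescence in deme d given k lineages."""
        rate0 = k * (k - 1) / 2.0 / sizes[d] * math.exp(growth[d] * (t - t_ref[d]))
        e = rng.exponential(1.0)
        if growth[d] == 0.0:
            return e / rate0
        arg = 1.0 + e * growth[d] / rate0
        return math.log(arg) / growth[d] if arg > 0 else math.inf

    while len(deme_of) > 1:
        per_deme: dict[int, list[int]] = {}
        for lin, d in deme_of.items():
            per_deme.setdefault(d, []).append(lin)
        candidates = []
        for d, lins in per_deme.items():
            if len(lins) >= 2:
                candidates.append((t + coal_wait(d, len(lins)), "coal", d))
        n_demes_alive = sum(alive)
        if cfg.migration_rate > 0 and n_demes_alive > 1:
            w = rng.exponential(1.0 / (cfg.migration_rate * len(deme_of)))
            candidates.append((t + w, "mig", -1))
        next_event = events[0] if events else None
        if next_event is not None:
            candidates.append((next_event.time, "demo", -1))
        if not candidates:
            raise RuntimeError("lineages can never coalesce under this scenario")
        t_next, kind, d = min(candidates, key=lambda x: x[0])
        t = t_next
        if kind == "coal":
            lins = per_deme[d]
            i, j = rng.choice(len(lins), 2, replace=False)
            node = tree.merge(lins[i], lins[j], t)
            del deme_of[lins[i]], deme_of[lins[j]]
            deme_of[node] = d
        elif kind == "mig":
            lin = list(deme_of)[rng.integers(len(deme_of))]
            others = [x for x in range(len(sizes)) if alive[x] and x != deme_of[lin]]
            if others:
                deme_of[lin] = others[rng.integers(len(others))]
        else:  # demographic event
            ev = events.pop(0)
            if ev.kind == "resize":
                sizes[ev.source] = ev.size
                growth[ev.source] = ev.growth
                t_ref[ev.source] = t
            elif ev.kind == "merge":
                movers = [lin for lin, dd in deme_of.items() if dd == ev.source]
                for lin in movers:
                    del deme_of[lin]
                if ev.bottleneck > 0 and len(movers) > 1:
                    movers = _bottleneck(tree, movers, ev.bottleneck, t, rng)
                for lin in movers:
                    deme_of[lin] = ev.dest
                alive[ev.source] = False
            else:
                raise ValueError(f"unknown event kind {ev.kind!r}")
    return tree.finish()


def place_mutations(lengths: np.ndarray, desc: np.ndarray, L: int,
                    rng: np.random.Generator, n_mutations: int | None = None):
    """Drop mutations on the genealogy (rate 1/2 per unit branch length, or a
    fixed count) at distinct uniform positions; returns (positions, branches).
    """
    total = float(lengths.sum())
    if n_mutations is None:
        n_mutations = rng.poisson(total / 2.0)
    if n_mutations > L:
        raise ValueError(
            f"{n_mutations} mutations exceed sequence length {L}; increase L")
    if n_mutations == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    p = lengths / total
    branches = rng.choice(len(lengths), size=n_mutations, p=p)
    positions = rng.choice(L, size=n_mutations, replace=False)
    return positions, branches


_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _alignment_from_genealogy(parent, lengths, desc, cfg: ScenarioConfig,
                              rng: np.random.Generator, ids):
    positions, branches = place_mutations(lengths, desc, cfg.L, rng)
    n = desc.shape[1]
    ancestral = rng.integers(0, 4, size=cfg.L)
    mat = _BASE_BYTES[ancestral][None, :].repeat(n, axis=0)
    branch_muts: list[list[int]] = [[] for _ in range(len(parent))]
    for pos, br in zip(positions, branches):
        derived = (ancestral[pos] + rng.integers(1, 4)) % 4
        mat[desc[br], pos] = _BASE_BYTES[derived]
        branch_muts[br].append(int(pos))
    return Alignment(tuple(ids), mat), branch_muts


def _freeze(branch_muts):
    return tuple(tuple(m) for m in branch_muts)


def simulate_coalescent(cfg: ScenarioConfig) -> tuple[Alignment, TruthRecord]:
    """Simulate an alignment under the configured demography.

    Returns the alignment (sample ids ``deme{d}_{i}``) and a truth record
    holding the genealogy, per-branch mutation lists, and parameters.
    """
    rng = np.random.default_rng(cfg.seed)
    parent, node_time, lengths, desc = simulate_genealogy(cfg, rng)
    ids = [f"deme{d}_{i}" for d, nd in enumerate(cfg.n) for i in range(nd)]
    aln, branch_muts = _alignment_from_genealogy(parent, lengths, desc, cfg, rng, ids)
    if cfg.missingness > 0:
        aln = inject_missingness(aln, cfg.missingness,
                                 seed=int(rng.integers(2 ** 31)))
    truth = TruthRecord(parent, node_time, _freeze(branch_muts),
                        np.array([p for m in branch_muts for p in m]),
                        {"cfg": cfg})
    return aln, truth


# ---------------------------------------------------------------------------
# Invasion preset
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InvasionPreset:
    """Serial-introduction scenario: structured native source, then two
    successively founded invasive populations, each expanding after a founder
    bottleneck.

    Defaults emulate a whole-mitogenome study design: sample sizes 13/25/94
    (native, first introduction, second introduction), ~17.3 kb sequences, a
    native source split into two lineages deep enough for >= 100 expected
    substitutions between them, and recent founder events that leave the
    introduced samples with star-like genealogies.
    """

    n_native: int = 13
    n_intro1: int = 25
    n_intro2: int = 94
    L: int = 17_270
    theta_native: float = 40.0
    native_split: float = 110.0       # expected min substitutions between clades
    theta_intro: float = 300.0
    t_intro1: float = 1.3             # founding times, mutational units
    t_intro2: float = 0.95
    bottleneck1: float = math.inf     # single surviving mtDNA founder lineage
    bottleneck2: float = 1.5
    missingness: float = 0.0


def invasion_config(preset: InvasionPreset = InvasionPreset(),
                    seed: int | None = None) -> ScenarioConfig:
    """Build the ScenarioConfig for the serial-invasion preset.

    Demes: 0/1 = the two native source lineages (sampled jointly as "native"),
    2 = first introduction, 3 = second introduction.  Backward in time the
    second introduction merges into the first, the first into native lineage
    0, and finally the two native lineages merge at time ``native_split``
    (in this engine's mutational-time units a pair coalescing at time T
    differs at Poisson(T) sites, so the split time is the expected minimum
    inter-clade distance).
    """
    p = preset
    n0 = p.n_native - p.n_native // 2
    if p.t_intro2 >= p.t_intro1:
        raise ValueError("second introduction must postdate the first")
    events = (
        DemographicEvent("merge", p.t_intro2, source=3, dest=2,
                         bottleneck=p.bottleneck2),
        DemographicEvent("merge", p.t_intro1, source=2, dest=0,
                         bottleneck=p.bottleneck1),
        DemographicEvent("merge", p.native_split, source=1, dest=0),
    )
    return ScenarioConfig(
        n=(n0, p.n_native // 2, p.n_intro1, p.n_intro2),
        L=p.L,
        sizes=(p.theta_native, p.theta_native, p.theta_intro, p.theta_intro),
        events=events,
        missingness=p.missingness,
        seed=seed,
    )


def simulate_invasion_series(preset: InvasionPreset = InvasionPreset(),
                             seed: int | None = None):
    """Simulate the serial-invasion preset.

    Returns (alignment, popmap, truth) with samples labelled native / intro1 /
    intro2 and groups assigning each population its own group.
    """
    cfg = invasion_config(preset, seed)
    aln, truth = simulate_coalescent(cfg)
    labels = (["native"] * preset.n_native
              + ["intro1"] * preset.n_intro1
              + ["intro2"] * preset.n_intro2)
    ids = [f"{pop}_{i}" for i, pop in enumerate(labels)]
    aln = Alignment(tuple(ids), aln.matrix)
    popmap = PopulationMap(dict(zip(ids, labels)),
                           {"native": "native", "intro1": "intro1", "intro2": "intro2"})
    return aln, popmap, truth


def inject_missingness(aln: Alignment, fraction: float, seed=None) -> Alignment:
    """Replace a uniform random fraction of base calls with N (reproducible)."""
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    if fraction == 0:
        return aln
    rng = np.random.default_rng(seed)
    mat = aln.matrix.copy()
    mask = rng.random(mat.shape) < fraction
    mat[mask] = ord("N")
    return Alignment(aln.ids, mat)


# ---------------------------------------------------------------------------
# Fixed demographies used as parametric-bootstrap generators
# ---------------------------------------------------------------------------

def sudden_expansion_genealogy(n: int, tau: float, theta0: float, theta1: float,
                               rng: np.random.Generator):
    """Single deme of size theta1 that was theta0 before time tau."""
    cfg = ScenarioConfig(
        n=(n,), sizes=(max(theta1, 1e-9),),
        events=(DemographicEvent("resize", tau, source=0, size=max(theta0, 1e-9)),))
    return simulate_genealogy(cfg, rng)


def island_expansion_genealogy(n: int, tau: float, theta: float, M: float,
                               rng: np.random.Generator):
    """Infinite-island spatial expansion demography.

    All n lineages start in one deme of size theta.  Pairs in the same deme
    coalesce at rate 1/theta; each lineage emigrates to a fresh, otherwise
    empty deme at rate M/(2 theta), so a within-deme pair is split by
    emigration at total rate M/theta and coalesces first with probability
    1/(1+M) (infinitely many islands: separated lineages never meet again).
    At time tau every lineage drops into the ancestral deme, also of size
    theta, and coalesces as a plain Kingman tree.
    """
    tree = _Genealogy(n)
    # Only co-located lineages can coalesce before tau, and a migration by an
    # isolated lineage is invisible to the genealogy, so singletons retire to
    # a "scattered" pool and the loop takes O(n) effective events even when
    # M/theta is enormous.
    per_deme: dict[int, list[int]] = {0: list(range(n))}
    scattered: list[int] = []
    t = 0.0
    while t < tau:
        for d in [d for d, l in per_deme.items() if len(l) < 2]:
            scattered.extend(per_deme.pop(d))
        if not per_deme:
            break
        k_shared = sum(len(l) for l in per_deme.values())
        coal_rate = sum(len(l) * (len(l) - 1) / 2.0 for l in per_deme.values()) / theta
        mig_rate = M / (2.0 * theta) * k_shared
        t_next = t + rng.exponential(1.0 / (coal_rate + mig_rate))
        if t_next >= tau:
            t = tau
            break
        t = t_next
        demes = list(per_deme)
        if rng.random() < coal_rate / (coal_rate + mig_rate):
            weights = np.array([len(per_deme[d]) * (len(per_deme[d]) - 1) for d in demes],
                               dtype=float)
            d = demes[rng.choice(len(demes), p=weights / weights.sum())]
            lins = per_deme[d]
            i, j = sorted(rng.choice(len(lins), 2, replace=False), reverse=True)
            node = tree.merge(lins[i], lins[j], t)
            lins.pop(i)
            lins.pop(j)
            lins.append(node)
        else:
            weights = np.array([len(per_deme[d]) for d in demes], dtype=float)
            d = demes[rng.choice(len(demes), p=weights / weights.sum())]
            lins = per_deme[d]
            scattered.append(lins.pop(rng.integers(len(lins))))
    # ancestral phase: plain coalescent in a deme of size theta
    t = max(t, tau)
    lineages = scattered + [lin for l in per_deme.values() for lin in l]
    while len(lineages) > 1:
        k = len(lineages)
        t += rng.exponential(theta / (k * (k - 1) / 2.0))
        i, j = rng.choice(k, 2, replace=False)
        node = tree.merge(lineages[i], lineages[j], t)
        lineages = [x for m, x in enumerate(lineages) if m not in (i, j)] + [node]
    return tree.finish()


def pairwise_differences_from_genealogy(lengths, desc,
                                        rng: np.random.Generator) -> np.ndarray:
    """Pairwise difference counts implied by Poisson mutations on a genealogy
    (no sequence is built; used by the mismatch parametric bootstrap)."""
    n_mut = rng.poisson(lengths.sum() / 2.0)
    n = desc.shape[1]
    if n_mut == 0:
        return np.zeros((n, n), dtype=int)
    p = lengths / lengths.sum()
    branches = rng.choice(len(lengths), size=n_mut, p=p)
    G = desc[branches]  # (n_mut, n) boolean
    d = np.zeros((n, n), dtype=int)
    for i in range(n):
        d[i] = (G != G[:, i][:, None]).sum(axis=0)
    return d
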