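"""Mismatch distributions and expansion-model fitting.

The observed mismatch distribution is the histogram of pairwise difference
counts over all unordered pairs of sampled individuals.  Two demographic
models supply expected distributions:

*Sudden (demographic) expansion* — a panmictic population of scaled size
theta0 that changed instantaneously to theta1 at mutational time tau before
the present.  The probability that a random pair differs at j sites is the
transient solution of Li (1977), as popularised by Rogers & Harpending
(1992):

    F_j(tau, theta0, theta1) = F^_j(theta1)
        + exp(-tau (theta1 + 1)/theta1)
          * sum_{i=0}^{j} (tau^i / i!) [ F^_{j-i}(theta0) - F^_{j-i}(theta1) ]

with the equilibrium law F^_j(theta) = theta^j / (theta + 1)^{j+1}.  The
expression reduces to F^_j(theta) when theta0 = theta1 and to a Poisson(tau)
mass function in the star-genealogy limit theta0 -> 0, theta1 -> inf.

*Spatial expansion* — an infinite-island population that expanded at time tau
out of one ancestral deme; parameters are the deme size theta and the scaled
migration rate M.  Tracing a within-deme pair backward, it either coalesces
(rate 1/theta) or is split forever by emigration (rate M/theta) until tau,
after which surviving pairs coalesce in the ancestral deme (size theta).
Mixing Poisson(t) differences over that coalescence-time law gives the
closed form coded in :func:`expected_mismatch` (regularised incomplete gamma
functions); it is validated against Monte-Carlo coalescent simulation of the
same demography in the test-suite.

Goodness of fit uses SSD = sum_j (x_j - E_j)^2 over the observed classes and
Harpending's (1994) raggedness index, with parametric-bootstrap p-values
(simulate under the fitted model, refit, count bootstrap statistics >= the
observed one).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .popstats import DistanceMatrix
from .simulate import (island_expansion_genealogy,
                       pairwise_differences_from_genealogy,
                       sudden_expansion_genealogy)

TAU_MAX = 50.0
THETA_MIN, THETA_MAX = 1e-6, 1e4
M_MIN, M_MAX = 1e-3, 1e4


@dataclass(frozen=True)
class MismatchDistribution:
    counts: np.ndarray

    @property
    def n_pairs(self) -> int:
        return int(self.counts.sum())

    @property
    def freqs(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    @property
    def d_max(self) -> int:
        return len(self.counts) - 1


def observed_mismatch(dist: DistanceMatrix) -> MismatchDistribution:
    """Histogram of pairwise difference counts over all individual pairs."""
    n = len(dist.ids)
    if n < 2:
        raise ValueError("mismatch distribution requires >= 2 sequences")
    iu = np.triu_indices(n, 1)
    d = dist.d[iu]
    counts = np.bincount(d, minlength=int(d.max()) + 1 if d.size else 1)
    return MismatchDistribution(counts.astype(int))


def _equilibrium(theta: float, j: np.ndarray) -> np.ndarray:
    """F^_j(theta) = theta^j / (theta+1)^(j+1), computed in log space."""
    if theta <= 0:
        out = np.zeros(len(j))
        out[0] = 1.0
        return out
    return np.exp(j * math.log(theta) - (j + 1) * math.log(theta + 1.0))


def expected_mismatch(model: str, params, j_max: int) -> np.ndarray:
    """Expected pairwise-difference probabilities for classes 0..j_max.

    ``model="sudden"`` takes params (tau, theta0, theta1); ``model="spatial"``
    takes (tau, theta, M).  The returned vector is the exact law truncated at
    j_max (it sums to < 1; the missing mass sits in higher classes).
    """
    j = np.arange(j_max + 1)
    if model == "sudden":
        tau, th0, th1 = (float(p) for p in params)
        if not all(map(math.isfinite, (tau, th0, th1))) or min(tau, th0, th1) < 0:
            raise ValueError(f"invalid sudden-model parameters {params}")
        eq1 = _equilibrium(th1, j)
        if tau == 0:
            return _equilibrium(th0, j)
        delta = _equilibrium(th0, j) - eq1
        pois = stats.poisson.pmf(j, tau)                      # e^-tau tau^i / i!
        conv = np.convolve(pois, delta)[: j_max + 1]
        decay = math.exp(-tau / th1) if th1 > 0 else 0.0      # completes e^{-tau(th1+1)/th1}
        return eq1 + decay * conv
    if model == "spatial":
        tau, theta, M = (float(p) for p in params)
        if not all(map(math.isfinite, (tau, theta, M))) or min(tau, theta, M) < 0:
            raise ValueError(f"invalid spatial-model parameters {params}")
        theta = max(theta, 1e-12)
        a = (1.0 + M) / theta + 1.0
        b = 1.0 + 1.0 / theta
        # pair coalesces within the deme before tau (Poisson-mixed over an
        # Exp((1+M)/theta) coalescence time truncated at tau):
        with np.errstate(over="ignore"):
            within = special.gammainc(j + 1, a * tau) / theta / a ** (j + 1.0)
            within = np.nan_to_num(within, posinf=0.0)
        # pair survives to tau uncoalesced (still together, or split by
        # migration) and then coalesces in the ancestral deme; the upper
        # incomplete gamma is expanded as a Poisson CDF so the e^{tau/theta}
        # factor cancels analytically and nothing overflows:
        surv = math.exp(-(1.0 + M) * tau / theta)
        w_anc = surv + M / (1.0 + M) * (1.0 - surv)
        i = np.arange(j_max + 1, dtype=float)
        if tau > 0:
            log_terms = -tau + i * math.log(b * tau) - special.gammaln(i + 1)
        else:
            log_terms = np.full(j_max + 1, -np.inf)
            log_terms[0] = 0.0
        log_cum = np.logaddexp.accumulate(log_terms)
        ancestral = np.exp(log_cum - (j + 1) * math.log(b) - math.log(theta))
        return within + w_anc * ancestral
    raise ValueError(f"unknown model {model!r}")


def raggedness_index(freqs, trailing_zero: bool = True) -> float:
    """Harpending's raggedness r = sum (x_i - x_{i-1})^2 for i = 1..d(+1).

    With ``trailing_zero`` (the default convention) an extra class x_{d+1} = 0
    closes the distribution, so a point mass at class 0 gives r = 1.
    """
    x = np.asarray(freqs, dtype=float)
    if trailing_zero:
        x = np.append(x, 0.0)
    return float(np.sum(np.diff(x) ** 2))


@dataclass(frozen=True)
class ExpansionFit:
    model: str
    params: dict
    ssd: float
    raggedness: float
    p_ssd: float | None = None
    p_raggedness: float | None = None
    n_boot: int = 0
    seed: int | None = None
    converged: bool = True
    flag: str | None = None
    diagnostics: dict = field(default_factory=dict)


def _ssd(obs_freqs: np.ndarray, model: str, params) -> float:
    exp = expected_mismatch(model, params, len(obs_freqs) - 1)
    return float(np.sum((obs_freqs - exp) ** 2))


def _fit_params(obs: MismatchDistribution, model: str,
                rng: np.random.Generator, starts=None):
    """Multi-start Nelder-Mead over log-transformed parameters.

    ``starts`` overrides the default start list (used by the bootstrap, which
    warm-starts at the fitted parameters to keep refits cheap).
    """
    x = obs.freqs
    mean_d = float(np.sum(np.arange(len(x)) * x))

    def _exp(v):
        return math.exp(min(max(v, -60.0), 60.0))

    if model == "sudden":
        def unpack(z):
            tau = min(_exp(z[0]), TAU_MAX)
            th0 = min(max(_exp(z[1]), THETA_MIN), THETA_MAX)
            th1 = min(max(_exp(z[2]), THETA_MIN), THETA_MAX)
            return tau, th0, th1
        default_starts = [
            (max(mean_d, 0.1), 0.1, 100.0),
            (max(mean_d / 2, 0.1), 1.0, 1000.0),
            (max(mean_d, 0.1), max(mean_d / 10, 0.01), THETA_MAX / 10),
            (1.0, 1.0, 10.0),
        ]
    elif model == "spatial":
        def unpack(z):
            tau = min(_exp(z[0]), TAU_MAX)
            theta = min(max(_exp(z[1]), THETA_MIN), THETA_MAX)
            M = min(max(_exp(z[2]), M_MIN), M_MAX)
            return tau, theta, M
        default_starts = [
            (max(mean_d, 0.1), 1.0, 1.0),
            (max(mean_d / 2, 0.1), 0.1, 10.0),
            (max(mean_d, 0.1), max(mean_d / 5, 0.05), 0.5),
            (1.0, 1.0, 100.0),
        ]
    else:
        raise ValueError(f"unknown model {model!r}")

    if starts is None:
        starts = default_starts + [
            tuple(math.exp(rng.uniform(math.log(0.05), math.log(20.0)))
                  for _ in range(3)) for _ in range(4)]

    best = None
    n_fail = 0
    for s in starts:
        z0 = np.log(np.maximum(np.asarray(s, dtype=float), 1e-8))
        res = optimize.minimize(lambda z: _ssd(x, model, unpack(z)), z0,
                                method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": 1e-12,
                                         "maxiter": 2000})
        if not res.success:
            n_fail += 1
        params = unpack(res.x)
        # tie-break: prefer smaller SSD, then smaller tau
        key = (round(res.fun, 12), params[0])
        if best is None or key < best[0]:
            best = (key, params, res.fun)
    params, ssd = best[1], float(best[2])
    return params, ssd, {"n_starts": len(starts), "n_failed_starts": n_fail}


def starts_fallback(model: str, obs: MismatchDistribution):
    """A single moment-style start: tau at the observed mean, vague sizes."""
    mean_d = float(np.sum(np.arange(len(obs.freqs)) * obs.freqs))
    if model == "sudden":
        return (max(mean_d, 0.1), 0.5, 100.0)
    return (max(mean_d, 0.1), 1.0, 1.0)


def _simulate_mismatch(model: str, params, n: int,
                       rng: np.random.Generator) -> MismatchDistribution:
    if model == "sudden":
        tau, th0, th1 = params
        _, _, lengths, desc = sudden_expansion_genealogy(n, tau, th0, th1, rng)
    else:
        tau, theta, M = params
        _, _, lengths, desc = island_expansion_genealogy(n, tau, theta, M, rng)
    d = pairwise_differences_from_genealogy(lengths, desc, rng)
    iu = np.triu_indices(n, 1)
    counts = np.bincount(d[iu], minlength=int(d[iu].max()) + 1 if d[iu].size else 1)
    return MismatchDistribution(counts.astype(int))


def fit_expansion(obs: MismatchDistribution, model: str = "sudden",
                  n_boot: int = 500, seed=None,
                  n_samples: int | None = None) -> ExpansionFit:
    """Least-squares fit of an expansion model, with bootstrap p-values.

    ``n_samples`` (the number of individuals behind ``obs``) is required for
    the parametric bootstrap; it is recovered from the pair count when
    omitted.  p_SSD and p_raggedness are the proportions of n_boot datasets
    simulated under the fitted model whose refitted SSD (resp. observed
    raggedness) is >= the observed value, with the (b+1)/(B+1) correction.
    """
    x = obs.freqs
    if np.count_nonzero(x) < 2:
        return ExpansionFit(model, {}, 0.0, raggedness_index(x),
                            flag="degenerate (fewer than 2 occupied classes)",
                            converged=False)
    rng = np.random.default_rng(seed)
    params, ssd, diag = _fit_params(obs, model, rng)
    names = ("tau", "theta0", "theta1") if model == "sudden" else ("tau", "theta", "M")
    rag = raggedness_index(x)
    fit = ExpansionFit(model, dict(zip(names, params)), ssd, rag,
                       n_boot=n_boot, seed=seed, diagnostics=diag)
    if n_boot <= 0:
        return fit
    if n_samples is None:
        # n(n-1)/2 pairs -> n
        n_samples = int(round((1 + math.sqrt(1 + 8 * obs.n_pairs)) / 2))
    exceed_ssd = exceed_rag = 0
    for _ in range(n_boot):
        sim = _simulate_mismatch(model, params, n_samples, rng)
        if np.count_nonzero(sim.freqs) < 2:
            sim_ssd = _ssd(sim.freqs, model, params)
        else:
            # warm-started refit (two starts) keeps the bootstrap affordable
            _, sim_ssd, _ = _fit_params(sim, model, rng,
                                        starts=[params, starts_fallback(model, sim)])
        if sim_ssd >= ssd:
            exceed_ssd += 1
        if raggedness_index(sim.freqs) >= rag:
            exceed_rag += 1
    return ExpansionFit(model, dict(zip(names, params)), ssd, rag,
                        p_ssd=(exceed_ssd + 1) / (n_boot + 1),
                        p_raggedness=(exceed_rag + 1) / (n_boot + 1),
                        n_boot=n_boot, seed=seed, diagnostics=diag)
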