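# Methods

`mitopop` analyses alignments of whole mitochondrial genomes from a species
that was serially introduced across continents: a diverse, demographically
stable native source and a chain of founder-effect populations expanding
after introduction.  This note records the models implemented, the defaults
and why, the numerical choices, and what the synthetic data do and do not
emulate.

## Data model and missing data

Sequences are equal-length haploid strings over `{A,C,G,T,N,-}`; `N` and `-`
are both treated as missing for every statistic (they are stored
distinctly).  All internal coordinates are 0-based half-open; VCF (1-based)
and BED (0-based half-open) conventions are honoured only at the file
boundary.

Two missing-data policies exist.  *Complete deletion* (drop every column
containing any missing call) is used for haplotype collapsing and site
classification, matching DnaSP's defaults for those quantities.  *Pairwise
deletion* (compare each pair over jointly called sites) is used for
nucleotide diversity.  Under pairwise comparison "same haplotype" is not
transitive; sequences therefore join the first existing haplotype (in input
order) they match with zero differences.

## Consensus construction

Variant hard filters: site QUAL < 20, FisherStrand > 30, QualByDepth < 2,
depth < 20, allele frequency < 0.05 (all strict inequalities; a record
sitting exactly on a threshold passes), removal of every SNP lying in a run
of 3 SNPs spanning <= 35 bases (1-based inclusive span; indels neither count
toward nor are removed by the cluster rule), and removal of variants
overlapping the repeat mask.  AF is read from the INFO field; a depth-ratio
alternative would be computable from AD but is not the default.  The mask
rule is applied after the cluster rule; the order only affects reporting,
not the surviving set, because rules are independent.  At multi-allelic or
mixed sites the allele with the highest supporting depth is written to the
consensus, with ties resolved to the reference (logged) — the tie rule is a
package choice, as no convention is established.  Masked intervals are
excised by default (an ~18.2 kb reference with an ~0.9 kb mask yields
~17.3 kb consensus sequences); `nfill` replaces them with N instead.

Cross-platform masking: a site where an individual's two platform-derived
sequences disagree (both called) in two or more individuals is set to N in
every sequence — such sites behave like RNA editing or systematic mapping
artefacts, not genotype.  Single-individual discordances are reported but
left untouched.

## Diversity statistics

* pi (per site) — average over pairs of (differences / jointly called
  sites); SD from Nei's (1987) approximation
  `V(pi) = (n+1)pi/(3(n-1)L) + 2(n^2+n+3)pi^2/(9n(n-1))` with L the mean
  jointly-called length.
* h — `n(1 - sum p_i^2)/(n-1)` with Nei's sampling variance.
* H_R — exact hypergeometric rarefaction
  `sum_h [1 - C(N-N_h, g)/C(N, g)]`; g defaults to the smallest analysed
  population size (FSTAT behaviour).
* Aggregate rows (e.g. a country pooled over its states) are computed on
  pooled samples, never by averaging per-population statistics.

## AMOVA and fixation indices

Variance components follow the Excoffier–Smouse–Quattro least-squares
decomposition with pairwise difference counts used directly as squared
distances (the Arlequin convention for sequence data), so the indices are
distance-based Phi statistics; tables label them F_ST following common
usage.  Negative components are reported as computed.  With every
population its own group (the default mapping) the group level is vacuous
and the classical two-level analysis is returned.  Permutation schemes:
individuals among populations (Phi_ST), whole populations among groups
(Phi_CT), individuals among populations within groups (Phi_SC);
`p = (#{permuted >= observed} + 1)/(n_perm + 1)`, default n_perm = 10,000.
Because the statistic is a function of a finite set of label assignments and
of integer distances, permutation p-values are exactly uniform only when the
statistic is effectively continuous; with few distinct haplotypes they are
valid but conservative (ties counted against rejection).  The calibration
test therefore uses continuous exchangeable data, which isolates the
machinery from the tie effect.

## Neutrality tests

Fu's Fs uses the Ewens sampling formula with theta estimated by the mean
pairwise difference count: `S' = P(K >= k_obs | theta_pi)`,
`Fs = ln(S'/(1-S'))`.  Unsigned Stirling numbers of the first kind are
computed once per n by the log-space recurrence
`|s(n+1,k)| = n|s(n,k)| + |s(n,k-1)|`; the implementation is overflow-free
to at least n = 200, theta = 1e4 and matches exact rational arithmetic to
n = 60.  The upper tail (at least the observed number of haplotypes) is
used: that is Fu's definition and what Arlequin computes, and large negative
values flag haplotype excess after expansion.  A monomorphic sample has
S' = 1 and is flagged undefined.

R2 (Ramos-Onsins & Rozas) is
`sqrt((1/n) sum_i (U_i - kbar/2)^2) / S`, with U_i the number of singleton
sites whose unique base is carried by sequence i.  For n = 2 both bases of a
variable site have count one, so no singleton is assignable and U stays
zero.  S = 0 is flagged undefined.

Significance for both comes from constant-size coalescent simulation
conditioned on the observed number of segregating sites (mutations placed
multinomially on the genealogy, proportional to branch length), lower-tail,
with the (b+1)/(B+1) correction; default 10,000 simulations.  Conditioning
on S rather than on an estimated theta removes theta-estimation noise from
the null.  The same tie caveat as for permutation tests applies when the
sample can only realise few (k, theta_pi) configurations.

## Mismatch distributions

The observed distribution is the histogram of difference counts over all
unordered individual pairs (not collapsed haplotypes).

*Sudden expansion* (tau, theta0, theta1) uses the exact transient law of a
stepwise size change:

    F_j = F^_j(theta1) + e^{-tau(theta1+1)/theta1}
          sum_{i<=j} (tau^i/i!) [F^_{j-i}(theta0) - F^_{j-i}(theta1)],

with equilibrium `F^_j(theta) = theta^j/(theta+1)^{j+1}`.  It reduces to the
equilibrium law when theta0 = theta1 and to Poisson(tau) as theta0 -> 0,
theta1 -> inf (both asserted in tests).

*Spatial expansion* (tau, theta, M) models an infinite-island range that
expanded out of a single deme at time tau.  Backward in time a within-deme
pair coalesces at rate 1/theta and is split permanently by emigration at
total rate M/theta (coalescence wins first with probability 1/(1+M));
pairs surviving to tau coalesce in an ancestral deme, also of size theta, so
tau = 0 nests the equilibrium law.  Mixing Poisson(t) differences over this
coalescence-time law gives a closed form in regularised incomplete gamma
functions; the upper-gamma branch is expanded as a Poisson CDF so the
exponentially growing prefactor cancels analytically.  Both laws are
validated against an independent Monte-Carlo structured-coalescent oracle
(15,000 pair draws, agreement within 3 Monte-Carlo SE per class).

Fitting minimises `SSD = sum_j (x_j - E_j)^2` over classes 0..d_max by
Nelder–Mead on log-parameters from eight starts (four heuristic, four
random), bounds tau in [0, 50], theta in [1e-6, 1e4], M in [1e-3, 1e4]; ties
resolve toward smaller tau.  Raggedness is `sum (x_i - x_{i-1})^2` with a
closing zero class appended (a point mass at class 0 gives r = 1); the open
convention is available by flag.  p-values are parametric bootstrap:
simulate the fitted demography at the same n, refit (warm-started at the
fitted parameters to keep 500 replicates affordable), and count
`statistic >= observed` with the (b+1)/(B+1) correction.  Default 500
bootstrap replicates, giving a Monte-Carlo standard error of at most
~0.022 on a p-value near 0.5.

One property of single-locus data is worth stating: the observed mismatch
histogram of one sample is built from correlated pairs sharing one
genealogy, so even a perfectly specified estimator recovers tau with
substantial scatter and a modest upward median offset at realistic sizes.
The parameter-recovery check therefore draws pair differences iid from the
model law — the regime in which the least-squares estimator is consistent
and SSD at the optimum is near zero — while the bootstrap machinery uses
full genealogical simulation, as it must.

## Median-joining networks

Haplotypes (complete-deletion collapsed) are joined by iterating: build the
epsilon-relaxed minimum spanning network under Hamming distance (epsilon = 0
default, the union of all MSTs); for every triplet forming a path or
triangle, propose the site-wise majority consensus as a median vector; add
all proposals whose connection cost is within epsilon of the round's best;
discard unsampled nodes that fall to degree <= 2; repeat to closure.
Triplets with a three-way conflict at any site have no single majority
median and are skipped (logged).  Maximum-parsimony post-processing keeps
exactly the links lying on a minimum-weight spanning structure over the
sampled haplotypes; among equal-weight optima, structures using fewer median
vectors are preferred (so retained medians always have degree >= 3), and the
union over all optima is kept — equal-length alternative paths survive, as
in the published algorithm.  The search enumerates median-vector subsets
exhaustively up to 18 medians; beyond that the network is returned unpruned
with a warning.  Tests verify exact agreement with an independent
quasi-median-closure Steiner search on datasets with up to 6 haplotypes and
8 segregating sites.

## Coalescent simulator

A structured Kingman coalescent runs directly in mutational time: a deme of
scaled size theta coalesces any pair at rate 1/theta, and mutations fall at
rate 1/2 per branch per unit time, so a pair coalescing at time t differs at
Poisson(t) sites and E[pairwise differences] = theta in a constant deme.
Infinite-sites mutations map to distinct uniform positions on [0, L); more
mutations than L is an error suggesting a larger L.  Events: instantaneous
resize, per-deme exponential growth (closed-form waiting times), deme
mergers, and instantaneous founder bottlenecks of given intensity
(pair-coalescence pseudo-time; infinity collapses to a single founder
lineage).  The truth record keeps the genealogy and per-branch mutation
lists, so genealogical path counts can be checked against alignment Hamming
distances exactly.

The invasion preset emulates the study design the analyses target: 13/25/94
samples (native, first and second introduction) of ~17.3 kb; a native source
split into two lineages deep enough for ~110 expected substitutions between
clades; a first introduction at time 1.3 (mutational units) through a
bottleneck that leaves a single surviving mtDNA founder lineage — matching
the observed pattern of an invasive range monophyletic for mtDNA, tens of
substitutions from the nearest native haplotype — and a second introduction
founded from the first at time 0.95 with a softer bottleneck (intensity
1.5), both expanding to scaled size 300 afterwards.  Typical realisations
give native pi ~ 6e-3 versus introduced pi ~ 5e-5..8e-5, strongly negative
introduced Fs, star-like introduced genealogies with singleton excess, and a
bimodal native mismatch distribution.  What the generator does **not**
emulate: sequencing error beyond uniform missingness, NUMT contamination,
recombination, selection, heteroplasmy, or platform-specific artefacts — so
passing tests demonstrate statistical correctness of the methods under the
assumed demographic models, not robustness to upstream data pathologies.

## Problem sizes in the test-suite and acceptance script

Oracle-equivalence checks run on 200 random alignments (n <= 12, L <= 300);
calibration experiments use 2,000 replicates with 99 permutations or 200
null simulations each; the invasion experiment uses 100 full-size replicates
with 200 null simulations per test; the acceptance script runs the complete
pipeline once at full preset size with 999 permutations, 1,000 null
simulations and 100 bootstrap replicates.  These sizes were chosen so each
experiment's Monte-Carlo error is small relative to the property being
asserted while the whole suite stays convenient to run routinely.

## Known limitations

* The spatial-expansion law assumes the ancestral deme has the same scaled
  size as a present-day deme; other conventions shift the fitted theta.
* Permutation and simulation p-values are conservative in the presence of
  ties (few haplotypes / few segregating sites).
* The SNP-cluster filter uses all input SNPs, not only those passing the
  threshold filters first (GATK semantics); pipelines that filter before
  clustering would keep slightly more SNPs.
* Exact MP pruning of networks is exponential in the number of median
  vectors and capped at 18.
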