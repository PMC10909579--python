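# mitopop

Population genetics of whole mitochondrial genomes, built for invasion
biology: quantifying how serial introductions reshape a species' maternal
lineage diversity.  The package takes an alignment of near-complete
mitogenomes (or a reference plus per-sample VCFs, from which it builds
filtered consensus sequences) together with a sample→population→group table,
and computes, per population:

* **Diversity** — segregating and parsimony-informative sites, haplotype
  number *H*, nucleotide diversity π ± SD, haplotype diversity *h* ± SD, and
  rarefied haplotype richness *H*<sub>R</sub>.
* **Structure** — hierarchical AMOVA (distance-based Φ statistics with
  pairwise difference counts as squared distances) and pairwise
  *F*<sub>ST</sub>, both with permutation *p*-values.
* **Demographic history** — Fu's *F*s from the Ewens sampling formula
  (*F*s = ln(*S*′/(1−*S*′)) with *S*′ = P(*K* ≥ *k*<sub>obs</sub> | θ̂<sub>π</sub>)),
  the Ramos-Onsins & Rozas *R*² statistic, both with coalescent-simulation
  *p*-values, and mismatch distributions fitted to the sudden-demographic
  and spatial (infinite-island) expansion models with SSD and raggedness
  tested by parametric bootstrap.
* **Genealogy** — median-joining haplotype networks with maximum-parsimony
  pruning of superfluous median vectors and links.

A built-in structured coalescent simulator generates alignments with known
truth — including a serial-invasion preset (deep-structured native source,
two successive founder bottlenecks, post-introduction expansion) — so every
stage is testable without downloading anything.  The model details, defaults
and numerical choices are documented in [docs/methods.md](docs/methods.md).

## Worked example

Simulate a serial-invasion dataset (13 native, 25 first-introduction, 94
second-introduction samples of ~17.3 kb) and run the full analysis:

```python
from mitopop.simulate import simulate_invasion_series
from mitopop.pipeline import run_analysis, summarize_tables

aln, popmap, truth = simulate_invasion_series(seed=11)
bundle = run_analysis(aln, popmap, n_perm=999, n_sims=1000, n_boot=0, seed=11)
print(summarize_tables(bundle)[["N", "polymorphic_sites", "H", "pi", "h",
                                "H_R", "Fs", "p_Fs", "R2", "p_R2"]].round(5))
```

```
         N  polymorphic_sites   H       pi        h      H_R        Fs     p_Fs       R2     p_R2
native  13                237  11  0.00545  0.97436     11.0   3.31775  0.91209  0.18002  0.86813
intro1  25                 15  13  0.00007     0.74     7.24 -12.17160  0.00100  0.04989  0.00300
intro2  94                 37  34  0.00005  0.59483  5.68428 -59.37397  0.00100  0.01477  0.00100
```

The native population carries two deep mitochondrial clades: high π
(0.0055 per site), nearly every individual its own haplotype (*h* ≈ 0.97),
and a positive, non-significant Fu's *F*s — a demographically stable source.
Both introduced populations show the founder-effect signature: π two orders
of magnitude lower, yet many closely related haplotypes (star-like
genealogies of post-introduction mutations), giving strongly negative,
highly significant *F*s and small significant *R*² — the signal of rapid
expansion after a bottleneck.  The same bundle carries the structure and
network results:

```
AMOVA: among-populations 62.03%, within 37.97%, Phi_ST = 0.62 (p = 0.001)
network: 57 sampled haplotypes, 7 median vectors, total length 293
```

Most variation lies among populations, driven by the native/introduced
divide.

The same analyses are available from the shell:

```sh
mitopop simulate --preset invasion --seed 11 --out sim.fa --popmap pops.tsv
mitopop stats     --aln sim.fa --popmap pops.tsv --out stats.tsv
mitopop amova     --aln sim.fa --popmap pops.tsv --perms 999 --seed 1
mitopop network   --aln sim.fa --popmap pops.tsv --out net.gml
mitopop run       --config run.cfg        # full pipeline, flat key=value config
```

and `mitopop consensus` builds a filtered consensus from a reference FASTA,
a VCF and a repeat-mask BED (QUAL/FS/QD/DP/AF thresholds, SNP-cluster
removal, mask excision).

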