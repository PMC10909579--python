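"""End-to-end orchestration: alignment (or consensus inputs) in, result
tables out, with per-stage seeds derived from one master seed."""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .amova import amova, pairwise_fst
from .consensus import FilterConfig, build_consensus, filter_variants
from .io import (Alignment, PopulationMap, export_results, load_alignment,
                 load_mask, load_popmap, load_reference, load_variants)
from .mismatch import fit_expansion, observed_mismatch
from .network import median_joining, mp_postprocess
from .neutrality import fu_fs_from_alignment, neutrality_pvalue, r2_statistic
from .popstats import (classify_sites, collapse_haplotypes, distance_matrix,
                       diversity_table)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs and per-stage parameters for a full run.

    Either ``alignment`` or (``reference`` + ``vcfs``) must be given; the
    consensus stage runs only in the latter case.  ``aggregates`` adds pooled
    rows (e.g. one country pooled over its states) computed on pooled samples.
    """

    popmap: str
    out_dir: str
    alignment: str | None = None
    reference: str | None = None
    vcfs: dict = field(default_factory=dict)   # sample id -> VCF path
    mask: str | None = None
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    aggregates: dict = field(default_factory=dict)
    n_perm: int = 10_000
    n_sims: int = 10_000
    n_boot: int = 500
    epsilon: int = 0
    models: tuple[str, ...] = ("sudden", "spatial")
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.alignment is None and not (self.reference and self.vcfs):
            raise ValueError("need an alignment, or a reference plus VCFs")
        stochastic = self.n_perm or self.n_sims or self.n_boot
        if stochastic and self.seed is None:
            raise ValueError("a seed is required when stochastic stages are enabled")


def _child_seeds(seed, n):
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in
            np.random.SeedSequence(seed).spawn(n)]


def neutrality_table(alignment: Alignment, popmap: PopulationMap,
                     n_sims: int, seed=None, aggregates: dict | None = None) -> pd.DataFrame:
    """Per-population Fu's Fs and R2 with coalescent-simulation p-values."""
    entries = {p: list(popmap.samples_in(p)) for p in popmap.populations}
    for name, pops in (aggregates or {}).items():
        entries[name] = [s for p in pops for s in entries[p]]
    seeds = _child_seeds(seed, 2 * len(entries))
    rows = {}
    for k, (name, samples) in enumerate(entries.items()):
        sub = alignment.subset(samples)
        row = {"N": sub.n}
        S = classify_sites(sub).S if sub.n >= 2 else 0
        row["S"] = S
        if sub.n < 3 or S == 0:
            row.update({"Fs": math.nan, "p_Fs": math.nan,
                        "R2": math.nan, "p_R2": math.nan})
        else:
            fs = fu_fs_from_alignment(sub)
            r2 = r2_statistic(sub)
            row["Fs"] = fs.Fs
            row["R2"] = r2.R2
            if n_sims:
                row["p_Fs"] = neutrality_pvalue("Fs", fs.Fs, sub.n, S,
                                                n_sims, seeds[2 * k])
                row["p_R2"] = neutrality_pvalue("R2", r2.R2, sub.n, S,
                                                n_sims, seeds[2 * k + 1])
        rows[name] = row
    return pd.DataFrame(rows).T


def mismatch_table(alignment: Alignment, popmap: PopulationMap,
                   models=("sudden", "spatial"), n_boot: int = 500,
                   seed=None, aggregates: dict | None = None) -> pd.DataFrame:
    """Per-population expansion-model fits (SSD, raggedness, bootstrap p)."""
    entries = {p: list(popmap.samples_in(p)) for p in popmap.populations}
    for name, pops in (aggregates or {}).items():
        entries[name] = [s for p in pops for s in entries[p]]
    seeds = _child_seeds(seed, len(entries) * len(models))
    rows = {}
    k = 0
    for name, samples in entries.items():
        sub = alignment.subset(samples)
        row = {}
        for model in models:
            prefix = "demographic" if model == "sudden" else "spatial"
            if sub.n < 3:
                row.update({f"{prefix}_SSD": math.nan, f"{prefix}_p_SSD": math.nan,
                            f"{prefix}_raggedness": math.nan,
                            f"{prefix}_p_raggedness": math.nan})
                k += 1
                continue
            obs = observed_mismatch(distance_matrix(sub))
            fit = fit_expansion(obs, model, n_boot=n_boot, seed=seeds[k],
                                n_samples=sub.n)
            k += 1
            row[f"{prefix}_SSD"] = fit.ssd
            row[f"{prefix}_p_SSD"] = fit.p_ssd
            row[f"{prefix}_raggedness"] = fit.raggedness
            row[f"{prefix}_p_raggedness"] = fit.p_raggedness
            row[f"{prefix}_tau"] = fit.params.get("tau")
        rows[name] = row
    return pd.DataFrame(rows).T


def run_analysis(alignment: Alignment, popmap: PopulationMap,
                 aggregates: dict | None = None, n_perm: int = 10_000,
                 n_sims: int = 10_000, n_boot: int = 500, epsilon: int = 0,
                 models=("sudden", "spatial"), seed=None) -> dict:
    """Run every analysis stage on an in-memory alignment; returns a bundle."""
    seeds = _child_seeds(seed, 4)
    bundle: dict = {}
    bundle["diversity"] = diversity_table(alignment, popmap, aggregates=aggregates)
    dm = distance_matrix(alignment)
    bundle["amova"] = amova(dm, popmap, n_perm=n_perm, seed=seeds[0])
    bundle["fst"] = pairwise_fst(dm, popmap, n_perm=n_perm, seed=seeds[1])
    bundle["neutrality"] = neutrality_table(alignment, popmap, n_sims,
                                            seed=seeds[2], aggregates=aggregates)
    bundle["mismatch"] = mismatch_table(alignment, popmap, models, n_boot,
                                        seed=seeds[3], aggregates=aggregates)
    haplos = collapse_haplotypes(alignment, popmap)
    bundle["haplotypes"] = haplos
    bundle["network"] = mp_postprocess(median_joining(haplos, epsilon))
    return bundle


def summarize_tables(bundle: dict) -> pd.DataFrame:
    """One row per population: N, S, H, pi, h, H_R, Fs(p), R2(p), SSD/raggedness."""
    div = bundle.get("diversity")
    neut = bundle.get("neutrality")
    mism = bundle.get("mismatch")
    if div is None:
        raise ValueError("bundle has no diversity table")
    out = div.copy()
    for name, tab in (("neutrality", neut), ("mismatch", mism)):
        if tab is None:
            logger.warning("stage %s missing; columns filled with NA", name)
            continue
        cols = [c for c in tab.columns if c not in out.columns]
        out = out.join(tab[cols], how="left")
    return out


def _summary_json(bundle: dict) -> dict:
    def clean(obj):
        if isinstance(obj, float):
            return None if math.isnan(obj) else obj
        return obj

    out = {"version": __version__}
    if "diversity" in bundle:
        out["diversity"] = json.loads(bundle["diversity"].to_json(orient="index"))
    if "neutrality" in bundle:
        out["neutrality"] = json.loads(bundle["neutrality"].to_json(orient="index"))
    if "mismatch" in bundle:
        out["mismatch"] = json.loads(bundle["mismatch"].to_json(orient="index"))
    if "amova" in bundle:
        a = bundle["amova"]
        out["amova"] = {"pct_variation": a.pct_variation, "phi": a.phi,
                        "p_values": a.p_values, "df": a.df}
    if "fst" in bundle:
        out["fst"] = json.loads(bundle["fst"].to_frame().to_json(orient="index"))
    if "network" in bundle:
        net = bundle["network"]
        out["network"] = {"n_nodes": len(net.names),
                          "n_medians": int(sum(not s for s in net.sampled)),
                          "total_length": net.total_length}
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute consensus (if VCF inputs) then the full analysis; write files."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = "input"
    try:
        if cfg.alignment is not None:
            aln = load_alignment(cfg.alignment)
            consensus_out = None
        else:
            stage = "consensus"
            ref = load_reference(cfg.reference)
            mask = load_mask(cfg.mask, ref.length) if cfg.mask else cfg.filter_config.mask
            fcfg = FilterConfig(**{**cfg.filter_config.__dict__, "mask": mask})
            seqs, ids = [], []
            for sample, vcf_path in cfg.vcfs.items():
                table = load_variants(vcf_path, ref)
                kept, report = filter_variants(table, fcfg)
                cons = build_consensus(ref, kept, mask, sample)
                report.table.to_csv(out_dir / f"{sample}.filters.tsv",
                                    sep="\t", index=False)
                ids.append(sample)
                seqs.append(cons.sequence(sample))
            aln = Alignment.from_seqs(ids, seqs)
            consensus_out = aln
        popmap = load_popmap(cfg.popmap, aln)
        stage = "analysis"
        bundle = run_analysis(aln, popmap, aggregates=cfg.aggregates,
                              n_perm=cfg.n_perm, n_sims=cfg.n_sims,
                              n_boot=cfg.n_boot, epsilon=cfg.epsilon,
                              models=cfg.models, seed=cfg.seed)
        if consensus_out is not None:
            bundle["consensus"] = consensus_out
        stage = "export"
        bundle["summary"] = summarize_tables(bundle)
        bundle["log"] = {
            "version": __version__, "seed": cfg.seed, "n_perm": cfg.n_perm,
            "n_sims": cfg.n_sims, "n_boot": cfg.n_boot, "epsilon": cfg.epsilon,
            "models": ",".join(cfg.models),
        }
        export_results({k: v for k, v in bundle.items()
                        if k in ("diversity", "neutrality", "mismatch", "amova",
                                 "fst", "network", "consensus", "log")}, out_dir)
        bundle["summary"].to_csv(out_dir / "summary.tsv", sep="\t")
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(_summary_json(bundle), fh, indent=1, sort_keys=True)
        return bundle
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
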