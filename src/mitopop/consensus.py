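"""Variant filtering, per-sample consensus construction, and cross-platform
discordance masking.

The filter chain reproduces a conservative GATK-style hard-filtering recipe
for mitochondrial variants called from short reads: site quality (QUAL),
FisherStrand (FS), QualByDepth (QD), depth (DP) and allele-frequency (AF)
thresholds, removal of SNP clusters (any run of ``cluster_size`` SNPs spanning
at most ``cluster_window`` bases), and exclusion of variants inside a repeat
mask (e.g. the hypervariable HV2 block of the control region, which short
reads cannot be mapped across reliably).

Consensus building substitutes the supported ALT allele into the reference
(most supported allele at mixed sites, REF on ties), applies indels
left-to-right with coordinate shifting, and excises the masked intervals, so
a ~18.2 kb reference with an ~0.9 kb mask yields ~17.3 kb consensus
sequences.  N-filling of the mask is available instead of excision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import Alignment, RegionMask, VariantTable

logger = logging.getLogger(__name__)

RULES = ("QUAL", "FS", "QD", "DP", "AF", "SNP_cluster", "mask")


@dataclass(frozen=True)
class FilterConfig:
    min_qual: float = 20.0
    max_fs: float = 30.0        # strict >
    min_qd: float = 2.0         # strict <
    min_dp: float = 20.0
    min_af: float = 0.05
    cluster_size: int = 3
    cluster_window: int = 35    # 1-based inclusive span, bp
    mask: RegionMask = field(default_factory=lambda: RegionMask(()))

    def __post_init__(self) -> None:
        for name in ("min_qual", "max_fs", "min_qd", "min_dp", "min_af"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.cluster_window < self.cluster_size:
            raise ValueError("cluster_window must be >= cluster_size")


@dataclass(frozen=True)
class FilterReport:
    """Per-variant outcome: kept or removed, with the ordered failed rules."""

    table: pd.DataFrame  # columns: pos, kept, reasons (tuple)

    @property
    def n_kept(self) -> int:
        return int(self.table["kept"].sum())

    @property
    def n_removed(self) -> int:
        return int((~self.table["kept"]).sum())


def _cluster_flags(snp_positions: np.ndarray, size: int, window: int) -> np.ndarray:
    """Flag every SNP inside any run of ``size`` consecutive SNPs whose
    1-based inclusive span is <= ``window`` bases."""
    flags = np.zeros(len(snp_positions), dtype=bool)
    for start in range(len(snp_positions) - size + 1):
        end = start + size - 1
        if snp_positions[end] - snp_positions[start] + 1 <= window:
            flags[start: end + 1] = True
    return flags


def filter_variants(table: VariantTable, cfg: FilterConfig,
                    sort_unsorted: bool = True) -> tuple[VariantTable, FilterReport]:
    """Apply the hard filters; returns the kept variants and a full report.

    Thresholds with missing annotations (NaN) cannot fail a rule.  The SNP
    cluster rule sees every SNP in the input (indels neither count toward nor
    are removed by it), and the mask rule is applied last.
    """
    df = table.df
    if not df["pos"].is_monotonic_increasing:
        if not sort_unsorted:
            raise ValueError("variant table is not position-sorted")
        logger.warning("variant table was unsorted; sorting by position")
        table = table.sorted()
        df = table.df
    reasons: list[list[str]] = [[] for _ in range(len(df))]

    def fail(mask_arr, rule):
        for i in np.flatnonzero(np.asarray(mask_arr, dtype=bool)):
            reasons[i].append(rule)

    fail(df["qual"] < cfg.min_qual, "QUAL")
    fail(df["FS"] > cfg.max_fs, "FS")
    fail(df["QD"] < cfg.min_qd, "QD")
    fail(df["DP"] < cfg.min_dp, "DP")
    fail(df["AF"] < cfg.min_af, "AF")

    snp_rows = np.flatnonzero(df["is_snp"].to_numpy())
    if len(snp_rows) >= cfg.cluster_size:
        flags = _cluster_flags(df["pos"].to_numpy()[snp_rows],
                               cfg.cluster_size, cfg.cluster_window)
        fail_idx = np.zeros(len(df), dtype=bool)
        fail_idx[snp_rows[flags]] = True
        fail(fail_idx, "SNP_cluster")

    in_mask = [any(a < pos - 1 + len(ref) and pos - 1 < b
                   for a, b in cfg.mask.intervals)
               for pos, ref in zip(df["pos"], df["ref"])]
    fail(in_mask, "mask")

    kept_mask = np.array([not r for r in reasons])
    report = FilterReport(pd.DataFrame({
        "pos": df["pos"].to_numpy(),
        "kept": kept_mask,
        "reasons": [tuple(r) for r in reasons],
    }))
    kept = VariantTable(df[kept_mask].reset_index(drop=True),
                        table.contig, table.reference_length)
    return kept, report


def _chosen_allele(row) -> str:
    """Most supported allele at a mixed site: max AD, ties to REF."""
    alleles = (row["ref"],) + tuple(row["alts"])
    ad = row["AD"]
    if ad is None or len(ad) != len(alleles):
        return row["alt"]
    best = max(range(len(alleles)), key=lambda i: (ad[i], i == 0))
    if len(set(ad)) < len(ad):
        tied = [i for i in range(len(alleles)) if ad[i] == ad[best]]
        if len(tied) > 1:
            if 0 in tied:
                logger.info("allele-depth tie at POS %d resolved to REF", row["pos"])
                return row["ref"]
            best = tied[0]
    return alleles[best]


def build_consensus(reference: Alignment, variants: VariantTable,
                    mask: RegionMask, sample_id: str,
                    mask_mode: str = "excise") -> Alignment:
    """Substitute filtered variants into the reference and apply the mask.

    Indels shift downstream coordinates; variants are applied left-to-right
    on reference coordinates.  ``mask_mode`` is ``"excise"`` (drop the masked
    bases, the default) or ``"nfill"``.  Overlapping variants, or a variant
    inside the mask (which filtering should have removed), are errors.
    """
    refseq = reference.sequence(reference.ids[0])
    L = len(refseq)
    if mask_mode not in ("excise", "nfill"):
        raise ValueError(f"unknown mask_mode {mask_mode!r}")
    df = variants.df.sort_values("pos", kind="stable")
    masked = np.zeros(L, dtype=bool)
    for a, b in mask.intervals:
        if b > L:
            raise ValueError(f"mask interval ({a}, {b}) exceeds reference length {L}")
        masked[a:b] = True

    out: list[str] = []
    cursor = 0  # 0-based position in reference

    def emit_ref(upto: int) -> None:
        nonlocal cursor
        seg = refseq[cursor:upto]
        seg_mask = masked[cursor:upto]
        if mask_mode == "excise":
            out.append("".join(c for c, m in zip(seg, seg_mask) if not m))
        else:
            out.append("".join("N" if m else c for c, m in zip(seg, seg_mask)))
        cursor = upto

    prev_end = 0
    for _, row in df.iterrows():
        start = int(row["pos"]) - 1
        end = start + len(row["ref"])
        if start < prev_end:
            raise ValueError(f"overlapping variants at positions {prev_end} and {row['pos']}")
        if masked[start:end].any():
            raise ValueError(
                f"variant at POS {row['pos']} lies inside a masked interval; "
                "it should have been removed by filtering")
        emit_ref(start)
        out.append(_chosen_allele(row))
        cursor = end
        prev_end = end
    emit_ref(L)
    return Alignment.from_seqs([sample_id], ["".join(out)])


@dataclass(frozen=True)
class DiscordanceReport:
    """Sites where an individual's two platform-specific sequences disagree."""

    table: pd.DataFrame  # columns: site (0-based), individuals, masked (bool)


def crossplatform_mask(pairs: dict, alignment: Alignment):
    """Mask sites that are intra-individually discordant in >= 2 individuals.

    ``pairs`` maps individual id -> (seq_platform_A, seq_platform_B), both
    already aligned to the alignment's coordinates.  A site is discordant for
    an individual when both platform calls are non-missing and differ.  Sites
    discordant in two or more individuals are set to N in *every* sequence of
    the alignment (likely RNA editing or systematic mapping error, not
    genotype); single-individual discordances are reported but left in place.
    Returns (masked alignment, DiscordanceReport).
    """
    L = alignment.length
    unknown = [k for k in pairs if k not in alignment.ids]
    if unknown:
        raise ValueError(f"paired ids not present in alignment: {sorted(unknown)}")
    per_site: dict[int, list[str]] = {}
    for ind, (sa, sb) in pairs.items():
        a = np.frombuffer(str(sa).upper().encode(), dtype=np.uint8)
        b = np.frombuffer(str(sb).upper().encode(), dtype=np.uint8)
        if len(a) != L or len(b) != L:
            raise ValueError(f"platform sequences for {ind!r} do not match alignment length")
        miss = np.isin(a, np.frombuffer(b"N-", dtype=np.uint8)) | \
            np.isin(b, np.frombuffer(b"N-", dtype=np.uint8))
        for site in np.flatnonzero((a != b) & ~miss):
            per_site.setdefault(int(site), []).append(ind)
    mat = alignment.matrix.copy()
    rows = []
    for site in sorted(per_site):
        inds = per_site[site]
        do_mask = len(inds) >= 2
        if do_mask:
            mat[:, site] = ord("N")
        rows.append({"site": site, "individuals": tuple(inds), "masked": do_mask})
    report = DiscordanceReport(pd.DataFrame(rows, columns=["site", "individuals", "masked"]))
    return Alignment(alignment.ids, mat), report
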