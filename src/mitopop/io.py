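"""Data model and readers/writers for the formats the pipeline touches.

Sequence data live in an :class:`Alignment`, a matrix of equal-length haploid
sequences over the alphabet ``{A, C, G, T, N, -}``.  Sample metadata live in a
:class:`PopulationMap` (sample -> population -> group).  Variant records parsed
from single-sample VCFs are held in a :class:`VariantTable` (a thin pandas
wrapper), and repeat-mask intervals in a :class:`RegionMask`.

Coordinate contract: VCF positions are 1-based and BED intervals 0-based
half-open at the file boundary; every internal coordinate in this package is
0-based half-open.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Allowed residue codes after case-folding and U->T normalisation.
ALPHABET = frozenset(b"ACGTN-")

#: Codes treated as missing data by the statistics modules.
MISSING = frozenset(b"N-")


class AlignmentError(ValueError):
    """Raised when sequences violate the alignment invariants."""


class ParseError(ValueError):
    """Raised on malformed input files."""


@dataclass(frozen=True)
class Alignment:
    """Equal-length haploid sequences indexed by unique sample ids.

    The sequence data are stored as an ``(n, L)`` uint8 matrix of ASCII codes
    so that column scans and pairwise comparisons vectorise.
    """

    ids: tuple[str, ...]
    matrix: np.ndarray  # (n, L) uint8, ASCII

    def __post_init__(self) -> None:
        if len(self.ids) != len(set(self.ids)):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise AlignmentError(f"duplicate sample ids: {dupes}")
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.ids):
            raise AlignmentError("matrix shape does not match id count")
        bad = set(np.unique(self.matrix).tobytes()) - set(ALPHABET)
        if bad:
            raise AlignmentError(
                f"illegal characters in alignment: {sorted(chr(b) for b in bad)}"
            )

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def sequence(self, sample_id: str) -> str:
        row = self.matrix[self.ids.index(sample_id)]
        return row.tobytes().decode("ascii")

    @property
    def seqs(self) -> tuple[str, ...]:
        return tuple(row.tobytes().decode("ascii") for row in self.matrix)

    def subset(self, sample_ids) -> "Alignment":
        """Row-subset preserving the requested order."""
        idx = [self.ids.index(s) for s in sample_ids]
        return Alignment(tuple(sample_ids), self.matrix[idx].copy())

    @classmethod
    def from_seqs(cls, ids, seqs) -> "Alignment":
        ids = tuple(str(i) for i in ids)
        norm = []
        lengths = {}
        for sid, seq in zip(ids, seqs):
            s = str(seq).upper().replace("U", "T")
            lengths[sid] = len(s)
            norm.append(s)
        if len(set(lengths.values())) > 1:
            # majority length wins; on a tie the longest is taken as reference
            modal = max(set(lengths.values()),
                        key=lambda v: (list(lengths.values()).count(v), v))
            offenders = sorted(k for k, v in lengths.items() if v != modal)
            raise AlignmentError(
                f"sequences of unequal length (expected {modal}): {offenders}"
            )
        if not norm:
            raise AlignmentError("empty alignment")
        mat = np.frombuffer("".join(norm).encode("ascii"), dtype=np.uint8)
        mat = mat.reshape(len(norm), -1).copy() if norm[0] else mat.reshape(len(norm), 0)
        for sid, row in zip(ids, mat):
            bad = set(row.tobytes()) - set(ALPHABET)
            if bad:
                pos = int(np.flatnonzero(~np.isin(row, np.frombuffer(b"ACGTN-", dtype=np.uint8)))[0])
                raise ParseError(
                    f"illegal character {chr(sorted(bad)[0])!r} in {sid} at position {pos + 1}"
                )
        return cls(ids, mat)


@dataclass(frozen=True)
class PopulationMap:
    """sample -> population and population -> group assignments.

    Groups partition populations; when no group column is supplied every
    population forms its own group, which makes the three-level AMOVA design
    collapse to the two-level one.
    """

    sample_to_pop: dict
    pop_to_group: dict

    def __post_init__(self) -> None:
        missing = set(self.sample_to_pop.values()) - set(self.pop_to_group)
        if missing:
            raise ValueError(f"populations without a group: {sorted(missing)}")

    @property
    def populations(self) -> tuple[str, ...]:
        seen = dict.fromkeys(self.sample_to_pop.values())
        return tuple(seen)

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.pop_to_group[p] for p in self.populations))

    def samples_in(self, population: str) -> tuple[str, ...]:
        return tuple(s for s, p in self.sample_to_pop.items() if p == population)

    def pops_in(self, group: str) -> tuple[str, ...]:
        return tuple(p for p in self.populations if self.pop_to_group[p] == group)

    def restrict(self, sample_ids) -> "PopulationMap":
        s2p = {s: self.sample_to_pop[s] for s in sample_ids}
        p2g = {p: g for p, g in self.pop_to_group.items() if p in set(s2p.values())}
        return PopulationMap(s2p, p2g)


@dataclass(frozen=True)
class RegionMask:
    """Non-overlapping 0-based half-open intervals on a reference."""

    intervals: tuple[tuple[int, int], ...]

    @classmethod
    def from_intervals(cls, intervals, reference_length: int | None = None) -> "RegionMask":
        ivals = sorted((int(a), int(b)) for a, b in intervals)
        for a, b in ivals:
            if a < 0 or b <= a:
                raise ValueError(f"invalid interval ({a}, {b})")
            if reference_length is not None and b > reference_length:
                raise ValueError(f"interval ({a}, {b}) exceeds reference length {reference_length}")
        merged: list[list[int]] = []
        for a, b in ivals:
            if merged and a <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], b)
            else:
                merged.append([a, b])
        return cls(tuple((a, b) for a, b in merged))

    @property
    def total_length(self) -> int:
        return sum(b - a for a, b in self.intervals)

    def contains(self, pos0: int) -> bool:
        """Membership of a single 0-based position."""
        return any(a <= pos0 < b for a, b in self.intervals)


@dataclass
class VariantTable:
    """Variant records from a single-sample, single-contig VCF.

    ``df`` columns: ``pos`` (1-based), ``ref``, ``alt`` (primary ALT), ``alts``
    (all ALT alleles), ``qual``, ``FS``, ``QD``, ``DP``, ``AF``, ``AD``
    (per-allele depths, REF first, or None), ``is_snp``, ``missing_info``
    (names of absent required INFO keys).
    """

    df: pd.DataFrame
    contig: str = ""
    reference_length: int = 0

    def __len__(self) -> int:
        return len(self.df)

    def sorted(self) -> "VariantTable":
        return VariantTable(self.df.sort_values("pos", kind="stable").reset_index(drop=True),
                            self.contig, self.reference_length)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def load_alignment(path) -> Alignment:
    """Read a multi-FASTA into an :class:`Alignment`.

    Mixed case is folded to upper and RNA ``U`` mapped to ``T``.  Records of
    unequal length raise :class:`AlignmentError` naming the offending ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"no FASTA records in {path}")
    return Alignment.from_seqs([r.id for r in records], [str(r.seq) for r in records])


def load_reference(path) -> Alignment:
    """Read a single-record FASTA reference (an alignment of one)."""
    aln = load_alignment(path)
    if aln.n != 1:
        raise ParseError(f"expected a single reference record, found {aln.n}")
    return aln


def load_popmap(path, alignment: Alignment | None = None) -> PopulationMap:
    """Read a sample/population(/group) TSV.

    Without a ``group`` column each population becomes its own group.  If an
    alignment is given, every alignment id must be mapped.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    for required in ("sample", "population"):
        if required not in cols:
            raise ParseError(f"popmap is missing required column {required!r}")
    samples = df[cols["sample"]]
    if samples.duplicated().any():
        dupes = sorted(samples[samples.duplicated()].unique())
        raise ParseError(f"duplicate sample rows in popmap: {dupes}")
    s2p = dict(zip(samples, df[cols["population"]]))
    if "group" in cols:
        p2g = {}
        for pop, grp in zip(df[cols["population"]], df[cols["group"]]):
            if pop in p2g and p2g[pop] != grp:
                raise ParseError(f"population {pop!r} assigned to multiple groups")
            p2g[pop] = grp
    else:
        p2g = {p: p for p in s2p.values()}
    pm = PopulationMap(s2p, p2g)
    if alignment is not None:
        unmapped = [i for i in alignment.ids if i not in s2p]
        if unmapped:
            raise ParseError(f"alignment ids missing from popmap: {unmapped}")
        pm = pm.restrict([i for i in alignment.ids])
        empty = [p for p in pm.populations if not pm.samples_in(p)]
        if empty:
            raise ParseError(f"populations with zero samples after intersection: {empty}")
    return pm


def load_mask(path, reference_length: int | None = None) -> RegionMask:
    """Read a BED file (0-based half-open) into a :class:`RegionMask`."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            rows.append((int(parts[1]), int(parts[2])))
    return RegionMask.from_intervals(rows, reference_length)


_REQUIRED_INFO = ("FS", "QD", "DP", "AF")


def load_variants(path, reference: Alignment) -> VariantTable:
    """Parse a single-contig VCF against a reference alignment-of-one.

    SNPs and indels are both retained.  FS/QD/DP/AF are taken from INFO;
    records lacking any of them are flagged in ``missing_info`` rather than
    dropped (the filter stage decides their fate).  A REF allele that
    disagrees with the reference sequence is an error.
    """
    from cyvcf2 import VCF

    refseq = reference.sequence(reference.ids[0])
    contigs = set()
    rows = []
    vcf = VCF(str(path))
    try:
        for v in vcf:
            contigs.add(v.CHROM)
            if len(contigs) > 1:
                raise ParseError(f"multi-contig VCF not supported: {sorted(contigs)}")
            pos = v.POS  # 1-based
            if pos < 1 or pos + len(v.REF) - 1 > len(refseq):
                raise ParseError(f"POS {pos} outside reference of length {len(refseq)}")
            expected = refseq[pos - 1 : pos - 1 + len(v.REF)]
            if expected != v.REF.upper():
                raise ParseError(
                    f"REF mismatch at POS {pos}: VCF has {v.REF!r}, reference has {expected!r}"
                )
            info = dict(v.INFO)
            missing = [k for k in _REQUIRED_INFO if k not in info]
            af = info.get("AF")
            if isinstance(af, tuple):
                af = max(af)
            ad = None
            try:
                if v.format("AD") is not None:
                    ad = tuple(int(x) for x in np.asarray(v.format("AD")).ravel())
            except Exception:  # no samples / no AD field
                ad = None
            alts = tuple(a.upper() for a in (v.ALT or ()))
            if not alts:
                continue
            rows.append({
                "pos": pos,
                "ref": v.REF.upper(),
                "alt": alts[0],
                "alts": alts,
                "qual": v.QUAL if v.QUAL is not None else np.nan,
                "FS": float(info["FS"]) if "FS" in info else np.nan,
                "QD": float(info["QD"]) if "QD" in info else np.nan,
                "DP": float(info["DP"]) if "DP" in info else np.nan,
                "AF": float(af) if af is not None else np.nan,
                "AD": ad,
                "is_snp": len(v.REF) == 1 and all(len(a) == 1 for a in alts),
                "missing_info": tuple(missing),
            })
    finally:
        vcf.close()
    columns = ["pos", "ref", "alt", "alts", "qual", "FS", "QD", "DP", "AF",
               "AD", "is_snp", "missing_info"]
    df = pd.DataFrame(rows, columns=columns)
    return VariantTable(df, contig=next(iter(contigs), reference.ids[0]),
                        reference_length=len(refseq))


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_alignment(alignment: Alignment, path, wrap: int = 70) -> None:
    """Write FASTA, wrapping at ``wrap`` columns; whitespace in ids -> '_'."""
    records = []
    for sid in alignment.ids:
        clean = "_".join(sid.split())
        if clean != sid:
            warnings.warn(f"whitespace in id {sid!r} replaced: {clean!r}")
        records.append(SeqRecord(Seq(alignment.sequence(sid)), id=clean, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(records)


def export_results(results: dict, out_dir) -> list[Path]:
    """Write whatever result objects are present to TSV/GML/FASTA files.

    Recognised keys: ``diversity`` (DataFrame -> diversity.tsv), ``amova``
    (AmovaResult -> amova.tsv), ``fst`` (FstMatrix -> fst.tsv, estimates below
    the diagonal and permutation p-values above), ``neutrality`` / ``mismatch``
    (DataFrames), ``network`` (HaploNetwork -> GML + edge/node TSVs),
    ``consensus`` (Alignment -> consensus.fa), ``log`` (dict -> run_log.tsv).
    Returns the paths written; an empty results dict writes nothing.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _save_df(df: pd.DataFrame, name: str, index=False):
        p = out_dir / name
        df.to_csv(p, sep="\t", index=index, float_format="%.6g")
        written.append(p)

    if not results:
        logger.warning("export_results called with no results; nothing written")
        return written

    if "diversity" in results:
        _save_df(results["diversity"], "diversity.tsv")
    if "neutrality" in results:
        _save_df(results["neutrality"], "neutrality.tsv")
    if "mismatch" in results:
        _save_df(results["mismatch"], "mismatch.tsv")
    if "amova" in results:
        _save_df(results["amova"].to_frame(), "amova.tsv")
    if "fst" in results:
        _save_df(results["fst"].to_frame(), "fst.tsv", index=True)
    if "network" in results:
        net = results["network"]
        import networkx as nx

        g = net.to_networkx()
        p = out_dir / "network.gml"
        nx.write_gml(g, str(p))
        written.append(p)
        _save_df(net.edge_table(), "network_edges.tsv")
        _save_df(net.node_table(), "network_nodes.tsv")
    if "consensus" in results:
        p = out_dir / "consensus.fa"
        write_alignment(results["consensus"], p)
        written.append(p)
    if "log" in results:
        p = out_dir / "run_log.tsv"
        pd.Series(results["log"]).to_csv(p, sep="\t", header=False)
        written.append(p)
    return written
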