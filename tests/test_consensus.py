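import numpy as np
import pandas as pd
import pytest

from mitopop.consensus import (FilterConfig, build_consensus,
                               crossplatform_mask, filter_variants)
from mitopop.io import Alignment, RegionMask, VariantTable


def make_table(records, ref_length=1000):
    """VariantTable straight from dicts (bypasses VCF parsing)."""
    defaults = {"qual": 50.0, "FS": 1.0, "QD": 10.0, "DP": 100.0, "AF": 0.9,
                "AD": None, "missing_info": ()}
    rows = []
    for rec in records:
        row = dict(defaults)
        row.update(rec)
        row.setdefault("alts", (row["alt"],))
        row.setdefault("is_snp",
                       len(row["ref"]) == 1 and all(len(a) == 1 for a in row["alts"]))
        rows.append(row)
    cols = ["pos", "ref", "alt", "alts", "qual", "FS", "QD", "DP", "AF",
            "AD", "is_snp", "missing_info"]
    return VariantTable(pd.DataFrame(rows, columns=cols), "ref", ref_length)


def snp(pos, **kw):
    return {"pos": pos, "ref": "A", "alt": "T", **kw}


class TestFilters:
    @pytest.mark.parametrize("field,value,rule", [
        ("qual", 19.9, "QUAL"),
        ("FS", 30.1, "FS"),
        ("QD", 1.5, "QD"),
        ("DP", 19.0, "DP"),
        ("AF", 0.04, "AF"),
    ])
    def test_threshold_rules(self, field, value, rule):
        table = make_table([snp(100, **{field: value})])
        kept, report = filter_variants(table, FilterConfig())
        assert len(kept) == 0
        assert report.table.loc[0, "reasons"] == (rule,)

    @pytest.mark.parametrize("field,value", [
        ("qual", 20.0), ("FS", 30.0), ("QD", 2.0), ("DP", 20.0), ("AF", 0.05),
    ])
    def test_boundary_values_kept(self, field, value):
        # every rule is strict, so the threshold value itself passes
        table = make_table([snp(100, **{field: value})])
        kept, _ = filter_variants(table, FilterConfig())
        assert len(kept) == 1

    def test_cluster_span_35_removed(self):
        table = make_table([snp(100), snp(120), snp(134)])
        kept, report = filter_variants(table, FilterConfig())
        assert len(kept) == 0
        assert all(r == ("SNP_cluster",) for r in report.table["reasons"])

    def test_cluster_span_37_kept(self):
        table = make_table([snp(100), snp(120), snp(136)])
        kept, _ = filter_variants(table, FilterConfig())
        assert len(kept) == 3

    def test_indels_do_not_join_clusters(self):
        table = make_table([snp(100), {"pos": 110, "ref": "A", "alt": "ATT"},
                            snp(120)])
        kept, _ = filter_variants(table, FilterConfig())
        assert len(kept) == 3

    def test_mask_rule(self):
        cfg = FilterConfig(mask=RegionMask.from_intervals([(99, 105)]))
        table = make_table([snp(100), snp(200)])
        kept, report = filter_variants(table, cfg)
        assert list(kept.df["pos"]) == [200]
        assert report.table.loc[0, "reasons"] == ("mask",)

    def test_unsorted_sorted_with_warning(self, caplog):
        import logging

        table = make_table([snp(200), snp(100)])
        with caplog.at_level(logging.WARNING):
            kept, _ = filter_variants(table, FilterConfig())
        assert "unsorted" in caplog.text
        assert list(kept.df["pos"]) == [100, 200]

    def test_unsorted_error_when_requested(self):
        table = make_table([snp(200), snp(100)])
        with pytest.raises(ValueError, match="sorted"):
            filter_variants(table, FilterConfig(), sort_unsorted=False)

    def test_idempotent(self, rng):
        records = [snp(int(p), QD=float(rng.uniform(0, 5)),
                       FS=float(rng.uniform(0, 40)))
                   for p in sorted(rng.choice(900, size=30, replace=False) + 1)]
        table = make_table(records)
        cfg = FilterConfig()
        once, _ = filter_variants(table, cfg)
        twice, report2 = filter_variants(once, cfg)
        pd.testing.assert_frame_equal(once.df, twice.df)
        assert report2.n_removed == 0

    def test_every_removed_variant_has_reason_and_partition(self, rng):
        records = [snp(int(p), QD=float(rng.uniform(0, 5)))
                   for p in sorted(rng.choice(900, size=25, replace=False) + 1)]
        table = make_table(records)
        kept, report = filter_variants(table, FilterConfig())
        assert report.n_kept + report.n_removed == len(table)
        removed = report.table[~report.table["kept"]]
        assert all(len(r) >= 1 for r in removed["reasons"])
        allowed = {"QUAL", "FS", "QD", "DP", "AF", "SNP_cluster", "mask"}
        assert all(set(r) <= allowed for r in report.table["reasons"])

    def test_mask_removal_gives_superset_when_dropped(self, rng):
        records = [snp(int(p)) for p in
                   sorted(rng.choice(900, size=20, replace=False) + 1)]
        table = make_table(records)
        with_mask, _ = filter_variants(
            table, FilterConfig(mask=RegionMask.from_intervals([(300, 500)])))
        without, _ = filter_variants(table, FilterConfig())
        assert set(with_mask.df["pos"]) <= set(without.df["pos"])


class TestConsensus:
    def _ref(self, seq):
        return Alignment.from_seqs(["ref"], [seq])

    def test_mask_excision_length(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=18_152))
        ref = self._ref(seq)
        mask = RegionMask.from_intervals([(2000, 2889)])
        cons = build_consensus(ref, make_table([], 18_152), mask, "s1")
        assert cons.length == 18_152 - 889 == 17_263

    def test_insertion(self):
        ref = self._ref("ACGT")
        table = make_table([{"pos": 2, "ref": "C", "alt": "CAA"}], 4)
        cons = build_consensus(ref, table, RegionMask(()), "s1")
        assert cons.sequence("s1") == "ACAAGT"

    def test_deletion(self):
        ref = self._ref("ACGTACGT")
        table = make_table([{"pos": 3, "ref": "GTA", "alt": "G"}], 8)
        cons = build_consensus(ref, table, RegionMask(()), "s1")
        assert cons.sequence("s1") == "ACGCGT"

    def test_single_snp_single_difference(self):
        ref = self._ref("AAAAAAAAAA")
        table = make_table([{"pos": 5, "ref": "A", "alt": "G"}], 10)
        cons = build_consensus(ref, table, RegionMask(()), "s1")
        diffs = [i for i, (a, b) in enumerate(zip(cons.sequence("s1"),
                                                  "AAAAAAAAAA")) if a != b]
        assert diffs == [4]

    def test_no_variants_no_mask_is_reference(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=500))
        ref = self._ref(seq)
        cons = build_consensus(ref, make_table([], 500), RegionMask(()), "s1")
        assert cons.sequence("s1") == seq

    def test_nfill_mode(self):
        ref = self._ref("ACGTACGT")
        mask = RegionMask.from_intervals([(2, 4)])
        cons = build_consensus(ref, make_table([], 8), mask, "s1",
                               mask_mode="nfill")
        assert cons.sequence("s1") == "ACNNACGT"

    def test_mixed_site_majority_allele_and_ref_tie(self):
        ref = self._ref("ACGTACGT")
        # AD: ref 10, alt1 40, alt2 50 -> alt2 wins
        table = make_table([{"pos": 1, "ref": "A", "alt": "T",
                             "alts": ("T", "G"), "AD": (10, 40, 50)}], 8)
        cons = build_consensus(ref, table, RegionMask(()), "s1")
        assert cons.sequence("s1")[0] == "G"
        # tie with REF -> REF retained
        table = make_table([{"pos": 1, "ref": "A", "alt": "T",
                             "alts": ("T",), "AD": (50, 50)}], 8)
        cons = build_consensus(ref, table, RegionMask(()), "s1")
        assert cons.sequence("s1")[0] == "A"

    def test_variant_in_mask_is_error(self):
        ref = self._ref("ACGTACGT")
        mask = RegionMask.from_intervals([(0, 4)])
        table = make_table([{"pos": 2, "ref": "C", "alt": "T"}], 8)
        with pytest.raises(ValueError, match="masked"):
            build_consensus(ref, table, mask, "s1")

    def test_overlapping_variants_error(self):
        ref = self._ref("ACGTACGT")
        table = make_table([{"pos": 2, "ref": "CGT", "alt": "C"},
                            {"pos": 4, "ref": "T", "alt": "A"}], 8)
        with pytest.raises(ValueError, match="overlap"):
            build_consensus(ref, table, RegionMask(()), "s1")


class TestCrossplatformMask:
    def _aln(self):
        return Alignment.from_seqs(
            [f"i{k}" for k in range(4)],
            ["ACGTACGT", "ACGTACGT", "ACCTACGT", "ACGTACGA"])

    def test_multi_individual_discordance_masks_column(self):
        aln = self._aln()
        pairs = {"i0": ("ACGTACGT", "ATGTACGT"),   # site 1 discordant
                 "i1": ("ACGTACGT", "AGGTACGT"),   # site 1 discordant
                 "i2": ("ACCTACGT", "ACCTACGT"),
                 "i3": ("ACGTACGA", "ACGTACGA")}
        masked, report = crossplatform_mask(pairs, aln)
        assert all(s[1] == "N" for s in masked.seqs)
        row = report.table.iloc[0]
        assert row["site"] == 1 and row["masked"]
        assert set(row["individuals"]) == {"i0", "i1"}

    def test_single_individual_discordance_reported_only(self):
        aln = self._aln()
        pairs = {"i0": ("ACGTACGT", "ATGTACGT"),
                 "i1": ("ACGTACGT", "ACGTACGT")}
        masked, report = crossplatform_mask(pairs, aln)
        assert masked.seqs == aln.seqs
        assert report.table.iloc[0]["masked"] == False  # noqa: E712
        assert report.table.iloc[0]["individuals"] == ("i0",)

    def test_identical_pairs_no_changes(self):
        aln = self._aln()
        pairs = {i: (aln.sequence(i), aln.sequence(i)) for i in aln.ids}
        masked, report = crossplatform_mask(pairs, aln)
        assert masked.seqs == aln.seqs
        assert len(report.table) == 0

    def test_unpaired_id_error(self):
        aln = self._aln()
        with pytest.raises(ValueError, match="ghost"):
            crossplatform_mask({"ghost": ("ACGTACGT", "ACGTACGT")}, aln)

    def test_n_calls_not_discordant(self):
        aln = self._aln()
        pairs = {"i0": ("NCGTACGT", "ACGTACGT"),
                 "i1": ("NCGTACGT", "ACGTACGT")}
        _, report = crossplatform_mask(pairs, aln)
        assert len(report.table) == 0
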