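from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitopop import popstats as ps
from mitopop.io import Alignment, PopulationMap
from _util import (oracle_haplotype_diversity, oracle_mean_pairwise, oracle_pi,
                   oracle_pairwise, oracle_site_counts, random_alignment)


class TestClassifySites:
    def test_categories(self):
        aln = Alignment.from_seqs(
            ["a", "b", "c", "d"],
            ["AAAA", "AAAT", "ATTT", "ATTN"])
        # col0 invariant, col1 informative (A2/T2), col2 informative, col3 singleton-ish
        sc = ps.classify_sites(aln)
        assert sc.categories[0] == "invariant"
        assert sc.categories[1] == "informative"
        assert sc.categories[2] == "informative"
        assert sc.categories[3] == "singleton"

    def test_all_missing_column_uncalled(self):
        aln = Alignment.from_seqs(["a", "b"], ["AN", "AN"])
        sc = ps.classify_sites(aln)
        assert sc.categories == ("invariant", "uncalled")
        assert sc.S == 0

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(25):
            aln = random_alignment(rng, int(rng.integers(2, 11)),
                                   int(rng.integers(20, 200)),
                                   missing=float(rng.uniform(0, 0.1)),
                                   n_variable=int(rng.integers(1, 15)))
            S, pinf, singles = oracle_site_counts(aln)
            sc = ps.classify_sites(aln)
            assert sc.S == S
            assert sc.parsimony_informative == pinf
            assert list(sc.singleton_sites) == singles

    def test_singletons_plus_informative_cover_biallelic_s(self, rng):
        aln = random_alignment(rng, 8, 100, n_variable=10)
        sc = ps.classify_sites(aln)
        assert len(sc.singleton_sites) + sc.parsimony_informative == sc.S

    def test_adding_missing_never_increases_s(self, rng):
        """Complete-deletion monotonicity: masking calls can only lose sites."""
        from mitopop.simulate import inject_missingness

        aln = random_alignment(rng, 10, 150, n_variable=20)
        s0 = ps.classify_sites(aln).S
        for frac in (0.02, 0.1, 0.3):
            masked = inject_missingness(aln, frac, seed=1)
            assert ps.classify_sites(masked).S <= s0


class TestHaplotypes:
    def test_identical_sequences_one_haplotype(self):
        aln = Alignment.from_seqs(["a", "b", "c"], ["AAT"] * 3)
        ht = ps.collapse_haplotypes(aln)
        assert ht.H == 1
        assert ht.total_counts.tolist() == [3]

    def test_two_haplotypes_with_counts(self):
        aln = Alignment.from_seqs(["a", "b", "c"], ["AAT", "AAT", "ATT"])
        ht = ps.collapse_haplotypes(aln)
        assert ht.H == 2
        assert ht.total_counts.tolist() == [2, 1]

    def test_missing_policy_changes_h(self):
        # column 1 separates a/b but carries an N in c
        aln = Alignment.from_seqs(["a", "b", "c"], ["AAT", "ATT", "ANT"])
        complete = ps.collapse_haplotypes(aln, missing_policy="complete")
        pairwise = ps.collapse_haplotypes(aln, missing_policy="pairwise")
        assert complete.H == 1       # discriminating column dropped
        assert pairwise.H == 2       # a vs b still compared at that column

    def test_per_population_counts(self):
        aln = Alignment.from_seqs(["a", "b", "c", "d"],
                                  ["AAT", "AAT", "ATT", "AAT"])
        pm = PopulationMap({"a": "P1", "b": "P1", "c": "P2", "d": "P2"},
                           {"P1": "P1", "P2": "P2"})
        ht = ps.collapse_haplotypes(aln, pm)
        assert ht.counts.loc["Hap1"].to_dict() == {"P1": 2, "P2": 1}
        assert ht.counts.loc["Hap2"].to_dict() == {"P1": 0, "P2": 1}

    def test_all_columns_missing_error(self):
        aln = Alignment.from_seqs(["a", "b"], ["AN", "NA"])
        with pytest.raises(ValueError, match="pairwise"):
            ps.collapse_haplotypes(aln)


class TestDiversity:
    def test_pi_two_sequences(self):
        aln = Alignment.from_seqs(["a", "b"], ["AAAAAAAAAT", "AAAAAAAAAA"])
        pi, sd = ps.nucleotide_diversity(aln)
        assert pi == pytest.approx(0.1)

    def test_pi_identical_zero(self):
        aln = Alignment.from_seqs(["a", "b", "c"], ["ACGT"] * 3)
        pi, sd = ps.nucleotide_diversity(aln)
        assert pi == 0.0 and sd == 0.0

    def test_pi_matches_bruteforce(self, rng):
        for _ in range(10):
            aln = random_alignment(rng, 8, 100, missing=0.05, n_variable=12)
            pi, _ = ps.nucleotide_diversity(aln)
            assert pi == pytest.approx(oracle_pi(aln))

    def test_pi_invariant_to_reordering(self, rng):
        aln = random_alignment(rng, 8, 80, n_variable=10)
        perm = rng.permutation(aln.n)
        shuffled = aln.subset([aln.ids[i] for i in perm])
        assert ps.nucleotide_diversity(aln)[0] == \
            pytest.approx(ps.nucleotide_diversity(shuffled)[0])

    def test_pi_under_duplication(self, rng):
        """Duplicating every sequence only changes pi through the pairwise
        average gaining zero-distance pairs, exactly as the oracle predicts."""
        aln = random_alignment(rng, 6, 80, n_variable=10)
        dup = Alignment.from_seqs(
            [f"{i}x{k}" for k in (0, 1) for i in aln.ids],
            [s for k in (0, 1) for s in aln.seqs])
        assert ps.nucleotide_diversity(dup)[0] == pytest.approx(oracle_pi(dup))

    def test_disjoint_called_sites_error(self):
        aln = Alignment.from_seqs(["a", "b"], ["ANN", "NNA"])
        with pytest.raises(ValueError, match="zero called"):
            ps.nucleotide_diversity(aln)

    def test_h_examples(self):
        assert ps.haplotype_diversity([1, 1])[0] == pytest.approx(1.0)
        assert ps.haplotype_diversity([5])[0] == 0.0
        # (4/3) * (1 - 6/16) = 5/6
        assert ps.haplotype_diversity([2, 1, 1])[0] == pytest.approx(5 / 6)

    def test_h_merging_haplotypes_decreases(self, rng):
        for _ in range(20):
            k = int(rng.integers(3, 6))
            counts = rng.integers(1, 10, size=k)
            h_full = ps.haplotype_diversity(counts)[0]
            merged = np.concatenate([[counts[0] + counts[1]], counts[2:]])
            assert ps.haplotype_diversity(merged)[0] < h_full

    def test_h_matches_oracle(self, rng):
        counts = rng.integers(1, 8, size=5)
        assert ps.haplotype_diversity(counts)[0] == \
            pytest.approx(oracle_haplotype_diversity(counts.tolist()))


class TestPropertyBased:
    @given(counts=st.lists(st.integers(min_value=1, max_value=12),
                           min_size=2, max_size=8))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_h_bounds_and_richness_consistency(self, counts):
        h, sd = ps.haplotype_diversity(counts)
        assert 0.0 <= h <= 1.0 + 1e-12
        assert sd >= 0.0
        N, H = sum(counts), len(counts)
        hr_full = ps.haplotype_richness(counts, N)
        assert hr_full == pytest.approx(H)
        hr_one = ps.haplotype_richness(counts, 1)
        assert hr_one == pytest.approx(1.0)
        for g in range(1, N):
            assert ps.haplotype_richness(counts, g) <= hr_full + 1e-9

    @given(data=st.data())
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_pi_bounds_and_symmetry(self, data):
        n = data.draw(st.integers(2, 6))
        L = data.draw(st.integers(5, 30))
        seqs = [data.draw(st.text(alphabet="ACGT", min_size=L, max_size=L))
                for _ in range(n)]
        aln = Alignment.from_seqs([f"s{i}" for i in range(n)], seqs)
        pi, sd = ps.nucleotide_diversity(aln)
        assert 0.0 <= pi <= 1.0
        dm = ps.distance_matrix(aln)
        assert np.array_equal(dm.d, dm.d.T)
        assert np.all(dm.d <= dm.compared)


class TestRarefaction:
    def test_full_sample_gives_h(self):
        counts = [4, 3, 2, 1]
        assert ps.haplotype_richness(counts, 10) == pytest.approx(4.0)

    def test_g1_gives_one(self):
        assert ps.haplotype_richness([5, 3], 1) == pytest.approx(1.0)

    def test_enumeration_example(self):
        # counts (3,1), g=2: of the C(4,2)=6 subsamples, 3 contain only the
        # common haplotype and 3 contain both
        assert ps.haplotype_richness([3, 1], 2) == pytest.approx(1.5)

    def test_monotone_in_g(self, rng):
        counts = [6, 4, 2, 1, 1]
        values = [ps.haplotype_richness(counts, g) for g in range(1, 15)]
        assert all(b >= a for a, b in zip(values, values[1:]))
        assert values[-1] == pytest.approx(5.0)

    def test_g_out_of_range(self):
        with pytest.raises(ValueError):
            ps.haplotype_richness([3, 1], 5)


class TestDistances:
    def test_examples(self):
        aln = Alignment.from_seqs(["a", "b", "c"], ["AAT", "ATT", "AAT"])
        dm = ps.distance_matrix(aln)
        assert dm.d[0, 1] == 1 and dm.d[0, 2] == 0
        assert np.all(dm.d == dm.d.T) and np.all(np.diag(dm.d) == 0)

    def test_matches_bruteforce(self, rng):
        aln = random_alignment(rng, 6, 50, missing=0.1)
        dm = ps.distance_matrix(aln)
        for i, j in combinations(range(6), 2):
            d, comp = oracle_pairwise(aln, i, j)
            assert dm.d[i, j] == d
            assert dm.compared[i, j] == comp


class TestDiversityTable:
    def test_pooled_aggregate_row(self, rng):
        aln = random_alignment(rng, 12, 100, n_variable=10)
        pops = ["A"] * 4 + ["B"] * 4 + ["C"] * 4
        pm = PopulationMap(dict(zip(aln.ids, pops)), {p: p for p in "ABC"})
        tab = ps.diversity_table(aln, pm, aggregates={"BC": ["B", "C"]})
        assert tab.loc["BC", "N"] == 8
        pooled = aln.subset([s for s in aln.ids
                             if pm.sample_to_pop[s] in ("B", "C")])
        assert float(tab.loc["BC", "pi"]) == \
            pytest.approx(ps.nucleotide_diversity(pooled)[0])
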