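"""Site classification, SNP distances and synapomorphy counting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gcpsr.datamodel import ConfigError, UnknownSpecimenError
from gcpsr.variation import (
    classify_sites,
    count_synapomorphies,
    group_distance,
    pairwise_snp_distance,
    variability_summary,
)

from conftest import aln, random_alignment
from _oracles import (
    oracle_column_classes,
    oracle_group_stats,
    oracle_pairwise,
    oracle_synapomorphic_columns,
)


class TestClassifySites:
    def test_identical_sequences_invariant(self):
        s = variability_summary(aln(a="ACGTACGT", b="ACGTACGT"))
        assert s["percent_variable"] == 0.0

    def test_gaps_and_ambiguity_never_create_variability(self):
        # columns: AA, AT, A-, AN over two sequences: only AT is variable
        a = aln(x="AAAA", y="AT-N")
        sites = classify_sites(a)
        assert [s.site_class for s in sites] == [
            "invariant", "variable", "invariant", "invariant",
        ]
        assert [s.coverage for s in sites] == [2, 2, 1, 1]

    def test_percent_denominator_excludes_low_coverage(self):
        # second column has coverage 1 and must not dilute the percentage
        s = variability_summary(aln(a="AT", b="G-"))
        assert s["assessable"] == 1 and s["percent_variable"] == 100.0

    def test_informative_needs_two_states_twice(self):
        a = aln(s1="AT", s2="AT", s3="GT", s4="GA")
        sites = classify_sites(a)
        assert sites[0].informative  # A:2, G:2
        assert not sites[1].informative  # T:3, A:1

    def test_single_sequence_rejected(self):
        with pytest.raises(ConfigError):
            classify_sites(aln(a="ACGT"))


class TestPairwiseDistance:
    def test_self_distance_zero(self):
        d, ov = pairwise_snp_distance(aln(a="ACGT-N", b="ACGTAA"), "a", "a")
        assert (d, ov) == (0, 4)  # gap and N columns carry no information

    def test_mixed_missing_data(self):
        d, ov = pairwise_snp_distance(aln(a="ACGT-", b="ACTTN"), "a", "b")
        assert (d, ov) == (1, 4)

    def test_unknown_specimen(self):
        with pytest.raises(UnknownSpecimenError):
            pairwise_snp_distance(aln(a="A", b="A"), "a", "zz")

    def test_ambiguity_intersect_mode(self):
        # R = {A,G}: overlaps A (match) but is disjoint from C (difference)
        a = aln(x="RR", y="AC")
        assert pairwise_snp_distance(a, "x", "y") == (0, 0)
        assert pairwise_snp_distance(a, "x", "y", ambiguity="intersect") == (1, 2)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_symmetry(self, seed):
        a = random_alignment(np.random.default_rng(seed))
        ids = a.specimens
        x, y = ids[0], ids[-1]
        assert pairwise_snp_distance(a, x, y) == pairwise_snp_distance(a, y, x)


class TestSynapomorphies:
    def test_identical_groups_share_nothing(self):
        a = aln(g1="AAT", g2="AAT", h1="AAT", h2="AAT")
        assert count_synapomorphies(a, {"g1", "g2"}, {"h1", "h2"}).count == 0

    def test_single_diagnostic_column(self):
        a = aln(g1="AAT", g2="AAT", h1="AGT", h2="AGT")
        rep = count_synapomorphies(a, {"g1", "g2"}, {"h1", "h2"})
        assert rep.sites == [(2, "A", "G")]

    def test_within_group_variation_disqualifies(self):
        a = aln(g1="AAT", g2="ACT", h1="AGT", h2="AGT")
        assert count_synapomorphies(a, {"g1", "g2"}, {"h1", "h2"}).count == 0

    def test_coverage_fraction_relaxation(self):
        # g2 has a gap at the diagnostic column: full coverage fails,
        # half coverage accepts it
        a = aln(g1="AAT", g2="A-T", h1="AGT", h2="AGT")
        G, H = {"g1", "g2"}, {"h1", "h2"}
        assert count_synapomorphies(a, G, H).count == 0
        assert count_synapomorphies(a, G, H, min_coverage_fraction=0.5).count == 1

    def test_group_swap_symmetry(self):
        a = aln(g1="AATC", g2="AATC", h1="AGTA", h2="AGTA")
        r1 = count_synapomorphies(a, {"g1", "g2"}, {"h1", "h2"})
        r2 = count_synapomorphies(a, {"h1", "h2"}, {"g1", "g2"})
        assert r1.columns == r2.columns
        assert [(c, b, a_) for c, a_, b in r1.sites] == r2.sites

    def test_overlapping_or_empty_groups_rejected(self):
        a = aln(g1="A", h1="A")
        with pytest.raises(ConfigError):
            count_synapomorphies(a, {"g1"}, {"g1"})
        with pytest.raises(ConfigError):
            count_synapomorphies(a, set(), {"g1"})


class TestGroupDistance:
    def test_identical_twin_groups(self):
        a = aln(g1="ACGT", g2="ACGT", h1="ACGT", h2="ACGT")
        s = group_distance([a], {"g1", "g2"}, {"h1", "h2"})
        d = s.per_locus[0]
        assert (d.min, d.max, d.mean) == (0, 0, 0)

    def test_hand_built_cross_distances(self):
        # distances to h1/h2: g1 -> 3, 4; g2 -> 5, 6
        base = "A" * 12

        def mut(positions):
            return "".join(
                "T" if i in positions else c for i, c in enumerate(base)
            )

        a = aln(
            g1=base,
            g2=mut({0, 4, 5, 6}),
            h1=mut({0, 1, 2}),
            h2=mut({0, 1, 2, 3}),
        )
        s = group_distance([a], {"g1", "g2"}, {"h1", "h2"})
        d = s.per_locus[0]
        assert (d.min, d.max, d.mean) == (3, 6, 4.5)

    def test_zero_overlap_pairs_reported_not_dropped(self):
        a = aln(g1="AC--", g2="ACGT", h1="--GT", h2="ACGA")
        s = group_distance([a], {"g1", "g2"}, {"h1", "h2"})
        assert ("g1", "h1") in s.per_locus[0].excluded_pairs
        assert s.per_locus[0].n_pairs == 3

    def test_locus_without_both_groups_skipped(self):
        a1 = aln("L1", g1="AAAA", h1="TTTT")
        a2 = aln("L2", g1="AAAA", x="TTTT")
        s = group_distance([a1, a2], {"g1"}, {"h1"})
        assert [d.locus_name for d in s.per_locus] == ["L1"]
        assert s.skipped_loci == ["L2"]
        assert s.total_min == 4

    def test_synapomorphies_bounded_by_min_distance(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            a = random_alignment(rng, n_seq=6)
            ids = a.specimens
            s = group_distance([a], set(ids[:3]), set(ids[3:]))
            for d in s.per_locus:
                assert d.total_synapomorphies <= d.min <= d.mean <= d.max


class TestOracleEquivalence:
    """Exhaustive per-column re-implementations agree on random inputs."""

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(1234)
        for _ in range(120):
            a = random_alignment(rng)
            seqs = [a[s] for s in a.specimens]
            expected = oracle_column_classes(seqs)
            got = classify_sites(a)
            assert [
                (s.site_class == "variable", s.informative, s.coverage)
                for s in got
            ] == expected
            ids = a.specimens
            x, y = ids[int(rng.integers(len(ids)))], ids[int(rng.integers(len(ids)))]
            assert pairwise_snp_distance(a, x, y) == oracle_pairwise(a[x], a[y])
            if len(ids) >= 4:
                k = len(ids) // 2
                G, H = set(ids[:k]), set(ids[k:])
                rep = count_synapomorphies(a, G, H)
                assert rep.columns == oracle_synapomorphic_columns(
                    [a[s] for s in sorted(G)], [a[s] for s in sorted(H)]
                )
                stats = oracle_group_stats(
                    [a[s] for s in sorted(G)], [a[s] for s in sorted(H)]
                )
                s = group_distance([a], G, H)
                if stats is None:
                    assert not s.per_locus
                else:
                    d = s.per_locus[0]
                    assert (d.min, d.max) == stats[:2]
                    assert d.mean == pytest.approx(stats[2])

    def test_invariant_under_reordering(self):
        rng = np.random.default_rng(99)
        a = random_alignment(rng, n_seq=6, n_col=40)
        ids = a.specimens
        shuffled = a.subset(list(reversed(ids)))
        G, H = set(ids[:3]), set(ids[3:])
        assert (
            count_synapomorphies(a, G, H).columns
            == count_synapomorphies(shuffled, G, H).columns
        )
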