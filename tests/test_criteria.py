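"""The five delimitation criteria and the merge-recommending model."""

import pytest

from gcpsr.datamodel import ConfigError, PartitionScheme, SpeciesHypothesis
from gcpsr.delimit import (
    GCPSRDelimitation,
    criterion_distinctness,
    criterion_genealogical,
    criterion_minimal_sampling,
    criterion_monophyly,
    criterion_polygenic_differentiation,
    delimit,
)

from conftest import aln, tree

G = {"a", "b"}
H = {"c", "d"}


def hv_locus(name, synapomorphy=True):
    """One highly variable locus; optionally with a single shared SNP
    separating {a,b} from {c,d}."""
    top = "AAGA" if synapomorphy else "AAAA"
    return aln(name, a="AAAA", b="AAAA", c=top, d=top)


class TestMonophylyCriterion:
    def test_reciprocal_pass(self):
        gt = tree("((a,b)0.99,(c,d)0.99);", "ITS")
        res = criterion_monophyly([gt], gt.clone(), G, sister=H)
        assert res.verdict == "pass"

    def test_no_resolved_gene_tree_fails(self):
        concat = tree("((a,b)0.99,(c,d)0.99);", "concat")
        gt = tree("((a,c)0.99,(b,d)0.99);", "ITS")
        assert criterion_monophyly([gt], concat, G, sister=H).verdict == "fail"

    def test_unsupported_sister_breaks_reciprocity(self):
        gt = tree("((a,b)0.99,(c,d)0.50,e);", "ITS")
        assert criterion_monophyly([gt], gt.clone(), G, sister=H).verdict == "fail"
        res = criterion_monophyly([gt], gt.clone(), G, sister=H, reciprocal=False)
        assert res.verdict == "pass"

    def test_single_specimen_not_assessable(self):
        gt = tree("((a,b)0.99,(c,d)0.99);", "ITS")
        res = criterion_monophyly([gt], gt.clone(), {"a"}, sister=H)
        assert res.verdict == "not_assessable"

    def test_singleton_sister_degrades_with_warning(self):
        gt = tree("((a,b)0.99,(c,d)0.99);", "ITS")
        res = criterion_monophyly([gt], gt.clone(), G, sister={"c"})
        assert res.verdict == "pass" and "warning" in res.evidence


class TestGenealogicalCriterion:
    def test_concordant_trees_pass(self):
        trees = [
            tree("((a,b)0.99,(c,d)0.99);", "ITS"),
            tree("((a,b),(c,d));", "LSU"),
        ]
        assert criterion_genealogical(trees, G).verdict == "pass"

    def test_one_supported_contradiction_fails(self):
        trees = [
            tree("((a,b)0.99,(c,d)0.99);", "ITS"),
            tree("((a,c)0.99,(b,d)0.99);", "RPB1"),
        ]
        res = criterion_genealogical(trees, G)
        assert res.verdict == "fail"
        assert res.evidence["per_locus"]["RPB1"]["contradicted"]
        assert not res.evidence["per_locus"]["ITS"]["contradicted"]

    def test_unsupported_discordance_tolerated(self):
        trees = [tree("((a,c)0.50,(b,d)0.50);", "ITS")]
        assert criterion_genealogical(trees, G).verdict == "pass"

    def test_no_informative_tree_not_assessable(self):
        trees = [tree("((x,y)0.9,(a,z)0.9);", "ITS")]
        assert criterion_genealogical(trees, G).verdict == "not_assessable"


class TestDistinctnessCriterion:
    def loci(self, near_min):
        """Five loci, all with min cross-distance 3 except the first, whose
        min is ``near_min``."""
        out = []
        for i, name in enumerate(["ITS", "LSU", "RPB1", "RPB2", "EF1a"]):
            k = near_min if i == 0 else 3
            other = "T" * k + "A" * (10 - k)
            out.append(aln(name, a="A" * 10, b="A" * 10, c=other, d=other))
        return out

    def test_boundary_minimum_passes(self):
        res = criterion_distinctness(self.loci(3), G, H)
        assert res.verdict == "pass" and res.evidence["total_min"] == 15

    def test_one_shallow_locus_fails(self):
        res = criterion_distinctness(self.loci(2), G, H)
        assert res.verdict == "fail"
        assert res.evidence["per_locus"]["ITS"]["min"] == 2

    def test_no_comparator_not_assessable(self):
        assert criterion_distinctness(self.loci(3), G, None).verdict == "not_assessable"

    def test_duplicate_specimen_leaves_summary_unchanged(self):
        base = self.loci(3)
        widened = [
            aln(a.locus_name, **{**{s: a[s] for s in a.specimens}, "a2": a["a"]})
            for a in base
        ]
        r1 = criterion_distinctness(base, G, H)
        r2 = criterion_distinctness(widened, G | {"a2"}, H)
        assert r1.verdict == r2.verdict == "pass"
        assert r1.evidence["total_min"] == r2.evidence["total_min"]


class TestMinimalSampling:
    def test_threshold(self):
        assert criterion_minimal_sampling({"a", "b", "c"}).verdict == "pass"
        assert criterion_minimal_sampling({"a", "b"}).verdict == "fail"
        assert criterion_minimal_sampling({"a", "b"}, n_min=2).verdict == "pass"

    def test_adding_specimens_never_hurts(self):
        grp = {"a", "b", "c"}
        assert criterion_minimal_sampling(grp | {"d"}).verdict == "pass"


class TestPolygenicDifferentiation:
    def test_majority_of_highly_variable_loci(self):
        part = PartitionScheme()
        three = [hv_locus(n, n != "ITS") for n in ["ITS", "EF1a", "RPB1", "RPB2"]]
        res = criterion_polygenic_differentiation(three, part, G, H)
        assert res.verdict == "pass" and res.evidence["loci_with_synapomorphy"] == 3

    def test_half_is_not_a_majority(self):
        part = PartitionScheme()
        two = [
            hv_locus(n, n in {"RPB1", "RPB2"})
            for n in ["ITS", "EF1a", "RPB1", "RPB2"]
        ]
        assert criterion_polygenic_differentiation(two, part, G, H).verdict == "fail"

    def test_non_hv_locus_ignored(self):
        part = PartitionScheme()
        alns = [hv_locus(n) for n in ["ITS", "EF1a", "RPB1", "RPB2"]]
        alns.append(hv_locus("LSU", False))
        res = criterion_polygenic_differentiation(alns, part, G, H)
        assert res.verdict == "pass"
        assert "LSU" not in res.evidence["synapomorphies"]

    def test_no_comparator_not_assessable(self):
        part = PartitionScheme()
        res = criterion_polygenic_differentiation([hv_locus("ITS")], part, G, None)
        assert res.verdict == "not_assessable"


class TestModelOnSimulatedData:
    def test_deeply_diverged_species_both_pass(self, clean_two_species):
        results = GCPSRDelimitation.from_dataset(clean_two_species).fit()
        assert results.labels == ["A", "B"]
        assert results.overall("A") == "pass" and results.overall("B") == "pass"
        assert results.merge_recommendations == []
        assert results.n_merge_rounds == 0

    def test_oversplit_single_species_collapses(self, four_label_one_species):
        results = GCPSRDelimitation.from_dataset(four_label_one_species).fit()
        assert results.labels == ["L1"]
        assert results.overall("L1") == "pass"
        assert results.merge_recommendations == [["L1", "L2", "L3", "L4"]]
        assert 1 <= results.n_merge_rounds <= 3  # at most labels - 1

    def test_single_specimen_fails_only_sampling(self, single_specimen):
        results = GCPSRDelimitation.from_dataset(single_specimen).fit()
        b = results.report.candidate("B")
        assert b.overall == "fail"
        assert b.failed_criteria == ["minimal_sampling"]
        # an undersampled but otherwise distinct lineage is never merged away
        assert results.merge_recommendations == []

    def test_label_renaming_equivariance(self, four_label_one_species):
        ds = four_label_one_species
        mapping = {"L1": "Q4", "L2": "Q3", "L3": "Q2", "L4": "Q1"}
        renamed = SpeciesHypothesis(
            {s: mapping[l] for s, l in ds.hypothesis.assignment.items()}
        )
        base = GCPSRDelimitation.from_dataset(ds).fit()
        other = GCPSRDelimitation(
            ds.alignments, ds.gene_trees, ds.concat_tree, renamed
        ).fit()
        assert [sorted(mapping[l] for l in grp) for grp in base.merge_recommendations] \
            == other.merge_recommendations
        assert other.n_merge_rounds == base.n_merge_rounds

    def test_functional_wrapper_matches_model(self, clean_two_species):
        ds = clean_two_species
        rep = delimit(ds.hypothesis, ds.alignments, ds.gene_trees, ds.concat_tree)
        assert rep == GCPSRDelimitation.from_dataset(ds).fit().report

    def test_summary_mentions_parameters(self, clean_two_species):
        text = GCPSRDelimitation.from_dataset(clean_two_species).fit().summary()
        assert "support_threshold = 0.95" in text
        assert "min_snp_per_locus = 3" in text


class TestValidation:
    def test_bad_support_threshold(self, clean_two_species):
        ds = clean_two_species
        with pytest.raises(ConfigError):
            GCPSRDelimitation.from_dataset(ds, support_threshold=1.5)

    def test_empty_hypothesis(self, clean_two_species):
        ds = clean_two_species
        empty = SpeciesHypothesis({s: None for s in ds.hypothesis.assignment})
        with pytest.raises(ConfigError):
            GCPSRDelimitation(ds.alignments, ds.gene_trees, ds.concat_tree, empty)
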