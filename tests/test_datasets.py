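import math

import pytest

from urimod.datasets import (
    balanced_subsample,
    composition_stats,
    exclude_organisms,
    normalize_organism,
    pairwise_identity,
    read_cluster_file,
    reduce_redundancy,
    split_by_taxon,
)
from urimod.records import AnnotatedTRNA


def rec(id, seq, organism="org", kingdom=None, compartment=None):
    return AnnotatedTRNA(
        id=id, organism=organism, kingdom=kingdom, compartment=compartment,
        sequence=seq,
    )


class TestCompositionStats:
    def test_toy_counts_forced_by_resolution(self, table):
        # U and Y both resolve to uridine, so U composition is 2/4
        report = composition_stats([rec("a", "AU"), rec("b", "YG")], table)
        assert report.n_bases == 4
        assert report.n_modified == 1
        assert report.per_base_composition["U"] == pytest.approx(0.5)
        assert report.per_parent_modified_share["U"] == pytest.approx(1.0)
        assert report.per_parent_modified_rate["U"] == pytest.approx(0.5)
        assert report.per_modification_counts == {"Y": 1}

    def test_fractions_sum_to_one(self, table, strong_corpus):
        report = composition_stats(strong_corpus, table)
        assert math.isclose(sum(report.per_base_composition.values()), 1.0,
                            abs_tol=1e-9)
        assert math.isclose(sum(report.per_parent_modified_share.values()), 1.0,
                            abs_tol=1e-9)
        assert report.n_modified <= report.n_bases

    def test_pooled_equals_per_record_accumulation(self, table, strong_corpus):
        pooled = composition_stats(strong_corpus, table)
        n_bases = n_mod = 0
        for r in strong_corpus:
            single = composition_stats([r], table)
            n_bases += single.n_bases
            n_mod += single.n_modified
        assert pooled.n_bases == n_bases
        assert pooled.n_modified == n_mod

    def test_empty_record_list_errors(self, table):
        with pytest.raises(ValueError):
            composition_stats([], table)


class TestOrganismExclusion:
    def test_exclusion_plus_complement_partitions_input(self):
        records = [
            rec("a", "ACGU", organism="Escherichia coli"),
            rec("b", "ACGU", organism="Bacillus subtilis"),
            rec("c", "ACGU", organism="Homo sapiens"),
        ]
        kept = exclude_organisms(records, {"Escherichia coli"})
        assert [r.id for r in kept.records] == ["b", "c"]
        removed = [r for r in records if r not in kept.records]
        assert {r.id for r in removed} | {r.id for r in kept.records} == {"a", "b", "c"}

    def test_empty_exclusion_set_is_identity(self):
        records = [rec("a", "ACGU")]
        assert exclude_organisms(records, set()).records == records

    def test_total_exclusion_yields_empty_with_provenance(self):
        records = [rec("a", "ACGU", organism="Escherichia coli")]
        split = exclude_organisms(records, {"escherichia  COLI "})
        assert split.records == []
        assert "empty after filter" in split.provenance

    def test_renamed_organism_alias_is_applied(self):
        # the archaeon was renamed; both spellings must match
        assert normalize_organism("Halobacterium volcanii") == \
            normalize_organism("Haloferax volcanii")
        records = [rec("a", "ACGU", organism="Halobacterium volcanii")]
        assert exclude_organisms(records, {"Haloferax volcanii"}).records == []


class TestTaxonSplit:
    def test_group_sizes_sum_to_total(self, strong_corpus):
        splits = split_by_taxon(strong_corpus)
        disjoint = ["archaea", "bacteria", "eukaryote-all", "virus", "unassigned"]
        assert sum(len(splits[g]) for g in disjoint) == len(strong_corpus)
        assert len(splits["all"]) == len(strong_corpus)

    def test_eukaryote_all_unions_compartments(self):
        records = [
            rec("a", "ACGU", kingdom="eukaryote", compartment="cytosol"),
            rec("b", "ACGU", kingdom="eukaryote", compartment="mitochondrion"),
            rec("c", "ACGU", kingdom="eukaryote", compartment="plastid"),
        ]
        splits = split_by_taxon(records)
        assert len(splits["eukaryote-all"]) == 3
        assert len(splits["eukaryote-cyto"]) == 1
        assert len(splits["eukaryote-mito"]) == 1
        assert len(splits["eukaryote-plastid"]) == 1

    def test_single_archaeal_record(self):
        splits = split_by_taxon([rec("a", "ACGU", kingdom="archaea")])
        assert len(splits["archaea"]) == 1
        assert len(splits["all"]) == 1
        for g in ("bacteria", "eukaryote-all", "virus", "unassigned"):
            assert len(splits[g]) == 0

    def test_unset_kingdom_goes_to_unassigned(self):
        splits = split_by_taxon([rec("a", "ACGU")])
        assert len(splits["unassigned"]) == 1
        assert len(splits["all"]) == 1


class TestRedundancyReduction:
    def test_identical_pair_collapses_to_one(self, table):
        records = [rec("a", "ACGUACGU"), rec("b", "ACGUACGU")]
        assert len(reduce_redundancy(records, table, 0.5)) == 1

    def test_dissimilar_sequences_all_retained(self, table):
        records = [rec("a", "AAAAAAAA"), rec("b", "CCCCCCCC"), rec("c", "GGGGGGGG")]
        assert len(reduce_redundancy(records, table, 0.5)) == 3

    def test_two_pairs_and_a_singleton_give_three_clusters(self, table):
        # brute-force identity matrix: 1≡2 and 3≡4 above 50%, 5 matches nothing
        records = [
            rec("s1", "ACGUACGUAC"),
            rec("s2", "ACGUACGUAC"),
            rec("s3", "GGGGCCCCGG"),
            rec("s4", "GGGGCCCCGG"),
            rec("s5", "UUUUUUUUUU"),
        ]
        seqs = {r.id: r.sequence for r in records}
        within = [("s1", "s2"), ("s3", "s4")]
        for a, b in within:
            assert pairwise_identity(seqs[a], seqs[b]) >= 0.5
        across = [("s1", "s3"), ("s1", "s5"), ("s3", "s5")]
        for a, b in across:
            assert pairwise_identity(seqs[a], seqs[b]) < 0.5
        kept = reduce_redundancy(records, table, 0.5)
        assert len(kept) == 3

    def test_output_has_no_pair_above_threshold(self, table, strong_corpus):
        subset = strong_corpus[:12]
        kept = reduce_redundancy(subset, table, 0.95).records
        from urimod.records import demodified_sequence
        demod = [demodified_sequence(r, table) for r in kept]
        for i in range(len(demod)):
            for j in range(i + 1, len(demod)):
                assert pairwise_identity(demod[i], demod[j]) < 0.95

    def test_precomputed_clusters_applied_verbatim(self, table, tmp_path):
        records = [rec("a", "AAAA"), rec("b", "CCCC"), rec("c", "GGGG")]
        cluster_file = tmp_path / "clusters.tsv"
        cluster_file.write_text("c1\ta\nc1\tb\nc2\tc\n")
        membership = read_cluster_file(cluster_file)
        kept = reduce_redundancy(records, table, 0.5, precomputed_clusters=membership)
        assert {r.id for r in kept.records} == {"a", "c"}

    def test_malformed_cluster_file_errors(self, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text("only_one_column\n")
        with pytest.raises(ValueError, match="columns"):
            read_cluster_file(bad)


class TestBalancedSubsample:
    def test_requested_counts_by_modification_type(self, um_windows):
        sample = balanced_subsample(
            um_windows, {"Y": 20, "D": 20, "T": 20}, seed=0
        )
        codes = [w.center_code for w in sample]
        assert codes.count("Y") == 20
        assert codes.count("D") == 20
        assert codes.count("T") == 20

    def test_same_seed_reproduces_selection(self, um_windows):
        a = balanced_subsample(um_windows, {"Y": 10, "D": 10}, seed=7)
        b = balanced_subsample(um_windows, {"Y": 10, "D": 10}, seed=7)
        assert a == b

    def test_insufficient_class_errors_naming_the_class(self, um_windows):
        with pytest.raises(ValueError, match="'Y'"):
            balanced_subsample(um_windows, {"Y": 10 ** 6}, seed=0)
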