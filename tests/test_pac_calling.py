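import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from patapa.io_formats import GenomeSeq, read_annotation
from patapa.pac_calling import (
    CallingParams,
    PolyATag,
    apa_gene_table,
    assign_pacs,
    cluster_tags,
    filter_internal_priming,
    filter_min_support,
    is_internal_priming,
)


def brute_force_ip(window: str, ip_max_a: int = 7, ip_run_a: int = 6) -> bool:
    """Literal re-statement of the rule, character by character."""
    n_a = sum(1 for c in window if c == "A")
    leading = 0
    for c in window:
        if c != "A":
            break
        leading += 1
    return n_a >= ip_max_a or leading >= ip_run_a


def tags_at(positions, strand="+", chrom="chr1", sample="s1"):
    return [PolyATag(chrom, strand, int(p), sample) for p in positions]


class TestInternalPrimingRule:
    @pytest.mark.parametrize(
        "window,expected",
        [
            ("AAAAAAAAAA", True),  # maximal A richness
            ("CGTACGTACG", False),  # zero A
            ("AAAAAACGTC", True),  # 6-A leading run, only 6 A total
            ("AACAAACAGG", False),  # 6 A total, longest run 3
            ("CAAAAAAGTC", False),  # 6-A run but not leading
        ],
    )
    def test_rule_examples(self, window, expected):
        assert is_internal_priming(window) is expected
        assert brute_force_ip(window) is expected

    def test_downstream_window_orientation_per_strand(self):
        # plus tag at 9: window is [10, 20); minus tag at 30: window is
        # the reverse complement of [20, 30)
        seq = "C" * 10 + "A" * 10 + "T" * 10 + "G" * 10
        genome = GenomeSeq({"chr1": seq})
        kept, removed = filter_internal_priming(tags_at([9]), genome)
        assert len(removed) == 1
        kept, removed = filter_internal_priming(tags_at([30], strand="-"), genome)
        assert len(removed) == 1  # T on + strand reads A in - sense
        kept, removed = filter_internal_priming(tags_at([30]), genome)
        assert len(kept) == 1

    def test_truncated_window_uses_available_bases_only(self):
        genome = GenomeSeq({"chr1": "C" * 95 + "AAAAA"})
        # window [96, 100) holds 4 A: below both thresholds
        kept, removed = filter_internal_priming(tags_at([95]), genome)
        assert len(kept) == 1

    def test_partition_is_disjoint_and_complete(self, flat_genome, rng):
        tags = tags_at(rng.integers(0, 1900, size=300))
        kept, removed = filter_internal_priming(tags, flat_genome)
        assert len(kept) + len(removed) == len(tags)

    def test_missing_chromosome_named_in_error(self, flat_genome):
        with pytest.raises(KeyError, match="chrUn"):
            filter_internal_priming(tags_at([5], chrom="chrUn"), flat_genome)


def cluster_oracle(positions, window):
    """O(n^2) transitive closure of the |a - b| <= window linkage."""
    positions = list(positions)
    n = len(positions)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(positions[i] - positions[j]) <= window:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(positions[i])
    return sorted(frozenset(g) for g in groups.values())


class TestClustering:
    def test_gap_rule_splits_at_window(self):
        pacs = cluster_tags(tags_at([100, 110, 150]))
        assert [(p.start, p.end) for p in pacs] == [(100, 111), (150, 151)]

    def test_chained_single_linkage_spans_many_windows(self):
        pacs = cluster_tags(tags_at([0, 24, 48, 72]))
        assert len(pacs) == 1
        assert (pacs[0].start, pacs[0].end) == (0, 73)

    def test_matches_transitive_closure_oracle_on_random_input(self, rng):
        positions = rng.integers(0, 5000, size=500)
        pacs = cluster_tags(tags_at(positions))
        called = {
            frozenset(p for p in set(positions.tolist()) if pac.start <= p < pac.end)
            for pac in pacs
        }
        assert called == set(cluster_oracle(set(positions.tolist()), 24))

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.integers(0, 2000), min_size=1, max_size=80))
    def test_partition_identical_under_permutation(self, positions):
        a = cluster_tags(tags_at(positions))
        b = cluster_tags(tags_at(reversed(positions)))
        assert [(p.start, p.end, p.summit) for p in a] == [
            (p.start, p.end, p.summit) for p in b
        ]

    def test_summit_is_mode_with_distal_tiebreak(self):
        # 100 x2, 110 x2 tie: distal is 110 on +, 100 on -
        plus = cluster_tags(tags_at([100, 100, 110, 110]))
        minus = cluster_tags(tags_at([100, 100, 110, 110], strand="-"))
        assert plus[0].summit == 110
        assert minus[0].summit == 100

    def test_counts_tallied_per_sample(self):
        tags = tags_at([5, 6], sample="a") + tags_at([7], sample="b")
        (pac,) = cluster_tags(tags)
        assert pac.counts == {"a": 2, "b": 1}

    def test_strict_mode_rejects_unfiltered_tags(self, flat_genome):
        tags = tags_at([100, 105])
        with pytest.raises(ValueError, match="strict"):
            cluster_tags(tags, require_filtered=True)
        kept, _ = filter_internal_priming(tags, flat_genome)
        assert len(cluster_tags(kept, require_filtered=True)) == 1

    def test_empty_input(self):
        assert cluster_tags([]) == []


def _pacs_at(summits, strand="+", chrom="chr1", n=12):
    pacs = cluster_tags(
        [PolyATag(chrom, strand, s, f"s{i}") for s in summits for i in range(n)]
    )
    return pacs


class TestAssignment:
    def test_region_labels_per_summit(self, gff_file):
        genes = read_annotation(gff_file)
        pacs = _pacs_at([900])  # inside geneA annotated 3' UTR
        pacs += _pacs_at([1150])  # 150 nt past the annotated UTR end
        pacs += _pacs_at([250])  # geneA CDS
        pacs += _pacs_at([450])  # geneA intron
        pacs += _pacs_at([50])  # geneA 5' UTR
        pacs += _pacs_at([1600])  # between extensions
        assign_pacs(pacs, genes)
        by_summit = {p.summit: (p.gene_id, p.region) for p in pacs}
        assert by_summit[900] == ("geneA", "UTR3")
        assert by_summit[1150] == ("geneA", "EXTENDED_UTR3")
        assert by_summit[250] == ("geneA", "CDS")
        assert by_summit[450] == ("geneA", "INTRON")
        assert by_summit[50] == ("geneA", "UTR5")
        assert by_summit[1600] == (None, "INTERGENIC")

    def test_overlapping_region_hits_are_ambiguous(self, gff_file, tmp_path):
        # same-strand gene whose CDS overlaps geneA's 3' UTR
        extra = (
            "chr1\ttest\tgene\t851\t1950\t.\t+\t.\tID=geneX\n"
            "chr1\ttest\tmRNA\t851\t1950\t.\t+\t.\tID=geneX.1;Parent=geneX\n"
            "chr1\ttest\texon\t851\t1950\t.\t+\t.\tParent=geneX.1\n"
            "chr1\ttest\tCDS\t851\t1950\t.\t+\t.\tParent=geneX.1\n"
        )
        p = tmp_path / "overlap.gff3"
        p.write_text(open(gff_file).read() + extra)
        genes = read_annotation(str(p))
        pacs = assign_pacs(_pacs_at([900]), genes)
        assert pacs[0].region == "AMB"
        assert pacs[0].gene_id == "geneA"  # 3' UTR hit takes priority

    def test_every_pac_gets_exactly_one_region(self, gff_file, rng):
        genes = read_annotation(gff_file)
        pacs = assign_pacs(_pacs_at(sorted(rng.integers(0, 4000, size=40))), genes)
        from patapa.io_formats import REGIONS

        assert all(p.region in REGIONS for p in pacs)

    def test_zero_extension_turns_recovered_pacs_intergenic(self, gff_file):
        with_ext = read_annotation(gff_file, ext_bp=200, fallback_bp=218)
        no_ext = read_annotation(gff_file, ext_bp=0, fallback_bp=0)
        pacs = assign_pacs(_pacs_at([1150]), with_ext)
        assert pacs[0].region == "EXTENDED_UTR3"
        pacs = assign_pacs(_pacs_at([1150]), no_ext)
        assert pacs[0].region == "INTERGENIC"


class TestSupportFilterAndAPATable:
    def test_boundary_at_min_pats(self):
        ten = _pacs_at([100], n=10)
        nine = _pacs_at([500], n=9)
        kept = filter_min_support(ten + nine)
        assert [p.summit for p in kept] == [100]

    def test_random_set_matches_filter_oracle(self, rng):
        sizes = rng.integers(5, 15, size=30)
        pacs = []
        for i, n in enumerate(sizes):
            pacs += _pacs_at([1000 * i], n=int(n))
        kept = filter_min_support(pacs)
        assert len(kept) == int((sizes >= 10).sum())

    def test_apa_definition_counts_pacs_per_gene(self, gff_file):
        genes = read_annotation(gff_file)
        pacs = assign_pacs(_pacs_at([250]) + _pacs_at([900]) + _pacs_at([2500]), genes)
        tab = apa_gene_table(pacs).set_index("gene_id")
        assert tab.loc["geneA", "n_pacs"] == 2 and bool(tab.loc["geneA", "is_apa"])
        assert tab.loc["geneB", "n_pacs"] == 1 and not bool(tab.loc["geneB", "is_apa"])

    def test_intergenic_pacs_never_count(self, gff_file):
        genes = read_annotation(gff_file)
        pacs = assign_pacs(_pacs_at([1600]), genes)
        assert len(apa_gene_table(pacs)) == 0


def test_calling_params_validate_positive():
    with pytest.raises(ValueError):
        CallingParams(cluster_window=0)
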