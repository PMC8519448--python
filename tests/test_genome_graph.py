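import numpy as np
import pytest

from hapmotif import genome_graph as gg
from hapmotif.fixtures import _haplotype_string, _Variant
from hapmotif.genome_graph import (
    GFAFormatError,
    PhasingError,
    RefMismatchError,
    UnsortedVariantsError,
    VariantRecord,
    WalkError,
    build_graph,
    path_sequence,
    read_gfa,
    region_window,
    write_gfa,
)


def _hap_seqs(graph):
    return {
        hp.path_name: path_sequence(graph, hp.node_ids)
        for hp in graph.haplotype_paths
    }


class TestBuildGraph:
    def test_no_variants_single_node(self):
        g = build_graph("ACGTACGT", [], chrom="chr1")
        assert path_sequence(g, g.ref_path) == "ACGTACGT"
        assert len(g.nodes) == 1
        assert not g.edges

    def test_snp_bubble(self, snp_graph):
        g = snp_graph
        assert path_sequence(g, g.ref_path) == "ACGTACGT"
        seqs = set(g.nodes.values())
        assert {"T", "G"} <= seqs  # both branch nodes of the bubble
        haps = _hap_seqs(g)
        assert haps["S1#0"] == "ACGTACGT"
        assert haps["S1#1"] == "ACGGACGT"

    def test_deletion_edge_skips_reference(self):
        vr = VariantRecord("chr1", 2, "CG", ("C",), {"S1": (1, 1, True)})
        g = build_graph("ACGTACGT", [vr], chrom="chr1")
        assert path_sequence(g, g.ref_path) == "ACGTACGT"
        haps = _hap_seqs(g)
        # reference with "G" removed
        assert haps["S1#0"] == "ACTACGT"
        assert haps["S1#1"] == "ACTACGT"

    def test_insertion_extra_node(self):
        vr = VariantRecord("chr1", 4, "T", ("TA",), {"S1": (0, 1, True)})
        g = build_graph("ACGTACGT", [vr], chrom="chr1")
        haps = _hap_seqs(g)
        assert haps["S1#0"] == "ACGTACGT"
        assert haps["S1#1"] == "ACGTAACGT"
        assert path_sequence(g, g.ref_path) == "ACGTACGT"

    def test_multiallelic_split_into_branches(self):
        vr = VariantRecord(
            "chr1", 4, "T", ("G", "C"), {"S1": (1, 2, True), "S2": (0, 0, True)}
        )
        g = build_graph("ACGTACGT", [vr], chrom="chr1")
        haps = _hap_seqs(g)
        assert haps["S1#0"] == "ACGGACGT"
        assert haps["S1#1"] == "ACGCACGT"
        assert haps["S2#0"] == "ACGTACGT"

    def test_ref_mismatch_error(self):
        vr = VariantRecord("chr1", 4, "A", ("G",), {"S1": (0, 1, True)})
        with pytest.raises(RefMismatchError):
            build_graph("ACGTACGT", [vr], chrom="chr1")

    def test_unsorted_error(self):
        v1 = VariantRecord("chr1", 6, "C", ("G",), {"S1": (0, 1, True)})
        v2 = VariantRecord("chr1", 2, "C", ("A",), {"S1": (0, 1, True)})
        with pytest.raises(UnsortedVariantsError):
            build_graph("ACGTACGT", [v1, v2], chrom="chr1")

    def test_unphased_het_error(self):
        vr = VariantRecord("chr1", 4, "T", ("G",), {"S1": (0, 1, False)})
        with pytest.raises(PhasingError):
            build_graph("ACGTACGT", [vr], chrom="chr1")

    def test_missing_genotype_defaults_to_reference_with_warning(self):
        vr = VariantRecord(
            "chr1", 4, "T", ("G",), {"S1": (None, None, False), "S2": (1, 1, True)}
        )
        with pytest.warns(UserWarning, match="missing genotype"):
            g = build_graph("ACGTACGT", [vr], chrom="chr1")
        haps = _hap_seqs(g)
        assert haps["S1#0"] == "ACGTACGT"
        assert haps["S2#0"] == "ACGGACGT"

    def test_overlapping_variant_skipped_with_warning(self):
        v1 = VariantRecord("chr1", 2, "CGT", ("C",), {"S1": (0, 1, True)})
        v2 = VariantRecord("chr1", 4, "T", ("G",), {"S1": (0, 1, True)})
        with pytest.warns(UserWarning, match="overlaps"):
            g = build_graph("ACGTACGT", [v1, v2], chrom="chr1")
        haps = _hap_seqs(g)
        assert haps["S1#1"] == "ACACGT"  # only the deletion applied

    def test_string_edit_oracle_random_fixture(self):
        # haplotype spellings must match direct string edits for SNPs+indels
        rng = np.random.default_rng(5)
        ref = "".join(rng.choice(list("ACGT"), size=300))
        raw = [
            _Variant(20, ref[19], (("A" if ref[19] != "A" else "C"),), ((0, 1),)),
            _Variant(60, ref[59 : 59 + 3], (ref[59],), ((1, 1),)),  # deletion
            _Variant(120, ref[119], (ref[119] + "GG",), ((1, 0),)),  # insertion
            _Variant(200, ref[199], (("T" if ref[199] != "T" else "G"),), ((0, 1),)),
        ]
        records = [
            VariantRecord("chr1", v.pos, v.ref, v.alts, {"S1": v.genotypes[0] + (True,)})
            for v in raw
        ]
        g = build_graph(ref, records, chrom="chr1")
        haps = _hap_seqs(g)
        for phase in (0, 1):
            alleles = [v.genotypes[0][phase] for v in raw]
            expected, _ = _haplotype_string(ref, raw, alleles)
            assert haps[f"S1#{phase}"] == expected

    def test_node_count_scales_with_variants(self):
        rng = np.random.default_rng(6)
        ref = "".join(rng.choice(list("ACGT"), size=500))
        records = [
            VariantRecord(
                "chr1", p, ref[p - 1],
                (("A" if ref[p - 1] != "A" else "C"),),
                {"S1": (0, 1, True)},
            )
            for p in range(10, 500, 50)
        ]
        g = build_graph(ref, records, chrom="chr1")
        assert len(g.nodes) <= 3 * len(records) + 1


class TestPathSequence:
    def test_single_node(self, snp_graph):
        nid = snp_graph.ref_path[0]
        assert path_sequence(snp_graph, [nid]) == snp_graph.nodes[nid]

    def test_walk_error_on_missing_edge(self, snp_graph):
        g = snp_graph
        bad = [g.ref_path[-1], g.ref_path[0]]
        with pytest.raises(WalkError):
            path_sequence(g, bad)


class TestGFA:
    def test_roundtrip_snp_bubble(self, snp_graph):
        g2 = read_gfa(write_gfa(snp_graph))
        assert g2.nodes == snp_graph.nodes
        assert g2.edges == snp_graph.edges
        assert g2.ref_path == snp_graph.ref_path
        assert g2.chrom == snp_graph.chrom
        assert g2.node_span == snp_graph.node_span
        assert [
            (h.sample_id, h.phase, h.node_ids) for h in g2.haplotype_paths
        ] == [
            (h.sample_id, h.phase, h.node_ids) for h in snp_graph.haplotype_paths
        ]

    def test_empty_graph_roundtrip(self):
        g = gg.VariationGraph(chrom="chrE")
        g2 = read_gfa(write_gfa(g))
        assert not g2.nodes and not g2.edges

    def test_handwritten_three_segment_gfa(self):
        text = (
            "H\tVN:Z:1.0\n"
            "S\t1\tACG\n"
            "S\t2\tT\n"
            "S\t3\tACGT\n"
            "L\t1\t+\t2\t+\t0M\n"
            "L\t2\t+\t3\t+\t0M\n"
            "P\tchr9\t1+,2+,3+\t*\n"
        )
        g = read_gfa(text)
        assert len(g.nodes) == 3
        assert g.ref_path == [1, 2, 3]
        assert g.chrom == "chr9"
        assert path_sequence(g, g.ref_path) == "ACGTACGT"
        # spans recomputed from the reference path when tags are absent
        assert g.node_span[2] == (3, 4, True)

    def test_malformed_line_error(self):
        with pytest.raises(GFAFormatError):
            read_gfa("S\t1\n")
        with pytest.raises(GFAFormatError):
            read_gfa("H\tVN:Z:1.0\nX\t1\t2\n")

    def test_pline_unknown_segment_error(self):
        text = "S\t1\tACG\nP\tchr1\t1+,2+\t*\n"
        with pytest.raises(GFAFormatError, match="unknown segment"):
            read_gfa(text)


class TestRegionWindow:
    def test_whole_chromosome_returns_whole_graph(self, snp_graph):
        view = region_window(snp_graph, "chr1", 0, 8)
        assert set(view.nodes) == set(snp_graph.nodes)
        assert view.edges == snp_graph.edges

    def test_region_inside_anchor_single_node(self, snp_graph):
        # bases 5..7 lie strictly inside the right anchor "ACGT"
        view = region_window(snp_graph, "chr1", 5, 7)
        assert len(view.nodes) == 1
        assert list(view.nodes.values()) == ["ACGT"]

    def test_region_over_bubble_includes_both_branches(self, snp_graph):
        view = region_window(snp_graph, "chr1", 3, 4)
        assert {"T", "G"} <= set(view.nodes.values())

    def test_clip_beyond_end_with_warning(self, snp_graph):
        with pytest.warns(UserWarning, match="clipped"):
            view = region_window(snp_graph, "chr1", 4, 100)
        assert view.end == 8

    def test_inverted_region_error(self, snp_graph):
        with pytest.raises(ValueError):
            region_window(snp_graph, "chr1", 5, 5)

    def test_wrong_chromosome_error(self, snp_graph):
        with pytest.raises(ValueError):
            region_window(snp_graph, "chr2", 0, 4)


class TestFileIngest:
    def test_fasta_vcf_roundtrip(self, tmp_path):
        fa = tmp_path / "r.fa"
        fa.write_text(">chr1\nACGTACGT\n>chr2\nGGGGCCCC\n")
        vcf = tmp_path / "v.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr1,length=8>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "chr1\t4\t.\tT\tG\t.\tPASS\t.\tGT\t0|1\n"
        )
        seqs = gg.read_fasta(str(fa))
        assert seqs["chr2"] == "GGGGCCCC"
        samples, by_chrom = gg.read_vcf(str(vcf))
        assert samples == ["S1"]
        rec = by_chrom["chr1"][0]
        assert (rec.pos, rec.ref_allele, rec.alt_alleles) == (4, "T", ("G",))
        assert rec.genotypes["S1"] == (0, 1, True)
        g = build_graph(seqs["chr1"], by_chrom["chr1"], chrom="chr1", samples=samples)
        assert _hap_seqs(g)["S1#1"] == "ACGGACGT"

    def test_symbolic_allele_rejected(self, tmp_path):
        vcf = tmp_path / "v.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr1,length=8>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "chr1\t4\t.\tT\t<DEL>\t.\tPASS\t.\tGT\t0|1\n"
        )
        with pytest.raises(ValueError, match="symbolic"):
            gg.read_vcf(str(vcf))
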