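"""Annotation parsing, anchor rules, window extraction and the intermediate file."""

import numpy as np
import pandas as pd
import pytest

from golem.annotation import (
    NO_FIVE_PRIME_UTR,
    NO_START_CODON,
    NO_TPM_DATA,
    AnchorUnavailableError,
    ContigNotFoundError,
    GeneRecord,
    SpeciesProfile,
    WindowOutOfContigError,
    WindowSpec,
    extract_window,
    parse_annotation,
    read_intermediate,
    write_intermediate,
)
from golem.expression import load_expression


class TestParseAnnotation:
    def test_three_gene_fixture_start_codon_rule(self, three_gene_gff, tiny_genome):
        profile = SpeciesProfile(atg_rule="start_codon_feature")
        records, log = parse_annotation(three_gene_gff, tiny_genome, profile)
        assert log.n_total == 3 and log.n_valid == 1
        assert [r.gene_id for r in records] == ["geneA"]
        rec = records[0]
        assert (rec.tss, rec.atg, rec.strand, rec.contig) == (101, 151, "+", "c1")
        # CDS-only gene and ncRNA gene both lack a start_codon feature
        assert sorted(log.excluded) == [("geneB", NO_START_CODON), ("geneC", NO_START_CODON)]
        # log conservation: every gene exactly once
        assert log.n_valid + len({g for g, _ in log.excluded}) == log.n_total

    def test_cds_minmax_minus_strand_atg(self, three_gene_gff, tiny_genome):
        profile = SpeciesProfile(tss_rule="none", atg_rule="cds_minmax")
        records, log = parse_annotation(three_gene_gff, tiny_genome, profile)
        by_id = {r.gene_id: r for r in records}
        assert by_id["geneB"].atg == 560  # max CDS coordinate on the minus strand
        assert by_id["geneA"].atg == 151  # min CDS coordinate on the plus strand
        assert [g for g, _ in log.excluded] == ["geneC"]

    def test_empty_gff(self, tiny_genome):
        records, log = parse_annotation("##gff-version 3\n", tiny_genome, SpeciesProfile())
        assert records == [] and log.n_total == 0

    def test_missing_utr_gene_retained_without_tss(self, three_gene_gff, tiny_genome):
        profile = SpeciesProfile(tss_rule="five_prime_utr", atg_rule="cds_minmax")
        records, log = parse_annotation(three_gene_gff, tiny_genome, profile)
        by_id = {r.gene_id: r for r in records}
        assert by_id["geneB"].tss is None
        assert log.tss_missing == ["geneB"]
        assert by_id["geneA"].tss == 101

    def test_unresolvable_contig_is_hard_error(self, three_gene_gff):
        with pytest.raises(ContigNotFoundError, match="c1"):
            parse_annotation(three_gene_gff, {"other": "ACGT" * 300}, SpeciesProfile())

    def test_malformed_lines_skipped_with_count(self, three_gene_gff, tiny_genome):
        gff = three_gene_gff + "not a gff line\nc1\tx\tgene\tBAD\t10\t.\t+\t.\tID=g\n"
        records, log = parse_annotation(gff, tiny_genome, SpeciesProfile())
        assert log.n_malformed_lines == 2
        assert log.n_total == 3  # the well-formed genes still parse

    def test_cds_dot1_rule_prefers_dot1_segment(self, tiny_genome):
        gff = "\n".join(
            [
                "##gff-version 3",
                "c1\tt\tgene\t101\t400\t.\t+\t.\tID=gX",
                "c1\tt\tmRNA\t101\t400\t.\t+\t.\tID=gX.t;Parent=gX",
                "c1\tt\tCDS\t101\t200\t.\t+\t0\tID=gX.t.cds.2;Parent=gX.t",
                "c1\tt\tCDS\t251\t400\t.\t+\t0\tID=gX.t.cds.1;Parent=gX.t",
            ]
        )
        profile = SpeciesProfile(tss_rule="none", atg_rule="cds_dot1")
        records, _ = parse_annotation(gff, tiny_genome, profile)
        assert records[0].atg == 251  # 5' end of the .1 segment, not the min CDS

    def test_cds_dot1_falls_back_to_minmax(self, tiny_genome):
        gff = "\n".join(
            [
                "##gff-version 3",
                "c1\tt\tgene\t101\t400\t.\t+\t.\tID=gX",
                "c1\tt\tmRNA\t101\t400\t.\t+\t.\tID=gX.t;Parent=gX",
                "c1\tt\tCDS\t101\t200\t.\t+\t0\tID=gX.t.cdsA;Parent=gX.t",
            ]
        )
        profile = SpeciesProfile(tss_rule="none", atg_rule="cds_dot1")
        records, log = parse_annotation(gff, tiny_genome, profile)
        assert records[0].atg == 101 and log.n_warnings >= 1

    def test_start_codon_spelled_with_space_accepted(self, tiny_genome):
        gff = "\n".join(
            [
                "##gff-version 3",
                "c1\tt\tgene\t101\t400\t.\t+\t.\tID=gY",
                "c1\tt\tmRNA\t101\t400\t.\t+\t.\tID=gY.t;Parent=gY",
                "c1\tt\tstart codon\t151\t153\t.\t+\t0\tID=gY.t.sc;Parent=gY.t",
            ]
        )
        profile = SpeciesProfile(tss_rule="none", atg_rule="start_codon_feature")
        records, _ = parse_annotation(gff, tiny_genome, profile)
        assert records[0].atg == 151


class TestExtractWindow:
    def test_plus_strand_coordinates(self, tiny_genome):
        rec = GeneRecord("g", "c1", "+", atg=101)
        win = extract_window(rec, tiny_genome, WindowSpec("ATG", -3, 3))
        assert win.seq == tiny_genome["c1"][97:103].upper()  # 1-based bases 98..103
        assert win.index_to_offset(3) == 0
        assert win.seq[3] == tiny_genome["c1"][100].upper()  # the anchor base

    def test_minus_strand_matches_brute_force(self, tiny_genome):
        """Oracle: reverse-complement the whole contig and rerun the '+' logic."""
        from Bio.Seq import Seq

        contig = tiny_genome["c1"]
        rec = GeneRecord("g", "c1", "-", atg=100)
        win = extract_window(rec, tiny_genome, WindowSpec("ATG", -3, 3))
        flipped = str(Seq(contig).reverse_complement())
        atg_flipped = len(contig) - 100 + 1
        rec2 = GeneRecord("g", "c1", "+", atg=atg_flipped)
        win2 = extract_window(rec2, {"c1": flipped}, WindowSpec("ATG", -3, 3))
        assert win.seq == win2.seq
        assert win.offset_to_index(0) == 3
        assert win.seq == str(Seq(contig[97:103]).reverse_complement()).upper()

    def test_left_truncation_at_contig_edge(self, tiny_genome):
        rec = GeneRecord("g", "c1", "+", atg=2)
        win = extract_window(rec, tiny_genome, WindowSpec("ATG", -1000, 10))
        assert win.truncated_left and not win.truncated_right
        assert win.lo == -1 and len(win.seq) == 11

    def test_anchor_unavailable(self, tiny_genome):
        rec = GeneRecord("g", "c1", "+", atg=100, tss=None)
        with pytest.raises(AnchorUnavailableError, match="anchor"):
            extract_window(rec, tiny_genome, WindowSpec("TSS", -10, 10))

    def test_window_entirely_off_contig(self, tiny_genome):
        rec = GeneRecord("g", "c1", "+", atg=5)
        with pytest.raises(WindowOutOfContigError):
            extract_window(rec, tiny_genome, WindowSpec("ATG", -2000, -1500))

    def test_offset_map_bijective(self, tiny_genome):
        rec = GeneRecord("g", "c1", "-", atg=400, tss=450)
        win = extract_window(rec, tiny_genome, WindowSpec("TSS", -57, 91))
        offsets = [win.index_to_offset(i) for i in range(len(win.seq))]
        assert offsets == list(range(-57, 91))
        assert [win.offset_to_index(o) for o in offsets] == list(range(len(win.seq)))
        with pytest.raises(IndexError):
            win.offset_to_index(91)


class TestIntermediateFile:
    @pytest.fixture()
    def matched_setup(self, three_gene_gff, tiny_genome):
        profile = SpeciesProfile(tss_rule="five_prime_utr", atg_rule="cds_minmax")
        records, log = parse_annotation(three_gene_gff, tiny_genome, profile)
        tpm = pd.DataFrame(
            {"stage1": [10.0, 3.5], "stage2": [0.0, 7.25]},
            index=pd.Index(["geneA", "geneB"], name="gene_id"),
        )
        return records, log, load_expression(tpm), tiny_genome

    def test_roundtrip_and_structure(self, matched_setup, tmp_path):
        records, log, matrix, genome = matched_setup
        path = tmp_path / "genes.fa"
        kept = write_intermediate(records, matrix, path, genome=genome,
                                  spec=WindowSpec("ATG", -50, 50), log=log)
        back = read_intermediate(path)
        assert len(back) == 2
        for orig, rt in zip(kept, back):
            assert (rt.gene_id, rt.contig, rt.strand, rt.tss, rt.atg) == (
                orig.gene_id, orig.contig, orig.strand, orig.tss, orig.atg)
            assert rt.tpm == orig.tpm
            assert len(rt.tpm) == 2  # one stage:TPM pair per stage

    def test_gene_without_tpm_row_logged(self, three_gene_gff, tiny_genome, tmp_path):
        profile = SpeciesProfile(tss_rule="five_prime_utr", atg_rule="cds_minmax")
        records, log = parse_annotation(three_gene_gff, tiny_genome, profile)
        tpm = pd.DataFrame({"s": [1.0]}, index=pd.Index(["geneA"], name="gene_id"))
        kept = write_intermediate(records, load_expression(tpm), tmp_path / "g.fa",
                                  genome=tiny_genome, spec=WindowSpec("ATG", -20, 20), log=log)
        assert [r.gene_id for r in kept] == ["geneA"]
        assert ("geneB", NO_TPM_DATA) in log.excluded
        assert log.n_valid + len({g for g, _ in log.excluded}) == log.n_total

    def test_validation_log_tsv(self, matched_setup, tmp_path):
        records, log, matrix, genome = matched_setup
        path = tmp_path / "log.tsv"
        log.write_tsv(path)
        text = path.read_text()
        assert f"geneB\t{NO_FIVE_PRIME_UTR}" in text
        assert text.strip().splitlines()[-1].startswith("# n_total=3")
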