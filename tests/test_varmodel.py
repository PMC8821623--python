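"""Annotation parsing, VCF round-trips and upstream QC validation."""

from __future__ import annotations

import pytest

from gprior.varmodel import (
    DEFAULT_DIALECT,
    Annotation,
    CohortTable,
    ConsequenceParseError,
    DialectError,
    GenotypeCall,
    NormalizationError,
    ValidationError,
    VariantRecord,
    parse_consequence_field,
    read_annotated_vcf,
    read_prioritized_table,
    validate_upstream_qc,
    write_annotated_vcf,
    write_prioritized_table,
)

VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="depth">
##INFO=<ID=CSQ,Number=.,Type=String,Description="Format: Gene|Transcript|IMPACT|Consequence|CADD|AF_1000G|AF_gnomAD|pLI">
##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="dp">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
"""


def _write_vcf(tmp_path, body, name="t.vcf"):
    path = tmp_path / name
    path.write_text(VCF_HEADER + body)
    return path


class TestParseConsequenceField:
    def test_single_block_moderate(self):
        anns = parse_consequence_field("STAG2|STAG2.t1|MODERATE|missense_variant|27.0|0.001|4.7e-05|0.999")
        assert len(anns) == 1
        a = anns[0]
        assert a.impact == "MODERATE"
        assert a.gene_symbol == "STAG2"
        assert a.consequence_terms == frozenset({"missense_variant"})
        assert a.ref_afs == {"1000G": 0.001, "gnomAD": 4.7e-05}
        assert a.pli == 0.999

    def test_empty_numeric_subfield_is_absent_not_zero(self):
        anns = parse_consequence_field("G1|G1.t1|HIGH|stop_gained|||0.01|")
        assert anns[0].cadd_scaled is None
        assert anns[0].pli is None
        assert "1000G" not in anns[0].ref_afs
        assert anns[0].ref_afs["gnomAD"] == 0.01

    def test_three_blocks_preserve_order(self):
        raw = ",".join(
            f"G{i}|G{i}.t1|MODERATE|missense_variant|10|0.01|0.01|0.5"
            for i in (1, 2, 3)
        )
        anns = parse_consequence_field(raw)
        assert [a.gene_symbol for a in anns] == ["G1", "G2", "G3"]

    def test_wrong_subfield_count_names_block(self):
        raw = "G1|G1.t1|MODERATE|missense_variant|10|0.01|0.01|0.5,G2|broken"
        with pytest.raises(ConsequenceParseError, match="block 1"):
            parse_consequence_field(raw)

    def test_ampersand_splits_consequence_terms(self):
        anns = parse_consequence_field(
            "G1|G1.t1|HIGH|stop_gained&splice_donor_variant|||0.01|"
        )
        assert anns[0].consequence_terms == frozenset(
            {"stop_gained", "splice_donor_variant"}
        )


class TestReadAnnotatedVcf:
    def test_header_only(self, tmp_path):
        table = read_annotated_vcf(_write_vcf(tmp_path, ""))
        assert len(table) == 0
        assert table.samples == ["S1", "S2"]

    def test_gnomad_frequency_annotation(self, tmp_path):
        body = (
            "chrX\t1000\trs913664484\tT\tG\t99.0\tPASS\t"
            "DP=100;CSQ=STAG2|STAG2.t1|HIGH|splice_donor_variant|30.0||4.7e-05|0.999\t"
            "GT:DP\t0/1:30\t0/0:28\n"
        )
        table = read_annotated_vcf(_write_vcf(tmp_path, body))
        assert table.variants[0].annotations[0].ref_afs["gnomAD"] == 4.7e-05

    def test_multiallelic_raises_with_position(self, tmp_path):
        body = "chr1\t500\t.\tA\tT,C\t99.0\tPASS\tDP=100;CSQ=x\tGT:DP\t0/1:30\t0/0:28\n"
        with pytest.raises(NormalizationError, match="chr1:500"):
            read_annotated_vcf(_write_vcf(tmp_path, body))

    def test_missing_annotation_key_names_expected_field(self, tmp_path):
        body = "chr1\t500\t.\tA\tT\t99.0\tPASS\tDP=100\tGT:DP\t0/1:30\t0/0:28\n"
        with pytest.raises(DialectError, match="CSQ"):
            read_annotated_vcf(_write_vcf(tmp_path, body))

    def test_hemizygous_and_missing_genotypes(self, tmp_path):
        body = (
            "chrX\t1000\t.\tA\tT\t99.0\tPASS\t"
            "DP=100;CSQ=G1|G1.t1|HIGH|stop_gained|20||0.001|0.95\t"
            "GT:DP\t1:25\t./.:10\n"
        )
        rec = read_annotated_vcf(_write_vcf(tmp_path, body)).variants[0]
        hemi, miss = rec.genotypes
        assert hemi.ploidy == 1 and hemi.dosage == 1 and hemi.is_carrier
        assert miss.missing and not miss.is_carrier

    def test_per_sample_depth_falls_back_to_site_depth(self, tmp_path):
        body = (
            "chr1\t1000\t.\tA\tT\t99.0\tPASS\t"
            "DP=77;CSQ=G1|G1.t1|HIGH|stop_gained|20||0.001|0.95\t"
            "GT\t0/1\t0/0\n"
        )
        rec = read_annotated_vcf(_write_vcf(tmp_path, body)).variants[0]
        assert [g.depth for g in rec.genotypes] == [77, 77]

    def test_unparseable_record_reported_not_silently_dropped(self, tmp_path, caplog):
        body = (
            "chr1\t500\t.\tA\tT\t99.0\tPASS\tDP=100;CSQ=broken\tGT:DP\t0/1:30\t0/0:28\n"
            "chr1\t600\t.\tA\tT\t99.0\tPASS\t"
            "DP=100;CSQ=G1|G1.t1|HIGH|stop_gained|20||0.001|0.95\tGT:DP\t0/1:30\t0/0:28\n"
        )
        with caplog.at_level("WARNING", logger="gprior.varmodel"):
            table = read_annotated_vcf(_write_vcf(tmp_path, body))
        assert len(table) == 1
        assert any("chr1:500" in r.message for r in caplog.records)


def test_vcf_round_trip_is_field_exact(small_sim, tmp_path):
    """Write -> read reproduces the generator's in-memory table exactly."""
    cases = small_sim["cases"]
    path = tmp_path / "roundtrip.vcf"
    write_annotated_vcf(cases, path)
    again = read_annotated_vcf(path)
    assert again.samples == cases.samples
    assert len(again) == len(cases)
    for a, b in zip(again.variants, cases.variants):
        assert a == b


class TestUpstreamQC:
    @staticmethod
    def _table(depth, qual):
        rec = VariantRecord(
            chrom="chr1", pos=100, ref="A", alt="T", qual=qual, site_depth=depth,
            annotations=[Annotation("G1", "G1.t1", "HIGH")],
            genotypes=[GenotypeCall("S1", 1)],
        )
        return CohortTable(samples=["S1"], variants=[rec])

    def test_clean_table_passes(self):
        report = validate_upstream_qc(self._table(30, 60.0))
        assert report.ok and report.n_violations == 0

    def test_depth_threshold_is_strict(self):
        # depth must be > 10; exactly 10 violates
        report = validate_upstream_qc(self._table(10, 60.0))
        assert len(report.depth_violations) == 1
        assert not report.qual_violations

    def test_quality_threshold_is_strict(self):
        report = validate_upstream_qc(self._table(30, 20.0))
        assert len(report.qual_violations) == 1
        assert not report.depth_violations

    def test_strict_mode_raises_with_counts(self):
        with pytest.raises(ValidationError, match="1 record"):
            validate_upstream_qc(self._table(5, 60.0), strict=True)

    def test_validation_does_not_mutate(self):
        table = self._table(5, 10.0)
        before = [v for v in table.variants]
        validate_upstream_qc(table)
        assert table.variants == before


class TestPrioritizedTable:
    def test_empty_hits_gives_header_only(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_prioritized_table([], path)
        frame = read_prioritized_table(path)
        assert len(frame) == 0
        assert list(frame.columns)[:6] == ["chrom", "pos", "id", "ref", "alt", "sample"]
        assert "criterion" in frame.columns

    def test_transcript_expansion_and_round_trip(self, small_sim, tmp_path):
        from gprior.filters import FilterConfig, filter_one

        hits = filter_one(small_sim["cases"], small_sim["lists"], FilterConfig())
        assert hits, "fixture should produce hits"
        path = tmp_path / "prior.tsv"
        write_prioritized_table(hits, path)
        frame = read_prioritized_table(path)
        # one row per (variant, sample, qualifying transcript)
        assert len(frame) == sum(len(h.qualifying_transcripts) for h in hits)
        # hit count and per-gene grouping are reproduced from the file
        file_hits = frame.groupby(["chrom", "pos", "alt", "sample", "gene"]).ngroups
        assert file_hits == len(hits)
        by_gene = {
            g: n for g, n in frame.groupby("gene")["sample"].count().items()
        }
        expect = {}
        for h in hits:
            expect[h.gene_symbol] = expect.get(h.gene_symbol, 0) + len(
                h.qualifying_transcripts
            )
        assert by_gene == expect

    def test_two_transcript_hit_shares_coordinates(self, tmp_path):
        from gprior.filters import Hit

        rec = VariantRecord(
            chrom="chr2", pos=500, ref="G", alt="A", qual=50.0, site_depth=40,
            annotations=[
                Annotation("G1", "G1.t1", "HIGH", cadd_scaled=25.0, pli=0.95),
                Annotation("G1", "G1.t2", "MODERATE", cadd_scaled=25.0, pli=0.95),
            ],
            genotypes=[GenotypeCall("S1", 1, 2, 33)],
        )
        hit = Hit(rec, "S1", "G1", ("G1.t1", "G1.t2"), "score", False, 33)
        path = tmp_path / "two.tsv"
        write_prioritized_table([hit], path)
        frame = read_prioritized_table(path)
        assert len(frame) == 2
        assert set(frame["transcript"]) == {"G1.t1", "G1.t2"}
        assert frame["pos"].nunique() == 1
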