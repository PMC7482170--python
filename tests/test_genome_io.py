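"""FASTA/VCF/sv_tsv parsing, coordinate conversion and the event table."""

import pytest

from radmut import io as rio
from radmut.events import build_events
from radmut.genome import ReferenceGenome
from radmut.variants import VariantClass, apply_variants, normalize_calls

from conftest import deletion, insertion, sbs


class TestFasta:
    def test_basic_parse_and_total_length(self, tmp_path):
        p = tmp_path / "r.fa"
        p.write_text(">chr1\nACGT\n")
        ref = rio.read_fasta(p)
        assert ref.sequences == {"chr1": "ACGT"}
        assert ref.total_length == 4

    def test_lowercase_folded(self, tmp_path):
        p = tmp_path / "r.fa"
        p.write_text(">c\nacgt\n")
        assert rio.read_fasta(p).sequences == {"c": "ACGT"}

    def test_two_records_additive(self, tmp_path):
        p = tmp_path / "r.fa"
        p.write_text(">a\nACGTAC\n>b\nGGG\n")
        assert rio.read_fasta(p).total_length == 9

    @pytest.mark.parametrize("content", ["", "ACGT\n"])
    def test_malformed_raises_format_error(self, tmp_path, content):
        p = tmp_path / "bad.fa"
        p.write_text(content)
        with pytest.raises(rio.FormatError):
            rio.read_fasta(p)

    def test_roundtrip(self, tmp_path, toy_ref):
        p = tmp_path / "r.fa"
        rio.write_fasta(toy_ref, p)
        assert rio.read_fasta(p).sequences == toy_ref.sequences


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=chr1,length=1000>\n"
    "##contig=<ID=chr2,length=1000>\n"
    '##INFO=<ID=AF,Number=A,Type=Float,Description="AF">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
)


def write_vcf_lines(tmp_path, lines):
    p = tmp_path / "calls.vcf"
    p.write_text(VCF_HEADER + "".join(line + "\n" for line in lines))
    return p


class TestVcfReading:
    def test_anchor_removal_deletion(self, tmp_path):
        p = write_vcf_lines(tmp_path, ["chr1\t100\t.\tCA\tC\t.\t.\tAF=0.5"])
        (call,) = rio.read_candidate_calls(p, "vcf", sample_id="s1")
        assert call.variant_class is VariantClass.DELETION
        assert (call.pos, call.ref_allele, call.alt_allele) == (101, "A", "")
        assert call.allele_frequency == 0.5

    def test_substitution(self, tmp_path):
        p = write_vcf_lines(tmp_path, ["chr1\t100\t.\tC\tT\t.\t.\tAF=0.9"])
        (call,) = rio.read_candidate_calls(p, "vcf", sample_id="s1")
        assert call.variant_class is VariantClass.SUBSTITUTION
        assert (call.pos, call.ref_allele, call.alt_allele) == (100, "C", "T")

    def test_insertion_anchor(self, tmp_path):
        p = write_vcf_lines(tmp_path, ["chr1\t100\t.\tC\tCAT\t.\t.\tAF=0.4"])
        (call,) = rio.read_candidate_calls(p, "vcf", sample_id="s1")
        assert call.variant_class is VariantClass.INSERTION
        assert (call.pos, call.alt_allele) == (100, "AT")

    def test_missing_af_names_record(self, tmp_path):
        p = write_vcf_lines(tmp_path, ["chr1\t77\t.\tC\tT\t.\t.\t."])
        with pytest.raises(rio.FormatError, match="77"):
            rio.read_candidate_calls(p, "vcf", sample_id="s1")

    def test_mnp_decomposed_to_sbs_calls(self, tmp_path):
        p = write_vcf_lines(tmp_path, ["chr1\t10\t.\tACG\tTCA\t.\t.\tAF=0.5"])
        calls = rio.read_candidate_calls(p, "vcf", sample_id="s1")
        assert [(c.pos, c.ref_allele, c.alt_allele) for c in calls] == [
            (10, "A", "T"),
            (12, "G", "A"),
        ]


class TestSvTsv:
    def test_inversion_breakpoints(self, tmp_path, toy_ref):
        p = tmp_path / "x.sv.tsv"
        p.write_text(
            "sample_id\tchrom\tstart\tend\ttype\tinserted_seq\tAF\n"
            "s1\tchr2\t5\t25\tINV\t\t0.5\n"
        )
        (call,) = rio.read_candidate_calls(p, "sv_tsv", ref=toy_ref)
        assert call.variant_class is VariantClass.INVERSION
        assert (call.pos, call.end) == (5, 25)

    def test_del_row_uses_reference_sequence(self, tmp_path, toy_ref):
        p = tmp_path / "x.sv.tsv"
        p.write_text(
            "sample_id\tchrom\tstart\tend\ttype\tinserted_seq\tAF\n"
            "s1\tchr1\t3\t6\tDEL\t\t1.0\n"
        )
        (call,) = rio.read_candidate_calls(p, "sv_tsv", ref=toy_ref)
        assert call.ref_allele == toy_ref.fetch("chr1", 3, 6)

    def test_unknown_type_rejected(self, tmp_path, toy_ref):
        p = tmp_path / "x.sv.tsv"
        p.write_text(
            "sample_id\tchrom\tstart\tend\ttype\tinserted_seq\tAF\n"
            "s1\tchr1\t3\t6\tDUP\t\t1.0\n"
        )
        with pytest.raises(rio.FormatError):
            rio.read_candidate_calls(p, "sv_tsv", ref=toy_ref)


class TestCoordinateConversion:
    """VCF -> internal -> VCF is an identity on the derived sequence."""

    @pytest.mark.parametrize(
        "call_factory",
        [
            lambda: sbs(9, "G", "T"),
            lambda: deletion(20, "AATT"),
            lambda: insertion(15, "CGG"),
            lambda: deletion(29, "AAA"),  # homopolymer deletion
        ],
    )
    def test_roundtrip_derived_sequence(self, tmp_path, toy_ref, call_factory):
        call = call_factory()
        before = apply_variants(toy_ref, "chr1", [call], 1, 60)
        p = tmp_path / "c.vcf"
        rio.write_vcf([call], toy_ref, p, sample_id="s1")
        calls_back = normalize_calls(
            rio.read_candidate_calls(p, "vcf", sample_id="s1"), toy_ref
        )
        after = apply_variants(toy_ref, "chr1", calls_back, 1, 60)
        assert before == after


class TestEventTable:
    def test_empty_events_header_only(self, tmp_path):
        p = tmp_path / "events.tsv"
        rio.write_event_table([], p)
        assert p.read_text().strip() == "\t".join(rio.EVENT_TABLE_COLUMNS)

    def test_single_sbs_row(self, tmp_path, toy_ref):
        events = build_events([sbs(9, "G", "T")], toy_ref)
        p = tmp_path / "events.tsv"
        rio.write_event_table(events, p, toy_ref)
        df = rio.read_event_table(p)
        assert len(df) == 1
        assert df.loc[0, "category"] == "SBS"

    def test_rows_sorted_regardless_of_input_order(self, tmp_path, toy_ref):
        calls_a = [sbs(43, "G", "C", sample="s2"), sbs(9, "G", "T", sample="s2")]
        events = build_events([calls_a[0]], toy_ref) + build_events(
            [sbs(9, "G", "T", sample="s1")], toy_ref
        ) + build_events([calls_a[1]], toy_ref)
        p = tmp_path / "events.tsv"
        rio.write_event_table(events, p, toy_ref)
        df = rio.read_event_table(p)
        assert list(zip(df["sample"], df["start"])) == [
            ("s1", 9),
            ("s2", 9),
            ("s2", 43),
        ]

    def test_write_read_roundtrip_identical(self, tmp_path, toy_ref):
        calls = [
            sbs(9, "G", "T"),
            deletion(20, "AATT", zygosity="homozygous"),
            insertion(44, "TT"),
            sbs(52, "C", "A"),
            sbs(55, "G", "T"),
        ]
        events = build_events(calls, toy_ref)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        rio.write_event_table(events, p1, toy_ref)
        df = rio.read_event_table(p1)
        df.to_csv(p2, sep="\t", index=False)
        assert p1.read_text() == p2.read_text()
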