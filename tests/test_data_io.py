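"""Format readers/writers and the optional pileup counter."""

import numpy as np
import pandas as pd
import pytest

from somalex import data_io
from somalex.types import InputFormatError, SomalexError, VariantSite

MAF_HEADER = (
    "Hugo_Symbol\tChromosome\tStart_Position\tEnd_Position\tReference_Allele\t"
    "Tumor_Seq_Allele2\tVariant_Classification\tVariant_Type\t"
    "Tumor_Sample_Barcode\tTranscript_ID\tcancer_type"
)


def write_maf(path, rows):
    lines = ["#version test", MAF_HEADER] + ["\t".join(map(str, r)) for r in rows]
    path.write_text("\n".join(lines) + "\n")


class TestReadMaf:
    def test_snv_parsed_and_indel_rejected(self, tmp_path):
        maf = tmp_path / "v.maf"
        write_maf(
            maf,
            [
                ("G1", "chr1", 100, 100, "A", "G", "Missense_Mutation", "SNP", "S1", "T1", "BLCA"),
                ("G2", "chr1", 200, 201, "A", "AT", "Frame_Shift_Ins", "INS", "S1", "T2", "BLCA"),
            ],
        )
        variants = data_io.read_variants(maf, "maf")
        assert len(variants) == 1
        v = variants[0]
        assert (v.chrom, v.pos, v.ref_allele, v.alt_allele) == ("chr1", 100, "A", "G")
        assert v.cancer_type == "BLCA"

    @pytest.mark.parametrize(
        "classification,expected",
        [
            ("Nonsense_Mutation", "PTV"),
            ("Missense_Mutation", "missense"),
            ("Silent", "silent"),
            ("Splice_Site", "splice"),
            ("3'UTR", "other"),
        ],
    )
    def test_consequence_mapping(self, tmp_path, classification, expected):
        maf = tmp_path / "v.maf"
        write_maf(
            maf,
            [("G1", "chr2", 5, 5, "C", "T", classification, "SNP", "S1", "T1", "LUAD")],
        )
        assert data_io.read_variants(maf, "maf")[0].consequence == expected

    def test_missing_column_named_in_error(self, tmp_path):
        maf = tmp_path / "v.maf"
        maf.write_text("Hugo_Symbol\tChromosome\nG1\tchr1\n")
        with pytest.raises(InputFormatError, match="Start_Position"):
            data_io.read_variants(maf, "maf")


class TestReadVcf:
    def test_identity_parse(self, tmp_path):
        vcf = tmp_path / "v.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=SAMPLE,Number=1,Type=String,Description="s">\n'
            '##INFO=<ID=GENE,Number=1,Type=String,Description="g">\n'
            '##INFO=<ID=CSQ,Number=1,Type=String,Description="c">\n'
            "##contig=<ID=chr1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t100\t.\tA\tG\t.\t.\tSAMPLE=S1;GENE=G1;CSQ=missense\n"
            "chr1\t200\t.\tA\tG,T\t.\t.\tSAMPLE=S1;GENE=G1;CSQ=missense\n"
        )
        variants = data_io.read_variants(vcf, "vcf")
        assert len(variants) == 1  # multi-allelic row rejected
        assert variants[0].pos == 100
        assert variants[0].ref_allele == "A"
        assert variants[0].alt_allele == "G"


GTF_LINES = [
    # plus-strand two-exon transcript with CDS
    'chr1\tx\texon\t100\t200\t.\t+\t.\tgene_id "G1"; transcript_id "T1";',
    'chr1\tx\texon\t300\t400\t.\t+\t.\tgene_id "G1"; transcript_id "T1";',
    'chr1\tx\tCDS\t150\t200\t.\t+\t0\tgene_id "G1"; transcript_id "T1";',
    'chr1\tx\tCDS\t300\t350\t.\t+\t0\tgene_id "G1"; transcript_id "T1";',
    # minus-strand, same exons, no CDS (non-coding)
    'chr1\tx\texon\t100\t200\t.\t-\t.\tgene_id "G2"; transcript_id "T2";',
    'chr1\tx\texon\t300\t400\t.\t-\t.\tgene_id "G2"; transcript_id "T2";',
]


class TestReadGeneModels:
    def test_exon_order_and_cds(self, tmp_path):
        gtf = tmp_path / "m.gtf"
        gtf.write_text("\n".join(GTF_LINES) + "\n")
        models = data_io.read_gene_models(gtf)
        t1 = models["T1"]
        assert t1.exons == ((100, 200), (300, 400))
        assert t1.exons_tx_order[0] == (100, 200)
        assert (t1.cds_start, t1.cds_end) == (150, 350)
        t2 = models["T2"]
        assert t2.exons_tx_order[0] == (300, 400)  # minus strand
        assert not t2.is_coding

    def test_cds_without_exons_is_an_error(self, tmp_path):
        gtf = tmp_path / "bad.gtf"
        gtf.write_text(
            'chr1\tx\tCDS\t150\t200\t.\t+\t0\tgene_id "G"; transcript_id "T9";\n'
        )
        with pytest.raises(InputFormatError, match="T9"):
            data_io.read_gene_models(gtf)


class TestTables:
    def test_purity_range_checked(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("sample_id\tESTIMATE\tCPE\nS1\t1.4\t0.5\n")
        with pytest.raises(InputFormatError):
            data_io.read_purity_table(path)

    def test_purity_missing_values_tolerated(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("sample_id\tESTIMATE\tABSOLUTE\tCPE\nS1\t0.7\t\t0.5\n")
        df = data_io.read_purity_table(path)
        est = data_io.purity_row_to_estimates(df.iloc[0])
        assert est.n_available == 2

    def test_segment_start_after_end_rejected(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text(
            "sample_id\tchrom\tstart\tend\tsegment_mean\nS1\tchr1\t50\t10\t0.1\n"
        )
        with pytest.raises(InputFormatError):
            data_io.read_segments_table(path)

    def test_negative_counts_rejected(self, tmp_path):
        path = tmp_path / "c.tsv"
        header = "\t".join(data_io._COUNT_TABLE_COLS)
        path.write_text(header + "\nS1\tchr1\t10\tA\tG\t1\t0\t1\t0\t-5\t1\t1\t1\n")
        with pytest.raises(InputFormatError):
            data_io.read_counts_table(path)

    def test_bed_converted_to_one_based_inclusive(self, tmp_path):
        bed = tmp_path / "i.bed"
        bed.write_text("chr1\t0\t10\nchr2\t99\t200\n")
        assert data_io.read_bed(bed) == [("chr1", 1, 10), ("chr2", 100, 200)]

    def test_write_read_round_trip_is_bit_exact(self, tmp_path):
        df = pd.DataFrame(
            {
                "gene": ["a", "b"],
                "v_rd": [0.1 + 0.2, 1 / 3],
                "n": [3, 7],
            }
        )
        path = tmp_path / "t.tsv"
        data_io.write_table(df, path, comment="round trip")
        back = data_io.read_table(path)
        pd.testing.assert_frame_equal(df, back)
        assert back["v_rd"][0] == 0.1 + 0.2  # bit-exact, not approx


class TestPileup:
    @pytest.fixture
    def bam_path(self, tmp_path):
        import pysam

        header = {"HD": {"VN": "1.6", "SO": "coordinate"},
                  "SQ": [{"SN": "chr1", "LN": 1000}]}
        path = tmp_path / "reads.bam"
        with pysam.AlignmentFile(path, "wb", header=header) as bam:
            def read(name, base, mapq=60, dup=False):
                a = pysam.AlignedSegment()
                a.query_name = name
                a.query_sequence = "AAAA" + base + "AAAA"
                a.reference_id = 0
                a.reference_start = 495  # covers 1-based position 500 at index 4
                a.mapping_quality = mapq
                a.cigarstring = "9M"
                a.query_qualities = pysam.qualitystring_to_array("I" * 9)
                if dup:
                    a.is_duplicate = True
                return a

            for i in range(7):
                bam.write(read(f"ref{i}", "A"))
            for i in range(3):
                bam.write(read(f"var{i}", "G"))
            bam.write(read("third", "T"))
            bam.write(read("lowmq", "G", mapq=5))
            bam.write(read("dup", "G", dup=True))
        pysam.index(str(path))
        return path

    def test_counts_match_constructed_reads(self, bam_path):
        site = VariantSite(
            sample_id="S1", chrom="chr1", pos=500, ref_allele="A", alt_allele="G"
        )
        q = data_io.pileup_quad_counts({"tex": bam_path}, site)
        # 7 ref reads; 3 var reads; the third-allele, low-MAPQ and duplicate
        # reads are ignored
        assert (q.tex_ref, q.tex_var) == (7, 3)

    def test_all_reads_below_mapping_quality(self, bam_path):
        site = VariantSite(
            sample_id="S1", chrom="chr1", pos=500, ref_allele="A", alt_allele="G"
        )
        q = data_io.pileup_quad_counts({"tex": bam_path}, site, min_mapping_quality=99)
        assert (q.tex_ref, q.tex_var) == (0, 0)

    def test_absent_contig_names_dataset(self, bam_path):
        site = VariantSite(
            sample_id="S1", chrom="chr9", pos=500, ref_allele="A", alt_allele="G"
        )
        with pytest.raises(SomalexError, match="ntr"):
            data_io.pileup_quad_counts({"ntr": bam_path}, site)
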