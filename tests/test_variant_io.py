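"""Allele normalization, VCF ingestion and table readers."""

import textwrap

import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from omixlink import (
    GAP,
    NO_EXPRESSION,
    NormalizedVariant,
    RejectedRecord,
    VariantIOError,
    denormalize_to_vcf,
    harmonize_chrom,
    normalize_vcf_allele,
    read_annotation_table,
    read_tpm_table,
    read_vcf_observations,
)


class TestNormalizeVcfAllele:
    @pytest.mark.parametrize(
        "chrom,pos,ref,alt,expected",
        [
            # published coordinate convention: SNV, anchored deletion,
            # anchored insertion
            ("chr6", 32589702, "G", "A", ("chr6", 32589702, 32589702, "G", "A", "SNV")),
            ("chr6", 32584351, "TCCC", "T", ("chr6", 32584352, 32584354, "CCC", GAP, "deletion")),
            ("chr6", 32584355, "A", "AATA", ("chr6", 32584355, 32584355, GAP, "ATA", "insertion")),
            # padded SNV and MNV
            ("chr1", 100, "CAT", "CGT", ("chr1", 101, 101, "A", "G", "SNV")),
            ("chr1", 100, "AT", "GC", ("chr1", 100, 101, "AT", "GC", "MNV")),
            # chromosome label harmonization
            ("6", 32589702, "G", "A", ("chr6", 32589702, 32589702, "G", "A", "SNV")),
            ("MT", 5, "A", "C", ("chrM", 5, 5, "A", "C", "SNV")),
        ],
    )
    def test_examples(self, chrom, pos, ref, alt, expected):
        v = normalize_vcf_allele(chrom, pos, ref, alt)
        assert (v.chrom, v.start, v.end, v.ref, v.alt, v.vclass) == expected

    @pytest.mark.parametrize(
        "ref,alt",
        [("AT", "AT"), ("A", "<DEL>"), ("A", "A[chr2:321[A"), ("A", "*"), ("AQ", "A")],
    )
    def test_rejected_records(self, ref, alt):
        with pytest.raises(RejectedRecord):
            normalize_vcf_allele("chr1", 100, ref, alt)

    def test_snv_idempotent(self):
        v = normalize_vcf_allele("chr1", 100, "G", "A")
        v2 = normalize_vcf_allele(v.chrom, v.start, v.ref, v.alt)
        assert v == v2

    @pytest.mark.parametrize(
        "pos,ref,alt,anchor",
        [
            (100, "G", "A", "n/a"),  # SNV
            (100, "GTT", "G", "G"),  # deletion
            (100, "G", "GCA", "G"),  # insertion
            (100, "AT", "GC", "n/a"),  # MNV
        ],
    )
    def test_round_trip_all_classes(self, pos, ref, alt, anchor):
        """denormalize(normalize(x)) re-normalizes to the identical key."""
        v = normalize_vcf_allele("chr1", pos, ref, alt)
        chrom, vpos, vref, valt = denormalize_to_vcf(v, anchor if anchor != "n/a" else "G")
        assert normalize_vcf_allele(chrom, vpos, vref, valt) == v


@st.composite
def padded_indels(draw):
    """A minimal anchored indel plus a left/right-padded spelling of it."""
    context = draw(st.text(alphabet="ACGT", min_size=30, max_size=40))
    pos = draw(st.integers(min_value=10, max_value=15))  # 1-based anchor
    is_del = draw(st.booleans())
    if is_del:
        length = draw(st.integers(1, 3))
        ref = context[pos - 1 : pos + length]
        alt = context[pos - 1]
    else:
        ins = draw(st.text(alphabet="ACGT", min_size=1, max_size=3))
        ref = context[pos - 1]
        alt = ref + ins
    left = draw(st.integers(0, 4))
    right = draw(st.integers(0, 4))
    pad_l = context[pos - 1 - left : pos - 1]
    pad_r = context[pos - 1 + len(ref) : pos - 1 + len(ref) + right]
    padded = (pos - left, pad_l + ref + pad_r, pad_l + alt + pad_r)
    return context, (pos, ref, alt), padded


@settings(
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
    deadline=None,
)
@given(padded_indels())
def test_padded_and_minimal_spellings_agree(make_fasta, case):
    """Any padded VCF spelling of an indel normalizes to the same key as the
    minimal spelling once left-aligned against the reference."""
    context, minimal, padded = case
    fasta = make_fasta(context)
    v_min = normalize_vcf_allele("chr1", *minimal, fasta=fasta)
    v_pad = normalize_vcf_allele("chr1", *padded, fasta=fasta)
    assert v_min == v_pad


@settings(derandomize=True, max_examples=200)
@given(padded_indels())
def test_left_padding_invariant_without_reference(case):
    """Left-padded spellings (extra shared prefix) normalize identically even
    with trim-only normalization, no reference needed."""
    context, (pos, ref, alt), _ = case
    left = 3
    pad = context[pos - 1 - left : pos - 1]
    v_min = normalize_vcf_allele("chr1", pos, ref, alt)
    v_pad = normalize_vcf_allele("chr1", pos - left, pad + ref, pad + alt)
    assert v_min == v_pad


def test_left_alignment_shifts_into_homopolymer(make_fasta):
    # deleting one A anywhere in the run AAAA (positions 5-8) is one variant
    fasta = make_fasta("CGTCAAAAGTC")
    keys = {
        normalize_vcf_allele("chr1", p, fasta.fetch("chr1", p - 1, p + 1), fasta.fetch("chr1", p - 1, p), fasta=fasta)
        for p in (4, 5, 6, 7)
    }
    assert len(keys) == 1
    (v,) = keys
    assert (v.start, v.ref, v.alt) == (5, "A", GAP)


def test_invariant_enforcement():
    with pytest.raises(ValueError):
        NormalizedVariant("chr1", 10, 10, "AC", GAP, "deletion")  # end wrong
    with pytest.raises(ValueError):
        NormalizedVariant("chr1", 10, 10, "A", "A", "SNV")


class TestReadVcf:
    VCF = textwrap.dedent(
        """\
        ##fileformat=VCFv4.2
        ##contig=<ID=chr1,length=1000000>
        ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
        ##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
        ##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="GQ">
        #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
        chr1\t100\t.\tG\tA\t50\tPASS\t.\tGT:DP:GQ\t0/1:40:99
        chr1\t200\t.\tC\tT\t50\tPASS\t.\tGT:DP:GQ\t1/1:30:80
        chr1\t300\t.\tA\tG,T\t50\tPASS\t.\tGT:DP:GQ\t1/2:25:60
        chr1\t400\t.\tT\tC\t50\tLowQual\t.\tGT:DP:GQ\t0/1:10:15
        chr1\t500\t.\tG\tC\t50\tPASS\t.\tDP:GQ\t22:33
        chr1\t600\t.\tA\t<DEL>\t50\tPASS\t.\tGT:DP:GQ\t0/1:40:99
        """
    )

    @pytest.fixture()
    def vcf_path(self, tmp_path):
        p = tmp_path / "s1.vcf"
        p.write_text(self.VCF)
        return p

    def test_field_mapping_and_split(self, vcf_path):
        obs = read_vcf_observations(vcf_path, "DNA")
        by_pos = {(o.variant.start, o.variant.alt): o for o in obs}
        het = by_pos[(100, "A")]
        assert (het.state, het.depth, het.gq, het.source) == ("het", 40, 99.0, "DNA")
        assert by_pos[(200, "T")].state == "hom_alt"
        # multi-allelic 1/2: both per-ALT observations map to `other`
        assert by_pos[(300, "G")].state == "other"
        assert by_pos[(300, "T")].state == "other"
        # missing GT format field -> state missing, never a crash
        assert by_pos[(500, "C")].state == "missing"
        # symbolic ALT rejected, not fatal
        assert (600, "<DEL>") not in by_pos

    def test_pass_only_flag(self, vcf_path):
        default = read_vcf_observations(vcf_path, "RNA")
        assert all(o.variant.start != 400 for o in default)
        lenient = read_vcf_observations(vcf_path, "RNA", pass_only=False)
        assert any(o.variant.start == 400 for o in lenient)

    def test_unreadable_file_is_fatal(self, tmp_path):
        with pytest.raises(VariantIOError, match="nope.vcf"):
            read_vcf_observations(tmp_path / "nope.vcf", "DNA")


class TestAnnotationTable:
    TSV = (
        "chr\tstart\tend\tref\talt\tgene\tlocation\tconsequence\tmaf\trsid\n"
        "chr6\t29888222\t29888222\tG\tC\tHLA-H\tncRNA_exonic\t–\t–\trs78277628\n"
        "chr6\t32584352\t32584354\tCCC\t-\tHLA-DRB1\texonic\tnonframeshift deletion\t0.00480\trs745615811\n"
        "chr1\t500\t500\tA\tG\tGENEX;GENEY\tintronic\t.\tbogus\t.\n"
        "chr1\t600\t600\tG\tT\tGZ\tweird_place\tnonsynonymous SNV\t0.5\trs1\n"
    )

    @pytest.fixture()
    def ann_path(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text(self.TSV)
        return p

    def test_vocabulary_mapping(self, ann_path):
        anns = read_annotation_table(ann_path)
        assert [a.variant.start for a in anns] == [29888222, 32584352, 500, 600]
        ncrna = anns[0]
        assert (ncrna.location, ncrna.consequence, ncrna.maf) == ("exonic_ncRNA", "none", None)
        assert ncrna.rsid == "rs78277628"
        assert anns[1].maf == pytest.approx(0.0048)
        assert anns[1].consequence == "nonframeshift_deletion"
        # intronic retained at ingest; multi-gene keeps first symbol;
        # unparseable MAF -> absent; non-exonic -> consequence none
        intronic = anns[2]
        assert (intronic.location, intronic.gene, intronic.maf) == ("intronic", "GENEX", None)
        assert intronic.consequence == "none"
        # unmapped location falls back to `other`
        assert anns[3].location == "other"

    def test_missing_mandatory_column_is_fatal(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("chr\tstart\tend\tref\talt\tgene\tlocation\n" "chr1\t1\t1\tA\tG\tX\texonic\n")
        with pytest.raises(VariantIOError, match="consequence"):
            read_annotation_table(p)

    def test_designated_maf_column(self, tmp_path):
        p = tmp_path / "maf.tsv"
        p.write_text(
            "chr\tstart\tend\tref\talt\tgene\tlocation\tconsequence\tgnomad_genome_AF\tpopfreq\n"
            "chr1\t1\t1\tA\tG\tX\texonic\tstopgain\t0.2\t0.001\n"
        )
        assert read_annotation_table(p)[0].maf == pytest.approx(0.2)
        assert read_annotation_table(p, maf_column="popfreq")[0].maf == pytest.approx(0.001)
        with pytest.raises(VariantIOError):
            read_annotation_table(p, maf_column="absent_col")


class TestTpmTable:
    def test_lookup_and_duplicates(self, tmp_path):
        p = tmp_path / "tpm.tsv"
        p.write_text("gene\ttpm\nKRT83\t241.31\nG\t5\nG\t7\n")
        table = read_tpm_table(p, label="ref")
        assert table.lookup("KRT83") == pytest.approx(241.31)
        assert table.lookup("G") == 7.0  # duplicates collapse to the maximum
        assert table.lookup("ABSENT") is NO_EXPRESSION
        assert table.lookup("ABSENT") != 0.0

    def test_negative_and_empty_fatal(self, tmp_path):
        neg = tmp_path / "neg.tsv"
        neg.write_text("gene\ttpm\nX\t-1\n")
        with pytest.raises(VariantIOError):
            read_tpm_table(neg, label="x")
        empty = tmp_path / "empty.tsv"
        empty.write_text("gene\ttpm\n")
        with pytest.raises(VariantIOError):
            read_tpm_table(empty, label="x")


def test_harmonize_chrom():
    assert harmonize_chrom("6") == "chr6"
    assert harmonize_chrom("chr6") == "chr6"
    assert harmonize_chrom("MT") == "chrM"
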