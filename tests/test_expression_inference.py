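"""TPM binning and the NMD / gain-of-function inference rules."""

import itertools

import numpy as np
import pytest

from omixlink import (
    NO_EXPRESSION,
    Thresholds,
    VariantAnnotation,
    expression_category,
    infer_gof,
    infer_nmd,
    normalize_vcf_allele,
)
from omixlink.expression_inference import ExpressionAssessment
from omixlink.synthetic_fixtures import PUBLISHED_NMD_VARIANTS

TH = Thresholds()


def _ann(consequence="nonsynonymous_SNV", location="exonic", gene="G", maf=None):
    v = normalize_vcf_allele("chr1", 100, "A", "G")
    return VariantAnnotation(v, gene, location, consequence, maf, None)


def _assess(sample, reference, gene="G", th=TH):
    return ExpressionAssessment(
        gene=gene,
        sample_tpm=sample,
        reference_tpm=reference,
        sample_category=expression_category(sample, th),
        reference_category=expression_category(reference, th),
    )


class TestExpressionCategory:
    @pytest.mark.parametrize(
        "tpm,expected",
        [
            (0.0, "not_expressed"),
            (0.999, "not_expressed"),
            (1.0, "low"),       # lower bounds inclusive
            (9.999, "low"),
            (10.0, "medium"),
            (99.999, "medium"),
            (100.0, "high"),
            (241.31, "high"),
        ],
    )
    def test_default_log_decade_bins(self, tpm, expected):
        assert expression_category(tpm, TH) == expected

    def test_no_data_passes_through(self):
        assert expression_category(NO_EXPRESSION, TH) == "no_data"

    def test_negative_tpm_rejected(self):
        with pytest.raises(ValueError):
            expression_category(-0.1, TH)


class TestInferNmd:
    @pytest.mark.parametrize(
        "sample,chrom,pos,ref,alt,gene,consequence,maf,rsid,ref_tpm,sample_tpm",
        list(PUBLISHED_NMD_VARIANTS),
    )
    def test_published_nmd_rows_all_true_and_rare(
        self, sample, chrom, pos, ref, alt, gene, consequence, maf, rsid, ref_tpm, sample_tpm
    ):
        """Every published NMD worked-example row evaluates NMD-true and
        passes the 1% rare-variant cut under default thresholds."""
        ann = _ann(consequence=consequence, gene=gene, maf=maf)
        assert infer_nmd(ann, _assess(sample_tpm, ref_tpm, gene=gene), TH)
        assert maf < TH.maf_cutoff

    @pytest.mark.parametrize(
        "consequence,sample,reference,expected",
        [
            ("stopgain", 0.00, 241.31, True),      # silenced gene
            ("startloss", 4.40, 14.67, True),      # 4.40 < 0.5 * 14.67
            ("stopgain", 100.0, 100.0, False),     # not under-expressed
            ("nonsynonymous_SNV", 0.0, 100.0, False),  # consequence not LoF
            ("frameshift_deletion", 2.0, 100.0, True),
            ("stopgain", 49.9, 100.0, True),       # just under the ratio
            ("stopgain", 50.0, 100.0, False),      # strict <
        ],
    )
    def test_rule(self, consequence, sample, reference, expected):
        ann = _ann(consequence=consequence)
        assert infer_nmd(ann, _assess(sample, reference), TH) is expected

    def test_no_data_never_calls(self):
        ann = _ann(consequence="stopgain")
        assert not infer_nmd(ann, _assess(NO_EXPRESSION, 100.0), TH)
        assert not infer_nmd(ann, _assess(0.0, NO_EXPRESSION), TH)


class TestInferGof:
    @pytest.mark.parametrize(
        "location,consequence,sample,reference,expected",
        [
            # UTR3 nonframeshift deletion, sample high, reference lower
            ("UTR3", "nonframeshift_deletion", 500.0, 100.0, True),
            # upstream site, reference not expressed
            ("upstream", "none", 150.0, 0.2, True),
            ("intronic", "nonsynonymous_SNV", 500.0, 0.0, False),   # excluded location
            ("intergenic", "none", 500.0, 0.0, False),
            ("exonic", "synonymous_SNV", 500.0, 1.0, False),        # excluded consequence
            ("exonic", "frameshift_insertion", 500.0, 1.0, False),
            ("exonic", "nonsynonymous_SNV", 5.0, 0.0, False),       # sample not medium/high
            ("exonic", "nonsynonymous_SNV", 50.0, 50.0, False),     # not above reference
            ("exonic", "nonsynonymous_SNV", 50.0, 49.0, True),
        ],
    )
    def test_rule(self, location, consequence, sample, reference, expected):
        ann = _ann(consequence=consequence, location=location)
        assert infer_gof(ann, _assess(sample, reference), TH) is expected

    def test_no_data_never_calls(self):
        ann = _ann()
        assert not infer_gof(ann, _assess(NO_EXPRESSION, 0.0), TH)
        assert not infer_gof(ann, _assess(500.0, NO_EXPRESSION), TH)


class TestThresholdProperties:
    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            Thresholds(tpm_not_expressed=10.0, tpm_low_upper=5.0)
        with pytest.raises(ValueError):
            Thresholds(nmd_ratio=0.0)
        with pytest.raises(ValueError):
            Thresholds(gof_fold=0.5)
        with pytest.raises(ValueError):
            Thresholds(maf_cutoff=1.5)

    def test_nmd_monotone_in_ratio(self):
        """Raising nmd_ratio never converts an NMD-true site to false."""
        rng = np.random.default_rng(0)
        ann = _ann(consequence="stopgain")
        grid = rng.uniform(0, 200, size=(200, 2))
        ratios = [0.1, 0.3, 0.5, 0.8, 1.0]
        for sample, reference in grid:
            calls = [
                infer_nmd(ann, _assess(sample, reference), Thresholds(nmd_ratio=r))
                for r in ratios
            ]
            # once true, stays true as the ratio loosens
            assert calls == sorted(calls)

    def test_gof_antitone_in_fold(self):
        """Raising gof_fold never converts a GoF-false site to true."""
        rng = np.random.default_rng(1)
        ann = _ann()
        grid = rng.uniform(0, 500, size=(200, 2))
        folds = [1.0, 1.5, 2.0, 4.0]
        for sample, reference in grid:
            calls = [
                infer_gof(ann, _assess(sample, reference), Thresholds(gof_fold=f))
                for f in folds
            ]
            assert calls == sorted(calls, reverse=True)

    def test_nmd_gof_mutually_exclusive_under_defaults(self):
        """No (consequence, location, TPM pair) yields both NMD and GoF under
        the default thresholds, checked over a full grid."""
        from omixlink.variant_io import CONSEQUENCES, LOCATIONS

        tpms = [0.0, 0.5, 1.0, 5.0, 10.0, 50.0, 100.0, 400.0]
        for consequence, location in itertools.product(CONSEQUENCES, LOCATIONS):
            ann = _ann(consequence=consequence, location=location)
            for sample, reference in itertools.product(tpms, tpms):
                assess = _assess(sample, reference)
                assert not (infer_nmd(ann, assess, TH) and infer_gof(ann, assess, TH))

    def test_config_file_round_trip(self, tmp_path):
        th = Thresholds(nmd_ratio=0.7, maf_cutoff=0.005, min_depth=20)
        p = tmp_path / "th.cfg"
        p.write_text(th.to_config_text())
        assert Thresholds.from_config_file(p) == th

    def test_config_file_unknown_key_fatal(self, tmp_path):
        p = tmp_path / "bad.cfg"
        p.write_text("frobnicate = 3\n")
        with pytest.raises(ValueError, match="frobnicate"):
            Thresholds.from_config_file(p)
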