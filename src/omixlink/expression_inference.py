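"""Expression categorization and NMD / gain-of-function inference.

Gene-level TPM is binned into conventional log-decade categories
(not_expressed < 1, low < 10, medium < 100, high ≥ 100 by default).  A
loss-of-function variant (premature stop, frameshift, start loss) in a gene
under-expressed relative to the tissue reference is flagged as a candidate
for nonsense-mediated decay (NMD); a non-intronic, non-intergenic variant
that is neither a synonymous SNV nor a frameshift indel, in a gene expressed
medium/high in the sample but absent or lower in the reference, is flagged
as a candidate gain-of-function (GoF).

Both inferences operate on gene-level TPM only — no transcript-isoform NMD
rules (50-nt rule, exon-junction logic) are applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

from .variant_io import NO_EXPRESSION, NoExpression, VariantAnnotation

EXPRESSION_CATEGORIES = ("not_expressed", "low", "medium", "high", "no_data")

_SET_FIELDS = (
    "lof_consequences",
    "gof_excluded_consequences",
    "gof_excluded_locations",
    "asernae_excluded_locations",
)


@dataclass
class Thresholds:
    """Every tunable the integration leaves open.

    TPM bins are half-open with inclusive lower bounds: a gene is
    not_expressed below ``tpm_not_expressed``, low in
    [tpm_not_expressed, tpm_low_upper), medium in
    [tpm_low_upper, tpm_medium_upper), high at or above ``tpm_medium_upper``.
    ``nmd_ratio`` is the sample/reference TPM ratio under which a gene counts
    as "less expressed"; ``gof_fold`` is the factor the sample must exceed
    the reference by (1.0 = strict reference < sample).
    """

    tpm_not_expressed: float = 1.0
    tpm_low_upper: float = 10.0
    tpm_medium_upper: float = 100.0
    nmd_ratio: float = 0.5
    gof_fold: float = 1.0
    maf_cutoff: float = 0.01
    min_depth: int = 10
    min_gq: float = 20.0
    lenient_evidence: bool = False
    lof_consequences: frozenset[str] = frozenset(
        {"stopgain", "frameshift_insertion", "frameshift_deletion", "startloss"}
    )
    gof_excluded_consequences: frozenset[str] = frozenset(
        {"synonymous_SNV", "frameshift_insertion", "frameshift_deletion"}
    )
    gof_excluded_locations: frozenset[str] = frozenset({"intronic", "intergenic"})
    asernae_excluded_locations: frozenset[str] = frozenset(
        {"intronic", "intergenic", "upstream", "downstream"}
    )

    def __post_init__(self) -> None:
        for name in _SET_FIELDS:
            setattr(self, name, frozenset(getattr(self, name)))
        if not (0 <= self.tpm_not_expressed < self.tpm_low_upper < self.tpm_medium_upper):
            raise ValueError("TPM bin bounds must satisfy 0 <= ne < low < medium")
        if not (0 < self.nmd_ratio <= 1):
            raise ValueError("nmd_ratio must lie in (0, 1]")
        if self.gof_fold < 1:
            raise ValueError("gof_fold must be >= 1")
        if not (0 < self.maf_cutoff < 1):
            raise ValueError("maf_cutoff must lie in (0, 1)")

    # -- config file (key = value) round trip ------------------------------
    def to_config_text(self) -> str:
        lines = []
        for f in fields(self):
            value = getattr(self, f.name)
            if isinstance(value, frozenset):
                value = ",".join(sorted(value))
            lines.append(f"{f.name} = {value}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_config_file(cls, path: str | Path) -> "Thresholds":
        """Parse a plain-text ``key = value`` config; unknown keys are fatal."""
        known = {f.name: f for f in fields(cls)}
        kwargs = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown threshold {key!r}")
            if key in _SET_FIELDS:
                kwargs[key] = frozenset(
                    s.strip() for s in value.split(",") if s.strip()
                )
            elif key == "lenient_evidence":
                kwargs[key] = value.lower() in ("1", "true", "yes", "on")
            elif key == "min_depth":
                kwargs[key] = int(value)
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)


@dataclass(frozen=True)
class ExpressionAssessment:
    """Sample-vs-reference TPM for one gene, with categories."""

    gene: str
    sample_tpm: float | NoExpression
    reference_tpm: float | NoExpression
    sample_category: str
    reference_category: str


def expression_category(tpm: float | NoExpression, thresholds: Thresholds) -> str:
    """Bin a TPM value; the no-data sentinel passes through as ``no_data``."""
    if isinstance(tpm, NoExpression):
        return "no_data"
    if tpm < 0:
        raise ValueError("negative TPM must be rejected upstream")
    if tpm < thresholds.tpm_not_expressed:
        return "not_expressed"
    if tpm < thresholds.tpm_low_upper:
        return "low"
    if tpm < thresholds.tpm_medium_upper:
        return "medium"
    return "high"


def assess_expression(
    gene: str,
    sample_table,
    reference_table,
    thresholds: Thresholds,
) -> ExpressionAssessment:
    """Look a gene up in both TPM tables and categorize both values."""
    sample_tpm = sample_table.lookup(gene) if gene else NO_EXPRESSION
    reference_tpm = reference_table.lookup(gene) if gene else NO_EXPRESSION
    return ExpressionAssessment(
        gene=gene,
        sample_tpm=sample_tpm,
        reference_tpm=reference_tpm,
        sample_category=expression_category(sample_tpm, thresholds),
        reference_category=expression_category(reference_tpm, thresholds),
    )


def infer_nmd(
    ann: VariantAnnotation,
    assess: ExpressionAssessment,
    thresholds: Thresholds,
) -> bool:
    """Candidate nonsense-mediated decay.

    True iff the consequence is loss-of-function and the gene is not
    expressed in the sample or expressed below ``nmd_ratio`` times the
    tissue reference.  Genes missing from either TPM table never qualify.
    """
    if ann.consequence not in thresholds.lof_consequences:
        return False
    if isinstance(assess.sample_tpm, NoExpression) or isinstance(
        assess.reference_tpm, NoExpression
    ):
        return False
    if assess.sample_category == "not_expressed":
        return True
    return assess.sample_tpm < thresholds.nmd_ratio * assess.reference_tpm


def infer_gof(
    ann: VariantAnnotation,
    assess: ExpressionAssessment,
    thresholds: Thresholds,
) -> bool:
    """Candidate gain-of-function.

    True iff the variant's location and consequence are allowed, the sample
    expresses the gene medium or high, and the reference either does not
    express it or lies more than ``gof_fold`` below the sample.
    """
    if ann.location in thresholds.gof_excluded_locations:
        return False
    if ann.consequence in thresholds.gof_excluded_consequences:
        return False
    if isinstance(assess.sample_tpm, NoExpression) or isinstance(
        assess.reference_tpm, NoExpression
    ):
        return False
    if assess.sample_category not in ("medium", "high"):
        return False
    if assess.reference_category == "not_expressed":
        return True
    return assess.reference_tpm * thresholds.gof_fold < assess.sample_tpm
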