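"""Readers, writers and allele normalization.

All coordinates inside the package follow the ANNOVAR table convention:
1-based inclusive ``start``/``end`` with a ``-`` placeholder allele for
indels (the anchor base of the VCF representation is stripped).  VCF's
anchored representation is converted at the boundary by
:func:`normalize_vcf_allele` and :func:`denormalize_to_vcf`.

Standard formats are delegated to established libraries: VCF parsing to
:mod:`pysam`, tabular files to :mod:`pandas`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

logger = logging.getLogger("omixlink")

GAP = "-"
_NUCLEOTIDES = frozenset("ACGTN")

#: closed vocabulary for variant classes
VARIANT_CLASSES = ("SNV", "insertion", "deletion", "MNV")

#: closed vocabulary for genotype states
GENOTYPE_STATES = ("hom_ref", "het", "hom_alt", "other", "missing")

#: closed vocabulary for gene-location classes (ANNOVAR Func-style)
LOCATIONS = (
    "exonic",
    "exonic_ncRNA",
    "splicing",
    "UTR5",
    "UTR3",
    "intronic",
    "upstream",
    "downstream",
    "intergenic",
    "other",
)

#: closed vocabulary for exonic consequence classes (ANNOVAR ExonicFunc-style)
CONSEQUENCES = (
    "nonsynonymous_SNV",
    "synonymous_SNV",
    "stopgain",
    "stoploss",
    "startloss",
    "frameshift_insertion",
    "frameshift_deletion",
    "nonframeshift_insertion",
    "nonframeshift_deletion",
    "unknown",
    "none",
)

_LOCATION_SYNONYMS = {
    "exonic": "exonic",
    "ncrna_exonic": "exonic_ncRNA",
    "exonic ncrna": "exonic_ncRNA",
    "exonic_ncrna": "exonic_ncRNA",
    "ncrna exonic": "exonic_ncRNA",
    "splicing": "splicing",
    "ncrna_splicing": "splicing",
    "utr5": "UTR5",
    "5utr": "UTR5",
    "utr3": "UTR3",
    "3utr": "UTR3",
    "intronic": "intronic",
    "ncrna_intronic": "intronic",
    "upstream": "upstream",
    "downstream": "downstream",
    "upstream;downstream": "upstream",
    "intergenic": "intergenic",
}

_CONSEQUENCE_SYNONYMS = {
    "nonsynonymous snv": "nonsynonymous_SNV",
    "nonsynonymous_snv": "nonsynonymous_SNV",
    "synonymous snv": "synonymous_SNV",
    "synonymous_snv": "synonymous_SNV",
    "stopgain": "stopgain",
    "stopgain snv": "stopgain",
    "stoploss": "stoploss",
    "stoploss snv": "stoploss",
    "startloss": "startloss",
    "startgain": "unknown",
    "frameshift insertion": "frameshift_insertion",
    "frameshift_insertion": "frameshift_insertion",
    "frameshift deletion": "frameshift_deletion",
    "frameshift_deletion": "frameshift_deletion",
    "nonframeshift insertion": "nonframeshift_insertion",
    "nonframeshift_insertion": "nonframeshift_insertion",
    "nonframeshift deletion": "nonframeshift_deletion",
    "nonframeshift_deletion": "nonframeshift_deletion",
    "frameshift substitution": "unknown",
    "nonframeshift substitution": "unknown",
    "unknown": "unknown",
}

#: spellings of "absent" in annotation cells
_ABSENT_CELLS = {"", ".", "-", "–", "—", "na", "nan", "none"}


class VariantIOError(ValueError):
    """Fatal input problem (missing file, malformed mandatory column...)."""


class RejectedRecord(ValueError):
    """A single record that cannot be normalized (symbolic allele etc.)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class NormalizedVariant:
    """Assay-independent variant key in ANNOVAR-style coordinates.

    ``start``/``end`` are 1-based inclusive.  Insertions carry ``ref == "-"``
    and ``start == end`` (the base after which the sequence is inserted);
    deletions carry ``alt == "-"``.
    """

    chrom: str
    start: int
    end: int
    ref: str
    alt: str
    vclass: str = field(compare=False)

    def __post_init__(self) -> None:
        if self.vclass not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant class {self.vclass!r}")
        if self.vclass == "SNV":
            ok = (
                self.start == self.end
                and len(self.ref) == len(self.alt) == 1
                and self.ref != self.alt
                and GAP not in (self.ref, self.alt)
            )
        elif self.vclass == "insertion":
            ok = self.ref == GAP and self.end == self.start and len(self.alt) >= 1
        elif self.vclass == "deletion":
            ok = self.alt == GAP and self.end == self.start + len(self.ref) - 1
        else:  # MNV
            ok = (
                len(self.ref) == len(self.alt) > 1
                and self.end == self.start + len(self.ref) - 1
            )
        if not ok:
            raise ValueError(
                f"inconsistent {self.vclass} key "
                f"({self.chrom}:{self.start}-{self.end} {self.ref}>{self.alt})"
            )

    @property
    def key(self) -> tuple[str, int, int, str, str]:
        return (self.chrom, self.start, self.end, self.ref, self.alt)


@dataclass(frozen=True)
class GenotypeObservation:
    """One assay's genotype state and quality evidence at a variant."""

    variant: NormalizedVariant
    state: str
    depth: int | None
    gq: float | None
    source: str  # "DNA" | "RNA"

    def __post_init__(self) -> None:
        if self.state not in GENOTYPE_STATES:
            raise ValueError(f"unknown genotype state {self.state!r}")
        if self.source not in ("DNA", "RNA"):
            raise ValueError(f"source must be DNA or RNA, got {self.source!r}")


@dataclass(frozen=True)
class VariantAnnotation:
    """Gene, location class, consequence class, MAF and rsid for a variant."""

    variant: NormalizedVariant
    gene: str
    location: str
    consequence: str
    maf: float | None = None
    rsid: str | None = None

    def __post_init__(self) -> None:
        if self.location not in LOCATIONS:
            raise ValueError(f"unknown location {self.location!r}")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")


class NoExpression:
    """Sentinel for "gene absent from the expression table" (distinct from 0)."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "NO_EXPRESSION"


NO_EXPRESSION = NoExpression()


@dataclass
class ExpressionTable:
    """Gene symbol → TPM mapping with provenance label."""

    tpm: dict[str, float]
    label: str

    def lookup(self, gene: str) -> float | NoExpression:
        return self.tpm.get(gene, NO_EXPRESSION)


# ---------------------------------------------------------------------------
# allele normalization (VCF anchored -> ANNOVAR trimmed convention)
# ---------------------------------------------------------------------------

def _trim(ref: str, alt: str) -> tuple[str, str, int]:
    """Trim shared leading then trailing bases; return (ref, alt, left_offset).

    Leading bases (the VCF anchor) are stripped first: this is what yields
    the printed annotation convention for anchored indels (e.g. REF ``A`` /
    ALT ``AATA`` at p becomes an ``ATA`` insertion after p, not an ``AAT``
    insertion after p-1).
    """
    offset = 0
    while ref and alt and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        offset += 1
    while ref and alt and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    return ref, alt, offset


def normalize_vcf_allele(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    fasta: "pysam.FastaFile | None" = None,
) -> NormalizedVariant:
    """Convert one (CHROM, POS, REF, ALT) VCF call to the ANNOVAR-style key.

    Shared leading/trailing bases are trimmed before classification.  When a
    reference ``fasta`` is supplied, trimmed indels are additionally shifted
    to their smallest start within a repeat run (left alignment); without it
    the result is trim-only, which matches parsimony-aligned caller output.

    Raises :class:`RejectedRecord` for symbolic alleles, non-nucleotide
    characters, or ``ref == alt`` after trimming.
    """
    ref = str(ref).upper()
    alt = str(alt).upper()
    if not ref or not alt:
        raise RejectedRecord(f"{chrom}:{pos} empty allele")
    if alt.startswith("<") or any(c in alt for c in "[]"):
        raise RejectedRecord(f"{chrom}:{pos} symbolic/breakend allele {alt!r}")
    if alt == "*":
        raise RejectedRecord(f"{chrom}:{pos} spanning-deletion placeholder")
    if not (_NUCLEOTIDES.issuperset(ref) and _NUCLEOTIDES.issuperset(alt)):
        raise RejectedRecord(f"{chrom}:{pos} non-ACGTN allele {ref!r}>{alt!r}")

    chrom = harmonize_chrom(chrom)
    t_ref, t_alt, offset = _trim(ref, alt)
    if not t_ref and not t_alt:
        raise RejectedRecord(f"{chrom}:{pos} ref == alt after trimming")

    if t_ref and t_alt:
        start = pos + offset
        if len(t_ref) == 1 and len(t_alt) == 1:
            return NormalizedVariant(chrom, start, start, t_ref, t_alt, "SNV")
        if len(t_ref) == len(t_alt):
            return NormalizedVariant(
                chrom, start, start + len(t_ref) - 1, t_ref, t_alt, "MNV"
            )
        # unequal block substitution: represent as deletion+insertion is out of
        # scope; fold into MNV-like rejection
        raise RejectedRecord(
            f"{chrom}:{pos} unbalanced block substitution {ref!r}>{alt!r}"
        )
    if not t_ref:  # insertion after base (pos + offset - 1)
        anchor = pos + offset - 1
        seq = t_alt
        if fasta is not None:
            anchor, seq = _left_shift_insertion(fasta, chrom, anchor, seq)
        return NormalizedVariant(chrom, anchor, anchor, GAP, seq, "insertion")
    # deletion of t_ref starting at pos + offset
    start = pos + offset
    seq = t_ref
    if fasta is not None:
        start, seq = _left_shift_deletion(fasta, chrom, start, seq)
    return NormalizedVariant(chrom, start, start + len(seq) - 1, seq, GAP, "deletion")


def _left_shift_deletion(
    fasta: pysam.FastaFile, chrom: str, start: int, seq: str
) -> tuple[int, str]:
    # shift while the base before the deleted run equals its last base
    while start > 1:
        prev = fasta.fetch(chrom, start - 2, start - 1).upper()
        if prev != seq[-1]:
            break
        seq = prev + seq[:-1]
        start -= 1
    return start, seq


def _left_shift_insertion(
    fasta: pysam.FastaFile, chrom: str, anchor: int, seq: str
) -> tuple[int, str]:
    # anchor is the 1-based position of the base the insertion follows
    while anchor > 0:
        prev = fasta.fetch(chrom, anchor - 1, anchor).upper() if anchor >= 1 else ""
        if prev != seq[-1]:
            break
        seq = prev + seq[:-1]
        anchor -= 1
    return anchor, seq


def denormalize_to_vcf(
    variant: NormalizedVariant, anchor_base: str
) -> tuple[str, int, str, str]:
    """Re-anchor an ANNOVAR-style key into (chrom, pos, REF, ALT) VCF fields.

    ``anchor_base`` is the reference base immediately before the event (the
    base at ``start`` for insertions, at ``start - 1`` for deletions); it is
    ignored for SNV/MNV.
    """
    if variant.vclass in ("SNV", "MNV"):
        return (variant.chrom, variant.start, variant.ref, variant.alt)
    anchor_base = anchor_base.upper()
    if len(anchor_base) != 1 or anchor_base not in _NUCLEOTIDES:
        raise ValueError(f"invalid anchor base {anchor_base!r}")
    if variant.vclass == "insertion":
        return (variant.chrom, variant.start, anchor_base, anchor_base + variant.alt)
    return (
        variant.chrom,
        variant.start - 1,
        anchor_base + variant.ref,
        anchor_base,
    )


def harmonize_chrom(chrom: str) -> str:
    """Harmonize chromosome labels to the "chr"-prefixed GRCh38 style."""
    chrom = str(chrom).strip()
    if chrom.upper() in ("MT", "CHRMT"):
        return "chrM"
    if not chrom.lower().startswith("chr"):
        return "chr" + chrom
    return "chr" + chrom[3:]


_CHROM_RANK = {f"chr{i}": i for i in range(1, 23)}
_CHROM_RANK.update({"chrX": 23, "chrY": 24, "chrM": 25})


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    """Natural chromosome ordering: chr1..chr22, chrX, chrY, chrM, then others."""
    return (_CHROM_RANK.get(chrom, 99), chrom)


def variant_sort_key(v: NormalizedVariant) -> tuple:
    return (*chrom_sort_key(v.chrom), v.start, v.end, v.ref, v.alt)


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------

def _genotype_state(gt: Sequence[int | None] | None, allele_index: int) -> str:
    """Map a GT tuple to a state relative to one ALT allele (1-based index)."""
    if gt is None or len(gt) == 0 or all(a is None for a in gt):
        return "missing"
    if any(a is None for a in gt):
        return "other"
    alleles = set(gt)
    if alleles == {0}:
        return "hom_ref"
    if alleles == {allele_index}:
        return "hom_alt"
    if alleles == {0, allele_index}:
        return "het"
    return "other"


def read_vcf_observations(
    path: str | Path,
    source: str,
    pass_only: bool = True,
    fasta: pysam.FastaFile | None = None,
) -> list[GenotypeObservation]:
    """Read a single-sample VCF into per-ALT genotype observations.

    Multi-allelic records are split into one observation per ALT; a genotype
    carrying two distinct non-reference alleles maps to state ``other``.
    Records failing FILTER are skipped when ``pass_only`` (default).
    Unnormalizable records (symbolic alleles...) are counted and reported in
    the log, never fatal.
    """
    path = Path(path)
    if not path.exists():
        raise VariantIOError(f"VCF file not found: {path}")
    try:
        vcf = pysam.VariantFile(str(path))
    except Exception as exc:  # pragma: no cover - pysam message varies
        raise VariantIOError(f"cannot read VCF {path}: {exc}") from exc

    observations: list[GenotypeObservation] = []
    n_rejected = 0
    with vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if pass_only:
                filters = list(rec.filter.keys())
                if filters and filters != ["PASS"]:
                    continue
            if not rec.alts:
                continue
            if samples:
                fmt = rec.samples[samples[0]]
                gt = fmt.get("GT")
                depth = fmt.get("DP")
                gq = fmt.get("GQ")
            else:
                gt, depth, gq = None, None, None
            depth = int(depth) if depth is not None else None
            gq = float(gq) if gq is not None else None
            for i, alt in enumerate(rec.alts, start=1):
                try:
                    variant = normalize_vcf_allele(
                        rec.chrom, rec.pos, rec.ref, alt, fasta=fasta
                    )
                except RejectedRecord as exc:
                    n_rejected += 1
                    logger.warning("rejected record: %s", exc)
                    continue
                observations.append(
                    GenotypeObservation(
                        variant=variant,
                        state=_genotype_state(gt, i),
                        depth=depth,
                        gq=gq,
                        source=source,
                    )
                )
    if n_rejected:
        logger.warning("%s: %d records rejected during normalization", path, n_rejected)
    return observations


# ---------------------------------------------------------------------------
# annotation table reading (ANNOVAR-multianno dialect)
# ---------------------------------------------------------------------------

_COLUMN_ALIASES: Mapping[str, tuple[str, ...]] = {
    "chrom": ("chr", "chrom", "chromosome"),
    "start": ("start", "start base", "start_base"),
    "end": ("end", "end base", "end_base"),
    "ref": ("ref", "reference"),
    "alt": ("alt", "alternative"),
    "gene": ("gene", "gene name", "gene_name", "gene.refgene", "gene.refgenewithver"),
    "location": (
        "location",
        "gene location",
        "gene_location",
        "func",
        "func.refgene",
        "func.refgenewithver",
    ),
    "consequence": (
        "consequence",
        "variant consequence",
        "variant_consequence",
        "exonicfunc",
        "exonicfunc.refgene",
        "exonicfunc.refgenewithver",
    ),
    "rsid": ("rsid", "rs id", "rs_id", "avsnp150", "avsnp151", "snp id"),
}

_MAF_CANDIDATES = (
    "maf",
    "gnomad_genome_af",
    "gnomad_exome_af",
    "af",
    "1000g2015aug_all",
    "esp6500siv2_all",
)


def _find_column(columns: Iterable[str], aliases: tuple[str, ...]) -> str | None:
    lowered = {c.lower().strip(): c for c in columns}
    for alias in aliases:
        if alias in lowered:
            return lowered[alias]
    return None


def _absent(cell) -> bool:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return True
    return str(cell).strip().lower() in _ABSENT_CELLS


def map_location(raw: str) -> str:
    """Map a raw Func-style cell onto the closed location vocabulary."""
    if _absent(raw):
        return "other"
    key = str(raw).strip().lower()
    # multi-valued cells ("exonic;splicing"): first mapped value wins
    for part in key.replace(",", ";").split(";"):
        mapped = _LOCATION_SYNONYMS.get(part.strip())
        if mapped:
            return mapped
    logger.warning("unmapped gene location %r -> other", raw)
    return "other"


def map_consequence(raw: str, location: str) -> str:
    """Map a raw ExonicFunc-style cell onto the closed consequence vocabulary.

    Non-exonic locations always carry ``none`` (the "–" cells of annotation
    tables).
    """
    if location not in ("exonic", "exonic_ncRNA"):
        return "none"
    if _absent(raw):
        return "none"
    key = str(raw).strip().lower().replace("–", "-")
    mapped = _CONSEQUENCE_SYNONYMS.get(key)
    if mapped is None:
        logger.warning("unmapped consequence %r -> unknown", raw)
        return "unknown"
    return mapped


def read_annotation_table(
    path: str | Path, maf_column: str | None = None
) -> list[VariantAnnotation]:
    """Read an ANNOVAR-multianno-style TSV into annotations.

    The designated population-frequency column may be named with
    ``maf_column``; otherwise the first of the conventional candidates found
    in the header is used.  Row order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise VariantIOError(f"annotation table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols: dict[str, str] = {}
    for canonical, aliases in _COLUMN_ALIASES.items():
        found = _find_column(df.columns, aliases)
        if found is None and canonical != "rsid":
            raise VariantIOError(
                f"annotation table {path} is missing mandatory column "
                f"{canonical!r} (accepted names: {', '.join(aliases)})"
            )
        if found is not None:
            cols[canonical] = found

    if maf_column is not None:
        if maf_column not in df.columns:
            raise VariantIOError(
                f"designated MAF column {maf_column!r} not in {path}"
            )
        maf_col = maf_column
    else:
        maf_col = _find_column(df.columns, _MAF_CANDIDATES)

    annotations: list[VariantAnnotation] = []
    for _, row in df.iterrows():
        chrom = harmonize_chrom(row[cols["chrom"]])
        start = int(row[cols["start"]])
        end = int(row[cols["end"]])
        ref = str(row[cols["ref"]]).strip().upper().replace("–", GAP)
        alt = str(row[cols["alt"]]).strip().upper().replace("–", GAP)
        vclass = _classify_annovar_alleles(start, end, ref, alt)
        variant = NormalizedVariant(chrom, start, end, ref, alt, vclass)

        gene = str(row[cols["gene"]]).strip()
        # multi-gene strings: keep the first symbol
        for sep in (";", ","):
            if sep in gene:
                gene = gene.split(sep)[0].strip()
        location = map_location(row[cols["location"]])
        consequence = map_consequence(row[cols["consequence"]], location)

        maf: float | None = None
        if maf_col is not None and not _absent(row[maf_col]):
            try:
                maf = float(str(row[maf_col]).strip())
            except ValueError:
                logger.warning(
                    "unparseable MAF %r at %s:%d -> absent", row[maf_col], chrom, start
                )
        rsid = None
        if "rsid" in cols and not _absent(row[cols["rsid"]]):
            rsid = str(row[cols["rsid"]]).strip()
        annotations.append(
            VariantAnnotation(variant, gene, location, consequence, maf, rsid)
        )
    return annotations


def _classify_annovar_alleles(start: int, end: int, ref: str, alt: str) -> str:
    if ref == GAP:
        return "insertion"
    if alt == GAP:
        return "deletion"
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    return "MNV"


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------

def read_tpm_table(path: str | Path, label: str) -> ExpressionTable:
    """Read a two-column (gene symbol, TPM) TSV.

    Duplicate symbols collapse to the maximum TPM with a warning; negative
    TPM or an empty file is fatal.
    """
    path = Path(path)
    if not path.exists():
        raise VariantIOError(f"TPM table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={0: str}, header=0)
    if df.shape[0] == 0:
        raise VariantIOError(f"TPM table {path} is empty")
    if df.shape[1] < 2:
        raise VariantIOError(f"TPM table {path} needs (gene, TPM) columns")
    genes = df.iloc[:, 0].astype(str).str.strip()
    tpms = pd.to_numeric(df.iloc[:, 1], errors="raise")
    if (tpms < 0).any():
        bad = genes[tpms < 0].iloc[0]
        raise VariantIOError(f"negative TPM for gene {bad!r} in {path}")
    mapping: dict[str, float] = {}
    for gene, tpm in zip(genes, tpms):
        tpm = float(tpm)
        if gene in mapping:
            logger.warning(
                "duplicate gene %r in %s: keeping max(%g, %g)",
                gene, path, mapping[gene], tpm,
            )
            mapping[gene] = max(mapping[gene], tpm)
        else:
            mapping[gene] = tpm
    return ExpressionTable(tpm=mapping, label=label)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame as UTF-8 TSV with mandatory header row."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, encoding="utf-8", lineterminator="\n")
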