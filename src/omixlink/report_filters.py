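"""Reporting filters, category tables and per-sample summaries.

The four multiomics categories (ASE, RNAe, NMD, GoF) are assembled into
tabular reports: an unfiltered "all" table per category plus a filtered
table applying, for ASE/RNAe, the location exclusions (intronic, intergenic,
upstream, downstream), the synonymous-SNV exclusion and the rare-variant MAF
cut; for NMD/GoF the MAF cut alone (their defining rules already constrain
location/consequence).  A missing MAF is treated as rare and retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .expression_inference import ExpressionAssessment, Thresholds
from .joint_genotype import JointState
from .variant_io import NoExpression, VariantAnnotation, chrom_sort_key

CATEGORIES = ("ASE", "RNAe", "NMD", "GoF")

#: Table-5-style location columns for the GoF per-location summary
GOF_LOCATION_COLUMNS = (
    "upstream",
    "UTR5",
    "exonic",
    "exonic_ncRNA",
    "splicing",
    "UTR3",
    "downstream",
)

#: column order of the category tables (coordinate block mirrors the
#: annotation convention, then expression and evidence columns)
TABLE_COLUMNS = (
    "sample",
    "chr",
    "start",
    "end",
    "ref",
    "alt",
    "gene",
    "location",
    "consequence",
    "maf",
    "rsid",
    "tpm_reference",
    "tpm_sample",
    "joint_label",
    "dna_state",
    "rna_state",
    "dna_depth",
    "dna_gq",
    "rna_depth",
    "rna_gq",
)


@dataclass
class MultiomicsCall:
    """The fully joined record for one (sample, variant)."""

    sample: str
    joint: JointState
    annotation: VariantAnnotation
    assessment: ExpressionAssessment
    categories: frozenset[str] = frozenset()
    filter_flags: dict[str, dict[str, bool]] = field(default_factory=dict)


@dataclass
class SampleSummary:
    """Per-sample counts (Table-1 layout) plus GoF-by-location (Table-5)."""

    sample: str
    wes_total: int
    rnaseq_total: int
    ase: int
    rnae: int
    nmd: int
    gof: int
    ase_all: int
    rnae_all: int
    gof_by_location: dict[str, int]


def passes_maf_filter(maf: float | None, cutoff: float) -> bool:
    """Rare-variant filter: pass iff MAF is absent or strictly below cutoff."""
    if maf is None:
        return True
    return maf < cutoff


def passes_location_filter(location: str, category: str, thresholds: Thresholds) -> bool:
    """Per-category location filter.

    ASE/RNAe exclude intronic, intergenic, upstream and downstream sites;
    GoF excludes intronic and intergenic only (upstream/downstream GoF sites
    are reportable); NMD has no location filter — its loss-of-function
    consequence requirement already restricts it to coding impact.
    """
    if category in ("ASE", "RNAe"):
        return location not in thresholds.asernae_excluded_locations
    if category == "GoF":
        return location not in thresholds.gof_excluded_locations
    if category == "NMD":
        return True
    raise ValueError(f"unknown category {category!r}")


def passes_consequence_filter(consequence: str, category: str) -> bool:
    """ASE/RNAe exclude synonymous SNVs; NMD/GoF constrain consequence in
    their defining rules, so no further exclusion applies here."""
    if category in ("ASE", "RNAe"):
        return consequence != "synonymous_SNV"
    return True


def call_passes_filters(call: MultiomicsCall, category: str, thresholds: Thresholds) -> bool:
    return (
        passes_location_filter(call.annotation.location, category, thresholds)
        and passes_consequence_filter(call.annotation.consequence, category)
        and passes_maf_filter(call.annotation.maf, thresholds.maf_cutoff)
    )


def assign_categories(call: MultiomicsCall, thresholds: Thresholds) -> MultiomicsCall:
    """Set the category membership and per-category filter flags of a call.

    ASE/RNAe membership mirrors the joint label; NMD/GoF come from the
    expression inferences (already evaluated into ``call.categories`` by the
    pipeline).  Here we only record the filter flags.
    """
    flags = {}
    for category in CATEGORIES:
        flags[category] = {
            "location_pass": passes_location_filter(
                call.annotation.location, category, thresholds
            ),
            "consequence_pass": passes_consequence_filter(
                call.annotation.consequence, category
            ),
            "maf_pass": passes_maf_filter(call.annotation.maf, thresholds.maf_cutoff),
        }
    call.filter_flags = flags
    return call


def _fmt(value) -> str:
    if value is None or isinstance(value, NoExpression):
        return "-"
    if isinstance(value, float):
        return f"{value:g}"
    return str(value)


def _call_row(call: MultiomicsCall) -> dict:
    v = call.joint.variant
    return {
        "sample": call.sample,
        "chr": v.chrom,
        "start": v.start,
        "end": v.end,
        "ref": v.ref,
        "alt": v.alt,
        "gene": call.annotation.gene or "-",
        "location": call.annotation.location,
        "consequence": call.annotation.consequence,
        "maf": _fmt(call.annotation.maf),
        "rsid": _fmt(call.annotation.rsid),
        "tpm_reference": _fmt(call.assessment.reference_tpm),
        "tpm_sample": _fmt(call.assessment.sample_tpm),
        "joint_label": call.joint.label,
        "dna_state": call.joint.dna,
        "rna_state": call.joint.rna,
        "dna_depth": _fmt(call.joint.dna_depth),
        "dna_gq": _fmt(call.joint.dna_gq),
        "rna_depth": _fmt(call.joint.rna_depth),
        "rna_gq": _fmt(call.joint.rna_gq),
    }


def _sorted_frame(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=list(TABLE_COLUMNS))
    if len(df):
        df = df.sort_values(
            by=["sample", "chr", "start", "end", "ref", "alt"],
            key=lambda col: col.map(lambda c: "%02d_%s" % chrom_sort_key(c))
            if col.name == "chr"
            else col,
            kind="mergesort",
        ).reset_index(drop=True)
    return df


def build_category_tables(
    calls: list[MultiomicsCall], thresholds: Thresholds
) -> dict[str, pd.DataFrame]:
    """Assemble filtered and unfiltered tables for each category.

    Returns a dict with keys ``ase``, ``rnae``, ``nmd``, ``gof`` (filtered)
    and ``ase_all`` .. ``gof_all`` (unfiltered analogues, so the filtered
    tables are reproducible from artifacts alone).
    """
    tables: dict[str, pd.DataFrame] = {}
    for category in CATEGORIES:
        members = [c for c in calls if category in c.categories]
        key = category.lower()
        tables[f"{key}_all"] = _sorted_frame([_call_row(c) for c in members])
        kept = [c for c in members if call_passes_filters(c, category, thresholds)]
        tables[key] = _sorted_frame([_call_row(c) for c in kept])
    return tables


def summarize_sample(
    sample: str,
    calls: list[MultiomicsCall],
    thresholds: Thresholds,
    wes_total: int = 0,
    rnaseq_total: int = 0,
) -> SampleSummary:
    """Per-sample category counts from the filtered tables, plus the
    GoF-by-location tally and (labelled separately) pre-filter ASE/RNAe
    counts."""
    own = [c for c in calls if c.sample == sample]

    def _count(category: str, filtered: bool) -> int:
        members = [c for c in own if category in c.categories]
        if filtered:
            members = [c for c in members if call_passes_filters(c, category, thresholds)]
        return len(members)

    gof_calls = [
        c
        for c in own
        if "GoF" in c.categories and call_passes_filters(c, "GoF", thresholds)
    ]
    by_loc = {loc: 0 for loc in GOF_LOCATION_COLUMNS}
    for c in gof_calls:
        loc = c.annotation.location
        if loc not in by_loc:  # locations outside the canonical seven
            by_loc[loc] = 0
        by_loc[loc] += 1
    return SampleSummary(
        sample=sample,
        wes_total=wes_total,
        rnaseq_total=rnaseq_total,
        ase=_count("ASE", filtered=True),
        rnae=_count("RNAe", filtered=True),
        nmd=_count("NMD", filtered=True),
        gof=len(gof_calls),
        ase_all=_count("ASE", filtered=False),
        rnae_all=_count("RNAe", filtered=False),
        gof_by_location=by_loc,
    )


def summary_frame(summaries: list[SampleSummary]) -> pd.DataFrame:
    """Table-1-layout summary: raw assay totals, filtered category counts,
    and pre-filter ASE/RNAe counts labelled ``*_all``."""
    rows = [
        {
            "sample": s.sample,
            "wes_total": s.wes_total,
            "rnaseq_total": s.rnaseq_total,
            "ase": s.ase,
            "rnae": s.rnae,
            "nmd": s.nmd,
            "gof": s.gof,
            "ase_all": s.ase_all,
            "rnae_all": s.rnae_all,
        }
        for s in sorted(summaries, key=lambda s: s.sample)
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "sample",
            "wes_total",
            "rnaseq_total",
            "ase",
            "rnae",
            "nmd",
            "gof",
            "ase_all",
            "rnae_all",
        ],
    )


def gof_by_location_frame(summaries: list[SampleSummary]) -> pd.DataFrame:
    """Table-5-layout frame: one row per sample, the seven location columns,
    and a total column equal to the sample's GoF count."""
    rows = []
    for s in sorted(summaries, key=lambda s: s.sample):
        row = {"sample": s.sample}
        for loc in GOF_LOCATION_COLUMNS:
            row[loc] = s.gof_by_location.get(loc, 0)
        row["total"] = s.gof
        rows.append(row)
    return pd.DataFrame(rows, columns=["sample", *GOF_LOCATION_COLUMNS, "total"])
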