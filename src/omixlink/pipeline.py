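"""End-to-end orchestration: files in, category tables out.

This module glues the stages together (read → join → label → infer → filter
→ write) for one sample or a cohort manifest; every number it writes is
reproducible by calling the library operations directly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .expression_inference import Thresholds, assess_expression, infer_gof, infer_nmd
from .joint_genotype import JointState, join_observations, label_joint_states
from .report_filters import (
    MultiomicsCall,
    assign_categories,
    build_category_tables,
    gof_by_location_frame,
    summarize_sample,
    summary_frame,
)
from .variant_io import (
    ExpressionTable,
    VariantAnnotation,
    VariantIOError,
    read_annotation_table,
    read_tpm_table,
    read_vcf_observations,
    write_tsv,
)

logger = logging.getLogger("omixlink")


@dataclass
class SampleInputs:
    sample_id: str
    dna_vcf: Path
    rna_vcf: Path
    sample_tpm: Path


@dataclass
class RunConfig:
    """Validated inputs and options for one classify run."""

    samples: list[SampleInputs]
    annotation: Path
    reference_tpm: Path
    out_dir: Path
    thresholds: Thresholds = field(default_factory=Thresholds)
    pass_only: bool = True
    emit_joint: bool = False
    maf_column: str | None = None

    def validate(self) -> None:
        missing = []
        for s in self.samples:
            for p in (s.dna_vcf, s.rna_vcf, s.sample_tpm):
                if not Path(p).exists():
                    missing.append(str(p))
        for p in (self.annotation, self.reference_tpm):
            if not Path(p).exists():
                missing.append(str(p))
        if missing:
            raise VariantIOError("missing input file(s): " + ", ".join(missing))


def classify_sample(
    sample_id: str,
    dna_obs,
    rna_obs,
    annotations: list[VariantAnnotation],
    sample_tpm: ExpressionTable,
    reference_tpm: ExpressionTable,
    thresholds: Thresholds,
) -> tuple[list[MultiomicsCall], list[JointState]]:
    """Join one individual's observations and assign multiomics categories.

    ASE/RNAe membership follows the joint genotype label; NMD and GoF are
    inferred from annotation plus the sample-vs-reference TPM contrast and
    do not require any particular joint label (a fully decayed transcript
    may yield no RNA call at all).
    """
    ann_by_key = {a.variant.key: a for a in annotations}
    joint = label_joint_states(join_observations(dna_obs, rna_obs), thresholds)
    calls: list[MultiomicsCall] = []
    for js in joint:
        ann = ann_by_key.get(js.variant.key)
        if ann is None:
            ann = VariantAnnotation(js.variant, "", "other", "unknown", None, None)
        assess = assess_expression(ann.gene, sample_tpm, reference_tpm, thresholds)
        categories = set()
        if js.label == "ASE":
            categories.add("ASE")
        elif js.label == "RNAe":
            categories.add("RNAe")
        if infer_nmd(ann, assess, thresholds):
            categories.add("NMD")
        if infer_gof(ann, assess, thresholds):
            categories.add("GoF")
        call = MultiomicsCall(
            sample=sample_id,
            joint=js,
            annotation=ann,
            assessment=assess,
            categories=frozenset(categories),
        )
        calls.append(assign_categories(call, thresholds))
    return calls, joint


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _joint_frame(sample_id: str, joint: list[JointState]) -> pd.DataFrame:
    rows = []
    for js in joint:
        v = js.variant
        rows.append(
            {
                "sample": sample_id,
                "chr": v.chrom,
                "start": v.start,
                "end": v.end,
                "ref": v.ref,
                "alt": v.alt,
                "dna_state": js.dna,
                "rna_state": js.rna,
                "dna_depth": js.dna_depth if js.dna_depth is not None else "-",
                "dna_gq": js.dna_gq if js.dna_gq is not None else "-",
                "rna_depth": js.rna_depth if js.rna_depth is not None else "-",
                "rna_gq": js.rna_gq if js.rna_gq is not None else "-",
                "label": js.label,
            }
        )
    return pd.DataFrame(rows)


def run_classify(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run the full integration for every sample in the config and write all
    output tables into ``config.out_dir``.  Returns the tables by name."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    annotations = read_annotation_table(config.annotation, maf_column=config.maf_column)
    reference = read_tpm_table(config.reference_tpm, label="reference")

    all_calls: list[MultiomicsCall] = []
    totals_rows = []
    joint_frames = []
    checksums = {str(config.annotation): _sha256(config.annotation),
                 str(config.reference_tpm): _sha256(config.reference_tpm)}
    for s in config.samples:
        dna_obs = read_vcf_observations(s.dna_vcf, "DNA", pass_only=config.pass_only)
        rna_obs = read_vcf_observations(s.rna_vcf, "RNA", pass_only=config.pass_only)
        sample_tpm = read_tpm_table(s.sample_tpm, label=s.sample_id)
        calls, joint = classify_sample(
            s.sample_id,
            dna_obs,
            rna_obs,
            annotations,
            sample_tpm,
            reference,
            config.thresholds,
        )
        all_calls.extend(calls)
        totals_rows.append(
            {
                "sample": s.sample_id,
                "wes_total": len(dna_obs),
                "rnaseq_total": len(rna_obs),
            }
        )
        if config.emit_joint:
            joint_frames.append(_joint_frame(s.sample_id, joint))
        for p in (s.dna_vcf, s.rna_vcf, s.sample_tpm):
            checksums[str(p)] = _sha256(p)

    tables = build_category_tables(all_calls, config.thresholds)
    for name, df in tables.items():
        write_tsv(df, out / f"{name}.tsv")
    totals = pd.DataFrame(totals_rows, columns=["sample", "wes_total", "rnaseq_total"])
    totals = totals.sort_values("sample").reset_index(drop=True)
    write_tsv(totals, out / "assay_totals.tsv")
    if config.emit_joint:
        write_tsv(pd.concat(joint_frames, ignore_index=True), out / "joint.tsv")

    summaries = [
        summarize_sample(
            row["sample"],
            all_calls,
            config.thresholds,
            wes_total=row["wes_total"],
            rnaseq_total=row["rnaseq_total"],
        )
        for row in totals.to_dict("records")
    ]
    sum_df = summary_frame(summaries)
    gof_df = gof_by_location_frame(summaries)
    write_tsv(sum_df, out / "summary.tsv")
    write_tsv(gof_df, out / "gof_by_location.tsv")
    tables["summary"] = sum_df
    tables["gof_by_location"] = gof_df
    tables["assay_totals"] = totals

    manifest = {
        "tool": "omixlink",
        "version": __version__,
        "thresholds": {
            k: (sorted(v) if isinstance(v, frozenset) else v)
            for k, v in vars(config.thresholds).items()
        },
        "pass_only": config.pass_only,
        "samples": [s.sample_id for s in config.samples],
        "input_sha256": checksums,
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return tables


def summarize_from_dir(out_dir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rebuild summary.tsv and gof_by_location.tsv from the category tables
    already present in an output directory."""
    out = Path(out_dir)
    needed = ["ase.tsv", "rnae.tsv", "nmd.tsv", "gof.tsv"]
    missing = [n for n in needed if not (out / n).exists()]
    if missing:
        raise VariantIOError(
            f"missing category tables in {out}: " + ", ".join(missing)
        )
    frames = {
        name: pd.read_csv(out / f"{name}.tsv", sep="\t", dtype=str)
        for name in ("ase", "rnae", "nmd", "gof", "ase_all", "rnae_all")
        if (out / f"{name}.tsv").exists()
    }
    totals_path = out / "assay_totals.tsv"
    if totals_path.exists():
        totals = pd.read_csv(totals_path, sep="\t")
    else:
        totals = pd.DataFrame(columns=["sample", "wes_total", "rnaseq_total"])

    samples = sorted(
        set().union(*(set(df.get("sample", pd.Series(dtype=str))) for df in frames.values()))
        | set(totals["sample"].astype(str))
    )
    from .report_filters import GOF_LOCATION_COLUMNS, SampleSummary

    summaries = []
    totals_idx = totals.set_index(totals["sample"].astype(str)) if len(totals) else None

    def _n(df: pd.DataFrame | None, sample: str) -> int:
        if df is None or "sample" not in df.columns:
            return 0
        return int((df["sample"] == sample).sum())

    for sample in samples:
        gof_rows = frames["gof"][frames["gof"].get("sample", pd.Series(dtype=str)) == sample]
        by_loc = {loc: 0 for loc in GOF_LOCATION_COLUMNS}
        if len(gof_rows):
            for loc, count in gof_rows["location"].value_counts().items():
                by_loc[loc] = by_loc.get(loc, 0) + int(count)
        wes = int(totals_idx.loc[sample, "wes_total"]) if totals_idx is not None and sample in totals_idx.index else 0
        rna = int(totals_idx.loc[sample, "rnaseq_total"]) if totals_idx is not None and sample in totals_idx.index else 0
        summaries.append(
            SampleSummary(
                sample=sample,
                wes_total=wes,
                rnaseq_total=rna,
                ase=_n(frames.get("ase"), sample),
                rnae=_n(frames.get("rnae"), sample),
                nmd=_n(frames.get("nmd"), sample),
                gof=_n(frames.get("gof"), sample),
                ase_all=_n(frames.get("ase_all"), sample),
                rnae_all=_n(frames.get("rnae_all"), sample),
                gof_by_location=by_loc,
            )
        )
    sum_df = summary_frame(summaries)
    gof_df = gof_by_location_frame(summaries)
    write_tsv(sum_df, out / "summary.tsv")
    write_tsv(gof_df, out / "gof_by_location.tsv")
    return sum_df, gof_df


def load_manifest(path: str | Path) -> tuple[list[SampleInputs], Path, Path]:
    """Read a simulate-produced manifest.json into classify inputs."""
    path = Path(path)
    if not path.exists():
        raise VariantIOError(f"manifest not found: {path}")
    data = json.loads(path.read_text())
    base = path.parent
    samples = [
        SampleInputs(
            sample_id=s["sample_id"],
            dna_vcf=base / s["dna_vcf"],
            rna_vcf=base / s["rna_vcf"],
            sample_tpm=base / s["sample_tpm"],
        )
        for s in data["samples"]
    ]
    return samples, base / data["annotation"], base / data["reference_tpm"]
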