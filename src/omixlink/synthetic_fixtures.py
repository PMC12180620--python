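"""Seeded synthetic paired-cohort generator with a truth ledger.

Emulates, at the variant-call level, the structure of a small paired
WES/RNA-seq cohort: per-sample DNA and RNA VCFs on a toy reference, an
annotation table in the ANNOVAR-multianno dialect, per-sample TPM tables and
a shared tissue-reference TPM table.  Injected events (ASE, RNAe, NMD, GoF)
and decoys that each violate exactly one reporting condition are recorded in
a truth ledger so recovery can be scored exactly.  No reads are simulated —
the generator starts where variant calling ends.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression_inference import Thresholds
from .variant_io import GAP, normalize_vcf_allele

_BASES = "ACGT"

#: default location cycle for injected GoF sites
_GOF_LOCATION_CYCLE = (
    "UTR3",
    "UTR5",
    "exonic",
    "exonic_ncRNA",
    "upstream",
    "downstream",
    "splicing",
)

_NMD_CONSEQUENCE_CYCLE = ("stopgain", "startloss", "frameshift_deletion")

ROLES = (
    "ase",
    "rnae",
    "nmd",
    "gof",
    "decoy_concordant",
    "decoy_discordant",
    "decoy_high_maf",
    "decoy_synonymous",
    "decoy_intronic",
    "neutral",
)


@dataclass
class SampleFixtureSpec:
    """Injection plan for one synthetic individual."""

    sample_id: str
    n_sites: int = 60
    n_ase: int = 5
    n_rnae: int = 5
    n_nmd: int = 4
    n_gof: int = 5
    n_decoy_concordant: int = 8
    n_decoy_discordant: int = 3
    n_decoy_high_maf: int = 3
    n_decoy_synonymous: int = 2
    n_decoy_intronic: int = 2
    gof_locations: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.gof_locations is not None:
            self.gof_locations = tuple(self.gof_locations)
            self.n_gof = len(self.gof_locations)
        injected = (
            self.n_ase
            + self.n_rnae
            + self.n_nmd
            + self.n_gof
            + self.n_decoy_concordant
            + self.n_decoy_discordant
            + self.n_decoy_high_maf
            + self.n_decoy_synonymous
            + self.n_decoy_intronic
        )
        if injected > self.n_sites:
            raise ValueError(
                f"{self.sample_id}: {injected} injected sites exceed n_sites={self.n_sites}"
            )

    def roles(self) -> list[str]:
        counts = [
            ("ase", self.n_ase),
            ("rnae", self.n_rnae),
            ("nmd", self.n_nmd),
            ("gof", self.n_gof),
            ("decoy_concordant", self.n_decoy_concordant),
            ("decoy_discordant", self.n_decoy_discordant),
            ("decoy_high_maf", self.n_decoy_high_maf),
            ("decoy_synonymous", self.n_decoy_synonymous),
            ("decoy_intronic", self.n_decoy_intronic),
        ]
        roles = [role for role, n in counts for _ in range(n)]
        roles += ["neutral"] * (self.n_sites - len(roles))
        return roles


@dataclass
class FixtureConfig:
    """Cohort-level generator parameters; the seed fully determines outputs."""

    samples: list[SampleFixtureSpec]
    seed: int = 0
    genotype_error_rate: float = 0.0
    depth_mean: float = 60.0
    gq_low: int = 60
    gq_high: int = 99
    tpm_log_mean: float = 3.0
    tpm_log_sigma: float = 2.0
    contig_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 9000, "chr2": 9000, "chr3": 9000}
    )
    thresholds: Thresholds = field(default_factory=Thresholds)

    @classmethod
    def uniform(cls, n_samples: int = 2, seed: int = 0, **spec_kwargs) -> "FixtureConfig":
        samples = [
            SampleFixtureSpec(sample_id=f"SYN{i + 1:03d}", **spec_kwargs)
            for i in range(n_samples)
        ]
        return cls(samples=samples, seed=seed)


@dataclass(frozen=True)
class TruthRecord:
    sample: str
    chrom: str
    start: int
    end: int
    ref: str
    alt: str
    role: str
    expected_label: str
    expected_categories: tuple[str, ...]
    expected_filter_fate: str


# role -> (DNA state, RNA state, expected joint label)
_ROLE_GENOTYPES = {
    "ase": ("het", "hom_alt", "ASE"),
    "rnae": ("hom_alt", "het", "RNAe"),
    "nmd": ("het", "het", "concordant"),
    "gof": ("het", "het", "concordant"),
    "decoy_concordant": ("het", "het", "concordant"),
    "decoy_discordant": ("het", "hom_ref", "discordant_other"),
    "decoy_high_maf": ("het", "hom_alt", "ASE"),
    "decoy_synonymous": ("het", "hom_alt", "ASE"),
    "decoy_intronic": ("het", "hom_alt", "ASE"),
    "neutral": ("het", "het", "concordant"),
}

_GT_STRING = {"hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1"}


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_BASES), size=length))


def _write_fasta(path: Path, contigs: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def _write_vcf(path: Path, contigs: dict[str, str], records: list[dict], sample: str) -> None:
    lines = ["##fileformat=VCFv4.2", "##source=omixlink-synthetic"]
    for name, seq in contigs.items():
        lines.append(f"##contig=<ID={name},length={len(seq)}>")
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample,
    ]
    for rec in sorted(records, key=lambda r: (r["chrom"], r["pos"])):
        lines.append(
            "\t".join(
                [
                    rec["chrom"],
                    str(rec["pos"]),
                    ".",
                    rec["ref"],
                    rec["alt"],
                    "50",
                    "PASS",
                    ".",
                    "GT:DP:GQ",
                    f"{rec['gt']}:{rec['dp']}:{rec['gq']}",
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")


@dataclass
class _Site:
    sample: str
    role: str
    chrom: str
    start: int
    end: int
    ref: str
    alt: str
    vclass: str
    vcf_pos: int
    vcf_ref: str
    vcf_alt: str
    gene: str
    location: str
    consequence: str
    maf: float | None
    rsid: str | None
    dna_state: str
    rna_state: str


def _make_variant(
    rng: np.random.Generator,
    contigs: dict[str, str],
    chrom: str,
    start: int,
    want_indel: bool,
) -> tuple[int, int, str, str, str, int, str, str]:
    """Return (start, end, ref, alt, vclass, vcf_pos, vcf_ref, vcf_alt)."""
    seq = contigs[chrom]
    if not want_indel:
        ref = seq[start - 1]
        alt = rng.choice([b for b in _BASES if b != ref])
        return start, start, ref, str(alt), "SNV", start, ref, str(alt)
    if rng.random() < 0.5:  # deletion of 1-3 bases starting at `start`
        dlen = int(rng.integers(1, 4))
        ref = seq[start - 1 : start - 1 + dlen]
        anchor = seq[start - 2]
        pos, vref, valt = start - 1, anchor + ref, anchor
        return start, start + dlen - 1, ref, GAP, "deletion", pos, vref, valt
    ins = _random_seq(rng, int(rng.integers(1, 4)))
    anchor = seq[start - 1]
    return start, start, GAP, ins, "insertion", start, anchor, anchor + ins


def _site_annotation(
    rng: np.random.Generator, role: str, vclass: str, gof_location: str | None, nmd_index: int
) -> tuple[str, str, float | None]:
    """(location, consequence, maf) for one injected site."""
    rare = lambda: (None if rng.random() < 0.3 else round(float(rng.uniform(0.0001, 0.009)), 5))
    nonsyn = {
        "SNV": "nonsynonymous_SNV",
        "deletion": "nonframeshift_deletion",
        "insertion": "nonframeshift_insertion",
        "MNV": "unknown",
    }[vclass]
    if role in ("ase", "rnae", "decoy_concordant", "decoy_discordant", "neutral"):
        return "exonic", nonsyn, rare()
    if role == "decoy_high_maf":
        return "exonic", nonsyn, round(float(rng.uniform(0.011, 0.3)), 5)
    if role == "decoy_synonymous":
        return "exonic", "synonymous_SNV", rare()
    if role == "decoy_intronic":
        return "intronic", "none", rare()
    if role == "nmd":
        consequence = _NMD_CONSEQUENCE_CYCLE[nmd_index % len(_NMD_CONSEQUENCE_CYCLE)]
        if consequence == "frameshift_deletion" and vclass != "deletion":
            consequence = "stopgain"
        return "exonic", consequence, rare()
    if role == "gof":
        location = gof_location or "UTR3"
        consequence = nonsyn if location == "exonic" else "none"
        return location, consequence, rare()
    raise ValueError(role)


def _expected(role: str, maf: float | None, thresholds: Thresholds) -> tuple[tuple[str, ...], str]:
    """(expected categories, expected filter fate) at zero noise."""
    if role == "ase":
        return ("ASE",), "pass"
    if role == "rnae":
        return ("RNAe",), "pass"
    if role == "nmd":
        return ("NMD",), "pass"
    if role == "gof":
        return ("GoF",), "pass"
    if role == "decoy_high_maf":
        fate = "fail_maf" if maf is not None and maf >= thresholds.maf_cutoff else "pass"
        return ("ASE",), fate
    if role == "decoy_synonymous":
        return ("ASE",), "fail_consequence"
    if role == "decoy_intronic":
        return ("ASE",), "fail_location"
    return (), "-"


def generate_cohort_fixture(config: FixtureConfig, out_dir: str | Path) -> dict:
    """Write a full synthetic cohort into ``out_dir``.

    Produces, deterministically under ``config.seed``: ``reference.fa``,
    per-sample ``dna_<id>.vcf`` / ``rna_<id>.vcf`` / ``tpm_<id>.tsv``,
    ``annotation.tsv``, ``reference_tpm.tsv``, ``truth_ledger.tsv`` and
    ``manifest.json``.  Returns the parsed manifest dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    th = config.thresholds

    contigs = {
        name: _random_seq(rng, length) for name, length in config.contig_lengths.items()
    }
    _write_fasta(out / "reference.fa", contigs)

    gene_counter = 0
    reference_tpm: dict[str, float] = {}
    sites_by_sample: dict[str, list[_Site]] = {}
    sample_tpm: dict[str, dict[str, float]] = {}
    ledger_rows: list[TruthRecord] = []

    contig_names = list(contigs)
    for si, spec in enumerate(config.samples):
        roles = spec.roles()
        n = len(roles)
        # deterministic evenly spaced positions, ≥ 20 bp apart, offset per
        # sample so no two individuals share a variant key
        per_contig = -(-n // len(contig_names))
        positions = []
        for ci, cname in enumerate(contig_names):
            length = len(contigs[cname])
            step = max(20, 4 * len(config.samples) + 8,
                       (length - 200) // max(per_contig, 1))
            for k in range(per_contig):
                pos = 100 + k * step + 4 * si
                if pos < length - 10:
                    positions.append((cname, pos))
        positions = positions[:n]

        sites: list[_Site] = []
        tpms: dict[str, float] = {}
        nmd_i = 0
        gof_i = 0
        for role, (chrom, base_pos) in zip(roles, positions):
            want_indel = role in ("ase", "neutral") and rng.random() < 0.2
            if role == "nmd" and _NMD_CONSEQUENCE_CYCLE[
                nmd_i % len(_NMD_CONSEQUENCE_CYCLE)
            ] == "frameshift_deletion":
                want_indel = True
            start, end, ref, alt, vclass, vpos, vref, valt = _make_variant(
                rng, contigs, chrom, base_pos, want_indel
            )
            gof_location = None
            if role == "gof":
                cycle = spec.gof_locations or _GOF_LOCATION_CYCLE
                gof_location = cycle[gof_i % len(cycle)]
                gof_i += 1
                if gof_location == "exonic" and vclass != "SNV":
                    # keep exonic GoF sites as SNVs so the consequence is a
                    # nonsynonymous SNV, never a frameshift
                    start, end, ref, alt, vclass, vpos, vref, valt = _make_variant(
                        rng, contigs, chrom, base_pos, want_indel=False
                    )
            # derive the annotation key by normalizing the VCF representation
            # so both sides of the join agree even in repeat contexts
            nv = normalize_vcf_allele(chrom, vpos, vref, valt)
            start, end, ref, alt, vclass = nv.start, nv.end, nv.ref, nv.alt, nv.vclass
            location, consequence, maf = _site_annotation(
                rng, role, vclass, gof_location, nmd_i
            )
            if role == "nmd":
                nmd_i += 1
            gene_counter += 1
            gene = f"G{gene_counter:05d}"
            dna_state, rna_state, _ = _ROLE_GENOTYPES[role]

            # engineered TPM contrast
            if role == "nmd":
                ref_tpm = float(max(20.0, rng.lognormal(config.tpm_log_mean, 1.0)))
                if rng.random() < 0.3:
                    s_tpm = 0.0
                else:
                    s_tpm = ref_tpm * th.nmd_ratio * float(rng.uniform(0.05, 0.8))
            elif role == "gof":
                s_tpm = float(rng.uniform(1.5 * th.tpm_low_upper, 5.0 * th.tpm_medium_upper))
                if rng.random() < 0.5:
                    ref_tpm = float(rng.uniform(0.0, 0.9 * th.tpm_not_expressed))
                else:
                    ref_tpm = s_tpm * float(rng.uniform(0.1, 0.5)) / th.gof_fold
            else:
                ref_tpm = float(rng.lognormal(config.tpm_log_mean, config.tpm_log_sigma))
                s_tpm = ref_tpm
            reference_tpm[gene] = round(ref_tpm, 3)
            tpms[gene] = round(s_tpm, 3)

            rsid = f"rs{int(rng.integers(10**6, 10**8))}" if rng.random() < 0.7 else None
            sites.append(
                _Site(
                    sample=spec.sample_id,
                    role=role,
                    chrom=chrom,
                    start=start,
                    end=end,
                    ref=ref,
                    alt=alt,
                    vclass=vclass,
                    vcf_pos=vpos,
                    vcf_ref=vref,
                    vcf_alt=valt,
                    gene=gene,
                    location=location,
                    consequence=consequence,
                    maf=maf,
                    rsid=rsid,
                    dna_state=dna_state,
                    rna_state=rna_state,
                )
            )
        # RNA genotype noise
        for site in sites:
            if config.genotype_error_rate > 0 and rng.random() < config.genotype_error_rate:
                choices = [s for s in ("hom_ref", "het", "hom_alt") if s != site.rna_state]
                site.rna_state = str(rng.choice(choices))
        sites_by_sample[spec.sample_id] = sites
        sample_tpm[spec.sample_id] = tpms
        for site in sites:
            categories, fate = _expected(site.role, site.maf, th)
            ledger_rows.append(
                TruthRecord(
                    sample=site.sample,
                    chrom=site.chrom,
                    start=site.start,
                    end=site.end,
                    ref=site.ref,
                    alt=site.alt,
                    role=site.role,
                    expected_label=_ROLE_GENOTYPES[site.role][2],
                    expected_categories=categories,
                    expected_filter_fate=fate,
                )
            )

    # ---- write per-sample files -----------------------------------------
    manifest_samples = []
    for spec in config.samples:
        sites = sites_by_sample[spec.sample_id]
        dna_records, rna_records = [], []
        for site in sites:
            dp = int(max(30, rng.poisson(config.depth_mean)))
            gq = int(rng.integers(config.gq_low, config.gq_high + 1))
            dna_records.append(
                {
                    "chrom": site.chrom,
                    "pos": site.vcf_pos,
                    "ref": site.vcf_ref,
                    "alt": site.vcf_alt,
                    "gt": _GT_STRING[site.dna_state],
                    "dp": dp,
                    "gq": gq,
                }
            )
            dp_r = int(max(30, rng.poisson(config.depth_mean)))
            gq_r = int(rng.integers(config.gq_low, config.gq_high + 1))
            rna_records.append(
                {
                    "chrom": site.chrom,
                    "pos": site.vcf_pos,
                    "ref": site.vcf_ref,
                    "alt": site.vcf_alt,
                    "gt": _GT_STRING[site.rna_state],
                    "dp": dp_r,
                    "gq": gq_r,
                }
            )
        dna_path = out / f"dna_{spec.sample_id}.vcf"
        rna_path = out / f"rna_{spec.sample_id}.vcf"
        _write_vcf(dna_path, contigs, dna_records, spec.sample_id)
        _write_vcf(rna_path, contigs, rna_records, spec.sample_id)
        tpm_path = out / f"tpm_{spec.sample_id}.tsv"
        tpm_df = pd.DataFrame(
            sorted(sample_tpm[spec.sample_id].items()), columns=["gene", "tpm"]
        )
        tpm_df.to_csv(tpm_path, sep="\t", index=False, lineterminator="\n")
        manifest_samples.append(
            {
                "sample_id": spec.sample_id,
                "dna_vcf": dna_path.name,
                "rna_vcf": rna_path.name,
                "sample_tpm": tpm_path.name,
            }
        )

    # ---- cohort-level tables --------------------------------------------
    ann_rows = []
    for spec in config.samples:
        for site in sites_by_sample[spec.sample_id]:
            ann_rows.append(
                {
                    "chr": site.chrom,
                    "start": site.start,
                    "end": site.end,
                    "ref": site.ref,
                    "alt": site.alt,
                    "gene": site.gene,
                    "location": site.location.replace("exonic_ncRNA", "ncRNA_exonic"),
                    "consequence": site.consequence.replace("_", " ")
                    if site.consequence not in ("none", "unknown")
                    else ("." if site.consequence == "none" else "unknown"),
                    "maf": "." if site.maf is None else f"{site.maf:.5f}",
                    "rsid": site.rsid or ".",
                }
            )
    pd.DataFrame(ann_rows).to_csv(
        out / "annotation.tsv", sep="\t", index=False, lineterminator="\n"
    )
    pd.DataFrame(
        sorted(reference_tpm.items()), columns=["gene", "tpm"]
    ).to_csv(out / "reference_tpm.tsv", sep="\t", index=False, lineterminator="\n")

    ledger_df = pd.DataFrame(
        [
            {
                "sample": r.sample,
                "chr": r.chrom,
                "start": r.start,
                "end": r.end,
                "ref": r.ref,
                "alt": r.alt,
                "role": r.role,
                "expected_label": r.expected_label,
                "expected_categories": ",".join(r.expected_categories) or "-",
                "expected_filter_fate": r.expected_filter_fate,
            }
            for r in ledger_rows
        ]
    )
    ledger_df.to_csv(out / "truth_ledger.tsv", sep="\t", index=False, lineterminator="\n")

    manifest = {
        "samples": manifest_samples,
        "annotation": "annotation.tsv",
        "reference_tpm": "reference_tpm.tsv",
        "fasta": "reference.fa",
        "truth_ledger": "truth_ledger.tsv",
        "seed": config.seed,
        "files": sorted(
            p.name for p in out.iterdir() if p.is_file() and p.name != "manifest.json"
        ),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# worked-example fixture: the five published NMD variants + high-MAF decoys
# ---------------------------------------------------------------------------

#: (sample, chrom, pos, ref, alt, gene, consequence, maf, rsid, ref_tpm, sample_tpm)
PUBLISHED_NMD_VARIANTS = (
    ("AUT101", "chr12", 52317765, "G", "T", "KRT83", "stopgain", 0.0069, "rs2857667", 241.31, 0.00),
    ("AUT101", "chr16", 31428324, "A", "G", "COX6A2", "startloss", 0.0005, "rs200780049", 118.48, 0.00),
    ("AUT101", "chr15", 75293804, "C", "T", "GOLGA6D", "stopgain", 0.0013, "rs201679690", 141.83, 7.34),
    ("AUT101", "chr16", 67884906, "G", "A", "NRN1L", "startloss", 0.0002, "rs201174409", 14.67, 4.40),
    ("AUT104", "chr17", 41065564, "C", "T", "KRTAP2-4", "stopgain", 0.0031, "rs200049107", 106.60, 5.90),
)

#: decoy loss-of-function variants whose MAF fails the rare cut (one exactly
#: at the boundary to exercise the strict-< rule)
_PUBLISHED_NMD_DECOYS = (
    ("AUT101", "chr1", 1000050, "G", "T", "DECOYA", "stopgain", 0.02, "rs900000001", 200.0, 1.5),
    ("AUT101", "chr1", 1000150, "C", "A", "DECOYB", "stopgain", 0.01, "rs900000002", 150.0, 0.0),
    ("AUT104", "chr2", 2000050, "A", "G", "DECOYC", "startloss", 0.05, "rs900000003", 90.0, 2.0),
    ("AUT104", "chr2", 2000150, "T", "C", "DECOYD", "stopgain", 0.15, "rs900000004", 50.0, 3.0),
)


def nmd_worked_example_fixture(out_dir: str | Path) -> dict:
    """Write the published five-variant NMD worked example plus four decoy
    loss-of-function variants with common MAF, as classify-ready files.

    All nine variants are heterozygous in DNA.  RNA calls are present (het)
    only where the sample still expresses the gene above the not-expressed
    bound; fully silenced genes yield no RNA-side call, as a decayed
    transcript would.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = list(PUBLISHED_NMD_VARIANTS) + list(_PUBLISHED_NMD_DECOYS)
    samples = sorted({r[0] for r in rows})
    contig_order = ("chr1", "chr2", "chr12", "chr15", "chr16", "chr17")
    contigs = {c: 250_000_000 for c in contig_order}

    def _vcf_lines(records, sample):
        lines = ["##fileformat=VCFv4.2", "##source=omixlink-worked-example"]
        for c in contig_order:
            lines.append(f"##contig=<ID={c},length={contigs[c]}>")
        lines += [
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
            '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample,
        ]
        for chrom, pos, ref, alt, gt in sorted(
            records, key=lambda r: (contig_order.index(r[0]), r[1])
        ):
            lines.append(
                f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t60\tPASS\t.\tGT:DP:GQ\t{gt}:60:90"
            )
        return "\n".join(lines) + "\n"

    manifest_samples = []
    for sample in samples:
        own = [r for r in rows if r[0] == sample]
        dna = [(r[1], r[2], r[3], r[4], "0/1") for r in own]
        rna = [(r[1], r[2], r[3], r[4], "0/1") for r in own if r[10] >= 1.0]
        (out / f"dna_{sample}.vcf").write_text(_vcf_lines(dna, sample))
        (out / f"rna_{sample}.vcf").write_text(_vcf_lines(rna, sample))
        tpm = pd.DataFrame(
            sorted({r[5]: r[10] for r in own}.items()), columns=["gene", "tpm"]
        )
        tpm.to_csv(out / f"tpm_{sample}.tsv", sep="\t", index=False, lineterminator="\n")
        manifest_samples.append(
            {
                "sample_id": sample,
                "dna_vcf": f"dna_{sample}.vcf",
                "rna_vcf": f"rna_{sample}.vcf",
                "sample_tpm": f"tpm_{sample}.tsv",
            }
        )

    ann = pd.DataFrame(
        [
            {
                "chr": r[1],
                "start": r[2],
                "end": r[2],
                "ref": r[3],
                "alt": r[4],
                "gene": r[5],
                "location": "exonic",
                "consequence": r[6],
                "maf": f"{r[7]:.4f}",
                "rsid": r[8],
            }
            for r in rows
        ]
    )
    ann.to_csv(out / "annotation.tsv", sep="\t", index=False, lineterminator="\n")
    ref_tpm = pd.DataFrame(
        sorted({r[5]: r[9] for r in rows}.items()), columns=["gene", "tpm"]
    )
    ref_tpm.to_csv(out / "reference_tpm.tsv", sep="\t", index=False, lineterminator="\n")

    manifest = {
        "samples": manifest_samples,
        "annotation": "annotation.tsv",
        "reference_tpm": "reference_tpm.tsv",
        "n_published_nmd": len(PUBLISHED_NMD_VARIANTS),
        "files": sorted(
            p.name for p in out.iterdir() if p.is_file() and p.name != "manifest.json"
        ),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
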