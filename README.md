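# omixlink

Per-individual integration of DNA and RNA variant calls. `omixlink` joins a
patient's whole-exome (WES) variant calls with variant calls made on the same
patient's aligned RNA-seq reads ("cDNA" calls), classifies every matched site
by its joint genotype state, and contrasts gene-level expression (TPM) against
a tissue reference to assign each variant to up to four multiomics categories:

- **ASE** (allele-specific expression): heterozygous in DNA (`0/1`) but
  homozygous for the alternative allele in RNA (`1/1`) — only the alt allele
  is expressed.
- **RNAe** (RNA-editing event): homozygous-alternative in DNA but
  heterozygous in RNA — an RNA–DNA genotype difference at a DNA hom-alt site.
- **NMD** (nonsense-mediated decay candidate): a loss-of-function variant
  (stopgain, frameshift, startloss) in a gene not expressed in the sample or
  expressed below `nmd_ratio ×` the tissue-reference TPM.
- **GoF** (gain-of-function candidate): a non-intronic, non-intergenic
  variant that is neither a synonymous SNV nor a frameshift indel, in a gene
  expressed medium/high (TPM ≥ 10) by the sample but absent or lower in the
  reference.

It is aimed at small, deeply characterized cohorts (rare-disease or pilot
studies) where association methods are underpowered and a variant-centric,
per-individual readout is the useful unit of analysis.

## What it consumes and produces

Inputs (per sample): a DNA VCF and an RNA VCF (single-sample, VCF 4.x, plain
or bgzipped), a shared ANNOVAR-multianno-style annotation TSV (gene, location,
consequence, MAF, rsid), a two-column gene→TPM table for the sample, and one
for the tissue reference (e.g. GTEx skin, not sun-exposed). All variant keys
are normalized internally to the ANNOVAR convention — 1-based inclusive
start/end with `-` placeholder alleles, anchor bases stripped — so any VCF
spelling of the same indel joins correctly.

Outputs (all TSV): filtered and unfiltered per-category tables
(`ase.tsv`/`ase_all.tsv`, … `gof.tsv`/`gof_all.tsv`), a per-sample summary
(`summary.tsv`) with raw assay totals and category counts, a GoF-by-gene-
location breakdown (`gof_by_location.tsv`), and a `run_manifest.json`
recording thresholds and input checksums. Filtered ASE/RNAe tables exclude
intronic, intergenic, upstream and downstream sites, synonymous SNVs, and
variants with MAF ≥ 1% (absent MAF is treated as rare); NMD/GoF filtered
tables apply the MAF cut.

## Worked example

No sequencing data ships with the package; the synthetic generator creates a
fully classify-ready cohort. The `--nmd-example` fixture reproduces a published
worked example: five rare (MAF < 1%) heterozygous loss-of-function variants
in under-expressed genes, plus four decoy LoF variants with common MAF.

```sh
omixlink simulate --nmd-example --out fixture/
omixlink classify --manifest fixture/manifest.json --out results/
cut -f7,9,10,12,13 results/nmd.tsv
```

prints

```text
gene       consequence  maf     tpm_reference  tpm_sample
KRT83      stopgain     0.0069  241.31         0
GOLGA6D    stopgain     0.0013  141.83         7.34
COX6A2     startloss    0.0005  118.48         0
NRN1L      startloss    0.0002  14.67          4.4
KRTAP2-4   stopgain     0.0031  106.6          5.9
```

Exactly the five rare variants survive the NMD filter: each has a
loss-of-function consequence and sample TPM below half the reference
(KRT83 and COX6A2 are fully silenced, `tpm_sample = 0`). The four decoys
appear only in `nmd_all.tsv` because their MAF is ≥ 0.01 — one sits exactly
on the boundary, which the strict `<` cut excludes.

A randomized cohort with a truth ledger:

```sh
omixlink simulate --seed 1 --n-samples 2 --n-sites 60 --out cohort/
omixlink classify --manifest cohort/manifest.json --out cohort_results/
omixlink summarize --out cohort_results/
```

`summary.tsv` then lists, per sample, the raw per-assay variant counts and
the filtered ASE/RNAe/NMD/GoF counts (plus pre-filter ASE/RNAe counts,
labelled `*_all`), and `gof_by_location.tsv` breaks the GoF count down over
the seven gene-location classes; its row sums always equal the GoF totals.
`cohort/truth_ledger.tsv` records every injected event so recovery can be
scored — with zero genotype noise, precision and recall are 1.0 in every
category.

All thresholds (TPM bins, `nmd_ratio`, `gof_fold`, MAF cutoff, depth/GQ
gates, consequence/location sets) are configurable via a `key = value` file
(`omixlink config --defaults` prints one) or CLI flags.

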