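# Methods

## The integration model

`omixlink` operates at the *call* level: it assumes upstream read QC,
alignment, variant calling (e.g. Strelka2 with its call-time quality
filters) and annotation (ANNOVAR-style) have already produced per-sample DNA
and RNA variant calls plus gene-level TPM estimates. Its job is the
integration step: match the two call sets per individual, classify each
matched site's joint genotype state, and contrast expression against a
tissue reference.

The central assumption is that a genotype *difference* between a person's
DNA and the transcripts they express is informative: a DNA-heterozygous site
reading homozygous-alternative in RNA means only the alt allele is expressed
(ASE); a DNA hom-alt site reading heterozygous in RNA is treated as an
RNA-editing-like event (RNAe). Note this RNAe definition is the reverse of
canonical A-to-I editing detection, which looks for RNA variants at DNA
*hom-ref* sites; such sites are surfaced here as the QC label `rna_only`,
not as a multiomics category. Likewise, monoallelic expression of the
*reference* allele (DNA het, RNA hom-ref) is surfaced as `discordant_other`
for QC rather than called ASE, because ASE is defined strictly as
alternative-allele expression.

## Variant keys and allele normalization

All joining happens on an assay-independent key `(chrom, start, end, ref,
alt)` in the ANNOVAR table convention: 1-based inclusive coordinates with
`-` placeholder alleles for indels. VCF's anchored representation is
converted at the boundary by trimming shared *leading* bases first (the
anchor), then shared trailing bases. Leading-first trimming is what the
annotation convention prints — REF `A` / ALT `AATA` at p becomes an `ATA`
insertion *after p*, not an `AAT` insertion after p−1.

Trim-only normalization cannot disambiguate spellings that pad an indel with
following reference bases inside a repeat run; when a reference FASTA is
supplied, trimmed indels are additionally left-shifted to their smallest
start within the repeat (standard left alignment), which makes all padded
spellings of one indel collapse to one key. Without a FASTA the result is
trim-only, which matches the parsimony-aligned output of the callers this
tool ingests. Symbolic alleles (`<DEL>`, breakends), spanning-deletion
placeholders and non-ACGTN strings are rejected per record (counted and
logged), never fatal. Chromosome labels are harmonized to the
`chr`-prefixed style.

Multi-allelic records are split into per-ALT observations; a genotype
carrying two distinct non-reference alleles (e.g. `1/2`) maps to state
`other` for both ALTs and is thereby excluded from ASE/RNAe logic. Duplicate
keys within one assay are resolved by highest GQ, then highest depth, then
first seen.

## Joint genotype classification

The joint label is a total function over all 5 × 5 genotype-state pairs plus
an eligibility flag, with a fixed precedence:

1. one assay missing → `dna_only` / `rna_only` (both missing → `ineligible`);
2. evidence gate failed → `ineligible`;
3. `(het, hom_alt)` → `ASE`; `(hom_alt, het)` → `RNAe`; equal states →
   `concordant`; anything else → `discordant_other`.

Absence labels take precedence over the evidence gate so that one-assay
sites remain distinguishable in QC output; swapping the two assays maps
ASE ↔ RNAe and `dna_only` ↔ `rna_only` while fixing the symmetric labels.
The evidence gate requires both states non-missing and per-assay depth ≥
`min_depth` (default 10) and genotype quality ≥ `min_gq` (default 20; the
GQ default mirrors the common call-time GQ < 20 exclusion). Unknown
depth/GQ fails the gate unless `--lenient-evidence` is set.

## Expression categories, NMD and GoF

Gene-level TPM is binned into conventional log-decade categories with
inclusive lower bounds: `not_expressed` < 1 ≤ `low` < 10 ≤ `medium` < 100 ≤
`high`. The bins are a design choice (the qualitative terms they quantify —
"less or not expressed", "medium or high expression" — come unquantified)
and are fully configurable; the defaults are validated against the worked
NMD example, whose weakest case (14.67 reference vs 4.40 sample TPM) passes
the default `nmd_ratio`.

- **NMD**: consequence ∈ {stopgain, frameshift insertion/deletion,
  startloss} AND (sample category `not_expressed` OR sample TPM <
  `nmd_ratio` × reference TPM). `nmd_ratio` defaults to 0.5; setting it to
  1.0 recovers a plain "sample < reference" rule. startloss is included in
  the loss-of-function set because the worked example lists startloss rows.
- **GoF**: location ∉ {intronic, intergenic} AND consequence ∉
  {synonymous SNV, frameshift insertion/deletion} AND sample category ∈
  {medium, high} AND (reference category `not_expressed` OR reference TPM ×
  `gof_fold` < sample TPM). `gof_fold` defaults to 1.0 (strict
  reference < sample). The exclusion reading of the GoF grammar (exclude
  synonymous SNVs and frameshift indels, rather than require a
  nonsynonymous SNV) is deliberate: reported GoF breakdowns include
  UTR/upstream/downstream sites, which carry no exonic consequence at all,
  and the canonical worked GoF case is a 3' UTR deletion. "Below cutoff"
  for the reference is mapped to reference category `not_expressed`.

Genes absent from either TPM table yield the `no_data` sentinel (distinct
from 0) and never produce NMD or GoF calls. NMD and GoF require no
particular zygosity or joint label — a fully decayed transcript typically
yields *no* RNA-side call at all, so `dna_only` sites legitimately carry
NMD. Under the default sets and bins the two inferences are mutually
exclusive on any single variant (asserted by grid enumeration in the test
suite): GoF needs sample > reference at medium/high expression, NMD needs
sample below half the reference or below the not-expressed bound.

## Reporting filters

Filtered ASE/RNAe tables exclude intronic, intergenic, upstream and
downstream locations and synonymous SNVs, and apply the rare-variant cut.
GoF excludes only intronic/intergenic (upstream/downstream GoF sites are
reportable by design); NMD has no location filter since its consequence
requirement already restricts it. The MAF boundary is strict (`maf <
cutoff`, default 0.01): the source material states both "MAF > 1% excluded"
and "MAF lower than 1% retained", and the strict reading is followed, so a
variant at exactly 1% is excluded. A missing MAF is retained
(rare-until-proven-common). Which annotation column holds the population
frequency is configurable (`--maf-column`); by default the first of the
conventional candidates (`MAF`, gnomAD AFs, 1000G…) found in the header is
used. Unfiltered `*_all` tables are always written so the filtered tables
are reproducible from artifacts alone. Per-sample summaries report both
filtered and pre-filter ASE/RNAe counts, labelled, because published
cohort-level summaries are ambiguous about which mode they count.

## The synthetic cohort generator

The generator emulates the *structure* of a paired WES/RNA-seq cohort at
the variant-call level: a toy reference FASTA (three 9 kb contigs), one DNA
and one RNA VCF per sample with GT/DP/GQ, a shared annotation table, a TPM
table per sample and a shared reference TPM table, plus a truth ledger.
Injected roles: ASE (DNA 0/1, RNA 1/1), RNAe (1/1, 0/1), NMD (a LoF
consequence with sample TPM engineered below `nmd_ratio` × reference, or
fully silenced), GoF (allowed location/consequence, sample TPM in the
medium/high band, reference absent or below sample), and decoys that each
violate exactly one reporting condition (common MAF, synonymous consequence,
intronic location, discordant-but-not-ASE genotypes, plain concordant
sites). Default per-sample plan: 60 sites with 5/5/4/5 injected
ASE/RNAe/NMD/GoF and 18 decoys, depths Poisson around 60× and GQ 60–99 —
i.e. evidence comfortably above the gates, sized like a small exome panel
excerpt rather than a full exome. Reference TPMs are drawn log-normal
(μ = 3, σ = 2 on the natural-log scale) to span the dynamic range of a real
tissue reference; neutral genes reuse the reference value for the sample so
they can never trip the expression inferences. Positions are evenly spaced
and offset per sample so no two individuals share a variant key, and
annotation keys are derived by normalizing the written VCF representation so
both sides of the join agree even for indels in repeat context. A fifth of
ASE/neutral sites are indels so normalization is exercised end to end. An
optional RNA genotype-error rate corrupts RNA states for negative-control
tests; the seed fully determines every output byte.

What the generator does **not** emulate: read-level evidence (no FASTQ/BAM,
no allelic read counts), linkage between nearby sites, shared variants
between individuals, annotation errors, transcript-isoform structure, or
the covariance of expression noise — so perfect recovery on these fixtures
demonstrates the correctness of the integration logic, not robustness to
upstream calling artifacts in real data.

The `--nmd-example` fixture embeds verbatim a published five-variant NMD worked
example (gene, consequence, MAF, rsid, reference/sample TPM) plus four decoy
LoF variants with MAF ≥ 1% (one exactly at the boundary). RNA calls are
written only for genes the sample still expresses above the not-expressed
bound, matching the expectation that a silenced gene yields no RNA call.

## Numerical and interface choices

Outputs are UTF-8 TSVs with mandatory headers, sorted by sample, then
natural chromosome order, then start; floats are rendered with `%g`;
absent values print as `-`. Runs are byte-deterministic given identical
inputs and configuration (the run manifest excludes timestamps). Exit code
2 signals input validation failure, and validation runs before any output
is written, so failed runs leave no partial artifacts. Thresholds come from
a plain `key = value` file overridden by CLI flags. Problem sizes in the
test and acceptance fixtures (40–60 sites, 2 samples, 10–20 seeds) were
chosen as the smallest cohorts that exercise every role and filter branch
at least twice.

## Known limitations

- ASE/RNAe are genotype-state calls only; no read-level allelic-imbalance
  test (binomial/beta-binomial) is performed.
- NMD inference is gene-level TPM only — no 50-nt rule or exon-junction
  logic, no isoform resolution.
- Unequal-length block substitutions (neither pure indel nor MNV) are
  rejected rather than decomposed.
- No liftover: DNA and RNA calls must share one genome build.
- The flat-TSV output replaces any database persistence layer by design.
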