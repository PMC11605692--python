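# hapmethyl

Haplotype-resolved methylation analysis for phased tumor/normal long-read
data, runnable end to end on synthetic inputs:

- **methylation_core** — parse/validate per-CpG, per-strand, per-haplotype
  methylation calls; strand merge to consensus frequencies; phased fraction.
- **admr** — allelic DMR detection: coverage-weighted smoothing, a
  beta-binomial Wald test per CpG with chromosome-pooled dispersion,
  run-based segmentation, the |delta methylation| >= 0.15 filter, and
  copy-number context classification (HetDip / HetCNV / LOH).
- **filters** — the tumor-specific exclusion cascade: matched-normal
  overlap, partial methylation ([0.35, 0.65], >60% of >=5 CpGs at depth
  >=5) in more than 1% of a normal WGBS panel, and a 10 kb window around
  known imprinted regions.
- **annotation** — strand-aware promoters (-1500/+500 bp around the TSS),
  polyA flanks (+-500 bp), reciprocal-50% interval annotation
  (`bedtools intersect -e -f 0.5 -F 0.5` semantics), promoter recurrence
  tallies, and >25% average-methylation classification.
- **hrd** — genomic scar scores (LOH/TAI/LST), the microhomology deletion
  fraction, ln(x+1) + z-score feature standardization, the published
  six-feature logistic HRD score (high at >= 0.7), and HR-gene promoter
  methylation calls (>1 SD above the matched-normal mean).
- **ase** — gene-level allele-specific expression from phased allelic
  counts: beta-binomial/binomial testing, BH adjustment, the
  MAF > 0.65 / padj < 0.05 / TPM >= 1 rule, and cis/trans phase relation
  to allelic promoter methylation.
- **synthetic** — ground-truth-annotated simulators for every input:
  phased methylomes with planted tumor-specific/imprinted/random-ASM
  regions, a normal WGBS panel, allelic RNA counts, allele-specific CN
  segments, and deletions with planted breakpoint microhomology.

All coordinates are 0-based half-open. All file formats are plain TSV/BED.

## CLI

```sh
hapmethyl --seed 7 --outdir demo_out run-demo      # full pipeline on synthetic data
hapmethyl --outdir out simulate                     # write a synthetic fixture bundle
hapmethyl --outdir out admr-call out/tumor_calls.tsv
hapmethyl --outdir out admr-filter tumor.bed normal.bed panel.tsv imprinted.bed
hapmethyl --outdir out hrd-score features.tsv
hapmethyl --outdir out ase-classify snvs.tsv tpm.tsv
```

A YAML config (`--config run.yaml`) can override any simulation or
detection parameter; unknown keys are rejected and the resolved
configuration is written next to the outputs. `run-demo` emits every
intermediate table, a `MANIFEST.tsv`, and a `run_report.json` whose stage
counts always reconcile.

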