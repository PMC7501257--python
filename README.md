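# popref

Analyses for building a population genome reference from a sequenced
cohort, plus a synthetic-data generator so every stage runs and is tested
entirely offline:

- **`popref.synthetic`** — seeded generators for every input the pipeline
  consumes: a diploid cohort with block-wise LD (founder-pool copying:
  high r² within blocks, ~0 across), per-sample depth tracks with planted
  carrier regions, SV call sets, alignment coverage with planted gaps,
  phase annotations and ROH segments. Each generator writes a
  machine-readable truth sidecar used by recovery tests.
- **`popref.cohort`** — per-site allele statistics from genotype dosages,
  common-variant selection (MAF strictly > 5 %, ≥ 100 genotyped),
  population-specific filtering against panel AF tables (< 1 % or absent
  in every panel), novel-variant flagging, and the major-allele rule
  (ref wins exact ties).
- **`popref.ldproxy`** — dosage-correlation r², greedy per-trait GWAS
  tag-SNP selection (±1 Mb loci, replication = ≥ 2 study ids), proxy
  discovery (r² strictly > 0.8 within ±1 Mb), shared/only proxy
  comparison between two populations (percentages rounded half away from
  zero, exact fractions retained), and AF contrast labelling.
- **`popref.insertions`** — non-reference insertion-region calling from
  multi-sample per-base depth: maximal runs ≥ 500 bp where > 5 reads per
  base in ≥ 10 samples (an `--inclusive` flag switches to ≥ 5).
- **`popref.svcollapse`** — single-linkage collapsing of ≥ 1 bp-overlapping
  SV calls per (sample, type, contig) stratum; per-individual and cohort
  summaries.
- **`popref.assembly`** — uncovered-gap detection (coverage complement),
  patch-region selection (strictly > 800 kb, zero centromere overlap),
  patch extraction from an alternative assembly via alignment blocks
  (minus strand reverse-complemented), and base-level QV:
  −10·log₁₀(weighted homozygous differences / effective genome size).
- **`popref.phasing`** — phased-variant fractions (both all-variant and
  het-only denominators), single-phase-block gene fractions (< 100 kb,
  ≥ 2 het sites), and per-individual totals of ROH strictly > 5 Mb.

## CLI

```sh
popref simulate --seed 3 --out sim/              # all fixtures + truth files
popref afstats sim/cohort.vcf --out stats.tsv
popref popspec sim/cohort.vcf panel.tsv --out-prefix ps
popref proxy associations.tsv popA.vcf popB.vcf --r2-min 0.8 --out proxy.tsv
popref insertions sim/depth sim/contigs.bed --out-prefix ins
popref svcollapse sim/sv_calls.tsv --out-prefix sv
popref metaasm coverage.bed contigs.bed --centromeres-bed cen.bed --out-prefix meta
popref qv diffs.tsv --effective-size 2820489739
popref phasing sim/phase_annotations.tsv
popref roh sim/roh_segments.tsv --out roh.tsv
popref run-all --simulate --seed 5 --out run/    # end-to-end demo + summary.json
```

All interval files are 0-based half-open (BED/BedGraph convention); VCF
positions are 1-based. Every run is deterministic given its seed.

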