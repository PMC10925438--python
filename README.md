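# dmrpipe

A tested, reusable pipeline for WGBS + RNA-seq differential-methylation
analysis: per-CpG differential methylation calling against averaged
controls, rule-based DMR segmentation with region-level Mann–Whitney U
testing, genomic-element annotation, cross-tumor recurrence signatures,
and promoter-methylation × gene-expression integration. A synthetic-data
module generates methylomes, annotations, and expression counts with
planted ground truth so every stage can be scored against known answers.

## What it does

- **simulate** — synthetic genome (CpG positions, promoters/exons/
  introns/enhancers/repeats), control and tumor methylomes sharing a
  latent profile, planted hypo-/hypermethylated regions with per-tumor
  carrier schedules, and negative-binomial expression counts inversely
  coupled to promoter methylation. Emits Bismark-coverage-style TSVs,
  BED6 files, count/length matrices, and a machine-readable truth table.
- **profile** — ≥5× coverage filtering, common-CpG intersection,
  methylation binning (0–25 / 26–50 / 51–75 / 76–100 %), unweighted
  promoter means over the −1,500/+500 bp TSS window, pairwise Pearson
  matrices, and promoter-methylation × FPKM strata with Welch t-tests.
- **dmr** — control averaging (sites covered in *all* controls), DMC
  calling at ≥10 percentage-point change, segmentation of ≥3
  consecutive same-direction DMCs with inter-CpG gaps ≤100 bp, and a
  two-sided region-level MWU test (exact enumeration for small tie-free
  groups, tie-corrected normal approximation otherwise), retained at
  p ≤ 0.05. Optional BH-FDR.
- **annotate** — interval-index overlap queries with bedtools-intersect
  semantics (half-open, ≥1 bp, multi-hit per category; optional
  exclusive priority scheme).
- **de** — FPKM and a single-tumor-vs-controls negative-binomial
  exceedance test (median-of-ratios size factors, trended dispersion
  from controls). This is a deliberate, documented simplification of a
  full two-group NB fit, which is not identifiable with one tumor.
- **signature** — base-pair depth-merged recurrent DMRs across tumors
  (core methylation signature), all-tumor core expression signature, and
  integrated hypo-up / hyper-down gene lists (promoter DMR in ≥6/7
  tumors plus matching expression change).

Coordinates are 0-based half-open throughout; Bismark coverage files
(1-based inclusive) are converted on read/write. Gzip is transparent.

## CLI

```sh
dmrpipe simulate --seed 7 --out data/
dmrpipe dmr --tumor data/tumor_1.cov \
    --controls data/control_1.cov --controls data/control_2.cov \
    --controls data/control_3.cov --controls data/control_4.cov \
    --controls data/control_5.cov --out dmrs_t1.tsv
dmrpipe annotate --dmrs dmrs_t1.tsv \
    --features promoter=data/promoters.bed --features repeat=data/repeats.bed \
    --priority --out-prefix annot_t1
dmrpipe de --counts data/counts.tsv --lengths data/gene_lengths.tsv \
    --tumor tumor_1 --controls control_1,control_2,control_3,control_4,control_5 \
    --out de_t1.tsv
dmrpipe run --simulate --seed 7 --out run/     # full pipeline + manifest.json
```

Every subcommand accepts a YAML config (`--config`) with `simulation:`
and `pipeline:` sections; `--seed` overrides the file seed. `dmrpipe
run` writes a manifest (config snapshot, input digests, per-stage
counts, output paths) and is bit-for-bit reproducible for a given seed.

## Layout

```
src/dmrpipe/
  simulate.py    synthetic genome/methylome/expression generator + truth
  io.py          Bismark coverage, BED, bedGraph, DMR/counts/truth TSV
  profile.py     filtering, intersection, binning, promoter means, Pearson, strata
  dmr.py         control profile, DMC calling, segmentation, MWU, DMR calling
  annotate.py    interval index + element annotation/distribution
  expression.py  FPKM, size factors, NB exceedance DE, high-expression set
  signature.py   recurrent DMRs, core expression signature, integration
  pipeline.py    end-to-end orchestration + run manifest
  cli.py         click CLI (simulate/profile/dmr/annotate/de/signature/run)
tests/           unit + property tests; test_acceptance.py holds the criteria
scripts/acceptance.py
```
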