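# cyclepeaks

Analysis pipeline for cell-cycle-phase-specific transcription factor
binding sites. Given ChIP peak sets from interphase and mitosis, the
package partitions sites into three occupancy classes —
interphase-mitosis-common (IM), interphase-only (IO) and mitosis-only
(MO) — and characterizes each class by:

- genomic category relative to gene models (TSS region, promoter,
  downstream, 5'UTR, coding exon, intron, intergenic) with Fisher exact
  comparison of category fractions between classes;
- cross-species conservation through chain-file lift-over
  (observed/expected ratios per class);
- occurrence of a bipartite (two-module) binding motif via log-odds PWM
  scanning, and GC content;
- binding-intensity meta-profiles from bedGraph signal tracks;
- spatial statistics: nearest-same-class distances against a
  chromosome-preserving shuffled null, enrichment at topological /
  syntenic domain boundaries, and minimum-domain-number spacing of
  same-class boundaries against label-permutation nulls (two-sided
  Wilcoxon rank-sum on pooled permutation distributions).

A first-class synthetic data generator (`cyclepeaks.simulate`) produces
every input the pipeline consumes — genome FASTA, chrom.sizes, gene
models (GFF3), peak BEDs, domain BEDs, UCSC chain files, bedGraph tracks
and a per-site truth table — with controllable class composition,
clustering, motif planting, GC targets and per-species mappability, so
the full pipeline is testable offline.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the property-based acceptance criteria
(exact classification recovery, permutation-test type-I calibration,
planted-clustering detection, lift-over and spacing oracle equivalence,
Fisher enumeration agreement, motif/GC recovery, end-to-end determinism).

## CLI

```bash
# generate a synthetic input bundle
cyclepeaks simulate --seed 1 --out data/

# classify only
cyclepeaks classify --interphase data/peaks.interphase.bed \
    --mitosis data/peaks.mitosis.bed \
    --chrom-sizes data/genome.chrom.sizes --out out/

# full pipeline from a YAML config
cyclepeaks run-all --config config.yaml
```

Example config (synthetic mode):

```yaml
outdir: out
seed: 1
synthetic:
  seed: 1
  chromosomes: {c1: 2000000, c2: 1500000}
  n_sites: {IM: 40, IO: 60, MO: 35}
  tss_fraction: {IM: 0.3, IO: 0.25, MO: 0.1}
  motif_fraction: {IM: 0.6, IO: 0.5, MO: 0.3}
  conservation_prob: {IM: 0.7, IO: 0.4, MO: 0.1}
params:
  n_perm: 1000
```

File-input mode replaces `synthetic:` with an `inputs:` section
(`interphase`, `mitosis`, `chrom_sizes`, and per-stage `genes`, `fasta`,
`domains`, `chains: {species: path}`, `species_peaks`, `tracks`).
`run-all` writes per-stage TSV/BED/JSON outputs plus `report.json` /
`report.txt`; identical config and seeds give byte-identical reports.

Defaults follow the analysis conventions the pipeline reimplements:
TSS window 200 bp, promoter/downstream flank 2 kb, lift-over minimum
match 0.5, 1,000 permutations.

## Layout

| module | contents |
| --- | --- |
| `cyclepeaks.intervals` | interval/genome/peak-set model, BED and chrom.sizes I/O, nearest-anchor distance, chromosome-preserving shuffle |
| `cyclepeaks.classify` | IM/IO/MO partition and class proportions |
| `cyclepeaks.annotate` | gene models (GFF3/BED12), genomic categories, Fisher comparison, GC content |
| `cyclepeaks.conservation` | UCSC chain parsing, lift-over, observed/expected conservation |
| `cyclepeaks.motifs` | PWM scanning (JASPAR/MEME readers), two-part motif fractions |
| `cyclepeaks.tracks` | bedGraph step-function tracks, anchor meta-profiles |
| `cyclepeaks.spatial` | domains/boundaries, permutation tests, enrichment profiles |
| `cyclepeaks.simulate` | synthetic data generator and truth tables |
| `cyclepeaks.pipeline`, `cyclepeaks.cli` | orchestration, YAML config, CLI |
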