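# compmap

Competitive-mapping toolkit for detecting and excluding human DNA
contamination in ancient faunal sequencing datasets.

Reads sequenced from ancient animal remains are routinely contaminated
with modern human DNA. Mapping reads against a *concatenated* reference —
the target-species genome and the human genome merged into one FASTA —
lets an aligner attribute each read to the genome it fits best: reads
fitting both parts receive low mapping quality and are discarded, reads
confidently placed in the human part are contaminant, and reads placed in
the target part are kept for downstream analysis. `compmap` implements
everything around that idea:

- **refbuild** — build the concatenated reference plus a part manifest
  (TSV) that authoritatively attributes every sequence to its source
  genome.
- **classify** — assign every alignment record a read fate (TARGET /
  CONTAMINANT / AMBIGUOUS / UNMAPPED / TOO_SHORT; MAPQ strictly > 30 and
  length ≥ 30 bp by default), split per-part SAM outputs with original
  names restored, deduplicate by start+end+strand, and account for data
  loss genome-wide vs inside conserved regions.
- **pmd** — per-read post-mortem-damage likelihood-ratio scores
  (position-dependent C→T / G→A excess, quality-aware, geometric decay
  `D(z) = p(1-p)^(z-1) + c`), the per-sample PMD ratio (fraction of reads
  scoring > 5), and median read length.
- **conserved** — conserved-region calling by tiling one genome into
  overlapping 30 bp k-mers (step 1), mapping them uniquely into the other
  genome across both strands, and merging covered positions into a BED
  track; an alternate path ingests an externally aligned tile SAM with a
  MAPQ ≥ 30 filter.
- **simulate** — a deterministic synthetic-data generator: short damaged
  fragments from the target genome mixed with contaminant-genome
  fragments, with sequencing errors, truth tables and a truth SAM against
  the concatenated reference, so the whole pipeline is testable offline.
- **stats** — Wilcoxon rank-sum tests (exact for small untied samples,
  normal approximation with tie/continuity corrections otherwise), OLS
  r²/F fits, per-sample summary reports.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end property checks (oracle
equivalence of the damage score, contamination recovery on simulated
data, conserved-region caller vs a string-search oracle, determinism,
damage-rate calibration, exact Wilcoxon enumeration).

## CLI

```sh
# 1. build a concatenated reference
compmap build-ref --target elephant.fa --human hg.fa \
    -o concat.fa --manifest concat.parts.tsv

# 2. (align FASTQ to concat.fa with your aligner of choice), then split
compmap classify --bam competitive.bam --manifest concat.parts.tsv \
    --mq 30 --min-len 30 -o outdir/

# conserved regions between the two genomes (internal exact tile mapper)
compmap conserved --source hg.fa --dest elephant.fa -k 30 --step 1 \
    -o conserved.bed

# data-loss accounting before/after competitive mapping
compmap loss --original single_ref.bam --competitive outdir/target.sam \
    --bed conserved.bed -o loss.json

# damage scores + per-sample summaries
compmap pmd --bam outdir/target.sam --ref elephant.fa -o pmd.tsv
compmap stats --fates outdir/fate_counts.json --pmd pmd.tsv \
    --bam outdir/target.sam -o sample_stats.tsv
compmap compare --group-a groupA.tsv --group-b groupB.tsv --metric PMDR

# synthetic data with truth labels
compmap simulate --config sim.toml -o simdir/ --seed 42 --original-sam
```

A minimal simulation config (flat TOML):

```toml
target_genome = "target.fa"
contaminant_genome = "human.fa"
n_reads = 10000
contamination_fraction = 0.05
seed = 42
target_damage_p = 0.3
target_damage_c = 0.01
```

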