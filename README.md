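# arbamp

Toolkit for designing low-bias short arbitrary PCR primers, predicting their
amplicons on a genome in silico, and quantifying reduced-representation
sequencing efficiency — with a synthetic-data module so the whole pipeline is
testable offline.

## What it does

| Module | Purpose |
| --- | --- |
| `arbamp.primer_filters` | Enumerate all k-mers and apply the exclusion cascade: simple-sequence-repeat filter, functional-motif filter (JASPAR PFM or consensus lists, IUPAC-aware, both strands), cross-taxon frequency-grade concordance, string-based self-complementarity (primer-dimer) screen, and short-primer derivation by prefix. |
| `arbamp.genome_profile` | Count k-mer occurrences in FASTA genomes (forward strand, N-containing windows skipped), stratify counts into LOW/MID/HIGH frequency grades, and select k-mers whose grade agrees in strictly more than a threshold fraction of species. |
| `arbamp.amplicon_prediction` | Assemble full primer constructs (adapter + N-spacer + target), find exact (or Hamming-tolerant) priming sites on both strands, and enumerate all forward/reverse site pairs whose product length falls in a size window (default 500–2000 bp). |
| `arbamp.sequencing_eval` | Ingest samtools-depth-style TSVs; compute depth-stratified coverage fractions, read-count standardization, saturation curves, common bases across individuals, reduction curves, and a bounded nonlinear least-squares fit of `Y = C1 * a^x + C2`. |
| `arbamp.synthetic_data` | Seed-deterministic simulators: genomes with planted priming sites, amplicon truth tables, log-normally biased read sets, and multi-individual cohorts with independent per-locus dropout (closed-form expectation `L * p^x + core`). |

## CLI

The console script `arbamp` exposes five subcommands:

```bash
# primer design cascade -> candidate TSV with per-filter verdicts
arbamp design --k 10 --short-k 7 --motifs motifs.txt --profiles grades_dir/ \
    --threshold 0.8 --out candidates.tsv

# genome k-mer profile and frequency grades
arbamp profile --fasta genome.fasta --k 10 --species-id myspecies \
    --boundaries 100,1000 --out counts.tsv --grades-out grades.tsv

# in-silico PCR (cocktail TSV: name, adapter, spacer_len, target)
arbamp pcr --fasta genome.fasta --cocktail cocktail.tsv \
    --min-len 500 --max-len 2000 --out-bed amplicons.bed

# sequencing-efficiency report (depth TSVs are samtools-depth compatible)
arbamp evaluate --depth-dir depth/ --genome-index genome.fasta.fai \
    --min-depth 10 --replicates 20 --seed 1 --out report.json

# synthetic dataset with truth manifest (genome, truth TSV, reads, cohort)
arbamp simulate --length 200000 --cocktail cocktail.tsv --n-amplicons 50 \
    --n-reads 100000 --individuals 30 --retention 0.71 --seed 1 --outdir sim/
```

## Conventions

- Coordinates are 0-based half-open everywhere except depth tables, which use
  1-based positions (samtools convention); BED output is 0-based.
- All randomized operations take a seed and are bit-reproducible.
- Grade boundaries: count < 100 is LOW, 100–1000 (inclusive) is MID,
  \> 1000 is HIGH; both cut-offs are configurable.
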