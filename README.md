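# ampdel

Detection and quantification of CRISPR-Cas9-induced large deletions (LDs),
intermediate deletions, large insertions and small INDELs from amplicon
sequencing, plus the supporting assays used to genotype single-cell clones.

Two sequencing workflows are covered end to end:

- **Dual-UMI long-read amplicons** — patterned 18-nt UMI extraction from
  both read ends, UMI-pair binning with error-tolerant merging, PCR-chimera
  filtering, ≥3-read medoid/plurality consensus, anchor-chain alignment to
  the amplicon reference, and four-way outcome classification
  (small INDEL &lt;50 bp / intermediate deletion 50–200 bp / large deletion
  ≥200 bp / large insertion ≥50 bp, with combined insertion+deletion folded
  into the insertion group). Large deletions are clustered with ±10 bp
  size/start tolerance, labeled symmetric/upstream/downstream by the
  δ = |midpoint − cut|/size index (δ ≤ 0.05 symmetric), annotated with
  junction microhomology (MMEJ = pure deletions ≥3 bp), and inserted
  sequences are mapped against a user-supplied candidate set.
- **Long-amplicon paired-end short reads** — pair merging by ungapped
  overlap (≤600 bp merged length), cut-site-spanning read filtering,
  split/gapped-alignment LD read fractions, control-normalized coverage
  depletion profiles, and small-INDEL tabulation on unsplit reads.

Quantification utilities include Poisson-corrected ddPCR drop-off
copy-number genotyping, the three-assay clonal genotype decision table
(short-read NGS + gel shift + ddPCR), cohort summaries (LD allele
frequency, LD-carrying clones, total-knockout rate), LD-adjusted bulk
allele frequencies, and T50 kinetics (time to half of the maximum
modification rate).

A first-class simulator (`ampdel.simdata`) generates the 9-template
deletion standard (WT 5490 bp plus eight barcoded templates with centered
deletions of 4416…921 bp pooled 80/20), edited-cell allele pools, and
reads for both workflows with length-biased PCR duplication, chimeras,
UMI tagging and substitution errors — each with a per-read truth table, so
every pipeline stage is testable without external data.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (worked cohort
examples, the simulated 80/20 standard benchmark, exact breakpoint
recovery, brute-force oracle suites, and parameter-recovery runs); it is
the slowest module (~1 min).

## CLI

One `ampdel` entry point with subcommands:

```sh
# simulate the 9-template standard as a dual-UMI long-read library
ampdel simulate-standard --n-molecules 5000 --chimera-rate 0.01 \
    --error-rate 0.002 --seed 0 --out-prefix std

# UMI extraction -> binning -> chimera filter -> consensus FASTA
ampdel umi-consensus --fastq std.reads.fastq \
    --primer5 CAGGTTCACGTAGCTGACCA --primer3 TGGACGATCCTGAACGTCAG \
    --min-reads 3 --out-prefix std

# align consensus reads and classify outcomes; writes calls.tsv,
# patterns.tsv (start, size, count, delta, side) and patterns.bed
ampdel call-variants --sequences std.consensus.fasta \
    --ref std.reference.fasta --cut-site 2745 --out-prefix std

# paired-end pipeline (optionally with a control for coverage ratios)
ampdel simulate-reads --pool alleles.fasta --fractions 0.75,0.25 \
    --n-fragments 10000 --out-prefix la
ampdel longamp --r1 la.R1.fastq --r2 la.R2.fastq \
    --ref ref.fasta --cut-site 2000 --out-prefix la

# quantification utilities
ampdel ddpcr --table droplets.tsv --out genotypes.tsv
ampdel genotype-clones --table clones.tsv --out clone_genotypes.tsv
ampdel kinetics --table timecourse.tsv --out t50.json
```

## Layout

| module              | contents                                                         |
| ------------------- | ---------------------------------------------------------------- |
| `ampdel.simdata`    | standard/allele-pool construction, read simulators, truth tables |
| `ampdel.umi`        | UMI extraction, binning, chimera filter, consensus               |
| `ampdel.align`      | anchor-chain aligner, event normalization, SAM/split-read parser |
| `ampdel.variants`   | outcome classification, LD clustering, symmetry, microhomology   |
| `ampdel.longamp`    | pair merging, spanning filter, LD fractions, coverage depletion  |
| `ampdel.quant`      | allele-frequency reports, ddPCR, clone genotypes, T50            |

Conventions: all coordinates are 0-based half-open; the cut site is a gap
coordinate; deletions are left-aligned before clustering or microhomology
analysis.
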