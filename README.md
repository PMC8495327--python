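# skimploid

Genome-skimming analysis of allopolyploid origins, with a built-in
synthetic-data simulator. The package covers the full workflow:

1. **simulate** — diploid and allopolyploid genomes on a known species
   tree (Jukes–Cantor substitutions), with satellite families, a tandem
   rDNA array, dispersed repeats, high-copy circular organelles
   (maternally inherited in hybrids), and paired-end reads (2 × 150 bp,
   ~350 bp inserts) with per-read ground truth.
2. **assemble** — de novo recovery of circular high-copy sequences
   (plastome, mitogenome, rDNA unit) by depth-thresholded de Bruijn
   walking; long-repeat detection; exact-anchor synteny blocks.
3. **classify** — per-read compartment binning (chloroplast,
   mitochondrial, satellite, rDNA, repeat-clustered, unassigned) by
   shared canonical k-mer fraction against reference panels.
4. **repeats** — ploidy/genome-size-scaled read sampling, k-mer
   similarity-graph clustering, majority de Bruijn consensus, tandem
   (satellite) periodicity detection, library annotation, and a
   cross-species repeat abundance table.
5. **satellitome** — unique-mapping satellite abundance across samples,
   the 0.01 %/any-sample presence rule, rotation/strand-aware
   family/variant grouping, and parental-signature inference for
   polyploids.
6. **phylo** — alignment-free (shared-k-mer) distances, neighbor
   joining, k-mer bootstrap supports, global-identity trees,
   Robinson–Foulds comparison, polyploid placement labels, maternal-
   parent inference, and secondary-calibration age scaling (root fixed
   at 12.4 Mya by default).
7. **pipeline** — one seeded, reproducible run from config to a
   machine-readable JSON report (per-compartment trees, RF matrix,
   topology labels, maternal calls, satellite tables, signatures).

## Tests

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (JC distance
recovery, diploid topology recovery, maternal-parent recovery and
compartment congruence over 20 seeds, satellite pipeline recovery,
assembler round-trips, NJ/RF oracle equivalence, threshold semantics,
and dating). The 20-seed sweep takes most of the runtime.

## CLI

```bash
skimploid simulate --seed 1 --outdir run        # FASTQ + truth tables
skimploid assemble R1.fastq R2.fastq --out contigs.fasta
skimploid classify R1.fastq R2.fastq --references refs.fasta --out bins.tsv
skimploid synteny a.fasta b.fasta --out blocks.tsv
skimploid repeats mito.fasta --out repeat_pairs.tsv
skimploid all --seed 1 --outdir run             # full pipeline + report
skimploid report run/report.json                # congruence summary
```

`skimploid all` accepts `--config config.yaml` (see
`skimploid.pipeline.RunConfig`; a default config is written to the
output directory of every run).

## Library example

```python
from skimploid import RunConfig, run_pipeline, congruence_summary

cfg = RunConfig.small(seed=1, outdir="demo")
report = run_pipeline(cfg)
print(report["maternal_calls"])        # organelle-based maternal parents
print(congruence_summary(report))      # per-compartment topology labels
```
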