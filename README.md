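# patphylo

Phyletic profiling of the cyanobacterial heterocyst-patterning module
(*all2656*, *patP*, *hetR*, *patX*) and one-site ITC binding analysis of
the HetR–PatX6 interaction.

## What this package is for

In filamentous, heterocyst-forming cyanobacteria, the master regulator HetR
is inhibited by short RGSGR-family peptides; PatX is a small, Sec-exported
precursor whose hexapeptide (HRGTGR) binds HetR, and PatP (Alr1666) is the
signal-peptide-bearing peptidase that matures it. Asking *when this module
was assembled in evolution* reduces to a comparative-genomics question:
which genomes carry which of the four genes, and which combinations
(phyletic patterns) are restricted to which clades?

`patphylo` provides the computational side of that survey as a tested,
reusable pipeline:

- **genome_io** — FASTA/GFF3/NCBI-feature-table/taxonomy/newick readers
  with a single 1-based→0-based coordinate conversion point;
- **orf_extraction** — intergenic and pseudogene region extraction and
  six-frame mining of methionine-initiated small ORFs (translation
  table 11, getorf-style ≥ 30 nt default), so tiny unannotated *patX*
  genes are not missed;
- **homolog_calling** — tiered calls from HMMER3-style domain-hit tables:
  *pre* (≥ 1 seed domain above its trusted cutoff), *strict* (exact ordered
  seed-domain architecture, no extra domains), *final* (SEC/SPI signal
  peptide present and no TM helix for the secreted genes; *hetR* exempt);
- **cooccurrence** — the genomes × genes presence matrix, 4-digit phyletic
  patterns ordered (*all2656*, *patP*, *hetR*, *patX*), pattern census and
  prevalences (truncation formatting, exact rationals available),
  co-evolution flags A = `0111` and B = `1111`, family collapse and
  tree-aligned output;
- **itc_fit** — a one-site (Kd, ΔH, n, offset) fit of integrated titration
  heats with perfusion-cell corrections, deterministic multi-start, and
  log-scale Kd confidence intervals;
- **synthetic_data** — a cohort generator that plants genes (including
  intergenic, annotation-invisible *patX* copies) at exact pattern counts
  with full ground truth, emitting every file format the pipeline reads.

The ITC model, in the field's standard notation: after injection *i*,
`Q_i = ΔH·V0·[MX]_i` with
`[MX] = ((nM_t + X_t + K_d) − √((nM_t + X_t + K_d)² − 4nM_tX_t))/2`, and
`q_i = Q_i − Q_{i−1} + (v_i/V0)(Q_i + Q_{i−1})/2 + c`.

## Worked example

Generate a 20-genome cohort with planted truth (half of the *patX* genes
hidden in intergenic space), run the pipeline, and check it against the
planted truth:

```bash
patphylo simulate --n 20 --seed 7 --out demo/cohort
patphylo run-all --cohort demo/cohort --out demo/results
patphylo verify --cohort demo/cohort --results demo/results
```

`run-all` prints the summary it also writes to `demo/results/summary.json`:

```json
{
 "calls": {"final": 36, "pre": 51, "strict": 41},
 "gene_prevalence_pct": {"all2656": 10.0, "hetR": 50.0, "patP": 90.0, "patX": 30.0},
 "n_genomes": 20,
 "n_patterns": 7,
 "tier": "final"
}
```

Reading this: of 20 genomes, 18 carry a final-tier *patP* homolog (90.0%),
10 carry *hetR*, 6 carry *patX* and 2 carry *all2656*; 51 pre-homolog
calls were narrowed to 41 by the strict architecture rule and to 36 by the
secretion screen (the planted decoys are what gets removed). The census in
`demo/results/census.tsv` starts:

```text
pattern  count  prevalence_pct  example_genome
0100     8      40.0            G0000
0111     5      25.0            G0003
0110     3      15.0            G0002
```

and `verify` reports `"exact_match": true` with zero false positives and
zero false negatives per gene — every planted homolog, including the
intergenic *patX* copies that only the ORF miner can see, was recovered.

Fitting a titration (columns `injection_index,volume_uL,heat_ucal`):

```bash
patphylo itc-fit heats.csv --v0 200 --cell-um 22 --syringe-um 200 --out fit.json
```

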