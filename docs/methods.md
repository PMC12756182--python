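# Methods

`patphylo` implements two independent analyses around the cyanobacterial
HetR/PatX/PatP regulatory module: (i) a comparative-genomics pipeline that
turns genome annotations, domain-hit tables and secretion predictions into a
phyletic presence/absence census of the four genes *all2656*, *patP*, *hetR*
and *patX*, including six-frame mining of intergenic space for small
unannotated *patX*-like genes; and (ii) a one-site binding fit for
isothermal titration calorimetry (ITC) of the HetR–PatX6 interaction. A
synthetic-cohort generator plants ground truth so the entire stack runs and
is validated without external data.

## Coordinates and formats

All interval arithmetic is done in 0-based half-open coordinates; GFF3 and
NCBI feature tables (both 1-based inclusive) are converted exactly once, in
`genome_io`. Sequences are restricted to `{A,C,G,T,N}`; codons containing
`N` translate to `X` and never act as start or stop, so assembly gaps
neither seed nor terminate ORFs. Circular replicons are not wrapped when
extracting regions — a region never spans the origin — because small-gene
discovery at the origin is a marginal case not worth the coordinate
ambiguity; GFF3 is read through `gffutils`, FASTA through Biopython, trees
through DendroPy.

## Noncoding-region extraction and ORF mining

Intergenic regions are the per-replicon complement of the union of all
annotated non-pseudogene feature intervals; every pseudogene interval is
additionally emitted as its own region, since degraded genes can still
contain intact small reading frames. Six-frame translation uses the
bacterial/archaeal code (translation table 11). An ORF runs from an ATG —
methionine starts only; GTG/TTG are not accepted — to the next in-frame
stop, or to the region edge (kept and flagged `edge_truncated`, so that
small genes abutting an annotation boundary are not silently lost). When
several ATGs share one stop, only the most 5′ start is reported by default,
matching the behaviour of EMBOSS getorf; nested starts can be requested.

The minimum-size threshold defaults to **30 nucleotides** of coding span
(10 residues). The getorf convention measures `-minsize` in nucleotides,
and that convention is kept here; a residue-unit override
(`min_size_unit="aa"`) is provided for users who want a 30-residue
reading. Mined peptides are merged with the annotated proteome; an exact
duplicate peptide keeps the annotated copy.

Correctness of the miner is established against a brute-force oracle that
enumerates every (strand, frame, ATG) triple and extends codon-by-codon
with an independently hard-coded codon table; the two agree on 200 random
300-nt sequences (with and without `N`) and on hand-built edge cases.

## Tiered homolog calling

Domain hits arrive as HMMER3 per-domain tables. A hit is *trusted* when its
bit score is ≥ the profile's curated cutoff — "above the cutoff" is read
inclusively, the common reading of curated gathering/trusted thresholds;
the boundary behaviour is documented here precisely because it is a
convention, and sub-cutoff hits are discarded before anything else happens.

- **pre**: the protein carries ≥ 1 of the gene's seed domains (trusted).
- **strict**: the protein's complete trusted-domain architecture — hits
  ordered by (alignment start, end, profile id), same-profile hits merged
  when they overlap by more than half of the shorter alignment — equals
  the gene's ordered seed-domain list: correct N→C order, no extra domain
  of any profile anywhere.
- **final**: for the secreted genes (*all2656*, *patP*, *patX*) the protein
  additionally has a SEC/SPI signal-peptide call and zero predicted
  transmembrane helices. *hetR* encodes a cytosolic transcription factor
  and is exempt; its final tier equals strict. Signal-peptide and TM
  predictions are consumed as the upstream tool's categorical calls — no
  probability threshold is re-derived here.

A protein strict for two genes is excluded from final for both: one-homolog
one-gene accounting requires unambiguous assignment, and exclusion is the
conservative resolution. Tier inclusion (final ⊆ strict ⊆ pre) and
invariance to input row order are asserted by the test suite on every run.

The seed-domain lists, cutoffs and screen flags ship as an editable YAML
config. The bundled config uses placeholder profile ids (the generator's
synthetic domains); a run on real genomes substitutes curated accessions.
patP is configured with two seed domains so the order-sensitive strict rule
is exercised end to end.

## Phyletic patterns and the census

Presence is defined as ≥ 1 tier-final homolog (a switch allows strict, for
sensitivity analysis). The gene axis is fixed as
(*all2656*, *patP*, *hetR*, *patX*); each genome's pattern is the 4-digit
0/1 string in that order. Pattern A = `0111`, pattern B = `1111`. Every
genome in the taxonomy gets a row, including all-zero ones, so prevalence
denominators are cohort sizes, not call counts.

Two prevalence statistics are deliberately distinct: **genome prevalence**
(fraction of genomes carrying ≥ 1 homolog) and **homolog share** (fraction
of a gene's homologs falling in a taxonomic order). Percentages are
formatted by **truncation** (floor) at the requested number of decimals,
computed in exact integer arithmetic, with the exact rational returned
alongside; half-up rounding is available as a mode. Truncation is the
package default because it is the only convention internally consistent
with the prevalence figures this pipeline is meant to reproduce
(72/474 = 15.1898… printed as 15.18).

## Synthetic cohorts

The generator plants, per genome, one protein per present gene. Annotated
genes are real embedded CDSs (ATG + deterministic codons + stop, either
strand) whose translation is the planted peptide. A configurable fraction
of *patX* instances (default 0.5) is instead written as a raw
stop–ATG–…–stop cassette in intergenic space with no feature, so only the
ORF-mining path can recover it; the flanking in-frame stop guarantees the
miner reports exactly the planted peptide, making the expected ORF
identifier computable in advance. Each genome also carries one decoy
cycling through the four failure modes (sub-cutoff score, wrong domain
order, extra domain, TM-helix-bearing patP architecture), and every seventh
genome a random pseudogene span. Background sequence is random at GC ≈ 0.45
(a typical cyanobacterial value).

The default cohort has 474 genomes distributed over 14 patterns
(`0100`:178, `0111`:110, `0110`:57, `1111`:30, `0010`:30, `1100`:20,
`0000`:15, `1110`:9, `0011`:9, `1101`:5, `1000`:5, `0001`:3, `1011`:2,
`1010`:1), chosen so the marginals land on the survey's printed values
under truncation: all2656 in 72 genomes (15.18%), patP in 409 (86.2%),
patX in 159. Orders are assigned so patterns A and B stay restricted to
the clades where the survey found them (A: Nostocales, Oscillatoriales,
Gomontiellales, Spirulinales; B: Nostocales, Oscillatoriales), with
morphology H for Nostocales, F for the other filamentous orders, U
otherwise. Smaller cohorts use largest-remainder scaling of this
distribution. All randomness flows from a single seed through one
`numpy` generator, making emitted files byte-identical across runs.

What the generator does **not** emulate: sequence evolution and homology at
the sequence level (domain hits are written directly with fixed scores),
HMMER score distributions, annotation noise beyond the planted decoys, and
multi-copy gene families (one planted homolog per present gene). Passing
the end-to-end identity tests therefore demonstrates the correctness of the
region/ORF/architecture/triage/census logic, not the sensitivity of a real
HMM search — which is an input to this pipeline, not a component of it.

## One-site ITC model

With cumulative injected fraction `d_i = ΣV_j / V0`, the perfusion-cell
corrections are `Mtot_i = M0(1 − d_i/2)/(1 + d_i/2)` and
`Xtot_i = X0 d_i/(1 + d_i/2)`. The 1:1 equilibrium with stoichiometry `n`
gives bound complex via the mass-action quadratic
`[MX]_i = ((nMtot_i + Xtot_i + Kd) − √((nMtot_i + Xtot_i + Kd)² − 4 nMtot_i Xtot_i))/2`,
cumulative heat `Q_i = ΔH·V0·[MX]_i`, and per-injection heat
`q_i = Q_i − Q_{i−1} + (v_i/V0)(Q_i + Q_{i−1})/2 + c` — the de facto
MicroCal formulation (stoichiometry multiplies the cell species; the
displaced-volume term accounts for liquid pushed out of the lock). Units:
µL, µM, kcal/mol, µcal.

Fitting minimises squared residuals over (log₁₀Kd, ΔH, n, c) with bounded
`scipy.optimize.least_squares`, restarted from seven deterministic
log-spaced Kd values (1 nM–1 mM) because the objective is multimodal at low
signal-to-noise. The first injection (the 0.4 µL priming shot) is excluded
by default, standard ITC practice. Standard errors come from the
Gauss–Newton curvature at the optimum; the Kd confidence interval is
computed on the log₁₀ scale (the natural parameterisation for a positive
scale parameter) and exponentiated. Degenerate (flat) heat vectors are
flagged unidentifiable rather than fitted.

The dilution offset `c` has three modes: fitted (default), fixed at the
mean of the last three injections, or fixed at zero. The zero mode is the
classic three-parameter instrument-software workflow for heats whose
constant dilution contribution was already subtracted from the baselines;
the Monte-Carlo recovery study in the test suite uses it, simulating
dilution-corrected heats (offset 0) at the published geometry (200 µL cell,
0.4 + 18 × 2 µL injections, 22 µM cell, 200 µM syringe) with per-point
noise of 2% of the largest heat. Across 100 replicates at each true Kd in
{10, 50, 88, 200, 1000} nM the pooled median relative Kd error is below
10% and the 95% intervals cover the truth in ≥ 90% of fits. Recovery is
intrinsically hardest at the tight-binding edge of that grid: at 10 nM the
titration curve is nearly rectangular and the local-curvature bound alone
puts the per-replicate median error near 17%, which the interval coverage —
not the point estimate — is designed to absorb.

## Problem sizes

The bundled studies use 20- and 474-genome cohorts (roughly 2–4 kb per
genome) and 500 Monte-Carlo titration fits; the full test suite and the
reproduction script each complete in about a minute on a single core.

## Known limitations

- Domain hits, signal-peptide and TM predictions are inputs; the pipeline's
  accuracy on real genomes is bounded by theirs.
- The strict-architecture rule is exact-match: a genuine homolog with a
  lineage-specific extra domain is rejected by design.
- The ITC module fits integrated heats only (no raw-power baseline
  integration) and a single-site model only.
- Plasmids and chromosomes are pooled per genome; the census does not
  distinguish replicon of origin.
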