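# Seed-domain configuration for the four reference genes.
#
# The profile ids below are synthetic placeholders used by the bundled
# cohort generator and the test suite; for a run against real genomes,
# replace them with the curated Pfam/PGAP accessions and trusted bit-score
# cutoffs of the reference proteins, keeping the same structure.
cutoffs:
  SEED_A56: 25.0
  SEED_PATP_N: 25.0
  SEED_PATP_C: 25.0
  SEED_HETR: 25.0
  SEED_PATX: 25.0
  EXTRA_DOM: 20.0

genes:
  all2656:
    domains: [SEED_A56]
    require_signal_peptide: true
    forbid_transmembrane: true
    reference_protein: All2656
  patP:
    domains: [SEED_PATP_N, SEED_PATP_C]
    require_signal_peptide: true
    forbid_transmembrane: true
    reference_protein: Alr1666
  hetR:
    domains: [SEED_HETR]
    require_signal_peptide: false
    forbid_transmembrane: false
    reference_protein: HetR
  patX:
    domains: [SEED_PATX]
    require_signal_peptide: true
    forbid_transmembrane: true
    reference_protein: PatX
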