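"""Self-contained synthetic genome cohorts with planted ground truth.

The generator emits everything the pipeline consumes — genome FASTA, GFF3
features, a domtblout-dialect domain-hit table, signal-peptide and
transmembrane annotation tables, a taxonomy table and an order-level species
tree — for a cohort whose phyletic patterns are planted at exact, specified
counts. A configurable fraction of patX genes is written as raw sequence in
intergenic space (no CDS feature) so that only the six-frame ORF-mining path
can recover them. Domain hits are written directly by the generator (short
placeholder profiles with fixed scores), so homolog-calling logic is tested
independently of any search engine.

The default cohort emulates the survey conditions: 474 genomes whose gene
margins reproduce the printed prevalences (all2656 in 72 genomes, patP in
409, patX in 159) across 14 distinct phyletic patterns with the three major
patterns at 0100=178, 0111=110, 0110=57 genomes.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .genome_io import (
    GeneFeature,
    GenomeRecord,
    Replicon,
    TaxonAnnotation,
    reverse_complement,
)
from .homolog_calling import (
    GENES,
    DomainHit,
    SeedProfile,
    default_seed_profiles,
    write_domain_hits,
)

# phyletic pattern -> genome count for the default 474-genome cohort;
# margins: all2656 72, patP 409, hetR 248, patX 159; 14 distinct patterns
DEFAULT_PATTERN_COUNTS_474: dict[str, int] = {
    "0100": 178,
    "0111": 110,
    "0110": 57,
    "1111": 30,
    "0010": 30,
    "1100": 20,
    "0000": 15,
    "1110": 9,
    "0011": 9,
    "1101": 5,
    "1000": 5,
    "0001": 3,
    "1011": 2,
    "1010": 1,
}

# orders eligible per pattern class; pattern A (0111) and B (1111) stay
# restricted to the clades where the survey found them
_ORDERS_A = ("Nostocales", "Oscillatoriales", "Gomontiellales", "Spirulinales")
_ORDERS_B = ("Nostocales", "Oscillatoriales")
_ORDERS_OTHER = ("Synechococcales", "Chroococcales", "Pleurocapsales", "Gloeobacterales")
_MORPHOLOGY = {
    "Nostocales": "H",
    "Oscillatoriales": "F",
    "Gomontiellales": "F",
    "Spirulinales": "F",
    "Synechococcales": "U",
    "Chroococcales": "U",
    "Pleurocapsales": "U",
    "Gloeobacterales": "U",
}

ORDER_TREE_NEWICK = (
    "(Gloeobacterales,(Synechococcales,(Chroococcales,(Pleurocapsales,"
    "(Spirulinales,(Gomontiellales,(Oscillatoriales,Nostocales)))))));"
)

# deterministic codon per amino acid (lexicographically smallest, table 11)
_fwd = CodonTable.unambiguous_dna_by_id[11].forward_table
_CODON_OF: dict[str, str] = {}
for codon in sorted(_fwd):
    aa = _fwd[codon]
    _CODON_OF.setdefault(aa, codon)

_AA_INTERIOR = "ACDEFGHIKLNPQRSTVWY"  # no Met: keeps planted ORF starts unique

_PEPTIDE_LEN = {"all2656": 120, "patP": 140, "hetR": 100, "patX": 50}


@dataclass(frozen=True)
class CohortSpec:
    n_genomes: int = 474
    pattern_counts: Optional[dict] = None  # pattern -> count; default scaled from 474
    intergenic_patx_fraction: float = 0.5
    seed: int = 0

    def resolved_counts(self) -> dict[str, int]:
        counts = self.pattern_counts or default_pattern_counts(self.n_genomes)
        if sum(counts.values()) != self.n_genomes:
            raise ValueError(
                f"pattern counts sum to {sum(counts.values())}, expected {self.n_genomes}"
            )
        for p in counts:
            if len(p) != 4 or set(p) - {"0", "1"}:
                raise ValueError(f"bad pattern {p!r}")
        if not 0 <= self.intergenic_patx_fraction <= 1:
            raise ValueError("intergenic_patx_fraction must be in [0,1]")
        return dict(counts)


def default_pattern_counts(n: int) -> dict[str, int]:
    """Scale the 474-genome pattern distribution to ``n`` genomes.

    Largest-remainder apportionment; patterns that would round to zero drop
    out, so small cohorts have fewer distinct patterns.
    """
    if n == 474:
        return dict(DEFAULT_PATTERN_COUNTS_474)
    items = list(DEFAULT_PATTERN_COUNTS_474.items())
    quotas = [(p, n * c / 474) for p, c in items]
    base = {p: int(q) for p, q in quotas}
    remainder = n - sum(base.values())
    by_frac = sorted(quotas, key=lambda t: (-(t[1] - int(t[1])), t[0]))
    for p, _ in by_frac[:remainder]:
        base[p] += 1
    return {p: c for p, c in base.items() if c > 0}


@dataclass
class PlantedGene:
    gene: str
    protein_id: str
    provenance: str  # annotated | intergenic_orf
    peptide: str
    seed_domains: tuple
    sp_type: str
    tm_helix_count: int


@dataclass
class GroundTruth:
    patterns: dict  # genome_id -> pattern string
    planted: dict  # genome_id -> list[PlantedGene]

    def expected_final(self) -> set:
        """(genome_id, gene, protein_id) triples expected at tier final."""
        out = set()
        for gid, genes in self.planted.items():
            for pg in genes:
                out.add((gid, pg.gene, pg.protein_id))
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "patterns": self.patterns,
                "planted": {
                    g: [asdict(pg) for pg in lst] for g, lst in self.planted.items()
                },
            },
            indent=1,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        raw = json.loads(text)
        planted = {
            g: [PlantedGene(**{**d, "seed_domains": tuple(d["seed_domains"])}) for d in lst]
            for g, lst in raw["planted"].items()
        }
        return cls(patterns=raw["patterns"], planted=planted)


@dataclass
class Cohort:
    spec: CohortSpec
    genomes: list  # list[GenomeRecord]
    features: dict  # genome_id -> list[GeneFeature]
    hits: list  # list[DomainHit]
    sp_table: pd.DataFrame  # indexed by protein_id
    tm_table: pd.DataFrame
    taxonomy: list  # list[TaxonAnnotation]
    tree_newick: str
    truth: GroundTruth


_BASES = np.array(list("ACGT"))
_BASE_P = np.array([0.275, 0.225, 0.225, 0.275])  # GC ~ 0.45


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.choice(4, size=n, p=_BASE_P)])


def _rand_peptide(rng: np.random.Generator, length: int) -> str:
    interior = "".join(
        _AA_INTERIOR[i] for i in rng.integers(0, len(_AA_INTERIOR), size=length - 1)
    )
    return "M" + interior


def _encode(peptide: str) -> str:
    return "".join(_CODON_OF[aa] for aa in peptide)


def _seed_hits(gene: str, protein_id: str, profiles: dict) -> list[DomainHit]:
    """Trusted-scoring hits laying out the gene's seed domains in order."""
    hits = []
    pos = 5
    for dom in profiles[gene].domains:
        width = 50
        hits.append(
            DomainHit(
                protein_id=protein_id,
                profile_id=dom,
                score=profiles[gene].cutoffs[dom] + 15.0,
                i_evalue=1e-12,
                ali_start=pos,
                ali_end=pos + width,
                env_start=max(pos - 2, 0),
                env_end=pos + width + 2,
            )
        )
        pos += width + 15
    return hits


def _assign_order(rng: np.random.Generator, pattern: str) -> str:
    has_hetr, has_patx = pattern[2] == "1", pattern[3] == "1"
    if pattern == "0111":
        return str(rng.choice(_ORDERS_A, p=[0.6, 0.25, 0.1, 0.05]))
    if pattern == "1111":
        return str(rng.choice(_ORDERS_B, p=[0.7, 0.3]))
    if has_hetr and has_patx:
        return str(rng.choice(_ORDERS_B, p=[0.5, 0.5]))
    if has_hetr:
        return str(rng.choice(("Oscillatoriales", "Nostocales", "Synechococcales")))
    return str(rng.choice(_ORDERS_OTHER))


def simulate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a cohort per ``spec``; deterministic given the seed."""
    counts = spec.resolved_counts()
    profiles = default_seed_profiles()
    rng = np.random.default_rng(spec.seed)

    pattern_list: list[str] = []
    for pattern in sorted(counts):
        pattern_list.extend([pattern] * counts[pattern])
    rng.shuffle(pattern_list)

    genomes: list[GenomeRecord] = []
    features: dict[str, list[GeneFeature]] = {}
    hits: list[DomainHit] = []
    sp_rows, tm_rows = [], []
    taxonomy: list[TaxonAnnotation] = []
    truth_patterns: dict[str, str] = {}
    truth_planted: dict[str, list[PlantedGene]] = {}

    def annotate_sp_tm(pid: str, sp_type: str, tm: int) -> None:
        sp_rows.append({"protein_id": pid, "sp_type": sp_type,
                        "probability": 0.98 if sp_type != "none" else 0.96})
        tm_rows.append({"protein_id": pid, "tm_helix_count": tm})

    for idx, pattern in enumerate(pattern_list):
        gid = f"G{idx:04d}"
        rep_id = f"{gid}_chr"
        parts: list[str] = []
        pos = 0
        feats: list[GeneFeature] = []
        planted: list[PlantedGene] = []

        def spacer() -> None:
            nonlocal pos
            n = int(rng.integers(150, 300))
            parts.append(_rand_seq(rng, n))
            pos += n

        def plant_cds(pid: str, peptide: str) -> None:
            """Insert an annotated CDS (stop codon included in the feature)."""
            nonlocal pos
            cds = _encode(peptide) + "TAA"
            strand = "+" if rng.random() < 0.5 else "-"
            parts.append(cds if strand == "+" else reverse_complement(cds))
            feats.append(GeneFeature(rep_id, pos, pos + len(cds), strand, "CDS", pid))
            pos += len(cds)

        spacer()
        present = [g for g, d in zip(GENES, pattern) if d == "1"]
        for gene in present:
            peptide = _rand_peptide(rng, _PEPTIDE_LEN[gene])
            intergenic = (
                gene == "patX" and rng.random() < spec.intergenic_patx_fraction
            )
            if not intergenic:
                pid = f"{gid}_{gene}"
                plant_cds(pid, peptide)
                provenance = "annotated"
            else:
                # hidden gene: stop + ATG..stop cassette, no feature; only the
                # ORF-mining path can recover it
                cds = _encode(peptide) + "TAA"
                cassette = "TAA" + cds
                strand = "+" if rng.random() < 0.5 else "-"
                if strand == "+":
                    parts.append(cassette)
                    orf_start, orf_end = pos + 3, pos + len(cassette)
                else:
                    parts.append(reverse_complement(cassette))
                    orf_start, orf_end = pos, pos + len(cassette) - 3
                pos += len(cassette)
                pid = f"{rep_id}:{orf_start}-{orf_end}:{strand}"
                provenance = "intergenic_orf"
            hits.extend(_seed_hits(gene, pid, profiles))
            sp_type = "none" if gene == "hetR" else "SEC/SPI"
            annotate_sp_tm(pid, sp_type, 0)
            planted.append(
                PlantedGene(gene, pid, provenance, peptide,
                            profiles[gene].domains, sp_type, 0)
            )
            spacer()

        # one decoy per genome, cycling through the failure modes
        decoy_kind = ("subcutoff", "wrong_order", "extra_domain", "tm_helix")[idx % 4]
        dpid = f"{gid}_decoy"
        dpep = _rand_peptide(rng, 150)
        plant_cds(dpid, dpep)
        spacer()
        if decoy_kind == "subcutoff":
            h = _seed_hits("hetR", dpid, profiles)[0]
            hits.append(DomainHit(dpid, h.profile_id, profiles["hetR"].cutoffs[h.profile_id] - 5.0,
                                  h.i_evalue, h.ali_start, h.ali_end, h.env_start, h.env_end))
            annotate_sp_tm(dpid, "none", 0)
        elif decoy_kind == "wrong_order":
            n_dom, c_dom = profiles["patP"].domains
            hits.append(DomainHit(dpid, c_dom, 40.0, 1e-12, 5, 55, 3, 57))
            hits.append(DomainHit(dpid, n_dom, 40.0, 1e-12, 70, 120, 68, 122))
            annotate_sp_tm(dpid, "SEC/SPI", 0)
        elif decoy_kind == "extra_domain":
            hits.extend(_seed_hits("hetR", dpid, profiles))
            hits.append(DomainHit(dpid, "EXTRA_DOM", 30.0, 1e-8, 100, 140, 98, 142))
            annotate_sp_tm(dpid, "none", 0)
        else:  # tm_helix: full patP architecture but membrane-anchored
            hits.extend(_seed_hits("patP", dpid, profiles))
            annotate_sp_tm(dpid, "SEC/SPI", 2)

        # occasional pseudogene span (random content) to exercise that path
        if idx % 7 == 0:
            n = 150
            feats.append(GeneFeature(rep_id, pos, pos + n, "+", "pseudogene", None))
            parts.append(_rand_seq(rng, n))
            pos += n
            spacer()

        seq = "".join(parts)
        genomes.append(GenomeRecord(gid, [Replicon(rep_id, seq)]))
        features[gid] = feats
        order = _assign_order(rng, pattern)
        family = f"{order}_fam{idx % 3}"
        taxonomy.append(TaxonAnnotation(gid, order, family, _MORPHOLOGY[order]))
        truth_patterns[gid] = pattern
        truth_planted[gid] = planted

    sp_table = pd.DataFrame(sp_rows).set_index("protein_id")
    tm_table = pd.DataFrame(tm_rows).set_index("protein_id")
    return Cohort(
        spec=spec,
        genomes=genomes,
        features=features,
        hits=hits,
        sp_table=sp_table,
        tm_table=tm_table,
        taxonomy=taxonomy,
        tree_newick=ORDER_TREE_NEWICK,
        truth=GroundTruth(truth_patterns, truth_planted),
    )


# ---------------------------------------------------------------------------
# file round-trip


def write_cohort(cohort: Cohort, outdir: str) -> None:
    """Write the cohort in exactly the formats the pipeline readers consume."""
    os.makedirs(outdir, exist_ok=True)
    gdir = os.path.join(outdir, "genomes")
    os.makedirs(gdir, exist_ok=True)
    for genome in cohort.genomes:
        with open(os.path.join(gdir, f"{genome.genome_id}.fna"), "w") as fh:
            for rep in genome.replicons:
                fh.write(f">{rep.replicon_id}\n")
                for i in range(0, len(rep.seq), 70):
                    fh.write(rep.seq[i : i + 70] + "\n")
        with open(os.path.join(gdir, f"{genome.genome_id}.gff"), "w") as fh:
            fh.write("##gff-version 3\n")
            for rep in genome.replicons:
                fh.write(f"##sequence-region {rep.replicon_id} 1 {len(rep)}\n")
            for k, f in enumerate(cohort.features[genome.genome_id]):
                ftype = "CDS" if f.kind == "CDS" else ("pseudogene" if f.kind == "pseudogene" else "misc_feature")
                attrs = f"ID={genome.genome_id}_f{k}"
                if f.protein_id:
                    attrs += f";protein_id={f.protein_id}"
                fh.write(
                    f"{f.replicon_id}\tpatphylo_synth\t{ftype}\t{f.start + 1}\t{f.end}"
                    f"\t.\t{f.strand}\t0\t{attrs}\n"
                )
    write_domain_hits(cohort.hits, os.path.join(outdir, "hits.domtbl"))
    cohort.sp_table.reset_index().to_csv(os.path.join(outdir, "sp.tsv"), sep="\t", index=False)
    cohort.tm_table.reset_index().to_csv(os.path.join(outdir, "tm.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [
            {"genome_id": t.genome_id, "order": t.order, "family": t.family,
             "morphology": t.morphology}
            for t in cohort.taxonomy
        ]
    ).to_csv(os.path.join(outdir, "taxonomy.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "tree.nwk"), "w") as fh:
        fh.write(cohort.tree_newick + "\n")
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        fh.write(cohort.truth.to_json() + "\n")
    with open(os.path.join(outdir, "spec.json"), "w") as fh:
        json.dump(
            {
                "n_genomes": cohort.spec.n_genomes,
                "pattern_counts": cohort.spec.resolved_counts(),
                "intergenic_patx_fraction": cohort.spec.intergenic_patx_fraction,
                "seed": cohort.spec.seed,
            },
            fh, indent=1, sort_keys=True,
        )
        fh.write("\n")


def load_cohort(indir: str) -> Cohort:
    """Read a written cohort back through the standard-format readers."""
    from .genome_io import read_genome, read_taxonomy
    from .homolog_calling import parse_domain_hits, read_sp_annotations, read_tm_annotations

    with open(os.path.join(indir, "spec.json")) as fh:
        raw = json.load(fh)
    spec = CohortSpec(
        n_genomes=raw["n_genomes"],
        pattern_counts=raw["pattern_counts"],
        intergenic_patx_fraction=raw["intergenic_patx_fraction"],
        seed=raw["seed"],
    )
    gdir = os.path.join(indir, "genomes")
    genomes, features = [], {}
    for fname in sorted(os.listdir(gdir)):
        if not fname.endswith(".fna"):
            continue
        gid = fname[: -len(".fna")]
        genome, feats = read_genome(
            os.path.join(gdir, fname), os.path.join(gdir, f"{gid}.gff"),
            dialect="gff3", genome_id=gid,
        )
        genomes.append(genome)
        features[gid] = feats
    with open(os.path.join(indir, "truth.json")) as fh:
        truth = GroundTruth.from_json(fh.read())
    with open(os.path.join(indir, "tree.nwk")) as fh:
        newick = fh.read().strip()
    return Cohort(
        spec=spec,
        genomes=genomes,
        features=features,
        hits=parse_domain_hits(os.path.join(indir, "hits.domtbl")),
        sp_table=read_sp_annotations(os.path.join(indir, "sp.tsv")),
        tm_table=read_tm_annotations(os.path.join(indir, "tm.tsv")),
        taxonomy=read_taxonomy(os.path.join(indir, "taxonomy.tsv")),
        tree_newick=newick,
        truth=truth,
    )


def verify_ground_truth(final_calls, truth: GroundTruth) -> dict:
    """Compare tier-final calls against the planted truth.

    Returns per-gene confusion counts (true/false positives, false
    negatives) and an ``exact_match`` flag.
    """
    called = {(c.genome_id, c.gene, c.protein_id) for c in final_calls}
    expected = truth.expected_final()
    report = {"genes": {}, "exact_match": called == expected}
    for gene in GENES:
        exp_g = {t for t in expected if t[1] == gene}
        got_g = {t for t in called if t[1] == gene}
        report["genes"][gene] = {
            "planted": len(exp_g),
            "called": len(got_g),
            "tp": len(exp_g & got_g),
            "fp": len(got_g - exp_g),
            "fn": len(exp_g - got_g),
        }
    return report
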