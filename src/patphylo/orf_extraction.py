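"""Noncoding-region extraction and six-frame small-ORF mining.

Small genes (notably patX homologs) are routinely missed by genome
annotation. This module extracts intergenic and pseudogene regions,
translates them in all six frames under the bacterial genetic code
(translation table 11), and reports methionine-initiated ORFs above a
minimum size, which are then merged with the annotated proteome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

from Bio.Seq import Seq

from .genome_io import GeneFeature, GenomeRecord, reverse_complement

logger = logging.getLogger(__name__)

RegionClass = Literal["intergenic", "pseudogene"]

#: default minimum ORF size, in NUCLEOTIDES of the coding span (getorf convention)
DEFAULT_MIN_ORF_NT = 30


@dataclass(frozen=True)
class Region:
    replicon_id: str
    start: int
    end: int
    region_class: RegionClass

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad region interval [{self.start},{self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Orf:
    """A Met-initiated open reading frame.

    ``start``/``end`` are 0-based half-open on the forward strand of the
    sequence the ORF was found in (the stop codon, when present, is included
    in the span and flagged by ``has_stop``). ``frame`` is the frame offset
    0-2 on the reading strand.
    """

    replicon_id: str
    start: int
    end: int
    strand: Literal["+", "-"]
    frame: int
    peptide: str
    has_stop: bool
    edge_truncated: bool
    region_class: RegionClass = "intergenic"

    @property
    def orf_id(self) -> str:
        return f"{self.replicon_id}:{self.start}-{self.end}:{self.strand}"


@dataclass(frozen=True)
class CandidateProtein:
    protein_id: str
    genome_id: str
    seq: str
    provenance: Literal["annotated", "intergenic_orf", "pseudogene_orf"]


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for a, b in intervals[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def extract_noncoding_regions(
    genome: GenomeRecord, features: list[GeneFeature]
) -> list[Region]:
    """Complement of annotated (non-pseudogene) features, plus pseudogene spans.

    Intergenic regions are the per-replicon complement of the union of every
    feature interval except pseudogenes; each pseudogene interval is emitted
    separately as a ``pseudogene`` region. Zero-length regions are dropped.
    """
    regions: list[Region] = []
    by_rep: dict[str, list[GeneFeature]] = {}
    for f in features:
        by_rep.setdefault(f.replicon_id, []).append(f)
    for rep in genome.replicons:
        feats = by_rep.get(rep.replicon_id, [])
        blocked = _merge_intervals(
            [(f.start, f.end) for f in feats if f.kind != "pseudogene"]
        )
        pos = 0
        for a, b in blocked:
            if a > pos:
                regions.append(Region(rep.replicon_id, pos, a, "intergenic"))
            pos = max(pos, b)
        if pos < len(rep):
            regions.append(Region(rep.replicon_id, pos, len(rep), "intergenic"))
        for f in feats:
            if f.kind == "pseudogene":
                regions.append(Region(rep.replicon_id, f.start, f.end, "pseudogene"))
    return regions


def _frame_translation(seq: str, table: int) -> str:
    """Translate one frame; codons containing N become X (never stop/start)."""
    usable = len(seq) - len(seq) % 3
    s = seq[:usable]
    pep = list(str(Seq(s).translate(table=table)))
    if "N" in s:
        i = s.find("N")
        while i != -1:
            pep[i // 3] = "X"
            i = s.find("N", i + 1)
    return "".join(pep)


def six_frame_orfs(
    region_seq: str,
    min_size: int = DEFAULT_MIN_ORF_NT,
    *,
    min_size_unit: Literal["nt", "aa"] = "nt",
    table: int = 11,
    longest_per_stop: bool = True,
    include_edge_truncated: bool = True,
    replicon_id: str = "seq",
    offset: int = 0,
    region_class: RegionClass = "intergenic",
) -> list[Orf]:
    """Find Met-initiated ORFs in all six frames of ``region_seq``.

    An ORF runs from an ATG to the next in-frame stop codon (or to the end of
    the sequence, in which case it is flagged ``edge_truncated``). With
    ``longest_per_stop`` (the default, matching getorf) only the most 5' Met
    sharing a stop is reported; otherwise every nested Met start is emitted.
    ``min_size`` is a threshold on the coding span excluding the stop codon,
    in nucleotides by default (``min_size_unit="aa"`` reads it as residues).

    Coordinates in the returned :class:`Orf` objects are on the forward
    strand of ``region_seq`` shifted by ``offset`` (pass the region's genomic
    start to obtain genomic coordinates).
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    bad = set(region_seq.upper()) - set("ACGTN")
    if bad:
        raise ValueError(f"non-nucleotide characters {sorted(bad)}")
    seq = region_seq.upper()
    min_aa = min_size if min_size_unit == "aa" else -(-min_size // 3)  # ceil
    L = len(seq)
    out: list[Orf] = []
    for strand in ("+", "-"):
        s = seq if strand == "+" else reverse_complement(seq)
        for frame in range(3):
            prot = _frame_translation(s[frame:], table)
            seg_start = 0  # aa index where the current stop-free segment begins
            n = len(prot)
            i = 0
            while i <= n:
                is_end = i == n
                if is_end or prot[i] == "*":
                    segment = prot[seg_start:i]
                    has_stop = not is_end
                    met_positions: Iterable[int]
                    first_m = segment.find("M")
                    if first_m != -1:
                        if longest_per_stop:
                            met_positions = [first_m]
                        else:
                            met_positions = [
                                j for j, aa in enumerate(segment) if aa == "M"
                            ]
                        for m in met_positions:
                            pep = segment[m:]
                            if len(pep) < min_aa:
                                continue
                            edge = not has_stop
                            if edge and not include_edge_truncated:
                                continue
                            aa_start = seg_start + m
                            nt_start = frame + 3 * aa_start
                            nt_end = frame + 3 * (i + (1 if has_stop else 0))
                            if strand == "+":
                                a, b = nt_start, nt_end
                            else:
                                a, b = L - nt_end, L - nt_start
                            out.append(
                                Orf(
                                    replicon_id=replicon_id,
                                    start=offset + a,
                                    end=offset + b,
                                    strand=strand,
                                    frame=frame,
                                    peptide=pep,
                                    has_stop=has_stop,
                                    edge_truncated=edge,
                                    region_class=region_class,
                                )
                            )
                    seg_start = i + 1
                i += 1
    return out


def mine_genome_orfs(
    genome: GenomeRecord,
    regions: list[Region],
    min_size: int = DEFAULT_MIN_ORF_NT,
    **kwargs,
) -> list[Orf]:
    """Run :func:`six_frame_orfs` over every extracted region of a genome."""
    orfs: list[Orf] = []
    for region in regions:
        rep = genome.replicon(region.replicon_id)
        orfs.extend(
            six_frame_orfs(
                rep.seq[region.start : region.end],
                min_size,
                replicon_id=region.replicon_id,
                offset=region.start,
                region_class=region.region_class,
                **kwargs,
            )
        )
    return orfs


def merge_with_proteome(
    orfs: list[Orf],
    proteome: dict[str, str],
    genome_id: str,
) -> list[CandidateProtein]:
    """Union annotated proteins and mined ORF peptides with provenance tags.

    Exact duplicate peptides within the genome keep the annotated copy. An
    ORF id colliding with an annotated id is deterministically re-suffixed.
    """
    candidates: list[CandidateProtein] = [
        CandidateProtein(pid, genome_id, seq, "annotated")
        for pid, seq in proteome.items()
    ]
    seen_seqs = set(proteome.values())
    seen_ids = set(proteome.keys())
    for orf in sorted(orfs, key=lambda o: (o.replicon_id, o.start, o.end, o.strand)):
        if orf.peptide in seen_seqs:
            continue
        pid = orf.orf_id
        while pid in seen_ids:
            logger.warning("candidate id collision, re-suffixing %s", pid)
            pid += "_orf"
        seen_ids.add(pid)
        seen_seqs.add(orf.peptide)
        provenance = (
            "pseudogene_orf" if orf.region_class == "pseudogene" else "intergenic_orf"
        )
        candidates.append(CandidateProtein(pid, genome_id, orf.peptide, provenance))
    return candidates
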