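"""Readers and domain types for genomes, annotations, taxonomy and trees.

All coordinates are converted exactly once, here, from the 1-based inclusive
conventions of GFF3 / NCBI feature tables to the internal 0-based half-open
convention used by every downstream module.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

VALID_ALPHABET = set("ACGTN")
MORPHOLOGY_CODES = ("U", "F", "H")

FeatureKind = Literal["CDS", "pseudogene", "other"]


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


class ValidationError(ValueError):
    """Structurally parseable input that violates an invariant."""


@dataclass(frozen=True)
class Replicon:
    replicon_id: str
    seq: str
    circular: bool = False

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GenomeRecord:
    """A genome: one or more replicons plus an opaque identifier."""

    genome_id: str
    replicons: list[Replicon] = field(default_factory=list)
    taxon_ref: Optional["TaxonAnnotation"] = None

    def __post_init__(self) -> None:
        ids = [r.replicon_id for r in self.replicons]
        if len(ids) != len(set(ids)):
            raise ValidationError(
                f"genome {self.genome_id}: duplicate replicon ids {sorted(ids)}"
            )
        for r in self.replicons:
            if not r.seq:
                raise ValidationError(
                    f"genome {self.genome_id}: replicon {r.replicon_id} is empty"
                )
            bad = set(r.seq) - VALID_ALPHABET
            if bad:
                raise ValidationError(
                    f"genome {self.genome_id}: replicon {r.replicon_id} contains "
                    f"non-ACGTN characters {sorted(bad)}"
                )

    def replicon(self, replicon_id: str) -> Replicon:
        for r in self.replicons:
            if r.replicon_id == replicon_id:
                return r
        raise KeyError(replicon_id)


@dataclass(frozen=True)
class GeneFeature:
    """An annotated feature in internal 0-based half-open coordinates."""

    replicon_id: str
    start: int
    end: int
    strand: Literal["+", "-"]
    kind: FeatureKind
    protein_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"feature on {self.replicon_id}: bad interval [{self.start},{self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"feature on {self.replicon_id}: strand {self.strand!r}")
        if self.kind == "CDS" and not self.protein_id:
            raise ValidationError(
                f"CDS [{self.start},{self.end}) on {self.replicon_id} lacks a protein_id"
            )

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class TaxonAnnotation:
    genome_id: str
    order: str
    family: str
    morphology: str  # U unicellular, F filamentous, H filamentous w/ heterocysts

    def __post_init__(self) -> None:
        if self.morphology not in MORPHOLOGY_CODES:
            raise ValidationError(
                f"genome {self.genome_id}: morphology {self.morphology!r} "
                f"not in {MORPHOLOGY_CODES}"
            )


def to_internal(start_1based: int, end_inclusive: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start_1based - 1, end_inclusive


def to_external(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive (inverse of :func:`to_internal`)."""
    return start + 1, end


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _classify(feature_type: str, attributes: dict) -> FeatureKind:
    ft = feature_type.lower()
    if ft == "pseudogene" or "pseudo" in attributes:
        return "pseudogene"
    if ft == "cds":
        return "CDS"
    return "other"


def _read_gff3(path: str) -> list[dict]:
    import gffutils

    db = gffutils.create_db(
        path, dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for f in db.all_features():
        attrs = {k: v for k, v in f.attributes.items()}
        protein_id = None
        for key in ("protein_id", "ID", "Name"):
            if key in attrs and attrs[key]:
                protein_id = attrs[key][0]
                break
        rows.append(
            {
                "replicon_id": f.seqid,
                "start": f.start,  # gffutils keeps 1-based inclusive
                "end": f.end,
                "strand": f.strand if f.strand in ("+", "-") else "+",
                "kind": _classify(f.featuretype, attrs),
                "protein_id": protein_id,
                "feature_type": f.featuretype,
            }
        )
    return rows


_FT_HEADER = re.compile(r"^>Feature\s+(\S+)")


def _read_ncbi_feature_table(path: str) -> list[dict]:
    """Minimal reader for the 5-column NCBI feature-table (.tbl) format."""
    rows: list[dict] = []
    current_replicon = None
    pending: Optional[dict] = None

    def flush() -> None:
        nonlocal pending
        if pending is not None:
            rows.append(pending)
            pending = None

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            m = _FT_HEADER.match(line)
            if m:
                flush()
                current_replicon = m.group(1)
                continue
            cols = line.split("\t")
            if cols[0].strip():  # interval line: start, end, [type]
                if current_replicon is None:
                    raise ParseError(f"{path}:{lineno}: interval before >Feature header")
                try:
                    a = int(cols[0].strip().lstrip("<>"))
                    b = int(cols[1].strip().lstrip("<>"))
                except (IndexError, ValueError) as exc:
                    raise ParseError(f"{path}:{lineno}: bad interval line {line!r}") from exc
                ftype = cols[2].strip() if len(cols) > 2 and cols[2].strip() else None
                if ftype is None and pending is not None:
                    continue  # multi-interval feature: keep the first span only
                flush()
                strand = "+" if a <= b else "-"
                lo, hi = (a, b) if a <= b else (b, a)
                pending = {
                    "replicon_id": current_replicon,
                    "start": lo,
                    "end": hi,
                    "strand": strand,
                    "kind": _classify(ftype or "other", {}),
                    "protein_id": None,
                    "feature_type": ftype or "other",
                }
            else:  # qualifier line
                if pending is None or len(cols) < 5:
                    continue
                key, val = cols[3].strip(), cols[4].strip()
                if key == "protein_id":
                    pending["protein_id"] = val.split("|")[-2] if "|" in val else val
                elif key == "pseudo":
                    pending["kind"] = "pseudogene"
    flush()
    return rows


def read_genome(
    fasta_path: str,
    features_path: Optional[str] = None,
    dialect: str = "gff3",
    genome_id: Optional[str] = None,
) -> tuple[GenomeRecord, list[GeneFeature]]:
    """Read a genome FASTA plus its annotation into validated internal types.

    Parameters
    ----------
    dialect : {"gff3", "ncbi_feature_table"}
        Source convention of ``features_path``. Both are 1-based inclusive and
        are converted to 0-based half-open here.
    """
    if dialect not in ("gff3", "ncbi_feature_table"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if not os.path.exists(fasta_path):
        raise FileNotFoundError(fasta_path)

    replicons = []
    for rec in SeqIO.parse(fasta_path, "fasta"):
        circular = "circular=true" in rec.description.lower()
        replicons.append(Replicon(rec.id, str(rec.seq).upper(), circular))
    if not replicons:
        raise ParseError(f"{fasta_path}: no FASTA records")
    gid = genome_id or os.path.basename(fasta_path).split(".")[0]
    genome = GenomeRecord(genome_id=gid, replicons=replicons)

    features: list[GeneFeature] = []
    if features_path is not None and os.path.getsize(features_path) > 0:
        raw = _read_gff3(features_path) if dialect == "gff3" else _read_ncbi_feature_table(features_path)
        lengths = {r.replicon_id: len(r) for r in replicons}
        for row in raw:
            if row["feature_type"] in ("region", "gene"):  # containers, not extents
                continue
            start, end = to_internal(row["start"], row["end"])
            rid = row["replicon_id"]
            if rid not in lengths:
                raise ValidationError(f"feature on unknown replicon {rid!r}")
            if end > lengths[rid]:
                raise ValidationError(
                    f"feature [{start},{end}) exceeds length {lengths[rid]} of {rid}"
                )
            pid = row["protein_id"] if row["kind"] == "CDS" else row["protein_id"]
            features.append(
                GeneFeature(rid, start, end, row["strand"], row["kind"], pid)
            )
    return genome, features


def read_taxonomy(tsv_path: str) -> list[TaxonAnnotation]:
    """Read the genome -> (order, family, morphology) table."""
    df = pd.read_csv(tsv_path, sep="\t", dtype=str).rename(columns=str.strip)
    required = {"genome_id", "order", "family", "morphology"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{tsv_path}: missing columns {sorted(missing)}")
    dupes = df["genome_id"][df["genome_id"].duplicated()].tolist()
    if dupes:
        raise ValidationError(f"{tsv_path}: duplicated genome_id(s) {sorted(set(dupes))}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            TaxonAnnotation(
                genome_id=row.genome_id.strip(),
                order=row.order.strip(),
                family=row.family.strip(),
                morphology=row.morphology.strip(),
            )
        )
    return out


def read_tree(newick_path: str) -> dendropy.Tree:
    """Read a rooted newick tree; tip labels must be unique."""
    try:
        tree = dendropy.Tree.get(
            path=newick_path, schema="newick", preserve_underscores=True
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValidationError(str(exc)) from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]
    if len(labels) != len(set(labels)):
        seen, dup = set(), set()
        for lab in labels:
            (dup if lab in seen else seen).add(lab)
        raise ValidationError(f"duplicate tip labels: {sorted(dup)}")
    return tree


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]


def extract_feature_seq(genome: GenomeRecord, feature: GeneFeature) -> str:
    """Nucleotide sequence of a feature in reading orientation."""
    rep = genome.replicon(feature.replicon_id)
    sub = rep.seq[feature.start : feature.end]
    return reverse_complement(sub) if feature.strand == "-" else sub


def translate_cds(nt: str, table: int = 11) -> str:
    """Translate a CDS (stop codon included or not); trailing stop stripped.

    Codons containing N are rendered as X.
    """
    pep = []
    for i in range(0, len(nt) - len(nt) % 3, 3):
        codon = nt[i : i + 3]
        if "N" in codon:
            pep.append("X")
        else:
            pep.append(str(Seq(codon).translate(table=table)))
    s = "".join(pep)
    return s[:-1] if s.endswith("*") else s
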