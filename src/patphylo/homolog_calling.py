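"""Tiered homolog calling from domain hits and signal-peptide/TM annotations.

A candidate protein is promoted through three tiers:

pre
    carries at least one of the gene's seed domains above the profile's
    trusted bit-score cutoff;
strict
    its full trusted-domain architecture equals the gene's ordered seed list
    (correct N->C order, no extra domains anywhere);
final
    for the secreted genes (all2656, patP, patX) it additionally carries a
    SEC/SPI signal peptide and no predicted transmembrane helix; hetR is a
    cytosolic regulator and is exempt from the secretion screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Literal, Optional

import pandas as pd
import yaml

from .orf_extraction import CandidateProtein

logger = logging.getLogger(__name__)

GENES = ("all2656", "patP", "hetR", "patX")
Tier = Literal["pre", "strict", "final"]


@dataclass(frozen=True)
class DomainHit:
    protein_id: str
    profile_id: str
    score: float
    i_evalue: Optional[float]
    ali_start: int  # 0-based half-open, converted from the 1-based table
    ali_end: int
    env_start: int
    env_end: int

    def __post_init__(self) -> None:
        if not (self.score == self.score and abs(self.score) != float("inf")):
            raise ValueError(f"non-finite score for {self.protein_id}")
        if not (self.env_start <= self.ali_start and self.ali_end <= self.env_end):
            raise ValueError(
                f"{self.protein_id}/{self.profile_id}: alignment outside envelope"
            )


@dataclass(frozen=True)
class SeedProfile:
    gene: str
    domains: tuple[str, ...]  # ordered N->C
    cutoffs: dict  # profile_id -> trusted bit-score cutoff
    require_signal_peptide: bool
    forbid_transmembrane: bool
    reference_protein: str = ""

    def __post_init__(self) -> None:
        if not self.domains:
            raise ValueError(f"{self.gene}: empty seed domain list")
        for d in self.domains:
            if self.cutoffs.get(d, 0) <= 0:
                raise ValueError(f"{self.gene}: missing/nonpositive cutoff for {d}")


@dataclass(frozen=True)
class HomologCall:
    protein_id: str
    genome_id: str
    gene: str
    tier: Tier
    provenance: str
    ambiguous: bool = False


def default_seed_profiles() -> dict[str, SeedProfile]:
    """Placeholder seed-domain configuration shipped with the package.

    Real runs replace the profile accessions and trusted cutoffs with the
    curated values for the four reference proteins; the shape of the config
    is what the pipeline relies on.
    """
    text = resources.files("patphylo.data").joinpath("seed_profiles.yaml").read_text()
    return load_seed_profiles_text(text)


def load_seed_profiles_text(text: str) -> dict[str, SeedProfile]:
    raw = yaml.safe_load(text)
    profiles = {}
    for gene, cfg in raw["genes"].items():
        profiles[gene] = SeedProfile(
            gene=gene,
            domains=tuple(cfg["domains"]),
            cutoffs=dict(raw["cutoffs"]),
            require_signal_peptide=bool(cfg["require_signal_peptide"]),
            forbid_transmembrane=bool(cfg.get("forbid_transmembrane", True)),
            reference_protein=cfg.get("reference_protein", ""),
        )
    return profiles


def load_seed_profiles(path: str) -> dict[str, SeedProfile]:
    with open(path) as fh:
        return load_seed_profiles_text(fh.read())


# ---------------------------------------------------------------------------
# domtblout-dialect parsing

_N_MANDATORY = 22  # columns before the free-text description


def parse_domain_hits(table_path: str) -> list[DomainHit]:
    """Parse a HMMER3 per-domain (domtblout-style) whitespace table.

    Column usage follows hmmsearch --domtblout: target name (1), query/profile
    name (4), this-domain i-Evalue (13) and bit score (14), alignment
    coordinates (18-19) and envelope coordinates (20-21), all 1-based
    inclusive in the file.
    """
    hits: list[DomainHit] = []
    with open(table_path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < _N_MANDATORY:
                raise ValueError(
                    f"{table_path}:{lineno}: expected >= {_N_MANDATORY} columns, "
                    f"got {len(cols)}"
                )
            try:
                score = float(cols[13])
                i_evalue = float(cols[12])
                ali_from, ali_to = int(cols[17]), int(cols[18])
                env_from, env_to = int(cols[19]), int(cols[20])
            except ValueError as exc:
                raise ValueError(f"{table_path}:{lineno}: {exc}") from exc
            hits.append(
                DomainHit(
                    protein_id=cols[0],
                    profile_id=cols[3],
                    score=score,
                    i_evalue=i_evalue,
                    ali_start=ali_from - 1,
                    ali_end=ali_to,
                    env_start=env_from - 1,
                    env_end=env_to,
                )
            )
    return hits


def write_domain_hits(hits: Iterable[DomainHit], path: str) -> None:
    """Emit hits in the domtblout dialect read by :func:`parse_domain_hits`."""
    with open(path, "w") as fh:
        fh.write(
            "# target_name acc tlen query_name acc qlen full_E full_score full_bias "
            "n of c_Evalue i_Evalue dom_score dom_bias hmm_from hmm_to ali_from "
            "ali_to env_from env_to acc description\n"
        )
        for h in hits:
            fh.write(
                f"{h.protein_id} - 0 {h.profile_id} - 0 "
                f"{h.i_evalue or 1e-10:.2g} {h.score:.1f} 0.0 1 1 "
                f"{h.i_evalue or 1e-10:.2g} {h.i_evalue or 1e-10:.2g} {h.score:.1f} 0.0 "
                f"1 {h.ali_end - h.ali_start} "
                f"{h.ali_start + 1} {h.ali_end} {h.env_start + 1} {h.env_end} 0.99 -\n"
            )


# ---------------------------------------------------------------------------
# filtering and architectures


def trusted_cutoffs(seed_profiles: dict[str, SeedProfile]) -> dict[str, float]:
    cutoffs: dict[str, float] = {}
    for sp in seed_profiles.values():
        cutoffs.update(sp.cutoffs)
    return cutoffs


def filter_trusted(
    hits: list[DomainHit],
    seed_profiles: dict[str, SeedProfile],
    on_missing_cutoff: Literal["drop", "error"] = "drop",
) -> list[DomainHit]:
    """Keep hits with bit score >= the profile's trusted cutoff (inclusive)."""
    cutoffs = trusted_cutoffs(seed_profiles)
    kept = []
    for h in hits:
        if h.profile_id not in cutoffs:
            if on_missing_cutoff == "error":
                raise ValueError(f"no trusted cutoff for profile {h.profile_id}")
            logger.warning("dropping hit to %s: no trusted cutoff", h.profile_id)
            continue
        if h.score >= cutoffs[h.profile_id]:
            kept.append(h)
    return kept


def architecture_of(protein_id: str, hits: list[DomainHit]) -> tuple[str, ...]:
    """Ordered domain string of one protein from its trusted hits.

    Hits are ordered by (alignment start, end, profile id); overlapping hits
    to the same profile are merged into a single occurrence when the overlap
    exceeds 50% of the shorter alignment.
    """
    mine = sorted(
        (h for h in hits if h.protein_id == protein_id),
        key=lambda h: (h.ali_start, h.ali_end, h.profile_id),
    )
    merged: list[list] = []  # [profile, start, end]
    for h in mine:
        if merged:
            prof, a, b = merged[-1]
            if prof == h.profile_id:
                overlap = min(b, h.ali_end) - max(a, h.ali_start)
                shorter = min(b - a, h.ali_end - h.ali_start)
                if shorter > 0 and overlap / shorter > 0.5:
                    merged[-1][2] = max(b, h.ali_end)
                    continue
        merged.append([h.profile_id, h.ali_start, h.ali_end])
    return tuple(m[0] for m in merged)


def architectures(hits: list[DomainHit]) -> dict[str, tuple[str, ...]]:
    by_protein: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_protein.setdefault(h.protein_id, []).append(h)
    return {pid: architecture_of(pid, hs) for pid, hs in by_protein.items()}


# ---------------------------------------------------------------------------
# tiered calls


def call_prehomologs(
    candidates: list[CandidateProtein],
    trusted_hits: list[DomainHit],
    seed_profiles: dict[str, SeedProfile],
) -> list[HomologCall]:
    """Tier pre: >= 1 seed domain of the gene above its trusted cutoff."""
    seed_of: dict[str, set[str]] = {g: set(sp.domains) for g, sp in seed_profiles.items()}
    hit_profiles: dict[str, set[str]] = {}
    for h in trusted_hits:
        hit_profiles.setdefault(h.protein_id, set()).add(h.profile_id)
    calls = []
    for cand in candidates:
        profs = hit_profiles.get(cand.protein_id, set())
        genes_hit = [g for g in seed_profiles if profs & seed_of[g]]
        for g in genes_hit:
            calls.append(
                HomologCall(
                    protein_id=cand.protein_id,
                    genome_id=cand.genome_id,
                    gene=g,
                    tier="pre",
                    provenance=cand.provenance,
                    ambiguous=len(genes_hit) > 1,
                )
            )
    return calls


def call_strict(
    prehomologs: list[HomologCall],
    archs: dict[str, tuple[str, ...]],
    seed_profiles: dict[str, SeedProfile],
) -> list[HomologCall]:
    """Tier strict: full architecture == the gene's ordered seed-domain list."""
    calls = []
    for c in prehomologs:
        if archs.get(c.protein_id, ()) == seed_profiles[c.gene].domains:
            calls.append(
                HomologCall(c.protein_id, c.genome_id, c.gene, "strict",
                            c.provenance, c.ambiguous)
            )
    return calls


def read_sp_annotations(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    need = {"protein_id", "sp_type", "probability"}
    if need - set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(need - set(df.columns))}")
    if not df["probability"].between(0, 1).all():
        raise ValueError(f"{path}: probabilities outside [0,1]")
    return df.set_index("protein_id")


def read_tm_annotations(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    need = {"protein_id", "tm_helix_count"}
    if need - set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(need - set(df.columns))}")
    if (df["tm_helix_count"] < 0).any():
        raise ValueError(f"{path}: negative tm_helix_count")
    return df.set_index("protein_id")


def triage_secreted(
    strict_calls: list[HomologCall],
    sp_annotations: pd.DataFrame,
    tm_annotations: pd.DataFrame,
    seed_profiles: dict[str, SeedProfile],
) -> list[HomologCall]:
    """Tier final: SEC/SPI present and no TM helix for the secreted genes.

    hetR calls pass through unchanged. A protein that is strict for more than
    one gene is excluded from final for all of them (logged): the one gene per
    homolog accounting requires unambiguous assignment.
    """
    strict_genes: dict[str, set[str]] = {}
    for c in strict_calls:
        strict_genes.setdefault(c.protein_id, set()).add(c.gene)
    finals = []
    for c in strict_calls:
        if len(strict_genes[c.protein_id]) > 1:
            logger.warning(
                "%s is a strict homolog of %s; excluded from final",
                c.protein_id, sorted(strict_genes[c.protein_id]),
            )
            continue
        sp = seed_profiles[c.gene]
        if sp.require_signal_peptide:
            if c.protein_id not in sp_annotations.index:
                logger.warning("no SP annotation for %s; dropped from final", c.protein_id)
                continue
            if sp_annotations.loc[c.protein_id, "sp_type"] != "SEC/SPI":
                continue
            if sp.forbid_transmembrane:
                if c.protein_id not in tm_annotations.index:
                    logger.warning("no TM annotation for %s; dropped from final", c.protein_id)
                    continue
                if int(tm_annotations.loc[c.protein_id, "tm_helix_count"]) != 0:
                    continue
        finals.append(
            HomologCall(c.protein_id, c.genome_id, c.gene, "final",
                        c.provenance, c.ambiguous)
        )
    return finals


def call_homologs(
    candidates: list[CandidateProtein],
    hits: list[DomainHit],
    sp_annotations: pd.DataFrame,
    tm_annotations: pd.DataFrame,
    seed_profiles: Optional[dict[str, SeedProfile]] = None,
) -> dict[str, list[HomologCall]]:
    """Run the full pre -> strict -> final cascade; returns calls per tier."""
    if seed_profiles is None:
        seed_profiles = default_seed_profiles()
    trusted = filter_trusted(hits, seed_profiles)
    archs = architectures(trusted)
    pre = call_prehomologs(candidates, trusted, seed_profiles)
    strict = call_strict(pre, archs, seed_profiles)
    final = triage_secreted(strict, sp_annotations, tm_annotations, seed_profiles)
    return {"pre": pre, "strict": strict, "final": final}


def calls_to_frame(calls: Iterable[HomologCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "genome_id": c.genome_id,
                "protein_id": c.protein_id,
                "gene": c.gene,
                "tier": c.tier,
                "provenance": c.provenance,
            }
            for c in calls
        ],
        columns=["genome_id", "protein_id", "gene", "tier", "provenance"],
    )
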