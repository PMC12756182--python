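"""End-to-end orchestration: cohort -> candidates -> calls -> pattern census."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from . import cooccurrence as co
from .genome_io import extract_feature_seq, translate_cds
from .homolog_calling import HomologCall, SeedProfile, call_homologs, default_seed_profiles
from .orf_extraction import (
    DEFAULT_MIN_ORF_NT,
    CandidateProtein,
    extract_noncoding_regions,
    merge_with_proteome,
    mine_genome_orfs,
)
from .synthetic_data import Cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    candidates: list  # list[CandidateProtein]
    calls: dict  # tier -> list[HomologCall]
    presence: pd.DataFrame
    counts: pd.DataFrame
    census: pd.DataFrame
    prevalence: pd.DataFrame
    flags: pd.DataFrame
    flags_per_order: Optional[pd.DataFrame]
    tier: str


def build_candidates(
    cohort: Cohort,
    orf_mining: bool = True,
    min_orf: int = DEFAULT_MIN_ORF_NT,
    min_orf_unit: str = "nt",
) -> list[CandidateProtein]:
    """Annotated proteomes merged with mined small-ORF peptides, per genome."""
    candidates: list[CandidateProtein] = []
    for genome in cohort.genomes:
        feats = cohort.features.get(genome.genome_id, [])
        proteome = {
            f.protein_id: translate_cds(extract_feature_seq(genome, f))
            for f in feats
            if f.kind == "CDS"
        }
        orfs = []
        if orf_mining:
            regions = extract_noncoding_regions(genome, feats)
            orfs = mine_genome_orfs(
                genome, regions, min_size=min_orf, min_size_unit=min_orf_unit
            )
        candidates.extend(merge_with_proteome(orfs, proteome, genome.genome_id))
    return candidates


def run_pipeline(
    cohort: Cohort,
    seed_profiles: Optional[dict] = None,
    orf_mining: bool = True,
    min_orf: int = DEFAULT_MIN_ORF_NT,
    min_orf_unit: str = "nt",
    tier: str = "final",
    percent_mode: str = "truncate",
) -> PipelineResult:
    """Run candidate building, homolog calling and the pattern census.

    ``tier`` selects which call tier defines presence ("final" by default,
    "strict" for sensitivity analysis).
    """
    t0 = time.monotonic()
    if seed_profiles is None:
        seed_profiles = default_seed_profiles()
    candidates = build_candidates(cohort, orf_mining, min_orf, min_orf_unit)
    logger.info("candidates: %d (%.1fs)", len(candidates), time.monotonic() - t0)
    calls = call_homologs(
        candidates, cohort.hits, cohort.sp_table, cohort.tm_table, seed_profiles
    )
    logger.info(
        "calls: pre=%d strict=%d final=%d",
        len(calls["pre"]), len(calls["strict"]), len(calls["final"]),
    )
    presence, counts = co.build_matrix(calls[tier], cohort.taxonomy)
    census = co.pattern_census(presence, mode=percent_mode)
    prevalence = co.gene_prevalence(presence, cohort.taxonomy, mode=percent_mode)
    flags, flags_per_order = co.coevolution_flags(
        presence, cohort.taxonomy, mode=percent_mode
    )
    logger.info("pipeline done in %.1fs", time.monotonic() - t0)
    return PipelineResult(
        candidates=candidates,
        calls=calls,
        presence=presence,
        counts=counts,
        census=census,
        prevalence=prevalence,
        flags=flags,
        flags_per_order=flags_per_order,
        tier=tier,
    )
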