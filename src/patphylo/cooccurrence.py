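"""Phyletic presence/absence patterns and their census across a genome cohort.

The gene axis is fixed as (all2656, patP, hetR, patX); a genome's phyletic
pattern is the 4-character 0/1 string over that order, e.g. "0111" when
everything but all2656 is present. Two co-evolution patterns are flagged:
A = 0111 (patP + hetR + patX) and B = 1111 (all four genes).

Percentages are, by default, truncated (floored) to the requested number of
decimals rather than rounded half-up; `percent` returns the exact rational
alongside the formatted value, and half-up rounding is available via
``mode="round"``.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Iterable, Literal, Optional

import numpy as np
import pandas as pd

from .genome_io import TaxonAnnotation
from .homolog_calling import GENES, HomologCall

PATTERN_A = "0111"
PATTERN_B = "1111"


def percent(
    count: int, total: int, decimals: int = 2, mode: Literal["truncate", "round"] = "truncate"
) -> tuple[Fraction, float]:
    """Prevalence 100*count/total as (exact rational, formatted value)."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= count <= total:
        raise ValueError("count must satisfy 0 <= count <= total")
    exact = Fraction(100 * count, total)
    scale = 10 ** decimals
    if mode == "truncate":
        formatted = (100 * count * scale // total) / scale
    else:
        formatted = float(round(exact * scale)) / scale
    return exact, formatted


def build_matrix(
    final_calls: Iterable[HomologCall],
    taxonomy: list[TaxonAnnotation],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genomes x genes binary presence matrix plus the homolog-count matrix.

    Every genome of the taxonomy gets a row, including all-zero ones; a call
    referencing a genome absent from the taxonomy is an error.
    """
    final_calls = list(final_calls)
    genome_ids = [t.genome_id for t in taxonomy]
    index = pd.Index(genome_ids, name="genome_id")
    counts = pd.DataFrame(0, index=index, columns=list(GENES), dtype=int)
    unknown = sorted({c.genome_id for c in final_calls} - set(genome_ids))
    if unknown:
        raise ValueError(f"calls reference genomes missing from taxonomy: {unknown}")
    for c in final_calls:
        counts.loc[c.genome_id, c.gene] += 1
    presence = (counts > 0).astype(int)
    return presence, counts


def pattern_code(row: Iterable[int]) -> str:
    digits = tuple(int(x) for x in row)
    if len(digits) != len(GENES) or any(d not in (0, 1) for d in digits):
        raise ValueError(f"row must be a 4-tuple over {{0,1}}, got {digits}")
    return "".join(str(d) for d in digits)


def pattern_decode(pattern: str) -> tuple[int, ...]:
    if len(pattern) != len(GENES) or set(pattern) - {"0", "1"}:
        raise ValueError(f"bad pattern {pattern!r}")
    return tuple(int(c) for c in pattern)


def genome_patterns(presence: pd.DataFrame) -> pd.Series:
    return presence.apply(lambda row: pattern_code(row.values), axis=1).rename("pattern")


def pattern_census(
    presence: pd.DataFrame, decimals: int = 1, mode: str = "truncate"
) -> pd.DataFrame:
    """Per-pattern genome counts, prevalence, and a deterministic example.

    Returns one row per observed pattern sorted by descending count then
    pattern string; the example genome is the lexicographically smallest id.
    """
    pats = genome_patterns(presence)
    rows = []
    total = len(presence)
    for pattern, group in pats.groupby(pats):
        _, prev = percent(len(group), total, decimals, mode)
        rows.append(
            {
                "pattern": pattern,
                "count": len(group),
                "prevalence_pct": prev,
                "example_genome": min(group.index),
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["count", "pattern"], ascending=[False, True]
    ).reset_index(drop=True)
    return df


def gene_prevalence(
    presence: pd.DataFrame,
    taxonomy: Optional[list[TaxonAnnotation]] = None,
    group_by_order: bool = False,
    decimals: int = 2,
    mode: str = "truncate",
) -> pd.DataFrame:
    """Per-gene genome prevalence, overall or per taxonomic order."""
    rows = []
    if group_by_order:
        if taxonomy is None:
            raise ValueError("taxonomy required for per-order grouping")
        order_of = {t.genome_id: t.order for t in taxonomy}
        groups = presence.groupby(presence.index.map(order_of))
    else:
        groups = [("all", presence)]
    for group, sub in groups:
        for gene in GENES:
            count = int(sub[gene].sum())
            _, prev = percent(count, len(sub), decimals, mode)
            rows.append(
                {"gene": gene, "group": group, "count": count,
                 "n_genomes": len(sub), "prevalence_pct": prev}
            )
    return pd.DataFrame(rows)


def homolog_share(
    counts: pd.DataFrame,
    taxonomy: list[TaxonAnnotation],
    decimals: int = 1,
    mode: str = "truncate",
) -> pd.DataFrame:
    """Per-gene share of HOMOLOGS (not genomes) found in each order.

    This is the statistic behind phrasings like "63.5% of patX homologs are
    in Nostocales": the denominator is the gene's total homolog count.
    """
    order_of = {t.genome_id: t.order for t in taxonomy}
    per_order = counts.groupby(counts.index.map(order_of)).sum()
    rows = []
    for gene in GENES:
        total = int(counts[gene].sum())
        for order, n in per_order[gene].items():
            if total == 0:
                continue
            _, share = percent(int(n), total, decimals, mode)
            rows.append(
                {"gene": gene, "order": order, "homologs": int(n),
                 "total_homologs": total, "share_pct": share}
            )
    return pd.DataFrame(rows)


def coevolution_flags(
    presence: pd.DataFrame,
    taxonomy: Optional[list[TaxonAnnotation]] = None,
    decimals: int = 1,
    mode: str = "truncate",
) -> tuple[pd.DataFrame, Optional[pd.DataFrame]]:
    """Flag pattern A (0111) and B (1111) per genome; optional per-order rates."""
    pats = genome_patterns(presence)
    flags = pd.DataFrame(
        {"pattern": pats, "pattern_A": pats == PATTERN_A, "pattern_B": pats == PATTERN_B}
    )
    per_order = None
    if taxonomy is not None:
        order_of = {t.genome_id: t.order for t in taxonomy}
        rows = []
        for order, sub in flags.groupby(flags.index.map(order_of)):
            for name in ("pattern_A", "pattern_B"):
                _, prev = percent(int(sub[name].sum()), len(sub), decimals, mode)
                rows.append(
                    {"order": order, "flag": name, "count": int(sub[name].sum()),
                     "n_genomes": len(sub), "prevalence_pct": prev}
                )
        per_order = pd.DataFrame(rows)
    return flags, per_order


def family_collapse(
    presence: pd.DataFrame, taxonomy: list[TaxonAnnotation]
) -> pd.DataFrame:
    """Merge identical patterns within each family into one row with multiplicity."""
    family_of = {t.genome_id: t.family for t in taxonomy}
    order_of = {t.genome_id: t.order for t in taxonomy}
    pats = genome_patterns(presence)
    df = pd.DataFrame(
        {
            "family": presence.index.map(family_of),
            "order": presence.index.map(order_of),
            "pattern": pats,
        }
    )
    collapsed = (
        df.groupby(["order", "family", "pattern"], sort=True)
        .size()
        .rename("multiplicity")
        .reset_index()
    )
    return collapsed


def render_profile(
    presence: pd.DataFrame,
    tree,
    taxonomy: list[TaxonAnnotation],
    out_tsv: Optional[str] = None,
    out_plot: Optional[str] = None,
) -> pd.DataFrame:
    """Tree-tip-ordered presence table with morphology, optionally plotted.

    Tips may be genome ids or order names; unmapped tips yield a warning row
    of blanks, matrix rows without a tip are appended after the tree-ordered
    block and flagged.
    """
    from .genome_io import tip_labels

    order_of = {t.genome_id: t.order for t in taxonomy}
    morph_of = {t.genome_id: t.morphology for t in taxonomy}
    tips = tip_labels(tree)
    by_order: dict[str, list[str]] = {}
    for gid in presence.index:
        by_order.setdefault(order_of.get(gid, ""), []).append(gid)

    rows, placed = [], set()
    for tip in tips:
        if tip in presence.index:
            gids = [tip]
        elif tip in by_order:
            gids = sorted(by_order[tip])
        else:
            import logging

            logging.getLogger(__name__).warning("tree tip %r has no matrix row", tip)
            rows.append({"tip": tip, "genome_id": "", "morphology": "",
                         **{g: "" for g in GENES}, "unmapped_tip": True})
            continue
        for gid in gids:
            placed.add(gid)
            rows.append(
                {"tip": tip, "genome_id": gid, "morphology": morph_of.get(gid, ""),
                 **{g: int(presence.loc[gid, g]) for g in GENES}, "unmapped_tip": False}
            )
    for gid in presence.index:
        if gid not in placed:
            rows.append(
                {"tip": "", "genome_id": gid, "morphology": morph_of.get(gid, ""),
                 **{g: int(presence.loc[gid, g]) for g in GENES}, "unmapped_tip": False}
            )
    table = pd.DataFrame(rows)
    if out_tsv:
        table.to_csv(out_tsv, sep="\t", index=False)
    if out_plot:
        _plot_profile(table, out_plot)
    return table


def _plot_profile(table: pd.DataFrame, path: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = table[table["genome_id"] != ""]
    mat = data[list(GENES)].astype(int).values
    fig, ax = plt.subplots(figsize=(4, max(2, 0.18 * len(data))))
    ax.imshow(mat, aspect="auto", cmap="Greys", vmin=0, vmax=1)
    ax.set_xticks(range(len(GENES)), GENES, rotation=45, ha="right")
    ax.set_yticks(range(len(data)), data["genome_id"], fontsize=4)
    ax.set_title("gene presence")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
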