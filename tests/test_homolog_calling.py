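import random
import textwrap

import pandas as pd
import pytest

from patphylo.homolog_calling import (
    GENES,
    DomainHit,
    SeedProfile,
    architecture_of,
    architectures,
    call_homologs,
    call_prehomologs,
    call_strict,
    default_seed_profiles,
    filter_trusted,
    parse_domain_hits,
    triage_secreted,
)
from patphylo.orf_extraction import CandidateProtein


def hit(pid, prof, score, a, b):
    return DomainHit(pid, prof, score, 1e-10, a, b, max(a - 2, 0), b + 2)


@pytest.fixture
def profiles():
    return default_seed_profiles()


def sp_frame(rows):
    return pd.DataFrame(
        rows, columns=["protein_id", "sp_type", "probability"]
    ).set_index("protein_id")


def tm_frame(rows):
    return pd.DataFrame(rows, columns=["protein_id", "tm_helix_count"]).set_index(
        "protein_id"
    )


class TestParseDomainHits:
    ROW = (
        "P1 - 200 SEED_HETR - 100 1e-30 120.0 0.1 1 1 "
        "1e-30 1e-30 {score} 0.1 1 100 {af} {at} 9 112 0.98 -"
    )

    def test_well_formed_rows(self, tmp_path):
        path = tmp_path / "hits.domtbl"
        rows = [self.ROW.format(score=40.0, af=10, at=110)] * 3
        path.write_text("# comment\n" + "\n".join(rows) + "\n")
        hits = parse_domain_hits(str(path))
        assert len(hits) == 3
        h = hits[0]
        # 1-based inclusive [10,110] -> 0-based half-open [9,110)
        assert (h.protein_id, h.profile_id, h.score) == ("P1", "SEED_HETR", 40.0)
        assert (h.ali_start, h.ali_end) == (9, 110)

    def test_comments_only_gives_empty_list(self, tmp_path):
        path = tmp_path / "hits.domtbl"
        path.write_text("# a\n# b\n")
        assert parse_domain_hits(str(path)) == []

    def test_non_numeric_score_names_the_line(self, tmp_path):
        path = tmp_path / "hits.domtbl"
        path.write_text(self.ROW.format(score="oops", af=10, at=110) + "\n")
        with pytest.raises(ValueError, match=r":1"):
            parse_domain_hits(str(path))

    def test_short_row_rejected(self, tmp_path):
        path = tmp_path / "hits.domtbl"
        path.write_text("P1 SEED_HETR 40.0\n")
        with pytest.raises(ValueError, match="columns"):
            parse_domain_hits(str(path))


class TestFilterTrusted:
    def test_boundary_score_kept(self, profiles):
        kept = filter_trusted([hit("P", "SEED_HETR", 25.0, 0, 50)], profiles)
        assert len(kept) == 1

    def test_below_cutoff_dropped(self, profiles):
        assert filter_trusted([hit("P", "SEED_HETR", 24.9, 0, 50)], profiles) == []

    def test_matches_bruteforce_filter(self, profiles):
        rng = random.Random(0)
        cutoffs = {}
        for sp in profiles.values():
            cutoffs.update(sp.cutoffs)
        hits = [
            hit(f"P{i}", rng.choice(list(cutoffs)), rng.uniform(10, 40), 0, 50)
            for i in range(200)
        ]
        kept = filter_trusted(hits, profiles)
        assert kept == [h for h in hits if h.score >= cutoffs[h.profile_id]]

    def test_unknown_profile_drop_or_error(self, profiles):
        hits = [hit("P", "NOT_A_PROFILE", 99.0, 0, 50)]
        assert filter_trusted(hits, profiles) == []
        with pytest.raises(ValueError):
            filter_trusted(hits, profiles, on_missing_cutoff="error")


class TestArchitecture:
    def test_ordered_by_alignment_start(self):
        hits = [hit("P", "D1", 30, 10, 60), hit("P", "D2", 30, 80, 120)]
        assert architecture_of("P", hits) == ("D1", "D2")
        assert architecture_of("P", hits[::-1]) == ("D1", "D2")

    def test_same_profile_overlap_merged(self):
        # 90% overlap of the shorter hit -> one occurrence
        hits = [hit("P", "D1", 30, 10, 110), hit("P", "D1", 30, 20, 110)]
        assert architecture_of("P", hits) == ("D1",)
        # oracle: two same-profile hits merge iff overlap > 50% of the shorter
        a, b = (10, 110), (20, 110)
        overlap = min(a[1], b[1]) - max(a[0], b[0])
        assert overlap / min(a[1] - a[0], b[1] - b[0]) > 0.5

    def test_disjoint_same_profile_not_merged(self):
        hits = [hit("P", "D1", 30, 0, 40), hit("P", "D1", 30, 60, 100)]
        assert architecture_of("P", hits) == ("D1", "D1")


class TestTierRules:
    def cands(self, *pids):
        return [CandidateProtein(p, "G1", "MAAA", "annotated") for p in pids]

    def test_single_seed_domain_gives_pre_call(self, profiles):
        calls = call_prehomologs(
            self.cands("P"), [hit("P", "SEED_HETR", 30, 0, 50)], profiles
        )
        assert [(c.gene, c.tier) for c in calls] == [("hetR", "pre")]

    def test_no_seed_hit_no_call(self, profiles):
        assert call_prehomologs(self.cands("P"), [], profiles) == []

    def test_two_gene_seed_hits_flagged_ambiguous(self, profiles):
        hits = [hit("P", "SEED_HETR", 30, 0, 50), hit("P", "SEED_PATX", 30, 60, 100)]
        calls = call_prehomologs(self.cands("P"), hits, profiles)
        assert sorted(c.gene for c in calls) == ["hetR", "patX"]
        assert all(c.ambiguous for c in calls)

    def test_strict_requires_exact_ordered_architecture(self, profiles):
        pre = call_prehomologs(
            self.cands("P"), [hit("P", "SEED_PATP_N", 30, 0, 50)], profiles
        )
        ok = {"P": ("SEED_PATP_N", "SEED_PATP_C")}
        wrong_order = {"P": ("SEED_PATP_C", "SEED_PATP_N")}
        extra = {"P": ("SEED_PATP_N", "SEED_PATP_C", "EXTRA_DOM")}
        assert [c.tier for c in call_strict(pre, ok, profiles)] == ["strict"]
        assert call_strict(pre, wrong_order, profiles) == []
        assert call_strict(pre, extra, profiles) == []

    def test_triage_applies_sp_tm_to_secreted_genes_only(self, profiles):
        pre = [
            hit("PX", "SEED_PATX", 30, 0, 40),
            hit("PP", "SEED_PATP_N", 30, 0, 50),
            hit("PP", "SEED_PATP_C", 30, 60, 110),
            hit("HR", "SEED_HETR", 30, 0, 50),
        ]
        cands = self.cands("PX", "PP", "HR")
        calls = call_homologs(
            cands,
            pre,
            sp_frame([("PX", "SEC/SPI", 0.99), ("PP", "SEC/SPI", 0.99)]),
            tm_frame([("PX", 0), ("PP", 2)]),
            profiles,
        )
        finals = {(c.protein_id, c.gene) for c in calls["final"]}
        # patX passes SP+TM screen; patP decoy has 2 TM helices; hetR exempt
        assert finals == {("PX", "patX"), ("HR", "hetR")}

    def test_hetr_final_without_any_sp_annotation(self, profiles):
        strict = call_strict(
            call_prehomologs(self.cands("HR"), [hit("HR", "SEED_HETR", 30, 0, 50)], profiles),
            {"HR": ("SEED_HETR",)},
            profiles,
        )
        finals = triage_secreted(strict, sp_frame([]), tm_frame([]), profiles)
        assert [(c.gene, c.tier) for c in finals] == [("hetR", "final")]

    def test_protein_strict_for_two_genes_excluded_from_final(self, profiles):
        # identical seed lists make a protein strict for two synthetic genes
        twin = {
            "g1": SeedProfile("g1", ("D",), {"D": 25.0}, False, False),
            "g2": SeedProfile("g2", ("D",), {"D": 25.0}, False, False),
        }
        pre = call_prehomologs(self.cands("P"), [hit("P", "D", 30, 0, 50)], twin)
        strict = call_strict(pre, {"P": ("D",)}, twin)
        assert len(strict) == 2
        assert triage_secreted(strict, sp_frame([]), tm_frame([]), twin) == []


class TestInvariants:
    def test_tier_monotonicity_and_shuffle_determinism(self, cohort474, result474):
        by_tier = {
            t: {(c.protein_id, c.gene) for c in result474.calls[t]}
            for t in ("pre", "strict", "final")
        }
        assert by_tier["final"] <= by_tier["strict"] <= by_tier["pre"]

        # shuffling hit-table row order changes no call
        rng = random.Random(1)
        shuffled = list(cohort474.hits)
        rng.shuffle(shuffled)
        calls = call_homologs(
            result474.candidates, shuffled, cohort474.sp_table, cohort474.tm_table
        )
        for tier in ("pre", "strict", "final"):
            assert {(c.protein_id, c.gene) for c in calls[tier]} == by_tier[tier]
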