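from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from patphylo.cooccurrence import (
    build_matrix,
    coevolution_flags,
    family_collapse,
    gene_prevalence,
    genome_patterns,
    homolog_share,
    pattern_census,
    pattern_code,
    pattern_decode,
    percent,
    render_profile,
)
from patphylo.genome_io import TaxonAnnotation
from patphylo.homolog_calling import GENES, HomologCall


def call(gid, gene, pid=None):
    return HomologCall(pid or f"{gid}_{gene}", gid, gene, "final", "annotated")


def tax(*gids, order="Nostocales", family="fam", morphology="H"):
    return [TaxonAnnotation(g, order, family, morphology) for g in gids]


def presence_of(rows: dict) -> pd.DataFrame:
    return pd.DataFrame.from_dict(
        {g: list(map(int, p)) for g, p in rows.items()},
        orient="index", columns=list(GENES),
    ).rename_axis("genome_id")


class TestPercent:
    def test_printed_prevalence_values(self):
        assert percent(72, 474, 2)[1] == 15.18
        assert percent(118, 237, 1)[1] == 49.7  # truncation of 49.78...
        assert percent(0, 474, 2)[1] == 0.00

    def test_exact_rational_returned(self):
        exact, _ = percent(72, 474, 2)
        assert exact == Fraction(7200, 474)

    def test_round_mode_differs_when_digit_would_round_up(self):
        assert percent(72, 474, 2, mode="round")[1] == 15.19

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            percent(1, 0, 2)
        with pytest.raises(ValueError):
            percent(5, 4, 2)

    @given(st.integers(0, 1000), st.integers(1, 1000), st.integers(0, 4))
    @settings(max_examples=100, deadline=None)
    def test_truncation_never_exceeds_exact_value(self, count, total, decimals):
        if count > total:
            return
        exact, formatted = percent(count, total, decimals)
        scale = 10**decimals
        t = 100 * count * scale // total
        assert formatted == t / scale
        assert Fraction(t, scale) <= exact < Fraction(t + 1, scale)


class TestBuildMatrix:
    def test_zero_rows_for_genomes_without_calls(self):
        taxonomy = tax("G1", "G2", "G3")
        calls = [call("G1", "patP"), call("G2", "patP"), call("G2", "hetR"),
                 call("G2", "patX")]
        presence, counts = build_matrix(calls, taxonomy)
        pats = genome_patterns(presence)
        assert pats.to_dict() == {"G1": "0100", "G2": "0111", "G3": "0000"}

    def test_multiple_homologs_counted_once_for_presence(self):
        taxonomy = tax("G1")
        calls = [call("G1", "patP", "a"), call("G1", "patP", "b")]
        presence, counts = build_matrix(calls, taxonomy)
        assert presence.loc["G1", "patP"] == 1
        assert counts.loc["G1", "patP"] == 2

    def test_empty_calls_gives_all_zero_matrix(self):
        presence, _ = build_matrix([], tax("G1", "G2"))
        assert presence.values.sum() == 0 and len(presence) == 2

    def test_unknown_genome_rejected(self):
        with pytest.raises(ValueError, match="GX"):
            build_matrix([call("GX", "patP")], tax("G1"))


class TestPatternCode:
    @pytest.mark.parametrize(
        "row,code", [((0, 1, 1, 1), "0111"), ((1, 1, 1, 1), "1111"), ((0, 0, 0, 0), "0000")]
    )
    def test_encode(self, row, code):
        assert pattern_code(row) == code

    @given(st.tuples(*[st.integers(0, 1)] * 4))
    @settings(max_examples=16, deadline=None)
    def test_bijection(self, row):
        assert pattern_decode(pattern_code(row)) == row

    def test_bad_rows_rejected(self):
        with pytest.raises(ValueError):
            pattern_code((0, 1))
        with pytest.raises(ValueError):
            pattern_code((0, 1, 2, 1))


class TestCensus:
    def test_two_pattern_split(self):
        rows = {f"G{i}": "0100" for i in range(5)}
        rows.update({f"H{i}": "0111" for i in range(5)})
        census = pattern_census(presence_of(rows))
        assert len(census) == 2
        assert set(census["prevalence_pct"]) == {50.0}

    def test_single_pattern_at_100(self):
        census = pattern_census(presence_of({"G1": "0110", "G2": "0110"}))
        assert census.iloc[0]["prevalence_pct"] == 100.0
        assert census.iloc[0]["example_genome"] == "G1"

    @pytest.mark.parametrize("seed", range(10))
    def test_counts_match_bruteforce_tally(self, seed):
        rng = np.random.default_rng(seed)
        mat = rng.integers(0, 2, size=(rng.integers(1, 60), 4))
        presence = pd.DataFrame(mat, columns=list(GENES),
                                index=[f"G{i}" for i in range(len(mat))])
        census = pattern_census(presence)
        tally: dict = {}
        for row in mat:
            code = "".join(map(str, row))
            tally[code] = tally.get(code, 0) + 1
        assert dict(zip(census["pattern"], census["count"])) == tally
        assert census["count"].sum() == len(mat)


class TestPrevalence:
    def test_gene_prevalence_known_fraction(self):
        rows = {f"G{i:03d}": ("1000" if i < 72 else "0000") for i in range(474)}
        prev = gene_prevalence(presence_of(rows))
        assert prev[prev.gene == "all2656"]["prevalence_pct"].item() == 15.18

    def test_all_positive_column(self):
        prev = gene_prevalence(presence_of({"G1": "0100", "G2": "1100"}))
        assert prev[prev.gene == "patP"]["prevalence_pct"].item() == 100.0

    def test_grouped_counts_partition_ungrouped(self):
        rng = np.random.default_rng(3)
        rows = {f"G{i}": "".join(map(str, rng.integers(0, 2, 4))) for i in range(40)}
        taxonomy = [
            TaxonAnnotation(g, f"Order{i % 3}", "fam", "U")
            for i, g in enumerate(rows)
        ]
        presence = presence_of(rows)
        total = gene_prevalence(presence)
        grouped = gene_prevalence(presence, taxonomy, group_by_order=True)
        for gene in GENES:
            assert (
                grouped[grouped.gene == gene]["count"].sum()
                == total[total.gene == gene]["count"].item()
            )

    def test_homolog_share_denominator_is_homologs_not_genomes(self):
        taxonomy = tax("G1") + tax("G2", order="Oscillatoriales")
        calls = [call("G1", "patX", "a"), call("G1", "patX", "b"),
                 call("G2", "patX", "c")]
        _, counts = build_matrix(calls, taxonomy)
        share = homolog_share(counts, taxonomy)
        nosto = share[(share.gene == "patX") & (share.order == "Nostocales")]
        assert nosto["share_pct"].item() == 66.6  # 2 of 3 homologs, truncated


class TestCoevolutionFlags:
    @pytest.mark.parametrize(
        "pattern,a,b", [("0111", True, False), ("1111", False, True), ("0101", False, False)]
    )
    def test_flags(self, pattern, a, b):
        flags, _ = coevolution_flags(presence_of({"G1": pattern}))
        assert bool(flags.loc["G1", "pattern_A"]) is a
        assert bool(flags.loc["G1", "pattern_B"]) is b

    def test_flags_mutually_exclusive_everywhere(self, result474):
        assert not (result474.flags["pattern_A"] & result474.flags["pattern_B"]).any()


class TestFamilyCollapse:
    def test_identical_patterns_merge_with_multiplicity(self):
        taxonomy = tax("G1", "G2", "G3", family="famA")
        collapsed = family_collapse(
            presence_of({"G1": "0100", "G2": "0100", "G3": "0100"}), taxonomy
        )
        assert collapsed["multiplicity"].tolist() == [3]

    def test_distinct_patterns_stay_separate(self):
        taxonomy = tax("G1", "G2", family="famA")
        collapsed = family_collapse(
            presence_of({"G1": "0100", "G2": "0110"}), taxonomy
        )
        assert sorted(collapsed["multiplicity"]) == [1, 1]

    @pytest.mark.parametrize("seed", range(5))
    def test_collapse_conserves_total_genome_count(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 50))
        rows = {f"G{i}": "".join(map(str, rng.integers(0, 2, 4))) for i in range(n)}
        taxonomy = [
            TaxonAnnotation(g, f"O{i % 2}", f"F{i % 4}", "U")
            for i, g in enumerate(rows)
        ]
        collapsed = family_collapse(presence_of(rows), taxonomy)
        assert collapsed["multiplicity"].sum() == n


class TestRenderProfile:
    def make_tree(self, tmp_path, newick):
        from patphylo.genome_io import read_tree

        p = tmp_path / "t.nwk"
        p.write_text(newick)
        return read_tree(str(p))

    def test_rows_in_tree_tip_order(self, tmp_path):
        tree = self.make_tree(tmp_path, "(G3,(G1,G2));")
        taxonomy = tax("G1", "G2", "G3")
        table = render_profile(
            presence_of({"G1": "0100", "G2": "0111", "G3": "0000"}), tree, taxonomy
        )
        assert table["genome_id"].tolist() == ["G3", "G1", "G2"]

    def test_unmapped_tip_gets_blank_row(self, tmp_path):
        tree = self.make_tree(tmp_path, "(G1,GX);")
        table = render_profile(presence_of({"G1": "0100"}), tree, tax("G1"))
        assert table[table["tip"] == "GX"]["unmapped_tip"].item()

    def test_matrix_row_without_tip_appended(self, tmp_path):
        tree = self.make_tree(tmp_path, "(G1);")
        table = render_profile(
            presence_of({"G1": "0100", "G2": "0111"}), tree, tax("G1", "G2")
        )
        assert table.iloc[-1]["genome_id"] == "G2" and table.iloc[-1]["tip"] == ""


class TestGlobalInvariants:
    def test_pattern_marginals_equal_gene_prevalence(self, result474):
        census = result474.census
        assert census["count"].sum() == len(result474.presence)
        for gi, gene in enumerate(GENES):
            marginal = census[census["pattern"].str[gi] == "1"]["count"].sum()
            assert marginal == result474.presence[gene].sum()

    def test_prevalence_invariant_under_genome_reordering(self):
        rng = np.random.default_rng(11)
        rows = {f"G{i}": "".join(map(str, rng.integers(0, 2, 4))) for i in range(30)}
        presence = presence_of(rows)
        shuffled = presence.sample(frac=1, random_state=5)
        a = gene_prevalence(presence).set_index("gene")["prevalence_pct"]
        b = gene_prevalence(shuffled).set_index("gene")["prevalence_pct"]
        assert (a == b).all()
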