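"""Substrate-set algebra, positional composition and clustering."""

import io

import numpy as np
import pandas as pd
import pytest
from Bio import Phylo

from oligopm.errors import ValidationError
from oligopm.peptides import peptide
from oligopm.profiles import (
    SubstrateSet,
    cluster_profiles,
    combination_specific,
    composition_permutation_pvalue,
    consumed_set,
    export_heatmap,
    level_difference_set,
    positional_composition,
    specific_fraction,
    to_newick,
)
from oligopm.scoring import ProfileMatrix
from oligopm.simulate import random_peptides, sample_enriched_set


def matrix_from(rows: dict[str, list[int]], peptides: list) -> ProfileMatrix:
    levels = pd.DataFrame(
        rows, index=[p.display_name for p in peptides]
    ).T.astype("Int64")
    levels.index.name = "strain_id"
    return ProfileMatrix.from_levels(levels, peptides)


@pytest.fixture()
def small_matrix():
    peps = [peptide(s) for s in ("GL", "GA", "HP", "WY", "FE")]
    return matrix_from(
        {
            "wt": [2, 4, 1, 3, 5],
            "pair": [1, 4, 0, 3, 5],
            "s1": [0, 4, 0, 0, 5],
            "s2": [0, 0, 0, 3, 0],
            "ko": [0, 0, 0, 0, 0],
        },
        peps,
    )


class TestConsumedSet:
    def test_all_zero_row_is_empty(self, small_matrix):
        assert len(consumed_set(small_matrix, "ko")) == 0

    def test_min_level_filters(self, small_matrix):
        assert len(consumed_set(small_matrix, "wt")) == 5
        assert len(consumed_set(small_matrix, "wt", min_level=4)) == 2
        assert len(consumed_set(small_matrix, "s2", min_level=5)) == 0

    def test_unknown_strain_rejected(self, small_matrix):
        with pytest.raises(ValidationError):
            consumed_set(small_matrix, "nope")

    def test_missing_levels_do_not_count_as_consumed(self):
        peps = [peptide("GL"), peptide("GA")]
        m = matrix_from({"a": [1, 0]}, peps)
        m.levels.iloc[0, 1] = pd.NA
        assert consumed_set(m, "a").members == frozenset({peps[0]})


class TestCombinationSpecific:
    def test_pure_additivity_gives_empty_set(self):
        peps = [peptide(s) for s in ("GL", "GA", "HP")]
        m = matrix_from({"pair": [1, 2, 0], "s1": [1, 0, 0], "s2": [0, 3, 0]}, peps)
        assert len(combination_specific(m, "pair", ["s1", "s2"])) == 0

    def test_pair_only_substrate_identified(self, small_matrix):
        # GL is consumed by pair and by neither single
        only = combination_specific(small_matrix, "pair", ["s1", "s2"])
        assert only.members == {peptide("GL")}

    def test_empty_singles_is_consumed_set(self, small_matrix):
        got = combination_specific(small_matrix, "pair", [])
        assert got.members == consumed_set(small_matrix, "pair").members

    def test_disjoint_from_each_single(self, small_matrix):
        got = combination_specific(small_matrix, "pair", ["s1", "s2"])
        for s in ("s1", "s2"):
            assert not (got.members & consumed_set(small_matrix, s).members)

    def test_planted_synergy_recovered(self, paper_like):
        scenario, _, m = paper_like
        got = combination_specific(m, scenario.pair_strain, list(scenario.single_strains))
        assert got.members == scenario.sets["synergy_59"]

    def test_level_difference_filter(self, small_matrix):
        # wt has GL at 2 vs max single 0 -> diff 2
        got = level_difference_set(small_matrix, "wt", ["s1", "s2"], min_diff=2)
        assert peptide("GL") in got.members
        assert peptide("GA") not in got.members  # 4 - 4 = 0


class TestSpecificFraction:
    def test_no_constraints_is_consumed_set(self, small_matrix):
        got = specific_fraction(small_matrix, "wt", [], [])
        assert got.members == consumed_set(small_matrix, "wt").members

    def test_reference_consuming_nothing_is_empty(self, small_matrix):
        assert len(specific_fraction(small_matrix, "ko", [], ["wt"])) == 0

    def test_subset_of_reference(self, small_matrix):
        got = specific_fraction(small_matrix, "wt", ["s1"], ["pair"])
        assert got.members <= consumed_set(small_matrix, "wt").members

    def test_planted_nonfot_fraction_recovered(self, paper_like):
        scenario, _, m = paper_like
        got = specific_fraction(
            m,
            scenario.reference_strain,
            list(scenario.lacking_strains),
            list(scenario.having_strains),
        )
        assert got.members == scenario.sets["nonfot_14"]
        assert all(p.n_terminal.code == "G" for p in got.members)


class TestPositionalComposition:
    def test_all_gly_n_terminus(self):
        s = SubstrateSet("glyx", frozenset({peptide("GL"), peptide("GA")}))
        bg = SubstrateSet("bg", frozenset({peptide("GL"), peptide("GA"), peptide("HP")}))
        table = positional_composition(s, bg, "N_terminal")
        assert table.frequencies == {"G": 1.0}
        assert table.counts["G"] == 2

    def test_set_equal_to_background_has_unit_folds(self):
        members = frozenset({peptide("GL"), peptide("HP"), peptide("WY")})
        s = SubstrateSet("s", members)
        table = positional_composition(s, SubstrateSet("bg", members), "C_terminal")
        assert all(f == pytest.approx(1.0) for f in table.fold_vs_background.values())

    def test_counts_sum_to_set_size_at_terminal_positions(self, small_matrix):
        s = consumed_set(small_matrix, "wt")
        bg = SubstrateSet("bg", frozenset(small_matrix.substrates))
        for position in ("N_terminal", "C_terminal"):
            table = positional_composition(s, bg, position)
            assert sum(table.counts.values()) == len(s)

    def test_empty_set_rejected(self):
        bg = SubstrateSet("bg", frozenset({peptide("GL")}))
        with pytest.raises(ValidationError):
            positional_composition(SubstrateSet("s", frozenset()), bg)

    def test_planted_threefold_enrichment_recovered(self):
        bg_peps = random_peptides(2000, length=3, seed=42)
        chosen = sample_enriched_set(bg_peps, "E", "C_terminal", fold=3.0, n=200, seed=43)
        s = SubstrateSet("enriched", frozenset(chosen))
        bg = SubstrateSet("bg", frozenset(bg_peps))
        table = positional_composition(s, bg, "C_terminal")
        assert 2.5 <= table.fold_vs_background["E"] <= 3.5

    def test_permutation_pvalue_detects_planted_enrichment(self):
        bg_peps = random_peptides(400, length=3, seed=42)
        chosen = sample_enriched_set(bg_peps, "E", "C_terminal", fold=3.0, n=60, seed=43)
        s = SubstrateSet("enriched", frozenset(chosen))
        bg = SubstrateSet("bg", frozenset(bg_peps))
        p = composition_permutation_pvalue(
            s, bg, "E", "C_terminal", n_resamples=199, seed=44
        )
        assert p < 0.05


class TestClustering:
    def test_identical_rows_merge_at_height_zero(self):
        peps = [peptide(s) for s in ("GL", "GA", "HP")]
        m = matrix_from({"A": [1, 2, 3], "B": [1, 2, 3], "C": [5, 0, 0]}, peps)
        cr = cluster_profiles(m, "rows")
        first = cr.linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}  # A with B
        assert first[2] == 0.0

    def test_two_block_structure_recovered_by_cutting(self, rng):
        peps = random_peptides(60, length=2, seed=9)
        block_a = {f"a{i}": (rng.integers(3, 6, 60)).tolist() for i in range(3)}
        block_b = {f"b{i}": (rng.integers(0, 2, 60)).tolist() for i in range(3)}
        m = matrix_from({**block_a, **block_b}, peps)
        cr = cluster_profiles(m, "rows")
        cut = cr.cut(2)
        a_labels = {cut[s] for s in block_a}
        b_labels = {cut[s] for s in block_b}
        assert len(a_labels) == 1 and len(b_labels) == 1 and a_labels != b_labels

    def test_label_invariance_under_row_permutation(self, paper_like):
        _, _, m = paper_like
        cr = cluster_profiles(m, "rows")
        permuted = ProfileMatrix(
            levels=m.levels.iloc[::-1], substrates=m.substrates,
            percents=m.percents.iloc[::-1],
        )
        cr2 = cluster_profiles(permuted, "rows")
        # same partition at every cut depth, independent of input order
        for k in (2, 3, 5):
            c1, c2 = cr.cut(k), cr2.cut(k)
            pairs1 = {frozenset({a, b}) for a in c1 for b in c1
                      if a < b and c1[a] == c1[b]}
            pairs2 = {frozenset({a, b}) for a in c2 for b in c2
                      if a < b and c2[a] == c2[b]}
            assert pairs1 == pairs2

    def test_single_item_axis_rejected(self):
        peps = [peptide("GL"), peptide("GA")]
        m = matrix_from({"only": [1, 2]}, peps)
        with pytest.raises(ValidationError):
            cluster_profiles(m, "rows")

    def test_newick_export_preserves_leaves(self, small_matrix):
        cr = cluster_profiles(small_matrix, "rows")
        tree = Phylo.read(io.StringIO(to_newick(cr)), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == sorted(cr.labels)


class TestExportHeatmap:
    def test_ordered_tsv_is_permutation_of_levels(self, small_matrix, tmp_path):
        rows = cluster_profiles(small_matrix, "rows")
        cols = cluster_profiles(small_matrix, "cols")
        tsv = tmp_path / "ordered.tsv"
        png = tmp_path / "heatmap.png"
        ordered = export_heatmap(small_matrix, rows, cols, str(png), str(tsv))
        assert sorted(ordered.index) == sorted(small_matrix.levels.index)
        assert sorted(ordered.columns) == sorted(small_matrix.levels.columns)
        back = pd.read_csv(tsv, sep="\t", index_col=0)
        np.testing.assert_array_equal(
            back.to_numpy(),
            small_matrix.levels.loc[back.index, back.columns].astype(int).to_numpy(),
        )
        assert png.stat().st_size > 0

    def test_tsv_deterministic_across_runs(self, small_matrix, tmp_path):
        rows = cluster_profiles(small_matrix, "rows")
        p1, p2 = tmp_path / "o1.tsv", tmp_path / "o2.tsv"
        export_heatmap(small_matrix, rows, None, None, str(p1))
        export_heatmap(small_matrix, rows, None, None, str(p2))
        assert p1.read_bytes() == p2.read_bytes()
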