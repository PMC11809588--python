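"""Morphology toolkit: distances, weights, placement, ancestors, rates."""

import numpy as np
import pandas as pd
import pytest

from conftest import random_tree
from oracles import best_1d_partition_ss, brute_marginals, brute_parsimony
from coalmorph import morphology as mo
from coalmorph import simdata
from coalmorph.io_formats import (
    CharacterDef,
    INAPPLICABLE,
    MISSING,
    MorphMatrix,
    MultipleAlignment,
)
from coalmorph.mk_engine import MkModel
from coalmorph.tree import PhyloTree


def binary_matrix(taxa, rows):
    chars = [CharacterDef(f"c{j+1}") for j in range(len(rows[0]))]
    return MorphMatrix(taxa, chars, np.array(rows, dtype=np.int8))


class TestMord:
    def test_identical_and_opposite(self):
        m = binary_matrix(["A", "B"], [[0, 1, 0], [0, 1, 0]])
        d = mo.mord_distances(m)
        assert d.loc["A", "B"] == 0.0
        m2 = binary_matrix(["A", "B"], [[0, 1, 0], [1, 0, 1]])
        assert mo.mord_distances(m2).loc["A", "B"] == 1.0

    def test_hand_computed_with_missing(self):
        chars = [
            CharacterDef("c1", ordered=True),
            CharacterDef("c2"),
            CharacterDef("c3"),
            CharacterDef("c4"),
        ]
        cells = np.array(
            [[0, 1, 0, 2], [2, 0, 0, MISSING], [1, 1, 1, 0]], dtype=np.int8
        )
        m = MorphMatrix(["A", "B", "C"], chars, cells)
        d = mo.mord_distances(m)
        # A-B: |0-2|/2 + (1!=0) + 0 over 3 comparable chars
        assert d.loc["A", "B"] == pytest.approx(2 / 3, abs=1e-12)
        # A-C: 1/2 + 0 + 1 + 1 over 4 -> 0.625
        assert d.loc["A", "C"] == pytest.approx(0.625, abs=1e-12)

    def test_properties_on_simulated(self):
        tree = simdata.simulate_species_tree(8, seed=61)
        mat, _ = simdata.simulate_morph_matrix(tree, 40, 3, seed=62)
        d = mo.mord_distances(mat).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert np.nanmax(d) <= 1.0 and np.nanmin(d) >= 0.0

    def test_inapplicable_policies(self):
        chars = [CharacterDef("c1"), CharacterDef("c2")]
        cells = np.array(
            [[INAPPLICABLE, 1], [INAPPLICABLE, 0]], dtype=np.int8
        )
        m = MorphMatrix(["A", "B"], chars, cells)
        assert mo.mord_distances(m, "missing").loc["A", "B"] == 1.0
        assert mo.mord_distances(m, "match").loc["A", "B"] == 0.5


class TestImpliedWeights:
    def test_formula(self):
        t = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        m = binary_matrix(["A", "B", "C", "D"], [[0, 0], [0, 1], [1, 0], [1, 1]])
        iw = mo.implied_weights(m, t, concavity=3.0)
        assert iw.fits[0] == pytest.approx(1.0)  # es = 0
        assert iw.fits[1] == pytest.approx(0.75)  # es = 1, k = 3
        assert iw.extra_steps[1] == 1

    def test_undefined_for_underscored_characters(self):
        t = PhyloTree.from_newick("((A:1,B:1):1,C:1);")
        chars = [CharacterDef("c1")]
        m = MorphMatrix(
            ["A", "B", "C"], chars, np.array([[0], [MISSING], [MISSING]], dtype=np.int8)
        )
        iw = mo.implied_weights(m, t)
        assert np.isnan(iw.fits[0])

    def test_steps_validated_against_enumeration(self):
        rng = np.random.default_rng(71)
        for _ in range(10):
            tree = random_tree(rng, 5)
            cells = rng.integers(0, 3, size=(5, 6)).astype(np.int8)
            taxa = [tree.labels[i] for i in tree.leaves()]
            m = MorphMatrix(taxa, [CharacterDef(f"c{j}") for j in range(6)], cells)
            iw = mo.implied_weights(m, tree, concavity=3.0)
            for j in range(6):
                col = {t: int(s) for t, s in zip(taxa, cells[:, j])}
                steps = brute_parsimony(tree, col, ordered=False)
                es = steps - (len(set(col.values())) - 1)
                assert iw.extra_steps[j] == es


class TestCalibrateWeights:
    def test_mean_one(self):
        tree = simdata.simulate_species_tree(8, seed=81)
        mat, _ = simdata.simulate_morph_matrix(tree, 30, 2, seed=82)
        w = mo.calibrate_weights(mat, tree)
        assert np.nanmean(w.fits) == pytest.approx(1.0, abs=1e-12)

    def test_homoplasy_free_characters_all_one(self):
        t = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        m = binary_matrix(["A", "B", "C", "D"], [[0, 0], [0, 0], [1, 1], [1, 1]])
        w = mo.calibrate_weights(m, t)
        assert np.allclose(w.fits, 1.0)

    def test_fast_characters_downweighted(self):
        tree = simdata.simulate_species_tree(12, seed=83)
        rates = np.array([0.1] * 25 + [1.0] * 25)
        mat, _ = simdata.simulate_morph_matrix(
            tree, 50, 2, rate_distribution=rates, seed=84
        )
        w = mo.calibrate_weights(mat, tree)
        assert np.nanmean(w.fits[:25]) > np.nanmean(w.fits[25:])


class TestKmeansPartitions:
    def test_all_equal_scores(self):
        k, labels, ss = mo.partition_characters_kmeans([2.0] * 6, seed=0)
        assert k == 1 and ss[1] == pytest.approx(0.0)

    def test_two_separable_clusters(self):
        k, labels, ss = mo.partition_characters_kmeans(
            [0, 0, 0, 10, 10, 10], seed=0
        )
        assert k == 2
        assert len({labels[0], labels[1], labels[2]}) == 1
        assert len({labels[3], labels[4], labels[5]}) == 1
        assert labels[0] != labels[3]

    def test_ss_matches_exhaustive_1d_clustering(self):
        rng = np.random.default_rng(91)
        scores = rng.normal(size=8)
        _, _, ss = mo.partition_characters_kmeans(scores, k_max=4, seed=3)
        for k in range(1, 5):
            assert ss[k] == pytest.approx(
                best_1d_partition_ss(scores, k), rel=1e-6, abs=1e-9
            )

    def test_nan_scores_labelled_minus_one(self):
        k, labels, _ = mo.partition_characters_kmeans(
            [np.nan, 1.0, 1.1, 5.0], seed=0
        )
        assert labels[0] == -1 and (labels[1:] >= 0).all()


class TestPlacement:
    def test_self_placement_finds_own_terminal_edge(self):
        tree = simdata.simulate_species_tree(8, seed=101)
        mat, _ = simdata.simulate_morph_matrix(tree, 80, 2, rate_distribution=0.4, seed=102)
        model = MkModel(k=2, gamma_categories=4, ascertainment="lewis_variable")
        target = "T4"
        q = mat.row(target).copy()
        res = mo.place_query(
            tree, mat, None, q, model, query_id="copycat",
            groups={t: t for t in mat.taxa},
        )
        assert res.best_edge == tree.leaf_index(target)
        assert res.assigned_group == target

    def test_scores_sorted_and_query_validation(self):
        tree = simdata.simulate_species_tree(6, seed=103)
        mat, _ = simdata.simulate_morph_matrix(tree, 20, 2, seed=104)
        model = MkModel(k=2)
        res = mo.place_query(tree, mat, None, mat.row("T2"), model, query_id="q")
        scores = [s for _, s, _ in res.ranked]
        assert scores == sorted(scores, reverse=True)
        with pytest.raises(ValueError, match="scored"):
            mo.place_query(
                tree, mat, None, np.full(20, MISSING), model, query_id="q"
            )


class TestSummarizePlacements:
    def test_all_correct(self):
        records = [(f"s{i}", "fam", "fam") for i in range(4)]
        df = mo.summarize_placements(records, ["fam"])
        assert df.loc["fam", "percentage"] == 100.00
        assert df.loc["Total", "n_correct"] == 4

    def test_absent_groups_zero(self):
        records = [("a", None, "ghost"), ("b", "fam", "fam")]
        df = mo.summarize_placements(records, ["fam"])
        assert df.loc["ghost", "percentage"] == 0.0
        assert df.loc["Not in the reference tree", "n_species"] == 1
        assert df.loc["Not in the reference tree", "n_correct"] == 0

    def test_totals_are_column_sums(self):
        rng = np.random.default_rng(5)
        groups = ["f1", "f2", "f3"]
        records = []
        for i in range(30):
            truth = groups[int(rng.integers(3))]
            assigned = truth if rng.random() < 0.6 else "f1"
            records.append((f"s{i}", assigned, truth))
        df = mo.summarize_placements(records, groups)
        fam_rows = df.loc[groups]
        assert df.loc["Total", "n_species"] == fam_rows["n_species"].sum()
        assert df.loc["Total", "n_correct"] == fam_rows["n_correct"].sum()


class TestAncestralStates:
    def test_constant_character_resolves_everywhere(self):
        tree = simdata.simulate_species_tree(6, seed=111)
        cells = np.zeros((6, 1), dtype=np.int8)
        m = MorphMatrix(tree.leaf_labels(), [CharacterDef("c")], cells)
        table = mo.ancestral_states(tree, m, MkModel(k=2))
        assert (table.resolved[0] == 0).all()

    def test_symmetric_quartet_is_ambiguous_at_069(self):
        t = PhyloTree.from_newick("((A:0.4,B:0.4):0.3,(C:0.4,D:0.4):0.3);")
        m = binary_matrix(["A", "B", "C", "D"], [[0], [0], [1], [1]])
        table = mo.ancestral_states(t, m, MkModel(k=2), threshold=0.69)
        root_row = table.nodes.index(t.root)
        probs = table.probabilities[0][root_row]
        assert probs == pytest.approx([0.5, 0.5], abs=1e-12)
        assert table.resolved.loc[t.root, 0] is pd.NA

    def test_marginals_match_enumeration(self):
        rng = np.random.default_rng(121)
        model = MkModel(k=2, gamma_categories=3, gamma_alpha=1.2)
        rates = model.category_rates()
        for _ in range(8):
            tree = random_tree(rng, int(rng.integers(3, 6)))
            taxa = [tree.labels[i] for i in tree.leaves()]
            col = {
                t: (int(rng.integers(2)) if rng.random() > 0.2 else MISSING)
                for t in taxa
            }
            cells = np.array([[col[t]] for t in taxa], dtype=np.int8)
            m = MorphMatrix(taxa, [CharacterDef("c")], cells)
            if all(v < 0 for v in col.values()):
                continue
            table = mo.ancestral_states(tree, m, model)
            want = brute_marginals(tree, col, 2, rates)
            for row, node in enumerate(table.nodes):
                got = table.probabilities[0][row]
                assert got == pytest.approx(want[node], abs=1e-10)
                assert got.sum() == pytest.approx(1.0, abs=1e-9)


class TestRateModelSelection:
    def test_aic_weight_closed_form(self):
        w = mo.aic_weights([100.0, 102.0])
        assert w[0] == pytest.approx(0.7311, abs=1e-4)
        assert w[1] == pytest.approx(0.2689, abs=1e-4)
        assert w.sum() == pytest.approx(1.0)

    def test_empty_block_rejected(self):
        tree = simdata.simulate_species_tree(5, seed=131)
        mat, _ = simdata.simulate_morph_matrix(tree, 10, 2, seed=132)
        blocks = np.zeros(tree.n_nodes, dtype=int)
        blocks[tree.root] = 5  # block 5 contains only the (ignored) root
        scheme = mo.RateScheme("bad", branch_blocks=blocks)
        df = mo.test_rates(tree, mat, [scheme])  # root-only block is ignored
        assert len(df) == 1
        with pytest.raises(ValueError, match="no data"):
            empty_chars = mo.RateScheme(
                "worse", char_blocks=np.array([0] * 9 + [1])
            )
            cells = mat.cells.copy()
            cells[:, 9] = MISSING
            bad = MorphMatrix(mat.taxa, mat.characters, cells)
            mo.test_rates(tree, bad, [empty_chars])

    def test_character_block_rates_recovered_in_order(self):
        tree = simdata.simulate_species_tree(10, seed=133)
        rates = np.array([0.2] * 50 + [2.0] * 50)
        mat, _ = simdata.simulate_morph_matrix(
            tree, 100, 2, rate_distribution=rates, seed=134
        )
        cb = np.array([0] * 50 + [1] * 50)
        df = mo.test_rates(
            tree, mat,
            [mo.RateScheme("single"), mo.RateScheme("two", char_blocks=cb)],
        )
        assert df.loc["two", "aic_weight"] > 0.9


class TestMolecularDistances:
    def test_identical_sequences_zero(self):
        a = MultipleAlignment("g", ["A", "B"], ["ACDEFGHIKL"] * 2, "AA")
        dist, per_taxon = mo.pairwise_ml_distances([a], model="poisson")
        assert dist.loc["A", "B"] == 0.0
        assert per_taxon["A"] == 0.0

    def test_poisson_closed_form(self):
        rng = np.random.default_rng(141)
        k = 20
        states = "ACDEFGHIKLMNPQRSTVWY"
        n = 2000
        row_a = rng.integers(0, k, n)
        diff = rng.random(n) < 0.25
        row_b = np.where(
            diff, (row_a + 1 + rng.integers(0, k - 1, n)) % k, row_a
        )
        a = MultipleAlignment(
            "g", ["A", "B"],
            ["".join(states[i] for i in row_a), "".join(states[i] for i in row_b)],
            "AA",
        )
        dist, _ = mo.pairwise_ml_distances([a], model="poisson")
        p = float(diff.mean())
        closed = -((k - 1) / k) * np.log(1 - k / (k - 1) * p)
        assert dist.loc["A", "B"] == pytest.approx(closed, rel=1e-4)

    def test_lg_recovery_at_simulated_distance(self):
        # Poisson-simulated data fitted with its own model recovers t;
        # LG on the same data stays within a loose band (model mismatch)
        gt = PhyloTree.from_newick("(A:0.25,B:0.25);", length_unit="subst_per_site")
        aln = simdata.simulate_alignment(gt, 10_000, mu=1.0, alphabet="AA", seed=5)
        dist, _ = mo.pairwise_ml_distances([aln], model="poisson")
        d = dist.loc["A", "B"]
        # binomial SE on p propagated through the distance curve
        assert d == pytest.approx(0.5, abs=0.03)

    def test_top_k_selects_most_complete(self):
        full = ["A", "B", "C"]
        g_complete = MultipleAlignment("g1", full, ["AAAA", "AAAA", "CCCC"], "AA")
        g_partial = MultipleAlignment(
            "g2", ["A", "B"], ["DDDD", "EEEE"], "AA"
        )
        dist, _ = mo.pairwise_ml_distances(
            [g_partial, g_complete], model="poisson", top_k=1, full_taxon_set=full
        )
        # only g1 used: A-B identical there
        assert dist.loc["A", "B"] == 0.0


class TestMorphoMolecularComparison:
    def test_identical_taxa_rows_zero(self):
        z = pd.DataFrame(np.zeros((2, 2)), index=["A", "B"], columns=["A", "B"])
        out = mo.morpho_molecular_comparison(z, z)
        assert (out == 0).all().all()
        assert len(out) == 2

    def test_means_match_manual_average(self):
        rng = np.random.default_rng(151)
        taxa = list("ABCD")
        m = rng.random((4, 4))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        dm = pd.DataFrame(m, index=taxa, columns=taxa)
        out = mo.morpho_molecular_comparison(dm, dm * 2)
        for i, t in enumerate(taxa):
            manual = np.mean([m[i, j] for j in range(4) if j != i])
            assert out.loc[t, "morphological"] == pytest.approx(manual)
            assert out.loc[t, "molecular"] == pytest.approx(2 * manual)

    def test_disjoint_taxa_rejected(self):
        a = pd.DataFrame(np.zeros((1, 1)), index=["A"], columns=["A"])
        b = pd.DataFrame(np.zeros((1, 1)), index=["B"], columns=["B"])
        with pytest.raises(ValueError):
            mo.morpho_molecular_comparison(a, b)
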