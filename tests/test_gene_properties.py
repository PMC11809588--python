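"""Gene filtering properties against hand values and brute-force scans."""

import numpy as np
import pytest

from coalmorph import gene_properties as gp
from coalmorph import simdata
from coalmorph.io_formats import MultipleAlignment, build_supermatrix
from coalmorph.tree import PhyloTree


class TestOccupancy:
    def test_fractions(self):
        full = [f"T{i}" for i in range(40)]
        aln = MultipleAlignment("g", full, ["A" * 5] * 40, "AA")
        assert gp.occupancy(aln, full) == 1.0
        sub = aln.subset(full[:10])
        assert gp.occupancy(sub, full) == 0.25

    def test_empty_taxon_set(self):
        aln = MultipleAlignment("g", ["A"], ["AC"], "AA")
        with pytest.raises(ValueError):
            gp.occupancy(aln, [])


class TestTreeLength:
    def test_examples(self):
        t = PhyloTree.from_newick("((A:1,B:1):0.5,C:1.5);", length_unit="subst_per_site")
        assert gp.tree_length(t) == pytest.approx(4.0)
        z = PhyloTree.from_newick("((A:0,B:0):0,C:0);", length_unit="subst_per_site")
        assert gp.tree_length(z) == 0.0

    def test_missing_lengths_error(self):
        t = PhyloTree.from_newick("((A,B),C);")
        with pytest.raises(Exception):
            gp.tree_length(t)

    def test_matches_edge_sum_oracle(self):
        rng = np.random.default_rng(3)
        from conftest import random_tree

        for _ in range(50):
            t = random_tree(rng, int(rng.integers(4, 10)))
            manual = float(sum(t.lengths[i] for i in range(t.n_nodes) if t.parent[i] >= 0))
            assert gp.tree_length(t) == pytest.approx(manual)


class TestSaturation:
    def test_low_mu_no_saturation(self):
        sp = simdata.simulate_species_tree(8, seed=21)
        aln = simdata.simulate_alignment(sp, 50_000, mu=0.01, alphabet="AA", seed=2)
        scaled = sp.with_lengths(sp.lengths * 0.01, "subst_per_site")
        assert abs(gp.saturation(aln, scaled)) < 0.05

    def test_exact_linear_slope_is_zero(self):
        # p-distances exactly equal to patristic distances (all 0.10 on a
        # star) -> through-origin slope 1, saturation 0
        star = PhyloTree.from_newick(
            "(A:0.05,B:0.05,C:0.05);", length_unit="subst_per_site"
        )
        aln = MultipleAlignment(
            "g",
            ["A", "B", "C"],
            ["A" * 90 + "CCCCC" + "AAAAA", "A" * 90 + "AAAAA" + "CCCCC",
             "A" * 90 + "GGGGG" + "GGGGG"],
            "DNA",
        )
        # pairwise p: A-B = 0.10, A-C = 0.10, B-C = 0.10; patristic all 0.10
        assert gp.saturation(aln, star) == pytest.approx(0.0, abs=1e-12)

    def test_deep_divergence_saturates(self):
        deep = PhyloTree.from_newick(
            "((A:1.5,B:1.5):1,(C:1.5,D:1.5):1);", length_unit="subst_per_site"
        )
        aln = simdata.simulate_alignment(deep, 20_000, mu=1.0, alphabet="DNA", seed=5)
        labels, pat = deep.patristic_matrix()
        iu = np.triu_indices(len(labels), 1)
        assert pat[iu].min() >= 2.0  # deep enough that p plateaus at 3/4
        assert gp.saturation(aln, deep) > 0.5


class TestRcfv:
    def test_identical_sequences_zero(self):
        aln = MultipleAlignment("g", ["A", "B", "C"], ["ACGT"] * 3, "DNA")
        assert gp.rcfv(aln) == 0.0

    def test_two_taxon_binary_contrast(self):
        aln = MultipleAlignment("g", ["A", "B"], ["AAAA", "CCCC"], "DNA")
        assert gp.rcfv(aln) == pytest.approx(1.0)

    def test_taxon_permutation_invariant(self):
        rng = np.random.default_rng(8)
        sp = simdata.simulate_species_tree(6, seed=30)
        aln = simdata.simulate_alignment(sp, 200, 0.3, alphabet="AA", seed=31)
        perm = list(rng.permutation(aln.taxa))
        assert gp.rcfv(aln.subset(perm)) == pytest.approx(gp.rcfv(aln))

    def test_all_gap_taxon_named_in_error(self):
        aln = MultipleAlignment("g", ["ok", "empty"], ["ACGT", "----"], "DNA")
        with pytest.raises(ValueError, match="empty"):
            gp.rcfv(aln)


class TestMeanPatristic:
    def test_examples(self):
        pair = PhyloTree.from_newick("(A:1,B:1);", length_unit="subst_per_site")
        assert gp.mean_patristic(pair) == pytest.approx(2.0)
        star = PhyloTree.from_newick("(A:1,B:1,C:1,D:1);", length_unit="subst_per_site")
        assert gp.mean_patristic(star) == pytest.approx(2.0)


class TestVariableSites:
    def test_limits(self):
        const = MultipleAlignment("g", ["A", "B"], ["AAAA", "AAAA"], "DNA")
        assert gp.proportion_variable_sites(const) == 0.0
        var = MultipleAlignment("g", ["A", "B"], ["ACGT", "CAAA"], "DNA")
        assert gp.proportion_variable_sites(var) == 1.0

    def test_matches_column_scan(self):
        sp = simdata.simulate_species_tree(6, seed=12)
        alns = [
            simdata.simulate_alignment(sp, 50, 0.1, seed=s, name=f"g{s}")
            for s in range(5)
        ]
        sm, _ = build_supermatrix(alns)
        manual = 0
        for j in range(sm.length):
            col = {r[j] for r in sm.rows} - {"-", "N", "X"}
            manual += len(col) >= 2
        assert gp.proportion_variable_sites(sm) == pytest.approx(manual / sm.length)


class TestRanking:
    @staticmethod
    def records(n, rng):
        return [
            gp.GenePropertyRecord(
                gene=f"OG{i:04d}",
                occupancy=float(rng.random()),
                tree_length=float(rng.random() * 10),
                saturation=float(rng.random()),
                rcfv=float(rng.random()),
                mean_patristic=float(rng.random() * 5),
            )
            for i in range(n)
        ]

    def test_full_k_returns_everything(self):
        recs = self.records(10, np.random.default_rng(0))
        assert set(gp.rank_and_subset(recs, "rcfv", 10)) == {r.gene for r in recs}

    def test_study_scale_subset(self):
        recs = self.records(2764, np.random.default_rng(1))
        best = gp.rank_and_subset(recs, "occupancy", 300)
        assert len(best) == 300
        values = {r.gene: r.occupancy for r in recs}
        cutoff = min(values[g] for g in best)
        outside = [values[r.gene] for r in recs if r.gene not in set(best)]
        assert all(v <= cutoff for v in outside)

    def test_nestedness_and_tie_determinism(self):
        recs = self.records(50, np.random.default_rng(2))
        for r in recs[:10]:
            r.saturation = 0.5  # forced ties
        k1 = gp.rank_and_subset(recs, "saturation", 8)
        k2 = gp.rank_and_subset(recs, "saturation", 20)
        assert set(k1) <= set(k2)
        assert k1 == gp.rank_and_subset(list(reversed(recs)), "saturation", 8)

    def test_unknown_property(self):
        with pytest.raises(ValueError):
            gp.rank_and_subset([], "bootstrap", 0)


def test_tree_length_ranking_tracks_rate_scaling():
    sp = simdata.simulate_species_tree(8, seed=40)
    scales = [0.3, 1.7, 0.9, 2.5, 0.1]
    trees = {f"g{i}": sp.with_lengths(sp.lengths * s, "subst_per_site")
             for i, s in enumerate(scales)}
    lengths = {g: gp.tree_length(t) for g, t in trees.items()}
    by_length = sorted(lengths, key=lengths.get)
    by_scale = [f"g{i}" for i in np.argsort(scales)]
    assert by_length == by_scale


def test_compute_gene_properties_frame():
    cfg = simdata.SimConfig(seed=13, n_taxa=6, n_genes=8, sites_per_gene=60)
    data = simdata.simulate_dataset(cfg)
    trees = {a.name: gt for a, gt in zip(data.alignments, data.gene_trees)}
    df = gp.compute_gene_properties(
        data.alignments, trees, data.species_tree.leaf_labels()
    )
    assert df.shape == (8, 5)
    assert df["occupancy"].between(0, 1).all()
    assert (df["saturation"] <= 1).all()
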