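"""ABBA-BABA / D_FOIL machinery: counting, jackknife, symmetries."""

import numpy as np
import pytest

from oracles import classify_quartet_column
from coalmorph import introgression as intro
from coalmorph import simdata
from coalmorph.io_formats import MultipleAlignment
from coalmorph.tree import PhyloTree

SPEC = intro.QuartetSpec("P1", "P2", "P3", "O")


def quartet_alignment(columns: list[str]) -> MultipleAlignment:
    """columns like 'ABBA' as residue states per taxon (A/C used)."""
    rows = ["".join(c[i] for c in columns) for i in range(4)]
    trans = str.maketrans("AB", "AC")
    return MultipleAlignment(
        "q", ["P1", "P2", "P3", "O"], [r.translate(trans) for r in rows], "DNA"
    )


class TestCombinationMatrices:
    @staticmethod
    def genes(taxa_sets):
        out = []
        for i, taxa in enumerate(taxa_sets):
            out.append(
                MultipleAlignment(
                    f"g{i}", list(taxa), ["ACGT" for _ in taxa], "DNA"
                )
            )
        return out

    def test_cartesian_count_2x2x2(self):
        genes = self.genes([["a1", "a2", "b1", "b2", "c1", "c2", "OUT"]])
        combos = intro.enumerate_combination_matrices(
            genes, [["a1", "a2"], ["b1", "b2"], ["c1", "c2"]], "OUT"
        )
        assert len(combos) == 8

    def test_family_scale_count_75(self):
        # group sizes 5 x 5 x 3 reproduce a 75-matrix design
        g1 = [f"a{i}" for i in range(5)]
        g2 = [f"b{i}" for i in range(5)]
        g3 = [f"c{i}" for i in range(3)]
        genes = self.genes([g1 + g2 + g3 + ["OUT"]])
        combos = intro.enumerate_combination_matrices(genes, [g1, g2, g3], "OUT")
        assert len(combos) == 75

    def test_four_rows_and_all_present_filtering(self):
        genes = self.genes(
            [
                ["a", "b", "c", "OUT", "extra"],
                ["a", "b", "OUT"],  # missing c -> dropped
                ["a", "b", "c", "OUT"],
            ]
        )
        combos = intro.enumerate_combination_matrices(
            genes, [["a"], ["b"], ["c"]], "OUT"
        )
        (spec, mat), = combos
        assert mat.n_taxa == 4
        assert mat.length == 8  # genes 1 and 3 only

    def test_group_validation(self):
        genes = self.genes([["a", "b", "OUT"]])
        with pytest.raises(ValueError):
            intro.enumerate_combination_matrices(genes, [["a"], ["a"], ["b"]], "OUT")
        with pytest.raises(ValueError):
            intro.enumerate_combination_matrices(genes, [["a"], ["b"], []], "OUT")


class TestQuartetCounts:
    def test_direct_counts(self):
        cols = ["ABBA"] * 3 + ["BABA"] + ["AAAA"] * 6
        counts = intro.count_quartet_patterns(quartet_alignment(cols), SPEC)
        assert counts.n_abba == 3 and counts.n_baba == 1
        assert counts.n_informative >= 4
        assert counts.n_sites_scanned == 10

    def test_gap_excluded(self):
        aln = MultipleAlignment("q", ["P1", "P2", "P3", "O"],
                                ["A-", "CC", "CC", "AA"], "DNA")
        counts = intro.count_quartet_patterns(aln, SPEC)
        assert counts.n_abba == 1 and counts.n_informative == 1
        assert counts.n_sites_scanned == 2

    def test_matches_per_column_classifier(self):
        sp = PhyloTree.from_newick(
            "(((P1:1,P2:1):1,P3:2):2,O:4);", length_unit="coalescent_units"
        )
        aln, _ = simdata.simulate_concatenated_loci(sp, 100, 50, mu=0.05, seed=7)
        counts = intro.count_quartet_patterns(aln, SPEC)
        rows = {t: aln.row(t) for t in aln.taxa}
        tally = {"abba": 0, "baba": 0, "informative": 0}
        for j in range(aln.length):
            c = classify_quartet_column(
                rows["P1"][j], rows["P2"][j], rows["P3"][j], rows["O"][j]
            )
            if c in ("abba", "baba"):
                tally[c] += 1
                tally["informative"] += 1
            elif c == "informative":
                tally["informative"] += 1
        assert counts.n_abba == tally["abba"]
        assert counts.n_baba == tally["baba"]
        assert counts.n_informative == tally["informative"]


class TestPattersonD:
    def test_formula(self):
        cols = ["ABBA"] * 3 + ["BABA"] + ["AAAA"] * 3000
        res = intro.patterson_d(quartet_alignment(cols), SPEC, block_size=1000)
        assert res.d == pytest.approx(0.5)

    def test_symmetry_zero(self):
        cols = (["ABBA"] * 5 + ["BABA"] * 5 + ["AAAA"] * 1000) * 3
        res = intro.patterson_d(quartet_alignment(cols), SPEC, block_size=1000)
        assert res.d == 0.0

    def test_swapping_p1_p2_negates_d(self):
        sp = PhyloTree.from_newick(
            "(((P1:1,P2:1):1,P3:2):2,O:4);", length_unit="coalescent_units"
        )
        pulse = simdata.IntrogressionPulse("P3", "P2", 0.5, 0.3)
        aln, _ = simdata.simulate_concatenated_loci(
            sp, 500, 100, mu=0.03, pulses=[pulse], seed=8
        )
        res = intro.patterson_d(aln, SPEC, block_size=5000)
        swapped = intro.patterson_d(
            aln, intro.QuartetSpec("P2", "P1", "P3", "O"), block_size=5000
        )
        assert swapped.d == pytest.approx(-res.d)
        assert -1.0 <= res.d <= 1.0

    def test_jackknife_invariant_under_block_permutation(self):
        sp = PhyloTree.from_newick(
            "(((P1:1,P2:1):1,P3:2):2,O:4);", length_unit="coalescent_units"
        )
        aln, _ = simdata.simulate_concatenated_loci(sp, 100, 100, mu=0.05, seed=9)
        block = 1000
        res = intro.patterson_d(aln, SPEC, block_size=block)
        # permute whole blocks of columns
        rng = np.random.default_rng(1)
        mat = aln.matrix()
        order = rng.permutation(aln.length // block)
        permuted = np.concatenate(
            [mat[:, b * block : (b + 1) * block] for b in order], axis=1
        )
        aln_p = MultipleAlignment("p", aln.taxa, permuted, "DNA")
        res_p = intro.patterson_d(aln_p, SPEC, block_size=block)
        assert res_p.se == pytest.approx(res.se, abs=1e-12)
        assert res_p.d == pytest.approx(res.d)

    def test_error_cases(self):
        with pytest.raises(ValueError, match="informative"):
            intro.patterson_d(quartet_alignment(["AAAA"] * 3000), SPEC)
        with pytest.raises(ValueError, match="block"):
            intro.patterson_d(quartet_alignment(["ABBA"] * 10), SPEC, block_size=1000)


QUINTET = intro.QuintetSpec("P1", "P2", "P3", "P4", "O")


def quintet_alignment(columns: list[str]) -> MultipleAlignment:
    rows = ["".join(c[i] for c in columns) for i in range(4)]
    rows.append("A" * len(columns))
    trans = str.maketrans("AB", "AC")
    return MultipleAlignment(
        "q5", ["P1", "P2", "P3", "P4", "O"], [r.translate(trans) for r in rows], "DNA"
    )


class TestDfoil:
    def test_symmetric_counts_give_zero_and_none(self):
        pats = ["BABA", "ABBA", "ABAB", "BAAB", "BBBA", "BBAB",
                "AAAB", "AABA", "ABAA", "BAAA"]
        cols = [p for p in pats for _ in range(50)]
        res = intro.dfoil(quintet_alignment(cols), QUINTET)
        assert all(abs(v) < 1e-12 for v in res.stats.values())
        assert res.introgression_class == "none"

    def test_insufficient_data_flag(self):
        res = intro.dfoil(quintet_alignment(["BABA"] * 10), QUINTET)
        assert not res.sufficient_data
        assert res.introgression_class == "insufficient data"

    def test_p1_p2_relabelling_swaps_fo_il_and_negates_fi_ol(self):
        sp = PhyloTree.from_newick(
            "(((P1:1,P2:1):2,(P3:2,P4:2):1):2,O:5);",
            length_unit="coalescent_units",
        )
        pulse = simdata.IntrogressionPulse("P1", "P3", 0.5, 0.4)
        aln, _ = simdata.simulate_concatenated_loci(
            sp, 500, 100, mu=0.03, pulses=[pulse], seed=13
        )
        res = intro.dfoil(aln, QUINTET)
        swapped = intro.dfoil(
            aln, intro.QuintetSpec("P2", "P1", "P3", "P4", "O")
        )
        assert swapped.stats["DFO"] == pytest.approx(res.stats["DIL"])
        assert swapped.stats["DIL"] == pytest.approx(res.stats["DFO"])
        assert swapped.stats["DFI"] == pytest.approx(-res.stats["DFI"])
        assert swapped.stats["DOL"] == pytest.approx(-res.stats["DOL"])

    def test_directional_pulse_recovers_class(self):
        sp = PhyloTree.from_newick(
            "(((P1:1,P2:1):2,(P3:2,P4:2):1):2,O:5);",
            length_unit="coalescent_units",
        )
        hits = 0
        n_reps = 15
        for rep in range(n_reps):
            pulse = simdata.IntrogressionPulse("P1", "P3", 0.5, 0.5)
            aln, _ = simdata.simulate_concatenated_loci(
                sp, 2000, 200, mu=0.02, pulses=[pulse], seed=300 + rep
            )
            res = intro.dfoil(aln, QUINTET)
            hits += res.introgression_class in ("P1=>P3", "P3=>P1")
        assert hits / n_reps >= 0.8
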