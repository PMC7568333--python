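"""Ortholog selection, trimming, concatenation, and gene ranking."""

import numpy as np
import pytest

from pterochron.clockdating import BranchRateSet, ClockModelSpec
from pterochron.errors import RosterError
from pterochron.formats import GeneAlignment, read_newick_dated
from pterochron.supermatrix import (
    GeneScore,
    OrthologSet,
    Supermatrix,
    concatenate,
    gene_support_scores,
    missing_fraction,
    select_single_copy,
    select_top_genes,
    trim_columns,
)
from pterochron.synthdata import SimulationSpec, gen_alignments


def aln(gid, taxa, length=10):
    return GeneAlignment(gid, {t: "A" * length for t in taxa})


class TestSelectSingleCopy:
    def make_set(self, genes):
        ingroup = [f"in{i}" for i in range(28)]
        outgroup = ["out1", "out2", "out3"]
        return OrthologSet(genes, ingroup, outgroup), ingroup, outgroup

    def test_threshold_arithmetic(self):
        ing = [f"in{i}" for i in range(28)]
        genes = {
            "keep": aln("keep", ing[:14] + ["out1"]),      # 14 in + 1 out
            "few_in": aln("few_in", ing[:13] + ["out1", "out2", "out3"]),
            "no_out": aln("no_out", ing[:20]),
        }
        oset, *_ = self.make_set(genes)
        assert select_single_copy(oset) == ["keep"]

    def test_zero_thresholds_keep_all(self):
        ing = [f"in{i}" for i in range(28)]
        genes = {"g1": aln("g1", ing[:2]), "g2": aln("g2", ["out1"])}
        oset, *_ = self.make_set(genes)
        assert select_single_copy(oset, min_outgroup=0, min_ingroup_frac=0.0) == [
            "g1", "g2",
        ]

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(0)
        ing = [f"in{i}" for i in range(28)]
        out = ["out1", "out2", "out3"]
        genes = {}
        for i in range(40):
            taxa = [t for t in ing if rng.random() < 0.6]
            taxa += [t for t in out if rng.random() < 0.5]
            if taxa:
                genes[f"g{i}"] = aln(f"g{i}", taxa)
        oset = OrthologSet(genes, ing, out)
        base = set(select_single_copy(oset, 1, 0.5))
        assert set(select_single_copy(oset, 2, 0.5)) <= base
        assert set(select_single_copy(oset, 1, 0.75)) <= base


class TestTrimColumns:
    def test_gappy_column_dropped(self):
        rows = {f"t{i}": ("A" if i == 0 else "-") + "AAAA" for i in range(10)}
        trimmed = trim_columns(GeneAlignment("g", rows))
        assert trimmed.length == 4

    def test_identical_alignment_untouched(self):
        g = GeneAlignment("g", {"a": "MKVL", "b": "MKVL", "c": "MKVL"})
        assert trim_columns(g).rows == g.rows

    def test_idempotent_on_random_alignments(self, rng):
        letters = np.array(list("ACDEFGHIKLMNPQRSTVWY-"))
        for _ in range(20):
            mat = rng.choice(letters, size=(8, 40), p=[0.035] * 20 + [0.3])
            rows = {f"t{i}": "".join(mat[i]) for i in range(8)}
            g = GeneAlignment("g", rows)
            once = trim_columns(g)
            twice = trim_columns(once) if once.length else once
            assert twice.rows == once.rows

    def test_all_columns_removed_warns(self):
        rows = {f"t{i}": "----" if i else "A-A-" for i in range(10)}
        with pytest.warns(UserWarning):
            out = trim_columns(GeneAlignment("g", rows))
        assert out.length == 0


class TestConcatenate:
    def test_reference_fixture(self):
        g1 = GeneAlignment("g1", {"A": "MKVLA", "B": "MKVLA", "C": "MKVLA"})
        g2 = GeneAlignment("g2", {"A": "MKVLAAA", "B": "MKVLAAA"})
        sm = concatenate([g1, g2], ["A", "B", "C"])
        assert sm.length == 12
        assert sm.partitions == {"g1": (0, 5), "g2": (5, 12)}
        assert sm.missing_fraction == pytest.approx(7 / 36)
        assert missing_fraction(sm) == pytest.approx(sm.missing_fraction)

    def test_complete_gapless_zero_missing(self):
        g = GeneAlignment("g", {"A": "MKVL", "B": "MKVL"})
        sm = concatenate([g], ["A", "B"])
        assert sm.missing_fraction == 0.0

    def test_single_gene_identity(self):
        g = GeneAlignment("g", {"A": "MK-L", "B": "MKVL"})
        sm = concatenate([g], ["A", "B"])
        assert sm.rows == g.rows and sm.partitions == {"g": (0, 4)}

    def test_unknown_taxon_rejected(self):
        g = GeneAlignment("g", {"A": "MK", "Z": "MK"})
        with pytest.raises(RosterError):
            concatenate([g], ["A", "B"])

    def test_residue_conservation(self, sim_bundle):
        _, tree, _, genes = sim_bundle
        sm = concatenate(genes, tree.taxa)
        gene_res = sum(
            sum(len(s) - s.count("-") - s.count("X") for s in g.rows.values())
            for g in genes
        )
        sm_res = sum(
            len(s) - s.count("-") - s.count("X") for s in sm.rows.values()
        )
        assert gene_res == sm_res

    def test_extremes_of_missingness(self):
        allgap = GeneAlignment("g", {"A": "--", "B": "--"})
        sm = concatenate([allgap], ["A", "B"])
        assert missing_fraction(sm) == 1.0


class TestGeneScores:
    def test_informative_gene_scores_high(self):
        """A long gene on a tree with long internal edges recovers its
        topology in essentially every bootstrap replicate."""
        tree = read_newick_dated(
            "(((A:10,B:10):40,(C:10,D:10):40):50,(E:60,F:60):40);"
        )
        rates = BranchRateSet(branch_rates=np.full(tree.n_nodes, 0.005))
        spec = SimulationSpec(
            seed=21, n_extant_taxa=6, n_genes=1, gene_length_min=1000,
            gene_length_max=1000, missing_prob=0.0, gamma_shape=None,
            gamma_categories=1,
        )
        (g,) = gen_alignments(tree, rates, spec)
        (score,) = gene_support_scores([g], n_boot=100, seed=5)
        assert score.support >= 95

    def test_uninformative_gene_scores_low(self):
        g = GeneAlignment("g", {t: "MKVLAMKVLA" for t in "ABCD"})
        (score,) = gene_support_scores([g], n_boot=50, seed=1)
        # identical sequences: an arbitrary resolution with no support signal
        assert score.support is None or score.support <= 100

    def test_small_gene_unscored(self):
        g = GeneAlignment("g", {t: "MKVL" for t in "ABC"})
        (score,) = gene_support_scores([g], n_boot=10, seed=1)
        assert score.support is None


class TestSelectTop:
    def test_ordering(self):
        scores = [GeneScore("g1", 90, 5), GeneScore("g2", 80, 5),
                  GeneScore("g3", 70, 5)]
        assert select_top_genes(scores, k=2) == ["g1", "g2"]

    def test_tie_break_lexicographic(self):
        scores = [GeneScore("b", 50, 5), GeneScore("a", 50, 5),
                  GeneScore("c", 50, 5)]
        assert select_top_genes(scores, k=1) == ["a"]

    def test_tie_break_prefers_more_taxa(self):
        scores = [GeneScore("b", 50, 9), GeneScore("a", 50, 5)]
        assert select_top_genes(scores, k=1) == ["b"]

    def test_input_order_irrelevant(self, rng):
        scores = [GeneScore(f"g{i}", float(rng.integers(0, 100)), 5)
                  for i in range(30)]
        ref = select_top_genes(scores, k=10)
        for _ in range(5):
            rng.shuffle(scores)
            assert select_top_genes(scores, k=10) == ref

    def test_too_few_scored_warns(self):
        with pytest.warns(UserWarning):
            out = select_top_genes([GeneScore("a", 10, 4)], k=5)
        assert out == ["a"]
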