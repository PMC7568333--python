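"""Pruning likelihood: closed forms, brute-force enumeration, invariances."""

import itertools
import math

import numpy as np
import pytest

from pterochron.clockdating import (
    BranchRateSet,
    PruningEngine,
    branch_lengths_from,
    encode_genes,
    log_likelihood,
)
from pterochron.formats import GeneAlignment, read_newick_dated
from pterochron.subst import discrete_gamma_rates, get_model, p_same_equal_rates


def two_taxon_rates(nu):
    return BranchRateSet(branch_rates=np.array([nu / 2, nu / 2, np.nan]))


PAIR_TREE = read_newick_dated("(A:1,B:1);")


class TestClosedForms:
    def test_zero_distance_same_residue(self):
        ll = log_likelihood(
            [GeneAlignment("g", {"A": "M", "B": "M"})], PAIR_TREE,
            two_taxon_rates(0.0), "poisson", gamma_categories=1,
        )
        assert ll == pytest.approx(math.log(1 / 20), abs=1e-12)

    @pytest.mark.parametrize("nu", [0.0, 0.1, 1.0])
    def test_equal_rates_pair_probability(self, nu):
        same = log_likelihood(
            [GeneAlignment("g", {"A": "M", "B": "M"})], PAIR_TREE,
            two_taxon_rates(nu), "poisson", gamma_categories=1,
        )
        assert same == pytest.approx(
            math.log(0.05 * p_same_equal_rates(nu)), abs=1e-10
        )
        if nu > 0:
            diff = log_likelihood(
                [GeneAlignment("g", {"A": "M", "B": "K"})], PAIR_TREE,
                two_taxon_rates(nu), "poisson", gamma_categories=1,
            )
            assert diff == pytest.approx(
                math.log(0.05 * (1 - p_same_equal_rates(nu)) / 19), abs=1e-10
            )


class TestBruteForce:
    @pytest.mark.parametrize("model,gcats", [("poisson", 1), ("lg", 4)])
    def test_four_taxa_enumeration(self, model, gcats):
        """Pruning equals summation over all internal-state assignments."""
        tree = read_newick_dated("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")
        rng = np.random.default_rng(3)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        g = GeneAlignment(
            "g", {t: "".join(rng.choice(list(aa), 10)) for t in "ABCD"}
        )
        br = np.full(tree.n_nodes, np.nan)
        for n in range(tree.n_nodes):
            if tree.parent[n] >= 0:
                br[n] = 0.25 + 0.05 * n
        rates = BranchRateSet(branch_rates=br)
        ll = log_likelihood([g], tree, rates, model, gamma_categories=gcats,
                            gamma_shape=0.7)

        m = get_model(model)
        cr = discrete_gamma_rates(0.7, gcats)
        codes = encode_genes([g], tree.taxa)
        bl = branch_lengths_from(tree, tree.ages, rates)
        total = 0.0
        for site in range(10):
            sitelik = 0.0
            for k in range(gcats):
                P = {
                    n: m.transition_matrix(bl[n] * cr[k])
                    for n in range(tree.n_nodes) if tree.parent[n] >= 0
                }
                internals = [n for n in tree.postorder if n >= tree.n_tips]
                for states in itertools.product(range(20), repeat=3):
                    st = dict(zip(internals, states))
                    for i in range(tree.n_tips):
                        st[i] = codes[i, site]
                    p = m.freqs[st[tree.root]]
                    for n in range(tree.n_nodes):
                        if tree.parent[n] >= 0:
                            p *= P[n][st[tree.parent[n]], st[n]]
                    sitelik += p / gcats
            total += math.log(sitelik)
        assert ll == pytest.approx(total, abs=1e-8)


class TestInvariances:
    def test_rate_time_confounding(self, sim_bundle):
        """Multiplying rates by c and dividing durations by c leaves the
        likelihood unchanged."""
        _, tree, rates, genes = sim_bundle
        ll1 = log_likelihood(genes, tree, rates, "poisson", gamma_categories=1)
        c = 3.7
        scaled = BranchRateSet(
            branch_rates=rates.branch_rates * c, node_rates=None
        )
        ll2 = log_likelihood(
            genes, tree, scaled, "poisson", gamma_categories=1,
            ages=tree.ages / c,
        )
        assert ll1 == pytest.approx(ll2, abs=1e-8)

    def test_missing_taxa_marginalised(self):
        """A taxon absent from a gene contributes nothing: the likelihood
        equals that of the alignment restricted to... the full tree with the
        absent row marginalised, which must match a direct 2-taxon value."""
        tree = read_newick_dated("((A:1,B:1):1,C:2);")
        g = GeneAlignment("g", {"A": "M", "B": "M"})  # C absent
        br = np.full(tree.n_nodes, np.nan)
        for n in range(tree.n_nodes):
            if tree.parent[n] >= 0:
                br[n] = 0.05
        ll = log_likelihood([g], tree, BranchRateSet(branch_rates=br),
                            "poisson", gamma_categories=1)
        pair = log_likelihood([g], PAIR_TREE, two_taxon_rates(0.1), "poisson",
                              gamma_categories=1)
        assert ll == pytest.approx(pair, abs=1e-10)

    def test_path_update_matches_full_recompute(self, sim_bundle):
        """Transactional branch updates agree with a fresh full evaluation."""
        _, tree, rates, genes = sim_bundle
        eng = PruningEngine(tree, encode_genes(genes, tree.taxa), "poisson", 1)
        bl = branch_lengths_from(tree, tree.ages, rates)
        eng.set_lengths(bl)
        rng = np.random.default_rng(5)
        for _ in range(30):
            node = int(rng.integers(tree.n_nodes - 1))
            new = {node: float(bl[node] * rng.uniform(0.5, 2))}
            eng.propose(new)
            if rng.random() < 0.5:
                eng.accept()
                bl[node] = new[node]
            else:
                eng.reject()
            fresh = PruningEngine(tree, encode_genes(genes, tree.taxa), "poisson", 1)
            assert eng.loglik == pytest.approx(fresh.set_lengths(eng.bl), abs=1e-9)

    def test_negative_duration_rejected(self, sim_bundle):
        _, tree, rates, genes = sim_bundle
        eng = PruningEngine(tree, encode_genes(genes, tree.taxa), "poisson", 1)
        with pytest.raises(ValueError):
            eng.set_lengths(np.full(tree.n_nodes, -0.1))
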