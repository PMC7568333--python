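"""Age and rate priors: moment matching, normalisation, degenerate limits."""

import numpy as np
import pytest
from scipy import integrate, stats

from pterochron.clockdating import (
    AgePrior,
    BranchRateSet,
    ClockModelSpec,
    NodeAgePriorSpec,
    bd_kernel_logcdf,
    bd_kernel_logpdf,
    cir_transition_logpdf,
    log_prior_node_ages,
    log_prior_rates,
)
from pterochron.formats import read_newick_dated
from pterochron.synthdata import gen_branch_rates


class TestRootGamma:
    def test_moment_matching(self):
        spec = NodeAgePriorSpec(root_mean=150.0, root_sd=70.0)
        assert spec.root_shape == pytest.approx(4.5918, abs=1e-4)
        assert spec.root_rate == pytest.approx(0.030612, abs=1e-6)


class TestBirthDeathKernel:
    @pytest.mark.parametrize("lam,mu,rho", [
        (0.1, 0.05, 1.0), (0.1, 0.0, 1.0), (0.2, 0.1, 0.5),
    ])
    def test_pdf_integrates_to_cdf(self, lam, mu, rho):
        for T in (10.0, 120.0):
            total, _ = integrate.quad(
                lambda t: np.exp(bd_kernel_logpdf(t, lam, mu, rho)), 0, T
            )
            assert total == pytest.approx(
                np.exp(bd_kernel_logcdf(T, lam, mu, rho)), rel=1e-8
            )

    def test_yule_kernel_is_truncated_exponential(self):
        """With mu = 0 the speciation-age kernel is Exp(lambda) truncated at
        the root age: node ages cluster toward the present, the classic
        "tippy" shape of reconstructed pure-birth trees, and increasingly so
        as the birth rate grows."""
        T = 100.0
        lam = 0.05
        ref = stats.truncexpon(b=lam * T, scale=1.0 / lam)
        for t in (1.0, 20.0, 80.0):
            lp = bd_kernel_logpdf(t, lam, 0.0) - bd_kernel_logcdf(T, lam, 0.0)
            assert lp == pytest.approx(ref.logpdf(t), rel=1e-9)
        means = []
        for lam in (0.01, 0.05, 0.2):
            f = lambda t: np.exp(
                bd_kernel_logpdf(t, lam, 0.0) - bd_kernel_logcdf(T, lam, 0.0)
            )
            m, _ = integrate.quad(lambda t: t * f(t), 0, T)
            means.append(m)
        assert means[0] > means[1] > means[2]


class TestUniformPrior:
    def test_three_taxon_internal_uniform_given_root(self):
        """Prior-only sampling: internal age | root is U(0, root)."""
        tree = read_newick_dated("((A:50,B:50):50,C:100);")
        prior = AgePrior(tree, NodeAgePriorSpec(kind="uniform"), mode="conditional")
        rng = np.random.default_rng(1)
        ratios = []
        for _ in range(20_000):
            ages = prior.sample(rng)
            inner = [n for n in tree.internal_nodes if n != tree.root][0]
            ratios.append(ages[inner] / ages[tree.root])
        d, p = stats.kstest(ratios, "uniform")
        assert d < 0.02

    def test_ordering_violation_minus_inf(self):
        tree = read_newick_dated("((A:50,B:50):50,C:100);")
        spec = NodeAgePriorSpec(kind="uniform")
        ages = tree.ages.copy()
        inner = [n for n in tree.internal_nodes if n != tree.root][0]
        ages[inner] = ages[tree.root] + 1
        assert log_prior_node_ages(tree, spec, ages) == -np.inf


class TestDirichletPrior:
    def test_finite_and_penalises_nothing_at_conc_one(self):
        tree = read_newick_dated("((A:50,B:50):50,(C:80,D:80):20);")
        spec = NodeAgePriorSpec(kind="dirichlet")
        lp = log_prior_node_ages(tree, spec)
        assert np.isfinite(lp)


class TestRatePriors:
    def test_ugam_concentrates_as_nu_vanishes(self, sim_bundle):
        _, tree, _, _ = sim_bundle
        br = np.full(tree.n_nodes, 0.01)
        br[tree.root] = np.nan
        rates = BranchRateSet(branch_rates=br)
        vals = [
            log_prior_rates(rates, tree, ClockModelSpec("UGAM", mean_rate=0.01, nu=nu))
            for nu in (1.0, 0.1, 0.01)
        ]
        assert vals[0] < vals[1] < vals[2]

    def test_lognormal_zero_sigma_degenerate(self, sim_bundle):
        _, tree, _, _ = sim_bundle
        nr = np.full(tree.n_nodes, 0.01)
        rates = BranchRateSet(branch_rates=nr, node_rates=nr)
        clock = ClockModelSpec("LOGNORMAL_AC", mean_rate=0.01, sigma2=0.0)
        assert log_prior_rates(rates, tree, clock) == 0.0
        nr2 = nr.copy()
        nr2[0] *= 2
        rates2 = BranchRateSet(branch_rates=nr, node_rates=nr2)
        assert log_prior_rates(rates2, tree, clock) == -np.inf

    @pytest.mark.parametrize("dt", [0.1, 1.0, 10.0])
    def test_cir_transition_normalised(self, dt):
        total, _ = integrate.quad(
            lambda r: np.exp(cir_transition_logpdf(r, 1.0, dt, 1.0, 1.0, 1.0)),
            0, 60, limit=200,
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_cir_feller_enforced(self, sim_bundle):
        _, tree, _, _ = sim_bundle
        nr = np.full(tree.n_nodes, 0.01)
        rates = BranchRateSet(branch_rates=nr, node_rates=nr)
        with pytest.raises(ValueError):
            ClockModelSpec("CIR", mean_rate=0.01, sigma2=1.0, theta=1.0)

    def test_density_agrees_with_simulation(self):
        """Monte-Carlo check: CIR transition density matches the histogram of
        exact simulated transitions."""
        tree = read_newick_dated("(A:5,B:5);")
        clock = ClockModelSpec("CIR", mean_rate=1.0, sigma2=0.5, theta=0.5)
        draws = np.array([
            gen_branch_rates(tree, clock, s).node_rates[0] for s in range(4000)
        ])
        starts = np.array([
            gen_branch_rates(tree, clock, s).node_rates[tree.root]
            for s in range(4000)
        ])
        # compare conditional mean E[r_t | r_0] = mu + (r0-mu) e^{-theta t}
        e = np.exp(-0.5 * 5.0)
        expected = 1.0 + (starts - 1.0) * e
        assert draws.mean() == pytest.approx(expected.mean(), rel=0.05)
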