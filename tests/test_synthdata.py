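"""Synthetic-data generators: determinism, moments, closed-form checks."""

import numpy as np
import pytest

from pterochron.clockdating import ClockModelSpec
from pterochron.formats import read_newick_dated
from pterochron.fossildiv import default_timescale
from pterochron.subst import p_same_equal_rates
from pterochron.synthdata import (
    ContaminationSpec,
    SimulationSpec,
    gen_alignments,
    gen_branch_rates,
    gen_chronogram,
    gen_contaminated_expression,
    gen_fossil_record,
)


class TestChronogram:
    def test_two_taxa_forced_cherry(self):
        spec = SimulationSpec(seed=1, n_extant_taxa=2, root_age=50.0)
        t = gen_chronogram(spec)
        assert t.n_tips == 2 and t.root_age == pytest.approx(50.0)

    def test_deterministic(self):
        spec = SimulationSpec(seed=9, n_extant_taxa=28)
        t1, t2 = gen_chronogram(spec), gen_chronogram(spec)
        assert t1.taxa == t2.taxa
        assert np.allclose(t1.ages, t2.ages)
        assert t1.to_newick() == t2.to_newick()

    def test_roundtrips_ultrametric(self):
        spec = SimulationSpec(seed=3, n_extant_taxa=15, root_age=77.0)
        t = gen_chronogram(spec)
        back = read_newick_dated(t.to_newick())
        assert back.root_age == pytest.approx(77.0, rel=1e-9)

    def test_yule_node_depths_match_order_statistics(self):
        """Mean rescaled node ages of simulated pure-birth trees agree with a
        direct Monte-Carlo of the exponential waiting-time construction."""
        n, lam = 6, 1.0
        rng = np.random.default_rng(42)
        # oracle: waiting time with k lineages ~ Exp(k*lam), k = 2..n-1, then
        # an extra holding draw at n lineages before the present
        reps = 200_000
        w = np.column_stack([
            rng.exponential(1.0 / (k * lam), size=reps) for k in range(2, n + 1)
        ])
        t_stop = w.sum(axis=1)
        # age fraction of the j-th split (j=1 root): (t_stop - tau_j)/t_stop
        taus = np.concatenate(
            [np.zeros((reps, 1)), np.cumsum(w[:, :-1], axis=1)], axis=1
        )
        oracle = ((t_stop[:, None] - taus) / t_stop[:, None]).mean(axis=0)

        sim_fracs = []
        for seed in range(3000):
            spec = SimulationSpec(
                seed=seed + 1, n_extant_taxa=n, birth_rate=lam, death_rate=0.0,
                root_age=1.0,
            )
            t = gen_chronogram(spec)
            ages = sorted(
                (t.ages[m] for m in t.postorder if m >= t.n_tips), reverse=True
            )
            sim_fracs.append(ages)
        sim = np.array(sim_fracs).mean(axis=0)
        assert np.allclose(sim, oracle[: n - 1], atol=0.02)


class TestBranchRates:
    def test_ugam_zero_variance_degenerates(self, sim_bundle):
        _, tree, _, _ = sim_bundle
        r = gen_branch_rates(tree, ClockModelSpec("UGAM", mean_rate=0.02, nu=0.0), 5)
        br = r.branch_rates[~np.isnan(r.branch_rates)]
        assert np.allclose(br, 0.02)

    def test_cir_stationary_variance(self):
        """theta=1, mean 1, sigma2=1: stationary variance sigma2*mu/(2 theta)."""
        tree = read_newick_dated("(A:1000,B:1000);")
        clock = ClockModelSpec("CIR", mean_rate=1.0, sigma2=1.0, theta=1.0)
        draws = [
            gen_branch_rates(tree, clock, seed).node_rates[tree.root]
            for seed in range(20_000)
        ]
        assert np.var(draws) == pytest.approx(0.5, rel=0.05)

    def test_cir_feller_violation_rejected(self, sim_bundle):
        _, tree, _, _ = sim_bundle
        with pytest.raises(ValueError):
            gen_branch_rates(
                tree, ClockModelSpec("CIR", mean_rate=0.01, sigma2=1.0, theta=1.0), 1
            )

    def test_lognormal_increment_moments(self):
        """Child/parent log-rate increments: mean -s2*dt/2, variance s2*dt."""
        dt, s2 = 7.0, 0.04
        tree = read_newick_dated(f"(A:{dt},B:{dt});")
        clock = ClockModelSpec("LOGNORMAL_AC", mean_rate=0.01, sigma2=s2)
        incs = []
        for seed in range(8000):
            r = gen_branch_rates(tree, clock, seed)
            incs.append(np.log(r.node_rates[0]) - np.log(r.node_rates[tree.root]))
        incs = np.array(incs)
        assert incs.mean() == pytest.approx(-s2 * dt / 2, abs=3 * np.sqrt(s2 * dt / 8000))
        assert incs.var() == pytest.approx(s2 * dt, rel=0.1)

    def test_deterministic(self, sim_bundle):
        _, tree, _, _ = sim_bundle
        clock = ClockModelSpec("CIR", mean_rate=0.01)
        a = gen_branch_rates(tree, clock, 99)
        b = gen_branch_rates(tree, clock, 99)
        assert np.allclose(a.node_rates, b.node_rates)


class TestAlignments:
    def test_zero_lengths_identical_sequences(self):
        tree = read_newick_dated("((A:1,B:1):1,C:2);")
        from pterochron.clockdating import BranchRateSet

        rates = BranchRateSet(branch_rates=np.zeros(tree.n_nodes))
        spec = SimulationSpec(
            seed=4, n_extant_taxa=3, n_genes=2, gene_length_min=30,
            gene_length_max=30, missing_prob=0.0,
        )
        genes = gen_alignments(tree, rates, spec)
        for g in genes:
            seqs = set(g.rows.values())
            assert len(seqs) == 1

    def test_missing_prob_zero_full_occupancy(self, sim_bundle):
        spec, tree, rates, _ = sim_bundle
        full = SimulationSpec(
            seed=5, n_extant_taxa=spec.n_extant_taxa, n_genes=3,
            gene_length_min=50, gene_length_max=50, missing_prob=0.0,
        )
        genes = gen_alignments(tree, rates, full)
        assert all(g.n_taxa == tree.n_tips for g in genes)

    def test_pairwise_identity_matches_closed_form(self):
        """P(same residue) at distance nu under the 20-state equal-rates
        model, within binomial error at 10^4 sites."""
        nu = 0.3
        tree = read_newick_dated("(A:1,B:1);")
        from pterochron.clockdating import BranchRateSet

        rates = BranchRateSet(
            branch_rates=np.array([nu / 2, nu / 2, np.nan])
        )
        spec = SimulationSpec(
            seed=8, n_extant_taxa=2, n_genes=1, gene_length_min=10_000,
            gene_length_max=10_000, missing_prob=0.0, gamma_shape=None,
            gamma_categories=1,
        )
        (g,) = gen_alignments(tree, rates, spec)
        a, b = (np.frombuffer(s.encode(), dtype="S1") for s in g.rows.values())
        p_hat = (a == b).mean()
        p = p_same_equal_rates(nu)
        assert p_hat == pytest.approx(p, abs=3.5 * np.sqrt(p * (1 - p) / 10_000))


class TestContamination:
    def test_zero_contamination_no_foreign_transcripts(self):
        spec = ContaminationSpec(seed=2, n_datasets=4, n_transcripts=200,
                                 library_size=50_000, contamination=0.0)
        df = gen_contaminated_expression(spec)
        assert not df["is_contaminant"].any()
        assert (df["origin_dataset"] == df["dataset_id"]).all()

    def test_single_dataset_lane_uncontaminated(self):
        spec = ContaminationSpec(
            seed=2, n_datasets=2, lanes=[[0], [1]], n_transcripts=200,
            library_size=50_000, contamination=0.3,
        )
        df = gen_contaminated_expression(spec)
        assert not df["is_contaminant"].any()

    def test_tpm_sums_to_million(self):
        spec = ContaminationSpec(seed=6, n_datasets=4, n_transcripts=300,
                                 library_size=100_000)
        df = gen_contaminated_expression(spec)
        for _, grp in df.groupby("dataset_id"):
            assert grp["tpm"].sum() == pytest.approx(1e6, rel=1e-6)

    def test_deterministic(self):
        spec = ContaminationSpec(seed=6, n_datasets=4, n_transcripts=100,
                                 library_size=20_000)
        assert gen_contaminated_expression(spec).equals(
            gen_contaminated_expression(spec)
        )


class TestFossilRecord:
    def test_full_preservation_observes_truth(self):
        ts = default_timescale()
        occ, truth = gen_fossil_record(
            ["Gymnosomata"], ts, preservation=1.0,
            richness={"Gymnosomata": 30}, seed=3,
        )
        obs = occ.groupby("stage")["species"].nunique()
        tru = truth.groupby("stage")["species"].nunique()
        assert obs.reindex(tru.index, fill_value=0).equals(tru)

    def test_zero_preservation_flat_before_recent(self):
        ts = default_timescale()
        occ, _ = gen_fossil_record(
            ["Gymnosomata"], ts, preservation=0.0,
            richness={"Gymnosomata": 30}, seed=3,
        )
        assert set(occ["stage"]) <= {ts.recent_stage}

    def test_binomial_thinning_mean(self):
        ts = default_timescale()
        p = 0.3
        obs_tot = tru_tot = 0
        for seed in range(40):
            occ, truth = gen_fossil_record(
                ["Cavolinioidea"], ts, preservation=p,
                richness={"Cavolinioidea": 30}, seed=seed,
            )
            pre = truth[truth["stage"] != ts.recent_stage]
            obs = occ[occ["stage"] != ts.recent_stage]
            tru_tot += len(pre)
            obs_tot += len(obs)
        assert obs_tot / tru_tot == pytest.approx(p, abs=0.03)
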