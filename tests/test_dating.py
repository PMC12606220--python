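"""Bayesian node dating: calibrations, MCMC, HPD, ESS and MCC summaries."""

import numpy as np
import pytest
from scipy.stats import kstest, uniform

from collagenphylo.dating import (
    Calibration,
    DatingProblem,
    PosteriorSample,
    ess,
    hpd_interval,
    mcmc_date,
    read_calibrations,
    summarize,
)
from collagenphylo.simulate import simulate_alignment
from collagenphylo.substitution import make_model
from collagenphylo.tree import Tree


class TestHpd:
    def test_uniform_width_near_mass(self, rng):
        x = rng.uniform(0, 1, 20_000)
        lo, hi = hpd_interval(x, 0.95)
        assert hi - lo == pytest.approx(0.95, abs=0.02)

    def test_constant_vector_zero_width(self):
        lo, hi = hpd_interval([3.2] * 50, 0.95)
        assert lo == hi == 3.2

    def test_bimodal_matches_window_enumeration(self, rng):
        x = np.concatenate([rng.normal(0, 0.3, 300), rng.normal(10, 0.1, 700)])
        lo, hi = hpd_interval(x, 0.90)
        xs = np.sort(x)
        m = int(np.ceil(0.90 * len(xs)))
        widths = [(xs[i + m - 1] - xs[i], xs[i], xs[i + m - 1]) for i in range(len(xs) - m + 1)]
        w, blo, bhi = min(widths)
        assert (lo, hi) == (blo, bhi)

    def test_bad_mass(self):
        with pytest.raises(ValueError):
            hpd_interval([1, 2, 3], 1.5)


class TestEss:
    def test_iid_normal_near_n(self, rng):
        x = rng.normal(size=10_000)
        e, flag = ess(x)
        assert e == pytest.approx(10_000, rel=0.10)

    def test_ar1_closed_form(self, rng):
        rho = 0.9
        n = 40_000
        x = np.empty(n)
        x[0] = rng.normal()
        eps = rng.normal(size=n) * np.sqrt(1 - rho**2)
        for i in range(1, n):
            x[i] = rho * x[i - 1] + eps[i]
        e, _ = ess(x)
        assert e == pytest.approx(n * (1 - rho) / (1 + rho), rel=0.20)

    def test_alternating_chain_flagged_above_n(self):
        x = np.tile([1.0, -1.0], 500)
        e, flag = ess(x)
        assert flag
        assert e > len(x)

    def test_constant_chain(self):
        e, flag = ess([2.0] * 100)
        assert e == 100 and flag


PRIOR_TOPO = "((A:1,B:1):1,C:2);"


class TestMcmcDate:
    def test_prior_only_uniform_calibrated_marginals(self):
        """Likelihood off, tree prior off: calibrated node ages sample their
        stated uniform(23.03, 54.6) prior (KS)."""
        topo = Tree.from_newick(PRIOR_TOPO)
        cals = [
            Calibration(frozenset("AB"), 23.03, 54.6, node="crown"),
            Calibration(frozenset("ABC"), 60.0, 80.0, node="crown"),
        ]
        chains = mcmc_date(
            None, topo, None, cals, chain_length=40_000, sample_every=20,
            n_chains=1, seeds=[3], clock="strict",
            use_likelihood=False, use_tree_prior=False,
        )
        samples = chains[0][100:]
        clades = samples[0].clades
        ab = np.array([s.ages[clades.index(frozenset("AB"))] for s in samples])
        root = np.array([s.ages[clades.index(frozenset("ABC"))] for s in samples])
        assert kstest(ab, uniform(23.03, 54.6 - 23.03).cdf).pvalue > 0.01
        assert kstest(root, uniform(60.0, 20.0).cdf).pvalue > 0.01
        # order constraints hold in every sample
        assert (root > ab).all()

    def test_zero_length_chain_errors(self):
        topo = Tree.from_newick(PRIOR_TOPO)
        with pytest.raises(ValueError):
            mcmc_date(None, topo, None, [], chain_length=0, sample_every=10,
                      use_likelihood=False)

    def test_inconsistent_calibrations_error(self):
        topo = Tree.from_newick(PRIOR_TOPO)
        cals = [
            Calibration(frozenset("AB"), 50.0, 80.0, node="crown"),
            Calibration(frozenset("ABC"), 10.0, 40.0, node="crown"),
        ]
        with pytest.raises(ValueError, match="[Ii]nconsistent|empty feasible"):
            mcmc_date(None, topo, None, cals, chain_length=100, sample_every=10,
                      use_likelihood=False)

    def test_stem_vs_crown_calibration_targets(self):
        topo = Tree.from_newick("(((A:1,B:1):1,C:2):1,D:3);")
        problem = DatingProblem(topo)
        crown = problem.calibrated_node(Calibration(frozenset("AB"), 1, 2, node="crown"))
        stem = problem.calibrated_node(Calibration(frozenset("AB"), 1, 2, node="stem"))
        assert problem.clades[crown] == frozenset("AB")
        assert problem.clades[stem] == frozenset("ABC")

    def test_strict_clock_posterior_covers_truth(self):
        """4-taxon strict-clock data: posterior root age within 2 posterior
        SDs of the truth, and all samples respect constraints."""
        truth = Tree.from_newick("(((A:10,B:10):15,C:25):15,D:40);")
        model = make_model("mtMAM")
        aln, _ = simulate_alignment(truth, model, 800, clock_mean=0.004, seed=31)
        cals = [Calibration(frozenset("ABCD"), 20.0, 60.0, node="crown")]
        chains = mcmc_date(
            aln, truth, model, cals, chain_length=12_000, sample_every=20,
            n_chains=3, seeds=[5, 6, 7], clock="strict",
            init={"clock_mean": 0.004},
        )
        pooled = [s for c in chains for s in c[len(c) // 10:]]
        clades = pooled[0].clades
        i_root = clades.index(frozenset("ABCD"))
        ages = np.array([s.ages[i_root] for s in pooled])
        assert abs(ages.mean() - 40.0) <= 2 * ages.std() + 1e-9
        # constraint check on every retained sample
        problem = DatingProblem(truth)
        for s in pooled[::50]:
            for i, p in enumerate(problem.parent):
                if p != -1 and not problem.is_leaf[i]:
                    assert s.ages[p] > s.ages[i]
            assert 20.0 <= s.ages[i_root] <= 60.0


class TestSummarize:
    def _chain(self, ages_list):
        clades = (
            frozenset("A"), frozenset("B"), frozenset("AB"),
            frozenset("C"), frozenset("ABC"),
        )
        return [
            PosteriorSample(
                step=i, ages=np.array(a), clades=clades, clock_mean=0.01,
                clock_sigma=0.1, birth=0.5, death=0.1,
                log_likelihood=-1.0, log_prior=-1.0,
            )
            for i, a in enumerate(ages_list)
        ]

    def test_fixed_topology_mcc_equals_input(self):
        chain = self._chain([[0, 0, 10, 0, 20], [0, 0, 12, 0, 22]] * 10)
        summ = summarize([chain], burnin_fraction=0.0)
        assert frozenset("AB") in summ.mcc_clades
        node = next(ns for ns in summ.nodes if ns.clade == frozenset("AB"))
        assert node.mean_age == pytest.approx(11.0)
        assert node.posterior_support == 1.0

    def test_two_identical_chains_match_single(self):
        ages = [[0, 0, float(i % 7 + 5), 0, 20.0 + i % 3] for i in range(50)]
        one = summarize([self._chain(ages)], burnin_fraction=0.1)
        two = summarize([self._chain(ages), self._chain(ages)], burnin_fraction=0.1)
        for n1 in one.nodes:
            n2 = next(n for n in two.nodes if n.clade == n1.clade)
            assert n2.mean_age == pytest.approx(n1.mean_age)
            assert n2.hpd == pytest.approx(n1.hpd)

    def test_hand_built_mcc_enumeration(self):
        """Three samples, two topologies: the MCC topology maximizes the
        product of clade frequencies (here the majority topology)."""
        clades_t1 = (frozenset("A"), frozenset("B"), frozenset("AB"),
                     frozenset("C"), frozenset("ABC"))
        clades_t2 = (frozenset("B"), frozenset("C"), frozenset("BC"),
                     frozenset("A"), frozenset("ABC"))
        def s(clades, step):
            return PosteriorSample(
                step=step, ages=np.array([0, 0, 5.0, 0, 9.0]), clades=clades,
                clock_mean=1, clock_sigma=0, birth=1, death=0,
                log_likelihood=0, log_prior=0,
            )
        chain = [s(clades_t1, 1), s(clades_t1, 2), s(clades_t2, 3)]
        summ = summarize([chain], burnin_fraction=0.0)
        assert frozenset("AB") in summ.mcc_clades
        assert frozenset("BC") not in summ.mcc_clades
        ab = next(ns for ns in summ.nodes if ns.clade == frozenset("AB"))
        assert ab.posterior_support == pytest.approx(2 / 3)

    def test_all_burned_errors(self):
        with pytest.raises(ValueError):
            summarize([self._chain([[0, 0, 1, 0, 2]])], burnin_fraction=1.0)


def test_calibration_table_round_trip(tmp_path):
    path = tmp_path / "cal.tsv"
    path.write_text(
        "taxa\tmin\tmax\tnode\n"
        "A,B\t23.03\t54.6\tcrown\n"
        "A,B,C\t23.03\t54.6\n"
    )
    cals = read_calibrations(path)
    assert cals[0] == Calibration(frozenset("AB"), 23.03, 54.6, node="crown")
    assert cals[1].node == "stem"
    with pytest.raises(ValueError):
        Calibration(frozenset("AB"), 54.6, 23.03)
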