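"""ML optimization, NNI tree search, bootstrap support and model selection."""

import itertools

import numpy as np
import pytest

from collagenphylo.likelihood import CompressedAlignment, log_likelihood
from collagenphylo.modelselect import count_free_parameters, model_select
from collagenphylo.optimize import optimize, optimize_branch_lengths
from collagenphylo.search import annotate_support, bootstrap_support, nni_search
from collagenphylo.simulate import simulate_alignment
from collagenphylo.substitution import make_model
from collagenphylo.tree import Tree, nni_neighbors
from tests.conftest import random_alignment


@pytest.fixture(scope="module")
def four_taxon_data():
    truth = Tree.from_newick("((A:0.10,B:0.20):0.05,C:0.30,D:0.15);")
    model = make_model("mtMAM")
    aln, _ = simulate_alignment(truth, model, 5000, seed=3)
    return truth, model, CompressedAlignment(aln)


class TestOptimize:
    def test_branch_length_recovery(self, four_taxon_data):
        truth, model, comp = four_taxon_data
        start = Tree.from_newick("((A:0.1,B:0.1):0.1,C:0.1,D:0.1);")
        optimize_branch_lengths(start, comp, model, rounds=5)
        est = {
            frozenset(x.name for x in Tree(n).leaves()): n.length
            for n in start.branches()
        }
        tru = {
            frozenset(x.name for x in Tree(n).leaves()): n.length
            for n in truth.branches()
        }
        for k, v in tru.items():
            # finite-sample noise on a 5000-column simulation
            assert est[k] == pytest.approx(v, rel=0.15)

    def test_optimum_is_fixed_point(self, four_taxon_data):
        truth, model, comp = four_taxon_data
        t = truth.copy()
        ll1 = optimize_branch_lengths(t, comp, model, rounds=4)
        lengths = [n.length for n in t.branches()]
        ll2 = optimize_branch_lengths(t, comp, model, rounds=1)
        assert ll2 == pytest.approx(ll1, abs=1e-3)
        assert np.allclose([n.length for n in t.branches()], lengths, atol=1e-4)

    def test_monotone_improvement(self, four_taxon_data):
        truth, model, comp = four_taxon_data
        t = Tree.from_newick("((A:1.0,B:0.01):0.5,C:0.9,D:0.002);")
        ll0 = log_likelihood(t, comp, model)
        lls = [optimize_branch_lengths(t, comp, model, rounds=1) for _ in range(3)]
        assert lls[0] >= ll0
        assert lls[1] >= lls[0] - 1e-9
        assert lls[2] >= lls[1] - 1e-9

    def test_pinv_recovery(self):
        truth = Tree.from_newick("((A:0.3,B:0.5):0.15,C:0.6,D:0.4);")
        gen = make_model("mtMAM", p_inv=0.3)
        aln, _ = simulate_alignment(truth, gen, 5000, seed=17)
        fit = make_model("mtMAM", p_inv=0.1)
        t = truth.copy()
        optimize(t, aln, fit, free_rates=False)
        assert 0.2 <= fit.p_inv <= 0.4

    def test_free_rates_stay_feasible(self, four_taxon_data):
        truth, _, comp = four_taxon_data
        model = make_model("mtMAM", p_inv=0.05, r2=(0.5, 0.5))
        t = truth.copy()
        res = optimize(t, comp, model)
        assert res.loglik == pytest.approx(log_likelihood(t, comp, model), abs=1e-6)
        assert (1 - model.p_inv) * float(model.rate_weights @ model.rates) == pytest.approx(1.0)


class TestNniSearch:
    def test_four_taxon_equals_exhaustive(self, four_taxon_data):
        truth, model, comp = four_taxon_data
        # All three unrooted quartet topologies, each optimized.
        quartets = [
            "((A:0.1,B:0.1):0.1,C:0.1,D:0.1);",
            "((A:0.1,C:0.1):0.1,B:0.1,D:0.1);",
            "((A:0.1,D:0.1):0.1,B:0.1,C:0.1);",
        ]
        scored = []
        for nwk in quartets:
            t = Tree.from_newick(nwk)
            scored.append((optimize_branch_lengths(t, comp, model, rounds=4), t))
        best_exh = max(scored, key=lambda x: x[0])
        found, ll = nni_search(comp, model, seed=2, optimize_model=False)
        assert found.topology_id() == best_exh[1].topology_id()
        assert ll == pytest.approx(best_exh[0], abs=0.01)

    def test_start_at_optimum_returns_start(self, four_taxon_data):
        truth, model, comp = four_taxon_data
        found, _ = nni_search(comp, model, start=truth, seed=0, optimize_model=False)
        assert found.topology_id() == truth.topology_id()

    def test_six_taxon_recovery_over_seeds(self):
        """Strong-signal 6-taxon data: true topology found in >=95% of 20
        seeded searches."""
        truth = Tree.from_newick(
            "(((A:0.15,B:0.15):0.1,(C:0.15,D:0.15):0.1):0.1,E:0.3,F:0.35);"
        )
        model = make_model("mtMAM")
        aln, _ = simulate_alignment(truth, model, 2000, seed=41)
        comp = CompressedAlignment(aln)
        hits = 0
        for seed in range(20):
            found, _ = nni_search(comp, model, seed=seed, optimize_model=False)
            hits += found.topology_id() == truth.topology_id()
        assert hits >= 19

    def test_too_few_taxa(self, rng):
        aln = random_alignment(rng, ["A", "B", "C"], 10)
        with pytest.raises(ValueError):
            nni_search(aln, make_model("mtMAM"), seed=0)

    def test_nni_neighbors_count(self):
        t = Tree.from_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        nbs = nni_neighbors(t)
        assert len(nbs) == 4  # two internal edges x two swaps
        ids = {nb.topology_id() for nb in nbs}
        assert t.topology_id() not in ids
        assert len(ids) == 4


class TestBootstrap:
    def test_degenerate_signal_full_support(self):
        from collagenphylo.assembly import AminoAcidAlignment

        rows = {
            "A": "GPKGPAGPRGDK" * 10,
            "B": "GPKGPAGPRGDK" * 10,
            "C": "APNAPEAPNAPE" * 10,
            "D": "APNAPEAPNAPE" * 10,
        }
        aln = AminoAcidAlignment(taxa=list("ABCD"), rows=rows)
        model = make_model("mtMAM")
        best, _ = nni_search(aln, model, seed=1, optimize_model=False)
        sup = bootstrap_support(aln, model, best, replicates=30, seed=4)
        assert list(sup.values()) == [100.0]
        nwk = annotate_support(best, sup)
        assert "100" in nwk

    def test_invariant_to_taxon_order(self, four_taxon_data):
        truth, model, comp_ = four_taxon_data
        from collagenphylo.assembly import AminoAcidAlignment

        aln, _ = simulate_alignment(truth, model, 400, seed=8)
        perm = AminoAcidAlignment(taxa=["D", "B", "A", "C"], rows=aln.rows)
        s1 = bootstrap_support(aln, model, truth, replicates=25, seed=9, search="none")
        s2 = bootstrap_support(perm, model, truth, replicates=25, seed=9, search="none")
        assert s1 == s2

    def test_support_grows_with_alignment_length(self):
        truth = Tree.from_newick(
            "(((A:0.1,B:0.1):0.04,C:0.2):0.05,(D:0.1,E:0.1):0.04,F:0.2);"
        )
        model = make_model("mtMAM")
        clade = frozenset({"D", "E"})
        sups = []
        for length in (150, 3000):
            aln, _ = simulate_alignment(truth, model, length, seed=23)
            sup = bootstrap_support(aln, model, truth, replicates=25, seed=5, search="none")
            sups.append(sup[clade])
        assert sups[1] >= sups[0]
        assert sups[1] >= 95.0


class TestModelSelect:
    def test_parameter_counts(self):
        assert count_free_parameters(4, False, False, False) == 5
        assert count_free_parameters(4, True, True, True) == 5 + 19 + 1 + 2

    def test_nested_models_never_beat_supersets(self, rng):
        truth = Tree.from_newick("((A:0.2,B:0.3):0.1,C:0.4,D:0.2);")
        gen = make_model("mtMAM", p_inv=0.3)
        aln, _ = simulate_alignment(truth, gen, 800, seed=2)
        fits = {f.description: f for f in model_select(aln, truth, matrices=("mtMAM",))}
        assert fits["mtMAM+I"].loglik >= fits["mtMAM"].loglik - 1e-6
        assert fits["mtMAM+F+I"].loglik >= fits["mtMAM+F"].loglik - 1e-6

    def test_generating_matrix_preferred(self):
        truth = Tree.from_newick("((A:0.3,B:0.4):0.15,C:0.5,D:0.3);")
        gen = make_model("mtMAM", p_inv=0.3)
        aln, _ = simulate_alignment(truth, gen, 3000, seed=6)
        fits = model_select(aln, truth, matrices=("mtMAM", "mtREV"))
        assert fits[0].description.startswith("mtMAM")

    def test_single_column_still_ranks(self, rng):
        aln = random_alignment(rng, ["A", "B", "C", "D"], 1)
        tree = Tree.from_newick("((A:0.1,B:0.1):0.1,C:0.1,D:0.1);")
        fits = model_select(aln, tree, matrices=("mtMAM",))
        assert len(fits) == 8
        assert fits[0].aic <= fits[-1].aic
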