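"""Synthetic-data generator: trees, sequence evolution, masking, spectra."""

import numpy as np
import pytest
from scipy.stats import chisquare

from collagenphylo.assembly import coverage_stats
from collagenphylo.likelihood import log_likelihood
from collagenphylo.pmf import classify_taxon, deamidation_index, preservation_class
from collagenphylo.simulate import (
    SimulationConfig,
    deamidation_ratio_for_age,
    mask_coverage,
    node_ages,
    simulate_alignment,
    simulate_dataset,
    simulate_spectrum,
    simulate_tree,
    write_bundle,
)
from collagenphylo.substitution import make_model
from collagenphylo.tree import Tree
from tests.conftest import random_alignment


class TestSimulateTree:
    def test_three_taxa_topology(self):
        t = simulate_tree(SimulationConfig(n_taxa=3, seed=2))
        internals = [n for n in t.postorder() if not n.is_leaf]
        assert len(t.leaves()) == 3
        assert len(internals) == 2  # root + 1

    def test_same_seed_identical_newick(self):
        cfg = SimulationConfig(seed=5)
        assert simulate_tree(cfg).to_newick() == simulate_tree(cfg).to_newick()

    def test_ultrametric_with_requested_root_age(self):
        cfg = SimulationConfig(n_taxa=7, root_age=50.0, seed=9)
        t = simulate_tree(cfg)
        depths = []
        for leaf in t.leaves():
            d, n = 0.0, leaf
            while n.parent is not None:
                d += n.length
                n = n.parent
            depths.append(d)
        assert np.allclose(depths, 50.0, atol=1e-9)
        ages = node_ages(t)
        assert max(ages.values()) == pytest.approx(50.0)
        assert min(ages.values()) > 0  # no zero-age cherry

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_taxa=2)
        with pytest.raises(ValueError):
            SimulationConfig(birth_rate=0.0)


class TestSimulateAlignment:
    def test_zero_length_branches_copy_parent(self):
        t = Tree.from_newick("(A:0.0,B:0.0,C:0.0);")
        aln, _ = simulate_alignment(t, make_model("mtMAM"), 200, seed=1)
        assert aln.rows["A"] == aln.rows["B"] == aln.rows["C"]

    def test_stationary_frequencies(self):
        """Column frequencies converge to pi (chi-square on one long branch)."""
        t = Tree.from_newick("(A:0.5,B:0.5);")
        model = make_model("mtMAM")
        aln, _ = simulate_alignment(t, model, 50_000, seed=4)
        counts = np.zeros(20)
        for i, aa in enumerate("ARNDCQEGHILKMFPSTWYV"):
            counts[i] = aln.rows["A"].count(aa)
        stat, p = chisquare(counts, model.pi * 50_000)
        assert p > 0.001

    def test_truth_beats_perturbed_parameters(self):
        t = Tree.from_newick("((A:0.2,B:0.2):0.1,C:0.3,D:0.3);")
        model = make_model("mtMAM")
        aln, _ = simulate_alignment(t, model, 3000, seed=12)
        ll_true = log_likelihood(t, aln, model)
        worse = t.copy()
        for n in worse.postorder():
            n.length *= 3.0
        assert ll_true > log_likelihood(worse, aln, model)


class TestMaskCoverage:
    def test_fraction_zero_is_identity(self, rng):
        aln = random_alignment(rng, ["a", "b"], 120)
        assert mask_coverage(aln, 0.0, seed=1).rows == aln.rows

    def test_fraction_one_is_all_x(self, rng):
        aln = random_alignment(rng, ["a"], 90)
        assert set(mask_coverage(aln, 1.0, seed=1).rows["a"]) == {"X"}

    def test_target_fraction_hit(self, rng):
        aln = random_alignment(rng, ["a", "b", "c"], 2000)
        masked = mask_coverage(aln, 0.24, seed=3)
        cov = coverage_stats(masked).coverage
        for t in cov:
            assert cov[t] == pytest.approx(76.0, abs=0.5)

    def test_masking_is_blockwise(self, rng):
        """Masked runs should be peptide-length blocks, not scattered cells."""
        aln = random_alignment(rng, ["a"], 5000)
        masked = mask_coverage(aln, 0.3, seed=7, block_length=15.0)
        row = masked.rows["a"]
        runs = [len(r) for r in "".join("X" if c == "X" else " " for c in row).split()]
        assert np.mean(runs) > 5.0


class TestSimulateSpectrum:
    def _noiseless(self, seq, cfg_kwargs=None):
        cfg = SimulationConfig(
            mz_jitter_sd=0.0, intensity_sigma=0.0, dropout=0.0, seed=1,
            **(cfg_kwargs or {}),
        )
        return cfg

    def test_noiseless_peaks_match_theoretical(self, bundle8):
        from collagenphylo.collagen import theoretical_fingerprint

        seq = bundle8.sequences[0]
        cfg = self._noiseless(seq)
        pl = simulate_spectrum(seq, cfg, sample_age=50.0, seed=2)
        theo = {round(mz, 4) for _, mz in theoretical_fingerprint(
            seq, max_missed=0, max_hydroxylations=1, max_deamidations=0)}
        got = {round(mz, 4) for mz, _ in pl.peaks}
        # injected deamidation pair is extra; everything else is theoretical
        assert got - theo == {1105.58, 1106.56}
        assert theo <= got

    def test_configured_deamidation_ratio_recovered(self, bundle8):
        seq = bundle8.sequences[0]
        cfg = SimulationConfig(
            seed=1, deamidation_ratio_range=(0.62, 0.62), mz_jitter_sd=0.01,
        )
        pl = simulate_spectrum(seq, cfg, sample_age=40.0, seed=3)
        assert deamidation_index(pl) == pytest.approx(0.62, abs=0.02)

    def test_poor_sample_classified_poor(self, bundle8):
        seq = bundle8.sequences[0]
        cfg = self._noiseless(seq)
        pl = simulate_spectrum(seq, cfg, sample_age=50.0, seed=4, poor=True)
        assert preservation_class(pl) == "poor"
        good = simulate_spectrum(seq, cfg, sample_age=50.0, seed=4, poor=False)
        assert preservation_class(good) == "good"

    def test_age_ratio_map_monotone_within_range(self):
        cfg = SimulationConfig(seed=1)
        r_young = deamidation_ratio_for_age(cfg, 5.0)
        r_old = deamidation_ratio_for_age(cfg, 150.0)
        lo, hi = cfg.deamidation_ratio_range
        assert lo <= r_old < r_young <= hi


class TestSimulateDataset:
    def test_manifest_complete(self, bundle8):
        truth = bundle8.truth
        assert set(truth["coverage"]) == set(bundle8.alignment.taxa)
        for pl in bundle8.spectra:
            entry = truth["samples"][pl.sample_id]
            assert {"taxon", "age_ka", "poor", "expected_deamidation_ratio"} <= set(entry)
        assert truth["tree_newick"].endswith(";")

    def test_same_seed_byte_identical_bundle(self, tmp_path):
        cfg = SimulationConfig(seed=42, n_taxa=5, sequence_length=600)
        for sub in ("a", "b"):
            write_bundle(simulate_dataset(cfg), tmp_path / sub)
        for rel in ("collagen.fasta", "alignment.fasta", "tree.nwk",
                    "panel.tsv", "truth.json", "peptides.tsv"):
            assert (tmp_path / "a" / rel).read_bytes() == (tmp_path / "b" / rel).read_bytes()
        a_specs = sorted((tmp_path / "a" / "spectra").iterdir())
        b_specs = sorted((tmp_path / "b" / "spectra").iterdir())
        for pa, pb in zip(a_specs, b_specs):
            assert pa.read_bytes() == pb.read_bytes()

    def test_classification_recovers_truth(self, bundle8):
        ok = 0
        for pl in bundle8.spectra:
            r = classify_taxon(pl, bundle8.panel)
            ok += bundle8.truth["samples"][pl.sample_id]["taxon"] in r.assignment.split("/")
        assert ok / len(bundle8.spectra) >= 0.95

    def test_coverage_in_study_range(self, bundle8):
        cov = coverage_stats(bundle8.alignment).coverage
        for t, c in cov.items():
            assert 70.0 <= c <= 88.0  # target window 74-84% plus block rounding
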