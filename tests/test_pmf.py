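"""Peak lists, marker matching, taxon assignment, preservation and
deamidation scoring."""

import numpy as np
import pytest

from collagenphylo.peaks import PeakList, read_peaklist, write_peaklist_mzml
from collagenphylo.pmf import (
    MarkerPanel,
    build_marker_panel,
    classify_taxon,
    deamidation_index,
    match_peaks,
    preservation_class,
    read_marker_panel,
    write_marker_panel,
)
from collagenphylo.simulate import SimulationConfig, simulate_dataset, simulate_spectrum


class TestReadPeaklist:
    def test_three_line_tsv(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("1105.58\t58\n1106.56\t100\n2869.41\t20\n")
        pl = read_peaklist(p)
        assert len(pl) == 3
        assert pl.peaks[0] == (1105.58, 58.0)

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        with pytest.raises(ValueError, match="no peaks"):
            read_peaklist(p)

    def test_mzml_round_trip(self, tmp_path):
        pl = PeakList("s1", [(900.5, 10.0), (1105.58, 58.0), (2869.41, 5.0)])
        path = tmp_path / "s1.mzML"
        write_peaklist_mzml(pl, path)
        back = read_peaklist(path)
        assert back.peaks == pl.peaks

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            read_peaklist("/nonexistent/x.tsv")


class TestMatchPeaks:
    def test_exact_match(self):
        assert match_peaks([1105.58], [1105.58], 0.2) == [(0, 0, 0.0)]

    def test_boundary_just_outside_tolerance(self):
        assert match_peaks([1105.80], [1105.58], 0.2) == []

    def test_jittered_matches_optimal_assignment(self, rng):
        from itertools import permutations

        theo = np.sort(rng.uniform(800, 3600, 7))
        obs = theo + rng.uniform(-0.05, 0.05, len(theo))
        matches = match_peaks(obs, theo, tolerance=0.2)
        assert len(matches) == len(theo)
        # Exhaustive optimal one-to-one assignment on this small instance.
        best = None
        for perm in permutations(range(len(theo))):
            if all(abs(obs[i] - theo[j]) <= 0.2 for i, j in enumerate(perm)):
                cost = sum(abs(obs[i] - theo[j]) for i, j in enumerate(perm))
                if best is None or cost < best[0]:
                    best = (cost, perm)
        greedy_cost = sum(abs(d) for _, _, d in matches)
        assert greedy_cost == pytest.approx(best[0], abs=1e-9)

    def test_one_to_one_and_bounded(self, rng):
        theo = np.sort(rng.uniform(800, 1000, 20))
        obs = np.sort(rng.uniform(800, 1000, 15))
        m = match_peaks(obs, theo, tolerance=0.5)
        assert len(m) <= min(len(obs), len(theo))
        assert all(abs(d) <= 0.5 for _, _, d in m)
        assert len({i for i, _, _ in m}) == len(m)
        assert len({j for _, j, _ in m}) == len(m)

    def test_bad_tolerance(self):
        with pytest.raises(ValueError):
            match_peaks([1000.0], [1000.0], 0.0)


class TestPreservation:
    def test_strong_high_mz_is_good(self):
        pl = PeakList("s", [(m, 80.0) for m in (1200, 2600, 2800, 3000, 3200, 3400)])
        assert preservation_class(pl, 2500, 2, 0.1) == "good"

    def test_truncated_spectrum_is_poor(self):
        pl = PeakList("s", [(m, 80.0) for m in (900, 1100, 1300, 1450)])
        assert preservation_class(pl, 2500, 2, 0.1) == "poor"

    def test_weak_high_mz_is_poor(self):
        """High-mass peptides present but at 5% of base peak: degraded."""
        pl = PeakList("s", [(1105.0, 100.0), (2600.0, 5.0), (2900.0, 5.0)])
        assert preservation_class(pl, 2400, 2, 0.10) == "poor"

    def test_empty_is_poor(self):
        assert preservation_class(PeakList("s", []), 2400, 2, 0.1) == "poor"


class TestDeamidationIndex:
    def test_ratio_58_to_100(self):
        pl = PeakList("s", [(1105.58, 58.0), (1106.56, 100.0)])
        assert deamidation_index(pl) == pytest.approx(0.58)

    def test_equal_heights_give_one(self):
        pl = PeakList("s", [(1105.58, 42.0), (1106.56, 42.0)])
        assert deamidation_index(pl) == pytest.approx(1.0)

    def test_missing_peak_is_undefined(self):
        pl = PeakList("s", [(1105.58, 58.0), (1300.0, 10.0)])
        assert deamidation_index(pl) is None

    def test_scale_invariance(self):
        peaks = [(1105.58, 58.0), (1106.56, 100.0), (900.0, 10.0)]
        a = deamidation_index(PeakList("s", peaks))
        b = deamidation_index(PeakList("s", [(m, 7.3 * h) for m, h in peaks]))
        assert a == pytest.approx(b)


class TestClassifyTaxon:
    def _panel(self):
        return MarkerPanel(
            markers={
                "Wallaby": {1105.6, 1477.7, 2869.4, 2201.1},
                "Pademelon": {1105.6, 1477.7, 2869.4, 2201.1},
                "Wombat": {1105.6, 1523.8, 2105.0, 3033.2},
            },
            ambiguity_groups=[frozenset({"Wallaby", "Pademelon"})],
        )

    def test_self_identification(self, bundle8):
        for taxon, mzs in bundle8.panel.markers.items():
            pl = PeakList(taxon, [(mz, 50.0) for mz in sorted(mzs)])
            r = classify_taxon(pl, bundle8.panel)
            grp = bundle8.panel.group_of(taxon)
            want = taxon if len(grp) == 1 else MarkerPanel.group_label(grp)
            assert r.assignment == want
            assert r.marker_counts[taxon] == len(mzs)

    def test_ambiguity_group_label(self):
        panel = self._panel()
        pl = PeakList("s", [(1105.6, 10.0), (1477.7, 10.0), (2869.4, 10.0)])
        r = classify_taxon(pl, panel, min_markers=2)
        assert r.assignment == "Pademelon/Wallaby"

    def test_two_random_peaks_indeterminate(self):
        panel = self._panel()
        pl = PeakList("s", [(1600.0, 5.0), (1900.0, 5.0)])
        assert classify_taxon(pl, panel, min_markers=3).assignment == "indeterminate"

    def test_bad_tolerance(self):
        with pytest.raises(ValueError):
            classify_taxon(PeakList("s", []), self._panel(), tolerance=-1)

    def test_robustness_to_jitter_and_dropout(self, bundle8):
        """>=95% assignment accuracy over 200 noisy synthetic spectra
        (m/z jitter sd = tolerance/3, 20% peak dropout)."""
        cfg = SimulationConfig(
            seed=bundle8.config.seed,
            mz_jitter_sd=0.2 / 3,
            dropout=0.2,
            intensity_sigma=0.5,
        )
        rng = np.random.default_rng(99)
        n_ok = n = 0
        seqs = bundle8.sequences
        for rep in range(200 // len(seqs) + 1):
            for s in seqs:
                pl = simulate_spectrum(
                    s, cfg, sample_age=50.0, seed=int(rng.integers(2**31 - 1))
                )
                r = classify_taxon(pl, bundle8.panel, tolerance=0.2)
                n += 1
                n_ok += s.taxon_id in r.assignment.split("/")
        assert n >= 200
        assert n_ok / n >= 0.95


def test_panel_round_trip(tmp_path, bundle8):
    path = tmp_path / "panel.tsv"
    write_marker_panel(bundle8.panel, path)
    back = read_marker_panel(path)
    assert set(back.markers) == set(bundle8.panel.markers)
    assert back.ambiguity_groups == bundle8.panel.ambiguity_groups
    for t in back.markers:
        assert len(back.markers[t]) == len(bundle8.panel.markers[t])


def test_build_panel_groups_indistinguishable_taxa():
    fps = {
        "A": [1000.0, 1500.0, 2000.0],
        "B": [1000.05, 1500.1, 2000.0],  # within 0.2 Da of A everywhere
        "C": [1000.0, 1800.0, 2400.0],
    }
    panel = build_marker_panel(fps, tolerance=0.2)
    assert frozenset({"A", "B"}) in panel.ambiguity_groups
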