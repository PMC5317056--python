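"""Ratio track, sweep calling, permutation null, pairing and QTL overlap."""

import numpy as np
import pandas as pd
import pytest

import cottonpop as cp
from cottonpop.sweep_scan import (call_sweeps, homoeolog_pairs,
                                  permutation_fpr, qtl_overlap, scan_sweeps,
                                  sweep_ratio_profile)


def track_from(ratios_race, ratios_cult, chrom="A01", size=100_000):
    """Build matching window_pi-like frames from raw pi values."""
    n = len(ratios_race)
    base = pd.DataFrame({
        "chrom": [chrom] * n,
        "start": np.arange(n) * size,
        "end": (np.arange(n) + 1) * size,
        "label": [f"w{i}" for i in range(n)]})
    a = base.copy()
    a["pi"] = ratios_race
    b = base.copy()
    b["pi"] = ratios_cult
    return a, b


class TestRatioProfile:
    def test_simple_division(self):
        a, b = track_from([0.0025], [0.0001])
        track = sweep_ratio_profile(a, b)
        assert track["ratio"].iloc[0] == pytest.approx(25.0)

    def test_low_diversity_in_both_masks_window(self):
        a, b = track_from([0.0005], [0.0005])
        track = sweep_ratio_profile(a, b)
        assert track["masked"].iloc[0]

    def test_infinite_sentinel_for_zero_cultivar(self):
        a, b = track_from([0.002], [0.0])
        track = sweep_ratio_profile(a, b)
        assert np.isinf(track["ratio"].iloc[0])
        assert not track["masked"].iloc[0]

    def test_masked_set_matches_bruteforce(self):
        rng = np.random.default_rng(20)
        pi_r = rng.uniform(0, 0.003, 200)
        pi_c = rng.uniform(0, 0.003, 200)
        a, b = track_from(pi_r, pi_c)
        track = sweep_ratio_profile(a, b)
        want = [(r < 0.001 and c < 0.001) for r, c in zip(pi_r, pi_c)]
        assert track["masked"].tolist() == want

    def test_mismatched_tilings_rejected(self):
        a, _ = track_from([0.002, 0.002], [0.001, 0.001])
        _, b = track_from([0.002], [0.001])
        with pytest.raises(ValueError):
            sweep_ratio_profile(a, b)


class TestCallSweeps:
    def test_gap_splits_regions(self):
        a, b = track_from([0.003] * 4, [0.0001, 0.0001, 0.0006, 0.000075])
        track = sweep_ratio_profile(a, b)  # ratios 30, 30, 5, 40
        regions = call_sweeps(track, threshold=25)
        assert [len(r.windows) for r in regions] == [2, 1]

    def test_no_exceedance_gives_empty(self):
        a, b = track_from([0.002] * 5, [0.002] * 5)
        assert call_sweeps(sweep_ratio_profile(a, b), 25) == []

    def test_masked_window_breaks_and_never_joins(self):
        a, b = track_from([0.003, 0.0005, 0.003],
                          [0.0001, 0.0005, 0.0001])
        track = sweep_ratio_profile(a, b)
        regions = call_sweeps(track, 25)
        assert len(regions) == 2
        members = [w for r in regions for w in r.windows]
        assert 1 not in members

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(21)
        a, b = track_from(rng.uniform(0, 0.004, 300),
                          rng.uniform(0, 0.0004, 300))
        track = sweep_ratio_profile(a, b)
        low = {w for r in call_sweeps(track, 10) for w in r.windows}
        high = {w for r in call_sweeps(track, 30) for w in r.windows}
        assert high <= low

    def test_chromosome_edge_never_merges(self):
        a, b = track_from([0.003, 0.003], [0.0001, 0.0001])
        a.loc[1, "chrom"] = b.loc[1, "chrom"] = "D01"
        a.loc[1, ["start", "end"]] = b.loc[1, ["start", "end"]] = [0,
                                                                   100_000]
        track = sweep_ratio_profile(a, b)
        assert len(call_sweeps(track, 25)) == 2


class TestPermutationFpr:
    def test_determinism_and_degenerate_threshold(self, default_filtered):
        m = default_filtered
        race = m.panel.ids_where(species="hirsutum", group="race")
        cult = m.panel.ids_where(species="hirsutum", group="cultivar")
        windows = cp.make_windows(cp.default_layout())
        _, d1 = permutation_fpr(m, race, cult, windows, threshold=25,
                                n_perm=5, seed=3)
        _, d2 = permutation_fpr(m, race, cult, windows, threshold=25,
                                n_perm=5, seed=3)
        assert np.array_equal(d1, d2)
        fpr0, _ = permutation_fpr(m, race, cult, windows, threshold=-1,
                                  n_perm=2, seed=3)
        assert fpr0 == pytest.approx(1.0)  # every unmasked window exceeds

    def test_small_groups_rejected(self, default_filtered):
        m = default_filtered
        windows = cp.make_windows(cp.default_layout())
        with pytest.raises(ValueError):
            permutation_fpr(m, m.panel.ids[:2], m.panel.ids[2:6], windows)


class TestHomoeologPairs:
    def layout(self):
        return cp.default_layout()

    def test_mirrored_sweeps_pair_and_lone_sweep_unpaired(self):
        a, b = track_from([0.003, 0.0025, 0.0025, 0.0025],
                          [0.0001, 0.0025, 0.0025, 0.0025])
        # windows 0..3 on A01; add matching D01 windows with signal in w0
        a2, b2 = track_from([0.003, 0.0025], [0.0001, 0.0025], chrom="D01")
        race = pd.concat([a, a2], ignore_index=True)
        cult = pd.concat([b, b2], ignore_index=True)
        track = sweep_ratio_profile(race, cult)
        sweeps = call_sweeps(track, 25)
        assert len(sweeps) == 2
        pairs = homoeolog_pairs(sweeps, self.layout(), track,
                                partner_threshold=15)
        assert (0, 1) in pairs

        # remove the D01 signal -> A01 sweep stays unpaired
        cult.loc[4, "pi"] = 0.0025
        track2 = sweep_ratio_profile(race, cult)
        sweeps2 = call_sweeps(track2, 25)
        assert len(sweeps2) == 1
        assert homoeolog_pairs(sweeps2, self.layout(), track2, 15) == []

    def test_pairing_symmetric_on_random_plantings(self):
        rng = np.random.default_rng(22)
        layout = self.layout()
        for _ in range(20):
            n = 20
            pi_r = np.full(2 * n, 0.0025)
            pi_c = np.full(2 * n, 0.0024)
            k = int(rng.integers(0, n))
            pi_c[k] = 0.00003        # sweep on A01
            if rng.random() < 0.5:
                pi_c[n + k] = 0.00003  # mirrored sweep on D01
            a, b = track_from(pi_r[:n], pi_c[:n], chrom="A01")
            a2, b2 = track_from(pi_r[n:], pi_c[n:], chrom="D01")
            race = pd.concat([a, a2], ignore_index=True)
            cult = pd.concat([b, b2], ignore_index=True)
            track = sweep_ratio_profile(race, cult)
            sweeps = call_sweeps(track, 25)
            pairs = homoeolog_pairs(sweeps, layout, track, 15)
            mutual = {(i, j) for i, j in pairs if j is not None}
            if len(sweeps) == 2:
                assert (0, 1) in mutual  # found regardless of direction
            else:
                assert mutual == set()

    def test_unmapped_chromosome_errors(self):
        a, b = track_from([0.003], [0.00005], chrom="Z99")
        track = sweep_ratio_profile(a, b)
        sweeps = call_sweeps(track, 25)
        with pytest.raises(ValueError, match="absent"):
            homoeolog_pairs(sweeps, self.layout(), track)


class TestQtlOverlap:
    def sweep(self, chrom, start, end):
        return cp.SweepRegion(chrom, start, end, [], 30.0, 30.0)

    def test_halfopen_boundary_semantics(self):
        sw = [self.sweep("A01", 100_000, 200_000)]
        qtls = cp.IntervalSet.from_tuples([
            ("A01", 200_000, 300_000, "abut"),     # touches end: no overlap
            ("A01", 0, 500_000, "contains"),
            ("A01", 199_999, 250_000, "clips")])
        rep = qtl_overlap(sw, qtls)
        assert sorted(sw[0].qtls) == ["clips", "contains"]
        assert rep["sweeps_with_qtl"] == 1
        assert rep["qtls_near_sweeps"] == 2

    def test_counts_match_bruteforce_on_random_intervals(self):
        rng = np.random.default_rng(23)
        chroms = ["A01", "A02", "D01"]
        sweeps = [self.sweep(rng.choice(chroms), s, s + int(rng.integers(
            1, 50_000))) for s in rng.integers(0, 10**6, 100)]
        qtl_rows = []
        for i, s in enumerate(rng.integers(0, 10**6, 1000)):
            qtl_rows.append((str(rng.choice(chroms)), int(s),
                             int(s + rng.integers(1, 80_000)), f"q{i}"))
        qtls = cp.IntervalSet.from_tuples(qtl_rows)
        rep = qtl_overlap(sweeps, qtls)
        # brute force all-pairs
        hit_sweeps = set()
        hit_qtls = set()
        for k, sw in enumerate(sweeps):
            for c, s, e, lab in qtl_rows:
                if c == sw.chrom and s < sw.end and e > sw.start:
                    hit_sweeps.add(k)
                    hit_qtls.add(lab)
        assert rep["sweeps_with_qtl"] == len(hit_sweeps)
        assert rep["qtls_near_sweeps"] == len(hit_qtls)


def test_planted_sweeps_recovered_end_to_end():
    w = cp.IntervalSet.from_tuples([("A01", 500_000, 700_000, "s1"),
                                    ("D02", 1_000_000, 1_100_000, "s2")])
    cfg = cp.SimConfig(seed=42, sweep_windows=w, sweep_target_ratio=50)
    sim = cp.simulate_genotypes(cfg)
    f = cp.filter_cascade(sim.matrix, seed=42)
    race = f.panel.ids_where(species="hirsutum", group="race")
    cult = f.panel.ids_where(species="hirsutum", group="cultivar")
    track, sweeps = scan_sweeps(f, race, cult, cfg.layout)
    called = {(s.chrom, s.start, s.end) for s in sweeps}
    assert ("A01", 500_000, 700_000) in called
    assert ("D02", 1_000_000, 1_100_000) in called
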