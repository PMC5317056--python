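"""Distances, NJ, clade calling, bias tests and f3, with oracles."""

import itertools
import math
import random

import dendropy
import numpy as np
import pandas as pd
import pytest
from scipy.stats import binomtest

import cottonpop as cp
from cottonpop.introgression import (block_distances, clade_membership,
                                     call_introgression_events,
                                     direction_bias_test, f3_from_matrix,
                                     f3_statistic, nj_tree,
                                     simple_matching_distance)

from conftest import matrix_from_calls, random_matrix, tiny_panel


class TestSimpleMatching:
    def test_hand_values(self):
        calls = np.array([[0, 2, 2], [0, 0, 2], [0, 2, 2]], dtype=np.int8)
        d, joint = simple_matching_distance(calls)
        assert d[0, 1] == pytest.approx(1 / 3)
        assert d[0, 2] == 0.0
        assert joint[0, 1] == 3

    def test_matches_bruteforce_on_random_blocks(self):
        rng = np.random.default_rng(30)
        for _ in range(20):
            calls = rng.integers(0, 3, (6, 25)).astype(np.int8)
            calls[rng.random(calls.shape) < 0.2] = cp.MISSING
            d, joint = simple_matching_distance(calls)
            for i, j in itertools.combinations(range(6), 2):
                both = (calls[i] >= 0) & (calls[j] >= 0)
                nb = int(both.sum())
                if nb == 0:
                    assert np.isnan(d[i, j])
                    continue
                nm = int(((calls[i] == calls[j]) & both).sum())
                assert d[i, j] == pytest.approx(1 - nm / nb)
                assert d[i, j] == d[j, i]

    def test_metric_on_complete_data(self):
        rng = np.random.default_rng(31)
        calls = rng.integers(0, 3, (8, 40)).astype(np.int8)
        d, _ = simple_matching_distance(calls)
        assert np.allclose(np.diag(d), 0)
        assert np.allclose(d, d.T)
        for i, j, k in itertools.permutations(range(8), 3):
            assert d[i, k] <= d[i, j] + d[j, k] + 1e-12

    def test_zero_joint_sites_flagged(self):
        calls = np.array([[0, cp.MISSING], [cp.MISSING, 1]], dtype=np.int8)
        d, _ = simple_matching_distance(calls)
        assert np.isnan(d[0, 1])


def path_length_matrix(tree, labels):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    return np.array([[pdm.distance(taxa[a], taxa[b]) for b in labels]
                     for a in labels])


class TestNjTree:
    def test_three_taxa_closed_form(self):
        D = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float)
        tree = nj_tree(D, ["a", "b", "c"])
        # three-point solution: da=2, db=3, dc=7
        lens = {lf.taxon.label: lf.edge.length
                for lf in tree.leaf_node_iter()}
        assert lens == pytest.approx({"a": 2.0, "b": 3.0, "c": 7.0})

    def test_additive_five_taxon_recovery(self):
        # tree ((a:2,b:3):1,(c:4,d:1):2,e:6); path lengths by hand
        newick = "((a:2,b:3):1,(c:4,d:1):2,e:6);"
        src = dendropy.Tree.get(data=newick, schema="newick")
        labels = list("abcde")
        D = path_length_matrix(src, labels)
        tree = nj_tree(D, labels)
        D2 = path_length_matrix(tree, labels)
        assert np.abs(D - D2).max() < 1e-9
        # topology: a,b together apart from c,d
        bip = {frozenset(lf.taxon.label for lf in n.leaf_iter())
               for n in tree.preorder_node_iter() if not n.is_leaf()}
        assert frozenset("ab") in bip or frozenset("cde") in bip

    @pytest.mark.parametrize("seed", range(5))
    def test_random_additive_matrices_reproduced(self, seed):
        taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(9)])
        src = dendropy.simulate.treesim.birth_death_tree(
            0.6, 0.1, taxon_namespace=taxa, num_extant_tips=9,
            rng=random.Random(seed))
        labels = [t.label for t in taxa]
        D = path_length_matrix(src, labels)
        tree = nj_tree(D, labels)
        assert np.abs(path_length_matrix(tree, labels) - D).max() < 1e-9

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(32)
        calls = rng.integers(0, 3, (7, 60)).astype(np.int8)
        D, _ = simple_matching_distance(calls)
        labels = [f"x{i}" for i in range(7)]
        t1 = nj_tree(D, labels)
        perm = rng.permutation(7)
        t2 = nj_tree(D[np.ix_(perm, perm)], [labels[i] for i in perm])
        m1 = path_length_matrix(t1, labels)
        m2 = path_length_matrix(t2, labels)
        assert np.abs(m1 - m2).max() < 1e-9

    def test_missing_distance_rejected(self):
        D = np.array([[0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0]])
        with pytest.raises(ValueError):
            nj_tree(D, list("abc"))


class TestCladeMembership:
    def panel(self):
        rows = ([(f"H{i}", "hirsutum", "cultivar", "") for i in range(4)]
                + [(f"B{i}", "barbadense", "cultivar", "") for i in range(4)]
                + [("O0", "outgroup", "outgroup", "")])
        return cp.AccessionPanel(pd.DataFrame(
            rows, columns=["id", "species", "group", "origin"]))

    def tree(self, newick):
        return dendropy.Tree.get(data=newick, schema="newick")

    def test_misplaced_leaf_detected(self):
        nwk = ("((H0:1,(H1:1,H2:1):1):2,((B0:1,B1:1,(B2:1,(B3:1,H3:1):1)"
               ":1):2):1,O0:5);")
        # 4 accessions per species: a 0.9 core fraction would force the
        # misplaced H3 into its own species' core, so use 0.7 here
        placements, ok = clade_membership(self.tree(nwk), self.panel(),
                                          ["O0"], core_fraction=0.7)
        assert ok
        assert placements == {"H3": "barbadense"}

    def test_clean_separation_gives_no_placements(self):
        nwk = ("((H0:1,H1:1,H2:1,H3:1):2,(B0:1,B1:1,B2:1,B3:1):2,O0:5);")
        placements, ok = clade_membership(self.tree(nwk), self.panel(),
                                          ["O0"])
        assert ok and placements == {}

    def test_no_outgroup_errors(self):
        nwk = "((H0:1,H1:1):1,(B0:1,B1:1):1);"
        with pytest.raises(ValueError, match="outgroup"):
            clade_membership(self.tree(nwk), self.panel(), ["O0"])

    def test_scattered_species_unresolvable(self):
        # species interleaved: no small clade holds 90% of either species
        nwk = ("((H0:1,B0:1):1,((H1:1,B1:1):1,((H2:1,B2:1):1,(H3:1,B3:1)"
               ":1):1):1,O0:5);")
        placements, ok = clade_membership(self.tree(nwk), self.panel(),
                                          ["O0"])
        assert not ok and placements == {}


class TestEventCalling:
    def layout(self):
        return cp.default_layout()

    def panel(self):
        return tiny_panel(n_h=6, n_b=6, n_out=2)

    def test_single_accession_is_not_an_event(self):
        placed = [("A01", 0, 10**6, "b0", {"B0": "hirsutum"}, True)]
        assert call_introgression_events(placed, self.panel(),
                                         self.layout()) == []

    def test_two_accessions_make_one_directed_event(self):
        placed = [("A01", 0, 10**6, "b0",
                   {"B0": "hirsutum", "B1": "hirsutum"}, True)]
        events = call_introgression_events(placed, self.panel(),
                                           self.layout())
        assert len(events) == 1
        ev = events[0]
        assert ev.direction == "Gh->Gb"
        assert ev.subgenome == "A"
        assert ev.recipients == ("B0", "B1")

    def test_matches_bruteforce_grouping_on_random_blocks(self):
        rng = np.random.default_rng(33)
        panel = self.panel()
        layout = self.layout()
        hir = [f"H{i}" for i in range(6)]
        bar = [f"B{i}" for i in range(6)]
        placed = []
        for b in range(50):
            chrom = str(rng.choice(layout.names()))
            placements = {}
            for acc in rng.choice(bar, rng.integers(0, 4), replace=False):
                placements[str(acc)] = "hirsutum"
            for acc in rng.choice(hir, rng.integers(0, 4), replace=False):
                placements[str(acc)] = "barbadense"
            placed.append((chrom, 0, 10**6, f"b{b}", placements, True))
        events = call_introgression_events(placed, panel, layout)
        # brute force
        want = 0
        for chrom, s, e, lab, pl, ok in placed:
            n_gb = sum(1 for a, h in pl.items() if a.startswith("B"))
            n_gh = sum(1 for a, h in pl.items() if a.startswith("H"))
            want += (n_gb >= 2) + (n_gh >= 2)
        assert len(events) == want


class TestDirectionBias:
    @staticmethod
    def fisher_oracle(table):
        """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
        (a, b), (c, d) = table
        r1, r2 = a + b, c + d
        c1 = a + c
        n = r1 + r2

        def log_choose(n_, k_):
            return (math.lgamma(n_ + 1) - math.lgamma(k_ + 1)
                    - math.lgamma(n_ - k_ + 1))

        def prob(x):
            return math.exp(log_choose(r1, x) + log_choose(r2, c1 - x)
                            - log_choose(n, c1))

        p_obs = prob(a)
        total = 0.0
        for x in range(max(0, c1 - r2), min(r1, c1) + 1):
            px = prob(x)
            if px <= p_obs * (1 + 1e-9):
                total += px
        return min(total, 1.0)

    def test_balanced_counts_give_p_one(self):
        assert direction_bias_test(10, 10).p_fisher == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(34)
        cases = [(265, 119), (250, 134), (0, 5), (1, 1), (40, 2)]
        cases += [tuple(rng.integers(0, 40, 2)) for _ in range(40)]
        for n1, n2 in cases:
            if n1 + n2 == 0:
                continue
            res = direction_bias_test(int(n1), int(n2))
            want = self.fisher_oracle(res.table)
            assert res.p_fisher == pytest.approx(want, rel=1e-6)

    def test_symmetric_plantings_rarely_significant(self):
        rng = np.random.default_rng(35)
        n_ok = 0
        for _ in range(50):
            n1 = rng.binomial(384, 0.5)
            if direction_bias_test(int(n1), int(384 - n1)).p_fisher > 0.05:
                n_ok += 1
        assert n_ok >= 45

    def test_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            direction_bias_test(0, 0)


class TestF3:
    def test_single_site_hand_value(self):
        # a=0, b=1, c=0.5: (c-a)(c-b) = -0.25, denominator 2c(1-c) = 0.5
        c = np.full(20, 0.5)
        a = np.zeros(20)
        b = np.ones(20)
        res = f3_statistic(c, a, b, block_size=1, corrected=False)
        assert res.f3 == pytest.approx(-0.5)

    def test_monomorphic_target_undefined(self):
        with pytest.raises(ValueError, match="monomorphic"):
            f3_statistic(np.zeros(100), np.ones(100), np.ones(100),
                         block_size=5)

    def test_too_few_blocks_rejected(self):
        c = np.full(30, 0.5)
        with pytest.raises(ValueError, match="blocks"):
            f3_statistic(c, c * 0, c * 0 + 1, block_size=10)

    def test_signs_under_drift_and_admixture(self, small_sim_config):
        for seed in range(3):
            cfg = small_sim_config(seed, snp_density=4.0)
            sim = cp.simulate_genotypes(cfg)
            m = sim.matrix
            p = m.panel
            cult = p.ids_where(species="hirsutum", group="cultivar")
            race = p.ids_where(species="hirsutum", group="race")
            gb = p.ids_where(species="barbadense")
            drift = f3_from_matrix(m, cult, race, gb,
                                   block_size=m.n_sites // 40)
            assert drift.f3 > 0
            mixed = cp.plant_admixture(m, gb[:6], race, gb[6:], 0.5,
                                       seed=seed)
            adm = f3_from_matrix(mixed, gb[:6], race, gb[6:],
                                 block_size=m.n_sites // 40)
            assert adm.f3 < 0 and adm.z < -3


def test_block_scan_recovers_planted_events(default_sim):
    cfg_layout = cp.default_layout()
    m = default_sim.matrix
    recips_gb = m.panel.ids_where(species="barbadense")[:3]
    recips_gh = m.panel.ids_where(species="hirsutum", group="race")[:2]
    events_in = [
        cp.IntrogressionPlan("A02", 0, 10**6, "hirsutum", recips_gb),
        cp.IntrogressionPlan("D02", 10**6, 2 * 10**6, "barbadense",
                             recips_gh)]
    planted, _ = cp.plant_introgressions(m, events_in, layout=cfg_layout,
                                         seed=5)
    f = cp.filter_cascade(planted, seed=5)
    from cottonpop.introgression import scan_introgression
    placed, events = scan_introgression(
        f, cfg_layout, m.panel.ids_where(species="outgroup"))
    found = {(e.chrom, e.start, e.direction): e for e in events}
    assert ("A02", 0, "Gh->Gb") in found
    assert set(recips_gb) <= set(found[("A02", 0, "Gh->Gb")].recipients)
    assert ("D02", 10**6, "Gb->Gh") in found
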