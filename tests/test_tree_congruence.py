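import itertools

import numpy as np
import pytest
from scipy.stats import chisquare
from skbio import DistanceMatrix

from phylosym import tree_congruence as tc
from phylosym.feature_tables import collapse_by_group, filter_samples_min_depth, rarefy
from phylosym import beta_diversity as bd
from phylosym.synthdata import SimConfig, simulate_communities, simulate_host_tree

from _oracles import all_topologies, brute_rf, random_ultrametric


class TestUPGMA:
    def test_two_samples_cherry(self):
        dm = DistanceMatrix([[0, 3], [3, 0]], ids=["A", "B"])
        t = tc.upgma(dm)
        tips = {n.name: n.length for n in t.tips()}
        assert tips == {"A": 1.5, "B": 1.5}

    def test_hand_agglomeration(self):
        dm = DistanceMatrix([[0, 2, 6], [2, 0, 6], [6, 6, 0]],
                            ids=["A", "B", "C"])
        t = tc.upgma(dm)
        # topology ((A,B),C); A,B join at height 1, C at height 3
        lengths = {n.name: n.length for n in t.tips()}
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(1.0)
        assert lengths["C"] == pytest.approx(3.0)
        ab = t.lca(["A", "B"])
        assert ab.length == pytest.approx(2.0)

    def test_ultrametric_output(self):
        rng = np.random.default_rng(3)
        n = 8
        vals = rng.uniform(1, 10, size=(n, n))
        d = (vals + vals.T) / 2
        np.fill_diagonal(d, 0)
        t = tc.upgma(DistanceMatrix(d, ids=[f"s{i}" for i in range(n)]))
        depths = [tip.accumulate_to_ancestor(t) for tip in t.tips()]
        assert max(depths) - min(depths) < 1e-9

    def test_cophenetic_reconstruction_on_ultrametric_input(self):
        rng = np.random.default_rng(11)
        for trial in range(20):
            labels = [f"s{i}" for i in range(int(rng.integers(4, 10)))]
            d = random_ultrametric(labels, rng)
            t = tc.upgma(DistanceMatrix(d, ids=labels))
            coph = t.tip_tip_distances(endpoints=labels)
            np.testing.assert_allclose(coph.data, d, atol=1e-9)

    def test_label_order_invariance(self):
        rng = np.random.default_rng(7)
        labels = [f"s{i}" for i in range(6)]
        d = random_ultrametric(labels, rng)
        dm1 = DistanceMatrix(d, ids=labels)
        perm = list(rng.permutation(6))
        dm2 = DistanceMatrix(d[np.ix_(perm, perm)],
                             ids=[labels[i] for i in perm])
        t1, t2 = tc.upgma(dm1), tc.upgma(dm2)
        assert tc.bipartitions(t1) == tc.bipartitions(t2)
        c1 = t1.tip_tip_distances(endpoints=labels)
        c2 = t2.tip_tip_distances(endpoints=labels)
        np.testing.assert_allclose(c1.data, c2.data, atol=1e-12)

    def test_nan_rejected(self):
        d = np.array([[0.0, np.nan], [np.nan, 0.0]])
        dm = DistanceMatrix.__new__(DistanceMatrix)  # bypass skbio checks
        dm._data = d
        dm._ids = ("A", "B")
        dm._id_index = {"A": 0, "B": 1}
        with pytest.raises(ValueError, match="NaN"):
            tc.upgma(dm)


class TestRobinsonFoulds:
    def test_identical_trees_zero(self):
        t = tc.read_newick("((A,B),(C,(D,E)));")
        assert tc.robinson_foulds(t, t.copy()) == (0, 0.0)

    def test_conflicting_quartets(self):
        t1 = tc.read_newick("((A,B),(C,D));")
        t2 = tc.read_newick("((A,C),(B,D));")
        rf, nrf = tc.robinson_foulds(t1, t2)
        assert rf == 2 and nrf == 1.0

    def test_tip_set_mismatch_lists_difference(self):
        t1 = tc.read_newick("((A,B),(C,D));")
        t2 = tc.read_newick("((A,B),(C,E));")
        with pytest.raises(ValueError, match="D.*E|E.*D"):
            tc.robinson_foulds(t1, t2)

    def test_too_few_tips(self):
        t = tc.read_newick("((A,B),C);")
        with pytest.raises(ValueError, match="4 tips"):
            tc.robinson_foulds(t, t.copy())

    def test_rooted_vs_unrooted_encoding_agree(self):
        rooted = tc.read_newick("((A,B),((C,D),E));")
        unrooted = tc.read_newick("(A,B,((C,D),E));")
        assert tc.robinson_foulds(rooted, unrooted) == (0, 0.0)

    def test_nrf_in_unit_interval_random_pairs(self):
        rng = np.random.default_rng(5)
        for n in range(5, 11):
            labels = [f"x{i}" for i in range(n)]
            for _ in range(20):
                t1 = tc.random_topology(labels, int(rng.integers(2**31)))
                t2 = tc.random_topology(labels, int(rng.integers(2**31)))
                rf, nrf = tc.robinson_foulds(t1, t2)
                assert 0.0 <= nrf <= 1.0
                assert rf % 2 == 0  # binary trees: symmetric difference even

    def test_exhaustive_oracle_small_n(self):
        # every pair of unrooted binary topologies on 5 and 6 tips
        for n in (5, 6):
            labels = [chr(65 + i) for i in range(n)]
            topos = all_topologies(labels)
            assert len(topos) == {5: 15, 6: 105}[n]
            trees = [tc.read_newick(s) for s in topos]
            splits = [tc.bipartitions(t) for t in trees]
            for i, j in itertools.combinations_with_replacement(
                    range(len(topos)), 2):
                got = len(splits[i] ^ splits[j])
                assert got == brute_rf(topos[i], topos[j])

    def test_sampled_oracle_seven_tips(self):
        labels = [chr(65 + i) for i in range(7)]
        topos = all_topologies(labels)
        assert len(topos) == 945
        rng = np.random.default_rng(17)
        idx = rng.integers(0, len(topos), size=(400, 2))
        trees = {i: tc.read_newick(topos[i]) for i in set(idx.ravel())}
        for i, j in idx:
            got, _ = tc.robinson_foulds(trees[i], trees[j])
            assert got == brute_rf(topos[i], topos[j])


class TestRandomTopology:
    def test_tip_set_matches_labels(self):
        labels = {"w", "x", "y", "z", "q"}
        t = tc.random_topology(labels, seed=0)
        assert {tip.name for tip in t.tips()} == labels

    def test_quartet_uniformity(self):
        labels = ["A", "B", "C", "D"]
        counts = {}
        n_draws = 3000
        for seed in range(n_draws):
            key = tc.bipartitions(tc.random_topology(labels, seed))
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 3
        se = np.sqrt(n_draws * (1 / 3) * (2 / 3))
        for c in counts.values():
            assert abs(c - n_draws / 3) < 3 * se

    def test_five_tip_uniformity_chisquare(self):
        labels = ["A", "B", "C", "D", "E"]
        counts = {}
        n_draws = 15000
        for seed in range(n_draws):
            key = tc.bipartitions(tc.random_topology(labels, seed))
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 15
        stat, p = chisquare(list(counts.values()))
        assert p > 0.01

    def test_determinism(self):
        labels = list("abcdef")
        assert str(tc.random_topology(labels, 99)) == \
            str(tc.random_topology(labels, 99))


class TestBootstrapSupport:
    def _ref(self):
        dm = DistanceMatrix(random_ultrametric(list("ABCDE"),
                                               np.random.default_rng(2)),
                            ids=list("ABCDE"))
        return tc.upgma(dm)

    def test_all_identical_replicates_full_support(self):
        ref = self._ref()
        out = tc.bootstrap_support([ref.copy() for _ in range(10)], ref)
        for node in out.non_tips(include_self=False):
            assert node.support == 1.0

    def test_absent_clade_zero_support(self):
        ref = tc.read_newick("((A,B),(C,D),E);")
        reps = [tc.read_newick("((A,C),(B,D),E);")] * 5
        out = tc.bootstrap_support(reps, ref)
        supports = [n.support for n in out.non_tips(include_self=False)]
        assert 0.0 in supports

    def test_replicate_order_invariant(self):
        ref = self._ref()
        reps = [tc.random_topology(list("ABCDE"), s) for s in range(6)]
        a = tc.bootstrap_support(reps, ref)
        b = tc.bootstrap_support(reps[::-1], ref)
        sa = [n.support for n in a.non_tips(include_self=False)]
        sb = [n.support for n in b.non_tips(include_self=False)]
        assert sa == sb
        assert all(0.0 <= s <= 1.0 for s in sa)

    def test_tip_mismatch_raises(self):
        ref = self._ref()
        bad = tc.random_topology(list("ABCDF"), 0)
        with pytest.raises(ValueError, match="tip set"):
            tc.bootstrap_support([bad], ref)


class TestCongruenceTest:
    def _host9(self, seed=0):
        return simulate_host_tree(9, seed)

    def test_identical_tree_small_p(self):
        host = self._host9()
        res = tc.congruence_test(host, host.copy(), n_random=1000, seed=1)
        assert res.rf == 0
        # 9 tips: 135,135 topologies; a random rf=0 hit in 1000 draws is
        # overwhelmingly unlikely
        assert res.p_value == pytest.approx(1 / 1001)

    def test_null_distribution_recorded(self):
        host = self._host9()
        res = tc.congruence_test(host, host.copy(), n_random=200, seed=2)
        assert sum(res.null_rf_distribution.values()) == 200
        assert all(v % 2 == 0 for v in res.null_rf_distribution)

    def test_n_random_zero_rejected(self):
        host = self._host9()
        with pytest.raises(ValueError, match="n_random"):
            tc.congruence_test(host, host.copy(), n_random=0, seed=0)

    def test_paper_literal_tail_flag(self):
        host = self._host9()
        rand = tc.random_topology([t.name for t in host.tips()], 3)
        a = tc.congruence_test(host, rand, n_random=300, seed=4,
                               tail="congruent")
        b = tc.congruence_test(host, rand, n_random=300, seed=4,
                               tail="paper-literal")
        # the two tails partition the null (ties counted by both)
        assert a.p_value + b.p_value >= 1.0

    def test_null_calibration_super_uniform(self):
        # dendrogram itself random: the RF statistic is heavily discrete
        # (ties at the maximal value dominate), so the add-one p-value is
        # super-uniform, never mean-0.5 uniform: P(p <= a) <= a at every
        # level, with mass pushed toward 1 by ties
        labels = [f"h{i}" for i in range(9)]
        host = tc.random_topology(labels, 12345)
        ps = np.array([
            tc.congruence_test(host, tc.random_topology(labels, 50_000 + s),
                               n_random=199, seed=s).p_value
            for s in range(200)])
        for alpha in (0.01, 0.05, 0.1, 0.25, 0.5):
            se = np.sqrt(alpha * (1 - alpha) / len(ps))
            assert (ps <= alpha).mean() <= alpha + 3 * se
        assert np.mean(ps) >= 0.5 - 0.06  # validity lower bound
        assert (ps <= 0.25).mean() > 0    # and not degenerately conservative


class TestEndToEndPower:
    def _rejection_rate(self, signal_s, n_seeds=50):
        rejections = 0
        for seed in range(n_seeds):
            host = simulate_host_tree(9, seed)
            cfg = SimConfig(signal_s=signal_s, depth_log_mean=9.2,
                            depth_log_sd=0.4, seed=seed)
            sim = simulate_communities(host, cfg)
            ft = filter_samples_min_depth(sim.table_hires, 1000)
            coll = collapse_by_group(ft)
            sub = rarefy(coll, 5000, seed)
            dm = bd.bray_curtis(sub)
            res = tc.congruence_test(host, tc.upgma(dm), n_random=500,
                                     seed=seed)
            rejections += res.p_value < 0.05
        return rejections / n_seeds

    def test_full_signal_power(self):
        assert self._rejection_rate(1.0) >= 0.8

    def test_null_signal_type_one_error(self):
        assert abs(self._rejection_rate(0.0) - 0.05) <= 0.03

    def test_signal_monotonicity(self):
        rates = [self._rejection_rate(s, n_seeds=25)
                 for s in (0.0, 0.5, 1.0)]
        assert rates[0] <= rates[1] <= rates[2]
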