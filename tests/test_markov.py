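import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.linalg
from scipy.integrate import simpson

from conftest import simulate_surviving
from geoshift.markov import (MkModel, _Mapper, _pruning_partials,
                             _root_weights, count_transitions, fit_mk,
                             lineages_in_bin, make_bins, mk_loglik,
                             node_marginals, relative_shift_rates,
                             sample_stochastic_map, transition_matrices)
from geoshift.simulate import SimConfig, simulate_musse_tree
from geoshift.trees import Chronogram


def enumeration_loglik(tree, state_idx, q, prior):
    """Brute-force likelihood: sum over all internal-node state
    assignments of prior x edge transition probabilities."""
    k = q.shape[0]
    p = {c: scipy.linalg.expm(q * tree.blen[c])
         for c in range(tree.n_nodes) if tree.parent[c] >= 0}
    internals = list(range(tree.n_tips, tree.n_nodes))
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internals)):
        s = {nd: a for nd, a in zip(internals, assign)}
        for t in range(tree.n_tips):
            s[t] = state_idx[t]
        pr = prior[s[tree.root]]
        for c in range(tree.n_nodes):
            par = tree.parent[c]
            if par >= 0:
                pr *= p[c][s[par], s[c]]
        total += pr
    return np.log(total)


class TestMkLikelihood:
    def test_matches_brute_force_enumeration(self, quartet):
        states = pd.Series({"A": 0, "B": 1, "C": 1, "D": 0})
        q = np.array([[-0.3, 0.3], [0.12, -0.12]])
        for prior_name, prior in [("uniform", np.array([0.5, 0.5])),
                                  ("stationary", None)]:
            if prior is None:
                prior = _root_weights("stationary", None, q)
            ll = mk_loglik(quartet, states, q, root_prior=prior)
            oracle = enumeration_loglik(quartet, states[quartet.tip_labels]
                                        .to_numpy(), q, prior)
            assert ll == pytest.approx(oracle, abs=1e-10)

    def test_zero_rates_reduce_to_root_prior(self, quartet):
        states = pd.Series({t: "s" for t in "ABCD"})
        q = np.zeros((1, 1))
        ll = mk_loglik(quartet, states, q, root_prior=np.array([1.0]))
        assert ll == pytest.approx(0.0)

    def test_invariant_under_joint_state_relabelling(self, quartet):
        states = pd.Series({"A": 0, "B": 1, "C": 1, "D": 0})
        q = np.array([[-0.3, 0.3], [0.12, -0.12]])
        perm = [1, 0]
        qp = q[np.ix_(perm, perm)]
        swapped = states.map({0: 1, 1: 0})
        assert mk_loglik(quartet, states, q, "uniform") == pytest.approx(
            mk_loglik(quartet, swapped, qp, "uniform"), abs=1e-12)

    def test_time_rate_scale_identity(self, quartet):
        states = pd.Series({"A": 0, "B": 1, "C": 1, "D": 0})
        q = np.array([[-0.3, 0.3], [0.12, -0.12]])
        doubled = Chronogram(quartet.parent, quartet.blen * 2,
                             quartet.tip_labels)
        assert mk_loglik(quartet, states, q, "uniform") == pytest.approx(
            mk_loglik(doubled, states, q / 2, "uniform"), abs=1e-12)

    def test_unknown_state_and_non_ultrametric_raise(self, quartet):
        q = np.zeros((2, 2))
        with pytest.raises(ValueError, match="unknown tip state"):
            MkModel(quartet, pd.Series({"A": 0, "B": 1, "C": 2, "D": 0}),
                    state_names=[0, 1])
        bad = Chronogram.from_newick("((A:1,B:2):1,(C:1,D:1):2);")
        with pytest.raises(Exception):
            mk_loglik(bad, pd.Series({"A": 0, "B": 1, "C": 1, "D": 0}), q)


class TestMkFit:
    def test_equal_rates_recovery_within_fifty_percent(self):
        hits = 0
        n_rep = 12
        seed = 100
        for rep in range(n_rep):
            tree, _, states, seed = simulate_surviving(
                2, [0.15, 0.15], 0.0, 0.05, seed=seed + 1, max_taxa=300,
                require_both_states=True)
            res = fit_mk(tree, states, model="ER")
            if 0.025 <= res.rates[0] <= 0.075:
                hits += 1
        assert hits >= 0.75 * n_rep

    def test_nested_models_ordered_by_likelihood(self):
        tree, _, states, _ = simulate_surviving(
            2, [0.2, 0.2], 0.0, 0.05, seed=55, max_taxa=150,
            require_both_states=True)
        ll_er = fit_mk(tree, states, model="ER").llf
        ll_sym = fit_mk(tree, states, model="SYM").llf
        ll_ard = fit_mk(tree, states, model="ARD").llf
        assert ll_ard >= ll_sym - 1e-6
        assert ll_sym >= ll_er - 1e-6

    def test_invariant_character_rejected(self, quartet):
        states = pd.Series({t: "s" for t in "ABCD"})
        with pytest.raises(ValueError, match="invariant"):
            MkModel(quartet, states).fit()

    def test_summary_mentions_model_and_rates(self):
        tree, _, states, _ = simulate_surviving(
            2, [0.2, 0.2], 0.0, 0.05, seed=77, max_taxa=60,
            require_both_states=True)
        res = fit_mk(tree, states, model="ER")
        s = res.summary()
        assert "ER" in s and "log-likelihood" in s


class TestStochasticMapping:
    def test_zero_rate_matrix_gives_empty_history(self, quartet):
        states = pd.Series({t: "s" for t in "ABCD"})
        h = sample_stochastic_map(quartet, states, np.zeros((1, 1)),
                                  root_prior=np.array([1.0]), seed=1)
        assert h.n_events == 0

    def test_event_parity_matches_endpoints(self):
        tree, _, states, _ = simulate_surviving(
            2, [0.2, 0.2], 0.0, 0.06, seed=91, max_taxa=40,
            require_both_states=True)
        q = np.array([[-0.06, 0.06], [0.06, -0.06]])
        for s in range(8):
            h = sample_stochastic_map(tree, states, q, seed=s)
            for c in range(tree.n_nodes):
                par = tree.parent[c]
                if par < 0:
                    continue
                n = int((h.events["branch"] == c).sum())
                differ = h.node_states[c] != h.node_states[par]
                assert (n % 2 == 1) == bool(differ)

    def test_tip_states_preserved_and_reproducible(self, tree100):
        tree, _, states = tree100
        q = np.array([[-0.05, 0.05], [0.08, -0.08]])
        h1 = sample_stochastic_map(tree, states, q, seed=5)
        h2 = sample_stochastic_map(tree, states, q, seed=5)
        pd.testing.assert_frame_equal(h1.events, h2.events)
        assert (h1.node_states[: tree.n_tips]
                == states[tree.tip_labels].to_numpy()).all()

    def test_node_marginals_converge_to_sampled_frequencies(self):
        tree, _, states, _ = simulate_surviving(
            2, [0.2, 0.2], 0.0, 0.05, seed=61, max_taxa=50,
            require_both_states=True)
        q = np.array([[-0.06, 0.06], [0.03, -0.03]])
        marg = node_marginals(tree, states, q, root_prior="stationary")
        m = _Mapper(tree, states, q, "stationary")
        n_maps = 2000
        freq = np.zeros((tree.n_nodes, 2))
        for r in range(n_maps):
            h = m.sample(seed=r)
            freq[np.arange(tree.n_nodes), h.node_states] += 1
        freq /= n_maps
        tv = 0.5 * np.abs(freq - marg).sum(axis=1)
        assert tv.max() <= 0.02

    def test_mean_branch_event_counts_match_quadrature_oracle(self,
                                                              tree100):
        """Monte Carlo event counts vs an analytic conditional-expectation
        oracle (endpoint posterior x Markov-bridge expectation)."""
        tree, _, states = tree100
        q = np.array([[-0.05, 0.05], [0.08, -0.08]])
        d, _, p = _pruning_partials(
            tree, states[tree.tip_labels].to_numpy(), q)
        w = _root_weights("stationary", d[tree.root], q)
        f = np.zeros((tree.n_nodes, 2))
        f[tree.root] = w
        for nd in tree.postorder[::-1]:
            if nd < tree.n_tips:
                continue
            msgs = {c: p[c] @ d[c] for c in tree.children[nd]}
            for c in tree.children[nd]:
                g = f[nd].copy()
                for s in tree.children[nd]:
                    if s != c:
                        g *= msgs[s]
                f[c] = g @ p[c]

        def bridge(i, j, a, b, t):
            s = np.linspace(0.0, t, 801)
            ps = transition_matrices(q, s)
            pr = transition_matrices(q, t - s)
            val = simpson(ps[:, a, i] * pr[:, j, b], x=s)
            return q[i, j] * val / p_branch[a, b]

        lengths = sorted(((tree.blen[c], c) for c in range(tree.n_nodes)
                          if tree.parent[c] >= 0), reverse=True)
        chosen = [lengths[0][1], lengths[5][1], lengths[20][1]]
        m = _Mapper(tree, states, q, "stationary")
        n_maps = 2000
        counts = {c: np.zeros((n_maps, 2)) for c in chosen}
        for r in range(n_maps):
            ev = m.sample(seed=r).events
            for c in chosen:
                sub = ev[ev["branch"] == c]
                counts[c][r, 0] = ((sub["from_state"] == 0)
                                   & (sub["to_state"] == 1)).sum()
                counts[c][r, 1] = ((sub["from_state"] == 1)
                                   & (sub["to_state"] == 0)).sum()
        for c in chosen:
            par = tree.parent[c]
            t = float(tree.blen[c])
            p_branch = p[c]
            msgs = {cc: p[cc] @ d[cc] for cc in tree.children[par]}
            g = f[par].copy()
            for s in tree.children[par]:
                if s != c:
                    g *= msgs[s]
            joint = np.einsum("a,ab,b->ab", g, p_branch, d[c])
            joint /= joint.sum()
            for di, (i, j) in enumerate([(0, 1), (1, 0)]):
                oracle = sum(joint[a, b] * bridge(i, j, a, b, t)
                             for a in range(2) for b in range(2))
                mc = counts[c][:, di]
                se = mc.std(ddof=1) / np.sqrt(n_maps)
                assert abs(mc.mean() - oracle) <= 3 * se + 1e-4

    def test_total_events_match_unconditional_expectation(self):
        """Pooled over trees and maps drawn under the same Q, events per
        unit branch length match sum_i pi_i sum_j q_ij."""
        q = np.array([[-0.06, 0.06], [0.03, -0.03]])
        pi = np.array([1.0, 2.0]) / 3.0
        expected = pi[0] * 0.06 + pi[1] * 0.03
        rates, seed = [], 200
        for rep in range(20):
            tree, _, states, seed = simulate_surviving(
                2, [0.2, 0.2], 0.0, [[0, 0.06], [0.03, 0]], seed=seed + 1,
                max_taxa=60)
            m = _Mapper(tree, states, q, "stationary")
            ev = np.mean([m.sample(seed=r).n_events for r in range(20)])
            rates.append(ev / tree.total_length)
        rates = np.asarray(rates)
        se = rates.std(ddof=1) / np.sqrt(len(rates))
        assert abs(rates.mean() - expected) <= 3 * se


class TestBinnedStatistics:
    def test_count_transitions_arithmetic(self):
        ev = pd.DataFrame({"branch": [1, 2, 3],
                           "age": [2.0, 7.0, 7.5],
                           "from_state": [0, 0, 1],
                           "to_state": [1, 1, 0]})
        from geoshift.markov import StochasticHistory
        h = StochasticHistory(ev, np.zeros(4, int))
        bins = np.array([0.0, 5.0, 10.0])
        assert count_transitions(h, bins, "all").tolist() == [1, 2]
        assert count_transitions(h, bins, (0, 1)).tolist() == [1, 1]
        assert count_transitions(h, bins, ("any", 0)).tolist() == [0, 1]
        # conservation over exclusive directions
        total = sum(count_transitions(h, bins, d).sum()
                    for d in [(0, 1), (1, 0)])
        assert total == 3
        with pytest.raises(ValueError, match="outside"):
            count_transitions(h, np.array([0.0, 5.0]), "all")

    def test_empty_history_all_zero(self):
        from geoshift.markov import StochasticHistory
        h = StochasticHistory()
        assert count_transitions(h, np.array([0.0, 5.0]), "all").sum() == 0

    def test_lineages_in_bin_hand_counts(self):
        two = Chronogram.from_newick("(A:10,B:10);")
        assert lineages_in_bin(two, (5, 10)) == 2
        four = Chronogram.from_newick("((A:2,B:2):8,(C:6,D:6):4);")
        assert lineages_in_bin(four, (0, 5)) == 5
        assert lineages_in_bin(four, (5, 10)) == 4
        assert lineages_in_bin(four, (0, 5), "nodes") == 1
        assert lineages_in_bin(four, (5, 10), "nodes") == 1

    def test_lineage_counts_decrease_back_in_time(self, tree100):
        # lineages-through-time: the number of branches crossing a single
        # age is non-increasing going back in time on an ultrametric tree,
        # and every bin's branch count is at least the crossing count at
        # either of its edges
        tree, _, _ = tree100
        bins = make_bins(tree.root_age, 2.0)

        def crossing(age):
            return sum(1 for c in range(tree.n_nodes)
                       if tree.parent[c] >= 0
                       and tree.age[c] <= age < tree.age[tree.parent[c]])

        mids = (bins[:-1] + bins[1:]) / 2.0
        cross = [crossing(a) for a in mids]
        assert all(cross[b] >= cross[b + 1]
                   for b in range(len(cross) - 1))
        for b in range(len(bins) - 1):
            n_bin = lineages_in_bin(tree, (bins[b], bins[b + 1]))
            assert n_bin >= cross[b]

    def test_relative_rates_zero_q(self, quartet):
        states = pd.Series({t: "s" for t in "ABCD"})
        out = relative_shift_rates(quartet, states, np.zeros((1, 1)),
                                   root_prior=np.array([1.0]), n_maps=5,
                                   bin_width=5.0, seed=0)
        assert np.nansum(out.mean) == 0.0
        assert np.nansum(out.hi95) == 0.0

    def test_default_bin_and_map_settings(self):
        import inspect
        sig = inspect.signature(relative_shift_rates)
        assert sig.parameters["n_maps"].default == 100
        assert sig.parameters["bin_width"].default == 5.0

    def test_invariant_to_tip_order_permutation(self, tree100):
        tree, _, states = tree100
        q = np.array([[-0.05, 0.05], [0.08, -0.08]])
        a = relative_shift_rates(tree, states, q, n_maps=10, seed=3)
        shuffled = states.sample(frac=1.0, random_state=1)
        b = relative_shift_rates(tree, shuffled, q, n_maps=10, seed=3)
        np.testing.assert_allclose(a.mean, b.mean)

    def test_denominator_definition_preserves_directionality(self):
        # transient regime: root in state 0 with strongly asymmetric q, so
        # 0->1 flux dominates regardless of the denominator definition
        tree, _, states, _ = simulate_surviving(
            2, [0.2, 0.2], 0.0, [[0, 0.10], [0.01, 0]], seed=300,
            max_taxa=120, require_both_states=True, root_state=0)
        q = np.array([[-0.10, 0.10], [0.01, -0.01]])
        diffs = {}
        for den in ("branches", "nodes"):
            out = relative_shift_rates(tree, states, q,
                                       root_prior=np.array([1.0, 0.0]),
                                       n_maps=40, seed=9,
                                       denominator=den,
                                       directions=[(0, 1), (1, 0)])
            em = np.nansum(out.mean[0])
            im = np.nansum(out.mean[1])
            diffs[den] = em - im
        assert np.sign(diffs["branches"]) == np.sign(diffs["nodes"]) == 1
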