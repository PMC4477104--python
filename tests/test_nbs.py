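"""Network-based statistic: edge statistics, components, FWE inference."""

import numpy as np
import pytest
from scipy import stats as sps

from fcgraph import synthetic as syn
from fcgraph.connectivity import ConnectivityMatrix
from fcgraph.nbs import (EdgeStatMatrix, edgewise_tstats, nbs_test,
                         suprathreshold_components)

import oracles


def conn_stack(rng, n_subjects, n_regions=6, shift=None):
    labels = [f"R{i + 1:03d}" for i in range(n_regions)]
    out = []
    for _ in range(n_subjects):
        w = rng.uniform(-0.5, 0.5, size=(n_regions, n_regions))
        w = np.triu(w, 1)
        if shift is not None:
            w = w + np.triu(shift, 1)
        w = w + w.T
        out.append(ConnectivityMatrix(np.clip(w, -1, 1), labels))
    return out


class TestEdgewiseTstats:
    def test_identical_stacks_give_zero(self, rng):
        stack = conn_stack(rng, 4)
        res = edgewise_tstats(stack, stack)
        assert np.allclose(res.t_values, 0.0)

    def test_zero_pooled_variance_warns(self, rng):
        c = conn_stack(rng, 1)[0]
        with pytest.warns(RuntimeWarning, match="zero pooled variance"):
            res = edgewise_tstats([c, c], [c, c])
        assert np.allclose(res.t_values, 0.0)

    def test_matches_textbook_pooled_formula(self):
        # one edge, two subjects per group, evaluated by hand
        labels = ["a", "b"]
        def conn(v):
            w = np.array([[0.0, v], [v, 0.0]])
            return ConnectivityMatrix(w, labels)
        a_vals, b_vals = [0.5, 0.7], [0.1, 0.3]
        res = edgewise_tstats([conn(v) for v in a_vals],
                              [conn(v) for v in b_vals])
        sp2 = (np.var(a_vals, ddof=1) + np.var(b_vals, ddof=1)) / 2
        expected = (np.mean(a_vals) - np.mean(b_vals)) / \
            np.sqrt(sp2 * (1 / 2 + 1 / 2))
        assert res.t_values[0, 1] == pytest.approx(expected)
        assert res.df == 2

    def test_agrees_with_scipy_ttest(self, rng):
        a = conn_stack(rng, 5)
        b = conn_stack(rng, 7)
        res = edgewise_tstats(a, b)
        i, j = 1, 4
        va = [c.weights[i, j] for c in a]
        vb = [c.weights[i, j] for c in b]
        expected = sps.ttest_ind(va, vb, equal_var=True).statistic
        assert res.t_values[i, j] == pytest.approx(expected)

    def test_symmetric_zero_diagonal(self, rng):
        res = edgewise_tstats(conn_stack(rng, 3), conn_stack(rng, 3))
        assert np.allclose(res.t_values, res.t_values.T)
        assert np.allclose(np.diag(res.t_values), 0.0)

    def test_node_subset_restriction(self, rng):
        a, b = conn_stack(rng, 3), conn_stack(rng, 3)
        res = edgewise_tstats(a, b, node_subset=["R002", "R005"])
        assert res.node_subset == ["R002", "R005"]
        assert res.t_values.shape == (2, 2)


def stat_matrix(t, labels=None):
    t = np.asarray(t, dtype=float)
    labels = labels or [f"R{i + 1:03d}" for i in range(t.shape[0])]
    return EdgeStatMatrix(t, labels, df=10)


class TestSuprathresholdComponents:
    def test_all_below_threshold_is_empty(self, rng):
        t = rng.uniform(-1, 1, size=(6, 6))
        t = np.triu(t, 1) + np.triu(t, 1).T
        assert suprathreshold_components(stat_matrix(t), 1.6) == []

    def test_two_components_from_known_edges(self):
        t = np.zeros((5, 5))
        for i, j in [(0, 1), (1, 2)]:
            t[i, j] = t[j, i] = 2.0
        t[3, 4] = t[4, 3] = -2.5
        comps = suprathreshold_components(stat_matrix(t), 1.6)
        assert [c.size for c in comps] == [2, 1]
        assert comps[0].nodes == ["R001", "R002", "R003"]
        assert comps[1].nodes == ["R004", "R005"]
        assert {e["direction"] for e in comps[0].edges} == {"increase"}
        assert comps[1].edges[0]["direction"] == "decrease"

    def test_matches_union_find_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 11))
            t = rng.standard_normal((n, n)) * 1.5
            t = np.triu(t, 1) + np.triu(t, 1).T
            comps = suprathreshold_components(stat_matrix(t), 1.6)
            iu, ju = np.triu_indices(n, 1)
            edges = [(int(i), int(j)) for i, j in zip(iu, ju)
                     if abs(t[i, j]) >= 1.6]
            expected = oracles.union_find_components(n, edges)
            got = sorted((frozenset(int(lab[1:]) - 1 for lab in c.nodes),
                          c.size) for c in comps)
            want = sorted((frozenset(ns), sz) for ns, sz in expected)
            assert got == want

    def test_tiny_threshold_degenerates_to_connectivity(self, rng):
        t = rng.standard_normal((6, 6)) + 5
        t = np.triu(t, 1) + np.triu(t, 1).T
        comps = suprathreshold_components(stat_matrix(t), 1e-9)
        assert len(comps) == 1
        assert comps[0].size == 15

    def test_one_sided_screening(self):
        t = np.zeros((4, 4))
        t[0, 1] = t[1, 0] = 2.0
        t[2, 3] = t[3, 2] = -2.0
        up = suprathreshold_components(stat_matrix(t), 1.6, sided="greater")
        down = suprathreshold_components(stat_matrix(t), 1.6, sided="less")
        assert len(up) == 1 and up[0].nodes == ["R001", "R002"]
        assert len(down) == 1 and down[0].nodes == ["R003", "R004"]


class TestNbsTest:
    def test_null_groups_give_no_confident_component(self, rng):
        a, b = conn_stack(rng, 8), conn_stack(rng, 8)
        res = nbs_test(a, b, n_perm=300, seed=0)
        assert all(c.p_value > 0.05 for c in res.components)

    def test_planted_component_detected(self):
        ma = syn.make_precision_model(
            30, 6, within_block_strength=0.25, within_block_density=0.5,
            seed=100)
        edges = syn.connected_edge_set(30, 100)
        planted = sorted({i for e in edges for i in e})
        mb = syn.plant_group_effect(ma, edges, -0.22)
        spec = syn.CohortSpec(n_per_group=10, n_timepoints=200, seed=1)
        cohort = syn.simulate_cohort(ma, mb, spec)
        from fcgraph.connectivity import (bandpass_filter,
                                          partial_correlation_matrix,
                                          regress_nuisance)
        conns = [partial_correlation_matrix(
            regress_nuisance(bandpass_filter(ts), cohort.motion[i]))
            for i, ts in enumerate(cohort.subjects)]
        idx_a, idx_b = cohort.by_group()
        subset = [cohort.subjects[0].region_labels[i] for i in planted]
        res = nbs_test([conns[i] for i in idx_a], [conns[i] for i in idx_b],
                       node_subset=subset, n_perm=500, seed=2)
        sig = res.significant(0.05)
        assert sig, "planted component should reach significance"
        found = {int(lab[1:]) - 1 for lab in sig[0].nodes}
        assert len(found & set(planted)) >= 5

    def test_component_p_nonincreasing_in_size(self, rng):
        a = conn_stack(rng, 6)
        b = conn_stack(rng, 6, shift=rng.standard_normal((6, 6)) * 0.3)
        res = nbs_test(a, b, t_threshold=1.0, n_perm=300, seed=4)
        sizes = [c.size for c in res.components]
        ps = [c.p_value for c in res.components]
        for (s1, p1), (s2, p2) in zip(zip(sizes, ps), zip(sizes[1:], ps[1:])):
            if s1 > s2:
                assert p1 <= p2

    def test_within_group_subject_order_irrelevant_for_observed(self, rng):
        a, b = conn_stack(rng, 5), conn_stack(rng, 5)
        r1 = nbs_test(a, b, n_perm=200, seed=1)
        r2 = nbs_test(list(reversed(a)), b, n_perm=200, seed=1)
        t1 = edgewise_tstats(a, b).t_values
        t2 = edgewise_tstats(list(reversed(a)), b).t_values
        assert np.allclose(t1, t2)
        assert [c.size for c in r1.components] == \
            [c.size for c in r2.components]

    def test_deterministic_given_seed(self, rng):
        a, b = conn_stack(rng, 4), conn_stack(rng, 4)
        r1 = nbs_test(a, b, n_perm=200, seed=7)
        r2 = nbs_test(a, b, n_perm=200, seed=7)
        assert np.array_equal(r1.null_max_sizes, r2.null_max_sizes)
        assert [c.p_value for c in r1.components] == \
            [c.p_value for c in r2.components]
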