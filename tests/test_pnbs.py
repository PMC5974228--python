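"""Paired network-based statistic: thresholds, components, permutation p."""

import numpy as np
import pytest
from scipy import stats

from multiseed.pnbs import (
    DifferenceMatrix,
    difference_matrices,
    first_level_threshold,
    paired_t_pvalues,
    pnbs_test,
    supra_components,
)
from multiseed.types import ConnectivityMatrix

from oracles import pnbs_enumerate


def zmat(vals, directed=False):
    return ConnectivityMatrix(values=np.asarray(vals, float), directed=directed,
                              scale="fisher_z")


def diff(values, sid="s", group="control", region_ids=None):
    values = np.asarray(values, float)
    if region_ids is None:
        region_ids = np.arange(1, values.shape[0] + 1)
    return DifferenceMatrix(values=values, subject_id=sid, group=group,
                            directed=False, region_ids=np.asarray(region_ids))


class TestDifferenceMatrices:
    def test_equal_sessions_give_zero(self, rng):
        v = rng.normal(size=(4, 4)) * 0.1
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        out = difference_matrices({"s1": (zmat(v), zmat(v))}, {"s1": "control"})
        assert np.allclose(out[0].values, 0)

    def test_constant_shift(self, rng):
        v = rng.normal(size=(4, 4)) * 0.1
        np.fill_diagonal(v, 0)
        out = difference_matrices(
            {"s1": (zmat(v, directed=True), zmat(v + 0.2, directed=True))},
            {"s1": "experimental"},
        )
        assert np.allclose(out[0].values, 0.2)
        assert out[0].group == "experimental"

    def test_elementwise_subtraction(self, rng):
        a = rng.normal(size=(5, 5))
        b = rng.normal(size=(5, 5))
        np.fill_diagonal(a, 0)
        np.fill_diagonal(b, 0)
        out = difference_matrices(
            {"s": (zmat(a, directed=True), zmat(b, directed=True))}, {"s": "control"}
        )
        assert np.array_equal(out[0].values, b - a)

    def test_missing_session_raises(self, rng):
        with pytest.raises(ValueError, match="missing"):
            difference_matrices({"s": (zmat(np.zeros((3, 3))), None)}, {"s": "control"})

    def test_wrong_scale_raises(self):
        raw = ConnectivityMatrix(values=np.zeros((3, 3)), directed=False, scale="pearson_r")
        with pytest.raises(ValueError, match="Fisher"):
            difference_matrices({"s": (raw, raw)}, {"s": "control"})


class TestPairedT:
    def test_zero_differences_are_degenerate(self):
        diffs = [diff(np.zeros((3, 3))) for _ in range(4)]
        t, p = paired_t_pvalues(diffs)
        assert np.all(p == 1.0)
        assert np.all(t == 0.0)

    def test_hand_computed_t(self):
        # differences {1.1, 0.9, 1.0, 1.0} on one edge: t = 24.49, df = 3
        diffs = []
        for d in (1.1, 0.9, 1.0, 1.0):
            v = np.zeros((3, 3))
            v[0, 1] = v[1, 0] = d
            diffs.append(diff(v))
        t, p = paired_t_pvalues(diffs)
        assert t[0, 1] == pytest.approx(24.494897, abs=1e-4)
        assert p[0, 1] == pytest.approx(1.49e-4, rel=0.02)

    def test_p_symmetric_under_sign_flip(self, rng):
        base = [rng.normal(size=(4, 4)) * 0.3 for _ in range(6)]
        diffs = [diff(v) for v in base]
        flipped = [diff(-v) for v in base]
        _, p1 = paired_t_pvalues(diffs)
        _, p2 = paired_t_pvalues(flipped)
        assert np.allclose(p1, p2)

    def test_matches_scipy_ttest(self, rng):
        base = [rng.normal(size=(5, 5)) for _ in range(7)]
        diffs = [diff(v) for v in base]
        t, p = paired_t_pvalues(diffs)
        arr = np.stack(base)
        expected = stats.ttest_1samp(arr[:, 0, 3], 0.0)
        assert t[0, 3] == pytest.approx(expected.statistic)
        assert p[0, 3] == pytest.approx(expected.pvalue)

    def test_too_few_subjects_raise(self):
        with pytest.raises(ValueError, match="3 subjects"):
            paired_t_pvalues([diff(np.zeros((3, 3)))] * 2)


class TestFirstLevelThreshold:
    def test_exactly_one_percent_supra(self, rng):
        p = rng.uniform(size=1000)
        cutoff = first_level_threshold(p, fraction=0.01)
        assert (p <= cutoff).sum() == 10

    def test_fraction_one_keeps_everything(self, rng):
        p = rng.uniform(size=50)
        cutoff = first_level_threshold(p, fraction=1.0)
        assert (p <= cutoff).sum() == 50

    def test_uniform_cutoff_near_fraction(self, rng):
        # order statistics: the 1% quantile of 10_000 uniforms is ~0.01
        p = rng.uniform(size=10_000)
        cutoff = first_level_threshold(p, fraction=0.01)
        assert cutoff == pytest.approx(0.01, abs=0.004)

    def test_too_few_connections_raise(self, rng):
        with pytest.raises(ValueError, match="supra"):
            first_level_threshold(rng.uniform(size=50), fraction=0.01)


class TestSupraComponents:
    def test_empty_experimental_graph(self):
        conn = np.array([[1, 2], [2, 3], [3, 4]])
        ctrl_p = np.array([0.001, 0.5, 0.5])
        exp_p = np.array([0.9, 0.9, 0.9])
        surviving, k, cmax = supra_components(exp_p, 0.01, ctrl_p, conn)
        assert k == 0 and cmax == 1

    def test_rule_walkthrough(self):
        # control: one 3-edge component; experimental: components of 2 and 5 edges
        nodes = np.arange(1, 20)
        conn = np.array(
            [[1, 2], [2, 3], [3, 1],        # control triangle (3 edges)
             [5, 6], [6, 7],                # experimental 2-edge path (eliminated)
             [10, 11], [11, 12], [12, 13], [13, 14], [14, 10]]  # 5-edge cycle (kept)
        )
        ctrl_p = np.array([0.001] * 3 + [0.9] * 7)
        exp_p = np.array([0.9] * 3 + [0.001] * 7)
        surviving, k, cmax = supra_components(exp_p, 0.01, ctrl_p, conn)
        assert cmax == 3
        assert k == 5
        assert set(map(tuple, conn[surviving])) == set(map(tuple, conn[5:]))

    def test_all_experimental_components_eliminated(self):
        conn = np.array([[1, 2], [2, 3], [3, 4], [6, 7]])
        ctrl_p = np.array([0.001, 0.001, 0.001, 0.9])  # 3-edge control component
        exp_p = np.array([0.9, 0.9, 0.9, 0.001])  # single edge <= 3
        _, k, cmax = supra_components(exp_p, 0.01, ctrl_p, conn)
        assert cmax == 3 and k == 0

    def test_k_nonincreasing_in_control_component(self, rng):
        # enlarging the control component can only shrink k
        conn = np.array([[1, 2], [2, 3], [5, 6], [6, 7], [7, 8]])
        exp_p = np.array([0.9, 0.9, 0.001, 0.001, 0.001])
        weak_ctrl = np.array([0.001, 0.9, 0.9, 0.9, 0.9])   # max component 1
        strong_ctrl = np.array([0.001, 0.001, 0.9, 0.9, 0.9])  # max component 2
        _, k_weak, _ = supra_components(exp_p, 0.01, weak_ctrl, conn)
        _, k_strong, _ = supra_components(exp_p, 0.01, strong_ctrl, conn)
        assert k_weak >= k_strong


def random_diffs(rng, n_subj, n_regions, group, effect=None):
    out = []
    for s in range(n_subj):
        v = rng.normal(size=(n_regions, n_regions)) * 0.1
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        if effect:
            for i, j in effect:
                v[i - 1, j - 1] += 0.5
                v[j - 1, i - 1] += 0.5
        out.append(diff(v, sid=f"{group}{s}", group=group))
    return out


class TestPnbsTest:
    def test_exhaustive_matches_independent_enumeration(self, rng):
        # 3 vs 3 subjects: all C(6,3) = 20 assignments enumerated
        ctrl = random_diffs(rng, 3, 16, "control")
        expd = random_diffs(rng, 3, 16, "experimental", effect=[(1, 2), (2, 3)])
        res = pnbs_test(ctrl, expd, fraction=0.01, n_permutations=20)
        assert res.exhaustive and res.n_permutations == 20
        src, dst = np.triu_indices(16, k=1)
        conn = np.column_stack([src + 1, dst + 1])
        c_arr = np.stack([d.values[src, dst] for d in ctrl])
        e_arr = np.stack([d.values[src, dst] for d in expd])
        k_obs, ks = pnbs_enumerate(c_arr, e_arr, conn, fraction=0.01)
        assert res.k == k_obs
        assert sorted(res.null_sizes.tolist()) == sorted(ks)
        assert res.p_fwe == sum(kk > k_obs for kk in ks) / 20

    def test_identity_assignment_reproduces_observed_k(self, rng):
        ctrl = random_diffs(rng, 3, 12, "control")
        expd = random_diffs(rng, 3, 12, "experimental", effect=[(1, 2)])
        res = pnbs_test(ctrl, expd, fraction=0.02, n_permutations=20)
        # the true labelling is one of the enumerated assignments
        assert res.k in res.null_sizes

    def test_node_relabeling_invariance(self, rng):
        ctrl = random_diffs(rng, 4, 10, "control")
        expd = random_diffs(rng, 4, 10, "experimental", effect=[(1, 2), (2, 3)])
        res_a = pnbs_test(ctrl, expd, fraction=0.05, n_permutations=100, seed=3)
        perm = np.arange(10)[::-1]  # reverse node order
        relabeled_ids = np.arange(1, 11)

        def relabel(d):
            return DifferenceMatrix(
                values=d.values[np.ix_(perm, perm)],
                subject_id=d.subject_id,
                group=d.group,
                directed=False,
                region_ids=relabeled_ids,
            )

        res_b = pnbs_test(
            [relabel(d) for d in ctrl],
            [relabel(d) for d in expd],
            fraction=0.05,
            n_permutations=100,
            seed=3,
        )
        assert res_a.k == res_b.k
        assert res_a.p_fwe == res_b.p_fwe

    def test_tie_rule_ge_is_conservative(self, rng):
        ctrl = random_diffs(rng, 4, 10, "control")
        expd = random_diffs(rng, 4, 10, "experimental")
        gt = pnbs_test(ctrl, expd, fraction=0.05, n_permutations=70, seed=1)
        ge = pnbs_test(ctrl, expd, fraction=0.05, n_permutations=70, seed=1, tie_rule="ge")
        assert ge.p_fwe >= gt.p_fwe

    def test_seed_mandatory_for_random_sampling(self, rng):
        ctrl = random_diffs(rng, 6, 10, "control")
        expd = random_diffs(rng, 6, 10, "experimental")
        with pytest.raises(ValueError, match="seed"):
            pnbs_test(ctrl, expd, fraction=0.05, n_permutations=200)

    def test_planted_component_recovered_and_ranked_extreme(self):
        # a planted 6-edge path must survive elimination, and the observed
        # labelling must look far more extreme than the same data without
        # any effect (power at study scale is exercised elsewhere)
        planted = [(1, 2), (2, 3), (3, 4), (4, 5), (5, 6), (6, 7)]
        rng = np.random.default_rng(77)
        ctrl = random_diffs(rng, 8, 14, "control")
        expd = random_diffs(rng, 8, 14, "experimental", effect=planted)
        res = pnbs_test(ctrl, expd, fraction=0.02, n_permutations=200, seed=9)
        assert res.k >= 6
        survived = {(i, j) for i, j, _ in res.surviving_edges}
        assert set(planted) <= survived
        rng = np.random.default_rng(77)
        ctrl0 = random_diffs(rng, 8, 14, "control")
        expd0 = random_diffs(rng, 8, 14, "experimental")
        null = pnbs_test(ctrl0, expd0, fraction=0.02, n_permutations=200, seed=9)
        assert res.p_fwe < null.p_fwe

    def test_small_group_raises(self, rng):
        with pytest.raises(ValueError, match="3 subjects"):
            pnbs_test(random_diffs(rng, 2, 8, "control"),
                      random_diffs(rng, 4, 8, "experimental"))


class TestConnectionSets:
    def test_union_of_graph_edges(self):
        from multiseed.graph import threshold_graph
        from multiseed.pnbs import connection_set_from_graphs

        a = np.zeros((5, 5))
        a[0, 1] = a[1, 0] = 0.9
        b = np.zeros((5, 5))
        b[1, 2] = b[2, 1] = 0.8
        b[0, 1] = b[1, 0] = 0.7  # overlaps graph a
        ga = threshold_graph(ConnectivityMatrix(values=a, directed=False, scale="fisher_z"),
                             "z_cutoff", 0.1)
        gb = threshold_graph(ConnectivityMatrix(values=b, directed=False, scale="fisher_z"),
                             "z_cutoff", 0.1)
        conn = connection_set_from_graphs([ga, gb])
        assert conn.tolist() == [[1, 2], [2, 3]]

    def test_restricted_connection_set_changes_universe(self, rng):
        ctrl = random_diffs(rng, 4, 10, "control")
        expd = random_diffs(rng, 4, 10, "experimental", effect=[(1, 2)])
        conn = np.array([[i, j] for i in range(1, 11) for j in range(i + 1, 11)][:20])
        res = pnbs_test(ctrl, expd, connection_set=conn, fraction=0.05,
                        n_permutations=50, seed=2)
        assert res.connection_set.shape == (20, 2)
        for i, j, _ in res.surviving_edges:
            assert [i, j] in conn.tolist()
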