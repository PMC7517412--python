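import numpy as np
import pandas as pd
import pytest

from fdnet.community import ModulePartition
from fdnet.exceptions import DomainError, ValidationError
from fdnet.metrics import (
    classify_hubs,
    compute_node_metrics,
    connectivity_report,
    group_ratio,
    lobe_mean,
    lobe_weight_connectivity,
    node_metric_report,
    participation_coeff,
    within_module_z,
)

from conftest import random_symmetric


def brute_force_z(w, comm, weighted):
    n = w.shape[0]
    m = w if weighted else (w > 0).astype(float)
    k = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if comm[i] == comm[j]:
                k[i] += m[i, j]
    z = np.zeros(n)
    for c in set(comm):
        idx = [i for i in range(n) if comm[i] == c]
        mu = np.mean([k[i] for i in idx])
        sd = np.sqrt(np.mean([(k[i] - mu) ** 2 for i in idx]))
        for i in idx:
            z[i] = (k[i] - mu) / sd if sd > 0 else 0.0
    return z


def brute_force_p(w, comm, weighted):
    n = w.shape[0]
    m = w if weighted else (w > 0).astype(float)
    p = np.zeros(n)
    for i in range(n):
        ki = m[i].sum()
        if ki == 0:
            continue
        acc = 0.0
        for c in set(comm):
            kci = sum(m[i, j] for j in range(n) if comm[j] == c)
            acc += (kci / ki) ** 2
        p[i] = 1 - acc
    return p


def partition_of(labels):
    return ModulePartition(assignment=np.asarray(labels), q=0.0)


class TestWithinModuleZ:
    def test_uniform_module_all_zero(self):
        w = np.ones((4, 4)) - np.eye(4)
        z = within_module_z(w, partition_of([1, 1, 1, 1]))
        np.testing.assert_allclose(z, 0.0)

    def test_three_node_star_module_binary(self):
        # node 0 linked to 1 and 2: within-degrees {2, 1, 1}
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.9
        w[0, 2] = w[2, 0] = 0.4
        z = within_module_z(w, partition_of([1, 1, 1]), weighted=False)
        np.testing.assert_allclose(z, [np.sqrt(2), -1 / np.sqrt(2), -1 / np.sqrt(2)])

    def test_singleton_module_zero(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        z = within_module_z(w, partition_of([1, 1, 2]))
        assert z[2] == 0.0

    def test_zero_mean_within_module(self):
        rng = np.random.default_rng(0)
        w = random_symmetric(20, rng, density=0.5)
        comm = rng.integers(1, 4, size=20)
        z = within_module_z(w, partition_of(_compact(comm)))
        for c in np.unique(_compact(comm)):
            members = z[_compact(comm) == c]
            if members.std() > 0:
                assert abs(members.mean()) < 1e-9

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        w = random_symmetric(15, rng, density=0.5)
        comm = partition_of(_compact(rng.integers(1, 4, size=15)))
        np.testing.assert_allclose(
            within_module_z(w, comm), within_module_z(10 * w, comm), atol=1e-12)


def _compact(labels):
    _, inv = np.unique(labels, return_inverse=True)
    return inv + 1


class TestParticipation:
    def test_all_edges_internal_is_zero(self):
        w = np.ones((4, 4)) - np.eye(4)
        p = participation_coeff(w, partition_of([1, 1, 1, 1]))
        np.testing.assert_allclose(p, 0.0)

    def test_even_spread_over_four_modules(self):
        # hub node 0 with one edge into each of 4 modules
        w = np.zeros((9, 9))
        for j in (1, 3, 5, 7):
            w[0, j] = w[j, 0] = 1.0
        labels = [1, 1, 2, 2, 3, 3, 4, 4, 1]
        p = participation_coeff(w, partition_of(labels), weighted=False)
        assert p[0] == pytest.approx(0.75)

    def test_isolated_node_zero(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        p = participation_coeff(w, partition_of([1, 1, 2]))
        assert p[2] == 0.0

    @pytest.mark.parametrize("weighted", [True, False])
    def test_bounds_and_module_count_cap(self, weighted):
        rng = np.random.default_rng(2)
        w = random_symmetric(16, rng, density=0.4)
        comm = _compact(rng.integers(1, 5, size=16))
        p = participation_coeff(w, partition_of(comm), weighted=weighted)
        assert ((0 <= p) & (p <= 1)).all()
        m = w if weighted else (w > 0).astype(float)
        for i in range(16):
            if m[i].sum() == 0:
                continue
            touched = len({comm[j] for j in np.nonzero(m[i])[0]})
            assert p[i] <= 1 - 1 / touched + 1e-12

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        w = random_symmetric(12, rng, density=0.5)
        comm = partition_of(_compact(rng.integers(1, 4, size=12)))
        np.testing.assert_allclose(
            participation_coeff(w, comm), participation_coeff(3 * w, comm), atol=1e-12)


class TestBruteForceOracles:
    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("weighted", [True, False])
    def test_z_and_p_match_naive_loops(self, seed, weighted):
        rng = np.random.default_rng(400 + seed)
        n = int(rng.integers(4, 13))
        w = random_symmetric(n, rng, density=0.5)
        comm = _compact(rng.integers(1, 4, size=n))
        part = partition_of(comm)
        np.testing.assert_allclose(
            within_module_z(w, part, weighted=weighted),
            brute_force_z(w, comm, weighted), atol=1e-12)
        np.testing.assert_allclose(
            participation_coeff(w, part, weighted=weighted),
            brute_force_p(w, comm, weighted), atol=1e-12)


class TestHubs:
    def test_no_hubs_at_zero_z(self):
        assert not classify_hubs(np.zeros(5)).any()

    def test_boundary_inclusive(self):
        np.testing.assert_array_equal(
            classify_hubs(np.array([2.6, 2.5, 2.4])), [True, True, False])

    def test_zero_threshold(self):
        z = np.array([-0.1, 0.0, 1.0])
        np.testing.assert_array_equal(classify_hubs(z, 0.0), [False, True, True])


class TestLobeMeans:
    def test_constant_vector(self, atlas):
        assert lobe_mean(np.ones(68), atlas, "temporal", "both") == 1.0

    def test_whole_network_mean(self, atlas):
        rng = np.random.default_rng(4)
        v = rng.standard_normal(68)
        assert lobe_mean(v, atlas, "all", "both") == pytest.approx(v.mean())

    def test_occipital_left_selection(self, atlas):
        v = np.zeros(68)
        for i in (61, 63, 65, 67):
            v[i - 1] = 1.0
        assert lobe_mean(v, atlas, "occipital", "left") == pytest.approx(1.0)
        assert lobe_mean(v, atlas, "occipital", "right") == 0.0

    def test_report_layout(self, atlas):
        rng = np.random.default_rng(5)
        rep = node_metric_report(rng.standard_normal(68), atlas)
        assert list(rep.columns) == ["total", "left", "right"]
        assert list(rep.index) == ["frontal", "temporal", "parietal", "occipital", "whole"]


class TestLobeWeightConnectivity:
    def _frontal_left_triple(self, atlas):
        from fdnet.network import BrainNetwork

        w = np.zeros((68, 68))
        # three weight-0.5 edges inside the frontal-left set {1,3,5,...}
        for i, j in ((1, 3), (3, 5), (5, 7)):
            w[i - 1, j - 1] = w[j - 1, i - 1] = 0.5
        return BrainNetwork(w)

    def test_intra_sum_and_mean(self, atlas):
        net = self._frontal_left_triple(atlas)
        total = lobe_weight_connectivity(net, atlas, "intra", "frontal", "left", "sum")
        assert total == pytest.approx(1.5)
        mean = lobe_weight_connectivity(net, atlas, "intra", "frontal", "left", "mean")
        assert mean == pytest.approx(1.5 / (14 * 13 / 2))

    def test_empty_network_all_zero(self, atlas):
        from fdnet.network import BrainNetwork

        net = BrainNetwork(np.zeros((68, 68)))
        for scope in ("intra", "inter"):
            rep = connectivity_report(net, atlas, scope, "sum")
            assert (rep.to_numpy() == 0).all()

    @pytest.mark.parametrize("seed", range(4))
    def test_conservation_identity(self, atlas, seed):
        from fdnet.network import BrainNetwork

        w = random_symmetric(68, np.random.default_rng(500 + seed), density=0.2)
        net = BrainNetwork(w)
        intra = sum(
            lobe_weight_connectivity(net, atlas, "intra", lobe, "both", "sum")
            for lobe in ("frontal", "temporal", "parietal", "occipital"))
        inter = sum(
            lobe_weight_connectivity(net, atlas, "inter", lobe, "both", "sum")
            for lobe in ("frontal", "temporal", "parietal", "occipital"))
        # each lobe-crossing edge appears in exactly two lobes' inter sums
        assert intra + inter / 2 == pytest.approx(net.total_strength, rel=1e-12)

    def test_bad_scope_rejected(self, atlas):
        net = self._frontal_left_triple(atlas)
        with pytest.raises(ValidationError):
            lobe_weight_connectivity(net, atlas, "within", "frontal")


class TestGroupRatio:
    def _report(self, value):
        idx = ["frontal", "temporal", "parietal", "occipital"]
        cols = ["total", "left", "right"]
        return pd.DataFrame(np.full((4, 3), value), index=idx, columns=cols)

    def test_reference_cells(self):
        elderly = self._report(1.0)
        middle = self._report(1.0)
        elderly.loc["temporal", "total"] = 0.4239
        middle.loc["temporal", "total"] = 0.3351
        ratio = group_ratio(elderly, middle)
        assert ratio.loc["temporal", "total"] == pytest.approx(126.5)

    def test_inter_frontal_cell(self):
        elderly = self._report(0.6345)
        middle = self._report(0.7119)
        assert group_ratio(elderly, middle).loc["frontal", "total"] == pytest.approx(89.1)

    def test_equal_reports_give_hundred(self):
        r = group_ratio(self._report(0.5), self._report(0.5))
        assert (r.to_numpy() == 100.0).all()

    def test_zero_denominator_is_nan(self):
        r = group_ratio(self._report(0.5), self._report(0.0))
        assert np.isnan(r.to_numpy()).all()

    def test_layout_mismatch_rejected(self):
        a = self._report(1.0)
        b = self._report(1.0).iloc[::-1]
        with pytest.raises(ValidationError):
            group_ratio(a, b)
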