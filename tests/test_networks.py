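"""Interaction networks, regularized Laplacians, SPD geodesics, network of networks."""

import numpy as np
import pytest
from scipy import linalg

from voxelage.networks import (
    build_network,
    dynamic_network_panel,
    network_of_networks,
    regularized_laplacian,
    spd_geodesic,
    spd_geodesic_matrixlog,
)
from voxelage.shapley import InteractionTensor, ShapDecomposition
from voxelage.synthetic import SubjectRecord


def tensor(values, sid="s"):
    return InteractionTensor(sid, np.asarray(values, dtype=float))


def random_spd(rng, n=4, scale=1.0):
    A = rng.normal(size=(n, n))
    return A @ A.T + scale * np.eye(n)


class TestBuildNetwork:
    def test_additive_model_has_zero_off_diagonal(self):
        t = tensor(np.diag([1.0, 2.0, 3.0]))
        net = build_network(t)
        off = net.adjacency - np.diag(np.diag(net.adjacency))
        np.testing.assert_array_equal(off, 0.0)

    def test_keep_fraction_one_exports_full_graph(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(5, 5))
        A = (A + A.T) / 2
        net = build_network(tensor(A), edge_keep_fraction=1.0)
        assert len(net.display_edges) == 10

    def test_asymmetric_tensor_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            build_network(tensor([[0.0, 1.0], [2.0, 0.0]]))

    def test_strongest_edges_selected_by_magnitude(self):
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = -5.0
        A[2, 3] = A[3, 2] = 1.0
        net = build_network(tensor(A), edge_keep_fraction=0.2)
        assert net.display_edges == [(0, 1, -5.0)]


class TestRegularizedLaplacian:
    def test_edgeless_graph_gives_lambda_identity(self):
        net = build_network(tensor(np.zeros((3, 3))))
        spd = regularized_laplacian(net, lam=1.0)
        np.testing.assert_array_equal(spd.matrix, np.eye(3))

    def test_two_node_hand_example(self):
        A = np.array([[0.0, 0.3], [0.3, 0.0]])
        spd = regularized_laplacian(build_network(tensor(A)), lam=1.0)
        np.testing.assert_allclose(spd.matrix, [[1.3, -0.3], [-0.3, 1.3]])
        np.testing.assert_allclose(np.sort(linalg.eigvalsh(spd.matrix)), [1.0, 1.6])

    @pytest.mark.parametrize("seed", range(5))
    def test_absolute_mode_min_eigenvalue_at_least_lambda(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(6, 6))
        A = (A + A.T) / 2
        for lam in (0.1, 1.0, 10.0):
            spd = regularized_laplacian(build_network(tensor(A)), lam=lam)
            assert linalg.eigvalsh(spd.matrix)[0] >= lam - 1e-10

    def test_signed_mode_rejects_indefinite(self):
        A = np.array([[0.0, -0.5], [-0.5, 0.0]])
        with pytest.raises(ValueError, match="positive definite"):
            regularized_laplacian(build_network(tensor(A)), lam=0.1, weight_mode="signed")

    def test_diagonal_zeroed_by_default(self):
        A = np.array([[9.0, 0.2], [0.2, 9.0]])
        spd = regularized_laplacian(build_network(tensor(A)), lam=1.0)
        np.testing.assert_allclose(spd.matrix, [[1.2, -0.2], [-0.2, 1.2]])

    def test_invalid_lambda_raises(self):
        with pytest.raises(ValueError, match="lambda"):
            regularized_laplacian(build_network(tensor(np.zeros((2, 2)))), lam=0.0)


class TestGeodesic:
    def test_identity_of_indiscernibles(self):
        rng = np.random.default_rng(0)
        P = random_spd(rng)
        d2, d = spd_geodesic(P, P)
        assert d2 == pytest.approx(0.0, abs=1e-18)
        assert d == pytest.approx(0.0, abs=1e-9)

    def test_diagonal_closed_form(self):
        """P = I3, Q = e^2 I3: d^2 = 3 * 2^2 = 12."""
        d2, d = spd_geodesic(np.eye(3), np.exp(2.0) * np.eye(3))
        assert d2 == pytest.approx(12.0, rel=1e-12)
        assert d == pytest.approx(np.sqrt(12.0), rel=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        P, Q = random_spd(rng), random_spd(rng)
        assert spd_geodesic(P, Q)[1] == pytest.approx(spd_geodesic(Q, P)[1], rel=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_affine_invariance(self, seed):
        rng = np.random.default_rng(seed)
        P, Q = random_spd(rng), random_spd(rng)
        G = rng.normal(size=P.shape)
        while abs(np.linalg.det(G)) < 1e-3:
            G = rng.normal(size=P.shape)
        d = spd_geodesic(P, Q)[1]
        d_t = spd_geodesic(G.T @ P @ G, G.T @ Q @ G)[1]
        assert d_t == pytest.approx(d, rel=1e-8)

    @pytest.mark.parametrize("seed", range(10))
    def test_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        P, Q, R = (random_spd(rng) for _ in range(3))
        dpq, dqr, dpr = (spd_geodesic(a, b)[1] for a, b in ((P, Q), (Q, R), (P, R)))
        assert dpr <= dpq + dqr + 1e-8

    @pytest.mark.parametrize("seed", range(10))
    def test_generalized_eigenvalue_route_matches_matrix_log(self, seed):
        rng = np.random.default_rng(seed)
        P, Q = random_spd(rng), random_spd(rng)
        d2_eig, _ = spd_geodesic(P, Q)
        d2_log = spd_geodesic_matrixlog(P, Q)
        assert d2_eig == pytest.approx(d2_log, rel=1e-8, abs=1e-8)

    def test_non_pd_rejected(self):
        with pytest.raises(ValueError):
            spd_geodesic(np.diag([1.0, -1.0]), np.eye(2))


class TestNetworkOfNetworks:
    def _spds(self, n, seed=0, m=4):
        rng = np.random.default_rng(seed)
        from voxelage.networks import SPDNet

        return [SPDNet(f"s{i}", random_spd(rng, m), 1.0, "absolute") for i in range(n)]

    def test_identical_networks_give_zero_distance_always_retained(self):
        spds = self._spds(4)
        spds[1] = type(spds[0])("s1", spds[0].matrix.copy(), 1.0, "absolute")
        net = network_of_networks(spds, keep_fraction=0.2)
        assert net.B[0, 1] == pytest.approx(0.0, abs=1e-9)
        assert (0, 1) in {(i, j) for i, j, _ in net.retained_edges}

    def test_keep_fraction_one_is_complete_graph(self):
        net = network_of_networks(self._spds(5), keep_fraction=1.0)
        assert len(net.retained_edges) == 10

    def test_b_symmetric_zero_diagonal_non_negative(self):
        net = network_of_networks(self._spds(6), keep_fraction=0.5)
        np.testing.assert_allclose(net.B, net.B.T)
        np.testing.assert_array_equal(np.diag(net.B), 0.0)
        assert np.all(net.B >= 0)

    def test_retained_edges_invariant_to_subject_reordering(self):
        spds = self._spds(6, seed=3)
        net1 = network_of_networks(spds, keep_fraction=0.4)
        perm = [4, 2, 0, 5, 1, 3]
        net2 = network_of_networks([spds[i] for i in perm], keep_fraction=0.4)
        inv = {p: i for i, p in enumerate(perm)}
        edges1 = {frozenset((i, j)) for i, j, _ in net1.retained_edges}
        edges2 = {frozenset((perm[i], perm[j])) for i, j, _ in net2.retained_edges}
        assert edges1 == edges2

    def test_invalid_keep_fraction(self):
        with pytest.raises(ValueError, match="keep_fraction"):
            network_of_networks(self._spds(3), keep_fraction=0.0)


class TestDynamicPanel:
    def _cohort(self, ages):
        decs, tensors, records = [], [], []
        rng = np.random.default_rng(0)
        for i, age in enumerate(ages):
            sid = f"s{i}"
            phi = rng.normal(size=3)
            decs.append(ShapDecomposition(sid, 50.0, phi, 50.0 + phi.sum()))
            A = rng.normal(size=(3, 3))
            tensors.append(InteractionTensor(sid, (A + A.T) / 2))
            records.append(SubjectRecord(sid, age, "male", 0))
        return decs, tensors, records

    def test_sorted_by_age_then_id(self):
        decs, tensors, records = self._cohort([40.0, 30.0, 40.0, 20.0])
        panel = dynamic_network_panel(decs, tensors, records)
        assert [e["subject_id"] for e in panel] == ["s3", "s1", "s0", "s2"]

    def test_export_count_matches_cohort(self):
        decs, tensors, records = self._cohort([25.0, 35.0, 45.0])
        assert len(dynamic_network_panel(decs, tensors, records)) == 3
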