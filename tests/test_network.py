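"""Network construction, the coupled vector field, and its symmetries."""

import numpy as np
import pytest

from ecosocnet import (
    ModelParams,
    NetworkModel,
    build_interaction,
    build_laplacian,
    read_edge_list,
    rhs_network,
    rhs_single,
    sync_error,
)
from ecosocnet.errors import InvalidStateError


def test_chain_and_ring_laplacians():
    np.testing.assert_array_equal(
        build_laplacian("chain", 3), [[1, -1, 0], [-1, 2, -1], [0, -1, 1]]
    )
    np.testing.assert_array_equal(
        build_laplacian("ring", 3), [[2, -1, -1], [-1, 2, -1], [-1, -1, 2]]
    )


def test_star_laplacian_hub_degree():
    B = build_laplacian("star", 5)
    assert B[0, 0] == 4
    assert np.all(np.diag(B)[1:] == 1)


def test_random_laplacian_statistics():
    degrees = []
    for seed in range(100):
        B = build_laplacian("random", 20, seed=seed, avg_degree=4)
        eig = np.linalg.eigvalsh(B)
        assert eig[0] == pytest.approx(0.0, abs=1e-9)
        assert eig[1] > 1e-9  # connected: single zero eigenvalue
        degrees.append(np.diag(B).mean())
    assert 3.0 <= np.mean(degrees) <= 5.0


def test_laplacian_kernel_is_constant_vector():
    B = build_laplacian("random", 12, seed=3, avg_degree=3)
    np.testing.assert_allclose(B @ np.ones(12), 0.0, atol=1e-12)


def test_interaction_builders():
    U = build_interaction("uniform", 3)
    assert np.all(U == 1 / 3)
    np.testing.assert_allclose(U.sum(axis=1), 1.0)
    D = build_interaction("uniform_plus_delta", 3, delta=1e-2 / 3)
    np.testing.assert_allclose(np.diag(D), 1 / 3 + 1e-2 / 3)
    np.testing.assert_allclose(D[0, 1], 1 / 3)
    np.testing.assert_array_equal(build_interaction("identity", 5), np.eye(5))


def test_single_node_network_reduces_to_single_system():
    p = ModelParams()
    m = NetworkModel.single(p)
    s = np.array([2.0, 80.0, 5.0])
    np.testing.assert_allclose(rhs_network(s, m), rhs_single(s, p), rtol=1e-14)


def test_synchronized_uniform_network_matches_single_system():
    p = ModelParams()
    m = NetworkModel.uniform(p, 4, interaction="uniform")
    s = np.array([2.0, 80.0, 5.0])
    v = np.tile(s, 4)
    out = rhs_network(v, m).reshape(4, 3)
    single = rhs_single(s, p)
    for i in range(4):
        np.testing.assert_allclose(out[i], single, rtol=1e-12)


def test_identity_interaction_decouples_extraction():
    p = ModelParams()
    alphas = np.array([2e-5, 5e-5, 9e-5])
    m = NetworkModel(p, alphas, np.eye(3), np.zeros((3, 3)), 0.0)
    rng = np.random.default_rng(0)
    v = rng.uniform(0.5, 50.0, 9)
    out = rhs_network(v, m).reshape(3, 3)
    for i in range(3):
        p_i = ModelParams(**{**p.to_dict(), "alpha": alphas[i]})
        np.testing.assert_allclose(out[i], rhs_single(v[3 * i:3 * i + 3], p_i), rtol=1e-12)


@pytest.mark.parametrize("sigma", [0.0, 0.1, 0.3])
def test_migration_conserves_total_population(sigma):
    """d/dt sum(x_i) must not depend on the diffusion constant."""
    p = ModelParams()
    B = build_laplacian("random", 8, seed=5, avg_degree=3)
    m = NetworkModel.uniform(p, 8, interaction="identity", B=B, sigma=sigma)
    rng = np.random.default_rng(7)
    v = rng.uniform(0.1, 60.0, 24)
    m0 = NetworkModel.uniform(p, 8, interaction="identity", B=B, sigma=0.0)
    xdot_sum = rhs_network(v, m)[0::3].sum()
    xdot_sum_nodiff = rhs_network(v, m0)[0::3].sum()
    assert xdot_sum == pytest.approx(xdot_sum_nodiff, abs=1e-12 * max(abs(xdot_sum_nodiff), 1.0))


def test_symmetric_subspace_is_invariant():
    """Equal nodes, permutation-symmetric coupling: derivatives stay equal."""
    p = ModelParams()
    B = build_laplacian("ring", 5)
    m = NetworkModel.uniform(p, 5, interaction="uniform", B=B, sigma=0.2)
    v = np.tile([3.0, 70.0, 8.0], 5)
    out = rhs_network(v, m).reshape(5, 3)
    for i in range(1, 5):
        np.testing.assert_allclose(out[i], out[0], rtol=1e-12)


def test_sync_error_cases():
    states = np.tile([1.0, 2.0, 3.0], (10, 3))  # 3 identical nodes over time
    np.testing.assert_array_equal(sync_error(states), 0.0)
    states2 = states.copy()
    states2[:, 3] += 1.0  # node 2 differs in x by 1
    np.testing.assert_allclose(sync_error(states2), 1.0)
    with pytest.raises(ValueError):
        sync_error(np.ones((5, 3)))


def test_network_model_validation():
    p = ModelParams()
    with pytest.raises(ValueError):  # asymmetric B
        NetworkModel(p, [1e-5, 1e-5], np.eye(2), [[1.0, -1.0], [0.0, 0.0]], 0.0)
    with pytest.raises(ValueError):  # off-diagonal must be 0 or -1
        NetworkModel(p, [1e-5, 1e-5], np.eye(2), [[0.5, -0.5], [-0.5, 0.5]], 0.0)
    with pytest.raises(ValueError):  # negative interaction
        NetworkModel(p, [1e-5, 1e-5], -np.eye(2), np.zeros((2, 2)), 0.0)
    with pytest.raises(InvalidStateError):
        rhs_network([1.0, 2.0], NetworkModel.single(p))


def test_edge_list_round_trip(tmp_path):
    path = tmp_path / "net.edges"
    path.write_text("0 1\n1 2\n2 0\n")
    np.testing.assert_array_equal(read_edge_list(path), build_laplacian("ring", 3))
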