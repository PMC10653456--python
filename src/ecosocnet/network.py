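"""Networks of interacting societies.

Each of ``N`` nodes carries a ``(x_i, y_i, z_i)`` triple.  Two separate
couplings act on the network:

* an extraction interaction matrix ``A`` (non-negative): node ``i``'s
  extraction term is ``alpha_i x_i y_i sum_j A_ij x_j``, so capacities
  cooperate (or not) in depleting each node's resource stock;
* migration as diffusion of capacity through ``-sigma * B x``, with ``B``
  the graph Laplacian of an undirected migration network.  Because the
  Laplacian's columns sum to zero, migration conserves the total
  population at every instant.

The state layout is node-major: ``(x_1, y_1, z_1, ..., x_N, y_N, z_N)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from . import _kernels
from .errors import InvalidStateError
from .params import ModelParams

__all__ = [
    "NetworkModel",
    "build_laplacian",
    "build_interaction",
    "rhs_network",
    "sync_error",
    "read_edge_list",
    "interaction_from_csv",
]

TOPOLOGIES = ("chain", "ring", "star", "random")


@dataclass(frozen=True)
class NetworkModel:
    """An ``N``-society model: shared constants, per-node extraction rates,
    interaction matrix ``A``, migration Laplacian ``B`` and diffusion
    constant ``sigma``."""

    params: ModelParams
    alphas: np.ndarray
    A: np.ndarray
    B: np.ndarray
    sigma: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "alphas", np.asarray(self.alphas, dtype=float))
        object.__setattr__(self, "A", np.asarray(self.A, dtype=float))
        object.__setattr__(self, "B", np.asarray(self.B, dtype=float))
        n = self.alphas.shape[0]
        if n < 1:
            raise ValueError("need at least one node")
        if self.A.shape != (n, n) or self.B.shape != (n, n):
            raise ValueError(
                f"A and B must be {n}x{n}; got {self.A.shape} and {self.B.shape}"
            )
        if not np.all(np.isfinite(self.A)) or np.any(self.A < 0):
            raise ValueError("interaction matrix A must be finite and non-negative")
        if self.sigma < 0:
            raise ValueError("diffusion constant sigma must be >= 0")
        if np.any(self.alphas <= 0):
            raise ValueError("all extraction rates must be strictly positive")
        _validate_laplacian(self.B)

    @property
    def n_nodes(self) -> int:
        return int(self.alphas.shape[0])

    @classmethod
    def single(cls, params: ModelParams) -> "NetworkModel":
        """The one-node network, identical to the single-society model."""
        return cls(params, np.array([params.alpha]), np.ones((1, 1)), np.zeros((1, 1)), 0.0)

    @classmethod
    def uniform(
        cls,
        params: ModelParams,
        n_nodes: int,
        alpha: Optional[float] = None,
        interaction: str = "uniform",
        delta: float = 0.0,
        B: Optional[np.ndarray] = None,
        sigma: float = 0.0,
    ) -> "NetworkModel":
        """All nodes share one extraction rate; convenience constructor."""
        a = params.alpha if alpha is None else alpha
        A = build_interaction(interaction, n_nodes, delta)
        Bm = np.zeros((n_nodes, n_nodes)) if B is None else B
        return cls(params, np.full(n_nodes, a), A, Bm, sigma)

    def kernel_args(self) -> tuple:
        """Positional arguments shared by all compiled kernels."""
        p = self.params
        return (
            self.alphas,
            self.A,
            self.B,
            self.sigma,
            p.b,
            p.d,
            p.r,
            p.K,
            p.c,
            p.epsilon,
        )


def _validate_laplacian(B: np.ndarray) -> None:
    if B.size == 0:
        raise ValueError("empty Laplacian")
    if not np.allclose(B, B.T, atol=1e-9):
        raise ValueError("Laplacian B must be symmetric (undirected migration)")
    if not np.allclose(B.sum(axis=1), 0.0, atol=1e-9):
        raise ValueError("Laplacian rows must sum to zero")
    off = B[~np.eye(B.shape[0], dtype=bool)]
    if not np.all(np.isclose(off, 0.0) | np.isclose(off, -1.0)):
        raise ValueError("off-diagonal Laplacian entries must be 0 or -1")
    deg = -B.sum(axis=1) + np.diag(B)  # row sums are 0, so diag == degree
    if np.any(np.diag(B) < -1e-12):
        raise ValueError("Laplacian diagonal (node degrees) must be non-negative")
    del deg


def build_laplacian(
    topology: str,
    n_nodes: int,
    seed: Optional[int] = None,
    avg_degree: Optional[float] = None,
    max_attempts: int = 1000,
) -> np.ndarray:
    """Graph Laplacian of a named undirected topology.

    ``random`` draws an Erdős–Rényi graph with edge probability
    ``avg_degree / (n_nodes - 1)``, resampled until connected (up to
    ``max_attempts`` draws).
    """
    if topology not in TOPOLOGIES:
        raise ValueError(f"unknown topology {topology!r}; choose from {TOPOLOGIES}")
    if n_nodes < 2:
        raise ValueError("a migration network needs at least 2 nodes")
    if topology == "chain":
        g = nx.path_graph(n_nodes)
    elif topology == "ring":
        g = nx.cycle_graph(n_nodes)
    elif topology == "star":
        if n_nodes < 3:
            warnings.warn("star with fewer than 3 nodes degenerates to a chain", stacklevel=2)
        g = nx.star_graph(n_nodes - 1)  # node 0 is the hub
    else:
        if avg_degree is None:
            raise ValueError("random topology requires avg_degree")
        if seed is None:
            raise ValueError("random topology requires a seed")
        rng = np.random.default_rng(seed)
        p_edge = avg_degree / (n_nodes - 1)
        for _ in range(max_attempts):
            g = nx.gnp_random_graph(n_nodes, p_edge, seed=int(rng.integers(2**31)))
            if nx.is_connected(g):
                break
        else:
            raise RuntimeError(
                f"no connected G(n={n_nodes}, p={p_edge:.3f}) in {max_attempts} draws"
            )
    return nx.laplacian_matrix(g, nodelist=range(n_nodes)).toarray().astype(float)


def build_interaction(kind: str, n_nodes: int, delta: float = 0.0) -> np.ndarray:
    """Extraction interaction matrix.

    ``identity``: independent extraction (``A = I``); ``uniform``: all
    entries ``1/N`` (exactly synchronizable to the single system);
    ``uniform_plus_delta``: uniform plus ``delta`` on the diagonal — the
    small non-uniformity that makes the synchronized cycle transversally
    unstable and opens the door to chaos.
    """
    if n_nodes < 1:
        raise ValueError("need at least one node")
    if delta < 0:
        raise ValueError("delta must be >= 0")
    if kind == "identity":
        return np.eye(n_nodes)
    if kind == "uniform":
        return np.full((n_nodes, n_nodes), 1.0 / n_nodes)
    if kind == "uniform_plus_delta":
        return np.full((n_nodes, n_nodes), 1.0 / n_nodes) + delta * np.eye(n_nodes)
    raise ValueError(f"unknown interaction kind {kind!r}")


def rhs_network(v: Sequence[float], m: NetworkModel) -> np.ndarray:
    """Evaluate the network vector field at state vector ``v``."""
    v = np.asarray(v, dtype=float)
    if v.shape != (3 * m.n_nodes,):
        raise InvalidStateError(
            f"state must have shape ({3 * m.n_nodes},) for N={m.n_nodes}, got {v.shape}"
        )
    if not np.all(np.isfinite(v)):
        raise InvalidStateError("non-finite state vector")
    out = np.empty_like(v)
    _kernels.rhs(v, *m.kernel_args(), out)
    return out


def sync_error(states: np.ndarray) -> np.ndarray:
    """Max pairwise node-state distance at each sample of a trajectory.

    ``states`` has shape ``(n_samples, 3N)`` (node-major).  Returns zero
    identically iff all nodes are exactly synchronized.
    """
    states = np.asarray(states, dtype=float)
    n = states.shape[1] // 3
    if n < 2:
        raise ValueError("sync_error is undefined for a single-node network")
    nodes = states.reshape(states.shape[0], n, 3)
    diff = nodes[:, :, None, :] - nodes[:, None, :, :]
    return np.sqrt((diff**2).sum(axis=-1)).max(axis=(1, 2))


def read_edge_list(path, n_nodes: Optional[int] = None) -> np.ndarray:
    """Laplacian from a two-column whitespace edge list of 0-based node ids."""
    edges = np.loadtxt(path, dtype=int, ndmin=2)
    if edges.shape[1] != 2:
        raise ValueError("edge list must have exactly two columns")
    n = int(edges.max()) + 1 if n_nodes is None else n_nodes
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(map(tuple, edges))
    return nx.laplacian_matrix(g, nodelist=range(n)).toarray().astype(float)


def interaction_from_csv(path) -> np.ndarray:
    """Interaction matrix A from a CSV file (plain numeric grid)."""
    A = np.loadtxt(path, delimiter=",", ndmin=2)
    if A.shape[0] != A.shape[1]:
        raise ValueError(f"interaction matrix must be square, got {A.shape}")
    return A
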