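"""Wired-network generation and complex-network measures.

The "wired network" is the fixed anatomical connectivity of the oscillator
network: a directed weighted graph on ``n`` nodes whose weight matrix ``W``
stores ``W[j, i]`` = influence of node ``j`` on node ``i`` (columns are
targets).  Four topology families are supported — ring-regular,
Watts–Strogatz small-world, Barabási–Albert scale-free, and random (WS with
p=1) — under two weighting schemes: uniform (all weights 1) and random
(i.i.d. uniform on [-1, 1], normalised so incoming absolute weights sum to 1
per node).

The network measures (weighted directed clustering coefficient, inverse-
weight shortest-path length, absolute-weight node degree) are shared with
the information networks estimated from transfer entropy, so they take a
bare weight matrix rather than a :class:`WiredNetwork`.
"""

from __future__ import annotations

import functools
import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

logger = logging.getLogger(__name__)

#: Number of interface nodes in the default configuration (one per muscle).
N_INTERFACE_DEFAULT = 26


class InvalidParameterError(ValueError):
    """Raised when generator parameters violate their preconditions."""


class DegenerateNetworkError(ValueError):
    """Raised when a measure is undefined for the given graph."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class WiredNetwork:
    """Directed weighted oscillator connectivity.

    Attributes
    ----------
    weight_matrix:
        ``(n, n)`` signed reals, ``W[j, i]`` = weight of edge j -> i.
    roles:
        Per-node string flag, ``"interface"`` or ``"hidden"``.
    topology_tag:
        One of ``{"regular", "ws", "ba", "random"}``.
    weight_scheme:
        ``"uniform"`` or ``"random"`` (or ``"none"`` before assignment).
    gen_params:
        Generator parameters (m, m0, p as applicable).
    """

    weight_matrix: np.ndarray
    roles: np.ndarray
    topology_tag: str
    weight_scheme: str = "none"
    gen_params: dict = field(default_factory=dict)
    seed: int | None = None

    @property
    def n_nodes(self) -> int:
        return self.weight_matrix.shape[0]

    # Derived attributes are cached; WiredNetwork is treated as immutable
    # after construction (assign_weights returns a new instance).

    @functools.cached_property
    def adjacency(self) -> np.ndarray:
        """Binary support of the weight matrix."""
        return (self.weight_matrix != 0).astype(np.int64)

    @functools.cached_property
    def interface_index(self) -> np.ndarray:
        return np.flatnonzero(self.roles == "interface")

    @functools.cached_property
    def hidden_index(self) -> np.ndarray:
        return np.flatnonzero(self.roles == "hidden")

    @functools.cached_property
    def in_degree_counts(self) -> np.ndarray:
        """Number of incoming connections K_i per node (column counts)."""
        return self.adjacency.sum(axis=0)

    @functools.cached_property
    def coupling_matrix(self) -> np.ndarray:
        """W with each column divided by the node's in-degree count K_i.

        The network coupling term of every node is then the single product
        ``x @ coupling_matrix``.
        """
        K = self.in_degree_counts
        Wn = self.weight_matrix.astype(float).copy()
        nz = K > 0
        Wn[:, nz] = Wn[:, nz] / K[nz]
        return Wn

    def validate(self) -> None:
        W = self.weight_matrix
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise InvalidParameterError("weight matrix must be square")
        if np.any(np.diag(W) != 0):
            raise InvalidParameterError("self-connections are not allowed")


@dataclass
class NetworkMeasures:
    """Complex-network measures on |W|."""

    clustering_per_node: np.ndarray
    avg_clustering: float
    avg_shortest_path: float
    n_unreachable_pairs: int
    degree_per_node: np.ndarray
    max_degree: float


# ---------------------------------------------------------------------------
# Topology generators
# ---------------------------------------------------------------------------


def _roles_array(n: int, n_interface: int, rng: np.random.Generator | None,
                 strategy: str = "random") -> np.ndarray:
    """Flag ``n_interface`` nodes as interface, the rest hidden.

    Placement strategies: ``random`` (default; uniform without replacement),
    ``spread`` (evenly spaced indices), ``hubs`` is resolved by the caller
    after weights exist.
    """
    if n_interface > n:
        raise InvalidParameterError(
            f"cannot place {n_interface} interface nodes on {n} nodes")
    roles = np.full(n, "hidden", dtype=object)
    if strategy == "spread":
        idx = np.linspace(0, n - 1, n_interface).round().astype(int)
    else:
        if rng is None:
            rng = np.random.default_rng()
        idx = rng.choice(n, size=n_interface, replace=False)
    roles[idx] = "interface"
    return roles


def build_regular(n: int, m: int, *, n_interface: int = N_INTERFACE_DEFAULT,
                  rng: np.random.Generator | None = None,
                  role_strategy: str = "random") -> WiredNetwork:
    """Ring lattice: each node connected bidirectionally to its m nearest
    neighbours on each side (2*n*m directed edges)."""
    if m < 1:
        raise InvalidParameterError("m must be >= 1")
    if n <= 2 * m:
        raise InvalidParameterError(f"need n > 2m (got n={n}, m={m})")
    W = np.zeros((n, n))
    for offset in range(1, m + 1):
        idx = np.arange(n)
        W[idx, (idx + offset) % n] = 1.0
        W[idx, (idx - offset) % n] = 1.0
    net = WiredNetwork(W, _roles_array(n, n_interface, rng, role_strategy),
                       "regular", "uniform", {"m": m})
    net.validate()
    return net


def build_ws(n: int, m: int, p: float, rng: np.random.Generator, *,
             n_interface: int = N_INTERFACE_DEFAULT,
             role_strategy: str = "random") -> WiredNetwork:
    """Watts–Strogatz rewiring of the ring lattice.

    The graph is generated as undirected and symmetrised: each undirected
    lattice edge is rewired with probability ``p`` to a uniformly chosen
    non-self, non-duplicate target, preserving the edge count.  ``p = 1``
    yields a purely random graph, ``p = 0`` the regular lattice.
    """
    if not 0.0 <= p <= 1.0:
        raise InvalidParameterError("p must be in [0, 1]")
    base = build_regular(n, m, n_interface=n_interface, rng=rng,
                         role_strategy=role_strategy)
    A = base.weight_matrix != 0
    # undirected edge list from the upper-triangular support
    src, dst = np.where(np.triu(A))
    und = set(zip(src.tolist(), dst.tolist()))

    def has_edge(u, v):
        return (min(u, v), max(u, v)) in und

    for u, v in list(zip(src.tolist(), dst.tolist())):
        if rng.random() >= p:
            continue
        # rewire u--v to u--w
        candidates = [w for w in range(n) if w != u and not has_edge(u, w)]
        if not candidates:
            continue
        w = int(rng.choice(candidates))
        und.discard((min(u, v), max(u, v)))
        und.add((min(u, w), max(u, w)))

    W = np.zeros((n, n))
    for u, v in und:
        W[u, v] = W[v, u] = 1.0
    tag = "random" if p == 1.0 else ("regular" if p == 0.0 else "ws")
    net = WiredNetwork(W, base.roles, tag, "uniform", {"m": m, "p": p})
    net.validate()
    return net


def build_ba(n: int, m0: int, m: int, rng: np.random.Generator, *,
             n_interface: int = N_INTERFACE_DEFAULT,
             role_strategy: str = "random") -> WiredNetwork:
    """Barabási–Albert preferential attachment with +1 degree smoothing.

    Starts from ``m0`` disconnected seed nodes; each new node attaches to
    ``m`` distinct existing nodes with probability proportional to
    ``k_i + 1`` (the smoothing makes the empty seed graph non-degenerate).
    Edges are undirected and symmetrised into W.
    """
    if not m < m0:
        raise InvalidParameterError(f"need m < m0 (got m={m}, m0={m0})")
    if not m0 < n:
        raise InvalidParameterError(f"need m0 < n (got m0={m0}, n={n})")
    W = np.zeros((n, n))
    degree = np.zeros(n)
    for new in range(m0, n):
        probs = degree[:new] + 1.0
        probs /= probs.sum()
        targets = rng.choice(new, size=m, replace=False, p=probs)
        for t in targets:
            W[new, t] = W[t, new] = 1.0
            degree[new] += 1
            degree[t] += 1
    net = WiredNetwork(W, _roles_array(n, n_interface, rng, role_strategy),
                       "ba", "uniform", {"m0": m0, "m": m})
    net.validate()
    return net


def assign_weights(net: WiredNetwork, scheme: str,
                   rng: np.random.Generator | None = None) -> WiredNetwork:
    """Assign edge weights in place of the current ones.

    ``uniform``: every existing edge gets weight 1 (W equals the adjacency).
    ``random``: i.i.d. uniform on [-1, 1] per edge, then each node's incoming
    absolute weights are normalised to sum to 1.  Nodes with no incoming
    edges are left empty and logged.
    """
    A = net.adjacency.astype(float)
    if scheme == "uniform":
        W = A.copy()
    elif scheme == "random":
        if rng is None:
            raise InvalidParameterError("random scheme requires an rng")
        raw = rng.uniform(-1.0, 1.0, size=A.shape) * A
        col_abs = np.abs(raw).sum(axis=0)
        W = np.zeros_like(raw)
        nz = col_abs > 0
        W[:, nz] = raw[:, nz] / col_abs[nz]
        n_zero_in = int((A.sum(axis=0) == 0).sum())
        if n_zero_in:
            logger.info("assign_weights: %d node(s) with zero in-degree left empty",
                        n_zero_in)
    else:
        raise InvalidParameterError(f"unknown weight scheme {scheme!r}")
    return WiredNetwork(W, net.roles.copy(), net.topology_tag, scheme,
                        dict(net.gen_params), net.seed)


# ---------------------------------------------------------------------------
# Network measures (shared with information networks)
# ---------------------------------------------------------------------------


def clustering_coefficient(W: np.ndarray) -> tuple[np.ndarray, float]:
    """Weighted directed clustering coefficient (Fagiolo).

    Uses absolute weights rescaled by their maximum, ``Ŵ = |W| / max|W|``,
    so every C_i lies in [0, 1]:

        C_i = [ (Ŵ^{1/3} + (Ŵ^T)^{1/3})^3 ]_ii / ( 2 [k_tot (k_tot - 1) - 2 k_bidir] )

    with k_tot the total (in+out) binary degree and k_bidir the number of
    reciprocal neighbours.  Nodes with an undefined denominator get C_i = 0
    and are counted in the average.

    Returns (C per node, mean C).
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise InvalidParameterError("W must be square")
    if np.any(np.diag(W) != 0):
        raise InvalidParameterError("W must have zero diagonal")
    n = W.shape[0]
    absW = np.abs(W)
    wmax = absW.max()
    if wmax == 0:
        return np.zeros(n), 0.0
    What = absW / wmax
    Wc = np.cbrt(What)
    S = Wc + Wc.T
    numer = np.einsum("ij,jk,ki->i", S, S, S)
    A = (absW > 0).astype(float)
    k_tot = A.sum(axis=0) + A.sum(axis=1)
    k_bidir = np.diag(A @ A)
    denom = 2.0 * (k_tot * (k_tot - 1.0) - 2.0 * k_bidir)
    C = np.zeros(n)
    ok = denom > 0
    C[ok] = numer[ok] / denom[ok]
    return C, float(C.mean())


def shortest_path_length(W: np.ndarray) -> tuple[float, int]:
    """Average inverse-weight shortest-path length.

    Edge distance is ``1/|w|``; the average runs over all ordered reachable
    pairs (i != j).  Unreachable pairs are excluded and their count returned.
    Raises :class:`DegenerateNetworkError` if no pair is reachable.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    absW = np.abs(W)
    with np.errstate(divide="ignore"):
        dist = np.where(absW > 0, 1.0 / absW, 0.0)
    D = dijkstra(csr_matrix(dist), directed=True)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(D) & off
    n_unreachable = int(off.sum() - finite.sum())
    if not finite.any():
        raise DegenerateNetworkError("no reachable node pair: average undefined")
    return float(D[finite].mean()), n_unreachable


def node_degrees(W: np.ndarray) -> tuple[np.ndarray, float]:
    """Absolute-weight node degree ``degree_i = sum_j |w_ji|`` (incoming)."""
    absW = np.abs(np.asarray(W, dtype=float))
    deg = absW.sum(axis=0)
    return deg, float(deg.max()) if deg.size else 0.0


def network_measures(W: np.ndarray) -> NetworkMeasures:
    """All measures bundled; path average NaN when undefined."""
    C, Cbar = clustering_coefficient(W)
    try:
        spl, n_unreach = shortest_path_length(W)
    except DegenerateNetworkError:
        spl, n_unreach = float("nan"), W.shape[0] * (W.shape[0] - 1)
    deg, maxdeg = node_degrees(W)
    return NetworkMeasures(C, Cbar, spl, n_unreach, deg, maxdeg)


# ---------------------------------------------------------------------------
# I/O: edge-list text + JSON header, dense CSV
# ---------------------------------------------------------------------------


def save_network(net: WiredNetwork, path: str) -> None:
    """Write a JSON header line then ``src dst weight`` rows."""
    header = {
        "n_nodes": net.n_nodes,
        "roles": net.roles.tolist(),
        "topology_tag": net.topology_tag,
        "weight_scheme": net.weight_scheme,
        "gen_params": net.gen_params,
        "seed": net.seed,
    }
    src, dst = np.nonzero(net.weight_matrix)
    with open(path, "w") as fh:
        fh.write("#" + json.dumps(header) + "\n")
        for s, d in zip(src, dst):
            fh.write(f"{s} {d} {float(net.weight_matrix[s, d])!r}\n")


def load_network(path: str) -> WiredNetwork:
    with open(path) as fh:
        header = json.loads(fh.readline().lstrip("#"))
        W = np.zeros((header["n_nodes"], header["n_nodes"]))
        for line in fh:
            s, d, w = line.split()
            W[int(s), int(d)] = float(w)
    return WiredNetwork(W, np.array(header["roles"], dtype=object),
                        header["topology_tag"], header["weight_scheme"],
                        header["gen_params"], header["seed"])
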