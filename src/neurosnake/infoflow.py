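"""Information-network estimation from neural time series.

For each movement pattern, pairwise transfer entropy (TE) between neuron
activation series defines a directed "information network" (stored like the
wired network: ``te[j, i]`` = TE from neuron j to neuron i).  The chain is:

1. KSG (Kraskov–Stögbauer–Grassberger) k-nearest-neighbour estimators for
   mutual information and for TE with history lengths l = k = 1 (TE is the
   conditional MI ``I(x_{t+1}; y_t | x_t)``, estimated Frenzel–Pompe style);
2. Otsu binarization of the pairwise MI matrix;
3. infinite relational model (IRM): collapsed Gibbs sampling of a CRP
   partition with Beta-Bernoulli block-link likelihood, to discover
   subnetworks;
4. complex-network measures on the TE matrix (shared with
   :mod:`neurosnake.wirednet`) and hidden<->interface influence summaries.

Estimates are in nats.  Series are z-scored and perturbed by a deterministic
1e-10-scale jitter before neighbour counting to break ties (the KSG
derivation assumes continuous marginals).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import betaln, digamma, gammaln

from . import wirednet
from .behavior import otsu_threshold

logger = logging.getLogger(__name__)

_JITTER = 1e-10


class DegenerateInputError(ValueError):
    pass


# ---------------------------------------------------------------------------
# KSG estimators
# ---------------------------------------------------------------------------


def _prepare(series: np.ndarray, tag: int) -> np.ndarray:
    """z-score and add deterministic tiny jitter (tag decorrelates streams)."""
    s = np.asarray(series, dtype=float).ravel()
    sd = s.std()
    if sd > 0:
        s = (s - s.mean()) / sd
    jit = np.random.default_rng(tag).normal(0.0, _JITTER, s.size)
    return s + jit


def _count_strict_1d(sorted_vals: np.ndarray, centers: np.ndarray,
                     eps: np.ndarray) -> np.ndarray:
    """# of points with |v - center| < eps (self included)."""
    hi = np.searchsorted(sorted_vals, centers + eps, side="left")
    lo = np.searchsorted(sorted_vals, centers - eps, side="right")
    return hi - lo


def ksg_mutual_information(xs: np.ndarray, ys: np.ndarray,
                           k_neighbors: int = 4) -> float:
    """KSG (algorithm 1) mutual information estimate in nats.

    Constant input yields 0 with a warning.  Identical continuous series are
    a degenerate case: the estimator returns a finite value that grows with
    n (flagged in the log).
    """
    x = np.asarray(xs, dtype=float).ravel()
    y = np.asarray(ys, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("series must have equal length")
    n = x.size
    if n < 100:
        raise ValueError("need at least 100 samples")
    if x.std() == 0 or y.std() == 0:
        logger.warning("constant series: MI set to 0")
        return 0.0
    if np.allclose(x, y) or np.allclose(x, -y):
        logger.warning("identical series: KSG MI is unbounded in n")
    x = _prepare(x, 1)
    y = _prepare(y, 2)
    joint = np.column_stack([x, y])
    tree = cKDTree(joint)
    eps = tree.query(joint, k=k_neighbors + 1, p=np.inf)[0][:, -1]
    eps_in = np.nextafter(eps, 0.0)  # strict inequality
    xs_sorted = np.sort(x)
    ys_sorted = np.sort(y)
    nx = _count_strict_1d(xs_sorted, x, eps_in) - 1
    ny = _count_strict_1d(ys_sorted, y, eps_in) - 1
    mi = (digamma(k_neighbors) + digamma(n)
          - np.mean(digamma(nx + 1) + digamma(ny + 1)))
    return float(mi)


def _cmi_ksg(w: np.ndarray, y: np.ndarray, z: np.ndarray,
             k_neighbors: int) -> float:
    """I(W; Y | Z) by the KSG-style conditional estimator (nats).

    eps from the k-th neighbour in the joint (w,y,z) max-norm space;
    counts in the (w,z), (y,z) and (z) marginal spaces.
    """
    n = w.size
    joint = np.column_stack([w, y, z])
    eps = cKDTree(joint).query(joint, k=k_neighbors + 1, p=np.inf)[0][:, -1]
    eps_in = np.nextafter(eps, 0.0)
    wz = cKDTree(np.column_stack([w, z]))
    yz = cKDTree(np.column_stack([y, z]))
    n_wz = wz.query_ball_point(np.column_stack([w, z]), eps_in, p=np.inf,
                               return_length=True) - 1
    n_yz = yz.query_ball_point(np.column_stack([y, z]), eps_in, p=np.inf,
                               return_length=True) - 1
    z_sorted = np.sort(z)
    n_z = _count_strict_1d(z_sorted, z, eps_in) - 1
    return float(digamma(k_neighbors)
                 - np.mean(digamma(n_wz + 1) + digamma(n_yz + 1)
                           - digamma(n_z + 1)))


def ksg_transfer_entropy(source: np.ndarray, target: np.ndarray,
                         l_hist: int = 1, k_hist: int = 1,
                         k_neighbors: int = 4) -> float:
    """KSG transfer entropy source -> target with history l = k = 1, nats.

    TE(Y->X) = I(X_{t+1}; Y_t | X_t); larger histories are out of scope and
    rejected.
    """
    if l_hist != 1 or k_hist != 1:
        raise NotImplementedError("only l = k = 1 histories are supported")
    y = np.asarray(source, dtype=float).ravel()
    x = np.asarray(target, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("series must be aligned and equal length")
    if x.size - 1 < 500:
        raise ValueError("need at least 500 samples after embedding")
    if x.std() == 0:
        logger.warning("constant target: TE set to 0")
        return 0.0
    xp = _prepare(x, 3)
    yp = _prepare(y, 4)
    return _cmi_ksg(xp[1:], yp[:-1], xp[:-1], k_neighbors)


# ---------------------------------------------------------------------------
# Information network per movement pattern
# ---------------------------------------------------------------------------


@dataclass
class InfoNetwork:
    """Pairwise TE/MI network for one movement pattern."""

    te_matrix: np.ndarray               # te[j, i] = TE(j -> i), nats
    mi_matrix: np.ndarray
    pattern_label: int
    segment_duration: float
    roles: np.ndarray
    binarized: np.ndarray | None = None
    irm_partition: np.ndarray | None = None
    measures: wirednet.NetworkMeasures | None = None
    block_te: np.ndarray | None = None  # block-to-block mean TE overlay

    @property
    def n_nodes(self) -> int:
        return self.te_matrix.shape[0]


def estimate_info_network(x_series: np.ndarray, sample_mask: np.ndarray,
                          roles: np.ndarray, pattern_label: int = 0, *,
                          sample_dt: float = 0.1, stride: int = 1,
                          min_samples: int = 500, max_samples: int | None = None,
                          k_neighbors: int = 4,
                          with_mi: bool = True) -> InfoNetwork | None:
    """Pairwise TE (and optionally MI) over one pattern's segment.

    ``x_series`` is (n_samples, n_neurons); ``sample_mask`` selects the
    samples belonging to the pattern (the union of its episodes).  Returns
    None (with a log entry) when the segment is too short.  ``max_samples``
    thins long segments by increasing the stride — neighbouring samples of
    the slow oscillation are strongly autocorrelated, so thinning costs
    little information while the KSG cost drops linearly.  ``with_mi=False``
    skips the MI matrix (enough for network measures and influence means).
    """
    mask = np.asarray(sample_mask, dtype=bool)
    duration = float(mask.sum()) * sample_dt
    sel = np.flatnonzero(mask)[::stride]
    if sel.size < min_samples + 1:
        logger.info("pattern %s skipped: %d samples < %d",
                    pattern_label, sel.size, min_samples)
        return None
    if max_samples is not None and sel.size > max_samples:
        sel = sel[::int(np.ceil(sel.size / max_samples))]
    X = np.asarray(x_series, dtype=float)[sel]
    n_neurons = X.shape[1]
    prepped = [_prepare(X[:, i], 10 + i) for i in range(n_neurons)]
    te = np.zeros((n_neurons, n_neurons))
    mi = np.zeros((n_neurons, n_neurons))
    for i in range(n_neurons):
        xi = prepped[i]
        for j in range(n_neurons):
            if j == i:
                continue
            te[j, i] = _cmi_ksg(xi[1:], prepped[j][:-1], xi[:-1], k_neighbors)
    if not with_mi:
        return InfoNetwork(te, mi, pattern_label, duration,
                           np.asarray(roles, dtype=object))
    for i in range(n_neurons):
        for j in range(i + 1, n_neurons):
            joint = np.column_stack([prepped[i], prepped[j]])
            tree = cKDTree(joint)
            eps = tree.query(joint, k=k_neighbors + 1, p=np.inf)[0][:, -1]
            eps_in = np.nextafter(eps, 0.0)
            ni = _count_strict_1d(np.sort(prepped[i]), prepped[i], eps_in) - 1
            nj = _count_strict_1d(np.sort(prepped[j]), prepped[j], eps_in) - 1
            val = (digamma(k_neighbors) + digamma(X.shape[0])
                   - np.mean(digamma(ni + 1) + digamma(nj + 1)))
            mi[i, j] = mi[j, i] = val
    return InfoNetwork(te, mi, pattern_label, duration,
                       np.asarray(roles, dtype=object))


def binarize_otsu_matrix(M: np.ndarray) -> np.ndarray:
    """Binary adjacency: off-diagonal entries above the Otsu threshold."""
    M = np.asarray(M, dtype=float)
    off = ~np.eye(M.shape[0], dtype=bool)
    vals = M[off]
    if np.unique(vals).size < 2:
        raise DegenerateInputError("constant off-diagonal: Otsu undefined")
    if np.unique(vals).size == 2:
        thr = float(np.unique(vals).mean())  # two-valued: exact split
    else:
        thr = otsu_threshold(vals)
    B = np.zeros_like(M, dtype=np.int64)
    B[off] = (M[off] > thr).astype(np.int64)
    return B


# ---------------------------------------------------------------------------
# Infinite relational model (collapsed Gibbs)
# ---------------------------------------------------------------------------


def _block_stats(R: np.ndarray, assign: np.ndarray, exclude: int | None = None
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Block labels, sizes and edge sufficient statistics.

    Returns (labels, sizes, one, tot) where ``one[a, b]`` is the number of
    1-edges from block a to block b and ``tot[a, b]`` the number of ordered
    node pairs between them (self-pairs excluded).  ``exclude`` removes one
    node from the tally.
    """
    mask = np.ones(R.shape[0], dtype=bool)
    if exclude is not None:
        mask[exclude] = False
    labs = np.unique(assign[mask])
    Z = (assign[mask][:, None] == labs[None, :]).astype(float)
    sizes = Z.sum(axis=0)
    Rm = R[np.ix_(mask, mask)].astype(float)
    one = Z.T @ Rm @ Z
    tot = np.outer(sizes, sizes) - np.diag(sizes)
    return labs, sizes, one, tot


def irm_log_posterior(R: np.ndarray, assign: np.ndarray, gamma: float = 1.0,
                      beta: float = 7.0) -> float:
    """CRP log prior + Beta-Bernoulli marginal log likelihood."""
    a0, b0 = 1.0, float(beta)
    n = R.shape[0]
    labs, sizes, one, tot = _block_stats(np.asarray(R, dtype=float), assign)
    logp = labs.size * np.log(gamma) + gammaln(sizes).sum()
    logp += gammaln(gamma) - gammaln(gamma + n)
    logp += (betaln(one + a0, tot - one + b0) - betaln(a0, b0)).sum()
    return float(logp)


def irm_fit(R: np.ndarray, gamma: float = 1.0, beta: float = 7.0,
            n_sweeps: int = 50,
            rng: np.random.Generator | None = None) -> np.ndarray:
    """IRM partition of a directed binary adjacency matrix.

    Collapsed Gibbs over node-to-block assignments with CRP concentration
    ``gamma`` and Beta(1, beta) block-link priors (the single noise
    hyper-parameter is mapped to the failure pseudo-count, biasing block
    links toward sparsity).  Ends with a greedy (argmax) sweep and returns
    the highest-posterior partition visited, relabelled 0..B-1 in block-size
    order.
    """
    R = np.asarray(R)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("R must be square")
    if np.any(np.diag(R) != 0):
        raise ValueError("R must have zero diagonal")
    if not np.isin(R, (0, 1)).all():
        raise DegenerateInputError("IRM requires a binary matrix")
    rng = rng or np.random.default_rng()
    n = R.shape[0]
    a0, b0 = 1.0, float(beta)
    Rf = R.astype(float)
    # singleton initialisation mixes far better than one big block: merging
    # is downhill for Gibbs, splitting a block node-by-node is not
    assign = np.arange(n, dtype=np.int64)

    def lb(o, t):
        return betaln(o + a0, t - o + b0)

    def sweep(greedy: bool) -> None:
        for v in rng.permutation(n):
            labs, sizes, one, tot = _block_stats(Rf, assign, exclude=v)
            keep = np.arange(n) != v
            Zb = (assign[keep][:, None] == labs[None, :]).astype(float)
            r_out = Rf[v, keep] @ Zb   # 1-edges v -> block b
            r_in = Rf[keep, v] @ Zb    # 1-edges block b -> v
            # candidate = join existing block c: pairs (c,b), (b,c), (c,c)
            # d_row[c, b]: pair (c,b) gains r_out[b] ones, s_b pairs
            d_row = lb(one + r_out[None, :], tot + sizes[None, :]) - lb(one, tot)
            # d_col[c, b]: pair (b,c) gains r_in[b] ones, s_b pairs
            d_col = lb(one.T + r_in[None, :], tot.T + sizes[None, :]) - lb(one.T, tot.T)
            diag_idx = np.arange(labs.size)
            d_diag = (lb(one[diag_idx, diag_idx] + r_out + r_in,
                         tot[diag_idx, diag_idx] + 2 * sizes)
                      - lb(one[diag_idx, diag_idx], tot[diag_idx, diag_idx]))
            delta = d_row.sum(axis=1) + d_col.sum(axis=1)
            delta += d_diag - d_row[diag_idx, diag_idx] - d_col[diag_idx, diag_idx]
            logps = np.log(sizes) + delta
            # candidate = open a new block: fresh pairs (new,b) and (b,new);
            # the empty (new,new) pair contributes betaln(a0,b0) - betaln(a0,b0) = 0
            d_new = float((lb(r_out, sizes) + lb(r_in, sizes)
                           - 2.0 * betaln(a0, b0)).sum())
            logps = np.append(logps, np.log(gamma) + d_new)
            if greedy:
                choice = int(np.argmax(logps))
            else:
                p = np.exp(logps - logps.max())
                p /= p.sum()
                choice = int(rng.choice(logps.size, p=p))
            if choice < labs.size:
                assign[v] = labs[choice]
            else:
                assign[v] = assign.max() + 1

    best = assign.copy()
    best_logp = irm_log_posterior(R, assign, gamma, beta)
    for s in range(n_sweeps):
        sweep(greedy=(s == n_sweeps - 1))
        lp = irm_log_posterior(R, assign, gamma, beta)
        if lp > best_logp:
            best_logp, best = lp, assign.copy()
    # relabel blocks by decreasing size, ties by first occurrence
    labs, counts = np.unique(best, return_counts=True)
    order = labs[np.argsort(-counts, kind="stable")]
    remap = {int(old): new for new, old in enumerate(order)}
    return np.array([remap[int(a)] for a in best], dtype=np.int64)


def block_order(partition: np.ndarray) -> np.ndarray:
    """Node order that rearranges a matrix into diagonal block sequence."""
    return np.argsort(partition, kind="stable")


def block_te_overlay(te: np.ndarray, partition: np.ndarray) -> np.ndarray:
    """Block-to-block mean TE (the overlay on the IRM-ordered matrix)."""
    labs = np.unique(partition)
    out = np.zeros((labs.size, labs.size))
    off = ~np.eye(te.shape[0], dtype=bool)
    for ai, a in enumerate(labs):
        ia = partition == a
        for bi, b in enumerate(labs):
            mask = np.outer(ia, partition == b) & off
            out[ai, bi] = te[mask].mean() if mask.any() else 0.0
    return out


# ---------------------------------------------------------------------------
# Measures and influence summaries
# ---------------------------------------------------------------------------


def info_network_measures(net: InfoNetwork) -> wirednet.NetworkMeasures:
    """Wired-network measures on the TE matrix (negatives clamped to 0)."""
    W = np.clip(net.te_matrix, 0.0, None)
    return wirednet.network_measures(W)


@dataclass
class InfluenceSummary:
    te_hidden_to_interface: float
    te_interface_to_hidden: float
    duration: float


def body_influence(net: InfoNetwork) -> InfluenceSummary:
    """Mean TE across role-crossing ordered pairs."""
    roles = net.roles
    hid = np.flatnonzero(roles == "hidden")
    ifc = np.flatnonzero(roles == "interface")
    te = net.te_matrix
    h2i = float(te[np.ix_(hid, ifc)].mean()) if hid.size and ifc.size else 0.0
    i2h = float(te[np.ix_(ifc, hid)].mean()) if hid.size and ifc.size else 0.0
    return InfluenceSummary(h2i, i2h, net.segment_duration)


def analyze_info_network(net: InfoNetwork, gamma: float = 1.0,
                         beta: float = 7.0, n_sweeps: int = 30,
                         rng: np.random.Generator | None = None,
                         binarize_on: str = "mi") -> InfoNetwork:
    """Run binarization, IRM, measures and overlay on an estimated network."""
    M = net.mi_matrix if binarize_on == "mi" else net.te_matrix
    net.binarized = binarize_otsu_matrix(M)
    net.irm_partition = irm_fit(net.binarized, gamma, beta, n_sweeps, rng)
    net.measures = info_network_measures(net)
    net.block_te = block_te_overlay(net.te_matrix, net.irm_partition)
    return net
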