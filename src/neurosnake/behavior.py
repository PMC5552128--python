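"""Movement-pattern analysis of joint-angle trajectories.

Pipeline: sliding-window Pearson correlations of all joint-angle pairs
(feature vectors of dimension k(k-1)/2; 91 for the 14-joint body) ->
Laplacian-eigenmaps embedding to 3 dimensions -> DBSCAN density clustering
(noise label = unstable windows) -> episode extraction -> Otsu threshold on
episode durations -> stable/unstable classification of each pattern.

The embedding uses the binary-weight k-nearest-neighbour variant of
Laplacian eigenmaps: symmetrised kNN adjacency, normalised graph Laplacian,
bottom non-trivial eigenvectors, with eigenvector signs fixed so the first
nonzero coordinate of each column is positive (determinism).  A
disconnected kNN graph is repaired by adding the single nearest cross-
component link per component pair on the minimum spanning structure (and
logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import eigsh
from skimage.filters import threshold_otsu
from sklearn.cluster import DBSCAN
from sklearn.neighbors import kneighbors_graph

logger = logging.getLogger(__name__)

NOISE_LABEL = -1

# Clustering-stage defaults
DBSCAN_EPS = 0.16
DBSCAN_MIN_PTS = 10
KNN_DEFAULT = 350

# The eigenmap scale per run is arbitrary (eigenvectors are normalised), so
# before clustering the embedding is rescaled so the median step between
# temporally adjacent windows is this constant.  The DBSCAN radius then
# separates slow (dwelling, dense) stretches of the trajectory from fast
# transits, which is what distinguishes a movement pattern from a switch.
EMBED_STEP_NORM = 0.08

# When the data fall into fewer than out_dim+1 well-separated clusters, the
# surplus eigenvectors express variation *within* one cluster and sit far
# above the cluster-separating eigenvalues; such dimensions are down-
# weighted by sqrt(lambda_2/lambda_c).  Legitimate structure keeps ratios
# lambda_c/lambda_2 around 2-11 in practice while the degenerate modes sit
# near 100, so the gate has a wide margin on both sides.
SPECTRAL_GAP_RATIO = 30.0

# Upper bound on the rescaling factor, in units of the unit-RMS embedding.
# For data that are already strongly clustered the median adjacent-window
# step measures only within-cluster jitter and would stretch the embedding
# until clusters fragment; the cap keeps the stretch within the regime
# where the DBSCAN radius still spans a cluster's interior.
EMBED_SCALE_CAP = 6.0


@dataclass
class FeatureMatrix:
    """Windowed joint-pair correlation features."""

    features: np.ndarray      # (n_windows, k(k-1)/2), entries in [-1, 1]
    window_size: float        # Delta t [s]
    shift: float              # t_s [s]
    start_times: np.ndarray   # window start times [s]

    @property
    def n_windows(self) -> int:
        return self.features.shape[0]


@dataclass
class Episode:
    label: int
    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class WindowLabeling:
    """Per-window labels with episodes and stability classification."""

    embedding: np.ndarray
    labels: np.ndarray
    start_times: np.ndarray
    shift: float
    episodes: list[Episode] = field(default_factory=list)
    stability_threshold: float = float("nan")
    stable_patterns: dict[int, bool] = field(default_factory=dict)

    @property
    def pattern_labels(self) -> np.ndarray:
        """Cluster ids excluding the noise label."""
        labs = np.unique(self.labels)
        return labs[labs != NOISE_LABEL]

    def summary(self) -> dict:
        """(n_patterns, n_stable, max episode duration) for this run."""
        n_patterns = int(self.pattern_labels.size)
        n_stable = int(sum(self.stable_patterns.get(int(l), False)
                           for l in self.pattern_labels))
        durations = [e.duration for e in self.episodes if e.label != NOISE_LABEL]
        return {"n_patterns": n_patterns, "n_stable": n_stable,
                "max_duration": max(durations) if durations else 0.0}


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------


def windowed_correlation_features(theta: np.ndarray, times: np.ndarray,
                                  window_size: float = 10.0,
                                  shift: float = 0.5) -> FeatureMatrix:
    """Pearson correlations of every joint pair over sliding windows.

    ``theta`` is (n_samples, k); ``times`` the sample times.  Feature order
    is (0,1), (0,2), ..., (0,k-1), (1,2), ...  A zero-variance joint within
    a window yields correlation 0 for its pairs (flagged in the log).
    """
    theta = np.asarray(theta, dtype=float)
    times = np.asarray(times, dtype=float)
    if theta.ndim != 2 or theta.shape[1] < 2:
        raise ValueError("theta must be (n_samples, k>=2)")
    sample_dt = float(np.median(np.diff(times)))
    win = max(2, round(window_size / sample_dt))
    step = max(1, round(shift / sample_dt))
    n_samples, k = theta.shape
    if n_samples < win:
        raise ValueError("series shorter than one window")
    starts = np.arange(0, n_samples - win + 1, step)
    iu = np.triu_indices(k, 1)
    feats = np.empty((starts.size, iu[0].size))
    n_flagged = 0
    for w, s in enumerate(starts):
        seg = theta[s:s + win]
        sd = seg.std(axis=0)
        if np.any(sd == 0):
            n_flagged += 1
            segn = (seg - seg.mean(axis=0))
            with np.errstate(invalid="ignore"):
                segn = np.where(sd > 0, segn / np.where(sd > 0, sd, 1.0), 0.0)
            R = (segn.T @ segn) / win
        else:
            R = np.corrcoef(seg, rowvar=False)
        feats[w] = R[iu]
    if n_flagged:
        logger.warning("zero-variance joint in %d window(s); correlations set to 0",
                       n_flagged)
    np.clip(feats, -1.0, 1.0, out=feats)
    return FeatureMatrix(feats, window_size, shift, times[starts])


# ---------------------------------------------------------------------------
# Embedding
# ---------------------------------------------------------------------------


def embed_laplacian_eigenmaps(F: FeatureMatrix | np.ndarray, k_nn: int = KNN_DEFAULT,
                              out_dim: int = 3) -> np.ndarray:
    """Binary-weight kNN Laplacian-eigenmaps embedding to ``out_dim``."""
    X = F.features if isinstance(F, FeatureMatrix) else np.asarray(F, dtype=float)
    n = X.shape[0]
    if n <= k_nn:
        raise ValueError(f"need more windows ({n}) than k_nn ({k_nn})")
    A = kneighbors_graph(X, n_neighbors=k_nn, mode="connectivity",
                         include_self=False)
    A = A.maximum(A.T)  # symmetrise

    n_comp, comp = connected_components(A, directed=False)
    if n_comp > 1:
        logger.warning("kNN graph has %d components; adding nearest cross-links",
                       n_comp)
        from scipy.spatial.distance import cdist

        A = A.tolil()
        for c in range(1, n_comp):
            inside = np.flatnonzero(np.isin(comp, np.arange(c)))
            outside = np.flatnonzero(comp == c)
            d2 = cdist(X[outside], X[inside], "sqeuclidean")
            i, j = np.unravel_index(np.argmin(d2), d2.shape)
            A[outside[i], inside[j]] = 1.0
            A[inside[j], outside[i]] = 1.0
        A = A.tocsr()

    deg = np.asarray(A.sum(axis=1)).ravel()
    d_isqrt = 1.0 / np.sqrt(np.maximum(deg, 1e-12))
    Dn = csr_matrix((d_isqrt, (np.arange(n), np.arange(n))))
    L_sym = csr_matrix((np.ones(n), (np.arange(n), np.arange(n)))) - Dn @ A @ Dn
    # bottom eigenvectors; skip the trivial constant mode
    vals, vecs = eigsh(L_sym, k=out_dim + 1, sigma=-1e-6, which="LM")
    order = np.argsort(vals)
    lam = np.maximum(vals[order[1:out_dim + 1]], 1e-12)
    Y = (vecs[:, order[1:out_dim + 1]].T * d_isqrt).T
    # unit-RMS columns: the embedding scale is then independent of the
    # number of windows, which keeps the DBSCAN radius meaningful
    rms = np.sqrt((Y ** 2).mean(axis=0))
    Y = Y / np.where(rms > 0, rms, 1.0)
    # suppress degenerate within-cluster modes (see SPECTRAL_GAP_RATIO)
    rel = lam / lam[0]
    Y = Y * np.where(rel > SPECTRAL_GAP_RATIO, 1.0 / rel, 1.0)[None, :]
    # deterministic sign: first nonzero coordinate of each column positive
    for c in range(Y.shape[1]):
        nz = np.flatnonzero(np.abs(Y[:, c]) > 1e-12)
        if nz.size and Y[nz[0], c] < 0:
            Y[:, c] = -Y[:, c]
    return Y


# ---------------------------------------------------------------------------
# Clustering, episodes, stability
# ---------------------------------------------------------------------------


def normalize_step_scale(embedding: np.ndarray,
                         target: float = EMBED_STEP_NORM,
                         cap: float = EMBED_SCALE_CAP) -> np.ndarray:
    """Rescale an embedding so the median adjacent-window step is ``target``.

    Rows must be time-ordered and the input is expected on the unit-RMS
    scale produced by :func:`embed_laplacian_eigenmaps`.  The scale factor
    is capped at ``cap`` so that strongly clustered data (median step =
    within-cluster jitter only) are not stretched until clusters fragment.
    Degenerate (zero-median) step distributions fall back to the mean step;
    a fully static embedding is returned as is.
    """
    steps = np.linalg.norm(np.diff(embedding, axis=0), axis=1)
    if steps.size == 0:
        return embedding
    m = float(np.median(steps))
    if m <= 1e-12:
        m = float(steps.mean())
    if m <= 1e-12:
        return embedding
    return embedding * min(target / m, cap)


def cluster_dbscan(embedding: np.ndarray, eps: float = DBSCAN_EPS,
                   min_pts: int = DBSCAN_MIN_PTS) -> np.ndarray:
    """DBSCAN labels in the embedded space; -1 marks unstable (noise)."""
    return DBSCAN(eps=eps, min_samples=min_pts).fit_predict(embedding)


def episodes_and_durations(labels: np.ndarray, shift: float,
                           start_times: np.ndarray | None = None) -> list[Episode]:
    """Maximal constant-label runs; duration = run length * shift."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return []
    if start_times is None:
        start_times = np.arange(labels.size) * shift
    episodes = []
    run_start = 0
    for i in range(1, labels.size + 1):
        if i == labels.size or labels[i] != labels[run_start]:
            t0 = start_times[run_start]
            episodes.append(Episode(int(labels[run_start]), float(t0),
                                    float(t0 + (i - run_start) * shift)))
            run_start = i
    return episodes


def otsu_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Otsu threshold maximising between-class variance (256-bin histogram)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2 or np.unique(values).size < 2:
        raise ValueError("Otsu threshold undefined for fewer than 2 distinct values")
    return float(threshold_otsu(values, nbins=nbins))


def classify_patterns(episodes: list[Episode],
                      threshold: float) -> dict[int, bool]:
    """A pattern is stable iff its longest episode reaches the threshold.

    The noise label is never stable.
    """
    max_dur: dict[int, float] = {}
    for e in episodes:
        max_dur[e.label] = max(max_dur.get(e.label, 0.0), e.duration)
    return {lab: (lab != NOISE_LABEL and dur >= threshold)
            for lab, dur in max_dur.items()}


def analyze_joint_angles(theta: np.ndarray, times: np.ndarray, *,
                         window_size: float = 10.0, shift: float = 0.5,
                         k_nn: int = KNN_DEFAULT, out_dim: int = 3,
                         eps: float = DBSCAN_EPS, min_pts: int = DBSCAN_MIN_PTS,
                         threshold: float | None = None) -> WindowLabeling:
    """Full behavior pipeline on one joint-angle trajectory.

    ``threshold`` overrides the per-run Otsu duration threshold (used when a
    batch pools durations across runs).  ``k_nn`` is reduced automatically
    if the run yields too few windows.
    """
    F = windowed_correlation_features(theta, times, window_size, shift)
    k_nn_eff = min(k_nn, F.n_windows - 1)
    if k_nn_eff < 1:
        raise ValueError(
            f"only {F.n_windows} window(s); need a longer series for embedding")
    Y = normalize_step_scale(embed_laplacian_eigenmaps(F, k_nn_eff, out_dim))
    labels = cluster_dbscan(Y, eps, min_pts)
    episodes = episodes_and_durations(labels, shift, F.start_times)
    lab = WindowLabeling(Y, labels, F.start_times, shift, episodes)
    durations = np.array([e.duration for e in episodes])
    if threshold is None:
        try:
            threshold = otsu_threshold(durations)
        except ValueError:
            threshold = float("inf")  # degenerate: nothing classified stable
    lab.stability_threshold = float(threshold)
    lab.stable_patterns = classify_patterns(episodes, threshold)
    return lab
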