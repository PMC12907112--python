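"""Cluster-based permutation tests (CBPT) and multiple-comparison helpers.

Three flavours of the max-statistic CBPT are provided:

* :func:`one_sample_cbpt` — decoding accuracies against chance, on a 1-D time
  course or a 2-D train x test grid (orthogonal-neighbour adjacency).  The
  null is built by random per-subject sign flips of (score - chance); the
  maximum cluster mass (sum of t-values) per permutation forms the
  family-wise-error-controlling reference distribution.
* :func:`paired_sensor_cbpt` — paired condition contrasts over electrodes on
  a montage adjacency graph, two-sided, with sign-consistent clustering and
  a minimum cluster extent (>= 2 electrodes by default).
* :func:`triangulation_adjacency` — electrode adjacency from the Delaunay
  triangulation of the azimuthal-equidistant-projected montage.

When ``2**n_subjects <= n_perm`` the sign-flip null is enumerated
exhaustively (p = count / 2**n, identity included); otherwise random
permutations are drawn and p = (1 + count) / (1 + n_perm), which never
reaches zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage
import scipy.sparse
import scipy.sparse.csgraph
import scipy.spatial
import scipy.stats

from .montage import Montage


@dataclass
class ClusterConfig:
    """CBPT parameters.

    ``cluster_alpha`` is the point-wise cluster-forming threshold;
    ``test_alpha`` (default: same value) is the cluster-level significance
    threshold applied to the Monte-Carlo p-values, which is where a
    Bonferroni-adjusted level is passed when testing several networks.
    """

    cluster_alpha: float = 0.05
    n_perm: int = 5000
    tail: str = "greater"          # "greater" | "two-sided"
    min_cluster_channels: int = 2  # sensor-space tests only
    seed: int = 0
    test_alpha: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.cluster_alpha < 1.0:
            raise ValueError("cluster_alpha must be in (0, 1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.tail not in ("greater", "two-sided"):
            raise ValueError("tail must be 'greater' or 'two-sided'")

    @property
    def alpha_out(self) -> float:
        return self.test_alpha if self.test_alpha is not None \
            else self.cluster_alpha


@dataclass
class Cluster:
    """One suprathreshold cluster: flat member indices, mass, Monte-Carlo p."""

    indices: np.ndarray
    mass: float
    p: float


@dataclass
class ClusterResult:
    """All clusters, the significance mask, and the permutation null."""

    clusters: list[Cluster]
    mask: np.ndarray               # bool, same shape as the input points
    alpha: float
    null_max: np.ndarray = field(repr=False, default=None)
    exact: bool = False

    @property
    def significant_clusters(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p < self.alpha]

    @property
    def any_significant(self) -> bool:
        return bool(self.mask.any())


def bonferroni_adjust(alpha: float, m: int) -> float:
    """Per-test threshold alpha / m (reported to 4 decimals in summaries)."""
    if m < 1:
        raise ValueError("number of tests m must be >= 1")
    return alpha / m


# ---------------------------------------------------------------------------
# shared machinery
# ---------------------------------------------------------------------------

def _t_maps(signs: np.ndarray, centered: np.ndarray, ssq: np.ndarray) -> np.ndarray:
    """One-sample t maps for many sign-flip assignments at once.

    Per-subject sign flips leave the per-point sum of squares unchanged, so
    only the mean needs recomputing: t = mean / sqrt(var / n) with
    var = (ssq - n * mean^2) / (n - 1).
    """
    n = centered.shape[0]
    mean = signs @ centered / n
    var = np.maximum(ssq - n * mean ** 2, 0.0) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    return np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)


def _sign_matrix(n_subj: int, config: ClusterConfig) -> tuple[np.ndarray, bool]:
    """All sign assignments (exact) or random ones (Monte-Carlo)."""
    if 2 ** n_subj <= config.n_perm:
        bits = np.arange(2 ** n_subj)[:, None] >> np.arange(n_subj) & 1
        return 2.0 * bits - 1.0, True
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    return rng.choice([-1.0, 1.0], size=(config.n_perm, n_subj)), False


def _grid_clusters(t_map: np.ndarray, thr: float, tail: str):
    """Sign-consistent suprathreshold clusters on a 1-D/2-D grid.

    Returns a list of (flat indices, mass) pairs.  2-D grids use orthogonal
    (4-connectivity) adjacency.
    """
    structure = scipy.ndimage.generate_binary_structure(t_map.ndim, 1)
    out = []
    signs = (1,) if tail == "greater" else (1, -1)
    for sign in signs:
        mask = sign * t_map > thr
        lab, n = scipy.ndimage.label(mask, structure=structure)
        if n == 0:
            continue
        masses = scipy.ndimage.sum_labels(t_map, lab,
                                          index=np.arange(1, n + 1))
        lab_flat = lab.ravel()
        for i, mass in enumerate(np.atleast_1d(masses), start=1):
            out.append((np.flatnonzero(lab_flat == i), float(mass)))
    return out


def _max_null_mass(t_map: np.ndarray, thr: float, tail: str) -> float:
    clusters = _grid_clusters(t_map, thr, tail)
    if not clusters:
        return 0.0
    return max(abs(m) for _, m in clusters)


def _cluster_p(
    obs_mass: float, null_max: np.ndarray, exact: bool, n_perm: int
) -> float:
    count = int(np.sum(null_max >= abs(obs_mass) - 1e-12))
    if exact:
        return count / len(null_max)
    return (1 + count) / (1 + n_perm)


def one_sample_cbpt(
    scores: np.ndarray,
    chance: float = 0.5,
    config: ClusterConfig | None = None,
) -> ClusterResult:
    """One-sample CBPT of subject scores against chance on a 1-D/2-D grid.

    ``scores`` has shape (n_subjects, n_points) or (n_subjects, n1, n2).
    Points with a one-sided (default) p below ``cluster_alpha`` are grouped
    by grid adjacency; cluster mass is the sum of t-values; the null takes
    the maximum cluster mass over per-subject sign flips of
    (score - chance).  Zero-variance points get t = 0 and never join a
    cluster.
    """
    config = config or ClusterConfig()
    scores = np.asarray(scores, dtype=float)
    if scores.ndim not in (2, 3):
        raise ValueError("scores must be subjects x points (1-D or 2-D grid)")
    n_subj = scores.shape[0]
    if n_subj < 2:
        raise ValueError("need at least 2 subjects")
    shape = scores.shape[1:]
    centered = (scores - chance).reshape(n_subj, -1)
    ssq = np.sum(centered ** 2, axis=0)
    df = n_subj - 1
    if config.tail == "greater":
        thr = scipy.stats.t.ppf(1.0 - config.cluster_alpha, df)
    else:
        thr = scipy.stats.t.ppf(1.0 - config.cluster_alpha / 2.0, df)

    obs_t = _t_maps(np.ones((1, n_subj)), centered, ssq)[0].reshape(shape)
    obs_clusters = _grid_clusters(obs_t, thr, config.tail)

    signs, exact = _sign_matrix(n_subj, config)
    n_null = len(signs)
    null_max = np.empty(n_null)
    chunk = max(1, int(2e6 // max(1, centered.shape[1])))
    for start in range(0, n_null, chunk):
        t_block = _t_maps(signs[start:start + chunk], centered, ssq)
        for i, t_map in enumerate(t_block):
            null_max[start + i] = _max_null_mass(
                t_map.reshape(shape), thr, config.tail)

    clusters = [
        Cluster(indices=idx, mass=mass,
                p=_cluster_p(mass, null_max, exact, config.n_perm))
        for idx, mass in obs_clusters
    ]
    mask = np.zeros(int(np.prod(shape)), dtype=bool)
    for c in clusters:
        if c.p < config.alpha_out:
            mask[c.indices] = True
    return ClusterResult(clusters=clusters, mask=mask.reshape(shape),
                         alpha=config.alpha_out, null_max=null_max,
                         exact=exact)


# ---------------------------------------------------------------------------
# sensor space
# ---------------------------------------------------------------------------

def _graph_clusters(
    t_vals: np.ndarray, thr: float, adjacency: np.ndarray, min_channels: int
):
    """Sign-consistent suprathreshold clusters on an electrode graph."""
    out = []
    for sign in (1, -1):
        mask = sign * t_vals > thr
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            continue
        sub = scipy.sparse.csr_matrix(adjacency[np.ix_(idx, idx)])
        n_comp, labels = scipy.sparse.csgraph.connected_components(
            sub, directed=False)
        for comp in range(n_comp):
            members = idx[labels == comp]
            if len(members) < min_channels:
                continue
            out.append((members, float(t_vals[members].sum())))
    return out


def paired_sensor_cbpt(
    amp_a: np.ndarray,
    amp_b: np.ndarray,
    adjacency: np.ndarray,
    config: ClusterConfig | None = None,
) -> ClusterResult:
    """Two-sided paired CBPT over electrodes on an adjacency graph.

    ``amp_a`` and ``amp_b`` are (n_subjects, n_electrodes) condition
    amplitudes; ``adjacency`` a symmetric boolean electrode graph.  A cluster
    needs at least ``min_cluster_channels`` sign-consistent adjacent
    suprathreshold electrodes; the null swaps condition labels per subject
    (sign flips of the paired differences) and uses the maximum |mass|.
    """
    config = config or ClusterConfig(tail="two-sided")
    amp_a = np.asarray(amp_a, dtype=float)
    amp_b = np.asarray(amp_b, dtype=float)
    if amp_a.shape != amp_b.shape or amp_a.ndim != 2:
        raise ValueError("amplitude arrays must both be subjects x electrodes")
    n_subj, n_elec = amp_a.shape
    if n_subj < 2:
        raise ValueError("need at least 2 subjects")
    adjacency = np.asarray(adjacency, dtype=bool)
    if adjacency.shape != (n_elec, n_elec):
        raise ValueError("adjacency must be n_electrodes x n_electrodes")
    if not np.array_equal(adjacency, adjacency.T):
        raise ValueError("adjacency must be symmetric")

    diffs = amp_a - amp_b
    ssq = np.sum(diffs ** 2, axis=0)
    df = n_subj - 1
    thr = scipy.stats.t.ppf(1.0 - config.cluster_alpha / 2.0, df)

    obs_t = _t_maps(np.ones((1, n_subj)), diffs, ssq)[0]
    obs_clusters = _graph_clusters(obs_t, thr, adjacency,
                                   config.min_cluster_channels)

    signs, exact = _sign_matrix(n_subj, config)
    t_all = _t_maps(signs, diffs, ssq)
    null_max = np.zeros(len(signs))
    for i, t_vals in enumerate(t_all):
        clusters = _graph_clusters(t_vals, thr, adjacency,
                                   config.min_cluster_channels)
        if clusters:
            null_max[i] = max(abs(m) for _, m in clusters)

    clusters = [
        Cluster(indices=idx, mass=mass,
                p=_cluster_p(mass, null_max, exact, config.n_perm))
        for idx, mass in obs_clusters
    ]
    mask = np.zeros(n_elec, dtype=bool)
    for c in clusters:
        if c.p < config.alpha_out:
            mask[c.indices] = True
    return ClusterResult(clusters=clusters, mask=mask,
                         alpha=config.alpha_out, null_max=null_max,
                         exact=exact)


# ---------------------------------------------------------------------------
# adjacency from the montage
# ---------------------------------------------------------------------------

def _cocircular(p: np.ndarray, q: np.ndarray, r: np.ndarray, s: np.ndarray,
                tol: float = 1e-9) -> bool:
    """In-circle determinant test: True when the four points are co-circular."""
    mat = np.array([
        [*(x - s), (x - s) @ (x - s)] for x in (p, q, r)
    ])
    scale = max(1.0, np.abs(mat).max()) ** 3
    return abs(np.linalg.det(mat)) / scale < tol


def triangulation_adjacency(
    montage: Montage,
) -> tuple[tuple[str, ...], np.ndarray]:
    """Electrode adjacency from Delaunay triangulation of 2-D projections.

    Returns the channel names and a symmetric, irreflexive boolean matrix;
    two electrodes are adjacent iff they share a triangle edge.  Degenerate
    co-circular quadrilaterals (where both diagonals are equally valid) are
    resolved toward the lexicographically smallest diagonal by name.
    """
    pts = montage.projected_2d()
    if len(pts) < 3:
        raise ValueError("need at least 3 electrodes for triangulation")
    if len(np.unique(np.round(pts, 9), axis=0)) != len(pts):
        raise ValueError("duplicate projected electrode positions")
    try:
        tri = scipy.spatial.Delaunay(pts)
    except scipy.spatial.QhullError as err:
        raise ValueError(f"degenerate montage geometry: {err}") from err

    n = len(pts)
    adj = np.zeros((n, n), dtype=bool)
    for simplex in tri.simplices:
        for i in range(3):
            a, b = simplex[i], simplex[(i + 1) % 3]
            adj[a, b] = adj[b, a] = True

    # lexicographic tie-break for exactly co-circular quads
    names = montage.channels
    for simplex_i, nbrs in enumerate(tri.neighbors):
        for edge_i in range(3):
            simplex_j = nbrs[edge_i]
            if simplex_j < simplex_i:
                continue  # each internal edge once
            shared = [v for v in tri.simplices[simplex_i]
                      if v in tri.simplices[simplex_j]]
            if len(shared) != 2:
                continue
            opp_i = [v for v in tri.simplices[simplex_i] if v not in shared][0]
            opp_j = [v for v in tri.simplices[simplex_j] if v not in shared][0]
            p, q = shared
            if _cocircular(pts[p], pts[q], pts[opp_i], pts[opp_j]):
                cur = tuple(sorted((names[p], names[q])))
                alt = tuple(sorted((names[opp_i], names[opp_j])))
                if alt < cur:
                    adj[p, q] = adj[q, p] = False
                    adj[opp_i, opp_j] = adj[opp_j, opp_i] = True
    np.fill_diagonal(adj, False)
    return names, adj
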