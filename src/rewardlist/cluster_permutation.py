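"""Nonparametric spatiotemporal cluster-based permutation inference.

Within-subject paired contrasts on (channel x time) feature maps: a paired t
test at every sample, suprathreshold samples (two-tailed alpha = .05,
uncorrected) joined into same-sign connected clusters under spatiotemporal
adjacency (same channel at neighboring time steps, or spatially neighboring
channels at the same time step), clusters spanning fewer than two distinct
channels discarded, and each cluster's summed-t mass referred to the
distribution of the permutation extremum obtained by randomly sign-flipping
each subject's difference map. Monte-Carlo p-values use the +1 correction
and significance is declared per tail at .025.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

from .core_data import CONDITIONS

__all__ = [
    "NeighborGraph",
    "TStatMap",
    "Cluster",
    "ClusterResult",
    "build_neighbor_graph",
    "paired_t_map",
    "form_clusters",
    "cluster_test",
    "interaction_contrast",
]

#: clamp value replacing infinite t at zero-variance samples
T_CLAMP = 1e9


@dataclass
class NeighborGraph:
    """Symmetric channel adjacency (no self-edges)."""

    n_channels: int
    edges: set[tuple[int, int]]  # i < j
    method: str
    param: float

    def adjacency(self) -> np.ndarray:
        A = np.zeros((self.n_channels, self.n_channels), dtype=bool)
        for i, j in self.edges:
            A[i, j] = A[j, i] = True
        return A

    def degree(self) -> np.ndarray:
        return self.adjacency().sum(axis=1)


def build_neighbor_graph(
    channel_xyz: np.ndarray, method: str = "distance", param: float | None = None
) -> NeighborGraph:
    """Channel neighborhood from sensor coordinates.

    ``distance``: edge iff Euclidean (chord) distance <= param; the default
    param is 1.5x the median nearest-neighbor distance. ``knn``: symmetrized
    k-nearest neighbors with param = k (default 4).
    """
    xyz = np.asarray(channel_xyz, dtype=float)
    n = xyz.shape[0]
    if n < 2:
        raise ValueError("need at least 2 channels")
    D = np.linalg.norm(xyz[:, None] - xyz[None, :], axis=2)
    if np.any(D[~np.eye(n, dtype=bool)] == 0):
        raise ValueError("channel coordinates must be distinct")
    edges: set[tuple[int, int]] = set()
    if method == "distance":
        if param is None:
            nn = np.where(np.eye(n, dtype=bool), np.inf, D).min(axis=1)
            param = 1.5 * float(np.median(nn))
        ii, jj = np.nonzero((D <= param) & ~np.eye(n, dtype=bool))
        edges = {(int(i), int(j)) for i, j in zip(ii, jj) if i < j}
    elif method == "knn":
        k = int(param) if param is not None else 4
        if k < 1:
            raise ValueError("knn param must be >= 1")
        order = np.argsort(np.where(np.eye(n, dtype=bool), np.inf, D), axis=1)
        for i in range(n):
            for j in order[i, :k]:
                a, b = (i, int(j)) if i < j else (int(j), i)
                edges.add((a, b))
        param = float(k)
    else:
        raise ValueError(f"unknown method {method!r}")
    graph = NeighborGraph(n, edges, method, float(param))
    if np.any(graph.degree() == 0):
        warnings.warn("neighbor graph has isolated channels", stacklevel=2)
    return graph


@dataclass
class TStatMap:
    t: np.ndarray  # (channels, times)
    df: int


def paired_t_map(data_a: np.ndarray, data_b: np.ndarray) -> TStatMap:
    """Samplewise paired t-values for subject x channel x time arrays.

    Zero-variance samples get t = ±T_CLAMP with the sign of the mean
    difference (0 when the mean is 0) so that clustering stays defined.
    """
    a = np.asarray(data_a, dtype=float)
    b = np.asarray(data_b, dtype=float)
    if a.shape != b.shape or a.ndim != 3:
        raise ValueError("inputs must be equal-shape (subjects, channels, times)")
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    d = a - b
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    t = np.where(sd == 0, np.sign(mean) * T_CLAMP, t)
    return TStatMap(t, n - 1)


@dataclass
class Cluster:
    members: list[tuple[int, int]]  # (channel, time) samples
    sign: int  # +1 or -1
    mass: float  # sum of member t-values
    channels: set[int]  # distinct channels spanned
    p: float | None = None

    @property
    def time_extent(self) -> tuple[int, int]:
        times = [t for _, t in self.members]
        return min(times), max(times)


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    n_perm: int
    seed: int
    alpha_cluster: float = 0.025
    max_pos_null: np.ndarray | None = None
    min_neg_null: np.ndarray | None = None

    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p is not None and c.p < self.alpha_cluster]

    def summary(self) -> str:
        if not self.clusters:
            return "no suprathreshold clusters"
        lines = []
        for c in sorted(self.clusters, key=lambda c: c.p or 1.0):
            sig = "*" if c.p is not None and c.p < self.alpha_cluster else " "
            lines.append(
                f"{sig} sign={c.sign:+d} mass={c.mass:10.2f} "
                f"channels={len(c.channels):3d} times={c.time_extent} p={c.p:.4f}"
            )
        return "\n".join(lines)


class _ClusterEngine:
    """Precomputed spatiotemporal adjacency for one (graph, map shape)."""

    def __init__(self, graph: NeighborGraph, n_channels: int, n_times: int):
        if graph.n_channels != n_channels:
            raise ValueError("graph does not cover the channels of the map")
        self.n_channels = n_channels
        self.n_times = n_times
        N = n_channels * n_times
        rows: list[np.ndarray] = []
        cols: list[np.ndarray] = []
        node = np.arange(N).reshape(n_channels, n_times)
        # temporal edges: same channel, adjacent time steps
        rows.append(node[:, :-1].ravel())
        cols.append(node[:, 1:].ravel())
        # spatial edges: neighboring channels, same time step
        for i, j in graph.edges:
            rows.append(node[i])
            cols.append(node[j])
        r = np.concatenate(rows)
        c = np.concatenate(cols)
        self.adj = sparse.csr_matrix(
            (np.ones(2 * r.size, dtype=np.int8), (np.r_[r, c], np.r_[c, r])),
            shape=(N, N),
        )

    def _components(self, mask_flat: np.ndarray):
        """Yield (member_node_ids,) arrays of connected suprathreshold sets."""
        idx = np.flatnonzero(mask_flat)
        if idx.size == 0:
            return []
        sub = self.adj[idx][:, idx]
        n_comp, labels = connected_components(sub, directed=False)
        return [idx[labels == c] for c in range(n_comp)]

    def clusters(self, tmap: np.ndarray, t_crit: float) -> list[Cluster]:
        out: list[Cluster] = []
        flat = tmap.ravel()
        for sign in (1, -1):
            mask = (sign * flat) >= t_crit
            for nodes in self._components(mask):
                chans = set(int(v) for v in nodes // self.n_times)
                if len(chans) < 2:
                    continue  # must include at least two electrodes
                members = [(int(v // self.n_times), int(v % self.n_times)) for v in nodes]
                out.append(Cluster(members, sign, float(flat[nodes].sum()), chans))
        return out

    def extrema(self, tmap: np.ndarray, t_crit: float) -> tuple[float, float]:
        """(max positive mass, min negative mass) of valid clusters; 0 if none."""
        max_pos = 0.0
        min_neg = 0.0
        flat = tmap.ravel()
        for sign in (1, -1):
            mask = (sign * flat) >= t_crit
            for nodes in self._components(mask):
                if np.unique(nodes // self.n_times).size < 2:
                    continue
                mass = float(flat[nodes].sum())
                if sign > 0:
                    max_pos = max(max_pos, mass)
                else:
                    min_neg = min(min_neg, mass)
        return max_pos, min_neg


def form_clusters(
    tmap: TStatMap,
    graph: NeighborGraph,
    alpha_sample: float = 0.05,
) -> list[Cluster]:
    """Partition suprathreshold samples into same-sign connected clusters.

    The sample threshold is the two-tailed critical t at ``alpha_sample`` for
    the map's df; components spanning fewer than two distinct channels are
    discarded.
    """
    t_crit = float(stats.t.ppf(1 - alpha_sample / 2, tmap.df))
    engine = _ClusterEngine(graph, *tmap.t.shape)
    return engine.clusters(tmap.t, t_crit)


def _null_t_maps(d_flat: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """Vectorized paired-t maps for sign-flipped differences.

    d_flat: (n_subjects, S) differences; signs: (n_perm, n_subjects) of ±1.
    Exploits sign^2 = 1 so only the mean changes under flipping.
    """
    n = d_flat.shape[0]
    sumsq = (d_flat**2).sum(axis=0)  # invariant under sign flips
    mean = signs @ d_flat / n
    var = (sumsq - n * mean**2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / np.sqrt(var / n)
    return np.where(var == 0, np.sign(mean) * T_CLAMP, t)


def cluster_test(
    data_a: np.ndarray,
    data_b: np.ndarray,
    graph: NeighborGraph,
    n_perm: int = 5000,
    seed: int = 0,
    alpha_sample: float = 0.05,
    alpha_cluster: float = 0.025,
    chunk: int = 200,
) -> ClusterResult:
    """Cluster-based permutation test of a paired condition contrast.

    The null distribution records, per permutation of random subject-level
    sign flips, the maximal positive and minimal negative cluster mass; each
    observed cluster's Monte-Carlo p is the +1-corrected proportion of
    permutation extrema at least as extreme in its own tail, judged
    significant at ``alpha_cluster`` per tail (two-tailed .05 overall).
    """
    tmap = paired_t_map(data_a, data_b)
    t_crit = float(stats.t.ppf(1 - alpha_sample / 2, tmap.df))
    n_sub, n_ch, n_time = np.asarray(data_a).shape
    engine = _ClusterEngine(graph, n_ch, n_time)
    observed = engine.clusters(tmap.t, t_crit)

    d_flat = (np.asarray(data_a, dtype=float) - np.asarray(data_b, dtype=float)).reshape(
        n_sub, -1
    )
    rng = np.random.default_rng(seed)
    max_pos = np.empty(n_perm)
    min_neg = np.empty(n_perm)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        signs = rng.integers(0, 2, size=(m, n_sub)) * 2 - 1
        tmaps = _null_t_maps(d_flat, signs)
        for i in range(m):
            max_pos[done + i], min_neg[done + i] = engine.extrema(
                tmaps[i].reshape(n_ch, n_time), t_crit
            )
        done += m

    for c in observed:
        if c.sign > 0:
            b = int(np.count_nonzero(max_pos >= c.mass))
        else:
            b = int(np.count_nonzero(min_neg <= c.mass))
        c.p = (b + 1) / (n_perm + 1)
    return ClusterResult(observed, n_perm, seed, alpha_cluster, max_pos, min_neg)


def interaction_contrast(
    features: dict[str, np.ndarray], contrast: str
) -> tuple[np.ndarray, np.ndarray]:
    """Build the paired inputs for a 2x2 within-subject contrast.

    ``features`` maps each condition to a (subjects, channels, times) array.
    ``reward`` and ``list`` are main effects (mean of two cells vs mean of
    the other two); ``interaction`` pairs the per-subject reward differences
    of mixed vs pure lists; ``reward_within_mixed`` / ``reward_within_pure``
    are the simple effects.
    """
    missing = set(CONDITIONS) - set(features)
    if missing:
        raise ValueError(f"missing condition cells {sorted(missing)}")
    mh, ml = features["mixed_high"], features["mixed_low"]
    ph, pl = features["pure_high"], features["pure_low"]
    if contrast == "reward":
        return (mh + ph) / 2.0, (ml + pl) / 2.0
    if contrast == "list":
        return (mh + ml) / 2.0, (ph + pl) / 2.0
    if contrast == "interaction":
        return mh - ml, ph - pl
    if contrast == "reward_within_mixed":
        return mh, ml
    if contrast == "reward_within_pure":
        return ph, pl
    raise ValueError(f"unknown contrast {contrast!r}")
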