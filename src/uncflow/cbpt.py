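"""Cluster-based permutation testing over electrode space.

Per-channel paired t statistics are thresholded, suprathreshold channels are
grouped into connected components of a spatial neighbour graph (positive and
negative t separately), each component's mass is the sum of its t values, and
significance comes from a max-statistic Monte-Carlo null built by sign-flipping
subject-wise condition differences.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "NeighborGraph",
    "Cluster",
    "ClusterResult",
    "build_neighbors",
    "cluster_test",
    "cluster_test_trials",
    "bonferroni",
]

logger = logging.getLogger(__name__)


@dataclass
class NeighborGraph:
    """Symmetric channel adjacency (no self edges)."""

    adjacency: np.ndarray  # (n_channels, n_channels) bool
    neighbors: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency, dtype=bool)
        if adj.shape[0] != adj.shape[1] or not np.array_equal(adj, adj.T):
            raise ValueError("adjacency must be square and symmetric")
        if adj.diagonal().any():
            raise ValueError("adjacency must not contain self edges")
        self.adjacency = adj
        if not self.neighbors:
            self.neighbors = [np.flatnonzero(adj[i]) for i in range(adj.shape[0])]

    @property
    def n_channels(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


def build_neighbors(channel_coords: np.ndarray, threshold: float | None = None) -> NeighborGraph:
    """Edges between channels at Euclidean distance <= threshold.

    With ``threshold=None`` the smallest threshold that leaves no channel
    isolated is used (the largest nearest-neighbour distance).
    """
    coords = np.asarray(channel_coords, dtype=float)
    if coords.shape[0] < 2:
        raise ValueError("need at least 2 channels")
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    if threshold is None:
        threshold = float(d.min(axis=1).max()) * (1 + 1e-9)
    adj = d <= threshold
    graph = NeighborGraph(adjacency=adj)
    isolated = [i for i in range(graph.n_channels) if graph.neighbors[i].size == 0]
    if isolated:
        warnings.warn(f"channels with no neighbours at threshold {threshold}: {isolated}",
                      stacklevel=2)
    return graph


@dataclass
class Cluster:
    channels: tuple[int, ...]
    mass: float  # signed sum of t values
    p: float


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    t_map: np.ndarray
    n_permutations: int
    alpha_sample: float
    alpha_cluster: float = 0.05

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p < self.alpha_cluster]

    def channel_labels(self) -> np.ndarray:
        """Cluster id per channel (-1 outside any cluster)."""
        labels = np.full(self.t_map.size, -1, dtype=int)
        for ci, c in enumerate(self.clusters):
            labels[list(c.channels)] = ci
        return labels


def _components(channels: np.ndarray, graph: NeighborGraph) -> list[np.ndarray]:
    """Connected components of the induced subgraph over ``channels``."""
    in_set = np.zeros(graph.n_channels, dtype=bool)
    in_set[channels] = True
    seen = np.zeros(graph.n_channels, dtype=bool)
    comps = []
    for start in channels:
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        comp = []
        while stack:
            node = stack.pop()
            comp.append(node)
            for nb in graph.neighbors[node]:
                if in_set[nb] and not seen[nb]:
                    seen[nb] = True
                    stack.append(nb)
        comps.append(np.array(sorted(comp)))
    return comps


def _cluster_masses(
    t: np.ndarray, t_crit: float, graph: NeighborGraph, min_edges: int
) -> list[tuple[np.ndarray, float]]:
    """Suprathreshold clusters (same-sign connected components) and masses."""
    out = []
    for sign in (1.0, -1.0):
        supra = np.flatnonzero(sign * t > t_crit)
        if supra.size == 0:
            continue
        for comp in _components(supra, graph):
            edges = int(graph.adjacency[np.ix_(comp, comp)].sum()) // 2
            if edges < min_edges:
                continue
            out.append((comp, float(t[comp].sum())))
    return out


def _paired_t(diffs: np.ndarray) -> np.ndarray:
    """Per-channel paired t over subjects; zero-variance channels get t = 0."""
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    t = np.zeros_like(mean)
    ok = sd > 0
    if not ok.all():
        logger.info("zero-variance channels set to t=0: %s", np.flatnonzero(~ok).tolist())
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    return t


def cluster_test(
    values_a: np.ndarray,
    values_b: np.ndarray,
    graph: NeighborGraph,
    alpha_sample: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = None,
    min_edges: int = 2,
) -> ClusterResult:
    """Paired (within-subject) cluster permutation test.

    Parameters
    ----------
    values_a, values_b : ndarray, shape (n_subjects, n_channels)
        Per-subject scalar maps (e.g. band/window-averaged power) for the two
        conditions, channel-aligned with ``graph``.
    min_edges : int
        Minimum number of neighbour-graph edges a suprathreshold component
        must contain to count as a cluster (default 2; the stricter reading
        of the two-neighbouring-pairs rule).

    The null swaps condition labels within subjects — a random sign flip of
    each subject's difference map — and records the maximum absolute cluster
    mass per draw; cluster p values are the proportion of null maxima at or
    above the observed absolute mass (with the observed data counted once).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("values_a and values_b must both be (n_subjects, n_channels)")
    if a.shape[1] != graph.n_channels:
        raise ValueError("channel count does not match the neighbour graph")
    n_subj = a.shape[0]
    if n_subj < 2:
        raise ValueError("need at least 2 subjects")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; p values will be coarse", stacklevel=2)

    diffs = a - b
    t_crit = float(stats.t.ppf(1.0 - alpha_sample / 2.0, n_subj - 1))
    t_obs = _paired_t(diffs)
    observed = _cluster_masses(t_obs, t_crit, graph, min_edges)

    rng = np.random.default_rng(seed)
    # sign flips leave per-subject squared values unchanged, so the permuted
    # t maps follow from flipped means and the fixed sum of squares
    ssq = (diffs**2).sum(axis=0)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_subj))
    null_max = np.zeros(n_perm)
    for pi in range(n_perm):
        mean = signs[pi] @ diffs / n_subj
        var = (ssq / n_subj - mean**2) * (n_subj / (n_subj - 1))
        var = np.maximum(var, 0.0)
        t_perm = np.zeros_like(mean)
        ok = var > 0
        t_perm[ok] = mean[ok] / np.sqrt(var[ok] / n_subj)
        masses = _cluster_masses(t_perm, t_crit, graph, min_edges)
        if masses:
            null_max[pi] = max(abs(m) for _, m in masses)

    clusters = [
        Cluster(
            channels=tuple(int(c) for c in comp),
            mass=mass,
            p=float((1 + np.sum(null_max >= abs(mass))) / (1 + n_perm)),
        )
        for comp, mass in observed
    ]
    clusters.sort(key=lambda c: -abs(c.mass))
    return ClusterResult(
        clusters=clusters, t_map=t_obs, n_permutations=n_perm, alpha_sample=alpha_sample
    )


def cluster_test_trials(
    trials_a: np.ndarray,
    trials_b: np.ndarray,
    graph: NeighborGraph,
    alpha_sample: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = None,
    min_edges: int = 2,
) -> ClusterResult:
    """Trial-level variant: independent t per channel, trial-label permutation null.

    ``trials_a``/``trials_b`` are (n_trials, n_channels) for one subject (or
    one pooled dataset); each draw reassigns trials to the two conditions.
    """
    a = np.asarray(trials_a, dtype=float)
    b = np.asarray(trials_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("trial arrays must be (n_trials, n_channels) with matching channels")
    if a.shape[1] != graph.n_channels:
        raise ValueError("channel count does not match the neighbour graph")
    n_a = a.shape[0]
    pooled = np.vstack([a, b])
    df = n_a + b.shape[0] - 2
    t_crit = float(stats.t.ppf(1.0 - alpha_sample / 2.0, df))

    def _tmap(x: np.ndarray, y: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            t, _ = stats.ttest_ind(x, y, axis=0)
        return np.nan_to_num(t)

    observed = _cluster_masses(_tmap(a, b), t_crit, graph, min_edges)
    rng = np.random.default_rng(seed)
    null_max = np.zeros(n_perm)
    for pi in range(n_perm):
        perm = rng.permutation(pooled.shape[0])
        pa, pb = pooled[perm[:n_a]], pooled[perm[n_a:]]
        masses = _cluster_masses(_tmap(pa, pb), t_crit, graph, min_edges)
        if masses:
            null_max[pi] = max(abs(m) for _, m in masses)
    clusters = [
        Cluster(
            channels=tuple(int(c) for c in comp),
            mass=mass,
            p=float((1 + np.sum(null_max >= abs(mass))) / (1 + n_perm)),
        )
        for comp, mass in observed
    ]
    clusters.sort(key=lambda c: -abs(c.mass))
    return ClusterResult(
        clusters=clusters,
        t_map=_tmap(a, b),
        n_permutations=n_perm,
        alpha_sample=alpha_sample,
    )


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Multiply p values by the number of comparisons, capped at 1."""
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(1.0, m * p)
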