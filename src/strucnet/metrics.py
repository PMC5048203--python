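"""Weighted graph metrics and degree-preserving null-model normalization.

Nodal measures on the NOS-weighted connectome: strength (sum of incident
weights), the Onnela weighted clustering coefficient (geometric mean of
triangle weights, normalized by the global maximum weight), and mean
shortest weighted path length with edge lengths 1/w — the standard
transform for streamline-count networks, where stronger connections are
shorter. Global summaries are the mean nodal strength, the total fiber
count (sum of NOS over node pairs), and the small-world indices: gamma
and lambda are the observed global clustering and characteristic path
length divided by their means over an ensemble of degree-matched random
networks generated by Maslov-Sneppen double-edge swaps in which weights
travel with their edges.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components as _sp_components
from scipy.sparse.csgraph import dijkstra

from .core import GraphMetricSet, SubjectConnectome

__all__ = [
    "nodal_strength",
    "weighted_clustering",
    "weighted_distances",
    "char_path_length",
    "global_summaries",
    "rewire_preserving_degree",
    "normalized_small_world",
    "compute_metrics",
]


def nodal_strength(connectome: SubjectConnectome) -> np.ndarray:
    """Per-node sum of incident edge weights."""
    return connectome.weights.sum(axis=1).astype(float)


def weighted_clustering(connectome: SubjectConnectome) -> np.ndarray:
    """Onnela weighted clustering coefficient per node.

    C_i = (1 / (k_i (k_i - 1))) * sum_{j,h} (w'_ij w'_ih w'_jh)^(1/3)
    with w' = w / max(w) and k_i the binary degree; C_i = 0 for k_i < 2.
    """
    w = connectome.weights.astype(float)
    wmax = w.max()
    n = w.shape[0]
    if wmax == 0:
        return np.zeros(n)
    cube_root = np.cbrt(w / wmax)
    triangles = np.diagonal(cube_root @ cube_root @ cube_root)
    k = (w > 0).sum(axis=1)
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, triangles / denom, 0.0)
    return c


def weighted_distances(connectome: SubjectConnectome) -> np.ndarray:
    """All-pairs shortest weighted path lengths with edge length 1/w.

    Unreachable pairs are infinite; the diagonal is zero.
    """
    w = connectome.weights.astype(float)
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / w, 0.0)
    return dijkstra(csr_matrix(lengths), directed=False)


def char_path_length(
    connectome: SubjectConnectome, distances: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Characteristic weighted path length and per-node mean path length.

    Per node: mean finite distance to all other nodes; global: mean over
    all ordered reachable pairs. Unreachable pairs are excluded with a
    warning naming their count.
    """
    if not connectome.weights.any():
        raise ValueError("graph has no edges")
    d = weighted_distances(connectome) if distances is None else distances
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    n_unreachable = int((off & ~np.isfinite(d)).sum())
    if n_unreachable:
        warnings.warn(
            f"{n_unreachable} ordered node pair(s) unreachable; "
            "excluded from path-length means",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore"):
        per_node = np.where(
            finite.sum(axis=1) > 0,
            np.where(finite, d, 0.0).sum(axis=1) / np.maximum(finite.sum(axis=1), 1),
            np.inf,
        )
    global_l = float(d[finite].mean())
    return global_l, per_node


def global_summaries(connectome: SubjectConnectome) -> tuple[float, float]:
    """(global strength, total fiber count).

    global_strength = mean nodal strength; total_fibers = sum of NOS over
    unordered pairs. The identity global_strength * N / 2 == total_fibers
    holds exactly because every edge contributes to two nodal strengths.
    """
    s = nodal_strength(connectome)
    iu = np.triu_indices(connectome.n_nodes, k=1)
    return float(s.mean()), float(connectome.weights[iu].sum())


def rewire_preserving_degree(
    connectome: SubjectConnectome, swaps_per_edge: int = 10, seed: int = 0
) -> SubjectConnectome:
    """Degree-preserving randomization by weighted double-edge swaps.

    Repeatedly picks two edges (a, b) and (c, d) and rewires them to
    (a, d) and (c, b) when that creates no self-loop or multi-edge;
    weights travel with their edges, so both the binary degree sequence
    and the weight multiset are exactly preserved.
    """
    w = connectome.weights
    n = w.shape[0]
    iu = np.triu_indices(n, k=1)
    rows, cols = iu[0][w[iu] > 0], iu[1][w[iu] > 0]
    m = len(rows)
    if m < 2:
        warnings.warn("graph too small to swap; returning a copy", stacklevel=2)
        return connectome.copy()
    edges = np.column_stack([rows, cols])
    wts = w[rows, cols].copy()
    adj = (w > 0).copy()
    rng = np.random.default_rng(seed)
    n_attempts = swaps_per_edge * m
    ei = rng.integers(0, m, size=n_attempts)
    ej = rng.integers(0, m, size=n_attempts)
    flips = rng.integers(0, 2, size=n_attempts)
    for k in range(n_attempts):
        i, j = ei[k], ej[k]
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if flips[k]:
            c, d = d, c
        # proposed: (a, d) and (c, b)
        if a == d or c == b or adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = adj[b, a] = False
        adj[c, d] = adj[d, c] = False
        adj[a, d] = adj[d, a] = True
        adj[c, b] = adj[b, c] = True
        edges[i] = (a, d)
        edges[j] = (c, b)
    out = np.zeros_like(w)
    out[edges[:, 0], edges[:, 1]] = wts
    out[edges[:, 1], edges[:, 0]] = wts
    return SubjectConnectome(
        connectome.schema, out, subject_id=f"{connectome.subject_id}__rand"
    )


def normalized_small_world(
    connectome: SubjectConnectome,
    n_random: int = 1000,
    seed: int = 0,
    swaps_per_edge: int = 10,
) -> tuple[float, float]:
    """Small-world normalization: gamma and lambda.

    gamma = mean nodal Onnela clustering of the observed graph divided by
    the ensemble mean over degree-matched random networks; lambda is the
    same ratio for characteristic weighted path length. gamma > 1 with
    lambda ~ 1 is the small-world regime.
    """
    n_comp, _ = _sp_components(csr_matrix(connectome.weights), directed=False)
    if n_comp > 1:
        warnings.warn(
            f"connectome has {n_comp} connected components; "
            "path lengths use reachable pairs only",
            stacklevel=2,
        )
    c_obs = float(weighted_clustering(connectome).mean())
    l_obs, _ = char_path_length(connectome)
    rng = np.random.default_rng(seed)
    c_rand = np.empty(n_random)
    l_rand = np.empty(n_random)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k in range(n_random):
            rand = rewire_preserving_degree(
                connectome,
                swaps_per_edge=swaps_per_edge,
                seed=int(rng.integers(2**31 - 1)),
            )
            c_rand[k] = float(weighted_clustering(rand).mean())
            l_rand[k] = char_path_length(rand)[0]
    if c_rand.mean() == 0:
        raise ValueError("zero mean random clustering; cannot normalize")
    return c_obs / c_rand.mean(), l_obs / l_rand.mean()


def compute_metrics(
    connectome: SubjectConnectome,
    n_random: int = 1000,
    seed: int = 0,
    swaps_per_edge: int = 10,
    normalize: bool = True,
) -> GraphMetricSet:
    """All nodal and global metrics for one connectome."""
    strength = nodal_strength(connectome)
    clustering = weighted_clustering(connectome)
    global_l, per_node_l = char_path_length(connectome)
    global_strength, total_fibers = global_summaries(connectome)
    gamma = lam = float("nan")
    if normalize:
        gamma, lam = normalized_small_world(
            connectome, n_random=n_random, seed=seed, swaps_per_edge=swaps_per_edge
        )
    return GraphMetricSet(
        nodal_strength=strength,
        nodal_clustering=clustering,
        nodal_path_length=per_node_l,
        global_strength=global_strength,
        total_fibers=total_fibers,
        gamma=gamma,
        lam=lam,
    )
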