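"""Network-based statistic (NBS) for connectome group comparison.

Mass-univariate edge testing in a connectome multiplies comparisons by
the thousands; the NBS controls the family-wise error rate at the level
of connected suprathreshold components instead of single edges. The
procedure: (1) a pooled-variance two-sample t statistic per kept edge;
(2) a primary component-forming threshold (p < 0.01 one-sided by
default, converted to a t cutoff at df = n_a + n_b - 2); (3) connected
components of the suprathreshold graph, sized by edge count (extent);
(4) a permutation null for the maximum component size obtained by
shuffling group labels and re-running steps 1-3, from which each
observed component receives a family-wise-error-corrected p-value.
"""

from __future__ import annotations

import math
import warnings
from itertools import combinations

import numpy as np
from scipy import stats as sps

from .core import EdgeStatMap, GroupStudy, NBSComponent, NBSResult
from .graphs import GroupMask

__all__ = [
    "edge_t",
    "t_from_p",
    "suprathreshold_components",
    "nbs_test",
]


def _pooled_t(
    sum_a: np.ndarray,
    sumsq_a: np.ndarray,
    sum_b: np.ndarray,
    sumsq_b: np.ndarray,
    n_a: int,
    n_b: int,
) -> np.ndarray:
    """Vectorized pooled-variance two-sample t (a minus b)."""
    df = n_a + n_b - 2
    mean_a = sum_a / n_a
    mean_b = sum_b / n_b
    ss_a = sumsq_a - sum_a**2 / n_a
    ss_b = sumsq_b - sum_b**2 / n_b
    sp2 = (ss_a + ss_b) / df
    se2 = sp2 * (1.0 / n_a + 1.0 / n_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (mean_a - mean_b) / np.sqrt(se2)
    # degenerate zero-variance edges can never form components
    return np.where(se2 > 0, t, 0.0)


def edge_t(study: GroupStudy, mask: GroupMask, direction: str = "b_gt_a") -> EdgeStatMap:
    """Edge-wise pooled-variance two-sample t map on the kept edge set.

    The sign convention follows ``direction``: positive t means the named
    contrast (e.g. ``b_gt_a``: controls above cases). Edges outside the
    mask are NaN (absent).
    """
    if direction not in ("a_gt_b", "b_gt_a"):
        raise ValueError(f"invalid direction {direction!r}")
    if study.n_a < 2 or study.n_b < 2:
        raise ValueError("need at least 2 subjects per group")
    if not mask.keep.any():
        raise ValueError("empty mask")
    a, b = study.stacked()
    a = a.astype(float)
    b = b.astype(float)
    t = _pooled_t(
        a.sum(0), (a**2).sum(0), b.sum(0), (b**2).sum(0), study.n_a, study.n_b
    )
    if direction == "b_gt_a":
        t = -t
    iu = np.triu_indices(len(study.schema), k=1)
    pooled = np.concatenate([a, b])
    degenerate = mask.keep & (pooled.std(axis=0) == 0)
    n_degen = int(degenerate[iu].sum())
    if n_degen:
        warnings.warn(
            f"{n_degen} kept edge(s) have zero pooled variance; t set to 0",
            stacklevel=2,
        )
    t = np.where(mask.keep, t, np.nan)
    return EdgeStatMap(
        schema=study.schema, t=t, df=study.n_a + study.n_b - 2, direction=direction
    )


def t_from_p(primary_p: float = 0.01, df: int = 81) -> float:
    """Upper-tail one-sided t quantile for the component-forming p."""
    if not (0.0 < primary_p < 1.0):
        raise ValueError("primary_p must lie in (0, 1)")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(sps.t.isf(primary_p, df))


def _max_component_size(edges: np.ndarray) -> int:
    """Largest connected component by edge count; union-find over an edge list."""
    if len(edges) == 0:
        return 0
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    for u, v in edges:
        u, v = int(u), int(v)
        parent.setdefault(u, u)
        parent.setdefault(v, v)
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    counts: dict[int, int] = {}
    for u, v in edges:
        r = find(int(u))
        counts[r] = counts.get(r, 0) + 1
    return max(counts.values())


def suprathreshold_components(
    stat_map: EdgeStatMap, t_threshold: float
) -> list[NBSComponent]:
    """Connected components of the graph of edges with t >= threshold.

    Components are sized by edge count and returned largest first with
    placeholder p_fwer = 1 (permutation inference assigns real values).
    """
    t = stat_map.t
    n = len(stat_map.schema)
    iu = np.triu_indices(n, k=1)
    with np.errstate(invalid="ignore"):
        supra = np.where(np.isnan(t), False, t >= t_threshold)
    rows, cols = iu[0][supra[iu]], iu[1][supra[iu]]
    if len(rows) == 0:
        return []
    # label nodes via union-find, then collect per-root node and edge sets
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    for u, v in zip(rows, cols):
        parent.setdefault(int(u), int(u))
        parent.setdefault(int(v), int(v))
        ru, rv = find(int(u)), find(int(v))
        if ru != rv:
            parent[ru] = rv
    comp_edges: dict[int, list[tuple[int, int]]] = {}
    for u, v in zip(rows, cols):
        comp_edges.setdefault(find(int(u)), []).append((int(u), int(v)))
    ids = stat_map.schema.node_ids
    components = [
        NBSComponent(
            nodes=frozenset(ids[i] for e in edges for i in e),
            edges=frozenset(tuple(sorted((ids[u], ids[v]))) for u, v in edges),
            size=len(edges),
            p_fwer=1.0,
        )
        for edges in comp_edges.values()
    ]
    components.sort(key=lambda c: c.size, reverse=True)
    return components


def _null_max_sizes(
    values: np.ndarray,
    pairs: np.ndarray,
    n_a: int,
    n_b: int,
    t_threshold: float,
    perms: np.ndarray,
    sign: float,
    two_sided: bool,
    block: int = 250,
) -> np.ndarray:
    """Max suprathreshold component size per permutation.

    ``values`` is (n_subj, n_edges) on the kept edge set, ``pairs`` the
    (n_edges, 2) node index pairs, ``perms`` a boolean (n_perm, n_subj)
    group-a selector. Group sums are computed by one matrix product per
    block, so the permutation loop only pays for component extraction on
    the (few) suprathreshold edges.
    """
    vsq = values**2
    tot = values.sum(0)
    tot2 = vsq.sum(0)
    out = np.empty(len(perms), dtype=np.int64)
    for start in range(0, len(perms), block):
        P = perms[start : start + block].astype(float)
        sum_a = P @ values
        sumsq_a = P @ vsq
        t = _pooled_t(sum_a, sumsq_a, tot - sum_a, tot2 - sumsq_a, n_a, n_b)
        t = np.abs(t) if two_sided else sign * t
        for k in range(len(P)):
            supra = t[k] >= t_threshold
            out[start + k] = _max_component_size(pairs[supra])
    return out


def nbs_test(
    study: GroupStudy,
    mask: GroupMask,
    primary_p: float = 0.01,
    n_perm: int = 5000,
    alpha: float = 0.05,
    direction: str = "b_gt_a",
    seed: int = 0,
    two_sided: bool = False,
) -> NBSResult:
    """Full NBS: observed components plus max-component permutation null.

    Group labels are randomly reassigned (preserving group sizes) n_perm
    times; the largest suprathreshold component size of each permutation
    forms the null. p_fwer = (1 + #{null >= observed size}) / (1 + n_perm)
    so p-values never reach zero. When the total number of distinct group
    relabelings is at most n_perm, the null is enumerated exhaustively
    instead (with the identity relabeling included).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    n_a, n_b = study.n_a, study.n_b
    n = n_a + n_b
    df = n - 2
    p_tail = primary_p / 2 if two_sided else primary_p
    t_thr = t_from_p(p_tail, df)

    stat_map = edge_t(study, mask, direction)
    if two_sided:
        abs_map = EdgeStatMap(
            schema=stat_map.schema,
            t=np.where(np.isnan(stat_map.t), np.nan, np.abs(stat_map.t)),
            df=df,
            direction=direction,
        )
        observed = suprathreshold_components(abs_map, t_thr)
    else:
        observed = suprathreshold_components(stat_map, t_thr)

    a, b = study.stacked()
    iu = np.triu_indices(len(study.schema), k=1)
    kept = mask.keep[iu]
    pairs = np.column_stack([iu[0][kept], iu[1][kept]])
    values = np.concatenate([a, b]).astype(float)[:, iu[0], iu[1]][:, kept]
    sign = -1.0 if direction == "b_gt_a" else 1.0

    n_total = math.comb(n, n_a)
    if n_total <= n_perm:
        warnings.warn(
            f"only {n_total} distinct relabelings; enumerating exhaustively",
            stacklevel=2,
        )
        perms = np.zeros((n_total, n), dtype=bool)
        for k, combo in enumerate(combinations(range(n), n_a)):
            perms[k, list(combo)] = True
        exhaustive = True
    else:
        rng = np.random.default_rng(seed)
        perms = np.zeros((n_perm, n), dtype=bool)
        for k in range(n_perm):
            perms[k, rng.choice(n, size=n_a, replace=False)] = True
        exhaustive = False

    null_max = _null_max_sizes(
        values, pairs, n_a, n_b, t_thr, perms, sign, two_sided
    )

    def p_of(size: int) -> float:
        ge = int((null_max >= size).sum())
        if exhaustive:
            return ge / len(null_max)
        return (1 + ge) / (1 + n_perm)

    components = [
        NBSComponent(nodes=c.nodes, edges=c.edges, size=c.size, p_fwer=p_of(c.size))
        for c in observed
    ]
    return NBSResult(
        components=components,
        primary_p=primary_p,
        t_threshold=t_thr,
        n_perm=len(perms),
        alpha=alpha,
        seed=seed,
        null_max_sizes=null_max,
        direction=direction,
    )
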