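"""Synthetic two-group connectome cohorts and tractography phantoms.

The cohort generator emulates the study design this package targets: two
groups of roughly 41 and 42 subjects over an 83-node whole-brain schema,
NOS edge weights in the tens-to-hundreds range, and a group deficit of
30-50% planted on a small connected subnetwork confined to one hemisphere.

The template topology is a stochastic block model with within-hemisphere
modules and weaker inter-module / inter-hemispheric connection
probabilities, which places the resulting weighted graphs in the
small-world regime (normalized clustering gamma > 1, normalized path
length lambda ~ 1) like real structural connectomes. Subject-level
variability is multiplicative lognormal per subject-edge, rounded to
integer streamline counts: NOS are nonnegative, right-skewed counts whose
standard deviation is comparable to half the mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    GroupStudy,
    NodeSchema,
    Phantom,
    SubjectConnectome,
    default_schema,
    generic_schema,
)

__all__ = [
    "EffectSpec",
    "CohortSpec",
    "default_effect_edges",
    "make_template",
    "sample_cohort",
    "sample_clinical",
    "make_phantom",
    "phantom_schema",
]

#: Default planted deficit: seven edges over seven left-hemisphere nodes
#: (orbitofrontal-striatal-temporo-limbic), a connected subgraph.
DEFAULT_EFFECT_EDGES = (
    ("lh.putamen", "lh.amygdala"),
    ("lh.pallidum", "lh.amygdala"),
    ("lh.putamen", "lh.temporalpole"),
    ("lh.amygdala", "lh.temporalpole"),
    ("lh.temporalpole", "lh.insula"),
    ("lh.medialorbitofrontal", "lh.insula"),
    ("lh.amygdala", "lh.entorhinal"),
)


def default_effect_edges(schema: NodeSchema | None = None) -> frozenset[tuple[str, str]]:
    """The default 7-edge connected left-hemisphere deficit subnetwork."""
    if schema is None:
        schema = default_schema()
    edges = frozenset(tuple(sorted(e)) for e in DEFAULT_EFFECT_EDGES)
    for u, v in edges:
        if u not in schema.node_ids or v not in schema.node_ids:
            raise ValueError(f"default effect edge ({u}, {v}) not in schema")
    return edges


def _edges_connected(edges: frozenset[tuple[str, str]]) -> bool:
    if not edges:
        return True
    nodes = {n for e in edges for n in e}
    adj: dict[str, set[str]] = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    seen = set()
    stack = [next(iter(nodes))]
    while stack:
        n = stack.pop()
        if n in seen:
            continue
        seen.add(n)
        stack.extend(adj[n] - seen)
    return seen == nodes


@dataclass(frozen=True)
class EffectSpec:
    """A multiplicative deficit planted on a connected edge set.

    ``reduction`` (delta) scales group-a means on ``target_edges`` by
    (1 - delta); delta = 0 makes the two groups exchangeable. When
    ``reduction_medicated`` is set, medicated group-a subjects carry that
    (typically larger) deficit instead.
    """

    target_edges: frozenset[tuple[str, str]]
    reduction: float = 0.37
    reduction_medicated: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "target_edges",
            frozenset(tuple(sorted(e)) for e in self.target_edges),
        )
        if not (0.0 <= self.reduction < 1.0):
            raise ValueError("reduction must lie in [0, 1)")
        if not _edges_connected(self.target_edges):
            raise ValueError("target_edges must form a connected subgraph")


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort.

    Defaults mirror the target design: 41 cases vs 42 controls over 83
    nodes, ~25% template edge density, lognormal edge means (median ~150
    streamlines), and subject-level coefficient of variation 0.5, which
    reproduces between-subject NOS dispersions of roughly half the mean.
    """

    n_a: int = 41
    n_b: int = 42
    n_nodes: int = 83
    density: float = 0.25
    weight_scale: tuple[float, float] = (5.0, 0.8)
    subject_cv: float = 0.5
    effect: EffectSpec | None = None
    medicated_fraction: float = 29 / 41
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.density <= 1.0):
            raise ValueError("density must lie in (0, 1]")
        if self.n_a < 2 or self.n_b < 2:
            raise ValueError("each group needs at least 2 subjects")


def _block_probabilities(schema: NodeSchema, density: float) -> np.ndarray:
    """Pairwise connection probabilities for the modular template.

    Nodes within a hemisphere are split into contiguous modules; the
    probability ratio within-module : within-hemisphere : cross-hemisphere
    is 1 : 0.35 : 0.12, with an additional exponential decay in module
    distance, all rescaled to hit the requested mean density.
    """
    n = len(schema)
    hemi = np.array([0 if h == "left" else (1 if h == "right" else 2)
                     for h in schema.hemisphere])
    module = np.zeros(n, dtype=int)
    next_mod = 0
    for h in (0, 1, 2):
        idx = np.flatnonzero(hemi == h)
        if idx.size == 0:
            continue
        n_mod = max(1, round(idx.size / 12))  # ~12 nodes per module
        for k, chunk in enumerate(np.array_split(idx, n_mod)):
            module[chunk] = next_mod + k
        next_mod += n_mod

    same_mod = module[:, None] == module[None, :]
    same_hemi = hemi[:, None] == hemi[None, :]
    mod_dist = np.abs(module[:, None] - module[None, :])
    rel = np.where(same_mod, 1.0,
                   np.where(same_hemi, 0.35, 0.12) * np.exp(-0.3 * mod_dist))
    np.fill_diagonal(rel, 0.0)
    iu = np.triu_indices(n, k=1)
    scale = density / rel[iu].mean()
    p = np.minimum(rel * scale, 1.0)
    # renormalize once after capping so the mean stays on target
    short = density - p[iu].mean()
    if short > 1e-12:
        room = (1.0 - p) * (rel > 0)
        np.fill_diagonal(room, 0.0)
        p = np.minimum(p + short * room / max(room[iu].mean(), 1e-12), 1.0)
    return p


def _is_connected(adj: np.ndarray) -> bool:
    n = len(adj)
    seen = np.zeros(n, dtype=bool)
    stack = [0]
    seen[0] = True
    while stack:
        i = stack.pop()
        nb = np.flatnonzero(adj[i] & ~seen)
        seen[nb] = True
        stack.extend(nb.tolist())
    return bool(seen.all())


def make_template(
    n_nodes: int = 83,
    density: float = 0.25,
    weight_scale: float | tuple[float, float] = (5.0, 0.8),
    modular_structure: bool = True,
    seed: int = 0,
    schema: NodeSchema | None = None,
    ensure_edges: frozenset[tuple[str, str]] | None = None,
) -> np.ndarray:
    """Draw a symmetric nonnegative template of edge-mean NOS values.

    The binary topology is resampled until connected and within 10%
    relative of the requested density. ``weight_scale`` is either
    (mu, sigma) of a lognormal over edge means or a constant edge weight.
    ``ensure_edges`` forces the listed node-id pairs to be present.
    """
    if schema is None:
        schema = generic_schema(n_nodes)
    if len(schema) != n_nodes:
        raise ValueError("schema size must equal n_nodes")
    min_density = 2.0 / n_nodes  # n-1 edges out of n(n-1)/2
    if density < min_density:
        raise ValueError(
            f"density {density} below the minimal connected density "
            f"{min_density:.4g} (= 2/n_nodes) for n_nodes={n_nodes}"
        )
    if density > 1.0:
        raise ValueError("density cannot exceed 1")

    rng = np.random.default_rng(seed)
    if modular_structure:
        p = _block_probabilities(schema, density)
    else:
        p = np.full((n_nodes, n_nodes), density)
        np.fill_diagonal(p, 0.0)

    idx = {nid: i for i, nid in enumerate(schema.node_ids)}
    forced = np.zeros((n_nodes, n_nodes), dtype=bool)
    if ensure_edges:
        for u, v in ensure_edges:
            forced[idx[u], idx[v]] = forced[idx[v], idx[u]] = True

    iu = np.triu_indices(n_nodes, k=1)
    n_pairs = len(iu[0])
    for _ in range(200):
        adj = np.zeros((n_nodes, n_nodes), dtype=bool)
        draw = rng.random(n_pairs) < p[iu]
        adj[iu] = draw
        adj |= adj.T
        adj |= forced
        realized = adj[iu].sum() / n_pairs
        if abs(realized - density) <= 0.1 * density and _is_connected(adj):
            break
    else:
        raise RuntimeError("could not realize a connected template at this density")

    weights = np.zeros((n_nodes, n_nodes))
    if isinstance(weight_scale, (int, float)):
        w = np.full(n_pairs, float(weight_scale))
    else:
        mu, sigma = weight_scale
        w = rng.lognormal(mean=mu, sigma=sigma, size=n_pairs)
    weights[iu] = np.where(adj[iu], w, 0.0)
    weights += weights.T
    return weights


def _round_half_even_nonneg(x: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(x), 0, None).astype(np.int64)


def sample_cohort(
    spec: CohortSpec, template: np.ndarray | None = None
) -> GroupStudy:
    """Sample a two-group cohort of integer NOS connectomes.

    Each subject matrix is round(template * lognormal noise) with the
    planted deficit applied multiplicatively to group-a target edges. The
    per-subject-edge noise multiplier has mean exactly 1 (lognormal with
    mu = -sigma^2/2), so group means stay on the template scale.
    """
    schema = generic_schema(spec.n_nodes)
    rng = np.random.default_rng(spec.seed)
    effect = spec.effect
    target = effect.target_edges if effect is not None else frozenset()

    if template is None:
        template = make_template(
            spec.n_nodes,
            spec.density,
            spec.weight_scale,
            seed=spec.seed,
            schema=schema,
            ensure_edges=target or None,
        )
    idx = {nid: i for i, nid in enumerate(schema.node_ids)}
    if target:
        missing = [e for e in sorted(target) if template[idx[e[0]], idx[e[1]]] == 0]
        if missing:
            raise ValueError(f"effect target edges absent from template: {missing}")

    n = spec.n_nodes
    iu = np.triu_indices(n, k=1)
    base = template[iu]
    cv = spec.subject_cv
    if cv > 0:
        sigma2 = math.log(1.0 + cv * cv)
        mu, sigma = -sigma2 / 2.0, math.sqrt(sigma2)
    else:
        mu = sigma = 0.0

    effect_vec = np.ones(len(base))
    effect_vec_med = np.ones(len(base))
    if effect is not None:
        tmask = np.zeros((n, n), dtype=bool)
        for u, v in target:
            tmask[idx[u], idx[v]] = tmask[idx[v], idx[u]] = True
        tvec = tmask[iu]
        effect_vec[tvec] = 1.0 - effect.reduction
        red_med = (effect.reduction_medicated
                   if effect.reduction_medicated is not None else effect.reduction)
        effect_vec_med[tvec] = 1.0 - red_med

    medicated = rng.random(spec.n_a) < spec.medicated_fraction

    def draw_subject(sid: str, scale: np.ndarray) -> SubjectConnectome:
        noise = rng.lognormal(mu, sigma, size=len(base)) if cv > 0 else 1.0
        vals = _round_half_even_nonneg(base * noise * scale)
        w = np.zeros((n, n), dtype=np.int64)
        w[iu] = vals
        w += w.T
        return SubjectConnectome(schema, w, subject_id=sid)

    group_a = [
        draw_subject(f"a{i + 1:03d}", effect_vec_med if medicated[i] else effect_vec)
        for i in range(spec.n_a)
    ]
    group_b = [draw_subject(f"b{i + 1:03d}", np.ones(len(base)))
               for i in range(spec.n_b)]
    med_flags = {c.subject_id: bool(medicated[i]) for i, c in enumerate(group_a)}
    return GroupStudy(group_a=group_a, group_b=group_b, medicated=med_flags)


# Clinical score scales: (mean, sd, low, high). Means/sds follow typical
# moderately ill OCD cohorts; low/high are hard instrument bounds used for
# clipping (Y-BOCS total clipped to the observed 15-36 case range).
_SCALES = {
    "ybocs_total": (22.0, 5.4, 15, 36),
    "ybocs_obsession": (11.4, 3.2, 0, 20),
    "ybocs_compulsion": (10.6, 3.5, 0, 20),
    "ocir_total": (25.2, 9.2, 0, 72),
    "bdi": (18.1, 11.4, 0, 53),
}


def sample_clinical(
    study: GroupStudy,
    association: str = "none",
    seed: int = 0,
    r: float = 0.5,
    target_edges: frozenset[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Generate per-case clinical scores (Y-BOCS, OCI-R, BDI).

    With ``association='linear'`` every score is built as
    r * z(feature) + sqrt(1-r^2) * noise on the standardized per-subject
    mean NOS over ``target_edges``, so the population correlation with
    that network feature is r (clipping to instrument bounds attenuates it
    slightly). With ``association='none'`` scores are independent of the
    connectomes.
    """
    if association not in ("none", "linear"):
        raise ValueError("association must be 'none' or 'linear'")
    if association == "linear":
        if not (-1.0 < r < 1.0):
            raise ValueError("association r must lie in (-1, 1)")
        if not target_edges:
            raise ValueError("linear association requires target_edges")

    rng = np.random.default_rng(seed)
    n = study.n_a
    if association == "linear":
        idx = {nid: i for i, nid in enumerate(study.schema.node_ids)}
        pairs = [(idx[u], idx[v]) for u, v in target_edges]
        feat = np.array(
            [np.mean([c.weights[i, j] for i, j in pairs]) for c in study.group_a]
        )
        sd = feat.std()
        z = (feat - feat.mean()) / sd if sd > 0 else np.zeros(n)

    table: dict[str, list] = {"subject_id": [c.subject_id for c in study.group_a]}
    for name, (mean, s, lo, hi) in _SCALES.items():
        eps = rng.standard_normal(n)
        latent = r * z + math.sqrt(1 - r * r) * eps if association == "linear" else eps
        table[name] = np.clip(np.round(mean + s * latent), lo, hi).astype(int)
    return pd.DataFrame(table)


# ---------------------------------------------------------------------------
# Tractography phantoms
# ---------------------------------------------------------------------------

def phantom_schema(n_parcels: int) -> NodeSchema:
    """Schema whose node k (0-based) corresponds to parcel label k+1."""
    ids = tuple(f"parcel{k + 1}" for k in range(n_parcels))
    return NodeSchema(ids, ids, ("midline",) * n_parcels, ("brainstem",) * n_parcels)


def make_phantom(
    kind: str = "straight",
    shape: tuple[int, int, int] = (20, 7, 7),
    cross_section: int = 3,
    turn_deg: float = 50.0,
    gap_fa: float = 0.05,
    bundle_fa: float = 0.7,
    seed: int = 0,
) -> Phantom:
    """Build a synthetic tensor-field phantom for tractography testing.

    kinds:
      straight — one high-FA bundle along x joining parcels at both x ends.
      gap      — the straight bundle with a low-FA slab interrupting it.
      curved   — the bundle's direction field turns by ``turn_deg``
                 between consecutive voxels along x (alternating
                 +-turn_deg/2 about the bundle axis in the x-y plane), so
                 a sub-threshold turn lets streamlines pass while a
                 supra-threshold turn stops every streamline at its first
                 step.
      crossing — two orthogonal, non-interacting bundles in separate z
                 slabs, one along x and one along y, each with its own
                 parcel pair.
    """
    if kind not in ("straight", "curved", "crossing", "gap"):
        raise ValueError(f"unknown phantom kind {kind!r}")
    nx, ny, nz = shape
    if cross_section > min(ny, nz) or (kind == "crossing" and nz < 2 * cross_section):
        raise ValueError("bundle cross-section does not fit inside shape")

    fa = np.zeros(shape)
    direction = np.zeros(shape + (3,))
    wm = np.zeros(shape, dtype=bool)
    labels = np.zeros(shape, dtype=np.int32)

    def span(center: int, width: int) -> slice:
        lo = center - width // 2
        return slice(lo, lo + width)

    ys = span(ny // 2, cross_section)
    zs = span(nz // 2, cross_section)

    def place_parcel(region: tuple, label: int) -> None:
        if (labels[region] != 0).any():
            raise ValueError("overlapping parcels")
        labels[region] = label

    if kind in ("straight", "gap", "curved"):
        wm[1:nx - 1, ys, zs] = True
        fa[wm] = bundle_fa
        if kind == "gap":
            mid = nx // 2
            fa[mid, ys, zs] = gap_fa
        if kind == "curved":
            half = np.deg2rad(turn_deg) / 2.0
            for x in range(1, nx - 1):
                theta = half if x % 2 == 0 else -half
                direction[x, ys, zs] = (math.cos(theta), math.sin(theta), 0.0)
        else:
            direction[wm] = (1.0, 0.0, 0.0)
        place_parcel((0, ys, zs), 1)
        place_parcel((nx - 1, ys, zs), 2)
    else:  # crossing
        z_a = span(nz // 4, cross_section)
        z_b = span(3 * nz // 4, cross_section)
        xs = span(nx // 2, cross_section)
        wm[1:nx - 1, ys, z_a] = True
        wm[xs, 1:ny - 1, z_b] = True
        fa[wm] = bundle_fa
        direction[1:nx - 1, ys, z_a] = (1.0, 0.0, 0.0)
        direction[xs, 1:ny - 1, z_b] = (0.0, 1.0, 0.0)
        place_parcel((0, ys, z_a), 1)
        place_parcel((nx - 1, ys, z_a), 2)
        place_parcel((xs, 0, z_b), 3)
        place_parcel((xs, ny - 1, z_b), 4)

    # parcels are endpoints, not tracking tissue
    wm &= labels == 0
    return Phantom(fa=fa, direction=direction, wm_mask=wm, labels=labels)
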