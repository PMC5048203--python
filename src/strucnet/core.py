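"""Shared domain types for structural connectome analysis.

The node schema follows the FreeSurfer whole-brain parcellation commonly
used in structural connectomics: 34 Desikan-Killiany cortical regions per
hemisphere (68 cortical nodes), 7 subcortical gray-matter structures per
hemisphere (14 nodes) and the brainstem, for 83 nodes in total. Every
subject's connectome is an undirected graph over this fixed node set whose
edge weights are streamline counts (NOS, number of streamlines).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "NodeSchema",
    "SubjectConnectome",
    "GroupStudy",
    "EdgeStatMap",
    "NBSComponent",
    "NBSResult",
    "GraphMetricSet",
    "Phantom",
    "Streamline",
    "default_schema",
    "read_connectome",
    "write_connectome",
    "read_schema",
    "write_schema",
]

# Desikan-Killiany cortical parcels (FreeSurfer aparc), 34 per hemisphere.
_DK_CORTICAL = [
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "frontalpole", "fusiform", "inferiorparietal",
    "inferiortemporal", "insula", "isthmuscingulate", "lateraloccipital",
    "lateralorbitofrontal", "lingual", "medialorbitofrontal",
    "middletemporal", "paracentral", "parahippocampal", "parsopercularis",
    "parsorbitalis", "parstriangularis", "pericalcarine", "postcentral",
    "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal", "temporalpole",
    "transversetemporal",
]

# FreeSurfer aseg subcortical gray structures, 7 per hemisphere.
_SUBCORTICAL = [
    "thalamus", "caudate", "putamen", "pallidum", "hippocampus", "amygdala",
    "accumbens",
]

HEMISPHERES = ("left", "right", "midline")
NODE_KINDS = ("cortical", "subcortical", "brainstem")


@dataclass(frozen=True)
class NodeSchema:
    """Fixed, ordered node set shared by every connectome in a study.

    Node order is defined by this schema and never inferred from matrix
    headers: permutation tests require stable subject-to-subject alignment.
    """

    node_ids: tuple[str, ...]
    names: tuple[str, ...]
    hemisphere: tuple[str, ...]
    kind: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.node_ids)
        if not (len(self.names) == len(self.hemisphere) == len(self.kind) == n):
            raise ValueError("schema columns must have equal length")
        if len(set(self.node_ids)) != n:
            raise ValueError("node_ids must be unique")
        for h in self.hemisphere:
            if h not in HEMISPHERES:
                raise ValueError(f"invalid hemisphere {h!r}")
        for k in self.kind:
            if k not in NODE_KINDS:
                raise ValueError(f"invalid node kind {k!r}")

    def __len__(self) -> int:
        return len(self.node_ids)

    def index(self, node_id: str) -> int:
        return self.node_ids.index(node_id)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.node_ids,
                "name": self.names,
                "hemisphere": self.hemisphere,
                "kind": self.kind,
            }
        )


def default_schema() -> NodeSchema:
    """The 83-node whole-brain schema: 68 cortical, 14 subcortical, brainstem."""
    ids, names, hemis, kinds = [], [], [], []
    for hemi, prefix in (("left", "lh"), ("right", "rh")):
        for region in _DK_CORTICAL:
            ids.append(f"{prefix}.{region}")
            names.append(f"{'L' if hemi == 'left' else 'R'} {region}")
            hemis.append(hemi)
            kinds.append("cortical")
    for hemi, prefix in (("left", "lh"), ("right", "rh")):
        for region in _SUBCORTICAL:
            ids.append(f"{prefix}.{region}")
            names.append(f"{'L' if hemi == 'left' else 'R'} {region}")
            hemis.append(hemi)
            kinds.append("subcortical")
    ids.append("brainstem")
    names.append("brainstem")
    hemis.append("midline")
    kinds.append("brainstem")
    return NodeSchema(tuple(ids), tuple(names), tuple(hemis), tuple(kinds))


def generic_schema(n_nodes: int) -> NodeSchema:
    """Minimal schema for synthetic studies at arbitrary size.

    The first half of the nodes is labeled left, the second half right
    (odd node out goes midline), so hemisphere-aware generators work at
    any size. Kinds are all cortical except a midline node.
    """
    if n_nodes == 83:
        return default_schema()
    ids = tuple(f"n{i:03d}" for i in range(n_nodes))
    half = n_nodes // 2
    hemis = tuple(
        "left" if i < half else ("right" if i < 2 * half else "midline")
        for i in range(n_nodes)
    )
    kinds = tuple("cortical" if h != "midline" else "brainstem" for h in hemis)
    return NodeSchema(ids, ids, hemis, kinds)


def _validate_weights(weights: np.ndarray, n: int) -> np.ndarray:
    w = np.asarray(weights)
    if w.shape != (n, n):
        raise ValueError(f"weights must be {n}x{n}, got {w.shape}")
    if np.issubdtype(w.dtype, np.floating):
        if not np.allclose(w, np.round(w)):
            raise ValueError("NOS weights must be integer-valued")
        w = np.round(w)
    w = w.astype(np.int64)
    if (w < 0).any():
        raise ValueError("NOS weights must be nonnegative")
    if not np.array_equal(w, w.T):
        raise ValueError("weights must be symmetric")
    if np.diagonal(w).any():
        raise ValueError("diagonal must be zero")
    return w


@dataclass
class SubjectConnectome:
    """One participant's undirected NOS-weighted graph over a fixed schema."""

    schema: NodeSchema
    weights: np.ndarray
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        self.weights = _validate_weights(self.weights, len(self.schema))

    @property
    def n_nodes(self) -> int:
        return len(self.schema)

    def copy(self) -> "SubjectConnectome":
        return SubjectConnectome(self.schema, self.weights.copy(), self.subject_id)


@dataclass
class GroupStudy:
    """Two cohorts of connectomes plus optional clinical/volume side tables.

    ``group_a`` is the case group (e.g. patients) and ``group_b`` the
    control group. ``clinical`` rows align one-to-one with ``group_a``
    subjects by subject_id; ``volumes`` covers all subjects; ``medicated``
    flags group_a subjects.
    """

    group_a: list[SubjectConnectome]
    group_b: list[SubjectConnectome]
    clinical: pd.DataFrame | None = None
    volumes: pd.DataFrame | None = None
    medicated: dict[str, bool] | None = None

    def __post_init__(self) -> None:
        if not self.group_a or not self.group_b:
            raise ValueError("both groups must be nonempty")
        schema = self.group_a[0].schema
        for c in self.group_a + self.group_b:
            if c.schema.node_ids != schema.node_ids:
                raise ValueError("all connectomes must share one schema")
        ids = [c.subject_id for c in self.group_a + self.group_b]
        if len(set(ids)) != len(ids):
            raise ValueError("subject ids must be unique across the study")
        if self.clinical is not None:
            a_ids = {c.subject_id for c in self.group_a}
            if set(self.clinical["subject_id"]) != a_ids:
                raise ValueError("clinical rows must map 1:1 to group_a subjects")

    @property
    def schema(self) -> NodeSchema:
        return self.group_a[0].schema

    @property
    def n_a(self) -> int:
        return len(self.group_a)

    @property
    def n_b(self) -> int:
        return len(self.group_b)

    def stacked(self) -> tuple[np.ndarray, np.ndarray]:
        """Weights as (n_a, N, N) and (n_b, N, N) arrays."""
        a = np.stack([c.weights for c in self.group_a])
        b = np.stack([c.weights for c in self.group_b])
        return a, b


@dataclass
class EdgeStatMap:
    """Edge-wise two-sample t statistics on the kept edge set.

    ``t`` is symmetric; entries outside the group mask carry NaN and are
    flagged absent in ``defined``.
    """

    schema: NodeSchema
    t: np.ndarray
    df: int
    direction: str  # "a_gt_b" or "b_gt_a"

    def __post_init__(self) -> None:
        if self.direction not in ("a_gt_b", "b_gt_a"):
            raise ValueError(f"invalid direction {self.direction!r}")
        t = np.asarray(self.t, dtype=float)
        n = len(self.schema)
        if t.shape != (n, n):
            raise ValueError("t matrix shape mismatch")
        if not np.array_equal(np.isnan(t), np.isnan(t.T)):
            raise ValueError("t definedness must be symmetric")
        finite = ~np.isnan(t)
        if not np.allclose(t[finite], t.T[finite]):
            raise ValueError("t must be symmetric")
        self.t = t

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.t)


@dataclass
class NBSComponent:
    """A connected suprathreshold subnetwork with its permutation p-value."""

    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]
    size: int
    p_fwer: float

    def __post_init__(self) -> None:
        if self.size != len(self.edges):
            raise ValueError("size must equal the edge count")
        if not (0.0 < self.p_fwer <= 1.0):
            raise ValueError("p_fwer must lie in (0, 1]")


@dataclass
class NBSResult:
    """All suprathreshold components plus the permutation null distribution."""

    components: list[NBSComponent]
    primary_p: float
    t_threshold: float
    n_perm: int
    alpha: float
    seed: int
    null_max_sizes: np.ndarray
    direction: str = "b_gt_a"

    def __post_init__(self) -> None:
        sizes = [c.size for c in self.components]
        if sizes != sorted(sizes, reverse=True):
            raise ValueError("components must be sorted by size descending")

    @property
    def significant(self) -> list[NBSComponent]:
        return [c for c in self.components if c.p_fwer < self.alpha]


@dataclass
class GraphMetricSet:
    """Nodal and global weighted metrics for one connectome.

    gamma and lam are the small-world normalizations: observed global
    clustering / path length divided by their means over degree-matched
    random networks; NaN until normalization has been run.
    """

    nodal_strength: np.ndarray
    nodal_clustering: np.ndarray
    nodal_path_length: np.ndarray
    global_strength: float
    total_fibers: float
    gamma: float = float("nan")
    lam: float = float("nan")


@dataclass
class Phantom:
    """Synthetic tensor-derived volumes for tractography testing.

    All coordinates are 0-based voxel indices; streamline points live in
    continuous voxel space with voxel centers at integer coordinates.
    Parcels (nonzero labels) are streamline endpoints: they sit outside or
    adjacent to the white-matter mask.
    """

    fa: np.ndarray
    direction: np.ndarray  # (X, Y, Z, 3) unit vectors inside wm_mask
    wm_mask: np.ndarray
    labels: np.ndarray
    voxel_size: float = 2.0

    def __post_init__(self) -> None:
        if self.fa.ndim != 3 or self.direction.shape != self.fa.shape + (3,):
            raise ValueError("direction must be fa.shape + (3,)")
        if self.wm_mask.shape != self.fa.shape or self.labels.shape != self.fa.shape:
            raise ValueError("volume shapes must agree")
        if ((self.fa < 0) | (self.fa > 1)).any():
            raise ValueError("FA must lie in [0, 1]")
        norms = np.linalg.norm(self.direction[self.wm_mask.astype(bool)], axis=-1)
        if norms.size and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("direction vectors must be unit-norm inside the mask")


@dataclass
class Streamline:
    """An ordered polyline in continuous voxel space with termination info."""

    points: np.ndarray  # (n_points, 3)
    termination_reason: tuple[str, str]  # one reason per end
    end_labels: tuple[int, int] = (0, 0)  # parcel id reached at each end, 0 = none

    VALID_REASONS = ("low_fa", "angle", "mask_exit", "reached_label")

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be (n, 3)")
        if len(self.points) < 1:
            raise ValueError("streamline must contain at least one point")
        if len(self.points) > 1:
            if (np.diff(self.points, axis=0) == 0).all(axis=1).any():
                raise ValueError("consecutive points must differ")
        for r in self.termination_reason:
            if r not in self.VALID_REASONS:
                raise ValueError(f"invalid termination reason {r!r}")

    def __len__(self) -> int:
        return len(self.points)


# ---------------------------------------------------------------------------
# External interfaces: delimited text formats
# ---------------------------------------------------------------------------

def write_connectome(connectome: SubjectConnectome, path: str | Path) -> None:
    """Write a connectome as tab-delimited text with a node_id header row."""
    df = pd.DataFrame(connectome.weights, columns=list(connectome.schema.node_ids))
    df.to_csv(path, sep="\t", index=False)


def read_connectome(
    path: str | Path, schema: NodeSchema, subject_id: str | None = None
) -> SubjectConnectome:
    """Read a tab-delimited connectome, checking the header against the schema."""
    df = pd.read_csv(path, sep="\t")
    if tuple(df.columns) != schema.node_ids:
        raise ValueError(f"{path}: header does not match the node schema")
    sid = subject_id if subject_id is not None else Path(path).stem
    return SubjectConnectome(schema, df.to_numpy(), subject_id=sid)


def write_schema(schema: NodeSchema, path: str | Path) -> None:
    schema.to_frame().to_csv(path, sep="\t", index=False)


def read_schema(path: str | Path) -> NodeSchema:
    df = pd.read_csv(path, sep="\t")
    return NodeSchema(
        tuple(df["id"]), tuple(df["name"]), tuple(df["hemisphere"]), tuple(df["kind"])
    )
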