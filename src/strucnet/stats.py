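"""Permutation group comparison, FDR correction, and clinical correlations.

Group differences in graph metrics and nodal volumes are tested with
label-permutation tests on the difference of group means (two-sided by
default), corrected within each metric family across nodes by
Benjamini-Hochberg FDR. Global metrics are single tests without
correction. Clinical-score correlations (Pearson by default, Spearman by
flag) are FDR-corrected across all (feature, score) pairs.
"""

from __future__ import annotations

import math
import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core import GraphMetricSet, GroupStudy, NodeSchema
from .graphs import group_threshold

__all__ = [
    "perm_test_mean_diff",
    "perm_test_table",
    "fdr_bh",
    "compare_nodal_metrics",
    "compare_volumes",
    "correlate_clinical",
    "subgroup_comparison",
]

GLOBAL_METRICS = ("global_strength", "total_fibers", "gamma", "lambda")
NODAL_FAMILIES = ("nodal_strength", "nodal_clustering", "nodal_path_length")


def perm_test_mean_diff(
    values_a: np.ndarray,
    values_b: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
    sides: str = "two",
) -> float:
    """Permutation p-value for the difference of group means.

    Monte-Carlo estimate p = (1 + #{|perm diff| >= |observed|}) /
    (1 + n_perm); when the number of distinct relabelings is at most
    n_perm the exact enumeration p is returned instead.
    """
    if sides not in ("two", "greater", "less"):
        raise ValueError(f"invalid sides {sides!r}")
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")
    pooled = np.concatenate([a, b])
    n, n_a = len(pooled), len(a)
    obs = a.mean() - b.mean()

    def extreme(diff: np.ndarray) -> np.ndarray:
        if sides == "two":
            return np.abs(diff) >= abs(obs) - 1e-12
        if sides == "greater":
            return diff >= obs - 1e-12
        return diff <= obs + 1e-12

    total = math.comb(n, n_a)
    scale = n / (n_a * (n - n_a))  # mean_a - mean_b = scale*sum_a - tot/(n-n_a)
    tot = pooled.sum()
    if total <= n_perm:
        sums = np.array(
            [pooled[list(c)].sum() for c in combinations(range(n), n_a)]
        )
        diffs = sums * scale - tot / (n - n_a)
        return float(extreme(diffs).sum() / total)
    rng = np.random.default_rng(seed)
    perm = np.array([rng.permutation(n)[:n_a] for _ in range(n_perm)])
    sums = pooled[perm].sum(axis=1)
    diffs = sums * scale - tot / (n - n_a)
    return float((1 + extreme(diffs).sum()) / (1 + n_perm))


def perm_test_table(
    a: np.ndarray,
    b: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
) -> np.ndarray:
    """Two-sided mean-difference permutation p per column, shared perms.

    ``a`` is (n_a, m) and ``b`` (n_b, m); one set of label permutations
    is reused across all m features.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    n, n_a = len(pooled), len(a)
    obs = a.mean(axis=0) - b.mean(axis=0)
    scale = n / (n_a * (n - n_a))
    tot = pooled.sum(axis=0)
    rng = np.random.default_rng(seed)
    count = np.zeros(a.shape[1], dtype=np.int64)
    block = max(1, min(n_perm, 2_000_000 // max(a.shape[1], 1)))
    done = 0
    while done < n_perm:
        k = min(block, n_perm - done)
        sel = np.zeros((k, n), dtype=bool)
        for i in range(k):
            sel[i, rng.choice(n, size=n_a, replace=False)] = True
        sums = sel.astype(float) @ pooled
        diffs = sums * scale - tot / (n - n_a)
        count += (np.abs(diffs) >= np.abs(obs) - 1e-12).sum(axis=0)
        done += k
    return (1 + count) / (1 + n_perm)


def fdr_bh(
    p_values: np.ndarray, q: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (rejection flags, adjusted p-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def _metric_matrix(sets: list[GraphMetricSet], family: str) -> np.ndarray:
    return np.stack([getattr(ms, family) for ms in sets])


def compare_nodal_metrics(
    schema: NodeSchema,
    metrics_a: list[GraphMetricSet],
    metrics_b: list[GraphMetricSet],
    n_perm: int = 10_000,
    q: float = 0.05,
    seed: int = 0,
    fdr_family: str = "per_metric",
) -> pd.DataFrame:
    """Permutation comparison of every (node, metric) plus global metrics.

    One two-sided permutation test per node and metric family. FDR is
    applied within each metric family across nodes (``fdr_family=
    'per_metric'``, the default) or pooled over all nodal tests
    (``fdr_family='all'``); the four global metrics are standalone tests
    without correction.
    """
    if not metrics_a or not metrics_b:
        raise ValueError("both metric lists must be nonempty")
    if fdr_family not in ("per_metric", "all"):
        raise ValueError(f"invalid fdr_family {fdr_family!r}")
    rows = []
    rng = np.random.default_rng(seed)
    for family in NODAL_FAMILIES:
        a = _metric_matrix(metrics_a, family)
        b = _metric_matrix(metrics_b, family)
        if a.shape[1] != len(schema) or b.shape[1] != len(schema):
            raise ValueError("metric vectors do not match the schema size")
        p = perm_test_table(a, b, n_perm=n_perm, seed=int(rng.integers(2**31 - 1)))
        for i, nid in enumerate(schema.node_ids):
            rows.append(
                {
                    "feature": f"{family}:{nid}",
                    "family": family,
                    "node_id": nid,
                    "mean_a": a[:, i].mean(),
                    "mean_b": b[:, i].mean(),
                    "p_perm": p[i],
                }
            )
    nodal = pd.DataFrame(rows)
    if fdr_family == "all":
        flags, p_adj = fdr_bh(nodal["p_perm"].to_numpy(), q=q)
        nodal["p_fdr"] = p_adj
        nodal["p_fdr_pass"] = flags
    else:
        nodal["p_fdr"] = np.nan
        nodal["p_fdr_pass"] = False
        for family in NODAL_FAMILIES:
            sel = nodal["family"] == family
            flags, p_adj = fdr_bh(nodal.loc[sel, "p_perm"].to_numpy(), q=q)
            nodal.loc[sel, "p_fdr"] = p_adj
            nodal.loc[sel, "p_fdr_pass"] = flags
    rows = nodal.to_dict("records")
    attr = {"global_strength": "global_strength", "total_fibers": "total_fibers",
            "gamma": "gamma", "lambda": "lam"}
    for name in GLOBAL_METRICS:
        a = np.array([getattr(ms, attr[name]) for ms in metrics_a])
        b = np.array([getattr(ms, attr[name]) for ms in metrics_b])
        if np.isnan(a).all() or np.isnan(b).all():
            continue
        p = perm_test_mean_diff(
            a, b, n_perm=n_perm, seed=int(rng.integers(2**31 - 1))
        )
        rows.append(
            {
                "feature": name,
                "family": "global",
                "node_id": "",
                "mean_a": a.mean(),
                "mean_b": b.mean(),
                "p_perm": p,
                "p_fdr": p,
                "p_fdr_pass": bool(p < q),
            }
        )
    return pd.DataFrame(rows)


def compare_volumes(
    volumes_a: pd.DataFrame | np.ndarray,
    volumes_b: pd.DataFrame | np.ndarray,
    n_perm: int = 10_000,
    q: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation comparison of per-node volumes with FDR across nodes.

    Rows are subjects, columns nodes (mm^3). This is the control analysis
    ruling out nodal-volume differences as the driver of NOS findings.
    """
    if isinstance(volumes_a, pd.DataFrame):
        cols = list(volumes_a.columns)
        a = volumes_a.to_numpy(dtype=float)
        b = volumes_b[cols].to_numpy(dtype=float)
    else:
        a = np.asarray(volumes_a, dtype=float)
        b = np.asarray(volumes_b, dtype=float)
        cols = [f"node{i}" for i in range(a.shape[1])]
    if a.shape[1] != b.shape[1]:
        raise ValueError("volume tables must share the node columns")
    p = perm_test_table(a, b, n_perm=n_perm, seed=seed)
    flags, p_adj = fdr_bh(p, q=q)
    return pd.DataFrame(
        {
            "feature": [f"volume:{c}" for c in cols],
            "family": "volume",
            "node_id": cols,
            "mean_a": a.mean(axis=0),
            "mean_b": b.mean(axis=0),
            "p_perm": p,
            "p_fdr": p_adj,
            "p_fdr_pass": flags,
        }
    )


def correlate_clinical(
    features: pd.DataFrame,
    scores: pd.DataFrame,
    method: str = "pearson",
    q: float = 0.05,
) -> pd.DataFrame:
    """Correlate network features with clinical scores, FDR over all pairs.

    ``features`` and ``scores`` must be row-aligned on the same subjects
    (a shared ``subject_id`` column is used for alignment when present).
    Zero-variance features are skipped with a warning.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"invalid method {method!r}")
    if "subject_id" in features.columns and "subject_id" in scores.columns:
        scores = (
            scores.set_index("subject_id")
            .loc[features["subject_id"]]
            .reset_index(drop=True)
        )
        features = features.drop(columns="subject_id")
    if len(features) != len(scores):
        raise ValueError("features and scores must align on the same subjects")
    corr = sps.pearsonr if method == "pearson" else sps.spearmanr
    rows = []
    for f in features.columns:
        x = features[f].to_numpy(dtype=float)
        if x.std() == 0:
            warnings.warn(f"feature {f!r} has zero variance; skipped", stacklevel=2)
            continue
        for s in scores.columns:
            y = scores[s].to_numpy(dtype=float)
            if y.std() == 0:
                r, p = 0.0, 1.0
            else:
                res = corr(x, y)
                r, p = float(res[0]), float(res[1])
            rows.append({"feature": f, "score": s, "r": r, "p": max(p, 1e-300)})
    table = pd.DataFrame(rows)
    if len(table):
        flags, p_adj = fdr_bh(table["p"].to_numpy(), q=q)
        table["p_fdr"] = p_adj
        table["p_fdr_pass"] = flags
    return table


def subgroup_comparison(
    study: GroupStudy,
    flag: str = "medicated",
    proportion: float = 0.6,
    primary_p: float = 0.01,
    n_perm_nbs: int = 5000,
    alpha: float = 0.05,
    direction: str = "b_gt_a",
    seed: int = 0,
    metric_fn=None,
    n_perm_stats: int = 10_000,
    q: float = 0.05,
):
    """Re-run NBS (and optionally metric comparison) on a case subgroup.

    Restricts group_a to flagged subjects (all of group_b retained),
    re-applies the group threshold, and re-runs the NBS. If ``metric_fn``
    (a callable connectome -> GraphMetricSet) is given, the nodal metric
    comparison is re-run as well. Used to check whether effects grow or
    shrink in the flagged subgroup (e.g. medicated cases).
    """
    from .nbs import nbs_test  # local import avoids a cycle

    if flag != "medicated":
        raise ValueError("only the 'medicated' flag is supported")
    if study.medicated is None:
        raise ValueError("study has no medicated flags")
    sub_a = [c for c in study.group_a if study.medicated.get(c.subject_id)]
    if len(sub_a) < 3:
        raise ValueError(f"subgroup has {len(sub_a)} subjects; need at least 3")
    sub_study = GroupStudy(group_a=sub_a, group_b=list(study.group_b))
    masked, mask = group_threshold(sub_study, proportion)
    nbs_result = nbs_test(
        masked,
        mask,
        primary_p=primary_p,
        n_perm=n_perm_nbs,
        alpha=alpha,
        direction=direction,
        seed=seed,
    )
    out = {"study": masked, "mask": mask, "nbs": nbs_result, "metrics": None}
    if metric_fn is not None:
        m_a = [metric_fn(c) for c in masked.group_a]
        m_b = [metric_fn(c) for c in masked.group_b]
        out["metrics"] = compare_nodal_metrics(
            study.schema, m_a, m_b, n_perm=n_perm_stats, q=q, seed=seed
        )
    return out
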