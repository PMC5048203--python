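"""End-to-end orchestration: configuration, stage sequencing, reporting.

The pipeline runs the full analysis in method order: per-subject edge
pruning, two-step group thresholding, NBS in both contrast directions,
per-subject graph metrics with null-model normalization, permutation
group comparison of metrics (and of nodal volumes when provided),
clinical correlations on the significant network features, an optional
medicated-subgroup re-analysis, and a threshold-sweep stability report.
All stage seeds derive deterministically from one top-level seed, so a
run is reproducible bit-for-bit from its config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (
    GroupStudy,
    NodeSchema,
    SubjectConnectome,
    generic_schema,
    read_connectome,
    write_connectome,
)
from .graphs import DEFAULT_SWEEP, density, group_threshold, prune_spurious, threshold_sweep
from .metrics import compute_metrics
from .nbs import nbs_test
from .stats import (
    compare_nodal_metrics,
    compare_volumes,
    correlate_clinical,
    subgroup_comparison,
)

logger = logging.getLogger("strucnet")

__all__ = ["PipelineConfig", "run_pipeline", "write_report", "load_cohort", "save_cohort"]


@dataclass
class PipelineConfig:
    """All pipeline settings; defaults are the reference study design."""

    input_dir: str = "."
    output_dir: str = "results"
    min_nos: int = 2
    tau: float = 0.6
    sweep: tuple = tuple(float(t) for t in DEFAULT_SWEEP)
    nbs_primary_p: float = 0.01
    nbs_n_perm: int = 5000
    nbs_alpha: float = 0.05
    nbs_directions: tuple = ("b_gt_a", "a_gt_b")
    metrics_n_random: int = 1000
    metrics_swaps_per_edge: int = 10
    stats_n_perm: int = 10_000
    stats_q: float = 0.05
    correlation_method: str = "pearson"
    run_sweep: bool = True
    run_subgroup: bool = True
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["sweep"] = list(self.sweep)
        d["nbs_directions"] = list(self.nbs_directions)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["sweep"] = tuple(d.get("sweep", cls.sweep))
        d["nbs_directions"] = tuple(d.get("nbs_directions", cls.nbs_directions))
        return cls(**d)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent stage seeds below 2^31 from one top-level seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


# ---------------------------------------------------------------------------
# Cohort directory IO: one TSV matrix per subject + manifest + side tables
# ---------------------------------------------------------------------------

def save_cohort(study: GroupStudy, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from .core import write_schema

    write_schema(study.schema, out / "schema.tsv")
    rows = []
    for grp, members in (("a", study.group_a), ("b", study.group_b)):
        for c in members:
            write_connectome(c, out / f"{c.subject_id}.tsv")
            med = bool(study.medicated.get(c.subject_id)) if study.medicated else False
            rows.append({"subject_id": c.subject_id, "group": grp, "medicated": med})
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    if study.clinical is not None:
        study.clinical.to_csv(out / "clinical.csv", index=False)
    if study.volumes is not None:
        study.volumes.to_csv(out / "volumes.csv", index=False)


def load_cohort(in_dir: str | Path, schema: NodeSchema | None = None) -> GroupStudy:
    src = Path(in_dir)
    if schema is None:
        from .core import read_schema

        schema_path = src / "schema.tsv"
        if schema_path.exists():
            schema = read_schema(schema_path)
        else:
            first = pd.read_csv(src / "manifest.csv").iloc[0]["subject_id"]
            n = len(pd.read_csv(src / f"{first}.tsv", sep="\t").columns)
            schema = generic_schema(n)
    manifest = pd.read_csv(src / "manifest.csv")
    groups: dict[str, list[SubjectConnectome]] = {"a": [], "b": []}
    medicated = {}
    for _, row in manifest.iterrows():
        c = read_connectome(src / f"{row.subject_id}.tsv", schema, row.subject_id)
        groups[row.group].append(c)
        if "medicated" in manifest.columns and row.group == "a":
            medicated[row.subject_id] = bool(row.medicated)
    clinical = volumes = None
    if (src / "clinical.csv").exists():
        clinical = pd.read_csv(src / "clinical.csv")
    if (src / "volumes.csv").exists():
        volumes = pd.read_csv(src / "volumes.csv")
    return GroupStudy(
        group_a=groups["a"],
        group_b=groups["b"],
        clinical=clinical,
        volumes=volumes,
        medicated=medicated or None,
    )


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _edge_nos_features(study: GroupStudy, components) -> pd.DataFrame:
    """Per-case NOS of every edge in the significant components."""
    idx = {nid: i for i, nid in enumerate(study.schema.node_ids)}
    cols = {"subject_id": [c.subject_id for c in study.group_a]}
    for comp in components:
        for u, v in sorted(comp.edges):
            cols[f"nos:{u}|{v}"] = [c.weights[idx[u], idx[v]] for c in study.group_a]
    return pd.DataFrame(cols)


def run_pipeline(config: PipelineConfig, study: GroupStudy | None = None) -> dict:
    """Execute every stage and return the result bundle.

    ``study`` overrides loading from ``config.input_dir``. Any stage
    failure is re-raised annotated with the stage name.
    """
    seeds = _stage_seeds(config.seed, 8)
    bundle: dict = {
        "config": config,
        "provenance": {
            "config_digest": config.digest(),
            "seed": config.seed,
            "version": __version__,
        },
        "log": [],
    }

    def stage(name: str, fn):
        logger.info("stage %s: start", name)
        try:
            result = fn()
        except Exception as exc:  # annotate failures with the stage name
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        bundle["log"].append({"stage": name})
        return result

    if study is None:
        study = stage("load", lambda: load_cohort(config.input_dir))

    pruned = stage(
        "prune",
        lambda: GroupStudy(
            group_a=[prune_spurious(c, config.min_nos) for c in study.group_a],
            group_b=[prune_spurious(c, config.min_nos) for c in study.group_b],
            clinical=study.clinical,
            volumes=study.volumes,
            medicated=study.medicated,
        ),
    )
    masked, mask = stage(
        "threshold", lambda: group_threshold(pruned, config.tau, mode="two_step")
    )
    bundle["mask"] = mask
    bundle["study"] = masked
    bundle["log"][-1]["edges_kept"] = mask.n_edges
    bundle["log"][-1]["density"] = density(mask)

    bundle["nbs"] = {}
    for k, direction in enumerate(config.nbs_directions):
        res = stage(
            f"nbs_{direction}",
            lambda d=direction, s=seeds[0] + k: nbs_test(
                masked,
                mask,
                primary_p=config.nbs_primary_p,
                n_perm=config.nbs_n_perm,
                alpha=config.nbs_alpha,
                direction=d,
                seed=s,
            ),
        )
        bundle["nbs"][direction] = res
        bundle["log"][-1]["components"] = len(res.components)

    def compute_all_metrics():
        out = {}
        for grp, members in (("a", masked.group_a), ("b", masked.group_b)):
            out[grp] = [
                compute_metrics(
                    c,
                    n_random=config.metrics_n_random,
                    seed=seeds[1] + i,
                    swaps_per_edge=config.metrics_swaps_per_edge,
                )
                for i, c in enumerate(members)
            ]
        return out

    metric_sets = stage("metrics", compute_all_metrics)
    bundle["metrics"] = metric_sets

    bundle["comparison"] = stage(
        "compare_metrics",
        lambda: compare_nodal_metrics(
            masked.schema,
            metric_sets["a"],
            metric_sets["b"],
            n_perm=config.stats_n_perm,
            q=config.stats_q,
            seed=seeds[2],
        ),
    )

    if study.volumes is not None:
        ids_a = {c.subject_id for c in study.group_a}
        vols = study.volumes
        va = vols[vols.subject_id.isin(ids_a)].drop(columns="subject_id")
        vb = vols[~vols.subject_id.isin(ids_a)].drop(columns="subject_id")
        bundle["volume_comparison"] = stage(
            "compare_volumes",
            lambda: compare_volumes(
                va, vb, n_perm=config.stats_n_perm, q=config.stats_q, seed=seeds[3]
            ),
        )

    if study.clinical is not None:
        primary = config.nbs_directions[0]
        sig = bundle["nbs"][primary].significant
        features = _edge_nos_features(masked, sig)
        comp = bundle["comparison"]
        sig_rows = comp[comp.p_fdr_pass]
        for _, row in sig_rows.iterrows():
            if row.family == "global":
                vals = [getattr(ms, "lam" if row.feature == "lambda" else row.feature)
                        for ms in metric_sets["a"]]
            else:
                i = masked.schema.index(row.node_id)
                vals = [getattr(ms, row.family)[i] for ms in metric_sets["a"]]
            features[row.feature] = vals
        if features.shape[1] > 1:
            bundle["correlations"] = stage(
                "correlate",
                lambda: correlate_clinical(
                    features,
                    study.clinical,
                    method=config.correlation_method,
                    q=config.stats_q,
                ),
            )

    n_flagged = sum(bool(v) for v in (study.medicated or {}).values())
    if config.run_subgroup and 3 <= n_flagged < study.n_a:
        bundle["subgroup"] = stage(
            "subgroup",
            lambda: subgroup_comparison(
                pruned,
                proportion=config.tau,
                primary_p=config.nbs_primary_p,
                n_perm_nbs=config.nbs_n_perm,
                alpha=config.nbs_alpha,
                direction=config.nbs_directions[0],
                seed=seeds[4],
            ),
        )

    if config.run_sweep:
        def sweep_fn():
            rows = []
            for k, (tau, swept, smask) in enumerate(
                threshold_sweep(pruned, tuple(config.sweep))
            ):
                res = nbs_test(
                    swept,
                    smask,
                    primary_p=config.nbs_primary_p,
                    n_perm=config.nbs_n_perm,
                    alpha=config.nbs_alpha,
                    direction=config.nbs_directions[0],
                    seed=seeds[5] + k,
                )
                largest = res.components[0] if res.components else None
                rows.append(
                    {
                        "tau": tau,
                        "edges_kept": smask.n_edges,
                        "density": density(smask),
                        "largest_component_size": largest.size if largest else 0,
                        "largest_component_p": largest.p_fwer if largest else np.nan,
                        "n_significant": len(res.significant),
                    }
                )
            return pd.DataFrame(rows)

        bundle["sweep"] = stage("sweep", sweep_fn)

    bundle["report"] = write_report(bundle)
    return bundle


def _nbs_section(lines: list[str], study: GroupStudy, result, direction: str) -> None:
    lines.append(f"NBS contrast {direction}: {len(result.components)} component(s), "
                 f"t threshold {result.t_threshold:.3f}, {result.n_perm} permutations")
    sig = result.significant
    if not sig:
        lines.append("  no significant component")
        return
    idx = {nid: i for i, nid in enumerate(study.schema.node_ids)}
    a, b = study.stacked()
    for comp in sig:
        lines.append(
            f"  component: {comp.size} edges over {len(comp.nodes)} nodes, "
            f"p_fwer = {comp.p_fwer:.4f}"
        )
        lines.append("    edge\tmean_a±sd\tmean_b±sd\tt")
        for u, v in sorted(comp.edges):
            i, j = idx[u], idx[v]
            va, vb = a[:, i, j], b[:, i, j]
            t_num = (vb.mean() - va.mean()) if direction == "b_gt_a" else (
                va.mean() - vb.mean()
            )
            na, nb = len(va), len(vb)
            sp2 = (va.var(ddof=1) * (na - 1) + vb.var(ddof=1) * (nb - 1)) / (na + nb - 2)
            t = t_num / np.sqrt(sp2 * (1 / na + 1 / nb)) if sp2 > 0 else 0.0
            lines.append(
                f"    {u}–{v}\t{va.mean():.1f}±{va.std(ddof=1):.1f}"
                f"\t{vb.mean():.1f}±{vb.std(ddof=1):.1f}\t{t:.2f}"
            )


def write_report(bundle: dict) -> str:
    """Render the human-readable run summary."""
    config: PipelineConfig = bundle["config"]
    lines = ["strucnet pipeline report", "=" * 40, ""]
    lines.append(f"config digest: {bundle['provenance']['config_digest']}")
    lines.append(f"seed: {config.seed}   version: {bundle['provenance']['version']}")
    lines.append("configuration:")
    for k, v in sorted(asdict(config).items()):
        lines.append(f"  {k}: {v}")
    lines.append("")

    mask = bundle.get("mask")
    if mask is not None:
        lines.append(
            f"group threshold tau={config.tau}: {mask.n_edges} edges kept "
            f"(density {density(mask):.4f})"
        )
        lines.append("")
    for direction, result in bundle.get("nbs", {}).items():
        _nbs_section(lines, bundle["study"], result, direction)
        lines.append("")

    comp = bundle.get("comparison")
    if comp is not None:
        sig = comp[comp.p_fdr_pass]
        lines.append(f"metric comparison: {len(sig)} significant feature(s) "
                     f"(q = {config.stats_q})")
        for _, row in sig.iterrows():
            lines.append(
                f"  {row.feature}: mean_a {row.mean_a:.4g}, mean_b {row.mean_b:.4g}, "
                f"p_perm {row.p_perm:.4f}, p_fdr {row.p_fdr:.4f}"
            )
        lines.append("")

    vols = bundle.get("volume_comparison")
    if vols is not None:
        n_sig = int(vols.p_fdr_pass.sum())
        lines.append(f"nodal volume comparison: {n_sig} significant node(s)")
        lines.append("")

    corr = bundle.get("correlations")
    if corr is not None and len(corr):
        n_sig = int(corr.p_fdr_pass.sum())
        lines.append(f"clinical correlations: {n_sig} significant pair(s) after FDR")
        lines.append("")

    sub = bundle.get("subgroup")
    if sub is not None:
        lines.append("medicated-subgroup NBS:")
        _nbs_section(lines, sub["study"], sub["nbs"], sub["nbs"].direction)
        lines.append("")

    sweep = bundle.get("sweep")
    if sweep is not None:
        lines.append("threshold sweep stability:")
        lines.append(sweep.to_string(index=False))
        lines.append("")
    return "\n".join(lines)


def save_bundle(bundle: dict, out_dir: str | Path) -> None:
    """Write every artifact of a result bundle to disk."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config: PipelineConfig = bundle["config"]
    config.to_yaml(out / "config.yaml")
    with open(out / "provenance.json", "w") as fh:
        json.dump(bundle["provenance"], fh, indent=2, sort_keys=True)
    mask = bundle.get("mask")
    if mask is not None:
        pd.DataFrame(
            mask.keep.astype(int), columns=list(mask.schema.node_ids)
        ).to_csv(out / "mask.tsv", sep="\t", index=False)
    for direction, res in bundle.get("nbs", {}).items():
        payload = {
            "direction": direction,
            "primary_p": res.primary_p,
            "t_threshold": res.t_threshold,
            "n_perm": res.n_perm,
            "alpha": res.alpha,
            "seed": res.seed,
            "components": [
                {
                    "nodes": sorted(c.nodes),
                    "edges": sorted(map(list, c.edges)),
                    "size": c.size,
                    "p_fwer": c.p_fwer,
                }
                for c in res.components
            ],
            "null_max_sizes": np.asarray(res.null_max_sizes).tolist(),
        }
        with open(out / f"nbs_{direction}.json", "w") as fh:
            json.dump(payload, fh, indent=2)
    if bundle.get("comparison") is not None:
        bundle["comparison"].to_csv(out / "comparison.csv", index=False)
    if bundle.get("volume_comparison") is not None:
        bundle["volume_comparison"].to_csv(out / "volume_comparison.csv", index=False)
    if bundle.get("correlations") is not None:
        bundle["correlations"].to_csv(out / "correlations.csv", index=False)
    if bundle.get("sweep") is not None:
        bundle["sweep"].to_csv(out / "sweep.csv", index=False)
    (out / "report.txt").write_text(bundle["report"])
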