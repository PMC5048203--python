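"""Edge pruning and group-level thresholding of connectome cohorts.

Spurious reconstructions are suppressed in two stages. First, per
subject, edges with fewer than ``min_nos`` streamlines are zeroed.
Second, a group threshold keeps only edges present (nonzero) in at least
a proportion tau of subjects — either in two steps (within each group
separately, then across the pooled sample computed on the step-1 output)
or in a single whole-sample step. Presence is defined on edge existence,
never on weight magnitude, and the tau comparison uses exact rational
arithmetic so that boundary cases like exactly 60% are kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .core import GroupStudy, NodeSchema, SubjectConnectome

__all__ = [
    "GroupMask",
    "prune_spurious",
    "group_threshold",
    "threshold_sweep",
    "density",
    "DEFAULT_SWEEP",
]

#: 30% to 90% in 5% increments: the 13-point stability sweep.
DEFAULT_SWEEP = tuple(Fraction(p, 100) for p in range(30, 95, 5))


@dataclass
class GroupMask:
    """The kept edge set produced by group thresholding."""

    schema: NodeSchema
    keep: np.ndarray
    proportion: float
    mode: str  # "two_step" or "whole_sample"

    def __post_init__(self) -> None:
        k = np.asarray(self.keep, dtype=bool)
        if not np.array_equal(k, k.T):
            raise ValueError("keep mask must be symmetric")
        if np.diagonal(k).any():
            raise ValueError("keep mask diagonal must be zero")
        self.keep = k

    @property
    def n_edges(self) -> int:
        return int(self.keep[np.triu_indices(len(self.schema), k=1)].sum())


def prune_spurious(connectome: SubjectConnectome, min_nos: int = 2) -> SubjectConnectome:
    """Zero every edge with a streamline count below ``min_nos``.

    The default removes single-streamline edges; counts equal to
    ``min_nos`` are retained unchanged.
    """
    if min_nos < 1:
        raise ValueError("min_nos must be >= 1")
    w = connectome.weights.copy()
    w[w < min_nos] = 0
    return SubjectConnectome(connectome.schema, w, connectome.subject_id)


def _as_fraction(tau: float | Fraction) -> Fraction:
    if isinstance(tau, Fraction):
        return tau
    # go through the decimal string so 0.6 means exactly 3/5
    return Fraction(repr(float(tau)))


def _presence_keep(stack: np.ndarray, tau: Fraction) -> np.ndarray:
    """Keep mask: edges nonzero in at least tau of the stacked subjects."""
    n_subj = stack.shape[0]
    counts = (stack > 0).sum(axis=0)
    # count / n_subj >= tau  <=>  count * tau.denominator >= tau.numerator * n_subj
    return counts * tau.denominator >= tau.numerator * n_subj


def group_threshold(
    study: GroupStudy,
    proportion: float | Fraction = Fraction(3, 5),
    mode: str = "two_step",
    step2_on: str = "step1",
) -> tuple[GroupStudy, GroupMask]:
    """Apply the group presence threshold, returning the masked study.

    two_step: edges present in fewer than tau of each group's members are
    zeroed within that group; presence is then recomputed over the pooled
    step-1 output (or the raw matrices with ``step2_on='raw'``) and edges
    below tau across the entire sample are zeroed everywhere. The
    returned mask is the final pooled-sample keep set; kept edges retain
    their subject-level weights.
    """
    if mode not in ("two_step", "whole_sample"):
        raise ValueError(f"invalid mode {mode!r}")
    if step2_on not in ("step1", "raw"):
        raise ValueError(f"invalid step2_on {step2_on!r}")
    tau = _as_fraction(proportion)
    if not (0 < tau <= 1):
        raise ValueError("proportion must lie in (0, 1]")
    if study.n_a == 0 or study.n_b == 0:
        raise ValueError("both groups must be nonempty")

    a, b = study.stacked()
    if mode == "two_step":
        keep_a = _presence_keep(a, tau)
        keep_b = _presence_keep(b, tau)
        a1 = a * keep_a
        b1 = b * keep_b
        pooled = (
            np.concatenate([a1, b1]) if step2_on == "step1"
            else np.concatenate([a, b])
        )
        keep = _presence_keep(pooled, tau)
        a_out, b_out = a1 * keep, b1 * keep
    else:
        pooled = np.concatenate([a, b])
        keep = _presence_keep(pooled, tau)
        a_out, b_out = a * keep, b * keep

    np.fill_diagonal(keep, False)
    mask = GroupMask(study.schema, keep, float(tau), mode)
    masked = GroupStudy(
        group_a=[
            SubjectConnectome(study.schema, a_out[i], c.subject_id)
            for i, c in enumerate(study.group_a)
        ],
        group_b=[
            SubjectConnectome(study.schema, b_out[i], c.subject_id)
            for i, c in enumerate(study.group_b)
        ],
        clinical=study.clinical,
        volumes=study.volumes,
        medicated=study.medicated,
    )
    return masked, mask


def threshold_sweep(
    study: GroupStudy,
    proportions: tuple = DEFAULT_SWEEP,
    mode: str = "two_step",
) -> list[tuple[float, GroupStudy, GroupMask]]:
    """Threshold the cohort at every proportion of the stability sweep."""
    out = []
    for tau in proportions:
        masked, mask = group_threshold(study, tau, mode=mode)
        out.append((float(_as_fraction(tau)), masked, mask))
    return out


def density(obj: SubjectConnectome | GroupMask | np.ndarray) -> float:
    """Fraction of possible edges present: nonzero upper triangle / C(N,2)."""
    if isinstance(obj, SubjectConnectome):
        mat = obj.weights
    elif isinstance(obj, GroupMask):
        mat = obj.keep
    else:
        mat = np.asarray(obj)
    n = mat.shape[0]
    if n < 2:
        raise ValueError("density needs at least 2 nodes")
    iu = np.triu_indices(n, k=1)
    return float((mat[iu] != 0).sum() / len(iu[0]))
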