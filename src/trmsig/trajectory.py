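"""Developmental-trajectory scoring against staged reference signatures.

A staged reference (naive plus ordered post-infection timepoints) yields one
differential-expression signature per timepoint versus naive; query groups
are then scored against each timepoint signature with the usual randomized
control, producing a per-group profile over the time course. A group that
completed differentiation rises through the series and stays high at late
timepoints; a group arrested early peaks against early signatures and falls
away from the late ones.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneSignature
from .signatures import derive_signature, score_with_control

__all__ = ["TrajectoryProfile", "build_timepoint_signatures", "score_trajectory"]


@dataclass
class TrajectoryProfile:
    """Adjusted scores of one group across an ordered timepoint series."""

    group: str
    timepoints: list[str]
    adjusted_scores: list[float]
    random_baseline: list[float]
    control_sd: list[float]
    ci95: list[tuple[float, float]]
    n_cells: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.group,
                "timepoint": self.timepoints,
                "adjusted_score": self.adjusted_scores,
                "random_baseline": self.random_baseline,
                "control_sd": self.control_sd,
                "ci_low": [c[0] for c in self.ci95],
                "ci_high": [c[1] for c in self.ci95],
                "n_cells": self.n_cells,
            }
        )


def build_timepoint_signatures(
    reference_expr: ExpressionMatrix,
    stage_labels: Mapping[str, str] | pd.Series,
    naive_label: str = "naive",
    top_n: int = 100,
    min_abs_lfc: float = 0.25,
    direction: str = "both",
) -> list[GeneSignature]:
    """One DE signature per non-naive stage, ordered as in the reference.

    Each stage is compared against the naive samples with
    :func:`~trmsig.signatures.derive_signature` (top ``top_n`` genes per
    direction). ``direction='up'`` keeps up-genes only; ``'both'`` keeps
    down-genes too when any qualify. Stage order follows first appearance in
    ``stage_labels``.
    """
    if direction not in ("both", "up"):
        raise ValueError(f"unknown direction {direction!r}")
    labels = pd.Series(stage_labels) if not isinstance(stage_labels, pd.Series) else stage_labels
    labels = labels.reindex(reference_expr.cells)
    if labels.isna().any():
        raise ValueError("every reference sample needs a stage label")
    stages = list(dict.fromkeys(labels))
    if naive_label not in stages:
        raise ValueError(f"missing naive stage {naive_label!r} in the reference")
    other = [s for s in stages if s != naive_label]
    if not other:
        raise ValueError("reference needs at least one non-naive stage")
    naive_cells = list(labels.index[labels == naive_label])

    signatures = []
    for stage in other:
        cells = list(labels.index[labels == stage])
        sig = derive_signature(
            reference_expr, cells, naive_cells,
            name=str(stage), top_n=top_n, min_abs_lfc=min_abs_lfc,
        )
        if direction == "up":
            sig = GeneSignature(sig.name, sig.up_genes, (), sig.notes)
        signatures.append(sig)
    return signatures


def score_trajectory(
    query_expr: ExpressionMatrix,
    groups: Mapping[str, str] | pd.Series,
    timepoint_signatures: Sequence[GeneSignature],
    n_iter: int = 1000,
    seed: int = 0,
) -> dict[str, TrajectoryProfile]:
    """Adjusted score of each query group against each timepoint signature.

    The query matrix must be gene-centered. Each (group, timepoint) cell of
    the profile carries the adjusted score, its 95% CI over the group's
    cells, and the randomized-control baseline (control mean, reported on
    the adjusted scale where it is zero by construction, kept alongside its
    sd for plotting the gray control band).
    """
    if not timepoint_signatures:
        raise ValueError("timepoint_signatures must be non-empty")
    labels = pd.Series(groups) if not isinstance(groups, pd.Series) else groups

    profiles: dict[str, TrajectoryProfile] = {}
    for ti, sig in enumerate(timepoint_signatures):
        results = score_with_control(
            query_expr, sig, labels, n_iter=n_iter, seed=seed + ti
        )
        for group, res in results.items():
            prof = profiles.setdefault(
                group,
                TrajectoryProfile(
                    group=group, timepoints=[], adjusted_scores=[],
                    random_baseline=[], control_sd=[], ci95=[],
                    n_cells=res.n_cells,
                ),
            )
            prof.timepoints.append(sig.name)
            prof.adjusted_scores.append(res.adjusted_score)
            # baseline on the adjusted scale: control minus itself = 0; keep
            # the control sd so the gray band has width
            prof.random_baseline.append(0.0)
            prof.control_sd.append(res.control_sd)
            prof.ci95.append(res.ci95)

    requested = set(labels.unique())
    missing = requested - set(profiles)
    if missing:
        raise ValueError(f"groups absent from the expression matrix: {sorted(missing)}")
    return profiles
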