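"""Quantification statistics: cluster frequencies, epidermal densities, tests.

Covers the study's declared statistical toolkit: per-condition cluster
frequency tables, cell densities from epidermal whole-mount image counts
(cells per mm^2, equal 1 mm^2 fields), two-tailed paired and unpaired
Student's t-tests, and Dunnett's many-to-one comparison of several
treatments against a single control with familywise error control.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "ClusterFrequencyTable",
    "cluster_frequencies",
    "density",
    "paired_t",
    "unpaired_t",
    "many_to_one",
]


@dataclass
class ClusterFrequencyTable:
    """Counts and within-condition fractions per (condition, cluster)."""

    counts: pd.DataFrame  # conditions x clusters, integer counts
    fractions: pd.DataFrame  # conditions x clusters, rows sum to 1

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for cond in self.counts.index:
            for clus in self.counts.columns:
                rows.append(
                    {
                        "condition": cond,
                        "cluster": clus,
                        "count": int(self.counts.loc[cond, clus]),
                        "fraction": float(self.fractions.loc[cond, clus]),
                    }
                )
        return pd.DataFrame(rows)

    def chi_square(self) -> tuple[float, float]:
        """Optional chi-square test of homogeneity across conditions
        (an extension beyond the paired-density comparison)."""
        stat, p, _, _ = scipy.stats.chi2_contingency(self.counts.to_numpy())
        return float(stat), float(p)


def cluster_frequencies(
    assignments: Mapping[str, str] | pd.Series,
    conditions: Mapping[str, str] | pd.Series,
) -> ClusterFrequencyTable:
    """Percentage of cells in each transcriptional cluster per condition.

    Every barcode must carry both a cluster and a condition label; clusters
    absent from a condition are reported with count 0. Raises on a condition
    with no cells.
    """
    clus = pd.Series(assignments) if not isinstance(assignments, pd.Series) else assignments
    cond = pd.Series(conditions) if not isinstance(conditions, pd.Series) else conditions
    if set(clus.index) != set(cond.index):
        raise ValueError("cluster and condition labels must cover the same barcodes")
    cond = cond.reindex(clus.index)

    counts = pd.crosstab(cond, clus)
    counts.index.name, counts.columns.name = "condition", "cluster"
    row_totals = counts.sum(axis=1)
    if (row_totals == 0).any():
        empty = list(row_totals.index[row_totals == 0])
        raise ValueError(f"condition(s) with zero cells: {empty}")
    fractions = counts.div(row_totals, axis=0)
    return ClusterFrequencyTable(counts=counts, fractions=fractions)


def density(
    per_image_counts: Sequence[float],
    area_per_image: float | Sequence[float] = 1.0,
    allow_unequal_areas: bool = False,
) -> float:
    """Average cells per mm^2 over replicate images of an epidermal sheet.

    The imaging protocol uses equal fields (1 mm^2 each), so the density is
    the mean per-image count divided by the per-image area; unequal areas
    are rejected unless ``allow_unequal_areas`` is set, in which case the
    pooled count over pooled area is returned.
    """
    counts = np.asarray(per_image_counts, dtype=float)
    if counts.size == 0:
        raise ValueError("need at least one image count")
    if np.any(counts < 0):
        raise ValueError("image counts must be non-negative")
    areas = np.broadcast_to(np.asarray(area_per_image, dtype=float), counts.shape)
    if np.any(areas <= 0):
        raise ValueError("image areas must be positive")
    if not np.allclose(areas, areas[0]):
        if not allow_unequal_areas:
            raise ValueError(
                "unequal image areas; protocol specifies equal fields "
                "(pass allow_unequal_areas=True to pool)"
            )
        return float(counts.sum() / areas.sum())
    return float(counts.mean() / areas[0])


def _degenerate(a: np.ndarray, b: np.ndarray | None = None) -> tuple[float, float] | None:
    """Zero-variance convention: equal means -> (0, 1), else (+/-inf, 0)."""
    if b is None:
        if np.ptp(a) == 0:
            return (0.0, 1.0)
        return None
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return (0.0, 1.0)
        return (float(np.sign(a[0] - b[0]) * np.inf), 0.0)
    return None


def paired_t(x_left: Sequence[float], x_right: Sequence[float]) -> tuple[float, float]:
    """Two-tailed paired Student's t-test (e.g. left vs right flanks).

    Identical pairs (all differences zero) return ``(0, 1)`` by convention.
    """
    a = np.asarray(x_left, dtype=float)
    b = np.asarray(x_right, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if a.size < 2:
        raise ValueError("paired test needs at least 2 pairs")
    deg = _degenerate(a - b)
    if deg is not None:
        return deg
    if np.ptp(a - b) == 0:  # constant nonzero difference
        return (float(np.sign((a - b)[0]) * np.inf), 0.0)
    stat, p = scipy.stats.ttest_rel(a, b)
    return float(stat), float(p)


def unpaired_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-tailed unpaired Student's t-test (comparison between animals)."""
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    deg = _degenerate(a, b)
    if deg is not None:
        return deg
    stat, p = scipy.stats.ttest_ind(a, b)
    return float(stat), float(p)


def many_to_one(
    control: Sequence[float],
    treatments: Sequence[Sequence[float]],
    seed: int | None = None,
) -> pd.DataFrame:
    """Dunnett's two-sided many-to-one comparison against a single control.

    Familywise error is controlled via the multivariate-t distribution of
    the contrast statistics (critical points estimated with a seeded
    randomized quadrature). Returns one row per treatment with the contrast
    statistic, the Dunnett-adjusted p-value, and the unadjusted marginal
    p-value of the same pooled-variance statistic (which the adjusted value
    always dominates). With a single treatment the decision reduces to the
    ordinary unpaired t-test.
    """
    ctrl = np.asarray(control, dtype=float)
    groups = [np.asarray(t, dtype=float) for t in treatments]
    if not groups:
        raise ValueError("need at least one treatment group")
    if ctrl.size < 2 or any(g.size < 2 for g in groups):
        raise ValueError("each group needs at least 2 observations")

    rng = np.random.default_rng(seed)
    res = scipy.stats.dunnett(*groups, control=ctrl, alternative="two-sided", rng=rng)
    df = ctrl.size + sum(g.size for g in groups) - (len(groups) + 1)
    rows = []
    for i, g in enumerate(groups):
        stat = float(res.statistic[i])
        rows.append(
            {
                "treatment": i,
                "statistic": stat,
                "p_adjusted": float(np.clip(res.pvalue[i], 0.0, 1.0)),
                "p_unadjusted": float(2 * scipy.stats.t.sf(abs(stat), df)),
            }
        )
    return pd.DataFrame(rows)
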