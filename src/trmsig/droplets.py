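"""Cell calling by inflection-point detection on the barcode rank curve.

Barcodes sorted by total UMI count form a curve with two regimes — a
cell-containing plateau and an ambient/empty tail. The knee between them is
located as the steepest drop of the smoothed log(total) vs log(rank) curve;
barcodes strictly above the total at that point are called cells. Calling is
done independently on the RNA and antibody (TotalSeq-C) count curves and the
two called sets intersected.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CountMatrix

__all__ = ["RankCurve", "rank_barcodes", "find_inflection", "call_cells"]

logger = logging.getLogger(__name__)


@dataclass
class RankCurve:
    """Barcodes ranked by descending total count.

    ``ranks`` are 1-based; ``totals`` is non-increasing; ``barcode_order``
    aligns barcode identifiers to ranks. Ties are broken lexicographically by
    barcode identifier so the curve is reproducible.
    """

    ranks: np.ndarray
    totals: np.ndarray
    barcode_order: list[str]

    def __post_init__(self) -> None:
        self.ranks = np.asarray(self.ranks)
        self.totals = np.asarray(self.totals)
        if len(self.ranks) != len(self.totals) or len(self.ranks) != len(self.barcode_order):
            raise ValueError("ranks, totals and barcode_order must have equal length")
        if np.any(np.diff(self.totals) > 0):
            raise ValueError("totals must be sorted non-increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rank": self.ranks, "total": self.totals, "barcode": self.barcode_order}
        )


def rank_barcodes(counts: CountMatrix) -> RankCurve:
    """Sort barcodes by total count, descending, ties lexicographic.

    Raises ``ValueError`` if no barcode has a nonzero total.
    """
    totals = counts.barcode_totals()
    if (totals > 0).sum() == 0:
        raise ValueError("no populated barcodes (all totals are zero)")
    if len(totals) < 2:
        raise ValueError("need at least 2 barcodes to form a rank curve")
    ordered = totals.sort_index().sort_values(ascending=False, kind="stable")
    return RankCurve(
        ranks=np.arange(1, len(ordered) + 1),
        totals=ordered.to_numpy(),
        barcode_order=list(ordered.index),
    )


def find_inflection(
    curve: RankCurve,
    min_rank: int = 10,
    max_rank: int | None = None,
    window: int = 21,
    min_fold_drop: float = 2.0,
) -> float:
    """Total-count threshold at the steepest drop of the rank curve.

    The log10(total) vs log10(rank) curve, restricted to barcodes with
    positive totals, is smoothed with a centered moving average of ``window``
    ranks; the rank in ``[min_rank, max_rank]`` minimizing the first
    derivative marks the inflection. Returns the raw total just below that
    drop; barcodes with total strictly above the threshold are cells.

    ``max_rank`` defaults to 99% of the positive-total barcodes, excluding
    the unstable extreme tail. Raises ``ValueError`` when the search window
    spans less than a ``min_fold_drop``-fold decrease (no inflection found).
    """
    totals = np.asarray(curve.totals, dtype=float)
    n_pos = int((totals > 0).sum())
    if max_rank is None:
        max_rank = max(int(0.99 * n_pos), 2)
    max_rank = min(max_rank, n_pos)
    if not (0 < min_rank < max_rank):
        raise ValueError(
            f"require 0 < min_rank < max_rank <= positive barcodes "
            f"(got min_rank={min_rank}, max_rank={max_rank}, positive={n_pos})"
        )

    t = totals[:n_pos]
    logt = np.log10(t)
    logr = np.log10(np.arange(1, n_pos + 1, dtype=float))
    smooth = (
        pd.Series(logt).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )

    if t[min_rank - 1] / t[max_rank - 1] < min_fold_drop:
        raise ValueError(
            "no inflection found: curve is flat over the search window "
            f"(fold drop < {min_fold_drop})"
        )

    # derivative between consecutive ranks; index i covers the step i+1 -> i+2
    lo, hi = min_rank - 1, max_rank - 1  # 0-based rank indices
    dlogt = np.diff(smooth[lo : hi + 1])
    dlogr = np.diff(logr[lo : hi + 1])
    deriv = dlogt / dlogr
    steepest = int(np.argmin(deriv))
    # threshold = raw total just after the steepest step (bottom of the knee)
    return float(t[lo + steepest + 1])


def call_cells(
    counts: CountMatrix,
    adt_counts: CountMatrix,
    min_rank: int = 10,
    max_rank: int | None = None,
    window: int = 21,
) -> set[str]:
    """Barcodes called as cells on both the RNA and antibody rank curves.

    Each matrix is ranked and thresholded independently via
    :func:`find_inflection`; the called sets are intersected, matching the
    requirement that cell-containing droplets are high in both RNA and
    TotalSeq-C counts. Raises ``ValueError`` on disjoint barcode spaces; an
    empty intersection is returned with a warning in the run log.
    """
    shared = set(counts.barcodes) & set(adt_counts.barcodes)
    if not shared:
        raise ValueError("RNA and antibody matrices have disjoint barcode spaces")

    called: list[set[str]] = []
    for mat in (counts, adt_counts):
        curve = rank_barcodes(mat)
        thr = find_inflection(curve, min_rank=min_rank, max_rank=max_rank, window=window)
        keep = {b for b, t in zip(curve.barcode_order, curve.totals) if t > thr}
        called.append(keep & shared)

    cells = called[0] & called[1]
    if not cells:
        logger.warning("cell calling produced an empty intersection of RNA and ADT calls")
    return cells
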