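"""Hashtag sample demultiplexing with doublet exclusion.

Each called cell is assigned to the hashtag with the highest count, provided
that count is at least ``min_counts`` and more than ``ratio`` times the
second most abundant hashtag. Droplets positive for two hashtags (both at or
above ``doublet_positive_threshold``) whose top tag fails the ratio test are
doublets; everything else is unassigned. The rule operates on raw counts —
no normalization is applied before thresholding.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import CountMatrix

__all__ = ["DOUBLET", "UNASSIGNED", "DemuxResult", "demultiplex", "classify_counts"]

DOUBLET = "DOUBLET"
UNASSIGNED = "UNASSIGNED"


@dataclass
class DemuxResult:
    """Per-barcode assignment with supporting counts.

    ``table`` is indexed by barcode with columns ``assignment`` (sample label,
    ``DOUBLET`` or ``UNASSIGNED``), ``top_tag``, ``top_count``,
    ``second_count``.
    """

    table: pd.DataFrame
    min_counts: int
    ratio: float
    doublet_positive_threshold: int

    def assignments(self) -> pd.Series:
        return self.table["assignment"]

    def singlets(self) -> pd.DataFrame:
        mask = ~self.table["assignment"].isin([DOUBLET, UNASSIGNED])
        return self.table[mask]


def classify_counts(
    c1: int,
    c2: int,
    min_counts: int = 10,
    ratio: float = 2.0,
    doublet_positive_threshold: int = 10,
) -> str:
    """Assignment category for one barcode's top two hashtag counts.

    ``"assigned"`` when the top count clears the floor and is more than
    ``ratio`` times the runner-up; ``DOUBLET`` when two tags are positive and
    the ratio test fails (ties included); ``UNASSIGNED`` otherwise.
    """
    if c1 < c2:
        raise ValueError("c1 must be the larger count")
    if c1 >= doublet_positive_threshold and c2 >= doublet_positive_threshold and not c1 > ratio * c2:
        return DOUBLET
    if c1 >= min_counts and c1 > ratio * c2:
        return "assigned"
    return UNASSIGNED


def demultiplex(
    hashtag_counts: CountMatrix,
    min_counts: int = 10,
    ratio: float = 2.0,
    doublet_positive_threshold: int = 10,
    sample_map: Mapping[str, str] | None = None,
) -> DemuxResult:
    """Assign each barcode to a sample, DOUBLET or UNASSIGNED.

    ``hashtag_counts`` must contain only hashtag features (>= 2), restricted
    to called cells. ``sample_map`` optionally translates tag names to sample
    labels; unmapped tags keep their own name. Ties for the top tag are
    broken lexicographically for reporting (tied barcodes are doublets or
    unassigned regardless).
    """
    n_tags = len(hashtag_counts.genes)
    if n_tags < 2:
        raise ValueError("demultiplexing rule requires >=2 tags")

    counts = hashtag_counts.matrix.toarray()  # tags x barcodes
    tags = np.array(hashtag_counts.genes)
    # stable lexicographic tie-break: sort rows by tag name first
    tag_order = np.argsort(tags, kind="stable")
    counts = counts[tag_order]
    tags = tags[tag_order]

    # top and runner-up per barcode
    order = np.argsort(-counts, axis=0, kind="stable")
    top_idx = order[0]
    ncols = counts.shape[1]
    cols = np.arange(ncols)
    c1 = counts[top_idx, cols]
    c2 = counts[order[1], cols] if n_tags > 1 else np.zeros(ncols, dtype=counts.dtype)

    both_pos = (c1 >= doublet_positive_threshold) & (c2 >= doublet_positive_threshold)
    clear_top = c1 > ratio * c2
    is_doublet = both_pos & ~clear_top
    is_assigned = ~is_doublet & (c1 >= min_counts) & clear_top

    top_tags = tags[top_idx]
    labels = np.array(
        [sample_map.get(t, t) if sample_map else t for t in top_tags], dtype=object
    )
    assignment = np.where(is_doublet, DOUBLET, np.where(is_assigned, labels, UNASSIGNED))

    table = pd.DataFrame(
        {
            "assignment": assignment,
            "top_tag": top_tags,
            "top_count": c1.astype(int),
            "second_count": c2.astype(int),
        },
        index=pd.Index(hashtag_counts.barcodes, name="barcode"),
    )
    return DemuxResult(
        table=table,
        min_counts=min_counts,
        ratio=ratio,
        doublet_positive_threshold=doublet_positive_threshold,
    )
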