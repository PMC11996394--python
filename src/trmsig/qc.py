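"""Quality-control filtering of called cells.

Four conjunctive exclusion rules, each taken literally from the study design:
a cell is removed when it has fewer than 500 RNA counts, over 10% of counts
mapping to mitochondrial genes, fewer than 500 antibody (TotalSeq-C) counts,
or is positive for two isotype controls (non-specific antibody binding).
Per-filter attrition is tallied against the full input, so a cell failing
several filters is counted under each.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .containers import CountMatrix

__all__ = ["QCReport", "filter_cells", "default_mito_genes", "default_isotype_features"]

logger = logging.getLogger(__name__)


def default_mito_genes(genes: Iterable[str]) -> set[str]:
    """Mitochondrial genes by the standard mouse ``mt-`` prefix (case-insensitive)."""
    return {g for g in genes if g.lower().startswith("mt-")}


def default_isotype_features(features: Iterable[str]) -> set[str]:
    return {f for f in features if f.lower().startswith("isotype")}


@dataclass
class QCReport:
    """Outcome of QC filtering.

    ``removed`` tallies each filter against the full input independently;
    ``kept`` is the conjunction (a barcode is kept iff it passes all four),
    so the removal counts can sum to more than the number of barcodes lost.
    """

    kept: list[str]
    removed: dict[str, int]
    thresholds: dict[str, float]
    n_input: int
    skipped_filters: list[str] = field(default_factory=list)
    per_barcode: pd.DataFrame | None = None

    @property
    def n_kept(self) -> int:
        return len(self.kept)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "removed": self.removed,
            "thresholds": self.thresholds,
            "skipped_filters": self.skipped_filters,
        }


def filter_cells(
    counts: CountMatrix,
    adt_counts: CountMatrix,
    mito_genes: Iterable[str] | None = None,
    isotype_controls: Iterable[str] | None = None,
    min_rna: int = 500,
    max_mito_frac: float = 0.10,
    min_adt: int = 500,
    isotype_positive_threshold: int = 10,
) -> QCReport:
    """Apply the four exclusion rules and report per-filter attrition.

    Boundary semantics are strict readings of the rules: "fewer than 500"
    removes totals <= 499 (500 passes); "over 10%" removes fractions strictly
    above ``max_mito_frac`` (exactly 0.10 is kept); isotype positivity needs
    two or more controls at/above ``isotype_positive_threshold`` (one is
    kept). ``mito_genes`` / ``isotype_controls`` default to prefix detection
    (``mt-`` / ``isotype``); an empty mito set skips that filter with a
    warning recorded in the report.
    """
    if set(counts.barcodes) != set(adt_counts.barcodes):
        raise ValueError("RNA and antibody matrices must cover the same barcodes")
    barcodes = list(counts.barcodes)
    adt_aligned = adt_counts.subset_barcodes(barcodes)

    if mito_genes is None:
        mito_genes = default_mito_genes(counts.genes)
    mito_genes = set(mito_genes) & set(counts.genes)
    if isotype_controls is None:
        isotype_controls = default_isotype_features(adt_counts.genes)
    isotype_controls = set(isotype_controls)
    unknown_iso = isotype_controls - set(adt_counts.genes)
    if unknown_iso:
        raise ValueError(f"isotype controls absent from antibody panel: {sorted(unknown_iso)}")

    rna_totals = counts.barcode_totals().to_numpy(dtype=float)
    adt_totals = adt_aligned.barcode_totals().to_numpy(dtype=float)

    fail_rna = rna_totals < min_rna
    fail_adt = adt_totals < min_adt

    skipped: list[str] = []
    if mito_genes:
        mito_counts = counts.subset_genes(sorted(mito_genes)).barcode_totals().to_numpy(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(rna_totals > 0, mito_counts / rna_totals, 0.0)
        fail_mito = mito_frac > max_mito_frac
    else:
        logger.warning("no mitochondrial genes found; mito filter skipped")
        skipped.append("high_mito")
        fail_mito = np.zeros(len(barcodes), dtype=bool)

    if isotype_controls:
        iso = adt_aligned.subset_genes(sorted(isotype_controls)).matrix.toarray()
        n_positive = (iso >= isotype_positive_threshold).sum(axis=0)
        fail_iso = n_positive >= 2
    else:
        skipped.append("isotype_double_positive")
        fail_iso = np.zeros(len(barcodes), dtype=bool)

    keep_mask = ~(fail_rna | fail_mito | fail_adt | fail_iso)
    per_barcode = pd.DataFrame(
        {
            "low_rna": fail_rna,
            "high_mito": fail_mito,
            "low_adt": fail_adt,
            "isotype_double_positive": fail_iso,
            "kept": keep_mask,
        },
        index=pd.Index(barcodes, name="barcode"),
    )

    return QCReport(
        kept=[b for b, k in zip(barcodes, keep_mask) if k],
        removed={
            "low_rna": int(fail_rna.sum()),
            "high_mito": int(fail_mito.sum()),
            "low_adt": int(fail_adt.sum()),
            "isotype_double_positive": int(fail_iso.sum()),
        },
        thresholds={
            "min_rna": min_rna,
            "max_mito_frac": max_mito_frac,
            "min_adt": min_adt,
            "isotype_positive_threshold": isotype_positive_threshold,
        },
        n_input=len(barcodes),
        skipped_filters=skipped,
        per_barcode=per_barcode,
    )
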