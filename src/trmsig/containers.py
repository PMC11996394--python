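"""Core in-memory containers shared across pipeline stages.

All matrices are identifier-keyed: genes/features and barcodes are addressed
by name, never by position, across module boundaries.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["CountMatrix", "GeneSignature", "ExpressionMatrix"]


@dataclass
class CountMatrix:
    """Sparse genes x barcodes matrix of non-negative integer UMI counts.

    Parameters
    ----------
    matrix
        Sparse (or dense array-like) of shape ``(n_genes, n_barcodes)``.
    genes
        Feature identifiers, one per row.
    barcodes
        Droplet barcode identifiers, one per column.
    """

    matrix: sp.csr_matrix
    genes: list[str]
    barcodes: list[str]

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        self.genes = [str(g) for g in self.genes]
        self.barcodes = [str(b) for b in self.barcodes]
        if self.matrix.shape != (len(self.genes), len(self.barcodes)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.genes)} genes x {len(self.barcodes)} barcodes"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("duplicate barcode identifiers")
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def barcode_totals(self) -> pd.Series:
        """Total counts per barcode, indexed by barcode identifier."""
        totals = np.asarray(self.matrix.sum(axis=0)).ravel()
        return pd.Series(totals, index=self.barcodes, name="total")

    def gene_totals(self) -> pd.Series:
        totals = np.asarray(self.matrix.sum(axis=1)).ravel()
        return pd.Series(totals, index=self.genes, name="total")

    def subset_barcodes(self, barcodes: Iterable[str]) -> "CountMatrix":
        wanted = list(barcodes)
        index = {b: i for i, b in enumerate(self.barcodes)}
        missing = [b for b in wanted if b not in index]
        if missing:
            raise KeyError(f"barcodes not in matrix: {missing[:5]}")
        cols = [index[b] for b in wanted]
        return CountMatrix(self.matrix[:, cols], list(self.genes), wanted)

    def subset_genes(self, genes: Iterable[str]) -> "CountMatrix":
        wanted = list(genes)
        index = {g: i for i, g in enumerate(self.genes)}
        missing = [g for g in wanted if g not in index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        rows = [index[g] for g in wanted]
        return CountMatrix(self.matrix[rows, :], wanted, list(self.barcodes))

    def to_frame(self) -> pd.DataFrame:
        """Dense genes x barcodes DataFrame (small matrices only)."""
        return pd.DataFrame(
            self.matrix.toarray(), index=self.genes, columns=self.barcodes
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.genes == other.genes
            and self.barcodes == other.barcodes
            and (self.matrix != other.matrix).nnz == 0
        )


@dataclass(frozen=True)
class GeneSignature:
    """A named reference transcriptional state: up-regulated and (optionally)
    down-regulated gene sets.

    ``up_genes`` and ``down_genes`` must be disjoint. An empty up set is
    representable (e.g. the output of signature derivation on identical
    groups) but cannot be scored.
    """

    name: str
    up_genes: frozenset[str]
    down_genes: frozenset[str] = frozenset()
    notes: tuple[str, ...] = ()

    def __init__(
        self,
        name: str,
        up_genes: Iterable[str],
        down_genes: Iterable[str] = (),
        notes: Sequence[str] = (),
    ) -> None:
        object.__setattr__(self, "name", str(name))
        object.__setattr__(self, "up_genes", frozenset(map(str, up_genes)))
        object.__setattr__(self, "down_genes", frozenset(map(str, down_genes)))
        object.__setattr__(self, "notes", tuple(notes))
        if self.up_genes & self.down_genes:
            raise ValueError(
                f"signature {self.name!r}: up and down gene sets overlap"
            )

    def __len__(self) -> int:
        return len(self.up_genes) + len(self.down_genes)


@dataclass
class ExpressionMatrix:
    """Cells/samples x genes real-valued expression on log scale.

    ``normalization`` records how the values were produced
    (``log2_tpm1``, ``log2_cp10k1`` or ``none-provided-prelogged``);
    ``centered`` flags whether each gene has been mean-centered across all
    cells.
    """

    values: pd.DataFrame  # rows = cells/samples, columns = genes
    normalization: str = "none-provided-prelogged"
    centered: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.centered:
            maxdev = float(np.abs(self.values.mean(axis=0)).max()) if self.values.size else 0.0
            if maxdev > 1e-8:
                raise ValueError(
                    f"centered flag set but max |gene mean| = {maxdev:.3g} > 1e-8"
                )

    @property
    def cells(self) -> pd.Index:
        return self.values.index

    @property
    def genes(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape
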