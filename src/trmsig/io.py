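"""Readers and writers for the on-disk formats.

MatrixMarket MTX with companion ``barcodes.tsv`` / ``features.tsv`` (plain or
gzip) for count matrices, GMT and two-column CSV for gene sets, tidy CSV for
results. MTX indices are 1-based on disk and converted at this boundary; in
memory everything is identifier-keyed.
"""
from __future__ import annotations

import gzip
import hashlib
import io as _io
import json
import logging
from pathlib import Path
from typing import Sequence

import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import CountMatrix, GeneSignature

__all__ = [
    "read_mtx",
    "write_mtx",
    "read_gmt",
    "write_gmt",
    "read_signature_csv",
    "write_signature_csv",
    "write_tidy_csv",
    "read_tidy_csv",
    "params_hash",
]

logger = logging.getLogger(__name__)


def _find(directory: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = directory / name
        if p.exists():
            return p
    raise FileNotFoundError(f"{stem}[.gz] not found in {directory}")


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _read_tsv_column(path: Path) -> list[str]:
    with _open_text(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_mtx(directory: str | Path) -> CountMatrix:
    """Read ``matrix.mtx`` + ``barcodes.tsv`` + ``features.tsv`` (or ``.gz``).

    ``features.tsv`` may carry extra columns (name, type); the first column
    is the identifier. Raises on malformed MTX or a dimension mismatch
    between the matrix header and the companion files.
    """
    directory = Path(directory)
    mtx_path = _find(directory, "matrix.mtx")
    try:
        if mtx_path.suffix == ".gz":
            with gzip.open(mtx_path, "rb") as fh:
                matrix = scipy.io.mmread(_io.BytesIO(fh.read()))
        else:
            matrix = scipy.io.mmread(str(mtx_path))
    except Exception as exc:  # noqa: BLE001 — name the offending file
        raise ValueError(f"malformed MatrixMarket file {mtx_path}: {exc}") from exc
    genes = _read_tsv_column(_find(directory, "features.tsv"))
    barcodes = _read_tsv_column(_find(directory, "barcodes.tsv"))
    if matrix.shape != (len(genes), len(barcodes)):
        raise ValueError(
            f"dimension mismatch in {directory}: matrix is {matrix.shape}, "
            f"companions give {len(genes)} features x {len(barcodes)} barcodes"
        )
    return CountMatrix(sp.csr_matrix(matrix, dtype=int), genes, barcodes)


def write_mtx(matrix: CountMatrix, directory: str | Path) -> Path:
    """Write a count matrix as plain-text MTX with TSV companions."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(directory / "matrix.mtx", matrix.matrix.astype(int))
    (directory / "features.tsv").write_text("".join(g + "\n" for g in matrix.genes))
    (directory / "barcodes.tsv").write_text("".join(b + "\n" for b in matrix.barcodes))
    return directory


def read_gmt(path: str | Path) -> list[GeneSignature]:
    """Parse a GMT file (name, description, genes...) into signatures.

    GMT sets are undirected; genes become up-genes. Duplicates within a set
    are dropped with a warning.
    """
    signatures = []
    with _open_text(Path(path)) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: GMT line needs name, description, >=1 gene")
            name, _desc, *genes = parts
            genes = [g for g in genes if g]
            unique = list(dict.fromkeys(genes))
            if len(unique) != len(genes):
                logger.warning("%s:%d: duplicate genes in set %r deduplicated", path, ln, name)
            signatures.append(GeneSignature(name=name, up_genes=unique))
    return signatures


def write_gmt(signatures: Sequence[GeneSignature], path: str | Path) -> Path:
    """Write signatures as GMT; directed sets get ``_UP``/``_DN`` lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for sig in signatures:
            if sig.down_genes:
                fh.write("\t".join([f"{sig.name}_UP", ""] + sorted(sig.up_genes)) + "\n")
                fh.write("\t".join([f"{sig.name}_DN", ""] + sorted(sig.down_genes)) + "\n")
            else:
                fh.write("\t".join([sig.name, ""] + sorted(sig.up_genes)) + "\n")
    return path


def read_signature_csv(path: str | Path, name: str | None = None) -> GeneSignature:
    """Two-column CSV (gene, direction in {up, down}) -> one signature."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "gene" not in cols or "direction" not in cols:
        raise ValueError(f"{path}: need columns 'gene' and 'direction'")
    direction = df[cols["direction"]].str.lower()
    bad = set(direction) - {"up", "down"}
    if bad:
        raise ValueError(f"{path}: unknown direction values {sorted(bad)}")
    return GeneSignature(
        name=name or Path(path).stem,
        up_genes=df.loc[direction == "up", cols["gene"]].tolist(),
        down_genes=df.loc[direction == "down", cols["gene"]].tolist(),
    )


def write_signature_csv(signature: GeneSignature, path: str | Path) -> Path:
    rows = [{"gene": g, "direction": "up"} for g in sorted(signature.up_genes)]
    rows += [{"gene": g, "direction": "down"} for g in sorted(signature.down_genes)]
    pd.DataFrame(rows, columns=["gene", "direction"]).to_csv(path, index=False)
    return Path(path)


def params_hash(params: dict) -> str:
    """Stable short hash of a parameter dictionary."""
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_tidy_csv(
    df: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    params: dict | None = None,
    index: bool = False,
) -> Path:
    """Write a result CSV with a provenance header (seed, parameter hash)."""
    path = Path(path)
    buf = _io.StringIO()
    buf.write(f"# seed={seed} params_hash={params_hash(params or {})}\n")
    df.to_csv(buf, index=index)
    path.write_text(buf.getvalue())
    return path


def read_tidy_csv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)
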