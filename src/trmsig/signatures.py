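"""Gene-signature enrichment scoring with a random-gene-set control.

The score of a signature in a cell is the mean of gene-centered log
expression over the signature's up-genes minus the mean over its down-genes;
a group's raw score is the mean of its cells' scores. Because the score
depends on the number and coverage of signature genes, a control score —
the same statistic on randomly drawn gene sets of equal sizes — is
subtracted to give an adjusted score, with a randomized baseline whose mean
is zero under exchangeability.

The pipeline is: normalize counts to log scale (log2(TPM+1) for bulk with
gene lengths, log2(CP10K+1) for UMI data), center each gene across all
cells, then average over gene sets. Centering makes the score invariant to
per-gene additive offsets; an optional unit-variance scaling gives strict
z-scores.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .containers import CountMatrix, ExpressionMatrix, GeneSignature

__all__ = [
    "SignatureScoreResult",
    "normalize_and_log",
    "center_genes",
    "score_signature",
    "random_control",
    "adjusted_score",
    "score_with_control",
    "pseudobulk_scores",
    "derive_signature",
]


@dataclass
class SignatureScoreResult:
    """Score of one signature in one group, with its randomized control."""

    group: str
    signature: str
    raw_score: float
    control_mean: float
    control_sd: float
    adjusted_score: float
    ci95: tuple[float, float]
    n_cells: int
    n_up_used: int
    n_down_used: int
    n_random_iter: int
    seed: int | None

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["ci_low"], d["ci_high"] = d.pop("ci95")
        return d


def _as_series(groups: Mapping[str, str] | pd.Series, index: pd.Index) -> pd.Series:
    s = pd.Series(groups) if not isinstance(groups, pd.Series) else groups
    missing = index.difference(s.index)
    if len(missing):
        raise KeyError(f"cells without a group label: {list(missing[:5])}")
    return s.reindex(index)


def normalize_and_log(
    counts: CountMatrix,
    mode: str = "log2_cp10k1",
    gene_lengths: pd.Series | Mapping[str, float] | None = None,
) -> ExpressionMatrix:
    """Normalize a count matrix and log-transform it.

    ``log2_tpm1`` computes transcripts-per-million with per-gene lengths
    (in bases or kilobases — only relative lengths matter) and returns
    log2(TPM+1); it is appropriate for full-length bulk data. ``log2_cp10k1``
    scales each cell to 10,000 total counts and returns log2(x+1), the
    UMI-appropriate stand-in where length correction is undefined. The
    result is cells x genes.
    """
    X = counts.matrix.toarray().T.astype(float)  # cells x genes
    if mode == "log2_cp10k1":
        totals = X.sum(axis=1, keepdims=True)
        totals[totals == 0] = 1.0
        vals = np.log2(X / totals * 1e4 + 1.0)
    elif mode == "log2_tpm1":
        if gene_lengths is None:
            raise ValueError("log2_tpm1 mode requires gene lengths")
        lengths = pd.Series(gene_lengths).reindex(counts.genes)
        if lengths.isna().any():
            missing = list(lengths.index[lengths.isna()][:5])
            raise ValueError(f"gene lengths missing for: {missing}")
        rate = X / lengths.to_numpy(float)[None, :]
        denom = rate.sum(axis=1, keepdims=True)
        denom[denom == 0] = 1.0
        vals = np.log2(rate / denom * 1e6 + 1.0)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return ExpressionMatrix(
        pd.DataFrame(vals, index=counts.barcodes, columns=counts.genes),
        normalization=mode,
    )


def center_genes(expr: ExpressionMatrix, scale: bool = False) -> ExpressionMatrix:
    """Subtract each gene's mean across all cells (optionally scale to unit sd).

    Re-centering an already centered matrix is a contract violation: it is
    returned unchanged with a warning.
    """
    if expr.centered:
        warnings.warn("matrix is already centered; returning it unchanged")
        return expr
    vals = expr.values - expr.values.mean(axis=0)
    if scale:
        sd = expr.values.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        vals = vals / sd
    return ExpressionMatrix(vals, normalization=expr.normalization, centered=True)


def _signature_cell_scores(
    expr: ExpressionMatrix, signature: GeneSignature
) -> tuple[pd.Series, int, int]:
    present = set(expr.genes)
    up = sorted(signature.up_genes & present)
    down = sorted(signature.down_genes & present)
    if not up:
        raise ValueError(
            f"signature {signature.name!r}: no up gene present in the expression matrix"
        )
    scores = expr.values[up].mean(axis=1)
    if down:
        scores = scores - expr.values[down].mean(axis=1)
    return scores, len(up), len(down)


def score_signature(
    expr: ExpressionMatrix,
    signature: GeneSignature,
    groups: Mapping[str, str] | pd.Series,
) -> dict[str, SignatureScoreResult]:
    """Raw per-group signature scores with normal-approximation 95% CIs.

    Requires a centered matrix. Signature genes absent from the matrix are
    dropped and reflected in ``n_up_used`` / ``n_down_used``; the control
    fields are NaN until filled by :func:`score_with_control`.
    """
    if not expr.centered:
        raise ValueError("expression matrix must be gene-centered before scoring")
    labels = _as_series(groups, expr.cells)
    scores, n_up, n_down = _signature_cell_scores(expr, signature)

    out: dict[str, SignatureScoreResult] = {}
    for group, vals in scores.groupby(labels, observed=True):
        mean = float(vals.mean())
        n = len(vals)
        se = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        out[str(group)] = SignatureScoreResult(
            group=str(group),
            signature=signature.name,
            raw_score=mean,
            control_mean=float("nan"),
            control_sd=float("nan"),
            adjusted_score=float("nan"),
            ci95=(mean - 1.96 * se, mean + 1.96 * se),
            n_cells=n,
            n_up_used=n_up,
            n_down_used=n_down,
            n_random_iter=0,
            seed=None,
        )
    return out


def random_control(
    expr: ExpressionMatrix,
    n_up: int,
    n_down: int,
    groups: Mapping[str, str] | pd.Series,
    n_iter: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-group mean and sd of scores over random gene sets of equal sizes.

    Each iteration draws ``n_up + n_down`` genes uniformly without
    replacement (signature genes are not excluded from the pool) and scores
    them exactly like a signature. Because the group score is linear in
    expression, it is computed on per-group mean profiles. Deterministic
    given ``seed``; returns a DataFrame indexed by group with columns
    ``control_mean`` and ``control_sd``.
    """
    if not expr.centered:
        raise ValueError("expression matrix must be gene-centered before scoring")
    if n_up < 1:
        raise ValueError("n_up must be >= 1")
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2")
    n_genes = expr.shape[1]
    k = n_up + n_down
    if k > n_genes:
        raise ValueError(f"n_up + n_down = {k} exceeds the {n_genes} genes available")

    labels = _as_series(groups, expr.cells)
    profiles = expr.values.groupby(labels, observed=True).mean()  # groups x genes
    G = profiles.to_numpy()

    rng = np.random.default_rng(seed)
    u = rng.random((n_iter, n_genes))
    idx = np.argpartition(u, k - 1, axis=1)[:, :k]
    up_idx, down_idx = idx[:, :n_up], idx[:, n_up:]

    scores = G[:, up_idx].mean(axis=2)  # groups x iters
    if n_down:
        scores = scores - G[:, down_idx].mean(axis=2)
    return pd.DataFrame(
        {
            "control_mean": scores.mean(axis=1),
            "control_sd": scores.std(axis=1, ddof=1),
        },
        index=profiles.index,
    )


def adjusted_score(raw: float, control_mean: float) -> float:
    """Signature score with the randomized control subtracted."""
    return raw - control_mean


def score_with_control(
    expr: ExpressionMatrix,
    signature: GeneSignature,
    groups: Mapping[str, str] | pd.Series,
    n_iter: int = 1000,
    seed: int = 0,
) -> dict[str, SignatureScoreResult]:
    """Raw score, random control and adjusted score per group."""
    results = score_signature(expr, signature, groups)
    any_res = next(iter(results.values()))
    ctrl = random_control(
        expr, any_res.n_up_used, any_res.n_down_used, groups, n_iter=n_iter, seed=seed
    )
    for group, res in results.items():
        cm = float(ctrl.loc[group, "control_mean"])
        res.control_mean = cm
        res.control_sd = float(ctrl.loc[group, "control_sd"])
        res.adjusted_score = adjusted_score(res.raw_score, cm)
        res.ci95 = (res.ci95[0] - cm, res.ci95[1] - cm)
        res.n_random_iter = n_iter
        res.seed = seed
    return results


def pseudobulk_scores(
    expr: ExpressionMatrix,
    condition: Mapping[str, str] | pd.Series,
    signatures: Sequence[GeneSignature],
    mode: str = "pseudobulk",
    n_iter: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Score signatures per condition, collapsing cells first if requested.

    ``pseudobulk`` mode averages the centered profiles of each condition's
    cells into a single profile before scoring, so every condition yields one
    score with no cell-level CI; ``cell`` mode scores per cell and compares
    group means. The mode is recorded in the output. Raises on an empty
    condition.
    """
    if mode not in ("pseudobulk", "cell"):
        raise ValueError(f"unknown mode {mode!r}")
    labels = _as_series(condition, expr.cells)
    counts = labels.value_counts()
    if (counts == 0).any() or len(counts) == 0:
        raise ValueError("every condition must contain at least one cell")

    if mode == "pseudobulk":
        collapsed = expr.values.groupby(labels, observed=True).mean()
        # means of centered values are scored directly (no re-centering), so
        # one cell per condition reduces exactly to the cell-mode result
        work = ExpressionMatrix(collapsed, normalization=expr.normalization)
        # collapsed profiles inherit centering from the cell matrix; their own
        # per-gene means need not be zero, so bypass the construction check
        work.centered = expr.centered
        groups = pd.Series(collapsed.index, index=collapsed.index)
    else:
        work = expr
        groups = labels

    rows = []
    for si, sig in enumerate(signatures):
        results = score_with_control(
            work, sig, groups, n_iter=n_iter, seed=seed + si
        )
        for res in results.values():
            d = res.to_dict()
            d["mode"] = mode
            rows.append(d)
    return pd.DataFrame(rows)


def derive_signature(
    expr: ExpressionMatrix,
    group_cells: Iterable[str],
    reference_cells: Iterable[str],
    name: str = "derived",
    top_n: int = 100,
    min_abs_lfc: float = 0.25,
    max_p: float = 0.05,
) -> GeneSignature:
    """Differential-expression signature of a group against a reference.

    Genes are compared by a two-sided Wilcoxon rank-sum test on log
    expression; up-genes are the ``top_n`` most significant genes with
    p < ``max_p`` and mean log-fold-change >= ``min_abs_lfc``, down-genes
    the ``top_n`` most significant with lfc <= -``min_abs_lfc``. Identical
    groups therefore yield an (almost) empty signature. Fewer qualifying
    genes than requested yields a shorter signature with a note in
    ``notes`` and a warning.
    """
    g_cells = list(group_cells)
    r_cells = list(reference_cells)
    if len(g_cells) < 3 or len(r_cells) < 3:
        raise ValueError("both groups need at least 3 cells/samples")
    Xg = expr.values.loc[g_cells].to_numpy(float)
    Xr = expr.values.loc[r_cells].to_numpy(float)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant genes give degenerate ranksums
        stat, pval = scipy.stats.ranksums(Xg, Xr, axis=0)
    pval = np.nan_to_num(pval, nan=1.0)
    lfc = Xg.mean(axis=0) - Xr.mean(axis=0)

    genes = np.asarray(expr.genes)
    order = np.lexsort((genes, pval))  # p ascending, ties by gene name

    up, down = [], []
    for i in order:
        if pval[i] >= max_p:
            break  # p is ascending; nothing further qualifies
        if lfc[i] >= min_abs_lfc and len(up) < top_n:
            up.append(str(genes[i]))
        elif lfc[i] <= -min_abs_lfc and len(down) < top_n:
            down.append(str(genes[i]))
        if len(up) >= top_n and len(down) >= top_n:
            break

    notes = []
    if len(up) < top_n:
        notes.append(f"only {len(up)}/{top_n} up genes passed p<{max_p}, lfc>={min_abs_lfc}")
    if len(down) < top_n:
        notes.append(f"only {len(down)}/{top_n} down genes passed p<{max_p}, lfc<=-{min_abs_lfc}")
    if notes:
        warnings.warn(f"signature {name!r}: " + "; ".join(notes))
    return GeneSignature(name=name, up_genes=up, down_genes=down, notes=notes)
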