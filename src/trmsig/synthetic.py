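"""Synthetic droplet experiments and staged reference tables with known truth.

The generator emulates a hashtag-multiplexed droplet single-cell experiment:
real cells with negative-binomial UMI noise around group-specific gene means,
empty droplets carrying a scaled ambient profile, doublets formed by summing
two cells from distinct samples, a TotalSeq-C-like protein panel (hashtags,
isotype controls and generic surface markers), dying cells with inflated
mitochondrial content, and planted up-regulated gene signatures per
transcriptional group. Every emitted barcode is annotated in a ground-truth
table so each downstream stage can be scored against what was simulated.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CountMatrix, ExpressionMatrix, GeneSignature

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "StagedTruth",
    "generate_droplet_experiment",
    "generate_staged_reference",
    "simulate_expression_groups",
]

DOUBLET = "DOUBLET"


@dataclass
class SimulationConfig:
    """Parameters of one simulated droplet experiment.

    Defaults describe a small but realistic epidermal T cell run: 500 sorted
    cells against a 10x-scale background of ~5,000 empty droplets, four
    hashtagged samples, ~2,000 UMI per cell versus ~50 ambient UMI per empty
    droplet, hashtag signal an order of magnitude over background, and a
    small dying (high-mitochondrial) subpopulation.
    """

    n_cells: int = 500
    n_empty_droplets: int = 5000
    n_genes: int = 1000
    n_hashtags: int = 4
    doublet_fraction: float = 0.05
    cell_mean_counts: float = 2000.0
    empty_mean_counts: float = 50.0
    hashtag_signal: float = 100.0
    hashtag_background: float = 5.0
    mito_gene_count: int = 10
    mito_high_fraction: float = 0.05
    n_groups: int = 2
    signature_effect: float = 2.0  # log2 fold-change of planted up-genes
    dispersion: float = 2.0  # negative-binomial size parameter r
    seed: int = 0
    # panel/plumbing knobs beyond the core study conditions
    signature_genes_per_group: int = 25
    n_isotype_controls: int = 2
    n_surface_proteins: int = 12
    surface_mean_counts: float = 60.0
    mito_base_fraction: float = 0.02
    mito_high_level: float = 0.30
    isotype_sticky_fraction: float = 0.02
    isotype_sticky_mean: float = 30.0
    isotype_base_mean: float = 1.0
    ambient_capture_ratio: float | None = None  # default: empty/cell mean ratio

    def validate(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("n_cells must be a positive integer (no cells to simulate)")
        if self.n_empty_droplets <= 0:
            raise ValueError("n_empty_droplets must be a positive integer")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be a positive integer")
        if self.n_hashtags < 2:
            raise ValueError("n_hashtags must be >= 2")
        if not 0 <= self.doublet_fraction < 1:
            raise ValueError("doublet_fraction must lie in [0, 1)")
        if self.cell_mean_counts <= 0 or self.empty_mean_counts <= 0:
            raise ValueError("mean counts must be positive")
        if not self.empty_mean_counts < self.cell_mean_counts:
            raise ValueError(
                "empty_mean_counts must be < cell_mean_counts "
                "(rank curve needs two regimes)"
            )
        if self.hashtag_background < 0:
            raise ValueError("hashtag_background must be non-negative")
        if not self.hashtag_signal > 2 * self.hashtag_background + 10:
            raise ValueError(
                "hashtag_signal must exceed 2*hashtag_background + 10 so the "
                "assignment rule is satisfiable by construction"
            )
        if self.mito_gene_count < 0 or self.mito_gene_count > self.n_genes:
            raise ValueError("mito_gene_count must lie in [0, n_genes]")
        if not 0 <= self.mito_high_fraction <= 1:
            raise ValueError("mito_high_fraction must lie in [0, 1]")
        if self.n_groups <= 0:
            raise ValueError("n_groups must be a positive integer")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        n_regular = self.n_genes - self.mito_gene_count
        if self.n_groups * self.signature_genes_per_group > n_regular:
            raise ValueError("not enough non-mitochondrial genes for planted signatures")


@dataclass
class GroundTruth:
    """Per-barcode truth plus the planted group signatures.

    ``table`` is indexed by barcode with columns ``is_cell``,
    ``sample_of_origin`` (sample label or ``DOUBLET``), ``group``,
    ``is_high_mito`` and ``is_sticky`` (isotype double-positive).
    ``doublet_samples`` records both contributing samples per doublet.
    """

    table: pd.DataFrame
    planted_signatures: dict[str, GeneSignature]
    doublet_samples: dict[str, tuple[str, str]] = field(default_factory=dict)

    def cell_barcodes(self) -> list[str]:
        return list(self.table.index[self.table["is_cell"]])

    def singlet_barcodes(self) -> list[str]:
        mask = self.table["is_cell"] & (self.table["sample_of_origin"] != DOUBLET)
        return list(self.table.index[mask])


def _gene_names(config: SimulationConfig) -> list[str]:
    # mito genes carry the mouse "mt-" prefix so default QC detection applies
    n_regular = config.n_genes - config.mito_gene_count
    names = [f"gene{i:04d}" for i in range(n_regular)]
    names += [f"mt-{i}" for i in range(config.mito_gene_count)]
    return names


def _base_profile(rng: np.random.Generator, config: SimulationConfig) -> np.ndarray:
    """Relative gene abundance summing to 1, mito genes pinned to a baseline share."""
    n = config.n_genes
    weights = rng.gamma(shape=0.6, scale=1.0, size=n) + 1e-6
    if config.mito_gene_count:
        mito = slice(n - config.mito_gene_count, n)
        reg = slice(0, n - config.mito_gene_count)
        weights[reg] *= (1 - config.mito_base_fraction) / weights[reg].sum()
        weights[mito] *= config.mito_base_fraction / weights[mito].sum()
    else:
        weights /= weights.sum()
    return weights


def _apply_mito_inflation(profile: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Rescale so mito genes carry ``mito_high_level`` of the total."""
    if not config.mito_gene_count:
        return profile
    out = profile.copy()
    n = config.n_genes
    mito = slice(n - config.mito_gene_count, n)
    reg = slice(0, n - config.mito_gene_count)
    out[mito] *= config.mito_high_level / out[mito].sum()
    out[reg] *= (1 - config.mito_high_level) / out[reg].sum()
    return out


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, r: float, size: tuple) -> np.ndarray:
    """Negative-binomial counts with mean ``mean`` and size (dispersion) ``r``."""
    mean = np.broadcast_to(mean, size)
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def generate_droplet_experiment(
    config: SimulationConfig,
) -> tuple[CountMatrix, CountMatrix, GroundTruth]:
    """Simulate one hashtag-multiplexed droplet experiment.

    Returns ``(rna_counts, protein_counts, truth)`` where both matrices share
    a barcode space covering real cells, doublets and empty droplets. The
    protein matrix contains hashtag features (``HTO1..``), isotype-control
    channels (``isotype1..``) and generic surface markers (``adt01..``).
    Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = _gene_names(config)
    n_genes = config.n_genes
    samples = [f"sample{i + 1}" for i in range(config.n_hashtags)]
    tags = [f"HTO{i + 1}" for i in range(config.n_hashtags)]
    isotypes = [f"isotype{i + 1}" for i in range(config.n_isotype_controls)]
    surface = [f"adt{i + 1:02d}" for i in range(config.n_surface_proteins)]
    groups = [f"group{i + 1}" for i in range(config.n_groups)]

    base = _base_profile(rng, config)

    # disjoint planted up-gene sets per group among non-mito genes
    n_regular = n_genes - config.mito_gene_count
    planted_pool = rng.permutation(n_regular)
    planted_signatures: dict[str, GeneSignature] = {}
    group_profiles: dict[str, np.ndarray] = {}
    planted_idx: dict[str, np.ndarray] = {}
    for gi, group in enumerate(groups):
        k = config.signature_genes_per_group
        idx = np.sort(planted_pool[gi * k : (gi + 1) * k])
        planted_idx[group] = idx
        prof = base.copy()
        prof[idx] *= 2.0 ** config.signature_effect
        prof /= prof.sum()
        group_profiles[group] = prof
        planted_signatures[group] = GeneSignature(
            name=f"{group}_planted", up_genes=[genes[i] for i in idx]
        )

    n_cells = config.n_cells
    n_doublets = int(round(config.doublet_fraction * n_cells))
    n_empty = config.n_empty_droplets

    cell_group = rng.integers(0, config.n_groups, size=n_cells)
    cell_sample = rng.integers(0, config.n_hashtags, size=n_cells)
    cell_himito = rng.random(n_cells) < config.mito_high_fraction
    cell_sticky = rng.random(n_cells) < config.isotype_sticky_fraction

    def draw_cell_rna(group_i: int, high_mito: bool) -> np.ndarray:
        prof = group_profiles[groups[group_i]]
        if high_mito:
            prof = _apply_mito_inflation(prof, config)
        return _nb_draw(rng, config.cell_mean_counts * prof, config.dispersion, (n_genes,))

    # real singlet cells — vectorized per (group, high_mito) class
    rna_cells = np.zeros((n_genes, n_cells), dtype=np.int64)
    for gi in range(config.n_groups):
        for hm in (False, True):
            mask = (cell_group == gi) & (cell_himito == hm)
            k = int(mask.sum())
            if not k:
                continue
            prof = group_profiles[groups[gi]]
            if hm:
                prof = _apply_mito_inflation(prof, config)
            mean = config.cell_mean_counts * prof
            rna_cells[:, mask] = _nb_draw(rng, mean[:, None], config.dispersion, (n_genes, k))

    # doublets: sum of two freshly drawn cells from distinct samples
    rna_doublets = np.zeros((n_genes, n_doublets), dtype=np.int64)
    doublet_pairs: list[tuple[int, int]] = []
    doublet_groups: list[str] = []
    for d in range(n_doublets):
        s1, s2 = rng.choice(config.n_hashtags, size=2, replace=False)
        g1, g2 = rng.integers(0, config.n_groups, size=2)
        rna_doublets[:, d] = draw_cell_rna(g1, False) + draw_cell_rna(g2, False)
        doublet_pairs.append((int(s1), int(s2)))
        doublet_groups.append(groups[int(g1)])

    # empty droplets: Poisson around a scaled ambient profile (group average)
    ambient = np.mean([group_profiles[g] for g in groups], axis=0)
    ambient /= ambient.sum()
    rna_empty = rng.poisson(
        config.empty_mean_counts * ambient[:, None], size=(n_genes, n_empty)
    )

    # ---- protein panel ----------------------------------------------------
    n_tags = config.n_hashtags
    capture = (
        config.ambient_capture_ratio
        if config.ambient_capture_ratio is not None
        else config.empty_mean_counts / config.cell_mean_counts
    )

    def cell_protein(own_tags: Sequence[int], sticky: bool, k: int = 1) -> np.ndarray:
        tagc = rng.poisson(config.hashtag_background, size=(n_tags, k))
        for t in own_tags:
            tagc[t] += rng.poisson(config.hashtag_signal, size=k)
        iso_mean = config.isotype_sticky_mean if sticky else config.isotype_base_mean
        isoc = rng.poisson(iso_mean, size=(config.n_isotype_controls, k))
        surfc = rng.poisson(config.surface_mean_counts, size=(config.n_surface_proteins, k))
        return np.vstack([tagc, isoc, surfc])

    n_prot = n_tags + config.n_isotype_controls + config.n_surface_proteins
    prot_cells = np.zeros((n_prot, n_cells), dtype=np.int64)
    for c in range(n_cells):
        prot_cells[:, c] = cell_protein([int(cell_sample[c])], bool(cell_sticky[c]))[:, 0]
    prot_doublets = np.zeros((n_prot, n_doublets), dtype=np.int64)
    for d, (s1, s2) in enumerate(doublet_pairs):
        prot_doublets[:, d] = cell_protein([s1, s2], False)[:, 0]
    prot_empty = np.vstack(
        [
            rng.poisson(config.hashtag_background * capture, size=(n_tags, n_empty)),
            rng.poisson(config.isotype_base_mean * capture, size=(config.n_isotype_controls, n_empty)),
            rng.poisson(config.surface_mean_counts * capture, size=(config.n_surface_proteins, n_empty)),
        ]
    )

    # ---- assemble, shuffle barcode order ----------------------------------
    n_total = n_cells + n_doublets + n_empty
    order = rng.permutation(n_total)
    barcodes = [f"BC{i + 1:06d}" for i in range(n_total)]

    rna_all = np.concatenate([rna_cells, rna_doublets, rna_empty], axis=1)[:, order]
    prot_all = np.concatenate([prot_cells, prot_doublets, prot_empty], axis=1)[:, order]

    kind = np.array(
        ["cell"] * n_cells + ["doublet"] * n_doublets + ["empty"] * n_empty
    )[order]
    origin = np.array(
        [samples[s] for s in cell_sample]
        + [DOUBLET] * n_doublets
        + [""] * n_empty
    )[order]
    group_lab = np.array(
        [groups[g] for g in cell_group] + doublet_groups + [""] * n_empty
    )[order]
    himito = np.concatenate(
        [cell_himito, np.zeros(n_doublets, bool), np.zeros(n_empty, bool)]
    )[order]
    sticky = np.concatenate(
        [cell_sticky, np.zeros(n_doublets, bool), np.zeros(n_empty, bool)]
    )[order]

    table = pd.DataFrame(
        {
            "is_cell": kind != "empty",
            "sample_of_origin": origin,
            "group": group_lab,
            "is_high_mito": himito,
            "is_sticky": sticky,
        },
        index=pd.Index(barcodes, name="barcode"),
    )

    doublet_samples: dict[str, tuple[str, str]] = {}
    orig_pos = np.argsort(order)  # original index -> emitted position
    for d, (s1, s2) in enumerate(doublet_pairs):
        bc = barcodes[int(orig_pos[n_cells + d])]
        doublet_samples[bc] = (samples[s1], samples[s2])

    rna = CountMatrix(sp.csr_matrix(rna_all), genes, barcodes)
    prot = CountMatrix(sp.csr_matrix(prot_all), tags + isotypes + surface, barcodes)
    truth = GroundTruth(
        table=table,
        planted_signatures=planted_signatures,
        doublet_samples=doublet_samples,
    )
    return rna, prot, truth


# ---------------------------------------------------------------------------
# staged reference (bulk-like differentiation time course)
# ---------------------------------------------------------------------------


@dataclass
class StagedTruth:
    """Planted genes per stage of a simulated differentiation time course."""

    planted: dict[str, list[str]]  # stage -> genes newly up-regulated at that stage
    mode: str  # "cumulative" or "exclusive"
    naive_label: str = "naive"

    def cumulative_planted(self, stage: str) -> list[str]:
        if self.mode == "exclusive":
            return list(self.planted[stage])
        out: list[str] = []
        for s, genes in self.planted.items():
            out.extend(genes)
            if s == stage:
                break
        return out


def generate_staged_reference(
    n_timepoints: int,
    genes_per_stage: int,
    config: SimulationConfig,
    n_samples_per_stage: int = 20,
    mode: str = "cumulative",
    bulk_depth: float = 1_000_000.0,
) -> tuple[ExpressionMatrix, pd.Series, StagedTruth]:
    """Simulate a samples x genes staged reference expression table.

    Emits a naive stage plus ``n_timepoints`` ordered timepoints
    (``d05, d10, ...``). Each timepoint plants ``genes_per_stage`` up-regulated
    genes (log2 fold-change ``config.signature_effect``); in ``cumulative``
    mode a stage also keeps all earlier stages' genes up (a differentiation
    program that accrues), in ``exclusive`` mode each stage's genes are up at
    that stage only. Samples are drawn at ``bulk_depth`` total counts —
    bulk-scale sequencing, unlike droplet UMI depth. Values are returned as
    log2(CP10K+1).
    """
    if n_timepoints < 2:
        raise ValueError("n_timepoints must be >= 2")
    if mode not in ("cumulative", "exclusive"):
        raise ValueError(f"unknown mode {mode!r}")
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_genes = config.n_genes
    genes = [f"gene{i:04d}" for i in range(n_genes)]
    stages = ["naive"] + [f"d{5 * (i + 1):02d}" for i in range(n_timepoints)]
    if n_timepoints * genes_per_stage > n_genes:
        raise ValueError("not enough genes for the requested planted sets")

    base = rng.gamma(shape=0.6, scale=1.0, size=n_genes) + 1e-6
    base /= base.sum()
    pool = rng.permutation(n_genes)
    planted = {
        stage: sorted(genes[i] for i in pool[k * genes_per_stage : (k + 1) * genes_per_stage])
        for k, stage in enumerate(stages[1:])
    }

    rows, labels = [], []
    for si, stage in enumerate(stages):
        prof = base.copy()
        if si > 0:
            active = stages[1 : si + 1] if mode == "cumulative" else [stage]
            for s in active:
                idx = [genes.index(g) for g in planted[s]]
                prof[idx] *= 2.0 ** config.signature_effect
            prof /= prof.sum()
        mean = bulk_depth * prof
        counts = _nb_draw(rng, mean[None, :], config.dispersion, (n_samples_per_stage, n_genes))
        rows.append(counts)
        labels += [stage] * n_samples_per_stage

    counts = np.concatenate(rows, axis=0)
    sample_ids = [f"{lab}_s{i + 1:02d}" for i, lab in enumerate(labels)]
    totals = counts.sum(axis=1, keepdims=True).astype(float)
    totals[totals == 0] = 1.0
    values = np.log2(counts / totals * 1e4 + 1.0)
    expr = ExpressionMatrix(
        pd.DataFrame(values, index=sample_ids, columns=genes),
        normalization="log2_cp10k1",
    )
    stage_labels = pd.Series(labels, index=sample_ids, name="stage")
    return expr, stage_labels, StagedTruth(planted=planted, mode=mode)


def simulate_expression_groups(
    genes: Sequence[str],
    group_up_genes: Mapping[str, Sequence[str]],
    n_cells_per_group: int,
    effect: float,
    mean_counts: float = 2000.0,
    dispersion: float = 2.0,
    seed: int = 0,
) -> tuple[CountMatrix, pd.Series]:
    """Simulate labelled cell groups with planted up-genes (no droplet layer).

    Convenience generator for scoring experiments: each group's planted genes
    get a log2 fold-change of ``effect`` over a shared baseline profile;
    groups with an empty planted list are null. Returns a genes x cells
    :class:`CountMatrix` and the cell -> group label Series.
    """
    rng = np.random.default_rng(seed)
    genes = list(genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    base = rng.gamma(shape=0.6, scale=1.0, size=len(genes)) + 1e-6
    base /= base.sum()

    blocks, labels, barcodes = [], [], []
    for group, up in group_up_genes.items():
        prof = base.copy()
        idx = [gene_index[g] for g in up]
        if idx:
            prof[idx] *= 2.0 ** effect
            prof /= prof.sum()
        counts = _nb_draw(
            rng, mean_counts * prof[:, None], dispersion, (len(genes), n_cells_per_group)
        )
        blocks.append(counts)
        labels += [group] * n_cells_per_group
        barcodes += [f"{group}_c{i + 1:04d}" for i in range(n_cells_per_group)]

    matrix = sp.csr_matrix(np.concatenate(blocks, axis=1))
    return (
        CountMatrix(matrix, genes, barcodes),
        pd.Series(labels, index=barcodes, name="group"),
    )
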