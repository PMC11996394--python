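"""End-to-end pipeline: cell calling -> demux -> QC -> scoring -> quantification.

Stages run in a fixed order, each writing its artifact into the output
directory; a machine-readable run log records parameters, seed, stage
toggles and per-stage barcode counts. Any stage failure aborts with the
stage name while keeping the artifacts already written.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .containers import CountMatrix
from .demux import DOUBLET, UNASSIGNED, demultiplex
from .droplets import call_cells, find_inflection, rank_barcodes
from .io import (
    params_hash,
    read_gmt,
    read_mtx,
    write_tidy_csv,
)
from .qc import default_isotype_features, default_mito_genes, filter_cells
from .quantify import cluster_frequencies
from .signatures import center_genes, normalize_and_log, score_with_control
from .trajectory import build_timepoint_signatures, score_trajectory
from .containers import ExpressionMatrix

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Paths, stage toggles and parameters of one pipeline run."""

    rna_dir: str
    adt_dir: str
    out_dir: str
    seed: int
    hashtag_prefix: str = "HTO"
    sample_map: dict[str, str] = field(default_factory=dict)
    groups_csv: str | None = None  # barcode,cluster (and optional condition)
    signatures_gmt: str | None = None
    reference_csv: str | None = None  # staged reference, stage-label column "stage"
    # stage toggles
    run_callcells: bool = True
    run_demux: bool = True
    run_qc: bool = True
    run_score: bool = True
    run_trajectory: bool = True
    run_quantify: bool = True
    # parameters
    min_counts: int = 10
    ratio: float = 2.0
    doublet_positive_threshold: int = 10
    min_rna: int = 500
    max_mito_frac: float = 0.10
    min_adt: int = 500
    isotype_positive_threshold: int = 10
    normalization: str = "log2_cp10k1"
    n_iter: int = 1000
    top_n: int = 100

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def params(self) -> dict:
        return asdict(self)

    def analysis_params(self) -> dict:
        """Parameters that determine results (output location excluded)."""
        d = asdict(self)
        d.pop("out_dir", None)
        return d


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the enabled stages in order; returns the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_log: dict = {
        "version": __version__,
        "seed": config.seed,
        "params_hash": params_hash(config.analysis_params()),
        "params": config.params(),
        "stages": {},
        "warnings": [],
    }

    def finish_stage(stage: str, **info) -> None:
        run_log["stages"][stage] = info
        (out / "run_log.json").write_text(json.dumps(run_log, indent=2, default=str))

    stage = "load"
    try:
        rna = read_mtx(config.rna_dir)
        adt = read_mtx(config.adt_dir)
        finish_stage(stage, n_barcodes=len(rna.barcodes), n_genes=len(rna.genes))

        if config.run_callcells:
            stage = "callcells"
            cells = sorted(call_cells(rna, adt))
            if not cells:
                run_log["warnings"].append("empty intersection of RNA and ADT cell calls")
            curve = rank_barcodes(rna)
            write_tidy_csv(curve.to_frame(), out / "rank_curve.csv",
                           seed=config.seed, params=config.analysis_params())
            (out / "called_barcodes.tsv").write_text("".join(b + "\n" for b in cells))
            finish_stage(stage, n_called=len(cells))
        else:
            cells = list(rna.barcodes)
            finish_stage("callcells", skipped=True, n_called=len(cells))

        rna_cells = rna.subset_barcodes(cells)
        adt_cells = adt.subset_barcodes(cells)

        if config.run_demux:
            stage = "demux"
            tags = [f for f in adt.genes if f.startswith(config.hashtag_prefix)]
            result = demultiplex(
                adt_cells.subset_genes(tags),
                min_counts=config.min_counts,
                ratio=config.ratio,
                doublet_positive_threshold=config.doublet_positive_threshold,
                sample_map=config.sample_map or None,
            )
            write_tidy_csv(result.table.reset_index(), out / "demux.csv",
                           seed=config.seed, params=config.analysis_params())
            singlets = list(result.singlets().index)
            finish_stage(
                stage,
                n_singlet=len(singlets),
                n_doublet=int((result.assignments() == DOUBLET).sum()),
                n_unassigned=int((result.assignments() == UNASSIGNED).sum()),
            )
            sample_of: pd.Series | None = result.singlets()["assignment"]
        else:
            singlets = cells
            sample_of = None
            finish_stage("demux", skipped=True)

        rna_s = rna_cells.subset_barcodes(singlets)
        adt_s = adt_cells.subset_barcodes(singlets)

        if config.run_qc:
            stage = "qc"
            report = filter_cells(
                rna_s, adt_s,
                mito_genes=default_mito_genes(rna.genes),
                isotype_controls=default_isotype_features(adt.genes),
                min_rna=config.min_rna,
                max_mito_frac=config.max_mito_frac,
                min_adt=config.min_adt,
                isotype_positive_threshold=config.isotype_positive_threshold,
            )
            (out / "qc_report.json").write_text(json.dumps(report.to_dict(), indent=2))
            (out / "kept_barcodes.tsv").write_text("".join(b + "\n" for b in report.kept))
            kept = report.kept
            finish_stage(stage, **report.to_dict())
        else:
            kept = singlets
            finish_stage("qc", skipped=True, n_kept=len(kept))

        stage = "normalize"
        expr = center_genes(
            normalize_and_log(rna_s.subset_barcodes(kept), mode=config.normalization)
        )
        finish_stage(stage, n_cells=len(kept), normalization=config.normalization)

        groups: pd.Series | None = None
        conditions: pd.Series | None = None
        if config.groups_csv:
            gdf = pd.read_csv(config.groups_csv, comment="#").set_index("barcode")
            groups = gdf["cluster"].reindex(kept).dropna().astype(str)
            if "condition" in gdf.columns:
                conditions = gdf["condition"].reindex(kept).dropna().astype(str)
        elif sample_of is not None:
            groups = sample_of.reindex(kept).dropna().astype(str)

        if config.run_score and config.signatures_gmt and groups is not None:
            stage = "score"
            rows = []
            for si, sig in enumerate(read_gmt(config.signatures_gmt)):
                results = score_with_control(
                    expr, sig, groups, n_iter=config.n_iter, seed=config.seed + si
                )
                rows += [r.to_dict() for r in results.values()]
            write_tidy_csv(pd.DataFrame(rows), out / "scores.csv",
                           seed=config.seed, params=config.analysis_params())
            finish_stage(stage, n_signatures=si + 1, n_groups=groups.nunique())

        if config.run_trajectory and config.reference_csv and groups is not None:
            stage = "trajectory"
            ref = pd.read_csv(config.reference_csv, comment="#", index_col=0)
            stages_col = ref.pop("stage")
            ref_expr = ExpressionMatrix(ref, normalization="none-provided-prelogged")
            sigs = build_timepoint_signatures(ref_expr, stages_col, top_n=config.top_n)
            profiles = score_trajectory(
                expr, groups, sigs, n_iter=config.n_iter, seed=config.seed
            )
            tidy = pd.concat([p.to_frame() for p in profiles.values()], ignore_index=True)
            write_tidy_csv(tidy, out / "trajectory.csv",
                           seed=config.seed, params=config.analysis_params())
            finish_stage(stage, n_timepoints=len(sigs))

        if config.run_quantify and groups is not None and conditions is not None:
            stage = "quantify"
            shared = groups.index.intersection(conditions.index)
            table = cluster_frequencies(groups.loc[shared], conditions.loc[shared])
            write_tidy_csv(table.to_tidy(), out / "cluster_frequencies.csv",
                           seed=config.seed, params=config.analysis_params())
            finish_stage(stage, n_conditions=int(table.counts.shape[0]))

    except PipelineError:
        raise
    except Exception as exc:
        finish_stage(stage, error=str(exc))
        raise PipelineError(stage, exc) from exc

    return out
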