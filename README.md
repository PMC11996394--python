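# trmsig

Analysis pipeline for hashtag-multiplexed droplet single-cell experiments on
epidermal CD8⁺ tissue-resident memory (T_RM) T cells. The package covers the
computational path from a raw gene×barcode UMI matrix to biological
quantities: separating cell-containing droplets from empties on the barcode
rank curve, assigning cells to their sample of origin from hashtag counts,
excluding low-quality cells, scoring cells and groups against reference
transcriptional-state gene signatures with a randomized control,
staging groups along a differentiation time course, and the statistics used
to compare conditions (paired/unpaired t, Dunnett many-to-one, cluster
frequencies, epidermal cell densities). A synthetic-data module generates
droplet experiments and staged reference tables with known ground truth, so
every stage is testable end to end without external data.

## The core statistic

For a gene signature with up-set *U* and down-set *D*, expression is
normalized to log scale (log₂(TPM+1) for bulk, log₂(CP10K+1) for UMI data)
and centered per gene across all cells, giving values *z₍c,g₎*. The score of
cell *c* is

    s(c) = mean_{g∈U} z(c,g) − mean_{g∈D} z(c,g)

and a group's raw score is the mean of its cells' scores, with a 95% normal
CI. Because the statistic depends on |U|, |D| and gene coverage, a control
score — the same quantity on randomly drawn gene sets of equal sizes
(default 1,000 iterations) — is subtracted:

    adjusted = raw − mean(control)

Under gene exchangeability the adjusted score is null-calibrated at zero.
Signatures can be supplied (GMT / two-column CSV) or derived as the top-*n*
rank-sum DEGs of a group versus a reference (e.g. each T_RM timepoint versus
naive), which is how the trajectory stage builds its ordered signature
series.

## Worked example

```python
from trmsig import (
    SimulationConfig, generate_droplet_experiment, call_cells, demultiplex,
    filter_cells, normalize_and_log, center_genes, score_with_control,
)

config = SimulationConfig(seed=1)          # 500 cells, 5000 empties, 4 hashtags
rna, adt, truth = generate_droplet_experiment(config)

cells = sorted(call_cells(rna, adt))       # knee on RNA and antibody curves
print(len(cells))                          # 525  (500 cells + 25 doublets)

tags = [f for f in adt.genes if f.startswith("HTO")]
demux = demultiplex(adt.subset_barcodes(cells).subset_genes(tags),
                    sample_map={f"HTO{i+1}": f"sample{i+1}" for i in range(4)})
print(demux.assignments().value_counts().to_dict())
# {'sample1': 137, 'sample2': 125, 'sample4': 120, 'sample3': 118, 'DOUBLET': 25}

report = filter_cells(rna.subset_barcodes(cells), adt.subset_barcodes(cells))
print(report.removed)                      # {'low_rna': 0, 'high_mito': 27,
                                           #  'low_adt': 0, 'isotype_double_positive': 8}

expr = center_genes(normalize_and_log(rna.subset_barcodes(report.kept)))
groups = truth.table.loc[report.kept, "group"]
sig = truth.planted_signatures["group1"]
for res in score_with_control(expr, sig, groups, n_iter=1000, seed=1).values():
    print(res.group, round(res.adjusted_score, 3), tuple(round(x, 3) for x in res.ci95))
# group1 0.728 (0.693, 0.762)
# group2 -0.78 (-0.82, -0.74)
```

The 525 called barcodes are exactly the simulated real droplets; the 25
hashtag doublets are flagged and excluded; QC removes the planted dying
(high-mitochondrial) and antibody-sticky cells; and the planted signature
scores strongly positive in its own group and negative in the other (with
two groups, centering makes the scores mirror images).

A `trmsig` console command exposes each stage
(`simulate, callcells, demux, qc, score, trajectory, quantify, run`); `run`
executes the full pipeline from a YAML config and writes per-stage
artifacts plus a JSON run log with seeds and parameter hashes.

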