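"""Signature scoring: normalization, centering, score formula, randomized
control, signature derivation. The scoring path is checked against an
element-by-element brute-force oracle written with explicit loops."""
import numpy as np
import pandas as pd
import pytest

from trmsig import (
    ExpressionMatrix,
    GeneSignature,
    adjusted_score,
    center_genes,
    derive_signature,
    normalize_and_log,
    pseudobulk_scores,
    random_control,
    score_signature,
    score_with_control,
    simulate_expression_groups,
)

from conftest import make_count_matrix


# ---- independent oracle ----------------------------------------------------


def brute_force_group_score(values: pd.DataFrame, up, down, cells) -> float:
    """Mean over cells of (mean up-gene value - mean down-gene value),
    computed with explicit Python loops."""
    total = 0.0
    for cell in cells:
        up_sum = 0.0
        for g in up:
            up_sum += values.loc[cell, g]
        cell_score = up_sum / len(up)
        if down:
            down_sum = 0.0
            for g in down:
                down_sum += values.loc[cell, g]
            cell_score -= down_sum / len(down)
        total += cell_score
    return total / len(cells)


def centered(values: np.ndarray) -> ExpressionMatrix:
    df = pd.DataFrame(
        values,
        index=[f"c{i}" for i in range(values.shape[0])],
        columns=[f"g{i}" for i in range(values.shape[1])],
    )
    return ExpressionMatrix(df - df.mean(axis=0), centered=True)


# ---- normalization ---------------------------------------------------------


def test_cp10k_on_uniform_counts_is_closed_form():
    counts = make_count_matrix(np.full((4, 3), 7))
    expr = normalize_and_log(counts, mode="log2_cp10k1")
    expected = np.log2(10_000 / 4 + 1)
    assert np.allclose(expr.values.to_numpy(), expected)


def test_zero_counts_map_to_zero():
    counts = make_count_matrix([[0, 5], [10, 0]])
    expr = normalize_and_log(counts)
    assert expr.values.loc["b0", "g0"] == 0.0
    assert expr.values.loc["b1", "g1"] == 0.0


def test_tpm_matches_hand_computation():
    counts = make_count_matrix([[10], [10]], genes=["gA", "gB"], barcodes=["cell"])
    lengths = pd.Series({"gA": 1000.0, "gB": 2000.0})
    expr = normalize_and_log(counts, mode="log2_tpm1", gene_lengths=lengths)
    # rates (10/1, 10/2) -> TPM (666666.67, 333333.33)
    assert expr.values.loc["cell", "gA"] == pytest.approx(np.log2(666666.67 + 1), rel=1e-6)
    assert expr.values.loc["cell", "gB"] == pytest.approx(np.log2(333333.33 + 1), rel=1e-6)


def test_tpm_requires_gene_lengths():
    with pytest.raises(ValueError, match="lengths"):
        normalize_and_log(make_count_matrix([[1]]), mode="log2_tpm1")


# ---- centering -------------------------------------------------------------


def test_centering_subtracts_gene_means():
    expr = ExpressionMatrix(pd.DataFrame({"g": [1.0, 2.0, 3.0]}))
    out = center_genes(expr)
    assert list(out.values["g"]) == [-1.0, 0.0, 1.0]
    assert out.centered


def test_recentering_warns_and_is_identity():
    expr = center_genes(ExpressionMatrix(pd.DataFrame({"g": [1.0, 3.0]})))
    with pytest.warns(UserWarning, match="already centered"):
        again = center_genes(expr)
    pd.testing.assert_frame_equal(again.values, expr.values)


def test_centered_gene_means_are_zero(small_experiment):
    _, rna, _, truth = small_experiment
    expr = center_genes(normalize_and_log(rna.subset_barcodes(truth.cell_barcodes())))
    assert np.abs(expr.values.mean(axis=0)).max() < 1e-8


# ---- score formula ---------------------------------------------------------


def test_score_formula_on_constructed_cell():
    values = pd.DataFrame(
        [[1.0, 1.0, -1.0, -1.0], [-1.0, -1.0, 1.0, 1.0]],
        index=["hit", "anti"], columns=["u1", "u2", "d1", "d2"],
    )
    expr = ExpressionMatrix(values, centered=True)
    sig = GeneSignature("s", ["u1", "u2"], ["d1", "d2"])
    res = score_signature(expr, sig, pd.Series({"hit": "A", "anti": "B"}))
    assert res["A"].raw_score == pytest.approx(2.0)
    assert res["B"].raw_score == pytest.approx(-2.0)


def test_identical_up_and_down_content_scores_zero():
    rng = np.random.default_rng(0)
    expr = centered(rng.normal(size=(5, 6)))
    dup = ExpressionMatrix(
        pd.concat([expr.values, expr.values.add_suffix("_copy")], axis=1),
        centered=True,
    )
    sig = GeneSignature("sym", ["g0", "g1"], ["g0_copy", "g1_copy"])
    res = score_signature(dup, sig, pd.Series("all", index=dup.cells))
    assert res["all"].raw_score == pytest.approx(0.0, abs=1e-12)


def test_group_score_matches_brute_force_oracle():
    rng = np.random.default_rng(42)
    expr = centered(rng.normal(size=(3, 4)))
    groups = pd.Series({"c0": "x", "c1": "x", "c2": "y"})
    sig = GeneSignature("s", ["g0", "g2"], ["g3"])
    res = score_signature(expr, sig, groups)
    for group, cells in [("x", ["c0", "c1"]), ("y", ["c2"])]:
        expected = brute_force_group_score(expr.values, ["g0", "g2"], ["g3"], cells)
        assert res[group].raw_score == pytest.approx(expected, abs=1e-12)


def test_absent_genes_are_dropped_and_counted():
    expr = centered(np.random.default_rng(1).normal(size=(4, 5)))
    sig = GeneSignature("s", ["g0", "nope"], ["g1", "missing"])
    res = score_signature(expr, sig, pd.Series("a", index=expr.cells))
    assert res["a"].n_up_used == 1 and res["a"].n_down_used == 1


def test_no_up_genes_present_is_an_error_naming_the_signature():
    expr = centered(np.zeros((2, 3)))
    with pytest.raises(ValueError, match="mysig"):
        score_signature(expr, GeneSignature("mysig", ["nope"]), pd.Series("a", index=expr.cells))


def test_uncentered_matrix_is_rejected():
    expr = ExpressionMatrix(pd.DataFrame({"g": [1.0, 2.0]}))
    with pytest.raises(ValueError, match="centered"):
        score_signature(expr, GeneSignature("s", ["g"]), pd.Series("a", index=expr.cells))


# ---- invariances -----------------------------------------------------------


def test_score_invariant_to_gene_and_cell_order():
    rng = np.random.default_rng(7)
    expr = centered(rng.normal(size=(6, 8)))
    sig = GeneSignature("s", ["g1", "g4"], ["g6"])
    groups = pd.Series(["a", "a", "b", "b", "a", "b"], index=expr.cells)
    base = score_signature(expr, sig, groups)
    shuffled = ExpressionMatrix(
        expr.values.iloc[::-1, ::-1], centered=True
    )
    perm = score_signature(shuffled, sig, groups)
    for g in ("a", "b"):
        assert perm[g].raw_score == pytest.approx(base[g].raw_score, abs=1e-12)


def test_per_gene_additive_offset_is_removed_by_centering():
    rng = np.random.default_rng(8)
    raw = pd.DataFrame(rng.normal(size=(5, 4)),
                       index=[f"c{i}" for i in range(5)],
                       columns=[f"g{i}" for i in range(4)])
    shifted = raw.copy()
    shifted["g2"] += 17.0
    sig = GeneSignature("s", ["g0", "g2"], ["g1"])
    groups = pd.Series("a", index=raw.index)
    base = score_signature(center_genes(ExpressionMatrix(raw)), sig, groups)
    offs = score_signature(center_genes(ExpressionMatrix(shifted)), sig, groups)
    assert offs["a"].raw_score == pytest.approx(base["a"].raw_score, abs=1e-12)


def test_score_is_linear_in_expression():
    rng = np.random.default_rng(9)
    expr = centered(rng.normal(size=(5, 6)))
    sig = GeneSignature("s", ["g0", "g3"], ["g5"])
    groups = pd.Series("a", index=expr.cells)
    base = score_signature(expr, sig, groups)["a"].raw_score
    scaled = ExpressionMatrix(expr.values * 3.0, centered=True)
    assert score_signature(scaled, sig, groups)["a"].raw_score == pytest.approx(3 * base)


# ---- random control --------------------------------------------------------


def test_random_control_is_deterministic():
    rng = np.random.default_rng(10)
    expr = centered(rng.normal(size=(10, 20)))
    groups = pd.Series("a", index=expr.cells)
    c1 = random_control(expr, 3, 2, groups, n_iter=2, seed=5)
    c2 = random_control(expr, 3, 2, groups, n_iter=2, seed=5)
    pd.testing.assert_frame_equal(c1, c2)


def test_random_control_rejects_oversized_sets():
    expr = centered(np.zeros((3, 4)))
    with pytest.raises(ValueError, match="exceeds"):
        random_control(expr, 3, 2, pd.Series("a", index=expr.cells), n_iter=5, seed=0)


def test_control_mean_is_null_on_exchangeable_genes():
    rng = np.random.default_rng(11)
    expr = centered(rng.normal(size=(50, 200)))
    groups = pd.Series("a", index=expr.cells)
    ctrl = random_control(expr, 10, 10, groups, n_iter=2000, seed=3)
    mean, sd = ctrl.loc["a", "control_mean"], ctrl.loc["a", "control_sd"]
    assert abs(mean) < 3 * sd / np.sqrt(2000)


def test_excluding_signature_genes_changes_little_under_the_null():
    """Signature genes stay in the sampling pool by design; dropping them
    from the pool shifts the control by less than sampling error on an
    exchangeable fixture."""
    rng = np.random.default_rng(12)
    expr = centered(rng.normal(size=(40, 300)))
    groups = pd.Series("a", index=expr.cells)
    full = random_control(expr, 10, 0, groups, n_iter=2000, seed=4)
    reduced_expr = ExpressionMatrix(expr.values.iloc[:, 20:], centered=True)
    reduced = random_control(reduced_expr, 10, 0, groups, n_iter=2000, seed=4)
    se = full.loc["a", "control_sd"] / np.sqrt(2000)
    assert abs(full.loc["a", "control_mean"] - reduced.loc["a", "control_mean"]) < 4 * se


# ---- adjusted score --------------------------------------------------------


def test_adjusted_score_is_plain_subtraction():
    assert adjusted_score(0.8, 0.05) == pytest.approx(0.75)
    assert adjusted_score(0.3, 0.3) == 0.0


def test_planted_group_outscores_null_group():
    genes = [f"g{i}" for i in range(200)]
    planted = genes[:20]
    counts, labels = simulate_expression_groups(
        genes, {"planted": planted, "null": []}, n_cells_per_group=40,
        effect=2.0, seed=21,
    )
    expr = center_genes(normalize_and_log(counts))
    res = score_with_control(expr, GeneSignature("sig", planted), labels,
                             n_iter=200, seed=22)
    assert res["planted"].adjusted_score > res["null"].adjusted_score
    assert res["planted"].adjusted_score == pytest.approx(
        res["planted"].raw_score - res["planted"].control_mean
    )
    lo, hi = res["planted"].ci95
    assert lo <= res["planted"].adjusted_score <= hi


# ---- pseudobulk ------------------------------------------------------------


def test_pseudobulk_of_identical_populations_scores_equal():
    rng = np.random.default_rng(13)
    block = rng.normal(size=(10, 12))
    expr = centered(np.vstack([block, block]))
    cond = pd.Series(["A"] * 10 + ["B"] * 10, index=expr.cells)
    sig = GeneSignature("s", ["g0", "g4"], ["g7"])
    df = pseudobulk_scores(expr, cond, [sig], mode="pseudobulk", n_iter=50, seed=1)
    scores = df.set_index("group")["raw_score"]
    assert scores["A"] == pytest.approx(scores["B"], abs=1e-12)


def test_single_cell_pseudobulk_equals_cell_mode():
    rng = np.random.default_rng(14)
    expr = centered(rng.normal(size=(2, 6)))
    cond = pd.Series(["A", "B"], index=expr.cells)
    sig = GeneSignature("s", ["g0", "g2"], ["g5"])
    pb = pseudobulk_scores(expr, cond, [sig], mode="pseudobulk", n_iter=50, seed=2)
    cm = pseudobulk_scores(expr, cond, [sig], mode="cell", n_iter=50, seed=2)
    for g in ("A", "B"):
        assert (
            pb.set_index("group").loc[g, "raw_score"]
            == pytest.approx(cm.set_index("group").loc[g, "raw_score"], abs=1e-12)
        )


def test_pseudobulk_rejects_empty_condition():
    expr = centered(np.zeros((2, 3)))
    cond = pd.Series(["A", "A"], index=expr.cells).reindex(expr.cells)
    with pytest.raises((ValueError, KeyError)):
        pseudobulk_scores(expr, pd.Series({"c0": "A"}), [GeneSignature("s", ["g0"])])


# ---- signature derivation --------------------------------------------------


def test_identical_groups_yield_near_empty_signature():
    rng = np.random.default_rng(15)
    expr = centered(rng.normal(size=(20, 50)))
    with pytest.warns(UserWarning):
        sig = derive_signature(expr, list(expr.cells[:10]), list(expr.cells[10:]),
                               top_n=10, min_abs_lfc=0.25)
    assert len(sig) <= 4
    assert sig.notes


def test_top_n_one_picks_the_strongest_gene():
    rng = np.random.default_rng(16)
    vals = rng.normal(size=(20, 10))
    vals[:10, 3] += 5.0  # unambiguous winner in the first group
    expr = centered(vals)
    sig = derive_signature(expr, list(expr.cells[:10]), list(expr.cells[10:]),
                           top_n=1, min_abs_lfc=0.25)
    assert set(sig.up_genes) == {"g3"}


def test_derivation_recovers_planted_genes():
    genes = [f"g{i}" for i in range(300)]
    planted = genes[:25]
    counts, labels = simulate_expression_groups(
        genes, {"hot": planted, "ref": []}, n_cells_per_group=50, effect=2.0, seed=17,
    )
    expr = center_genes(normalize_and_log(counts))
    sig = derive_signature(
        expr, list(labels.index[labels == "hot"]), list(labels.index[labels == "ref"]),
        top_n=25,
    )
    assert len(set(sig.up_genes) & set(planted)) / len(planted) >= 0.9
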