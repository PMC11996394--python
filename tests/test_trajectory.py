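"""Staged-reference signatures and trajectory profiles."""
import numpy as np
import pandas as pd
import pytest

from trmsig import (
    ExpressionMatrix,
    GeneSignature,
    SimulationConfig,
    build_timepoint_signatures,
    center_genes,
    generate_staged_reference,
    normalize_and_log,
    score_trajectory,
    score_with_control,
    simulate_expression_groups,
)


@pytest.fixture(scope="module")
def staged():
    config = SimulationConfig(seed=31, n_genes=300, signature_effect=2.0)
    expr, stages, truth = generate_staged_reference(
        3, 20, config, n_samples_per_stage=15, mode="exclusive"
    )
    return expr, stages, truth


def test_missing_naive_stage_is_an_error(staged):
    expr, stages, _ = staged
    with pytest.raises(ValueError, match="naive"):
        build_timepoint_signatures(expr, stages, naive_label="not-there")


def test_signatures_come_out_in_stage_order(staged):
    expr, stages, _ = staged
    sigs = build_timepoint_signatures(expr, stages, top_n=20)
    assert [s.name for s in sigs] == ["d05", "d10", "d15"]


def test_up_only_direction_drops_down_genes(staged):
    expr, stages, _ = staged
    sigs = build_timepoint_signatures(expr, stages, top_n=20, direction="up")
    assert all(not s.down_genes for s in sigs)
    assert all(s.up_genes for s in sigs)


def test_stage_signatures_recover_planted_genes(staged):
    expr, stages, truth = staged
    sigs = build_timepoint_signatures(expr, stages, top_n=20)
    for sig in sigs:
        planted = set(truth.planted[sig.name])
        assert len(set(sig.up_genes) & planted) / len(planted) >= 0.9


def test_identical_stages_give_overlapping_signatures():
    """Duplicating one stage's samples under a new label must reproduce its
    signature up to noise."""
    config = SimulationConfig(seed=32, n_genes=300)
    expr, stages, _ = generate_staged_reference(
        2, 20, config, n_samples_per_stage=15, mode="exclusive"
    )
    dup_values = pd.concat(
        [expr.values, expr.values.loc[stages == "d10"].rename(lambda s: s + "_dup")]
    )
    dup_stages = pd.concat(
        [stages, pd.Series("d10b", index=[s + "_dup" for s in stages.index[stages == "d10"]])]
    )
    dup_expr = ExpressionMatrix(dup_values, normalization=expr.normalization)
    sigs = {s.name: s for s in build_timepoint_signatures(dup_expr, dup_stages, top_n=20)}
    overlap = len(sigs["d10"].up_genes & sigs["d10b"].up_genes) / 20
    assert overlap >= 0.8


def _query(staged, groups_planted, n_cells=30, seed=33):
    expr, _, truth = staged
    counts, labels = simulate_expression_groups(
        list(expr.genes), groups_planted, n_cells_per_group=n_cells,
        effect=2.0, seed=seed,
    )
    return center_genes(normalize_and_log(counts)), labels


def test_single_timepoint_reduces_to_signature_score(staged):
    expr, stages, _ = staged
    sigs = build_timepoint_signatures(expr, stages, top_n=20)[:1]
    qexpr, labels = _query(staged, {"grp": []})
    profiles = score_trajectory(qexpr, labels, sigs, n_iter=100, seed=1)
    direct = score_with_control(qexpr, sigs[0], labels, n_iter=100, seed=1)
    assert profiles["grp"].adjusted_scores[0] == pytest.approx(
        direct["grp"].adjusted_score
    )


def test_group_absent_from_matrix_is_an_error(staged):
    expr, stages, _ = staged
    sigs = build_timepoint_signatures(expr, stages, top_n=20)
    qexpr, labels = _query(staged, {"grp": []})
    ghost = pd.concat([labels, pd.Series({"missing_cell": "ghost"})])
    with pytest.raises((ValueError, KeyError), match="ghost|missing"):
        score_trajectory(qexpr, ghost, sigs, n_iter=50, seed=2)


def test_profile_invariant_to_cell_permutation(staged):
    expr, stages, truth = staged
    sigs = build_timepoint_signatures(expr, stages, top_n=20)
    qexpr, labels = _query(staged, {"grp": truth.planted["d05"]})
    base = score_trajectory(qexpr, labels, sigs, n_iter=100, seed=3)
    perm = np.random.default_rng(0).permutation(len(qexpr.cells))
    shuffled = ExpressionMatrix(qexpr.values.iloc[perm], centered=True)
    again = score_trajectory(shuffled, labels, sigs, n_iter=100, seed=3)
    assert np.allclose(base["grp"].adjusted_scores, again["grp"].adjusted_scores)


def test_concatenated_groups_score_their_weighted_mean(staged):
    expr, stages, truth = staged
    sig = build_timepoint_signatures(expr, stages, top_n=20)[:1]
    counts, labels = simulate_expression_groups(
        list(expr.genes), {"a": truth.planted["d05"], "b": []},
        n_cells_per_group=20, effect=2.0, seed=34,
    )
    qexpr = center_genes(normalize_and_log(counts))
    separate = score_trajectory(qexpr, labels, sig, n_iter=100, seed=4)
    merged = score_trajectory(
        qexpr, pd.Series("ab", index=labels.index), sig, n_iter=100, seed=4
    )
    weighted = 0.5 * (
        separate["a"].adjusted_scores[0] + separate["b"].adjusted_scores[0]
    )
    assert merged["ab"].adjusted_scores[0] == pytest.approx(weighted, abs=1e-9)


def test_null_group_stays_within_control_band(staged):
    """A group with no stage-related planted genes scores within the
    randomized-control band at every timepoint, even alongside a group
    carrying unrelated planted genes."""
    expr, stages, truth = staged
    sigs = build_timepoint_signatures(expr, stages, top_n=20)
    stage_genes = {g for genes in truth.planted.values() for g in genes}
    unrelated = [g for g in expr.genes if g not in stage_genes][:20]
    qexpr, labels = _query(staged, {"null": [], "other": unrelated}, seed=35)
    profiles = score_trajectory(qexpr, labels, sigs, n_iter=300, seed=5)
    prof = profiles["null"]
    for score, sd in zip(prof.adjusted_scores, prof.control_sd):
        assert abs(score) < 3 * sd
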