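"""Expression binarization and GIMME reduction."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mbgem.integration import (
    ExpressionMatrix,
    THRESHOLD_PRESETS,
    binarize_expression,
    gimme_reduce,
)
from mbgem.solve import InfeasibleProblemError, fba

from conftest import make_model


def _expr(values: dict, condition: str = "c") -> ExpressionMatrix:
    frame = pd.DataFrame({f"{condition}_1": values})
    return ExpressionMatrix(values=frame, condition_of={f"{condition}_1": condition})


def test_binarize_threshold_arithmetic():
    """Gene means (10, 5, 1) at fraction 0.5: threshold 2.667 -> P, P, A."""
    states = binarize_expression(_expr({"g1": 10.0, "g2": 5.0, "g3": 1.0}), "c", 0.5)
    assert states.threshold_value == pytest.approx(16.0 / 6.0)
    assert states.states == {"g1": "Present", "g2": "Present", "g3": "Absent"}


def test_binarize_tie_counts_as_present():
    states = binarize_expression(_expr({"g1": 7.0, "g2": 7.0}), "c", 1.0)
    assert set(states.states.values()) == {"Present"}


def test_binarize_input_validation():
    expr = _expr({"g1": 1.0})
    with pytest.raises(ValueError):
        binarize_expression(expr, "c", 0.0)
    with pytest.raises(ValueError):
        binarize_expression(expr, "missing_condition", 0.5)
    with pytest.raises(ValueError, match="non-negative"):
        ExpressionMatrix(
            values=pd.DataFrame({"s1": {"g": -1.0}}), condition_of={"s1": "c"}
        )


def test_binarize_recovers_planted_absent_genes(expression):
    """GSE37418-like fixture at the 72.3% preset: planted-low genes are Absent."""
    expr, truth = expression
    states = binarize_expression(expr, "MB", THRESHOLD_PRESETS["GSE37418"])
    planted = truth["planted_absent"]
    recovered = sum(states.states[g] == "Absent" for g in planted)
    assert recovered / len(planted) >= 0.95


def test_binarize_monotone_in_fraction(expression):
    expr, _ = expression
    lo = set(binarize_expression(expr, "MB", 0.5).absent_genes)
    hi = set(binarize_expression(expr, "MB", 0.723).absent_genes)
    assert lo <= hi


# ---------------------------------------------------------------------------
# GIMME
# ---------------------------------------------------------------------------

def _states(model, absent):
    from mbgem.integration import GeneStateMap

    return GeneStateMap(
        states={g: ("Absent" if g in absent else "Present") for g in model.genes},
        threshold_value=1.0, threshold_fraction=0.5, condition="case",
    )


def _branch_model():
    # main route to biomass plus an absent-gated side branch that is a dead end
    return make_model(
        [
            ("EX_a_N", {"a_N": -1}, -10.0, 0.0, "", True),
            ("MAIN", {"a_N": -1, "b_N": 1}, 0.0, 100.0, "g_main"),
            ("BIO", {"b_N": -1}, 0.0, 100.0),
            ("EX_c_N", {"c_N": -1}, 0.0, 0.0, "", True),
            ("SIDE", {"c_N": 1, "a_N": -1}, 0.0, 100.0, "g_side"),
        ],
        "BIO",
    )


def test_gimme_removes_unneeded_absent_branch():
    model = _branch_model()
    reduced, score, removed = gimme_reduce(model, _states(model, {"g_side"}))
    assert removed == ["SIDE"]
    assert score == pytest.approx(0.0, abs=1e-9)
    assert "SIDE" not in reduced.reaction_index
    assert fba(reduced).objective_value == pytest.approx(10.0, abs=1e-6)


def test_gimme_retains_sole_biomass_route_with_positive_score():
    model = _branch_model()
    reduced, score, removed = gimme_reduce(model, _states(model, {"g_main"}))
    assert removed == []
    assert score > 0  # flux through the penalized reaction is forced by growth
    assert "MAIN" in reduced.reaction_index


def test_gimme_all_present_is_identity(mb_model):
    reduced, score, removed = gimme_reduce(mb_model, _states(mb_model, set()))
    assert removed == []
    assert score == 0.0
    assert reduced is mb_model


def test_gimme_fixture_removes_exactly_planted_branches(
    mb_model, expression, ground_truth
):
    expr, _ = expression
    states = binarize_expression(expr, "MB", THRESHOLD_PRESETS["GSE37418"])
    reduced, score, removed = gimme_reduce(mb_model, states)
    assert removed == ground_truth["gimme_prunable_reactions"]
    # the reduced model still validates and grows at >= 90% of the optimum
    assert fba(reduced).objective_value >= 0.9 * fba(mb_model).objective_value - 1e-9


def test_gimme_monotone_in_threshold(mb_model, expression):
    expr, _ = expression
    removed_sets = []
    for frac in (0.3, 0.723):
        states = binarize_expression(expr, "MB", frac)
        _, _, removed = gimme_reduce(mb_model, states)
        removed_sets.append(set(removed))
    assert removed_sets[0] <= removed_sets[1]


def test_gimme_infeasible_growth_constraint_raises():
    model = _branch_model()
    # close the only route via the penalty-free bound: growth can never reach 90%
    model = model.with_bounds({"MAIN": (0.0, 0.0)})
    with pytest.raises(InfeasibleProblemError):
        gimme_reduce(model, _states(model, {"g_side"}))


def test_gimme_growth_fraction_validation(mb_model):
    states = _states(mb_model, set())
    with pytest.raises(ValueError):
        gimme_reduce(mb_model, states, growth_fraction=0.0)
    with pytest.raises(ValueError):
        gimme_reduce(mb_model, states, growth_fraction=1.5)


def test_expression_tsv_round_trip(expression, tmp_path):
    expr, _ = expression
    p = tmp_path / "expr.tsv"
    expr.to_tsv(p)
    back = ExpressionMatrix.from_tsv(p)
    assert back.condition_of == expr.condition_of
    pd.testing.assert_frame_equal(back.values, expr.values)
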