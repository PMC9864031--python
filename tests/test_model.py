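"""Model structures, GPR logic, stoichiometric matrix, and I/O round trips."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mbgem.gpr import GPRParseError, parse_gpr
from mbgem.model import (
    MetabolicModel,
    Metabolite,
    ModelFormatError,
    ModelValidationError,
    Reaction,
    build_stoichiometric_matrix,
    dumps_model,
    evaluate_gpr,
    load_model,
    model_from_dict,
    model_to_dict,
    save_model,
)

from conftest import make_model


# ---------------------------------------------------------------------------
# GPR parsing and evaluation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "rule, knocked_out, active",
    [
        ("g1 and g2", {"g1"}, False),
        ("(g1 and g2) or g3", {"g1"}, True),
        ("(g1 and g2) or g3", {"g1", "g3"}, False),
        ("", {"g1"}, True),  # constitutive reaction survives any knockout
        ("g1 or g2", {"g1", "g2"}, False),
        ("g1", set(), True),
    ],
)
def test_gpr_evaluation(rule, knocked_out, active):
    assert evaluate_gpr(parse_gpr(rule), knocked_out) is active


def test_gpr_round_trip_and_genes():
    rule = "(HK1 or HK2) and GPI"
    gpr = parse_gpr(rule)
    assert gpr.genes == {"HK1", "HK2", "GPI"}
    assert parse_gpr(gpr.to_string()).root == gpr.root


@pytest.mark.parametrize("bad", ["g1 and", "(g1 or g2", "and g1", "g1 ) g2"])
def test_gpr_parse_errors(bad):
    with pytest.raises(GPRParseError):
        parse_gpr(bad)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    ko_small=st.sets(st.sampled_from(["a", "b", "c", "d"])),
    extra=st.sets(st.sampled_from(["a", "b", "c", "d"])),
)
def test_gpr_knockout_monotone(ko_small, extra):
    """Enlarging the knockout set can never reactivate a reaction."""
    gpr = parse_gpr("(a and b) or (c and d)")
    if not gpr.evaluate(ko_small):
        assert not gpr.evaluate(ko_small | extra)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def test_validation_rejects_inverted_bounds():
    data = model_to_dict(
        make_model([("EX_a_N", {"a_N": -1}, -1, 0, "", True),
                    ("BIO", {"a_N": -1}, 0, 10)], "BIO")
    )
    data["reactions"][1]["lower_bound"] = 5.0
    data["reactions"][1]["upper_bound"] = 1.0
    with pytest.raises((ModelValidationError, ModelFormatError)):
        model_from_dict(data)


def test_validation_rejects_missing_biomass_and_bad_exchange():
    with pytest.raises(ModelValidationError, match="biomass"):
        make_model([("EX_a_N", {"a_N": -1}, -1, 0, "", True),
                    ("SINK", {"a_N": -1}, 0, 10)], "NOPE")
    with pytest.raises(ModelValidationError, match="exactly one"):
        make_model([("EX_a_N", {"a_N": -1, "b_N": 1}, -1, 0, "", True),
                    ("BIO", {"a_N": -1, "b_N": -1}, 0, 10)], "BIO")


def test_validation_checks_atp_yield_against_stoichiometry():
    with pytest.raises(ModelValidationError, match="atp_yield"):
        make_model(
            [("EX_a_N", {"a_N": -1}, -1, 0, "", True),
             ("GEN", {"a_N": -1, "atp_N": 1}, 0, 10, "", False, 2),
             ("BIO", {"atp_N": -1}, 0, 10, "", False, -1)],
            "BIO",
        )


def test_metabolite_cell_tags():
    assert Metabolite("glc_N", "glucose").cell_tag == "N"
    assert Metabolite("lac_C", "lactate").cell_tag == "C"
    assert Metabolite("glc_N", "glucose").base_id == "glc"
    assert Metabolite("foo", "x").cell_tag is None


# ---------------------------------------------------------------------------
# stoichiometric matrix
# ---------------------------------------------------------------------------

def test_stoichiometric_matrix_columns(chain_model):
    S = build_stoichiometric_matrix(chain_model)
    midx = chain_model.metabolite_index
    ridx = chain_model.reaction_index
    col = S[:, ridx["UPT"]].toarray().ravel()
    assert col[midx["glc_N"]] == -1 and col[midx["a_N"]] == 1
    ex_col = S[:, ridx["EX_glc_N"]].toarray().ravel()
    assert ex_col[midx["glc_N"]] == -1 and np.count_nonzero(ex_col) == 1


def test_stoichiometric_matrix_permutation_invariance(mb_model):
    S = build_stoichiometric_matrix(mb_model).toarray()
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(mb_model.reactions))
    from mbgem.model import replace_model

    shuffled = replace_model(
        mb_model, reactions=[mb_model.reactions[i] for i in perm]
    )
    S2 = build_stoichiometric_matrix(shuffled).toarray()
    assert np.array_equal(S[:, perm], S2)


# ---------------------------------------------------------------------------
# I/O round trips
# ---------------------------------------------------------------------------

def test_json_round_trip_byte_identical(mb_model, tmp_path):
    p1, p2 = tmp_path / "m1.json", tmp_path / "m2.json"
    save_model(mb_model, p1)
    save_model(load_model(p1), p2)
    assert p1.read_bytes() == p2.read_bytes()


def _structurally_equal(a, b) -> bool:
    """Recursive equality with relative float tolerance (SBML prints ~15 digits)."""
    if isinstance(a, MetabolicModel):
        a, b = model_to_dict(a), model_to_dict(b)
    if isinstance(a, float) or isinstance(b, float):
        return math.isclose(float(a), float(b), rel_tol=1e-9, abs_tol=1e-12)
    if isinstance(a, dict):
        return set(a) == set(b) and all(_structurally_equal(a[k], b[k]) for k in a)
    if isinstance(a, list):
        return len(a) == len(b) and all(map(_structurally_equal, a, b))
    return a == b


def test_sbml_round_trip_structural(mb_model, tmp_path):
    p = tmp_path / "m.xml"
    save_model(mb_model, p, format="sbml")
    back = load_model(p, format="sbml")
    assert _structurally_equal(mb_model, back)


def test_loaded_toy_model_shape(mb_model, tmp_path):
    p = tmp_path / "toy.json"
    save_model(mb_model, p)
    m = load_model(p)
    assert m.biomass_id in m.reaction_index
    assert len([p for p in m.pathway_index if p]) >= 8
    assert dumps_model(m) == dumps_model(mb_model)


def test_json_parse_error_names_line(tmp_path):
    p = tmp_path / "broken.json"
    p.write_text('{"metabolites": [,]}')
    with pytest.raises(ModelFormatError, match="line"):
        load_model(p)


def test_knockout_bounds_and_unknown_gene_warning(mb_model, caplog):
    overrides = mb_model.knockout_bounds(["GLS"])
    assert overrides == {"GLS_N": (0.0, 0.0)}
    with caplog.at_level("WARNING"):
        assert mb_model.knockout_bounds(["NOT_A_GENE"]) == {}
    assert "unknown gene" in caplog.text
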