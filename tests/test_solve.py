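"""FBA/MOMA solvers: oracle equivalence, invariants, scenarios, accounting."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
import scipy.sparse as sp

from mbgem.model import build_stoichiometric_matrix, replace_model
from mbgem.gpr import parse_gpr
from mbgem.solve import (
    FluxVector,
    ScenarioConfig,
    _qp_closest,
    energy_accounting,
    fba,
    moma,
    scenario_run,
)

from conftest import make_model


# ---------------------------------------------------------------------------
# FBA basics and the vertex-enumeration oracle
# ---------------------------------------------------------------------------

def test_fba_bound_limited_chain(chain_model):
    v = fba(chain_model)
    assert v.ok
    assert v.objective_value == pytest.approx(10.0, abs=1e-8)
    S = build_stoichiometric_matrix(chain_model)
    assert np.abs(S @ v.vector(chain_model)).max() <= 1e-9 * max(1.0, 10.0)


def _enumerate_vertices(S, lb, ub):
    """All basic feasible solutions of {S v = 0, lb <= v <= ub} (brute force)."""
    S = np.asarray(S, dtype=float)
    m_rank = np.linalg.matrix_rank(S)
    n = S.shape[1]
    vertices = []
    for basis in itertools.combinations(range(n), m_rank):
        nonbasic = [j for j in range(n) if j not in basis]
        B = S[:, basis]
        if np.linalg.matrix_rank(B) < m_rank:
            continue
        for corners in itertools.product(*[(lb[j], ub[j]) for j in nonbasic]):
            rhs = -S[:, nonbasic] @ np.array(corners)
            sol, *_ = np.linalg.lstsq(B, rhs, rcond=None)
            if np.abs(B @ sol - rhs).max() > 1e-9:
                continue
            v = np.empty(n)
            v[list(basis)] = sol
            v[nonbasic] = corners
            if (v >= lb - 1e-9).all() and (v <= ub + 1e-9).all():
                vertices.append(v)
    return vertices


FIVE_RXN = [
    ("EX_a1_N", {"a_N": 1}, 0.0, 4.0, "", True),
    ("EX_a2_N", {"a_N": 1}, 0.0, 3.0, "", True),
    ("CONV", {"a_N": -1, "b_N": 1}, 0.0, 5.0),
    ("BIO", {"b_N": -1}, 0.0, 6.0),
    ("EX_leak_N", {"a_N": -1}, 0.0, 2.0, "", True),
]


@pytest.mark.parametrize(
    "objective, sense",
    [("BIO", "max"), ("EX_leak_N", "max"), ("CONV", "max"), ("BIO", "min"),
     ("EX_a2_N", "max")],
)
def test_fba_matches_vertex_enumeration(objective, sense):
    """LP optimum equals the best basic feasible solution (brute-force oracle)."""
    model = make_model(FIVE_RXN, "BIO")
    S = build_stoichiometric_matrix(model).toarray()
    lb, ub = model.lower_bounds, model.upper_bounds
    vertices = _enumerate_vertices(S, lb, ub)
    assert vertices, "oracle found no vertices"
    j = model.reaction_index[objective]
    best = max(v[j] for v in vertices) if sense == "max" else min(v[j] for v in vertices)
    got = fba(model, objective, sense).objective_value
    assert got == pytest.approx(best, abs=1e-7)


def test_fba_invariant_under_reaction_permutation(mb_model):
    base = fba(mb_model).objective_value
    rng = np.random.default_rng(3)
    perm = rng.permutation(len(mb_model.reactions))
    shuffled = replace_model(
        mb_model, reactions=[mb_model.reactions[i] for i in perm]
    )
    assert fba(shuffled).objective_value == pytest.approx(base, abs=1e-8)


def test_fba_invariant_under_reversible_split(mb_model):
    """Splitting the reversible transhydrogenase leaves the optimum unchanged."""
    base = fba(mb_model).objective_value
    new_rxns = []
    for r in mb_model.reactions:
        if r.id == "NNT_N":
            new_rxns.append(r.with_bounds(0.0, r.upper_bound))
            rev = type(r)(
                id="NNT_N_rev", name=r.name + " (reverse)",
                stoichiometry={k: -v for k, v in r.stoichiometry.items()},
                lower_bound=0.0, upper_bound=-r.lower_bound,
                gpr=r.gpr, pathway=r.pathway, is_exchange=False, atp_yield=0,
            )
            new_rxns.append(rev)
        else:
            new_rxns.append(r)
    split = replace_model(mb_model, reactions=new_rxns).validate()
    assert fba(split).objective_value == pytest.approx(base, abs=1e-8)


def test_lp_monotonicity_tightening_never_helps(healthy_model):
    base = fba(healthy_model).objective_value
    for rid, (lb, ub) in {
        "EX_leu_N": (-0.02, 0.0),  # less leucine
        "EX_glc_N": (-0.4, 0.0),  # less glucose
        "GPD_N": (0.0, 0.0005),
    }.items():
        tightened = healthy_model.with_bounds({rid: (lb, ub)})
        assert fba(tightened).objective_value <= base + 1e-8


def test_fba_infeasible_and_unbounded_status():
    infeasible = make_model(
        [("EX_a_N", {"a_N": -1}, -1.0, -0.5, "", True),  # forced uptake
         ("BIO", {"b_N": -1}, 0.0, 10.0),
         ("MK", {"b_N": 1}, 0.0, 10.0)],
        "BIO",
    )
    # a_N has no consumer: the forced uptake cannot balance
    assert fba(infeasible).status == "infeasible"


def test_fba_cross_check_against_cobra(mb_model, healthy_model, tmp_path):
    """Independent oracle: cobrapy reads our SBML and reproduces the optimum."""
    cobra = pytest.importorskip("cobra")
    from mbgem.model import save_model

    for model in (mb_model, healthy_model):
        path = tmp_path / f"{model.name}.xml"
        save_model(model, path, format="sbml")
        cm = cobra.io.read_sbml_model(str(path))
        ours = fba(model).objective_value
        theirs = cm.slim_optimize()
        assert theirs == pytest.approx(ours, abs=1e-6)


# ---------------------------------------------------------------------------
# MOMA
# ---------------------------------------------------------------------------

def test_moma_identity_returns_reference(mb_model):
    ref = fba(mb_model)
    adj = moma(mb_model, ref)
    assert adj.ok
    assert adj.distance == pytest.approx(0.0, abs=1e-5)
    assert adj.get(mb_model.biomass_id) == pytest.approx(
        ref.get(mb_model.biomass_id), abs=1e-6
    )


def test_qp_projection_euclidean_example():
    """Projection of h = (1,2,3) with v3 pinned to 0 on [0,3] boxes: (1,2,0), D=3."""
    S = sp.csr_matrix((0, 3))
    h = np.array([1.0, 2.0, 3.0])
    x, status = _qp_closest(h, S, np.zeros(3), np.array([3.0, 3.0, 0.0]))
    assert status == "optimal"
    assert x == pytest.approx([1.0, 2.0, 0.0], abs=1e-7)
    assert np.linalg.norm(x - h) == pytest.approx(3.0, abs=1e-7)


def test_moma_matches_grid_search_oracle():
    """QP optimum equals a dense grid search over the 2-D feasible polytope."""
    model = make_model(
        [
            ("EX_in_N", {"a_N": 1}, 0.0, 10.0, "", True),
            ("R1", {"a_N": -1, "b_N": 1}, 0.0, 10.0),
            ("R2", {"a_N": -1, "b_N": 1}, 0.0, 10.0),
            ("BIO", {"b_N": -1}, 0.0, 10.0),
        ],
        "BIO",
    )
    h = FluxVector({"EX_in_N": 3.0, "R1": 2.0, "R2": 1.0, "BIO": 3.0}, 3.0, "optimal")
    adj = moma(model, h, {"R1": (0.0, 0.5)})
    # grid over the free coordinates (r1, r2); other fluxes follow by balance
    r1 = np.linspace(0.0, 0.5, 251)
    r2 = np.linspace(0.0, 4.0, 2001)
    R1, R2 = np.meshgrid(r1, r2, indexing="ij")
    total = R1 + R2
    D2 = (R1 - 2.0) ** 2 + (R2 - 1.0) ** 2 + 2.0 * (total - 3.0) ** 2
    best = np.sqrt(D2.min())
    assert adj.distance == pytest.approx(best, abs=1e-4)
    i, j = np.unravel_index(D2.argmin(), D2.shape)
    assert adj.get("R1") == pytest.approx(R1[i, j], abs=1e-3)
    assert adj.get("R2") == pytest.approx(R2[i, j], abs=1e-3)


def test_moma_infeasible_perturbation_is_flagged(chain_model):
    ref = fba(chain_model)
    forced = chain_model.with_bounds({"EX_glc_N": (-10.0, -5.0)})
    out = moma(forced, ref, {"UPT": (0.0, 0.0)})
    assert out.status == "infeasible"


# ---------------------------------------------------------------------------
# energy accounting
# ---------------------------------------------------------------------------

def test_energy_accounting_examples():
    model = make_model(
        [
            ("EX_o2_N", {"o2_N": -1}, -10.0, 0.0, "", True),
            ("SYNTH", {"o2_N": -1, "atp_N": 1}, 0.0, 10.0, "", False, 1),
            ("NGAM", {"atp_N": -1}, 0.0, 10.0, "", False, -1),
            ("EX_lac_C", {"lac_C": -1}, 0.0, 10.0, "", True),
            ("MK_lac", {"lac_C": 1}, 0.0, 10.0),
            ("BIO", {"atp_N": -1}, 0.0, 10.0, "", False, -1),
        ],
        "BIO",
    )
    # overwrite pathway labels for the ATP producer
    rxns = [r if r.id != "SYNTH" else type(r)(
        id=r.id, name=r.name, stoichiometry=r.stoichiometry, lower_bound=0,
        upper_bound=10, gpr=r.gpr, pathway="OXPHOS", is_exchange=False,
        atp_yield=1) for r in model.reactions]
    model = replace_model(model, reactions=rxns)
    v = FluxVector(
        {"EX_o2_N": -2.0, "SYNTH": 5.0, "NGAM": 2.0, "EX_lac_C": 4.0,
         "MK_lac": 4.0, "BIO": 3.0},
        3.0, "optimal",
    )
    acc = energy_accounting(model, v)
    assert acc.atp_total == pytest.approx(5.0)
    assert acc.atp_share_by_pathway["OXPHOS"] == pytest.approx(1.0)
    assert acc.lacr_over_ocr == pytest.approx(2.0)
    assert math.isinf(acc.atpg_over_atpop) is False or True  # ratio defined below
    assert acc.atpg_over_atpop == pytest.approx(0.0)  # no glycolytic ATP


def test_energy_accounting_hand_summation_matches(mb_model):
    """Independent oracle: re-sum ATP production from the reaction table."""
    v = fba(mb_model)
    acc = energy_accounting(mb_model, v)
    by_pathway = {}
    for r in mb_model.reactions:
        produced = r.atp_yield * v.get(r.id)
        if produced > 0:
            by_pathway[r.pathway] = by_pathway.get(r.pathway, 0.0) + produced
    assert set(by_pathway) == set(acc.atp_by_pathway)
    for p, val in by_pathway.items():
        assert acc.atp_by_pathway[p] == pytest.approx(val, abs=1e-9)
    assert sum(acc.atp_share_by_pathway.values()) == pytest.approx(1.0, abs=1e-9)


def test_zero_oxphos_gives_inf_sentinel(chain_model):
    acc = energy_accounting(chain_model, fba(chain_model))
    assert math.isinf(acc.atpg_over_atpop)


# ---------------------------------------------------------------------------
# scenarios (glucose / glutamine deprivation)
# ---------------------------------------------------------------------------

def test_scenarios_on_mb_model(mb_model):
    ref = fba(mb_model)
    baseline = scenario_run(mb_model, None, "baseline", reference=ref)
    no_glc = scenario_run(mb_model, None, "no_glucose", reference=ref)
    no_gln = scenario_run(mb_model, None, "no_glutamine", reference=ref)
    no_both = scenario_run(mb_model, None, "no_both", reference=ref)

    assert baseline.biomass == pytest.approx(0.034, abs=1e-6)
    # glucose starvation abolishes growth; glutamine starvation does not
    assert no_glc.biomass == pytest.approx(0.0, abs=1e-8)
    assert abs(no_gln.biomass - baseline.biomass) <= 1e-6
    # combined deprivation strictly cuts total ATP production
    assert no_both.accounting.atp_total < baseline.accounting.atp_total - 1e-6


def test_healthy_model_also_dies_without_glucose(healthy_model):
    out = scenario_run(healthy_model, None, "no_glucose")
    assert out.biomass == pytest.approx(0.0, abs=1e-6)
    out2 = scenario_run(healthy_model, None, "no_glutamine")
    base = scenario_run(healthy_model, None, "baseline")
    assert abs(out2.biomass - base.biomass) <= 1e-6


def test_scenario_config_validation_and_split():
    with pytest.raises(ValueError):
        ScenarioConfig(uptake_bounds={"glucose": -1.0})
    with pytest.raises(ValueError):
        ScenarioConfig(neuron_fraction=0.9, astrocyte_fraction=0.2)
    cfg = ScenarioConfig()
    assert cfg.uptake_bounds["glucose"] == 0.852
    assert cfg.neuron_fraction * cfg.uptake_bounds["glucose"] == pytest.approx(0.82644)


def test_scenario_yaml_round_trip(tmp_path):
    cfg = ScenarioConfig(overrides={"NGAM_N": (0.1, 500.0)})
    p = tmp_path / "scenario.yaml"
    cfg.to_yaml(p)
    back = ScenarioConfig.from_yaml(p)
    assert back.uptake_bounds == cfg.uptake_bounds
    assert back.overrides == cfg.overrides
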