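"""Flux coupling classes vs an extreme-ray enumeration oracle."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from mbgem.coupling import biomass_coupled_set, classify_pair_coupling
from mbgem.essentiality import single_deletion
from mbgem.model import build_stoichiometric_matrix

from conftest import make_model


def _chain():
    return make_model(
        [
            ("EX_in_N", {"a_N": 1}, 0.0, 10.0, "", True),
            ("AB", {"a_N": -1, "b_N": 1}, 0.0, 10.0),
            ("BC", {"b_N": -1, "c_N": 1}, 0.0, 10.0),
            ("BIO", {"c_N": -1}, 0.0, 10.0),
        ],
        "BIO",
    )


def test_consecutive_chain_reactions_fully_coupled():
    rec = classify_pair_coupling(_chain(), "AB", "BC")
    assert rec.klass == "fully"
    assert rec.ratio_min == pytest.approx(1.0, abs=1e-6)
    assert rec.ratio_max == pytest.approx(1.0, abs=1e-6)


def test_branch_point_reactions_uncoupled():
    model = make_model(
        [
            ("EX_in_N", {"a_N": 1}, 0.0, 10.0, "", True),
            ("AB", {"a_N": -1, "b_N": 1}, 0.0, 10.0),
            ("AC", {"a_N": -1, "c_N": 1}, 0.0, 10.0),
            ("EX_b_N", {"b_N": -1}, 0.0, 10.0, "", True),
            ("BIO", {"c_N": -1}, 0.0, 10.0),
        ],
        "BIO",
    )
    assert classify_pair_coupling(model, "AB", "AC").klass == "uncoupled"


# ---------------------------------------------------------------------------
# extreme-ray oracle on a 6-reaction cone
# ---------------------------------------------------------------------------

SIX_RXN = [
    ("EX_in_N", {"a_N": 1}, 0.0, 10.0, "", True),
    ("AB", {"a_N": -1, "b_N": 1}, 0.0, 10.0),
    ("AC", {"a_N": -1, "c_N": 1}, 0.0, 10.0),
    ("EX_b_N", {"b_N": -1}, 0.0, 10.0, "", True),
    ("EX_c_N", {"c_N": -1}, 0.0, 10.0, "", True),
    ("BC", {"b_N": -1, "c_N": 1}, 0.0, 10.0),
]


def _extreme_rays(S):
    """Vertices of {S v = 0, v >= 0, sum v = 1} by brute-force enumeration."""
    S = np.asarray(S, dtype=float)
    m, n = S.shape
    A = np.vstack([S, np.ones(n)])
    b = np.concatenate([np.zeros(m), [1.0]])
    rank = np.linalg.matrix_rank(A)
    rays = []
    for support in itertools.combinations(range(n), rank):
        cols = A[:, support]
        if np.linalg.matrix_rank(cols) < len(support):
            continue
        sol, *_ = np.linalg.lstsq(cols, b, rcond=None)
        if np.abs(cols @ sol - b).max() > 1e-9:
            continue
        if (sol < -1e-9).any():
            continue
        v = np.zeros(n)
        v[list(support)] = sol
        if not any(np.allclose(v, r) for r in rays):
            rays.append(v)
    return rays


def _oracle_class(rays, i, j, tol=1e-9):
    blocked_i = all(r[i] <= tol for r in rays)
    blocked_j = all(r[j] <= tol for r in rays)
    if blocked_i or blocked_j:
        return "blocked"
    i_wo_j = any(r[i] > tol and r[j] <= tol for r in rays)
    j_wo_i = any(r[j] > tol and r[i] <= tol for r in rays)
    if i_wo_j and j_wo_i:
        return "uncoupled"
    if i_wo_j:
        return "directionally_j_to_i"
    if j_wo_i:
        return "directionally_i_to_j"
    ratios = [r[i] / r[j] for r in rays if r[j] > tol]
    if max(ratios) - min(ratios) <= 1e-9:
        return "fully"
    return "partially"


def test_six_reaction_cone_matches_extreme_ray_oracle():
    model = make_model(SIX_RXN, "EX_c_N")
    rays = _extreme_rays(build_stoichiometric_matrix(model).toarray())
    assert len(rays) >= 3
    ids = [r.id for r in model.reactions]
    for i, j in itertools.combinations(range(len(ids)), 2):
        expected = _oracle_class(rays, i, j)
        got = classify_pair_coupling(model, ids[i], ids[j]).klass
        assert got == expected, f"pair ({ids[i]}, {ids[j]}): {got} != {expected}"


def test_coupling_invariant_under_bound_rescaling():
    model = make_model(SIX_RXN, "EX_c_N")
    scaled = model.with_bounds(
        {r.id: (r.lower_bound * 7, r.upper_bound * 7) for r in model.reactions}
    )
    ids = [r.id for r in model.reactions]
    for i, j in [("AB", "BC"), ("AB", "AC"), ("EX_in_N", "AB")]:
        assert (
            classify_pair_coupling(model, i, j).klass
            == classify_pair_coupling(scaled, i, j).klass
        )


# ---------------------------------------------------------------------------
# biomass-coupled set on the toy fixture
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def mb_coupling(mb_model):
    return biomass_coupled_set(mb_model)


def test_fully_coupled_set_matches_ground_truth(mb_coupling, ground_truth):
    fully = sorted(r.pair[0] for r in mb_coupling.get("fully", []))
    assert fully == ground_truth["fully_coupled_to_biomass"]


def test_biomass_exclusive_precursor_exchange_fully_coupled(mb_coupling):
    """Leucine enters only to feed biomass: its exchange has a fixed ratio."""
    rec = {r.pair[0]: r for r in mb_coupling["fully"]}["EX_leu_N"]
    assert rec.ratio_min == pytest.approx(-1.0, abs=1e-6)  # uptake sign
    assert rec.ratio_max == pytest.approx(-1.0, abs=1e-6)


def test_dead_branches_are_blocked(mb_coupling):
    blocked = {r.pair[0] for r in mb_coupling.get("blocked", [])}
    assert {"PYG_N", "OXCT_N", "BDH_N"} <= blocked


def test_full_coupling_is_transitive(mb_model, ground_truth):
    """Spot-check transitivity within the fully-coupled-to-biomass class."""
    fully = ground_truth["fully_coupled_to_biomass"]
    for i, j in [(fully[0], fully[1]), (fully[1], fully[2]), (fully[0], fully[2])]:
        assert classify_pair_coupling(mb_model, i, j).klass == "fully"


def test_blocked_anchor_raises():
    model = make_model(
        [
            ("EX_in_N", {"a_N": 1}, 0.0, 10.0, "", True),
            ("EX_a_N", {"a_N": -1}, 0.0, 10.0, "", True),
            ("BIO", {"b_N": -1}, 0.0, 10.0),
            ("MK_b", {"b_N": 1, "c_N": 1}, 0.0, 10.0),  # c_N has no sink
        ],
        "BIO",
    )
    with pytest.raises(ValueError, match="blocked"):
        biomass_coupled_set(model)


def test_every_essential_reaction_is_biomass_coupled(healthy_model):
    """A reaction whose removal zeroes growth cannot be uncoupled from it."""
    coupled = biomass_coupled_set(healthy_model)
    klass_of = {
        r.pair[0]: klass for klass, recs in coupled.items() for r in recs
    }
    results = single_deletion(
        healthy_model, None, "biomass", kind="reaction", method="fba"
    )
    for r in results:
        if r.target == healthy_model.biomass_id:
            continue
        if r.ko_value <= 1e-9:  # removal abolishes growth entirely
            assert klass_of[r.target] not in ("uncoupled", "blocked"), r.target
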