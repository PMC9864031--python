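"""Shared fixtures: the toy model pair, expression data, and tiny networks."""

from __future__ import annotations

import pytest

from mbgem.gpr import parse_gpr
from mbgem.model import MetabolicModel, Metabolite, Reaction
from mbgem.synthetic import (
    generate_compound_table,
    generate_expression_series,
    generate_toy_models,
    mb_expression_spec,
)


@pytest.fixture(scope="session")
def toy_pair():
    """(healthy, mb, ground_truth) for the packaged two-cell cerebellum model."""
    return generate_toy_models()


@pytest.fixture(scope="session")
def healthy_model(toy_pair):
    return toy_pair[0]


@pytest.fixture(scope="session")
def mb_model(toy_pair):
    return toy_pair[1]


@pytest.fixture(scope="session")
def ground_truth(toy_pair):
    return toy_pair[2]


@pytest.fixture(scope="session")
def expression(mb_model):
    """(ExpressionMatrix, ground truth) with the default planted design."""
    return generate_expression_series(mb_expression_spec(mb_model.genes, seed=0))


@pytest.fixture(scope="session")
def compound_table():
    return generate_compound_table()


@pytest.fixture(scope="session")
def mb_samples(mb_model):
    """Moderate-size ACHR sampling of the MB model, shared across tests."""
    from mbgem.sampling import achr_sample

    return achr_sample(mb_model, n_samples=2000, seed=101, thinning=50)


@pytest.fixture(scope="session")
def healthy_samples(healthy_model):
    from mbgem.sampling import achr_sample

    return achr_sample(healthy_model, n_samples=2000, seed=102, thinning=50)


def make_model(reactions, biomass_id, genes=None, name="tiny", annotations=None):
    """Assemble a validated model from (id, stoich, lb, ub, gpr, exchange) specs."""
    rxns = []
    for spec in reactions:
        rid, stoich, lb, ub = spec[:4]
        gpr = spec[4] if len(spec) > 4 else ""
        exchange = spec[5] if len(spec) > 5 else len(stoich) == 1 and rid.startswith("EX_")
        atp = spec[6] if len(spec) > 6 else 0
        rxns.append(
            Reaction(
                id=rid, name=rid, stoichiometry=dict(stoich),
                lower_bound=lb, upper_bound=ub, gpr=parse_gpr(gpr),
                pathway="test", is_exchange=exchange, atp_yield=atp,
            )
        )
    met_ids = sorted({m for r in rxns for m in r.stoichiometry})
    mets = [Metabolite(id=m, name=m) for m in met_ids]
    if genes is None:
        genes = sorted({g for r in rxns for g in r.gpr.genes})
    return MetabolicModel(
        metabolites=mets, reactions=rxns, genes=genes,
        biomass_id=biomass_id, name=name, annotations=annotations or {},
    ).validate()


@pytest.fixture
def chain_model():
    """EX_glc -(ub 10)-> A -> biomass: optimum pinned by the uptake bound."""
    return make_model(
        [
            ("EX_glc_N", {"glc_N": -1}, -10.0, 0.0, "", True),
            ("UPT", {"glc_N": -1, "a_N": 1}, 0.0, 1000.0),
            ("BIO", {"a_N": -1}, 0.0, 1000.0),
        ],
        biomass_id="BIO",
    )
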