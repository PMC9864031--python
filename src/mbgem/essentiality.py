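"""Gene/reaction essentiality, synthetic lethality, and the safety screen.

A deletion disables exactly the reactions whose GPR evaluates inactive
without the target gene(s); the knockout value of the objective is read
from the MOMA solution against the wild-type minimum-norm reference (the
FBA + MOMA pairing; a raw-FBA mode exists for comparison). A target is
essential when it reduces the objective by strictly more than the 40%
cutoff. An infeasible knockout model (the perturbed network cannot satisfy
its obligatory exchanges) counts as complete loss of function.

Three objectives are screened: biomass, total ATP production (the
atp_yield-weighted sum over producing reactions) and lactate excretion.
Genes essential for all three on the tumor model are then re-tested on the
healthy model; a gene is healthy-safe when its knockout reduces neither
healthy biomass nor healthy ATP production by more than the safety cutoff.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple, Union

import numpy as np

from .model import MetabolicModel
from .solve import (
    DEFAULT_OPTIONS,
    FluxVector,
    InfeasibleProblemError,
    ScenarioConfig,
    SolverOptions,
    apply_scenario,
    fba,
    moma,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DeletionResult",
    "CommonEssentialRecord",
    "ESSENTIAL_CUTOFF",
    "objective_coefficients",
    "single_deletion",
    "double_deletion_synthetic_lethals",
    "common_essential_screen",
]

ESSENTIAL_CUTOFF = 0.40  # strict > : "decrease growth by more than 40%"
OBJECTIVES = ("biomass", "atp", "lactate")


@dataclass
class DeletionResult:
    target: Union[str, Tuple[str, str]]
    objective: str
    wt_value: float
    ko_value: float
    reduction_fraction: float
    essential: bool
    status: str = "optimal"
    healthy_reduction_fraction: Optional[float] = None
    healthy_safe: Optional[bool] = None


@dataclass
class CommonEssentialRecord:
    gene: str
    essential_for: Set[str]
    healthy_biomass_reduction: float
    healthy_atp_reduction: float
    healthy_safe: bool


def objective_coefficients(
    model: MetabolicModel, objective: str
) -> Union[str, Dict[str, float]]:
    """Linear objective for a named screen target.

    biomass -> the biomass reaction; atp -> atp_yield-weighted production
    over ATP-producing reactions; lactate -> total lactate excretion flux.
    """
    if objective == "biomass":
        return model.biomass_id
    if objective == "atp":
        coefs = {
            r.id: float(r.atp_yield) for r in model.reactions if r.atp_yield > 0
        }
        if not coefs:
            raise ValueError("model has no ATP-producing reactions")
        return coefs
    if objective == "lactate":
        lac_ex = model.annotations.get("lactate_exchange")
        if lac_ex and lac_ex in model.reaction_index:
            return {lac_ex: 1.0}
        coefs = {
            r.id: 1.0
            for r in model.reactions
            if r.is_exchange and r.id.startswith("EX_lac_")
        }
        if not coefs:
            raise ValueError("model has no lactate exchange reaction")
        return coefs
    raise ValueError(f"unknown objective {objective!r}; choose from {OBJECTIVES}")


def _objective_value(
    model: MetabolicModel, obj: Union[str, Dict[str, float]], v: FluxVector
) -> float:
    if isinstance(obj, str):
        return v.get(obj)
    return sum(coef * v.get(rid) for rid, coef in obj.items())


class _Screen:
    """Shared wild-type state for a batch of deletions on one model."""

    def __init__(
        self,
        model: MetabolicModel,
        objective: str,
        config: Optional[ScenarioConfig],
        method: str,
        options: SolverOptions,
    ):
        if method not in ("moma", "fba"):
            raise ValueError("method must be 'moma' or 'fba'")
        self.model = apply_scenario(model, config)
        self.objective = objective
        self.obj = objective_coefficients(model, objective)
        self.method = method
        self.options = options
        self.reference = fba(self.model, self.obj, "max", None, options=options)
        if not self.reference.ok:
            raise InfeasibleProblemError(
                f"wild-type FBA ({objective}) is {self.reference.status}"
            )
        self.wt = self.reference.objective_value
        if self.wt <= 0:
            raise InfeasibleProblemError(
                f"wild-type {objective} objective is not positive ({self.wt})"
            )

    def knockout(self, genes: Iterable[str]) -> Tuple[float, str]:
        overrides = self.model.knockout_bounds(genes)
        return self._apply(overrides)

    def remove_reaction(self, rid: str) -> Tuple[float, str]:
        return self._apply({rid: (0.0, 0.0)})

    def _apply(self, overrides: Dict[str, Tuple[float, float]]) -> Tuple[float, str]:
        if not overrides:
            return self.wt, "optimal"
        ref_hit = max(abs(self.reference.get(rid)) for rid in overrides)
        if self.method == "moma":
            if ref_hit <= 1e-9:
                # reference remains feasible: MOMA returns it unchanged
                return self.wt, "optimal"
            sol = moma(self.model, self.reference, overrides, options=self.options)
            if not sol.ok:
                return 0.0, "infeasible"
            return _objective_value(self.model, self.obj, sol), "optimal"
        ko_model = self.model.with_bounds(overrides)
        sol = fba(ko_model, self.obj, "max", None, minimum_norm=False,
                  options=self.options)
        if not sol.ok:
            return 0.0, sol.status
        return sol.objective_value, "optimal"

    def result(
        self, target, ko_value: float, status: str, cutoff: float
    ) -> DeletionResult:
        reduction = float(np.clip(1.0 - ko_value / self.wt, 0.0, 1.0))
        return DeletionResult(
            target=target,
            objective=self.objective,
            wt_value=self.wt,
            ko_value=ko_value,
            reduction_fraction=reduction,
            essential=reduction > cutoff,
            status=status,
        )


def single_deletion(
    model: MetabolicModel,
    targets: Optional[Sequence[str]] = None,
    objective: str = "biomass",
    config: Optional[ScenarioConfig] = None,
    kind: str = "gene",
    cutoff: float = ESSENTIAL_CUTOFF,
    method: str = "moma",
    options: SolverOptions = DEFAULT_OPTIONS,
) -> List[DeletionResult]:
    """Delete genes (or reactions) one at a time and score the objective loss."""
    screen = _Screen(model, objective, config, method, options)
    if targets is None:
        targets = list(model.genes) if kind == "gene" else [
            r.id for r in model.reactions
        ]
    out = []
    for t in targets:
        if kind == "gene":
            ko, status = screen.knockout([t])
        else:
            ko, status = screen.remove_reaction(t)
        out.append(screen.result(t, ko, status, cutoff))
    return out


def double_deletion_synthetic_lethals(
    model: MetabolicModel,
    genes: Optional[Sequence[str]] = None,
    objective: str = "biomass",
    config: Optional[ScenarioConfig] = None,
    cutoff: float = ESSENTIAL_CUTOFF,
    method: str = "moma",
    options: SolverOptions = DEFAULT_OPTIONS,
) -> List[DeletionResult]:
    """All unordered pairs of genes that are not single-essential.

    A pair is synthetic lethal when the joint deletion reduces the objective
    by more than the cutoff while both single deletions stay at or below it
    (singles are screened first and excluded from pairing).
    """
    screen = _Screen(model, objective, config, method, options)
    genes = list(genes) if genes is not None else list(model.genes)
    singles = single_deletion(
        model, genes, objective, config, "gene", cutoff, method, options
    )
    tolerated = [r.target for r in singles if not r.essential]
    out = []
    for g1, g2 in itertools.combinations(sorted(tolerated), 2):
        ko, status = screen.knockout([g1, g2])
        out.append(screen.result((g1, g2), ko, status, cutoff))
    return out


def common_essential_screen(
    mb_model: MetabolicModel,
    healthy_model: MetabolicModel,
    config: Optional[ScenarioConfig] = None,
    cutoff: float = ESSENTIAL_CUTOFF,
    safety_cutoff: float = ESSENTIAL_CUTOFF,
    method: str = "moma",
    options: SolverOptions = DEFAULT_OPTIONS,
) -> List[CommonEssentialRecord]:
    """Genes essential for biomass, ATP and lactate on the tumor model,
    re-tested on the healthy model for tolerability.

    Returns one record per common-essential gene; ``healthy_safe`` is True
    when the healthy knockout keeps both healthy biomass and healthy ATP
    production within the safety cutoff.
    """
    essential_for: Dict[str, Set[str]] = {}
    for objective in OBJECTIVES:
        for r in single_deletion(
            mb_model, None, objective, config, "gene", cutoff, method, options
        ):
            if r.essential:
                essential_for.setdefault(r.target, set()).add(objective)
    common = sorted(g for g, objs in essential_for.items() if len(objs) == len(OBJECTIVES))

    healthy_screens = {
        obj: _Screen(healthy_model, obj, config, method, options)
        for obj in ("biomass", "atp")
    }
    records = []
    for g in common:
        reductions = {}
        for obj, screen in healthy_screens.items():
            if g in healthy_model.genes:
                ko, _status = screen.knockout([g])
            else:
                ko = screen.wt  # gene absent from the healthy network: no effect
            reductions[obj] = float(np.clip(1.0 - ko / screen.wt, 0.0, 1.0))
        safe = all(x <= safety_cutoff for x in reductions.values())
        records.append(
            CommonEssentialRecord(
                gene=g,
                essential_for=essential_for[g],
                healthy_biomass_reduction=reductions["biomass"],
                healthy_atp_reduction=reductions["atp"],
                healthy_safe=safe,
            )
        )
    return records
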