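"""FBA, MOMA, scenario constraints and ATP accounting.

Flux balance analysis maximizes (or minimizes) a linear objective c.v over
the steady-state polytope {S.v = 0, lb <= v <= ub}. Because the optimal
face is usually degenerate, reported flux maps are the minimum-norm optimal
solution (argmin ||v||^2 subject to c.v = optimum), which is unique and
deterministic. Knockouts and nutrient deprivations are then re-solved with
MOMA: the feasible flux vector of the perturbed model closest (Euclidean
distance D = sqrt(sum_i (h_i - m_i)^2)) to the unperturbed reference h.

Uptake constraints are carried by a :class:`ScenarioConfig`. An uptake
magnitude b for a nutrient shared by both cell types is split 97/3 between
the neuron and astrocyte exchange reactions, following the neuron/astrocyte
distribution of the cerebellum; a nutrient with a single-cell transporter
receives the full bound (logged).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from .model import MetabolicModel, build_stoichiometric_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "FluxVector",
    "ScenarioConfig",
    "EnergyAccounting",
    "ScenarioResult",
    "SolverOptions",
    "CEREBELLUM_UPTAKE_BOUNDS",
    "fba",
    "moma",
    "minimum_norm_solution",
    "flux_variability",
    "energy_accounting",
    "scenario_run",
    "apply_scenario",
    "InfeasibleProblemError",
]

#: Default uptake magnitudes, mmol/gDW/h (cerebellum scenario table).
CEREBELLUM_UPTAKE_BOUNDS: Dict[str, float] = {
    "glucose": 0.852,
    "glutamine": 0.080,
    "oxygen": 0.142,
    "leucine": 0.034,
    "tryptophan": 0.0074,
    "tyrosine": 0.0028,
    "methionine": 0.008,
    "glycogen": 0.0,
    "ketone_bodies": 0.0,
    "threonine": 0.06,
}

#: Metabolite base ids carried by each named nutrient.
NUTRIENT_SPECIES: Dict[str, Tuple[str, ...]] = {
    "glucose": ("glc",),
    "glutamine": ("gln",),
    "oxygen": ("o2",),
    "leucine": ("leu",),
    "tryptophan": ("trp",),
    "tyrosine": ("tyr",),
    "methionine": ("met",),
    "glycogen": ("glycogen",),
    "ketone_bodies": ("bhb", "acac"),
    "threonine": ("thr",),
}

SCENARIOS = ("baseline", "no_glucose", "no_glutamine", "no_both")


class InfeasibleProblemError(RuntimeError):
    pass


@dataclass
class SolverOptions:
    """Numerical tolerances (documented defaults; override per call)."""

    qp_tolerance: float = 1e-8
    feasibility_tolerance: float = 1e-9
    lp_method: str = "highs"


DEFAULT_OPTIONS = SolverOptions()


@dataclass
class FluxVector:
    """One steady-state flux assignment (mmol/gDW/h per reaction)."""

    fluxes: Dict[str, float]
    objective_value: float
    status: str  # optimal | infeasible | unbounded
    distance: Optional[float] = None  # MOMA distance D, when applicable

    def __getitem__(self, rid: str) -> float:
        return self.fluxes[rid]

    def get(self, rid: str, default: float = 0.0) -> float:
        return self.fluxes.get(rid, default)

    def vector(self, model: MetabolicModel) -> np.ndarray:
        return np.array([self.fluxes[r.id] for r in model.reactions], dtype=float)

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


@dataclass
class ScenarioConfig:
    """Uptake magnitudes plus the neuron/astrocyte split and raw overrides."""

    uptake_bounds: Dict[str, float] = field(
        default_factory=lambda: dict(CEREBELLUM_UPTAKE_BOUNDS)
    )
    neuron_fraction: float = 0.97
    astrocyte_fraction: float = 0.03
    overrides: Dict[str, Tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for nutrient, b in self.uptake_bounds.items():
            if b < 0:
                raise ValueError(f"uptake magnitude for {nutrient!r} must be >= 0, got {b}")
        for frac in (self.neuron_fraction, self.astrocyte_fraction):
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"cell fraction {frac} outside [0, 1]")
        if abs(self.neuron_fraction + self.astrocyte_fraction - 1.0) > 1e-9:
            raise ValueError("neuron_fraction + astrocyte_fraction must equal 1")

    def with_zeroed(self, nutrients: Iterable[str]) -> "ScenarioConfig":
        bounds = dict(self.uptake_bounds)
        for n in nutrients:
            bounds[n] = 0.0
        return ScenarioConfig(
            uptake_bounds=bounds,
            neuron_fraction=self.neuron_fraction,
            astrocyte_fraction=self.astrocyte_fraction,
            overrides=dict(self.overrides),
        )

    # -- YAML round trip ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "uptake_bounds": dict(self.uptake_bounds),
            "neuron_fraction": self.neuron_fraction,
            "astrocyte_fraction": self.astrocyte_fraction,
            "overrides": {k: list(v) for k, v in self.overrides.items()},
        }

    @classmethod
    def from_dict(cls, data: Optional[dict]) -> "ScenarioConfig":
        data = data or {}
        bounds = dict(CEREBELLUM_UPTAKE_BOUNDS)
        bounds.update(data.get("uptake_bounds", {}))
        return cls(
            uptake_bounds=bounds,
            neuron_fraction=data.get("neuron_fraction", 0.97),
            astrocyte_fraction=data.get("astrocyte_fraction", 0.03),
            overrides={
                k: (float(v[0]), float(v[1]))
                for k, v in data.get("overrides", {}).items()
            },
        )

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def apply_scenario(
    model: MetabolicModel, config: Optional[ScenarioConfig]
) -> MetabolicModel:
    """Model copy with scenario uptake bounds and raw overrides applied.

    Exchange reactions are located by the ``EX_<base>_<tag>`` convention.
    Uptake is negative flux on an exchange, so magnitude b becomes a lower
    bound of -b. Nutrients listed in the model annotation ``forced_uptakes``
    are pinned (lb = ub = -b): their uptake is obligatory, which is how the
    tumor variant encodes its avid glucose/glutamine consumption.
    """
    if config is None:
        return model
    rid_set = set(model.reaction_index)
    forced = set(model.annotations.get("forced_uptakes", []))
    overrides: Dict[str, Tuple[float, float]] = {}
    for nutrient, magnitude in config.uptake_bounds.items():
        species = NUTRIENT_SPECIES.get(nutrient, (nutrient,))
        for base in species:
            ex_n, ex_a = f"EX_{base}_N", f"EX_{base}_A"
            targets: List[Tuple[str, float]] = []
            if ex_n in rid_set and ex_a in rid_set:
                targets = [
                    (ex_n, config.neuron_fraction * magnitude),
                    (ex_a, config.astrocyte_fraction * magnitude),
                ]
            elif ex_n in rid_set:
                logger.info(
                    "nutrient %s has a single-cell (neuron) transporter; full bound", base
                )
                targets = [(ex_n, magnitude)]
            elif ex_a in rid_set:
                logger.info(
                    "nutrient %s has a single-cell (astrocyte) transporter; full bound", base
                )
                targets = [(ex_a, magnitude)]
            for rid, b in targets:
                ub = -b if nutrient in forced else 0.0
                overrides[rid] = (-b, ub)
    overrides.update(config.overrides)
    return model.with_bounds(overrides)


# ---------------------------------------------------------------------------
# LP / QP primitives
# ---------------------------------------------------------------------------

def _objective_vector(
    model: MetabolicModel, objective: Union[str, Mapping[str, float], None]
) -> np.ndarray:
    c = np.zeros(len(model.reactions))
    ridx = model.reaction_index
    if objective is None:
        objective = model.biomass_id
    if isinstance(objective, str):
        if objective not in ridx:
            raise KeyError(f"objective reaction {objective!r} not in model")
        c[ridx[objective]] = 1.0
    else:
        for rid, coef in objective.items():
            c[ridx[rid]] = float(coef)
    return c


def _solve_lp(
    c: np.ndarray,
    S: sp.spmatrix,
    lb: np.ndarray,
    ub: np.ndarray,
    sense: str,
    extra_A: Optional[sp.spmatrix] = None,
    extra_lu: Optional[Tuple[np.ndarray, np.ndarray]] = None,
    options: SolverOptions = DEFAULT_OPTIONS,
):
    sign = -1.0 if sense == "max" else 1.0
    A_ub = None
    b_ub = None
    if extra_A is not None:
        lo, hi = extra_lu
        blocks, rhs = [], []
        finite_hi = np.isfinite(hi)
        finite_lo = np.isfinite(lo)
        if finite_hi.any():
            blocks.append(extra_A[finite_hi])
            rhs.append(hi[finite_hi])
        if finite_lo.any():
            blocks.append(-extra_A[finite_lo])
            rhs.append(-lo[finite_lo])
        if blocks:
            A_ub = sp.vstack(blocks, format="csr")
            b_ub = np.concatenate(rhs)
    res = linprog(
        sign * c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=np.column_stack([lb, ub]),
        method=options.lp_method,
    )
    return res


def _qp_closest(
    target: np.ndarray,
    S: sp.spmatrix,
    lb: np.ndarray,
    ub: np.ndarray,
    extra_A: Optional[sp.spmatrix] = None,
    extra_lu: Optional[Tuple[np.ndarray, np.ndarray]] = None,
    options: SolverOptions = DEFAULT_OPTIONS,
) -> Tuple[Optional[np.ndarray], str]:
    """argmin ||v - target||^2 s.t. S v = 0, bounds, optional extra rows."""
    import osqp

    n = len(target)
    P = sp.identity(n, format="csc")
    q = -np.asarray(target, dtype=float)
    rows = [S, sp.identity(n, format="csc")]
    lo = [np.zeros(S.shape[0]), lb]
    hi = [np.zeros(S.shape[0]), ub]
    if extra_A is not None:
        rows.append(extra_A)
        lo.append(extra_lu[0])
        hi.append(extra_lu[1])
    A = sp.vstack(rows, format="csc")
    l = np.concatenate(lo)
    u = np.concatenate(hi)
    prob = osqp.OSQP()
    prob.setup(
        P=P,
        q=q,
        A=A,
        l=l,
        u=u,
        eps_abs=options.qp_tolerance,
        eps_rel=options.qp_tolerance,
        eps_prim_inf=options.feasibility_tolerance,
        eps_dual_inf=options.feasibility_tolerance,
        polishing=True,
        verbose=False,
        max_iter=400_000,
    )
    res = prob.solve(raise_error=False)
    status = res.info.status
    if "solved" in status:
        return np.asarray(res.x, dtype=float), "optimal"
    if "infeasible" in status:
        return None, "infeasible"
    return None, status.replace(" ", "_")


def _flux_vector(
    model: MetabolicModel, x: np.ndarray, objective_value: float, status: str, **kw
) -> FluxVector:
    fluxes = {r.id: float(v) for r, v in zip(model.reactions, x)}
    return FluxVector(fluxes=fluxes, objective_value=objective_value, status=status, **kw)


def fba(
    model: MetabolicModel,
    objective: Union[str, Mapping[str, float], None] = None,
    sense: str = "max",
    config: Optional[ScenarioConfig] = None,
    minimum_norm: bool = True,
    options: SolverOptions = DEFAULT_OPTIONS,
) -> FluxVector:
    """Flux balance analysis; flux map is the minimum-norm optimum by default.

    ``objective`` is a reaction id (default: the biomass reaction) or a map
    of reaction id -> linear coefficient (used e.g. for total ATP yield).
    """
    if sense not in ("max", "min"):
        raise ValueError("sense must be 'max' or 'min'")
    m = apply_scenario(model, config)
    S = build_stoichiometric_matrix(m)
    lb, ub = m.lower_bounds, m.upper_bounds
    c = _objective_vector(m, objective)
    res = _solve_lp(c, S, lb, ub, sense, options=options)
    if res.status == 2:
        return FluxVector({}, math.nan, "infeasible")
    if res.status == 3:
        return FluxVector({}, math.nan, "unbounded")
    if res.status != 0:
        raise RuntimeError(f"LP solver failure: {res.message}")
    opt = float(c @ res.x)
    if not minimum_norm:
        return _flux_vector(m, res.x, opt, "optimal")
    x = minimum_norm_solution(m, c, opt, sense, S=S, options=options)
    if x is None:  # QP hiccup: fall back to the vertex solution
        logger.warning("minimum-norm QP did not converge; reporting vertex solution")
        return _flux_vector(m, res.x, opt, "optimal")
    return _flux_vector(m, x, opt, "optimal")


def minimum_norm_solution(
    model: MetabolicModel,
    c: np.ndarray,
    optimum: float,
    sense: str = "max",
    S: Optional[sp.spmatrix] = None,
    options: SolverOptions = DEFAULT_OPTIONS,
) -> Optional[np.ndarray]:
    """Minimum-Euclidean-norm flux vector on the optimal face of an LP."""
    if S is None:
        S = build_stoichiometric_matrix(model)
    slack = max(1.0, abs(optimum)) * 1e-9
    extra = sp.csr_matrix(c.reshape(1, -1))
    lo = np.array([optimum - slack if sense == "max" else -np.inf])
    hi = np.array([np.inf if sense == "max" else optimum + slack])
    x, status = _qp_closest(
        np.zeros(S.shape[1]),
        S,
        model.lower_bounds,
        model.upper_bounds,
        extra_A=extra,
        extra_lu=(lo, hi),
        options=options,
    )
    return x


def moma(
    model: MetabolicModel,
    reference: FluxVector,
    perturbation: Optional[Dict[str, Tuple[float, float]]] = None,
    config: Optional[ScenarioConfig] = None,
    options: SolverOptions = DEFAULT_OPTIONS,
) -> FluxVector:
    """Minimization of metabolic adjustment.

    Finds m = argmin D(h, m) = sqrt(sum_i (h_i - m_i)^2) over the feasible
    set of the (optionally bound-perturbed) model, where h is ``reference``.
    The distance D is reported on the result; ``objective_value`` is D.
    """
    m = apply_scenario(model, config)
    if perturbation:
        m = m.with_bounds(dict(perturbation))
    S = build_stoichiometric_matrix(m)
    h = reference.vector(m)
    x, status = _qp_closest(h, S, m.lower_bounds, m.upper_bounds, options=options)
    if x is None:
        return FluxVector({}, math.nan, status, distance=math.nan)
    d = float(np.linalg.norm(x - h))
    return _flux_vector(m, x, d, "optimal", distance=d)


def flux_variability(
    model: MetabolicModel,
    reactions: Optional[Sequence[str]] = None,
    extra_A: Optional[sp.spmatrix] = None,
    extra_lu: Optional[Tuple[np.ndarray, np.ndarray]] = None,
    options: SolverOptions = DEFAULT_OPTIONS,
) -> Dict[str, Tuple[float, float]]:
    """Per-reaction (min, max) flux over the feasible set (plus extra rows)."""
    S = build_stoichiometric_matrix(model)
    lb, ub = model.lower_bounds, model.upper_bounds
    ridx = model.reaction_index
    if reactions is None:
        reactions = [r.id for r in model.reactions]
    out: Dict[str, Tuple[float, float]] = {}
    for rid in reactions:
        c = np.zeros(len(model.reactions))
        c[ridx[rid]] = 1.0
        lo_hi = []
        for sense in ("min", "max"):
            res = _solve_lp(c, S, lb, ub, sense, extra_A, extra_lu, options)
            if res.status != 0:
                raise InfeasibleProblemError(
                    f"FVA LP for {rid} returned status {res.status}"
                )
            lo_hi.append(float(res.x[ridx[rid]]))
        out[rid] = (lo_hi[0], lo_hi[1])
    return out


# ---------------------------------------------------------------------------
# energy accounting and scenarios
# ---------------------------------------------------------------------------

@dataclass
class EnergyAccounting:
    """ATP production by pathway plus the Warburg indicator ratios.

    ``atpg_over_atpop`` is ATP produced in glycolysis over ATP produced in
    OXPHOS; ``lacr_over_ocr`` is lactate excretion over oxygen uptake rate.
    """

    atp_total: float
    atp_by_pathway: Dict[str, float]
    atp_share_by_pathway: Dict[str, float]
    atpg_over_atpop: float
    lacr_over_ocr: float


def _exchange_flux(model: MetabolicModel, v: FluxVector, base: str) -> float:
    total = 0.0
    for r in model.reactions:
        if r.is_exchange and r.id.startswith(f"EX_{base}_"):
            total += v.get(r.id)
    return total


def energy_accounting(model: MetabolicModel, v: FluxVector) -> EnergyAccounting:
    """ATP produced per pathway: sum over reactions of max(0, atp_yield * flux)."""
    by_pathway: Dict[str, float] = {}
    for r in model.reactions:
        if r.atp_yield == 0:
            continue
        produced = max(0.0, r.atp_yield * v.get(r.id))
        if produced > 0.0:
            by_pathway[r.pathway] = by_pathway.get(r.pathway, 0.0) + produced
    total = sum(by_pathway.values())
    shares = {p: (x / total if total > 0 else 0.0) for p, x in by_pathway.items()}
    glyc = by_pathway.get("glycolysis", 0.0)
    oxphos = by_pathway.get("OXPHOS", 0.0)
    atpg_over_atpop = glyc / oxphos if oxphos > 0 else math.inf
    lac_excretion = _exchange_flux(model, v, "lac")  # positive = excretion
    o2_uptake = -_exchange_flux(model, v, "o2")  # uptake is negative flux
    lacr_over_ocr = lac_excretion / o2_uptake if o2_uptake > 0 else math.inf
    return EnergyAccounting(
        atp_total=total,
        atp_by_pathway=by_pathway,
        atp_share_by_pathway=shares,
        atpg_over_atpop=atpg_over_atpop,
        lacr_over_ocr=lacr_over_ocr,
    )


@dataclass
class ScenarioResult:
    scenario: str
    flux: FluxVector
    accounting: EnergyAccounting
    biomass: float


_SCENARIO_ZEROES = {
    "baseline": (),
    "no_glucose": ("glucose",),
    "no_glutamine": ("glutamine",),
    "no_both": ("glucose", "glutamine"),
}


def scenario_run(
    model: MetabolicModel,
    config: Optional[ScenarioConfig] = None,
    scenario: str = "baseline",
    reference: Optional[FluxVector] = None,
    options: SolverOptions = DEFAULT_OPTIONS,
) -> ScenarioResult:
    """Deprivation scenario: zero the named uptakes, FBA, then MOMA vs baseline.

    ``reference`` (the baseline minimum-norm FBA solution) is computed when
    not supplied; passing it avoids recomputation across scenarios.
    """
    if scenario not in _SCENARIO_ZEROES:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    config = config or ScenarioConfig()
    if reference is None:
        reference = fba(model, None, "max", config, options=options)
    if not reference.ok:
        raise InfeasibleProblemError("baseline FBA is not optimal; cannot run scenario")
    dep_config = config.with_zeroed(_SCENARIO_ZEROES[scenario])
    dep_fba = fba(model, None, "max", dep_config, options=options)
    if not dep_fba.ok:
        return ScenarioResult(scenario, dep_fba, energy_accounting(model, FluxVector({}, 0, dep_fba.status)), math.nan)
    result = moma(model, reference, config=dep_config, options=options)
    if not result.ok:
        return ScenarioResult(scenario, result, energy_accounting(model, FluxVector({}, 0, result.status)), math.nan)
    biomass = result.get(model.biomass_id)
    return ScenarioResult(scenario, result, energy_accounting(model, result), biomass)
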