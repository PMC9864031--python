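"""Transcriptome integration: Present/Absent calls and GIMME model reduction.

Expression values (linear scale) are binarized per condition against a
percent-of-mean threshold: a gene is Present iff its mean expression across
the condition's samples reaches ``threshold_fraction`` times the grand mean
of all gene means in that condition (ties count as Present). The fractions
used for the published datasets ship as named presets.

GIMME then penalizes flux through reactions whose GPR is inactive under the
Absent genes while holding growth at a required fraction of the untreated
optimum: minimize sum of |v_r| over penalized reactions subject to
S.v = 0, bounds, and biomass >= growth_fraction * optimum. Penalized
reactions that carry no flux at the optimum and cannot carry any flux under
the growth constraint are removed from the model; the objective value is
reported as the inconsistency score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import linprog

from .model import MetabolicModel, Reaction, build_stoichiometric_matrix, replace_model
from .solve import InfeasibleProblemError, SolverOptions, DEFAULT_OPTIONS, fba

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneStateMap",
    "THRESHOLD_PRESETS",
    "binarize_expression",
    "gimme_reduce",
]

#: Percent-of-mean binarization fractions used for the published series.
THRESHOLD_PRESETS: Dict[str, float] = {
    "GSE37418": 0.723,
    "WNT": 0.725,
    "SHH": 0.747,
    "GR3": 0.9024,
    "GR4": 0.7634,
    "GSE62600": 0.30,
    "GSE10327_M0": 0.45,
    "GSE10327_M2": 0.50,
    "GSE10327_M4": 0.55,
}


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with per-sample condition labels."""

    values: pd.DataFrame  # index: gene ids; columns: sample ids
    condition_of: Dict[str, str]

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.condition_of)
        if missing:
            raise ValueError(f"samples without condition labels: {sorted(missing)}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative (linear scale)")

    @property
    def genes(self) -> List[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> List[str]:
        return sorted(set(self.condition_of.values()))

    def samples_for(self, condition: str) -> List[str]:
        return [s for s in self.values.columns if self.condition_of[s] == condition]

    def condition_values(self, condition: str) -> pd.DataFrame:
        samples = self.samples_for(condition)
        if not samples:
            raise ValueError(f"condition {condition!r} has no samples")
        return self.values[samples]

    # -- TSV + YAML sidecar I/O (series-matrix-like layout) -----------------

    def to_tsv(self, path, sidecar: Optional[str] = None) -> None:
        import yaml

        path = Path(path)
        self.values.to_csv(path, sep="\t", index_label="gene")
        side = Path(sidecar) if sidecar else path.with_suffix(".yaml")
        with open(side, "w") as fh:
            yaml.safe_dump({"conditions": self.condition_of}, fh, sort_keys=True)

    @classmethod
    def from_tsv(cls, path, sidecar: Optional[str] = None) -> "ExpressionMatrix":
        import yaml

        path = Path(path)
        values = pd.read_csv(path, sep="\t", index_col=0)
        values.index.name = None
        side = Path(sidecar) if sidecar else path.with_suffix(".yaml")
        with open(side) as fh:
            meta = yaml.safe_load(fh)
        return cls(values=values, condition_of=dict(meta["conditions"]))


@dataclass
class GeneStateMap:
    """Present/Absent call per gene at a percent-of-mean threshold."""

    states: Dict[str, str]
    threshold_value: float
    threshold_fraction: float
    condition: str

    @property
    def absent_genes(self) -> List[str]:
        return sorted(g for g, s in self.states.items() if s == "Absent")

    @property
    def present_genes(self) -> List[str]:
        return sorted(g for g, s in self.states.items() if s == "Present")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": list(self.states), "state": list(self.states.values())}
        )


def binarize_expression(
    expr: ExpressionMatrix, condition: str, threshold_fraction: float
) -> GeneStateMap:
    """Present/Absent calls for one condition.

    threshold_value = threshold_fraction x (grand mean of per-gene means in
    the condition); a gene is Present iff its mean >= threshold_value.
    """
    if threshold_fraction <= 0:
        raise ValueError("threshold_fraction must be positive")
    block = expr.condition_values(condition)
    gene_means = block.mean(axis=1)
    threshold_value = float(threshold_fraction * gene_means.mean())
    states = {
        g: ("Present" if m >= threshold_value else "Absent")
        for g, m in gene_means.items()
    }
    return GeneStateMap(
        states=states,
        threshold_value=threshold_value,
        threshold_fraction=float(threshold_fraction),
        condition=condition,
    )


def _prune(model: MetabolicModel, removed: List[str]) -> MetabolicModel:
    keep = [r for r in model.reactions if r.id not in set(removed)]
    used_mets = {m for r in keep for m in r.stoichiometry}
    used_genes = {g for r in keep for g in r.gpr.genes}
    return replace_model(
        model,
        reactions=keep,
        metabolites=[m for m in model.metabolites if m.id in used_mets],
        genes=[g for g in model.genes if g in used_genes],
    ).validate()


def gimme_reduce(
    model: MetabolicModel,
    states: GeneStateMap,
    growth_fraction: float = 0.9,
    flux_tolerance: float = 1e-6,
    options: SolverOptions = DEFAULT_OPTIONS,
) -> Tuple[MetabolicModel, float, List[str]]:
    """GIMME context-specific reduction.

    Returns ``(reduced_model, inconsistency_score, removed_reaction_ids)``.
    Raises :class:`InfeasibleProblemError` when the growth constraint cannot
    be met (threshold too aggressive).
    """
    if not (0.0 < growth_fraction <= 1.0):
        raise ValueError("growth_fraction must lie in (0, 1]")
    absent = set(states.absent_genes)
    missing = set(model.genes) - set(states.states)
    if missing:
        logger.info(
            "%d model genes missing from expression; treated as Present", len(missing)
        )
    penalized = [
        r.id
        for r in model.reactions
        if not r.gpr.is_empty and not r.gpr.evaluate(absent)
    ]
    if not penalized:
        return model, 0.0, []

    wt = fba(model, None, "max", None, minimum_norm=False, options=options)
    if not wt.ok:
        raise InfeasibleProblemError(f"wild-type FBA is {wt.status}")
    if wt.objective_value <= flux_tolerance:
        raise InfeasibleProblemError(
            "model cannot grow; GIMME growth constraint is vacuous "
            "(threshold too aggressive)"
        )
    required = growth_fraction * wt.objective_value

    S = build_stoichiometric_matrix(model)
    n = len(model.reactions)
    ridx = model.reaction_index
    pen_idx = [ridx[rid] for rid in penalized]
    k = len(pen_idx)

    # variables: [v (n), t (k)] with t_j >= |v_{pen_j}|; minimize sum t
    c = np.concatenate([np.zeros(n), np.ones(k)])
    A_eq = sp.hstack([S, sp.csr_matrix((S.shape[0], k))], format="csr")
    rows, cols, vals = [], [], []
    for j, idx in enumerate(pen_idx):
        rows += [2 * j, 2 * j, 2 * j + 1, 2 * j + 1]
        cols += [idx, n + j, idx, n + j]
        vals += [1.0, -1.0, -1.0, -1.0]  # v - t <= 0 ; -v - t <= 0
    A_ub = sp.csr_matrix((vals, (rows, cols)), shape=(2 * k, n + k))
    b_ub = np.zeros(2 * k)
    # growth constraint: -biomass <= -required
    g_row = sp.csr_matrix(
        ([-1.0], ([0], [ridx[model.biomass_id]])), shape=(1, n + k)
    )
    A_ub = sp.vstack([A_ub, g_row], format="csr")
    b_ub = np.concatenate([b_ub, [-required]])
    bounds = [(lb, ub) for lb, ub in zip(model.lower_bounds, model.upper_bounds)]
    bounds += [(0, None)] * k
    res = linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=np.zeros(S.shape[0]),
        bounds=bounds, method=options.lp_method,
    )
    if res.status == 2:
        raise InfeasibleProblemError(
            "GIMME growth constraint infeasible (threshold too aggressive)"
        )
    if res.status != 0:
        raise RuntimeError(f"GIMME LP failed: {res.message}")
    inconsistency = float(res.fun)
    v_opt = res.x[:n]

    # removal: zero optimal flux AND zero attainable flux under growth
    extra_A = sp.csr_matrix(
        ([1.0], ([0], [ridx[model.biomass_id]])), shape=(1, n)
    )
    extra_lu = (np.array([required]), np.array([np.inf]))
    removed: List[str] = []
    from .solve import flux_variability

    candidates = [
        rid for rid, idx in zip(penalized, pen_idx)
        if abs(v_opt[idx]) <= flux_tolerance
    ]
    if candidates:
        spans = flux_variability(model, candidates, extra_A, extra_lu, options)
        for rid in candidates:
            lo, hi = spans[rid]
            if max(abs(lo), abs(hi)) <= flux_tolerance:
                removed.append(rid)
    removed.sort()
    reduced = _prune(model, removed) if removed else model
    return reduced, inconsistency, removed
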