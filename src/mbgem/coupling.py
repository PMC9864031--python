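"""Flux coupling analysis (FCA) against anchor reactions.

Reaction pairs are classified over the steady-state cone: the model is put
in irreversible form (reversible reactions split; only the signs of the
original bounds are kept, with a large cap making LPs bounded), and the
attainable range of the flux ratio v_i / v_j is probed with LPs.

Classes follow the standard taxonomy:

* ``blocked`` — either reaction can carry no flux at all;
* ``fully`` — the ratio is a nonzero constant (within tolerance);
* ``partially`` — each reaction's activity forces the other's, but the
  ratio varies;
* ``directionally_i_to_j`` — flux through i forces flux through j, not
  conversely (``j_to_i`` symmetric);
* ``uncoupled`` — either can run without the other.

Only pairs against configured anchors (the biomass reaction by default) are
computed; an all-pairs matrix would be quadratic in model size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from .model import MetabolicModel, build_stoichiometric_matrix
from .solve import DEFAULT_OPTIONS, SolverOptions

__all__ = ["CouplingRecord", "classify_pair_coupling", "biomass_coupled_set"]

RATIO_TOL = 1e-6  # numerical equality of ratio extremes for the "fully" call


@dataclass
class CouplingRecord:
    pair: Tuple[str, str]  # (i, j); j is the anchor (biomass) in set queries
    ratio_min: float
    ratio_max: float
    klass: str


class _Cone:
    """Irreversible-split steady-state cone with sign-only bounds."""

    def __init__(self, model: MetabolicModel, cap: float = 1000.0):
        S = build_stoichiometric_matrix(model).tocsc()
        self.n = len(model.reactions)
        self.cap = cap
        self.S_split = sp.hstack([S, -S], format="csc")
        fwd_cap = np.where(model.upper_bounds > 0, cap, 0.0)
        bwd_cap = np.where(model.lower_bounds < 0, cap, 0.0)
        self.lb = np.zeros(2 * self.n)
        self.ub = np.concatenate([fwd_cap, bwd_cap])
        self.rid_index = model.reaction_index

    def net_coef(self, idx: int) -> np.ndarray:
        c = np.zeros(2 * self.n)
        c[idx] = 1.0
        c[self.n + idx] = -1.0
        return c

    def _lp(self, c, sense, extra_A=None, extra_b=None, fixed_zero=None):
        lb, ub = self.lb, self.ub.copy()
        if fixed_zero is not None:
            for idx in fixed_zero:
                ub[idx] = 0.0
                ub[self.n + idx] = 0.0
        res = linprog(
            -c if sense == "max" else c,
            A_eq=sp.vstack([self.S_split] + ([extra_A] if extra_A is not None else []), format="csr"),
            b_eq=np.concatenate([np.zeros(self.S_split.shape[0])] + ([extra_b] if extra_b is not None else [])),
            bounds=np.column_stack([lb, ub]),
            method="highs",
        )
        return res

    def max_abs_flux(self, idx: int, fixed_zero=None) -> float:
        """Largest attainable |net flux| (forward/backward probed separately)."""
        c = self.net_coef(idx)
        best = 0.0
        for sense in ("max", "min"):
            res = self._lp(c, sense, fixed_zero=fixed_zero)
            if res.status == 0:
                best = max(best, abs(float(c @ res.x)))
        return best

    def ratio_extremes(self, i: int, j: int) -> List[float]:
        """Attainable v_i values with v_j normalized to +-1 (net fluxes)."""
        out: List[float] = []
        ci, cj = self.net_coef(i), self.net_coef(j)
        for sigma in (1.0, -1.0):
            extra_A = sp.csr_matrix(cj.reshape(1, -1))
            extra_b = np.array([sigma])
            for sense in ("min", "max"):
                res = self._lp(ci, sense, extra_A, extra_b)
                if res.status == 0:
                    out.append(float(ci @ res.x) / sigma)
        return out


def _classify(
    cone: _Cone, i: int, j: int, blocked_i: bool, blocked_j: bool
) -> CouplingRecord:
    names = (i, j)
    if blocked_i or blocked_j:
        return CouplingRecord(names, math.nan, math.nan, "blocked")
    # can i run while j is shut off, and vice versa?
    i_without_j = cone.max_abs_flux(i, fixed_zero=[j]) > RATIO_TOL
    j_without_i = cone.max_abs_flux(j, fixed_zero=[i]) > RATIO_TOL
    ratios = cone.ratio_extremes(i, j)
    if ratios:
        rmin, rmax = min(ratios), max(ratios)
        big = cone.cap / 10.0
        rmin_r = -math.inf if rmin < -big else rmin
        rmax_r = math.inf if rmax > big else rmax
    else:
        rmin_r = rmax_r = math.nan
    if not i_without_j and not j_without_i:
        if (
            ratios
            and math.isfinite(rmin_r)
            and math.isfinite(rmax_r)
            and abs(rmax_r - rmin_r) <= RATIO_TOL * max(1.0, abs(rmax_r))
            and abs(rmax_r) > RATIO_TOL
        ):
            klass = "fully"
        else:
            klass = "partially"
    elif not i_without_j:
        klass = "directionally_i_to_j"
    elif not j_without_i:
        klass = "directionally_j_to_i"
    else:
        klass = "uncoupled"
    return CouplingRecord(names, rmin_r, rmax_r, klass)


def classify_pair_coupling(
    model: MetabolicModel,
    i: str,
    j: str,
    cone: Optional[_Cone] = None,
    options: SolverOptions = DEFAULT_OPTIONS,
) -> CouplingRecord:
    """Coupling class of reaction pair (i, j) over the steady-state cone."""
    cone = cone or _Cone(model)
    ii, jj = cone.rid_index[i], cone.rid_index[j]
    blocked_i = cone.max_abs_flux(ii) <= RATIO_TOL
    blocked_j = cone.max_abs_flux(jj) <= RATIO_TOL
    rec = _classify(cone, ii, jj, blocked_i, blocked_j)
    return CouplingRecord((i, j), rec.ratio_min, rec.ratio_max, rec.klass)


def biomass_coupled_set(
    model: MetabolicModel,
    anchor: Optional[str] = None,
    options: SolverOptions = DEFAULT_OPTIONS,
) -> Dict[str, List[CouplingRecord]]:
    """One coupling record per reaction against the biomass (or anchor) reaction.

    Returns records partitioned by class. Reactions in any class except
    ``uncoupled``/``blocked`` constitute the biomass-coupled set; a reaction
    the biomass cannot run without (deletion forces zero growth) appears as
    ``directionally_j_to_i`` (anchor forces reaction) or stronger.
    """
    anchor = anchor or model.biomass_id
    cone = _Cone(model)
    jj = cone.rid_index[anchor]
    if cone.max_abs_flux(jj) <= RATIO_TOL:
        raise ValueError(f"anchor reaction {anchor!r} is blocked")
    out: Dict[str, List[CouplingRecord]] = {}
    for r in model.reactions:
        if r.id == anchor:
            continue
        ii = cone.rid_index[r.id]
        blocked_i = cone.max_abs_flux(ii) <= RATIO_TOL
        rec = _classify(cone, ii, jj, blocked_i, False)
        rec = CouplingRecord((r.id, anchor), rec.ratio_min, rec.ratio_max, rec.klass)
        out.setdefault(rec.klass, []).append(rec)
    return out
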