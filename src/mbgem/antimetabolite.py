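"""Antimetabolite screening: fingerprint similarity + competitive inhibition.

An antimetabolite is a compound structurally close to a natural metabolite
that competitively inhibits the enzymes consuming it. Candidate compounds
are matched to model metabolites by the Tanimoto coefficient of hashed
circular (Morgan) substructure fingerprints, radius 2, 2048 bits; matches
above 0.90 pass the similarity gate. Inhibition of a matched metabolite is
simulated by tightening, in both the tumor and the healthy model, the
bound of every enzymatic reaction consuming it to 0.1 x its uninhibited
baseline flux (toward zero, for either flux sign), then re-solving with
MOMA against the baseline. A metabolite is a hit when the similarity gate
passes, tumor growth falls by more than 40%, and the healthy model stays
within the safety cutoff.

Boundary (exchange) pseudo-reactions carry no enzyme and are never
targeted; currency cofactors (ATP, NAD(P)H, oxygen...) are excluded via a
configurable stop-list, otherwise every screen would hit energy metabolism.
A reaction with zero baseline flux is left untouched: scaling zero would
amount to a full knockout and overstate the inhibition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import MetabolicModel
from .solve import (
    DEFAULT_OPTIONS,
    FluxVector,
    ScenarioConfig,
    SolverOptions,
    apply_scenario,
    fba,
    moma,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Fingerprint",
    "AntimetaboliteHit",
    "fingerprint",
    "tanimoto",
    "competitive_inhibition_screen",
    "TANIMOTO_CUTOFF",
    "INHIBITION_FACTOR",
    "DEFAULT_STOPLIST",
]

TANIMOTO_CUTOFF = 0.90
INHIBITION_FACTOR = 0.1
DEFAULT_STOPLIST = ("atp", "adp", "nadh", "nadph", "o2", "co2", "h2o")


@dataclass(frozen=True)
class Fingerprint:
    """Hashed circular substructure bit set of one molecule."""

    bits: FrozenSet[int]
    radius: int = 2
    n_bits: int = 2048


def fingerprint(smiles: str, radius: int = 2, n_bits: int = 2048) -> Fingerprint:
    """Morgan fingerprint of a SMILES string; invalid/empty structures raise."""
    from rdkit import Chem, RDLogger
    from rdkit.Chem import rdFingerprintGenerator

    RDLogger.DisableLog("rdApp.*")
    if not smiles or not smiles.strip():
        raise ValueError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumAtoms() == 0:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    return Fingerprint(bits=frozenset(fp.GetOnBits()), radius=radius, n_bits=n_bits)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|A & B| / |A | B|; fingerprints must share parameters."""
    if (a.radius, a.n_bits) != (b.radius, b.n_bits):
        raise ValueError("fingerprint parameter mismatch")
    if not a.bits and not b.bits:
        raise ValueError("Tanimoto of two empty fingerprints is undefined")
    inter = len(a.bits & b.bits)
    union = len(a.bits | b.bits)
    return inter / union


@dataclass
class AntimetaboliteHit:
    metabolite_id: str
    analog_id: Optional[str]
    tanimoto: float
    targeted_reactions: List[str]
    mb_growth_reduction: float
    healthy_reduction: float
    hit: bool


def _load_compounds(compounds) -> pd.DataFrame:
    if isinstance(compounds, pd.DataFrame):
        df = compounds
    else:
        df = pd.read_csv(compounds, sep="\t")
    missing = {"id", "smiles"} - set(df.columns)
    if missing:
        raise ValueError(f"compound table lacks columns: {sorted(missing)}")
    return df


def _compound_fingerprints(df: pd.DataFrame) -> Dict[str, Fingerprint]:
    out = {}
    for _, row in df.iterrows():
        try:
            out[str(row["id"])] = fingerprint(str(row["smiles"]))
        except ValueError as exc:
            logger.warning("skipping compound %s: %s", row["id"], exc)
    return out


def _inhibition_overrides(
    model: MetabolicModel,
    reference: FluxVector,
    targets: Sequence[str],
    factor: float,
    flux_tol: float = 1e-9,
) -> Dict[str, Tuple[float, float]]:
    overrides = {}
    for rid in targets:
        rxn = model.reaction(rid)
        flux = reference.get(rid)
        if abs(flux) <= flux_tol:
            continue  # untouched: no carried flux to inhibit
        if flux > 0:
            overrides[rid] = (min(rxn.lower_bound, factor * flux), factor * flux)
        else:
            overrides[rid] = (factor * flux, max(rxn.upper_bound, factor * flux))
    return overrides


def competitive_inhibition_screen(
    mb_model: MetabolicModel,
    healthy_model: MetabolicModel,
    compounds,
    config: Optional[ScenarioConfig] = None,
    tanimoto_cutoff: float = TANIMOTO_CUTOFF,
    inhibition_factor: float = INHIBITION_FACTOR,
    growth_cutoff: float = 0.40,
    safety_cutoff: float = 0.40,
    stop_list: Optional[Sequence[str]] = None,
    options: SolverOptions = DEFAULT_OPTIONS,
) -> List[AntimetaboliteHit]:
    """Simulate competitive inhibition of every SMILES-annotated metabolite.

    ``compounds`` is a DataFrame or TSV path with columns (id, name, smiles).
    Returns one record per screened metabolite, sorted by id.
    """
    if not (0.0 <= tanimoto_cutoff <= 1.0):
        raise ValueError("tanimoto_cutoff must lie in [0, 1]")
    if not (0.0 < inhibition_factor <= 1.0):
        raise ValueError("inhibition_factor must lie in (0, 1]")
    comp_df = _load_compounds(compounds)
    comp_fps = _compound_fingerprints(comp_df)
    if stop_list is None:
        stop_list = mb_model.annotations.get("cofactor_stoplist", DEFAULT_STOPLIST)
    stop = {s.lower() for s in stop_list}

    models = {"mb": apply_scenario(mb_model, config),
              "healthy": apply_scenario(healthy_model, config)}
    refs = {}
    for key, m in models.items():
        ref = fba(m, None, "max", None, options=options)
        if not ref.ok:
            raise RuntimeError(f"baseline FBA for {key} model is {ref.status}")
        refs[key] = ref

    out: List[AntimetaboliteHit] = []
    for met in sorted(mb_model.metabolites, key=lambda m: m.id):
        if met.smiles is None or met.base_id.lower() in stop:
            continue
        try:
            met_fp = fingerprint(met.smiles)
        except ValueError as exc:
            logger.warning("metabolite %s: %s", met.id, exc)
            continue
        best_id, best_score = None, 0.0
        for cid, fp in comp_fps.items():
            score = tanimoto(met_fp, fp)
            if score > best_score:
                best_id, best_score = cid, score

        targets = [
            rid
            for rid in mb_model.consumers_of(met.id)
            if not mb_model.reaction(rid).is_exchange
        ]
        reductions = {}
        for key, m in models.items():
            ref = refs[key]
            wt = ref.get(m.biomass_id)
            overrides = _inhibition_overrides(
                m, ref, [t for t in targets if t in m.reaction_index],
                inhibition_factor,
            )
            if not overrides or wt <= 0:
                reductions[key] = 0.0
                continue
            sol = moma(m, ref, overrides, options=options)
            if not sol.ok:
                reductions[key] = 1.0
                continue
            reductions[key] = float(np.clip(1.0 - sol.get(m.biomass_id) / wt, 0.0, 1.0))
        if not targets:
            logger.info("metabolite %s is consumed by no enzymatic reaction", met.id)
        hit = (
            best_score > tanimoto_cutoff
            and reductions["mb"] > growth_cutoff
            and reductions["healthy"] <= safety_cutoff
        )
        out.append(
            AntimetaboliteHit(
                metabolite_id=met.id,
                analog_id=best_id,
                tanimoto=best_score,
                targeted_reactions=sorted(targets),
                mb_growth_reduction=reductions["mb"],
                healthy_reduction=reductions["healthy"],
                hit=hit,
            )
        )
    return out


def hits_to_frame(records: Sequence[AntimetaboliteHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "metabolite": r.metabolite_id,
                "analog": r.analog_id,
                "tanimoto": r.tanimoto,
                "targeted_reactions": ";".join(r.targeted_reactions),
                "mb_growth_reduction": r.mb_growth_reduction,
                "healthy_reduction": r.healthy_reduction,
                "hit": r.hit,
            }
            for r in records
        ]
    ).set_index("metabolite")
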