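"""Synthetic study inputs: a toy two-cell cerebellum model and expression data.

The real medulloblastoma network (hundreds of reactions reconstructed from a
brain model) is not distributable, so this module generates a deliberately
small but topologically faithful surrogate: a neuron/astrocyte pair with
lumped glycolysis, pentose phosphate, TCA, OXPHOS, glutamine/GABA disposal,
fatty-acid, mevalonate/cholesterol, cardiolipin, sphingolipid/ganglioside
and taurine pathways, shared-nutrient uptake split 97/3 between the cells,
and a cerebellar biomass drain in the neuron.

Two variants share every reaction id and differ only in bounds and GPR gene
sets:

* ``healthy`` — uptakes are free up to the scenario magnitudes, pyruvate
  dehydrogenase is unconstrained, and glucose transport is redundant
  (``SLC2A1 or SLC2A3``).
* ``mb`` — glucose, glutamine and threonine uptake are obligatory
  (lb = ub), pyruvate dehydrogenase is capped, and glucose transport
  depends on SLC2A1 alone. Forced glycolytic influx plus the oxidation cap
  reproduce the Warburg phenotype: lactate excretion at least twice the
  glucose uptake, glucose-dependent growth, dispensable glutamine.

The generator also emits a ground-truth report derived purely from the
wiring arithmetic (never from running the solvers), listing the planted
essential genes, isoenzyme synthetic-lethal pairs, expression-prunable dead
branches, antimetabolite hits and the reactions fully coupled to biomass.
Pipeline outputs are expected to match it exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .integration import ExpressionMatrix
from .model import MetabolicModel, Metabolite, Reaction, replace_model
from .gpr import parse_gpr
from .solve import CEREBELLUM_UPTAKE_BOUNDS

__all__ = [
    "ToyModelSpec",
    "ExpressionSpec",
    "generate_toy_models",
    "generate_expression_series",
    "mb_expression_spec",
    "generate_compound_table",
    "SMILES",
]

# Canonical SMILES used for model metabolites and the screening fixture.
SMILES: Dict[str, str] = {
    "glc": "OC[C@H]1OC(O)[C@H](O)[C@@H](O)[C@@H]1O",
    "pyr": "CC(=O)C(=O)O",
    "lac": "CC(O)C(=O)O",
    "thr": "C[C@@H](O)[C@H](N)C(=O)O",
    "gln": "NC(=O)CC[C@H](N)C(=O)O",
    "glu": "OC(=O)CC[C@H](N)C(=O)O",
    "ser": "OC[C@H](N)C(=O)O",
    "mev": "CC(O)(CCO)CC(=O)O",
    "sph": "CCCCCCCCCCCCCCC[C@@H](O)[C@@H](N)CO",
    "tau": "NCCS(=O)(=O)O",
}

_ANALOG_COMPOUNDS = [
    # (id, name, smiles) — analog_* entries reuse the metabolite SMILES so the
    # similarity gate is exact (Tanimoto 1.0); the rest are real compounds
    # whose fingerprint scores are reported but never asserted.
    ("analog_lactate", "synthetic lactate analog", SMILES["lac"]),
    ("analog_threonine", "synthetic threonine analog", SMILES["thr"]),
    ("analog_glutamine", "synthetic glutamine analog", SMILES["gln"]),
    ("analog_glutamate", "synthetic glutamate analog", SMILES["glu"]),
    ("phytosphingosine", "phytosphingosine", "CCCCCCCCCCCCCC[C@@H](O)[C@@H](O)[C@@H](N)CO"),
    ("meglutol", "meglutol (3-hydroxy-3-methylglutarate)", "CC(O)(CC(=O)O)CC(=O)O"),
    ("oxamate", "oxamate", "NC(=O)C(=O)O"),
    ("aspirin", "acetylsalicylic acid", "CC(=O)Oc1ccccc1C(=O)O"),
]

REQUIRED_PATHWAYS = frozenset(
    {"glycolysis", "PPP", "OXPHOS", "fatty_acid", "cholesterol", "cardiolipin", "sphingolipid"}
)
OPTIONAL_PATHWAYS = frozenset({"TCA", "glutamine_GABA", "taurine"})


@dataclass
class ToyModelSpec:
    """Design parameters of the generated healthy/MB model pair."""

    pathways: Dict[str, bool] = field(
        default_factory=lambda: {p: True for p in sorted(REQUIRED_PATHWAYS | OPTIONAL_PATHWAYS)}
    )
    neuron_fraction: float = 0.97
    uptake_bounds: Dict[str, float] = field(
        default_factory=lambda: dict(CEREBELLUM_UPTAKE_BOUNDS)
    )
    lactate_glucose_ratio_target: float = 2.0
    biomass_glucose_dependent: bool = True
    maintenance_atp: float = 0.2  # obligatory non-growth ATP drain, mmol/gDW/h
    mb_pdh_cap: float = 0.03  # MB pyruvate-oxidation cap (Warburg bound)

    @property
    def astrocyte_fraction(self) -> float:
        return 1.0 - self.neuron_fraction


# Biomass composition (mmol precursor per unit biomass flux). Cerebellar
# composition coefficients are not published at this granularity; these are
# uniform-order placeholders chosen so leucine is the single binding nutrient.
BIOMASS_COEFS = {
    "leu_N": 1.0,
    "trp_N": 0.1,
    "tyr_N": 0.05,
    "met_N": 0.15,
    "r5p_N": 0.2,
    "fa_N": 0.05,
    "chol_N": 0.04,
    "cl_N": 0.02,
    "sm_N": 0.02,
    "atp_N": 10.0,
}


def _build_reactions(spec: ToyModelSpec, variant: str) -> Tuple[List[Reaction], List[str]]:
    mb = variant == "mb"
    nf, af = spec.neuron_fraction, spec.astrocyte_fraction
    ub_def = 1000.0
    u = spec.uptake_bounds

    def ex_bounds(magnitude: float, forced: bool) -> Tuple[float, float]:
        return (-magnitude, -magnitude if forced else 0.0)

    forced_uptakes = ["glucose", "glutamine", "threonine"] if mb else []

    glut_gpr = "SLC2A1" if mb else "SLC2A1 or SLC2A3"
    pdh_ub = spec.mb_pdh_cap if mb else ub_def

    R: List[Reaction] = []

    def add(rid, stoich, lb=0.0, ub=ub_def, gpr="", pathway="", exchange=False,
            atp=0, name="", published_id=None):
        R.append(
            Reaction(
                id=rid, name=name or rid, stoichiometry=stoich, lower_bound=lb,
                upper_bound=ub, gpr=parse_gpr(gpr), pathway=pathway,
                is_exchange=exchange, atp_yield=atp, published_id=published_id,
            )
        )

    # --- exchanges (uptake = negative flux) --------------------------------
    lbg, ubg = ex_bounds(nf * u["glucose"], "glucose" in forced_uptakes)
    add("EX_glc_N", {"glc_N": -1}, lbg, ubg, glut_gpr, "transport", True,
        name="glucose uptake (neuron)")
    lbg, ubg = ex_bounds(af * u["glucose"], "glucose" in forced_uptakes)
    add("EX_glc_A", {"glc_A": -1}, lbg, ubg, glut_gpr, "transport", True,
        name="glucose uptake (astrocyte)")
    lbq, ubq = ex_bounds(u["glutamine"], "glutamine" in forced_uptakes)
    add("EX_gln_N", {"gln_N": -1}, lbq, ubq, "SLC1A5", "transport", True,
        name="glutamine uptake (neuron)")
    add("EX_o2_N", {"o2_N": -1}, -nf * u["oxygen"], 0.0, "", "transport", True)
    add("EX_o2_A", {"o2_A": -1}, -af * u["oxygen"], 0.0, "", "transport", True)
    add("EX_leu_N", {"leu_N": -1}, -u["leucine"], 0.0, "SLC7A5", "transport", True,
        name="leucine uptake (LAT1)")
    add("EX_trp_N", {"trp_N": -1}, -u["tryptophan"], 0.0, "", "transport", True)
    add("EX_tyr_N", {"tyr_N": -1}, -u["tyrosine"], 0.0, "", "transport", True)
    add("EX_met_N", {"met_N": -1}, -u["methionine"], 0.0, "", "transport", True)
    lbt, ubt = ex_bounds(u["threonine"], "threonine" in forced_uptakes)
    add("EX_thr_N", {"thr_N": -1}, lbt, ubt, "", "transport", True,
        name="threonine uptake", published_id="E621")
    add("EX_glycogen_N", {"glycogen_N": -1}, -u["glycogen"], 0.0, "", "transport", True)
    add("EX_bhb_N", {"bhb_N": -1}, -u["ketone_bodies"], 0.0, "", "transport", True)
    add("EX_acac_N", {"acac_N": -1}, -u["ketone_bodies"], 0.0, "", "transport", True)
    add("EX_lac_C", {"lac_C": -1}, 0.0, ub_def, "", "exchange", True,
        name="lactate excretion")
    add("EX_gm2_C", {"gm2_C": -1}, 0.0, ub_def, "", "exchange", True,
        name="ganglioside shedding")
    add("EX_tau_C", {"tau_C": -1}, 0.0, ub_def, "", "exchange", True,
        name="taurine release")

    # --- neuron core -------------------------------------------------------
    add("HK_N", {"glc_N": -1, "atp_N": -1, "g6p_N": 1}, 0, ub_def,
        "HK1 or HK2", "glycolysis", atp=-1, name="hexokinase (neuron)")
    add("GLY_N", {"g6p_N": -1, "pyr_N": 2, "atp_N": 2, "nadh_N": 2}, 0, ub_def,
        "PKM", "glycolysis", atp=2, name="lower glycolysis (neuron)")
    add("LDH_N", {"pyr_N": -1, "nadh_N": -1, "lac_N": 1}, 0, ub_def,
        "LDHA", "glycolysis", name="lactate dehydrogenase (neuron)")
    add("MCT_N", {"lac_N": -1, "lac_C": 1}, 0, ub_def, "", "transport",
        name="lactate export (neuron)")
    add("G6PD_N", {"g6p_N": -1, "r5p_N": 1, "nadph_N": 2}, 0, ub_def,
        "G6PD", "PPP", name="oxidative PPP (lumped)")
    add("SER_N", {"g6p_N": -1, "ser_N": 2}, 0, ub_def, "PHGDH", "sphingolipid",
        name="serine synthesis (lumped)")
    add("GPD_N", {"g6p_N": -1, "nadh_N": -2, "g3p_N": 2}, 0, ub_def,
        "GPD1 or GPD2", "cardiolipin", name="glycerol-3-phosphate synthesis")
    add("PDH_N", {"pyr_N": -1, "accoa_N": 1, "nadh_N": 1}, 0, pdh_ub,
        "PDHA1", "TCA", name="pyruvate dehydrogenase (neuron)")
    add("TCA_N", {"accoa_N": -1, "nadh_N": 3}, 0, ub_def, "CS", "TCA",
        name="TCA cycle (lumped, neuron)")
    add("OXPHOS_N", {"nadh_N": -1, "o2_N": -0.5, "atp_N": 2}, 0, ub_def,
        "NDUFS1", "OXPHOS", atp=2, name="oxidative phosphorylation (neuron)")
    add("NNT_N", {"nadh_N": -1, "nadph_N": 1}, -ub_def, ub_def, "", "redox",
        name="transhydrogenase (neuron)")
    add("NGAM_N", {"atp_N": -1}, spec.maintenance_atp, ub_def, "", "maintenance",
        atp=-1, name="non-growth ATP maintenance")
    add("SDS_N", {"thr_N": -1, "pyr_N": 1, "nadh_N": 1}, 0, ub_def, "SDS",
        "amino_acid", name="threonine dehydratase")

    # glutamine / glutamate / GABA disposal (no ATP or redox side effects)
    add("GLS_N", {"gln_N": -1, "glu_N": 1}, 0, ub_def, "GLS", "glutamine_GABA",
        name="glutaminase", published_id="R96")
    add("GLUX_N", {"glu_N": -1, "glu_C": 1}, 0, ub_def, "", "glutamine_GABA",
        name="glutamate release to cerebellum")
    add("EX_glu_C", {"glu_C": -1}, 0.0, ub_def, "", "exchange", True,
        name="glutamate accumulation")
    add("GAD_N", {"glu_N": -1, "gaba_N": 1}, 0, ub_def, "GAD1", "glutamine_GABA",
        name="glutamate decarboxylase")
    add("ABAT_N", {"gaba_N": -1, "succ_C": 1}, 0, ub_def, "ABAT", "glutamine_GABA",
        name="GABA shunt to succinate (lumped)")
    add("EX_succ_C", {"succ_C": -1}, 0.0, ub_def, "", "exchange", True,
        name="succinate release")

    # fatty acid synthesis
    add("ACC_N", {"accoa_N": -1, "atp_N": -1, "malcoa_N": 1}, 0, ub_def,
        "ACACA", "fatty_acid", atp=-1, name="acetyl-CoA carboxylase")
    add("FAS_N", {"accoa_N": -1, "malcoa_N": -3, "nadph_N": -4, "fa_N": 1},
        0, ub_def, "FASN", "fatty_acid", name="fatty acid synthase (lumped)")

    # cardiolipin branch
    add("GPAM_N", {"g3p_N": -1, "fa_N": -2, "pa_N": 1}, 0, ub_def, "GPAM",
        "cardiolipin", name="phosphatidate synthesis")
    add("CDS_N", {"pa_N": -1, "cdpdag_N": 1}, 0, ub_def, "CDS1", "cardiolipin",
        name="CDP-diacylglycerol synthase")
    add("CRLS_N", {"cdpdag_N": -1, "g3p_N": -1, "cl_N": 1}, 0, ub_def, "CRLS1",
        "cardiolipin", name="cardiolipin synthase")

    # sphingolipid / ganglioside branch
    add("SPT_N", {"ser_N": -1, "fa_N": -1, "sph_N": 1}, 0, ub_def, "SPTLC1",
        "sphingolipid", name="serine palmitoyltransferase (lumped)")
    add("CERS_N", {"sph_N": -1, "fa_N": -1, "cer_N": 1}, 0, ub_def,
        "KDSR and CERS1", "sphingolipid", name="ceramide synthesis")
    add("SGMS_N", {"cer_N": -1, "sm_N": 1}, 0, ub_def, "SGMS1", "sphingolipid",
        name="sphingomyelin synthase")
    add("ST3GAL5_N", {"cer_N": -1, "gm3_N": 1}, 0, ub_def, "ST3GAL5",
        "sphingolipid", name="GM3 synthase (lumped from ceramide)")
    add("B4GALNT_N", {"gm3_N": -1, "gm2_C": 1}, 0, ub_def, "B4GALNT1",
        "sphingolipid", name="GM2 synthesis and shedding")

    # taurine branch
    add("CBS_N", {"met_N": -1, "cys_N": 1}, 0, ub_def, "CBS", "taurine",
        name="transsulfuration (lumped)")
    add("CDO_N", {"cys_N": -1, "tau_N": 1}, 0, ub_def, "CDO1", "taurine",
        name="taurine synthesis (lumped)")
    add("TAUX_N", {"tau_N": -1, "tau_C": 1}, 0, ub_def, "", "taurine",
        name="taurine release to cerebellum")

    # dead side branches (uptake bounds are zero): expression-prunable
    add("PYG_N", {"glycogen_N": -1, "g6p_N": 1}, 0, ub_def, "PYGB",
        "glycolysis", name="glycogen phosphorylase (lumped)")
    add("OXCT_N", {"bhb_N": -1, "accoa_N": 1}, 0, ub_def, "OXCT1", "TCA",
        name="ketone body utilization (BHB)")
    add("BDH_N", {"acac_N": -1, "accoa_N": 1}, 0, ub_def, "BDH1", "TCA",
        name="ketone body utilization (AcAc)")

    # --- astrocyte ---------------------------------------------------------
    add("HK_A", {"glc_A": -1, "atp_A": -1, "g6p_A": 1}, 0, ub_def,
        "HK1 or HK2", "glycolysis", atp=-1, name="hexokinase (astrocyte)")
    add("GLY_A", {"g6p_A": -1, "pyr_A": 2, "atp_A": 2, "nadh_A": 2}, 0, ub_def,
        "PKM", "glycolysis", atp=2, name="lower glycolysis (astrocyte)")
    add("LDH_A", {"pyr_A": -1, "nadh_A": -1, "lac_A": 1}, 0, ub_def,
        "LDHA", "glycolysis", name="lactate dehydrogenase (astrocyte)")
    add("MCT_A", {"lac_A": -1, "lac_C": 1}, 0, ub_def, "", "transport",
        name="lactate export (astrocyte)")
    add("PDH_A", {"pyr_A": -1, "accoa_A": 1, "nadh_A": 1}, 0, pdh_ub,
        "PDHA1", "TCA", name="pyruvate dehydrogenase (astrocyte)")
    add("TCA_A", {"accoa_A": -1, "nadh_A": 3}, 0, ub_def, "CS", "TCA",
        name="TCA cycle (lumped, astrocyte)")
    add("OXPHOS_A", {"nadh_A": -1, "o2_A": -0.5, "atp_A": 2}, 0, ub_def,
        "NDUFS1", "OXPHOS", atp=2, name="oxidative phosphorylation (astrocyte)")
    add("NNT_A", {"nadh_A": -1, "nadph_A": 1}, -ub_def, ub_def, "", "redox",
        name="transhydrogenase (astrocyte)")
    add("NGAM_A", {"atp_A": -1}, 0.0, ub_def, "", "maintenance", atp=-1,
        name="astrocyte ATP sink")

    # mevalonate / cholesterol branch (astrocyte) + shuttle to neuron
    add("HMGCS_A", {"accoa_A": -1, "hmg_A": 1}, 0, ub_def, "HMGCS1",
        "cholesterol", name="HMG-CoA synthase (lumped)")
    add("HMGCR_A", {"hmg_A": -1, "nadph_A": -2, "mev_A": 1}, 0, ub_def,
        "HMGCR", "cholesterol", name="HMG-CoA reductase")
    add("MVK_A", {"mev_A": -3, "chol_A": 1}, 0, ub_def, "MVK",
        "cholesterol", name="mevalonate pathway to cholesterol (lumped)")
    add("CHOLT", {"chol_A": -1, "chol_N": 1}, 0, ub_def, "", "transport",
        name="astrocyte-to-neuron cholesterol shuttle")

    # --- biomass -----------------------------------------------------------
    add("BIOMASS_N",
        {m: -c for m, c in BIOMASS_COEFS.items()},
        0, ub_def, "", "biomass", atp=-int(BIOMASS_COEFS["atp_N"]),
        name="cerebellar biomass (neuron)", published_id="R25")

    return R, forced_uptakes


_PATHWAY_MEMBERS = {
    # reactions (and their private metabolites) dropped when a toggle is off
    "TCA": ["TCA_N"],
    "glutamine_GABA": ["EX_gln_N", "GLS_N", "GLUX_N", "EX_glu_C", "GAD_N",
                       "ABAT_N", "EX_succ_C"],
    "taurine": ["CBS_N", "CDO_N", "TAUX_N", "EX_tau_C"],
}


def _apply_toggles(spec: ToyModelSpec, reactions: List[Reaction],
                   forced: List[str]) -> Tuple[List[Reaction], List[str]]:
    disabled = {p for p, on in spec.pathways.items() if not on}
    bad = disabled & REQUIRED_PATHWAYS
    if bad:
        raise ValueError(
            f"cannot disable biomass-precursor pathway(s): {sorted(bad)}"
        )
    drop: set = set()
    for p in disabled & OPTIONAL_PATHWAYS:
        drop.update(_PATHWAY_MEMBERS[p])
    if "TCA" in disabled:
        # the ketone-utilization stubs and PDH are TCA-labelled but PDH feeds
        # lipogenesis; only the pure TCA lump goes
        pass
    reactions = [r for r in reactions if r.id not in drop]
    if "glutamine_GABA" in disabled and "glutamine" in forced:
        forced = [f for f in forced if f != "glutamine"]
    return reactions, forced


def _mk_model(spec: ToyModelSpec, variant: str) -> MetabolicModel:
    reactions, forced = _build_reactions(spec, variant)
    reactions, forced = _apply_toggles(spec, reactions, forced)
    if not spec.biomass_glucose_dependent:
        # growth no longer drains glucose-derived ribose-5-phosphate
        new = []
        for r in reactions:
            if r.id == "BIOMASS_N":
                st = {k: v for k, v in r.stoichiometry.items() if k != "r5p_N"}
                r = Reaction(id=r.id, name=r.name, stoichiometry=st,
                             lower_bound=r.lower_bound, upper_bound=r.upper_bound,
                             gpr=r.gpr, pathway=r.pathway, is_exchange=False,
                             atp_yield=r.atp_yield, published_id=r.published_id)
            new.append(r)
        reactions = new
        reactions = [r for r in reactions if r.id != "G6PD_N"]

    met_ids = sorted({m for r in reactions for m in r.stoichiometry})
    mets = [
        Metabolite(
            id=mid,
            name=mid,
            smiles=SMILES.get(mid.rsplit("_", 1)[0]),
        )
        for mid in met_ids
    ]
    genes = sorted({g for r in reactions for g in r.gpr.genes})
    model = MetabolicModel(
        metabolites=mets,
        reactions=reactions,
        genes=genes,
        biomass_id="BIOMASS_N",
        name=f"toy_cerebellum_{variant}",
        annotations={
            "variant": variant,
            "forced_uptakes": forced,
            "lactate_exchange": "EX_lac_C",
            "cofactor_stoplist": ["atp", "nadh", "nadph", "o2"],
        },
    )
    return model.validate()


def _design_arithmetic(spec: ToyModelSpec) -> Dict[str, float]:
    """Closed-form baseline predictions from the wiring (solver-independent)."""
    b = spec.uptake_bounds["leucine"] / BIOMASS_COEFS["leu_N"]  # leucine-limited growth
    glc_total = spec.uptake_bounds["glucose"]
    glc_N = spec.neuron_fraction * glc_total
    glc_A = spec.astrocyte_fraction * glc_total
    thr = spec.uptake_bounds["threonine"]

    r5p = BIOMASS_COEFS["r5p_N"] * b
    cl = BIOMASS_COEFS["cl_N"] * b
    sm = BIOMASS_COEFS["sm_N"] * b
    chol = BIOMASS_COEFS["chol_N"] * b
    fa = BIOMASS_COEFS["fa_N"] * b + 2 * cl + 2 * sm  # GPAM + SPT + CERS demand
    ser = sm
    g6p_branches = r5p + ser / 2 + cl  # G6PD + SER + GPD (2 g3p per g6p)
    gly_N = glc_N - g6p_branches
    pyr_N = 2 * gly_N + thr
    pdh_N = 4 * fa  # FAS(1) + ACC(3) acetyl-CoA per fatty acid
    lac_N = pyr_N - pdh_N
    pdh_A = 3 * chol
    pyr_A = 2 * glc_A
    lac_A = pyr_A - pdh_A
    lactate = lac_N + lac_A
    atp_glycolysis = 2 * (gly_N + glc_A)
    return {
        "biomass": b,
        "lactate_excretion": lactate,
        "lactate_glucose_ratio": lactate / glc_total,
        "glycolytic_atp": atp_glycolysis,
        "neuron_pdh": pdh_N,
    }


def generate_toy_models(
    spec: Optional[ToyModelSpec] = None,
) -> Tuple[MetabolicModel, MetabolicModel, Dict[str, object]]:
    """Build the (healthy, MB) model pair plus the design ground truth."""
    spec = spec or ToyModelSpec()
    healthy = _mk_model(spec, "healthy")
    mb = _mk_model(spec, "mb")

    predicted = _design_arithmetic(spec)
    if spec.biomass_glucose_dependent and (
        predicted["lactate_glucose_ratio"] < spec.lactate_glucose_ratio_target
    ):
        raise ValueError(
            "designed lactate:glucose ratio "
            f"{predicted['lactate_glucose_ratio']:.3f} below target "
            f"{spec.lactate_glucose_ratio_target}; adjust biomass coefficients"
        )
    if predicted["neuron_pdh"] > spec.mb_pdh_cap:
        raise ValueError("lipogenic acetyl-CoA demand exceeds the MB oxidation cap")

    gln_on = spec.pathways.get("glutamine_GABA", True)
    tca_on = spec.pathways.get("TCA", True)
    taurine_on = spec.pathways.get("taurine", True)

    essential = [
        "ACACA", "CDS1", "CERS1", "CRLS1", "FASN", "G6PD", "GPAM", "HMGCR",
        "HMGCS1", "KDSR", "LDHA", "MVK", "NDUFS1", "PDHA1", "PHGDH", "PKM",
        "SDS", "SGMS1", "SLC2A1", "SLC7A5", "SPTLC1",
    ]
    if gln_on:
        # SLC1A5 itself is not essential: deleting the transporter also lifts
        # the obligatory glutamine influx, while a GLS knockout leaves the
        # forced uptake with no consumer.
        essential += ["GLS"]
    if not spec.biomass_glucose_dependent:
        essential.remove("G6PD")
    # NDUFS1 is biomass-essential only: without a growth demand there is no
    # lipogenic redox surplus, so ATP/lactate maxima survive an OXPHOS loss.
    common3 = ["LDHA", "PKM", "SDS", "SLC2A1"]
    safe_common = ["SDS", "SLC2A1"]
    if gln_on:
        common3 += ["GLS"]
        safe_common += ["GLS"]
    # LDHA and PKM are common-essential in MB but intolerable for healthy
    # ATP/biomass capacity, so the safety filter removes them.
    hits = ["lac_A", "lac_N", "thr_N"]
    if gln_on:
        hits += ["gln_N", "glu_N"]

    # NNT_A is the sole astrocyte NADPH source and HMG-CoA reductase its only
    # sink, so its flux is stoichiometrically pinned to cholesterol demand.
    fully_coupled = [
        "CDS_N", "CHOLT", "CRLS_N", "EX_leu_N", "EX_trp_N", "EX_tyr_N",
        "G6PD_N", "GPAM_N", "GPD_N", "HMGCR_A", "HMGCS_A", "MVK_A", "NNT_A",
        "SGMS_N",
    ]
    if not spec.biomass_glucose_dependent:
        fully_coupled.remove("G6PD_N")

    prunable = ["BDH_N", "OXCT_N", "PYG_N"]

    ground_truth: Dict[str, object] = {
        "biomass_id": "BIOMASS_N",
        "predicted_baseline": predicted,
        "designed": {
            "lactate_glucose_ratio_target": spec.lactate_glucose_ratio_target,
            "biomass_glucose_dependent": spec.biomass_glucose_dependent,
            "forced_uptakes": list(mb.annotations["forced_uptakes"]),
            "neuron_glucose_uptake_bound": spec.neuron_fraction
            * spec.uptake_bounds["glucose"],
        },
        "essential_genes_biomass_mb": sorted(essential),
        "common_essential_genes_mb": sorted(common3),
        "common_essential_healthy_safe": sorted(safe_common),
        "synthetic_lethal_pairs": [["GPD1", "GPD2"], ["HK1", "HK2"]],
        "gimme_prunable_reactions": sorted(prunable),
        "antimetabolite_hits": sorted(hits),
        "fully_coupled_to_biomass": sorted(fully_coupled),
        "model_deltas": {
            "bounds": ["EX_glc_N", "EX_glc_A", "EX_gln_N", "EX_thr_N",
                       "PDH_N", "PDH_A"],
            "gpr": ["EX_glc_N", "EX_glc_A"],
        },
    }
    if not gln_on:
        ground_truth["model_deltas"]["bounds"].remove("EX_gln_N")
    if not tca_on or not taurine_on:
        pass  # toggles only drop uncoupled side branches; lists above unaffected
    return healthy, mb, ground_truth


# ---------------------------------------------------------------------------
# expression series
# ---------------------------------------------------------------------------

@dataclass
class ExpressionSpec:
    """Parameters of a two-condition series-matrix-like expression dataset."""

    genes: List[str]
    samples_per_condition: Dict[str, int] = field(
        default_factory=lambda: {"healthy": 10, "MB": 10}
    )
    case_condition: str = "MB"
    planted_up: Dict[str, float] = field(default_factory=dict)  # gene -> fold > 1
    planted_down: Dict[str, float] = field(default_factory=dict)  # gene -> fold < 1
    noise_sigma: float = 0.3  # lognormal replicate noise (log-scale sd)
    baseline_log_mean: float = math.log(100.0)
    baseline_log_sigma: float = 0.15
    seed: int = 0

    def validate(self) -> "ExpressionSpec":
        gene_set = set(self.genes)
        overlap = set(self.planted_up) & set(self.planted_down)
        if overlap:
            raise ValueError(f"planted up/down sets overlap: {sorted(overlap)}")
        for d in (self.planted_up, self.planted_down):
            unknown = set(d) - gene_set
            if unknown:
                raise ValueError(f"planted genes not in gene list: {sorted(unknown)}")
            for g, fold in d.items():
                if fold <= 0:
                    raise ValueError(f"fold change for {g} must be > 0")
        if self.case_condition not in self.samples_per_condition:
            raise ValueError("case_condition has no samples")
        return self


def mb_expression_spec(genes: List[str], seed: int = 0) -> ExpressionSpec:
    """Default MB-vs-healthy design: Warburg genes up, dead branches down."""
    genes = list(genes)
    extra = [f"filler_{i:03d}" for i in range(200)]
    up = {g: 4.0 for g in
          ("HK2", "PKM", "LDHA", "GLS", "SLC1A5", "FASN", "SLC2A1") if g in genes}
    down = {g: 0.2 for g in ("ABAT", "PYGB", "OXCT1", "BDH1") if g in genes}
    return ExpressionSpec(
        genes=genes + extra, planted_up=up, planted_down=down, seed=seed
    ).validate()


def generate_expression_series(
    spec: ExpressionSpec,
) -> Tuple[ExpressionMatrix, Dict[str, object]]:
    """Lognormal two-condition expression with planted fold changes.

    Per gene g: a baseline mean mu_g ~ LogNormal(baseline_log_mean,
    baseline_log_sigma); every replicate value is mu_g (times the planted
    fold in the case condition) times LogNormal(0, noise_sigma) noise.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes = list(spec.genes)
    mu = np.exp(rng.normal(spec.baseline_log_mean, spec.baseline_log_sigma, len(genes)))
    folds = np.ones(len(genes))
    for i, g in enumerate(genes):
        if g in spec.planted_up:
            folds[i] = spec.planted_up[g]
        elif g in spec.planted_down:
            folds[i] = spec.planted_down[g]

    columns, condition_of = [], {}
    data = []
    for cond in sorted(spec.samples_per_condition):
        n = spec.samples_per_condition[cond]
        cond_mu = mu * folds if cond == spec.case_condition else mu
        noise = np.exp(rng.normal(0.0, spec.noise_sigma, size=(len(genes), n)))
        block = cond_mu[:, None] * noise
        for k in range(n):
            name = f"{cond}_{k + 1:02d}"
            columns.append(name)
            condition_of[name] = cond
        data.append(block)
    values = pd.DataFrame(np.hstack(data), index=genes, columns=columns)
    expr = ExpressionMatrix(values=values, condition_of=condition_of)

    ground_truth = {
        "case_condition": spec.case_condition,
        "planted_up": dict(spec.planted_up),
        "planted_down": dict(spec.planted_down),
        "planted_absent": sorted(spec.planted_down),
        "seed": spec.seed,
    }
    return expr, ground_truth


def generate_compound_table(path=None) -> pd.DataFrame:
    """Fixture compound table (id, name, smiles) for the antimetabolite screen."""
    df = pd.DataFrame(_ANALOG_COMPOUNDS, columns=["id", "name", "smiles"])
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
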