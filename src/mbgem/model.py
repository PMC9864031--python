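"""Metabolic-model data structures, validation, stoichiometry and I/O.

The model is a classic genome-scale metabolic network: metabolites,
reactions with flux bounds (mmol/gDW/h) and boolean gene rules, and a
biomass pseudo-reaction that drains growth precursors. Metabolite ids
follow the two-cell cerebellum naming convention: a trailing ``N``, ``A``
or ``C`` tag marks species internal to neurons, astrocytes, or accumulated
in the shared cerebellar (extracellular) space.

Two serialization formats are supported:

* a flat JSON dialect (canonical key order, human-diffable), and
* SBML Level 3 with the FBC package (bounds + gene products).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import scipy.sparse as sp

from .gpr import GPRExpression, parse_gpr

logger = logging.getLogger(__name__)

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ModelValidationError",
    "ModelFormatError",
    "load_model",
    "save_model",
    "build_stoichiometric_matrix",
    "evaluate_gpr",
]

CELL_TAGS = ("N", "A", "C")


class ModelValidationError(ValueError):
    """A structural invariant of the model is violated."""


class ModelFormatError(ValueError):
    """A model file cannot be parsed in the requested format."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    formula: Optional[str] = None
    smiles: Optional[str] = None

    @property
    def cell_tag(self) -> Optional[str]:
        """Trailing cell tag: N (neuron), A (astrocyte), C (cerebellum)."""
        if "_" in self.id:
            tag = self.id.rsplit("_", 1)[1]
            if tag in CELL_TAGS:
                return tag
        return None

    @property
    def base_id(self) -> str:
        """Metabolite id with the cell tag stripped (``glc_N`` -> ``glc``)."""
        if self.cell_tag is not None:
            return self.id.rsplit("_", 1)[0]
        return self.id


@dataclass(frozen=True)
class Reaction:
    id: str
    name: str = ""
    stoichiometry: Dict[str, float] = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    gpr: GPRExpression = field(default_factory=GPRExpression)
    pathway: str = ""
    is_exchange: bool = False
    atp_yield: int = 0
    published_id: Optional[str] = None

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    def with_bounds(self, lb: float, ub: float) -> "Reaction":
        return replace(self, lower_bound=lb, upper_bound=ub)


@dataclass
class MetabolicModel:
    metabolites: List[Metabolite]
    reactions: List[Reaction]
    genes: List[str]
    biomass_id: str
    name: str = "model"
    annotations: Dict[str, object] = field(default_factory=dict)

    # ---- indexing helpers -------------------------------------------------

    @property
    def metabolite_index(self) -> Dict[str, int]:
        return {m.id: i for i, m in enumerate(self.metabolites)}

    @property
    def reaction_index(self) -> Dict[str, int]:
        return {r.id: i for i, r in enumerate(self.reactions)}

    def reaction(self, rid: str) -> Reaction:
        try:
            return self.reactions[self.reaction_index[rid]]
        except KeyError:
            raise KeyError(f"no reaction {rid!r} in model {self.name!r}") from None

    def metabolite(self, mid: str) -> Metabolite:
        return self.metabolites[self.metabolite_index[mid]]

    @property
    def pathway_index(self) -> Dict[str, List[str]]:
        out: Dict[str, List[str]] = {}
        for r in self.reactions:
            out.setdefault(r.pathway, []).append(r.id)
        return out

    @property
    def lower_bounds(self) -> np.ndarray:
        return np.array([r.lower_bound for r in self.reactions], dtype=float)

    @property
    def upper_bounds(self) -> np.ndarray:
        return np.array([r.upper_bound for r in self.reactions], dtype=float)

    def consumers_of(self, met_id: str) -> List[str]:
        """Reactions with a negative stoichiometric coefficient for ``met_id``."""
        return [
            r.id for r in self.reactions if r.stoichiometry.get(met_id, 0.0) < 0
        ]

    # ---- editing ----------------------------------------------------------

    def with_bounds(self, overrides: Dict[str, Tuple[float, float]]) -> "MetabolicModel":
        """Copy of the model with per-reaction (lb, ub) overrides applied."""
        new_rxns = []
        unknown = set(overrides) - set(self.reaction_index)
        if unknown:
            raise KeyError(f"bounds override for unknown reactions: {sorted(unknown)}")
        for r in self.reactions:
            if r.id in overrides:
                lb, ub = overrides[r.id]
                new_rxns.append(r.with_bounds(lb, ub))
            else:
                new_rxns.append(r)
        return replace_model(self, reactions=new_rxns)

    def knockout_bounds(self, genes: Iterable[str]) -> Dict[str, Tuple[float, float]]:
        """Bounds overrides closing every reaction whose GPR goes inactive."""
        ko = set(genes)
        unknown = ko - set(self.genes)
        if unknown:
            logger.warning("unknown gene(s) in knockout set ignored: %s", sorted(unknown))
        out = {}
        for r in self.reactions:
            if not r.gpr.is_empty and not r.gpr.evaluate(ko):
                out[r.id] = (0.0, 0.0)
        return out

    # ---- validation -------------------------------------------------------

    def validate(self) -> "MetabolicModel":
        seen: Set[str] = set()
        for m in self.metabolites:
            if not m.id:
                raise ModelValidationError("metabolite with empty id")
            if m.id in seen:
                raise ModelValidationError(f"duplicate metabolite id {m.id!r}")
            seen.add(m.id)
        rseen: Set[str] = set()
        used_mets: Set[str] = set()
        used_genes: Set[str] = set()
        declared = set(self.genes)
        for r in self.reactions:
            if r.id in rseen:
                raise ModelValidationError(f"duplicate reaction id {r.id!r}")
            rseen.add(r.id)
            if r.lower_bound > r.upper_bound:
                raise ModelValidationError(
                    f"reaction {r.id!r}: lower_bound {r.lower_bound} > "
                    f"upper_bound {r.upper_bound}"
                )
            if not r.stoichiometry and not r.is_exchange:
                raise ModelValidationError(f"reaction {r.id!r} has empty stoichiometry")
            if r.is_exchange and len(r.stoichiometry) != 1:
                raise ModelValidationError(
                    f"exchange reaction {r.id!r} must touch exactly one metabolite"
                )
            missing = set(r.stoichiometry) - seen
            if missing:
                raise ModelValidationError(
                    f"reaction {r.id!r} references undeclared metabolites {sorted(missing)}"
                )
            used_mets.update(r.stoichiometry)
            undeclared = r.gpr.genes - declared
            if undeclared:
                raise ModelValidationError(
                    f"reaction {r.id!r} GPR uses undeclared genes {sorted(undeclared)}"
                )
            used_genes.update(r.gpr.genes)
            atp_coefs = [
                c for mid, c in r.stoichiometry.items()
                if mid.rsplit("_", 1)[0] == "atp"
            ]
            if atp_coefs:
                total = sum(atp_coefs)
                if abs(total - r.atp_yield) > 1e-9:
                    raise ModelValidationError(
                        f"reaction {r.id!r}: atp_yield {r.atp_yield} does not match "
                        f"ATP stoichiometric coefficient {total}"
                    )
        if self.biomass_id not in rseen:
            raise ModelValidationError(f"biomass reaction {self.biomass_id!r} missing")
        orphan_mets = seen - used_mets
        if orphan_mets:
            raise ModelValidationError(
                f"metabolites not used by any reaction: {sorted(orphan_mets)}"
            )
        orphan_genes = declared - used_genes
        if orphan_genes:
            raise ModelValidationError(
                f"declared genes absent from every GPR: {sorted(orphan_genes)}"
            )
        return self


def replace_model(model: MetabolicModel, **kwargs) -> MetabolicModel:
    """Shallow functional update of a MetabolicModel."""
    data = dict(
        metabolites=model.metabolites,
        reactions=model.reactions,
        genes=model.genes,
        biomass_id=model.biomass_id,
        name=model.name,
        annotations=dict(model.annotations),
    )
    data.update(kwargs)
    return MetabolicModel(**data)


def evaluate_gpr(gpr: GPRExpression, knocked_out: Iterable[str]) -> bool:
    """Is a reaction with this rule still active under the knockout set?"""
    return gpr.evaluate(knocked_out)


def build_stoichiometric_matrix(model: MetabolicModel) -> sp.csr_matrix:
    """Sparse S (metabolites x reactions); S[i, j] = coefficient of met i in rxn j."""
    midx = model.metabolite_index
    rows, cols, vals = [], [], []
    for j, r in enumerate(model.reactions):
        for mid, coef in r.stoichiometry.items():
            rows.append(midx[mid])
            cols.append(j)
            vals.append(float(coef))
    return sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(model.metabolites), len(model.reactions))
    )


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def model_to_dict(model: MetabolicModel) -> dict:
    mets = []
    for m in model.metabolites:
        d: Dict[str, object] = {"id": m.id, "name": m.name}
        if m.formula is not None:
            d["formula"] = m.formula
        if m.smiles is not None:
            d["smiles"] = m.smiles
        mets.append(d)
    rxns = []
    for r in model.reactions:
        d = {
            "id": r.id,
            "name": r.name,
            "stoichiometry": {k: float(v) for k, v in r.stoichiometry.items()},
            "lower_bound": float(r.lower_bound),
            "upper_bound": float(r.upper_bound),
            "gpr": r.gpr.to_string(),
            "pathway": r.pathway,
            "is_exchange": r.is_exchange,
            "atp_yield": int(r.atp_yield),
        }
        if r.published_id is not None:
            d["published_id"] = r.published_id
        rxns.append(d)
    return {
        "name": model.name,
        "metabolites": mets,
        "reactions": rxns,
        "genes": list(model.genes),
        "biomass_id": model.biomass_id,
        "annotations": model.annotations,
    }


def model_from_dict(data: dict) -> MetabolicModel:
    try:
        mets = [
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                formula=m.get("formula"),
                smiles=m.get("smiles"),
            )
            for m in data["metabolites"]
        ]
        rxns = [
            Reaction(
                id=r["id"],
                name=r.get("name", ""),
                stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                lower_bound=float(r["lower_bound"]),
                upper_bound=float(r["upper_bound"]),
                gpr=parse_gpr(r.get("gpr", "")),
                pathway=r.get("pathway", ""),
                is_exchange=bool(r.get("is_exchange", False)),
                atp_yield=int(r.get("atp_yield", 0)),
                published_id=r.get("published_id"),
            )
            for r in data["reactions"]
        ]
        model = MetabolicModel(
            metabolites=mets,
            reactions=rxns,
            genes=list(data["genes"]),
            biomass_id=data["biomass_id"],
            name=data.get("name", "model"),
            annotations=dict(data.get("annotations", {})),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelFormatError(f"malformed model JSON: {exc}") from exc
    return model.validate()


def dumps_model(model: MetabolicModel) -> str:
    """Canonical JSON text (sorted keys, fixed indent) for byte-stable round trips."""
    return json.dumps(model_to_dict(model), sort_keys=True, indent=1) + "\n"


# ---------------------------------------------------------------------------
# SBML Level 3 + FBC
# ---------------------------------------------------------------------------

def _notes_dict(notes_str: Optional[str]) -> Dict[str, str]:
    out: Dict[str, str] = {}
    if not notes_str:
        return out
    import re
    from xml.sax.saxutils import unescape

    for m in re.finditer(r"<p>\s*([^:<]+):\s*([^<]*)</p>", notes_str):
        value = unescape(m.group(2).strip(), {"&quot;": '"', "&apos;": "'"})
        out[m.group(1).strip()] = value
    return out


def _notes_xml(pairs: Dict[str, str]) -> str:
    body = "".join(f"<p>{k}: {v}</p>" for k, v in pairs.items())
    return f'<body xmlns="http://www.w3.org/1999/xhtml">{body}</body>'


def _sbml_id(raw: str) -> str:
    # SBML SIds must match [a-zA-Z_][a-zA-Z0-9_]*
    out = "".join(c if c.isalnum() or c == "_" else "_" for c in raw)
    if not out or not (out[0].isalpha() or out[0] == "_"):
        out = "x_" + out
    return out


def _write_sbml(model: MetabolicModel, path: Path) -> None:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(_sbml_id(model.name))
    sbml_model.setName(model.name)
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(False)

    comp = sbml_model.createCompartment()
    comp.setId("c")
    comp.setConstant(True)

    for m in model.metabolites:
        sp_ = sbml_model.createSpecies()
        sp_.setId("M_" + _sbml_id(m.id))
        sp_.setName(m.name or m.id)
        sp_.setCompartment("c")
        sp_.setConstant(False)
        sp_.setBoundaryCondition(False)
        sp_.setHasOnlySubstanceUnits(False)
        notes = {"raw_id": m.id}
        if m.formula:
            notes["formula"] = m.formula
        if m.smiles:
            notes["smiles"] = m.smiles
        sp_.setNotes(_notes_xml(notes))

    for g in model.genes:
        gp = mplug.createGeneProduct()
        gp.setId("G_" + _sbml_id(g))
        gp.setLabel(g)

    for i, r in enumerate(model.reactions):
        for tag, val in (("lb", r.lower_bound), ("ub", r.upper_bound)):
            par = sbml_model.createParameter()
            par.setId(f"bnd_{i}_{tag}")
            par.setValue(float(val))
            par.setConstant(True)
        rxn = sbml_model.createReaction()
        rxn.setId("R_" + _sbml_id(r.id))
        rxn.setName(r.name or r.id)
        rxn.setFast(False)
        rxn.setReversible(r.lower_bound < 0)
        rplug = rxn.getPlugin("fbc")
        rplug.setLowerFluxBound(f"bnd_{i}_lb")
        rplug.setUpperFluxBound(f"bnd_{i}_ub")
        for mid, coef in sorted(r.stoichiometry.items()):
            if coef < 0:
                ref = rxn.createReactant()
                ref.setStoichiometry(-float(coef))
            else:
                ref = rxn.createProduct()
                ref.setStoichiometry(float(coef))
            ref.setSpecies("M_" + _sbml_id(mid))
            ref.setConstant(True)
        if not r.gpr.is_empty:
            assoc = rplug.createGeneProductAssociation()
            infix = r.gpr.to_string()
            for g in sorted(r.gpr.genes, key=len, reverse=True):
                infix = infix.replace(g, "G_" + _sbml_id(g))
            # resolve by gene-product id; never auto-create munged products
            assoc.setAssociation(infix, True, False)
        notes = {
            "raw_id": r.id,
            "pathway": r.pathway,
            "atp_yield": str(r.atp_yield),
            "is_exchange": str(r.is_exchange),
        }
        if r.published_id:
            notes["published_id"] = r.published_id
        rxn.setNotes(_notes_xml(notes))

    if model.biomass_id in model.reaction_index:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        mplug.setActiveObjectiveId("obj")
        fo = obj.createFluxObjective()
        fo.setReaction("R_" + _sbml_id(model.biomass_id))
        fo.setCoefficient(1.0)

    if model.annotations:
        sbml_model.setNotes(
            _notes_xml({"annotations_json": json.dumps(model.annotations, sort_keys=True)})
        )
    libsbml.writeSBMLToFile(doc, str(path))


def _gpa_to_infix(assoc) -> str:
    import libsbml

    if assoc is None:
        return ""
    if isinstance(assoc, libsbml.GeneProductRef):
        return assoc.getGeneProduct()
    if isinstance(assoc, libsbml.FbcAnd):
        parts = [_gpa_to_infix(assoc.getAssociation(i)) for i in range(assoc.getNumAssociations())]
        return "(" + " and ".join(parts) + ")"
    if isinstance(assoc, libsbml.FbcOr):
        parts = [_gpa_to_infix(assoc.getAssociation(i)) for i in range(assoc.getNumAssociations())]
        return "(" + " or ".join(parts) + ")"
    raise ModelFormatError(f"unsupported gene association node {assoc!r}")


def _read_sbml(path: Path) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelFormatError(
            f"SBML parse failure at line {err.getLine()}: {err.getMessage()}"
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelFormatError("SBML file contains no model element")
    mplug = sbml_model.getPlugin("fbc")

    gene_label: Dict[str, str] = {}
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            gene_label[gp.getId()] = gp.getLabel() or gp.getId()

    mets: List[Metabolite] = []
    species_raw: Dict[str, str] = {}
    for i in range(sbml_model.getNumSpecies()):
        s = sbml_model.getSpecies(i)
        notes = _notes_dict(s.getNotesString())
        raw = notes.get("raw_id") or (s.getId()[2:] if s.getId().startswith("M_") else s.getId())
        species_raw[s.getId()] = raw
        mets.append(
            Metabolite(
                id=raw,
                name=s.getName() or raw,
                formula=notes.get("formula"),
                smiles=notes.get("smiles"),
            )
        )

    params = {
        sbml_model.getParameter(i).getId(): sbml_model.getParameter(i).getValue()
        for i in range(sbml_model.getNumParameters())
    }

    rxns: List[Reaction] = []
    for i in range(sbml_model.getNumReactions()):
        rx = sbml_model.getReaction(i)
        if rx.isSetKineticLaw():
            logger.warning("ignoring kinetic law on SBML reaction %s", rx.getId())
        notes = _notes_dict(rx.getNotesString())
        raw = notes.get("raw_id") or (rx.getId()[2:] if rx.getId().startswith("R_") else rx.getId())
        stoich: Dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            stoich[species_raw[ref.getSpecies()]] = stoich.get(
                species_raw[ref.getSpecies()], 0.0
            ) - ref.getStoichiometry()
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            stoich[species_raw[ref.getSpecies()]] = stoich.get(
                species_raw[ref.getSpecies()], 0.0
            ) + ref.getStoichiometry()
        rplug = rx.getPlugin("fbc")
        lb, ub = -math.inf, math.inf
        if rplug is not None:
            lb = params.get(rplug.getLowerFluxBound(), lb)
            ub = params.get(rplug.getUpperFluxBound(), ub)
        gpr_str = ""
        if rplug is not None and rplug.isSetGeneProductAssociation():
            gpr_str = _gpa_to_infix(rplug.getGeneProductAssociation().getAssociation())
            for gid, label in sorted(gene_label.items(), key=lambda kv: -len(kv[0])):
                gpr_str = gpr_str.replace(gid, label)
        rxns.append(
            Reaction(
                id=raw,
                name=rx.getName() or raw,
                stoichiometry=stoich,
                lower_bound=float(lb),
                upper_bound=float(ub),
                gpr=parse_gpr(gpr_str),
                pathway=notes.get("pathway", ""),
                is_exchange=notes.get("is_exchange", str(len(stoich) == 1)) == "True",
                atp_yield=int(notes.get("atp_yield", "0")),
                published_id=notes.get("published_id"),
            )
        )

    biomass_id = None
    if mplug is not None and mplug.getNumObjectives() > 0:
        obj = mplug.getObjective(0)
        if obj.getNumFluxObjectives() > 0:
            rid = obj.getFluxObjective(0).getReaction()
            biomass_id = rid[2:] if rid.startswith("R_") else rid
    if biomass_id is None:
        raise ModelValidationError("SBML model declares no (biomass) flux objective")

    annotations: Dict[str, object] = {}
    mnotes = _notes_dict(sbml_model.getNotesString())
    if "annotations_json" in mnotes:
        annotations = json.loads(mnotes["annotations_json"])

    model = MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        genes=sorted(gene_label.values()),
        biomass_id=biomass_id,
        name=sbml_model.getName() or sbml_model.getId(),
        annotations=annotations,
    )
    return model.validate()


# ---------------------------------------------------------------------------
# public I/O
# ---------------------------------------------------------------------------

def _infer_format(path: Path, format: Optional[str]) -> str:
    if format is not None:
        return format
    if path.suffix.lower() in (".xml", ".sbml"):
        return "sbml"
    return "json"


def load_model(path, format: Optional[str] = None) -> MetabolicModel:
    """Load and validate a model from JSON or SBML (L3 FBC)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        try:
            data = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ModelFormatError(
                f"JSON parse failure in {path} at line {exc.lineno}: {exc.msg}"
            ) from exc
        return model_from_dict(data)
    if fmt == "sbml":
        return _read_sbml(path)
    raise ValueError(f"unknown model format {fmt!r}")


def save_model(model: MetabolicModel, path, format: Optional[str] = None) -> None:
    """Serialize a model; JSON output uses canonical key order."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        path.write_text(dumps_model(model))
    elif fmt == "sbml":
        _write_sbml(model, path)
    else:
        raise ValueError(f"unknown model format {fmt!r}")
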