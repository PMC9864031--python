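"""End-to-end workflow: integrate -> solve -> sample -> regulate -> couple ->
essentiality -> antimetabolite, from a single config.

Stages write TSV/JSON artifacts under the output directory plus a summary
of headline counts. Stage outputs are cached: each stage records a content
hash of its inputs in ``manifest.json`` and is skipped on re-runs when the
hash matches and its outputs exist (sampling is the slow stage). Identical
config + seed produces byte-identical summaries.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd

from . import antimetabolite as anti
from . import coupling as cpl
from . import essentiality as ess
from . import integration as integ
from . import regulation as reg
from . import sampling as smp
from . import synthetic as syn
from .model import MetabolicModel, dumps_model, load_model, save_model
from .solve import ScenarioConfig, energy_accounting, fba, scenario_run

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All knobs of the full workflow (cutoffs at their published defaults)."""

    outdir: str = "mbgem_out"
    seed: int = 0
    # inputs; None -> generate the packaged synthetic stand-ins
    healthy_model: Optional[str] = None
    mb_model: Optional[str] = None
    expression: Optional[str] = None
    compounds: Optional[str] = None
    healthy_condition: str = "healthy"
    case_condition: str = "MB"
    threshold: object = "GSE37418"  # preset name or fraction
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    # sampler
    n_samples: int = 10_000
    thinning: int = 100
    save_samples: bool = False
    # cutoffs
    growth_fraction: float = 0.9
    z_crit: float = reg.Z_CRITICAL
    essential_cutoff: float = ess.ESSENTIAL_CUTOFF
    safety_cutoff: float = ess.ESSENTIAL_CUTOFF
    tanimoto_cutoff: float = anti.TANIMOTO_CUTOFF
    inhibition_factor: float = anti.INHIBITION_FACTOR
    alpha: float = 0.05

    def validate(self) -> "PipelineConfig":
        checks = {
            "growth_fraction": (self.growth_fraction, 0.0, 1.0),
            "essential_cutoff": (self.essential_cutoff, 0.0, 1.0),
            "safety_cutoff": (self.safety_cutoff, 0.0, 1.0),
            "tanimoto_cutoff": (self.tanimoto_cutoff, 0.0, 1.0),
            "inhibition_factor": (self.inhibition_factor, 0.0, 1.0),
            "alpha": (self.alpha, 0.0, 1.0),
        }
        for name, (val, lo, hi) in checks.items():
            if not (lo < val <= hi):
                raise ValueError(f"{name} = {val} outside ({lo}, {hi}]")
        if self.z_crit <= 0:
            raise ValueError("z_crit must be positive")
        if self.n_samples < 1 or self.thinning < 1:
            raise ValueError("n_samples and thinning must be >= 1")
        for attr in ("healthy_model", "mb_model", "expression", "compounds"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{attr} file not found: {p}")
        threshold_fraction(self.threshold)  # raises on bad preset
        return self

    @property
    def threshold_fraction(self) -> float:
        return threshold_fraction(self.threshold)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        scenario = ScenarioConfig.from_dict(data.pop("scenario", None))
        return cls(scenario=scenario, **data).validate()


def threshold_fraction(threshold) -> float:
    if isinstance(threshold, str):
        try:
            return integ.THRESHOLD_PRESETS[threshold]
        except KeyError:
            raise ValueError(
                f"unknown threshold preset {threshold!r}; "
                f"known: {sorted(integ.THRESHOLD_PRESETS)}"
            ) from None
    frac = float(threshold)
    if frac <= 0:
        raise ValueError("threshold fraction must be positive")
    return frac


class _Manifest:
    def __init__(self, outdir: Path):
        self.path = outdir / "manifest.json"
        self.data: Dict[str, Dict[str, str]] = {}
        if self.path.exists():
            self.data = json.loads(self.path.read_text())

    def fresh(self, stage: str, input_hash: str, outputs: List[Path]) -> bool:
        entry = self.data.get(stage)
        return (
            entry is not None
            and entry.get("input_hash") == input_hash
            and entry.get("status") == "complete"
            and all(p.exists() for p in outputs)
        )

    def record(self, stage: str, input_hash: str, status: str) -> None:
        self.data[stage] = {"input_hash": input_hash, "status": status}
        self.path.write_text(json.dumps(self.data, sort_keys=True, indent=1))


def _hash(*parts: str) -> str:
    h = hashlib.sha256()
    for p in parts:
        h.update(p.encode())
        h.update(b"\x00")
    return h.hexdigest()[:16]


def _round(x, nd=9):
    if isinstance(x, dict):
        return {k: _round(v, nd) for k, v in sorted(x.items())}
    if isinstance(x, float):
        return round(x, nd)
    return x


def run_pipeline(config: PipelineConfig) -> Dict[str, object]:
    """Execute every stage; returns (and writes) the summary dict."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out)

    # ---- stage: inputs ----------------------------------------------------
    ground_truth: Optional[dict] = None
    if config.healthy_model and config.mb_model:
        healthy = load_model(config.healthy_model)
        mb = load_model(config.mb_model)
    else:
        healthy, mb, ground_truth = syn.generate_toy_models()
        save_model(healthy, out / "healthy_model.json")
        save_model(mb, out / "mb_model.json")
        (out / "model_ground_truth.json").write_text(
            json.dumps(_round(ground_truth), sort_keys=True, indent=1, default=list)
        )
    if config.expression:
        expr = integ.ExpressionMatrix.from_tsv(config.expression)
    else:
        spec = syn.mb_expression_spec(mb.genes, seed=config.seed + 2)
        expr, expr_truth = syn.generate_expression_series(spec)
        expr.to_tsv(out / "expression.tsv")
    compounds = (
        pd.read_csv(config.compounds, sep="\t")
        if config.compounds
        else syn.generate_compound_table()
    )
    model_hash = _hash(dumps_model(healthy), dumps_model(mb), str(config.seed))

    # ---- stage: integration ----------------------------------------------
    frac = config.threshold_fraction
    states = integ.binarize_expression(expr, config.case_condition, frac)
    states.to_frame().to_csv(out / "gene_states.tsv", sep="\t", index=False)
    h_int = _hash(model_hash, str(frac), json.dumps(states.states, sort_keys=True),
                  str(config.growth_fraction))
    reduced_path = out / "mb_model_reduced.json"
    removed_path = out / "gimme_removed.txt"
    if manifest.fresh("integration", h_int, [reduced_path, removed_path]):
        mb_red = load_model(reduced_path)
        removed = removed_path.read_text().split()
        inconsistency = json.loads((out / "gimme_score.json").read_text())["inconsistency"]
    else:
        mb_red, inconsistency, removed = integ.gimme_reduce(
            mb, states, config.growth_fraction
        )
        save_model(mb_red, reduced_path)
        removed_path.write_text("\n".join(removed) + ("\n" if removed else ""))
        (out / "gimme_score.json").write_text(
            json.dumps({"inconsistency": round(inconsistency, 9)})
        )
        manifest.record("integration", h_int, "complete")

    # ---- stage: scenarios -------------------------------------------------
    scenarios = {}
    for name, model, label in (("mb", mb_red, "MB"), ("healthy", healthy, "healthy")):
        reference = fba(model, None, "max", config.scenario)
        block = {}
        for scen in ("baseline", "no_glucose", "no_glutamine", "no_both"):
            r = scenario_run(model, config.scenario, scen, reference=reference)
            block[scen] = {
                "biomass": r.biomass,
                "atp_total": r.accounting.atp_total,
                "atpg_over_atpop": r.accounting.atpg_over_atpop,
                "lacr_over_ocr": r.accounting.lacr_over_ocr,
            }
        scenarios[name] = block
    (out / "scenarios.json").write_text(
        json.dumps(_round(scenarios), sort_keys=True, indent=1, default=str)
    )

    # ---- stage: sampling --------------------------------------------------
    h_smp = _hash(model_hash, str(config.n_samples), str(config.thinning))
    diff_path = out / "differential_flux.tsv"
    sample_mb = smp.achr_sample(
        mb_red, config.scenario, config.n_samples, config.seed, config.thinning
    )
    sample_h = smp.achr_sample(
        healthy, config.scenario, config.n_samples, config.seed + 1, config.thinning
    )
    if config.save_samples:
        sample_mb.save(out / "samples_mb.tsv")
        sample_h.save(out / "samples_healthy.tsv")
    diff = smp.differential_flux_test(sample_h, sample_mb, config.alpha)
    smp.records_to_frame(diff).to_csv(diff_path, sep="\t")
    manifest.record("sampling", h_smp, "complete")

    # ---- stage: regulation ------------------------------------------------
    zrecords = reg.compute_z_scores(
        sample_h, sample_mb, expr, config.healthy_condition,
        config.case_condition, mb_red,
    )
    zrecords = reg.classify_regulation(zrecords, config.z_crit)
    reg.records_to_frame(zrecords, mb_red).to_csv(out / "regulation.tsv", sep="\t")
    reg.per_pathway_counts(zrecords, mb_red).to_csv(
        out / "regulation_by_pathway.tsv", sep="\t"
    )

    # ---- stage: coupling --------------------------------------------------
    coupled = cpl.biomass_coupled_set(mb_red)
    rows = [
        {"reaction": r.pair[0], "class": klass,
         "ratio_min": r.ratio_min, "ratio_max": r.ratio_max}
        for klass, recs in sorted(coupled.items()) for r in recs
    ]
    pd.DataFrame(rows).to_csv(out / "biomass_coupling.tsv", sep="\t", index=False)

    # ---- stage: essentiality ----------------------------------------------
    singles: Dict[str, List[ess.DeletionResult]] = {}
    for objective in ess.OBJECTIVES:
        singles[objective] = ess.single_deletion(
            mb_red, None, objective, config.scenario,
            cutoff=config.essential_cutoff,
        )
    single_frame = pd.DataFrame(
        [
            {"gene": r.target, "objective": r.objective,
             "reduction": r.reduction_fraction, "essential": r.essential}
            for obj in ess.OBJECTIVES for r in singles[obj]
        ]
    )
    single_frame.to_csv(out / "single_deletions.tsv", sep="\t", index=False)
    pairs = ess.double_deletion_synthetic_lethals(
        mb_red, None, "biomass", config.scenario, cutoff=config.essential_cutoff
    )
    lethal_pairs = [r for r in pairs if r.essential]
    pd.DataFrame(
        [
            {"gene_1": r.target[0], "gene_2": r.target[1],
             "reduction": r.reduction_fraction, "synthetic_lethal": r.essential}
            for r in pairs
        ]
    ).to_csv(out / "double_deletions.tsv", sep="\t", index=False)
    common = ess.common_essential_screen(
        mb_red, healthy, config.scenario,
        cutoff=config.essential_cutoff, safety_cutoff=config.safety_cutoff,
    )
    pd.DataFrame(
        [
            {"gene": r.gene, "healthy_biomass_reduction": r.healthy_biomass_reduction,
             "healthy_atp_reduction": r.healthy_atp_reduction,
             "healthy_safe": r.healthy_safe}
            for r in common
        ]
    ).to_csv(out / "common_essential.tsv", sep="\t", index=False)

    # ---- stage: antimetabolite ---------------------------------------------
    hits = anti.competitive_inhibition_screen(
        mb_red, healthy, compounds, config.scenario,
        tanimoto_cutoff=config.tanimoto_cutoff,
        inhibition_factor=config.inhibition_factor,
        growth_cutoff=config.essential_cutoff,
        safety_cutoff=config.safety_cutoff,
    )
    anti.hits_to_frame(hits).to_csv(out / "antimetabolites.tsv", sep="\t")

    # ---- summary ----------------------------------------------------------
    essential_biomass = sorted(
        r.target for r in singles["biomass"] if r.essential
    )
    summary = {
        "seed": config.seed,
        "gimme": {"removed": removed, "n_removed": len(removed),
                  "inconsistency": round(float(inconsistency), 9)},
        "scenarios": _round(scenarios),
        "sampling": {
            "n_samples": config.n_samples,
            "n_shared_reactions": len(diff),
            "n_significant": int(sum(r.significant for r in diff)),
        },
        "regulation": {
            "n_tr": int(sum(r.klass == "TR" for r in zrecords)),
            "n_ntr": int(sum(r.klass == "NTR" for r in zrecords)),
        },
        "coupling": {
            klass: len(recs) for klass, recs in sorted(coupled.items())
        },
        "essentiality": {
            "essential_genes_biomass": essential_biomass,
            "n_essential_biomass": len(essential_biomass),
            "synthetic_lethal_pairs": sorted(
                [list(r.target) for r in lethal_pairs]
            ),
            "common_essential": sorted(r.gene for r in common),
            "common_essential_healthy_safe": sorted(
                r.gene for r in common if r.healthy_safe
            ),
        },
        "antimetabolites": {
            "n_screened": len(hits),
            "hits": sorted(r.metabolite_id for r in hits if r.hit),
        },
    }
    (out / "summary.json").write_text(
        json.dumps(_round(summary), sort_keys=True, indent=1) + "\n"
    )
    manifest.record("summary", model_hash, "complete")
    return summary
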