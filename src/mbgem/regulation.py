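"""Transcriptional-regulation classification of reactions (ZF/ZG scores).

Flux change between two conditions is summarized per reaction as a
standardized score ZF computed from sampled flux distributions; expression
change is summarized per gene as a Welch-type standardized difference ZG,
and summed over the genes of the reaction's GPR to give ZG_total. Reactions
with |ZF| above the critical value are transcriptionally regulated (TR)
when |ZG_total| also exceeds it, and not transcriptionally regulated (NTR)
otherwise. The critical value defaults to the two-sided 5% standard-normal
quantile, 1.96.

Sign concordance between ZF and ZG is recorded for reporting but is not
required for the TR call: a reaction can carry more flux while its genes
are unchanged (e.g. substrate-driven lactate dehydrogenase activation).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .integration import ExpressionMatrix
from .model import MetabolicModel
from .sampling import SamplingResult

logger = logging.getLogger(__name__)

__all__ = [
    "RegulationRecord",
    "compute_z_scores",
    "classify_regulation",
    "per_pathway_counts",
    "Z_CRITICAL",
]

Z_CRITICAL = 1.96  # two-sided 5% standard-normal quantile, rounded


@dataclass
class RegulationRecord:
    reaction_id: str
    zf: float
    zg_total: float
    genes: List[str]
    klass: str = "none"  # TR | NTR | none
    sign_concordant: Optional[bool] = None


def gene_z_scores(
    expr: ExpressionMatrix,
    cond_a: str,
    cond_b: str,
    log2: bool = False,
) -> pd.Series:
    """Per-gene Welch-type standardized difference of expression (b vs a)."""
    xa = expr.condition_values(cond_a).to_numpy(dtype=float)
    xb = expr.condition_values(cond_b).to_numpy(dtype=float)
    if log2:
        xa = np.log2(xa + 1.0)
        xb = np.log2(xb + 1.0)
    na, nb = xa.shape[1], xb.shape[1]
    ma, mb = xa.mean(axis=1), xb.mean(axis=1)
    va = xa.var(axis=1, ddof=1) if na > 1 else np.zeros(len(ma))
    vb = xb.var(axis=1, ddof=1) if nb > 1 else np.zeros(len(mb))
    se = np.sqrt(va / max(na, 1) + vb / max(nb, 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, (mb - ma) / se, 0.0)
    return pd.Series(z, index=expr.genes)


def compute_z_scores(
    flux_a: SamplingResult,
    flux_b: SamplingResult,
    expr: ExpressionMatrix,
    cond_a: str,
    cond_b: str,
    model: MetabolicModel,
    log2: bool = False,
    gene_aggregation: str = "sum",
) -> List[RegulationRecord]:
    """ZF and summed ZG per reaction shared by the two sampling results.

    ZF = (mean_b - mean_a) / sqrt(var_a + var_b) over sampled fluxes (zero
    pooled variance gives ZF = 0). ZG_total sums the per-gene scores of the
    reaction's GPR genes (``gene_aggregation="mean"`` averages instead);
    genes absent from the expression matrix contribute 0 and are logged.
    """
    if gene_aggregation not in ("sum", "mean"):
        raise ValueError("gene_aggregation must be 'sum' or 'mean'")
    shared = sorted(set(flux_a.reaction_ids) & set(flux_b.reaction_ids))
    mean_a, var_a = flux_a.mean(), flux_a.var()
    mean_b, var_b = flux_b.mean(), flux_b.var()
    zg = gene_z_scores(expr, cond_a, cond_b, log2=log2)

    missing_total = set()
    records: List[RegulationRecord] = []
    ridx = model.reaction_index
    for rid in shared:
        pooled = var_a[rid] + var_b[rid]
        zf = float((mean_b[rid] - mean_a[rid]) / math.sqrt(pooled)) if pooled > 0 else 0.0
        genes = sorted(model.reactions[ridx[rid]].gpr.genes) if rid in ridx else []
        vals = []
        for g in genes:
            if g in zg.index:
                vals.append(float(zg[g]))
            else:
                missing_total.add(g)
                vals.append(0.0)
        if not vals:
            zg_total = 0.0
        elif gene_aggregation == "sum":
            zg_total = float(np.sum(vals))
        else:
            zg_total = float(np.mean(vals))
        records.append(RegulationRecord(rid, zf, zg_total, genes))
    if missing_total:
        logger.info(
            "%d GPR genes missing from expression contributed ZG = 0", len(missing_total)
        )
    return records


def classify_regulation(
    records: Sequence[RegulationRecord],
    z_crit: float = Z_CRITICAL,
) -> List[RegulationRecord]:
    """Assign TR / NTR / none per record at the |z| > z_crit criterion."""
    if z_crit <= 0:
        raise ValueError("z_crit must be positive")
    out = []
    for r in records:
        if abs(r.zf) > z_crit:
            klass = "TR" if abs(r.zg_total) > z_crit else "NTR"
        else:
            klass = "none"
        concordant = None
        if r.zf != 0 and r.zg_total != 0:
            concordant = (r.zf > 0) == (r.zg_total > 0)
        out.append(
            RegulationRecord(
                r.reaction_id, r.zf, r.zg_total, r.genes, klass, concordant
            )
        )
    return out


def per_pathway_counts(
    records: Sequence[RegulationRecord], model: MetabolicModel
) -> pd.DataFrame:
    """TR/NTR counts per pathway (the Fig-4-style summary table)."""
    ridx = model.reaction_index
    rows: Dict[str, Dict[str, int]] = {}
    for r in records:
        pw = model.reactions[ridx[r.reaction_id]].pathway if r.reaction_id in ridx else ""
        d = rows.setdefault(pw, {"TR": 0, "NTR": 0, "none": 0})
        d[r.klass] += 1
    return (
        pd.DataFrame.from_dict(rows, orient="index")
        .rename_axis("pathway")
        .sort_index()
    )


def records_to_frame(
    records: Sequence[RegulationRecord], model: Optional[MetabolicModel] = None
) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "reaction": r.reaction_id,
                "ZF": r.zf,
                "ZG_total": r.zg_total,
                "class": r.klass,
                "sign_concordant": r.sign_concordant,
            }
            for r in records
        ]
    ).set_index("reaction")
    if model is not None:
        ridx = model.reaction_index
        df.insert(
            0,
            "pathway",
            [
                model.reactions[ridx[r]].pathway if r in ridx else ""
                for r in df.index
            ],
        )
    return df
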