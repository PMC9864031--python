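# Methods

## Model representation

A metabolic model is a list of metabolites, a list of reactions with flux
bounds (mmol/gDW/h) and GPR boolean rules, a declared gene list, and a
biomass pseudo-reaction. Reversibility is encoded purely by a negative
lower bound; exchanges touch exactly one metabolite, with uptake as
negative flux. Each reaction carries an integer `atp_yield` equal to the
stoichiometric coefficient of its ATP species (validated), which is the
basis of all energy accounting: the model does not enumerate which
reactions count toward "whole energy generation", so ATP production is
defined as Σ max(0, atp_yield · v) per pathway label.

The two-cell cerebellum convention tags metabolite ids with `N` (neuron),
`A` (astrocyte) or `C` (shared cerebellar space). A scenario configuration
maps nutrient names to uptake magnitudes; a magnitude *b* for a nutrient
with both cell-side exchanges is split 0.97·b / 0.03·b following the
neuron/astrocyte distribution of the cerebellum, and a nutrient with a
single-cell transporter receives the full bound (logged). Nutrients listed
in the model annotation `forced_uptakes` are pinned (lb = ub = −b): this is
how the tumor variant encodes obligatory glucose/glutamine consumption.
The defaults are glucose 0.852, glutamine 0.080, oxygen 0.142, leucine
0.034 (= glucose/25), tryptophan 0.0074, tyrosine 0.0028, methionine
0.008, glycogen 0 and ketone bodies 0 mmol/gDW/h. Threonine, which the
deprivation analyses use as the fallback carbon source, has no published
bound; the package fixes its uptake capacity at 0.06 mmol/gDW/h, the order
of magnitude the deprivation response requires, and treats it as part of
the scenario table.

## Solvers and determinism

LPs (FBA, FVA, warmup, coupling, GIMME) are solved with HiGHS via
`scipy.optimize.linprog`. Quadratic programs (MOMA, minimum-norm
reporting) use OSQP with absolute/relative tolerance 1e-8, primal/dual
infeasibility tolerance 1e-9, and solution polishing; both tolerances are
configurable through `SolverOptions`.

FBA optima are generally degenerate, so every reported flux map is the
**minimum-Euclidean-norm point of the optimal face** (a second, strictly
convex QP). This makes flux reports unique and deterministic, resolves
parallel-route ties by spreading flux (the quadratic analogue of a
resistor network), and provides a canonical reference for MOMA. Knockout
and deprivation outcomes are then evaluated with MOMA against that
reference, matching the FBA + MOMA pairing of the overall workflow; a raw
FBA mode exists for comparison. A knockout that leaves the reference
feasible returns it exactly (reduction 0); a knockout that makes the model
infeasible — possible when obligatory uptakes can no longer be digested —
counts as complete loss (reduction 1).

One consequence of the obligatory-uptake encoding is worth stating: a
transporter-gene knockout removes the forced uptake itself (the exchange
closes), while a knockout downstream of the transporter leaves the forced
influx with no consumer and is therefore lethal. The glutamine transporter
is consequently *not* essential in the tumor model, but glutaminase is.

## GIMME

Expression is binarized per condition: threshold = fraction × grand mean
of per-gene means; a gene is Present iff its mean reaches the threshold
(ties → Present, the conservative choice that keeps reactions). The
shipped presets are the per-dataset fractions used for the published
series (GSE37418 0.723; WNT 0.725, SHH 0.747, GR3 0.9024, GR4 0.7634;
GSE62600 0.30; GSE10327 M0/M2/M4 0.45/0.50/0.55). The reduction LP
minimizes Σ|v| over reactions whose GPR is inactive under the Absent genes
(uniform penalty weight 1 — no expression-distance weighting), subject to
biomass ≥ `growth_fraction` × optimum. `growth_fraction` defaults to 0.9,
the common choice in the GIMME literature; the source analyses do not
state theirs. Penalized reactions with zero optimal flux *and* zero
attainable flux under the growth constraint are removed; the LP objective
is reported as the inconsistency score. A model whose wild type cannot
grow at all raises the "threshold too aggressive" error.

## ACHR sampling and differential testing

Warmup points are the 2·n per-reaction min/max LP solutions with bounds
capped at ±1000 (warning on capping). The chain direction at each step is
(random stored point − running center), projected onto an orthonormal
basis of null(S) intersected with the pinned-coordinate hyperplanes; the
projection is computed once by SVD, so every iterate satisfies S·v = 0 and
the obligatory exchanges exactly, by construction. Default thinning is
100 chain steps per kept sample; a single root seed drives warmup order
and chain randomness, and runs are bitwise reproducible.

Hit-and-run draws remain autocorrelated after thinning, and a Welch test
that treats them as independent is badly anti-conservative (on this model
it flags ~70% of reactions when comparing two chains of the *same*
polytope). The differential test therefore estimates each reaction's
integrated autocorrelation time (initial-positive-sequence cutoff, lags ≤
1000) and uses the effective sample size n/τ in the standard error and
Welch–Satterthwaite degrees of freedom; the correction can be disabled.
Benjamini–Hochberg step-up control is applied across the shared reaction
set (the intersection of the two models' reactions). Zero variance in both
groups with equal means yields p = 1 by convention.

## Regulation scores

The exact ZF/ZG formulas behind the published analysis are not printed;
the package implements standardized mean differences: ZF = (mean_b −
mean_a)/√(var_a + var_b) over sampled flux distributions (0 when the
pooled variance vanishes), and per-gene ZG as the Welch-type standardized
difference of expression between the two conditions' samples (linear
scale, log2 optional). ZG_total sums the per-gene scores over a reaction's
GPR genes — the summation rule is kept even though it inflates magnitude
for large GPRs; a mean-aggregation variant sits behind a flag. TR requires
|ZF| > 1.96 and |ZG_total| > 1.96; NTR requires only the flux criterion.
Sign concordance is recorded but not required (substrate-driven flux
increases without transcriptional change are real, e.g. lactate
dehydrogenase).

## Flux coupling

FCA works on the steady-state cone: reversible reactions are split, only
the signs of the original bounds are kept (inhomogeneous bound values,
including forced uptakes, are relaxed to sign-only with a large cap), and
ratio extremes are probed with v_j normalized to ±1. Blockedness and the
"can i run without j" probes use net fluxes, so split forward/backward
pairs cannot fake activity through futile pumping. Ratio-extreme equality
within 1e-6 (relative) makes the "fully coupled" call. Pair records
against the biomass anchor are partitioned into the standard five classes;
reactions in any class except uncoupled/blocked constitute the
biomass-coupled set.

## Essentiality and safety

Essential = objective reduction strictly greater than 0.40, for every
objective (biomass; ATP = atp_yield-weighted production; lactate = total
lactate excretion). Double deletions pair only genes that are not
single-essential; a pair is synthetic lethal iff the joint reduction
crosses the cutoff. Genes essential for all three objectives on the tumor
model are re-tested on the healthy model; "healthy-safe" is operationalized
symmetrically as ≤ 0.40 reduction of *both* healthy biomass and healthy
ATP production (the source criterion — "does not affect the main functions
of healthy cells" — is not quantified; the symmetric cutoff is
configurable).

## Antimetabolite screen

Fingerprints are hashed circular (Morgan) substructures, radius 2, 2048
bits — the fingerprint family is a package choice, so published Tanimoto
scores for specific compound pairs are reported but never asserted.
Matching is restricted to metabolites with SMILES annotations; currency
cofactors (ATP, NAD(P)H, O₂, …) are excluded via a configurable stop-list,
otherwise every screen would hit energy metabolism. Inhibition caps each
*enzymatic* consuming reaction (boundary exchanges carry no enzyme and are
never targeted) at 0.1× its baseline flux, toward zero for either sign; a
reaction with zero baseline flux is left untouched, since scaling zero
would be a full knockout and overstate the inhibition. A hit requires
Tanimoto > 0.90, tumor growth reduction > 0.40, and a healthy reduction
within the safety cutoff.

## The synthetic study inputs

The generator builds a deliberately small (~65 reactions, 37 genes) but
topologically faithful two-cell network: lumped glycolysis, oxidative PPP,
serine synthesis, glycerol-3-phosphate, TCA, OXPHOS, a transhydrogenase
valve, threonine catabolism, a glutamine→glutamate/GABA disposal system,
fatty-acid, mevalonate/cholesterol (astrocyte-side, with a cholesterol
shuttle to the neuron), cardiolipin, sphingolipid/ganglioside and taurine
branches, plus dead glycogen/ketone stubs gated by their own genes.
Biomass drains leucine (the binding nutrient), tryptophan, tyrosine,
methionine, ribose-5-phosphate, fatty acid, cholesterol, cardiolipin,
sphingomyelin and 10 ATP per unit flux; the coefficients are
uniform-order placeholders, since cerebellar composition values at this
granularity are not published.

The MB variant differs from healthy only in bounds and GPR gene sets:
obligatory glucose/glutamine/threonine uptake, a pyruvate-dehydrogenase
cap of 0.03 mmol/gDW/h (low TCA/OXPHOS), and loss of the redundant
glucose transporter (`SLC2A1 or SLC2A3` → `SLC2A1`). Forced glycolytic
influx plus the oxidation cap *structurally* enforce the Warburg
phenotype: lactate:glucose ≥ 2 (glutamine contributes no lactate; the
extra carbon comes from threonine), glucose-dependent growth, and
dispensable glutamine. The glutamine disposal chains (glutamate export and
the GABA shunt to succinate export) deliberately carry no ATP or redox
side effects: any coupling between glutamine flux and the lactate/ATP
pools would let the MOMA quadratic trade growth against disposal
residuals, and glutamine deprivation would no longer leave biomass exactly
unchanged.

The designed ground truth (planted essential genes, the two isoenzyme
synthetic-lethal pairs HK1/HK2 and GPD1/GPD2, three expression-prunable
dead branches, five antimetabolite hits on the lactate/threonine/glutamine
axis, and the fourteen reactions fully coupled to biomass) is derived from
the wiring arithmetic, never by running the solvers, and the pipeline is
required to reproduce it exactly.

Expression matrices are gene-level lognormal: per-gene baseline means
LogNormal(ln 100, 0.15), replicate noise LogNormal(0, 0.3), 10 samples per
condition, planted 4-fold up-regulation of the Warburg genes and 0.2-fold
down-regulation of the dead-branch genes in the case condition. What this
does **not** emulate: microarray probe sets and probe-to-gene collapsing,
platform batch effects, heavy-tailed baselines, correlated co-regulation,
or condition-dependent variance — so passing recovery tests demonstrates
the statistical machinery, not robustness to real microarray artifacts.
Likewise the toy network's behavior (exact 0-or-1 essentiality outcomes,
a single binding nutrient) is cleaner than any genome-scale
reconstruction; counts measured on it are not comparable in magnitude to
those from the full 753-reaction tumor model.

## Problem sizes and runtime choices

The default analyses run on the ~65-reaction toy pair: 10,000 ACHR
profiles per model at thinning 100 (≈ 30 s each), full single/double
deletion screens (~40 genes, ~100 pairs, milliseconds per MOMA solve),
and coupling against biomass (~400 LPs). The test suite uses smaller
chains (≈ 2,000 profiles) for shared fixtures and reserves full-size
sampling for the acceptance checks.

## Known limitations

- MOMA is the only adjustment model; no loopless or parsimonious FBA
  beyond minimum-norm reporting, no dynamic FBA, no thermodynamics.
- The ATP objective maximizes Σ yield⁺·v, which assumes ATP-producing
  reactions are irreversible-forward (true of the packaged models;
  documented rather than enforced).
- FCA reports pairs against configured anchors only; an all-pairs matrix
  would be quadratic in model size.
- The ESS-corrected Welch test calibrates the null adequately (≈ 0–3%
  significant at α = 0.05 across seeds) but is still an approximation for
  strongly non-normal marginal flux distributions.
- SBML support covers Level 3 + FBC (bounds, gene products, objectives);
  kinetic laws are ignored with a warning.
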