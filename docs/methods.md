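# Methods

`hepatoflux` implements a fasting hepatic-glucose-flux analysis for steatotic
liver disease cohorts: tracer-dilution fluxomics, clinical insulin-resistance
indices, personalized constraint-based models of hepatocyte glucose
metabolism, LP-based estimation and decomposition of hepatic glucose
production (HGP), and the nonparametric cohort statistics. This note
documents the models, the defaults and why they were chosen, and what the
synthetic data do and do not establish.

## Tracer-dilution fluxomics

At isotopic steady state during a primed-continuous co-infusion of
6,6-²H₂-glucose and U-²H₅-glycerol, the rate of appearance of the traced
metabolite follows from dilution of the infusate:

    Ra_total = F · E_inf / Ē,    Ra_endo = Ra_total − F

with infusion rate `F` (µmol/min), infusate enrichment `E_inf` (mole
fraction, default 1.0) and plateau enrichment `Ē` (mean of the provided
plateau samples). Subtraction of the tracer infusion is the default and can
be switched off (`subtract_infusion=False`); the two conventions differ by
`F`, under 2 % at typical enrichments. Steady state is accepted when the
plateau sample CV is at or below a threshold (default 15 %); above it a
`NonSteadyStateError` is raised rather than silently averaging a drifting
signal. Non-steady-state (Steele-style) kinetics and mass-isotopomer
modeling are out of scope.

The fractional gluconeogenesis is the product-to-precursor enrichment ratio,
clipped to [0, 1] with a warning above 1 (measurement noise can push the raw
ratio past unity). Gluconeogenesis flux is `%GNG × HGP`; glycogenolysis
follows by difference. Fluxes are normalized to lean body mass (LBM),
µmol/min/kg, with an optional mmol/h conversion (× 60/1000) for comparison
with whole-liver model fluxes.

## Body composition and insulin-resistance indices

When LBM is not measured it is estimated with Hume's sex-specific linear
formula (coefficients in `IndexConfig`, from the 1966 reference):

    LBM_male   = 0.32810·W + 0.33929·H − 29.5336
    LBM_female = 0.29569·W + 0.41813·H − 43.2933

(`W` kg, `H` cm). Muscle mass is `0.63·LBM − 4.1` kg. Indices are plain
products as used in fasting phenotyping: Hep-IR = HGP × insulin,
Adipo-IR = FFA × insulin, HOMA-IR = glucose(mmol/L) × insulin(mU/L) with the
mg/dL→mmol/L factor fixed at 0.0555. HOMA-IR is implemented as the pure
product by default; the conventional /22.5 divisor is available via
`IndexConfig(homa_divisor=22.5)` and is *not* applied silently.

## The miniature hepatocyte network

`build_toy_hepatocyte()` returns a 28-reaction, 19-metabolite network of
fasting hepatic glucose metabolism: glucose exchange (`HMR_9034`, alias R1;
import blocked by the fasting policy), uptakes for lactate, alanine,
glutamine, glycerol, FFA and O₂, exchanges for phosphate, CO₂, ketone
bodies and the lipid pool, a glycogen store, the gluconeogenic chain
(pyruvate carboxylase, PEPCK-2 = R28, lumped enolase/PGK = R4,
fructose-1,6-bisphosphatase = R5, glucose-6-phosphatase = R2), glucokinase
and lumped upper glycolysis (R3, R6), lactate dehydrogenase (R14, the only
reversible internal reaction), alanine transamination, glutaminolysis, a
lumped TCA segment containing the α-ketoglutarate dehydrogenase complex
(R23), β-oxidation, ketogenesis, terminal oxidation and lipid synthesis
(`HMR_0031`). Only R1/R2/R5/R14/R23/R28 and the two HMR ids carry canonical
numbering; the remaining ids are artifact choices of this package.

Design rules:

* **Carbon is conserved** in every internal reaction (each metabolite is
  annotated with a carbon count; `validate_model` checks the balance).
  Two C3 precursors yield one glucose; one glycogen-glucosyl unit yields
  one glucose; even-chain FFA cannot contribute net carbon to glucose
  (acetyl-CoA entering the TCA segment leaves as CO₂, with oxaloacetate
  acting catalytically), matching the biochemistry.
* **Cofactors (ATP/NAD) are not tracked.** The network answers carbon-routing
  questions only; energy-based constraints (e.g., O₂-limited gluconeogenesis)
  are outside its reach. O₂ appears only in the lumped terminal oxidation.
* **Glycogen breakdown is one lumped, GPR-free reaction**
  (`glycogen_breakdown`: glycogen → glucose, added by
  `add_glycogenolysis_reaction`), so hepatic glycogen output is controlled
  by a single clinical bound rather than by transcript-scaled intermediates.
  Its upper bound is the handle used in the shadow-price decomposition.
* **GPRs** use the marker genes of each step — isoform alternatives as OR
  (`LDHA or LDHB`), complex subunits as AND (`OGDH and DLST and DLD`,
  `PDHA1 and DLAT`), single genes elsewhere. Respiration and glycogen
  breakdown carry no GPR. PEPCK-2 (R28) is given a higher V_max than the
  distal chain so that its transcript does not limit flux — hepatic
  gluconeogenic flux is known to diverge from PCK transcript levels, and the
  synthetic generator programs PCK2 expression to be *inversely* coupled to
  flux.
* The committed distal steps (R2, R4, R5) carry finite V_max (25–80 mmol/h)
  on the scale of the substrate-supply ceiling, with glucose-6-phosphatase
  (R2, V_max 25 mmol/h) the narrowest — the terminal committed step is the
  transcriptional control point of gluconeogenic output.

A 4-reaction worked example (`build_chain_model`) ships for hand-checking:
lactate uptake ≤ 6 with 2:1 stoichiometry plus a glycogen source ≤ 2 gives
an FBA optimum of 5, glycogenolysis contribution 2 (shadow price exactly 1)
and gluconeogenesis 3.

Reversible reactions are split into complementary forward pairs before any
LP (`split_reversible`; bounds [0, ub] and [0, −lb]); net fluxes are always
reported per original reaction, and splitting provably leaves the net-flux
polytope — and hence all FVA ranges — unchanged.

## Personalization

For each subject, bounds are assembled from four sources and merged with
precedence **policy > clinical > expression > default**; every bound carries
its provenance tag.

* **Reaction activity scores.** GPR trees are evaluated with AND→min
  (complex subunits) and OR→max (isoforms). Genes missing from a profile do
  not constrain (ignored in both AND and OR, with a warning); a reaction
  whose genes are all missing, or which has no GPR, keeps its default
  bounds.
* **Expression bounds (E-flux-style).** Internal reaction capacity is
  `V_max · min(1, s/cap)`, where `cap` is the 99th percentile of the
  reaction's activity scores across the cohort (computed once per cohort so
  all subjects scale against the same reference). The high percentile makes
  the scaling effectively linear — only the extreme tail saturates. A
  binary on/off mode at a score threshold is available
  (`expression_mode="binary"`).
* **Substrate uptake bounds.** Uptake capacity = release rate × source
  tissue mass: muscle mass for lactate/alanine/glutamine, the fat-mass proxy
  (weight − LBM) for glycerol/FFA (lipolysis originates in adipose tissue).
  Default release rates (mmol/h per kg): lactate 0.75, alanine 0.25,
  glutamine 0.25, glycerol 0.20, FFA 0.50 — literature-scale values chosen
  once so that a 30-kg-muscle subject supplies roughly 20 mmol/h of
  gluconeogenic carbon; they are config entries, not measured constants.
  For subjects with T2D and BMI < 30, lactate and glutamine bounds are
  doubled and alanine multiplied by 1.5; glycerol's factor defaults to 1.0
  because no factor is established for it (configurable).
* **Glycogenolysis bound.** A 4-cell table keyed by (T2D, BMI ≥ 27) holds
  tracer-style rates in µmol/min/kg LBM (defaults 5.5 / 4.6 / 4.3 / 3.7 for
  non-T2D lean / non-T2D high-BMI / T2D lean / T2D high-BMI — glycogenolysis
  falls with adiposity and diabetes). `personalize` converts the selected
  rate to a whole-liver mmol/h bound with the subject's LBM. Keeping the
  table in per-kg units matches how tracer rates are reported and avoids
  making the bound's per-LBM value depend on body size twice.
* **Fasting exchange policy.** Glucose import is blocked (export stays
  open), O₂/phosphate/CO₂/ketone/lipid exchanges are opened, and any
  configured extra uptakes are closed.

A merge that leaves `lb > ub` (e.g., a forced flux colliding with a zero
expression score) raises an error naming the reaction and provenance.

## Flux estimation and decomposition

All LPs are solved with HiGHS (`scipy.optimize.linprog`) at feasibility/
optimality tolerances of 1e−9; comparisons use 1e−6.

* **FBA** maximizes glucose export subject to S·v = 0 and bounds, returning
  primal fluxes and the duals of every bound constraint under the
  maximization sign convention (dual ≥ 0 on a binding upper bound).
* **FVA** reports per-reaction min/max and midpoint. The default
  `objective_fraction` is 0 (pure feasibility ranges): a pinned optimum
  would collapse the objective reaction's own range to a point, whereas the
  analysis treats the glucose-export *midpoint* as the HGP estimate — a
  non-degenerate range for the objective is only possible if the optimum is
  not enforced. Any fraction in [0, 1] can be requested.
* **HGP** is the FVA midpoint of glucose export, converted to
  µmol/min/kg LBM at reporting time. Because feasibility ranges start at 0,
  the midpoint is half the maximal capacity; cohort contrasts are driven by
  the personalized bounds.
* **Decomposition.** With FBA at the optimum, the glycogenolysis
  contribution is `v_glycogen × λ`, where `λ` is the shadow price of the
  glycogen-breakdown upper bound (the marginal HGP per extra unit of
  glycogen); gluconeogenesis is the remainder, so the two add to HGP
  exactly. The same construction gives per-precursor contributions from the
  uptake-bound duals. Shadow prices at degenerate optima are not unique:
  the implementation brackets the dual by ±ε bound perturbation (ε = 1e−4)
  and warns, reporting the interval, when the one-sided slopes disagree.
* **Outliers.** Per-subject flux values deviating from the cohort mean by
  more than 3 sample SDs are excluded (two-sided by default; one-sided
  available), with removed ids reported. A zero-SD vector removes nothing.

A brute-force vertex-enumeration oracle (`lp_oracle`, ≤ 12 reactions after
splitting) provides exact optima and ranges for test models; the full toy
network is additionally cross-checked against cobrapy in the test suite.

## Synthetic cohort generator

The generator emulates the statistical structure of a MASLD cohort without
claiming any study's data distributions. Each subject carries **latent**
truth (true HGP, lipolysis, gluconeogenesis fraction) next to noisy
observables, enabling parameter-recovery tests.

* Group × T2D cells are sampled i.i.d. from an 8-cell simplex weight vector
  (default: MASL 30 %, MASH F0–F1 30 %, MASH F2 20 %, MASH F3–F4 20 %,
  T2D fraction 30 %). Histology follows the group (MASL has activity score
  0; fibrosis stage determines the MASH subgroup).
* Latent HGP = 9.0 + {0, 1.2, 2.4, 3.6} (fibrosis group) + 1.5·T2D + ε,
  ε ~ N(0, 1.0), all in µmol/min/kg LBM — a stepwise ~13 % rise per group
  and a ~10 % within-group CV, typical of tracer HGP measurements. Latent
  lipolysis couples to HGP with slope 0.25. Concentrations (glucose,
  insulin, FFA, ALT, AST) receive lognormal noise so positivity is
  structural; enrichments receive normal noise.
* Expression: log-expression of gene *g* is `b_g + c_g·(HGP_latent − 9)/2 +
  ε`, ε ~ N(0, 0.25). The baseline `b_g` is a deterministic function of the
  gene name (hash-seeded), so separately generated cohort arms behave like
  one platform. Default couplings `c_g`: +0.6 for FBP1/G6PC, +0.5 for
  PC/ENO1, +0.3 for GK/GPT/GLS, **−0.4 for PCK2** (transcript down while
  flux up), 0 elsewhere — expression is deliberately only a weak, partly
  inverse, proxy of flux. Coupling to the *absolute* latent deviation (not
  cohort z-scores) keeps a subject's expression a function of their own
  physiology, independent of cohort composition.
* Tracer series: the noiseless plateau is the steady-state dilution value
  `E = F·E_inf/(Ra_endo + F)`; samples get normal noise with the requested
  CV. Round-tripping through `steady_state_ra` at zero noise recovers the
  programmed Ra exactly.

Every generator is fully determined by the config seed (independent
substreams for cohort, expression and tracer noise).

**What the synthetic data do not show.** Groups are sampled i.i.d. (no
covariate shift between arms unless configured); expression has no
batch/library-depth structure; histology is generated from the group label
rather than scored; and the latent-to-observable maps are simple
monotone transforms. Passing recovery tests therefore demonstrates that the
pipeline's machinery is correct and sensitive at realistic effect sizes —
not that real transcriptomes carry this much flux information.

## Cohort statistics

Mann-Whitney (exact null for ≤ 8 per group without ties, tie-corrected
normal approximation otherwise), Kruskal-Wallis with tie correction,
Spearman correlation (permutation p for n ≤ 10, t-approximation above),
Benjamini-Hochberg step-up FDR, and heatmap tables that z-scale each
variable across all subjects before taking within-group medians
(zero-variance variables are dropped with a warning).

Cross-cohort matching minimizes Euclidean distance on pooled-standardized
continuous features with sex and T2D as hard strata (categorical "(yes/no)"
matching; cross-level pairs forbidden). The default assignment is greedy
nearest-neighbour without replacement in order of ascending best distance;
an optimal mode (Hungarian assignment per stratum) is available and is the
one compared against exhaustive enumeration in tests. Regression validation
of model-derived against measured fluxes uses OLS with Pearson r and emits a
Bland-Altman-style agreement table (bias and 95 % limits of agreement).

## Problem sizes used in the shipped tests

The recovery study runs 100 seeded replicates of a 180-subject cohort
(80 non-T2D plus 100 mixed with T2D fraction 0.5) through
personalize → FVA → decompose → Kruskal-Wallis and requires strictly
ordered group medians plus p < 0.05 in at least 95 of them. Null
calibration runs 600 replicates of a 40-subject cohort with all effects
zeroed (type-I error of the test battery is independent of sample size, so
the smaller cohort is used) and requires the rejection rate to sit inside
the central 99 % binomial interval around 0.05. Per-subject LP work is
restricted to the three solves that the estimates need (FVA min/max of
glucose export plus one FBA for the decomposition).

## Known limitations

* The toy network omits cofactor balancing, compartments and the
  pentose-phosphate route; absolute HGP values (~3–6 µmol/min/kg at the
  default configuration) sit below typical fasting measurements (~10)
  because the FVA midpoint halves the feasible capacity — cohort contrasts,
  not absolute levels, are the analysis target.
* Futile cycles (e.g., R5/R6, R2/R3) are not excluded (no loopless
  constraint), which inflates individual FVA ranges of the cycling
  reactions; net glucose export is unaffected.
* Shadow-price decompositions are reported as single numbers only where the
  dual is unique; degenerate cases carry a warning and an interval.
* Greedy matching is order-dependent and can exceed the optimal total
  distance; use `method="optimal"` when a global minimum matters.
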