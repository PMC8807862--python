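# Methods

`ischemix` simulates perfusion recovery in the mouse hindlimb-ischemia (HLI)
model of peripheral arterial disease. It couples two ODE components across
scales: a cell-level macrophage signal-transduction model, instantiated once
per recruitment cohort, and a tissue-level model of cell populations,
cytokines, oxygen and perfusion. This note describes the model, its
assumptions, the tunable parameters that matter, what the synthetic fixtures
do and do not emulate, the numerical choices, and known limitations.

## Cell-level macrophage model

Each macrophage cohort carries a 36-species intracellular state driven by
eight ligand pathways — IFN-γ, TNF-α, IL-4, IL-10, IL-12, IL-6 and type-I IFN
(the base roster), plus HMGB1 — and a hypoxia input in [0, 1]. Receptor
binding is mass-action against a conserved receptor pool; downstream nodes
(STAT1/3/4/6, the IκB/NF-κB pair, ERK, p38, JNK, SOCS1/3, and a lumped
hypoxia/HIF transcriptional program) are capacity-limited activation–
deactivation balances, mostly Hill-type. Thirteen phenotype markers are
produced from node activities with basal terms (so the control panel is
strictly positive) and first-order turnover: eight M1-like (TNF-α, IFN-γ,
iNOS, IL-1β, IL-12, CXCL9, CXCL10, VEGF165b) and five M2-like (IL-10,
IL-1Ra, VEGF165a, IL-4, ARG1).

The HMGB1/TLR4 axis adds exactly four species (the HMGB1·TLR4 complex,
active PI3K, active AKT, and a lumped IRAK/TRAF6 adapter node) and eight
reactions (binding/turnover of the complex and activation/deactivation of
the three downstream nodes), tagged `hmgb1_tlr4` in the model file so the
counts are machine-checkable. The occupied receptor signals through two
parallel branches: PI3K→AKT, and IRAK/TRAF6 feeding the *shared* IκB
degradation and MAPK activation terms. With zero HMGB1 the axis species stay
at zero and the model is exactly the seven-pathway base model; no
marker-production parameter is touched by the axis.

Design choices worth flagging:

- **Thresholded axis activation.** PI3K and IRAK/TRAF6 activation are Hill
  functions of receptor occupancy (n = 2 and 4). Without the threshold,
  trace HMGB1 from background necrosis polarizes every cohort; with it the
  axis responds to the pathological danger-signal range while remaining
  responsive at the calibration stimulus (1 model unit ≈ 100 ng/mL).
- **HIF as a day-scale program with M1 output.** The HIF node represents
  the hypoxic transcriptional program, not instantaneous protein
  stabilization: activation is cooperative in oxygen deficit (half-max 0.7,
  n = 5, so moderate ischemia barely engages it) and slow (≈ half-day
  activation, multi-day decay). It drives iNOS and IL-1β (HIF-1α-like
  pro-inflammatory output) as well as VEGF165a (M2 side), which is what
  makes a deep acute insult genuinely more M1-polarizing than a slow
  moderate one.
- **IL-10/STAT3 brake.** STAT3 suppresses NF-κB activation (the classic
  resolution loop); it is the main driver of the late decline of the
  population M1/M2 score.
- **Marker turnover sets population timing.** Marker half-lives are in the
  0.5–1.5 day range (M1 faster than M2, TNF-α fastest, IL-10 slowest); the
  size-weighted mean score therefore peaks days 3–5 after acute HLI and
  resolves over weeks, while single-cell signaling still responds on the
  hour scale for the calibration-style curves.
- HMGB1 unit conversion is linear: `model units = 0.01 × ng/mL`.

## Tissue-level model

The tissue component declares exactly 34 species governed by 23 reactions
and rules (machine-counted from `models/tissue.yaml`): myocytes, a myoblast
pool, ECs and the macrophage census; ten dynamic cytokine/chemokine pools
(HMGB1, VEGF165a/b, ECM-bound VEGF and free ECM sites, IFN-γ, TNF-α, IL-10,
IL-4, MCP-1, MMP9, CXCL9/10); perfusion, oxygen and an arteriogenesis state;
seven cumulative-flux bookkeeping species; and eight boundary species held
constant (basal IL-12/IL-6/type-I-IFN/IL-1β/IL-1Ra/TGF-β pools, arterial
oxygen, endothelial NO). Populations and perfusion are normalized to the
pre-HLI baseline (= 1); time is in hours internally, days in outputs.

Key mechanisms:

- **Cell turnover.** Each cell type has one coarse-grained production and
  one constitutive removal channel, oxygen- and cytokine-modulated via Hill
  factors; myocytes and ECs additionally undergo necrosis at a rate exactly
  proportional to the perfusion deficit `max(0, 1 − P)` (zero under
  hyperemia). Apoptosis and necrosis are separate channels; only necrosis
  sources HMGB1 (myocyte deaths weighted 2× for their fiber size), and
  macrophages scavenge HMGB1. Myoblast supply carries an injury-activated
  (satellite-cell) term that vanishes at baseline.
- **Cytokine provenance.** IFN-γ and TNF-α are produced exclusively by
  macrophages (cohort secretion summaries); VEGF isoforms come from
  myocytes, ECs (hypoxia-induced, via a Hill in oxygen deficit) and
  macrophages; MCP-1 is induced by HMGB1, TNF-α and deep hypoxia. IL-10 and
  IL-4 clearance scales with the macrophage census (receptor-mediated
  consumption), which keeps the resolution signal proportional to per-cell
  output rather than raw cell number.
- **Perfusion** is semi-mechanistic: `dP/dt` is the sum of an angiogenic
  term — `nonleakiness · k13 · (net EC growth)` with the *signed* net growth,
  so ischemic EC destruction subtracts perfusable vessels and only the
  non-leaky fraction of new vessels conducts — and an arteriogenic term
  `k8 · A`, both gated by the remaining deficit so the pre-HLI state is a
  fixed point and recovery asymptotes below baseline on the 35-day horizon.
  The arteriogenesis state `A` grows with a saturating shear-stress stimulus
  (a Hill in the perfusion deficit), macrophage infiltration and MMP9, and
  decays slowly.
- **Oxygen** relaxes to `P × (arterial O2)` with a 1-hour time constant,
  far below the day scale, so oxygenation parallels perfusion.

A baseline builder derives a small set of balance constants (basal
recruitment drive, EC growth scale, myoblast pool and supply, normoxic VEGF
secretion, MCP-1/ECM equilibria, and per-marker secretion coefficients) so
that the declared pre-HLI state is an *exact* fixed point of the fully
coupled system at the default parameters; the constants are then frozen, so
parameter perturbations (sensitivity analysis, virtual mice) retain their
full dynamic effect.

Parameters follow the field's naming where established (`k1`–`k15` rate
constants, `nonleakiness` ∈ (0,1], `perfusion_IC` ∈ (0,1] — the day-1
perfusion initial condition after acute surgery, default 0.15). Every value
is flagged with its provenance in the YAML; all are package defaults chosen
so the coupled system reproduces the qualitative in vivo behaviors the
package tests assert (perfusion drop-and-partial-recovery, myocyte dip and
regeneration, EC overshoot, macrophage influx and contraction, early M1
dominance resolving over weeks).

## Protocols and coupling

The horizon (default 35 days) is divided into coupling intervals (24 h
default; 4 h for phenotype-resolution runs). Within an interval the tissue
component is integrated using the secretion summary implied by the
start-of-interval cohort states (sizes decay analytically at the shared
removal rate; marker panels held), then all cohorts are integrated in one
batched solve against the tissue cytokine/hypoxia interpolant. End-of-
interval states become the next initial conditions. One cohort is spawned
per interval at the macrophage control condition, sized by the
removal-discounted recruitment integral — this makes the cohort census agree
exactly with the tissue macrophage ODE, and sham stays flat to solver
precision. Cohorts below 1e-6 of the baseline pool are pruned.

Halving the interval moves the acute perfusion trajectory by ≈ 1e-3 and the
4 h run differs from the 24 h run by ≈ 2e-3; the documented coupling
tolerance in the config is 0.05 (relative perfusion units).

Acute HLI is a single drop of the perfusion initial condition to
`perfusion_IC`. Gradual HLI applies an exponential occlusion-progression
schedule `ω(t) = 1 − (1 − perfusion_IC)(1 − e^{−rt})` (default r = 0.004/h,
near-complete occlusion in ~2 weeks, the ameroid-constrictor scale) as
*additive decrements of the remaining native-artery supply* at each interval
start. The decrements sum exactly to the acute drop; an infinitely fast rate
reproduces the acute protocol and rate zero reproduces sham. Applying the
schedule multiplicatively to the whole perfusion state was rejected because
it re-occludes collateral-driven recovery every interval, which forces the
deficit exposure to be protocol-independent and contradicts the observed
milder necrosis and macrophage response under gradual occlusion.

Interventions are bounded multiplicative parameter changes (or additive
infusions) over a day window, resolved at interval boundaries; every arm's
magnitude and target parameters live in the config registry, with 10-fold
promotion / 90% inhibition as generic defaults.

## Phenotype analytics

The M1/M2-like score of a panel is
`log10[(Π M1 / Π M2) / (Π M1₀ / Π M2₀)]` against the control-condition
panel; markers are floored at 1e-6 of baseline before products so the log
stays finite. Scores are computed from accumulated marker levels (the
`phenotype.marker_quantity` switch documents the alternative of
instantaneous production). Spectra are cohort-score histograms weighted by
cohort size (weight conservation is exact); population marker means are
size-weighted and normalized to the day-0 panel.

## Inference machinery

- **Loss:** per-curve mean squared error on max-normalized,
  baseline-subtracted response curves (IκB reported as degraded fraction),
  equally weighted by default; simulation failures map to +∞.
- **Pattern search:** coordinate poll with mesh expansion (×2) on success
  and contraction (×½) on a failed poll, bound-clipped, deterministic per
  seed (the seed only shuffles poll order); incumbent loss is monotone.
- **LHS/PRCC:** Latin hypercube via `scipy.stats.qmc` (one sample per
  stratum per dimension); PRCC rank-transforms, residualizes each parameter
  and the outcome on all others with an intercept, correlates residuals,
  and reports p-values from `t = r√((n−2−k)/(1−r²))` with k = p−1.
- **Antirecovery composite:** 24-h cell simulation under hypoxia 0.8 plus
  low-dose HMGB1 (50 ng/mL); the composite is the integral of the
  control-normalized unlogged M1/M2 product ratio divided by the integral
  of normalized VEGF165a output (the model's recruitment/angiogenesis-
  promoting macrophage signal). Larger = worse for recovery.
- **Virtual mice:** log-uniform resampling around the base parameter set
  (default ±1.25–1.3-fold on the eight parameters most relevant to
  perfusion: k2, k3, k8, k9, k10, k13, nonleakiness, perfusion_IC); a
  candidate is accepted when its acute *and* gradual perfusion trajectories
  stay inside the envelope at all checkpoints (days 1–35). The envelope is
  mean ± 2 SD of a 20-mouse synthetic cohort drawn from the same
  distribution — a stand-in for curated in vivo recovery data.
- **Screening:** per-mouse paired control/intervention 35-day integrals of
  perfusion and myocyte count, two-tailed paired t-test, mean ± SEM,
  pairwise exclusion of failed simulations.

## Synthetic fixtures: what they do and do not emulate

The fixture generator reproduces the *structure* of the calibration and
validation targets — max-normalized stimulus-response time courses
(PI3K/ERK/p38/JNK activation, IκB degradation, TNF-α/IL-12/IL-10 production)
on a log-spaced 0.25–24 h grid that resolves the sub-hour rise phase, with
multiplicative Gaussian noise (5% default), and a perfusion acceptance
envelope — but the values are generated by this model, not digitized from
experiments. Passing the calibration-recovery and VMP tests therefore
demonstrates that the pipeline identifies parameters and populations under
the stated noise model and study design; it does not certify agreement with
any laboratory's measurements, inter-animal variability structure, or
digitization error of published figures.

## Numerical choices

ODE integration uses LSODA at rtol 1e-6 / atol 1e-9 by default for the
tissue and single-cell paths; batched cohort integration uses RK45 (the cell
model is nonstiff by construction). Negative values are clipped only in
readouts and milieu construction, never in the solver state. Rate laws are
declared once in the YAML model files, parsed with sympy, and compiled to a
vectorized numpy kernel (JIT-compiled with numba when available); a slow
substitution-based evaluator over the same declarations serves as the
term-by-term oracle in tests, and the SBML exporter serializes the same
expressions as content MathML. The resting state is found by long
relaxation plus a Newton polish and verified to residuals below 1e-10.
Trajectory integrals are trapezoidal on the stored grid (12 points per
coupling interval by default; within 0.1% of a 48-point grid).

Problem sizes used by the shipped tests and the acceptance script: 35-day
horizons at 24 h intervals (4 h for phenotype runs), a 20-mouse envelope
cohort, a 10-mouse panel population, a 50-mouse VMP, pattern-search budgets
of 300–500 evaluations, and LHS/PRCC instances up to n = 200.

## Known limitations

No spatial structure, vascular network geometry or hemodynamics; no T
cells, fibroblasts or smooth muscle cells; cells within a cohort are
identical and cohorts interact only through the shared milieu; intervention
doses change only at interval boundaries; oxygen is a monotone function of
perfusion without metabolic demand dynamics; the base-pathway kinetics are
package defaults rather than a re-derivation from primary signaling data;
and the virtual-mouse acceptance criterion considers only the perfusion
trajectory, not cell-count or cytokine constraints.
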