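# ischemix

Multiscale ODE simulation of perfusion recovery after hindlimb ischemia
(HLI), the standard mouse model of peripheral arterial disease. The package
is aimed at systems-biology and quantitative-systems-pharmacology work on
post-ischemic revascularization: it mechanistically couples macrophage
signal transduction to tissue-level cell-population, cytokine and perfusion
dynamics, and layers calibration, global sensitivity analysis,
virtual-mouse-population (VMP) generation and in silico intervention
screening on top of the simulator.

## The model in brief

**Cell level.** Each macrophage cohort (the group of cells recruited in one
coupling interval) carries an intracellular ODE model with eight ligand
pathways — IFN-γ, TNF-α, IL-4, IL-10, IL-12, IL-6, type-I IFN and the
HMGB1/TLR4 danger-signal axis — plus a hypoxia input. The TLR4 axis signals
through two parallel branches (PI3K/AKT, and IRAK/TRAF6 into the shared
NF-κB and MAPK machinery) and consists of exactly 4 species and 8 reactions.
The model outputs 13 phenotype markers: 8 M1-like (TNF-α, IFN-γ, iNOS,
IL-1β, IL-12, CXCL9, CXCL10, VEGF165b) and 5 M2-like (IL-10, IL-1Ra,
VEGF165a, IL-4, ARG1).

**Tissue level.** 34 species and 23 reactions/rules: skeletal myocytes, ECs
and the macrophage pool with coarse-grained production/removal; necrosis of
myocytes and ECs exactly proportional to the perfusion deficit
`max(0, 1 − P)`, sourcing the HMGB1 pool; cytokine pools with
macrophage-exclusive IFN-γ/TNF-α production; ECM sequestration of VEGF165a;
and semi-mechanistic perfusion

```
dP/dt = nonleakiness · k13 · (net EC growth) · (1 − P)₊  +  k8 · A · (1 − P)₊
```

— an angiogenic term following signed net EC growth and an arteriogenic
term following the shear/macrophage/MMP9-driven collateral state `A`.

**Coupling.** The horizon is split into discrete intervals (24 h default,
4 h for phenotype runs). Per interval: the tissue is integrated under the
cohorts' secretion summary, cohorts are integrated against the shared
tissue milieu, end states become the next initial conditions, and one new
cohort spawns at the macrophage control condition, sized by the
removal-discounted recruitment integral.

**Phenotype metric.** The non-dichotomous M1/M2-like score of a cohort is

```
score = log10[(Π 8 M1 markers / Π 5 M2 markers) / (same ratio at control)]
```

**Analysis layer.** Weighted-SSE loss on max-normalized curves with a
mesh-adaptive pattern search; Latin-hypercube sampling with partial rank
correlation coefficients (PRCC, residual-rank method); VMP generation by
log-uniform resampling with acceptance inside a perfusion envelope; paired
two-tailed t-tests on 35-day trajectory integrals for screening.

See `docs/methods.md` for assumptions, parameter conventions and numerical
choices. Model structure and every parameter live in
`src/ischemix/models/*.yaml`; protocol magnitudes, intervention effect sizes
and tolerances live in `src/ischemix/config/defaults.yaml`.

## Worked example

```python
import numpy as np
from ischemix import Protocol, Intervention, simulate
from ischemix.inference import outcome_integral

ctrl = simulate(Protocol("acute"))                     # 35-day acute HLI
P = ctrl.normalized("Perfusion")
print(f"perfusion: min {P.min():.3f}, day-35 {P[-1]:.3f}, "
      f"macrophage peak {ctrl.normalized('Mac').max():.2f}x")

arm = simulate(Protocol("acute",
                        interventions=(Intervention("ec_myo_nec_inhibit"),)))
dI = (outcome_integral(arm, "Perfusion", (0, 35))
      - outcome_integral(ctrl, "Perfusion", (0, 35)))
print(f"necrosis inhibition changes the 35-day perfusion integral by {dI:+.2f} a.u.")
```

prints

```
perfusion: min 0.146, day-35 0.878, macrophage peak 4.37x
necrosis inhibition changes the 35-day perfusion integral by +0.45 a.u.
```

i.e. perfusion collapses to ~15% of baseline after ligation, recovers to
~88% by day 35 while macrophages transiently expand ~4.4-fold, and
pharmacologic inhibition of EC + myocyte necrotic death improves the
cumulative 35-day perfusion exposure — the model's top-ranked realizable
intervention class.

A CLI mirrors the library (`ischemix simulate|calibrate|sensitivity|vmp|
screen|spectrum|export-sbml|make-fixtures`); e.g.
`ischemix export-sbml --model tissue` writes the tissue component as SBML
Level 3 XML.

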