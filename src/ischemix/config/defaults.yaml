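# Default run configuration. All protocol magnitudes, intervention effect
# sizes, tolerances and unit conversions live here, never in code.

coupling:
  interval_hours: 24        # discrete coupling interval; 4 h for phenotype runs
  horizon_days: 35
  tissue_method: LSODA
  cell_method: RK45         # batched cohort integration (nonstiff by design)
  rtol: 1.0e-6
  atol: 1.0e-9
  store_points_per_interval: 12
  cohort_size_floor: 1.0e-6   # fraction of the baseline macrophage pool
  # documented coupling-discretization tolerance: halving the interval length
  # moves the perfusion trajectory by less than this (absolute, relative units)
  coupling_tol_perfusion: 0.05
  perfusion_cap: 1.2

# tissue cytokine pool -> ligand model units seen by macrophage cohorts
milieu_conversion:
  IFNg: 1.0
  TNFa: 1.0
  IL4: 1.0
  IL10: 1.0
  IL12: 1.0
  IL6: 1.0
  IFNI: 1.0
  HMGB1: 5.0

# pre-HLI steady-state cytokine pool levels (dimensionless model units)
baseline_pools:
  IFNg: 0.02
  TNFa: 0.02
  IL10: 0.02
  IL4: 0.01
  CXCL9_10: 0.02
  VEGF165a: 0.03
  VEGF165b: 0.034

secretion:
  # fraction of the baseline free-VEGF pool turnover attributed to macrophages
  mac_share_vegfa: 0.3
  mac_share_vegfb: 0.3
  mmp9_per_cell: 0.02       # constant MMP9 secretion per macrophage unit per hour

protocols:
  acute: {}                  # single perfusion_IC drop at the first interval
  gradual:
    rate_per_h: 0.004        # exponential occlusion-progression rate
  sham: {}

phenotype:
  marker_quantity: level     # 'level' (accumulated marker amount) or 'production'
  marker_floor_rel: 1.0e-6   # floor, relative to baseline, applied before products
  spectrum_bins: 40

vmp:
  population_size: 50
  candidate_budget_factor: 20
  envelope_k_sd: 2.0
  checkpoints_days: [1, 3, 5, 7, 10, 14, 21, 28, 35]
  # log-uniform resampling half-width (fold change) per parameter
  resample:
    k8: 1.3
    k13: 1.3
    nonleakiness: 1.25
    k3: 1.3
    k9: 1.3
    perfusion_IC: 1.25
    k2: 1.3
    k10: 1.3

antirecovery:
  hypoxia: 0.8
  hmgb1_ng_ml: 50.0          # low-dose HMGB1 stimulus
  window_hours: 24

# Intervention registry. Each arm lists parameter effects:
#   scale: factor = magnitude ** exponent     (magnitude 1 -> no change)
#   add:   added = unit_amount * (magnitude - 1)
# 'magnitude' defaults to the value below; generic defaults are 10-fold
# promotion and 90% inhibition (magnitude 0.1) unless an arm states otherwise.
interventions:
  v165ab_ratio_up:
    magnitude: 10.0
    window_days: [0, 35]
    effects:
      - {param: k14, mode: scale, exponent: 0.5}
      - {param: k14b, mode: scale, exponent: -0.5}
  ec_nec_inhibit:
    magnitude: 0.1
    window_days: [0, 35]
    effects:
      - {param: k10, mode: scale, exponent: 1.0}
  ec_myo_nec_inhibit:
    magnitude: 0.1
    window_days: [0, 35]
    effects:
      - {param: k10, mode: scale, exponent: 1.0}
      - {param: k2, mode: scale, exponent: 1.0}
  myo_nec_inhibit:
    magnitude: 0.1
    window_days: [0, 35]
    effects:
      - {param: k2, mode: scale, exponent: 1.0}
  mac_recruit_up:
    magnitude: 3.0
    window_days: [0, 35]
    effects:
      - {param: k3, mode: scale, exponent: 1.0}
  ifng_low_dose:
    magnitude: 2.0
    window_days: [0, 7]      # short-term, low-dose administration
    effects:
      - {param: ifng_infusion, mode: add, unit_amount: 0.01}
  hmgb1_inhibit:
    magnitude: 0.1
    window_days: [0, 35]
    effects:
      - {param: hmgb1_eff, mode: scale, exponent: 1.0}
  vegfa_overexpress:
    magnitude: 2.0
    window_days: [0, 35]
    effects:
      - {param: vegfa_infusion, mode: add, unit_amount: 0.02}
  vegfb_inhibit:
    magnitude: 10.0
    window_days: [0, 35]
    effects:
      - {param: vegfb_eff, mode: scale, exponent: 1.0}   # antibody -> faster removal
  mac_depletion:
    magnitude: 0.1
    window_days: [0, 35]
    effects:
      - {param: mac_depletion_eff, mode: scale, exponent: 1.0}
  cxcr3_ko:
    magnitude: 0.0
    window_days: [0, 35]
    effects:
      - {param: cxcr3_eff, mode: scale, exponent: 1.0}
  mmp9_ko:
    magnitude: 0.0
    window_days: [0, 35]
    effects:
      - {param: mmp9_eff, mode: scale, exponent: 1.0}
  diabetes:
    magnitude: 0.4
    window_days: [0, 35]
    effects:
      - {param: endo_fn, mode: scale, exponent: 1.0}
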