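"""Discrete-interval coupling of macrophage cohorts to the tissue component.

The simulated horizon is divided into intervals (default 24 h; 4 h for
phenotype-resolution runs).  Within an interval the tissue component is
integrated with the macrophage secretion summary implied by the start-of-
interval cohort states (cohort sizes decay analytically, marker panels are
held); the resulting tissue trajectory provides the shared cytokine/hypoxia
milieu interpolant against which all cohort intracellular states are then
integrated in one batched solve.  End-of-interval values become the next
interval's initial conditions; each interval spawns one new cohort at the
macrophage control condition, sized by the removal-discounted recruitment
flux so the cohort census matches the tissue macrophage ODE exactly.

Hindlimb-ischemia protocols: ``sham`` (no perturbation), ``acute`` (a single
drop of the perfusion initial condition to ``perfusion_IC``), and ``gradual``
(an exponential occlusion-progression factor applied multiplicatively to the
perfusion initial condition at the beginning of every interval).  Timed
interventions act as bounded multiplicative parameter changes over their
day window, resolved at interval boundaries.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .config import load_config
from .signaling import LIGANDS, MARKERS, CellModel
from .tissue import Baseline, build_baseline

__all__ = [
    "Intervention",
    "Protocol",
    "CouplingConfig",
    "MacrophageCohort",
    "SimulationResult",
    "apply_acute_hli",
    "gradual_supply_factor",
    "apply_gradual_hli",
    "apply_intervention",
    "spawn_and_retire_cohorts",
    "step_interval",
    "simulate",
]


@dataclass(frozen=True)
class Intervention:
    """A timed, bounded perturbation from the registry in the run config."""

    kind: str
    start_day: float = 0.0
    stop_day: float = 35.0
    magnitude: float | None = None  # None -> registry default

    def __post_init__(self):
        if not self.start_day < self.stop_day:
            raise ValueError("intervention start must precede stop")


@dataclass(frozen=True)
class Protocol:
    """HLI mode plus zero or more timed interventions."""

    mode: str = "sham"
    gradual_rate_per_h: float | None = None
    interventions: tuple[Intervention, ...] = ()

    def __post_init__(self):
        if self.mode not in ("sham", "acute", "gradual"):
            raise ValueError(f"unknown protocol mode {self.mode!r}")


@dataclass(frozen=True)
class CouplingConfig:
    interval_hours: float = 24.0
    horizon_days: float = 35.0
    rtol: float = 1e-6
    atol: float = 1e-9
    tissue_method: str = "LSODA"
    cell_method: str = "RK45"
    store_points_per_interval: int = 12
    cohort_size_floor: float = 1e-6
    perfusion_cap: float = 1.2
    seed: int = 0

    def __post_init__(self):
        if not 1.0 <= self.interval_hours <= 24.0:
            raise ValueError("interval length must be in [1, 24] hours")
        if self.horizon_days <= 0:
            raise ValueError("horizon must be positive")

    @classmethod
    def from_dict(cls, d: Mapping) -> "CouplingConfig":
        return cls(
            interval_hours=float(d.get("interval_hours", 24)),
            horizon_days=float(d.get("horizon_days", 35)),
            rtol=float(d.get("rtol", 1e-6)),
            atol=float(d.get("atol", 1e-9)),
            tissue_method=str(d.get("tissue_method", "LSODA")),
            cell_method=str(d.get("cell_method", "RK45")),
            store_points_per_interval=int(d.get("store_points_per_interval", 12)),
            cohort_size_floor=float(d.get("cohort_size_floor", 1e-6)),
            perfusion_cap=float(d.get("perfusion_cap", 1.2)),
        )


@dataclass
class MacrophageCohort:
    """Macrophages recruited in one interval, sharing one intracellular state."""

    birth_interval: int
    size: float
    state: np.ndarray

    def __post_init__(self):
        if self.size < 0:
            raise ValueError("cohort size must be >= 0")


@dataclass
class SimulationResult:
    """Time-gridded tissue trajectories plus per-interval cohort snapshots."""

    t_hours: np.ndarray                  # store grid
    tissue: np.ndarray                   # (n_t, n_species)
    names: list[str]
    interval_end_hours: np.ndarray
    cohort_sizes: list[np.ndarray]       # per interval end
    cohort_births: list[np.ndarray]
    cohort_panels: list[np.ndarray]      # (n_cohort, 13) marker panels
    baseline_state: np.ndarray
    marker0: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def t_days(self) -> np.ndarray:
        return self.t_hours / 24.0

    def series(self, name: str) -> np.ndarray:
        return self.tissue[:, self.names.index(name)]

    def normalized(self, name: str) -> np.ndarray:
        """Trajectory normalized to the pre-HLI baseline value (= 1)."""
        base = self.baseline_state[self.names.index(name)]
        if base <= 0:
            raise ValueError(f"{name!r} has zero baseline; not normalizable")
        return self.series(name) / base

    def observable(self, key: str) -> np.ndarray:
        """Derived observables on the store grid (normalized conventions)."""
        if key == "arterioles_per_fiber":
            i_e, i_m = self.names.index("EC"), self.names.index("Myo")
            base = self.baseline_state[i_e] / self.baseline_state[i_m]
            return (self.tissue[:, i_e] / self.tissue[:, i_m]) / base
        if key == "necrosis_rate":
            k2 = self.metadata["params"]["k2"]
            k10 = self.metadata["params"]["k10"]
            deficit = np.maximum(0.0, 1.0 - self.series("Perfusion"))
            return k2 * deficit * self.series("Myo") + k10 * deficit * self.series("EC")
        raise KeyError(key)

    def to_frame(self) -> pd.DataFrame:
        """Tidy (time_day, species, value) table of the tissue trajectories."""
        n_t = len(self.t_hours)
        return pd.DataFrame({
            "time_day": np.repeat(self.t_days, len(self.names)),
            "species": np.tile(self.names, n_t),
            "value": self.tissue.ravel(),
        })

    def export(self, prefix: str | Path) -> tuple[Path, Path]:
        """Write tidy CSV plus run-metadata JSON; returns the two paths."""
        prefix = Path(prefix)
        csv_path = prefix.with_suffix(".csv")
        json_path = prefix.with_suffix(".json")
        self.to_frame().to_csv(csv_path, index=False)
        json_path.write_text(json.dumps(self.metadata, indent=2, sort_keys=True))
        return csv_path, json_path


# ----------------------------------------------------------------------
# protocol inputs
# ----------------------------------------------------------------------

def apply_acute_hli(y0: np.ndarray, names: Sequence[str],
                    params: Mapping[str, float]) -> np.ndarray:
    """Acute HLI: set the perfusion initial condition to ``perfusion_IC``."""
    pic = float(params["perfusion_IC"])
    if not 0.0 < pic <= 1.0:
        raise ValueError("perfusion_IC must be in (0, 1]")
    y = np.array(y0, float)
    y[list(names).index("Perfusion")] = pic
    return y


def gradual_supply_factor(t_h: float, params: Mapping[str, float],
                          rate_per_h: float) -> float:
    """Occlusion-progression factor ``1 - (1 - perfusion_IC)(1 - e^(-r t))``.

    Tends to ``perfusion_IC`` (full occlusion effect) as t grows; ``r -> inf``
    recovers the acute single drop, ``r = 0`` recovers sham.
    """
    pic = float(params["perfusion_IC"])
    if rate_per_h < 0:
        raise ValueError("decay rate must be >= 0")
    return 1.0 - (1.0 - pic) * (1.0 - math.exp(-rate_per_h * t_h))


def apply_gradual_hli(interval_index: int, params: Mapping[str, float],
                      rate_per_h: float, interval_h: float) -> float:
    """Perfusion-IC decrement applied at the start of one interval.

    The exponential occlusion schedule throttles the remaining native-artery
    supply; its per-interval decrements are subtracted from the perfusion
    initial condition, so collateral-driven recovery already gained is not
    re-occluded.  The decrements sum to the acute drop ``1 - perfusion_IC``.
    """
    t1 = interval_index * interval_h
    t0 = max(0.0, t1 - interval_h)
    return (gradual_supply_factor(t0, params, rate_per_h)
            - gradual_supply_factor(t1, params, rate_per_h))


def apply_intervention(
    params: Mapping[str, float],
    intervention: Intervention,
    registry: Mapping | None = None,
) -> dict[str, float]:
    """Parameter set implementing one intervention (inputs untouched).

    Effects come from the config registry: ``scale`` entries multiply a
    parameter by ``magnitude ** exponent``; ``add`` entries add
    ``unit_amount * (magnitude - 1)``.  Magnitude 1 is the identity.
    """
    reg = registry if registry is not None else load_config()["interventions"]
    if intervention.kind not in reg:
        raise KeyError(f"unknown intervention kind {intervention.kind!r}; "
                       f"known: {sorted(reg)}")
    arm = reg[intervention.kind]
    mag = intervention.magnitude if intervention.magnitude is not None else arm["magnitude"]
    out = dict(params)
    for eff in arm["effects"]:
        name = eff["param"]
        if name not in out:
            raise KeyError(f"intervention targets unknown parameter {name!r}")
        if eff["mode"] == "scale":
            out[name] = out[name] * mag ** eff["exponent"]
        elif eff["mode"] == "add":
            out[name] = out[name] + eff["unit_amount"] * (mag - 1.0)
        else:
            raise ValueError(f"unknown effect mode {eff['mode']!r}")
    return out


def _intervention_window(iv: Intervention, registry: Mapping) -> tuple[float, float]:
    if iv.start_day is not None and iv.stop_day is not None:
        return iv.start_day, iv.stop_day
    w = registry[iv.kind].get("window_days", [0, 35])
    return float(w[0]), float(w[1])


# ----------------------------------------------------------------------
# cohort bookkeeping
# ----------------------------------------------------------------------

def spawn_and_retire_cohorts(
    cohorts: list[MacrophageCohort],
    recruit_discounted: float,
    removal_rate: float,
    dt: float,
    rest_state: np.ndarray,
    interval_index: int,
    size_floor: float = 1e-6,
) -> list[MacrophageCohort]:
    """Decay existing cohorts, append one newborn cohort, prune small ones.

    ``recruit_discounted`` is the removal-discounted recruitment integral
    ``int flux(s) e^(-removal (dt - s)) ds`` over the interval, which keeps
    the cohort census identical to the tissue macrophage ODE.
    """
    if recruit_discounted < 0 or removal_rate < 0:
        raise ValueError("recruitment and removal must be >= 0")
    decay = math.exp(-removal_rate * dt)
    out = []
    for c in cohorts:
        ns = c.size * decay
        if ns >= size_floor:
            out.append(MacrophageCohort(c.birth_interval, ns, c.state))
    if recruit_discounted >= size_floor:
        out.append(MacrophageCohort(interval_index, recruit_discounted,
                                    np.array(rest_state, float)))
    return out


# ----------------------------------------------------------------------
# interval stepping
# ----------------------------------------------------------------------

def _effective_params(base: Mapping[str, float], protocol: Protocol,
                      t0_day: float, registry: Mapping) -> dict[str, float]:
    p = dict(base)
    for iv in protocol.interventions:
        lo, hi = _intervention_window(iv, registry)
        if lo <= t0_day < hi:
            p = apply_intervention(p, iv, registry)
    return p


def step_interval(
    baseline: Baseline,
    y: np.ndarray,
    cohorts: list[MacrophageCohort],
    eff_params: Mapping[str, float],
    cfg: CouplingConfig,
    interval_index: int,
    dt: float | None = None,
):
    """Advance tissue state and cohorts by one coupling interval.

    Returns ``(y_end, cohorts', t_local, tissue_states)`` where the last two
    give the within-interval store grid (hours from interval start) and the
    tissue trajectory on it.
    """
    dt = cfg.interval_hours if dt is None else dt
    if dt == 0:
        panels = baseline.cell.marker_panel(
            np.array([c.state for c in cohorts])) if cohorts else np.zeros((0, 13))
        return y.copy(), list(cohorts), np.array([0.0]), y[None, :].copy()

    tm = baseline.tissue.with_params(
        {k: v for k, v in eff_params.items() if k in baseline.tissue.params})
    p = tm.params
    cell = baseline.cell
    m0 = baseline.marker0
    from .tissue import hill  # local import to avoid cycle at module load

    k7_eff = p["k7"] * (1 + p["w_rem_tgfb"]
                        * hill(baseline._boundary("TGFb"), p["K_rem_tgfb"], 1))
    i_mac = tm.index["Mac"]
    i_perf = tm.index["Perfusion"]

    # size-weighted marker excess over the control panel, held within interval
    if cohorts:
        sizes = np.array([c.size for c in cohorts])
        states = np.array([c.state for c in cohorts])
        panels = cell.marker_panel(states)
        D = sizes @ (panels - m0[None, :])
        mac0 = sizes.sum()
    else:
        sizes = np.zeros(0)
        states = np.zeros((0, len(cell.names)))
        D = np.zeros(len(MARKERS))
        mac0 = 0.0

    def secretion(t: float, mac_count: float) -> np.ndarray:
        weighted = math.exp(-k7_eff * t) * D + mac_count * m0
        return baseline.secretion_from(weighted, mac_count, p)

    def rhs(t, yv):
        if not np.all(np.isfinite(yv)):
            raise FloatingPointError(
                f"non-finite tissue state in interval {interval_index}: "
                f"{dict(zip(tm.names, yv))}")
        return tm._rhs(np.maximum(yv, 0.0), secretion(t, max(yv[i_mac], 0.0)),
                       tm._pvec)

    y_start = np.array(y, float)
    y_start[i_mac] = mac0  # census mirror
    n_store = max(2, cfg.store_points_per_interval + 1)
    t_local = np.linspace(0.0, dt, n_store)
    sol = solve_ivp(rhs, (0.0, dt), y_start, method=cfg.tissue_method,
                    t_eval=t_local, rtol=cfg.rtol, atol=cfg.atol)
    if not sol.success:
        raise RuntimeError(
            f"tissue solver failure in interval {interval_index}: {sol.message}")
    tissue_states = sol.y.T.copy()
    tissue_states[:, i_perf] = np.clip(tissue_states[:, i_perf], 0.0,
                                       cfg.perfusion_cap)
    y_end = tissue_states[-1].copy()

    # shared milieu interpolant for all cohorts
    conv = baseline.milieu_conv
    i = tm.index
    bIL12 = baseline._boundary("IL12")
    bIL6 = baseline._boundary("IL6")
    bIFNI = baseline._boundary("IFN_I")
    U = np.empty((n_store, len(LIGANDS) + 1))
    U[:, 0] = conv["IFNg"] * tissue_states[:, i["IFNg"]]
    U[:, 1] = conv["TNFa"] * tissue_states[:, i["TNFa"]]
    U[:, 2] = conv["IL4"] * tissue_states[:, i["IL4"]]
    U[:, 3] = conv["IL10"] * tissue_states[:, i["IL10"]]
    U[:, 4] = conv["IL12"] * bIL12
    U[:, 5] = conv["IL6"] * bIL6
    U[:, 6] = conv["IFNI"] * bIFNI
    U[:, 7] = conv["HMGB1"] * tissue_states[:, i["HMGB1"]]
    U[:, 8] = np.clip(1.0 - tissue_states[:, i["Oxygen"]], 0.0, 1.0)
    U = np.maximum(U, 0.0)

    def milieu_fn(t: float) -> np.ndarray:
        j = np.searchsorted(t_local, t, side="right") - 1
        j = min(max(j, 0), n_store - 2)
        w = (t - t_local[j]) / (t_local[j + 1] - t_local[j])
        return (1 - w) * U[j] + w * U[j + 1]

    if len(cohorts):
        new_states = cell.simulate_batch(states0=states, milieu_fn=milieu_fn,
                                         t_span=(0.0, dt), method=cfg.cell_method,
                                         rtol=cfg.rtol, atol=cfg.atol)
        new_states = np.maximum(new_states, 0.0)
    else:
        new_states = states

    updated = [MacrophageCohort(c.birth_interval, c.size, new_states[j])
               for j, c in enumerate(cohorts)]
    recruit_disc = max(0.0, y_end[i_mac] - mac0 * math.exp(-k7_eff * dt))
    cohorts_out = spawn_and_retire_cohorts(
        updated, recruit_disc, k7_eff, dt, baseline.rest_state, interval_index + 1,
        size_floor=cfg.cohort_size_floor)
    y_end[i_mac] = sum(c.size for c in cohorts_out)
    return y_end, cohorts_out, t_local, tissue_states


# ----------------------------------------------------------------------
# top-level entry point
# ----------------------------------------------------------------------

def simulate(
    protocol: Protocol,
    params: Mapping[str, float] | None = None,
    config: CouplingConfig | dict | None = None,
    baseline: Baseline | None = None,
    run_config: dict | None = None,
) -> SimulationResult:
    """Run the full multiscale simulation for one protocol.

    ``params`` are tissue-parameter overrides (e.g. one virtual mouse);
    ``baseline`` may be passed to reuse a prebuilt operating point (it must
    have been built with the same overrides).  Deterministic given
    (protocol, params, config).
    """
    rc = run_config or load_config()
    if config is None:
        cfg = CouplingConfig.from_dict(rc["coupling"])
    elif isinstance(config, dict):
        cfg = CouplingConfig.from_dict({**rc["coupling"], **config})
    else:
        cfg = config
    registry = rc["interventions"]
    bl = baseline if baseline is not None else build_baseline(
        tissue_overrides=params, config=rc)
    base_params = dict(bl.tissue.params)

    grad_rate = protocol.gradual_rate_per_h
    if protocol.mode == "gradual" and grad_rate is None:
        grad_rate = float(rc["protocols"]["gradual"]["rate_per_h"])

    names = bl.tissue.names
    y = bl.y0.copy()
    if protocol.mode == "acute":
        y = apply_acute_hli(y, names, base_params)
    cohorts = [MacrophageCohort(0, 1.0, np.array(bl.rest_state))]

    n_int = int(round(cfg.horizon_days * 24.0 / cfg.interval_hours))
    dt = cfg.interval_hours
    i_perf = bl.tissue.index["Perfusion"]

    t_store: list[np.ndarray] = []
    x_store: list[np.ndarray] = []
    end_hours = np.empty(n_int)
    sizes_l, births_l, panels_l = [], [], []

    for k in range(n_int):
        t0 = k * dt
        if protocol.mode == "gradual" and k > 0:
            y[i_perf] = max(
                0.0, y[i_perf] - apply_gradual_hli(k, base_params, grad_rate, dt))
        eff = _effective_params(base_params, protocol, t0 / 24.0, registry)
        y, cohorts, t_loc, x_loc = step_interval(bl, y, cohorts, eff, cfg, k)
        keep = slice(0, len(t_loc) - 1) if k < n_int - 1 else slice(0, len(t_loc))
        t_store.append(t0 + t_loc[keep])
        x_store.append(x_loc[keep])
        end_hours[k] = t0 + dt
        sizes_l.append(np.array([c.size for c in cohorts]))
        births_l.append(np.array([c.birth_interval for c in cohorts]))
        panels_l.append(bl.cell.marker_panel(np.array([c.state for c in cohorts]))
                        if cohorts else np.zeros((0, len(MARKERS))))

    t_hours = np.concatenate(t_store)
    tissue = np.vstack(x_store)
    meta = {
        "protocol": protocol.mode,
        "gradual_rate_per_h": grad_rate,
        "interventions": [
            {"kind": iv.kind, "start_day": iv.start_day, "stop_day": iv.stop_day,
             "magnitude": iv.magnitude} for iv in protocol.interventions],
        "interval_hours": cfg.interval_hours,
        "horizon_days": cfg.horizon_days,
        "rtol": cfg.rtol,
        "atol": cfg.atol,
        "seed": cfg.seed,
        "params": {k: float(v) for k, v in base_params.items()},
        "params_sha256": hashlib.sha256(
            json.dumps({k: float(v) for k, v in sorted(base_params.items())}
                       ).encode()).hexdigest(),
    }
    return SimulationResult(
        t_hours=t_hours, tissue=tissue, names=list(names),
        interval_end_hours=end_hours, cohort_sizes=sizes_l,
        cohort_births=births_l, cohort_panels=panels_l,
        baseline_state=bl.y0.copy(), marker0=bl.marker0.copy(), metadata=meta,
    )
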