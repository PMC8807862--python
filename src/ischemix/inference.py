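"""Calibration, global sensitivity analysis, virtual mice and screening.

* Weighted least-squares loss on max-normalized calibration curves.
* Mesh-adaptive pattern search (coordinate poll with expansion/contraction)
  for derivative-free global fitting within bounds.
* Latin hypercube sampling and partial rank correlation coefficients (PRCC):
  rank-transform, residualize each parameter and the outcome on all other
  parameters, and correlate the residuals; significance from the standard
  PRCC t-statistic.
* Virtual mouse population (VMP): log-uniform resampling around the base
  parameter set, accepted when the simulated perfusion trajectories (acute
  and gradual) stay inside a data-derived envelope at every checkpoint.
* In silico intervention screening over a VMP with paired two-tailed
  t-statistics on 35-day trajectory integrals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc

from .config import load_config
from .multiscale import Intervention, Protocol, SimulationResult, simulate
from .signaling import CellModel, LigandMilieu, default_cell_model, hmgb1_to_model_input

__all__ = [
    "CalibrationDataset",
    "loss",
    "pattern_search_fit",
    "lhs",
    "prcc",
    "outcome_integral",
    "antirecovery_outcome",
    "PerfusionEnvelope",
    "VirtualMouse",
    "generate_vmp",
    "screen",
]


# ----------------------------------------------------------------------
# calibration
# ----------------------------------------------------------------------

@dataclass
class CalibrationDataset:
    """Named normalized time-series targets (one entry per curve).

    ``curves`` maps a curve id (a readout species name) to ``(t_hours,
    values)``; values follow the per-curve max-normalization convention.
    """

    curves: dict[str, tuple[np.ndarray, np.ndarray]]
    weights: dict[str, float] = field(default_factory=dict)
    stimulus_hmgb1: float = 1.0  # ligand model units
    hypoxia: float = 0.0

    def __post_init__(self):
        for cid, (t, v) in self.curves.items():
            t, v = np.asarray(t, float), np.asarray(v, float)
            if np.any(np.diff(t) <= 0) or not np.all(np.isfinite(v)):
                raise ValueError(f"curve {cid!r}: times must increase, values finite")
            self.curves[cid] = (t, v)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cid, (t, v) in self.curves.items():
            for ti, vi in zip(t, v):
                rows.append({"curve": cid, "time_h": ti, "value": vi})
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kw) -> "CalibrationDataset":
        curves = {}
        for cid, sub in df.groupby("curve"):
            sub = sub.sort_values("time_h")
            curves[cid] = (sub["time_h"].to_numpy(), sub["value"].to_numpy())
        return cls(curves=curves, **kw)


def _simulate_curves(params: Mapping[str, float], dataset: CalibrationDataset,
                     cell: CellModel | None = None) -> dict[str, np.ndarray]:
    cm = CellModel(overrides=dict(params)) if params else (cell or default_cell_model())
    t_all = np.unique(np.concatenate([t for t, _ in dataset.curves.values()]))
    if t_all[0] > 0:
        t_all = np.insert(t_all, 0, 0.0)
    rest = cm.resting_state()
    mil = LigandMilieu({"HMGB1": dataset.stimulus_hmgb1}, hypoxia=dataset.hypoxia)
    traj = cm.simulate(rest, mil, t_all)
    out = {}
    for cid, (t, _) in dataset.curves.items():
        if cid == "IkB_degradation":
            y = traj.series("IkB")
            y = y[0] - y  # degraded fraction of initial IkB
        else:
            y = traj.series(cid)
            y = y - y[0]  # stimulus-induced activation above rest
        m = np.max(np.abs(y))
        yn = y / m if m > 0 else y
        out[cid] = np.interp(t, t_all, yn)
    return out


def loss(params: Mapping[str, float], dataset: CalibrationDataset,
         cell: CellModel | None = None) -> float:
    """Weighted SSE between simulated and target max-normalized curves.

    Returns ``inf`` (never raises) when the simulation fails, so optimizers
    can treat failures as infeasible points.
    """
    try:
        sim = _simulate_curves(params, dataset, cell)
    except Exception:
        return float("inf")
    total = 0.0
    for cid, (t, v) in dataset.curves.items():
        w = dataset.weights.get(cid, 1.0)
        total += w * float(np.sum((sim[cid] - v) ** 2)) / len(v)
    return total


def pattern_search_fit(
    loss_fn: Callable[[np.ndarray], float],
    bounds: Sequence[tuple[float, float]],
    x0: np.ndarray,
    seed: int = 0,
    budget: int = 400,
    mesh0: float = 0.25,
    mesh_tol: float = 1e-8,
) -> dict:
    """Mesh-adaptive direct (pattern) search within box bounds.

    Polls ``x +- mesh * scale_j`` along every coordinate; a success moves the
    incumbent and expands the mesh (x2), a full failed poll contracts it
    (x1/2).  The incumbent loss is monotone nonincreasing and the procedure
    is deterministic for a given seed (the seed only shuffles the polling
    order).  Returns the incumbent with a convergence trace and an
    ``exhausted`` flag when the budget runs out before the mesh tolerance is
    reached.
    """
    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in bounds], float)
    hi = np.array([b[1] for b in bounds], float)
    x = np.clip(np.asarray(x0, float), lo, hi)
    if np.any(x != np.asarray(x0, float)):
        raise ValueError("x0 must lie within bounds")
    scale = hi - lo
    n = len(x)
    f = loss_fn(x)
    evals = 1
    mesh = mesh0
    trace = [(evals, f, mesh)]
    while evals < budget and mesh > mesh_tol:
        improved = False
        order = rng.permutation(2 * n)
        for k in order:
            if evals >= budget:
                break
            j, sgn = divmod(k, 2)
            step = (1 if sgn == 0 else -1) * mesh * scale[j]
            cand = x.copy()
            cand[j] = np.clip(cand[j] + step, lo[j], hi[j])
            if cand[j] == x[j]:
                continue
            fc = loss_fn(cand)
            evals += 1
            if fc < f:
                x, f = cand, fc
                improved = True
                trace.append((evals, f, mesh))
                break
        mesh = min(mesh * 2.0, mesh0) if improved else mesh * 0.5
    return {
        "x": x,
        "loss": f,
        "evals": evals,
        "mesh": mesh,
        "trace": trace,
        "exhausted": evals >= budget and mesh > mesh_tol,
    }


def fit_hmgb1_axis(
    dataset: CalibrationDataset,
    param_names: Sequence[str],
    bounds: Mapping[str, tuple[float, float]],
    x0: Mapping[str, float],
    seed: int = 0,
    budget: int = 400,
) -> dict:
    """Fit selected HMGB1/TLR4-axis kinetic constants to a curve dataset."""
    names = list(param_names)

    def f(x: np.ndarray) -> float:
        return loss(dict(zip(names, x)), dataset)

    res = pattern_search_fit(
        f, [bounds[n] for n in names], np.array([x0[n] for n in names]),
        seed=seed, budget=budget)
    res["params"] = dict(zip(names, res["x"]))
    return res


# ----------------------------------------------------------------------
# sensitivity analysis
# ----------------------------------------------------------------------

def lhs(bounds: Sequence[tuple[float, float]], n: int, seed: int = 0) -> np.ndarray:
    """Latin hypercube sample: one point per stratum in every dimension."""
    if n < 2:
        raise ValueError("need n >= 2 samples")
    lo = np.array([b[0] for b in bounds], float)
    hi = np.array([b[1] for b in bounds], float)
    if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi))):
        raise ValueError("bounds must be finite")
    sampler = qmc.LatinHypercube(d=len(bounds), seed=seed)
    return qmc.scale(sampler.random(n), lo, hi)


def prcc(X: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    """Partial rank correlation coefficients with significance.

    For each column j: rank-transform everything, regress out the other
    columns (with intercept) from both rank(x_j) and rank(y), and correlate
    the residuals.  p-values use ``t = r sqrt((n - 2 - k)/(1 - r^2))`` with
    ``k = p - 1`` controlled variables.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    if len(y) != n or n <= p + 2:
        raise ValueError("need rows(X) == len(y) > p + 2")
    for j in range(p):
        if np.ptp(X[:, j]) == 0:
            raise ValueError(f"column {j} is constant; PRCC undefined")
    Xr = np.column_stack([stats.rankdata(X[:, j]) for j in range(p)])
    yr = stats.rankdata(y)
    out = []
    dof = n - 2 - (p - 1)
    for j in range(p):
        others = np.delete(Xr, j, axis=1)
        A = np.column_stack([np.ones(n), others])
        rx = Xr[:, j] - A @ np.linalg.lstsq(A, Xr[:, j], rcond=None)[0]
        ry = yr - A @ np.linalg.lstsq(A, yr, rcond=None)[0]
        denom = np.sqrt(np.sum(rx**2) * np.sum(ry**2))
        r = float(np.sum(rx * ry) / denom) if denom > 0 else 0.0
        r = max(-1.0, min(1.0, r))
        if abs(r) < 1.0:
            tstat = r * math.sqrt(dof / (1.0 - r * r))
            pval = 2.0 * stats.t.sf(abs(tstat), dof)
        else:
            tstat, pval = math.copysign(np.inf, r), 0.0
        out.append({"index": j, "prcc": r, "t": tstat, "p": pval})
    df = pd.DataFrame(out)
    df["rank"] = df["prcc"].abs().rank(ascending=False).astype(int)
    return df


def tissue_sensitivity(
    param_names: Sequence[str],
    n: int = 60,
    seed: int = 0,
    outcome: str = "Perfusion",
    span: float = 2.0,
    protocol: Protocol | None = None,
) -> pd.DataFrame:
    """LHS+PRCC of tissue parameters against a 35-day trajectory integral."""
    from .tissue import build_baseline

    base = build_baseline()
    p0 = {k: base.tissue.params[k] for k in param_names}
    bounds = [(v / span, v * span) for v in p0.values()]
    X = lhs(bounds, n, seed)
    proto = protocol or Protocol("acute")
    ys = np.empty(n)
    for i in range(n):
        res = simulate(proto, params=dict(zip(param_names, X[i])))
        ys[i] = outcome_integral(res, outcome, (0.0, res.metadata["horizon_days"]))
    df = prcc(X, ys)
    df.insert(0, "parameter", list(param_names))
    return df.sort_values("rank").reset_index(drop=True)


# ----------------------------------------------------------------------
# outcomes
# ----------------------------------------------------------------------

def outcome_integral(result: SimulationResult, variable: str,
                     window_days: tuple[float, float]) -> float:
    """Trapezoidal integral of a normalized trajectory over a day window."""
    lo, hi = window_days
    t = result.t_days
    if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9:
        raise ValueError(f"window {window_days} outside horizon [{t[0]}, {t[-1]}]")
    if variable not in result.names:
        raise KeyError(f"unknown variable {variable!r}")
    y = result.normalized(variable)
    mask = (t >= lo - 1e-12) & (t <= hi + 1e-12)
    return float(np.trapezoid(y[mask], t[mask]))


def antirecovery_outcome(
    cell: CellModel | None = None,
    params: Mapping[str, float] | None = None,
    config: dict | None = None,
) -> float:
    """Composite anti-recovery score of one macrophage under ischemic stimulus.

    24-hour simulation under hypoxia plus low-dose HMGB1; the composite is
    the ratio of the 24-h integral of the (control-normalized, unlogged)
    M1/M2 product ratio to the 24-h integral of normalized VEGF165a marker
    production, the model's recruitment/angiogenesis-promoting macrophage
    output.  Larger values mean a more inflammatory, less regenerative
    response — worse for perfusion recovery.
    """
    cfg = config or load_config()
    ar = cfg["antirecovery"]
    cm = CellModel(overrides=dict(params)) if params else (cell or default_cell_model())
    rest = cm.resting_state()
    panel0 = cm.marker_panel(rest)
    stim = LigandMilieu(
        {"HMGB1": hmgb1_to_model_input(ar["hmgb1_ng_ml"], cm.params)},
        hypoxia=ar["hypoxia"])
    t = np.linspace(0.0, float(ar["window_hours"]), 97)
    traj = cm.simulate(rest, stim, t)
    panels = cm.marker_panel(traj.states)
    rel = np.maximum(panels, 1e-9 * panel0) / panel0
    n_m1 = 8
    ratio = np.exp(np.log(rel[:, :n_m1]).sum(1) - np.log(rel[:, n_m1:]).sum(1))
    num = float(np.trapezoid(ratio, t))
    from .signaling import MARKERS

    vegfa = rel[:, MARKERS.index("mVEGFa")]
    den = float(np.trapezoid(vegfa, t))
    if den <= 0:
        raise ZeroDivisionError("recruitment-promoting output integral is zero")
    return num / den


# ----------------------------------------------------------------------
# virtual mouse population
# ----------------------------------------------------------------------

@dataclass
class PerfusionEnvelope:
    """Acceptance band for perfusion trajectories at day checkpoints."""

    checkpoints_days: np.ndarray
    lower: dict[str, np.ndarray]  # protocol -> band
    upper: dict[str, np.ndarray]

    def contains(self, protocol: str, t_days: np.ndarray, perf: np.ndarray) -> bool:
        v = np.interp(self.checkpoints_days, t_days, perf)
        return bool(np.all(v >= self.lower[protocol] - 1e-12)
                    and np.all(v <= self.upper[protocol] + 1e-12))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for proto in self.lower:
            for d, lo, hi in zip(self.checkpoints_days, self.lower[proto],
                                 self.upper[proto]):
                rows.append({"protocol": proto, "day": d, "lower": lo, "upper": hi})
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PerfusionEnvelope":
        days = np.sort(df["day"].unique().astype(float))
        lower, upper = {}, {}
        for proto, sub in df.groupby("protocol"):
            sub = sub.sort_values("day")
            lower[proto] = sub["lower"].to_numpy(float)
            upper[proto] = sub["upper"].to_numpy(float)
        return cls(checkpoints_days=days, lower=lower, upper=upper)


@dataclass
class VirtualMouse:
    params: dict[str, float]
    accepted: bool
    deviations: dict[str, float]  # worst band violation per protocol (<=0 inside)


def _resample(base_params: Mapping[str, float], spec: Mapping[str, float],
              rng: np.random.Generator,
              hard_bounds: Mapping[str, tuple[float, float]] | None = None,
              ) -> dict[str, float]:
    out = {}
    for name, fold in spec.items():
        lo, hi = math.log(1.0 / fold), math.log(fold)
        v = base_params[name] * math.exp(rng.uniform(lo, hi))
        if hard_bounds and name in hard_bounds:
            b = hard_bounds[name]
            v = min(max(v, b[0]), b[1])
        out[name] = v
    return out


def generate_vmp(
    envelope: PerfusionEnvelope,
    target_n: int = 50,
    seed: int = 7,
    resample_spec: Mapping[str, float] | None = None,
    budget: int | None = None,
    run_config: dict | None = None,
) -> tuple[list[VirtualMouse], list[VirtualMouse]]:
    """Sample virtual mice until ``target_n`` are accepted (or budget spent).

    Candidates are drawn log-uniformly around the base parameter set per the
    resampling spec; a candidate is accepted when both its acute and gradual
    perfusion trajectories stay inside the envelope at every checkpoint.
    Returns ``(accepted, rejected)``; reproducible for a given seed.
    """
    rc = run_config or load_config()
    spec = dict(resample_spec or rc["vmp"]["resample"])
    budget = budget or int(rc["vmp"]["candidate_budget_factor"]) * target_n
    from .tissue import build_baseline

    base = build_baseline(config=rc)
    bounds = {p.name: (p.lower, p.upper) for p in base.tissue.doc.parameters}
    rng = np.random.default_rng(seed)
    accepted: list[VirtualMouse] = []
    rejected: list[VirtualMouse] = []
    protos = {"acute": Protocol("acute"), "gradual": Protocol("gradual")}
    for _ in range(budget):
        if len(accepted) >= target_n:
            break
        cand = _resample(base.tissue.params, spec, rng, bounds)
        devs = {}
        ok = True
        for name, proto in protos.items():
            res = simulate(proto, params=cand, run_config=rc)
            perf = res.normalized("Perfusion")
            v = np.interp(envelope.checkpoints_days, res.t_days, perf)
            dev = float(np.max(np.maximum(envelope.lower[name] - v,
                                          v - envelope.upper[name])))
            devs[name] = dev
            if dev > 0:
                ok = False
        mouse = VirtualMouse(params=cand, accepted=ok, deviations=devs)
        (accepted if ok else rejected).append(mouse)
    if not accepted:
        nearest = min(rejected, key=lambda m: max(m.deviations.values()),
                      default=None)
        raise RuntimeError(
            "VMP generation accepted no candidates within budget; nearest miss "
            f"deviations: {nearest.deviations if nearest else 'n/a'}")
    return accepted, rejected


# ----------------------------------------------------------------------
# screening
# ----------------------------------------------------------------------

def paired_t(diff: np.ndarray) -> tuple[float, float]:
    """Two-tailed paired t-test statistic and p-value on per-mouse differences."""
    diff = np.asarray(diff, float)
    n = len(diff)
    sd = diff.std(ddof=1)
    if sd == 0:
        return (0.0, 1.0) if np.allclose(diff, 0) else (math.inf, 0.0)
    t = diff.mean() / (sd / math.sqrt(n))
    return float(t), float(2.0 * stats.t.sf(abs(t), n - 1))


def screen(
    vmp: Sequence[VirtualMouse],
    interventions: Sequence[Intervention],
    protocol_mode: str = "acute",
    window_days: tuple[float, float] = (0.0, 35.0),
    run_config: dict | None = None,
    per_mouse: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Per-arm paired comparison of trajectory integrals across the VMP.

    For every virtual mouse the control and intervention arms are simulated
    with identical parameters; the 35-day perfusion and myocyte integrals
    are compared with a two-tailed paired t-test.  Mice whose simulation
    fails in any arm are excluded pairwise (with a log entry in the output).
    """
    if not vmp:
        raise ValueError("empty virtual mouse population")
    rc = run_config or load_config()
    ctrl_perf, ctrl_myo = [], []
    ok_idx = []
    for i, m in enumerate(vmp):
        try:
            res = simulate(Protocol(protocol_mode), params=m.params, run_config=rc)
            ctrl_perf.append(outcome_integral(res, "Perfusion", window_days))
            ctrl_myo.append(outcome_integral(res, "Myo", window_days))
            ok_idx.append(i)
        except Exception:
            continue
    rows = []
    pm_rows = []
    for iv in interventions:
        arm_perf, arm_myo, pairs = [], [], []
        for j, i in enumerate(ok_idx):
            try:
                res = simulate(Protocol(protocol_mode, interventions=(iv,)),
                               params=vmp[i].params, run_config=rc)
                arm_perf.append(outcome_integral(res, "Perfusion", window_days))
                arm_myo.append(outcome_integral(res, "Myo", window_days))
                pairs.append(j)
            except Exception:
                continue
        cp = np.array([ctrl_perf[j] for j in pairs])
        cm = np.array([ctrl_myo[j] for j in pairs])
        ap, am = np.array(arm_perf), np.array(arm_myo)
        for j, pj in enumerate(pairs):
            pm_rows.append({"arm": iv.kind, "mouse": ok_idx[pj],
                            "perfusion_ctrl": cp[j], "perfusion_arm": ap[j],
                            "myocyte_ctrl": cm[j], "myocyte_arm": am[j]})
        tP, pP = paired_t(ap - cp)
        tM, pM = paired_t(am - cm)
        n = len(pairs)
        rows.append({
            "arm": iv.kind,
            "n": n,
            "perfusion_ctrl_mean": cp.mean(),
            "perfusion_ctrl_sem": cp.std(ddof=1) / math.sqrt(n) if n > 1 else 0.0,
            "perfusion_arm_mean": ap.mean(),
            "perfusion_arm_sem": ap.std(ddof=1) / math.sqrt(n) if n > 1 else 0.0,
            "perfusion_delta_mean": (ap - cp).mean(),
            "perfusion_t": tP,
            "perfusion_p": pP,
            "myocyte_ctrl_mean": cm.mean(),
            "myocyte_arm_mean": am.mean(),
            "myocyte_delta_mean": (am - cm).mean(),
            "myocyte_t": tM,
            "myocyte_p": pM,
            "excluded": len(vmp) - n,
        })
    df = pd.DataFrame(rows)
    if per_mouse:
        return df, pd.DataFrame(pm_rows)
    return df
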