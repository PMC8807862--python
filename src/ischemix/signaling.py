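"""Cell-level macrophage signal-transduction model.

Eight ligand pathways (seven base cytokine pathways plus the HMGB1/TLR4 axis)
drive receptor complexes, transcription-factor and kinase nodes, and the
production of 13 phenotype markers (8 M1-like, 5 M2-like).  The model
structure and parameters live in ``models/macrophage_cell.yaml``; this module
compiles it and provides the simulation-facing API.

The HMGB1/TLR4 axis signals through two parallel branches: a PI3K/AKT cascade
and an IRAK/TRAF6 adapter node that feeds the shared NF-kB (via IkB
degradation) and MAPK (ERK/p38/JNK) machinery.  With zero HMGB1 input the
axis species stay at zero and the model reduces exactly to the seven-pathway
base model; none of the marker-production parameters are touched by the axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .modeldef import ModelDocument, load_model

__all__ = [
    "LIGANDS",
    "M1_MARKERS",
    "M2_MARKERS",
    "MARKERS",
    "LigandMilieu",
    "CellModel",
    "CellTrajectory",
    "hmgb1_to_model_input",
    "hmgb1_from_model_input",
]

#: the seven base-pathway ligands plus HMGB1, in milieu order
LIGANDS = ["IFNg", "TNFa", "IL4", "IL10", "IL12", "IL6", "IFNI", "HMGB1"]

M1_MARKERS = ["mTNFa", "mIFNg", "miNOS", "mIL1b", "mIL12", "mCXCL9", "mCXCL10", "mVEGFb"]
M2_MARKERS = ["mIL10", "mIL1Ra", "mVEGFa", "mIL4", "mARG1"]
MARKERS = M1_MARKERS + M2_MARKERS

#: signaling readouts reported for calibration-style outputs
SIGNAL_READOUTS = ["PI3K", "AKT", "ERK", "P38", "JNK", "IkB", "NFkB"]


@dataclass(frozen=True)
class LigandMilieu:
    """Extracellular condition seen by one macrophage cohort.

    Ligand concentrations are in dimensionless model units; ``hypoxia`` is the
    relative oxygen deficit in [0, 1].
    """

    ligands: Mapping[str, float] = field(default_factory=dict)
    hypoxia: float = 0.0

    def __post_init__(self):
        unknown = set(self.ligands) - set(LIGANDS)
        if unknown:
            raise ValueError(f"unknown ligands: {sorted(unknown)}")
        for name, v in self.ligands.items():
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"ligand {name} must be finite and >= 0, got {v}")
        if not 0.0 <= self.hypoxia <= 1.0:
            raise ValueError(f"hypoxia must be in [0, 1], got {self.hypoxia}")

    def vector(self) -> np.ndarray:
        """Milieu as the input vector expected by the compiled rhs."""
        return np.array([self.ligands.get(l, 0.0) for l in LIGANDS] + [self.hypoxia])

    @classmethod
    def zero(cls) -> "LigandMilieu":
        return cls()


@dataclass
class CellTrajectory:
    """Time-gridded intracellular trajectory of one cohort simulation."""

    t: np.ndarray  # hours
    states: np.ndarray  # (n_time, n_species)
    names: list[str]

    def series(self, name: str) -> np.ndarray:
        return self.states[:, self.names.index(name)]

    def normalized(self, name: str) -> np.ndarray:
        """Curve normalized to its own maximum (calibration convention)."""
        y = self.series(name)
        m = y.max()
        if m <= 0:
            raise ValueError(f"cannot max-normalize non-positive series {name!r}")
        return y / m

    def to_frame(self) -> pd.DataFrame:
        """Tidy (time, species, value) export."""
        n_t = len(self.t)
        return pd.DataFrame(
            {
                "time_h": np.repeat(self.t, len(self.names)),
                "species": np.tile(self.names, n_t),
                "value": self.states.ravel(),
            }
        )


def hmgb1_to_model_input(conc_ng_ml: float, params: Mapping[str, float]) -> float:
    """Convert an extracellular HMGB1 concentration (ng/mL) to ligand model units.

    The conversion is linear (``0 -> 0``), with slope ``hmgb1_unit_conv``.
    """
    if conc_ng_ml < 0:
        raise ValueError("HMGB1 concentration must be >= 0")
    return float(params["hmgb1_unit_conv"]) * float(conc_ng_ml)


def hmgb1_from_model_input(units: float, params: Mapping[str, float]) -> float:
    """Inverse of :func:`hmgb1_to_model_input`."""
    if units < 0:
        raise ValueError("model units must be >= 0")
    return float(units) / float(params["hmgb1_unit_conv"])


class CellModel:
    """Compiled cell-level model bound to one parameter vector."""

    def __init__(self, doc: ModelDocument | None = None,
                 overrides: Mapping[str, float] | None = None):
        self.doc = doc if doc is not None else load_model("macrophage_cell")
        self.names = self.doc.dynamic_species
        self.index = {n: i for i, n in enumerate(self.names)}
        self.marker_idx = np.array([self.index[m] for m in MARKERS])
        self.params = {p.name: p.value for p in self.doc.parameters}
        if overrides:
            unknown = set(overrides) - set(self.params)
            if unknown:
                raise KeyError(f"unknown cell parameters: {sorted(unknown)}")
            self._check_bounds(overrides)
            self.params.update(overrides)
        self._pvec = self.doc.param_vector(overrides)
        self._rhs = self.doc.compile_rhs()

    def _check_bounds(self, overrides: Mapping[str, float]) -> None:
        bounds = {p.name: (p.lower, p.upper) for p in self.doc.parameters}
        for k, v in overrides.items():
            lo, hi = bounds[k]
            if not lo <= v <= hi:
                raise ValueError(f"parameter {k}={v} outside declared bounds [{lo}, {hi}]")

    # -- core API ------------------------------------------------------

    def rhs(self, state: np.ndarray, milieu: LigandMilieu | np.ndarray) -> np.ndarray:
        """Time derivative of the intracellular state.

        ``state`` may be a single vector or a ``(n_species, m)`` batch sharing
        one milieu.  Inputs are validated for finiteness and nonnegativity.
        """
        y = np.asarray(state, float)
        if not np.all(np.isfinite(y)) or np.any(y < -1e-12):
            raise ValueError("state must be finite and nonnegative")
        u = milieu.vector() if isinstance(milieu, LigandMilieu) else np.asarray(milieu, float)
        if not np.all(np.isfinite(u)) or np.any(u < 0):
            raise ValueError("milieu must be finite and nonnegative")
        return self._rhs(y, u, self._pvec)

    def resting_state(self, milieu: LigandMilieu | None = None,
                      tol: float = 1e-10, t_relax: float = 4000.0) -> np.ndarray:
        """Fixed point under a constant (default zero) milieu.

        Relaxes the declared initial conditions for ``t_relax`` hours, then
        polishes with a Newton solve.  Raises if no fixed point is found
        within the iteration budget.
        """
        m = milieu if milieu is not None else LigandMilieu.zero()
        u = m.vector()
        y0 = self.doc.initial_state()
        sol = solve_ivp(lambda t, y: self._rhs(y, u, self._pvec), (0, t_relax), y0,
                        method="LSODA", rtol=1e-10, atol=1e-12)
        if not sol.success:
            raise RuntimeError(f"relaxation toward resting state failed: {sol.message}")
        res = root(lambda y: self._rhs(y, u, self._pvec), sol.y[:, -1], method="hybr",
                   tol=1e-13)
        y = res.x if res.success else sol.y[:, -1]
        y = np.maximum(y, 0.0)
        d = self._rhs(y, u, self._pvec)
        if np.max(np.abs(d)) > tol:
            raise RuntimeError(
                f"no resting state within tolerance: max|dy/dt| = {np.max(np.abs(d)):.3e}"
            )
        return y

    def simulate(
        self,
        state0: np.ndarray,
        milieu: LigandMilieu | Callable[[float], np.ndarray],
        t_grid: np.ndarray,
        method: str = "LSODA",
        rtol: float = 1e-6,
        atol: float = 1e-9,
    ) -> CellTrajectory:
        """Integrate one cohort over ``t_grid`` (hours, strictly increasing).

        ``milieu`` is either a constant :class:`LigandMilieu` or a callable
        ``t -> input vector`` (ligands + hypoxia).
        """
        t_grid = np.asarray(t_grid, float)
        if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
            raise ValueError("t_grid must be strictly increasing with >= 2 points")
        if isinstance(milieu, LigandMilieu):
            u = milieu.vector()
            fun = lambda t, y: self._rhs(y, u, self._pvec)
        else:
            fun = lambda t, y: self._rhs(y, np.asarray(milieu(t), float), self._pvec)
        sol = solve_ivp(fun, (t_grid[0], t_grid[-1]), np.asarray(state0, float),
                        method=method, t_eval=t_grid, rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(
                f"cell solver failure at t={sol.t[-1] if len(sol.t) else t_grid[0]:.3f} h: "
                f"{sol.message}; last state: {sol.y[:, -1] if sol.y.size else state0}"
            )
        return CellTrajectory(t=sol.t, states=sol.y.T.copy(), names=list(self.names))

    def simulate_batch(
        self,
        states0: np.ndarray,
        milieu_fn: Callable[[float], np.ndarray],
        t_span: tuple[float, float],
        t_eval: np.ndarray | None = None,
        method: str = "RK45",
        rtol: float = 1e-6,
        atol: float = 1e-9,
    ) -> np.ndarray:
        """Integrate ``m`` cohorts sharing one milieu trajectory.

        ``states0`` has shape ``(m, n_species)``.  Returns end states of the
        same shape (or ``(len(t_eval), m, n)`` when ``t_eval`` is given).
        All cohorts are stacked into one ODE system; the compiled rhs
        broadcasts across the batch axis.
        """
        m, n = states0.shape

        def fun(t, yflat):
            y = yflat.reshape(m, n).T  # (n_species, m)
            return self._rhs(y, np.asarray(milieu_fn(t), float), self._pvec).T.ravel()

        sol = solve_ivp(fun, t_span, states0.ravel(), method=method,
                        t_eval=t_eval, rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"batched cell solver failure: {sol.message}")
        if t_eval is None:
            return sol.y[:, -1].reshape(m, n)
        return sol.y.T.reshape(len(sol.t), m, n)

    # -- readouts ------------------------------------------------------

    def marker_panel(self, state: np.ndarray) -> np.ndarray:
        """13-entry marker panel (M1 first, then M2), clipped at zero."""
        state = np.asarray(state, float)
        return np.maximum(state[..., self.marker_idx], 0.0)

    def marker_readout(self, traj: CellTrajectory) -> pd.DataFrame:
        """Marker panel time series extracted from a trajectory by index map."""
        panels = self.marker_panel(traj.states)
        return pd.DataFrame(panels, index=pd.Index(traj.t, name="time_h"), columns=MARKERS)


@lru_cache(maxsize=1)
def default_cell_model() -> CellModel:
    """Shared read-only instance with packaged default parameters."""
    return CellModel()
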