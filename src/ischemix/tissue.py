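"""Tissue-level component: cell populations, cytokines, perfusion, oxygen.

The governing structure (34 species, 23 reactions and rules) is declared in
``models/tissue.yaml``.  This module compiles it, exposes the individual
rate-law building blocks (Hill factors, necrotic fluxes, cytokine sources,
the perfusion rate) for direct inspection and testing, and constructs the
pre-ischemia baseline: a handful of balance constants are derived so the
declared baseline state is an exact steady state of the full coupled system,
including the macrophage-cohort secretion summary.

Conventions: time in hours; cell populations and perfusion/oxygen are
normalized to the pre-HLI baseline (= 1); cytokine pools in dimensionless
concentration units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .config import load_config
from .modeldef import ModelDocument, load_model
from .signaling import LIGANDS, MARKERS, CellModel, LigandMilieu, default_cell_model

__all__ = [
    "hill",
    "TissueModel",
    "Baseline",
    "build_baseline",
    "necrotic_flux",
    "cytokine_sources",
    "perfusion_rate",
    "derived_observables",
]

#: tissue cytokine pools fed by macrophage marker secretion, with the marker
#: species that source each pool
SECRETED_POOLS = {
    "IFNg": ["mIFNg"],
    "TNFa": ["mTNFa"],
    "IL10": ["mIL10"],
    "IL4": ["mIL4"],
    "VEGFa": ["mVEGFa"],
    "VEGFb": ["mVEGFb"],
    "CXCL": ["mCXCL9", "mCXCL10"],
}
SEC_INPUTS = ["sec_IFNg", "sec_TNFa", "sec_IL10", "sec_IL4", "sec_VEGFa", "sec_VEGFb",
              "sec_CXCL", "sec_MMP9"]


def hill(x: float | np.ndarray, K: float, n: float, mode: str = "activation"):
    """Hill-type regulatory factor.

    ``activation`` returns ``x**n / (K**n + x**n)``; ``inhibition`` returns
    ``K**n / (K**n + x**n)``.
    """
    if K <= 0 or n <= 0:
        raise ValueError("hill requires K > 0 and n > 0")
    x = np.asarray(x, float)
    if np.any(x < 0):
        raise ValueError("hill requires x >= 0")
    xn = x**n
    Kn = K**n
    if mode == "activation":
        out = xn / (Kn + xn)
    elif mode == "inhibition":
        out = Kn / (Kn + xn)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(out) if out.ndim == 0 else out


class TissueModel:
    """Compiled tissue component bound to one parameter assignment."""

    def __init__(self, doc: ModelDocument | None = None,
                 overrides: Mapping[str, float] | None = None):
        self.doc = doc if doc is not None else load_model("tissue")
        self.names = self.doc.dynamic_species
        self.index = {n: i for i, n in enumerate(self.names)}
        self.params = {p.name: p.value for p in self.doc.parameters}
        if overrides:
            unknown = set(overrides) - set(self.params)
            if unknown:
                raise KeyError(f"unknown tissue parameters: {sorted(unknown)}")
            self.params.update(overrides)
        self._pvec = self.doc.param_vector(dict(overrides or {}))
        self._rhs = self.doc.compile_rhs()
        assert list(self.doc.inputs) == SEC_INPUTS

    def with_params(self, overrides: Mapping[str, float]) -> "TissueModel":
        merged = dict(self.params)
        merged.update(overrides)
        tm = object.__new__(TissueModel)
        tm.doc = self.doc
        tm.names = self.names
        tm.index = self.index
        tm.params = merged
        tm._pvec = self.doc.param_vector(merged)
        tm._rhs = self._rhs
        return tm

    def rhs(self, state: np.ndarray, secretion: np.ndarray) -> np.ndarray:
        """Derivative of the tissue state given the macrophage secretion summary.

        ``secretion`` follows :data:`SEC_INPUTS` order (total production rates
        of the macrophage-sourced cytokine pools, concentration units per hour).
        """
        y = np.asarray(state, float)
        if not np.all(np.isfinite(y)):
            raise FloatingPointError(
                f"non-finite tissue state: "
                f"{dict(zip(self.names, y))}"
            )
        if np.any(y < -1e-9):
            raise ValueError("tissue state must be nonnegative")
        return self._rhs(y, np.asarray(secretion, float), self._pvec)

    def state_dict(self, y: np.ndarray) -> dict[str, float]:
        return dict(zip(self.names, np.asarray(y, float)))


def necrotic_flux(state: Mapping[str, float], params: Mapping[str, float]) -> dict[str, float]:
    """Necrosis rates of myocytes and ECs.

    Necrotic death is proportional to the perfusion deficit ``max(0, 1 - P)``
    and clamps to zero under hyperemia (P >= 1).
    """
    deficit = max(0.0, 1.0 - float(state["Perfusion"]))
    return {
        "Myo": params["k2"] * deficit * float(state["Myo"]),
        "EC": params["k10"] * deficit * float(state["EC"]),
    }


def cytokine_sources(
    state: Mapping[str, float],
    params: Mapping[str, float],
    necrotic_rates: Mapping[str, float],
    mac_secretion: Mapping[str, float],
) -> dict[str, float]:
    """Production (source-only) rates of the principal cytokine pools.

    HMGB1 is sourced exclusively by necrotic (never apoptotic) myocyte and EC
    death; IFN-gamma and TNF-alpha come exclusively from the macrophage
    secretion summary; the VEGF isoforms are sourced by myocytes, ECs and
    macrophages.
    """
    hyp = max(0.0, 1.0 - float(state["Oxygen"]))
    cells = float(state["Myo"]) + float(state["EC"])
    return {
        "HMGB1": params["k_h_src"] * params["hmgb1_eff"]
        * (necrotic_rates["Myo"] + necrotic_rates["EC"]),
        "IFNg": mac_secretion.get("sec_IFNg", 0.0) + params["ifng_infusion"],
        "TNFa": mac_secretion.get("sec_TNFa", 0.0),
        "IL10": mac_secretion.get("sec_IL10", 0.0),
        "IL4": mac_secretion.get("sec_IL4", 0.0),
        "VEGF165a": params["k14"] * cells
        * (params["b_v"] + params["w_vh"] * hill(hyp, params["kb2"], 2))
        + mac_secretion.get("sec_VEGFa", 0.0) + params["vegfa_infusion"],
        "VEGF165b": params["k14b"] * cells + mac_secretion.get("sec_VEGFb", 0.0),
    }


def perfusion_rate(
    state: Mapping[str, float],
    params: Mapping[str, float],
    ec_net_growth: float,
) -> float:
    """dP/dt: leakiness-weighted angiogenic term plus arteriogenic term.

    The angiogenic contribution follows net EC growth (only productive, i.e.
    positive, net growth builds perfusable vessels and only the non-leaky
    fraction conducts); the arteriogenic contribution follows the collateral
    remodeling state.  Both shut off as the perfusion deficit closes, so the
    pre-HLI baseline is a fixed point.
    """
    deficit = max(0.0, 1.0 - float(state["Perfusion"]))
    angio = params["nonleakiness"] * params["k13"] * max(0.0, ec_net_growth) * deficit
    arterio = params["k8"] * float(state["Arterio"]) * deficit
    return angio + arterio


def derived_observables(
    state: Mapping[str, float],
    baseline: Mapping[str, float],
    params: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Figure-convention observables, normalized to the pre-HLI baseline.

    ``arterioles_per_fiber`` is the EC-to-myocyte population ratio; when
    ``params`` is given the instantaneous total necrosis rate (myocytes plus
    ECs, absolute units, zero at baseline) is included as ``necrosis_rate``.
    """
    M = float(state["Myo"])
    if M <= 0:
        raise ZeroDivisionError("arterioles-per-fiber ratio undefined: Myo = 0")
    ratio = float(state["EC"]) / M
    ratio0 = float(baseline["EC"]) / float(baseline["Myo"])
    out = {
        "arterioles_per_fiber": ratio / ratio0,
        "perfusion": float(state["Perfusion"]) / float(baseline["Perfusion"]),
        "oxygenation": float(state["Oxygen"]) / float(baseline["Oxygen"]),
    }
    if params is not None:
        nec = necrotic_flux(state, params)
        out["necrosis_rate"] = nec["Myo"] + nec["EC"]
    return out


@dataclass
class Baseline:
    """Self-consistent pre-ischemia operating point of the coupled model.

    Holds the balanced tissue parameters and initial state, the control-
    condition milieu, the macrophage resting state and marker panel, and the
    derived per-marker secretion coefficients that make the baseline an exact
    fixed point of the tissue + cohort system.
    """

    tissue: TissueModel
    cell: CellModel
    y0: np.ndarray                 # tissue initial state (dynamic species)
    milieu0: LigandMilieu
    rest_state: np.ndarray         # macrophage control-condition fixed point
    marker0: np.ndarray            # 13-marker control panel
    k_sec: dict[str, float]        # pool -> secretion coefficient
    mmp9_per_cell: float
    milieu_conv: dict[str, float]

    def secretion_from(self, total_weighted_markers: np.ndarray,
                       mac_count: float, params: Mapping[str, float]) -> np.ndarray:
        """Secretion-summary vector (SEC_INPUTS order) from a size-weighted
        marker sum and the current macrophage count."""
        midx = {m: i for i, m in enumerate(MARKERS)}
        out = []
        for pool, markers in SECRETED_POOLS.items():
            tot = sum(total_weighted_markers[midx[m]] for m in markers)
            out.append(self.k_sec[pool] * tot)
        out.append(self.mmp9_per_cell * mac_count)
        return np.array(out)

    def milieu_from_state(self, tissue_state: Mapping[str, float]) -> LigandMilieu:
        """Ligand milieu seen by cohorts, derived from the tissue state."""
        conv = self.milieu_conv
        lig = {
            "IFNg": conv["IFNg"] * float(tissue_state["IFNg"]),
            "TNFa": conv["TNFa"] * float(tissue_state["TNFa"]),
            "IL4": conv["IL4"] * float(tissue_state["IL4"]),
            "IL10": conv["IL10"] * float(tissue_state["IL10"]),
            "IL12": conv["IL12"] * self._boundary("IL12"),
            "IL6": conv["IL6"] * self._boundary("IL6"),
            "IFNI": conv["IFNI"] * self._boundary("IFN_I"),
            "HMGB1": conv["HMGB1"] * float(tissue_state["HMGB1"]),
        }
        hyp = min(1.0, max(0.0, 1.0 - float(tissue_state["Oxygen"])))
        return LigandMilieu(lig, hypoxia=hyp)

    def _boundary(self, name: str) -> float:
        return next(s.initial for s in self.tissue.doc.species if s.name == name)


def build_baseline(
    tissue_overrides: Mapping[str, float] | None = None,
    cell_model: CellModel | None = None,
    config: dict | None = None,
) -> Baseline:
    """Construct the balanced pre-HLI operating point.

    Balance constants derived here (at the *default* parameter values, then
    frozen): myoblast supply ``k12`` and pool size, the EC growth constant
    ``g9``, the basal recruitment drive ``b_rec``, the normoxic VEGF secretion
    terms ``b_v``/``k14b``, the MCP1/ECM equilibria, and the per-marker
    secretion coefficients.  Parameter overrides are applied *after* balancing
    so perturbation studies (sensitivity analysis, virtual mice) see their
    full dynamic effect.
    """
    cfg = config or load_config()
    cell = cell_model if cell_model is not None else default_cell_model()
    tm = TissueModel()
    p = dict(tm.params)
    pools = dict(cfg["baseline_pools"])
    conv = dict(cfg["milieu_conversion"])
    boundary = {s.name: s.initial for s in tm.doc.species if s.boundary}

    # control-condition milieu and macrophage fixed point
    milieu0 = LigandMilieu(
        {
            "IFNg": conv["IFNg"] * pools["IFNg"],
            "TNFa": conv["TNFa"] * pools["TNFa"],
            "IL4": conv["IL4"] * pools["IL4"],
            "IL10": conv["IL10"] * pools["IL10"],
            "IL12": conv["IL12"] * boundary["IL12"],
            "IL6": conv["IL6"] * boundary["IL6"],
            "IFNI": conv["IFNI"] * boundary["IFN_I"],
            "HMGB1": 0.0,
        },
        hypoxia=0.0,
    )
    rest = cell.resting_state(milieu0)
    marker0 = cell.marker_panel(rest)
    m0 = dict(zip(MARKERS, marker0))
    if np.any(marker0 <= 0):
        raise RuntimeError("control marker panel must be strictly positive")

    # secretion coefficients so the baseline pools are steady with Mac = 1
    share_a = cfg["secretion"]["mac_share_vegfa"]
    share_b = cfg["secretion"]["mac_share_vegfb"]
    k_sec = {
        "IFNg": p["d_ifng"] * pools["IFNg"] / m0["mIFNg"],
        "TNFa": p["d_tnfa"] * pools["TNFa"] / m0["mTNFa"],
        "IL10": p["d_il10"] * pools["IL10"] / m0["mIL10"],
        "IL4": p["d_il4"] * pools["IL4"] / m0["mIL4"],
        "VEGFa": share_a * p["k15"] * pools["VEGF165a"] / m0["mVEGFa"],
        "VEGFb": share_b * p["k15b"] * pools["VEGF165b"] / m0["mVEGFb"],
        "CXCL": p["d_cxcl"] * pools["CXCL9_10"] / (m0["mCXCL9"] + m0["mCXCL10"]),
    }
    mmp9_per_cell = cfg["secretion"]["mmp9_per_cell"]
    pools["MMP9"] = mmp9_per_cell * 1.0 / p["d_mmp9"]

    # myocyte/EC secretion terms balancing the non-macrophage VEGF share
    p["b_v"] = (1.0 - share_a) * p["k15"] * pools["VEGF165a"] / (p["k14"] * 2.0)
    p["k14b"] = (1.0 - share_b) * p["k15b"] * pools["VEGF165b"] / 2.0

    # MCP1 and ECM equilibria
    mcp_src = p["k_mcp0"] * (p["b_mcp"]
                             + p["w_mcp_t"] * hill(pools["TNFa"], p["K_mcp_t"], 1))
    pools["MCP1"] = mcp_src / p["d_mcp"]
    rel = p["koff_ecm"] * (1 + p["w_mmp_rel"] * hill(pools["MMP9"], p["K_mmp_rel"], 1))
    sites_tot = 1.0
    bound = sites_tot * p["kon_ecm"] * pools["VEGF165a"] / (
        rel + p["kon_ecm"] * pools["VEGF165a"])
    ecm_free = sites_tot - bound

    # myocyte balance: regeneration flux == apoptotic removal at baseline
    apop0 = (p["kd1"] * 1.0
             * (1 + p["w_ap_tnf"] * hill(pools["TNFa"], p["K_ap_tnf"], 2))
             * (1 + p["w_ap_hyp"] * hill(1.0, p["K_ap_o"], 2, "inhibition")))
    g_regen0 = (hill(1.0, p["K_rg_o"], 2)
                * (1 + p["w_rg_v"] * hill(pools["VEGF165a"], p["K_rg_v"], 1))
                * max(0.0, 1 - 1.0 / p["cap_myo"]))
    myoblast0 = apop0 / (p["k1"] * g_regen0)
    p["k12"] = apop0 / hill(1.0, p["K_mb_o"], 2)

    # EC balance
    removal0 = (p["kc9"] * 1.0
                * (1 + p["w_ec_tnf"] * hill(pools["TNFa"], p["ka10"], 2))
                * (1 + p["w_ec_il1"] * hill(boundary["IL1b"], p["K_ec_il1"], 1)
                   * hill(boundary["IL1Ra"], p["K_ec_il1ra"], 1, "inhibition")))
    growth_gate = (hill(pools["VEGF165a"], p["kb9"], 1)
                   * hill(pools["VEGF165b"], p["K_vb_inh"], 1, "inhibition")
                   * boundary["NO"] * p["endo_fn"] * max(0.0, 1 - 1.0 / p["cap_ec"]))
    p["g9"] = removal0 / (p["k9"] * growth_gate)

    # macrophage balance: recruitment == removal at Mac = 1
    k7_eff = p["k7"] * (1 + p["w_rem_tgfb"] * hill(boundary["TGFb"], p["K_rem_tgfb"], 1))
    drive = (p["w_rec_mcp"] * hill(pools["MCP1"], p["K_rec_mcp"], 1)
             + p["w_rec_hmgb1"] * 0.0
             + p["w_rec_cxcl"] * p["cxcr3_eff"] * hill(pools["CXCL9_10"], p["K_rec_cx"], 1)
             + p["w_rec_ifng"] * hill(pools["IFNg"], p["K_rec_ifng"], 1)
             + p["w_rec_vegf"] * hill(pools["VEGF165a"], p["K_rec_v"], 1))
    p["b_rec"] = k7_eff * 1.0 / p["k3"] - drive
    if p["b_rec"] <= 0:
        raise RuntimeError("baseline recruitment drive went nonpositive")

    if tissue_overrides:
        p.update(tissue_overrides)
    tm = TissueModel(overrides={k: v for k, v in p.items() if k in tm.params})

    y0 = tm.doc.initial_state()
    idx = tm.index
    y0[idx["Myoblast"]] = myoblast0
    y0[idx["MCP1"]] = pools["MCP1"]
    y0[idx["MMP9"]] = pools["MMP9"]
    y0[idx["VEGF165a"]] = pools["VEGF165a"]
    y0[idx["VEGF165b"]] = pools["VEGF165b"]
    y0[idx["VEGF_ECM"]] = bound
    y0[idx["ECM_free"]] = ecm_free
    y0[idx["IFNg"]] = pools["IFNg"]
    y0[idx["TNFa"]] = pools["TNFa"]
    y0[idx["IL10"]] = pools["IL10"]
    y0[idx["IL4"]] = pools["IL4"]
    y0[idx["CXCL9_10"]] = pools["CXCL9_10"]

    return Baseline(
        tissue=tm, cell=cell, y0=y0, milieu0=milieu0, rest_state=rest,
        marker0=marker0, k_sec=k_sec, mmp9_per_cell=mmp9_per_cell,
        milieu_conv=conv,
    )
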