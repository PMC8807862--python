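"""Cell-level macrophage model: resting state, stimulus responses, readouts."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from ischemix.modeldef import load_model
from ischemix.signaling import (CellModel, LigandMilieu, M1_MARKERS, MARKERS,
                                hmgb1_from_model_input, hmgb1_to_model_input)


class TestLigandMilieu:
    def test_rejects_negative_and_unknown(self):
        with pytest.raises(ValueError):
            LigandMilieu({"TNFa": -0.1})
        with pytest.raises(ValueError):
            LigandMilieu({"nosuch": 0.1})
        with pytest.raises(ValueError):
            LigandMilieu({}, hypoxia=1.2)

    def test_vector_order(self):
        m = LigandMilieu({"HMGB1": 2.0}, hypoxia=0.5)
        v = m.vector()
        assert v[-2] == 2.0 and v[-1] == 0.5 and v[:-2].sum() == 0


class TestRestingState:
    def test_zero_stimulus_fixed_point(self, cell, rest_state):
        d = cell.rhs(rest_state, LigandMilieu.zero())
        assert np.max(np.abs(d)) < 1e-8
        assert np.all(rest_state >= 0)

    def test_steady_state_persists_24h(self, cell, rest_state):
        traj = cell.simulate(rest_state, LigandMilieu.zero(),
                             np.linspace(0, 24, 25))
        rel = np.abs(traj.states - rest_state[None, :]) / (
            np.abs(rest_state[None, :]) + 1e-12)
        assert rel[:, rest_state > 1e-9].max() < 1e-6

    def test_agrees_with_long_fine_step_explicit_integration(self, cell, rest_state):
        # independent oracle: plain RK45 at tight tolerance out to 1000 h
        u = LigandMilieu.zero().vector()
        sol = solve_ivp(lambda t, y: cell._rhs(y, u, cell._pvec), (0, 1000.0),
                        cell.doc.initial_state(), method="RK45",
                        rtol=1e-10, atol=1e-12, max_step=1.0)
        ref = sol.y[:, -1]
        mask = np.abs(ref) > 1e-9
        assert np.max(np.abs(rest_state[mask] - ref[mask]) / np.abs(ref[mask])) < 1e-4

    def test_unique_within_physiological_box_by_multistart(self, cell, rng):
        u = LigandMilieu.zero().vector()
        target = cell.resting_state()
        for _ in range(3):
            y0 = rng.uniform(0, 1, len(target))
            sol = solve_ivp(lambda t, y: cell._rhs(np.maximum(y, 0), u, cell._pvec),
                            (0, 4000.0), y0, method="LSODA", rtol=1e-10, atol=1e-12)
            end = sol.y[:, -1]
            mask = np.abs(target) > 1e-9
            assert np.max(np.abs(end[mask] - target[mask])
                          / np.abs(target[mask])) < 1e-5


class TestRhs:
    def test_rejects_nan_and_negative(self, cell, rest_state):
        bad = rest_state.copy()
        bad[0] = np.nan
        with pytest.raises(ValueError):
            cell.rhs(bad, LigandMilieu.zero())
        bad = rest_state.copy()
        bad[0] = -0.5
        with pytest.raises(ValueError):
            cell.rhs(bad, LigandMilieu.zero())

    def test_hmgb1_activates_both_parallel_branches(self, cell, rest_state):
        """HMGB1 input must drive both PI3K/AKT and IRAK/TRAF6 -> IkB loss."""
        mil = LigandMilieu({"HMGB1": 1.0})
        # give the receptor complex a brief moment to form, then inspect rhs
        traj = cell.simulate(rest_state, mil, np.linspace(0, 0.25, 6))
        d = cell.rhs(traj.states[-1], mil)
        assert d[cell.index["PI3K"]] > 0
        assert d[cell.index["IRAK"]] > 0
        assert d[cell.index["IkB"]] < 0  # net IkB degradation flux engaged
        # and at 6 h both branches are substantially activated
        late = cell.simulate(rest_state, mil, np.linspace(0, 6, 25)).states[-1]
        assert late[cell.index["PI3K"]] > 10 * rest_state[cell.index["PI3K"]] + 0.05
        assert late[cell.index["IkB"]] < 0.5 * rest_state[cell.index["IkB"]]

    def test_doubling_binding_constant_doubles_binding_flux(self, rest_state):
        """Term-by-term check against the declared mass-action law."""
        doc = load_model("macrophage_cell")
        state = dict(zip(doc.dynamic_species, rest_state))
        inputs = {"L_hmgb1": 1.0}
        f1 = doc.evaluate_processes(state, inputs)["tlr4_bind"]
        f2 = doc.evaluate_processes(state, inputs,
                                    {"kon_tlr4": 2 * doc.param_value("kon_tlr4")}
                                    )["tlr4_bind"]
        assert f2 == pytest.approx(2 * f1, rel=1e-12)
        kon, rtot = doc.param_value("kon_tlr4"), doc.param_value("rtot_tlr4")
        c = state["C_tlr4"]
        assert f1 == pytest.approx(kon * 1.0 * (rtot - c), rel=1e-12)


class TestSimulateCell:
    def test_rejects_bad_time_grid(self, cell, rest_state):
        with pytest.raises(ValueError):
            cell.simulate(rest_state, LigandMilieu.zero(), np.array([0.0, 0.0, 1.0]))

    def test_max_normalized_curves_peak_at_one(self, cell, rest_state):
        traj = cell.simulate(rest_state, LigandMilieu({"HMGB1": 1.0}),
                             np.linspace(0, 24, 97))
        for name in ["PI3K", "ERK"]:
            y = traj.normalized(name)
            assert y.max() == pytest.approx(1.0)
            assert y.min() >= 0

    def test_stiff_solver_matches_fine_step_explicit_oracle(self, cell, rest_state):
        mil = LigandMilieu({"HMGB1": 1.0}, hypoxia=0.5)
        t = np.linspace(0, 6, 13)
        a = cell.simulate(rest_state, mil, t, method="LSODA",
                          rtol=1e-8, atol=1e-11)
        u = mil.vector()
        sol = solve_ivp(lambda tt, y: cell._rhs(y, u, cell._pvec), (0, 6),
                        rest_state, method="RK45", t_eval=t,
                        rtol=1e-10, atol=1e-12, max_step=0.01)
        scale = np.abs(sol.y.T).max(axis=0) + 1e-9
        rel = np.abs(a.states - sol.y.T) / scale[None, :]
        assert rel.max() < 1e-3

    def test_nonnegative_along_trajectory(self, cell, rest_state, rng):
        for _ in range(2):
            lig = {l: float(v) for l, v in
                   zip(["IFNg", "TNFa", "IL4", "IL10", "HMGB1"],
                       rng.uniform(0, 1, 5))}
            traj = cell.simulate(rest_state,
                                 LigandMilieu(lig, hypoxia=float(rng.uniform(0, 1))),
                                 np.linspace(0, 48, 49))
            assert traj.states.min() > -1e-9

    def test_step_off_relaxes_toward_rest(self, cell, rest_state):
        mil = LigandMilieu({"HMGB1": 1.0})
        stim = cell.simulate(rest_state, mil, np.linspace(0, 6, 13))
        relax = cell.simulate(stim.states[-1], LigandMilieu.zero(),
                              np.linspace(0, 96, 97))
        for name in ["C_tlr4", "PI3K", "AKT", "IRAK"]:
            y = relax.series(name)
            assert np.all(np.diff(y) <= 1e-9), name  # monotone decay
            assert y[-1] < 0.05 * y[0] + 1e-9


class TestMarkerReadout:
    def test_identity_with_declared_production_states(self, cell, rest_state):
        traj = cell.simulate(rest_state, LigandMilieu({"HMGB1": 0.5}),
                             np.linspace(0, 12, 13))
        panel = cell.marker_readout(traj)
        for m in MARKERS:
            np.testing.assert_array_equal(panel[m].to_numpy(), traj.series(m))

    def test_zero_stimulus_panel_constant(self, cell, rest_state):
        traj = cell.simulate(rest_state, LigandMilieu.zero(),
                             np.linspace(0, 24, 13))
        panel = cell.marker_readout(traj)
        base = cell.marker_panel(rest_state)
        assert np.max(np.abs(panel.to_numpy() - base[None, :])
                      / (base[None, :])) < 1e-6

    def test_control_panel_strictly_positive(self, cell, rest_state):
        assert np.all(cell.marker_panel(rest_state) > 0)

    def test_tnfa_rises_before_il10_under_sustained_hmgb1(self, cell, rest_state):
        """Under sustained HMGB1 stimulation (the calibration setting) the
        TNF-alpha marker response rises earlier than the IL-10 response:
        it reaches both half and 90% of its window maximum sooner."""
        sus = cell.simulate(rest_state, LigandMilieu({"HMGB1": 1.0}),
                            np.linspace(0, 48, 193))

        def t_frac(name, frac):
            y = sus.series(name)
            yn = (y - y[0]) / (y.max() - y[0])
            return sus.t[np.argmax(yn >= frac)]

        assert t_frac("mTNFa", 0.5) < t_frac("mIL10", 0.5)
        assert t_frac("mTNFa", 0.9) < t_frac("mIL10", 0.9)


class TestBaseModelEquivalence:
    def test_zero_hmgb1_reduces_to_seven_pathway_base_model(self, cell, rest_state):
        """The HMGB1/TLR4 extension must not perturb base-model behavior:
        with zero HMGB1 the axis species stay at zero and trajectories match
        a seven-pathway document with the axis reactions removed."""
        doc = load_model("macrophage_cell")
        from ischemix.modeldef import ModelDocument

        base_doc = ModelDocument(
            name="base7",
            species=doc.species,
            parameters=doc.parameters,
            processes=[p for p in doc.processes if p.module != "hmgb1_tlr4"],
            inputs=doc.inputs,
        )
        disabled = CellModel(doc=base_doc)
        mil = LigandMilieu({"IFNg": 0.3, "TNFa": 0.3, "IL4": 0.2}, hypoxia=0.4)
        t = np.linspace(0, 48, 49)
        a = cell.simulate(rest_state, mil, t)
        b = disabled.simulate(rest_state, mil, t)
        axis = [cell.index[n] for n in ["C_tlr4", "PI3K", "AKT", "IRAK"]]
        assert np.abs(a.states[:, axis]).max() < 1e-9
        scale = np.abs(a.states).max(axis=0) + 1e-9
        assert (np.abs(a.states - b.states) / scale[None, :]).max() < 1e-6


class TestUnitConversion:
    def test_zero_and_linearity(self, cell):
        p = cell.params
        assert hmgb1_to_model_input(0.0, p) == 0.0
        for c in [0.5, 7.3, 120.0]:
            assert hmgb1_to_model_input(2 * c, p) == pytest.approx(
                2 * hmgb1_to_model_input(c, p), rel=1e-14)

    def test_round_trip_identity(self, cell):
        p = cell.params
        for units in [0.01, 0.5, 3.0]:
            back = hmgb1_to_model_input(hmgb1_from_model_input(units, p), p)
            assert back == pytest.approx(units, rel=1e-12)

    def test_negative_rejected(self, cell):
        with pytest.raises(ValueError):
            hmgb1_to_model_input(-1.0, cell.params)
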