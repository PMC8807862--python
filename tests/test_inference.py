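"""Calibration loss and optimizer, LHS/PRCC, outcomes, VMP, screening."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ischemix.fixtures import FixtureSpec, make_fixture_dataset
from ischemix.inference import (CalibrationDataset, PerfusionEnvelope,
                                VirtualMouse, antirecovery_outcome,
                                generate_vmp, lhs, loss, outcome_integral,
                                paired_t, pattern_search_fit, prcc, screen)
from ischemix.modeldef import load_model
from ischemix.multiscale import Intervention, Protocol, simulate


class TestLoss:
    def test_zero_on_self_generated_noise_free_data(self):
        ds = make_fixture_dataset(FixtureSpec(noise=0.0, seed=0))
        assert loss({}, ds) < 1e-12

    def test_invariant_to_target_max_renormalization(self):
        """Both simulation and targets are max-normalized, so re-normalizing
        an already-normalized target is a no-op on the loss."""
        ds = make_fixture_dataset(FixtureSpec(noise=0.05, seed=3))
        renorm = CalibrationDataset(
            curves={cid: (t, v / np.max(np.abs(v)) * np.max(np.abs(v)))
                    for cid, (t, v) in ds.curves.items()},
            stimulus_hmgb1=ds.stimulus_hmgb1, hypoxia=ds.hypoxia)
        assert loss({}, renorm) == pytest.approx(loss({}, ds), rel=1e-12)

    def test_perturbing_informative_parameter_increases_loss(self):
        ds = make_fixture_dataset(FixtureSpec(noise=0.0, seed=0))
        doc = load_model("macrophage_cell")
        base = loss({}, ds)
        bumped = loss({"kon_tlr4": 1.5 * doc.param_value("kon_tlr4")}, ds)
        assert bumped > base + 1e-4

    def test_failure_returns_inf(self):
        ds = make_fixture_dataset(FixtureSpec(noise=0.0, seed=0))
        assert loss({"kon_tlr4": -5.0}, ds) == np.inf


class TestPatternSearch:
    def test_recovers_interior_quadratic_minimum(self):
        target = np.array([0.3, -0.2])
        res = pattern_search_fit(lambda x: float(np.sum((x - target) ** 2)),
                                 [(-1, 1), (-1, 1)], np.zeros(2), seed=0,
                                 budget=500)
        np.testing.assert_allclose(res["x"], target, atol=1e-3)
        assert res["loss"] < 1e-6

    def test_zero_budget_returns_start(self):
        res = pattern_search_fit(lambda x: float(x[0] ** 2), [(-1, 1)],
                                 np.array([0.4]), budget=1)
        assert res["x"][0] == 0.4 and res["exhausted"]

    def test_incumbent_loss_monotone_and_deterministic(self):
        f = lambda x: float((x[0] - 0.5) ** 2 + np.sin(5 * x[1]) ** 2)
        a = pattern_search_fit(f, [(-2, 2), (-2, 2)], np.array([1.0, 1.0]),
                               seed=3, budget=200)
        b = pattern_search_fit(f, [(-2, 2), (-2, 2)], np.array([1.0, 1.0]),
                               seed=3, budget=200)
        losses = [l for _, l, _ in a["trace"]]
        assert all(l2 <= l1 for l1, l2 in zip(losses, losses[1:]))
        np.testing.assert_array_equal(a["x"], b["x"])

    def test_x0_outside_bounds_rejected(self):
        with pytest.raises(ValueError):
            pattern_search_fit(lambda x: 0.0, [(0, 1)], np.array([2.0]))


class TestLHS:
    def test_two_sample_stratification(self):
        x = lhs([(0.0, 1.0)], 2, seed=5).ravel()
        assert (x < 0.5).sum() == 1 and (x >= 0.5).sum() == 1

    def test_marginal_stratification_every_dimension(self):
        n, d = 17, 3
        X = lhs([(0.0, 1.0)] * d, n, seed=2)
        for j in range(d):
            strata = np.floor(X[:, j] * n).astype(int)
            assert sorted(strata) == list(range(n))

    def test_seed_determinism(self):
        a = lhs([(0, 2), (5, 9)], 8, seed=4)
        b = lhs([(0, 2), (5, 9)], 8, seed=4)
        c = lhs([(0, 2), (5, 9)], 8, seed=5)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)


def _prcc_oracle(X, y):
    """Direct residual-regression partial rank correlation (independent
    implementation used as the oracle)."""
    n, p = X.shape
    Xr = np.column_stack([stats.rankdata(X[:, j]) for j in range(p)])
    yr = stats.rankdata(y)
    out = []
    for j in range(p):
        A = np.column_stack([np.ones(n), np.delete(Xr, j, axis=1)])
        bx, _, _, _ = np.linalg.lstsq(A, Xr[:, j], rcond=None)
        by, _, _, _ = np.linalg.lstsq(A, yr, rcond=None)
        rx, ry = Xr[:, j] - A @ bx, yr - A @ by
        out.append(np.corrcoef(rx, ry)[0, 1])
    return np.array(out)


class TestPRCC:
    def test_matches_direct_residual_regression_oracle(self, rng):
        for n, p in [(12, 3), (20, 4), (15, 2)]:
            X = rng.uniform(0, 1, (n, p))
            y = X @ rng.uniform(-1, 1, p) + 0.3 * rng.standard_normal(n)
            df = prcc(X, y)
            np.testing.assert_allclose(df["prcc"].to_numpy(),
                                       _prcc_oracle(X, y), atol=1e-10)

    def test_outcome_equal_to_one_column(self, rng):
        X = rng.uniform(0, 1, (50, 3))
        df = prcc(X, X[:, 1])
        assert df.loc[1, "prcc"] > 0.999
        assert np.all(np.abs(df.loc[[0, 2], "prcc"]) < 0.3)

    def test_independent_outcome_gives_small_coefficients(self):
        rng = np.random.default_rng(42)
        X = rng.uniform(0, 1, (200, 4))
        y = rng.standard_normal(200)
        df = prcc(X, y)
        assert np.all(df["prcc"].abs() < 0.2)

    def test_constant_column_flagged(self, rng):
        X = rng.uniform(0, 1, (20, 3))
        X[:, 2] = 0.7
        with pytest.raises(ValueError, match="constant"):
            prcc(X, X[:, 0])

    def test_coefficients_bounded(self, rng):
        X = rng.uniform(0, 1, (30, 3))
        df = prcc(X, X[:, 0] ** 3)
        assert df["prcc"].between(-1, 1).all()
        assert df["p"].between(0, 1).all()


class TestOutcomeIntegral:
    def test_constant_and_ramp(self, sham_run):
        # sham perfusion is constant 1 -> 35-day integral is 35
        assert outcome_integral(sham_run, "Perfusion", (0, 35)) == pytest.approx(
            35.0, rel=1e-4)

    def test_linear_ramp_closed_form(self):
        from ischemix.multiscale import SimulationResult

        t = np.linspace(0, 10 * 24, 241)
        tissue = np.zeros((241, 1))
        tissue[:, 0] = t / t[-1]
        res = SimulationResult(
            t_hours=t, tissue=tissue, names=["Perfusion"],
            interval_end_hours=np.array([240.0]), cohort_sizes=[np.array([1.0])],
            cohort_births=[np.array([0])], cohort_panels=[np.ones((1, 13))],
            baseline_state=np.array([1.0]), marker0=np.ones(13))
        assert outcome_integral(res, "Perfusion", (0, 10)) == pytest.approx(5.0)

    def test_agrees_with_fine_grid_quadrature(self, acute_run):
        coarse = outcome_integral(acute_run, "Perfusion", (0, 35))
        fine = simulate(Protocol("acute"),
                        config={"store_points_per_interval": 48})
        ref = outcome_integral(fine, "Perfusion", (0, 35))
        assert coarse == pytest.approx(ref, rel=1e-3)

    def test_bad_window_and_variable(self, acute_run):
        with pytest.raises(ValueError):
            outcome_integral(acute_run, "Perfusion", (0, 99))
        with pytest.raises(KeyError):
            outcome_integral(acute_run, "Unobtainium", (0, 35))


class TestAntirecovery:
    def test_value_positive_and_deterministic(self):
        a = antirecovery_outcome()
        b = antirecovery_outcome()
        assert a > 0 and a == b

    def test_sensitive_to_axis_parameters_with_consistent_sign(self):
        """A stronger TLR4 coupling raises the pro-inflammatory composite;
        one-at-a-time perturbation agrees in sign with a big perturbation."""
        base = antirecovery_outcome()
        up_small = antirecovery_outcome(params={"kon_tlr4": 3.6})
        up_big = antirecovery_outcome(params={"kon_tlr4": 6.0})
        assert up_small > base and up_big > up_small


class TestPairedT:
    def test_matches_closed_form(self, rng):
        d = rng.standard_normal(50) + 0.4
        t, p = paired_t(d)
        t_ref = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert t == pytest.approx(t_ref, rel=1e-12)
        t_sp, p_sp = stats.ttest_rel(d, np.zeros(50))
        assert t == pytest.approx(t_sp, rel=1e-10)
        assert p == pytest.approx(p_sp, rel=1e-10)

    def test_all_zero_differences_p_is_one(self):
        t, p = paired_t(np.zeros(10))
        assert t == 0.0 and p == 1.0

    def test_large_effect_is_significant_at_n50(self, rng):
        d = 1.0 + 0.1 * rng.standard_normal(50)
        _, p = paired_t(d)
        assert p < 1e-10


@pytest.fixture(scope="module")
def tiny_vmp(baseline):
    rng = np.random.default_rng(9)
    mice = []
    for _ in range(4):
        params = {
            "k8": baseline.tissue.params["k8"] * rng.uniform(0.9, 1.1),
            "k13": baseline.tissue.params["k13"] * rng.uniform(0.9, 1.1),
        }
        mice.append(VirtualMouse(params=params, accepted=True, deviations={}))
    return mice


class TestVMPAndScreen:
    def test_infinitely_wide_envelope_accepts_everything(self):
        days = np.array([1.0, 17.0, 35.0])
        env = PerfusionEnvelope(
            checkpoints_days=days,
            lower={"acute": np.zeros(3), "gradual": np.zeros(3)},
            upper={"acute": np.full(3, 1e6), "gradual": np.full(3, 1e6)})
        acc, rej = generate_vmp(env, target_n=3, seed=1, budget=3)
        assert len(acc) == 3 and len(rej) == 0

    def test_zero_width_envelope_rejects_perturbed_candidates(self, acute_run,
                                                              gradual_run):
        days = np.array([1.0, 17.0, 35.0])
        pa = np.interp(days, acute_run.t_days, acute_run.normalized("Perfusion"))
        pg = np.interp(days, gradual_run.t_days,
                       gradual_run.normalized("Perfusion"))
        env = PerfusionEnvelope(checkpoints_days=days,
                                lower={"acute": pa, "gradual": pg},
                                upper={"acute": pa, "gradual": pg})
        with pytest.raises(RuntimeError, match="no candidates"):
            generate_vmp(env, target_n=1, seed=1, budget=3)

    def test_screen_identity_intervention_gives_zero_deltas(self, tiny_vmp):
        df = screen(tiny_vmp, [Intervention("ec_nec_inhibit", magnitude=1.0)],
                    window_days=(0, 35))
        assert df.loc[0, "perfusion_delta_mean"] == pytest.approx(0.0, abs=1e-9)
        assert df.loc[0, "perfusion_p"] == pytest.approx(1.0)
        assert df.loc[0, "n"] == 4

    def test_screen_t_statistics_match_per_mouse_oracle(self, tiny_vmp):
        df, pm = screen(tiny_vmp, [Intervention("ec_myo_nec_inhibit")],
                        window_days=(0, 35), per_mouse=True)
        d = (pm["perfusion_arm"] - pm["perfusion_ctrl"]).to_numpy()
        t_ref = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p_ref = 2 * stats.t.sf(abs(t_ref), len(d) - 1)
        assert df.loc[0, "perfusion_t"] == pytest.approx(t_ref, abs=1e-10)
        assert df.loc[0, "perfusion_p"] == pytest.approx(p_ref, abs=1e-10)
        # and the necrosis-inhibition arm helps perfusion in every mouse
        assert (d > 0).all()

    def test_screen_empty_vmp_rejected(self):
        with pytest.raises(ValueError):
            screen([], [Intervention("diabetes")])
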