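"""Compartment-model forward operators, WNLLS fitting, exclusion, SUV."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad, solve_ivp
from scipy.interpolate import interp1d

from petblock import (
    TAC,
    CohortConfig,
    TCMParams,
    compute_suv,
    compute_vt,
    fit_wnlls,
    model_2tcm,
    model_2tcm1k,
    simulate_subject,
)
from petblock._conv import frame_average
from petblock.tcm import PreparedInput, apply_exclusion_rules, wnlls_weights


@pytest.fixture(scope="module")
def prep(truth_input, schedule):
    return PreparedInput.from_input(truth_input, schedule)


class TestForwardModel:
    def test_vascular_only_when_k1_zero(self, prep, schedule):
        p = TCMParams(0.0, 0.1, 0.05, 0.05, vB=0.08)
        expected = 0.08 * frame_average(prep.cb, prep.dt, schedule)
        assert np.allclose(model_2tcm(p, prep, schedule), expected, rtol=1e-12)

    def test_k3_zero_equilibrates_at_k1_over_k2(self, schedule):
        # constant plasma input: the 1TCM limit approaches V_ND = K1/k2
        tgrid = np.linspace(0.0, schedule.total_duration, 18001)
        dt = tgrid[1] - tgrid[0]
        cp = np.full_like(tgrid, 5.0)
        prep_const = PreparedInput(
            schedule, dt, tgrid, cp, np.zeros_like(cp), np.zeros_like(cp)
        )
        p = TCMParams(0.15, 0.15, 0.0, 0.05, vB=0.0)
        m = model_2tcm(p, prep_const, schedule)
        assert m[-1] / 5.0 == pytest.approx(p.K1 / p.k2, rel=1e-3)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_analytic_solution_matches_ode_integration(self, prep, schedule, seed):
        rng = np.random.default_rng(seed)
        p = TCMParams(
            K1=rng.uniform(0.05, 0.3),
            k2=rng.uniform(0.02, 0.3),
            k3=rng.uniform(0.0, 0.15),
            k4=rng.uniform(0.01, 0.1),
            vB=rng.uniform(0.0, 0.1),
        )
        cp = interp1d(prep.tgrid, prep.cp)

        def rhs(t, y):
            c1, c2 = y
            return [p.K1 * cp(t) - (p.k2 + p.k3) * c1 + p.k4 * c2, p.k3 * c1 - p.k4 * c2]

        sol = solve_ivp(
            rhs, (0, schedule.total_duration), [0.0, 0.0], t_eval=prep.tgrid,
            rtol=1e-10, atol=1e-12, method="LSODA",
        )
        fine = (1 - p.vB) * (sol.y[0] + sol.y[1]) + p.vB * prep.cb
        oracle = frame_average(fine, prep.dt, schedule)
        ours = model_2tcm(p, prep, schedule)
        assert np.max(np.abs(ours - oracle)) / np.max(oracle) < 1e-4

    def test_2tcm1k_with_kb_zero_is_bit_equivalent_to_2tcm(self, prep, schedule):
        p = TCMParams(0.15, 0.075, 0.068, 0.05, 0.05, kb=0.0)
        assert np.array_equal(model_2tcm1k(p, prep, schedule), model_2tcm(p, prep, schedule))

    def test_vascular_trap_adds_monotonically(self, prep, schedule):
        p0 = TCMParams(0.15, 0.075, 0.068, 0.05, 0.05, kb=0.0)
        p1 = TCMParams(0.15, 0.075, 0.068, 0.05, 0.05, kb=0.02)
        assert np.all(model_2tcm1k(p1, prep, schedule) >= model_2tcm1k(p0, prep, schedule))

    def test_model_difference_equals_kb_times_blood_integral(self, truth_input, prep, schedule):
        kb = 0.03
        p = TCMParams(0.15, 0.075, 0.068, 0.05, 0.05, kb=kb)
        diff = model_2tcm1k(p, prep, schedule) - model_2tcm(p, prep, schedule)
        # independent quadrature of the frame-averaged running blood integral
        for i in (-1, -3):
            t0, t1 = schedule.frame_start[i], schedule.frame_end[i]
            inner = lambda t: quad(truth_input.wholeblood, 0, t, limit=400)[0]
            expected = kb * quad(inner, t0, t1, limit=100)[0] / (t1 - t0)
            assert diff[i] == pytest.approx(expected, rel=1e-3)


class TestMacroParameters:
    def test_vt_formula(self):
        assert compute_vt(TCMParams(0.1, 0.05, 0.03, 0.02)) == pytest.approx(5.0)

    def test_vt_undefined_for_irreversible_models(self):
        with pytest.raises(ValueError):
            compute_vt(TCMParams(0.1, 0.05, 0.03, 0.0))

    def test_vt_matches_steady_state_under_constant_input(self):
        rng = np.random.default_rng(11)
        p = TCMParams(
            K1=rng.uniform(0.05, 0.3), k2=rng.uniform(0.05, 0.3),
            k3=rng.uniform(0.01, 0.1), k4=rng.uniform(0.02, 0.1), vB=0.0,
        )
        c0 = 3.0

        def rhs(t, y):
            c1, c2 = y
            return [p.K1 * c0 - (p.k2 + p.k3) * c1 + p.k4 * c2, p.k3 * c1 - p.k4 * c2]

        t_end = 60.0 / min(p.k2, p.k4)  # long enough to equilibrate
        sol = solve_ivp(rhs, (0, t_end), [0.0, 0.0], rtol=1e-11, atol=1e-13, method="LSODA")
        vt_numeric = (sol.y[0][-1] + sol.y[1][-1]) / c0
        assert vt_numeric == pytest.approx(compute_vt(p), rel=1e-3)


class TestFitting:
    def test_noiseless_self_inversion_recovers_vt(self, truth_input, prep, schedule):
        p = TCMParams(0.18, 0.09, 0.06, 0.045, 0.04)
        tac = TAC(schedule, model_2tcm(p, prep, schedule))
        fit = fit_wnlls(tac, prep)
        assert fit.vt == pytest.approx(compute_vt(p), rel=5e-3)
        assert not fit.excluded

    def test_high_vt_truth_is_flagged_for_exclusion(self, prep, schedule):
        # V_T = (0.15/0.075)*(1+0.25/0.05) = 12 > 10
        p = TCMParams(0.15, 0.075, 0.25, 0.05, 0.05)
        tac = TAC(schedule, model_2tcm(p, prep, schedule))
        fit = fit_wnlls(tac, prep)
        assert fit.vt == pytest.approx(12.0, rel=0.01)
        assert fit.excluded and fit.exclusion_reason.startswith("V_T>")

    def test_vascular_model_nests_standard_model(self, truth_input, prep, schedule, rng):
        p = TCMParams(0.15, 0.075, 0.068, 0.05, 0.05)
        clean = model_2tcm(p, prep, schedule)
        noisy = clean + 0.05 * np.sqrt(clean / schedule.frame_duration) * rng.standard_normal(
            clean.size
        )
        tac = TAC(schedule, noisy)
        fit2 = fit_wnlls(tac, prep, model="2tcm")
        init = {"K1": fit2.params.K1, "k2": fit2.params.k2, "k3": fit2.params.k3,
                "k4": fit2.params.k4, "vB": fit2.params.vB, "kb": 1e-9}
        fit1k = fit_wnlls(tac, prep, model="2tcm1k", init=init)
        assert fit1k.wrss <= fit2.wrss * (1 + 1e-9)

    def test_parameter_recovery_under_default_noise(self):
        """Median |V_T error| < 5% and bias < 2% over ~100 noisy regional fits."""
        cfg = CohortConfig(n_subjects=4, seed=77)
        errs = []
        for i in range(4):
            subj = simulate_subject(cfg, i)
            for cond in ("baseline", "blocking"):
                scan = subj.scans[cond]
                prep = PreparedInput.from_input(scan.input_function, cfg.schedule)
                for region, tac in scan.tacs.items():
                    fit = fit_wnlls(tac, prep)
                    if not fit.excluded:
                        errs.append(fit.vt / scan.true_vt[region] - 1.0)
        errs = np.asarray(errs)
        assert errs.size >= 90
        assert np.median(np.abs(errs)) < 0.05
        assert abs(errs.mean()) < 0.02

    def test_weights_are_normalised_and_favour_long_quiet_frames(self, schedule):
        y = np.linspace(1, 5, len(schedule))
        w = wnlls_weights(y, schedule.frame_duration)
        assert w.sum() == pytest.approx(1.0)
        assert np.all(w > 0)
        # a 10-min late frame outweighs a 15-s early frame at similar activity
        assert w[-1] > w[0]


@given(
    vt=st.floats(0.1, 20.0, allow_nan=False),
    cv=st.floats(0.0, 200.0, allow_nan=False),
)
def test_exclusion_rule_is_pure_threshold_logic(vt, cv):
    excluded, reason = apply_exclusion_rules(vt, cv)
    assert excluded == (vt > 10.0 or cv > 50.0)
    if excluded:
        assert reason


class TestSUV:
    def test_unit_arithmetic(self, schedule):
        tac = TAC(schedule, np.full(len(schedule), 5.0))
        assert compute_suv(tac, 300.0, 75.0) == pytest.approx(1.25)

    def test_zero_dose_rejected(self, schedule):
        tac = TAC(schedule, np.ones(len(schedule)))
        with pytest.raises(ValueError):
            compute_suv(tac, 0.0, 75.0)

    def test_flat_tac_summaries_agree(self, schedule):
        tac = TAC(schedule, np.full(len(schedule), 2.0))
        assert compute_suv(tac, 320.0, 80.0, summary="mean") == pytest.approx(
            compute_suv(tac, 320.0, 80.0, summary="final")
        )
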