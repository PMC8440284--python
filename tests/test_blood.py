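"""Blood modelling: Hill fits, whole-blood fits, calibration, delay, composition."""

import numpy as np
import pytest

from petblock import (
    TAC,
    CohortConfig,
    HillFraction,
    HillRatio,
    InputFunction,
    WholeBloodModel,
    calibrate_continuous_to_discrete,
    default_schedule,
    derive_input_function,
    fit_delay,
    fit_parent_fraction,
    fit_pob,
    fit_wholeblood,
)
from petblock.blood import (
    HPLC_SAMPLE_TIMES,
    MANUAL_SAMPLE_TIMES,
    input_function_from_dict,
    input_function_to_dict,
)
from petblock.synth import generate_input_function
from petblock.tcm import TCMParams, model_2tcm

HPLC = np.asarray(HPLC_SAMPLE_TIMES)


class TestParentFraction:
    def test_no_metabolism_gives_flat_unity_curve(self):
        fit = fit_parent_fraction(HPLC, np.ones(HPLC.size))
        assert fit.model.a == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(fit.model(np.linspace(0, 90, 20)), 1.0, atol=1e-6)

    def test_noiseless_parameter_recovery(self):
        truth = HillFraction(0.9, 2.0, 50.0)
        fit = fit_parent_fraction(HPLC, truth(HPLC))
        assert fit.model.a == pytest.approx(0.9, rel=1e-3)
        assert fit.model.b == pytest.approx(2.0, rel=1e-3)
        assert fit.model.c == pytest.approx(50.0, rel=1e-3)
        assert fit.converged

    def test_fitted_curve_declines_from_one(self):
        truth = HillFraction(0.7, 1.5, 40.0)
        fit = fit_parent_fraction(HPLC, truth(HPLC))
        t = np.linspace(0, 90, 200)
        y = fit.model(t)
        assert y[0] == pytest.approx(1.0)
        assert np.all(np.diff(y) <= 1e-12)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            fit_parent_fraction(HPLC, np.full(HPLC.size, 1.2))
        with pytest.raises(ValueError):
            fit_parent_fraction(HPLC[:3], np.ones(3))


class TestPOB:
    times = np.asarray(MANUAL_SAMPLE_TIMES)

    def test_constant_samples_give_constant_curve(self):
        fit = fit_pob(self.times, np.full(self.times.size, 1.1))
        assert np.allclose(fit.model(np.linspace(0, 90, 50)), 1.1, atol=1e-6)

    def test_noiseless_parameter_recovery(self):
        truth = HillRatio(0.85, 0.55, 1.2, 30.0)
        fit = fit_pob(self.times, truth(self.times))
        for name in ("r0", "a", "b", "c"):
            assert getattr(fit.model, name) == pytest.approx(getattr(truth, name), rel=1e-3)

    def test_negative_sample_rejected(self):
        bad = np.full(self.times.size, 1.0)
        bad[3] = -0.2
        with pytest.raises(ValueError):
            fit_pob(self.times, bad)


class TestWholeBlood:
    def _truth(self):
        return WholeBloodModel(0.3, 1.2, 20.0, (14.0, 5.0, 1.0), (4.0, 0.4, 0.012))

    def _samples(self):
        t = np.concatenate([np.arange(0, 15.0 + 1e-9, 1 / 60), np.asarray(MANUAL_SAMPLE_TIMES)])
        t = np.unique(t)
        return t, self._truth()(t)

    def test_triexponential_recovery_noiseless(self):
        t, y = self._samples()
        fit = fit_wholeblood(t, y)
        truth = self._truth()
        assert fit.n_exp == 3
        assert np.allclose(fit.model.amps, truth.amps, rtol=1e-2)
        assert np.allclose(fit.model.lambdas, truth.lambdas, rtol=1e-2)
        assert fit.model.t_peak == pytest.approx(truth.t_peak)

    def test_all_zero_curve_rejected(self):
        t = np.linspace(0, 90, 50)
        with pytest.raises(ValueError):
            fit_wholeblood(t, np.zeros(50))

    def test_monotone_series_rejected(self):
        t = np.linspace(0, 90, 50)
        with pytest.raises(ValueError, match="peak"):
            fit_wholeblood(t, np.linspace(0, 10, 50))

    def test_extrapolation_beyond_data_follows_exponentials(self):
        t, y = self._samples()
        m = fit_wholeblood(t, y).model
        t_far = np.array([100.0, 120.0])
        expected = sum(
            a * np.exp(-l * (t_far - m.t_peak)) for a, l in zip(m.amps, m.lambdas)
        )
        assert np.allclose(m(t_far), expected)
        assert np.all(m(t_far) > 0)


class TestCalibration:
    def test_identical_modalities_give_unit_factor(self):
        t = np.linspace(0, 15, 100)
        v = np.exp(-0.1 * t) * 10
        disc_t = np.array([5.0, 10.0, 15.0])
        disc_v = np.interp(disc_t, t, v)
        assert calibrate_continuous_to_discrete(t, v, disc_t, disc_v) == pytest.approx(1.0)

    def test_half_scale_continuous_gives_factor_two(self):
        t = np.linspace(0, 15, 100)
        v = np.exp(-0.1 * t) * 10
        disc_t = np.array([5.0, 10.0, 15.0])
        disc_v = np.interp(disc_t, t, v)
        assert calibrate_continuous_to_discrete(t, 0.5 * v, disc_t, disc_v) == pytest.approx(2.0)

    def test_noisy_factor_matches_least_squares_closed_form(self, rng):
        t = np.linspace(0, 15, 901)
        v = np.exp(-0.1 * t) * 10
        disc_t = np.array([5.0, 10.0, 15.0])
        disc_v = np.interp(disc_t, t, v) * (1.3 + 0.1 * rng.standard_normal(3))
        c = np.interp(disc_t, t, v)
        expected = np.dot(c, disc_v) / np.dot(c, c)
        got = calibrate_continuous_to_discrete(t, v, disc_t, disc_v)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_insufficient_overlap_rejected(self):
        t = np.linspace(0, 4, 10)  # ends before the calibration times
        with pytest.raises(ValueError):
            calibrate_continuous_to_discrete(t, t + 1, np.array([5.0]), np.array([2.0]))


class TestDelay:
    def _tac_with_shift(self, truth_input, schedule, shift):
        p = TCMParams(0.15, 0.075, 0.068, 0.05, 0.05)
        shifted = truth_input.shifted(shift)
        return TAC(schedule, model_2tcm(p, shifted, schedule))

    @pytest.mark.parametrize("shift", [0.25, 0.0])
    def test_recovers_simulated_shift_within_grid_step(self, truth_input, schedule, shift):
        tac = self._tac_with_shift(truth_input, schedule, shift)
        fit = fit_delay(truth_input, tac)
        assert fit.delay == pytest.approx(shift, abs=0.011)
        assert not fit.boundary

    def test_flat_tac_flagged_degenerate(self, truth_input, schedule):
        tac = TAC(schedule, np.full(len(schedule), 3.0))
        fit = fit_delay(truth_input, tac)
        assert fit.degenerate


class TestComposition:
    def test_noiseless_roundtrip_recovers_generating_plasma_curve(self):
        cfg = CohortConfig(noise_scale=0.0)
        blood, (ct, cv), inp, _ = generate_input_function(cfg, seed=7)
        refit = derive_input_function(blood, ct, cv)
        t = np.linspace(0.1, 90, 400)
        err = np.max(np.abs(refit.plasma(t) - inp.plasma(t))) / inp.plasma(t).max()
        assert err < 0.01

    def test_metabolite_correction_only_reduces_plasma(self, truth_input):
        t = np.linspace(0, 90, 400)
        cp = truth_input.plasma(t)
        uncorrected = truth_input.wholeblood(t) * truth_input.pob_model(t - truth_input.delay)
        assert np.all(cp <= uncorrected + 1e-12)

    def test_no_metabolite_identity(self, truth_input):
        inp = InputFunction(
            truth_input.wholeblood_model, truth_input.pob_model, HillFraction(0.0, 1.0, 1.0)
        )
        t = np.linspace(0, 90, 200)
        assert np.allclose(inp.plasma(t), inp.wholeblood(t) * inp.pob_model(t))

    def test_plasma_zero_at_time_zero_and_nonnegative(self, truth_input):
        t = np.linspace(0, 120, 500)
        cp = truth_input.plasma(t)
        assert cp[0] == 0.0
        assert np.all(cp >= 0)

    def test_serialization_roundtrip(self, truth_input):
        d = input_function_to_dict(truth_input)
        back = input_function_from_dict(d)
        t = np.linspace(0, 90, 100)
        assert np.allclose(back.plasma(t), truth_input.plasma(t))
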