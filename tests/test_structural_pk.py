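import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import ode_concentration, ode_states
from prucapop.structural_pk import (ConcentrationProfile, DoseEvent,
                                    PKParameters,
                                    amounts_regimen, exposure_metrics,
                                    predict_concentrations, profile_to_frame,
                                    solve_regimen, steady_state_conc_after_dose,
                                    steady_state_profile)


class TestSingleDoseSolution:
    def test_zero_before_first_dose(self, typical_params):
        prof = solve_regimen(typical_params, [DoseEvent(10.0, 2000.0)],
                             np.array([0.0, 5.0, 9.99]))
        assert np.all(prof.concentrations == 0.0)

    def test_zero_dose_gives_zero_profile(self, typical_params):
        prof = solve_regimen(typical_params, [DoseEvent(0.0, 0.0)],
                             np.linspace(0, 48, 50))
        assert np.all(prof.concentrations == 0.0)

    def test_matches_stiff_ode_oracle(self, typical_params):
        """Closed form vs LSODA with the absorption-rate breakpoint."""
        t = np.array([0.1, 0.5, 0.734, 1.0, 2.0, 4.0, 12.0, 24.0, 72.0])
        prof = solve_regimen(typical_params, [DoseEvent(0.0, 2000.0)], t)
        ref = ode_concentration(typical_params, 2000.0, t)
        np.testing.assert_allclose(prof.concentrations, ref, rtol=1e-8)

    def test_concentration_at_2h_against_oracle(self, typical_params):
        t = np.array([2.0])
        c = solve_regimen(typical_params, [DoseEvent(0.0, 2000.0)], t)
        ref = ode_concentration(typical_params, 2000.0, t)[0]
        assert c.concentrations[0] == pytest.approx(ref, rel=1e-8)
        assert 3.0 < c.concentrations[0] < 4.0  # ng/mL, plausible magnitude

    def test_dose_linearity(self, typical_params):
        t = np.linspace(0.25, 72, 40)
        c1 = solve_regimen(typical_params, [DoseEvent(0.0, 1000.0)], t)
        c2 = solve_regimen(typical_params, [DoseEvent(0.0, 2000.0)], t)
        np.testing.assert_allclose(c2.concentrations, 2 * c1.concentrations,
                                   rtol=1e-12)

    def test_multi_dose_superposition(self, typical_params):
        t = np.linspace(0, 96, 97)
        doses = [DoseEvent(0.0, 1000.0), DoseEvent(24.0, 1500.0),
                 DoseEvent(48.0, 500.0)]
        combined = solve_regimen(typical_params, doses, t)
        summed = sum(solve_regimen(typical_params, [d], t).concentrations
                     for d in doses)
        np.testing.assert_allclose(combined.concentrations, summed, rtol=1e-12)

    def test_switch_inert_when_rates_equal(self, typical_params):
        """With ka1 = ka2 the cutoff has no effect on the profile."""
        t = np.linspace(0.1, 48, 60)
        base = dict(cl=typical_params.cl, v2=typical_params.v2,
                    q=typical_params.q, v3=typical_params.v3, f1=0.858)
        switched = PKParameters(**base, ka1=1.3, ka2=1.3, mtime=0.734)
        single = PKParameters(**base, ka1=1.3, ka2=1.3, mtime=0.0)
        c_sw = solve_regimen(switched, [DoseEvent(0.0, 2000.0)], t)
        c_sr = solve_regimen(single, [DoseEvent(0.0, 2000.0)], t)
        np.testing.assert_allclose(c_sw.concentrations, c_sr.concentrations,
                                   rtol=1e-9)

    def test_rejects_invalid_parameters(self):
        with pytest.raises(ValueError):
            PKParameters(cl=-1, v2=446, q=16.9, v3=248, ka1=0.792,
                         ka2=3.87, mtime=0.734, f1=0.858)
        with pytest.raises(ValueError):
            PKParameters(cl=np.nan, v2=446, q=16.9, v3=248, ka1=0.792,
                         ka2=3.87, mtime=0.734, f1=0.858)
        with pytest.raises(ValueError):
            PKParameters(cl=20.1, v2=446, q=16.9, v3=248, ka1=0.792,
                         ka2=3.87, mtime=0.734, f1=1.5)

    def test_rejects_decreasing_dose_times(self, typical_params):
        with pytest.raises(ValueError):
            solve_regimen(typical_params,
                          [DoseEvent(24.0, 1000.0), DoseEvent(0.0, 1000.0)],
                          np.linspace(0, 48, 10))


class TestMassBalance:
    def test_amounts_match_ode_states(self, typical_params):
        t = np.array([0.25, 0.734, 1.5, 6.0, 24.0, 72.0])
        table = amounts_regimen(typical_params, [DoseEvent(0.0, 2000.0)], t)
        ref = ode_states(typical_params, 2000.0, t)
        np.testing.assert_allclose(table["depot"], ref[:, 0], rtol=1e-6,
                                   atol=1e-9)
        np.testing.assert_allclose(table["central"], ref[:, 1], rtol=1e-6)
        np.testing.assert_allclose(table["peripheral"], ref[:, 2], rtol=1e-6)
        # mass balance against the independently integrated elimination
        np.testing.assert_allclose(table["eliminated"], ref[:, 3],
                                   rtol=1e-4, atol=1e-6)

    def test_conservation_within_one_hundredth_percent(self, typical_params):
        t = np.linspace(0.01, 120, 200)
        table = amounts_regimen(typical_params,
                                [DoseEvent(0.0, 2000.0), DoseEvent(24.0, 2000.0)],
                                t)
        total = (table["depot"] + table["central"] + table["peripheral"]
                 + table["eliminated"]).to_numpy()
        dosed = 0.858 * 2000.0 * (1 + (t >= 24.0))
        np.testing.assert_allclose(total, dosed, rtol=1e-4)


class TestSteadyState:
    def test_auc_equals_f_dose_over_cl(self, typical_params):
        prof = steady_state_profile(typical_params, 2000.0, 24.0)
        m = exposure_metrics(prof, 24.0, f1=0.858, dose=2000.0, cl=20.1)
        assert m.auc_tau == pytest.approx(0.858 * 2000.0 / 20.1, rel=1e-3)
        assert m.auc_tau == pytest.approx(85.37, abs=0.1)

    def test_auc_independent_of_absorption_parameters(self, typical_params):
        other = PKParameters(cl=20.1, v2=446, q=16.9, v3=248,
                             ka1=2.0, ka2=0.5, mtime=2.0, f1=0.858)
        for params in (typical_params, other):
            prof = steady_state_profile(params, 2000.0, 24.0)
            m = exposure_metrics(prof, 24.0)
            assert m.auc_tau == pytest.approx(85.373, rel=2e-3)

    def test_agrees_with_explicit_14_dose_superposition(self, typical_params):
        tau, step = 24.0, 0.25
        grid = np.arange(0.0, tau + step / 2, step)
        ss = steady_state_profile(typical_params, 2000.0, tau, grid_step=step)
        doses = [DoseEvent(k * tau, 2000.0) for k in range(14)]
        last = solve_regimen(typical_params, doses, grid + 13 * tau)
        np.testing.assert_allclose(ss.concentrations, last.concentrations,
                                   rtol=1e-3)

    def test_single_dose_limit_for_long_interval(self, typical_params):
        # with a dosing interval far beyond washout the "steady state"
        # profile is just the single-dose profile
        t = np.linspace(0, 24, 25)
        ss = steady_state_conc_after_dose(typical_params, 2000.0, 2000.0, t)
        single = solve_regimen(typical_params, [DoseEvent(0.0, 2000.0)], t)
        np.testing.assert_allclose(ss, single.concentrations, rtol=1e-6,
                                   atol=1e-12)

    def test_exposure_metric_ordering(self, typical_params):
        prof = steady_state_profile(typical_params, 2000.0, 24.0)
        m = exposure_metrics(prof, 24.0)
        assert m.cmin <= m.css <= m.cmax
        assert m.auc_tau == pytest.approx(m.css * 24.0)
        assert m.c0h == pytest.approx(prof.concentrations[0])


class TestExposureMetrics:
    def test_constant_profile(self):
        prof = ConcentrationProfile(times=np.linspace(0, 24, 100),
                                    concentrations=np.full(100, 3.0))
        m = exposure_metrics(prof, 24.0)
        assert m.auc_tau == pytest.approx(72.0)
        assert m.cmax == m.cmin == 3.0
        assert m.css == pytest.approx(3.0)

    def test_arithmetic_example(self):
        # CL_i = 9.0 L/h, 960 µg once daily, F1 = 0.858
        assert 0.858 * 960.0 / 9.0 == pytest.approx(91.5, abs=0.05)
        params = PKParameters(cl=9.0, v2=446 * 24 / 70, q=16.9 * 0.39,
                              v3=248 * 24 / 70, ka1=0.792, ka2=3.87,
                              mtime=0.734, f1=0.858)
        prof = steady_state_profile(params, 960.0, 24.0)
        m = exposure_metrics(prof, 24.0, f1=0.858, dose=960.0, cl=9.0)
        assert m.auc_tau == pytest.approx(91.52, rel=2e-3)

    def test_sparse_grid_warns(self, typical_params):
        prof = steady_state_profile(typical_params, 2000.0, 24.0, grid_step=8.0)
        with pytest.warns(RuntimeWarning, match="grid may be too sparse"):
            exposure_metrics(prof, 24.0, f1=0.858, dose=2000.0, cl=20.1)

    def test_tidy_export(self, typical_params):
        prof = steady_state_profile(typical_params, 2000.0, 24.0, grid_step=1.0)
        frame = profile_to_frame(prof, subject="s1")
        assert list(frame.columns) == ["subject", "time_h", "conc_ng_per_ml"]
        assert len(frame) == len(prof.times)


@st.composite
def pk_params(draw):
    return PKParameters(
        cl=draw(st.floats(2.0, 60.0)),
        v2=draw(st.floats(50.0, 800.0)),
        q=draw(st.floats(2.0, 60.0)),
        v3=draw(st.floats(50.0, 800.0)),
        ka1=draw(st.floats(0.2, 2.0)),
        ka2=draw(st.floats(0.5, 6.0)),
        mtime=draw(st.one_of(st.just(0.0), st.floats(0.01, 2.0))),
        f1=draw(st.floats(0.3, 1.0)),
    )


class TestProperties:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(params=pk_params(), dose=st.floats(100.0, 5000.0))
    def test_closed_form_tracks_ode_for_random_parameters(self, params, dose):
        t = np.array([0.3, 1.0, 3.0, 8.0, 30.0])
        prof = solve_regimen(params, [DoseEvent(0.0, dose)], t)
        ref = ode_concentration(params, dose, t)
        np.testing.assert_allclose(prof.concentrations, ref,
                                   rtol=1e-6, atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(params=pk_params())
    def test_nonnegative_and_linear(self, params):
        t = np.linspace(0, 48, 30)
        c = solve_regimen(params, [DoseEvent(0.0, 1000.0)], t).concentrations
        assert np.all(c >= 0)
        c3 = solve_regimen(params, [DoseEvent(0.0, 3000.0)], t).concentrations
        np.testing.assert_allclose(c3, 3 * c, rtol=1e-12, atol=1e-300)

    def test_predict_concentrations_matches_solve_regimen(self, typical_params):
        dose_times = np.arange(0.0, 10 * 24, 24.0)
        amounts = np.full(10, 1500.0)
        obs = np.array([1.7, 26.0, 9 * 24 + 14.0])
        via_predict = predict_concentrations(typical_params, dose_times,
                                             amounts, obs)
        doses = [DoseEvent(t, a) for t, a in zip(dose_times, amounts)]
        via_solve = solve_regimen(typical_params, doses, obs)
        np.testing.assert_allclose(via_predict, via_solve.concentrations,
                                   rtol=1e-12)
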