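import math

import numpy as np
import pandas as pd
import pytest

from oracles import marginal_m2ll_quadrature
from prucapop.cohort_simulator import generate_cohort, rich_design, simulate_trial
from prucapop.covariates import RandomEffects, individual_parameters
from prucapop.dataset import COLUMNS, PKDataset
from prucapop.estimation import (EstimationOptions, _one_shrinkage,
                                 build_subjects, estimate_ebe,
                                 fit_population, foce_objective)
from prucapop.population import STUDY_RICH, STUDY_SPARSE, default_population
from prucapop.structural_pk import predict_concentrations


def _row(sid, time, amt=0.0, dv=np.nan, evid=0, wt=70.0, age=10.0,
         study=STUDY_RICH):
    return {"ID": sid, "TIME": time, "AMT": amt, "DV": dv, "EVID": evid,
            "MDV": 1 if evid == 1 else 0, "II": 0.0, "ADDL": 0, "BQL": 0,
            "MISSTIME": 0, "MISSDOSE": 0, "MISSOBS": 0, "STUDY": study,
            "AGE": age, "WT": wt, "HT": 140.0, "SCR": 40.0, "SEX": "F"}


def _toy_pop(omega_cl=0.3, sigma=0.2):
    return default_population().with_updates(
        omega_cl_by_study={STUDY_RICH: omega_cl, STUDY_SPARSE: omega_cl},
        omega_v2=0.0, omega_v3=0.0,
        sigma_by_study={STUDY_RICH: sigma, STUDY_SPARSE: sigma})


def _toy_dataset(etas=(0.25, -0.4), seed=7, sigma=0.2):
    """Two 70 kg subjects, one clearance random effect, three samples each."""
    pop = _toy_pop(sigma=sigma)
    rng = np.random.default_rng(seed)
    rows = []
    obs_times = np.array([1.0, 6.0, 24.0])
    for i, eta in enumerate(etas):
        sid = f"toy-{i}"
        params = individual_parameters(pop, _toy_cov(),
                                       RandomEffects(eta_cl=eta),
                                       study=STUDY_RICH)
        pred = predict_concentrations(params, np.array([0.0]),
                                      np.array([2000.0]), obs_times)
        dv = pred * np.exp(rng.normal(0, sigma, obs_times.size))
        rows.append(_row(sid, 0.0, amt=2000.0, evid=1))
        rows.extend(_row(sid, t, dv=v) for t, v in zip(obs_times, dv))
    return PKDataset(pd.DataFrame(rows, columns=COLUMNS)), pop


def _toy_cov():
    from prucapop.covariates import PatientCovariates
    return PatientCovariates(age_years=10.0, weight_kg=70.0, height_cm=140.0,
                             serum_creatinine_umol_per_l=40.0)


class TestFOCEObjective:
    def test_matches_adaptive_quadrature_on_toy_problem(self):
        """FOCE-I −2LL within 0.5 of 64-node adaptive Gauss-Hermite."""
        ds, pop = _toy_dataset()
        ofv = foce_objective(pop, ds)
        total_oracle = 0.0
        for subj in build_subjects(ds):
            y = subj.y

            def f_of_eta(eta, subj=subj):
                params = individual_parameters(
                    pop, _toy_cov(), RandomEffects(eta_cl=eta),
                    study=subj.study)
                pred = predict_concentrations(params, np.array([0.0]),
                                              np.array([2000.0]),
                                              subj.obs_times)
                return np.log(pred)

            total_oracle += marginal_m2ll_quadrature(
                y, f_of_eta, omega=0.3, sigma=0.2, n_nodes=64)
        assert ofv == pytest.approx(total_oracle, abs=0.1)

    @pytest.mark.parametrize("sigma", [0.1, 0.35])
    def test_quadrature_agreement_across_noise_levels(self, sigma):
        ds, pop = _toy_dataset(etas=(0.5, -0.2), seed=11, sigma=sigma)
        ofv = foce_objective(pop, ds)
        total = 0.0
        for subj in build_subjects(ds):
            def f_of_eta(eta, subj=subj):
                params = individual_parameters(
                    pop, _toy_cov(), RandomEffects(eta_cl=eta),
                    study=subj.study)
                return np.log(predict_concentrations(
                    params, np.array([0.0]), np.array([2000.0]),
                    subj.obs_times))
            total += marginal_m2ll_quadrature(subj.y, f_of_eta, 0.3, sigma)
        assert ofv == pytest.approx(total, abs=0.5)

    def test_vanishing_iiv_reduces_to_fixed_effects_likelihood(self):
        """ω → 0 degenerates to the weighted least-squares lognormal −2LL."""
        ds, _ = _toy_dataset()
        sigma = 0.2
        tiny = _toy_pop(omega_cl=1e-8, sigma=sigma)
        ofv = foce_objective(tiny, ds)
        expected = 0.0
        for subj in build_subjects(ds):
            params = individual_parameters(tiny, _toy_cov(), RandomEffects(),
                                           study=subj.study)
            pred = predict_concentrations(params, np.array([0.0]),
                                          np.array([2000.0]), subj.obs_times)
            r = subj.y - np.log(pred)
            expected += (subj.n_obs * math.log(2 * math.pi * sigma**2)
                         + float(r @ r) / sigma**2)
        assert ofv == pytest.approx(expected, abs=1e-3)

    def test_zero_observation_subject_leaves_ofv_unchanged(self):
        ds, pop = _toy_dataset()
        base = foce_objective(pop, ds)
        extra = pd.concat([ds.records,
                           pd.DataFrame([_row("ghost", 0.0, amt=500.0,
                                              evid=1)])],
                          ignore_index=True)
        assert foce_objective(pop, PKDataset(extra)) == pytest.approx(base)

    def test_nonpositive_sigma_rejected(self):
        ds, _ = _toy_dataset()
        bad = _toy_pop(sigma=0.0)
        with pytest.raises(ValueError):
            foce_objective(bad, ds)


class TestEmpiricalBayes:
    def test_no_observations_returns_prior_mode(self):
        rows = [_row("lone", 0.0, amt=1000.0, evid=1)]
        eta, had_obs = estimate_ebe(_toy_pop(),
                                    pd.DataFrame(rows, columns=COLUMNS))
        assert not had_obs
        np.testing.assert_array_equal(eta, np.zeros(3))

    def test_one_dimensional_mode_matches_grid_search(self):
        """MAP η̂ against a brute-force fine grid of the penalized objective."""
        ds, pop = _toy_dataset(etas=(0.35,), seed=13)
        subj = build_subjects(ds)[0]
        eta_hat, had_obs = estimate_ebe(pop, ds.records)
        assert had_obs

        def objective(eta):
            params = individual_parameters(pop, _toy_cov(),
                                           RandomEffects(eta_cl=eta),
                                           study=STUDY_RICH)
            pred = predict_concentrations(params, np.array([0.0]),
                                          np.array([2000.0]), subj.obs_times)
            r = subj.y - np.log(pred)
            return float(r @ r) / 0.2**2 + eta**2 / 0.3**2

        coarse = np.linspace(-1.5, 1.5, 3001)
        best = coarse[np.argmin([objective(e) for e in coarse])]
        fine = np.linspace(best - 2e-3, best + 2e-3, 401)
        best = fine[np.argmin([objective(e) for e in fine])]
        assert eta_hat[0] == pytest.approx(best, abs=1e-4)

    def test_noise_free_rich_sampling_recovers_random_effects(self, pop):
        """With σ → 0 and 13 samples the EBEs reproduce the simulated η."""
        design = rich_design(1)
        quiet = pop.with_updates(sigma_by_study={STUDY_RICH: 1e-6,
                                                 STUDY_SPARSE: 1e-6})
        cohort = generate_cohort(design, n=1, seed=17)
        truth = RandomEffects(eta_cl=0.2, eta_v2=-0.3, eta_v3=0.25)
        params = individual_parameters(quiet, cohort[0].covariates, truth,
                                       study=STUDY_RICH)
        times = np.asarray(design.sample_times_h)
        dose = cohort[0].initial_dose_ug
        dv = predict_concentrations(params, np.array([0.0]), np.array([dose]),
                                    times)
        rows = [_row(cohort[0].sid, 0.0, amt=dose, evid=1,
                     wt=cohort[0].covariates.weight_kg,
                     age=cohort[0].covariates.age_years)]
        rows += [_row(cohort[0].sid, t, dv=v,
                      wt=cohort[0].covariates.weight_kg,
                      age=cohort[0].covariates.age_years)
                 for t, v in zip(times, dv)]
        eta, _ = estimate_ebe(quiet, pd.DataFrame(rows, columns=COLUMNS))
        assert eta[0] == pytest.approx(0.2, abs=0.002)
        assert eta[1] == pytest.approx(-0.3, abs=0.003)
        assert eta[2] == pytest.approx(0.25, abs=0.0025)


class TestShrinkage:
    def test_formula_arithmetic(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        x = 0.24 * (x - x.mean()) / x.std(ddof=1)  # sample SD exactly 0.24
        assert _one_shrinkage(x, 0.30) == pytest.approx(20.0, abs=1e-9)

    def test_all_zero_etas_give_full_shrinkage(self):
        assert _one_shrinkage(np.zeros(10), 0.30) == pytest.approx(100.0)

    def test_undefined_when_omega_zero(self):
        assert math.isnan(_one_shrinkage(np.array([0.1, -0.1]), 0.0))

    def test_shrinkage_increases_as_sampling_thins(self, pop):
        """Subsampling each subject's profile can only contract the EBEs."""
        design = rich_design(24)
        cohort = generate_cohort(design, seed=23)
        ds = simulate_trial(cohort, design, pop, seed=24,
                            apply_artifacts=False)
        full = _cl_shrinkage(pop, ds)
        thinned = _subsample_observations(ds, keep=1)
        sparse = _cl_shrinkage(pop, thinned)
        assert sparse > full


def _subsample_observations(ds: PKDataset, keep: int) -> PKDataset:
    parts = []
    for sid in ds.subject_ids:
        sub = ds.subject(sid)
        doses = sub[sub["EVID"] == 1]
        obs = sub[sub["EVID"] == 0]
        idx = np.linspace(0, len(obs) - 1, keep).astype(int)
        parts.append(pd.concat([doses, obs.iloc[idx]]))
    return PKDataset(pd.concat(parts, ignore_index=True))


def _cl_shrinkage(pop, ds) -> float:
    from prucapop.estimation import _Cohort, _shrinkage, _solve_etas
    subjects = build_subjects(ds)
    cohort = _Cohort(subjects)
    arrays = cohort.resolve(pop)
    etas, _, _, _ = _solve_etas(cohort, pop, arrays, EstimationOptions())
    eta_shr, _ = _shrinkage(pop, cohort, etas)
    return eta_shr[f"cl:{STUDY_RICH}"]


class TestFitPopulation:
    def test_self_consistency_near_truth(self, pop):
        """Noise-poor data, initialisation at truth: the optimizer stays put."""
        design = rich_design(8)
        cohort = generate_cohort(design, seed=31)
        quiet = pop.with_updates(
            omega_cl_by_study={STUDY_RICH: 0.0, STUDY_SPARSE: 0.0},
            omega_v2=0.0, omega_v3=0.0,
            sigma_by_study={STUDY_RICH: 0.01, STUDY_SPARSE: 0.01})
        ds = simulate_trial(cohort, design, quiet, seed=32,
                            apply_artifacts=False)
        init = quiet.with_updates(
            omega_cl_by_study={STUDY_RICH: 0.05, STUDY_SPARSE: 0.05},
            omega_v2=0.05, omega_v3=0.05)
        fixed = {f"omega_cl:{STUDY_RICH}", "omega_v2", "omega_v3"}
        fit = fit_population(ds, init, fixed=fixed,
                             options=EstimationOptions(compute_se=False,
                                                       polish_maxfev=100))
        assert fit.theta[f"cl:{STUDY_RICH}"] == pytest.approx(22.9, rel=0.01)
        assert fit.theta["v2"] == pytest.approx(446.0, rel=0.01)
        assert fit.theta["q"] == pytest.approx(16.9, rel=0.01)
        assert fit.theta["v3"] == pytest.approx(248.0, rel=0.01)
        assert fit.ofv <= foce_objective(init, ds) + 1e-6

    def test_optimum_beats_perturbed_starts(self, pop):
        design = rich_design(8)
        cohort = generate_cohort(design, seed=31)
        quiet = pop.with_updates(
            omega_cl_by_study={STUDY_RICH: 0.1, STUDY_SPARSE: 0.1},
            omega_v2=0.1, omega_v3=0.1,
            sigma_by_study={STUDY_RICH: 0.05, STUDY_SPARSE: 0.05})
        ds = simulate_trial(cohort, design, quiet, seed=33,
                            apply_artifacts=False)
        fit = fit_population(ds, quiet,
                             options=EstimationOptions(compute_se=False,
                                                       polish_maxfev=150))
        rng = np.random.default_rng(34)
        for _ in range(10):
            factors = np.exp(rng.uniform(math.log(0.7), math.log(1.3), 4))
            perturbed = fit.population.with_updates(
                cl_tv_by_study={STUDY_RICH: fit.theta[f"cl:{STUDY_RICH}"]
                                * factors[0]},
                v2_tv=fit.theta["v2"] * factors[1],
                q_tv=fit.theta["q"] * factors[2],
                v3_tv=fit.theta["v3"] * factors[3])
            assert foce_objective(perturbed, ds) >= fit.ofv - 1e-6

    def test_standard_errors_reported_on_natural_scale(self, pop):
        ds, toy_pop = _toy_dataset(etas=(0.1, -0.2, 0.3, 0.0, 0.15, -0.1),
                                   seed=37)
        fixed = {"v2", "q", "v3", f"omega_cl:{STUDY_RICH}",
                 "omega_v2", "omega_v3"}
        fit = fit_population(ds, toy_pop, fixed=fixed,
                             options=EstimationOptions(polish_maxfev=100))
        name = f"cl:{STUDY_RICH}"
        if fit.se_available:
            assert fit.se[name] > 0
            lo, hi = fit.ci95[name]
            assert lo < fit.theta[name] < hi
            assert fit.rse_percent[name] == pytest.approx(
                100 * fit.se[name] / fit.theta[name], rel=1e-6)
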