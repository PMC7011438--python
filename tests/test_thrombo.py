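"""Transit-compartment thrombopoiesis model: equilibrium, pulse response,
grading, MAP fitting, adaptation and dose tuning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from haemodesk import thrombo
from haemodesk.errors import InsufficientDataError, ValidationError
from haemodesk.thrombo import (
    AdaptationQuery,
    Application,
    Cycle,
    DEFAULT_DRUG_SLOPES,
    PlateletObservation,
    PopulationPrior,
    TherapySchedule,
    ThromboParams,
    adapt_schedule,
    build_regimen,
    default_prior,
    fit_thrombo,
    grade_tcp,
    grade_threshold,
    nadir_for_factors,
    predict_adapted,
    simulate_platelets,
    steady_state,
    tune_dose_factor,
)


@pytest.fixture
def params():
    return ThromboParams(
        t_ss=250.0, ktr=0.7, gamma=0.2, kel=0.11, drug_slopes=dict(DEFAULT_DRUG_SLOPES)
    )


@pytest.fixture
def chop21():
    return build_regimen("CHOP-21")


def noisy_platelets(true_params, schedule, times, noise_sd, seed):
    rng = np.random.default_rng(seed)
    sim = simulate_platelets(true_params, schedule, times)
    return [
        PlateletObservation(time=float(t), count=float(v * np.exp(rng.normal(0, noise_sd))))
        for t, v in zip(times, sim)
    ]


class TestSteadyState:
    def test_equilibrium_holds_for_a_year(self, params):
        times = np.linspace(0, 365, 400)
        c = simulate_platelets(params, None, times)
        assert np.max(np.abs(c - params.t_ss)) / params.t_ss < 1e-6

    def test_state_positive_and_feedback_unity(self, params):
        state = steady_state(params)
        assert np.all(state > 0)
        assert (params.t_ss / state[-1]) ** params.gamma == pytest.approx(1.0)

    def test_zero_slopes_keep_trajectory_flat(self, params, chop21):
        p0 = ThromboParams(
            t_ss=params.t_ss, ktr=params.ktr, gamma=params.gamma, kel=params.kel,
            drug_slopes={d: 0.0 for d in DEFAULT_DRUG_SLOPES},
        )
        times = np.linspace(0, 150, 300)
        c = simulate_platelets(p0, chop21, times)
        assert np.max(np.abs(c - params.t_ss)) / params.t_ss < 1e-6


class TestPulseResponse:
    def test_single_pulse_nadir_delay_and_recovery(self, params):
        """One application: the nadir trails the pulse by roughly the
        maturation delay, then the count recovers to near baseline."""
        schedule = TherapySchedule(
            regimen_label="single",
            cycles=(Cycle(start_day=0.0, applications=(Application(0.0, "cyclophosphamide", 1.0),)),),
        )
        times = np.arange(0.0, 400.0, 0.25)
        c = simulate_platelets(params, schedule, times)
        i_nadir = int(np.argmin(c))
        t_nadir = times[i_nadir]
        delay_scale = params.n_tr / params.ktr
        assert 0.5 * delay_scale <= t_nadir <= 5.0 * delay_scale
        assert c[i_nadir] < params.t_ss
        assert abs(c[-1] - params.t_ss) / params.t_ss < 0.05

    def test_doubling_dose_deepens_nadir(self, params):
        def nadir(rel_dose):
            schedule = TherapySchedule(
                regimen_label="single",
                cycles=(Cycle(0.0, (Application(0.0, "cyclophosphamide", rel_dose),)),),
            )
            c = simulate_platelets(params, schedule, np.arange(0, 120, 0.25))
            return c.min()

        assert nadir(2.0) < nadir(1.0)

    def test_mass_positivity(self, params, chop21):
        hot = ThromboParams(
            t_ss=200.0, ktr=1.0, gamma=0.3, kel=0.12,
            drug_slopes={d: s * 4 for d, s in DEFAULT_DRUG_SLOPES.items()},
        )
        c = simulate_platelets(hot, chop21, np.arange(0, 160, 0.25))
        assert np.all(c > 0)

    def test_unknown_drug_rejected(self, params):
        schedule = TherapySchedule(
            regimen_label="x",
            cycles=(Cycle(0.0, (Application(0.0, "quackamycin", 1.0),)),),
        )
        with pytest.raises(ValidationError, match="quackamycin"):
            simulate_platelets(params, schedule, [0.0, 10.0])

    def test_rk4_agrees_with_adaptive_solver(self, params, chop21):
        times = np.arange(0.0, 150.0, 1.0)
        rk4 = simulate_platelets(params, chop21, times, method="rk4", step=0.25)
        ada = simulate_platelets(params, chop21, times, method="adaptive", rtol=1e-10)
        assert np.max(np.abs(rk4 - ada)) < 0.05

    def test_solver_tolerance_insensitivity_of_nadir(self, params, chop21):
        times = np.arange(0.0, 150.0, 0.25)
        n8 = simulate_platelets(params, chop21, times, method="adaptive", rtol=1e-8).min()
        n10 = simulate_platelets(params, chop21, times, method="adaptive", rtol=1e-10).min()
        assert abs(n8 - n10) < 0.1


class TestRegimens:
    @pytest.mark.parametrize("label,cycle_len,n_drugs", [
        ("CHOP-14", 14, 4),
        ("CHOP-21", 21, 4),
        ("CHOEP-14", 14, 5),
        ("CHOEP-21", 21, 5),
    ])
    def test_library_protocol_facts(self, label, cycle_len, n_drugs):
        schedule = build_regimen(label)
        assert len(schedule.cycles) == 6
        starts = [c.start_day for c in schedule.cycles]
        assert np.allclose(np.diff(starts), cycle_len)
        drugs = {a.drug for c in schedule.cycles for a in c.applications}
        assert len(drugs) == n_drugs

    def test_etoposide_spans_three_days(self):
        schedule = build_regimen("CHOEP-21")
        offsets = sorted(
            a.day_offset for a in schedule.cycles[0].applications if a.drug == "etoposide"
        )
        assert offsets == [0.0, 1.0, 2.0]

    def test_unknown_regimen_rejected(self):
        with pytest.raises(ValidationError):
            build_regimen("R-CHOP-500")

    def test_schedule_json_round_trip(self, chop21):
        assert TherapySchedule.from_json(chop21.to_json()) == chop21


class TestGrading:
    @pytest.mark.parametrize("count,grade", [
        (300.0, 0), (160.0, 0), (150.0, 0), (149.9, 1), (75.0, 1),
        (74.9, 2), (60.0, 2), (50.0, 2), (49.9, 3), (25.0, 3), (24.9, 4), (0.0, 4),
    ])
    def test_boundaries(self, count, grade):
        assert grade_tcp(count) == grade

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            grade_tcp(-1.0)

    def test_threshold_inverse_of_grading(self):
        for g in range(5):
            assert grade_tcp(grade_threshold(g)) == g


class TestFit:
    def test_zero_observations_error(self, chop21):
        with pytest.raises(InsufficientDataError):
            fit_thrombo([], chop21)

    def test_observations_must_span_an_application(self, chop21):
        obs = [PlateletObservation(time=-10.0 + i, count=250.0) for i in range(5)]
        with pytest.raises(InsufficientDataError):
            fit_thrombo(obs, chop21)

    def test_noise_free_recovery_with_wide_prior(self, chop21):
        true = ThromboParams(
            t_ss=260.0, ktr=0.75, gamma=0.28, kel=0.11,
            drug_slopes=dict(DEFAULT_DRUG_SLOPES),
        )
        times = np.array([c.start_day + off for c in chop21.cycles for off in (0.0, 4.0, 7.0, 11.0)])
        obs = noisy_platelets(true, chop21, times, 0.0, seed=0)
        wide = PopulationPrior(
            log_params={
                "t_ss": (np.log(250.0), 2.0),
                "ktr": (np.log(0.7), 2.0),
                "gamma": (np.log(0.2), 2.0),
                "kel": (np.log(0.11), 0.2),
                "slope_scale": (0.0, 2.0),
            }
        )
        fitted = fit_thrombo(obs, chop21, prior=wide)
        assert fitted.converged
        assert fitted.params.t_ss == pytest.approx(true.t_ss, rel=1e-2)
        assert fitted.params.ktr == pytest.approx(true.ktr, rel=0.05)
        assert fitted.params.gamma == pytest.approx(true.gamma, rel=0.1)

    def test_fit_json_round_trip(self, chop21):
        true = ThromboParams(t_ss=260.0, ktr=0.75, gamma=0.28, kel=0.11,
                             drug_slopes=dict(DEFAULT_DRUG_SLOPES))
        times = np.array([c.start_day + off for c in chop21.cycles for off in (0.0, 7.0)])
        fitted = fit_thrombo(noisy_platelets(true, chop21, times, 0.1, seed=4), chop21)
        clone = thrombo.FittedThrombo.from_json(fitted.to_json())
        assert clone.params == fitted.params
        assert clone.slope_scale == fitted.slope_scale


@pytest.fixture(scope="module")
def fitted_patient():
    chop21 = build_regimen("CHOP-21")
    true = ThromboParams(
        t_ss=230.0, ktr=0.65, gamma=0.25, kel=0.11,
        drug_slopes={d: s * 1.8 for d, s in DEFAULT_DRUG_SLOPES.items()},
    )
    rng_times = np.array([c.start_day + off for c in chop21.cycles[:3] for off in (0.0, 4.0, 7.0, 11.0)])
    obs = noisy_platelets(true, chop21, rng_times, 0.08, seed=11)
    return fit_thrombo(obs, chop21), chop21


class TestAdaptation:
    def test_identity_adaptation_matches_plain_prediction(self, fitted_patient):
        fitted, schedule = fitted_patient
        a = predict_adapted(fitted, schedule, AdaptationQuery(0, 1.0, 160.0))
        b = predict_adapted(fitted, schedule, AdaptationQuery(0, 1.0, 160.0))
        assert np.array_equal(a.counts, b.counts)
        direct = simulate_platelets(fitted.params, schedule, a.times)
        assert np.allclose(a.counts, direct)

    def test_zero_future_dose_recovers_toward_baseline(self, fitted_patient):
        """With future doses zeroed the count climbs back from the last
        past-cycle nadir and settles near the steady state (feedback makes
        the approach overshoot, not monotone)."""
        fitted, schedule = fitted_patient
        pred = predict_adapted(fitted, schedule, AdaptationQuery(0, 0.0, 160.0))
        tail = pred.counts[pred.times > fitted.last_obs_day + 25]
        full = predict_adapted(fitted, schedule, AdaptationQuery(0, 1.0, 160.0))
        assert tail.min() > full.nadir
        assert abs(pred.counts[-1] - fitted.params.t_ss) / fitted.params.t_ss < 0.10

    def test_postponement_shifts_future_cycles_only(self, fitted_patient):
        fitted, schedule = fitted_patient
        shifted = adapt_schedule(schedule, from_day=fitted.last_obs_day, postpone_days=4.0)
        for orig, new in zip(schedule.cycles, shifted.cycles):
            if orig.start_day < fitted.last_obs_day:
                assert new.start_day == orig.start_day
            else:
                assert new.start_day == orig.start_day + 4.0

    def test_halving_dose_raises_nadir(self, fitted_patient):
        fitted, schedule = fitted_patient
        n_half = predict_adapted(fitted, schedule, AdaptationQuery(0, 0.5, 160.0)).nadir
        n_full = predict_adapted(fitted, schedule, AdaptationQuery(0, 1.0, 160.0)).nadir
        assert n_half >= n_full

    def test_short_horizon_rejected(self, fitted_patient):
        fitted, schedule = fitted_patient
        with pytest.raises(ValidationError):
            predict_adapted(fitted, schedule, AdaptationQuery(0, 1.0, 30.0))

    @settings(max_examples=15, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_nadir_non_increasing_in_dose_factor(self, seed):
        rng = np.random.default_rng(seed)
        params = ThromboParams(
            t_ss=float(rng.uniform(180, 350)),
            ktr=float(rng.uniform(0.5, 1.0)),
            gamma=float(rng.uniform(0.10, 0.30)),
            kel=float(rng.uniform(0.09, 0.13)),
            drug_slopes={d: s * float(rng.uniform(0.5, 2.5)) for d, s in DEFAULT_DRUG_SLOPES.items()},
        )
        schedule = build_regimen("CHOP-14")
        factors = np.linspace(0.0, 2.0, 21)
        nadirs = nadir_for_factors(params, schedule, factors, 120.0, from_day=0.0)
        assert np.all(np.diff(nadirs) <= 1e-6)


class TestDoseTuning:
    def test_unconstrained_when_limit_already_met(self, fitted_patient):
        fitted, schedule = fitted_patient
        result = tune_dose_factor(fitted, schedule, tolerable_grade=4, horizon_days=160.0)
        assert result.flag == "unconstrained" and result.factor == 2.0

    def test_tuned_factor_sits_at_threshold(self, fitted_patient):
        fitted, schedule = fitted_patient
        result = tune_dose_factor(fitted, schedule, tolerable_grade=0, horizon_days=160.0)
        if result.flag == "converged":
            assert result.nadir >= result.threshold
            just_above = nadir_for_factors(
                fitted.params, schedule, [result.factor + 0.01], 160.0,
                from_day=fitted.last_obs_day + 1e-9,
            )[0]
            assert just_above < result.threshold + 1.0

    def test_matches_grid_search_oracle(self, fitted_patient):
        fitted, schedule = fitted_patient
        horizon = 160.0
        from_day = fitted.last_obs_day + 1e-9
        for grade in (0, 1):
            result = tune_dose_factor(fitted, schedule, grade, horizon)
            grid = np.linspace(0.0, 2.0, 2001)
            nadirs = nadir_for_factors(fitted.params, schedule, grid, horizon, from_day=from_day)
            feasible = np.nonzero(nadirs >= result.threshold)[0]
            f_star = grid[feasible.max()] if len(feasible) else 0.0
            assert abs(result.factor - f_star) <= 2 * 0.001 + 1e-9

    def test_tightening_grade_never_raises_factor(self, fitted_patient):
        fitted, schedule = fitted_patient
        f3 = tune_dose_factor(fitted, schedule, 3, 160.0).factor
        f1 = tune_dose_factor(fitted, schedule, 1, 160.0).factor
        assert f1 <= f3 + 1e-9

    def test_invalid_grade_rejected(self, fitted_patient):
        fitted, schedule = fitted_patient
        with pytest.raises(ValidationError):
            tune_dose_factor(fitted, schedule, tolerable_grade=7, horizon_days=160.0)
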