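"""Schedule encoding, objectives, and the three optimizers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import differential_evolution as scipy_de

from pdsched.optimize import (ConstraintSet, DEParams, GAParams,
                              ObjectiveSpec, ScheduleProblem, TargetSpec,
                              exhaustive_search, make_objective,
                              model_evaluator, objective_below_threshold,
                              objective_dose_sum, objective_outside_range,
                              objective_sq_deviation, optimize_de,
                              optimize_ga, pkpd_evaluator, target_from_patient)
from pdsched.pkpd import DoseSchedule, PatientParameters, StateTrace


def _trace(values, step=10.0):
    values = np.asarray(values, dtype=float)
    return StateTrace(times=step * np.arange(values.size), values=values,
                      day_length=step * values.size)


TARGET = TargetSpec(theta=0.65, theta_min=0.4, theta_max=0.9, theta_t=0.2)


class TestEncoding:
    @pytest.mark.parametrize("numbers,dim", [
        ((), 8),        # [t1, dt2..dt4, d1..d4]
        ((1,), 8),      # discretization changes lattices, not the dimension
        ((2,), 7),      # t1 pinned at wake
        ((3,), 6),      # two dose sizes
        ((4,), 6),      # single interval, t1 kept
        ((1, 2, 3, 4), 3),
    ])
    def test_table_of_decision_variable_counts(self, numbers, dim):
        prob = ScheduleProblem(960.0, 4, ConstraintSet.from_numbers(numbers))
        assert prob.variable_spec().dim == dim

    def test_fully_constrained_names(self):
        prob = ScheduleProblem(960.0, 4, ConstraintSet.from_numbers([1, 2, 3, 4]))
        assert prob.variable_spec().names == ("dt", "d_mor", "d_main")

    def test_decode_layout_times_first_sizes_second(self):
        prob = ScheduleProblem(960.0, 3, ConstraintSet())
        s = prob.decode([30.0, 100.0, 120.0, 50.0, 150.0, 250.0])
        assert s.times.tolist() == [30.0, 130.0, 250.0]
        assert s.sizes == (50.0, 150.0, 250.0)

    def test_encode_decode_round_trip_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for numbers in [(), (2,), (3,), (4,), (1, 2), (1, 2, 3, 4)]:
            prob = ScheduleProblem(960.0, 5, ConstraintSet.from_numbers(numbers))
            spec = prob.variable_spec()
            for _ in range(20):
                x = spec.sample(rng)
                assert prob.encode(prob.decode(x)) == pytest.approx(x)

    def test_dimension_mismatch_rejected(self):
        prob = ScheduleProblem(960.0, 4, ConstraintSet.from_numbers([1, 2, 3, 4]))
        with pytest.raises(ValueError):
            prob.decode([100.0, 200.0])


class TestObjectives:
    def test_dose_sum(self):
        assert objective_dose_sum(DoseSchedule.from_times([0, 100], [100, 150])) == 250
        assert objective_dose_sum(DoseSchedule()) == 0

    def test_sq_deviation_constant_offsets(self):
        L = 400.0
        n = int(L / 10) + 1
        assert objective_sq_deviation(_trace(np.full(n, TARGET.theta)), TARGET) == 0
        got = objective_sq_deviation(_trace(np.full(n, TARGET.theta + 0.5)), TARGET)
        assert got == pytest.approx(0.25 * L)

    def test_sq_deviation_grid_convergence(self, patient):
        from pdsched.pkpd import simulate_trace
        sched = DoseSchedule.from_times([0, 200], [200, 100])
        c = objective_sq_deviation(simulate_trace(patient, sched, 800, 10), TARGET)
        f = objective_sq_deviation(simulate_trace(patient, sched, 800, 5), TARGET)
        assert abs(c - f) / f < 0.01

    def test_outside_range_closed_forms(self):
        L = 300.0
        n = int(L / 10) + 1
        inside = _trace(np.linspace(TARGET.theta_min, TARGET.theta_max, n))
        assert objective_outside_range(inside, TARGET) == 0
        above = _trace(np.full(n, TARGET.theta_max + 1.0))
        assert objective_outside_range(above, TARGET) == pytest.approx(L)
        below = _trace(np.full(n, TARGET.theta_min - 2.0))
        assert objective_outside_range(below, TARGET) == pytest.approx(4 * L)
        assert objective_outside_range(above, TARGET, squared=False) == pytest.approx(L)

    def test_below_threshold_closed_forms(self):
        L = 300.0
        n = int(L / 10) + 1
        above = _trace(np.full(n, TARGET.theta_t + 0.1))
        assert objective_below_threshold(above, TARGET) == 0
        under = _trace(np.full(n, TARGET.theta_t - 1.0))
        assert objective_below_threshold(under, TARGET) == pytest.approx(L)

    def test_below_threshold_additive_over_subintervals(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(-1, 1, size=41)
        whole = objective_below_threshold(_trace(v), TARGET)
        left = objective_below_threshold(_trace(v[:21]), TARGET)
        right = objective_below_threshold(_trace(v[20:]), TARGET)
        assert whole == pytest.approx(left + right)

    def test_after_onset_ignores_morning_climb(self):
        v = np.concatenate([np.linspace(-2.0, 0.5, 10), np.full(20, 0.5)])
        full = objective_below_threshold(_trace(v), TARGET)
        onset = objective_below_threshold(_trace(v), TARGET, after_onset=True)
        assert full > 0 and onset == 0

    def test_combined_objective_is_compositional(self, patient):
        ev = pkpd_evaluator(patient, 800.0)
        sched = DoseSchedule.from_times([0, 150, 300], [200, 100, 100])
        target = target_from_patient(patient)
        spec = ObjectiveSpec(dose_sum=0.01, sq_deviation=1.0, outside_range=2.0,
                             below_threshold=3.0)
        combined = make_objective(ev, spec, target)(sched)
        trace = ev(sched)
        parts = (0.01 * objective_dose_sum(sched)
                 + 1.0 * objective_sq_deviation(trace, target)
                 + 2.0 * objective_outside_range(trace, target)
                 + 3.0 * objective_below_threshold(trace, target))
        assert combined == pytest.approx(parts)

    def test_dose_sum_only_weights(self, patient):
        ev = pkpd_evaluator(patient, 800.0)
        spec = ObjectiveSpec(dose_sum=1.0, sq_deviation=0, outside_range=0,
                             below_threshold=0)
        sched = DoseSchedule.from_times([0, 100], [100, 150])
        assert make_objective(ev, spec, target_from_patient(patient))(sched) == 250

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            ObjectiveSpec(dose_sum=0, sq_deviation=0, outside_range=0,
                          below_threshold=0)


class TestTargetRule:
    def test_full_scale_patient(self):
        p = PatientParameters(ka=0.03, BIO=0.8, Q=0.5, V1=11, V2=27, CL=0.5,
                              Rsyn=0.01, kEO=0.02, BASE=-3.0, EMAX=6.0,
                              EC50=1.5, gamma=3.0)
        t = target_from_patient(p)
        assert t.theta_t == pytest.approx(0.3)
        assert (t.theta_min, t.theta_max) == (pytest.approx(0.6), pytest.approx(1.2))

    def test_unit_maximum(self):
        p = PatientParameters(ka=0.03, BIO=0.8, Q=0.5, V1=11, V2=27, CL=0.5,
                              Rsyn=0.01, kEO=0.02, BASE=-1.5, EMAX=2.5,
                              EC50=1.5, gamma=3.0)
        t = target_from_patient(p)
        assert t.theta_t == pytest.approx(0.1)
        assert (t.theta_min, t.theta_max) == (pytest.approx(0.2), pytest.approx(0.4))

    def test_range_is_proper_whenever_emax_positive(self, population):
        from pdsched.experiments import sample_treatable_patients
        for p in sample_treatable_patients(population, 10, 0):
            t = target_from_patient(p)
            assert t.theta_min < t.theta_max

    def test_non_positive_maximum_rejected(self):
        p = PatientParameters(ka=0.03, BIO=0.8, Q=0.5, V1=11, V2=27, CL=0.5,
                              Rsyn=0.01, kEO=0.02, BASE=-3.0, EMAX=2.5,
                              EC50=1.5, gamma=3.0)
        with pytest.raises(ValueError):
            target_from_patient(p)


def _coarse_problem(n_doses=5):
    return ScheduleProblem(960.0, n_doses,
                           ConstraintSet.from_numbers([1, 2, 3, 4], time_step=30),
                           dose_step=50.0, maintenance_max=300.0)


def _brute_force_reversed(problem, objective, interval_step):
    """Independent enumeration with reversed loop order."""
    n = problem.n_doses
    dt_max = (problem.day_length - problem.grid_step) / (n - 1)
    best = (np.inf, None)
    for d_main in np.arange(problem.maintenance_max, -1e-9, -problem.dose_step):
        for d_mor in np.arange(problem.dose_max, -1e-9, -problem.dose_step):
            for dt in np.arange(interval_step * np.floor(dt_max / interval_step),
                                problem.min_interval - 1e-9, -interval_step):
                s = DoseSchedule(first_time=0.0, intervals=(float(dt),) * (n - 1),
                                 sizes=(float(d_mor),) + (float(d_main),) * (n - 1))
                score = objective(s)
                if score < best[0] - 1e-12:
                    best = (score, s)
    return best


class TestExhaustive:
    def test_single_candidate_grid(self, patient):
        prob = ScheduleProblem(960.0, 5,
                               ConstraintSet.from_numbers([1, 2, 3, 4]),
                               dose_step=200.0, dose_max=200.0, maintenance_max=0.0)
        target = target_from_patient(patient)
        ev = pkpd_evaluator(patient, 960.0)
        obj = make_objective(ev, ObjectiveSpec(), target)
        res = exhaustive_search(prob, ev, target, interval_step=900.0, objective=obj)
        assert res.n_evaluations == 2 * 1 * 1  # intervals {90, 990->capped}; sizes fixed
        assert res.schedule.sizes[0] in (0.0, 200.0)

    def test_matches_independent_reversed_enumeration(self, patient):
        prob = _coarse_problem()
        target = target_from_patient(patient)
        ev = pkpd_evaluator(patient, 960.0)
        obj = make_objective(ev, ObjectiveSpec(), target)
        res = exhaustive_search(prob, ev, target, interval_step=30.0, objective=obj)
        ref_score, _ = _brute_force_reversed(prob, obj, 30.0)
        assert res.score == pytest.approx(ref_score, abs=1e-9)

    def test_requires_all_constraints(self, patient):
        prob = ScheduleProblem(960.0, 5, ConstraintSet.from_numbers([1, 2]))
        with pytest.raises(ValueError):
            exhaustive_search(prob, pkpd_evaluator(patient, 960.0),
                              target_from_patient(patient))

    def test_infeasible_grid_reported(self, patient):
        # zero doses allowed only -> state never reaches the threshold
        prob = ScheduleProblem(960.0, 5,
                               ConstraintSet.from_numbers([1, 2, 3, 4]),
                               dose_step=5.0, dose_max=0.0, maintenance_max=0.0)
        with pytest.raises(ValueError, match="feasible"):
            exhaustive_search(prob, pkpd_evaluator(patient, 960.0),
                              target_from_patient(patient))


class TestEvolutionaryOptimizers:
    def test_ga_and_de_find_the_exhaustive_optimum(self, patient):
        prob = _coarse_problem()
        target = target_from_patient(patient)
        ev = pkpd_evaluator(patient, 960.0)
        obj = make_objective(ev, ObjectiveSpec(), target)
        ex = exhaustive_search(prob, ev, target, interval_step=30.0, objective=obj)
        ga = optimize_ga(prob, obj, GAParams(population_size=60, generations=40),
                         rng_seed=1)
        de = optimize_de(prob, obj, DEParams(population_size=30, generations=40),
                         rng_seed=1)
        assert ga.score == pytest.approx(ex.score, abs=1e-9)
        assert de.score == pytest.approx(ex.score, abs=1e-9)

    def test_every_evaluated_candidate_within_bounds(self, patient):
        prob = _coarse_problem()
        spec = prob.variable_spec()
        seen = []

        def recording_objective(schedule):
            seen.append(prob.encode(schedule))
            return objective_dose_sum(schedule)

        optimize_ga(prob, recording_objective,
                    GAParams(population_size=20, generations=10), rng_seed=2)
        optimize_de(prob, recording_objective,
                    DEParams(population_size=10, generations=10), rng_seed=2)
        X = np.stack(seen)
        assert np.all(X >= spec.lower - 1e-9) and np.all(X <= spec.upper + 1e-9)
        on = spec.lattice > 0
        offsets = (X[:, on] - spec.lower[on]) / spec.lattice[on]
        assert np.allclose(offsets, np.round(offsets))

    def test_seeded_determinism(self, patient):
        prob = _coarse_problem()
        target = target_from_patient(patient)
        obj = make_objective(pkpd_evaluator(patient, 960.0), ObjectiveSpec(), target)
        for opt, params in [(optimize_ga, GAParams(population_size=20, generations=8)),
                            (optimize_de, DEParams(population_size=10, generations=8))]:
            a = opt(prob, obj, params, rng_seed=7)
            b = opt(prob, obj, params, rng_seed=7)
            assert a.score == b.score
            assert a.history == b.history
            assert a.schedule == b.schedule

    def test_de_degenerate_operators_leave_population_invariant(self, patient):
        prob = _coarse_problem()
        obj = objective_dose_sum
        res = optimize_de(prob, obj, DEParams(population_size=10, generations=15,
                                              cxpb=0.0, diff_weight=0.0), rng_seed=3)
        assert len(set(res.history)) == 1  # best never changes without variation

    def test_de_sphere_self_test(self):
        prob = ScheduleProblem(960.0, 3, ConstraintSet(), dose_step=5.0)
        spec = prob.variable_spec()
        center = spec.snap((spec.lower + spec.upper) / 2)

        def sphere(schedule):
            x = prob.encode(schedule)
            return float(np.sum(((x - center) / (spec.upper - spec.lower)) ** 2))

        res = optimize_de(prob, sphere, DEParams(population_size=40, generations=150),
                          rng_seed=4)
        assert res.score < 1e-3

    def test_scipy_de_agrees_on_the_constrained_problem(self, patient):
        """Independent cross-check with the scipy DE implementation."""
        prob = _coarse_problem()
        target = target_from_patient(patient)
        obj = make_objective(pkpd_evaluator(patient, 960.0), ObjectiveSpec(), target)
        spec = prob.variable_spec()
        res_scipy = scipy_de(lambda x: obj(prob.decode(spec.snap(x))),
                             bounds=list(zip(spec.lower, spec.upper)),
                             integrality=spec.lattice > 0, seed=5, tol=1e-8,
                             popsize=20, maxiter=200, polish=False)
        mine = optimize_de(prob, obj, DEParams(population_size=30, generations=60),
                           rng_seed=5)
        assert mine.score == pytest.approx(res_scipy.fun, abs=1e-6)

    def test_relaxation_never_worsens_the_optimized_score(self, patient):
        target = target_from_patient(patient)
        ev = pkpd_evaluator(patient, 960.0)
        obj = make_objective(ev, ObjectiveSpec(threshold_after_onset=True), target)
        prob_c = ScheduleProblem(960.0, 5, ConstraintSet.from_numbers([1, 2, 3, 4]),
                                 dose_step=50.0)
        res_c = optimize_de(prob_c, obj, DEParams(population_size=20, generations=40),
                            rng_seed=6)
        prob_r = ScheduleProblem(960.0, 5, ConstraintSet.from_numbers([1, 2]),
                                 dose_step=50.0)
        res_r = optimize_de(prob_r, obj, DEParams(population_size=30, generations=60),
                            rng_seed=6, init_schedules=[res_c.schedule])
        assert res_r.score <= res_c.score + 1e-9

    def test_returned_schedules_satisfy_their_constraints(self, patient):
        target = target_from_patient(patient)
        obj = make_objective(pkpd_evaluator(patient, 960.0), ObjectiveSpec(), target)
        prob = ScheduleProblem(960.0, 4, ConstraintSet.from_numbers([1, 2, 3, 4]),
                               dose_step=50.0)
        res = optimize_ga(prob, obj, GAParams(population_size=20, generations=10),
                          rng_seed=8)
        s = res.schedule
        assert s.first_time == 0.0
        assert len(set(s.intervals)) == 1 and s.intervals[0] >= 90.0
        assert len(set(s.sizes[1:])) == 1
        assert all(d % 50 == 0 and 0 <= d <= 400 for d in s.sizes)


class TestModelBackedEvaluation:
    def test_ml_evaluator_feeds_the_objective(self, tiny_impulse_model, patient):
        target = target_from_patient(patient)
        ev = model_evaluator(tiny_impulse_model, -1.5, 600.0)
        sched = DoseSchedule.from_times([0.0, 200.0], [200.0, 100.0])
        trace = ev(sched)
        assert len(trace) == 60
        score = make_objective(ev, ObjectiveSpec(), target)(sched)
        assert np.isfinite(score) and score >= 0


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10 ** 6))
def test_encode_decode_identity_property(seed):
    rng = np.random.default_rng(seed)
    prob = ScheduleProblem(960.0, 4, ConstraintSet.from_numbers([1, 3]))
    spec = prob.variable_spec()
    x = spec.sample(rng)
    assert np.allclose(prob.encode(prob.decode(x)), x)
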