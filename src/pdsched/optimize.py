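"""Constrained daily-schedule optimization.

A schedule is encoded as decision variables ``[times | sizes]``: the first
intake time, the inter-dose intervals, and the integer dose sizes.  Four
optional constraints shrink the encoding:

1. discrete intake times on a fixed lattice (default 10 min);
2. first dose at wake (drops ``t1``);
3. two dose sizes only — morning dose + equal maintenance doses;
4. equal intervals between doses (collapses the interval block to one
   variable).

With all four active an ``n``-dose day reduces to three variables
``[dt, d_mor, d_main]``.

Objectives are evaluated on a predicted TRS trace (PK/PD simulator or a
learned response model) over the waking day: total dose, squared deviation
from the optimal state, squared excursion outside the target range, and
squared shortfall below the safety threshold, each integrated with the
trapezoidal rule on the grid (units TRS^2*min).  Optimizers: exhaustive
enumeration of the fully-constrained lattice (the benchmark method), a
genetic algorithm (two-point crossover, gaussian/integer-uniform mutation,
tournament selection), and classic rand/1 differential evolution with
lattice rounding for integer-constrained genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from pdsched.pkpd import (CompartmentState, DoseSchedule, GridSimulator,
                          PatientParameters, StateTrace, simulate_trace)

__all__ = [
    "ConstraintSet",
    "TargetSpec",
    "ObjectiveSpec",
    "VariableSpec",
    "ScheduleProblem",
    "GAParams",
    "DEParams",
    "OptimizationResult",
    "objective_dose_sum",
    "objective_sq_deviation",
    "objective_outside_range",
    "objective_below_threshold",
    "make_objective",
    "target_from_patient",
    "pkpd_evaluator",
    "model_evaluator",
    "exhaustive_search",
    "optimize_ga",
    "optimize_de",
]


@dataclass(frozen=True)
class ConstraintSet:
    """Which of the four schedule constraints are active."""

    discrete_times: bool = False   # constraint 1
    first_at_wake: bool = False    # constraint 2
    two_dose_sizes: bool = False   # constraint 3
    equal_intervals: bool = False  # constraint 4
    time_step: float = 10.0

    @classmethod
    def from_numbers(cls, numbers: Sequence[int], time_step: float = 10.0) -> "ConstraintSet":
        s = set(numbers)
        if not s <= {1, 2, 3, 4}:
            raise ValueError("constraint numbers must be within 1..4")
        return cls(discrete_times=1 in s, first_at_wake=2 in s,
                   two_dose_sizes=3 in s, equal_intervals=4 in s,
                   time_step=time_step)

    @property
    def numbers(self) -> tuple[int, ...]:
        out = []
        for i, flag in enumerate([self.discrete_times, self.first_at_wake,
                                  self.two_dose_sizes, self.equal_intervals], start=1):
            if flag:
                out.append(i)
        return tuple(out)

    @property
    def label(self) -> str:
        return ",".join(map(str, self.numbers)) or "none"


@dataclass(frozen=True)
class TargetSpec:
    """Per-patient therapeutic targets, all in TRS units."""

    theta: float
    theta_min: float
    theta_max: float
    theta_t: float

    def __post_init__(self) -> None:
        if not self.theta_min <= self.theta <= self.theta_max:
            raise ValueError("theta must lie within [theta_min, theta_max]")
        if self.theta_t > self.theta_min:
            raise ValueError("threshold must not exceed theta_min")


def target_from_patient(params: PatientParameters) -> TargetSpec:
    """Threshold at 10% and target range at 20-40% of the patient's maximum state."""
    mx = params.max_effect
    if mx <= 0:
        raise ValueError("patient maximum state must be positive to define targets")
    return TargetSpec(theta=0.3 * mx, theta_min=0.2 * mx, theta_max=0.4 * mx,
                      theta_t=0.1 * mx)


@dataclass(frozen=True)
class ObjectiveSpec:
    """Weights combining the four scheduling criteria (all >= 0, not all zero).

    ``below_threshold`` doubles as the threshold-violation penalty weight
    when the area-outside-range objective is the primary criterion.
    ``squared`` selects the squared-max reading of the area criteria.
    ``threshold_after_onset`` restricts the below-threshold term to grid
    points after the state first reaches the threshold — the penalty then
    punishes falling back under the threshold between doses rather than the
    unavoidable morning climb from the drug-free baseline.
    """

    dose_sum: float = 0.0
    sq_deviation: float = 0.0
    outside_range: float = 1.0
    below_threshold: float = 10.0
    squared: bool = True
    threshold_after_onset: bool = False

    def __post_init__(self) -> None:
        w = (self.dose_sum, self.sq_deviation, self.outside_range, self.below_threshold)
        if any(x < 0 for x in w):
            raise ValueError("objective weights must be non-negative")
        if all(x == 0 for x in w):
            raise ValueError("at least one objective weight must be positive")


def _trapz(y: np.ndarray, dx: float) -> float:
    return float(np.trapezoid(y, dx=dx))


def objective_dose_sum(schedule: DoseSchedule) -> float:
    """Total daily medication load (mg)."""
    return schedule.total_dose


def objective_sq_deviation(trace: StateTrace, target: TargetSpec) -> float:
    """Integrated squared deviation from the optimal state."""
    return _trapz((trace.values - target.theta) ** 2, trace.grid_step)


def objective_outside_range(trace: StateTrace, target: TargetSpec,
                            squared: bool = True) -> float:
    """Integrated (squared) excursion outside [theta_min, theta_max]."""
    if not target.theta_min < target.theta_max:
        raise ValueError("theta_min must be below theta_max")
    v = trace.values
    exc = np.maximum(0.0, np.maximum(target.theta_min - v, v - target.theta_max))
    return _trapz(exc ** 2 if squared else exc, trace.grid_step)


def objective_below_threshold(trace: StateTrace, target: TargetSpec,
                              squared: bool = True,
                              after_onset: bool = False) -> float:
    """Integrated (squared) shortfall below the safety threshold.

    With ``after_onset`` the shortfall is only counted from the grid point
    where the state first reaches the threshold (zero if it never does not
    apply — a trace that never reaches the threshold scores zero shortfall
    after onset, so combine with the outside-range criterion).
    """
    v = trace.values
    short = np.maximum(0.0, target.theta_t - v)
    if after_onset:
        above = np.nonzero(v >= target.theta_t)[0]
        short = short.copy()
        short[: above[0] if above.size else short.size] = 0.0
    return _trapz(short ** 2 if squared else short, trace.grid_step)


def make_objective(evaluator: Callable[[DoseSchedule], StateTrace],
                   spec: ObjectiveSpec, target: TargetSpec
                   ) -> Callable[[DoseSchedule], float]:
    """Weighted combination of the criteria on the evaluated trace."""

    def objective(schedule: DoseSchedule) -> float:
        total = 0.0
        if spec.dose_sum:
            total += spec.dose_sum * objective_dose_sum(schedule)
        if spec.sq_deviation or spec.outside_range or spec.below_threshold:
            try:
                trace = evaluator(schedule)
            except Exception as exc:
                raise RuntimeError(f"trace evaluation failed for {schedule}") from exc
            if spec.sq_deviation:
                total += spec.sq_deviation * objective_sq_deviation(trace, target)
            if spec.outside_range:
                total += spec.outside_range * objective_outside_range(trace, target, spec.squared)
            if spec.below_threshold:
                total += spec.below_threshold * objective_below_threshold(
                    trace, target, spec.squared, after_onset=spec.threshold_after_onset)
        return total

    return objective


def pkpd_evaluator(params: PatientParameters, day_length: float,
                   grid_step: float = 10.0,
                   initial: CompartmentState | None = None
                   ) -> Callable[[DoseSchedule], StateTrace]:
    """Trace evaluator backed by the exact PK/PD simulator.

    Uses the cached one-step propagator; dose times are rounded to the grid
    (optimization encodings are grid-aligned anyway).
    """
    sim = GridSimulator(params, day_length, grid_step, initial=initial)
    return sim.trace


def model_evaluator(model, initial_state: float, day_length: float
                    ) -> Callable[[DoseSchedule], StateTrace]:
    """Trace evaluator backed by a trained response model (closed-loop rollout)."""
    n_steps = int(round(day_length / model.grid_step)) - 1

    def evaluate(schedule: DoseSchedule) -> StateTrace:
        return model.predict_day(initial_state, schedule, n_steps)

    return evaluate


# ---------------------------------------------------------------------------
# decision-variable encoding


@dataclass(frozen=True)
class VariableSpec:
    """Bounds and lattice steps of the encoded decision vector."""

    names: tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray
    lattice: np.ndarray  # lattice step per variable; 0 = continuous

    @property
    def dim(self) -> int:
        return len(self.names)

    def snap(self, x: np.ndarray) -> np.ndarray:
        """Round lattice-constrained genes to their lattice and clip to bounds."""
        x = np.asarray(x, dtype=float).copy()
        on = self.lattice > 0
        x[on] = self.lower[on] + np.round((x[on] - self.lower[on]) / self.lattice[on]) \
            * self.lattice[on]
        return np.clip(x, self.lower, self.upper)

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        x = rng.uniform(self.lower, self.upper)
        return self.snap(x)


class ScheduleProblem:
    """Encoding/decoding of an n-dose day under a constraint set.

    ``maintenance_max`` bounds non-morning doses (the benchmark enumeration
    uses 300 mg; general optimization uses the full 400 mg).
    ``first_dose_window`` bounds ``t1`` when the first dose is not pinned
    to wake-up.
    """

    def __init__(self, day_length: float, n_doses: int,
                 constraints: ConstraintSet,
                 dose_step: float = 5.0, min_interval: float = 90.0,
                 dose_max: float = 400.0, maintenance_max: float | None = None,
                 grid_step: float = 10.0, first_dose_window: float = 240.0):
        if n_doses < 1:
            raise ValueError("need at least one dose")
        if min_interval < grid_step:
            raise ValueError("min_interval must be >= grid_step")
        if (n_doses - 1) * min_interval > day_length - grid_step:
            raise ValueError("dose count infeasible for the day length")
        self.day_length = float(day_length)
        self.n_doses = int(n_doses)
        self.constraints = constraints
        self.dose_step = float(dose_step)
        self.min_interval = float(min_interval)
        self.dose_max = float(dose_max)
        self.maintenance_max = float(maintenance_max if maintenance_max is not None
                                     else dose_max)
        self.grid_step = float(grid_step)
        self.first_dose_window = float(first_dose_window)

    # -- encoding ----------------------------------------------------------

    def variable_spec(self) -> VariableSpec:
        c = self.constraints
        n = self.n_doses
        names: list[str] = []
        lower: list[float] = []
        upper: list[float] = []
        lattice: list[float] = []
        t_lat = c.time_step if c.discrete_times else 0.0
        t1_max = 0.0 if c.first_at_wake else min(
            self.first_dose_window,
            self.day_length - self.grid_step - self.min_interval * (n - 1))
        if not c.first_at_wake:
            names.append("t1")
            lower.append(0.0)
            upper.append(t1_max)
            lattice.append(t_lat)
        if n > 1:
            dt_max = (self.day_length - self.grid_step - t1_max) / (n - 1)
            if c.discrete_times:
                dt_max = c.time_step * np.floor(dt_max / c.time_step)
            n_dt = 1 if c.equal_intervals else n - 1
            for i in range(n_dt):
                names.append("dt" if c.equal_intervals else f"dt{i + 2}")
                lower.append(self.min_interval)
                upper.append(dt_max)
                lattice.append(t_lat)
        if c.two_dose_sizes and n > 1:
            names += ["d_mor", "d_main"]
            lower += [0.0, 0.0]
            upper += [self.dose_max, self.maintenance_max]
            lattice += [self.dose_step, self.dose_step]
        else:
            for i in range(n):
                names.append(f"d{i + 1}")
                lower.append(0.0)
                upper.append(self.dose_max if i == 0 else self.maintenance_max)
                lattice.append(self.dose_step)
        return VariableSpec(names=tuple(names), lower=np.array(lower),
                            upper=np.array(upper), lattice=np.array(lattice))

    def decode(self, x: Sequence[float]) -> DoseSchedule:
        """Decision vector -> schedule (times block first, sizes block second)."""
        x = np.asarray(x, dtype=float)
        spec = self.variable_spec()
        if x.shape != (spec.dim,):
            raise ValueError(f"expected {spec.dim} decision variables, got {x.shape}")
        c = self.constraints
        n = self.n_doses
        i = 0
        t1 = 0.0
        if not c.first_at_wake:
            t1 = float(x[i]); i += 1
        if n > 1:
            if c.equal_intervals:
                intervals = (float(x[i]),) * (n - 1); i += 1
            else:
                intervals = tuple(float(v) for v in x[i:i + n - 1]); i += n - 1
        else:
            intervals = ()
        if c.two_dose_sizes and n > 1:
            d_mor, d_main = float(x[i]), float(x[i + 1])
            sizes = (d_mor,) + (d_main,) * (n - 1)
        else:
            sizes = tuple(float(v) for v in x[i:i + n])
        return DoseSchedule(first_time=t1, intervals=intervals, sizes=sizes)

    def encode(self, schedule: DoseSchedule) -> np.ndarray:
        if schedule.n != self.n_doses:
            raise ValueError("schedule dose count does not match the problem")
        c = self.constraints
        out: list[float] = []
        if not c.first_at_wake:
            out.append(schedule.first_time or 0.0)
        if self.n_doses > 1:
            if c.equal_intervals:
                ivals = set(np.round(schedule.intervals, 9))
                if len(ivals) > 1:
                    raise ValueError("equal-interval constraint violated by schedule")
                out.append(schedule.intervals[0])
            else:
                out.extend(schedule.intervals)
        if c.two_dose_sizes and self.n_doses > 1:
            maint = set(schedule.sizes[1:])
            if len(maint) > 1:
                raise ValueError("two-dose-size constraint violated by schedule")
            out.extend([schedule.sizes[0], schedule.sizes[1]])
        else:
            out.extend(schedule.sizes)
        return np.asarray(out, dtype=float)

    def vector_objective(self, schedule_objective: Callable[[DoseSchedule], float]
                         ) -> Callable[[np.ndarray], float]:
        return lambda x: schedule_objective(self.decode(x))


# ---------------------------------------------------------------------------
# exhaustive benchmark


@dataclass(frozen=True)
class OptimizationResult:
    schedule: DoseSchedule
    score: float
    n_evaluations: int = 0
    history: tuple[float, ...] = ()


def _threshold_feasible(trace: StateTrace, target: TargetSpec) -> bool:
    """State reaches the threshold and never falls below it afterwards."""
    v = trace.values
    above = np.nonzero(v >= target.theta_t)[0]
    if above.size == 0:
        return False
    return bool(np.all(v[above[0]:] >= target.theta_t))


def exhaustive_search(problem: ScheduleProblem,
                      evaluator: Callable[[DoseSchedule], StateTrace],
                      target: TargetSpec,
                      interval_step: float = 10.0,
                      objective: Callable[[DoseSchedule], float] | None = None,
                      squared: bool = True) -> OptimizationResult:
    """Enumerate the fully-constrained lattice of (interval, morning, maintenance).

    Default benchmark behaviour: minimize the area outside the target range
    subject to the threshold-feasibility rule (after the state first reaches
    the threshold it must stay above it); ties broken by smaller total dose,
    then smaller interval.  A custom ``objective`` replaces both the score
    and the feasibility filter.
    """
    c = problem.constraints
    if not (c.discrete_times and c.first_at_wake and c.two_dose_sizes and c.equal_intervals):
        raise ValueError("exhaustive search requires all four constraints active")
    n = problem.n_doses
    dt_max = (problem.day_length - problem.grid_step) / max(1, n - 1)
    intervals = np.arange(problem.min_interval, dt_max + 1e-9, interval_step)
    mors = np.arange(0.0, problem.dose_max + 1e-9, problem.dose_step)
    mains = np.arange(0.0, problem.maintenance_max + 1e-9, problem.dose_step)
    best_key = None
    best: tuple[DoseSchedule, float] | None = None
    n_eval = 0
    for dt in intervals:
        for d_mor in mors:
            for d_main in mains:
                sched = DoseSchedule(first_time=0.0, intervals=(float(dt),) * (n - 1),
                                     sizes=(float(d_mor),) + (float(d_main),) * (n - 1))
                n_eval += 1
                if objective is not None:
                    score = objective(sched)
                else:
                    trace = evaluator(sched)
                    if not _threshold_feasible(trace, target):
                        continue
                    score = objective_outside_range(trace, target, squared)
                key = (score, sched.total_dose, dt)
                if best_key is None or key < best_key:
                    best_key = key
                    best = (sched, float(score))
    if best is None:
        raise ValueError("no feasible schedule on the enumerated grid")
    return OptimizationResult(schedule=best[0], score=best[1], n_evaluations=n_eval)


# ---------------------------------------------------------------------------
# genetic algorithm


@dataclass(frozen=True)
class GAParams:
    population_size: int = 100
    generations: int = 60
    cxpb: float = 0.5
    mutpb: float = 0.2
    per_variable_prob: float = 0.1
    tournament_k: int = 3
    gaussian_scale_frac: float = 0.1

    def __post_init__(self) -> None:
        for p in (self.cxpb, self.mutpb, self.per_variable_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        if self.population_size <= 2:
            raise ValueError("population must exceed 2")


def optimize_ga(problem: ScheduleProblem,
                schedule_objective: Callable[[DoseSchedule], float],
                params: GAParams = GAParams(), rng_seed=0) -> OptimizationResult:
    """Seeded genetic algorithm over the encoded schedule space.

    Tournament selection, two-point crossover, gaussian mutation for
    continuous genes (sd = 10% of the variable range, clipped to bounds) and
    uniform lattice resampling for discrete genes.  The best individual ever
    evaluated is returned.
    """
    rng = np.random.default_rng(rng_seed)
    spec = problem.variable_spec()
    fobj = problem.vector_objective(schedule_objective)
    n, dim = params.population_size, spec.dim
    pop = np.stack([spec.sample(rng) for _ in range(n)])
    fits = np.array([fobj(x) for x in pop])
    n_eval = n
    best_i = int(np.argmin(fits))
    best_x, best_f = pop[best_i].copy(), float(fits[best_i])
    history = [best_f]
    scale = params.gaussian_scale_frac * (spec.upper - spec.lower)
    for _ in range(params.generations):
        # tournament selection (fitness = negative objective, maximized)
        idx = rng.integers(0, n, size=(n, params.tournament_k))
        winners = idx[np.arange(n), np.argmin(fits[idx], axis=1)]
        pop = pop[winners].copy()
        fits = fits[winners].copy()
        changed = np.zeros(n, dtype=bool)
        for i in range(0, n - 1, 2):
            if rng.random() < params.cxpb and dim >= 2:
                a, b = sorted(rng.choice(dim + 1, size=2, replace=False))
                if a != b:
                    tmp = pop[i, a:b].copy()
                    pop[i, a:b] = pop[i + 1, a:b]
                    pop[i + 1, a:b] = tmp
                    changed[i] = changed[i + 1] = True
        for i in range(n):
            if rng.random() < params.mutpb:
                for j in range(dim):
                    if rng.random() < params.per_variable_prob:
                        if spec.lattice[j] > 0:
                            points = np.arange(spec.lower[j], spec.upper[j] + 1e-9,
                                               spec.lattice[j])
                            pop[i, j] = rng.choice(points)
                        else:
                            pop[i, j] += rng.normal(0.0, scale[j])
                        changed[i] = True
            if changed[i]:
                pop[i] = spec.snap(pop[i])
                fits[i] = fobj(pop[i])
                n_eval += 1
                if fits[i] < best_f:
                    best_f = float(fits[i])
                    best_x = pop[i].copy()
        history.append(best_f)
    return OptimizationResult(schedule=problem.decode(best_x), score=best_f,
                              n_evaluations=n_eval, history=tuple(history))


# ---------------------------------------------------------------------------
# differential evolution (rand/1, per the classic scheme)


@dataclass(frozen=True)
class DEParams:
    population_size: int = 40
    cxpb: float = 0.8
    diff_weight: float = 0.7
    generations: int = 80

    def __post_init__(self) -> None:
        if not 0 <= self.cxpb <= 1:
            raise ValueError("CXPB must be in [0, 1]")
        if self.diff_weight < 0:
            raise ValueError("differential weight must be non-negative")
        if self.population_size <= 2:
            raise ValueError("population must exceed 2")


def optimize_de(problem: ScheduleProblem,
                schedule_objective: Callable[[DoseSchedule], float],
                params: DEParams = DEParams(), rng_seed=0,
                init_schedules: Sequence[DoseSchedule] = ()) -> OptimizationResult:
    """Seeded rand/1 differential evolution with greedy replacement.

    For each member, a trial vector ``v[i] = a[i] + F*(b[i]-c[i])`` is built
    gene-wise under the crossover probability from three distinct random
    individuals, rounded to the admissible lattice for integer-constrained
    genes, clipped to bounds, and replaces the member if not worse.
    ``init_schedules`` are injected into the initial population (warm starts).
    """
    rng = np.random.default_rng(rng_seed)
    spec = problem.variable_spec()
    fobj = problem.vector_objective(schedule_objective)
    n = params.population_size
    pop = np.stack([spec.sample(rng) for _ in range(n)])
    for i, sched in enumerate(init_schedules):
        if i >= n:
            break
        pop[i] = spec.snap(problem.encode(sched))
    fits = np.array([fobj(x) for x in pop])
    n_eval = n
    history = [float(fits.min())]
    for _ in range(params.generations):
        for j in range(n):
            choices = [i for i in range(n) if i != j]
            a, b, c = pop[rng.choice(choices, size=3, replace=False)]
            cross = rng.random(spec.dim) < params.cxpb
            v = np.where(cross, a + params.diff_weight * (b - c), pop[j])
            v = spec.snap(v)
            fv = fobj(v)
            n_eval += 1
            if fv <= fits[j]:
                pop[j] = v
                fits[j] = fv
        history.append(float(fits.min()))
    best = int(np.argmin(fits))
    return OptimizationResult(schedule=problem.decode(pop[best]), score=float(fits[best]),
                              n_evaluations=n_eval, history=tuple(history))
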