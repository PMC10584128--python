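"""Virtual-patient PK/PD simulator for oral levodopa dosing.

The drug model is a linear three-compartment pharmacokinetic system (gut
depot ``a0``, central ``a1``, peripheral ``a2``) coupled to a hypothetical
effect compartment whose concentration ``ce`` equilibrates with plasma at
rate ``kEO``.  The observed clinical state is the Treatment Response Scale
(TRS, -3 severe parkinsonism .. +3 severe dyskinesia), obtained from ``ce``
through a sigmoid-Emax (Hill) law::

    E(ce) = BASE + EMAX * ce**gamma / (ce**gamma + EC50**gamma)

Oral doses are instantaneous boluses added to the depot compartment.  The
compartment system is linear, so trajectories are propagated exactly with
piecewise matrix exponentials (an adaptive ODE integrator is available as a
cross-check via ``method="ivp"``).

Virtual patients are drawn from a multivariate-normal population model
(means + covariance, clipped to admissible per-parameter intervals) and
medication days are generated on a 10-minute grid with randomized day
length, dose count, dose times and sizes.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import solve_ivp
from scipy.linalg import expm

__all__ = [
    "PARAM_NAMES",
    "PatientParameters",
    "CompartmentState",
    "DoseEvent",
    "DoseSchedule",
    "StateTrace",
    "PopulationModel",
    "DayGenConfig",
    "DayRecord",
    "effect_from_concentration",
    "pkpd_derivatives",
    "system_matrices",
    "simulate_compartments",
    "simulate_trace",
    "sample_patient",
    "sample_cohort",
    "generate_day",
    "default_population",
    "write_dataset",
    "read_dataset",
]

#: Canonical ordering of the 12 patient-specific constants.
PARAM_NAMES = (
    "ka", "BIO", "Q", "V1", "V2", "CL",
    "Rsyn", "kEO", "BASE", "EMAX", "EC50", "gamma",
)

TRS_MIN = -3.0
TRS_MAX = 3.0


@dataclass(frozen=True)
class PatientParameters:
    """Patient-specific PK/PD constants.

    Units: rates 1/min, volumes L, clearances L/min, ``Rsyn`` mg/min,
    ``EC50`` mg/L; ``BASE``/``EMAX`` in TRS units.
    """

    ka: float
    BIO: float
    Q: float
    V1: float
    V2: float
    CL: float
    Rsyn: float
    kEO: float
    BASE: float
    EMAX: float
    EC50: float
    gamma: float

    def __post_init__(self) -> None:
        for name in ("ka", "Q", "V1", "V2", "CL", "kEO", "EC50", "gamma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.BIO <= 1:
            raise ValueError("BIO must be in (0, 1]")
        if self.Rsyn < 0:
            raise ValueError("Rsyn must be non-negative")
        if self.BASE < TRS_MIN:
            raise ValueError("BASE must be >= -3")
        if self.BASE + self.EMAX > TRS_MAX + 1e-12:
            raise ValueError("BASE + EMAX must be <= 3")

    @property
    def max_effect(self) -> float:
        """Upper bound of the patient's reachable TRS range (BASE + EMAX)."""
        return self.BASE + self.EMAX

    def endogenous_steady_state(self) -> "CompartmentState":
        """Drug-free steady state sustained by endogenous synthesis."""
        a1 = self.Rsyn * self.V1 / self.CL
        a2 = (self.V2 / self.V1) * a1
        return CompartmentState(a0=0.0, a1=a1, a2=a2, ce=a1 / self.V1)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "PatientParameters":
        return cls(**dict(zip(PARAM_NAMES, map(float, values))))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class CompartmentState:
    """Amounts (mg) in the three PK compartments and effect concentration (mg/L)."""

    a0: float
    a1: float
    a2: float
    ce: float

    def as_array(self) -> np.ndarray:
        return np.array([self.a0, self.a1, self.a2, self.ce], dtype=float)

    @classmethod
    def from_array(cls, x: Sequence[float]) -> "CompartmentState":
        return cls(*map(float, x))


@dataclass(frozen=True)
class DoseEvent:
    """A single oral intake: time in minutes from wake, amount in mg."""

    time: float
    amount: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("dose time must be non-negative")
        if self.amount < 0:
            raise ValueError("dose amount must be non-negative")


@dataclass(frozen=True)
class DoseSchedule:
    """Daily intake schedule: first intake time, inter-dose intervals, sizes.

    ``times`` expands the (first_time, intervals) encoding to absolute
    minutes from wake.  An empty schedule has ``first_time=None``.
    """

    first_time: float | None = None
    intervals: tuple[float, ...] = ()
    sizes: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        n = len(self.sizes)
        if n == 0:
            if self.first_time is not None or self.intervals:
                raise ValueError("empty schedule must have no times")
            return
        if self.first_time is None or self.first_time < 0:
            raise ValueError("first_time must be >= 0 for a non-empty schedule")
        if len(self.intervals) != n - 1:
            raise ValueError("need exactly n-1 intervals for n doses")
        if any(dt <= 0 for dt in self.intervals):
            raise ValueError("intervals must be positive")
        if any(d < 0 for d in self.sizes):
            raise ValueError("dose sizes must be non-negative")

    @property
    def n(self) -> int:
        return len(self.sizes)

    @property
    def times(self) -> np.ndarray:
        if self.n == 0:
            return np.empty(0)
        return self.first_time + np.concatenate([[0.0], np.cumsum(self.intervals)])

    @property
    def total_dose(self) -> float:
        return float(sum(self.sizes))

    @classmethod
    def from_times(cls, times: Sequence[float], sizes: Sequence[float]) -> "DoseSchedule":
        times = [float(t) for t in times]
        sizes = [float(d) for d in sizes]
        if len(times) != len(sizes):
            raise ValueError("times and sizes must have equal length")
        if not times:
            return cls()
        order = np.argsort(times)
        times = [times[i] for i in order]
        sizes = [sizes[i] for i in order]
        intervals = tuple(float(b - a) for a, b in zip(times, times[1:]))
        return cls(first_time=times[0], intervals=intervals, sizes=tuple(sizes))

    def events(self) -> list[DoseEvent]:
        return [DoseEvent(t, d) for t, d in zip(self.times, self.sizes)]


@dataclass(frozen=True)
class StateTrace:
    """TRS scores on a fixed-step minutes-from-wake grid."""

    times: np.ndarray
    values: np.ndarray
    day_length: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or times.shape != values.shape:
            raise ValueError("times and values must be matching 1-D arrays")
        if times.size >= 2:
            steps = np.diff(times)
            if not np.allclose(steps, steps[0]) or steps[0] <= 0:
                raise ValueError("grid must be strictly increasing with constant step")

    @property
    def grid_step(self) -> float:
        if self.times.size < 2:
            return float("nan")
        return float(self.times[1] - self.times[0])

    def __len__(self) -> int:
        return self.times.size


def effect_from_concentration(ce, params: PatientParameters):
    """Map effect-compartment concentration to a TRS score via the Hill law.

    Accepts scalars or arrays; raises on negative concentrations.
    """
    ce_arr = np.asarray(ce, dtype=float)
    if np.any(ce_arr < 0):
        raise ValueError("effect-compartment concentration must be non-negative")
    num = np.power(ce_arr, params.gamma)
    frac = np.divide(num, num + params.EC50 ** params.gamma,
                     out=np.zeros_like(num), where=(num + params.EC50 ** params.gamma) > 0)
    out = params.BASE + params.EMAX * frac
    return float(out) if np.isscalar(ce) or out.ndim == 0 else out


def system_matrices(params: PatientParameters) -> tuple[np.ndarray, np.ndarray]:
    """Linear system ``dx/dt = A x + b`` for x = (a0, a1, a2, ce), no infusion."""
    p = params
    A = np.array([
        [-p.ka, 0.0, 0.0, 0.0],
        [p.BIO * p.ka, -(p.Q + p.CL) / p.V1, p.Q / p.V2, 0.0],
        [0.0, p.Q / p.V1, -p.Q / p.V2, 0.0],
        [0.0, p.kEO / p.V1, 0.0, -p.kEO],
    ])
    b = np.array([0.0, p.Rsyn, 0.0, 0.0])
    return A, b


def pkpd_derivatives(state: CompartmentState, params: PatientParameters,
                     inf_rate: float = 0.0) -> CompartmentState:
    """Time derivatives of the compartment system, optional infusion (mg/min)."""
    if inf_rate < 0:
        raise ValueError("infusion rate must be non-negative")
    x = state.as_array()
    if np.any(x < 0):
        raise ValueError("compartment amounts must be non-negative")
    A, b = system_matrices(params)
    dx = A @ x + b
    dx[0] += inf_rate
    return CompartmentState.from_array(dx)


def _validate_schedule_window(schedule: DoseSchedule, day_length: float) -> None:
    times = schedule.times
    if times.size and (times.min() < 0 or times.max() > day_length):
        raise ValueError("dose times must lie within [0, day_length]")


def simulate_compartments(params: PatientParameters, schedule: DoseSchedule,
                          day_length: float, grid_step: float = 10.0,
                          initial: CompartmentState | None = None,
                          method: str = "exact") -> tuple[np.ndarray, np.ndarray]:
    """Propagate the compartment system over the waking day.

    Returns ``(times, X)`` with ``X[i]`` the state at grid point ``times[i]``
    (grid ``0, step, ..., day_length - step``).  Doses are instantaneous
    boluses applied to ``a0``; the sample at a dosing time is taken before the
    bolus, so a dose influences strictly later grid points.

    ``method="exact"`` uses cached matrix exponentials (exact for this linear
    system); ``method="ivp"`` integrates with an adaptive Runge-Kutta scheme
    (rtol 1e-6, atol 1e-8) restarted at each dose event.
    """
    if day_length <= 0 or grid_step <= 0:
        raise ValueError("day_length and grid_step must be positive")
    _validate_schedule_window(schedule, day_length)
    grid = np.arange(0.0, day_length - grid_step / 2, grid_step)
    x = (initial or params.endogenous_steady_state()).as_array().copy()
    A, b = system_matrices(params)

    # breakpoints: grid points and dose times, with dose boluses applied
    # after sampling/propagation up to the event time
    dose_at: dict[float, float] = {}
    for ev in schedule.events():
        dose_at[ev.time] = dose_at.get(ev.time, 0.0) + ev.amount
    breakpoints = np.unique(np.concatenate([grid, np.array(sorted(dose_at))]))

    if method == "exact":
        xp = np.linalg.solve(A, -b)  # particular (steady-state) solution
        prop_cache: dict[float, np.ndarray] = {}
        out = np.empty((grid.size, 4))
        gi = 0
        t_prev = breakpoints[0]
        for t in breakpoints:
            dt = t - t_prev
            if dt > 0:
                key = round(dt, 9)
                P = prop_cache.get(key)
                if P is None:
                    P = prop_cache.setdefault(key, expm(A * dt))
                x = P @ (x - xp) + xp
            t_prev = t
            if gi < grid.size and np.isclose(t, grid[gi]):
                out[gi] = x
                gi += 1
            if t in dose_at:
                x[0] += dose_at[t]
        if gi != grid.size:  # pragma: no cover - defensive
            raise RuntimeError("grid points not fully sampled")
        return grid, out
    if method == "ivp":
        def rhs(_t, y):
            return A @ y + b

        out = np.empty((grid.size, 4))
        gi = 0
        t_prev = breakpoints[0]
        for t in breakpoints:
            if t > t_prev:
                sol = solve_ivp(rhs, (t_prev, t), x, method="RK45",
                                rtol=1e-6, atol=1e-8, dense_output=False)
                x = sol.y[:, -1]
            t_prev = t
            if gi < grid.size and np.isclose(t, grid[gi]):
                out[gi] = x
                gi += 1
            if t in dose_at:
                x = x.copy()
                x[0] += dose_at[t]
        return grid, out
    raise ValueError(f"unknown method {method!r}")


def simulate_trace(params: PatientParameters, schedule: DoseSchedule,
                   day_length: float, grid_step: float = 10.0,
                   initial: CompartmentState | None = None,
                   method: str = "exact") -> StateTrace:
    """Simulate the TRS trajectory of one medication day."""
    times, X = simulate_compartments(params, schedule, day_length, grid_step,
                                     initial=initial, method=method)
    values = effect_from_concentration(np.maximum(X[:, 3], 0.0), params)
    return StateTrace(times=times, values=np.asarray(values), day_length=float(day_length))


class GridSimulator:
    """Fast exact simulator for schedules with grid-aligned dose times.

    Precomputes the one-step propagator ``expm(A * grid_step)`` for a patient
    so that repeated schedule evaluations (optimization, RL) cost one 4x4
    matrix-vector product per grid step.  Dose times are rounded to the
    nearest grid point.  Identical to :func:`simulate_trace` for aligned
    schedules (both are exact for this linear system).
    """

    def __init__(self, params: PatientParameters, day_length: float,
                 grid_step: float = 10.0,
                 initial: CompartmentState | None = None):
        self.params = params
        self.day_length = float(day_length)
        self.grid_step = float(grid_step)
        A, b = system_matrices(params)
        self.P = expm(A * grid_step)
        self.xp = np.linalg.solve(A, -b)
        self.x0 = (initial or params.endogenous_steady_state()).as_array()
        self.n_steps = int(round(day_length / grid_step))
        self.times = grid_step * np.arange(self.n_steps)

    def trace(self, schedule: DoseSchedule) -> StateTrace:
        bolus = np.zeros(self.n_steps)
        for t, d in zip(schedule.times, schedule.sizes):
            i = int(round(t / self.grid_step))
            if not 0 <= i < self.n_steps:
                raise ValueError("dose times must lie within the waking day")
            bolus[i] += d
        x = self.x0.copy()
        ce = np.empty(self.n_steps)
        P, xp = self.P, self.xp
        for i in range(self.n_steps):
            ce[i] = x[3]
            x = x - xp
            x[0] += bolus[i]
            x = P @ x + xp
        values = effect_from_concentration(np.maximum(ce, 0.0), self.params)
        return StateTrace(times=self.times, values=values, day_length=self.day_length)


# ---------------------------------------------------------------------------
# population sampling


@dataclass(frozen=True)
class PopulationModel:
    """Multivariate-normal population over the 12 PK/PD constants.

    ``clip_bounds`` maps each parameter to its admissible interval; draws are
    clipped there, and EMAX is additionally capped at ``3 - BASE`` so every
    patient's reachable TRS range stays inside [-3, 3].
    """

    means: np.ndarray
    covariance: np.ndarray
    clip_bounds: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        means = np.asarray(self.means, dtype=float)
        cov = np.asarray(self.covariance, dtype=float)
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "covariance", cov)
        if means.shape != (len(PARAM_NAMES),):
            raise ValueError("means must have one entry per parameter")
        if cov.shape != (len(PARAM_NAMES),) * 2:
            raise ValueError("covariance must be 12x12")
        if not np.allclose(cov, cov.T):
            raise ValueError("covariance must be symmetric")
        eigvals = np.linalg.eigvalsh(cov)
        if eigvals.min() < -1e-10 * max(1.0, eigvals.max()):
            raise ValueError("covariance must be positive semi-definite")
        for i, name in enumerate(PARAM_NAMES):
            lo, hi = self.clip_bounds[name]
            if not lo <= means[i] <= hi:
                raise ValueError(f"mean of {name} outside its clip bounds")

    @classmethod
    def from_dict(cls, spec: dict) -> "PopulationModel":
        means = np.array([spec["means"][n] for n in PARAM_NAMES], dtype=float)
        sds = np.array([spec["sds"][n] for n in PARAM_NAMES], dtype=float)
        corr = np.eye(len(PARAM_NAMES))
        for a, b, r in spec.get("correlations", []):
            i, j = PARAM_NAMES.index(a), PARAM_NAMES.index(b)
            corr[i, j] = corr[j, i] = float(r)
        cov = corr * np.outer(sds, sds)
        bounds = {n: tuple(map(float, spec["clip_bounds"][n])) for n in PARAM_NAMES}
        return cls(means=means, covariance=cov, clip_bounds=bounds)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PopulationModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_population() -> PopulationModel:
    """The packaged synthetic levodopa population."""
    ref = importlib.resources.files("pdsched") / "data" / "population.yaml"
    return PopulationModel.from_dict(yaml.safe_load(ref.read_text()))


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_patient(pop: PopulationModel, rng_seed=None) -> PatientParameters:
    """Draw one virtual patient; reproducible under a seed."""
    rng = _as_rng(rng_seed)
    draw = rng.multivariate_normal(pop.means, pop.covariance, method="svd")
    lo = np.array([pop.clip_bounds[n][0] for n in PARAM_NAMES])
    hi = np.array([pop.clip_bounds[n][1] for n in PARAM_NAMES])
    draw = np.clip(draw, lo, hi)
    vals = dict(zip(PARAM_NAMES, draw))
    vals["EMAX"] = min(vals["EMAX"], TRS_MAX - vals["BASE"])
    return PatientParameters(**{k: float(v) for k, v in vals.items()})


def sample_cohort(pop: PopulationModel, n: int, rng_seed=None) -> list[PatientParameters]:
    rng = _as_rng(rng_seed)
    return [sample_patient(pop, rng) for _ in range(n)]


# ---------------------------------------------------------------------------
# medication-day generation


@dataclass(frozen=True)
class DayGenConfig:
    """Stochastic rules for generating one medication day.

    Defaults: 14-18 h waking day, 3-7 doses, sizes on the 5 mg lattice in
    [5, 400] mg, first dose at wake, inter-dose gaps >= 90 min, 10-min grid.
    """

    wake_length_range: tuple[float, float] = (840.0, 1080.0)
    dose_count_range: tuple[int, int] = (3, 7)
    dose_size_choices: tuple[float, ...] = tuple(float(d) for d in range(5, 405, 5))
    min_interdose_gap: float = 90.0
    grid_step: float = 10.0
    first_dose_at_wake: bool = True

    def __post_init__(self) -> None:
        if self.wake_length_range[0] > self.wake_length_range[1]:
            raise ValueError("empty wake_length_range")
        if self.dose_count_range[0] > self.dose_count_range[1]:
            raise ValueError("empty dose_count_range")
        if not self.dose_size_choices:
            raise ValueError("dose_size_choices must be non-empty")
        if self.min_interdose_gap < self.grid_step:
            raise ValueError("min_interdose_gap must be >= grid_step")


def _sample_dose_times(rng: np.random.Generator, n: int, day_length: float,
                       cfg: DayGenConfig) -> np.ndarray:
    step, gap = cfg.grid_step, cfg.min_interdose_gap
    t_first = 0.0 if cfg.first_dose_at_wake else \
        step * rng.integers(0, max(1, int((day_length - gap * (n - 1)) / step)))
    last_allowed = day_length - step
    if t_first + gap * (n - 1) > last_allowed:
        raise ValueError("dose count infeasible for day length and gap")
    if n == 1:
        return np.array([t_first])
    lattice = np.arange(t_first + gap, last_allowed + step / 2, step)
    for _ in range(500):
        rest = np.sort(rng.choice(lattice, size=n - 1, replace=False))
        times = np.concatenate([[t_first], rest])
        if np.all(np.diff(times) >= gap - 1e-9):
            return times
    # constructive fallback: equally spaced on the lattice
    dt = step * np.floor((last_allowed - t_first) / (n - 1) / step)
    return t_first + dt * np.arange(n)


def generate_day(params: PatientParameters, cfg: DayGenConfig,
                 rng_seed=None) -> tuple[DoseSchedule, StateTrace]:
    """Generate one randomized medication day and its simulated TRS trace."""
    rng = _as_rng(rng_seed)
    step = cfg.grid_step
    lo, hi = cfg.wake_length_range
    day_length = step * int(rng.integers(int(lo / step), int(hi / step) + 1))
    n = int(rng.integers(cfg.dose_count_range[0], cfg.dose_count_range[1] + 1))
    if n == 0:
        schedule = DoseSchedule()
    else:
        times = _sample_dose_times(rng, n, day_length, cfg)
        sizes = rng.choice(np.asarray(cfg.dose_size_choices, dtype=float), size=n)
        schedule = DoseSchedule.from_times(times, sizes)
    trace = simulate_trace(params, schedule, day_length, grid_step=step)
    return schedule, trace


# ---------------------------------------------------------------------------
# dataset serialization


@dataclass(frozen=True)
class DayRecord:
    """One patient-day: identifiers plus schedule and TRS trace."""

    patient_id: int
    day_id: int
    schedule: DoseSchedule
    trace: StateTrace


DATASET_COLUMNS = ("patient_id", "day_id", "time_min", "trs", "dose_mg")


def write_dataset(days: Iterable[DayRecord], path: str | Path) -> None:
    """Write patient-days as long-format CSV (patient_id, day_id, time_min, trs, dose_mg)."""
    rows = []
    for rec in days:
        dose_at = {float(t): d for t, d in zip(rec.schedule.times, rec.schedule.sizes)}
        for t, v in zip(rec.trace.times, rec.trace.values):
            rows.append((rec.patient_id, rec.day_id, float(t), float(v),
                         float(dose_at.get(float(t), 0.0))))
    df = pd.DataFrame(rows, columns=DATASET_COLUMNS)
    df.to_csv(path, index=False)


def read_dataset(path: str | Path) -> list[DayRecord]:
    """Read a long-format dataset CSV back into day records."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(DATASET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"malformed dataset CSV: missing columns {sorted(missing)}")
    bad = df[df["time_min"] < 0]
    if len(bad):
        raise ValueError(f"malformed dataset CSV at row {bad.index[0]}: negative time")
    records = []
    for (pid, did), grp in df.groupby(["patient_id", "day_id"], sort=True):
        grp = grp.sort_values("time_min")
        times = grp["time_min"].to_numpy(dtype=float)
        values = grp["trs"].to_numpy(dtype=float)
        doses = grp["dose_mg"].to_numpy(dtype=float)
        step = times[1] - times[0] if times.size > 1 else 10.0
        mask = doses > 0
        schedule = DoseSchedule.from_times(times[mask], doses[mask])
        trace = StateTrace(times=times, values=values, day_length=float(times[-1] + step))
        records.append(DayRecord(int(pid), int(did), schedule, trace))
    return records
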