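"""Learned patient-response models: history (MLP) and impulse (LSTM).

Both models predict the next TRS state on the 10-minute grid and are rolled
out closed-loop over the whole day: starting from the measured wake state,
each prediction is fed back as the next step's previous-state input, and the
training loss is the mean squared error over the entire predicted day.

Feature conventions (teacher-forced row ``i`` at grid time ``tau = i*step``):

- history model: ``n`` previous states (the initial state is replicated when
  fewer are available) followed by, for each of the ``k`` most recent doses
  taken at or before ``tau``, the pair (minutes since the dose, dose size),
  most recent first, zero-padded — a dose taken at ``tau`` has elapsed time 0;
- impulse model: (previous state, dose taken at ``tau`` or 0);
- target: the state one grid step later (optionally as a difference).

Dose times are rounded to the nearest grid point (a dose at 8:17 on a
10-minute grid is treated as taken at 8:20).

A *general* model is fitted on a cohort (random 80/20 day split, Adam,
early stopping, best-on-validation checkpoint) and then *transfer-fitted*
to an individual patient's 3 observed days (2 train / 1 validation); for
the impulse model the LSTM weights stay frozen during transfer.
"""

from __future__ import annotations

import copy
import json
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from pdsched.nn import Adam, HistoryNet, ImpulseNet, OutputSpec
from pdsched.pkpd import DayRecord, DoseSchedule, StateTrace

__all__ = [
    "HistoryModelConfig",
    "ImpulseModelConfig",
    "TrainConfig",
    "MetricsReport",
    "Normalizer",
    "ResponseModel",
    "WilcoxonResult",
    "parse_model_name",
    "build_history_features",
    "build_impulse_features",
    "history_dose_features",
    "impulse_dose_features",
    "rollout_predict",
    "train_general",
    "transfer_fit",
    "evaluate",
    "compare_models_wilcoxon",
]


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class HistoryModelConfig:
    """Feed-forward predictor over a fixed window of states and doses."""

    n_prev_states: int = 1
    k_prev_doses: int = 2
    hidden_sizes: tuple[int, int] = (64, 64)
    target_mode: str = "next_state"  # or "difference"
    tanh_output: bool = False

    def __post_init__(self) -> None:
        if self.target_mode not in ("next_state", "difference"):
            raise ValueError("target_mode must be 'next_state' or 'difference'")
        if self.n_prev_states < 1 or self.k_prev_doses < 0:
            raise ValueError("invalid window sizes")

    @property
    def input_width(self) -> int:
        return self.n_prev_states + 2 * self.k_prev_doses

    @property
    def name(self) -> str:
        base = f"H-{self.hidden_sizes[0]},{self.hidden_sizes[1]}"
        if self.tanh_output:
            base += "-tanh"
        if self.target_mode == "difference":
            base += "-diff"
        return base


@dataclass(frozen=True)
class ImpulseModelConfig:
    """Recurrent predictor fed (previous state, dose at the step) per step."""

    lstm_units: int = 8
    hidden_sizes: tuple[int, int] = (64, 64)
    target_mode: str = "next_state"
    tanh_output: bool = False

    def __post_init__(self) -> None:
        if self.target_mode not in ("next_state", "difference"):
            raise ValueError("target_mode must be 'next_state' or 'difference'")

    @property
    def input_width(self) -> int:
        return 2

    @property
    def name(self) -> str:
        base = f"I-({self.lstm_units}){self.hidden_sizes[0]},{self.hidden_sizes[1]}"
        if self.tanh_output:
            base += "-tanh"
        if self.target_mode == "difference":
            base += "-diff"
        return base


_NAME_RE = re.compile(
    r"^(?P<kind>[HI])-(?:\((?P<units>\d+)\))?(?P<h1>\d+),(?P<h2>\d+)"
    r"(?P<mods>(?:[-,]\s*(?:tanh|diff))*)$"
)


def parse_model_name(name: str) -> HistoryModelConfig | ImpulseModelConfig:
    """Parse architecture identifiers like ``H-128,128-diff`` or ``I-(8)64,64, tanh``."""
    m = _NAME_RE.match(name.strip())
    if not m:
        raise ValueError(f"unrecognized model identifier: {name!r}")
    mods = m.group("mods") or ""
    tanh = "tanh" in mods
    diff = "diff" in mods
    hidden = (int(m.group("h1")), int(m.group("h2")))
    target = "difference" if diff else "next_state"
    if m.group("kind") == "H":
        return HistoryModelConfig(hidden_sizes=hidden, target_mode=target, tanh_output=tanh)
    units = m.group("units")
    if units is None:
        raise ValueError(f"impulse identifier must carry an LSTM unit count: {name!r}")
    return ImpulseModelConfig(lstm_units=int(units), hidden_sizes=hidden,
                              target_mode=target, tanh_output=tanh)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings for fitting a response model."""

    max_epochs: int = 300
    patience: int = 10
    learning_rate: float = 1e-3
    split_fraction: float = 0.8
    batch_size: int = 32
    checkpoint_best: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")

    @classmethod
    def transfer(cls, rng_seed: int = 0, **kw) -> "TrainConfig":
        """Defaults for patient-specific fine-tuning."""
        merged = {"max_epochs": 100, "patience": 25, **kw}
        return cls(rng_seed=rng_seed, **merged)


@dataclass(frozen=True)
class MetricsReport:
    mse: float
    mae: float
    r2: float
    n_points: int = 0


@dataclass(frozen=True)
class Normalizer:
    """Per-feature standardization with training-split statistics."""

    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self) -> None:
        mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        std = np.atleast_1d(np.asarray(self.std, dtype=float))
        std = np.where(std < 1e-12, 1.0, std)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "std", std)

    @classmethod
    def fit(cls, rows: np.ndarray) -> "Normalizer":
        rows = np.asarray(rows, dtype=float).reshape(-1, rows.shape[-1])
        return cls(mean=rows.mean(axis=0), std=rows.std(axis=0))

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mean) / self.std

    def inverse(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float) * self.std + self.mean


# ---------------------------------------------------------------------------
# feature construction


def _rounded_dose_arrays(schedule: DoseSchedule, grid_step: float):
    times = np.round(np.asarray(schedule.times, dtype=float) / grid_step) * grid_step
    sizes = np.asarray(schedule.sizes, dtype=float)
    order = np.argsort(times, kind="stable")
    return times[order], sizes[order]


def history_dose_features(schedule: DoseSchedule, n_steps: int,
                          k_prev_doses: int, grid_step: float = 10.0) -> np.ndarray:
    """Dose-derived feature block, shape (n_steps, 2k): rows at t=0, step, ..."""
    times, sizes = _rounded_dose_arrays(schedule, grid_step)
    out = np.zeros((n_steps, 2 * k_prev_doses))
    for i in range(n_steps):
        tau = i * grid_step
        taken = np.nonzero(times <= tau + 1e-9)[0]
        recent = taken[::-1][:k_prev_doses]
        for slot, idx in enumerate(recent):
            out[i, 2 * slot] = tau - times[idx]
            out[i, 2 * slot + 1] = sizes[idx]
    return out


def impulse_dose_features(schedule: DoseSchedule, n_steps: int,
                          grid_step: float = 10.0) -> np.ndarray:
    """Per-step dose sizes, shape (n_steps, 1): rows at t=0, step, ..."""
    times, sizes = _rounded_dose_arrays(schedule, grid_step)
    out = np.zeros((n_steps, 1))
    for t, d in zip(times, sizes):
        i = int(round(t / grid_step))
        if 0 <= i < n_steps:
            out[i, 0] += d
    return out


def _prev_state_block(values: np.ndarray, n_prev: int) -> np.ndarray:
    """Teacher-forced previous-state columns, most recent first, initial replicated."""
    T = values.size - 1
    cols = [values[np.maximum(np.arange(T) - j, 0)] for j in range(n_prev)]
    return np.stack(cols, axis=1)


def build_history_features(trace: StateTrace, schedule: DoseSchedule,
                           cfg: HistoryModelConfig):
    """Teacher-forced feature rows and targets for one day.

    Row ``i`` (grid time ``i*step``) pairs the true state at that time with
    the dose features there and targets the state one step later.
    """
    step = trace.grid_step
    T = len(trace) - 1
    if T < 1:
        raise ValueError("trace must contain at least two grid points")
    dose_block = history_dose_features(schedule, T, cfg.k_prev_doses, step)
    X = np.concatenate([_prev_state_block(trace.values, cfg.n_prev_states), dose_block], axis=1)
    y = np.diff(trace.values) if cfg.target_mode == "difference" else trace.values[1:]
    return X, y


def build_impulse_features(trace: StateTrace, schedule: DoseSchedule,
                           cfg: ImpulseModelConfig | None = None):
    """Teacher-forced (previous state, dose) rows and targets for one day."""
    cfg = cfg or ImpulseModelConfig()
    step = trace.grid_step
    T = len(trace) - 1
    if T < 1:
        raise ValueError("trace must contain at least two grid points")
    dose_block = impulse_dose_features(schedule, T, step)
    X = np.concatenate([trace.values[:-1, None], dose_block], axis=1)
    y = np.diff(trace.values) if cfg.target_mode == "difference" else trace.values[1:]
    return X, y


# ---------------------------------------------------------------------------
# the trained model container


class ResponseModel:
    """A trained history or impulse predictor with its normalizer.

    Holds the architecture config, the weight arrays, and the per-feature
    input normalizer plus target scaling; provides whole-day closed-loop
    prediction and (de)serialization.
    """

    def __init__(self, config: HistoryModelConfig | ImpulseModelConfig,
                 weights: dict[str, np.ndarray] | None = None,
                 x_norm: Normalizer | None = None,
                 y_mean: float = 0.0, y_std: float = 1.0,
                 grid_step: float = 10.0, trained: bool = False):
        self.config = config
        self.kind = "history" if isinstance(config, HistoryModelConfig) else "impulse"
        if self.kind == "history":
            self.net = HistoryNet(config.n_prev_states, 2 * config.k_prev_doses,
                                  config.hidden_sizes)
        else:
            self.net = ImpulseNet(config.lstm_units, config.hidden_sizes)
        self.weights = weights
        self.x_norm = x_norm
        self.y_mean = float(y_mean)
        self.y_std = float(y_std)
        self.grid_step = float(grid_step)
        self.trained = trained

    # -- plumbing ----------------------------------------------------------

    @property
    def name(self) -> str:
        return self.config.name

    @property
    def output_spec(self) -> OutputSpec:
        return OutputSpec(difference=self.config.target_mode == "difference",
                          tanh=self.config.tanh_output,
                          y_mean=self.y_mean, y_std=self.y_std)

    def init_weights(self, seed) -> None:
        self.weights = self.net.init_weights(seed)

    def clone(self) -> "ResponseModel":
        return ResponseModel(self.config,
                             weights=None if self.weights is None else
                             {k: v.copy() for k, v in self.weights.items()},
                             x_norm=self.x_norm, y_mean=self.y_mean, y_std=self.y_std,
                             grid_step=self.grid_step, trained=self.trained)

    def _require_ready(self) -> None:
        if not self.trained or self.weights is None or self.x_norm is None:
            raise RuntimeError("model is not trained; fit or load it first")

    # -- inference ---------------------------------------------------------

    def dose_features(self, schedule: DoseSchedule, n_steps: int) -> np.ndarray:
        if self.kind == "history":
            return history_dose_features(schedule, n_steps,
                                         self.config.k_prev_doses, self.grid_step)
        return impulse_dose_features(schedule, n_steps, self.grid_step)

    def rollout_days(self, s_init: np.ndarray, dose_feats: np.ndarray) -> np.ndarray:
        """Batched closed-loop prediction: (B,), (B,T,df) -> raw states (B,T)."""
        self._require_ready()
        return self.net.rollout(self.weights, np.asarray(s_init, dtype=float),
                                np.asarray(dose_feats, dtype=float),
                                self.x_norm.mean, self.x_norm.std, self.output_spec)

    def predict_day(self, initial_state: float, schedule: DoseSchedule,
                    n_steps: int) -> StateTrace:
        """Closed-loop prediction of one day from the wake state."""
        self._require_ready()
        if n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        step = self.grid_step
        if n_steps == 0:
            return StateTrace(times=np.array([0.0]), values=np.array([float(initial_state)]),
                              day_length=step)
        F = self.dose_features(schedule, n_steps)[None]
        states = self.rollout_days(np.array([float(initial_state)]), F)[0]
        values = np.concatenate([[float(initial_state)], states])
        times = step * np.arange(n_steps + 1)
        return StateTrace(times=times, values=values, day_length=step * (n_steps + 1))

    def impulse_cell_step(self, h: np.ndarray, c: np.ndarray, s_prev: float,
                          dose: float) -> tuple[float, np.ndarray, np.ndarray]:
        """Single recurrent step (impulse models only); used by the RL backend."""
        self._require_ready()
        if self.kind != "impulse":
            raise RuntimeError("cell stepping is only defined for impulse models")
        states, h_new, c_new = self.net.rollout(
            self.weights, np.array([float(s_prev)]), np.array([[[float(dose)]]]),
            self.x_norm.mean, self.x_norm.std, self.output_spec,
            h0=h[None], c0=c[None], return_cells=True)
        return float(states[0, 0]), h_new[0], c_new[0]

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        self._require_ready()
        meta = {
            "kind": self.kind,
            "name": self.name,
            "grid_step": self.grid_step,
            "y_mean": self.y_mean,
            "y_std": self.y_std,
            "config": {k: list(v) if isinstance(v, tuple) else v
                       for k, v in vars(self.config).items()},
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 x_mean=self.x_norm.mean, x_std=self.x_norm.std,
                 **{f"w_{k}": v for k, v in self.weights.items()})

    @classmethod
    def load(cls, path: str | Path) -> "ResponseModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            cfg_kw = {k: tuple(v) if isinstance(v, list) else v
                      for k, v in meta["config"].items()}
            config = (HistoryModelConfig if meta["kind"] == "history"
                      else ImpulseModelConfig)(**cfg_kw)
            weights = {k[2:]: data[k].copy() for k in data.files if k.startswith("w_")}
            return cls(config, weights=weights,
                       x_norm=Normalizer(data["x_mean"].copy(), data["x_std"].copy()),
                       y_mean=meta["y_mean"], y_std=meta["y_std"],
                       grid_step=meta["grid_step"], trained=True)


def rollout_predict(model: ResponseModel, initial_state: float,
                    schedule: DoseSchedule, n_steps: int) -> StateTrace:
    """Functional alias for :meth:`ResponseModel.predict_day`."""
    return model.predict_day(initial_state, schedule, n_steps)


# ---------------------------------------------------------------------------
# training


def _day_tensors(days: Sequence[DayRecord], model: ResponseModel,
                 truncate_to: int | None = None):
    """Stack days into (s_init (B,), F (B,T,df), Y (B,T)) raw-state tensors."""
    lengths = [len(d.trace) - 1 for d in days]
    T = min(lengths) if truncate_to is None else truncate_to
    if T < 1:
        raise ValueError("days must contain at least two grid points")
    s_init = np.array([d.trace.values[0] for d in days])
    F = np.stack([model.dose_features(d.schedule, T) for d in days])
    Y = np.stack([d.trace.values[1:T + 1] for d in days])
    return s_init, F, Y


def _fit_scaling(days: Sequence[DayRecord], model: ResponseModel, T: int):
    """Input normalizer and target scaling from the training split."""
    cfg = model.config
    rows, targets = [], []
    for d in days:
        trunc = StateTrace(times=d.trace.times[:T + 1], values=d.trace.values[:T + 1],
                           day_length=d.trace.times[T] + model.grid_step)
        if model.kind == "history":
            X, y = build_history_features(trunc, d.schedule, cfg)
        else:
            X, y = build_impulse_features(trunc, d.schedule, cfg)
        rows.append(X)
        targets.append(y)
    X = np.concatenate(rows)
    y = np.concatenate(targets)
    model.x_norm = Normalizer.fit(X)
    if model.config.tanh_output:
        model.y_mean, model.y_std = 0.0, 1.0
    else:
        model.y_mean = float(y.mean())
        model.y_std = float(y.std()) or 1.0


def _rollout_loss(model: ResponseModel, s_init, F, Y) -> float:
    states = model.net.rollout(model.weights, s_init, F, model.x_norm.mean,
                               model.x_norm.std, model.output_spec)
    return float(np.mean((states - Y) ** 2))


def _train_loop(model: ResponseModel, train: tuple, val: tuple, cfg: TrainConfig,
                frozen: set[str] = frozenset()) -> dict:
    """Minibatch Adam with early stopping and best-on-validation checkpoint."""
    s_tr, F_tr, Y_tr = train
    rng = np.random.default_rng(cfg.rng_seed)
    opt = Adam(lr=cfg.learning_rate)
    n = s_tr.shape[0]
    batch = min(cfg.batch_size, n)
    spec = model.output_spec
    history = {"train_loss": [], "val_loss": []}
    # the starting point is a valid checkpoint: fine-tuning can never end
    # worse on validation than the model it started from
    best_val = _rollout_loss(model, *val)
    best_weights = {k: v.copy() for k, v in model.weights.items()}
    best_epoch = -1
    since_improve = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch):
            idx = order[start:start + batch]
            states, caches = model.net.rollout(
                model.weights, s_tr[idx], F_tr[idx], model.x_norm.mean,
                model.x_norm.std, spec, want_cache=True)
            grads = model.net.backward(model.weights, states, Y_tr[idx], caches,
                                       model.x_norm.std, spec)
            opt.step(model.weights, grads, frozen=frozen)
        train_loss = _rollout_loss(model, s_tr, F_tr, Y_tr)
        val_loss = _rollout_loss(model, *val)
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)
        if np.isfinite(val_loss) and val_loss < best_val - 1e-12:
            best_val = val_loss
            best_epoch = epoch
            if cfg.checkpoint_best:
                best_weights = {k: v.copy() for k, v in model.weights.items()}
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= cfg.patience:
                break
    if cfg.checkpoint_best:
        model.weights = best_weights
    history["best_epoch"] = best_epoch
    history["best_val_loss"] = float(best_val)
    return history


def train_general(days: Sequence[DayRecord],
                  model_cfg: HistoryModelConfig | ImpulseModelConfig,
                  train_cfg: TrainConfig = TrainConfig()) -> tuple[ResponseModel, dict]:
    """Fit the population-level model on a cohort of medication days.

    Days are split randomly into train/validation (``split_fraction``),
    truncated to the shortest day, and optimized by whole-day rollout MSE.
    Returns the best-on-validation model and the loss history.
    """
    days = list(days)
    if len(days) < 2:
        raise ValueError("need at least two days to split train/validation")
    rng = np.random.default_rng(train_cfg.rng_seed)
    order = rng.permutation(len(days))
    n_train = max(1, int(round(train_cfg.split_fraction * len(days))))
    n_train = min(n_train, len(days) - 1)
    train_days = [days[i] for i in order[:n_train]]
    val_days = [days[i] for i in order[n_train:]]

    grid_step = days[0].trace.grid_step
    model = ResponseModel(model_cfg, grid_step=grid_step)
    T = min(len(d.trace) - 1 for d in days)
    _fit_scaling(train_days, model, T)
    model.init_weights(np.random.default_rng(train_cfg.rng_seed + 1))
    model.trained = True
    history = _train_loop(model, _day_tensors(train_days, model, T),
                          _day_tensors(val_days, model, T), train_cfg)
    history["split"] = {"train": [(d.patient_id, d.day_id) for d in train_days],
                       "val": [(d.patient_id, d.day_id) for d in val_days]}
    return model, history


def train_general_best(days: Sequence[DayRecord],
                       model_cfg: HistoryModelConfig | ImpulseModelConfig,
                       train_cfg: TrainConfig = TrainConfig(),
                       n_restarts: int = 3) -> tuple[ResponseModel, dict]:
    """Repeat general-model training from different initializations.

    Whole-day rollout optimization from a random initialization can settle
    in poor basins, so the fit is repeated ``n_restarts`` times (seeds
    derived from ``train_cfg.rng_seed``) and the best-on-validation model
    is kept.
    """
    best: tuple[ResponseModel, dict] | None = None
    for r in range(n_restarts):
        cfg_r = replace(train_cfg, rng_seed=train_cfg.rng_seed + 1000 * r)
        model, hist = train_general(days, model_cfg, cfg_r)
        if best is None or hist["best_val_loss"] < best[1]["best_val_loss"]:
            best = (model, hist)
    return best


def transfer_fit(general: ResponseModel, patient_days: Sequence[DayRecord],
                 train_cfg: TrainConfig | None = None) -> tuple[ResponseModel, dict]:
    """Fine-tune the general model on one patient's 3 observed days.

    The first two days train, the third validates.  History models update
    all layers; impulse models keep the recurrent weights frozen and
    retrain only the dense head.  Best-on-validation weights are kept.
    """
    general._require_ready()
    patient_days = list(patient_days)
    if len(patient_days) != 3:
        raise ValueError("transfer fitting expects exactly 3 patient days")
    train_cfg = train_cfg or TrainConfig.transfer()
    model = general.clone()
    frozen = set(ImpulseNet.LSTM_KEYS) if model.kind == "impulse" else frozenset()
    T = min(len(d.trace) - 1 for d in patient_days)
    history = _train_loop(model,
                          _day_tensors(patient_days[:2], model, T),
                          _day_tensors(patient_days[2:], model, T),
                          train_cfg, frozen=frozen)
    return model, history


# ---------------------------------------------------------------------------
# evaluation


def regression_metrics(y_true: Sequence[float], y_pred: Sequence[float]) -> MetricsReport:
    """MSE, MAE and coefficient of determination, pooled over all points."""
    y = np.asarray(y_true, dtype=float).ravel()
    y_hat = np.asarray(y_pred, dtype=float).ravel()
    if y.shape != y_hat.shape or y.size == 0:
        raise ValueError("predictions and targets must match and be non-empty")
    err = y - y_hat
    mse = float(np.mean(err ** 2))
    mae = float(np.mean(np.abs(err)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("constant targets: R^2 is undefined", RuntimeWarning)
        r2 = float("nan")
    else:
        r2 = 1.0 - float(np.sum(err ** 2)) / ss_tot
    return MetricsReport(mse=mse, mae=mae, r2=r2, n_points=y.size)


def evaluate(model: ResponseModel, days: Sequence[DayRecord]) -> MetricsReport:
    """Whole-day closed-loop metrics pooled over all predicted states."""
    days = list(days)
    if not days:
        raise ValueError("need at least one day to evaluate")
    preds, truths = [], []
    for d in days:
        n_steps = len(d.trace) - 1
        trace = model.predict_day(d.trace.values[0], d.schedule, n_steps)
        preds.append(trace.values[1:])
        truths.append(d.trace.values[1:])
    return regression_metrics(np.concatenate(truths), np.concatenate(preds))


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float
    p_value: float
    degenerate: bool = False


def compare_models_wilcoxon(losses_a: Sequence[float], losses_b: Sequence[float],
                            alternative: str = "greater") -> WilcoxonResult:
    """Paired signed-rank comparison of per-trial losses.

    ``alternative="greater"`` tests whether ``losses_a`` are stochastically
    greater than ``losses_b``.  All-zero differences yield a flagged
    degenerate result instead of a p-value.
    """
    a = np.asarray(losses_a, dtype=float)
    b = np.asarray(losses_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("losses must be equal-length 1-D samples")
    if a.size < 5:
        raise ValueError("need at least 5 paired trials")
    if np.allclose(a, b):
        return WilcoxonResult(statistic=float("nan"), p_value=float("nan"),
                              degenerate=True)
    res = stats.wilcoxon(a, b, alternative=alternative)
    return WilcoxonResult(statistic=float(res.statistic), p_value=float(res.pvalue))
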