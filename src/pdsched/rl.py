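"""Reinforcement-learning dosing environment and PPO agent.

The environment follows the episodic reset/step convention (observation,
reward, terminated, truncated, info).  Actions are discrete dose multiples:
action ``a`` administers ``a * dose_step`` mg (action 0 = no medication),
giving ``max_dose/dose_step + 1`` actions.  Taking a dose locks further
dosing for the minimum inter-dose interval: the environment auto-advances
through ``ceil(90/10) = 9`` grid steps in one call, accumulating reward.
The reward of each traversed segment is the negative trapezoidal
area-outside-target-range contribution, so the episode return equals the
negative whole-day objective of the induced trace.  Episodes terminate when
the state exceeds a patient-specific maximum (dyskinesia guard) and
truncate after 110 grid steps.

Backends: ``pkpd`` observes the compartment vector (a0, a1, a2, ce);
``impulse`` steps a trained LSTM response model and observes its internal
cell activations (each in [-1, 1]); ``history`` observes the recent state
plus the k last (dose, elapsed-time) pairs.

The PPO implementation is a compact clipped-surrogate actor-critic in
numpy (separate two-hidden-layer ReLU policy and value networks, GAE,
minibatch Adam), with gradients verified against finite differences in the
test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from pdsched.pkpd import (CompartmentState, DoseSchedule, PatientParameters,
                          StateTrace, effect_from_concentration, system_matrices)
from pdsched.optimize import TargetSpec, objective_outside_range
from scipy.linalg import expm

__all__ = [
    "EnvConfig",
    "AgentConfig",
    "DosingEnv",
    "PPOAgent",
    "action_space_size",
    "segment_reward",
    "train_agent",
    "extract_schedule",
    "evaluate_policy",
]


def action_space_size(max_dose: float, dose_step: float) -> int:
    """Number of discrete actions including the no-medication action."""
    ratio = max_dose / dose_step
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("dose_step must divide max_dose")
    return int(round(ratio)) + 1


def segment_reward(states: np.ndarray, target: TargetSpec,
                   grid_step: float = 10.0) -> float:
    """Negative area-outside-range contribution of a traversed segment.

    ``states`` are the grid states bounding the segment (>= 1 value); the
    trapezoidal rule makes segment rewards add up exactly to the negative
    whole-day objective.
    """
    states = np.atleast_1d(np.asarray(states, dtype=float))
    if states.size < 1:
        raise ValueError("need at least one state")
    if states.size == 1:
        return 0.0
    trace = StateTrace(times=grid_step * np.arange(states.size), values=states,
                       day_length=grid_step * states.size)
    return -objective_outside_range(trace, target)


@dataclass(frozen=True)
class EnvConfig:
    """Dosing-environment settings."""

    dose_step: float = 50.0
    max_dose: float = 400.0
    min_interdose_interval: float = 90.0
    grid_step: float = 10.0
    max_steps: int = 110
    termination_max_state: float | None = None  # default: midway target-top .. max effect
    backend: str = "pkpd"  # or "impulse", "history"

    @property
    def n_actions(self) -> int:
        return action_space_size(self.max_dose, self.dose_step)

    @property
    def lockout_steps(self) -> int:
        return math.ceil(self.min_interdose_interval / self.grid_step)


class DosingEnv:
    """Stepwise dosing simulation for one patient.

    ``reset(seed)`` returns ``(observation, info)``; ``step(action)`` returns
    ``(observation, reward, terminated, truncated, info)``.
    """

    def __init__(self, params: PatientParameters, target: TargetSpec,
                 config: EnvConfig = EnvConfig(), model=None):
        self.params = params
        self.target = target
        self.config = config
        self.model = model
        if config.backend not in ("pkpd", "impulse", "history"):
            raise ValueError(f"unknown backend {config.backend!r}")
        if config.backend in ("impulse", "history"):
            if model is None:
                raise ValueError(f"{config.backend} backend requires a trained model")
            if model.kind != config.backend:
                raise ValueError("model kind does not match the backend")
        if config.termination_max_state is None:
            top = params.max_effect
            self.termination_max_state = target.theta_max + 0.5 * (top - target.theta_max)
        else:
            self.termination_max_state = config.termination_max_state
        A, b = system_matrices(params)
        self._P = expm(A * config.grid_step)
        self._xp = np.linalg.solve(A, -b)
        self.reset()

    # -- observation builders ---------------------------------------------

    @property
    def observation_size(self) -> int:
        if self.config.backend == "pkpd":
            return 4
        if self.config.backend == "impulse":
            return 2 * self.model.config.lstm_units
        return 1 + 2 * self.model.config.k_prev_doses

    def _observe(self) -> np.ndarray:
        if self.config.backend == "pkpd":
            return self._x.copy()
        if self.config.backend == "impulse":
            return np.concatenate([np.tanh(self._c), self._h])
        k = self.model.config.k_prev_doses
        obs = np.zeros(1 + 2 * k)
        obs[0] = self._state
        for slot, (t_d, d) in enumerate(self._dose_history[::-1][:k]):
            obs[1 + 2 * slot] = d
            obs[2 + 2 * slot] = self._t - t_d
        return obs

    # -- episode API -------------------------------------------------------

    def reset(self, seed=None) -> tuple[np.ndarray, dict]:
        ss = self.params.endogenous_steady_state()
        self._x = ss.as_array()
        self._state = float(effect_from_concentration(ss.ce, self.params))
        if self.config.backend == "impulse":
            H = self.model.config.lstm_units
            self._h = np.zeros(H)
            self._c = np.zeros(H)
        self._t = 0.0
        self._steps = 0
        self._dose_history: list[tuple[float, float]] = []
        self._state_history: list[float] = [self._state]
        self._done = False
        return self._observe(), {"dose_history": [], "time": 0.0}

    def _advance_one(self, dose: float) -> None:
        """One grid step forward with an optional bolus at the current time."""
        if self.config.backend == "pkpd":
            x = self._x - self._xp
            x[0] += dose
            self._x = self._P @ x + self._xp
            self._state = effect_from_concentration(max(self._x[3], 0.0), self.params)
        elif self.config.backend == "impulse":
            s, self._h, self._c = self.model.impulse_cell_step(
                self._h, self._c, self._state, dose)
            self._state = s
        else:
            sched = DoseSchedule.from_times([t for t, _ in self._dose_history],
                                            [d for _, d in self._dose_history])
            n_steps = self._steps + 1
            trace = self.model.predict_day(self._state_history[0], sched, n_steps)
            self._state = float(trace.values[-1])
        self._t += self.config.grid_step
        self._steps += 1
        self._state_history.append(float(self._state))

    def step(self, action: int) -> tuple[np.ndarray, float, bool, bool, dict]:
        if self._done:
            raise RuntimeError("episode finished; call reset()")
        if not 0 <= int(action) < self.config.n_actions:
            raise ValueError(f"action {action} outside the action space")
        dose = float(action) * self.config.dose_step
        n_sub = self.config.lockout_steps if action > 0 else 1
        if dose > 0:
            self._dose_history.append((self._t, dose))
        reward = 0.0
        terminated = truncated = False
        for i in range(n_sub):
            s_prev = self._state
            self._advance_one(dose if i == 0 else 0.0)
            reward += segment_reward(np.array([s_prev, self._state]), self.target,
                                     self.config.grid_step)
            if self._state > self.termination_max_state:
                terminated = True
                break
            if self._steps >= self.config.max_steps:
                truncated = True
                break
        self._done = terminated or truncated
        info = {"dose_history": list(self._dose_history), "time": self._t,
                "state": self._state, "steps": self._steps}
        return self._observe(), float(reward), terminated, truncated, info


# ---------------------------------------------------------------------------
# PPO


@dataclass(frozen=True)
class AgentConfig:
    """PPO training settings (clipped surrogate, GAE, Adam)."""

    hidden: int = 200           # per layer; 400 for the 5 mg dose step
    total_timesteps: int = 500_000
    check_period: int = 50_000  # evaluation/early-stop callback period
    n_steps: int = 2048
    batch_size: int = 64
    n_epochs: int = 10
    learning_rate: float = 3e-4
    gamma: float = 0.99
    gae_lambda: float = 0.95
    clip_range: float = 0.2
    ent_coef: float = 0.0
    vf_coef: float = 0.5
    max_grad_norm: float = 0.5
    eval_episodes: int = 5
    early_stop_checks: int = 2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.total_timesteps % self.check_period:
            raise ValueError("total_timesteps must be a multiple of check_period")


def _mlp_init(rng: np.random.Generator, sizes: list[int], out_scale: float = 0.01):
    w = {}
    for i, (a, b) in enumerate(zip(sizes[:-1], sizes[1:]), start=1):
        limit = np.sqrt(6.0 / (a + b))
        w[f"W{i}"] = rng.uniform(-limit, limit, size=(b, a))
        w[f"b{i}"] = np.zeros(b)
    return w


def _mlp_forward(w, x):
    """Two ReLU hidden layers + linear output; x (B,d) -> (out, cache)."""
    a1 = x @ w["W1"].T + w["b1"]
    h1 = np.maximum(a1, 0.0)
    a2 = h1 @ w["W2"].T + w["b2"]
    h2 = np.maximum(a2, 0.0)
    out = h2 @ w["W3"].T + w["b3"]
    return out, (x, a1 > 0, h1, a2 > 0, h2)


def _mlp_backward(w, g_out, cache, grads):
    x, m1, h1, m2, h2 = cache
    grads["W3"] += g_out.T @ h2
    grads["b3"] += g_out.sum(0)
    gh2 = g_out @ w["W3"]
    ga2 = gh2 * m2
    grads["W2"] += ga2.T @ h1
    grads["b2"] += ga2.sum(0)
    gh1 = ga2 @ w["W2"]
    ga1 = gh1 * m1
    grads["W1"] += ga1.T @ x
    grads["b1"] += ga1.sum(0)


class _RunningNorm:
    """Running mean/variance observation normalizer."""

    def __init__(self, dim: int):
        self.mean = np.zeros(dim)
        self.var = np.ones(dim)
        self.count = 1e-4

    def update(self, batch: np.ndarray) -> None:
        bm = batch.mean(0)
        bv = batch.var(0)
        bc = batch.shape[0]
        delta = bm - self.mean
        tot = self.count + bc
        self.mean += delta * bc / tot
        m_a = self.var * self.count
        m_b = bv * bc
        self.var = (m_a + m_b + delta ** 2 * self.count * bc / tot) / tot
        self.count = tot

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return np.clip((x - self.mean) / np.sqrt(self.var + 1e-8), -10.0, 10.0)


class PPOAgent:
    """Discrete-action PPO with separate policy and value networks."""

    def __init__(self, obs_dim: int, n_actions: int, cfg: AgentConfig):
        self.cfg = cfg
        self.obs_dim = obs_dim
        self.n_actions = n_actions
        rng = np.random.default_rng(cfg.rng_seed)
        h = cfg.hidden
        self.pi = _mlp_init(rng, [obs_dim, h, h, n_actions])
        self.pi["W3"] *= 0.01  # near-uniform initial policy
        self.vf = _mlp_init(rng, [obs_dim, h, h, 1])
        self.norm = _RunningNorm(obs_dim)
        self.rng = rng

    # -- policy evaluation -------------------------------------------------

    def _logits(self, obs: np.ndarray):
        return _mlp_forward(self.pi, obs)

    def policy_probs(self, obs: np.ndarray) -> np.ndarray:
        logits, _ = self._logits(self.norm(np.atleast_2d(obs)))
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def act(self, obs: np.ndarray, deterministic: bool = False) -> int:
        p = self.policy_probs(obs)[0]
        if deterministic:
            return int(np.argmax(p))
        return int(self.rng.choice(self.n_actions, p=p))

    def value(self, obs: np.ndarray) -> float:
        v, _ = _mlp_forward(self.vf, self.norm(np.atleast_2d(obs)))
        return float(v[0, 0])

    # -- loss and gradients ------------------------------------------------

    def loss_and_grads(self, obs_n: np.ndarray, actions: np.ndarray,
                       logp_old: np.ndarray, advantages: np.ndarray,
                       returns: np.ndarray):
        """Clipped-surrogate policy loss + value MSE + entropy bonus."""
        cfg = self.cfg
        B = obs_n.shape[0]
        logits, pi_cache = _mlp_forward(self.pi, obs_n)
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        probs = e / e.sum(axis=1, keepdims=True)
        logp_all = z - np.log(e.sum(axis=1, keepdims=True))
        logp = logp_all[np.arange(B), actions]
        ratio = np.exp(logp - logp_old)
        clipped = np.clip(ratio, 1.0 - cfg.clip_range, 1.0 + cfg.clip_range)
        surr1 = ratio * advantages
        surr2 = clipped * advantages
        pi_loss = -np.mean(np.minimum(surr1, surr2))
        entropy = -np.sum(probs * np.where(probs > 0, np.log(probs + 1e-12), 0.0), axis=1)
        ent_loss = -np.mean(entropy)
        v_out, vf_cache = _mlp_forward(self.vf, obs_n)
        v = v_out[:, 0]
        vf_loss = np.mean((v - returns) ** 2)
        total = pi_loss + cfg.ent_coef * ent_loss + cfg.vf_coef * vf_loss

        # gradient w.r.t. logits
        use_unclipped = surr1 <= surr2  # min picks surr1; gradient flows via ratio
        g_logp = np.where(use_unclipped, -advantages * ratio, 0.0) / B
        onehot = np.zeros_like(probs)
        onehot[np.arange(B), actions] = 1.0
        g_logits = g_logp[:, None] * (onehot - probs)
        # dH/dlogits = -p*(logp_all + H); the loss carries -mean(H)
        gH = -probs * (logp_all + entropy[:, None])
        g_logits -= cfg.ent_coef * (gH / B)
        pi_grads = {k: np.zeros_like(v_) for k, v_ in self.pi.items()}
        _mlp_backward(self.pi, g_logits, pi_cache, pi_grads)
        g_v = cfg.vf_coef * 2.0 * (v - returns)[:, None] / B
        vf_grads = {k: np.zeros_like(v_) for k, v_ in self.vf.items()}
        _mlp_backward(self.vf, g_v, vf_cache, vf_grads)
        return total, pi_grads, vf_grads, {"pi_loss": pi_loss, "vf_loss": vf_loss,
                                           "entropy": float(np.mean(entropy))}


def _clip_grads(grads: dict, max_norm: float) -> None:
    norm = math.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
    if norm > max_norm:
        scale = max_norm / (norm + 1e-12)
        for g in grads.values():
            g *= scale


def evaluate_policy(agent: PPOAgent, env: DosingEnv, n_episodes: int = 5,
                    deterministic: bool = True) -> float:
    """Mean episode return of the (deterministic) policy."""
    total = 0.0
    for _ in range(n_episodes):
        obs, _ = env.reset()
        done = False
        while not done:
            obs, r, term, trunc, _ = env.step(agent.act(obs, deterministic=deterministic))
            total += r
            done = term or trunc
    return total / n_episodes


def train_agent(env: DosingEnv, cfg: AgentConfig = AgentConfig()) -> tuple[PPOAgent, dict]:
    """PPO training with periodic evaluation and early stopping.

    Every ``check_period`` timesteps the deterministic policy is evaluated;
    training stops early when the best evaluation return has not improved
    for ``early_stop_checks`` consecutive checks, and the best-so-far
    parameters are restored.
    """
    from pdsched.nn import Adam

    agent = PPOAgent(env.observation_size, env.config.n_actions, cfg)
    opt_pi = Adam(lr=cfg.learning_rate, clipnorm=None)
    opt_vf = Adam(lr=cfg.learning_rate, clipnorm=None)
    rng = agent.rng
    history = {"eval": [], "timesteps": []}
    best_eval = -np.inf
    best_params = None
    checks_since_improve = 0
    obs, _ = env.reset()
    steps_done = 0
    next_check = cfg.check_period
    while steps_done < cfg.total_timesteps:
        n = min(cfg.n_steps, cfg.total_timesteps - steps_done)
        OBS = np.empty((n, env.observation_size))
        ACT = np.empty(n, dtype=int)
        REW = np.empty(n)
        DONE = np.empty(n, dtype=bool)
        TRUNC_BOOT = np.zeros(n)
        VAL = np.empty(n)
        LOGP = np.empty(n)
        for i in range(n):
            OBS[i] = obs
            p = agent.policy_probs(obs)[0]
            a = int(rng.choice(agent.n_actions, p=p))
            ACT[i] = a
            LOGP[i] = np.log(p[a] + 1e-12)
            VAL[i] = agent.value(obs)
            obs, r, term, trunc, _ = env.step(a)
            REW[i] = r
            DONE[i] = term or trunc
            if trunc and not term:
                TRUNC_BOOT[i] = agent.value(obs)  # bootstrap through truncation
            if DONE[i]:
                obs, _ = env.reset()
        last_val = agent.value(obs)
        agent.norm.update(OBS)
        obs_n = agent.norm(OBS)
        # GAE
        adv = np.empty(n)
        gae = 0.0
        for i in range(n - 1, -1, -1):
            next_v = (TRUNC_BOOT[i] if DONE[i] else (VAL[i + 1] if i + 1 < n else last_val))
            nonterm = 0.0 if DONE[i] and TRUNC_BOOT[i] == 0.0 else 1.0
            delta = REW[i] + cfg.gamma * next_v * nonterm - VAL[i]
            gae = delta + cfg.gamma * cfg.gae_lambda * nonterm * \
                (0.0 if DONE[i] else gae)
            adv[i] = gae
        returns = adv + VAL
        adv_n = (adv - adv.mean()) / (adv.std() + 1e-8)
        for _ in range(cfg.n_epochs):
            order = rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                _, gpi, gvf, _ = agent.loss_and_grads(
                    obs_n[idx], ACT[idx], LOGP[idx], adv_n[idx], returns[idx])
                _clip_grads(gpi, cfg.max_grad_norm)
                _clip_grads(gvf, cfg.max_grad_norm)
                opt_pi.step(agent.pi, gpi)
                opt_vf.step(agent.vf, gvf)
        steps_done += n
        if steps_done >= next_check:
            score = evaluate_policy(agent, env, cfg.eval_episodes)
            history["eval"].append(score)
            history["timesteps"].append(steps_done)
            obs, _ = env.reset()
            if score > best_eval:
                best_eval = score
                best_params = ({k: v.copy() for k, v in agent.pi.items()},
                               {k: v.copy() for k, v in agent.vf.items()})
                checks_since_improve = 0
            else:
                checks_since_improve += 1
                if checks_since_improve >= cfg.early_stop_checks:
                    break
            next_check += cfg.check_period
    if best_params is not None:
        agent.pi, agent.vf = best_params
    history["best_eval"] = float(best_eval)
    return agent, history


def extract_schedule(agent: PPOAgent, env: DosingEnv
                     ) -> tuple[DoseSchedule, float]:
    """Deterministic rollout; returns the induced schedule and episode score.

    The score is the negative cumulative reward, i.e. the area-outside-range
    objective of the induced day.
    """
    obs, _ = env.reset()
    total = 0.0
    done = False
    info: dict = {"dose_history": []}
    while not done:
        obs, r, term, trunc, info = env.step(agent.act(obs, deterministic=True))
        total += r
        done = term or trunc
    doses = info["dose_history"]
    schedule = DoseSchedule.from_times([t for t, _ in doses], [d for _, d in doses])
    return schedule, -total
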