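"""Population-of-spiking-neurons policy-gradient learner.

Architecture: a three-layer network.  The input layer ``X`` encodes each
stimulus as one dedicated sub-population firing Poisson spikes for the
stimulus duration.  The hidden layer ``Y`` consists of stochastic spiking
units driven through the learned synaptic matrix ``W_XY``; the decision
layer reads ``Y`` out with fixed (non-learned) weights — one readout
population per action, the action being the population with the most spikes
(for binary tasks: whether the majority of the single decision population
spiked).  Spike sampling is the sole exploration mechanism.

Credit assignment uses a cascade of three exponentially decaying
eligibility traces with increasing time constants — the spike timescale
(``tau1``), the stimulus duration (``tau2``) and the reward delay
(``tau3``).  Per-synapse Hebbian coincidences (post-spike deviation times
filtered pre-synaptic activity) feed the cascade, and the slowest trace
``e3`` holds them until reward delivery.  The weight update depends only on
``e3`` and the reward:

    dW = eta * (R - Rbar) * e3

with ``Rbar`` a running reward baseline (optionally fixed to zero).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .envs import (
    DelayedFeedbackEnv,
    SwitchStateEnv,
    initial_episode_state,
    env_step,
    run_feedback_session,
    TrialLog,
)

__all__ = [
    "SpikingConfig",
    "EligibilityTraces",
    "SpikingNetwork",
    "SpikingFeedbackAgent",
    "update_traces",
    "encode_stimulus",
    "run_switch_task",
    "run_feedback_task",
    "switch_learning_curves",
]


@dataclass
class SpikingConfig:
    """Hyperparameters of the spiking learner (all time units in seconds)."""

    n_stimuli: int
    n_actions: int
    n_x_per_stim: int = 10
    n_y_per_pop: int = 51
    rate: float = 40.0  # Hz, active X sub-population
    stim_duration: float = 0.5
    tau1: float = 0.02
    tau2: float = 0.5
    tau3: float = 4.0
    gain: float = 1.0
    eta: float = 0.6  # the learning rate — the model's single free parameter
    baseline: str = "running"  # "running" | "zero"
    baseline_step: float = 0.2
    step_duration: float = 0.5  # simulated time per decision in the switch task
    spontaneous: float = 0.05  # floor/ceiling on hidden spike probability

    # hidden units keep a spontaneous firing probability so the spike
    # variability (the exploration/plasticity signal) never vanishes even
    # when the drive saturates

    def __post_init__(self) -> None:
        if not (self.tau1 < self.tau2 < self.tau3):
            raise ValueError("trace time constants must satisfy tau1 < tau2 < tau3")
        if self.baseline not in ("running", "zero"):
            raise ValueError("baseline must be 'running' or 'zero'")


@dataclass
class EligibilityTraces:
    """Three per-synapse traces with distinct decay time constants.

    ``e1`` filters pre-synaptic spikes (shape ``(n_x,)``); ``e2`` holds
    Hebbian coincidences over the stimulus duration and ``e3`` accumulates
    ``e2`` until reward reception (both shape ``(n_y, n_x)``).
    """

    tau1: float
    tau2: float
    tau3: float
    e1: np.ndarray = field(default=None)  # type: ignore[assignment]
    e2: np.ndarray = field(default=None)  # type: ignore[assignment]
    e3: np.ndarray = field(default=None)  # type: ignore[assignment]

    @classmethod
    def zeros(cls, n_y: int, n_x: int, tau1: float, tau2: float, tau3: float):
        return cls(
            tau1=tau1,
            tau2=tau2,
            tau3=tau3,
            e1=np.zeros(n_x),
            e2=np.zeros((n_y, n_x)),
            e3=np.zeros((n_y, n_x)),
        )

    def decay(self, dt: float) -> None:
        """Exponential decay of all traces over ``dt`` (no events)."""
        if dt < 0:
            raise ValueError("dt must be non-negative")
        if dt == 0:
            return
        self.e1 *= math.exp(-dt / self.tau1)
        self.e2 *= math.exp(-dt / self.tau2)
        self.e3 *= math.exp(-dt / self.tau3)

    def reset(self) -> None:
        self.e1[:] = 0.0
        self.e2[:] = 0.0
        self.e3[:] = 0.0


def update_traces(
    traces: EligibilityTraces, events: dict | None, dt: float
) -> EligibilityTraces:
    """Decay all traces over ``dt`` then add impulse increments in place.

    ``events`` may contain ``"x_spikes"`` (added to ``e1``) and
    ``"coincidence"`` (a per-synapse Hebbian increment, added to ``e2`` and
    cascaded into ``e3`` so decision information persists until reward).
    """
    traces.decay(dt)
    if events:
        if "x_spikes" in events:
            traces.e1 += events["x_spikes"]
        if "coincidence" in events:
            inc = events["coincidence"]
            traces.e2 += inc
            traces.e3 += inc
    return traces


def _sigmoid(u: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-u))


def encode_stimulus(stimulus: int, n_stimuli: int, n_x_per_stim: int, rate: float):
    """Fixed one-sub-population-active rate pattern for a stimulus."""
    if not (0 <= stimulus < n_stimuli):
        raise ValueError(f"unknown stimulus {stimulus!r}")
    rates = np.zeros(n_stimuli * n_x_per_stim)
    lo = stimulus * n_x_per_stim
    rates[lo : lo + n_x_per_stim] = rate
    return rates


class SpikingNetwork:
    """The learner itself: weights, traces, clock and reward baseline."""

    def __init__(self, config: SpikingConfig, rng: np.random.Generator):
        self.config = config
        self.rng = rng
        c = config
        self.n_x = c.n_stimuli * c.n_x_per_stim
        # binary tasks use one decision population (majority rule);
        # multi-action tasks one readout population per action (argmax).
        self.majority = c.n_actions == 2
        self.n_pops = 1 if self.majority else c.n_actions
        self.n_y = self.n_pops * c.n_y_per_pop
        self.W = np.zeros((self.n_y, self.n_x))
        self.traces = EligibilityTraces.zeros(
            self.n_y, self.n_x, c.tau1, c.tau2, c.tau3
        )
        self.r_bar = 0.0
        self.time = 0.0

    # -- dynamics ----------------------------------------------------------

    def advance_to(self, t: float) -> None:
        if t < self.time:
            # a smaller timestamp marks a new session: re-base the clock
            # without decaying (inter-session gaps clear e3 anyway)
            self.time = t
            return
        self.traces.decay(t - self.time)
        self.time = t

    def sample_x(self, stimulus: int) -> np.ndarray:
        """Poisson spike counts of the X layer over the stimulus window,
        normalized by the expected count of an active neuron."""
        c = self.config
        rates = encode_stimulus(stimulus, c.n_stimuli, c.n_x_per_stim, c.rate)
        expected = c.rate * c.stim_duration
        counts = self.rng.poisson(rates * c.stim_duration)
        if expected == 0:
            return np.zeros_like(rates)
        return counts / expected

    def decide(self, x_norm: np.ndarray) -> int:
        """Sample hidden spikes, read out the action, store the coincidence.

        The per-synapse Hebbian coincidence ``(y - p) x`` is pushed through
        the trace cascade; ``e3`` will carry it to the next reward.
        """
        c = self.config
        u = self.W @ x_norm
        p = np.clip(_sigmoid(c.gain * u), c.spontaneous, 1.0 - c.spontaneous)
        y = (self.rng.random(self.n_y) < p).astype(float)
        if self.majority:
            action = int(2 * y.sum() > self.n_y)
        else:
            counts = y.reshape(self.n_pops, c.n_y_per_pop).sum(axis=1)
            best = np.flatnonzero(counts == counts.max())
            action = int(best[0] if len(best) == 1 else self.rng.choice(best))
        coincidence = c.gain * np.outer(y - p, x_norm)
        update_traces(self.traces, {"x_spikes": x_norm, "coincidence": coincidence}, 0.0)
        return action

    def act(self, stimulus: int, t: float) -> int:
        self.advance_to(t)
        return self.decide(self.sample_x(stimulus))

    def apply_reward(self, R: float, t: float | None = None) -> None:
        """Weight update from the slowest trace and the reward alone."""
        if not np.isfinite(R):
            raise ValueError("reward must be finite")
        if t is not None:
            self.advance_to(t)
        c = self.config
        baseline = self.r_bar if c.baseline == "running" else 0.0
        self.W += c.eta * (R - baseline) * self.traces.e3
        if c.baseline == "running":
            self.r_bar += c.baseline_step * (R - self.r_bar)

    def reset_traces(self) -> None:
        self.traces.reset()


# ---------------------------------------------------------------------------
# Task drivers
# ---------------------------------------------------------------------------

def run_switch_task(
    net: SpikingNetwork,
    env: SwitchStateEnv,
    n_episodes: int,
    max_steps: int = 100,
) -> list[int]:
    """Run episodes on the switch task; returns per-episode step counts.

    The stimulus at each step is the current image state.  The reward signal
    applied at episode end is the episode's reward *rate* (goal reward
    divided by episode length, 0 on truncation) — the quantity an
    average-reward learner maximizes — and is applied through ``e3``, so
    earlier steps of the episode receive exponentially less credit, on the
    reward-delay timescale ``tau3``.
    """
    c = net.config
    lengths: list[int] = []
    for _ in range(n_episodes):
        net.reset_traces()
        es = initial_episode_state(env)
        done = False
        while not done and es.step_count < max_steps:
            a = net.act(es.current_state, net.time + c.step_duration)
            es, r, done = env_step(env, es, a)
        net.apply_reward(1.0 / es.step_count if done else 0.0)
        lengths.append(es.step_count)
    return lengths


def switch_learning_curves(
    env: SwitchStateEnv,
    n_runs: int = 20,
    n_episodes: int = 60,
    seed: int = 0,
    config: SpikingConfig | None = None,
    max_steps: int = 100,
) -> np.ndarray:
    """Episode-length curves over seeded runs; shape ``(n_runs, n_episodes)``."""
    if config is None:
        # reward rates are ~1/episode-length, so the default learning rate
        # is correspondingly larger than in the feedback task
        config = SpikingConfig(
            n_stimuli=env.n_states, n_actions=env.n_actions, eta=5.0
        )
    ss = np.random.SeedSequence(seed)
    out = np.empty((n_runs, n_episodes), dtype=int)
    for i, child in enumerate(ss.spawn(n_runs)):
        net = SpikingNetwork(config, np.random.default_rng(child))
        out[i] = run_switch_task(net, env, n_episodes, max_steps=max_steps)
    return out


class SpikingFeedbackAgent:
    """:class:`~nonmarkov.envs.AgentPolicy` adapter for the feedback task."""

    def __init__(self, config: SpikingConfig, rng: np.random.Generator):
        if config.n_actions != 2:
            raise ValueError("the feedback task is binary")
        self.net = SpikingNetwork(config, rng)

    def act(self, stimulus: int, time: float) -> int:
        return self.net.act(stimulus, time)

    def receive_feedback(self, sign: float, time: float) -> None:
        self.net.apply_reward(sign, time)


def run_feedback_task(
    env: DelayedFeedbackEnv,
    n_trials: int,
    seed: int = 0,
    config: SpikingConfig | None = None,
) -> TrialLog:
    """Run the spiking learner through one feedback session."""
    if config is None:
        config = SpikingConfig(n_stimuli=env.n_images, n_actions=2)
    ss = np.random.SeedSequence(seed)
    agent_rng, env_rng = (np.random.default_rng(c) for c in ss.spawn(2))
    agent = SpikingFeedbackAgent(config, agent_rng)
    return run_feedback_session(env, agent, n_trials, env_rng)
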