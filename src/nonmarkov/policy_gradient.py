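"""Simple softmax policy-gradient baseline (single free parameter: eta).

Tabular REINFORCE with a running-mean baseline.  Preferences are kept per
(observation, action); action probabilities are the softmax of the
preferences at unit temperature.  For the switch task the observation is
the current state and one update is made per episode using the episode's
reward *rate* (reward divided by episode duration — the gradient of the
average reward collected over a given amount of time); for the feedback
task the observation is the image and one update is made per delivered
feedback event, attributed to the most recent response.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np

from .envs import (
    DelayedFeedbackEnv,
    SwitchStateEnv,
    EpisodeState,
    TrialLog,
    run_feedback_session,
    run_switch_episodes,
)

__all__ = [
    "SoftmaxPolicy",
    "pg_act",
    "pg_update",
    "PGSwitchAgent",
    "PGFeedbackAgent",
    "run_pg_switch",
    "run_pg_feedback",
    "fit_learning_rate",
    "default_eta_grid",
]


class SoftmaxPolicy:
    """Preference table with softmax action selection (temperature 1)."""

    def __init__(self, n_actions: int, eta: float = 0.1, baseline_step: float = 0.1):
        if eta < 0:
            raise ValueError("eta must be non-negative")
        self.n_actions = n_actions
        self.eta = eta
        self.baseline_step = baseline_step
        self.preferences: dict = defaultdict(lambda: np.zeros(n_actions))
        self.r_bar = 0.0

    def probabilities(self, observation) -> np.ndarray:
        h = self.preferences[observation]
        z = np.exp(h - h.max())
        return z / z.sum()


def pg_act(pol: SoftmaxPolicy, observation, rng: np.random.Generator) -> int:
    """Sample an action from the softmax distribution."""
    p = pol.probabilities(observation)
    return int(rng.choice(pol.n_actions, p=p))


def pg_update(pol: SoftmaxPolicy, trajectory, R: float) -> SoftmaxPolicy:
    """REINFORCE update with the running-mean baseline.

    For every (observation, action) in the trajectory the chosen action's
    preference moves up by ``eta * (R - r_bar) * (1 - pi(a|o))`` and every
    other action's moves down by ``eta * (R - r_bar) * pi(a'|o)``.
    """
    if not trajectory:
        raise ValueError("trajectory must be nonempty")
    adv = R - pol.r_bar
    for obs, action in trajectory:
        p = pol.probabilities(obs)
        grad = -p
        grad[action] += 1.0
        pol.preferences[obs] = pol.preferences[obs] + pol.eta * adv * grad
    pol.r_bar += pol.baseline_step * (R - pol.r_bar)
    return pol


class PGSwitchAgent:
    """EpisodeAgent adapter: per-episode update with the reward rate."""

    def __init__(self, n_actions: int, eta: float, rng: np.random.Generator):
        self.policy = SoftmaxPolicy(n_actions, eta=eta)
        self.rng = rng
        self.trajectory: list[tuple[int, int]] = []

    def begin_episode(self, start_state: int) -> None:
        self.trajectory = []

    def act(self, es: EpisodeState) -> int:
        return pg_act(self.policy, es.current_state, self.rng)

    def observe(self, state, action, next_state, reward, done) -> None:
        self.trajectory.append((state, action))

    def end_episode(self, rewarded: bool, truncated: bool) -> None:
        if self.trajectory:
            rate = (1.0 if rewarded else 0.0) / len(self.trajectory)
            pg_update(self.policy, self.trajectory, rate)


class PGFeedbackAgent:
    """AgentPolicy adapter: per-feedback update, naive last-response credit."""

    def __init__(self, n_actions: int, eta: float, rng: np.random.Generator):
        self.policy = SoftmaxPolicy(n_actions, eta=eta)
        self.rng = rng
        self.last: tuple[int, int] | None = None

    def act(self, stimulus: int, time: float) -> int:
        action = pg_act(self.policy, stimulus, self.rng)
        self.last = (stimulus, action)
        return action

    def receive_feedback(self, sign: float, time: float) -> None:
        if self.last is not None:
            pg_update(self.policy, [self.last], sign)


def run_pg_switch(
    env: SwitchStateEnv,
    eta: float,
    n_episodes: int,
    seed: int = 0,
    max_steps: int = 100,
) -> list[int]:
    agent = PGSwitchAgent(env.n_actions, eta, np.random.default_rng(seed))
    lengths, _ = run_switch_episodes(env, agent, n_episodes, max_steps=max_steps)
    return lengths


def run_pg_feedback(
    env: DelayedFeedbackEnv, eta: float, n_trials: int, seed: int = 0
) -> TrialLog:
    ss = np.random.SeedSequence(seed)
    agent_rng, env_rng = (np.random.default_rng(c) for c in ss.spawn(2))
    agent = PGFeedbackAgent(2, eta, agent_rng)
    return run_feedback_session(env, agent, n_trials, env_rng)


def default_eta_grid(n: int = 21, lo: float = 1e-3, hi: float = 1.0) -> np.ndarray:
    """Log-spaced learning-rate grid used by :func:`fit_learning_rate`."""
    return np.logspace(np.log10(lo), np.log10(hi), n)


def fit_learning_rate(
    agent_curve_fn,
    reference_curve: np.ndarray,
    eta_grid=None,
) -> tuple[float, float]:
    """Grid-search the learning rate against a reference learning curve.

    ``agent_curve_fn(eta)`` must return the agent's mean curve (over a fixed
    evaluation seed set) as an array comparable to ``reference_curve``;
    returns ``(eta_star, rss)`` minimizing the squared L2 residual over the
    common support.
    """
    reference_curve = np.asarray(reference_curve, dtype=float)
    if eta_grid is None:
        eta_grid = default_eta_grid()
    eta_grid = np.asarray(eta_grid, dtype=float)
    if eta_grid.size == 0 or reference_curve.size == 0:
        raise ValueError("reference curve and eta grid must be nonempty")
    best_eta, best_rss = None, np.inf
    for eta in eta_grid:
        curve = np.asarray(agent_curve_fn(float(eta)), dtype=float)
        n = min(len(curve), len(reference_curve))
        rss = float(np.sum((curve[:n] - reference_curve[:n]) ** 2))
        if rss < best_rss:
            best_eta, best_rss = float(eta), rss
    return best_eta, best_rss
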