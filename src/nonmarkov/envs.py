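"""Simulators for the two non-Markovian task paradigms.

Two environments are provided:

* :class:`SwitchStateEnv` — an episodic navigation task over a small
  deterministic state/action graph in which the goal transition is gated by
  a designated *switch* state: the goal can only be entered after the switch
  state has been visited within the current episode.  Attempting the goal
  transition beforehand silently redirects to a decoy state.

* :class:`DelayedFeedbackEnv` — a two-category image classification task in
  which feedback for each response is delivered after a gamma-distributed
  delay, so feedback events can arrive out of response order (intermixed
  feedback).

Both environments are fully deterministic given their seed, and both log to
the common :class:`TrialLog` interchange format consumed by the evaluation
layer.
"""

from __future__ import annotations

import heapq
import json
import math
from collections import deque
from dataclasses import dataclass, field, replace
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SwitchStateEnv",
    "EpisodeState",
    "DelayedFeedbackEnv",
    "TrialLog",
    "AgentPolicy",
    "EpisodeAgent",
    "build_switch_env",
    "env_step",
    "shortest_episode_length",
    "gamma_pdf",
    "sample_delay",
    "run_feedback_session",
    "run_switch_episodes",
    "UNREACHABLE",
]

#: Sentinel returned by :func:`shortest_episode_length` when the goal cannot
#: be reached under the imposed restrictions.
UNREACHABLE = math.inf


# ---------------------------------------------------------------------------
# Switch-state environment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SwitchStateEnv:
    """Deterministic gated navigation graph.

    States ``0 .. n_states-1`` are image states; ``goal_state == n_states``
    is the absorbing goal.  ``transitions[s, a]`` gives the successor image
    state for every (image state, action) pair.  The single goal transition
    is *not* stored in ``transitions``: taking ``goal_action`` in
    ``pre_goal_state`` leads to the goal when the switch flag is set and to
    ``decoy_state`` otherwise.
    """

    n_states: int
    n_actions: int
    transitions: np.ndarray  # shape (n_states, n_actions), int
    start_state: int
    switch_state: int
    pre_goal_state: int
    goal_action: int
    decoy_state: int
    seed: int | None = None

    @property
    def goal_state(self) -> int:
        return self.n_states

    def successor(self, state: int, action: int, switch_visited: bool) -> int:
        """Successor of ``(state, action)`` given the switch flag."""
        if state == self.pre_goal_state and action == self.goal_action:
            return self.goal_state if switch_visited else self.decoy_state
        return int(self.transitions[state, action])

    def to_dict(self) -> dict:
        return {
            "n_states": self.n_states,
            "n_actions": self.n_actions,
            "transitions": self.transitions.tolist(),
            "start_state": self.start_state,
            "switch_state": self.switch_state,
            "pre_goal_state": self.pre_goal_state,
            "goal_action": self.goal_action,
            "decoy_state": self.decoy_state,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SwitchStateEnv":
        d = dict(d)
        d["transitions"] = np.asarray(d["transitions"], dtype=int)
        return cls(**d)


@dataclass
class EpisodeState:
    """Mutable per-episode state: current position, switch flag, step count."""

    current_state: int
    switch_visited: bool = False
    step_count: int = 0


def initial_episode_state(env: SwitchStateEnv) -> EpisodeState:
    es = EpisodeState(current_state=env.start_state)
    # Degenerate fixtures may start on the switch itself.
    if env.start_state == env.switch_state:
        es.switch_visited = True
    return es


def env_step(
    env: SwitchStateEnv, es: EpisodeState, action: int
) -> tuple[EpisodeState, int, bool]:
    """Advance one step; returns ``(new_episode_state, reward, done)``.

    Reward is 1 exactly on entering the goal, which requires taking the goal
    action from the pre-goal state with the switch flag set; the same action
    with the flag unset redirects to the decoy state with reward 0.
    """
    if not (0 <= action < env.n_actions):
        raise ValueError(f"undefined action {action!r} (n_actions={env.n_actions})")
    if es.current_state == env.goal_state:
        raise RuntimeError("cannot step from the goal state; reset the episode")
    nxt = env.successor(es.current_state, action, es.switch_visited)
    done = nxt == env.goal_state
    reward = 1 if done else 0
    visited = es.switch_visited or nxt == env.switch_state
    return EpisodeState(nxt, visited, es.step_count + 1), reward, done


def _product_bfs(env: SwitchStateEnv, allow_switch: bool = True):
    """BFS over the (state, switch-flag) product space from the start.

    Returns ``(dist, parent)`` dicts keyed by product nodes; the goal node is
    ``(goal_state, True)``.  With ``allow_switch=False`` the switch flag is
    never raised, which makes the goal provably unreachable in a sound env.
    """
    start = (env.start_state, env.start_state == env.switch_state and allow_switch)
    dist = {start: 0}
    parent: dict[tuple, tuple | None] = {start: None}
    q = deque([start])
    goal = env.goal_state
    while q:
        s, flag = q.popleft()
        if s == goal:
            continue
        for a in range(env.n_actions):
            nxt = env.successor(s, a, flag)
            nflag = flag or (allow_switch and nxt == env.switch_state)
            node = (nxt, nflag if nxt != goal else True)
            if node not in dist:
                dist[node] = dist[(s, flag)] + 1
                parent[node] = (s, flag, a)
                q.append(node)
    return dist, parent


def shortest_episode_length(env: SwitchStateEnv, allow_switch: bool = True) -> float:
    """Minimum number of actions from start to goal (BFS on the product space).

    Returns :data:`UNREACHABLE` (``inf``) if the goal cannot be reached.
    This is the independent oracle for the construction constraint in
    :func:`build_switch_env`.
    """
    dist, _ = _product_bfs(env, allow_switch=allow_switch)
    best = UNREACHABLE
    for (s, _flag), d in dist.items():
        if s == env.goal_state:
            best = min(best, d)
    return best


def _has_stateloop_free_shortest_path(env: SwitchStateEnv, length: int) -> bool:
    """True if some shortest start→goal path visits no image state twice.

    Such a path is realizable by a memoryless (state-keyed) policy, which the
    non-history-aware learners need in order to attain the minimum length.
    """
    goal = env.goal_state
    # DFS over shortest-path product trajectories.
    dist, _ = _product_bfs(env)
    start = (env.start_state, env.start_state == env.switch_state)

    def dfs(node, d, seen: frozenset) -> bool:
        s, flag = node
        if s == goal:
            return d == length
        if d >= length:
            return False
        for a in range(env.n_actions):
            nxt = env.successor(s, a, flag)
            if nxt != goal and nxt in seen:
                continue
            nflag = flag or nxt == env.switch_state
            nnode = (nxt, True if nxt == goal else nflag)
            if dist.get(nnode, UNREACHABLE) != d + 1:
                continue
            if dfs(nnode, d + 1, seen if nxt == goal else seen | {nxt}):
                return True
        return False

    return dfs(start, 0, frozenset({env.start_state}))


def build_switch_env(
    seed: int,
    n_states: int = 8,
    n_actions: int = 3,
    min_episode: int = 5,
    max_attempts: int = 50_000,
) -> SwitchStateEnv:
    """Rejection-sample a switch-state environment with the given structure.

    Constraints enforced on every returned environment:

    * deterministic transitions (one successor per state/action pair);
    * the goal reachable only after visiting the switch state;
    * BFS-verified minimum episode length exactly ``min_episode``;
    * at least one recurrent (self-loop) and one outward-bound connection;
    * for ``min_episode >= 4``: the gate is binding (ignoring it would allow
      a strictly shorter episode) and some shortest path revisits no state,
      so a memoryless policy can realize the optimum.

    Deterministic given ``seed``; raises ``RuntimeError`` if no valid graph
    is found within ``max_attempts`` draws.
    """
    if n_states < 4 and min_episode >= 3:
        raise ValueError("n_states >= 4 required for min_episode >= 3")
    if n_states < 3:
        raise ValueError("n_states must be >= 3")
    if min_episode < 2:
        raise ValueError("min_episode must be >= 2")
    rng = np.random.default_rng(seed)
    strict = min_episode >= 4
    for _ in range(max_attempts):
        start = int(rng.integers(n_states))
        switch = int(rng.integers(n_states))
        pre_goal = int(rng.integers(n_states))
        decoy = int(rng.integers(n_states))
        if switch == start:
            continue
        if decoy in (pre_goal,):
            continue
        if strict and pre_goal in (switch, start):
            continue
        transitions = rng.integers(n_states, size=(n_states, n_actions))
        goal_action = int(rng.integers(n_actions))
        env = SwitchStateEnv(
            n_states=n_states,
            n_actions=n_actions,
            transitions=transitions,
            start_state=start,
            switch_state=switch,
            pre_goal_state=pre_goal,
            goal_action=goal_action,
            decoy_state=decoy,
            seed=seed,
        )
        if shortest_episode_length(env) != min_episode:
            continue
        # recurrent + outward-bound connections
        diag = transitions == np.arange(n_states)[:, None]
        if not diag.any() or diag.all():
            continue
        if strict:
            # every minimum-length route passes the switch (optimal play is
            # memoryless-learnable) ...
            if shortest_ungated_length(env) != min_episode:
                continue
            # ... but a longer switch-skipping route to the goal attempt
            # exists, so the decoy redirect is experienced while exploring
            avoid = _switch_avoiding_length(env)
            if not (min_episode < avoid < UNREACHABLE):
                continue
            # ... and some optimal route revisits no state, so a memoryless
            # policy can realize the optimum.
            if not _has_stateloop_free_shortest_path(env, min_episode):
                continue
        return env
    raise RuntimeError(
        f"no valid switch-state graph found in {max_attempts} attempts "
        f"(n_states={n_states}, n_actions={n_actions}, min_episode={min_episode})"
    )


def shortest_ungated_length(env: SwitchStateEnv) -> float:
    """Shortest start→goal length if the switch gate were removed."""
    ungated = replace(env, switch_state=env.start_state)
    return shortest_episode_length(ungated)


def _switch_avoiding_length(env: SwitchStateEnv) -> float:
    """Shortest start→goal length, gate open, never entering the switch state.

    If this equals the episode minimum, a minimum-length attempt that skips
    the switch exists — and is redirected to the decoy at the last step.
    """
    dist = {env.start_state: 0}
    q = deque([env.start_state])
    while q:
        s = q.popleft()
        for a in range(env.n_actions):
            nxt = env.successor(s, a, switch_visited=True)
            if nxt == env.goal_state:
                return dist[s] + 1
            if nxt != env.switch_state and nxt not in dist:
                dist[nxt] = dist[s] + 1
                q.append(nxt)
    return UNREACHABLE


# ---------------------------------------------------------------------------
# Delayed / intermixed feedback environment
# ---------------------------------------------------------------------------

def gamma_pdf(t, k: float, theta: float):
    """Gamma probability density ``t^(k-1) exp(-t/theta) / (Gamma(k) theta^k)``.

    ``t`` may be a scalar or array of non-negative delays (seconds); ``k`` is
    the shape and ``theta`` the scale parameter.
    """
    if k <= 0 or theta <= 0:
        raise ValueError("k and theta must be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("delays must be non-negative")
    logt = np.log(t, out=np.full_like(t, -np.inf), where=t > 0)
    # (k-1)*log(t) at t=0: 0 for k=1, -inf for k>1, +inf for k<1
    power = np.where(t > 0, (k - 1) * logt, 0.0) if k == 1 else (k - 1) * logt
    logpdf = power - t / theta - math.lgamma(k) - k * math.log(theta)
    out = np.exp(logpdf)
    if t.ndim == 0:
        return float(out)
    return out


@dataclass
class DelayedFeedbackEnv:
    """Image classification with (optionally) gamma-delayed feedback.

    ``category_map[i]`` gives the rewarded response (0 = left, 1 = right)
    for image ``i``.  In ``"gamma"`` mode feedback for a response at clock
    time ``t`` is delivered at ``t + d`` with ``d ~ Gamma(k, theta)``; the
    delivery queue is ordered by due time, so feedback may arrive out of
    response order.  In ``"immediate"`` mode feedback is delivered before
    the next stimulus.
    """

    category_map: np.ndarray  # shape (n_images,), values in {0, 1}
    delay_mode: str = "gamma"  # "immediate" | "gamma"
    gamma_shape: float = 2.0
    gamma_scale: float = 1.5
    inter_trial_interval: float = 1.5
    seed: int | None = None

    def __post_init__(self) -> None:
        self.category_map = np.asarray(self.category_map, dtype=int)
        if self.delay_mode not in ("immediate", "gamma"):
            raise ValueError(f"unknown delay_mode {self.delay_mode!r}")
        if not np.isin(self.category_map, (0, 1)).all():
            raise ValueError("category_map entries must be 0 (left) or 1 (right)")

    @property
    def n_images(self) -> int:
        return int(self.category_map.size)

    @classmethod
    def random(
        cls,
        n_images: int,
        seed: int,
        delay_mode: str = "gamma",
        **kwargs,
    ) -> "DelayedFeedbackEnv":
        rng = np.random.default_rng(seed)
        cmap = rng.integers(2, size=n_images)
        return cls(category_map=cmap, delay_mode=delay_mode, seed=seed, **kwargs)

    def swapped(self, images: Sequence[int]) -> "DelayedFeedbackEnv":
        """Copy of this environment with the categories of ``images`` flipped."""
        cmap = self.category_map.copy()
        cmap[list(images)] = 1 - cmap[list(images)]
        return replace(self, category_map=cmap)


def sample_delay(env: DelayedFeedbackEnv, rng: np.random.Generator) -> float:
    """One i.i.d. feedback delay draw from the environment's gamma density."""
    if env.delay_mode != "gamma":
        raise ValueError("sample_delay is only defined in gamma mode")
    return float(rng.gamma(shape=env.gamma_shape, scale=env.gamma_scale))


class AgentPolicy(Protocol):
    """Contract every feedback-task learner satisfies."""

    def act(self, stimulus: int, time: float) -> int:
        """Return a category response (0 = left, 1 = right) for the stimulus."""

    def receive_feedback(self, sign: float, time: float) -> None:
        """Consume one feedback event (+1 correct / -1 incorrect)."""


@dataclass
class TrialLog:
    """Timestamped record of a feedback session.

    The ``feedback_origin`` column records the originating trial of each
    delivered feedback event.  It exists solely for oracle tests and
    attribution-accuracy diagnostics — no learner ever sees it.
    """

    trial: list[int] = field(default_factory=list)
    stimulus: list[int] = field(default_factory=list)
    action: list[int] = field(default_factory=list)
    response_time: list[float] = field(default_factory=list)
    correct: list[int] = field(default_factory=list)
    feedback_time: list[float] = field(default_factory=list)
    feedback_sign: list[int] = field(default_factory=list)
    feedback_origin: list[int] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return len(self.trial)

    @property
    def n_feedback(self) -> int:
        return len(self.feedback_time)

    def correctness(self) -> np.ndarray:
        """Per-trial binary correctness in trial order."""
        return np.asarray(self.correct, dtype=int)

    def record_trial(self, trial, stimulus, action, t, correct) -> None:
        if self.trial and trial <= self.trial[-1]:
            raise ValueError("trial indices must be strictly increasing")
        self.trial.append(int(trial))
        self.stimulus.append(int(stimulus))
        self.action.append(int(action))
        self.response_time.append(float(t))
        self.correct.append(int(correct))

    def record_feedback(self, t, sign, origin) -> None:
        if self.feedback_time and t < self.feedback_time[-1]:
            raise ValueError("feedback delivery times must be non-decreasing")
        self.feedback_time.append(float(t))
        self.feedback_sign.append(int(sign))
        self.feedback_origin.append(int(origin))

    def n_inversions(self) -> int:
        """Number of delivered feedback pairs out of response order."""
        order = self.feedback_origin
        return sum(
            1
            for i in range(len(order))
            for j in range(i + 1, len(order))
            if order[i] > order[j]
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-event frame (responses and feedback interleaved)."""
        rows = []
        for i in range(self.n_trials):
            rows.append(
                {
                    "event_type": "response",
                    "trial": self.trial[i],
                    "time": self.response_time[i],
                    "stimulus": self.stimulus[i],
                    "action": self.action[i],
                    "reward": np.nan,
                }
            )
        for i in range(self.n_feedback):
            rows.append(
                {
                    "event_type": "feedback",
                    "trial": self.feedback_origin[i],
                    "time": self.feedback_time[i],
                    "stimulus": np.nan,
                    "action": np.nan,
                    "reward": self.feedback_sign[i],
                }
            )
        df = pd.DataFrame(rows)
        return df.sort_values(["time", "event_type"], kind="stable").reset_index(
            drop=True
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path=None):
        payload = {k: getattr(self, k) for k in (
            "trial", "stimulus", "action", "response_time", "correct",
            "feedback_time", "feedback_sign", "feedback_origin",
        )}
        if path is None:
            return json.dumps(payload)
        with open(path, "w") as fh:
            json.dump(payload, fh)
        return None


def balanced_schedule(
    n_images: int, n_trials: int, rng: np.random.Generator
) -> np.ndarray:
    """Stimulus order: shuffled blocks so each image appears equally often
    (up to rounding), with every image seen once per block of ``n_images``."""
    blocks = []
    remaining = n_trials
    while remaining > 0:
        perm = rng.permutation(n_images)
        blocks.append(perm[: min(n_images, remaining)])
        remaining -= len(blocks[-1])
    return np.concatenate(blocks)


def run_feedback_session(
    env: DelayedFeedbackEnv,
    agent: AgentPolicy,
    n_trials: int,
    rng: np.random.Generator,
) -> TrialLog:
    """Run one classification session and return the complete trial log.

    Stimuli are presented every ``inter_trial_interval`` seconds in a
    balanced shuffled order.  Due feedback is delivered to the agent before
    each stimulus onset; after the last trial the queue is drained so that
    exactly one feedback event is delivered per response.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    schedule = balanced_schedule(env.n_images, n_trials, rng)
    log = TrialLog()
    pending: list[tuple[float, int, int, int]] = []  # (due, seq, sign, origin)
    seq = 0
    iti = env.inter_trial_interval
    for t_idx in range(n_trials):
        clock = t_idx * iti
        while pending and pending[0][0] <= clock:
            due, _, sign, origin = heapq.heappop(pending)
            agent.receive_feedback(float(sign), due)
            log.record_feedback(due, sign, origin)
        stim = int(schedule[t_idx])
        action = agent.act(stim, clock)
        if action not in (0, 1):
            raise ValueError(f"agent returned invalid category {action!r}")
        correct = int(action == env.category_map[stim])
        log.record_trial(t_idx, stim, action, clock, correct)
        delay = sample_delay(env, rng) if env.delay_mode == "gamma" else 0.0
        sign = 1 if correct else -1
        heapq.heappush(pending, (clock + delay, seq, sign, t_idx))
        seq += 1
    while pending:
        due, _, sign, origin = heapq.heappop(pending)
        agent.receive_feedback(float(sign), due)
        log.record_feedback(due, sign, origin)
    return log


# ---------------------------------------------------------------------------
# Generic episodic runner for the switch task
# ---------------------------------------------------------------------------

class EpisodeAgent(Protocol):
    """Contract for switch-task learners driven by :func:`run_switch_episodes`."""

    def begin_episode(self, start_state: int) -> None: ...

    def act(self, es: EpisodeState) -> int: ...

    def observe(
        self, state: int, action: int, next_state: int, reward: int, done: bool
    ) -> None: ...

    def end_episode(self, rewarded: bool, truncated: bool) -> None: ...


def run_switch_episodes(
    env: SwitchStateEnv,
    agent: EpisodeAgent,
    n_episodes: int,
    max_steps: int = 100,
) -> tuple[list[int], list[bool]]:
    """Run ``n_episodes`` episodes; returns (episode lengths, truncation flags).

    Episodes are truncated at ``max_steps`` actions (the wall-clock analogue
    of the human 10-minute sessions); truncated episodes report the cap.
    """
    lengths: list[int] = []
    truncs: list[bool] = []
    for _ in range(n_episodes):
        es = initial_episode_state(env)
        agent.begin_episode(env.start_state)
        done = False
        while not done and es.step_count < max_steps:
            a = agent.act(es)
            new_es, r, done = env_step(env, es, a)
            agent.observe(es.current_state, a, new_es.current_state, r, done)
            es = new_es
        truncated = not done
        agent.end_episode(rewarded=done, truncated=truncated)
        lengths.append(es.step_count)
        truncs.append(truncated)
    return lengths, truncs
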