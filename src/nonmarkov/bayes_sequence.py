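"""Bayesian learners for the switch-state task.

Three learners of increasing task knowledge:

* **Model 1** maintains, for every action sequence ``s``, Beta-Bernoulli
  posteriors over whether the sequence continues (``P(C|s)``) and whether it
  is rewarded given termination (``P(R|not C, s)``).  It plans by Monte-Carlo
  tree generation: thousands of outcome trees are sampled from the
  posteriors, each grown breadth-first until the first depth containing a
  sampled rewarded terminal; that sequence's counter is incremented, and the
  sequence with the highest counter is the MAP estimate of the best
  sequence.  It keys on the full action history only — never on states.

* **Model 2** learns a Markov transition model per (state, action) with a
  Dirichlet prior and plans by value iteration on the posterior predictive.
  Its defining limitation is the Markov assumption: it cannot represent the
  switch gate.

* **Model 3** is Model 2 restricted to actions whose predicted successor has
  not yet been visited in the current episode (falling back to Model 2 when
  every successor has been visited).

In the deterministic environment the Beta posteriors collapse to certainty
after a single observation; unobserved nodes stay at their uniform prior.
"""

from __future__ import annotations

import json
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np

from .envs import EpisodeState

__all__ = [
    "SequencePosterior",
    "OutcomeTree",
    "TransitionPosterior",
    "update_sequence_posterior",
    "sample_outcome_tree",
    "map_sequence",
    "Model1Agent",
    "Model2Agent",
    "Model3Agent",
    "make_bayes_agent",
]


# ---------------------------------------------------------------------------
# Sequence posterior (Model 1)
# ---------------------------------------------------------------------------

@dataclass
class _Node:
    continue_obs: bool | None = None  # deterministic observation, if any
    reward_obs: bool | None = None
    p_continue_override: float | None = None  # test hook: arbitrary posteriors
    p_reward_override: float | None = None


@dataclass
class SequencePosterior:
    """Per-sequence posteriors P(C|s) and P(R|not C, s).

    ``prior_continue`` / ``prior_reward`` are Beta parameters; with the
    default uniform Beta(1,1) prior an unobserved node's predictive
    probability is 1/2.  Observations in the deterministic task collapse a
    node to probability 0 or 1.
    """

    n_actions: int
    prior_continue: tuple[float, float] = (1.0, 1.0)
    prior_reward: tuple[float, float] = (1.0, 1.0)
    nodes: dict[tuple, _Node] = field(default_factory=dict)

    def _node(self, seq: tuple) -> _Node:
        node = self.nodes.get(seq)
        if node is None:
            node = self.nodes[seq] = _Node()
        return node

    def p_continue(self, seq: tuple) -> float:
        node = self.nodes.get(seq)
        if node is None:
            return self.prior_continue[0] / sum(self.prior_continue)
        if node.p_continue_override is not None:
            return node.p_continue_override
        if node.continue_obs is not None:
            return 1.0 if node.continue_obs else 0.0
        return self.prior_continue[0] / sum(self.prior_continue)

    def p_reward(self, seq: tuple) -> float:
        node = self.nodes.get(seq)
        if node is None:
            return self.prior_reward[0] / sum(self.prior_reward)
        if node.p_reward_override is not None:
            return node.p_reward_override
        if node.reward_obs is not None:
            return 1.0 if node.reward_obs else 0.0
        return self.prior_reward[0] / sum(self.prior_reward)

    def is_explored(self, seq: tuple) -> bool:
        node = self.nodes.get(seq)
        return node is not None and node.continue_obs is not None

    def set_probability(
        self, seq: tuple, p_continue: float | None = None, p_reward: float | None = None
    ) -> None:
        """Pin a node to arbitrary probabilities (oracle-test hook)."""
        node = self._node(seq)
        if p_continue is not None:
            node.p_continue_override = float(p_continue)
        if p_reward is not None:
            node.p_reward_override = float(p_reward)

    def to_json(self) -> str:
        payload = {
            "n_actions": self.n_actions,
            "prior_continue": list(self.prior_continue),
            "prior_reward": list(self.prior_reward),
            "nodes": {
                ",".join(map(str, seq)): [n.continue_obs, n.reward_obs]
                for seq, n in self.nodes.items()
            },
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "SequencePosterior":
        d = json.loads(text)
        post = cls(
            n_actions=d["n_actions"],
            prior_continue=tuple(d["prior_continue"]),
            prior_reward=tuple(d["prior_reward"]),
        )
        for key, (cont, rew) in d["nodes"].items():
            seq = tuple(int(x) for x in key.split(",")) if key else ()
            post.nodes[seq] = _Node(continue_obs=cont, reward_obs=rew)
        return post


def update_sequence_posterior(
    post: SequencePosterior,
    actions: tuple | list,
    terminal: bool,
    rewarded: bool = False,
) -> SequencePosterior:
    """Record one episode: prefixes continue; the full sequence terminates
    (with its reward flag) if ``terminal``, else it continues too.

    Raises on contradictory observations (the environment is deterministic).
    """
    actions = tuple(actions)
    if not actions:
        return post
    for i in range(1, len(actions)):
        node = post._node(actions[:i])
        if node.continue_obs is False:
            raise ValueError(f"sequence {actions[:i]} observed both terminal and continuing")
        node.continue_obs = True
    node = post._node(actions)
    if terminal:
        if node.continue_obs is True:
            raise ValueError(f"sequence {actions} observed both continuing and terminal")
        node.continue_obs = False
        if node.reward_obs is not None and node.reward_obs != rewarded:
            raise ValueError(f"contradictory reward observations for {actions}")
        node.reward_obs = bool(rewarded)
    else:
        if node.continue_obs is False:
            raise ValueError(f"sequence {actions} observed both terminal and continuing")
        node.continue_obs = True
    return post


# ---------------------------------------------------------------------------
# Monte-Carlo outcome trees
# ---------------------------------------------------------------------------

@dataclass
class OutcomeTree:
    """Result of sampling one outcome tree."""

    credited: list[tuple]  # rewarded terminal sequences at the stopping depth
    nodes_sampled: int
    discarded: bool  # depth cap reached without finding a rewarded terminal


def sample_outcome_tree(
    post: SequencePosterior,
    rng: np.random.Generator,
    depth_cap: int = 12,
    prefix: tuple = (),
) -> OutcomeTree:
    """Grow one tree breadth-first from ``prefix``, sampling each node's
    continue/terminate and reward outcomes from its posterior.

    Growth stops at the first depth containing a sampled rewarded terminal;
    all rewarded terminals at that depth are credited.  If the frontier dies
    out no sequence is credited; if the depth cap is reached the tree is
    discarded.
    """
    frontier = [prefix]
    n_sampled = 0
    actions = range(post.n_actions)
    for _depth in range(depth_cap):
        children = [f + (a,) for f in frontier for a in actions]
        n_sampled += len(children)
        rewarded: list[tuple] = []
        nxt: list[tuple] = []
        u = rng.random(2 * len(children))
        for i, seq in enumerate(children):
            if u[2 * i] < post.p_continue(seq):
                nxt.append(seq)
            elif u[2 * i + 1] < post.p_reward(seq):
                rewarded.append(seq)
        if rewarded:
            return OutcomeTree(credited=rewarded, nodes_sampled=n_sampled, discarded=False)
        if not nxt:
            return OutcomeTree(credited=[], nodes_sampled=n_sampled, discarded=False)
        frontier = nxt
    return OutcomeTree(credited=[], nodes_sampled=n_sampled, discarded=True)


def _enumerate_nodes(n_actions: int, depth_cap: int, prefix: tuple = ()):
    """All sequences extending ``prefix`` by 1..depth_cap actions, by depth."""
    by_depth = []
    frontier = [prefix]
    for _ in range(depth_cap):
        frontier = [f + (a,) for f in frontier for a in range(n_actions)]
        by_depth.append(list(frontier))
    return by_depth


def _sample_counters_vectorized(
    post: SequencePosterior,
    n_trees: int,
    rng: np.random.Generator,
    depth_cap: int,
    prefix: tuple,
) -> Counter:
    """Vectorized equivalent of repeated :func:`sample_outcome_tree`."""
    by_depth = _enumerate_nodes(post.n_actions, depth_cap, prefix)
    nodes = [s for level in by_depth for s in level]
    depth = np.array([len(s) - len(prefix) for s in nodes])
    index = {s: i for i, s in enumerate(nodes)}
    pc = np.array([post.p_continue(s) for s in nodes])
    pr = np.array([post.p_reward(s) for s in nodes])
    n = len(nodes)
    cont = rng.random((n_trees, n)) < pc
    rew = rng.random((n_trees, n)) < pr
    reached = np.empty((n_trees, n), dtype=bool)
    for i, s in enumerate(nodes):
        parent = s[:-1]
        if len(parent) == len(prefix):
            reached[:, i] = True
        else:
            j = index[parent]
            reached[:, i] = reached[:, j] & cont[:, j]
    terminal_rewarded = reached & ~cont & rew
    # stopping depth per tree = first depth with any rewarded terminal
    big = depth_cap + 1
    d_masked = np.where(terminal_rewarded, depth[None, :], big)
    stop = d_masked.min(axis=1)  # (n_trees,)
    credit = terminal_rewarded & (d_masked == stop[:, None]) & (stop[:, None] <= depth_cap)
    counts = credit.sum(axis=0)
    return Counter({nodes[i]: int(c) for i, c in enumerate(counts) if c > 0})


_VECTORIZE_NODE_LIMIT = 5000


def map_sequence(
    post: SequencePosterior,
    n_trees: int = 5000,
    rng: np.random.Generator | None = None,
    depth_cap: int = 12,
    prefix: tuple = (),
) -> tuple:
    """MAP estimate of the best action sequence from tree counters.

    The sequence whose counter is highest across ``n_trees`` sampled trees;
    ties broken uniformly at random.  If no tree credited any sequence, the
    shortest unexplored sequence is returned as an exploration fallback.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    total_nodes = sum(post.n_actions**d for d in range(1, depth_cap + 1))
    if total_nodes <= _VECTORIZE_NODE_LIMIT:
        counters = _sample_counters_vectorized(post, n_trees, rng, depth_cap, prefix)
    else:
        counters = Counter()
        for _ in range(n_trees):
            tree = sample_outcome_tree(post, rng, depth_cap=depth_cap, prefix=prefix)
            for seq in tree.credited:
                counters[seq] += 1
    if not counters:
        return _shortest_unexplored(post, rng, depth_cap, prefix)
    best = max(counters.values())
    top = sorted(s for s, c in counters.items() if c == best)
    return top[int(rng.integers(len(top)))]


def _shortest_unexplored(
    post: SequencePosterior, rng: np.random.Generator, depth_cap: int, prefix: tuple
) -> tuple:
    frontier = [prefix]
    for _ in range(depth_cap):
        children = [f + (a,) for f in frontier for a in range(post.n_actions)]
        fresh = [s for s in children if not post.is_explored(s)]
        if fresh:
            return fresh[int(rng.integers(len(fresh)))]
        frontier = [s for s in children if post.p_continue(s) > 0]
        if not frontier:
            frontier = children
    return prefix + tuple(
        int(rng.integers(post.n_actions)) for _ in range(1)
    )


# ---------------------------------------------------------------------------
# Transition posterior (Models 2 and 3)
# ---------------------------------------------------------------------------

class TransitionPosterior:
    """Categorical successor posterior per (state, action), Dirichlet prior.

    The concentration is taken in the sparse limit, so the posterior
    predictive over successors equals the empirical visit-count ratio and
    collapses to a point mass after one observation of a deterministic
    transition.  Unvisited pairs have no predictive and are handled
    optimistically by the planners.

    Reward estimates are recency-weighted (exponential step
    ``reward_step``): under the switch gate the reward of the goal
    transition is nonstationary *as seen by a Markov model*, and a
    stationary estimate freezes the planner into repeating a failing
    transition forever.
    """

    def __init__(self, n_states: int, n_actions: int, reward_step: float = 0.15):
        self.n_states = n_states
        self.n_actions = n_actions
        self.reward_step = reward_step
        self.counts: dict[tuple[int, int], Counter] = defaultdict(Counter)
        self.reward_est: dict[tuple[int, int], float] = defaultdict(float)
        self.reward_sum: dict[tuple[int, int], float] = defaultdict(float)

    def observe(self, state: int, action: int, next_state: int, reward: float) -> None:
        self.counts[(state, action)][next_state] += 1
        self.reward_sum[(state, action)] += reward
        est = self.reward_est[(state, action)]
        self.reward_est[(state, action)] = est + self.reward_step * (reward - est)

    def n_visits(self, state: int, action: int) -> int:
        return sum(self.counts[(state, action)].values())

    def predictive(self, state: int, action: int) -> dict[int, float] | None:
        """Posterior-predictive successor distribution, or None if unvisited."""
        c = self.counts.get((state, action))
        if not c:
            return None
        total = sum(c.values())
        return {s: n / total for s, n in c.items()}

    def mean_reward(self, state: int, action: int) -> float:
        """Lifetime empirical mean reward (the raw visit-count ratio)."""
        n = self.n_visits(state, action)
        return self.reward_sum[(state, action)] / n if n else 0.0

    def expected_reward(self, state: int, action: int) -> float:
        """Recency-weighted reward estimate used by the planners."""
        if self.n_visits(state, action) == 0:
            return 0.0
        return self.reward_est[(state, action)]


def plan_values(
    tp: TransitionPosterior,
    goal_state: int,
    discount: float = 0.95,
    optimistic_value: float = 0.0,
    n_iter: int = 100,
    tol: float = 1e-4,
    v_init: dict[int, float] | None = None,
) -> dict[tuple[int, int], float]:
    """Value iteration on the posterior-predictive model over observed states.

    The goal is terminal with entry reward 1 (already folded into the
    observed rewards); unvisited (state, action) pairs carry the
    ``optimistic_value`` exploration value.  With the neutral default of 0
    an ignorant planner sees all-tied values and explores by uniform random
    tie-breaking — a random walk for Model 2, a self-avoiding walk for
    Model 3 (which is what separates them).  ``v_init`` warm-starts the
    iteration (the planners reuse their previous solution, which converges
    in a few sweeps).
    """
    states = {s for (s, _a) in tp.counts} | {
        s for c in tp.counts.values() for s in c
    }
    states.discard(goal_state)
    V = {s: (v_init.get(s, 0.0) if v_init else 0.0) for s in states}
    Q: dict[tuple[int, int], float] = {}
    for _ in range(n_iter):
        delta = 0.0
        for s in states:
            best = -np.inf
            for a in range(tp.n_actions):
                pred = tp.predictive(s, a)
                if pred is None:
                    q = optimistic_value
                else:
                    q = tp.expected_reward(s, a) + discount * sum(
                        p * V.get(s2, 0.0) for s2, p in pred.items() if s2 != goal_state
                    )
                Q[(s, a)] = q
                best = max(best, q)
            delta = max(delta, abs(best - V[s]))
            V[s] = best
        if delta < tol:
            break
    if v_init is not None:
        v_init.clear()
        v_init.update(V)
    return Q


# ---------------------------------------------------------------------------
# Agents (EpisodeAgent protocol)
# ---------------------------------------------------------------------------

class Model1Agent:
    """MAP-sequence learner: plans a full action sequence per episode."""

    def __init__(
        self,
        n_actions: int,
        rng: np.random.Generator,
        n_trees: int = 2000,
        replan_trees: int | None = None,
        depth_cap: int = 12,
    ):
        self.post = SequencePosterior(n_actions=n_actions)
        self.rng = rng
        self.n_trees = n_trees
        self.replan_trees = replan_trees if replan_trees is not None else max(1, n_trees // 10)
        self.depth_cap = depth_cap
        self.plan: tuple = ()
        self.history: list[int] = []
        self.rewarded = False

    def begin_episode(self, start_state: int) -> None:
        self.history = []
        self.plan = map_sequence(
            self.post, self.n_trees, self.rng, depth_cap=self.depth_cap
        )

    def act(self, es: EpisodeState) -> int:
        if len(self.history) >= len(self.plan):
            # planned sequence exhausted without termination: extend it
            # (depth is counted below the prefix, so a short cap suffices)
            self.plan = map_sequence(
                self.post,
                self.replan_trees,
                self.rng,
                depth_cap=min(self.depth_cap, 4),
                prefix=tuple(self.history),
            )
        return int(self.plan[len(self.history)])

    def observe(self, state, action, next_state, reward, done) -> None:
        self.history.append(int(action))
        self.rewarded = bool(reward)

    def end_episode(self, rewarded: bool, truncated: bool) -> None:
        if self.history:
            update_sequence_posterior(
                self.post, tuple(self.history), terminal=not truncated, rewarded=rewarded
            )


class Model2Agent:
    """Markov transition learner with optimistic value-iteration planning."""

    def __init__(
        self,
        n_states: int,
        n_actions: int,
        goal_state: int,
        rng: np.random.Generator,
        discount: float = 0.95,
        optimistic_value: float = 0.0,
    ):
        self.tp = TransitionPosterior(n_states, n_actions)
        self.goal_state = goal_state
        self.rng = rng
        self.discount = discount
        self.optimistic_value = optimistic_value
        self.visited_this_episode: set[int] = set()
        self._v_cache: dict[int, float] = {}

    def begin_episode(self, start_state: int) -> None:
        self.visited_this_episode = {start_state}

    def _q_values(self, state: int) -> np.ndarray:
        Q = plan_values(
            self.tp,
            self.goal_state,
            discount=self.discount,
            optimistic_value=self.optimistic_value,
            v_init=self._v_cache,
        )
        return np.array(
            [
                Q.get((state, a), self.optimistic_value)
                for a in range(self.tp.n_actions)
            ]
        )

    def _argmax(self, q: np.ndarray, allowed: np.ndarray | None = None) -> int:
        if allowed is not None:
            q = np.where(allowed, q, -np.inf)
        # values within the planner's tolerance count as tied (uniform pick),
        # so value-iteration residuals cannot freeze the policy into loops
        best = np.flatnonzero(q >= q.max() - 1e-3)
        return int(best[0] if len(best) == 1 else self.rng.choice(best))

    def act(self, es: EpisodeState) -> int:
        return self._argmax(self._q_values(es.current_state))

    def observe(self, state, action, next_state, reward, done) -> None:
        self.tp.observe(state, action, next_state, float(reward))
        self.visited_this_episode.add(next_state)

    def end_episode(self, rewarded: bool, truncated: bool) -> None:
        pass


class Model3Agent(Model2Agent):
    """Model 2 plus avoidance of states already visited this episode."""

    def act(self, es: EpisodeState) -> int:
        q = self._q_values(es.current_state)
        allowed = np.ones(self.tp.n_actions, dtype=bool)
        for a in range(self.tp.n_actions):
            pred = self.tp.predictive(es.current_state, a)
            if pred is None:
                continue  # unknown successor: exploring it is permitted
            if self.goal_state in pred:
                continue  # entering the goal is never a repeat
            successor = max(pred, key=pred.get)
            if successor in self.visited_this_episode:
                allowed[a] = False
        if not allowed.any():
            allowed[:] = True  # every successor visited: fall back to Model 2
        return self._argmax(q, allowed)


def make_bayes_agent(model: int, env, rng: np.random.Generator, **kwargs):
    """Factory for the three switch-task Bayesian learners."""
    if model == 1:
        return Model1Agent(n_actions=env.n_actions, rng=rng, **kwargs)
    if model == 2:
        return Model2Agent(env.n_states, env.n_actions, env.goal_state, rng, **kwargs)
    if model == 3:
        return Model3Agent(env.n_states, env.n_actions, env.goal_state, rng, **kwargs)
    raise ValueError("model must be 1, 2 or 3")
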