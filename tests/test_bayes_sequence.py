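"""Sequence-Bayes learners, including the exact-enumeration planner oracle."""

import itertools

import numpy as np
import pytest

from nonmarkov.bayes_sequence import (
    Model1Agent,
    Model2Agent,
    Model3Agent,
    SequencePosterior,
    TransitionPosterior,
    make_bayes_agent,
    map_sequence,
    sample_outcome_tree,
    update_sequence_posterior,
)
from nonmarkov.envs import EpisodeState, build_switch_env, run_switch_episodes


# ---------------------------------------------------------------------------
# Exact enumeration oracle for the tree planner
# ---------------------------------------------------------------------------

def exact_credit_probabilities(post, n_actions, depth_cap):
    """P(sequence s is credited in one sampled tree), for every s.

    Independent of the sampling code: uses the closed-form recursion
    g(node) = P(subtree below a reached node yields no rewarded terminal
    above the credit depth), exploiting independence of node draws.
    """

    def g(seq, depth_limit):
        if len(seq) >= depth_limit:
            return 1.0
        pc, pr = post.p_continue(seq), post.p_reward(seq)
        no_rew_terminal = (1 - pc) * (1 - pr)
        cont = pc
        for a in range(n_actions):
            cont *= g(seq + (a,), depth_limit)
        return no_rew_terminal + cont

    probs = {}
    seqs = []
    frontier = [()]
    for _ in range(depth_cap):
        frontier = [s + (a,) for s in frontier for a in range(n_actions)]
        seqs.extend(frontier)
    for s in seqs:
        d = len(s)
        p_chain = 1.0
        for i in range(1, d):
            prefix = s[:i]
            p_chain *= post.p_continue(prefix)
            # off-chain sibling subtrees must yield no rewarded terminal
            parent = s[: i - 1]
            for a in range(n_actions):
                sib = parent + (a,)
                if sib != prefix:
                    p_chain *= g(sib, d)
        # siblings of s itself (same depth) may also be rewarded: allowed
        probs[s] = p_chain * (1 - post.p_continue(s)) * post.p_reward(s)
    return probs


def random_posterior(rng, n_actions=2, depth_cap=3):
    post = SequencePosterior(n_actions=n_actions)
    frontier = [()]
    for _ in range(depth_cap):
        frontier = [s + (a,) for s in frontier for a in range(n_actions)]
        for s in frontier:
            post.set_probability(s, rng.random(), rng.random())
    return post


def test_tree_counter_distribution_matches_enumeration(rng):
    """Uniform priors, 2 actions, depth cap 2: MC counters vs closed form."""
    post = SequencePosterior(n_actions=2)
    exact = exact_credit_probabilities(post, 2, 2)
    n = 10_000
    counts = {s: 0 for s in exact}
    for _ in range(n):
        tree = sample_outcome_tree(post, rng, depth_cap=2)
        for s in tree.credited:
            counts[s] += 1
    for s, p in exact.items():
        se = max(np.sqrt(p * (1 - p) / n), 1e-4)
        assert abs(counts[s] / n - p) < 3.5 * se, (s, counts[s] / n, p)


def test_vectorized_and_loop_samplers_agree(rng):
    """The fast path inside map_sequence is the same generative process."""
    post = random_posterior(np.random.default_rng(0))
    exact = exact_credit_probabilities(post, 2, 3)
    n = 20_000
    loop_counts = {s: 0 for s in exact}
    for _ in range(n):
        for s in sample_outcome_tree(post, rng, depth_cap=3).credited:
            loop_counts[s] += 1
    from nonmarkov.bayes_sequence import _sample_counters_vectorized

    vec = _sample_counters_vectorized(post, n, rng, 3, ())
    for s, p in exact.items():
        se = max(np.sqrt(p * (1 - p) / n), 1e-4)
        assert abs(loop_counts[s] / n - p) < 4 * se
        assert abs(vec.get(s, 0) / n - p) < 4 * se


def test_map_matches_enumeration_on_random_posteriors():
    """>= 95% agreement between Monte-Carlo MAP and the exact oracle."""
    matches = 0
    n_configs = 200
    for i in range(n_configs):
        cfg_rng = np.random.default_rng(10_000 + i)
        post = random_posterior(cfg_rng)
        exact = exact_credit_probabilities(post, 2, 3)
        best = max(exact.values())
        mc = map_sequence(post, n_trees=100_000, rng=cfg_rng, depth_cap=3)
        # near-ties are legitimate either way at finite n_trees
        matches += exact[mc] >= best - 1e-9 or exact[mc] >= 0.995 * best
    assert matches >= 0.95 * n_configs


# ---------------------------------------------------------------------------
# Posterior updates (S1-figure scenarios)
# ---------------------------------------------------------------------------

L, R = 0, 1


def test_single_terminal_episode_updates():
    post = SequencePosterior(n_actions=2)
    update_sequence_posterior(post, (L,), terminal=True, rewarded=False)
    assert post.p_continue((L,)) == 0.0
    assert post.p_reward((L,)) == 0.0
    # untouched nodes stay at the uniform prior
    assert post.p_continue((R,)) == 0.5


def test_three_step_episode_marks_prefixes():
    post = SequencePosterior(n_actions=2)
    update_sequence_posterior(post, (L,), terminal=True, rewarded=False)
    update_sequence_posterior(post, (R, L, L), terminal=True, rewarded=False)
    assert post.p_continue((R,)) == 1.0
    assert post.p_continue((R, L)) == 1.0
    assert post.p_continue((R, L, L)) == 0.0
    assert post.p_reward((R, L, L)) == 0.0
    assert post.p_continue((R, R)) == 0.5  # still prior


def test_map_prefers_unexcluded_branch():
    # after the two episodes above, the MAP sequence must start with R
    post = SequencePosterior(n_actions=2)
    update_sequence_posterior(post, (L,), terminal=True, rewarded=False)
    update_sequence_posterior(post, (R, L, L), terminal=True, rewarded=False)
    seq = map_sequence(post, n_trees=3000, rng=np.random.default_rng(1), depth_cap=3)
    assert seq[0] == R


def test_forced_reward_always_credited(rng):
    post = SequencePosterior(n_actions=2)
    post.set_probability((L,), p_continue=0.0, p_reward=0.0)
    post.set_probability((R,), p_continue=1.0)
    post.set_probability((R, R), p_continue=0.0, p_reward=1.0)
    post.set_probability((R, L), p_continue=0.0, p_reward=0.0)
    for _ in range(50):
        tree = sample_outcome_tree(post, rng, depth_cap=3)
        assert tree.credited == [(R, R)]
    assert map_sequence(post, 200, rng, depth_cap=3) == (R, R)


def test_zero_probability_sequence_never_credited(rng):
    post = SequencePosterior(n_actions=2)
    post.set_probability((L,), p_continue=0.0, p_reward=0.0)
    for _ in range(200):
        assert (L,) not in sample_outcome_tree(post, rng, depth_cap=3).credited


def test_contradictory_observation_raises():
    post = SequencePosterior(n_actions=2)
    update_sequence_posterior(post, (L,), terminal=True, rewarded=False)
    with pytest.raises(ValueError):
        update_sequence_posterior(post, (L, L), terminal=True)  # (L,) continues


def test_empty_history_stays_at_prior():
    post = SequencePosterior(n_actions=2)
    update_sequence_posterior(post, (), terminal=False)
    assert not post.nodes


def test_known_optimum_planned_after_single_observation():
    post = SequencePosterior(n_actions=2)
    update_sequence_posterior(post, (R, R), terminal=True, rewarded=True)
    # exclude the short alternatives so exploitation is the MAP choice
    update_sequence_posterior(post, (L, L), terminal=True, rewarded=False)
    got = map_sequence(post, 4000, np.random.default_rng(0), depth_cap=2)
    assert got == (R, R)


def test_fallback_shortest_unexplored(rng):
    post = SequencePosterior(n_actions=2)
    # force everything unrewarded so counters stay at zero
    frontier = [()]
    for _ in range(2):
        frontier = [s + (a,) for s in frontier for a in range(2)]
        for s in frontier:
            post.set_probability(s, p_reward=0.0)
    seq = map_sequence(post, 50, rng, depth_cap=2)
    assert len(seq) == 1  # a length-1 exploratory candidate


def test_posterior_json_roundtrip():
    post = SequencePosterior(n_actions=2)
    update_sequence_posterior(post, (R, L), terminal=True, rewarded=True)
    again = SequencePosterior.from_json(post.to_json())
    assert again.p_continue((R,)) == 1.0
    assert again.p_reward((R, L)) == 1.0


# ---------------------------------------------------------------------------
# Transition posterior and planners
# ---------------------------------------------------------------------------

def bfs_distances(env):
    """Dijkstra/BFS oracle on the gate-open graph."""
    dist = {env.goal_state: 0}
    # reverse search over gate-open successors
    changed = True
    dist_s = {s: np.inf for s in range(env.n_states)}
    for _ in range(env.n_states + 1):
        for s in range(env.n_states):
            for a in range(env.n_actions):
                nxt = env.successor(s, a, switch_visited=True)
                d = 1 if nxt == env.goal_state else dist_s.get(nxt, np.inf) + 1
                if d < dist_s[s]:
                    dist_s[s] = d
    return dist_s


def test_point_mass_after_one_observation():
    tp = TransitionPosterior(4, 2)
    tp.observe(0, 1, 3, 0.0)
    assert tp.predictive(0, 1) == {3: 1.0}
    assert tp.predictive(0, 0) is None


def test_predictive_is_visit_ratio():
    tp = TransitionPosterior(4, 2)
    for _ in range(3):
        tp.observe(0, 0, 1, 0.0)
    tp.observe(0, 0, 2, 0.0)
    pred = tp.predictive(0, 0)
    assert pred == {1: 0.75, 2: 0.25}
    assert abs(sum(pred.values()) - 1.0) < 1e-12


def test_fully_observed_graph_greedy_shortest_path(canonical_env):
    """With the complete gate-open model, Model 2 acts like Dijkstra."""
    env = canonical_env
    tp = TransitionPosterior(env.n_states, env.n_actions)
    for s in range(env.n_states):
        for a in range(env.n_actions):
            nxt = env.successor(s, a, switch_visited=True)
            tp.observe(s, a, nxt, 1.0 if nxt == env.goal_state else 0.0)
    dist = bfs_distances(env)
    agent = Model2Agent(env.n_states, env.n_actions, env.goal_state,
                        np.random.default_rng(0))
    agent.tp = tp
    for s in range(env.n_states):
        if not np.isfinite(dist[s]):
            continue
        a = agent.act(EpisodeState(s, True))
        nxt = env.successor(s, a, switch_visited=True)
        d_next = 0 if nxt == env.goal_state else dist[nxt]
        assert d_next == dist[s] - 1  # greedy step lies on a shortest path


def test_gate_mixture_is_visit_ratio(canonical_env):
    env = canonical_env
    tp = TransitionPosterior(env.n_states, env.n_actions)
    for _ in range(3):
        tp.observe(env.pre_goal_state, env.goal_action, env.decoy_state, 0.0)
    tp.observe(env.pre_goal_state, env.goal_action, env.goal_state, 1.0)
    pred = tp.predictive(env.pre_goal_state, env.goal_action)
    assert pred[env.goal_state] == 0.25
    assert pred[env.decoy_state] == 0.75


def test_no_observations_explores_uniformly():
    agent = Model2Agent(8, 3, 8, np.random.default_rng(0))
    agent.begin_episode(0)
    actions = [agent.act(EpisodeState(0)) for _ in range(300)]
    counts = np.bincount(actions, minlength=3)
    assert (counts > 60).all()  # all-tied values: near-uniform exploration


def test_model3_takes_unvisited_successor(canonical_env):
    env = canonical_env
    agent = Model3Agent(env.n_states, env.n_actions, env.goal_state,
                        np.random.default_rng(0))
    s = 0
    succ = [env.successor(s, a, False) for a in range(3)]
    for a in range(3):
        agent.tp.observe(s, a, succ[a], 0.0)
    agent.begin_episode(s)
    agent.visited_this_episode |= {succ[0], succ[1], s}
    if succ[2] not in agent.visited_this_episode:
        assert agent.act(EpisodeState(s)) == 2


def test_model3_fallback_when_all_visited(canonical_env):
    env = canonical_env
    agent = Model3Agent(env.n_states, env.n_actions, env.goal_state,
                        np.random.default_rng(0))
    s = 0
    for a in range(3):
        agent.tp.observe(s, a, env.successor(s, a, False), 0.0)
    agent.begin_episode(s)
    agent.visited_this_episode = set(range(env.n_states))
    a = agent.act(EpisodeState(s))
    assert a in range(3)  # restriction dropped, model-2 choice returned


# ---------------------------------------------------------------------------
# End-to-end behavior on environments
# ---------------------------------------------------------------------------

def test_models_2_and_3_converge_to_minimum(canonical_env):
    for model in (2, 3):
        res = []
        for s in range(6):
            agent = make_bayes_agent(model, canonical_env, np.random.default_rng(s))
            lengths, _ = run_switch_episodes(canonical_env, agent, 40)
            res.append(lengths)
        res = np.array(res)
        assert np.median(res[:, -10:]) == 5, f"model {model}"
        assert res[:, -10:].mean() < res[:, :5].mean()


def test_model3_beats_model2_paired():
    """No-revisit exploration reaches the goal faster (paired, 50 seeds)."""
    env = build_switch_env(0)
    diffs = []
    for s in range(50):
        totals = {}
        for model in (2, 3):
            agent = make_bayes_agent(model, env, np.random.default_rng(900 + s))
            lengths, _ = run_switch_episodes(env, agent, 15)
            totals[model] = sum(lengths)
        diffs.append(totals[3] - totals[2])
    diffs = np.array(diffs)
    better = (diffs < 0).sum()
    worse = (diffs > 0).sum()
    assert diffs.mean() < 0
    assert better > worse


def test_model1_converges_on_small_env():
    env = build_switch_env(1, n_states=3, n_actions=2, min_episode=2)
    res = []
    for s in range(4):
        agent = Model1Agent(env.n_actions, np.random.default_rng(s), n_trees=400,
                            depth_cap=8)
        lengths, _ = run_switch_episodes(env, agent, 40, max_steps=40)
        res.append(lengths)
    res = np.array(res)
    assert np.median(res[:, -10:]) == 2


def test_model1_improves_on_canonical_env(canonical_env):
    # the uniform-prior MAP planner explores breadth-first, so its
    # improvement horizon is long (~150 episodes; see also the small-env
    # convergence test above)
    res = []
    for s in range(2):
        agent = Model1Agent(canonical_env.n_actions, np.random.default_rng(s),
                            n_trees=300)
        lengths, _ = run_switch_episodes(canonical_env, agent, 170)
        res.append(lengths)
    res = np.array(res)
    assert res[:, -20:].mean() < res[:, :20].mean()
    assert np.median(res[:, -20:]) <= 12


def test_posterior_soundness_after_exhaustive_observation():
    env = build_switch_env(1, n_states=3, n_actions=2, min_episode=2)
    post = SequencePosterior(n_actions=2)
    # observe every depth <= 2 sequence's true outcome by simulation
    from nonmarkov.envs import env_step, initial_episode_state

    for seq in itertools.chain(
        itertools.product(range(2), repeat=1), itertools.product(range(2), repeat=2)
    ):
        es = initial_episode_state(env)
        done = False
        for a in seq:
            if done:
                break
            es, r, done = env_step(env, es, a)
        if done:
            update_sequence_posterior(post, seq[: es.step_count], True, rewarded=r == 1)
        else:
            update_sequence_posterior(post, seq, terminal=False)
    # predicted outcomes now equal the environment's true outcomes
    for seq in itertools.product(range(2), repeat=2):
        es = initial_episode_state(env)
        done = False
        for a in seq:
            if done:
                break
            es, r, done = env_step(env, es, a)
        if not done:
            assert post.p_continue(seq) == 1.0
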