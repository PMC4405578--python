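"""Synthetic surrogates and miniature fixtures.

The study's human traces are not published, so model comparison is
exercised against *surrogate* learning curves drawn from simple
exponential-approach families with per-subject noise — test scaffolding,
not a claim about human data.  The module also builds tiny hand-specified
fixture environments whose dynamics are small enough for exhaustive
oracles, and provides the end-to-end pipeline that runs every learner on
both tasks and emits the comparison tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import bayes_delay, bayes_sequence, policy_gradient, spiking
from .envs import (
    DelayedFeedbackEnv,
    SwitchStateEnv,
    build_switch_env,
    run_switch_episodes,
)
from .evaluation import (
    LearningCurve,
    compare_models,
    episode_length_curve,
    sliding_proportion_correct,
)

__all__ = [
    "SurrogateCurveSpec",
    "FixtureEnv",
    "generate_surrogate_curves",
    "make_fixture",
    "absorption_expected_steps",
    "end_to_end_replica",
    "CANONICAL_ENV_SEED",
]

#: Seed frozen as "the" reconstructed switch-state environment.
CANONICAL_ENV_SEED = 0


@dataclass
class SurrogateCurveSpec:
    """Functional family + noise for surrogate 'human' learning curves.

    switch task:   L(e) = L_min + (L_0 - L_min) * exp(-e / tau_learn)
    feedback task: P(t) = 0.5 + (P_inf - 0.5) * (1 - exp(-t / tau_learn))
    """

    task: str  # "switch" | "feedback"
    n_points: int = 50
    tau_learn: float = 8.0
    l_min: float = 5.0
    l_0: float = 40.0
    p_inf: float = 0.9
    noise_sd: float = 0.0
    noise: str = "gaussian"  # "gaussian" | "binomial"
    window: int = 10  # binomial noise: trials per proportion estimate
    n_subjects: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in ("switch", "feedback"):
            raise ValueError("task must be 'switch' or 'feedback'")
        if self.task == "switch" and self.l_min < 1:
            raise ValueError("l_min must be >= 1")
        if self.task == "feedback" and not (0.5 <= self.p_inf <= 1.0):
            raise ValueError("p_inf must lie in [0.5, 1]")
        if self.tau_learn <= 0:
            raise ValueError("tau_learn must be positive")

    def mean_curve(self) -> np.ndarray:
        t = np.arange(1, self.n_points + 1, dtype=float)
        if self.task == "switch":
            return self.l_min + (self.l_0 - self.l_min) * np.exp(-t / self.tau_learn)
        return 0.5 + (self.p_inf - 0.5) * (1.0 - np.exp(-t / self.tau_learn))


def generate_surrogate_curves(
    spec: SurrogateCurveSpec,
) -> tuple[list[LearningCurve], LearningCurve]:
    """Noisy per-subject curves plus their across-subject mean (with SEM)."""
    rng = np.random.default_rng(spec.seed)
    base = spec.mean_curve()
    subjects = []
    for _ in range(spec.n_subjects):
        if spec.noise == "gaussian":
            y = base + rng.normal(0.0, spec.noise_sd, size=base.shape)
        elif spec.noise == "binomial":
            y = rng.binomial(spec.window, np.clip(base, 0, 1)) / spec.window
        else:
            raise ValueError("noise must be 'gaussian' or 'binomial'")
        if spec.task == "switch":
            y = np.maximum(y, spec.l_min)
        else:
            y = np.clip(y, 0.0, 1.0)
        subjects.append(y)
    stack = np.stack(subjects)
    mean = stack.mean(axis=0)
    sem = (
        stack.std(axis=0, ddof=1) / math.sqrt(spec.n_subjects)
        if spec.n_subjects > 1
        else np.zeros_like(mean)
    )
    x = np.arange(1, spec.n_points + 1)
    per_subject = [LearningCurve(x=x, y=y, n_runs=1) for y in subjects]
    return per_subject, LearningCurve(x=x, y=mean, sem=sem, n_runs=spec.n_subjects)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@dataclass
class FixtureEnv:
    """A tiny environment with precomputed oracle answers."""

    name: str
    env: object
    oracle: dict = field(default_factory=dict)


def absorption_expected_steps(env: SwitchStateEnv) -> float:
    """Expected episode length of the uniform random policy.

    Markov-chain absorption-time solve on the (state, switch-flag) product
    space: (I - Q) x = 1, with the goal absorbing.
    """
    nodes = [
        (s, f) for s in range(env.n_states) for f in (False, True)
    ]
    idx = {node: i for i, node in enumerate(nodes)}
    n = len(nodes)
    Q = np.zeros((n, n))
    for s, f in nodes:
        i = idx[(s, f)]
        for a in range(env.n_actions):
            nxt = env.successor(s, a, f)
            if nxt == env.goal_state:
                continue
            nf = f or nxt == env.switch_state
            Q[i, idx[(nxt, nf)]] += 1.0 / env.n_actions
    x = np.linalg.solve(np.eye(n) - Q, np.ones(n))
    start = (env.start_state, env.start_state == env.switch_state)
    return float(x[idx[start]])


def _gated_chain_3() -> FixtureEnv:
    # 0 = start, 1 = switch (= pre-goal), 2 = decoy; two actions.
    env = SwitchStateEnv(
        n_states=3,
        n_actions=2,
        transitions=np.array([[1, 0], [2, 0], [0, 2]]),
        start_state=0,
        switch_state=1,
        pre_goal_state=1,
        goal_action=0,
        decoy_state=2,
        seed=None,
    )
    oracle = {
        "shortest_episode_length": 2,
        "random_walk_expected_length": absorption_expected_steps(env),
    }
    return FixtureEnv(name="gated-chain-3", env=env, oracle=oracle)


def _two_image_immediate() -> FixtureEnv:
    env = DelayedFeedbackEnv(
        category_map=np.array([0, 1]), delay_mode="immediate", seed=None
    )
    return FixtureEnv(
        name="two-image-immediate",
        env=env,
        oracle={"oracle_agent_proportion_correct": 1.0},
    )


_FIXTURES = {
    "gated-chain-3": _gated_chain_3,
    "two-image-immediate": _two_image_immediate,
}


def make_fixture(name: str) -> FixtureEnv:
    """Deterministically construct a named fixture environment."""
    try:
        return _FIXTURES[name]()
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        ) from None


# ---------------------------------------------------------------------------
# End-to-end replica pipeline
# ---------------------------------------------------------------------------

SWITCH_AGENTS = (
    "spiking",
    "bayes_map_sequence",
    "bayes_transition",
    "bayes_no_revisit",
    "policy_gradient",
)
FEEDBACK_AGENTS = ("spiking", "delay_bayes", "policy_gradient")

#: Free-parameter counts entering the AICc (learning rate only for the
#: gradient learners; the Bayesian learners' constants are treated as fixed).
K_VALUES = {
    "spiking": 1,
    "policy_gradient": 1,
    "bayes_map_sequence": 0,
    "bayes_transition": 0,
    "bayes_no_revisit": 0,
    "delay_bayes": 0,
}


def run_switch_agent(
    name: str,
    env: SwitchStateEnv,
    n_runs: int,
    n_episodes: int,
    seed: int,
    max_steps: int = 100,
    pg_eta: float = 0.5,
    model1_trees: int = 500,
) -> np.ndarray:
    """Episode-length array (n_runs x n_episodes) for one learner family."""
    if name == "spiking":
        return spiking.switch_learning_curves(
            env, n_runs=n_runs, n_episodes=n_episodes, seed=seed, max_steps=max_steps
        )
    ss = np.random.SeedSequence(seed)
    out = np.empty((n_runs, n_episodes), dtype=int)
    for i, child in enumerate(ss.spawn(n_runs)):
        rng = np.random.default_rng(child)
        if name == "bayes_map_sequence":
            agent = bayes_sequence.Model1Agent(
                env.n_actions, rng, n_trees=model1_trees
            )
        elif name == "bayes_transition":
            agent = bayes_sequence.Model2Agent(
                env.n_states, env.n_actions, env.goal_state, rng
            )
        elif name == "bayes_no_revisit":
            agent = bayes_sequence.Model3Agent(
                env.n_states, env.n_actions, env.goal_state, rng
            )
        elif name == "policy_gradient":
            agent = policy_gradient.PGSwitchAgent(env.n_actions, pg_eta, rng)
        else:
            raise ValueError(f"unknown switch agent {name!r}")
        lengths, _ = run_switch_episodes(env, agent, n_episodes, max_steps=max_steps)
        out[i] = lengths
    return out


def run_feedback_agent(
    name: str,
    env: DelayedFeedbackEnv,
    n_runs: int,
    n_trials: int,
    seed: int,
    pg_eta: float = 0.3,
) -> np.ndarray:
    """Correctness array (n_runs x n_trials) for one learner family."""
    ss = np.random.SeedSequence(seed)
    out = np.empty((n_runs, n_trials), dtype=int)
    for i, child in enumerate(ss.spawn(n_runs)):
        run_seed = int(np.random.default_rng(child).integers(2**31))
        if name == "spiking":
            log = spiking.run_feedback_task(env, n_trials, seed=run_seed)
        elif name == "delay_bayes":
            log, _ = bayes_delay.run_delay_bayes_session(env, n_trials, seed=run_seed)
        elif name == "policy_gradient":
            log = policy_gradient.run_pg_feedback(env, pg_eta, n_trials, seed=run_seed)
        else:
            raise ValueError(f"unknown feedback agent {name!r}")
        out[i] = log.correctness()
    return out


def end_to_end_replica(config: dict | None = None, out_dir=None) -> dict:
    """Run every learner on both tasks and compare against surrogate curves.

    Returns a dict with the learning curves and the two comparison tables;
    if ``out_dir`` is given, curves and tables are also written as CSV (and
    figures as PNG when ``config['plots']`` is true).  Fully seeded: two
    invocations with the same config produce identical outputs.
    """
    cfg = {
        "seed": 0,
        "env_seed": CANONICAL_ENV_SEED,
        "switch_agents": list(SWITCH_AGENTS),
        "feedback_agents": list(FEEDBACK_AGENTS),
        "n_runs": 4,
        "switch_episodes": 50,
        "max_steps": 100,
        "feedback_trials": 400,
        "n_images": 10,
        "window": 10,
        "plots": False,
    }
    cfg.update(config or {})
    seed = int(cfg["seed"])

    switch_env = build_switch_env(seed=int(cfg["env_seed"]))
    feedback_env = DelayedFeedbackEnv.random(
        cfg["n_images"], seed=seed, delay_mode="gamma"
    )

    surro_switch = SurrogateCurveSpec(
        task="switch",
        n_points=cfg["switch_episodes"],
        noise_sd=2.0,
        n_subjects=10,
        seed=seed + 1,
    )
    surro_feedback = SurrogateCurveSpec(
        task="feedback",
        n_points=cfg["feedback_trials"] - cfg["window"] + 1,
        tau_learn=80.0,
        noise="binomial",
        n_subjects=14,
        seed=seed + 2,
    )
    _, ref_switch = generate_surrogate_curves(surro_switch)
    _, ref_feedback = generate_surrogate_curves(surro_feedback)

    switch_curves: dict[str, LearningCurve] = {}
    for i, name in enumerate(cfg["switch_agents"]):
        lengths = run_switch_agent(
            name,
            switch_env,
            n_runs=cfg["n_runs"],
            n_episodes=cfg["switch_episodes"],
            seed=seed * 1000 + i,
            max_steps=cfg["max_steps"],
        )
        switch_curves[name] = episode_length_curve(lengths)

    feedback_curves: dict[str, LearningCurve] = {}
    for i, name in enumerate(cfg["feedback_agents"]):
        correct = run_feedback_agent(
            name,
            feedback_env,
            n_runs=cfg["n_runs"],
            n_trials=cfg["feedback_trials"],
            seed=seed * 2000 + i,
        )
        feedback_curves[name] = sliding_proportion_correct(
            correct, window=cfg["window"]
        )

    table_switch = compare_models(ref_switch, switch_curves, K_VALUES)
    table_feedback = compare_models(ref_feedback, feedback_curves, K_VALUES)

    result = {
        "switch_reference": ref_switch,
        "feedback_reference": ref_feedback,
        "switch_curves": switch_curves,
        "feedback_curves": feedback_curves,
        "switch_table": table_switch,
        "feedback_table": table_feedback,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table_switch.to_csv(out / "switch_comparison.csv", index=False)
        table_feedback.to_csv(out / "feedback_comparison.csv", index=False)
        ref_switch.to_csv(out / "switch_reference.csv")
        ref_feedback.to_csv(out / "feedback_reference.csv")
        for name, curve in switch_curves.items():
            curve.to_csv(out / f"switch_{name}.csv")
        for name, curve in feedback_curves.items():
            curve.to_csv(out / f"feedback_{name}.csv")
        if cfg["plots"]:
            _plot_replica(result, out)
    return result


def _plot_replica(result: dict, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(11, 4))
    for name, curve in result["switch_curves"].items():
        axes[0].plot(curve.x, curve.y, label=name)
    ref = result["switch_reference"]
    axes[0].plot(ref.x, ref.y, "k--", label="surrogate reference")
    axes[0].set(xlabel="episode", ylabel="episode length", title="switch task")
    axes[0].legend(fontsize=7)
    for name, curve in result["feedback_curves"].items():
        axes[1].plot(curve.x, curve.y, label=name)
    ref = result["feedback_reference"]
    axes[1].plot(ref.x, ref.y, "k--", label="surrogate reference")
    axes[1].set(
        xlabel="trial", ylabel="proportion correct", title="intermixed feedback"
    )
    axes[1].set_ylim(0, 1.02)
    axes[1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "replica.png", dpi=120)
    plt.close(fig)
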