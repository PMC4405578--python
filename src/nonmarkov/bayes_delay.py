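"""Bayesian learner for intermixed feedback.

The learner maintains a Dirichlet-process prior over the unknown
feedback-delay distribution, realized computably as a finite Dirichlet on a
discretized delay grid (uniform base measure, concentration ``alpha``).
When a feedback event arrives, each recent outstanding response receives a
responsibility weight proportional to the posterior-predictive delay
density at its lag (delivery time minus response time); the weights update
both the delay posterior (fractional lag counts) and the per-image category
beliefs (fractional Beta evidence).  Decisions marginalize over delay
distributions via the posterior predictive and pick the category with the
higher posterior probability of being correct.

With immediate feedback there is exactly one outstanding response per
event, every weight is 1, and the learner reduces to plain Beta-Bernoulli
category learning (see :class:`PlainCategoryLearner`, the reference
implementation used by the reduction tests).

Category evidence is discounted by ``discount`` per (weighted) update so
the learner can track reversals — with ``discount=1`` the reduction to
exact Beta-Bernoulli updating is recovered.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .envs import DelayedFeedbackEnv, TrialLog, run_feedback_session

__all__ = [
    "DelayPosterior",
    "CategoryBelief",
    "DelayBayesAgent",
    "PlainCategoryLearner",
    "responsibility_weights",
    "update_delay_posterior",
    "update_category_belief",
    "act_delay_bayes",
    "run_delay_bayes_session",
]


@dataclass
class DelayPosterior:
    """Finite-Dirichlet posterior over a discretized delay distribution."""

    alpha: float = 1.0
    grid_max: float = 15.0
    bin_width: float = 0.25
    counts: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.counts is None:
            self.counts = np.zeros(self.n_bins)
        else:
            self.counts = np.asarray(self.counts, dtype=float)

    @property
    def n_bins(self) -> int:
        return int(round(self.grid_max / self.bin_width))

    @property
    def bin_centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_width

    def bin_of(self, lag: float) -> int:
        if lag < 0:
            raise ValueError("lags must be non-negative")
        return min(int(lag / self.bin_width), self.n_bins - 1)

    def posterior_mass(self) -> np.ndarray:
        """Mean of the Dirichlet posterior: (alpha*base + counts), normalized."""
        base = np.full(self.n_bins, 1.0 / self.n_bins)
        mass = self.alpha * base + self.counts
        return mass / mass.sum()

    def predictive_density(self, lag) -> np.ndarray | float:
        """Posterior-predictive delay density (per second) at given lag(s)."""
        mass = self.posterior_mass()
        lags = np.atleast_1d(np.asarray(lag, dtype=float))
        out = np.zeros_like(lags)
        inside = (lags >= 0) & (lags < self.grid_max)
        idx = np.clip((lags[inside] / self.bin_width).astype(int), 0, self.n_bins - 1)
        out[inside] = mass[idx] / self.bin_width
        return float(out[0]) if np.isscalar(lag) or np.ndim(lag) == 0 else out

    def mean_delay(self) -> float:
        return float(self.posterior_mass() @ self.bin_centers)

    def to_json(self) -> str:
        return json.dumps(
            {
                "alpha": self.alpha,
                "grid_max": self.grid_max,
                "bin_width": self.bin_width,
                "counts": self.counts.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "DelayPosterior":
        d = json.loads(text)
        return cls(
            alpha=d["alpha"],
            grid_max=d["grid_max"],
            bin_width=d["bin_width"],
            counts=np.asarray(d["counts"]),
        )


def update_delay_posterior(
    dp: DelayPosterior, lags, weights=None
) -> DelayPosterior:
    """Add (fractionally weighted) observed lags to the posterior counts."""
    lags = np.atleast_1d(np.asarray(lags, dtype=float))
    weights = (
        np.ones_like(lags) if weights is None else np.atleast_1d(np.asarray(weights))
    )
    for lag, w in zip(lags, weights):
        dp.counts[dp.bin_of(float(lag))] += float(w)
    return dp


@dataclass
class _Outstanding:
    trial: int
    time: float
    image: int
    action: int
    received: float = 0.0  # attribution weight already absorbed


def responsibility_weights(
    dp: DelayPosterior, delivery_time: float, candidates: list[_Outstanding]
) -> np.ndarray:
    """Per-candidate attribution weights for one feedback event.

    Weight of candidate ``i`` is proportional to the posterior-predictive
    delay density at its lag times its remaining attribution capacity
    ``1 - received`` (each response explains at most one feedback event in
    total); weights are normalized to sum to one.
    """
    if not candidates:
        raise ValueError("no candidate responses for feedback attribution")
    lags = np.array([delivery_time - c.time for c in candidates])
    if np.any(lags < 0):
        raise ValueError("candidates must precede the feedback event")
    dens = np.asarray(dp.predictive_density(lags), dtype=float)
    capacity = np.array([max(0.0, 1.0 - c.received) for c in candidates])
    w = dens * capacity
    total = w.sum()
    if total <= 0:
        w = capacity if capacity.sum() > 0 else np.ones(len(candidates))
        total = w.sum()
    return w / total


@dataclass
class CategoryBelief:
    """Per-image Beta posterior that 'left' (action 0) is the correct category.

    The symmetric Beta(1,1) prior is kept separate from the accumulated
    evidence so that evidence discounting never erodes the prior.
    """

    n_images: int
    prior: tuple[float, float] = (1.0, 1.0)
    discount: float = 1.0
    evidence: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.evidence is None:
            self.evidence = np.zeros((self.n_images, 2))  # columns: left, right
        else:
            self.evidence = np.asarray(self.evidence, dtype=float)

    def p_left(self, image: int) -> float:
        a = self.prior[0] + self.evidence[image, 0]
        b = self.prior[1] + self.evidence[image, 1]
        return a / (a + b)

    def update(self, image: int, action: int, sign: float, weight: float) -> None:
        """Fractional evidence that the response was correct/incorrect.

        A correct 'left' (or incorrect 'right') is evidence for left being
        the true category, and vice versa.  Evidence for the image is first
        discounted by ``discount ** weight``.
        """
        if weight == 0.0:
            return
        left_is_correct = (action == 0) == (sign > 0)
        self.evidence[image] *= self.discount**weight
        self.evidence[image, 0 if left_is_correct else 1] += weight

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_images": self.n_images,
                "prior": list(self.prior),
                "discount": self.discount,
                "evidence": self.evidence.tolist(),
            }
        )


def update_category_belief(
    cb: CategoryBelief,
    sign: float,
    candidates: list[_Outstanding],
    weights: np.ndarray,
) -> CategoryBelief:
    for cand, w in zip(candidates, weights):
        cb.update(cand.image, cand.action, sign, float(w))
    return cb


def act_delay_bayes(cb: CategoryBelief, image: int, rng: np.random.Generator) -> int:
    """Greedy argmax of the category posterior; ties broken uniformly."""
    p = cb.p_left(image)
    if p > 0.5:
        return 0
    if p < 0.5:
        return 1
    return int(rng.integers(2))


class DelayBayesAgent:
    """Full learner: delay posterior + category beliefs + soft attribution."""

    def __init__(
        self,
        n_images: int,
        rng: np.random.Generator,
        alpha: float = 1.0,
        grid_max: float = 15.0,
        bin_width: float = 0.25,
        discount: float = 0.9,
        attribution_window: int = 10,
    ):
        self.dp = DelayPosterior(alpha=alpha, grid_max=grid_max, bin_width=bin_width)
        self.cb = CategoryBelief(n_images=n_images, discount=discount)
        self.rng = rng
        self.attribution_window = attribution_window
        self.outstanding: list[_Outstanding] = []
        self.pending_feedback: list[tuple[float, float]] = []
        self.trial = 0

    def act(self, stimulus: int, time: float) -> int:
        action = act_delay_bayes(self.cb, stimulus, self.rng)
        self.outstanding.append(_Outstanding(self.trial, time, stimulus, action))
        self.outstanding = self.outstanding[-self.attribution_window :]
        self.trial += 1
        return action

    def receive_feedback(self, sign: float, time: float) -> None:
        candidates = [c for c in self.outstanding if c.time <= time and c.received < 1.0]
        if not candidates:
            self.pending_feedback.append((sign, time))  # held, attributed never
            return
        w = responsibility_weights(self.dp, time, candidates)
        update_category_belief(self.cb, sign, candidates, w)
        lags = [time - c.time for c in candidates]
        update_delay_posterior(self.dp, lags, w)
        for cand, wi in zip(candidates, w):
            cand.received += float(wi)


class PlainCategoryLearner:
    """Reference Beta-Bernoulli learner (valid for immediate feedback only).

    Attributes every feedback event to its (unique) outstanding response.
    Used as the behavioral oracle for the immediate-mode reduction test.
    """

    def __init__(
        self,
        n_images: int,
        rng: np.random.Generator,
        discount: float = 1.0,
    ):
        self.cb = CategoryBelief(n_images=n_images, discount=discount)
        self.rng = rng
        self.last: tuple[int, int] | None = None

    def act(self, stimulus: int, time: float) -> int:
        action = act_delay_bayes(self.cb, stimulus, self.rng)
        self.last = (stimulus, action)
        return action

    def receive_feedback(self, sign: float, time: float) -> None:
        if self.last is None:
            return
        image, action = self.last
        self.cb.update(image, action, sign, 1.0)
        self.last = None


def run_delay_bayes_session(
    env: DelayedFeedbackEnv,
    n_trials: int,
    seed: int = 0,
    agent: DelayBayesAgent | None = None,
    **agent_kwargs,
) -> tuple[TrialLog, DelayBayesAgent]:
    """Run one session with the delay-Bayes learner; returns (log, agent)."""
    ss = np.random.SeedSequence(seed)
    agent_rng, env_rng = (np.random.default_rng(c) for c in ss.spawn(2))
    if agent is None:
        agent = DelayBayesAgent(env.n_images, agent_rng, **agent_kwargs)
    log = run_feedback_session(env, agent, n_trials, env_rng)
    return log, agent
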