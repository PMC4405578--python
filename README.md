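# nonmarkov

Simulators, learners and model comparison for two prototypical
**non-Markovian decision tasks**:

1. **Switch-state navigation** — an episodic task on a small deterministic
   state/action graph whose goal transition is gated: the goal can only be
   entered after a designated *switch* state has been visited in the current
   episode; premature goal attempts are silently redirected to a decoy
   state. History matters, so the task violates the Markov property.
2. **Intermixed feedback** — two-category image classification in which
   feedback for each response is delayed by a gamma-distributed lag
   (shape 2, scale 1.5 s), so feedback events arrive out of response order
   and the response→feedback mapping is ambiguous.

Four learner families run on these tasks:

| module | learner | free parameters |
|---|---|---|
| `nonmarkov.spiking` | population-of-spiking-neurons policy gradient with a three-trace eligibility cascade | 1 (learning rate) |
| `nonmarkov.bayes_sequence` | three Bayesian learners for the switch task: Monte-Carlo tree MAP sequence planning (Model 1), Markov transition learning with value iteration (Model 2), Model 2 plus within-episode state-revisit avoidance (Model 3) | 0 |
| `nonmarkov.bayes_delay` | Dirichlet-process prior over the feedback-delay distribution with soft reward–response credit assignment | 0 |
| `nonmarkov.policy_gradient` | tabular softmax REINFORCE baseline | 1 (learning rate) |

The evaluation layer (`nonmarkov.evaluation`) builds 10-trial sliding-window
proportion-correct curves and episode-length curves, and compares models to
a reference curve by residual sum of squares and the finite-sample-corrected
Akaike information criterion (AICc). Since no human traces ship with the
package, `nonmarkov.synth` generates surrogate reference curves
(exponential-approach families with per-subject noise), miniature fixture
environments with exhaustive oracles, and an end-to-end pipeline that runs
every learner on both tasks and emits the comparison tables.

## Quick start

```python
import numpy as np
import nonmarkov as nm

env = nm.build_switch_env(seed=0)            # canonical 8-state, 3-action graph
nm.shortest_episode_length(env)              # -> 5 (BFS over (state, flag) space)

from nonmarkov.spiking import switch_learning_curves
curves = switch_learning_curves(env, n_runs=20, n_episodes=60, seed=1)
nm.episode_length_curve(curves)              # mean episode-length curve with SEM

from nonmarkov.bayes_delay import run_delay_bayes_session
fenv = nm.DelayedFeedbackEnv.random(10, seed=0, delay_mode="gamma")
log, agent = run_delay_bayes_session(fenv, n_trials=400, seed=0)
nm.sliding_proportion_correct(log.correctness(), window=10)
```

## Command line

A single entry point `nonmarkov` with command groups:

```bash
nonmarkov envs generate-switch --seed 0 --min-episode 5
nonmarkov agent spiking --task switch --runs 4 --episodes 50 --out curve.csv
nonmarkov agent bayes --model 3 --runs 4 --episodes 50 --out bayes3.csv
nonmarkov agent delay-bayes --trials 400 --out log.csv
nonmarkov agent pg --task switch --eta 0.5 --out pg.csv
nonmarkov eval curve --log log.csv --window 10 --out curve.csv
nonmarkov eval compare --reference ref.csv --models m1.csv --models m2.csv --k m1=1
nonmarkov synth curves --task feedback --out surrogate.csv
nonmarkov replica run --out results/    # full pipeline, both tasks, all models
```

## Layout

```
src/nonmarkov/
  envs.py              both task simulators, TrialLog, episode runner
  spiking.py           spiking policy-gradient learner (eligibility cascade)
  bayes_sequence.py    sequence/transition Bayesian learners + tree planner
  bayes_delay.py       Dirichlet-process delay learner
  policy_gradient.py   softmax REINFORCE baseline + learning-rate fitting
  evaluation.py        curves, RSS, AICc, model comparison
  synth.py             surrogate curves, fixtures, end-to-end replica
  cli.py               click CLI
tests/                 pytest suite (unit, property, acceptance criteria)
scripts/acceptance.py  acceptance report generator
```
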