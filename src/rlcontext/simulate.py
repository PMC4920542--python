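"""Ex-ante and ex-post simulation of the model lattice on the task.

Ex-ante simulation draws whole cohorts of virtual agents from chosen
parameters to characterise each model's predicted behaviour (option
values, decision values, learning curves, post-learning preferences).
Ex-post simulation replays a subject's actual choice/outcome history
under fitted parameters and returns the model's trial-by-trial
probability of the correct choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import models as m
from . import task as tk
from ._kernels import replay_pcorrect_kernel

__all__ = [
    "SimulationSummary",
    "simulate_agent",
    "simulate_population",
    "ex_post_choice_probs",
    "simulate_postlearning",
    "cue_values",
]


def simulate_agent(
    model: m.Model,
    params: m.Parameters,
    task_config: Optional[tk.TaskConfig] = None,
    seed: Optional[int] = None,
    subject_id: str = "sim",
) -> tuple[tk.SessionHistory, m.AgentState]:
    """Simulate one agent through a learning session.

    Each trial the agent samples its choice from the softmax over current
    Q-values, outcomes are drawn from the context's Bernoulli schedules,
    and the state is updated under `model`. Fully reproducible by `seed`.
    """
    if not params.satisfies(model):
        raise ValueError(f"parameters violate {model.value} constraints {model.zeroed}")
    config = task_config or tk.TaskConfig()
    rng = np.random.default_rng(seed)
    scaffold = tk.generate_session_scaffold(config, rng_seed=rng.integers(2**31))
    state = m.init_state(len(config.contexts))
    n = len(scaffold)
    ctx_idx = np.empty(n, dtype=np.int64)
    chosen = np.empty(n, dtype=np.int64)
    r_c = np.empty(n)
    r_u = np.full(n, np.nan)
    complete = np.empty(n, dtype=bool)
    sides = np.empty(n, dtype=object)
    for t, (s, side) in enumerate(scaffold):
        context = config.contexts[s]
        p_correct = m.choice_prob(state, s, tk.CORRECT, params.beta)
        choice = tk.CORRECT if rng.random() < p_correct else tk.INCORRECT
        out_c, out_u = tk.sample_outcomes(context, choice, rng)
        _, state = m.step(state, s, choice, out_c, out_u, params, model)
        ctx_idx[t] = s
        chosen[t] = choice
        r_c[t] = out_c
        if out_u is not None:
            r_u[t] = out_u
        complete[t] = context.feedback is tk.Feedback.COMPLETE
        sides[t] = side
    history = tk.SessionHistory(
        subject_id=subject_id,
        contexts=config.contexts,
        context_idx=ctx_idx,
        chosen=chosen,
        r_c=r_c,
        r_u=r_u,
        complete=complete,
        side_of_correct=sides,
    )
    return history, state


@dataclass
class SimulationSummary:
    """Cohort-level aggregates of an ex-ante simulation.

    Attributes
    ----------
    option_values : DataFrame
        Mean final Q per (context, cue); one row per cue.
    decision_values : DataFrame
        Mean final decision value ``Q(correct) - Q(incorrect)`` per context.
    learning_curves : DataFrame
        Mean correct-choice probability per (context, trial-in-context).
    postlearning_rates : DataFrame
        Mean softmax choice rate per cue over all 28 pairings of the
        post-learning test.
    """

    model: m.Model
    n_agents: int
    option_values: pd.DataFrame
    decision_values: pd.DataFrame
    learning_curves: pd.DataFrame
    postlearning_rates: pd.DataFrame

    def to_tidy(self) -> pd.DataFrame:
        """All aggregates as one long (model, context, trial, statistic, value) table."""
        rows = []
        for _, r in self.option_values.iterrows():
            rows.append((self.model.value, r["context"], None, f"Q[{r['cue']}]", r["mean_q"]))
        for _, r in self.decision_values.iterrows():
            rows.append((self.model.value, r["context"], None, "decision_value", r["mean_dq"]))
        for _, r in self.learning_curves.iterrows():
            rows.append(
                (self.model.value, r["context"], int(r["trial"]), "p_correct", r["mean_p_correct"])
            )
        for _, r in self.postlearning_rates.iterrows():
            rows.append((self.model.value, None, None, f"rate[{r['cue']}]", r["mean_rate"]))
        return pd.DataFrame(rows, columns=["model", "context", "trial", "statistic", "value"])


def cue_values(state: m.AgentState, contexts: Sequence[tk.ChoiceContext]) -> dict[str, float]:
    """Final Q-value of each of the 8 cues, keyed by cue label."""
    out = {}
    for i, c in enumerate(contexts):
        correct_cue, incorrect_cue = tk.cue_names_for_context(c)
        out[correct_cue] = float(state.q[i, tk.CORRECT])
        out[incorrect_cue] = float(state.q[i, tk.INCORRECT])
    return out


def simulate_population(
    model: m.Model,
    params: m.Parameters,
    n_agents: int = 1000,
    task_config: Optional[tk.TaskConfig] = None,
    seed: Optional[int] = None,
) -> SimulationSummary:
    """Aggregate :func:`simulate_agent` over a virtual cohort."""
    if n_agents < 1:
        raise ValueError("n_agents must be >= 1")
    config = task_config or tk.TaskConfig()
    rng = np.random.default_rng(seed)
    n_ctx = len(config.contexts)
    n_per = config.n_trials_per_context

    q_sum = np.zeros((n_ctx, 2))
    curve_sum = np.zeros((n_ctx, n_per))
    rate_sum: dict[str, float] = {}
    for _ in range(n_agents):
        hist, final = simulate_agent(
            model, params, config, seed=int(rng.integers(2**31))
        )
        q_sum += final.q
        # per-context trial-by-trial model probability of the correct choice
        p = ex_post_choice_probs(model, params, hist)
        for s in range(n_ctx):
            curve_sum[s] += p[hist.context_idx == s]
        rates = simulate_postlearning(final, params.beta, contexts=config.contexts)
        for cue, r in rates.items():
            rate_sum[cue] = rate_sum.get(cue, 0.0) + r

    ids = [c.context_id for c in config.contexts]
    option_rows = []
    for s, c in enumerate(config.contexts):
        cor, inc = tk.cue_names_for_context(c)
        option_rows.append((ids[s], cor, q_sum[s, tk.CORRECT] / n_agents))
        option_rows.append((ids[s], inc, q_sum[s, tk.INCORRECT] / n_agents))
    dq = (q_sum[:, tk.CORRECT] - q_sum[:, tk.INCORRECT]) / n_agents
    curves = [
        (ids[s], t + 1, curve_sum[s, t] / n_agents)
        for s in range(n_ctx)
        for t in range(n_per)
    ]
    return SimulationSummary(
        model=model,
        n_agents=n_agents,
        option_values=pd.DataFrame(option_rows, columns=["context", "cue", "mean_q"]),
        decision_values=pd.DataFrame({"context": ids, "mean_dq": dq}),
        learning_curves=pd.DataFrame(curves, columns=["context", "trial", "mean_p_correct"]),
        postlearning_rates=pd.DataFrame(
            {"cue": list(rate_sum), "mean_rate": [rate_sum[c] / n_agents for c in rate_sum]}
        ),
    )


def ex_post_choice_probs(
    model: m.Model, fitted_params: m.Parameters, observed: tk.SessionHistory
) -> np.ndarray:
    """Model probability of the correct choice at each trial of an
    observed history, conditioning on the subject's actual choices and
    outcomes up to (but not including) that trial. Trial 1 is 0.5."""
    p = fitted_params.constrained_to(model)
    r_u = observed.r_u.copy()
    r_u[~observed.complete] = 0.0  # unused under Partial; keep kernel nan-free
    return replay_pcorrect_kernel(
        p.beta,
        p.alpha1,
        p.alpha2,
        p.alpha3,
        observed.context_idx,
        observed.chosen,
        observed.r_c,
        r_u,
        observed.complete,
        observed.n_contexts,
    )


def simulate_postlearning(
    final_state: m.AgentState,
    beta: float,
    schedule: Optional[Sequence[tk.PostLearningTrial]] = None,
    contexts: Optional[Sequence[tk.ChoiceContext]] = None,
    rng: Optional[np.random.Generator] = None,
) -> dict[str, float]:
    """Per-cue choice rates in the post-learning transfer test.

    Each of the 28 cue pairings is decided by a softmax over the two
    cues' final learning-task Q-values, with the same inverse temperature
    fitted on the learning task. The default output is the expected rate
    (mean choice probability over a cue's 7 pairings); pass `rng` to
    resample discrete choices instead (generative mode).
    """
    contexts = tuple(contexts) if contexts is not None else tuple(tk.make_default_contexts())
    values = cue_values(final_state, contexts)
    if schedule is None:
        import itertools

        schedule = [
            tk.PostLearningTrial(a, b)
            for a, b in itertools.combinations(list(values), 2)
        ]
    won: dict[str, float] = {cue: 0.0 for cue in values}
    seen: dict[str, int] = {cue: 0 for cue in values}
    for trial in schedule:
        qa, qb = values[trial.cue_a], values[trial.cue_b]
        pa = float(np.exp(-np.logaddexp(0.0, beta * (qb - qa))))
        if rng is not None:
            pa = 1.0 if rng.random() < pa else 0.0
        won[trial.cue_a] += pa
        won[trial.cue_b] += 1.0 - pa
        seen[trial.cue_a] += 1
        seen[trial.cue_b] += 1
    return {cue: won[cue] / seen[cue] for cue in values}
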