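"""Behavioural dependent measures: learning curves, reaction-time
smoothing, and post-learning choice rates / cue discrimination.

These operate on trial-level data (real or synthetic) and emit tidy
tables; statistical inference on the group contrasts is left to
standard statistics tooling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import task as tk

__all__ = [
    "LearningCurve",
    "PostLearningRates",
    "learning_curve",
    "smooth_rt",
    "postlearning_rates",
    "cohort_choice_table",
    "cohort_postlearning_table",
]


@dataclass
class LearningCurve:
    """Cumulative correct-choice averages per context.

    ``curve`` holds one row per (context, trial-in-context) with the
    cumulative mean of correct responses over trials 1..t; ``improvement``
    is trial-20 minus trial-1 (chance: 0), ``final_rate`` the trial-20
    value (chance: 0.5).
    """

    subject_id: str
    curve: pd.DataFrame  # columns: context, trial, cum_correct
    improvement: pd.Series  # by context
    final_rate: pd.Series  # by context


def learning_curve(history: tk.SessionHistory) -> LearningCurve:
    """Trial-by-trial cumulative average of correct responses, per context."""
    n_per = len(history) // history.n_contexts
    rows = []
    improvement = {}
    final = {}
    for s, context in enumerate(history.contexts):
        correct = (history.chosen[history.context_idx == s] == tk.CORRECT).astype(float)
        if len(correct) != n_per:
            raise ValueError(
                f"context {context.context_id} has {len(correct)} trials, expected {n_per}"
            )
        cum = np.cumsum(correct) / np.arange(1, n_per + 1)
        for t, v in enumerate(cum, start=1):
            rows.append((context.context_id, t, v))
        improvement[context.context_id] = float(cum[-1] - cum[0])
        final[context.context_id] = float(cum[-1])
    return LearningCurve(
        subject_id=history.subject_id,
        curve=pd.DataFrame(rows, columns=["context", "trial", "cum_correct"]),
        improvement=pd.Series(improvement, name="improvement"),
        final_rate=pd.Series(final, name="final_rate"),
    )


def smooth_rt(rts: Sequence[float]) -> np.ndarray:
    """Three-trial centred sliding-window average of reaction times.

    At the series edges the window truncates to the two available
    trials. The RT reduction statistic is smoothed trial 1 minus
    smoothed trial 20.
    """
    arr = np.asarray(rts, dtype=float)
    if len(arr) < 3:
        raise ValueError("need at least 3 trials to smooth")
    if np.all(np.isnan(arr)):
        raise ValueError("no reaction times present")
    return (
        pd.Series(arr).rolling(window=3, center=True, min_periods=2).mean().to_numpy()
    )


@dataclass
class PostLearningRates:
    subject_id: str
    rates: pd.Series  # by cue, in [0, 1]
    discrimination: pd.Series  # by context: rate(correct cue) - rate(incorrect cue)


def postlearning_rates(
    trials: Sequence[tk.PostLearningTrial],
    subject_id: str = "",
    contexts: Sequence[tk.ChoiceContext] | None = None,
) -> PostLearningRates:
    """Per-cue choice rate (times chosen / times presented) over the
    post-learning test, and per-context cue discrimination (correct
    minus incorrect cue rate; chance 0)."""
    contexts = tuple(contexts) if contexts is not None else tuple(tk.make_default_contexts())
    chosen_count: dict[str, int] = {}
    seen_count: dict[str, int] = {}
    for trial in trials:
        if trial.chosen is None:
            raise ValueError("post-learning trial is missing a choice")
        if trial.chosen not in (trial.cue_a, trial.cue_b):
            raise ValueError(f"chosen cue {trial.chosen!r} not in the presented pair")
        for cue in (trial.cue_a, trial.cue_b):
            seen_count[cue] = seen_count.get(cue, 0) + 1
        chosen_count[trial.chosen] = chosen_count.get(trial.chosen, 0) + 1
    rates = pd.Series(
        {cue: chosen_count.get(cue, 0) / n for cue, n in seen_count.items()},
        name="choice_rate",
    ).sort_index()
    disc = {}
    for context in contexts:
        cor, inc = tk.cue_names_for_context(context)
        if cor in rates and inc in rates:
            disc[context.context_id] = float(rates[cor] - rates[inc])
    return PostLearningRates(
        subject_id=subject_id,
        rates=rates,
        discrimination=pd.Series(disc, name="discrimination"),
    )


def _mean_sem(frame: pd.DataFrame, by: list[str], value: str) -> pd.DataFrame:
    g = frame.groupby(by)[value]
    out = g.agg(["mean", "sem", "count"]).reset_index()
    return out.rename(columns={"mean": f"{value}_mean", "sem": f"{value}_sem", "count": "n"})


def cohort_choice_table(
    histories_by_group: dict[str, Sequence[tk.SessionHistory]]
) -> pd.DataFrame:
    """Correct choice rate per (group, context), mean +/- s.e.m. across
    subjects, plus an "Overall" row per group collapsing contexts."""
    rows = []
    for group, histories in histories_by_group.items():
        for hist in histories:
            per_ctx = {}
            for s, context in enumerate(hist.contexts):
                mask = hist.context_idx == s
                per_ctx[context.context_id] = float(
                    (hist.chosen[mask] == tk.CORRECT).mean()
                )
            for ctx, rate in per_ctx.items():
                rows.append({"group": group, "subject_id": hist.subject_id,
                             "context": ctx, "correct_rate": rate})
            rows.append({"group": group, "subject_id": hist.subject_id,
                         "context": "Overall",
                         "correct_rate": float(np.mean(list(per_ctx.values())))})
    return _mean_sem(pd.DataFrame(rows), ["group", "context"], "correct_rate")


def cohort_postlearning_table(
    rates_by_group: dict[str, Sequence[PostLearningRates]]
) -> pd.DataFrame:
    """Post-learning choice rate per (group, cue), mean +/- s.e.m. across
    subjects — one row per cue, as transfer-test results are reported."""
    rows = [
        {"group": group, "subject_id": r.subject_id, "cue": cue, "rate": rate}
        for group, results in rates_by_group.items()
        for r in results
        for cue, rate in r.rates.items()
    ]
    return _mean_sem(pd.DataFrame(rows), ["group", "cue"], "rate")
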