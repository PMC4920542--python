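"""Reading and writing sessions as tidy delimited text.

A cohort is stored as ``learning.csv`` (one row per learning trial),
optionally ``postlearning.csv`` (one row per transfer trial, keyed by
the same subject_id), and a ``config.json`` sidecar recording the task
configuration including the seed.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import task as tk

__all__ = ["write_sessions", "read_sessions", "config_to_dict", "config_from_dict"]


def config_to_dict(config: tk.TaskConfig) -> dict:
    return {
        "n_trials_per_context": config.n_trials_per_context,
        "n_postlearning_reps": config.n_postlearning_reps,
        "seed": config.seed,
        "contexts": [
            {
                "context_id": c.context_id,
                "valence": c.valence.value,
                "feedback": c.feedback.value,
                "p_good_correct": c.p_good_correct,
                "p_good_incorrect": c.p_good_incorrect,
                "outcome_good": c.outcome_good,
                "outcome_bad": c.outcome_bad,
            }
            for c in config.contexts
        ],
    }


def config_from_dict(d: dict) -> tk.TaskConfig:
    contexts = tuple(
        tk.ChoiceContext(
            context_id=c["context_id"],
            valence=tk.Valence(c["valence"]),
            feedback=tk.Feedback(c["feedback"]),
            p_good_correct=c["p_good_correct"],
            p_good_incorrect=c["p_good_incorrect"],
            outcome_good=c["outcome_good"],
            outcome_bad=c["outcome_bad"],
        )
        for c in d["contexts"]
    )
    return tk.TaskConfig(
        n_trials_per_context=d["n_trials_per_context"],
        contexts=contexts,
        n_postlearning_reps=d["n_postlearning_reps"],
        seed=d.get("seed"),
    )


def write_sessions(
    out_dir,
    sessions: Sequence[tk.SessionHistory],
    config: tk.TaskConfig,
    postlearning: Optional[dict[str, Sequence[tk.PostLearningTrial]]] = None,
) -> Path:
    """Write a cohort to ``out_dir``; returns the directory path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame = pd.concat([s.to_frame() for s in sessions], ignore_index=True)
    frame.to_csv(out / "learning.csv", index=False)
    (out / "config.json").write_text(json.dumps(config_to_dict(config), indent=2))
    if postlearning:
        rows = [
            {
                "subject_id": subject,
                "trial": t + 1,
                "cue_a": trial.cue_a,
                "cue_b": trial.cue_b,
                "chosen": trial.chosen,
            }
            for subject, trials in postlearning.items()
            for t, trial in enumerate(trials)
        ]
        pd.DataFrame(rows).to_csv(out / "postlearning.csv", index=False)
    return out


def read_sessions(
    in_dir,
) -> tuple[list[tk.SessionHistory], tk.TaskConfig, Optional[dict[str, list[tk.PostLearningTrial]]]]:
    """Read a cohort written by :func:`write_sessions`."""
    src = Path(in_dir)
    config = config_from_dict(json.loads((src / "config.json").read_text()))
    frame = pd.read_csv(src / "learning.csv")
    sessions = [
        tk.SessionHistory.from_frame(group, contexts=config.contexts)
        for _, group in frame.groupby("subject_id", sort=False)
    ]
    post = None
    pl_path = src / "postlearning.csv"
    if pl_path.exists():
        pl = pd.read_csv(pl_path)
        post = {
            str(subject): [
                tk.PostLearningTrial(r.cue_a, r.cue_b, r.chosen if pd.notna(r.chosen) else None)
                for r in group.itertuples()
            ]
            for subject, group in pl.groupby("subject_id", sort=False)
        }
    return sessions, config, post
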