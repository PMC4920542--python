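"""Task generator for the 2x2 valence-by-feedback probabilistic instrumental task.

The learning task crosses outcome valence (Reward vs Punishment) with
feedback information (Partial vs Complete), giving four fixed cue pairs
(choice contexts). Within each pair one cue ("correct") yields the good
outcome with probability 0.75 and the other ("incorrect") with probability
0.25. Good/bad outcomes are +1/0 points in Reward contexts and 0/-1 in
Punishment contexts. Each pair is shown 20 times (80 learning trials),
followed by a 112-trial post-learning transfer test pairing all 8 cues in
all 28 combinations, 4 times each.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Valence",
    "Feedback",
    "ChoiceContext",
    "TaskConfig",
    "TrialRecord",
    "SessionHistory",
    "PostLearningTrial",
    "CUE_NAMES",
    "CORRECT",
    "INCORRECT",
    "make_default_contexts",
    "generate_session_scaffold",
    "sample_outcomes",
    "prob_identical_outcomes",
    "identical_outcome_prob",
    "make_postlearning_schedule",
    "cue_names_for_context",
]

# option indices used throughout the package
CORRECT = 0
INCORRECT = 1


class Valence(str, Enum):
    REWARD = "Reward"
    PUNISHMENT = "Punishment"


class Feedback(str, Enum):
    PARTIAL = "Partial"
    COMPLETE = "Complete"


@dataclass(frozen=True)
class ChoiceContext:
    """One fixed cue pair (choice context) of the learning task.

    Parameters
    ----------
    context_id : str
        Label, e.g. ``"RewardPartial"``.
    valence, feedback : Valence, Feedback
        The factorial condition of this context.
    p_good_correct, p_good_incorrect : float
        Probability that the correct / incorrect cue delivers the good
        outcome (0.75 / 0.25 in the standard task).
    outcome_good, outcome_bad : float
        The two possible point outcomes: {+1, 0} under Reward,
        {0, -1} under Punishment.
    """

    context_id: str
    valence: Valence
    feedback: Feedback
    p_good_correct: float = 0.75
    p_good_incorrect: float = 0.25
    outcome_good: float = 1.0
    outcome_bad: float = 0.0

    def __post_init__(self) -> None:
        if not self.p_good_correct > self.p_good_incorrect:
            raise ValueError(
                "correct option must have the higher good-outcome probability"
            )
        if self.valence is Valence.REWARD and {self.outcome_good, self.outcome_bad} != {1.0, 0.0}:
            raise ValueError("Reward outcomes must be {+1, 0}")
        if self.valence is Valence.PUNISHMENT and {self.outcome_good, self.outcome_bad} != {0.0, -1.0}:
            raise ValueError("Punishment outcomes must be {0, -1}")

    def p_good(self, option: int) -> float:
        return self.p_good_correct if option == CORRECT else self.p_good_incorrect


def make_default_contexts() -> list[ChoiceContext]:
    """The four standard contexts of the 2x2 factorial design."""
    out = []
    for valence in (Valence.REWARD, Valence.PUNISHMENT):
        for feedback in (Feedback.PARTIAL, Feedback.COMPLETE):
            good, bad = (1.0, 0.0) if valence is Valence.REWARD else (0.0, -1.0)
            out.append(
                ChoiceContext(
                    context_id=f"{valence.value}{feedback.value}",
                    valence=valence,
                    feedback=feedback,
                    outcome_good=good,
                    outcome_bad=bad,
                )
            )
    return out


# Cue labels follow the G/L x 75/25 convention: G75 gains a point with
# probability .75, L25 loses one with probability .25 (the correct
# punishment cue); suffix p/c marks the Partial/Complete context.
_CUE_TABLE = {
    "RewardPartial": ("G75p", "G25p"),
    "RewardComplete": ("G75c", "G25c"),
    "PunishmentPartial": ("L25p", "L75p"),
    "PunishmentComplete": ("L25c", "L75c"),
}

CUE_NAMES: tuple[str, ...] = tuple(
    itertools.chain.from_iterable(_CUE_TABLE.values())
)


def cue_names_for_context(context: ChoiceContext) -> tuple[str, str]:
    """(correct cue, incorrect cue) labels for a standard context."""
    try:
        return _CUE_TABLE[context.context_id]
    except KeyError:
        return (f"{context.context_id}:correct", f"{context.context_id}:incorrect")


@dataclass(frozen=True)
class TaskConfig:
    n_trials_per_context: int = 20
    contexts: tuple[ChoiceContext, ...] = field(
        default_factory=lambda: tuple(make_default_contexts())
    )
    n_postlearning_reps: int = 4
    seed: Optional[int] = None

    @property
    def n_learning_trials(self) -> int:
        return self.n_trials_per_context * len(self.contexts)

    @property
    def n_cues(self) -> int:
        return 2 * len(self.contexts)

    @property
    def n_postlearning_trials(self) -> int:
        n = self.n_cues
        return n * (n - 1) // 2 * self.n_postlearning_reps


@dataclass
class TrialRecord:
    """One learning-task trial: context, choice, and sampled outcomes."""

    subject_id: str
    trial_index_global: int  # 1-based over the session
    trial_index_within_context: int  # 1-based, 1..n_trials_per_context
    context_id: str
    chosen: int  # CORRECT or INCORRECT
    side_of_correct: str  # "left" | "right"
    r_c: float
    r_u: Optional[float] = None  # absent under Partial feedback
    rt: Optional[float] = None


class SessionHistory:
    """One subject's ordered learning-task trials, array-backed.

    Wraps parallel numpy arrays (context index, chosen option, factual
    and counterfactual outcomes) for fast likelihood evaluation, with
    conversion to/from a tidy :class:`pandas.DataFrame`.
    """

    def __init__(
        self,
        subject_id: str,
        contexts: Sequence[ChoiceContext],
        context_idx: np.ndarray,
        chosen: np.ndarray,
        r_c: np.ndarray,
        r_u: np.ndarray,
        complete: np.ndarray,
        side_of_correct: Optional[np.ndarray] = None,
        rt: Optional[np.ndarray] = None,
    ) -> None:
        n = len(context_idx)
        self.subject_id = subject_id
        self.contexts = tuple(contexts)
        self.context_idx = np.asarray(context_idx, dtype=np.int64)
        self.chosen = np.asarray(chosen, dtype=np.int64)
        self.r_c = np.asarray(r_c, dtype=np.float64)
        self.r_u = np.asarray(r_u, dtype=np.float64)  # nan where absent
        self.complete = np.asarray(complete, dtype=np.bool_)
        self.side_of_correct = side_of_correct
        self.rt = rt
        if not (
            len(self.chosen) == len(self.r_c) == len(self.r_u) == len(self.complete) == n
        ):
            raise ValueError("ragged session arrays")
        if np.any(np.isnan(self.r_u[self.complete])):
            raise ValueError("missing counterfactual outcome in a Complete-feedback trial")
        if np.any(~np.isnan(self.r_u[~self.complete])):
            raise ValueError("counterfactual outcome supplied for a Partial-feedback trial")

    def __len__(self) -> int:
        return len(self.context_idx)

    @property
    def n_contexts(self) -> int:
        return len(self.contexts)

    def to_frame(self) -> pd.DataFrame:
        ids = [self.contexts[i].context_id for i in self.context_idx]
        within = np.zeros(len(self), dtype=int)
        counter: dict[int, int] = {}
        for t, s in enumerate(self.context_idx):
            counter[s] = counter.get(s, 0) + 1
            within[t] = counter[s]
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "trial": np.arange(1, len(self) + 1),
                "trial_in_context": within,
                "context": ids,
                "chosen": np.where(self.chosen == CORRECT, "correct", "incorrect"),
                "side_of_correct": (
                    self.side_of_correct
                    if self.side_of_correct is not None
                    else np.full(len(self), "", dtype=object)
                ),
                "outcome_chosen": self.r_c,
                "outcome_unchosen": self.r_u,
                "rt": self.rt if self.rt is not None else np.full(len(self), np.nan),
            }
        )

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, contexts: Optional[Sequence[ChoiceContext]] = None
    ) -> "SessionHistory":
        contexts = tuple(contexts) if contexts is not None else tuple(make_default_contexts())
        index = {c.context_id: i for i, c in enumerate(contexts)}
        ctx = frame["context"].map(index)
        if ctx.isna().any():
            unknown = sorted(set(frame.loc[ctx.isna(), "context"]))
            raise ValueError(f"unknown context ids: {unknown}")
        ctx = ctx.to_numpy(dtype=np.int64)
        complete = np.array(
            [contexts[i].feedback is Feedback.COMPLETE for i in ctx], dtype=bool
        )
        subj = frame["subject_id"].iloc[0] if len(frame) else ""
        rt = frame["rt"].to_numpy(dtype=float) if "rt" in frame else None
        if rt is not None and np.all(np.isnan(rt)):
            rt = None
        side = (
            frame["side_of_correct"].to_numpy(dtype=object)
            if "side_of_correct" in frame
            else None
        )
        return cls(
            subject_id=str(subj),
            contexts=contexts,
            context_idx=ctx,
            chosen=np.where(frame["chosen"].to_numpy() == "correct", CORRECT, INCORRECT),
            r_c=frame["outcome_chosen"].to_numpy(dtype=float),
            r_u=frame["outcome_unchosen"].to_numpy(dtype=float),
            complete=complete,
            side_of_correct=side,
            rt=rt,
        )


@dataclass(frozen=True)
class PostLearningTrial:
    cue_a: str
    cue_b: str
    chosen: Optional[str] = None

    def __post_init__(self) -> None:
        if self.cue_a == self.cue_b:
            raise ValueError("post-learning pair must contain two distinct cues")


def generate_session_scaffold(
    config: TaskConfig, rng_seed: Optional[int] = None
) -> list[tuple[int, str]]:
    """Ordered trial slots ``(context_index, side_of_correct)``.

    Pseudo-randomisation interleaves contexts in blocks: each block of
    ``len(contexts)`` trials contains one trial per context, in shuffled
    order. Side of the correct cue is counterbalanced exactly (half left,
    half right per context), which requires an even number of trials per
    context.
    """
    if config.n_trials_per_context % 2:
        raise ValueError(
            "n_trials_per_context must be even for exact side counterbalancing"
        )
    rng = np.random.default_rng(config.seed if rng_seed is None else rng_seed)
    n_ctx = len(config.contexts)

    order: list[int] = []
    for _ in range(config.n_trials_per_context):
        block = rng.permutation(n_ctx)
        order.extend(int(s) for s in block)

    half = config.n_trials_per_context // 2
    sides: dict[int, list[str]] = {}
    for s in range(n_ctx):
        seq = ["left"] * half + ["right"] * half
        rng.shuffle(seq)
        sides[s] = seq

    slots = []
    seen: dict[int, int] = {s: 0 for s in range(n_ctx)}
    for s in order:
        slots.append((s, sides[s][seen[s]]))
        seen[s] += 1
    return slots


def sample_outcomes(
    context: ChoiceContext, chosen: int, rng: np.random.Generator
) -> tuple[float, Optional[float]]:
    """Sample (factual, counterfactual) outcomes for one trial.

    The two cues' outcomes are independent Bernoulli draws; the
    counterfactual outcome is returned only under Complete feedback.
    """
    if chosen not in (CORRECT, INCORRECT):
        raise ValueError(f"chosen must be {CORRECT} or {INCORRECT}")
    good, bad = context.outcome_good, context.outcome_bad
    r_c = good if rng.random() < context.p_good(chosen) else bad
    if context.feedback is Feedback.COMPLETE:
        r_u = good if rng.random() < context.p_good(1 - chosen) else bad
        return r_c, r_u
    return r_c, None


def identical_outcome_prob(p: float, q: float) -> float:
    """P(two independent Bernoulli cues with good-outcome probabilities
    p and q show the same outcome): ``p*q + (1-p)*(1-q)``."""
    return p * q + (1.0 - p) * (1.0 - q)


def prob_identical_outcomes(context: ChoiceContext) -> float:
    """P(both cues show the same outcome) in a Complete-feedback context.

    0.375 for the standard (0.75, 0.25) schedule.
    """
    if context.feedback is not Feedback.COMPLETE:
        raise ValueError("identical-outcome probability is defined for Complete feedback only")
    return identical_outcome_prob(context.p_good_correct, context.p_good_incorrect)


def make_postlearning_schedule(
    config: TaskConfig, rng_seed: Optional[int] = None
) -> list[PostLearningTrial]:
    """All unordered cue pairs, repeated and shuffled.

    For the standard 8 cues: 28 pairs x 4 repetitions = 112 slots.
    Within-pair presentation order is also randomised.
    """
    rng = np.random.default_rng(config.seed if rng_seed is None else rng_seed)
    cues = [cue for c in config.contexts for cue in cue_names_for_context(c)]
    pairs = list(itertools.combinations(cues, 2)) * config.n_postlearning_reps
    perm = rng.permutation(len(pairs))
    out = []
    for i in perm:
        a, b = pairs[i]
        if rng.random() < 0.5:
            a, b = b, a
        out.append(PostLearningTrial(cue_a=a, cue_b=b))
    return out
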