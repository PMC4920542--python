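"""The nested model lattice: factual, counterfactual and contextual learning.

All models are delta-rule (Rescorla-Wagner) learners over per-context
option values Q(s, .) with softmax choice. The lattice:

* **M1** — basic Q-learning: only the chosen option's value is updated,
  from its own outcome (learning rate ``alpha1``).
* **M2** — adds a counterfactual module: under Complete feedback the
  unchosen option is updated from its displayed outcome (``alpha2``).
* **M3** — adds a contextual module: a context value V(s) tracks the
  average trial outcome (``alpha3``) and re-references both option
  prediction errors, so option values become relative to their context.
* **M4** — contextualisation without counterfactual learning
  (``alpha2 = 0``): V(s) is learnt, the unchosen option is not updated.

M1 and M2 are special cases of M3 (``alpha2 = alpha3 = 0`` and
``alpha3 = 0`` respectively); likewise M4 (``alpha2 = 0``). The update
equations, with all prediction errors computed from the trial's
pre-update values:

    delta_C = R_c - V(s) - Q(s, c)
    delta_U = R_u - V(s) - Q(s, u)        (Complete feedback; else 0)
    delta_V = R_tot - V(s)
    R_tot   = (R_c + R_u) / 2             (Complete)
            = (R_c + Q_t(s, u)) / 2       (Partial)

    Q(s, c) += alpha1 * delta_C
    Q(s, u) += alpha2 * delta_U
    V(s)    += alpha3 * delta_V

Choice follows P(a) = 1 / (1 + exp(beta * (Q(s, b) - Q(s, a)))).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from enum import Enum
from typing import Optional, Union

import numpy as np

__all__ = [
    "Model",
    "Parameters",
    "AgentState",
    "PredictionErrors",
    "init_state",
    "choice_prob",
    "compute_prediction_errors",
    "update_state",
    "step",
]


class Model(str, Enum):
    """Members of the nested lattice; the value is the conventional label."""

    M1 = "M1"
    M2 = "M2"
    M3 = "M3"
    M4 = "M4"

    @property
    def zeroed(self) -> tuple[str, ...]:
        """Learning rates pinned to zero under this model's constraints."""
        return _ZEROED[self]

    @property
    def free_parameters(self) -> tuple[str, ...]:
        return tuple(p for p in ("beta", "alpha1", "alpha2", "alpha3") if p not in self.zeroed)

    @property
    def n_free(self) -> int:
        return len(self.free_parameters)


_ZEROED = {
    Model.M1: ("alpha2", "alpha3"),
    Model.M2: ("alpha3",),
    Model.M3: (),
    Model.M4: ("alpha2",),
}


@dataclass(frozen=True)
class Parameters:
    """beta (inverse temperature, >= 0) and the three learning rates in [0, 1]."""

    beta: float
    alpha1: float
    alpha2: float = 0.0
    alpha3: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.beta) and self.beta >= 0):
            raise ValueError(f"beta must be finite and >= 0, got {self.beta}")
        for name in ("alpha1", "alpha2", "alpha3"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def constrained_to(self, model: Model) -> "Parameters":
        """A copy with this model's pinned learning rates set to zero."""
        return replace(self, **{name: 0.0 for name in model.zeroed})

    def satisfies(self, model: Model) -> bool:
        return all(getattr(self, name) == 0.0 for name in model.zeroed)

    def to_json(self, model: Optional[Model] = None) -> str:
        d = {
            "beta": self.beta,
            "alpha1": self.alpha1,
            "alpha2": self.alpha2,
            "alpha3": self.alpha3,
        }
        if model is not None:
            d = {"model": model.value, **d}
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> tuple["Parameters", Optional[Model]]:
        d = json.loads(s)
        model = Model(d.pop("model")) if "model" in d else None
        return cls(**d), model


@dataclass
class AgentState:
    """Per-context option values Q (n_contexts x 2) and context values V."""

    q: np.ndarray
    v: np.ndarray

    def copy(self) -> "AgentState":
        return AgentState(q=self.q.copy(), v=self.v.copy())


def init_state(n_contexts: int = 4) -> AgentState:
    """All option and context values start at 0, the symmetric prior
    between +1 and -1 outcomes; the first-trial choice probability is 0.5."""
    return AgentState(q=np.zeros((n_contexts, 2)), v=np.zeros(n_contexts))


def choice_prob(state: AgentState, context: int, option: int, beta: float) -> float:
    """Softmax probability of picking `option` over the alternative.

    Computed as a numerically safe logistic of beta * (Q(s,a) - Q(s,b)).
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    q = state.q[context]
    if not np.all(np.isfinite(q)):
        raise ValueError("non-finite Q values")
    other = 1 - option
    x = beta * (q[other] - q[option])
    # logistic via logaddexp for large |x|
    return float(np.exp(-np.logaddexp(0.0, x)))


@dataclass(frozen=True)
class PredictionErrors:
    delta_c: float
    delta_u: float
    delta_v: float
    r_tot: float


def compute_prediction_errors(
    state: AgentState,
    context: int,
    chosen: int,
    r_c: float,
    r_u: Optional[float],
    model: Model,
    feedback_complete: Optional[bool] = None,
) -> PredictionErrors:
    """Prediction errors from the trial's *pre-update* Q and V.

    ``r_u`` must be present iff the trial had Complete feedback. The
    counterfactual error is zero under Partial feedback and for models
    whose counterfactual module is off (alpha2 pinned to 0).
    """
    complete = (r_u is not None) if feedback_complete is None else feedback_complete
    if complete and r_u is None:
        raise ValueError("Complete-feedback trial is missing the counterfactual outcome")
    if not complete and r_u is not None:
        raise ValueError("counterfactual outcome supplied for a Partial-feedback trial")
    q = state.q[context]
    v = float(state.v[context])
    unchosen = 1 - chosen
    delta_c = r_c - v - q[chosen]
    if complete:
        delta_u = (r_u - v - q[unchosen]) if "alpha2" not in model.zeroed else 0.0
        r_tot = (r_c + r_u) / 2.0
    else:
        delta_u = 0.0
        r_tot = (r_c + q[unchosen]) / 2.0
    delta_v = r_tot - v
    return PredictionErrors(
        delta_c=float(delta_c), delta_u=float(delta_u), delta_v=float(delta_v), r_tot=float(r_tot)
    )


def update_state(
    state: AgentState,
    context: int,
    chosen: int,
    pe: PredictionErrors,
    params: Parameters,
    model: Model,
) -> AgentState:
    """Apply all three delta-rule updates simultaneously; returns a new state."""
    p = params.constrained_to(model)
    out = state.copy()
    out.q[context, chosen] += p.alpha1 * pe.delta_c
    out.q[context, 1 - chosen] += p.alpha2 * pe.delta_u
    out.v[context] += p.alpha3 * pe.delta_v
    return out


def step(
    state: AgentState,
    context: int,
    chosen: int,
    r_c: float,
    r_u: Optional[float],
    params: Parameters,
    model: Model,
) -> tuple[PredictionErrors, AgentState]:
    """Convenience: compute prediction errors then update, in one call."""
    pe = compute_prediction_errors(state, context, chosen, r_c, r_u, model)
    return pe, update_state(state, context, chosen, pe, params, model)
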