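"""Parameter estimation: maximum likelihood and MAP with Laplace evidence.

Subject-level fits minimise the negative log-likelihood of a session's
choices (multi-start bounded optimisation), or maximise the log
posterior under weakly-informative priors. The log model evidence is
approximated at the MAP by the Laplace method:

    log P(D | M)  ~  log P(D | th) + log P(th) + (k/2) log 2*pi
                     - (1/2) log det H,

with ``th`` the MAP estimate, ``k`` the number of free parameters and
``H`` the negative Hessian of the log posterior at ``th``. The evidence
is thus likelihood penalised by the effective size of the parameter
space, and feeds the random-effects model selection in
:mod:`rlcontext.selection`.

Group-level fits estimate a single parameter vector for a whole cohort
by summing the per-subject objective.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import optimize

from . import models as m
from . import task as tk
from ._kernels import nll_kernel

__all__ = [
    "Prior",
    "PriorSpec",
    "FitResult",
    "negative_log_likelihood",
    "fit_mle",
    "fit_map",
    "laplace_evidence",
    "laplace_log_evidence",
    "fit_group_level",
    "BETA_MAX",
]

logger = logging.getLogger(__name__)

BETA_MAX = 100.0  # numerical stand-in for an unbounded inverse temperature


@dataclass(frozen=True)
class Prior:
    """A univariate prior: ``gamma(shape, scale)``, ``beta(a, b)`` or
    ``uniform(lo, hi)``. Evaluated with closed-form logpdfs (these sit in
    the innermost loop of the recovery suite)."""

    family: str
    args: tuple[float, float]

    def __post_init__(self) -> None:
        if self.family not in ("gamma", "beta", "uniform"):
            raise ValueError(f"unknown prior family {self.family!r}")
        a, b = self.args
        if self.family == "uniform":
            if not (np.isfinite(a) and np.isfinite(b) and b > a):
                raise ValueError("improper uniform prior: bounds must be finite, hi > lo")
        elif a <= 0 or b <= 0:
            raise ValueError(f"{self.family} hyperparameters must be positive")

    def logpdf(self, x: float) -> float:
        a, b = self.args
        if self.family == "gamma":
            if x <= 0:
                return -np.inf
            return (a - 1.0) * math.log(x) - x / b - a * math.log(b) - math.lgamma(a)
        if self.family == "beta":
            if not 0.0 < x < 1.0:
                return -np.inf
            return (
                (a - 1.0) * math.log(x)
                + (b - 1.0) * math.log1p(-x)
                - (math.lgamma(a) + math.lgamma(b) - math.lgamma(a + b))
            )
        lo, hi = a, b
        return -math.log(hi - lo) if lo <= x <= hi else -np.inf

    def sample(self, rng: np.random.Generator) -> float:
        a, b = self.args
        if self.family == "gamma":
            return float(rng.gamma(a, b))
        if self.family == "beta":
            return float(rng.beta(a, b))
        return float(rng.uniform(a, b))


@dataclass(frozen=True)
class PriorSpec:
    """Priors over (beta, alpha1, alpha2, alpha3); identical for every
    subject and group so that model selection is not biased by the prior."""

    beta: Prior = Prior("gamma", (1.2, 5.0))
    alpha1: Prior = Prior("beta", (1.1, 1.1))
    alpha2: Prior = Prior("beta", (1.1, 1.1))
    alpha3: Prior = Prior("beta", (1.1, 1.1))

    def prior_for(self, name: str) -> Prior:
        return getattr(self, name)

    def log_density(self, theta: np.ndarray, names: Sequence[str]) -> float:
        return float(sum(self.prior_for(n).logpdf(x) for n, x in zip(names, theta)))

    @classmethod
    def flat(cls, beta_max: float = BETA_MAX) -> "PriorSpec":
        u = Prior("uniform", (0.0, 1.0))
        return cls(beta=Prior("uniform", (0.0, beta_max)), alpha1=u, alpha2=u, alpha3=u)


@dataclass
class FitResult:
    model: m.Model
    params: m.Parameters
    negll: float
    lpp: Optional[float] = None  # log posterior at the MAP (nats)
    log_evidence: Optional[float] = None
    hessian_logdet: Optional[float] = None
    n_restarts_converged: int = 0
    level: str = "subject"
    n_trials: int = 0
    subject_id: str = ""
    at_beta_bound: bool = False

    def bic(self) -> float:
        return 2.0 * self.negll + self.model.n_free * math.log(self.n_trials)


def _history_arrays(history: tk.SessionHistory):
    r_u = history.r_u.copy()
    r_u[~history.complete] = 0.0
    return (
        history.context_idx,
        history.chosen,
        history.r_c,
        r_u,
        history.complete,
        history.n_contexts,
    )


def negative_log_likelihood(
    params: m.Parameters, model: m.Model, history: tk.SessionHistory
) -> float:
    """-sum_t log P_t(chosen option), replaying the observed history.

    Guarded by a log-sum-exp softmax: finite for any finite beta.
    """
    p = params.constrained_to(model)
    arrays = _history_arrays(history)
    return float(nll_kernel(p.beta, p.alpha1, p.alpha2, p.alpha3, *arrays))


def _vector_to_params(theta: np.ndarray, model: m.Model) -> m.Parameters:
    kwargs = dict(zip(model.free_parameters, (float(x) for x in theta)))
    full = {"beta": 0.0, "alpha1": 0.0, "alpha2": 0.0, "alpha3": 0.0}
    full.update(kwargs)
    return m.Parameters(**full)


def _make_nll_fn(
    model: m.Model, histories: Sequence[tk.SessionHistory]
) -> Callable[[np.ndarray], float]:
    names = model.free_parameters
    idx = {name: i for i, name in enumerate(names)}
    arr = [_history_arrays(h) for h in histories]

    def fn(theta: np.ndarray) -> float:
        beta = theta[idx["beta"]]
        a1 = theta[idx["alpha1"]]
        a2 = theta[idx["alpha2"]] if "alpha2" in idx else 0.0
        a3 = theta[idx["alpha3"]] if "alpha3" in idx else 0.0
        return float(sum(nll_kernel(beta, a1, a2, a3, *a) for a in arr))

    return fn


def _multistart(
    objective: Callable[[np.ndarray], float],
    model: m.Model,
    bounds: list[tuple[float, float]],
    start_priors: PriorSpec,
    n_restarts: int,
    seed: Optional[int],
    extra_starts: Optional[Sequence[np.ndarray]] = None,
) -> tuple[np.ndarray, float, int]:
    rng = np.random.default_rng(seed)
    names = model.free_parameters
    best_theta, best_val = None, np.inf
    finals: list[float] = []
    n_failed = 0
    starts: list[np.ndarray] = [
        np.array(
            [
                np.clip(start_priors.prior_for(n).sample(rng), lo + 1e-3, hi - 1e-3)
                for n, (lo, hi) in zip(names, bounds)
            ]
        )
        for _ in range(n_restarts)
    ]
    for x0 in extra_starts or []:
        starts.append(
            np.array([np.clip(v, lo, hi) for v, (lo, hi) in zip(x0, bounds)])
        )
    for x0 in starts:
        res = optimize.minimize(objective, x0, method="L-BFGS-B", bounds=bounds)
        if not np.isfinite(res.fun):
            n_failed += 1
            continue
        finals.append(res.fun)
        if res.fun < best_val:
            best_val, best_theta = res.fun, res.x
    if best_theta is None:
        raise RuntimeError(
            f"all {n_restarts} restarts failed for {model.value} "
            f"(non-finite objective; {n_failed} failures)"
        )
    n_conv = int(sum(f <= best_val + 1e-3 for f in finals))
    return best_theta, float(best_val), n_conv


def fit_mle(
    model: m.Model,
    history: tk.SessionHistory,
    n_restarts: int = 20,
    seed: Optional[int] = 0,
    beta_max: float = BETA_MAX,
    extra_starts: Optional[Sequence[np.ndarray]] = None,
) -> FitResult:
    """Best-of-`n_restarts` bounded maximum-likelihood fit of one session.

    `extra_starts` adds deterministic starting points (e.g. the embedded
    optimum of a nested model) to the random restarts.
    """
    bounds = [(0.0, beta_max) if n == "beta" else (0.0, 1.0) for n in model.free_parameters]
    nll_fn = _make_nll_fn(model, [history])
    theta, val, n_conv = _multistart(
        nll_fn, model, bounds, PriorSpec(), n_restarts, seed, extra_starts
    )
    params = _vector_to_params(theta, model)
    return FitResult(
        model=model,
        params=params,
        negll=val,
        n_restarts_converged=n_conv,
        n_trials=len(history),
        subject_id=history.subject_id,
        at_beta_bound=bool(params.beta >= beta_max - 1e-3),
    )


def _neg_logpost_fn(
    model: m.Model, histories: Sequence[tk.SessionHistory], priors: PriorSpec
) -> Callable[[np.ndarray], float]:
    nll_fn = _make_nll_fn(model, histories)
    names = model.free_parameters

    def fn(theta: np.ndarray) -> float:
        lp = priors.log_density(theta, names)
        if not np.isfinite(lp):
            return np.inf
        return nll_fn(theta) - lp

    return fn


def fit_map(
    model: m.Model,
    history: tk.SessionHistory,
    priors: Optional[PriorSpec] = None,
    n_restarts: int = 20,
    seed: Optional[int] = 0,
    beta_max: float = BETA_MAX,
    extra_starts: Optional[Sequence[np.ndarray]] = None,
) -> FitResult:
    """MAP fit (maximises log-likelihood + log-prior) with Laplace evidence."""
    priors = priors or PriorSpec()
    eps = 1e-6
    bounds = [
        (eps, beta_max) if n == "beta" else (eps, 1.0 - eps) for n in model.free_parameters
    ]
    objective = _neg_logpost_fn(model, [history], priors)
    theta, val, n_conv = _multistart(
        objective, model, bounds, priors, n_restarts, seed, extra_starts
    )
    params = _vector_to_params(theta, model)
    fit = FitResult(
        model=model,
        params=params,
        negll=negative_log_likelihood(params, model, history),
        lpp=-val,
        n_restarts_converged=n_conv,
        n_trials=len(history),
        subject_id=history.subject_id,
        at_beta_bound=bool(params.beta >= beta_max - 1e-3),
    )
    fit.log_evidence, fit.hessian_logdet = _evidence_at(
        objective, theta, model.free_parameters, fit.negll, len(history), model.n_free
    )
    return fit


def finite_difference_hessian(
    fn: Callable[[np.ndarray], float],
    theta: np.ndarray,
    bounds: Optional[Sequence[tuple[float, float]]] = None,
    step: float = 1e-4,
) -> np.ndarray:
    """Central-difference Hessian with steps shrunk near the bounds."""
    k = len(theta)
    h = np.full(k, step) * np.maximum(1.0, np.abs(theta))
    if bounds is not None:
        for i, (lo, hi) in enumerate(bounds):
            h[i] = min(h[i], (theta[i] - lo) / 2.0, (hi - theta[i]) / 2.0)
            if h[i] <= 0:
                h[i] = step
    H = np.empty((k, k))
    f0 = fn(theta)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        H[i, i] = (fn(theta + ei) - 2.0 * f0 + fn(theta - ei)) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                fn(theta + ei + ej) - fn(theta + ei - ej) - fn(theta - ei + ej) + fn(theta - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def laplace_log_evidence(
    neg_logpost: Callable[[np.ndarray], float],
    theta_map: np.ndarray,
    bounds: Optional[Sequence[tuple[float, float]]] = None,
    step: float = 1e-4,
) -> tuple[float, float]:
    """Laplace approximation to the log marginal likelihood.

    Returns ``(log_evidence, logdet_H)`` where ``H`` is the Hessian of
    `neg_logpost` at `theta_map`. Raises :class:`np.linalg.LinAlgError`
    if ``H`` is not positive definite.
    """
    theta_map = np.asarray(theta_map, dtype=float)
    k = len(theta_map)
    if k == 0:
        return -neg_logpost(theta_map), 0.0
    H = finite_difference_hessian(neg_logpost, theta_map, bounds, step)
    L = np.linalg.cholesky(H)  # raises LinAlgError if not PD
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return float(-neg_logpost(theta_map) + 0.5 * k * math.log(2.0 * math.pi) - 0.5 * logdet), logdet


def _to_unconstrained(theta: np.ndarray, names: Sequence[str]) -> np.ndarray:
    """(beta, alpha...) -> (log beta, logit alpha...)."""
    out = np.empty(len(theta))
    for i, (name, x) in enumerate(zip(names, theta)):
        out[i] = math.log(x) if name == "beta" else math.log(x) - math.log1p(-x)
    return out


def _from_unconstrained(phi: np.ndarray, names: Sequence[str]) -> np.ndarray:
    out = np.empty(len(phi))
    for i, (name, u) in enumerate(zip(names, phi)):
        # clamp to keep the objective finite if the line search overshoots
        if name == "beta":
            out[i] = math.exp(min(max(u, -50.0), 30.0))
        else:
            # |u| <= 27 keeps sigmoid(u) strictly inside (0, 1) in float64
            out[i] = 1.0 / (1.0 + math.exp(-min(max(u, -27.0), 27.0)))
    return out


def _log_jacobian(phi: np.ndarray, names: Sequence[str]) -> float:
    """log |d theta / d phi| for the log/logit chart."""
    total = 0.0
    for name, u in zip(names, phi):
        if name == "beta":
            total += u  # d(e^u)/du = e^u
        else:
            # d sigmoid/du = sigmoid(u) * (1 - sigmoid(u))
            total += -np.logaddexp(0.0, -u) - np.logaddexp(0.0, u)
    return float(total)


def _evidence_at(
    objective: Callable[[np.ndarray], float],
    theta: np.ndarray,
    names: Sequence[str],
    negll: float,
    n_trials: int,
    k: int,
) -> tuple[float, Optional[float]]:
    """Laplace evidence evaluated in log/logit coordinates.

    The marginal likelihood is parameterisation-free, but the Gaussian
    approximation is not: near a bound the natural-scale posterior is
    strongly skewed and the Laplace integral underestimates it. The
    log/logit chart (with the Jacobian folded into the density) keeps the
    mode interior and the curvature well conditioned. The chart's mode is
    re-located with a short local optimisation from the natural MAP.
    """
    if k == 0:
        return -negll, 0.0

    def neg_logpost_t(phi: np.ndarray) -> float:
        th = _from_unconstrained(phi, names)
        return objective(th) - _log_jacobian(phi, names)

    phi0 = _to_unconstrained(theta, names)
    res = optimize.minimize(neg_logpost_t, phi0, method="BFGS")
    phi_hat = res.x if np.isfinite(res.fun) and res.fun <= neg_logpost_t(phi0) else phi0
    try:
        return laplace_log_evidence(neg_logpost_t, phi_hat)
    except np.linalg.LinAlgError:
        logger.warning(
            "non-positive-definite Hessian at the MAP; falling back to a BIC-style evidence"
        )
        return -negll - 0.5 * k * math.log(max(n_trials, 1)), None


def laplace_evidence(
    fit: FitResult,
    model: m.Model,
    history: tk.SessionHistory,
    priors: Optional[PriorSpec] = None,
) -> float:
    """Recompute the Laplace evidence for an existing MAP fit."""
    if fit.lpp is None:
        raise ValueError("laplace_evidence requires a MAP fit")
    priors = priors or PriorSpec()
    eps = 1e-6
    bounds = [
        (eps, BETA_MAX) if n == "beta" else (eps, 1.0 - eps) for n in model.free_parameters
    ]
    theta = np.array([getattr(fit.params, n) for n in model.free_parameters])
    objective = _neg_logpost_fn(model, [history], priors)
    ev, _ = _evidence_at(
        objective, theta, model.free_parameters, fit.negll, len(history), model.n_free
    )
    return ev


def fit_group_level(
    model: m.Model,
    histories: Sequence[tk.SessionHistory],
    objective: str = "nll",
    priors: Optional[PriorSpec] = None,
    n_restarts: int = 20,
    seed: Optional[int] = 0,
    beta_max: float = BETA_MAX,
) -> FitResult:
    """One parameter vector for the whole cohort (summed objective)."""
    if len(histories) < 1:
        raise ValueError("need at least one subject")
    if objective not in ("nll", "lpp"):
        raise ValueError("objective must be 'nll' or 'lpp'")
    n_total = sum(len(h) for h in histories)
    if objective == "nll":
        bounds = [
            (0.0, beta_max) if n == "beta" else (0.0, 1.0) for n in model.free_parameters
        ]
        fn = _make_nll_fn(model, histories)
        theta, val, n_conv = _multistart(fn, model, bounds, PriorSpec(), n_restarts, seed)
        params = _vector_to_params(theta, model)
        return FitResult(
            model=model,
            params=params,
            negll=val,
            n_restarts_converged=n_conv,
            level="group",
            n_trials=n_total,
            at_beta_bound=bool(params.beta >= beta_max - 1e-3),
        )
    priors = priors or PriorSpec()
    eps = 1e-6
    bounds = [
        (eps, beta_max) if n == "beta" else (eps, 1.0 - eps) for n in model.free_parameters
    ]
    fn = _neg_logpost_fn(model, histories, priors)
    theta, val, n_conv = _multistart(fn, model, bounds, priors, n_restarts, seed)
    params = _vector_to_params(theta, model)
    negll = float(sum(negative_log_likelihood(params, model, h) for h in histories))
    fit = FitResult(
        model=model,
        params=params,
        negll=negll,
        lpp=-val,
        n_restarts_converged=n_conv,
        level="group",
        n_trials=n_total,
        at_beta_bound=bool(params.beta >= beta_max - 1e-3),
    )
    fit.log_evidence, fit.hessian_logdet = _evidence_at(
        fn, theta, model.free_parameters, negll, n_total, model.n_free
    )
    return fit
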