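"""Model comparison: BIC, likelihood-ratio tables, and random-effects
Bayesian model selection (expected frequencies and exceedance
probabilities).

The random-effects scheme treats the model identity of each subject as
drawn from a population multinomial with Dirichlet-distributed
frequencies. Given per-subject log model evidences, a variational
update alternates subject responsibilities with the Dirichlet
concentration until convergence; the expected frequency of a model
(``PP``) is its posterior mean frequency, and the exceedance
probability (``XP``) — the posterior probability it is the most
frequent model — is estimated by Monte-Carlo sampling of the Dirichlet.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import digamma, logsumexp

__all__ = [
    "BMSResult",
    "rfx_bms",
    "bic",
    "loglik_ratio_table",
    "group_fixed_effects",
    "bms_summary_table",
]


@dataclass
class BMSResult:
    dirichlet_alpha: np.ndarray
    expected_frequency: np.ndarray  # PP, sums to 1
    exceedance_probability: np.ndarray  # XP, sums to 1
    responsibilities: np.ndarray  # subjects x models
    model_labels: tuple[str, ...]
    n_mc_samples: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": self.model_labels,
                "alpha": self.dirichlet_alpha,
                "expected_frequency": self.expected_frequency,
                "exceedance_probability": self.exceedance_probability,
            }
        )


def rfx_bms(
    log_evidence: np.ndarray,
    seed: Optional[int] = None,
    model_labels: Optional[Sequence[str]] = None,
    alpha0: float = 1.0,
    n_mc_samples: int = 1_000_000,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> BMSResult:
    """Random-effects Bayesian model selection over a cohort.

    Parameters
    ----------
    log_evidence : array, shape (n_subjects, n_models)
        Per-subject log model evidences (e.g. Laplace approximations),
        in nats.
    seed : int, optional
        Seed for the exceedance-probability Monte Carlo.
    alpha0 : float
        Symmetric Dirichlet prior concentration per model (uniform by
        default).

    Returns
    -------
    BMSResult with Dirichlet concentrations, expected frequencies (PP),
    exceedance probabilities (XP) and subject responsibilities.
    """
    ev = np.asarray(log_evidence, dtype=float)
    if ev.ndim != 2:
        raise ValueError("log_evidence must be 2-D (subjects x models)")
    n_subj, n_models = ev.shape
    if n_models < 2:
        raise ValueError("need at least two models")
    if n_subj < 1:
        raise ValueError("need at least one subject")
    if not np.all(np.isfinite(ev)):
        raise ValueError("log evidences must be finite")

    alpha = np.full(n_models, float(alpha0))
    g = np.empty_like(ev)
    for _ in range(max_iter):
        log_u = ev + digamma(alpha) - digamma(alpha.sum())
        g = np.exp(log_u - logsumexp(log_u, axis=1, keepdims=True))
        alpha_new = alpha0 + g.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new

    pp = alpha / alpha.sum()
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_mc_samples)
    winners = np.argmax(draws, axis=1)
    xp = np.bincount(winners, minlength=n_models) / n_mc_samples
    labels = tuple(model_labels) if model_labels is not None else tuple(
        f"M{i + 1}" for i in range(n_models)
    )
    return BMSResult(
        dirichlet_alpha=alpha,
        expected_frequency=pp,
        exceedance_probability=xp,
        responsibilities=g,
        model_labels=labels,
        n_mc_samples=n_mc_samples,
    )


def bic(negll: float, k: int, n: int) -> float:
    """Bayesian information criterion, ``2*NLL + k*log(n)`` (lower is better)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return 2.0 * negll + k * np.log(n)


def loglik_ratio_table(negll_by_model: Mapping[str, float]) -> pd.DataFrame:
    """Pairwise ``2 * (logL_row - logL_col)`` table (log-scale analogue of
    the likelihood ratio). Include a chance baseline by passing its NLL
    (``n * ln 2``) under a key such as ``"M0"``. Antisymmetric."""
    labels = list(negll_by_model)
    nll = np.array([negll_by_model[k] for k in labels])
    table = 2.0 * (nll[None, :] - nll[:, None])
    return pd.DataFrame(table, index=labels, columns=labels)


def bms_summary_table(results_by_group: Mapping[str, BMSResult]) -> pd.DataFrame:
    """Model-comparison summary across groups: per (group, model) the
    mean +/- s.e.m. of the per-subject model probabilities
    (responsibilities) and the group exceedance probability — the shape
    in which random-effects comparisons are conventionally reported."""
    rows = []
    for group, res in results_by_group.items():
        n = res.responsibilities.shape[0]
        for k, label in enumerate(res.model_labels):
            r = res.responsibilities[:, k]
            rows.append(
                {
                    "group": group,
                    "model": label,
                    "pp_mean": float(r.mean()),
                    "pp_sem": float(r.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
                    "xp": float(res.exceedance_probability[k]),
                    "expected_frequency": float(res.expected_frequency[k]),
                    "n_subjects": n,
                }
            )
    return pd.DataFrame(rows)


def group_fixed_effects(
    log_evidence: np.ndarray, model_labels: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Fixed-effects comparison: evidences summed over subjects, model
    posterior as a softmax of the sums under a uniform model prior."""
    ev = np.atleast_2d(np.asarray(log_evidence, dtype=float))
    total = ev.sum(axis=0)
    post = np.exp(total - logsumexp(total))
    labels = tuple(model_labels) if model_labels is not None else tuple(
        f"M{i + 1}" for i in range(ev.shape[1])
    )
    return pd.DataFrame(
        {"model": labels, "summed_log_evidence": total, "posterior": post}
    )
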